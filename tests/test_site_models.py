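import numpy as np
import pytest

from dupsel.core_io import STANDARD_CODE, SequenceRecord, build_codon_alignment
from dupsel.site_models import (
    CodonModelParams,
    _code_arrays,
    _Propagator,
    _raw_rate_matrix,
    beb_site_posteriors,
    build_rate_matrix,
    chi2_upper_tail,
    f3x4_frequencies,
    fit_site_model,
    likelihood_ratio_test,
    log_likelihood,
)
from dupsel.synthetic_data import CodonSimConfig, simulate_codon_alignment
from dupsel.trees import read_newick

UNIFORM_PI = np.full(61, 1 / 61)


def star_params(omega_classes, kappa=2.0, bl=0.1, pi=UNIFORM_PI):
    return CodonModelParams(
        kappa=kappa,
        pi=pi,
        branch_lengths=np.full(3, bl),
        omega_classes=omega_classes,
    )


class TestF3x4:
    def test_uniform_composition(self):
        sim = simulate_codon_alignment(
            CodonSimConfig(n_codons=40, branch_length=0.0, seed=0)
        )
        # analytic check on a hand-built alignment covering all bases evenly
        recs = [
            SequenceRecord(id="a", residues="ACGTACGTACGT"),
            SequenceRecord(id="b", residues="ACGTACGTACGT"),
        ]
        aln = build_codon_alignment(recs)
        pi = f3x4_frequencies(aln)
        assert pi.sum() == pytest.approx(1.0)
        # uniform base composition at every position -> uniform sense codons
        assert np.allclose(pi, 1 / 61, atol=1e-12)

    def test_degenerate_alignment(self):
        recs = [
            SequenceRecord(id="a", residues="AAAAAA"),
            SequenceRecord(id="b", residues="AAAAAA"),
        ]
        pi = f3x4_frequencies(build_codon_alignment(recs))
        idx = _code_arrays(STANDARD_CODE).index["AAA"]
        assert pi[idx] == pytest.approx(1.0, abs=1e-6)
        assert pi.sum() == pytest.approx(1.0)


class TestRateMatrix:
    def test_generator_properties(self):
        q = build_rate_matrix(2.0, 0.5, UNIFORM_PI)
        assert np.abs(q.sum(axis=1)).max() < 1e-12
        flux = UNIFORM_PI[:, None] * q
        assert np.abs(flux - flux.T).max() < 1e-14  # detailed balance
        assert -(UNIFORM_PI * np.diag(q)).sum() == pytest.approx(1.0)

    def test_omega_zero_blocks_nonsynonymous(self):
        arrays = _code_arrays(STANDARD_CODE)
        q, _ = _raw_rate_matrix(2.0, 0.0, UNIFORM_PI, STANDARD_CODE)
        nonsyn = ~arrays.synonymous
        assert np.all(q[arrays.rows[nonsyn], arrays.cols[nonsyn]] == 0)

    def test_transition_matrix_is_stochastic(self):
        q = build_rate_matrix(3.0, 0.2, UNIFORM_PI)
        p = _Propagator(q, UNIFORM_PI).transition_matrix(0.7)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0)


class TestLogLikelihood:
    def test_zero_branch_lengths_closed_form(self):
        sim = simulate_codon_alignment(
            CodonSimConfig(n_codons=30, branch_length=0.0, seed=1)
        )
        aln = sim.alignment
        params = star_params(((0.3, 1.0),), bl=1e-12)
        lnl = log_likelihood(aln, None, params)
        arrays = _code_arrays(STANDARD_CODE)
        expected = sum(
            np.log(UNIFORM_PI[arrays.index[aln.codon(0, i)]])
            for i in range(aln.n_codons)
        )
        assert lnl == pytest.approx(expected, abs=1e-6)

    def test_pruning_equals_brute_force_star(self):
        sim = simulate_codon_alignment(
            CodonSimConfig(n_codons=10, branch_length=0.1, seed=2)
        )
        aln = sim.alignment
        params = star_params(((0.4, 1.0),), kappa=1.7, bl=0.12)
        lnl = log_likelihood(aln, None, params)

        arrays = _code_arrays(STANDARD_CODE)
        q, rate = _raw_rate_matrix(1.7, 0.4, UNIFORM_PI, STANDARD_CODE)
        p = _Propagator(q / rate, UNIFORM_PI).transition_matrix(0.12)
        total = 0.0
        for s in range(aln.n_codons):
            obs = [arrays.index[aln.codon(k, s)] for k in range(3)]
            site = sum(
                UNIFORM_PI[x] * p[x, obs[0]] * p[x, obs[1]] * p[x, obs[2]]
                for x in range(61)
            )
            total += np.log(site)
        assert lnl == pytest.approx(total, abs=1e-8)

    def test_duplicated_columns_double_lnl(self):
        sim = simulate_codon_alignment(
            CodonSimConfig(n_codons=12, branch_length=0.1, seed=3)
        )
        aln = sim.alignment
        doubled = build_codon_alignment(
            [
                SequenceRecord(id=r.id, residues=r.residues * 2)
                for r in aln.records
            ]
        )
        params = star_params(((0.5, 1.0),))
        assert log_likelihood(doubled, None, params) == pytest.approx(
            2 * log_likelihood(aln, None, params)
        )

    def test_rerooting_invariance(self):
        tree_a = read_newick("((A:0.08,B:0.12):0.05,C:0.1,D:0.15);")
        tree_b = read_newick("((C:0.1,D:0.15):0.05,A:0.08,B:0.12);")
        sim = simulate_codon_alignment(
            CodonSimConfig(
                n_codons=20, tree=tree_a, tip_labels=("A", "B", "C", "D"), seed=4
            )
        )
        aln = sim.alignment
        params_a = CodonModelParams(
            kappa=2.0,
            pi=UNIFORM_PI,
            branch_lengths=np.array([0.08, 0.12, 0.05, 0.1, 0.15]),
            omega_classes=((0.4, 1.0),),
        )
        params_b = CodonModelParams(
            kappa=2.0,
            pi=UNIFORM_PI,
            branch_lengths=np.array([0.1, 0.15, 0.05, 0.08, 0.12]),
            omega_classes=((0.4, 1.0),),
        )
        assert log_likelihood(aln, tree_a, params_a) == pytest.approx(
            log_likelihood(aln, tree_b, params_b), abs=1e-8
        )

    def test_mismatched_tips_error(self, tiny_alignment):
        tree = read_newick("(x:0.1,y:0.1,z:0.1);")
        params = star_params(((0.5, 1.0),))
        with pytest.raises(ValueError, match="do not match"):
            log_likelihood(tiny_alignment, tree, params)


@pytest.fixture(scope="module")
def m1a_data():
    sim = simulate_codon_alignment(
        CodonSimConfig(
            n_codons=300,
            omega_classes=((0.2, 0.7), (1.0, 0.3)),
            branch_length=0.08,
            seed=17,
        )
    )
    return sim.alignment


@pytest.fixture(scope="module")
def ladder(m1a_data):
    m0 = fit_site_model(m1a_data, None, "M0", n_restarts=2, seed=0)
    m1a = fit_site_model(m1a_data, None, "M1a", n_restarts=2, seed=0, init=m0)
    m2a = fit_site_model(m1a_data, None, "M2a", n_restarts=2, seed=0, init=m1a)
    return m0, m1a, m2a


class TestFitSiteModel:
    def test_nested_lnl_ordering(self, ladder):
        m0, m1a, m2a = ladder
        assert m1a.lnl >= m0.lnl - 1e-6
        assert m2a.lnl >= m1a.lnl - 1e-6

    def test_m1a_neutral_class_fixed(self, ladder):
        _, m1a, m2a = ladder
        assert m1a.params.omega_classes[1][0] == 1.0
        assert m2a.params.omega_classes[1][0] == 1.0

    def test_class_constraints(self, ladder):
        _, m1a, m2a = ladder
        assert 0 <= m1a.params.omega_classes[0][0] < 1
        assert m2a.params.omega_classes[2][0] >= 1.0
        for fit in (m1a, m2a):
            props = [p for _, p in fit.params.omega_classes]
            assert sum(props) == pytest.approx(1.0)

    def test_unknown_model_rejected(self, m1a_data):
        with pytest.raises(ValueError, match="unknown model"):
            fit_site_model(m1a_data, None, "M8")


class TestChi2:
    def test_df2_closed_form(self):
        assert chi2_upper_tail(9.72, 2) == pytest.approx(np.exp(-4.86), rel=1e-10)

    def test_zero_statistic(self):
        assert chi2_upper_tail(0.0, 1) == 1.0

    def test_df1_tail(self):
        assert chi2_upper_tail(18.15, 1) == pytest.approx(2.04e-5, rel=0.01)


class TestLRT:
    def test_from_printed_lnl(self):
        res = likelihood_ratio_test(-3471.89, -3469.56, df=1)
        assert res.delta == pytest.approx(4.66)

    def test_identical_lnl(self):
        res = likelihood_ratio_test(-100.0, -100.0, df=2)
        assert res.delta == 0.0
        assert res.p_value == 1.0

    def test_negative_noise_clamped(self):
        with pytest.warns(RuntimeWarning, match="clamping"):
            res = likelihood_ratio_test(-99.9, -100.0, df=1)
        assert res.delta == 0.0
        assert res.p_value == 1.0


class TestBEB:
    def test_posteriors_on_conserved_alignment_are_low(self):
        sim = simulate_codon_alignment(
            CodonSimConfig(
                n_codons=120, omega_classes=((0.05, 1.0),), branch_length=0.05,
                seed=23,
            )
        )
        aln = sim.alignment
        m1a = fit_site_model(aln, None, "M1a", n_restarts=1, seed=0)
        m2a = fit_site_model(aln, None, "M2a", n_restarts=1, seed=0, init=m1a)
        sites = beb_site_posteriors(aln, None, m2a, reference_id="t1")
        assert len(sites) == aln.n_codons
        posts = np.array([s.posterior_positive for s in sites])
        assert np.all((posts >= 0) & (posts <= 1))
        assert not any(s.flagged for s in sites)

    def test_reference_id_checked(self):
        sim = simulate_codon_alignment(
            CodonSimConfig(n_codons=30, branch_length=0.05, seed=5)
        )
        aln = sim.alignment
        m1a = fit_site_model(aln, None, "M1a", n_restarts=1, seed=0)
        m2a = fit_site_model(aln, None, "M2a", n_restarts=1, seed=0, init=m1a)
        with pytest.raises(KeyError):
            beb_site_posteriors(aln, None, m2a, reference_id="nope")

    def test_flag_threshold_respected(self):
        sim = simulate_codon_alignment(
            CodonSimConfig(
                n_codons=200,
                omega_classes=((0.2, 0.5), (1.0, 0.3), (6.0, 0.2)),
                branch_length=0.15,
                seed=31,
            )
        )
        aln = sim.alignment
        m1a = fit_site_model(aln, None, "M1a", n_restarts=1, seed=0)
        m2a = fit_site_model(aln, None, "M2a", n_restarts=1, seed=0, init=m1a)
        sites = beb_site_posteriors(aln, None, m2a, reference_id="t1", threshold=0.5)
        for s in sites:
            assert s.flagged == (s.posterior_positive >= 0.5)
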