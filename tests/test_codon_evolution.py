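import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dupsel.codon_evolution import (
    DEFAULT_CLOCK_RATE,
    count_pathway_differences,
    count_sites,
    distance_summary,
    divergence_time,
    effective_number_of_codons,
    jukes_cantor,
    ng86_distance,
)
from dupsel.core_io import (
    STANDARD_CODE,
    CodonAlignment,
    SequenceRecord,
    build_codon_alignment,
)
from dupsel.synthetic_data import CodonSimConfig, simulate_codon_alignment


def brute_force_pathways(codon_a, codon_b, code=STANDARD_CODE):
    """Independent oracle: explicit walk over every mutational ordering."""
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    syn_counts = []
    for order in permutations(positions):
        current = codon_a
        syn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                blocked = True
                break
            if code.translate(nxt) == code.translate(current):
                syn += 1
            current = nxt
        if not blocked:
            syn_counts.append(syn)
    if not syn_counts:
        return None
    sd = sum(syn_counts) / len(syn_counts)
    return sd, len(positions) - sd


class TestCountSites:
    @pytest.mark.parametrize(
        "codon,s_expected",
        [("TTT", 1 / 3), ("GGG", 1.0), ("ATG", 0.0), ("TGG", 0.0)],
    )
    def test_known_codons(self, codon, s_expected):
        sc = count_sites(codon)
        assert sc.S == pytest.approx(s_expected)
        assert sc.S + sc.N == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites("TAA")

    @given(st.sampled_from(STANDARD_CODE.sense_codons))
    @settings(derandomize=True, max_examples=61)
    def test_sites_sum_to_three(self, codon):
        sc = count_sites(codon)
        assert 0 <= sc.S <= 3
        assert sc.S + sc.N == pytest.approx(3.0, abs=1e-12)


class TestPathwayCounting:
    @pytest.mark.parametrize(
        "a,b,sd,nd",
        [
            ("TTT", "TTA", 0.0, 1.0),
            ("TTT", "GTA", 0.5, 1.5),
            ("AAA", "AAA", 0.0, 0.0),
            ("AAA", "AAG", 1.0, 0.0),
        ],
    )
    def test_worked_examples(self, a, b, sd, nd):
        assert count_pathway_differences(a, b) == pytest.approx((sd, nd))

    def test_symmetry(self):
        for a, b in [("TTT", "GTA"), ("ATG", "CGG"), ("AAA", "CCC")]:
            assert count_pathway_differences(a, b) == pytest.approx(
                count_pathway_differences(b, a)
            )

    def test_sd_nd_sum_to_differences(self):
        rng = np.random.default_rng(0)
        codons = STANDARD_CODE.sense_codons
        for _ in range(200):
            a, b = rng.choice(codons, 2)
            k = sum(x != y for x, y in zip(a, b))
            sd, nd = count_pathway_differences(a, b)
            assert sd + nd == pytest.approx(k)


class TestJukesCantor:
    def test_closed_form(self):
        assert jukes_cantor(0.1) == pytest.approx(0.10732, abs=1e-5)

    def test_zero(self):
        assert jukes_cantor(0.0) == 0.0

    def test_saturation(self):
        with pytest.raises(ValueError, match="saturated"):
            jukes_cantor(0.75)


class TestNg86Distance:
    def test_identical_sequences_zero(self, tiny_alignment):
        aln = build_codon_alignment(
            [
                SequenceRecord(id="a", residues="ATGAAATTT"),
                SequenceRecord(id="b", residues="ATGAAATTT"),
            ]
        )
        d = ng86_distance(aln, "a", "b")
        assert d.dS == 0.0 and d.dN == 0.0

    def test_symmetric_in_pair_order(self, tiny_alignment):
        d1 = ng86_distance(tiny_alignment, "a", "b")
        d2 = ng86_distance(tiny_alignment, "b", "a")
        assert d1.dS == pytest.approx(d2.dS)
        assert d1.dN == pytest.approx(d2.dN)

    def test_synonymous_only_difference(self):
        # AAA->AAG is synonymous (Lys); all differences land in dS
        aln = build_codon_alignment(
            [
                SequenceRecord(id="a", residues="AAAGGGTTT"),
                SequenceRecord(id="b", residues="AAGGGGTTT"),
            ]
        )
        d = ng86_distance(aln, "a", "b")
        assert d.dN == 0.0
        assert d.dS > 0.0

    def test_appending_differences_increases_distance(self):
        base_a = base_b = "GGG" * 6  # synonymous-site-rich background
        aln1 = build_codon_alignment(
            [
                SequenceRecord(id="a", residues=base_a + "AAA"),
                SequenceRecord(id="b", residues=base_b + "AAG"),
            ]
        )
        aln2 = build_codon_alignment(
            [
                SequenceRecord(id="a", residues=base_a + "AAAAAA"),
                SequenceRecord(id="b", residues=base_b + "AAGAAG"),
            ]
        )
        d1 = ng86_distance(aln1, "a", "b")
        d2 = ng86_distance(aln2, "a", "b")
        assert d2.dS > d1.dS

    def test_simulation_recovery_within_3_se(self):
        """dS on simulated data matches the exact model expectation."""
        cfg = CodonSimConfig(
            n_codons=1000,
            omega_classes=((0.3, 1.0),),
            branch_length=0.05,
            kappa=2.0,
            seed=42,
        )
        sim = simulate_codon_alignment(cfg)
        aln = sim.alignment

        # exact expectation of (Sd, S) for two tips separated by 2t
        from dupsel.site_models import _Propagator, _code_arrays, _raw_rate_matrix

        arrays = _code_arrays(STANDARD_CODE)
        pi = np.full(61, 1 / 61)
        q, rate = _raw_rate_matrix(2.0, 0.3, pi, STANDARD_CODE)
        p2t = _Propagator(q / rate, pi).transition_matrix(0.10)
        e_sd = e_sd2 = 0.0
        for i in range(61):
            for j in range(61):
                sd, _ = count_pathway_differences(arrays.codons[i], arrays.codons[j])
                e_sd += pi[i] * p2t[i, j] * sd
                e_sd2 += pi[i] * p2t[i, j] * sd * sd
        s_bar = float(np.mean([count_sites(c).S for c in arrays.codons]))
        p_expected = e_sd / s_bar
        d_expected = jukes_cantor(p_expected)
        se = math.sqrt((e_sd2 - e_sd**2) / aln.n_codons) / s_bar

        d_obs = ng86_distance(aln, "t1", "t2")
        assert abs(d_obs.dS - d_expected) < 3 * se / (1 - 4 * p_expected / 3)


class TestDistanceSummary:
    def test_identical_sequences(self):
        rec = "ATGAAATTTGGG"
        aln = build_codon_alignment(
            [SequenceRecord(id=i, residues=rec) for i in "abc"]
        )
        s = distance_summary(aln)
        assert s.mean_dS == 0.0 and s.sd_dS == 0.0
        assert s.n_pairs == 3

    def test_sample_sd(self):
        values = np.array([0.0, 0.1, 0.2])
        assert np.std(values, ddof=1) == pytest.approx(0.1)
        # summary uses the same sample convention
        sim = simulate_codon_alignment(
            CodonSimConfig(n_codons=200, branch_length=0.05, seed=9)
        )
        summary = distance_summary(sim.alignment)
        from dupsel.codon_evolution import all_pairwise_distances

        ds = [p.dS for p in all_pairwise_distances(sim.alignment)]
        assert summary.mean_dS == pytest.approx(np.mean(ds))
        assert summary.sd_dS == pytest.approx(np.std(ds, ddof=1))


class TestDivergenceTime:
    def test_worked_example(self):
        est = divergence_time(0.0876, 4.38e-9)
        assert est.T_years == pytest.approx(1.0e7)
        assert est.T_my == pytest.approx(10.0)

    def test_zero_distance(self):
        assert divergence_time(0.0).T_years == 0.0

    def test_linearity(self):
        t1 = divergence_time(0.05, DEFAULT_CLOCK_RATE).T_years
        t2 = divergence_time(0.10, DEFAULT_CLOCK_RATE).T_years
        assert t2 == pytest.approx(2 * t1)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            divergence_time(0.1, K=0.0)


class TestEffectiveNumberOfCodons:
    def test_uniform_usage_is_61(self):
        cds = SequenceRecord(
            id="uniform", residues="".join(c * 3 for c in STANDARD_CODE.sense_codons)
        )
        assert effective_number_of_codons(cds).Nc == pytest.approx(61.0)

    def test_single_codon_per_amino_acid_is_20(self):
        chosen = {}
        for codon in STANDARD_CODE.sense_codons:
            chosen.setdefault(STANDARD_CODE.translate(codon), codon)
        cds = SequenceRecord(id="biased", residues="".join(c * 5 for c in chosen.values()))
        assert effective_number_of_codons(cds).Nc == pytest.approx(20.0)

    def test_partial_families_fall_back(self):
        # only Lys codons AAA/AAG used equally: F2 = 0.5, everything else
        # imputed at the no-bias expectation 1/k
        cds = SequenceRecord(id="lys", residues="AAAAAG" * 10)
        result = effective_number_of_codons(cds)
        assert result.Nc == pytest.approx(2 + 18 + 3 + 20 + 18)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        codons = list(rng.choice(STANDARD_CODE.sense_codons, 150))
        a = effective_number_of_codons(
            SequenceRecord(id="x", residues="".join(codons))
        )
        rng.shuffle(codons)
        b = effective_number_of_codons(
            SequenceRecord(id="x", residues="".join(codons))
        )
        assert a.Nc == pytest.approx(b.Nc)

    def test_stop_codons_ignored(self):
        with_stop = SequenceRecord(id="s", residues="AAAAAGTAA")
        without = SequenceRecord(id="s", residues="AAAAAG")
        assert (
            effective_number_of_codons(with_stop).Nc
            == effective_number_of_codons(without).Nc
        )

    def test_no_sense_codons_errors(self):
        with pytest.raises(ValueError, match="no sense codons"):
            effective_number_of_codons(SequenceRecord(id="x", residues="TAATAA"))

    def test_bias_corrected_estimator_runs(self):
        rng = np.random.default_rng(5)
        cds = SequenceRecord(
            id="x", residues="".join(rng.choice(STANDARD_CODE.sense_codons, 400))
        )
        raw = effective_number_of_codons(cds, estimator="raw")
        corrected = effective_number_of_codons(cds, estimator="bias_corrected")
        assert 20 <= raw.Nc <= 61
        assert corrected.Nc >= raw.Nc - 1e-9  # correction removes downward bias
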