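"""Codon site models of selection: M0, M1a, M2a with LRT and BEB.

The substitution process is the standard reversible codon model: instantaneous
rates between sense codons differing at a single nucleotide are

    q_ij = pi_j            synonymous transversion
    q_ij = kappa pi_j      synonymous transition
    q_ij = omega pi_j      non-synonymous transversion
    q_ij = omega kappa pi_j  non-synonymous transition

with pi the equilibrium codon frequencies (F3x4 by default: products of
position-specific nucleotide frequencies, renormalized over sense codons).
Site models place a mixture over the dN/dS ratio omega:

* **M0** — a single omega for every codon;
* **M1a** (nearly neutral) — a class with 0 <= omega0 < 1 (proportion p0) and
  a class fixed at omega1 = 1;
* **M2a** (positive selection) — M1a plus a third class with omega2 >= 1
  (proportion p2).

Models are fitted by maximum likelihood (Felsenstein pruning over the guide
tree, bounded quasi-Newton with multi-start), nested fits are compared with a
likelihood-ratio test against a chi-squared distribution (df 1 for M1a vs M0,
df 2 for M2a vs M1a), and positively selected sites are located by Bayes
empirical Bayes: the posterior probability that each codon belongs to the
omega2 class, integrating the mixture parameters over a discrete uniform
prior grid while holding kappa and branch lengths at their M2a estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import optimize, stats

import dendropy

from dupsel.core_io import (
    NUCLEOTIDES,
    CodonAlignment,
    GeneticCode,
    STANDARD_CODE,
    translate_alignment,
)

# ---------------------------------------------------------------------------
# Genetic-code-dependent structural arrays (cached per code instance)


class _CodeArrays:
    """Index arrays describing single-nucleotide neighbour pairs of codons."""

    def __init__(self, code: GeneticCode):
        self.code = code
        self.codons = list(code.sense_codons)
        self.index = {c: i for i, c in enumerate(self.codons)}
        n = len(self.codons)
        rows, cols, is_transition, is_synonymous = [], [], [], []
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for i, ci in enumerate(self.codons):
            for j, cj in enumerate(self.codons):
                if i == j:
                    continue
                diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
                if len(diffs) != 1:
                    continue
                rows.append(i)
                cols.append(j)
                is_transition.append(diffs[0] in transitions)
                is_synonymous.append(code.translate(ci) == code.translate(cj))
        self.n = n
        self.rows = np.array(rows)
        self.cols = np.array(cols)
        self.transition = np.array(is_transition, dtype=bool)
        self.synonymous = np.array(is_synonymous, dtype=bool)


_CODE_ARRAYS: dict[int, _CodeArrays] = {}


def _code_arrays(code: GeneticCode) -> _CodeArrays:
    key = id(code)
    if key not in _CODE_ARRAYS:
        _CODE_ARRAYS[key] = _CodeArrays(code)
    return _CODE_ARRAYS[key]


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class CodonModelParams:
    """Parameters of a fitted codon model.

    ``omega_classes`` is a list of ``(omega, proportion)`` pairs; branch
    lengths are expected substitutions per codon, in the edge order of the
    compiled guide tree.
    """

    kappa: float
    pi: np.ndarray
    branch_lengths: np.ndarray
    omega_classes: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class SiteModelFit:
    model: str
    params: CodonModelParams
    lnl: float
    n_free_params: int
    converged: bool
    n_restarts_used: int


@dataclass(frozen=True)
class LRTResult:
    delta: float
    df: int
    p_value: float
    null_model: str
    alt_model: str
    reject_at: str


@dataclass(frozen=True)
class BEBSiteResult:
    site_index: int  # 1-based codon position in the gap-deleted alignment
    reference_residue: str
    posterior_positive: float
    flagged: bool


# ---------------------------------------------------------------------------
# Frequencies and rate matrix


def f3x4_frequencies(
    aln: CodonAlignment, code: GeneticCode = STANDARD_CODE
) -> np.ndarray:
    """Equilibrium codon frequencies from position-specific base frequencies.

    Counts nucleotide frequencies separately at the three codon positions
    over all sequences, forms the product for each sense codon, and
    renormalizes (stop codons dropped).  Frequencies of observed codons that
    would round to zero are floored at 1e-10 with a warning.
    """
    arrays = _code_arrays(code)
    pos_freq = np.zeros((3, 4))
    base_idx = {b: k for k, b in enumerate(NUCLEOTIDES)}
    for rec in aln.records:
        for i in range(aln.n_codons):
            for pos in range(3):
                pos_freq[pos, base_idx[rec.residues[3 * i + pos]]] += 1
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, base_idx[c[0]]]
            * pos_freq[1, base_idx[c[1]]]
            * pos_freq[2, base_idx[c[2]]]
            for c in arrays.codons
        ]
    )
    observed = set()
    for rec in aln.records:
        for i in range(aln.n_codons):
            observed.add(rec.residues[3 * i : 3 * i + 3])
    floor_needed = [
        c for c in observed if c in arrays.index and pi[arrays.index[c]] < 1e-10
    ]
    if floor_needed:
        warnings.warn(
            f"flooring near-zero F3x4 frequency for observed codons {floor_needed}",
            RuntimeWarning,
        )
        for c in floor_needed:
            pi[arrays.index[c]] = 1e-10
    return pi / pi.sum()


def uniform_frequencies(code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    n = len(code.sense_codons)
    return np.full(n, 1.0 / n)


def _raw_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, code: GeneticCode
) -> tuple[np.ndarray, float]:
    """Unscaled generator and its mean rate (expected substitutions/codon)."""
    a = _code_arrays(code)
    q = np.zeros((a.n, a.n))
    rate = np.where(a.transition, kappa, 1.0) * np.where(a.synonymous, 1.0, omega)
    q[a.rows, a.cols] = rate * pi[a.cols]
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = float(-(pi * np.diag(q)).sum())
    return q, mean_rate


def build_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, code: GeneticCode = STANDARD_CODE
) -> np.ndarray:
    """Reversible codon generator scaled to one expected substitution per unit
    branch length.  Rows sum to zero; detailed balance pi_i q_ij = pi_j q_ji
    holds by construction."""
    q, mean_rate = _raw_rate_matrix(kappa, omega, pi, code)
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix (zero mean rate)")
    return q / mean_rate


class _Propagator:
    """Eigendecomposition of a reversible generator for fast expm(Q t).

    Works in the pi-symmetrized basis: S = D Q D^-1 with D = diag(sqrt(pi))
    is symmetric, so a single `eigh` yields all transition matrices.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        s = (q * d[:, None]) / d[None, :]
        s = (s + s.T) / 2.0  # symmetrize away rounding noise
        w, u = np.linalg.eigh(s)
        self.w = w
        self.left = u / d[:, None] * 1.0  # D^-1 U
        self.right = (u * d[:, None]).T  # U^T D

    def transition_matrix(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.w * t)) @ self.right
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Guide tree compilation and pruning likelihood


class _CompiledTree:
    """Unrooted guide tree flattened for pruning.

    ``postorder`` lists (node_id, parent_edge, children) with leaves carrying
    their alignment row; edges are numbered 0..n_edges-1.
    """

    def __init__(self, aln: CodonAlignment, tree: dendropy.Tree | str | None):
        ids = list(aln.ids)
        if tree is None:
            if len(ids) != 3:
                raise ValueError(
                    "a guide tree is required for more than 3 sequences; the "
                    "implicit star tree covers exactly 3"
                )
            # star: one internal node, three tip edges
            self.n_edges = 3
            self.leaf_edge_rows = list(enumerate(range(3)))  # (edge, row)
            self.internal = []  # no internal edges
            self.postorder = [("leaf", row, edge) for edge, row in enumerate(range(3))]
            self.root_children = [(edge, ("leaf", row)) for edge, row in enumerate(range(3))]
            self._simple_star = True
            return
        self._simple_star = False
        if isinstance(tree, str):
            tree = dendropy.Tree.get(data=tree, schema="newick")
        tree = tree.clone(depth=1)
        tree.is_rooted = False
        if len(tree.seed_node.child_nodes()) == 2:
            tree.collapse_basal_bifurcation()
        tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        if tip_labels != set(ids):
            raise ValueError(
                f"tree tips {sorted(tip_labels)} do not match alignment ids "
                f"{sorted(ids)}"
            )
        row_of = {label: i for i, label in enumerate(ids)}
        self.nodes = []
        edge_counter = 0
        node_info: dict[int, dict] = {}
        postorder_nodes = [nd for nd in tree.postorder_node_iter()]
        for nd in postorder_nodes:
            if nd is tree.seed_node:
                continue
            node_info[id(nd)] = {"edge": edge_counter}
            edge_counter += 1
        self.n_edges = edge_counter
        plan = []
        for nd in postorder_nodes:
            if nd.is_leaf():
                if nd is tree.seed_node:
                    raise ValueError("degenerate single-leaf tree")
                plan.append(
                    ("leaf", row_of[nd.taxon.label], node_info[id(nd)]["edge"], id(nd))
                )
            else:
                children = [
                    (node_info[id(ch)]["edge"], id(ch)) for ch in nd.child_nodes()
                ]
                edge = None if nd is tree.seed_node else node_info[id(nd)]["edge"]
                plan.append(("internal", children, edge, id(nd)))
        self.plan = plan
        self.initial_lengths = np.array(
            [
                max(nd.edge.length if nd.edge.length is not None else 0.1, 1e-6)
                for nd in postorder_nodes
                if nd is not tree.seed_node
            ]
        )

    def site_likelihoods(
        self, patterns: np.ndarray, p_edges: list[np.ndarray], pi: np.ndarray
    ) -> np.ndarray:
        """Per-pattern likelihoods by postorder pruning.

        ``patterns`` has shape (n_taxa, n_patterns) of sense-codon indices;
        ``p_edges[e]`` is the transition matrix of edge e.
        """
        if self._simple_star:
            lik = pi[:, None].copy()
            for edge, row in self.leaf_edge_rows:
                lik = lik * p_edges[edge][:, patterns[row]]
            return lik.sum(axis=0)
        partials: dict[int, np.ndarray] = {}
        root_partial = None
        for entry in self.plan:
            if entry[0] == "leaf":
                _, row, edge, nid = entry
                partials[nid] = p_edges[edge][:, patterns[row]]
            else:
                _, children, edge, nid = entry
                part = np.ones((len(pi), patterns.shape[1]))
                for _child_edge, child_id in children:
                    # child partials are already propagated along their edge
                    part *= partials.pop(child_id)
                if edge is None:
                    root_partial = part
                else:
                    partials[nid] = p_edges[edge] @ part
        assert root_partial is not None
        return pi @ root_partial


def _compile(aln: CodonAlignment, tree, code: GeneticCode):
    arrays = _code_arrays(code)
    n_taxa = len(aln.records)
    cols = np.empty((n_taxa, aln.n_codons), dtype=np.int64)
    for r, rec in enumerate(aln.records):
        for i in range(aln.n_codons):
            codon = rec.residues[3 * i : 3 * i + 3]
            cols[r, i] = arrays.index[codon]
    patterns, counts = np.unique(cols, axis=1, return_counts=True)
    ct = _CompiledTree(aln, tree)
    return arrays, patterns, counts.astype(float), ct


def _mixture_site_likelihoods(
    compiled, kappa, omega_classes, pi, branch_lengths, code
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pattern likelihood per omega class (classes jointly scaled).

    Rate matrices of all classes share kappa and pi and are divided by the
    mixture-averaged rate, so one unit of branch length is one expected
    substitution per codon under the fitted mixture.
    """
    arrays, patterns, counts, ct = compiled
    omegas = np.array([w for w, _ in omega_classes])
    props = np.array([p for _, p in omega_classes])
    raw = [_raw_rate_matrix(kappa, w, pi, code) for w in omegas]
    mean_rate = float(np.dot(props, [r for _, r in raw]))
    if mean_rate <= 0:
        raise ValueError("degenerate mixture rate")
    per_class = np.empty((len(omegas), patterns.shape[1]))
    for c, (q, _) in enumerate(raw):
        prop = _Propagator(q / mean_rate, pi)
        p_edges = [prop.transition_matrix(t) for t in branch_lengths]
        per_class[c] = ct.site_likelihoods(patterns, p_edges, pi)
    return per_class, counts


def log_likelihood(
    aln: CodonAlignment,
    tree,
    params: CodonModelParams,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Mixture log-likelihood of the alignment under a fitted parameter set."""
    compiled = _compile(aln, tree, code)
    per_class, counts = _mixture_site_likelihoods(
        compiled, params.kappa, params.omega_classes, params.pi,
        params.branch_lengths, code,
    )
    props = np.array([p for _, p in params.omega_classes])
    site = props @ per_class
    if np.any(site <= 0):
        return -np.inf
    return float(counts @ np.log(site))


# ---------------------------------------------------------------------------
# Fitting


_MODELS = ("M0", "M1a", "M2a")


def _unpack(model: str, theta: np.ndarray, n_edges: int):
    kappa = theta[0]
    bl = theta[1 : 1 + n_edges]
    rest = theta[1 + n_edges :]
    if model == "M0":
        classes = ((rest[0], 1.0),)
    elif model == "M1a":
        omega0, p0 = rest
        classes = ((omega0, p0), (1.0, 1.0 - p0))
    else:  # M2a
        omega0, omega2, p0, p1frac = rest
        p1 = (1.0 - p0) * p1frac
        classes = ((omega0, p0), (1.0, p1), (omega2, 1.0 - p0 - p1))
    return kappa, bl, classes


def _model_bounds(model: str, n_edges: int):
    bounds = [(0.1, 30.0)] + [(1e-6, 10.0)] * n_edges
    if model == "M0":
        bounds += [(1e-4, 99.0)]
    elif model == "M1a":
        bounds += [(1e-4, 1.0 - 1e-6), (1e-6, 1.0 - 1e-6)]
    else:
        bounds += [
            (1e-4, 1.0 - 1e-6),
            (1.0, 99.0),
            (1e-6, 1.0 - 1e-6),
            (1e-6, 1.0 - 1e-6),
        ]
    return bounds


def _default_start(model: str, n_edges: int, bl0: np.ndarray | None):
    bl = bl0 if bl0 is not None else np.full(n_edges, 0.1)
    head = [2.0, *bl]
    if model == "M0":
        return np.array(head + [0.3])
    if model == "M1a":
        return np.array(head + [0.2, 0.7])
    return np.array(head + [0.2, 3.0, 0.6, 0.8])


def _start_from_init(model: str, init: SiteModelFit, n_edges: int):
    """Warm start from a nested fit (M0 -> M1a -> M2a)."""
    p = init.params
    head = [p.kappa, *np.clip(p.branch_lengths, 1e-6, 10.0)]
    if model == "M1a":
        if init.model == "M0":
            w = min(p.omega_classes[0][0], 0.9)
            return np.array(head + [max(w, 1e-4), 0.7])
        return None
    if model == "M2a":
        if init.model == "M1a":
            (w0, p0), _ = p.omega_classes
            return np.array(
                head + [max(min(w0, 1.0 - 1e-6), 1e-4), 1.5, max(min(p0, 1 - 1e-6), 1e-6), 0.95]
            )
        return None
    return None


def fit_site_model(
    aln: CodonAlignment,
    tree=None,
    model: str = "M0",
    code: GeneticCode = STANDARD_CODE,
    pi: np.ndarray | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    init: SiteModelFit | None = None,
    tol: float = 1e-8,
) -> SiteModelFit:
    """Maximum-likelihood fit of a site model.

    Parameters are kappa, the branch lengths of the guide tree (the unrooted
    3-branch star when ``tree`` is None and the alignment has 3 sequences),
    and the per-model omega mixture.  Optimization is bounded L-BFGS-B from a
    deterministic start (optionally warm-started from a nested fit via
    ``init``) plus ``n_restarts - 1`` random restarts drawn from a seeded
    generator; the best optimum is kept.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {_MODELS}")
    compiled = _compile(aln, tree, code)
    n_edges = compiled[3].n_edges
    if pi is None:
        pi = f3x4_frequencies(aln, code)
    counts = compiled[2]

    def negative_lnl(theta: np.ndarray) -> float:
        kappa, bl, classes = _unpack(model, theta, n_edges)
        try:
            per_class, _ = _mixture_site_likelihoods(
                compiled, kappa, classes, pi, bl, code
            )
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        props = np.array([p for _, p in classes])
        site = props @ per_class
        if not np.all(site > 0):
            return 1e12
        val = counts @ np.log(site)
        return -float(val) if np.isfinite(val) else 1e12

    bounds = _model_bounds(model, n_edges)
    bl0 = getattr(compiled[3], "initial_lengths", None)
    starts = []
    warm = _start_from_init(model, init, n_edges) if init is not None else None
    if warm is not None:
        starts.append(warm)
    starts.append(_default_start(model, n_edges, bl0))
    rng = np.random.default_rng(seed)
    while len(starts) < max(n_restarts, 1) + (1 if warm is not None else 0):
        theta = np.array(
            [rng.uniform(lo, min(hi, lo + 5.0)) for lo, hi in bounds]
        )
        starts.append(theta)

    best = None
    converged = False
    for theta0 in starts:
        res = optimize.minimize(
            negative_lnl,
            np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": tol},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    if not converged:
        warnings.warn(
            f"{model} fit did not report convergence after {len(starts)} starts",
            RuntimeWarning,
        )

    kappa, bl, classes = _unpack(model, best.x, n_edges)
    n_free = {"M0": 1, "M1a": 2, "M2a": 4}[model] + 1 + n_edges
    return SiteModelFit(
        model=model,
        params=CodonModelParams(
            kappa=float(kappa),
            pi=pi,
            branch_lengths=np.asarray(bl, dtype=float),
            omega_classes=tuple((float(w), float(p)) for w, p in classes),
        ),
        lnl=-float(best.fun),
        n_free_params=n_free,
        converged=converged,
        n_restarts_used=len(starts),
    )


# ---------------------------------------------------------------------------
# LRT


def chi2_upper_tail(x: float, df: int) -> float:
    """Upper-tail probability of the chi-squared distribution."""
    if x < 0:
        raise ValueError("test statistic must be non-negative")
    return float(stats.chi2.sf(x, df))


def likelihood_ratio_test(
    fit_null, fit_alt, df: int, tol: float = 1e-6
) -> LRTResult:
    """LRT of nested fits: delta = 2(lnl_alt - lnl_null) ~ chi2(df).

    Accepts :class:`SiteModelFit` objects or raw log-likelihood floats.
    Slightly negative deltas (optimizer noise) are clamped to zero; a
    warning is emitted when the violation exceeds ``tol``.
    """
    lnl_null = getattr(fit_null, "lnl", fit_null)
    lnl_alt = getattr(fit_alt, "lnl", fit_alt)
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = 2.0 * (lnl_alt - lnl_null)
    if delta < 0:
        if delta < -tol:
            warnings.warn(
                f"alternative lnl below null by {-delta / 2:.3g}; clamping the "
                "LRT statistic to 0",
                RuntimeWarning,
            )
        delta = 0.0
    p = chi2_upper_tail(delta, df)
    notes = "ns"
    for alpha, label in ((0.05, "*"), (0.01, "**"), (0.001, "***")):
        if p < alpha:
            notes = label
    return LRTResult(
        delta=delta,
        df=df,
        p_value=p,
        null_model=getattr(fit_null, "model", "null"),
        alt_model=getattr(fit_alt, "model", "alt"),
        reject_at=notes,
    )


# ---------------------------------------------------------------------------
# Bayes empirical Bayes


def beb_site_posteriors(
    aln: CodonAlignment,
    tree,
    m2a_fit: SiteModelFit,
    reference_id: str,
    threshold: float = 0.95,
    n_bins: int = 10,
    omega_max: float = 11.0,
    code: GeneticCode = STANDARD_CODE,
) -> list[BEBSiteResult]:
    """Posterior probability per codon of membership in the omega2 class.

    Kappa, branch lengths, and pi are fixed at the M2a estimates; the mixture
    parameters are integrated over a discrete uniform prior: (p0, p1) on the
    midpoint grid of the unit triangle (``n_bins`` per axis), omega0 on
    ``n_bins`` midpoints of (0, 1), omega2 on ``n_bins`` midpoints of
    (1, omega_max).  Sites whose posterior reaches ``threshold`` are flagged
    and reported with the amino acid of the reference sequence.
    """
    if reference_id not in aln.ids:
        raise KeyError(f"reference id {reference_id!r} not in alignment")
    if m2a_fit.model != "M2a":
        raise ValueError("BEB requires an M2a fit")
    compiled = _compile(aln, tree, code)
    arrays, patterns, counts, ct = compiled
    pi = m2a_fit.params.pi
    kappa = m2a_fit.params.kappa
    bl = m2a_fit.params.branch_lengths

    # Branch lengths keep their fitted meaning: all candidate generators are
    # scaled by the M2a MLE mixture rate.
    mle_raw = [
        _raw_rate_matrix(kappa, w, pi, code) for w, _ in m2a_fit.params.omega_classes
    ]
    mle_props = np.array([p for _, p in m2a_fit.params.omega_classes])
    scale = float(np.dot(mle_props, [r for _, r in mle_raw]))

    omega0_grid = (np.arange(n_bins) + 0.5) / n_bins
    omega2_grid = 1.0 + (np.arange(n_bins) + 0.5) / n_bins * (omega_max - 1.0)
    all_omegas = np.concatenate([omega0_grid, [1.0], omega2_grid])

    def site_lik_for_omega(w: float) -> np.ndarray:
        q, _ = _raw_rate_matrix(kappa, w, pi, code)
        prop = _Propagator(q / scale, pi)
        p_edges = [prop.transition_matrix(t) for t in bl]
        return ct.site_likelihoods(patterns, p_edges, pi)

    lik = np.array([site_lik_for_omega(w) for w in all_omegas])
    lik0 = lik[:n_bins]  # per omega0 bin
    lik1 = lik[n_bins]  # omega = 1
    lik2 = lik[n_bins + 1 :]  # per omega2 bin

    mid = (np.arange(n_bins) + 0.5) / n_bins
    p_grid = [
        (p0, p1)
        for p0, p1 in product(mid, mid)
        if p0 + p1 <= 1.0 + 1e-12
    ]

    n_pat = patterns.shape[1]
    log_post = np.empty((len(p_grid), n_bins, n_bins))
    frac2 = np.empty((len(p_grid), n_bins, n_bins, n_pat))
    for g, (p0, p1) in enumerate(p_grid):
        p2 = 1.0 - p0 - p1
        for i0 in range(n_bins):
            base = p0 * lik0[i0] + p1 * lik1
            for i2 in range(n_bins):
                f = base + p2 * lik2[i2]
                log_post[g, i0, i2] = counts @ np.log(f)
                frac2[g, i0, i2] = (p2 * lik2[i2]) / f
    log_post -= log_post.max()
    weights = np.exp(log_post)
    weights /= weights.sum()
    pattern_posterior = np.tensordot(weights, frac2, axes=3)

    # map patterns back to sites
    cols = np.empty((len(aln.records), aln.n_codons), dtype=np.int64)
    for r, rec in enumerate(aln.records):
        for i in range(aln.n_codons):
            cols[r, i] = arrays.index[rec.residues[3 * i : 3 * i + 3]]
    _, inverse = np.unique(cols, axis=1, return_inverse=True)
    site_posterior = pattern_posterior[inverse]

    ref_aa = next(
        r.residues for r in translate_alignment(aln, code) if r.id == reference_id
    )
    return [
        BEBSiteResult(
            site_index=i + 1,
            reference_residue=ref_aa[i],
            posterior_positive=float(site_posterior[i]),
            flagged=bool(site_posterior[i] >= threshold),
        )
        for i in range(aln.n_codons)
    ]
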