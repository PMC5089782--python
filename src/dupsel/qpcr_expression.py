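"""qPCR analysis: window-of-linearity quantification, two-reference
normalization, fold change, and distribution-free permutation testing.

Quantification follows the window-of-linearity idea: after subtracting a
baseline (mean of the first five cycles), the log-linear stretch of the
amplification curve is found by scanning 4–6-cycle windows for the best
linear fit of log10 fluorescence against cycle.  The slope gives the
amplification efficiency E = 10^slope (E = 2 is perfect doubling), the
fitted line crossing a threshold inside the window gives a fractional Ct,
and the starting quantity is threshold / E^Ct.

Expression of a target gene in a sample is normalized to the mean of two
constitutively expressed reference genes, and differences between groups of
biological replicates are tested with a two-sided permutation test on the
absolute difference of group means — exact (full enumeration of label
reassignments) whenever that is feasible, Monte Carlo otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

#: Number of leading cycles averaged to estimate the baseline fluorescence.
BASELINE_CYCLES = 5
#: Window lengths (in cycles) scanned for the best log-linear fit.
WINDOW_LENGTHS = (4, 5, 6)
#: Above this number of distinct label reassignments the permutation test
#: switches from exhaustive enumeration to Monte Carlo sampling.
EXHAUSTIVE_LIMIT = 20000


@dataclass(frozen=True)
class AmplificationCurve:
    well_id: str
    target_gene: str
    sample_id: str
    fluorescence: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.fluorescence) < 10:
            raise ValueError("amplification curve needs at least 10 cycles")
        if not all(math.isfinite(f) for f in self.fluorescence):
            raise ValueError("fluorescence readings must be finite")


@dataclass(frozen=True)
class QuantResult:
    well_id: str
    target_gene: str
    sample_id: str
    efficiency: float
    ct: float
    window: tuple[int, int]
    r_squared: float
    quantity: float
    efficiency_flagged: bool = False


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of normalized expression.

    ``values`` carries one column per (condition, replicate); ``baseline``
    optionally names the reference condition used for fold changes.
    """

    values: pd.DataFrame  # columns: MultiIndex (condition, replicate)
    baseline: str | None = None

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    def condition_values(self, gene: str, condition: str) -> np.ndarray:
        return self.values.loc[gene, condition].to_numpy(dtype=float)


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    exhaustive: bool


def window_of_linearity(curve: AmplificationCurve) -> QuantResult:
    """Efficiency, Ct, and starting quantity from one amplification curve.

    The baseline is the mean of cycles 1–5; windows of 4–6 consecutive
    cycles with strictly positive baseline-corrected fluorescence are fitted
    by least squares in log10 space and the window maximizing r² wins (ties:
    longer, then earlier windows).  The threshold is the geometric midpoint
    of the winning window's fluorescence span.  Efficiencies outside
    (1, 2.5] are flagged but still reported.
    """
    f = np.asarray(curve.fluorescence, dtype=float)
    baseline = f[:BASELINE_CYCLES].mean()
    corrected = f - baseline
    positive = corrected > 0
    log_f = np.full_like(corrected, np.nan)
    log_f[positive] = np.log10(corrected[positive])
    cycles = np.arange(1, len(f) + 1, dtype=float)

    best = None
    for width in WINDOW_LENGTHS:
        for start in range(0, len(f) - width + 1):
            sl = slice(start, start + width)
            if not positive[sl].all():
                continue
            slope, intercept, r, _, _ = stats.linregress(cycles[sl], log_f[sl])
            if slope <= 0:
                continue
            # ties (e.g. several perfectly log-linear windows) resolve toward
            # the widest, then latest window: highest signal-to-noise, just
            # below the plateau
            key = (round(r * r, 12), width, start)
            if best is None or key > best[0]:
                best = (key, slope, intercept, sl, r * r)
    if best is None:
        raise ValueError(f"flat curve: no exponential phase in well {curve.well_id!r}")
    _, slope, intercept, sl, r2 = best
    efficiency = 10.0**slope
    log_thr = (log_f[sl][0] + log_f[sl][-1]) / 2.0  # geometric midpoint
    threshold = 10.0**log_thr
    ct = (log_thr - intercept) / slope
    quantity = threshold / efficiency**ct
    return QuantResult(
        well_id=curve.well_id,
        target_gene=curve.target_gene,
        sample_id=curve.sample_id,
        efficiency=efficiency,
        ct=ct,
        window=(sl.start + 1, sl.stop),
        r_squared=r2,
        quantity=quantity,
        efficiency_flagged=not (1.0 < efficiency <= 2.5),
    )


def quantify_ct_table(
    table: pd.DataFrame, threshold: float = 1.0
) -> list[QuantResult]:
    """Build quantities from a precomputed (well, gene, sample, Ct, E) table.

    With a shared threshold, quantity = threshold / E^Ct; the threshold
    cancels from all normalized expression values.
    """
    required = {"well", "gene", "sample", "ct", "efficiency"}
    missing = required - set(map(str.lower, table.columns))
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    table = table.rename(columns=str.lower)
    out = []
    for row in table.itertuples(index=False):
        e = float(row.efficiency)
        ct = float(row.ct)
        out.append(
            QuantResult(
                well_id=str(row.well),
                target_gene=str(row.gene),
                sample_id=str(row.sample),
                efficiency=e,
                ct=ct,
                window=(0, 0),
                r_squared=float("nan"),
                quantity=threshold / e**ct,
                efficiency_flagged=not (1.0 < e <= 2.5),
            )
        )
    return out


def _split_sample(sample_id: str) -> tuple[str, str]:
    """Sample ids are '<condition>:<replicate>' (or a bare condition)."""
    if ":" in sample_id:
        cond, rep = sample_id.rsplit(":", 1)
        return cond, rep
    return sample_id, "1"


def normalize_expression(
    quants: list[QuantResult],
    targets: list[str],
    references: tuple[str, str],
    reference_mean: str = "arithmetic",
) -> ExpressionMatrix:
    """Target quantities divided by the mean of two reference genes.

    Technical replicates (several wells with the same gene and sample) are
    combined by geometric mean before normalization; biological replicate
    structure is preserved in the columns.  The reference mean is arithmetic
    by default (geometric available).
    """
    if len(references) != 2:
        raise ValueError("exactly two reference genes are required")
    by_key: dict[tuple[str, str], list[float]] = {}
    for q in quants:
        by_key.setdefault((q.target_gene, q.sample_id), []).append(q.quantity)
    tech_mean = {
        key: float(np.exp(np.mean(np.log(vals)))) for key, vals in by_key.items()
    }
    samples = sorted({s for _, s in tech_mean})
    data: dict[str, dict[tuple[str, str], float]] = {}
    for gene in targets:
        row = {}
        for sample in samples:
            if (gene, sample) not in tech_mean:
                continue
            ref_vals = []
            for ref in references:
                if (ref, sample) not in tech_mean:
                    raise ValueError(
                        f"sample {sample!r} lacks reference gene {ref!r}"
                    )
                ref_vals.append(tech_mean[(ref, sample)])
            if reference_mean == "arithmetic":
                ref = float(np.mean(ref_vals))
            elif reference_mean == "geometric":
                ref = float(np.exp(np.mean(np.log(ref_vals))))
            else:
                raise ValueError(f"unknown reference mean {reference_mean!r}")
            row[_split_sample(sample)] = tech_mean[(gene, sample)] / ref
        data[gene] = row
    frame = pd.DataFrame.from_dict(data, orient="index")
    frame = frame.sort_index(axis=1)
    frame.columns = pd.MultiIndex.from_tuples(
        frame.columns, names=["condition", "replicate"]
    )
    return ExpressionMatrix(values=frame)


def permutation_test(
    group_a,
    group_b,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> PermutationResult:
    """Two-sided permutation test on |mean(a) - mean(b)|.

    All C(n_a + n_b, n_a) label reassignments are enumerated when their
    count is at most ``EXHAUSTIVE_LIMIT`` (p is then deterministic and
    seed-independent); otherwise ``n_permutations`` random reassignments are
    drawn and the add-one estimate p = (exceedances + 1) / (m + 1) is
    reported.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    total = math.comb(n, na)
    if total <= EXHAUSTIVE_LIMIT:
        count = 0
        pooled_sum = pooled.sum()
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            stat = abs(sa / na - (pooled_sum - sa) / (n - na))
            if stat >= observed - 1e-12:
                count += 1
        return PermutationResult(
            statistic=float(observed),
            p_value=count / total,
            n_permutations=total,
            seed=None,
            exhaustive=True,
        )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = abs(perm[:na].mean() - perm[na:].mean())
        if stat >= observed - 1e-12:
            count += 1
    return PermutationResult(
        statistic=float(observed),
        p_value=(count + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
        seed=seed,
        exhaustive=False,
    )


def fold_change_matrix(em: ExpressionMatrix, baseline: str) -> pd.DataFrame:
    """Condition-mean expression relative to the baseline condition.

    Replicates are averaged per condition, every row is divided by its
    baseline mean, so the baseline column is identically 1.
    """
    conds = em.conditions()
    if baseline not in conds:
        raise ValueError(f"baseline condition {baseline!r} not present")
    means = em.values.T.groupby(level="condition").mean().T[conds]
    base = means[baseline]
    if (base == 0).any() or base.isna().any():
        bad = base.index[(base == 0) | base.isna()].tolist()
        raise ValueError(f"zero or missing baseline expression for {bad}")
    return means.div(base, axis=0)
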