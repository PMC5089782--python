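"""Pairwise dN/dS (Nei–Gojobori 1986, Jukes–Cantor corrected), molecular-clock
dating, and codon-usage bias (Wright's effective number of codons).

The NG86 method counts, for each codon, the fraction of the three positions
that is synonymous (averaging over the single-base mutations at that
position, with mutations to stop codons excluded from the denominator), and,
for each differing codon pair, averages synonymous/non-synonymous step counts
over all mutational pathways between the two codons that avoid stop-codon
intermediates.  Observed proportions of synonymous (pS) and non-synonymous
(pN) differences are then corrected for multiple hits with the Jukes–Cantor
formula d = -(3/4) ln(1 - 4p/3).

Divergence times for duplicated genes use the strict molecular clock
T = dS / (2K), with K a per-lineage synonymous substitution rate in
substitutions per site per year.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np

from dupsel.core_io import (
    NUCLEOTIDES,
    CodonAlignment,
    GeneticCode,
    SequenceRecord,
    STANDARD_CODE,
)

#: Default clock rate: mean synonymous substitution rate for tomato/wild-tomato
#: loci, in substitutions per site per year.
DEFAULT_CLOCK_RATE = 4.38e-9


@dataclass(frozen=True)
class SiteCounts:
    """Fractional synonymous (S) and non-synonymous (N) site counts; S + N = 3."""

    S: float
    N: float


@dataclass(frozen=True)
class PairwiseDistance:
    id_a: str
    id_b: str
    pS: float
    pN: float
    dS: float
    dN: float


@dataclass(frozen=True)
class DistanceSummary:
    mean_dN: float
    sd_dN: float
    mean_dS: float
    sd_dS: float
    n_pairs: int


@dataclass(frozen=True)
class ClockEstimate:
    """Strict-clock divergence time T = dS / (2K)."""

    dS: float
    K: float
    T_years: float
    T_my: float


@dataclass(frozen=True)
class NcResult:
    Nc: float
    family_homozygosity: dict[int, float]
    families_used: dict[int, int]
    estimator: str
    clamped: bool = False


def _single_mutations(codon: str, position: int) -> list[str]:
    return [
        codon[:position] + base + codon[position + 1 :]
        for base in NUCLEOTIDES
        if base != codon[position]
    ]


@lru_cache(maxsize=None)
def _count_sites_cached(codon: str, code: GeneticCode) -> SiteCounts:
    aa = code.translate(codon)
    s_total = 0.0
    for pos in range(3):
        n_syn = 0
        n_counted = 0
        for mut in _single_mutations(codon, pos):
            if code.is_stop(mut):
                continue  # stops excluded from the denominator (NG86 convention)
            n_counted += 1
            if code.translate(mut) == aa:
                n_syn += 1
        if n_counted:
            s_total += n_syn / n_counted
    return SiteCounts(S=s_total, N=3.0 - s_total)


def count_sites(codon: str, code: GeneticCode = STANDARD_CODE) -> SiteCounts:
    """NG86 fractional synonymous/non-synonymous site counts for one codon."""
    codon = codon.upper()
    if code.is_stop(codon):
        raise ValueError(f"cannot count sites for stop codon {codon}")
    return _count_sites_cached(codon, code)


def count_pathway_differences(
    codon_a: str, codon_b: str, code: GeneticCode = STANDARD_CODE
) -> tuple[float, float]:
    """Average synonymous/non-synonymous step counts over mutational pathways.

    For k differing positions the k! orderings of single-base changes are
    enumerated; pathways passing through a stop codon are excluded before
    averaging.  If every pathway is blocked by stops, the average is taken
    over all pathways with stop-involving steps counted as non-synonymous
    (degenerate case, flagged with a warning).  Returns ``(Sd, Nd)`` with
    Sd + Nd = k.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_positions)
    if k == 0:
        return 0.0, 0.0

    def pathway_counts(order: tuple[int, ...], allow_stops: bool):
        current = codon_a
        syn = 0
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code.is_stop(nxt) or code.is_stop(current):
                if not allow_stops:
                    return None
            elif code.translate(nxt) == code.translate(current):
                syn += 1
            current = nxt
        return syn

    syn_counts = [
        s
        for order in permutations(diff_positions)
        if (s := pathway_counts(order, allow_stops=False)) is not None
    ]
    if not syn_counts:
        warnings.warn(
            f"all mutational pathways between {codon_a} and {codon_b} pass "
            "through stop codons; counting stop steps as non-synonymous",
            RuntimeWarning,
        )
        syn_counts = [
            pathway_counts(order, allow_stops=True)
            for order in permutations(diff_positions)
        ]
    sd = float(np.mean(syn_counts))
    return sd, k - sd


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - 4p/3); requires p < 3/4."""
    if p < 0:
        raise ValueError("proportion of differences must be non-negative")
    if p >= 0.75:
        raise ValueError(f"distance saturated/undefined: p = {p:.4f} >= 3/4")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_distance(
    aln: CodonAlignment, id_a: str, id_b: str, code: GeneticCode = STANDARD_CODE
) -> PairwiseDistance:
    """Jukes–Cantor-corrected NG86 dN/dS between two aligned sequences."""
    seq_a = aln.record(id_a).residues
    seq_b = aln.record(id_b).residues
    S_a = N_a = S_b = N_b = 0.0
    Sd = Nd = 0.0
    for i in range(aln.n_codons):
        ca = seq_a[3 * i : 3 * i + 3]
        cb = seq_b[3 * i : 3 * i + 3]
        sc_a = count_sites(ca, code)
        sc_b = count_sites(cb, code)
        S_a += sc_a.S
        N_a += sc_a.N
        S_b += sc_b.S
        N_b += sc_b.N
        sd, nd = count_pathway_differences(ca, cb, code)
        Sd += sd
        Nd += nd
    S = (S_a + S_b) / 2.0
    N = (N_a + N_b) / 2.0
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    try:
        dS = jukes_cantor(pS)
        dN = jukes_cantor(pN)
    except ValueError as exc:
        raise ValueError(f"pair ({id_a}, {id_b}): {exc}") from exc
    return PairwiseDistance(id_a=id_a, id_b=id_b, pS=pS, pN=pN, dS=dS, dN=dN)


def all_pairwise_distances(
    aln: CodonAlignment, code: GeneticCode = STANDARD_CODE
) -> list[PairwiseDistance]:
    return [
        ng86_distance(aln, a, b, code) for a, b in combinations(aln.ids, 2)
    ]


def distance_summary(
    aln: CodonAlignment, code: GeneticCode = STANDARD_CODE
) -> DistanceSummary:
    """Mean and sample SD of dN and dS over all sequence pairs."""
    pairs = all_pairwise_distances(aln, code)
    dn = np.array([p.dN for p in pairs])
    ds = np.array([p.dS for p in pairs])
    ddof = 1 if len(pairs) > 1 else 0
    return DistanceSummary(
        mean_dN=float(dn.mean()),
        sd_dN=float(dn.std(ddof=ddof)),
        mean_dS=float(ds.mean()),
        sd_dS=float(ds.std(ddof=ddof)),
        n_pairs=len(pairs),
    )


def divergence_time(dS: float, K: float = DEFAULT_CLOCK_RATE) -> ClockEstimate:
    """Strict molecular clock: T = dS / (2K), reported in years and MY."""
    if K <= 0:
        raise ValueError("substitution rate K must be positive")
    if dS < 0:
        raise ValueError("dS must be non-negative")
    t_years = dS / (2.0 * K)
    return ClockEstimate(dS=dS, K=K, T_years=t_years, T_my=t_years / 1e6)


def effective_number_of_codons(
    cds: SequenceRecord,
    code: GeneticCode = STANDARD_CODE,
    estimator: str = "raw",
) -> NcResult:
    """Wright's effective number of codons (Nc) of a coding sequence.

    Per amino-acid family the codon homozygosity is F = sum(p_i^2) over its
    synonymous codons ("raw"), or the small-sample corrected
    (n sum(p_i^2) - 1)/(n - 1) ("bias_corrected", as used by CodonW).  Nc is
    the sum over degeneracy classes of (number of families in the class)
    divided by the class's mean F; one-fold families contribute their count
    directly.  Under the standard code:

        Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

    ranging from 20 (one codon per amino acid) to 61 (uniform synonymous
    usage).  Families that are unobserved (or have n < 2 under the corrected
    estimator) take the mean F of the observed families in their class; a
    wholly unobserved class falls back to the no-bias expectation F = 1/k.
    Stop codons are never counted.  Values above the sense-codon count are
    clamped (with a flag) — the corrected estimator can overshoot on short
    sequences.
    """
    if estimator not in ("raw", "bias_corrected"):
        raise ValueError(f"unknown estimator {estimator!r}")
    seq = cds.residues.upper()
    counts: dict[str, dict[str, int]] = {}
    for i in range(len(seq) // 3):
        codon = seq[3 * i : 3 * i + 3]
        if any(b not in NUCLEOTIDES for b in codon) or code.is_stop(codon):
            continue
        aa = code.translate(codon)
        counts.setdefault(aa, {})[codon] = counts.setdefault(aa, {}).get(codon, 0) + 1
    if not counts:
        raise ValueError(f"no sense codons in {cds.id!r}")

    min_n = 2 if estimator == "bias_corrected" else 1
    f_by_class: dict[int, list[float]] = {}
    used: dict[int, int] = {}
    for aa, fam_size in code.degeneracy_families.items():
        if fam_size == 1:
            continue
        codon_counts = counts.get(aa, {})
        n = sum(codon_counts.values())
        if n < min_n:
            continue
        p = np.array(list(codon_counts.values()), dtype=float) / n
        f = float(np.sum(p**2))
        if estimator == "bias_corrected":
            f = (n * f - 1.0) / (n - 1.0)
            if f <= 0:
                continue  # unusable family, imputed below
        f_by_class.setdefault(fam_size, []).append(f)
        used[fam_size] = used.get(fam_size, 0) + 1

    class_sizes: dict[int, int] = {}
    for fam_size in code.degeneracy_families.values():
        class_sizes[fam_size] = class_sizes.get(fam_size, 0) + 1

    nc = float(class_sizes.get(1, 0))
    mean_f: dict[int, float] = {}
    for k, n_families in sorted(class_sizes.items()):
        if k == 1:
            continue
        observed = f_by_class.get(k)
        fbar = float(np.mean(observed)) if observed else 1.0 / k
        mean_f[k] = fbar
        nc += n_families / fbar

    max_nc = float(len(code.sense_codons))
    clamped = nc > max_nc + 1e-9
    if clamped:
        warnings.warn(
            f"Nc = {nc:.2f} exceeds the number of sense codons; clamping to "
            f"{max_nc:.0f}",
            RuntimeWarning,
        )
        nc = max_nc
    return NcResult(
        Nc=nc,
        family_homozygosity=mean_f,
        families_used=used,
        estimator=estimator,
        clamped=clamped,
    )
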