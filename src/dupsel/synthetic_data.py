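"""Synthetic-data generators mirroring the statistical structure the
analyses assume: codon alignments evolved under omega site-class mixtures,
qPCR experiments with reference genes and planted fold changes, and promoter
fragments with planted IUPAC motifs.

All generators are deterministic under a fixed seed and always emit the
ground truth (site classes, fold changes, motif coordinates) alongside the
data, so recovery tests never have to re-derive it from the outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from dupsel.core_io import (
    NUCLEOTIDES,
    CodonAlignment,
    GeneticCode,
    SequenceRecord,
    STANDARD_CODE,
)
from dupsel.promoter_motifs import (
    IUPAC,
    MotifDefinition,
    _expand_repeats,
    default_motifs,
    reverse_complement,
)
from dupsel.qpcr_expression import AmplificationCurve
from dupsel.site_models import _Propagator, _code_arrays, _raw_rate_matrix


# ---------------------------------------------------------------------------
# Codon alignments


@dataclass(frozen=True)
class CodonSimConfig:
    """Generative settings for a codon alignment under an omega mixture.

    Defaults emulate a small paralog/ortholog set: 3 taxa on a star tree,
    500 codons, kappa 2, purifying selection (omega 0.3), and branch lengths
    giving pairwise synonymous distances around 0.05-0.15.
    """

    n_codons: int = 500
    kappa: float = 2.0
    omega_classes: tuple[tuple[float, float], ...] = ((0.3, 1.0),)
    branch_length: float = 0.05
    tree: dendropy.Tree | None = None
    tip_labels: tuple[str, ...] = ("t1", "t2", "t3")
    pi_mode: str = "uniform"
    pi: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        props = [p for _, p in self.omega_classes]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("omega class proportions must sum to 1")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")


@dataclass(frozen=True)
class SimulatedAlignment:
    alignment: CodonAlignment
    site_classes: np.ndarray  # per-codon index into omega_classes
    root_codons: tuple[str, ...]


def simulate_codon_alignment(
    cfg: CodonSimConfig, code: GeneticCode = STANDARD_CODE
) -> SimulatedAlignment:
    """Evolve an in-frame codon alignment under the configured omega mixture.

    Each site draws its omega class from the mixture proportions; the root
    codon is drawn from the equilibrium frequencies and each branch applies
    the exact transition matrix exp(Q_class * t) of that site's class.  All
    class generators share kappa and pi and are jointly scaled so one unit
    of branch length is one expected substitution per codon under the
    mixture.
    """
    rng = np.random.default_rng(cfg.seed)
    arrays = _code_arrays(code)
    n_states = arrays.n
    if cfg.pi is not None:
        pi = np.asarray(cfg.pi, dtype=float)
        pi = pi / pi.sum()
    elif cfg.pi_mode == "uniform":
        pi = np.full(n_states, 1.0 / n_states)
    else:
        raise ValueError(f"unknown pi_mode {cfg.pi_mode!r}")

    omegas = [w for w, _ in cfg.omega_classes]
    props = np.array([p for _, p in cfg.omega_classes])
    raw = [_raw_rate_matrix(cfg.kappa, w, pi, code) for w in omegas]
    scale = float(np.dot(props, [r for _, r in raw]))
    propagators = [_Propagator(q / scale, pi) for q, _ in raw]

    # tree: explicit, or the unrooted star over tip_labels
    if cfg.tree is not None:
        tips = [leaf.taxon.label for leaf in cfg.tree.leaf_node_iter()]
        branches = None
    else:
        tips = list(cfg.tip_labels)
        branches = [cfg.branch_length] * len(tips)

    classes = rng.choice(len(omegas), size=cfg.n_codons, p=props)
    root = rng.choice(n_states, size=cfg.n_codons, p=pi)

    def evolve(parent_states: np.ndarray, t: float, site_classes: np.ndarray):
        child = np.empty_like(parent_states)
        for c, prop in enumerate(propagators):
            mask = site_classes == c
            if not mask.any():
                continue
            p = prop.transition_matrix(t)
            cum = np.cumsum(p, axis=1)
            u = rng.random(mask.sum())
            rows = parent_states[mask]
            child[mask] = np.array(
                [np.searchsorted(cum[row], x) for row, x in zip(rows, u)]
            )
        np.clip(child, 0, n_states - 1, out=child)
        return child

    tip_states: dict[str, np.ndarray] = {}
    if cfg.tree is None:
        for label, t in zip(tips, branches):
            tip_states[label] = evolve(root, t, classes)
    else:
        tree = cfg.tree
        states = {id(tree.seed_node): root}
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            t = nd.edge.length if nd.edge.length is not None else 0.0
            parent = states[id(nd.parent_node)]
            states[id(nd)] = evolve(parent, t, classes)
            if nd.is_leaf():
                tip_states[nd.taxon.label] = states[id(nd)]

    records = tuple(
        SequenceRecord(
            id=label,
            residues="".join(arrays.codons[s] for s in tip_states[label]),
        )
        for label in tips
    )
    return SimulatedAlignment(
        alignment=CodonAlignment(records=records, n_codons=cfg.n_codons),
        site_classes=classes,
        root_codons=tuple(arrays.codons[s] for s in root),
    )


# ---------------------------------------------------------------------------
# qPCR experiments


@dataclass(frozen=True)
class QpcrSimConfig:
    """A qPCR design: target genes x conditions with planted fold changes.

    ``true_fold_changes[gene][condition]`` is the expression of the gene in
    that condition relative to the first (baseline) condition.  Two
    reference genes are emitted with condition-independent expression.
    Defaults follow the common small design: 3 biological replicates, 2
    technical replicates, efficiency 2, 0.2-cycle Ct noise.
    """

    genes: tuple[str, ...] = ("target1",)
    conditions: tuple[str, ...] = ("day0", "day7")
    replicates: int = 3
    true_fold_changes: dict = field(default_factory=dict)
    reference_genes: tuple[str, str] = ("ref1", "ref2")
    efficiency: float = 2.0
    ct_noise_sd: float = 0.2
    base_ct: float = 24.0
    reference_ct: float = 20.0
    technical_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.5):
            raise ValueError("efficiency must be in (1, 2.5]")
        if self.ct_noise_sd < 0:
            raise ValueError("Ct noise sd must be >= 0")
        if self.replicates < 2:
            raise ValueError("need at least 2 biological replicates")


def simulate_qpcr_experiment(cfg: QpcrSimConfig) -> pd.DataFrame:
    """Tidy (well, gene, sample, ct, efficiency) table with planted truth.

    Target Ct per biological replicate is
    ``base_ct - log_E(fold change) + N(0, ct_noise_sd)``; reference genes sit
    at a constant Ct with the same noise model.  Technical replicates share
    the biological Ct (technical variability is not modelled).  Sample ids
    are ``condition:replicate``.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    well = 0
    log_e = math.log(cfg.efficiency)
    for condition in cfg.conditions:
        for rep in range(1, cfg.replicates + 1):
            sample = f"{condition}:{rep}"
            for gene in cfg.genes + cfg.reference_genes:
                if gene in cfg.reference_genes:
                    mean_ct = cfg.reference_ct
                else:
                    fold = cfg.true_fold_changes.get(gene, {}).get(condition, 1.0)
                    mean_ct = cfg.base_ct - math.log(fold) / log_e
                ct = mean_ct + rng.normal(0.0, cfg.ct_noise_sd)
                for _tech in range(cfg.technical_replicates):
                    well += 1
                    rows.append(
                        {
                            "well": f"w{well:03d}",
                            "gene": gene,
                            "sample": sample,
                            "ct": ct,
                            "efficiency": cfg.efficiency,
                        }
                    )
    return pd.DataFrame(rows)


def ct_table_to_curves(
    table: pd.DataFrame,
    n_cycles: int = 40,
    threshold: float = 1.0,
    baseline: float = 50.0,
    plateau: float = 5000.0,
) -> list[AmplificationCurve]:
    """Embed a Ct table into synthetic exponential amplification curves.

    Each well becomes ``baseline + q0 * E^cycle`` capped at ``plateau``,
    with q0 chosen so the curve crosses ``threshold`` (above baseline) at
    the tabulated Ct.
    """
    curves = []
    for row in table.drop_duplicates(subset="well").itertuples(index=False):
        e = float(row.efficiency)
        q0 = threshold / e ** float(row.ct)
        readings = tuple(
            baseline + min(q0 * e**c, plateau) for c in range(1, n_cycles + 1)
        )
        curves.append(
            AmplificationCurve(
                well_id=str(row.well),
                target_gene=str(row.gene),
                sample_id=str(row.sample),
                fluorescence=readings,
            )
        )
    return curves


# ---------------------------------------------------------------------------
# Promoters


@dataclass(frozen=True)
class PromoterSimConfig:
    """Random promoter fragments with motifs planted at known coordinates.

    ``planted`` lists (motif_name, position, strand) applied to every
    sequence; motif names resolve against ``motifs`` (the packaged default
    set when omitted).  Background composition defaults to uniform.
    """

    n_sequences: int = 2
    length: int = 2000
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted: tuple[tuple[str, int, str], ...] = ()
    motifs: tuple[MotifDefinition, ...] | None = None
    seed: int = 0


@dataclass(frozen=True)
class PlantedMotif:
    sequence_id: str
    motif_name: str
    start: int
    end: int
    strand: str
    realized: str


def simulate_promoters(
    cfg: PromoterSimConfig,
) -> tuple[list[SequenceRecord], list[PlantedMotif]]:
    """i.i.d. background sequences with planted motif instances.

    Each planted motif is realized by drawing uniformly among the bases each
    IUPAC code allows (minus-strand plants insert the reverse complement).
    Overlapping plants are allowed only where the already-placed base is
    compatible with the new motif's code; contradictory overlaps raise.
    Returns the sequences and the ground-truth hit list.
    """
    rng = np.random.default_rng(cfg.seed)
    motif_set = list(cfg.motifs) if cfg.motifs is not None else default_motifs()
    by_name = {m.name: m for m in motif_set}
    bg = np.asarray(cfg.background, dtype=float)
    bg = bg / bg.sum()

    records: list[SequenceRecord] = []
    truth: list[PlantedMotif] = []
    for s in range(cfg.n_sequences):
        seq_id = f"promoter{s + 1}"
        seq = list(rng.choice(list(NUCLEOTIDES), size=cfg.length, p=bg))
        fixed: dict[int, str] = {}
        for motif_name, position, strand in cfg.planted:
            if motif_name not in by_name:
                raise KeyError(f"unknown motif {motif_name!r}")
            consensus = _expand_repeats(by_name[motif_name].consensus).upper()
            if strand == "-":
                consensus = reverse_complement(by_name[motif_name].consensus)
            elif strand != "+":
                raise ValueError(f"strand must be '+' or '-', got {strand!r}")
            if position < 0 or position + len(consensus) > cfg.length:
                raise ValueError(
                    f"planted motif {motif_name!r} at {position} exceeds bounds"
                )
            realized = []
            for offset, code_char in enumerate(consensus):
                allowed = IUPAC[code_char]
                pos = position + offset
                if pos in fixed:
                    if fixed[pos] not in allowed:
                        raise ValueError(
                            f"contradictory overlap at position {pos}: "
                            f"{fixed[pos]!r} not allowed by {motif_name!r}"
                        )
                    base = fixed[pos]
                else:
                    base = allowed[rng.integers(len(allowed))]
                    fixed[pos] = base
                seq[pos] = base
                realized.append(base)
            truth.append(
                PlantedMotif(
                    sequence_id=seq_id,
                    motif_name=motif_name,
                    start=position,
                    end=position + len(consensus),
                    strand=strand,
                    realized="".join(realized),
                )
            )
        records.append(SequenceRecord(id=seq_id, residues="".join(seq)))
    return records, truth
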