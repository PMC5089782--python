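"""End-to-end orchestration: per-gene evolutionary reports and qPCR
expression reports, deterministic under configured seeds.

The selection pipeline runs, for each gene's codon alignment: pairwise
dN/dS with summary, molecular-clock dates per pair, Nc per sequence, the
M0/M1a/M2a ladder with both LRTs, and — when M2a beats M1a at the configured
level — BEB site identification.  The expression pipeline runs quantity
normalization against two reference genes, fold changes versus a baseline
condition, and per-gene permutation tests of each condition against the
baseline (raw p-values by default, Benjamini–Hochberg optionally).
Per-gene failures are isolated and recorded; a report is JSON-serializable
and carries the package version and a hash of its configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from dupsel import codon_evolution as ce
from dupsel import site_models as sm
from dupsel.core_io import build_codon_alignment, read_fasta
from dupsel.qpcr_expression import (
    fold_change_matrix,
    normalize_expression,
    permutation_test,
    quantify_ct_table,
    window_of_linearity,
)
from dupsel.trees import read_newick

log = logging.getLogger("dupsel")


@dataclass
class SelectionConfig:
    """Inputs for the per-gene evolutionary analysis."""

    cds_paths: dict[str, str]  # gene name -> FASTA of aligned CDS
    tree_paths: dict[str, str] = field(default_factory=dict)
    clock_rate: float = ce.DEFAULT_CLOCK_RATE
    models: tuple[str, ...] = ("M0", "M1a", "M2a")
    beb_threshold: float = 0.95
    lrt_alpha: float = 0.05
    n_restarts: int = 5
    seed: int = 0


@dataclass
class ExpressionConfig:
    """Inputs for the qPCR expression analysis."""

    table_path: str  # TSV: well/gene/sample/ct/efficiency, or per-cycle curves
    reference_genes: tuple[str, str] = ("ref1", "ref2")
    baseline: str = "day0"
    n_permutations: int = 10000
    adjust: str = "none"  # or "bh"
    seed: int = 0


def _config_hash(cfg) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class AnalysisReport:
    kind: str
    config_hash: str
    results: dict
    errors: dict
    version: str = "0.1.0"

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(_jsonable(asdict(self)), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _fit_ladder(aln, tree, cfg: SelectionConfig) -> dict:
    out: dict = {"models": {}, "lrt": {}}
    fits: dict[str, sm.SiteModelFit] = {}
    prev = None
    for model in cfg.models:
        fit = sm.fit_site_model(
            aln,
            tree,
            model=model,
            n_restarts=cfg.n_restarts,
            seed=cfg.seed,
            init=prev,
        )
        fits[model] = fit
        prev = fit
        out["models"][model] = {
            "lnl": fit.lnl,
            "kappa": fit.params.kappa,
            "omega_classes": list(fit.params.omega_classes),
            "converged": fit.converged,
        }
    if "M0" in fits and "M1a" in fits:
        lrt = sm.likelihood_ratio_test(fits["M0"], fits["M1a"], df=1)
        out["lrt"]["M1a_vs_M0"] = {"delta": lrt.delta, "df": 1, "p": lrt.p_value}
    if "M1a" in fits and "M2a" in fits:
        lrt = sm.likelihood_ratio_test(fits["M1a"], fits["M2a"], df=2)
        out["lrt"]["M2a_vs_M1a"] = {"delta": lrt.delta, "df": 2, "p": lrt.p_value}
        out["positive_selection"] = lrt.p_value < cfg.lrt_alpha
        if out["positive_selection"]:
            ref = aln.ids[0]
            sites = sm.beb_site_posteriors(
                aln, tree, fits["M2a"], reference_id=ref,
                threshold=cfg.beb_threshold,
            )
            out["beb_flagged_sites"] = [
                {
                    "site": s.site_index,
                    "residue": s.reference_residue,
                    "posterior": s.posterior_positive,
                }
                for s in sites
                if s.flagged
            ]
            out["beb_reference"] = ref
    return out


def run_selection_pipeline(cfg: SelectionConfig) -> AnalysisReport:
    """Distances -> clock -> Nc -> site-model ladder -> LRT/BEB, per gene."""
    results: dict = {}
    errors: dict = {}
    for gene, path in cfg.cds_paths.items():
        try:
            log.info("analyzing %s (%s)", gene, path)
            records = read_fasta(path)
            aln = build_codon_alignment(records)
            tree = None
            if gene in cfg.tree_paths:
                tree = read_newick(Path(cfg.tree_paths[gene]).read_text())
            summary = ce.distance_summary(aln)
            pairs = []
            for a, b in combinations(aln.ids, 2):
                d = ce.ng86_distance(aln, a, b)
                clock = ce.divergence_time(d.dS, cfg.clock_rate)
                pairs.append(
                    {
                        "pair": [a, b],
                        "dN": d.dN,
                        "dS": d.dS,
                        "T_my": clock.T_my,
                    }
                )
            nc = {
                rec.id: ce.effective_number_of_codons(rec).Nc
                for rec in aln.records
            }
            gene_out = {
                "n_codons": aln.n_codons,
                "n_sequences": len(aln.records),
                "mean_dN": summary.mean_dN,
                "sd_dN": summary.sd_dN,
                "mean_dS": summary.mean_dS,
                "sd_dS": summary.sd_dS,
                "pairs": pairs,
                "nc": nc,
                "clock_rate": cfg.clock_rate,
                "seed": cfg.seed,
            }
            gene_out.update(_fit_ladder(aln, tree, cfg))
            results[gene] = gene_out
        except Exception as exc:  # per-gene isolation
            log.warning("gene %s failed: %s", gene, exc)
            errors[gene] = str(exc)
    return AnalysisReport(
        kind="selection",
        config_hash=_config_hash(cfg),
        results=results,
        errors=errors,
    )


def _read_quants(path: str | Path):
    table = pd.read_csv(path, sep="\t")
    cols = set(map(str.lower, table.columns))
    if {"cycle", "value"} <= cols:
        from dupsel.qpcr_expression import AmplificationCurve

        table = table.rename(columns=str.lower)
        quants = []
        for (well, gene, sample), grp in table.groupby(["well", "gene", "sample"]):
            grp = grp.sort_values("cycle")
            curve = AmplificationCurve(
                well_id=str(well),
                target_gene=str(gene),
                sample_id=str(sample),
                fluorescence=tuple(grp["value"].astype(float)),
            )
            quants.append(window_of_linearity(curve))
        return quants
    return quantify_ct_table(table)


def run_expression_pipeline(cfg: ExpressionConfig) -> AnalysisReport:
    """Quantify -> normalize -> fold change -> permutation tests."""
    results: dict = {}
    errors: dict = {}
    quants = _read_quants(cfg.table_path)
    genes = sorted(
        {q.target_gene for q in quants} - set(cfg.reference_genes)
    )
    em = normalize_expression(quants, genes, cfg.reference_genes)
    fc = fold_change_matrix(em, cfg.baseline)
    results["fold_change"] = {
        gene: {cond: float(fc.loc[gene, cond]) for cond in fc.columns}
        for gene in fc.index
    }
    tests: dict = {}
    raw_p = []
    keys = []
    for gene in genes:
        try:
            base_vals = em.condition_values(gene, cfg.baseline)
            for cond in em.conditions():
                if cond == cfg.baseline:
                    continue
                res = permutation_test(
                    em.condition_values(gene, cond),
                    base_vals,
                    n_permutations=cfg.n_permutations,
                    seed=cfg.seed,
                )
                tests[f"{gene}|{cond}"] = {
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "exhaustive": res.exhaustive,
                }
                raw_p.append(res.p_value)
                keys.append(f"{gene}|{cond}")
        except Exception as exc:
            errors[gene] = str(exc)
    if cfg.adjust == "bh" and raw_p:
        order = np.argsort(raw_p)
        m = len(raw_p)
        adj = np.empty(m)
        running = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            i = m - rank_from_top  # 1-based rank of this p value
            running = min(running, raw_p[idx] * m / i)
            adj[idx] = running
        for key, p_adj in zip(keys, adj):
            tests[key]["p_adjusted"] = float(p_adj)
    results["tests"] = tests
    results["normalized"] = {
        gene: {
            f"{cond}:{rep}": float(v)
            for (cond, rep), v in em.values.loc[gene].items()
            if pd.notna(v)
        }
        for gene in em.values.index
    }
    results["seed"] = cfg.seed
    return AnalysisReport(
        kind="expression",
        config_hash=_config_hash(cfg),
        results=results,
        errors=errors,
    )
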