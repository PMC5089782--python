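"""qPCR expression profiling with permutation tests.

Simulates a small qPCR experiment (one induced target, one flat target,
two constitutive reference genes, four biological replicates), converts Ct
values to quantities, normalizes to the reference-gene mean, computes fold
changes versus the baseline condition, and tests each condition against
baseline with an exact permutation test.
"""

from dupsel import (
    fold_change_matrix,
    normalize_expression,
    permutation_test,
    quantify_ct_table,
)
from dupsel.synthetic_data import QpcrSimConfig, simulate_qpcr_experiment

cfg = QpcrSimConfig(
    genes=("induced", "flat"),
    conditions=("day0", "day3", "day7"),
    replicates=4,
    true_fold_changes={"induced": {"day3": 2.0, "day7": 4.0}},
    efficiency=2.0,
    ct_noise_sd=0.2,
    seed=99,
)
table = simulate_qpcr_experiment(cfg)
print(f"simulated {len(table)} wells "
      f"({cfg.technical_replicates} technical x {cfg.replicates} biological)")

quants = quantify_ct_table(table)
em = normalize_expression(quants, list(cfg.genes), cfg.reference_genes)
fc = fold_change_matrix(em, "day0")
print("\nfold change vs day0:")
print(fc.round(2).to_string())

print("\npermutation tests vs day0 (exact):")
for gene in cfg.genes:
    for cond in ("day3", "day7"):
        res = permutation_test(
            em.condition_values(gene, cond), em.condition_values(gene, "day0")
        )
        star = " *" if res.p_value < 0.05 else ""
        print(f"  {gene:<8} {cond}: p = {res.p_value:.4f}{star}")

print(
    "\nThe induced gene recovers its planted 2- and 4-fold changes and is "
    "flagged (p < 0.05); the flat gene is not."
)
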