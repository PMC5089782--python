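"""Site-model test of positive selection with BEB site identification.

Simulates an 800-codon, 3-taxon alignment in which 10% of codons evolve
with omega = 8 (positive selection), fits the M0 -> M1a -> M2a ladder,
runs both likelihood-ratio tests, and reports codons whose Bayes empirical
Bayes posterior of belonging to the positively selected class reaches 0.95.
"""

from dupsel import (
    beb_site_posteriors,
    fit_site_model,
    likelihood_ratio_test,
)
from dupsel.synthetic_data import CodonSimConfig, simulate_codon_alignment

sim = simulate_codon_alignment(
    CodonSimConfig(
        n_codons=800,
        omega_classes=((0.2, 0.6), (1.0, 0.3), (8.0, 0.1)),
        branch_length=0.15,
        kappa=2.0,
        seed=11,
    )
)
aln = sim.alignment

m0 = fit_site_model(aln, model="M0", n_restarts=2, seed=0)
m1a = fit_site_model(aln, model="M1a", n_restarts=2, seed=0, init=m0)
m2a = fit_site_model(aln, model="M2a", n_restarts=2, seed=0, init=m1a)

for fit in (m0, m1a, m2a):
    classes = ", ".join(
        f"omega={w:.2f} (p={p:.2f})" for w, p in fit.params.omega_classes
    )
    print(f"{fit.model}: lnl = {fit.lnl:.2f}  [{classes}]")

lrt1 = likelihood_ratio_test(m0, m1a, df=1)
lrt2 = likelihood_ratio_test(m1a, m2a, df=2)
print(f"\n2dl (M1a-M0) = {lrt1.delta:.2f}  p = {lrt1.p_value:.2e}")
print(f"2dl (M2a-M1a) = {lrt2.delta:.2f}  p = {lrt2.p_value:.2e}")

sites = beb_site_posteriors(aln, None, m2a, reference_id="t1", threshold=0.95)
flagged = [s for s in sites if s.flagged]
truly_positive = {i + 1 for i, c in enumerate(sim.site_classes) if c == 2}
print(f"\nBEB-flagged sites (posterior >= 0.95): {len(flagged)}")
for s in flagged[:10]:
    mark = "true" if s.site_index in truly_positive else "false"
    print(
        f"  site {s.site_index} ({s.reference_residue}) "
        f"posterior {s.posterior_positive:.3f}  [{mark} positive]"
    )

print(
    "\nA significant M2a-vs-M1a test (df 2) is the evidence for positive "
    "selection; flagged sites are the specific residues driving it."
)
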