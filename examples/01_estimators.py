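"""Estimate a planted free-energy difference from synthetic transition work.

Draws a Crooks-consistent bidirectional work set (true ΔG = −2.0 kcal/mol,
1.0 kcal/mol dissipated per switch, 50 transitions per direction — the
default protocol scale) and applies all three estimators.
"""

from neqcycle import SimSpec, estimate_all, sample_works

spec = SimSpec(dG_true=-2.0, dissipation=1.0, n_forward=50, n_reverse=50, seed=7)
ws = sample_works(spec)

for method, est in estimate_all(ws, n_bootstrap=500, seed=7).items():
    print(f"{method:>9}: dG = {est.value:+.3f} ± {est.uncertainty:.3f} kcal/mol")

print(
    "\nBAR uses both work directions and should sit closest to the planted "
    f"value of {spec.dG_true} kcal/mol; Jarzynski and the Gaussian "
    "approximation see only the forward works and carry more bias."
)
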