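"""Estimate a free-energy difference over stratified lambda windows.

Builds a toy harmonic system whose exact answer is known (spring constant
quadrupling: dG = kBT/2 * ln 4), samples 20 forward and 20 backward windows
with Metropolis Monte Carlo, and compares the simple-overlap-sampling (SOS)
and Bennett acceptance-ratio (BAR) estimates against the closed form.
"""

import fepcycle as fc
from fepcycle.constants import KB_KCAL_MOL_K

kbt = 0.596  # kcal/mol, i.e. T ~ 300 K
system = fc.ToyAlchemicalSystem("harmonic", k0=1.0, k1=4.0, T=kbt / KB_KCAL_MOL_K)

fwd = fc.sample_run(system, fc.make_lambda_schedule(20, "forward"), 5000, seed=11)
bwd = fc.sample_run(system, fc.make_lambda_schedule(20, "backward"), 5000, seed=12)

sos = fc.accumulate(fwd, bwd, method="sos", seed=1)
bar = fc.accumulate(fwd, bwd, method="bar", n_bootstrap=30, seed=2)
exact = fc.analytic_free_energy(system)

worst_overlap = min(
    fc.overlap_diagnostic(wf.samples_dU, wb.samples_dU)
    for wf, wb in zip(fwd.windows, reversed(bwd.windows))
)

print(f"analytic dG : {exact:.4f} kcal/mol")
print(f"SOS estimate: {sos.value:.4f} +/- {sos.stderr:.4f} kcal/mol")
print(f"BAR estimate: {bar.value:.4f} +/- {bar.stderr:.4f} kcal/mol")
print(f"worst window overlap score: {worst_overlap:.2f}")
print("Both estimators should land within a few bootstrap standard errors of")
print("the analytic value; overlap near 1 means the 0.05 lambda spacing gives")
print("neighbouring windows well-overlapping energy-gap distributions.")
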