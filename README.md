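# fepcycle

Tools for the energetic dissection of a cation-binding pocket: stratified
alchemical free-energy perturbation (FEP) with the simple overlap sampling
estimator, thermodynamic-cycle ΔΔG analysis of mutations, ΔΔG → pKa-shift
conversion, and one-site isothermal titration calorimetry (ITC) with
cooperativity-fold analysis.

The motivating system is melibiose permease (MelB), a Na⁺/Li⁺/H⁺-coupled
sugar symporter whose cation pocket residues (Asp55, Asp59, Thr121) control
both cation affinity and the thermodynamic coupling between sugar and
cation binding. The package is for computational biophysicists who want the
*analysis* layer of such a study — estimators, cycles, unit conversions and
isotherm fits — exercised and validated on synthetic systems with known
answers rather than on cluster-scale molecular dynamics.

## The science in brief

**Alchemical FEP.** A mutation is encoded as a λ-interpolated Hamiltonian
H(x; λ) = (1−λ)·H₀(x) + λ·H₁(x), stratified into windows (20 windows at
0.05 spacing by default). Sampling runs in both directions; each window's
free-energy change is estimated with simple overlap sampling (SOS),

```
exp(−β ΔG_{i→i+1}) = ⟨exp(−β ΔU/2)⟩_i / ⟨exp(−β ΔU′/2)⟩_{i+1},
```

where ΔU is the energy gap sampled at the lower end and ΔU′ the reverse
gap at the upper end, β = 1/k_BT. Zwanzig exponential averaging and the
Bennett acceptance ratio (BAR) are provided as a baseline and an
independent cross-check. Toy systems (harmonic, Gaussian work model,
double well) with closed-form ΔG validate every estimator statistically.

**Thermodynamic cycles.** The mutation-induced change in cation-binding
free energy is the difference of two alchemical mutation legs:

```
ΔΔG_binding = ΔG_mutation(cation-bound) − ΔG_mutation(cation-unbound),
```

positive ΔΔG meaning weakened binding. For proton binding, ΔΔG converts to
a pKa shift via ΔpKa = ΔΔG / (RT·ln 10); one pKa unit is 1.3643 kcal/mol
at 298.15 K.

**ITC.** One-site independent-binding (Wiseman) isotherms are simulated
with displaced-volume dilution bookkeeping and fitted by least squares,
yielding Ka, ΔH and n, with K_d = 1/K_a. Sugar–cation coupling is
summarised as the cooperativity fold K_d(without cation)/K_d(with cation).

## Worked example

```python
import fepcycle as fc
from fepcycle.constants import KB_KCAL_MOL_K

system = fc.ToyAlchemicalSystem("harmonic", k0=1.0, k1=4.0,
                                T=0.596 / KB_KCAL_MOL_K)
fwd = fc.sample_run(system, fc.make_lambda_schedule(20, "forward"), 5000, seed=11)
bwd = fc.sample_run(system, fc.make_lambda_schedule(20, "backward"), 5000, seed=12)
est = fc.accumulate(fwd, bwd, method="sos", seed=1)
print(f"SOS {est.value:.4f} +/- {est.stderr:.4f}, "
      f"exact {fc.analytic_free_energy(system):.4f}")
```

prints

```
SOS 0.4131 +/- 0.0014, exact 0.4131
```

— the estimator recovers the analytic spring-constant-quadrupling free
energy (k_BT/2 · ln 4) within one bootstrap standard error. The
`examples/` directory has narrative scripts for each capability
(`toy_fep_estimation.py`, `mutation_cycles.py`, `itc_binding_fit.py`), and
the `fepcycle` command exposes the same operations from the shell, e.g.

```bash
fepcycle reproduce --table 3          # recompute every ΔΔG from its legs
fepcycle pka-shift --ddg 2.0          # -> 1.466 pKa units
fepcycle simulate-toy --kt 0.596 --n 5000 --seed 7 | fepcycle estimate --method sos
```

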