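# Methods

## Scope and model of the analysis

The package implements the analysis layer of a mutation-energetics study of
a cation-coupled transporter: free-energy estimation over stratified
alchemical windows, thermodynamic-cycle algebra, pKa-shift conversion, and
one-site calorimetric binding analysis. It deliberately contains no force
field, no molecular system construction and no dynamics engine: everything
that in a production study comes from molecular dynamics is represented
here by one-dimensional toy Hamiltonians whose free-energy differences are
known in closed form, so that every estimator can be checked against an
exact answer.

## Toy alchemical systems (`fepcycle.toy_alchemy`)

The λ-mixed Hamiltonian is H(x; λ) = (1−λ)H₀(x) + λH₁(x), with λ = 0 the
initial variant and λ = 1 the final one. Kinetic terms are omitted: for
mass-preserving mutations the momentum contribution cancels exactly in
every ΔU, so only configurational energies matter.

* **harmonic** — H_k(x) = k/2 (x−c)², exact ΔG = (k_BT/2)·ln(k₁/k₀);
  centre shifts leave ΔG unchanged because each end-state minimum is zero.
* **shifted_gaussian_work** — an abstract per-window work model: forward
  ΔU ~ N(μ, σ²), so each window contributes exactly μ − σ²/(2k_BT); the
  backward distribution N(−μ + σ²/k_BT, σ²) is the one a thermodynamically
  consistent reverse process implies. Because this kind is *defined per
  window*, its analytic total scales with the number of windows traversed
  (`analytic_free_energy(system, n_windows=…)`); the path-independence
  property of the oracle applies to the coordinate-based kinds.
* **double_well** — H(x) = b(x²−1)² + (d/2)x; ΔG by adaptive quadrature of
  the two configurational integrals (relative tolerance 1e-10).

Sampling emulates the stratified protocol: per window an independent
random-walk Metropolis chain at that window's λ, with Boltzmann acceptance,
recording ΔU to the window's other endpoint at every post-burn-in step.
Defaults: 20 windows (0.05 spacing), burn-in 10 % of the requested samples,
no thinning, proposal width 2.4× the local thermal width (the classic
near-optimal 1-D random-walk scaling, acceptance ≈ 45 %). Temperature
defaults to 303.15 K (k_B = 1.987204259×10⁻³ kcal/mol/K); the validation
suite mostly uses k_BT = 0.596 kcal/mol (≈ 300 K) for round numbers.
Reproducibility: one root seed; each window derives an independent child
stream through `numpy.random.SeedSequence([root, direction, window_index])`.
The Gaussian work kind draws i.i.d. samples directly — a Markov chain would
add autocorrelation without adding information.

## Estimators (`fepcycle.estimators`)

* **Zwanzig**: ΔG = −k_BT·ln⟨e^(−βΔU)⟩, the one-directional baseline.
* **SOS**: ΔG = −k_BT·[ln⟨e^(−βΔU/2)⟩_i − ln⟨e^(−βΔU′/2)⟩_{i+1}] per
  window, using samples from both ends; exactly antisymmetric under role
  swap and exactly covariant under ΔU → ΔU + c, ΔU′ → ΔU′ − c.
* **BAR**: the Bennett self-consistency equation solved by bracketed root
  finding (Brent) between the two directional Zwanzig estimates widened by
  50 k_BT; the residual is monotone in ΔG so the root is unique. BAR serves
  as an independent cross-check of SOS, never as its implementation.

All exponential averages run through log-sum-exp; this is part of the
numerical contract (no overflow for |βΔU| ≤ ~700), not an optimisation.
Window pairing in `accumulate` is by λ-interval identity, so ragged or
misordered inputs fail loudly; the first argument's traversal direction
fixes the sign of the total. Errors: nonparametric bootstrap per window
(B = 200 by default, resampling forward and backward samples
independently), combined across windows in quadrature — windows are
sampled independently by construction. The error model behind published
per-window "±" values is generally unstated in experimental reports; the
bootstrap here is a declared, assumption-light choice, not a
reconstruction of any instrument's convention. A window whose exponents
diverge with unanimous sign yields ±∞ with stderr NaN and a logged
warning rather than an exception.

The overlap diagnostic is the histogram intersection (50 shared bins) of
the forward ΔU distribution and the negated backward distribution; values
near 1 indicate the regime where two-sided estimators are reliable.

## Thermodynamic cycles (`fepcycle.cycles`)

ΔΔG_binding = ΔG_mutation(bound) − ΔG_mutation(unbound); positive values
mean the mutation weakens cation binding. Leg errors combine in quadrature
by default (linear addition available, and the reproduction report prints
both, since published rows are not consistent about which rule they used).
pKa conversion uses ΔpKa = ΔΔG/(RT·ln 10) at 298.15 K by default — the
calorimetry temperature, and the value that reproduces the published
roundings of both proton cycles. Cooperativity folds are reported to two
decimals, matching how such tables are printed.

The shipped fixtures record printed per-leg values verbatim. Two
printed-vs-recomputed conflicts are *flagged, never corrected*: one ΔΔG
row recomputes to 6.61 from its own legs against a printed 6.7, and the
proton cycle of the D59C mutant recomputes to 5.0 against a printed 5.1.
In that same proton cycle the printed leg labels name Asp59 although the
cycle concerns protonation of Asp55 (Asp59 being mutated away); the
fixture keeps the printed labels and adds a corrected `site` role, with
roles assigned so the printed positive sign is reproduced.

## ITC (`fepcycle.itc`)

Single class of n independent sites. Cell bookkeeping uses the
displaced-volume ("perfusion") convention for an overfilled cell: after j
constant-volume injections the original contents retain (1−v/V₀)^j, total
titrant approaches the syringe concentration geometrically, and the
per-injection heat is q_j = Q_j − Q_{j−1} + (v_j/V₀)(Q_j+Q_{j−1})/2 with
Q_j the cumulative binding heat from the quadratic-root bound fraction.
Default design values (300 µL cell, 2 µL injections, tens-of-µM titrand,
mM-range titrant for low-affinity sugars) are typical low-volume
nano-calorimeter conditions. Enthalpies are stored signed (exothermic
negative); thermograms follow the instrument orientation in which
exothermic binding is a positive peak, with the flip applied exactly once.

Dilution correction subtracts the mean of the last `m_last = 3` injections
("the last few") from every injection; it is only meaningful when the tail
is past saturation — applying it to an unsaturated low-c titration removes
real signal, which the examples demonstrate.

Fitting is uniform-weight least squares over per-injection heats
(Levenberg–Marquardt, xtol 1e-10, at most 5000 evaluations), with Ka and n
optimised on a log scale for positivity; `fix_n` pins the stoichiometry,
which is the right choice in the low-c regime where n and ΔH are jointly
unresolvable (Kd itself remains identifiable from the isotherm shape).
Auto-initialisation: n = 1, ΔH from the first-injection heat assuming
complete binding, Kd from the total titrant concentration at half
amplitude. Standard errors are delta-method values from the Jacobian. A
thermogram whose largest |q| is below 3× the noise level estimated from
successive differences returns a "no detectable binding" result — the
correct scientific outcome for a non-binding titration — rather than
raising or returning a spurious fit.

## File formats and CLI (`fepcycle.fileio`, `fepcycle.cli`)

Window samples travel in a TSV dialect (`#T`, `#WINDOW λi λj` headers,
`step<TAB>dU` rows; byte-stable writes) or in a read-only parser for
NAMD-style fepout records (window bounds from `#NEW FEP WINDOW:` lines,
samples from the 7th field of `FepEnergy:` records; other fields ignored).
All energies are normalised to kcal/mol at the I/O boundary. Malformed
lines are collected and reported with line numbers. The CLI is a thin
layer over the library; results go to stdout or `--out`, logs to stderr,
so output bytes are deterministic for fixed argv and seed. A two-run
stream (`#RUN forward` / `#RUN backward` sections) lets `simulate-toy`
pipe directly into `estimate`.

## Validation problem sizes

The statistical checks run at sizes chosen to make three-standard-error
tests meaningful on a laptop: 20 windows × 5000 samples/window for the
harmonic benchmark (bootstrap SE ≈ 0.0015 kcal/mol against an exact
0.41312), 10⁵ samples for the Gaussian single-window closed form
(0.58054), 50 000 Metropolis steps for the sampler-variance check (5 %
tolerance), and 100 seeded replicates for the noisy ITC recovery study
(2 % of peak heat as Gaussian noise; median Kd error observed well under
the 15 % bound).

## What the synthetic data does and does not show

The toy Hamiltonians validate estimator correctness, numerical stability,
error calibration and the cycle/conversion algebra. They do not emulate
slow conformational degrees of freedom, soft-core endpoint singularities,
finite sampling correlation across windows, or force-field error — so
passing tests certify the analysis machinery, not the published protein
free-energy legs themselves, which at desk scale are accepted as printed
inputs. Likewise the synthetic thermograms assume ideal mixing, constant
baseline and uncorrelated Gaussian noise; real injections show drift,
peak-integration error and ionic-strength effects (e.g. the choline
chloride supplementation used in cation titrations) that are recorded
nowhere in the model.
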