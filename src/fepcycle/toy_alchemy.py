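"""Synthetic alchemical systems with analytically known free energies.

Real alchemical free-energy perturbation (FEP) stratifies the transformation
between two molecular Hamiltonians H0 and H1 into lambda windows,

    H(x; lambda) = (1 - lambda) * H0(x) + lambda * H1(x),

and samples the energy difference to the neighbouring window at equilibrium
within each window.  This module provides one-dimensional toy Hamiltonians
for which the end-state free-energy difference has a closed form (or is
obtainable by quadrature to near machine precision), a Metropolis Monte Carlo
sampler that emulates the stratified forward/backward window protocol, and
the lambda-schedule bookkeeping.  The toy runs exercise every estimator in
:mod:`fepcycle.estimators` against a known answer, which cluster-scale
molecular dynamics cannot.

Conventions
-----------
* ``lambda = 0`` is the initial variant, ``lambda = 1`` the final variant.
  The physical free-energy difference is convention-independent up to sign.
* Kinetic (momentum) terms are omitted: for mass-preserving mutations they
  cancel exactly in every Delta-U, so only configurational energies matter.
* Energies are kcal/mol, coordinates are Angstrom, temperatures Kelvin.

Three system kinds are provided:

``harmonic``
    H_k(x) = k/2 (x - c)^2 at each end state.  With equal centres the exact
    result is dG = (kB T / 2) ln(k1 / k0); unequal centres leave dG unchanged
    because each end-state minimum is zero.
``shifted_gaussian_work``
    An abstract per-window work model: forward Delta-U samples are Gaussian
    with mean ``mu`` and variance ``sigma2``, so each window contributes
    exactly dG = mu - sigma2 / (2 kB T).  Samples are drawn directly (no
    Markov chain); backward samples are drawn from the distribution that a
    physically consistent reverse process implies.
``double_well``
    H(x) = b (x^2 - 1)^2 + (d/2) x at each end state (barrier ``b``, well
    offset ``d``); dG comes from 1-D quadrature of the configurational
    integrals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad

from .constants import KB_KCAL_MOL_K, DEFAULT_T_SIM, beta

__all__ = [
    "ToyAlchemicalSystem",
    "LambdaSchedule",
    "LambdaWindow",
    "FEPRun",
    "interpolate_hamiltonian",
    "analytic_free_energy",
    "make_lambda_schedule",
    "sample_run",
]

logger = logging.getLogger(__name__)

_KINDS = ("harmonic", "shifted_gaussian_work", "double_well")


@dataclass(frozen=True)
class ToyAlchemicalSystem:
    """A pair of end-state toy Hamiltonians joined by linear lambda mixing.

    Parameters
    ----------
    kind
        One of ``harmonic``, ``shifted_gaussian_work``, ``double_well``.
    k0, k1
        Harmonic spring constants, kcal/mol/A^2 (harmonic kind).
    c0, c1
        Harmonic centres, Angstrom (harmonic kind).
    mu, sigma2
        Per-window forward work mean (kcal/mol) and variance
        (kcal^2/mol^2) for the ``shifted_gaussian_work`` kind.
    barrier0, barrier1
        Barrier heights b of the quartic double wells, kcal/mol.
    offset0, offset1
        Left/right well energy offsets d of the double wells, kcal/mol.
    T
        Temperature in Kelvin.
    """

    kind: str
    k0: float = 1.0
    k1: float = 1.0
    c0: float = 0.0
    c1: float = 0.0
    mu: float = 0.0
    sigma2: float = 0.0
    barrier0: float = 2.0
    barrier1: float = 2.0
    offset0: float = 0.0
    offset1: float = 0.0
    T: float = DEFAULT_T_SIM

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(
                f"unknown system kind {self.kind!r}; expected one of {_KINDS}"
            )
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T} K")
        if self.kind == "harmonic" and (self.k0 <= 0 or self.k1 <= 0):
            raise ValueError(
                f"harmonic spring constants must be positive, got k0={self.k0}, k1={self.k1}"
            )
        if self.kind == "shifted_gaussian_work" and self.sigma2 < 0:
            raise ValueError(f"sigma2 must be non-negative, got {self.sigma2}")
        if self.kind == "double_well" and (self.barrier0 <= 0 or self.barrier1 <= 0):
            raise ValueError("double_well barrier heights must be positive")

    @property
    def kBT(self) -> float:
        """Thermal energy kB*T in kcal/mol."""
        return KB_KCAL_MOL_K * self.T

    def endpoint_energy(self, which: int, x: float | np.ndarray) -> float | np.ndarray:
        """Potential energy of end state 0 or 1 at coordinate(s) ``x``."""
        if which not in (0, 1):
            raise ValueError("endpoint index must be 0 or 1")
        if self.kind == "harmonic":
            k = self.k0 if which == 0 else self.k1
            c = self.c0 if which == 0 else self.c1
            return 0.5 * k * (np.asarray(x, dtype=float) - c) ** 2
        if self.kind == "double_well":
            b = self.barrier0 if which == 0 else self.barrier1
            d = self.offset0 if which == 0 else self.offset1
            xx = np.asarray(x, dtype=float)
            return b * (xx**2 - 1.0) ** 2 + 0.5 * d * xx
        raise ValueError(
            "shifted_gaussian_work is an abstract work model without an "
            "explicit coordinate Hamiltonian"
        )


def interpolate_hamiltonian(
    system: ToyAlchemicalSystem, lam: float, x: float | np.ndarray
) -> float | np.ndarray:
    """Energy of the lambda-mixed Hamiltonian at coordinate ``x``.

    Returns ``(1 - lam) * H0(x) + lam * H1(x)`` in kcal/mol, so lambda = 0
    recovers the initial end state exactly and lambda = 1 the final one.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    if lam == 0.0:
        return system.endpoint_energy(0, x)
    if lam == 1.0:
        return system.endpoint_energy(1, x)
    return (1.0 - lam) * system.endpoint_energy(0, x) + lam * system.endpoint_energy(1, x)


def _config_integral(energy: Callable[[np.ndarray], np.ndarray], b: float) -> float:
    """1-D configurational integral of exp(-beta*E) over the real line."""
    val, _ = quad(lambda x: np.exp(-b * energy(np.asarray(x))), -np.inf, np.inf,
                  epsabs=1e-12, epsrel=1e-10, limit=400)
    return float(val)


def analytic_free_energy(system: ToyAlchemicalSystem, n_windows: int = 1) -> float:
    """Exact end-to-end free-energy difference dG(0 -> 1) in kcal/mol.

    For ``harmonic`` and ``double_well`` systems the result depends only on
    the two end states (``n_windows`` is ignored).  The
    ``shifted_gaussian_work`` kind is defined per window -- each window
    contributes ``mu - sigma2 / (2 kB T)`` -- so its total scales with the
    number of windows traversed.
    """
    kBT = system.kBT
    if system.kind == "harmonic":
        # End-state minima are both zero, so the centre shift contributes
        # nothing: dG depends only on the curvature ratio.
        return 0.5 * kBT * np.log(system.k1 / system.k0)
    if system.kind == "shifted_gaussian_work":
        per_window = system.mu - system.sigma2 / (2.0 * kBT)
        return n_windows * per_window
    if system.kind == "double_well":
        b = beta(system.T)
        z0 = _config_integral(lambda x: system.endpoint_energy(0, x), b)
        z1 = _config_integral(lambda x: system.endpoint_energy(1, x), b)
        return -kBT * np.log(z1 / z0)
    raise ValueError(f"no closed form for kind {system.kind!r}")


@dataclass(frozen=True)
class LambdaSchedule:
    """An ordered lambda grid from one end state to the other.

    ``values`` runs 0 -> 1 for ``direction='forward'`` and 1 -> 0 for
    ``'backward'``; both endpoints are always present exactly.
    """

    values: tuple[float, ...]
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"direction must be forward|backward, got {self.direction!r}")
        v = np.asarray(self.values, dtype=float)
        if v.size < 2:
            raise ValueError("schedule needs at least two lambda values")
        diffs = np.diff(v)
        if self.direction == "forward":
            if not np.all(diffs > 0):
                raise ValueError("forward schedule must be strictly increasing")
            if v[0] != 0.0 or v[-1] != 1.0:
                raise ValueError("forward schedule must start at 0 and end at 1")
        else:
            if not np.all(diffs < 0):
                raise ValueError("backward schedule must be strictly decreasing")
            if v[0] != 1.0 or v[-1] != 0.0:
                raise ValueError("backward schedule must start at 1 and end at 0")

    @property
    def n_windows(self) -> int:
        return len(self.values) - 1

    def windows(self) -> list[tuple[float, float]]:
        """(lambda_i, lambda_next) pairs in traversal order."""
        return list(zip(self.values[:-1], self.values[1:]))

    def reversed(self) -> "LambdaSchedule":
        other = "backward" if self.direction == "forward" else "forward"
        return LambdaSchedule(tuple(reversed(self.values)), other)


def make_lambda_schedule(n_windows: int = 20, direction: str = "forward") -> LambdaSchedule:
    """Evenly spaced schedule; the default reproduces a 20-window, 0.05 grid."""
    if n_windows < 1:
        raise ValueError(f"n_windows must be >= 1, got {n_windows}")
    grid = np.round(np.linspace(0.0, 1.0, n_windows + 1), 12)
    grid[0], grid[-1] = 0.0, 1.0
    values = tuple(float(v) for v in grid)
    if direction == "backward":
        values = tuple(reversed(values))
    return LambdaSchedule(values, direction)


@dataclass
class LambdaWindow:
    """Equilibrium Delta-U samples for one window of an alchemical path.

    ``samples_dU`` holds H(x; lam_next) - H(x; lam_i) in kcal/mol for
    configurations x drawn at ``lam_i`` (post burn-in).
    """

    lam_i: float
    lam_next: float
    samples_dU: np.ndarray
    T: float
    seed: int
    n_equilibrated: int = field(init=False)

    def __post_init__(self) -> None:
        self.samples_dU = np.asarray(self.samples_dU, dtype=float)
        if not (0.0 <= self.lam_i <= 1.0 and 0.0 <= self.lam_next <= 1.0):
            raise ValueError("window lambda values must lie in [0, 1]")
        if self.samples_dU.size < 1:
            raise ValueError("window must hold at least one equilibrated sample")
        if not np.all(np.isfinite(self.samples_dU)):
            raise ValueError(
                f"non-finite Delta-U sample in window ({self.lam_i}, {self.lam_next})"
            )
        self.n_equilibrated = int(self.samples_dU.size)

    @property
    def interval(self) -> tuple[float, float]:
        """The undirected lambda interval, low end first."""
        return (min(self.lam_i, self.lam_next), max(self.lam_i, self.lam_next))


@dataclass
class FEPRun:
    """An ordered set of windows tiling a schedule in one direction."""

    windows: list[LambdaWindow]
    direction: str
    system: ToyAlchemicalSystem | None
    T: float

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("a run needs at least one window")
        for a, bwin in zip(self.windows[:-1], self.windows[1:]):
            if a.lam_next != bwin.lam_i:
                raise ValueError(
                    f"windows do not tile the schedule: window ending at "
                    f"{a.lam_next} followed by window starting at {bwin.lam_i}"
                )
        temps = {w.T for w in self.windows}
        if len(temps) != 1 or self.T not in temps:
            raise ValueError(f"inconsistent temperatures across windows: {sorted(temps)}")

    @property
    def schedule_values(self) -> tuple[float, ...]:
        return tuple([w.lam_i for w in self.windows] + [self.windows[-1].lam_next])


def _metropolis_chain(
    energy: Callable[[float], float],
    x0: float,
    step: float,
    n_steps: int,
    b: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Random-walk Metropolis at inverse temperature ``b``.

    Returns the chain of coordinates (one per step) and the acceptance rate.
    Proposal increments and acceptance uniforms are pre-drawn so the chain is
    bit-reproducible for a fixed generator state.
    """
    xs = np.empty(n_steps)
    proposals = rng.normal(0.0, step, size=n_steps)
    unifs = rng.random(n_steps)
    x = x0
    e = energy(x)
    accepted = 0
    for i in range(n_steps):
        x_new = x + proposals[i]
        e_new = energy(x_new)
        if e_new <= e or unifs[i] < np.exp(-b * (e_new - e)):
            x, e = x_new, e_new
            accepted += 1
        xs[i] = x
    return xs, accepted / n_steps


def _window_seed(root_seed: int, window_index: int, direction: str) -> int:
    """Deterministic per-window child seed.

    Splitting rule: spawn key = (root, direction flag, window index) fed to
    ``numpy.random.SeedSequence``, collapsed to one 32-bit state word.  The
    rule is part of the reproducibility contract: same root seed, direction
    and window index always yield the same stream, and distinct windows get
    independent streams.
    """
    flag = 0 if direction == "forward" else 1
    ss = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, flag, window_index])
    return int(ss.generate_state(1)[0])


def sample_run(
    system: ToyAlchemicalSystem,
    schedule: LambdaSchedule,
    n_samples_per_window: int,
    seed: int,
    burn_in: int | None = None,
    step_scale: float = 2.4,
) -> FEPRun:
    """Generate equilibrium Delta-U samples for every window of ``schedule``.

    For coordinate-based kinds each window runs an independent Metropolis
    chain at its own lambda, with Boltzmann acceptance at ``system.T``, and
    records Delta-U to the window's other endpoint at every post-burn-in
    step.  ``burn_in`` defaults to 10% of the requested samples.  For the
    ``shifted_gaussian_work`` kind, Delta-U values are drawn directly from
    the stated Gaussian (forward) or from the physically consistent reverse
    distribution N(-mu + sigma2/kBT, sigma2) (backward); no chain is run.

    The proposal width is ``step_scale`` times the local thermal width
    (sqrt(kBT / k(lambda)) for harmonic; a fixed 0.5 A for double wells);
    2.4 sigma is the classic near-optimal random-walk scaling in 1-D.
    A window whose acceptance rate drops below 1% is logged as a warning
    with its index.
    """
    if n_samples_per_window < 1:
        raise ValueError("n_samples_per_window must be >= 1")
    if burn_in is None:
        burn_in = max(1, n_samples_per_window // 10)

    b = beta(system.T)
    windows: list[LambdaWindow] = []

    for j, (lam_i, lam_next) in enumerate(schedule.windows()):
        wseed = _window_seed(seed, j, schedule.direction)
        rng = np.random.default_rng(wseed)

        if system.kind == "shifted_gaussian_work":
            sd = float(np.sqrt(system.sigma2))
            if schedule.direction == "forward":
                mean = system.mu
            else:
                # Reverse work distribution implied by a Gaussian forward
                # process (Crooks relation): dU' ~ N(-mu + beta sigma2, sigma2).
                mean = -system.mu + b * system.sigma2
            dU = mean + sd * rng.standard_normal(n_samples_per_window)
            windows.append(LambdaWindow(lam_i, lam_next, dU, system.T, wseed))
            continue

        def energy_at(lam: float) -> Callable[[float], float]:
            return lambda x: float(interpolate_hamiltonian(system, lam, x))

        if system.kind == "harmonic":
            k_here = (1.0 - lam_i) * system.k0 + lam_i * system.k1
            width = np.sqrt(1.0 / (b * k_here))
            x0 = (1.0 - lam_i) * system.c0 + lam_i * system.c1
        else:  # double_well
            width = 0.5
            x0 = 1.0

        n_steps = n_samples_per_window + burn_in
        xs, acc = _metropolis_chain(
            energy_at(lam_i), x0, step_scale * width, n_steps, b, rng
        )
        if acc < 0.01:
            logger.warning(
                "window %d (lambda %.3f -> %.3f): Metropolis acceptance rate "
                "%.3f%% below 1%%", j, lam_i, lam_next, 100 * acc,
            )
        x_eq = xs[burn_in:]
        dU = np.asarray(interpolate_hamiltonian(system, lam_next, x_eq)) - np.asarray(
            interpolate_hamiltonian(system, lam_i, x_eq)
        )
        windows.append(LambdaWindow(lam_i, lam_next, dU, system.T, wseed))

    return FEPRun(windows=windows, direction=schedule.direction, system=system, T=system.T)
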