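"""One-site isothermal titration calorimetry: simulation and fitting.

An ITC experiment titrates a ligand (titrant, in the syringe) into a
receptor solution (titrand, in the cell) and records the heat evolved per
injection.  For a single class of ``n`` independent sites with association
constant Ka and molar enthalpy dH, the bound concentration after injection
j follows from the binding quadratic

    B_j = ( S_j + X_j + Kd - sqrt( (S_j + X_j + Kd)^2 - 4 S_j X_j ) ) / 2,

where S_j = n * M_j is the total site concentration, X_j the total titrant
concentration and Kd = 1/Ka, all in the cell after j injections.  The
cumulative heat is Q_j = B_j * dH * V0 and the per-injection observed heat
carries a displaced-volume correction

    q_j = Q_j - Q_{j-1} + (v_j / V0) * (Q_j + Q_{j-1}) / 2 ,

the standard "perfusion" bookkeeping for an overfilled cell in which each
injection expels an equal volume of partially-saturated solution.  Cell
contents dilute geometrically: M_j = M_0 * (1 - v/V0)^j for constant
injection volume v.

Sign convention: enthalpies are stored signed (exothermic dH < 0);
thermograms follow the instrument orientation in which exothermic binding
appears as a *positive* heat peak.  The flip happens exactly once, at the
simulation/fitting boundary.

Heats of dilution are handled as the instrument software does: the mean
heat of the last few post-saturation injections is subtracted from every
injection before fitting (:func:`subtract_dilution`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import DEFAULT_T_BINDING

__all__ = [
    "ITCDesign",
    "ITCThermogram",
    "OneSiteParams",
    "OneSiteFitResult",
    "simulate_thermogram",
    "subtract_dilution",
    "fit_one_site",
]

KCAL_TO_UJ = 4.184e9  # 1 kcal = 4184 J = 4.184e9 microjoule


@dataclass(frozen=True)
class ITCDesign:
    """Cell/syringe concentrations and the injection schedule.

    Concentrations are molar (M); volumes in microlitres.  The default
    2 uL injection aliquot matches a low-volume nano-calorimeter protocol.
    """

    V0_uL: float
    cell_conc_M: float
    syringe_conc_M: float
    n_injections: int
    inj_vol_uL: float = 2.0
    T: float = DEFAULT_T_BINDING

    def __post_init__(self) -> None:
        if min(self.V0_uL, self.cell_conc_M, self.syringe_conc_M, self.inj_vol_uL) <= 0:
            raise ValueError("volumes and concentrations must all be positive")
        if self.n_injections < 1:
            raise ValueError("need at least one injection")
        if self.total_injected_uL > self.V0_uL:
            warnings.warn(
                f"total injected volume {self.total_injected_uL:.1f} uL exceeds "
                f"the cell volume {self.V0_uL:.1f} uL", stacklevel=2,
            )

    @property
    def total_injected_uL(self) -> float:
        return self.n_injections * self.inj_vol_uL

    def concentrations_after(self) -> tuple[np.ndarray, np.ndarray]:
        """Total (titrand, titrant) cell concentrations after each injection.

        Geometric displaced-volume dilution: after j constant-volume
        injections the original cell contents retain a fraction
        (1 - v/V0)^j, and the total titrant approaches the syringe
        concentration as X0 * (1 - (1 - v/V0)^j).
        """
        j = np.arange(1, self.n_injections + 1)
        d = (1.0 - self.inj_vol_uL / self.V0_uL) ** j
        return self.cell_conc_M * d, self.syringe_conc_M * (1.0 - d)

    def molar_ratios(self) -> np.ndarray:
        m, x = self.concentrations_after()
        return x / m


@dataclass
class ITCThermogram:
    """Per-injection heats in instrument orientation (exothermic positive)."""

    heats_uJ: np.ndarray
    molar_ratio: np.ndarray
    dilution_corrected: bool = False

    def __post_init__(self) -> None:
        self.heats_uJ = np.asarray(self.heats_uJ, dtype=float)
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        if self.heats_uJ.shape != self.molar_ratio.shape:
            raise ValueError("heats and molar ratios must have equal length")

    @property
    def n_injections(self) -> int:
        return int(self.heats_uJ.size)


@dataclass(frozen=True)
class OneSiteParams:
    """Single-class independent-site binding parameters."""

    Ka: float  # 1/M
    dH: float  # kcal/mol of injectant, signed (exothermic < 0)
    n: float = 1.0  # stoichiometry, sites per titrand molecule

    def __post_init__(self) -> None:
        if self.Ka <= 0:
            raise ValueError(f"Ka must be positive, got {self.Ka}")
        if self.n <= 0:
            raise ValueError(f"n must be positive, got {self.n}")

    @property
    def Kd(self) -> float:
        """Dissociation constant, M: Kd = 1/Ka."""
        return 1.0 / self.Ka


def _bound_concentration(sites: np.ndarray, titrant: np.ndarray, Kd: float) -> np.ndarray:
    """Stable root of the binding quadratic, elementwise (concentrations in M)."""
    s = sites + titrant + Kd
    disc = s * s - 4.0 * sites * titrant
    if np.any(disc < 0):
        raise AssertionError("binding quadratic discriminant negative")
    return 0.5 * (s - np.sqrt(disc))


def _model_heats_uJ(params: OneSiteParams, design: ITCDesign) -> np.ndarray:
    """Noiseless per-injection heats in instrument orientation."""
    m_tot, x_tot = design.concentrations_after()
    bound = _bound_concentration(params.n * m_tot, x_tot, params.Kd)
    v0_L = design.V0_uL * 1e-6
    q_cum = bound * v0_L * params.dH  # kcal, signed
    q_prev = np.concatenate(([0.0], q_cum[:-1]))
    frac = design.inj_vol_uL / design.V0_uL
    q_inj = q_cum - q_prev + frac * 0.5 * (q_cum + q_prev)
    return -q_inj * KCAL_TO_UJ  # instrument: exothermic (negative dH) -> positive


def simulate_thermogram(
    params: OneSiteParams,
    design: ITCDesign,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ITCThermogram:
    """Simulate a one-site titration thermogram.

    ``noise_sd`` is the Gaussian measurement noise per injection in uJ,
    added with a fixed seed so replicates are reproducible.
    """
    q = _model_heats_uJ(params, design)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        q = q + noise_sd * rng.standard_normal(q.size)
    return ITCThermogram(q, design.molar_ratios(), dilution_corrected=False)


def subtract_dilution(thermogram: ITCThermogram, m_last: int = 3) -> ITCThermogram:
    """Subtract the mean heat of the final ``m_last`` injections everywhere.

    Emulates the background correction in which the residual heat of the
    last few injections -- past saturation, where no further binding occurs
    -- estimates the heat of dilution per injection.
    """
    n = thermogram.n_injections
    if not 1 <= m_last < n:
        raise ValueError(f"m_last must be in [1, {n - 1}], got {m_last}")
    offset = float(np.mean(thermogram.heats_uJ[-m_last:]))
    return ITCThermogram(
        thermogram.heats_uJ - offset, thermogram.molar_ratio.copy(),
        dilution_corrected=True,
    )


@dataclass
class OneSiteFitResult:
    """Outcome of a one-site fit; ``no_binding`` marks a flat thermogram."""

    params: OneSiteParams | None
    stderr: dict[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    no_binding: bool = False

    @property
    def Kd(self) -> float:
        if self.params is None:
            raise ValueError("no detectable binding: Kd undefined")
        return self.params.Kd


def _auto_init(thermogram: ITCThermogram, design: ITCDesign) -> OneSiteParams:
    """Heuristic starting point: n = 1, dH from the first injection,
    Ka from the molar ratio at half amplitude."""
    q = thermogram.heats_uJ
    # moles of titrant delivered per injection
    inj_mol = design.syringe_conc_M * design.inj_vol_uL * 1e-6
    dh0 = (-q[0] / KCAL_TO_UJ) / inj_mol  # kcal/mol if everything bound
    if dh0 == 0.0:
        dh0 = -1.0
    # total titrant concentration at which |q| has dropped to half its peak
    _, x_tot = design.concentrations_after()
    absq = np.abs(q)
    half = 0.5 * absq.max()
    below = np.nonzero(absq <= half)[0]
    i_half = int(below[0]) if below.size else design.n_injections - 1
    kd0 = max(x_tot[i_half], 1e-12)
    return OneSiteParams(Ka=1.0 / kd0, dH=float(dh0), n=1.0)


def fit_one_site(
    thermogram: ITCThermogram,
    design: ITCDesign,
    init: OneSiteParams | None = None,
    fix_n: float | None = None,
    flat_threshold: float = 3.0,
) -> OneSiteFitResult:
    """Weighted least-squares fit of the one-site model to a thermogram.

    Uniform weights; parameters are (Ka, dH, n) with Ka optimised on a log
    scale for positivity.  ``fix_n`` pins the stoichiometry (useful in the
    low-c regime where n and dH are jointly unresolvable).  Convergence:
    relative parameter change below 1e-10 within 500 iterations.

    A flat thermogram -- max |q| below ``flat_threshold`` times the noise
    level estimated from successive differences -- returns a
    ``no_binding`` result rather than raising, mirroring titrations where
    the ligand simply does not bind.
    """
    q = np.asarray(thermogram.heats_uJ, dtype=float)
    if q.size < 5:
        raise ValueError(f"need at least 5 usable injections, got {q.size}")
    if not np.all(np.isfinite(q)):
        raise ValueError("thermogram contains non-finite heats")

    noise_est = float(np.std(np.diff(q)) / math.sqrt(2.0)) if q.size > 1 else 0.0
    if np.max(np.abs(q)) <= flat_threshold * noise_est:
        return OneSiteFitResult(
            params=None, no_binding=True,
            diagnostics={"reason": "no detectable binding",
                         "noise_estimate_uJ": noise_est,
                         "max_abs_heat_uJ": float(np.max(np.abs(q)))},
        )

    p0 = init if init is not None else _auto_init(thermogram, design)

    def pack(p: OneSiteParams) -> np.ndarray:
        theta = [math.log(p.Ka), p.dH]
        if fix_n is None:
            theta.append(math.log(p.n))
        return np.asarray(theta)

    def unpack(theta: np.ndarray) -> OneSiteParams:
        n = math.exp(theta[2]) if fix_n is None else fix_n
        return OneSiteParams(Ka=math.exp(theta[0]), dH=float(theta[1]), n=n)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _model_heats_uJ(unpack(theta), design) - q

    sol = least_squares(
        residuals, pack(p0), method="lm",
        xtol=1e-10, ftol=1e-14, gtol=1e-14, max_nfev=500 * 10,
    )
    if not sol.success:
        raise RuntimeError(
            f"one-site fit did not converge: {sol.message}; "
            f"last iterate {unpack(sol.x)}"
        )
    params = unpack(sol.x)

    # delta-method standard errors on the natural scale
    dof = max(q.size - sol.x.size, 1)
    sigma2 = float(np.sum(sol.fun**2)) / dof
    try:
        cov_theta = sigma2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        se_theta = np.sqrt(np.maximum(np.diag(cov_theta), 0.0))
        stderr = {"Ka": params.Ka * se_theta[0], "dH": float(se_theta[1])}
        stderr["n"] = params.n * se_theta[2] if fix_n is None else 0.0
        stderr["Kd"] = params.Kd * se_theta[0]
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        stderr = {}

    diagnostics = {
        "n_evaluations": int(sol.nfev),
        "rmsd_uJ": math.sqrt(float(np.mean(sol.fun**2))),
        "noise_estimate_uJ": noise_est,
        "message": sol.message,
    }
    return OneSiteFitResult(params=params, stderr=stderr, diagnostics=diagnostics)
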