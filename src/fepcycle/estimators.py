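"""Free-energy estimators over stratified lambda windows.

The quantity of interest is the Gibbs free-energy change of an alchemical
transformation, accumulated window by window.  Three estimators are
provided:

* :func:`zwanzig` -- one-directional exponential averaging,
  dG = -kB T ln < exp(-beta dU) >, the baseline that a two-sided estimator
  improves upon;
* :func:`sos_window` -- simple overlap sampling (SOS), which combines
  half-exponent averages from samples at both ends of a window,

      exp(-beta dG) = < exp(-beta dU / 2) >_i / < exp(-beta dU' / 2) >_{i+1},

  where dU is sampled at the lower end and dU' = H_i - H_{i+1} at the upper
  end;
* :func:`bar_window` -- the Bennett acceptance-ratio (BAR) minimum-variance
  estimator, solved by bisection of its self-consistency equation, used as
  an independent cross-check of SOS.

Every exponential average goes through a log-sum-exp formulation: this is
part of the numerical contract, not an optimisation, so that |beta dU| up to
~700 produces no intermediate overflow.  Per-window standard errors come
from a nonparametric bootstrap; window errors combine in quadrature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .constants import beta
from .toy_alchemy import FEPRun

__all__ = [
    "FreeEnergyEstimate",
    "zwanzig",
    "sos_window",
    "bar_window",
    "bootstrap_stderr",
    "accumulate",
    "overlap_diagnostic",
]

logger = logging.getLogger(__name__)


@dataclass
class FreeEnergyEstimate:
    """A total dG with its per-window decomposition.

    ``per_window`` rows are (lam_lo, lam_hi, dG_window, stderr_window), with
    dG oriented along the forward (lambda-increasing) direction.  The total
    always equals the sum of window contributions.
    """

    value: float
    stderr: float
    method: str
    per_window: list[tuple[float, float, float, float]]
    T: float
    n_bootstrap: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("zwanzig_fwd", "zwanzig_bwd", "sos", "bar"):
            raise ValueError(f"unknown method tag {self.method!r}")
        total = sum(w[2] for w in self.per_window)
        if self.per_window and not math.isclose(total, self.value, abs_tol=1e-9):
            raise ValueError(
                f"total {self.value} does not match per-window sum {total}"
            )
        if np.isfinite(self.stderr) and self.stderr < 0:
            raise ValueError("stderr must be non-negative")


def _validate_samples(samples, name: str) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name}: empty sample list")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: non-finite Delta-U samples present")
    return arr


def _log_mean_exp(a: np.ndarray) -> float:
    """log( mean(exp(a)) ) without overflow."""
    return float(logsumexp(a) - np.log(a.size))


def zwanzig(samples_dU, T: float) -> float:
    """One-directional exponential-averaging estimate of dG (kcal/mol)."""
    dU = _validate_samples(samples_dU, "zwanzig")
    b = beta(T)
    return -(1.0 / b) * _log_mean_exp(-b * dU)


def _sos_value(dU_fwd: np.ndarray, dU_bwd: np.ndarray, b: float) -> float:
    lf = _log_mean_exp(-0.5 * b * dU_fwd)
    lb = _log_mean_exp(-0.5 * b * dU_bwd)
    return -(1.0 / b) * (lf - lb)


def sos_window(
    samples_fwd,
    samples_bwd,
    T: float,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Simple-overlap-sampling estimate for one window.

    ``samples_fwd`` are dU = H_{i+1} - H_i drawn at the lower end state;
    ``samples_bwd`` are dU' = H_i - H_{i+1} drawn at the upper end state.
    Returns (dG_i->i+1, bootstrap stderr) in kcal/mol.
    """
    dU_f = _validate_samples(samples_fwd, "sos_window forward")
    dU_b = _validate_samples(samples_bwd, "sos_window backward")
    b = beta(T)
    value = _sos_value(dU_f, dU_b, b)
    stderr = bootstrap_stderr(
        (dU_f, dU_b), lambda f, r: _sos_value(f, r, b), B=n_bootstrap, seed=seed
    )
    return value, stderr


def _bar_imbalance(dG: float, dU_f: np.ndarray, dU_b: np.ndarray, b: float) -> float:
    """Signed Bennett self-consistency residual; monotone increasing in dG."""
    M = np.log(dU_f.size / dU_b.size)
    # log of sum of Fermi functions, stabilised: log(1/(1+e^x)) = -log1p(e^x)
    lhs = logsumexp(-np.logaddexp(0.0, M + b * dU_f - b * dG))
    rhs = logsumexp(-np.logaddexp(0.0, -M + b * dU_b + b * dG))
    return lhs - rhs


def _bar_value(dU_f: np.ndarray, dU_b: np.ndarray, b: float, tol: float) -> float:
    kBT = 1.0 / b
    z_f = -kBT * _log_mean_exp(-b * dU_f)
    z_b = kBT * _log_mean_exp(-b * dU_b)
    lo = min(z_f, z_b) - 50.0 * kBT
    hi = max(z_f, z_b) + 50.0 * kBT
    f_lo = _bar_imbalance(lo, dU_f, dU_b, b)
    f_hi = _bar_imbalance(hi, dU_f, dU_b, b)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise RuntimeError(
            "Bennett self-consistency equation has no sign change in the "
            f"bracket [{lo:.4f}, {hi:.4f}] kcal/mol (residuals {f_lo:.3e}, "
            f"{f_hi:.3e}); the window ends likely do not overlap"
        )
    return float(brentq(_bar_imbalance, lo, hi, args=(dU_f, dU_b, b), xtol=tol))


def bar_window(
    samples_fwd,
    samples_bwd,
    T: float,
    tol: float = 1e-8,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Bennett acceptance-ratio estimate for one window.

    Solves the self-consistency condition by bracketed root finding between
    the two directional Zwanzig estimates widened by 50 kB T.  Returns
    (dG, bootstrap stderr).
    """
    dU_f = _validate_samples(samples_fwd, "bar_window forward")
    dU_b = _validate_samples(samples_bwd, "bar_window backward")
    b = beta(T)
    value = _bar_value(dU_f, dU_b, b, tol)
    stderr = bootstrap_stderr(
        (dU_f, dU_b), lambda f, r: _bar_value(f, r, b, tol), B=n_bootstrap, seed=seed
    )
    return value, stderr


def bootstrap_stderr(window_samples, estimator, B: int = 200, seed: int = 0) -> float:
    """Nonparametric bootstrap standard error of a per-window estimator.

    ``window_samples`` is either a single array or a (forward, backward)
    pair; each array is resampled with replacement independently, ``B``
    times, and the standard deviation of the estimator over the resamples is
    returned.  Deterministic for a fixed seed.
    """
    if B < 2:
        raise ValueError(f"bootstrap needs B >= 2 resamples, got {B}")
    if isinstance(window_samples, tuple):
        arrays = [np.asarray(a, dtype=float) for a in window_samples]
    else:
        arrays = [np.asarray(window_samples, dtype=float)]
    rng = np.random.default_rng(seed)
    estimates = np.empty(B)
    for i in range(B):
        resampled = [a[rng.integers(0, a.size, a.size)] for a in arrays]
        estimates[i] = estimator(*resampled)
    return float(np.std(estimates, ddof=1))


def _pair_windows(run_primary: FEPRun, run_reverse: FEPRun):
    """Match windows of opposite-direction runs by lambda-interval identity."""
    if run_primary.direction == run_reverse.direction:
        raise ValueError(
            f"runs must traverse opposite directions, both are {run_primary.direction!r}"
        )
    if run_primary.T != run_reverse.T:
        raise ValueError(
            f"temperature mismatch between runs: {run_primary.T} K vs {run_reverse.T} K"
        )
    rev_map = {w.interval: w for w in run_reverse.windows}
    primary_ivs = {w.interval for w in run_primary.windows}
    if primary_ivs != set(rev_map):
        only_p = sorted(primary_ivs - set(rev_map))
        only_r = sorted(set(rev_map) - primary_ivs)
        raise ValueError(
            "lambda schedules do not match between directions; "
            f"intervals only in first run: {only_p}; only in second run: {only_r}"
        )
    return [(w, rev_map[w.interval]) for w in run_primary.windows]


def accumulate(
    run_fwd: FEPRun,
    run_bwd: FEPRun,
    method: str = "sos",
    n_bootstrap: int = 200,
    seed: int = 0,
) -> FreeEnergyEstimate:
    """Accumulate per-window estimates into a total dG.

    The total is oriented along the traversal direction of the first run:
    passing the 0->1 run first yields dG(0 -> 1); swapping the arguments
    yields the exact negation.  In each window the first run supplies the
    averages at that window's sampling end and the second run the averages
    at the opposite end; pairing is by lambda-interval identity, so ragged
    or mismatched schedules raise rather than silently misalign.  Total
    stderr combines window stderrs in quadrature (windows are sampled
    independently).
    """
    if method not in ("sos", "bar"):
        raise ValueError(f"method must be 'sos' or 'bar', got {method!r}")
    pairs = _pair_windows(run_fwd, run_bwd)

    per_window: list[tuple[float, float, float, float]] = []
    est = sos_window if method == "sos" else bar_window
    for j, (wp, wr) in enumerate(pairs):
        dg, se = est(
            wp.samples_dU, wr.samples_dU, run_fwd.T,
            n_bootstrap=n_bootstrap, seed=seed + j,
        )
        if not np.isfinite(dg):
            logger.warning(
                "window %s: unanimous-sign divergent exponents, dG=%s with "
                "stderr NaN", wp.interval, dg,
            )
            se = float("nan")
        per_window.append((wp.lam_i, wp.lam_next, dg, se))

    total = float(sum(w[2] for w in per_window))
    stderr = float(np.sqrt(np.nansum([w[3] ** 2 for w in per_window])))
    if any(np.isnan(w[3]) for w in per_window):
        stderr = float("nan")
    return FreeEnergyEstimate(
        value=total, stderr=stderr, method=method, per_window=per_window,
        T=run_fwd.T, n_bootstrap=n_bootstrap,
    )


def overlap_diagnostic(samples_fwd, samples_bwd, n_bins: int = 50) -> float:
    """Histogram-intersection overlap score in [0, 1] for one window.

    Compares the forward dU distribution against the negated backward dU'
    distribution on a shared grid; 1 means the two end states sample the
    same energy-gap region (the regime where SOS is reliable), 0 means
    disjoint supports.
    """
    dU_f = _validate_samples(samples_fwd, "overlap forward")
    dU_b = -_validate_samples(samples_bwd, "overlap backward")
    lo = min(dU_f.min(), dU_b.min())
    hi = max(dU_f.max(), dU_b.max())
    if lo == hi:  # all mass at one point in both distributions
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p, _ = np.histogram(dU_f, bins=edges)
    q, _ = np.histogram(dU_b, bins=edges)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.minimum(p, q).sum())
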