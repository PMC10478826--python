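"""Biexponential blood input function fitted to the descending-aorta curve.

The aorta VOI concentration is taken as the blood concentration; the model is

    C_blood(t) = A1 * exp(-lambda1 * t) + A2 * exp(-lambda2 * t)

with all four parameters non-negative and rates in 1/h (physical decay of
177Lu is folded into the rates because activities are measured in situ).
Fitting uses bounded trust-region least squares with multi-start
initialization from log-linear fits to the early and late curve segments;
residuals carry unit weights. Data are normalized by their maximum before
fitting and the amplitudes rescaled afterwards, which makes the fit exactly
scale-equivariant.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .core import BloodModel, FitError, TimeActivityCurve

__all__ = ["fit_blood", "eval_blood", "integrate_blood", "LU177_PHYSICAL_LAMBDA"]

# 177Lu physical decay (T1/2 = 6.647 d). Concentrations are measured in situ,
# so no fitted rate can be slower than physical decay; using this as the lower
# bound keeps the extrapolated tail integral finite and physical.
LU177_PHYSICAL_LAMBDA = np.log(2) / (6.647 * 24.0)

# With 4 samples and 4 parameters the least-squares problem can reach exact
# interpolants whose fast component back-extrapolates to absurd t=0
# concentrations, exploding the [0, inf) integral that dosimetry needs.
# Two guards apply: amplitudes are capped at this multiple of the curve
# maximum (first scan ~4 h => minimum fast half-life ~25-40 min), and, in the
# package's standard units, the t=0 concentration A1+A2 cannot exceed the
# administered activity dissolved in a minimal whole-blood volume of ~1 L,
# i.e. 1.0 MBq/cm^3 per GBq administered.
BLOOD_PEAK_RATIO_CAP = 100.0
MAX_INITIAL_CONCENTRATION = 1.0

# residual differences below this fraction of the (normalized) curve maximum
# cannot be resolved by quantitative SPECT; such fits are treated as ties
EQUIVALENT_RESIDUAL_FRACTION = 1e-3


def eval_blood(model: BloodModel, t) -> float | np.ndarray:
    """Evaluate the blood curve at time(s) ``t`` (hours, >= 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = model.A1 * np.exp(-model.lambda1 * t) + model.A2 * np.exp(-model.lambda2 * t)
    return float(out) if out.ndim == 0 else out


def integrate_blood(model: BloodModel) -> float:
    """Closed-form time integral of the blood curve over [0, inf), in
    concentration * hours."""
    if model.lambda1 <= 0 or model.lambda2 <= 0:
        raise ValueError("rates must be positive for the integral to converge")
    return model.A1 / model.lambda1 + model.A2 / model.lambda2


def _biexp(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    return p[0] * np.exp(-p[1] * t) + p[2] * np.exp(-p[3] * t)


def _loglinear_rate(t: np.ndarray, y: np.ndarray) -> float:
    """Decay rate from a log-linear fit; falls back to 1/span on bad data."""
    mask = y > 0
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(y[mask]), 1)[0]
        if slope < 0:
            return -slope
    return 1.0 / (t[-1] - t[0])


def _amplitudes_nnls(t: np.ndarray, y: np.ndarray, l1: float, l2: float) -> np.ndarray:
    basis = np.column_stack([np.exp(-l1 * t), np.exp(-l2 * t)])
    coef, _ = optimize.nnls(basis, y)
    return coef


def _single_exp_fit(
    t: np.ndarray, y: np.ndarray, amp_cap: float = np.inf
) -> tuple[np.ndarray, float]:
    """Best single-exponential fit (A, lam); returns params and SSR."""
    lam0 = _loglinear_rate(t, y)
    a0 = min(max(y.max(), 1e-12), amp_cap * 0.999)

    def resid(p):
        return p[0] * np.exp(-p[1] * t) - y

    def jac(p):
        e = np.exp(-p[1] * t)
        return np.column_stack([e, -p[0] * t * e])

    best = None
    for lam in (lam0 / 3, lam0, lam0 * 3):
        try:
            sol = optimize.least_squares(
                resid, jac=jac, x0=[a0, max(lam, LU177_PHYSICAL_LAMBDA)],
                bounds=([0, LU177_PHYSICAL_LAMBDA], [amp_cap, np.inf]),
                method="trf", xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=120,
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("single-exponential reference fit failed")
    return best.x, 2.0 * best.cost


def fit_blood(
    curve: TimeActivityCurve,
    max_initial_concentration: float | None = MAX_INITIAL_CONCENTRATION,
) -> BloodModel:
    """Fit the biexponential input function to an aorta curve.

    Requires >= 4 samples with a positive first concentration. Returns the
    multi-start bounded least-squares winner with the fast term first
    (lambda1 >= lambda2); the residual norm never exceeds that of the best
    single-exponential fit, which is included as a fallback candidate.

    ``max_initial_concentration`` bounds each amplitude, i.e. the
    back-extrapolated t=0 concentration, in the curve's own units; the
    default assumes the package's standard MBq/cm^3 per GBq units (pass
    ``None`` for arbitrary-unit data, dropping the physical cap).
    """
    curve.require_samples(4, "biexponential blood fit")
    t = curve.t
    c = curve.c
    if c[0] <= 0:
        raise FitError("blood curve must start with a positive concentration")

    scale = float(c.max())
    y = c / scale

    # Rate guesses from the early and late segments of the curve.
    n = len(t)
    k = max(2, n // 2)
    l_fast = _loglinear_rate(t[:k], y[:k])
    l_slow = _loglinear_rate(t[-k:], y[-k:])
    if l_fast <= l_slow:
        l_fast = 3.0 * l_slow

    def resid(p):
        return _biexp(t, p) - y

    def jac(p):
        e1 = np.exp(-p[1] * t)
        e2 = np.exp(-p[3] * t)
        return np.column_stack([e1, -p[0] * t * e1, e2, -p[2] * t * e2])

    lam_lo = LU177_PHYSICAL_LAMBDA
    candidates = []
    for lf, ls in [(l_fast, l_slow), (3 * l_fast, l_slow), (l_fast, l_slow / 3),
                   (10 * l_fast, l_slow), (l_fast / 3, 3 * l_slow)]:
        lf = max(lf, lam_lo * 2)
        ls = max(ls, lam_lo)
        if lf <= ls:
            lf = 3 * ls
        a = _amplitudes_nnls(t, y, lf, ls)
        a = np.maximum(a, 1e-12 * y.max())
        candidates.append([a[0], lf, a[1], ls])

    amp_cap = BLOOD_PEAK_RATIO_CAP
    if max_initial_concentration is not None:
        amp_cap = min(amp_cap, max_initial_concentration / scale)
        if amp_cap <= y.max():
            raise FitError(
                "curve maximum already exceeds max_initial_concentration; "
                "check units"
            )
    lb = np.array([0.0, lam_lo, 0.0, lam_lo])
    ub = np.array([amp_cap, np.inf, amp_cap, np.inf])
    solutions = []
    for x0 in candidates:
        x0 = np.minimum(x0, ub * 0.999)
        try:
            sol = optimize.least_squares(
                resid, jac=jac, x0=x0, bounds=(lb, ub), method="trf",
                xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=160,
            )
        except ValueError:
            continue
        if np.all(np.isfinite(sol.x)) and np.isfinite(sol.cost):
            solutions.append(sol)
    if not solutions:
        raise FitError("biexponential blood fit did not converge from any start")
    min_cost = min(s.cost for s in solutions)
    # Solutions whose residuals differ by less than 0.1% of the curve maximum
    # are observationally equivalent (quantitative SPECT is accurate to a few
    # percent at best); among them prefer the most conservative
    # extrapolation, i.e. the smallest [0, inf) integral. This suppresses
    # exact interpolants that hide an implausibly large bolus before the
    # first scan.
    band = 0.5 * EQUIVALENT_RESIDUAL_FRACTION ** 2 * len(t)
    near = [s for s in solutions if s.cost <= min_cost + band]
    best = min(near, key=lambda s: s.x[0] / s.x[1] + s.x[2] / s.x[3])

    (a_se, lam_se), ssr_se = _single_exp_fit(t, y, amp_cap=amp_cap)
    ssr_bi = 2.0 * best.cost
    if ssr_bi <= ssr_se:
        A1, l1, A2, l2 = best.x
        if l1 < l2:  # enforce fast-first ordering by swapping the terms
            A1, l1, A2, l2 = A2, l2, A1, l1
        if l1 == l2:
            # amplitudes are exchangeable at equal rates; merge into one term
            A1, A2, l2 = A1 + A2, 0.0, l1 / 2
    else:
        A1, l1, A2, l2 = a_se, lam_se, 0.0, lam_se / 2
    l1 = max(l1, 1e-12)
    l2 = min(max(l2, 1e-12), l1)
    return BloodModel(A1=A1 * scale, A2=A2 * scale, lambda1=l1, lambda2=l2)
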