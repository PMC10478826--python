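"""One-compartment model separating specific from blood-borne uptake.

The specific (receptor-bound) activity concentration in a skeletal site or
tumor obeys

    dC_specific/dt = k1 * f * C_blood(t) - k2 * C_specific(t),   C_specific(0) = 0

where ``f`` maps the blood concentration onto the nonspecific (plasma-borne)
concentration inside the marrow cavity, ``k1`` is the uptake rate and ``k2``
the release rate. With a biexponential input the ODE has the closed form

    C_specific(t) = k1 * f * sum_i A_i / (k2 - lambda_i)
                    * (exp(-lambda_i t) - exp(-k2 t)),

with the limit term k1*f*A_i*t*exp(-k2 t) when k2 ~ lambda_i. The measured
tissue curve is modelled as f * C_blood + C_specific, and (k1, k2, f) are
found by a grid search minimizing the RMSE at the observed time points,
followed by one local refinement pass on a 5x finer grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import BloodModel, CompartmentFit, FitError, TimeActivityCurve

__all__ = [
    "specific_concentration",
    "tissue_model",
    "fit_compartment",
    "effective_half_life",
    "normalize_to_max",
    "halflife_difference_regression",
    "SearchGrid",
    "DEFAULT_GRID",
]

# below this separation the (k2 - lambda) denominator is treated as degenerate
DEGENERATE_RATE_TOL = 1e-10


def _s_basis(blood: BloodModel, k2s: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Closed-form response sum_i A_i/(k2-l_i)(e^(-l_i t) - e^(-k2 t)).

    ``k2s`` has shape (m,), ``t`` shape (T,); the result is (m, T). The
    specific concentration is k1 * f * this basis.
    """
    k2s = np.atleast_1d(np.asarray(k2s, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    ek2 = np.exp(-np.outer(k2s, t))  # (m, T)
    out = np.zeros((k2s.size, t.size))
    for amp, lam in ((blood.A1, blood.lambda1), (blood.A2, blood.lambda2)):
        delta = k2s - lam
        degen = np.abs(delta) < DEGENERATE_RATE_TOL
        safe = np.where(degen, 1.0, delta)
        term = (amp / safe)[:, None] * (np.exp(-lam * t)[None, :] - ek2)
        limit = amp * t[None, :] * ek2
        out += np.where(degen[:, None], limit, term)
    return out


def specific_concentration(blood: BloodModel, params: CompartmentFit, t):
    """Closed-form specific activity concentration at time(s) ``t`` (hours)."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    out = params.k1 * params.f * _s_basis(blood, np.array([params.k2]), t_arr)[0]
    return float(out[0]) if np.ndim(t) == 0 else out


def tissue_model(blood: BloodModel, params: CompartmentFit, t):
    """Modelled measured concentration: nonspecific f*C_blood plus specific."""
    from .blood import eval_blood

    return params.f * eval_blood(blood, t) + specific_concentration(blood, params, t)


@dataclass(frozen=True)
class SearchGrid:
    """Grid-search design for (k1, k2, f).

    Defaults: k1 log-spaced over [1e-4, 1] /h (25 points), k2 log-spaced over
    [1e-4, 0.2] /h (25 points) bracketing the observed effective half-lives,
    f linear over [0, 1] in steps of 0.02. One refinement pass shrinks each
    axis step by 5x around the coarse winner.
    """

    k1: np.ndarray = field(default_factory=lambda: np.geomspace(1e-4, 1.0, 25))
    k2: np.ndarray = field(default_factory=lambda: np.geomspace(1e-4, 0.2, 25))
    f: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 1.0, 51))


DEFAULT_GRID = SearchGrid()


def _rmse_cube(blood, t, obs, k1s, k2s, fs) -> np.ndarray:
    """RMSE of the tissue model on every (k1, k2, f) grid point; shape
    (len(k1s), len(k2s), len(fs))."""
    from .blood import eval_blood

    B = eval_blood(blood, t)  # (T,)
    S = _s_basis(blood, k2s, t)  # (m, T)
    model = fs[None, None, :, None] * (
        B[None, None, None, :] + k1s[:, None, None, None] * S[None, :, None, :]
    )
    resid = model - obs[None, None, None, :]
    return np.sqrt(np.mean(resid * resid, axis=-1))


def _argmin_first(cube: np.ndarray) -> tuple[int, int, int]:
    """First occurrence of the minimum in C order, i.e. ties break toward
    smaller k1, then smaller k2, then smaller f (axes are ascending)."""
    idx = int(np.argmin(cube))
    return np.unravel_index(idx, cube.shape)  # type: ignore[return-value]


def fit_compartment(
    blood: BloodModel,
    observed: TimeActivityCurve,
    grid: SearchGrid = DEFAULT_GRID,
) -> CompartmentFit:
    """Grid-search fit of (k1, k2, f) to an observed tissue curve.

    Minimizes the unweighted RMSE between the observed concentrations and
    ``tissue_model`` at the observed times over the coarse grid, then over a
    5x finer local grid around the winner (which always contains the winner
    itself, so refinement never worsens the fit). An all-zero curve returns
    k1 = 0, f = 0 with a warning.
    """
    observed.require_samples(3, "compartment fit")
    t = observed.t
    obs = observed.c
    if np.all(obs == 0):
        warnings.warn(
            f"all-zero curve ({observed.patient_id}/{observed.tissue.value}); "
            "returning k1=0, f=0", stacklevel=2,
        )
        k2_center = float(np.sqrt(grid.k2[0] * grid.k2[-1]))
        return CompartmentFit(k1=0.0, k2=k2_center, f=0.0, rmse=0.0,
                              site=observed.tissue)

    cube = _rmse_cube(blood, t, obs, grid.k1, grid.k2, grid.f)
    if not np.any(np.isfinite(cube)):
        raise FitError("compartment grid search produced no finite RMSE")

    # sparse 4-point designs can leave several shallow near-optimal basins;
    # refine the best few coarse candidates, not just the single winner
    order = np.argsort(cube, axis=None, kind="stable")[:5]
    r1 = (grid.k1[-1] / grid.k1[0]) ** (1.0 / (len(grid.k1) - 1))
    r2 = (grid.k2[-1] / grid.k2[0]) ** (1.0 / (len(grid.k2) - 1))
    df = float(grid.f[1] - grid.f[0]) if len(grid.f) > 1 else 0.02
    steps = np.arange(-5, 6) / 5.0

    best: tuple[float, float, float] | None = None
    best_rmse = np.inf

    def consider(k1, k2, f, rmse):
        nonlocal best, best_rmse
        if rmse < best_rmse or (rmse == best_rmse
                                and best is not None and (k1, k2, f) < best):
            best, best_rmse = (k1, k2, f), rmse

    for flat in order:
        i, j, l = np.unravel_index(flat, cube.shape)
        local = (float(grid.k1[i]), float(grid.k2[j]), float(grid.f[l]))
        local_rmse = float(cube[i, j, l])
        consider(*local, local_rmse)
        # two passes of 5x finer local grids descending this candidate's basin
        for ratio1, ratio2, fstep in ((r1 ** 0.2, r2 ** 0.2, df / 5.0),
                                      (r1 ** 0.04, r2 ** 0.04, df / 25.0)):
            k1_fine = np.unique(np.clip(local[0] * ratio1 ** steps,
                                        grid.k1[0], grid.k1[-1]))
            k2_fine = np.unique(np.clip(local[1] * ratio2 ** steps,
                                        grid.k2[0], grid.k2[-1]))
            f_fine = np.unique(np.clip(local[2] + steps * fstep, 0.0, 1.0))
            fine = _rmse_cube(blood, t, obs, k1_fine, k2_fine, f_fine)
            fi, fj, fl = _argmin_first(fine)
            if fine[fi, fj, fl] <= local_rmse:
                local = (float(k1_fine[fi]), float(k2_fine[fj]),
                         float(f_fine[fl]))
                local_rmse = float(fine[fi, fj, fl])
            consider(*local, local_rmse)

    return CompartmentFit(k1=best[0], k2=best[1], f=best[2],
                          rmse=best_rmse, site=observed.tissue)


def effective_half_life(
    curve_or_model,
    cutoff: float = 48.0,
    t_max: float = 170.0,
    dt: float = 1.0,
) -> float:
    """Effective half-life (hours) from a log-linear fit to late samples.

    Accepts either a measured :class:`TimeActivityCurve`, whose samples
    strictly later than ``cutoff`` are used directly (at least two required,
    all positive), or a ``(BloodModel, CompartmentFit)`` pair, whose specific
    concentration is evaluated on a ``dt``-spaced grid over
    (cutoff, t_max] before the same fit.
    """
    if isinstance(curve_or_model, TimeActivityCurve):
        t = curve_or_model.t
        c = curve_or_model.c
        mask = t > cutoff
        t, c = t[mask], c[mask]
    else:
        blood, params = curve_or_model
        t = np.arange(cutoff + dt, t_max + dt / 2, dt)
        c = specific_concentration(blood, params, t)
    if len(t) < 2:
        raise FitError(f"need >= 2 samples later than {cutoff} h")
    if np.any(c <= 0):
        raise FitError("non-positive concentrations in the late-time window")
    slope = np.polyfit(t, np.log(c), 1)[0]
    if slope >= 0:
        raise FitError("late-time activity does not decay; no half-life")
    return float(np.log(2) / -slope)


def normalize_to_max(curve: TimeActivityCurve) -> TimeActivityCurve:
    """Scale a curve so its maximum concentration is 1 (for biodistribution
    comparison across tissues)."""
    peak = max(curve.concentrations)
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero curve")
    return TimeActivityCurve(
        patient_id=curve.patient_id,
        tissue=curve.tissue,
        times=curve.times,
        concentrations=tuple(c / peak for c in curve.concentrations),
    )


def halflife_difference_regression(pairs) -> tuple[float, float, float, float]:
    """OLS of (T_site - T_tumor) on T_tumor across patients.

    ``pairs`` is a sequence of (T_eff_site, T_eff_tumor) in hours. Returns
    (slope, intercept, Pearson r, two-sided p-value). A negative slope means
    marrow retention is relatively prolonged in patients whose tumors clear
    quickly, the pattern expected if tumor-released 177Lu recirculates to
    marrow.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (T_site, T_tumor) pairs")
    t_site, t_tumor = arr[:, 0], arr[:, 1]
    diff = t_site - t_tumor
    if np.var(t_tumor) == 0 or np.var(diff) == 0:
        raise ValueError("degenerate variance; regression undefined")
    res = stats.linregress(t_tumor, diff)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue), float(res.pvalue))
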