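"""Kety-Tofts fitting of DCE-MRI concentration curves.

Stages mirror a standard preclinical DCE workflow:

1. per-voxel bolus-arrival time from a half-logistic enhancement fit,
2. global AIF calibration against a segmented skeletal-muscle curve with
   fixed reference muscle parameters,
3. bounded voxel-wise Kety-Tofts fits with the calibrated, arrival-shifted
   AIF, and
4. kep = Ktrans/ve with physiological-range validity.

``fit_kety_tofts`` fits a single curve by bounded trust-region least
squares with three Ktrans multi-starts.  ``fit_kety_tofts_map`` solves the
same objective for whole maps with a vectorised profiled search: Ktrans is
linear in the model for fixed kep, so each voxel reduces to a 1-D search
over a shared logarithmic kep grid (closed-form Ktrans, parabolic
refinement, and a constrained refit on the ve = 1 boundary when needed).
The two routes agree to fitting tolerance and are cross-checked in tests.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import least_squares

from .. import defaults
from ..kinetics import AIFModel, kety_tofts_basis, kety_tofts_curve

__all__ = [
    "estimate_bolus_arrival",
    "estimate_arrival_map",
    "calibrate_aif",
    "fit_kety_tofts",
    "fit_kety_tofts_map",
    "compute_kep",
]

NO_ARRIVAL = float("nan")


def _half_logistic_models(t_s, t0_grid, r_grid):
    """Unit-amplitude half-logistic curves for all (t0, r) combinations.

    f(t) = (1 - exp(-r*(t-t0))) / (1 + exp(-r*(t-t0))) for t >= t0, else 0.
    Returns array of shape (len(t0_grid)*len(r_grid), len(t_s)) and the
    matching list of (t0, r).
    """
    combos = [(t0, r) for t0 in t0_grid for r in r_grid]
    M = np.zeros((len(combos), t_s.shape[0]))
    for i, (t0, r) in enumerate(combos):
        tau = t_s - t0
        e = np.exp(-r * np.clip(tau, 0.0, None))
        M[i] = np.where(tau >= 0, (1.0 - e) / (1.0 + e), 0.0)
    return M, combos


def estimate_arrival_map(
    curves: np.ndarray,
    t_s: np.ndarray,
    noise_floor: float | None = None,
    r_grid=(0.005, 0.015, 0.04, 0.1, 0.3),
) -> np.ndarray:
    """Bolus-arrival time for each curve in ``curves`` (n, n_frames).

    Scans every frame time as a candidate onset t0 of a half-logistic
    enhancement, with the amplitude profiled out in closed form, and returns
    the least-squares t0 per curve.  Curves whose total enhancement is below
    the noise floor (default: 3x a robust noise estimate from first
    differences) get NaN (no-arrival flag).  Rates are in 1/s.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    t_s = np.asarray(t_s, dtype=float)
    t0_grid = t_s[1:-2]
    M, combos = _half_logistic_models(t_s, t0_grid, r_grid)
    mm = (M * M).sum(axis=1)
    C = curves @ M.T                                     # (n, n_combo)
    A = np.clip(C, 0.0, None) / mm[None, :]
    sse = (curves ** 2).sum(axis=1, keepdims=True) - np.clip(C, 0.0, None) ** 2 / mm[None, :]
    best = np.argmin(sse, axis=1)
    t0 = np.array([combos[b][0] for b in best])

    if noise_floor is None:
        diffs = np.diff(curves, axis=1)
        sigma = 1.4826 * np.median(np.abs(diffs - np.median(diffs, axis=1, keepdims=True)),
                                   axis=1) / np.sqrt(2.0)
        noise_floor = 3.0 * sigma
    enhancement = curves.max(axis=1) - np.median(curves[:, : max(3, curves.shape[1] // 10)], axis=1)
    t0 = np.where(enhancement > np.maximum(noise_floor, 1e-12), t0, NO_ARRIVAL)
    return t0


def estimate_bolus_arrival(ct_curve: np.ndarray, t_s: np.ndarray,
                           noise_floor: float | None = None) -> float:
    """Arrival time (s) of a single tissue curve; NaN when no enhancement."""
    nf = None if noise_floor is None else np.asarray([noise_floor])
    return float(estimate_arrival_map(ct_curve[None, :], t_s, noise_floor=nf)[0])


def calibrate_aif(
    base_aif: AIFModel,
    muscle_curve: np.ndarray,
    t_s: np.ndarray,
    ktrans_ref: float = 0.1,
    ve_ref: float = 0.1,
    clamp: tuple[float, float] = (0.1, 10.0),
) -> AIFModel:
    """Scale the population AIF so reference muscle kinetics match the data.

    The Kety-Tofts model is linear in Cp, so the least-squares scale is the
    inner-product ratio against the unit-scale muscle model.  Scales outside
    ``clamp`` raise a warning and are clamped.
    """
    model = kety_tofts_curve(ktrans_ref, ve_ref, np.asarray(t_s, float), base_aif)
    denom = float(model @ model)
    if denom == 0:
        raise ValueError("reference muscle model is identically zero")
    s = float(np.asarray(muscle_curve, float) @ model) / denom
    lo, hi = clamp
    if not (lo <= s <= hi):
        warnings.warn(f"AIF calibration scale {s:.3g} outside [{lo}, {hi}]; clamped")
        s = float(np.clip(s, lo, hi))
    return AIFModel(base=base_aif.base, scale=base_aif.scale * s,
                    arrival_s=base_aif.arrival_s)


def fit_kety_tofts(
    ct_curve: np.ndarray,
    aif: AIFModel,
    arrival_s: float | None = None,
    t_s: np.ndarray | None = None,
    bounds=((defaults.KTRANS_BOUNDS[0], 1e-6), (defaults.KTRANS_BOUNDS[1], 1.0)),
    ktrans_starts=(0.01, 0.1, 1.0),
    ve_start: float = 0.3,
    supersample: int = 16,
) -> tuple[float, float, float]:
    """Bounded trust-region Kety-Tofts fit of one concentration curve.

    Returns ``(ktrans, ve, residual_norm)``.  Multi-starts over Ktrans; ties
    broken by lowest residual then lowest Ktrans.  An identically-zero curve
    returns Ktrans = 0 with ve = NaN (unidentifiable).
    """
    y = np.asarray(ct_curve, dtype=float)
    if t_s is None:
        t_s = np.arange(y.shape[0]) * defaults.DCE_DT_S
    if not np.any(y != 0):
        return 0.0, float("nan"), 0.0
    lo = np.array([bounds[0][0], bounds[0][1]])
    hi = np.array([bounds[1][0], bounds[1][1]])

    def resid(p):
        return kety_tofts_curve(p[0], p[1], t_s, aif, arrival_s, supersample) - y

    candidates = []
    for k0 in ktrans_starts:
        x0 = np.clip([k0, ve_start], lo + 1e-9, hi)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        candidates.append((sol.cost, sol.x[0], sol.x))
    if not candidates:
        return float("nan"), float("nan"), float("nan")
    candidates.sort(key=lambda c: (c[0], c[1]))
    cost, _, x = candidates[0]
    return float(x[0]), float(x[1]), float(np.sqrt(2.0 * cost))


def fit_kety_tofts_map(
    curves: np.ndarray,
    aif: AIFModel,
    arrival_s: np.ndarray | float | None = None,
    t_s: np.ndarray | None = None,
    kep_grid: np.ndarray | None = None,
    supersample: int = 16,
) -> dict[str, np.ndarray]:
    """Vectorised Kety-Tofts fit of many curves (n, n_frames).

    Profiles Ktrans out in closed form on a shared log-kep grid per unique
    arrival time, refines kep parabolically, and enforces the physiological
    bounds (Ktrans in [0, 5], ve in (0, 1]); voxels pushed past ve = 1 are
    refit on that boundary.  Returns arrays 'ktrans', 've', 'residual' and a
    boolean 'identifiable' (False where the curve carries no enhancement).
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    n = curves.shape[0]
    if t_s is None:
        t_s = np.arange(curves.shape[1]) * defaults.DCE_DT_S
    if kep_grid is None:
        kep_grid = np.geomspace(5e-4, 20.0, 600)
    logk = np.log(kep_grid)
    h = logk[1] - logk[0]

    if arrival_s is None:
        arrival = np.full(n, aif.arrival_s, dtype=float)
    else:
        arrival = np.broadcast_to(np.asarray(arrival_s, dtype=float), (n,)).copy()
    # No-arrival voxels are fitted with the nominal arrival and flagged later.
    arrival = np.where(np.isnan(arrival), aif.arrival_s, arrival)
    fine_dt = (t_s[1] - t_s[0]) / supersample
    arrival = np.round(arrival / fine_dt) * fine_dt

    ktrans = np.zeros(n)
    kep_hat = np.zeros(n)
    resid = np.zeros(n)
    yy = (curves ** 2).sum(axis=1)

    for a in np.unique(arrival):
        sel = np.flatnonzero(arrival == a)
        B = kety_tofts_basis(kep_grid, t_s, aif, a, supersample)   # (K, T)
        bb = (B * B).sum(axis=1)
        C = curves[sel] @ B.T                                      # (m, K)
        Cp = np.clip(C, 0.0, None)
        sse = yy[sel, None] - Cp ** 2 / bb[None, :]
        best = np.clip(np.argmin(sse, axis=1), 1, kep_grid.shape[0] - 2)
        idx = np.arange(sel.shape[0])
        f0, f1, f2 = sse[idx, best - 1], sse[idx, best], sse[idx, best + 1]
        denom = f0 - 2 * f1 + f2
        shift = np.where(np.abs(denom) > 0, 0.5 * (f0 - f2) / np.where(denom == 0, 1, denom), 0.0)
        kep_sel = np.exp(logk[best] + np.clip(shift, -1, 1) * h)
        # Recompute the profiled Ktrans at the refined kep.
        Bref = kety_tofts_basis(kep_sel, t_s, aif, a, supersample)  # (m, T)
        bbr = (Bref * Bref).sum(axis=1)
        cr = np.clip((curves[sel] * Bref).sum(axis=1), 0.0, None)
        kt = np.where(bbr > 0, cr / np.where(bbr == 0, 1, bbr), 0.0)
        sse_ref = yy[sel] - np.where(bbr > 0, cr ** 2 / np.where(bbr == 0, 1, bbr), 0.0)
        ktrans[sel] = kt
        kep_hat[sel] = kep_sel
        resid[sel] = np.sqrt(np.clip(sse_ref, 0.0, None))

        # Enforce ve <= 1 (kep >= Ktrans): refit offenders on the boundary
        # ve = 1, where the model is Ktrans * basis(kep = Ktrans).
        off = np.flatnonzero(kt > kep_sel)
        if off.size:
            kg = np.geomspace(1e-3, defaults.KTRANS_BOUNDS[1], 300)
            Bb = kety_tofts_basis(kg, t_s, aif, a, supersample)
            model = kg[:, None] * Bb
            sse_b = yy[sel][off, None] - 2 * curves[sel][off] @ model.T \
                + (model * model).sum(axis=1)[None, :]
            bi = np.argmin(sse_b, axis=1)
            ktrans[sel[off]] = kg[bi]
            kep_hat[sel[off]] = kg[bi]
            resid[sel[off]] = np.sqrt(np.clip(sse_b[np.arange(off.size), bi], 0.0, None))

    ktrans = np.clip(ktrans, *defaults.KTRANS_BOUNDS)
    identifiable = ktrans > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ve = np.where(identifiable, ktrans / kep_hat, np.nan)
    ve = np.where(identifiable, np.clip(ve, 0.0, 1.0), np.nan)
    return {"ktrans": ktrans, "ve": ve, "residual": resid,
            "identifiable": identifiable}


def compute_kep(ktrans: np.ndarray, ve: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """kep = Ktrans/ve with the physiological validity predicate 0 < kep < 5.

    Returns ``(kep, valid)``; voxels with ve = 0 (or non-finite inputs) are
    invalid, as are kep values at or beyond the open interval bounds.
    """
    ktrans = np.asarray(ktrans, dtype=float)
    ve = np.asarray(ve, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        kep = np.where(ve != 0, ktrans / ve, 0.0)
    lo, hi = defaults.KEP_BOUNDS
    valid = np.isfinite(ktrans) & np.isfinite(ve) & (ve != 0) & (kep > lo) & (kep < hi)
    return kep, valid
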