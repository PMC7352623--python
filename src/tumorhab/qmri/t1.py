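"""T1 mapping from magnitude inversion-recovery data.

Model: S(TI) = |S0 * (1 - 2*exp(-TI/T1) + exp(-TR/T1))|, the standard
inversion-recovery snapshot expression with incomplete longitudinal
recovery between repetitions.

For fixed T1 the amplitude S0 is linear in the *signed* model, but the
magnitude operator couples them; with S0 > 0 the profile over T1 still has
a closed-form amplitude, S0*(T1) = <y, |g(T1)|> / <|g(T1)|, |g(T1)|>, so
the fit reduces to a 1-D search.  A dense logarithmic T1 grid (a dense
variant of multi-start initialisation) followed by parabolic refinement of
the profiled residual locates the optimum.
"""

from __future__ import annotations

import numpy as np

from .. import defaults

__all__ = ["fit_t1"]


def _profile_grids(ti_s, tr_s, t1_grid):
    g = 1.0 - 2.0 * np.exp(-ti_s[None, :] / t1_grid[:, None]) \
        + np.exp(-tr_s / t1_grid)[:, None]
    return np.abs(g)


def fit_t1(
    ir_series: np.ndarray,
    inversion_times_ms=defaults.INVERSION_TIMES_MS,
    tr_ms: float = defaults.IR_TR_MS,
    mask: np.ndarray | None = None,
    t1_grid_s: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit T1 and S0 voxel-wise from a magnitude IR series.

    Returns ``(t1_map_s, s0_map, valid_mask)``; voxels where the profiled
    residual search fails to bracket an optimum (flat or degenerate series)
    are flagged invalid.
    """
    ti_s = np.asarray(inversion_times_ms, dtype=float) / 1000.0
    if ti_s.shape[0] < 3:
        raise ValueError("at least three inversion times are required")
    tr_s = tr_ms / 1000.0
    series = np.asarray(ir_series, dtype=float)
    spatial = series.shape[:-1]
    if series.shape[-1] != ti_s.shape[0]:
        raise ValueError("series last axis must match inversion times")
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, bool)

    if t1_grid_s is None:
        t1_grid_s = np.geomspace(0.05, 10.0, 400)
    G = _profile_grids(ti_s, tr_s, t1_grid_s)          # (K, nTI)
    gg = (G * G).sum(axis=1)                            # (K,)

    Y = series[mask]                                    # (n, nTI)
    t1_map = np.zeros(spatial, dtype=float)
    s0_map = np.zeros(spatial, dtype=float)
    valid = np.zeros(spatial, dtype=bool)
    if Y.shape[0] == 0:
        return t1_map, s0_map, valid

    C = Y @ G.T                                         # (n, K)
    s0_grid = np.clip(C, 0.0, None) / gg[None, :]
    sse = (Y * Y).sum(axis=1, keepdims=True) - np.clip(C, 0.0, None) ** 2 / gg[None, :]
    best = np.argmin(sse, axis=1)

    # Two rounds of local log-T1 grid refinement around the coarse minimum.
    logt = np.log(t1_grid_s)
    h = logt[1] - logt[0]
    t1_hat = t1_grid_s[np.clip(best, 1, t1_grid_s.shape[0] - 2)]
    for _ in range(2):
        local = t1_hat[:, None] * np.exp(np.linspace(-h, h, 25))[None, :]
        g = np.abs(1.0 - 2.0 * np.exp(-ti_s[None, None, :] / local[..., None])
                   + np.exp(-tr_s / local)[..., None])          # (n, 25, nTI)
        c = np.clip(np.einsum("ij,ikj->ik", Y, g), 0.0, None)
        sse_loc = (Y * Y).sum(axis=1, keepdims=True) - c ** 2 / (g * g).sum(axis=2)
        t1_hat = local[np.arange(Y.shape[0]), np.argmin(sse_loc, axis=1)]
        h = h / 12.0

    # Recompute S0 at the refined T1.
    g_hat = np.abs(1.0 - 2.0 * np.exp(-ti_s[None, :] / t1_hat[:, None])
                   + np.exp(-tr_s / t1_hat)[:, None])
    s0_hat = np.clip((Y * g_hat).sum(axis=1), 0.0, None) / (g_hat * g_hat).sum(axis=1)

    ok = (s0_hat > 0) & np.isfinite(t1_hat)
    # Grid-edge hits indicate a failed fit (e.g. zero or flat signal).
    ok &= (best > 0) & (best < t1_grid_s.shape[0] - 1)
    t1_map[mask] = np.where(ok, t1_hat, 0.0)
    s0_map[mask] = np.where(ok, s0_hat, 0.0)
    valid[mask] = ok
    return t1_map, s0_map, valid
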