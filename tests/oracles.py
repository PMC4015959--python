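"""Independent brute-force oracles for the nonlinear fitters.

Each oracle profiles the single nonlinear parameter over a dense grid and
solves the remaining (conditionally linear) parameters exactly, so it
shares no code path with the Levenberg–Marquardt fits it cross-checks.
"""

from __future__ import annotations

import numpy as np


def _linear_lsq(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(resid @ resid)


def grid_tight_binding(p_nM, emission, ligand_total_nM, kd_grid):
    """Best (kd, f_free, f_bound) by grid over kd, linear in the others."""
    best = (np.inf, None)
    for kd in kd_grid:
        s = p_nM + ligand_total_nM + kd
        c = (s - np.sqrt(s * s - 4.0 * p_nM * ligand_total_nM)) / 2.0
        design = np.column_stack([ligand_total_nM - c, c])
        coef, sse = _linear_lsq(design, emission)
        if sse < best[0]:
            best = (sse, (kd, coef[0], coef[1]))
    return best[1]


def grid_mm(s_uM, v, e_tot, km_grid):
    """Best (km, kcat) by grid over km, velocity linear in kcat."""
    best = (np.inf, None)
    for km in km_grid:
        design = (e_tot * s_uM / (km + s_uM))[:, None]
        coef, sse = _linear_lsq(design, v)
        if sse < best[0]:
            best = (sse, (km, coef[0]))
    return best[1]


def grid_exponential(t, a, k_grid):
    """Best (kobs, amplitude, offset) by grid over kobs."""
    best = (np.inf, None)
    for k in k_grid:
        design = np.column_stack([np.exp(-k * t), np.ones_like(t)])
        coef, sse = _linear_lsq(design, a)
        if sse < best[0]:
            best = (sse, (k, coef[0], coef[1]))
    return best[1]


def grid_mixture2(curve, comps, step=0.01):
    """Two-component mixture: exhaustive weight grid, scale analytic."""
    w_grid = np.arange(0.0, 1.0 + step / 2, step)
    best = (np.inf, None)
    for w in w_grid:
        model = w * comps[0] + (1.0 - w) * comps[1]
        mw = model / curve.sigma
        bw = curve.intensity / curve.sigma
        scale = float(mw @ bw / (mw @ mw))
        resid = bw - scale * mw
        sse = float(resid @ resid)
        if sse < best[0]:
            best = (sse, (w, scale))
    return best[1]
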