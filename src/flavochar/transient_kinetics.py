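"""Stopped-flow transient kinetics of the reductive half-reaction.

Rapid mixing of an oxidized flavoenzyme with NAD(P)H bleaches the 450 nm
flavin band; with substrate in excess the decay is a single exponential
A(t) = offset + amplitude · exp(−k_obs t).  The observed rate constant
saturates hyperbolically in substrate,

    k_obs = k_max · S / (K_half + S),

with k_max the limiting electron-transfer rate constant of the enzyme–
substrate complex and K_half an apparent substrate affinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit

__all__ = [
    "StoppedFlowTrace",
    "ExponentialFit",
    "HyperbolaFit",
    "fit_exponential",
    "fit_kobs_hyperbola",
    "solvent_kie",
]


@dataclass
class StoppedFlowTrace:
    """A single stopped-flow absorbance trace (post dead time)."""

    t_s: np.ndarray
    a450: np.ndarray
    nadh_uM: float = np.nan  # post-mix concentration
    temperature_C: float = 10.0

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.a450 = np.asarray(self.a450, dtype=float)
        if self.t_s.shape != self.a450.shape:
            raise ValueError("time and absorbance series must match")
        if self.t_s.size < 20:
            raise ValueError("at least 20 points are required")
        if np.any(self.t_s < 0) or np.any(np.diff(self.t_s) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")

    def shifted(self, dead_time_s: float) -> "StoppedFlowTrace":
        """Return a copy with the time axis advanced by a dead time."""
        return StoppedFlowTrace(
            self.t_s + dead_time_s, self.a450.copy(), self.nadh_uM, self.temperature_C
        )


@dataclass
class ExponentialFit:
    kobs_s: float
    kobs_se_s: float
    amplitude: float
    amplitude_se: float
    offset: float
    offset_se: float
    residual_rms: float
    ok: bool = True
    flags: list[str] = field(default_factory=list)


@dataclass
class HyperbolaFit:
    """Saturation of k_obs with substrate: limit and half-saturation."""

    k_max_s: float
    k_max_se_s: float
    k_half_uM: float
    k_half_se_uM: float
    ok: bool = True
    flags: list[str] = field(default_factory=list)


def _loglinear_guess(t: np.ndarray, a: np.ndarray) -> tuple[float, float, float]:
    """Initial (kobs, amplitude, offset) from a log-linear transform."""
    offset = float(np.mean(a[-max(3, a.size // 10):]))
    amp = float(a[0] - offset)
    d = a - offset
    sign = np.sign(amp) if amp != 0 else 1.0
    usable = sign * d > 1e-4 * max(abs(amp), 1e-12)
    if usable.sum() >= 3:
        slope = np.polyfit(t[usable], np.log(sign * d[usable]), 1)[0]
        kobs = max(-slope, 1e-9)
    else:
        kobs = 1.0 / max(t[-1], 1e-9)
    return kobs, amp, offset


def fit_exponential(trace: StoppedFlowTrace) -> ExponentialFit:
    """Fit A(t) = offset + amplitude·exp(−k_obs t) by least squares.

    Initial guesses come from a log-linear transform of the baseline-
    subtracted signal.  Flags: ``flat_trace`` when the amplitude is
    indistinguishable from the noise (k_obs unidentifiable) and
    ``under_sampled`` when k_obs·t_max < 1 (the decay is not followed to
    completion).
    """
    t, a = trace.t_s, trace.a450
    k0, amp0, off0 = _loglinear_guess(t, a)
    noise = float(np.std(np.diff(a)) / np.sqrt(2.0)) if a.size > 2 else 0.0
    span = float(a.max() - a.min())
    if span <= max(3.0 * noise * 0, 1e-12) or abs(amp0) <= 2.0 * noise:
        return ExponentialFit(
            kobs_s=np.nan, kobs_se_s=np.nan, amplitude=0.0, amplitude_se=np.nan,
            offset=float(np.mean(a)), offset_se=np.nan,
            residual_rms=float(np.std(a)), ok=False, flags=["flat_trace"],
        )
    params = lmfit.Parameters()
    params.add("kobs", value=k0, min=1e-12)
    params.add("amplitude", value=amp0)
    params.add("offset", value=off0)

    def residual(p):
        return p["offset"].value + p["amplitude"].value * np.exp(
            -p["kobs"].value * t
        ) - a

    res = lmfit.minimize(residual, params, method="leastsq")
    flags: list[str] = []
    ok = bool(res.success)
    if not ok:
        flags.append("no_convergence")
    kobs = float(res.params["kobs"].value)
    if kobs * t[-1] < 1.0:
        flags.append("under_sampled")
    # second-phase warning: runs of same-signed residuals
    r = res.residual
    if r.size > 10:
        runs = np.sign(r[np.abs(r) > 0])
        frac_flips = np.mean(runs[1:] != runs[:-1]) if runs.size > 1 else 0.5
        if frac_flips < 0.25:
            flags.append("residual_structure")
    return ExponentialFit(
        kobs_s=kobs,
        kobs_se_s=float(res.params["kobs"].stderr or np.nan),
        amplitude=float(res.params["amplitude"].value),
        amplitude_se=float(res.params["amplitude"].stderr or np.nan),
        offset=float(res.params["offset"].value),
        offset_se=float(res.params["offset"].stderr or np.nan),
        residual_rms=float(np.sqrt(np.mean(r**2))),
        ok=ok,
        flags=flags,
    )


def fit_kobs_hyperbola(points: list[tuple[float, float]]) -> HyperbolaFit:
    """Fit k_obs = k_max·S/(K_half + S) to (S µM, k_obs s^-1) pairs.

    Needs ≥ 4 concentrations; when every S lies far above the fitted
    K_half the half-saturation constant is unidentifiable and the result
    is flagged ``k_half_unidentified``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (concentration, kobs) points")
    s, k = pts[:, 0], pts[:, 1]
    params = lmfit.Parameters()
    params.add("k_max", value=float(k.max()), min=1e-12)
    params.add("k_half", value=float(np.median(s)), min=1e-12)

    def residual(p):
        return p["k_max"].value * s / (p["k_half"].value + s) - k

    res = lmfit.minimize(residual, params, method="leastsq")
    flags: list[str] = []
    ok = bool(res.success)
    if not ok:
        flags.append("no_convergence")
    k_half = float(res.params["k_half"].value)
    k_half_se = float(res.params["k_half"].stderr or np.nan)
    if s.min() > 10.0 * k_half or (
        np.isfinite(k_half_se) and k_half_se > 2.0 * k_half
    ):
        flags.append("k_half_unidentified")
    return HyperbolaFit(
        k_max_s=float(res.params["k_max"].value),
        k_max_se_s=float(res.params["k_max"].stderr or np.nan),
        k_half_uM=k_half,
        k_half_se_uM=k_half_se,
        ok=ok,
        flags=flags,
    )


def solvent_kie(
    k_h2o: float,
    k_d2o: float,
    se_h: float | None = None,
    se_d: float | None = None,
):
    """Kinetic solvent isotope effect k_obs(H2O)/k_obs(D2O)."""
    from .steady_state_kinetics import _ratio

    return _ratio(k_h2o, k_d2o, se_h, se_d)
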