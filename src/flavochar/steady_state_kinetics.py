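"""Steady-state kinetics: Michaelis–Menten and bi-bi ping-pong analysis.

Initial velocities of NAD(P)H oxidation are read out as A340 slopes
(ε(NADH, 340 nm) = 6.22 mM^-1 cm^-1).  Single-substrate datasets are fit to
the Michaelis–Menten law; two-substrate flavin-reductase datasets to the
ping-pong bi-bi law

    v = kcat · E · A · B / (Ka · B + Kb · A + A · B)

whose double-reciprocal plots at fixed co-substrate are parallel lines —
a diagnostic, not a fitting device.  Derived quantities: the specificity
constant kcat/Km, kinetic isotope effect ratios, activity ratios, and the
specific-activity → kcat conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit
from scipy import stats

__all__ = [
    "EPS_NADH_340",
    "RateDataset",
    "PingPongDataset",
    "MMFit",
    "PingPongFit",
    "RatioResult",
    "rate_from_a340",
    "fit_mm",
    "specificity",
    "fit_pingpong",
    "kcat_from_specific_activity",
    "kie",
    "activity_ratio",
]

#: extinction coefficient of NADH at 340 nm, mM^-1 cm^-1
EPS_NADH_340 = 6.22


@dataclass
class RateDataset:
    """Initial velocities versus a single varied substrate concentration."""

    substrate_uM: np.ndarray
    velocity: np.ndarray  # µM s^-1 (or s^-1 if pre-normalized and enzyme_total_uM=1)
    enzyme_total_uM: float
    acceptor: str = ""
    acceptor_uM: float = np.nan

    def __post_init__(self) -> None:
        self.substrate_uM = np.asarray(self.substrate_uM, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.substrate_uM.shape != self.velocity.shape:
            raise ValueError("substrate and velocity series must match")
        if self.substrate_uM.size < 5:
            raise ValueError("at least 5 substrate levels are required")
        if np.unique(self.substrate_uM).size != self.substrate_uM.size:
            raise ValueError("substrate values must be distinct")
        if np.any(self.velocity < 0):
            raise ValueError("velocities must be non-negative")
        if self.enzyme_total_uM <= 0:
            raise ValueError("enzyme_total_uM must be positive")


@dataclass
class PingPongDataset:
    """Initial velocities on a (substrate A, substrate B) design grid."""

    a_uM: np.ndarray
    b_uM: np.ndarray
    velocity: np.ndarray
    enzyme_total_uM: float

    def __post_init__(self) -> None:
        self.a_uM = np.asarray(self.a_uM, dtype=float)
        self.b_uM = np.asarray(self.b_uM, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if not (self.a_uM.shape == self.b_uM.shape == self.velocity.shape):
            raise ValueError("A, B and velocity series must have equal length")
        if self.enzyme_total_uM <= 0:
            raise ValueError("enzyme_total_uM must be positive")

    @property
    def b_levels(self) -> np.ndarray:
        return np.unique(self.b_uM)


@dataclass
class MMFit:
    """Michaelis–Menten parameters with asymptotic standard errors."""

    km_uM: float
    km_se_uM: float
    kcat_s: float
    kcat_se_s: float
    specificity_mM_s: float
    specificity_se_mM_s: float
    ok: bool = True
    flags: list[str] = field(default_factory=list)


@dataclass
class PingPongFit:
    """Global ping-pong bi-bi fit plus the parallel-lines diagnostic.

    ``parallelism_stat`` is the coefficient of variation of the per-B-level
    double-reciprocal slopes; ≈ 0 under a genuine ping-pong mechanism.
    """

    kcat_s: float
    kcat_se_s: float
    ka_uM: float
    ka_se_uM: float
    kb_uM: float
    kb_se_uM: float
    parallelism_stat: float
    ok: bool = True
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class RatioResult:
    """A dimensionless rate ratio with (optionally) a propagated SE."""

    value: float
    se: float | None = None


def rate_from_a340(slope_per_min: float, path_cm: float = 1.0) -> float:
    """Initial velocity (µM s^-1) from an A340 slope (absorbance min^-1).

    v = |slope| / (6.22 · path) · 1000 / 60.  The division by ε converts to
    mM min^-1, the factors convert to µM s^-1.
    """
    if path_cm <= 0:
        raise ValueError("path length must be positive")
    return abs(slope_per_min) / (EPS_NADH_340 * path_cm) * 1000.0 / 60.0


def specificity(km_uM: float, kcat_s: float) -> float:
    """Specificity constant kcat/Km in mM^-1 s^-1 (Km supplied in µM)."""
    if km_uM <= 0:
        raise ValueError("km must be positive")
    return kcat_s / (km_uM / 1000.0)


def fit_mm(data: RateDataset, weighting: str = "none") -> MMFit:
    """Fit v = kcat·E·S/(Km + S) by unweighted nonlinear least squares.

    ``weighting="inv_v2"`` applies 1/v² weights (relative-error model);
    default is unweighted, matching common initial-velocity practice.
    """
    s, v, e = data.substrate_uM, data.velocity, data.enzyme_total_uM
    vmax0 = v.max() * 1.2
    # initial Km: substrate at half-max velocity
    km0 = float(np.interp(vmax0 / 2.4, np.sort(v), np.sort(s))) or float(np.median(s))
    params = lmfit.Parameters()
    params.add("km", value=max(km0, 1e-6), min=1e-12)
    params.add("kcat", value=max(vmax0 / e, 1e-12), min=1e-12)

    if weighting == "inv_v2":
        w = 1.0 / np.maximum(v, 1e-12)
    elif weighting == "none":
        w = np.ones_like(v)
    else:
        raise ValueError("weighting must be 'none' or 'inv_v2'")

    def residual(p):
        model = p["kcat"].value * e * s / (p["km"].value + s)
        return (model - v) * w

    res = lmfit.minimize(residual, params, method="leastsq")
    flags: list[str] = []
    ok = bool(res.success)
    if not ok:
        flags.append("no_convergence")
    km = float(res.params["km"].value)
    kcat = float(res.params["kcat"].value)
    km_se = res.params["km"].stderr or np.nan
    kcat_se = res.params["kcat"].stderr or np.nan
    if km > 100.0 * s.max() or km < s.min() / 100.0:
        flags.append("km_outside_data_range")
    spec = specificity(km, kcat)
    # delta-method SE for the quotient; covariance term included when available
    if np.isfinite(km_se) and np.isfinite(kcat_se) and km > 0 and kcat > 0:
        try:
            cov = res.covar
            r = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        except Exception:
            r = 0.0
        rel2 = (kcat_se / kcat) ** 2 + (km_se / km) ** 2 \
            - 2.0 * r * (kcat_se / kcat) * (km_se / km)
        spec_se = spec * np.sqrt(max(rel2, 0.0))
    else:
        spec_se = np.nan
    return MMFit(
        km_uM=km, km_se_uM=float(km_se), kcat_s=kcat, kcat_se_s=float(kcat_se),
        specificity_mM_s=spec, specificity_se_mM_s=float(spec_se),
        ok=ok, flags=flags,
    )


def _reciprocal_slopes(data: PingPongDataset) -> np.ndarray:
    """Per-B-level slopes of 1/v against 1/A (diagnostic only)."""
    slopes = []
    for b in data.b_levels:
        m = data.b_uM == b
        if m.sum() < 2:
            continue
        inv_a = 1.0 / data.a_uM[m]
        inv_v = 1.0 / np.maximum(data.velocity[m], 1e-300)
        slopes.append(stats.linregress(inv_a, inv_v).slope)
    return np.asarray(slopes)


def fit_pingpong(data: PingPongDataset) -> PingPongFit:
    """Global nonlinear fit of the ping-pong bi-bi rate law.

    v = kcat·E·A·B/(Ka·B + Kb·A + A·B), fit over all (A, B) points at
    once.  Requires ≥ 3 levels of B and ≥ 4 of A.  Strong non-parallelism
    of the double-reciprocal lines (CV of slopes > 0.15) raises a mechanism
    warning — the data may instead follow a sequential (ternary-complex)
    law.
    """
    if data.b_levels.size < 3:
        raise ValueError("need at least 3 fixed levels of substrate B")
    if np.unique(data.a_uM).size < 4:
        raise ValueError("need at least 4 levels of substrate A")
    a, b, v, e = data.a_uM, data.b_uM, data.velocity, data.enzyme_total_uM
    params = lmfit.Parameters()
    params.add("kcat", value=max(v.max() / e, 1e-9), min=1e-12)
    params.add("ka", value=float(np.median(a)), min=1e-12)
    params.add("kb", value=float(np.median(b)), min=1e-12)

    def residual(p):
        kcat, ka, kb = p["kcat"].value, p["ka"].value, p["kb"].value
        return kcat * e * a * b / (ka * b + kb * a + a * b) - v

    res = lmfit.minimize(residual, params, method="leastsq")
    slopes = _reciprocal_slopes(data)
    cv = float(np.std(slopes) / np.mean(slopes)) if slopes.size > 1 else np.nan
    flags: list[str] = []
    ok = bool(res.success)
    if not ok:
        flags.append("no_convergence")
    if np.isfinite(cv) and cv > 0.15:
        flags.append("non_parallel_reciprocal_plots")
        warnings.warn(
            f"double-reciprocal slopes vary (CV = {cv:.2f}); "
            "ping-pong mechanism questionable",
            stacklevel=2,
        )
    return PingPongFit(
        kcat_s=float(res.params["kcat"].value),
        kcat_se_s=float(res.params["kcat"].stderr or np.nan),
        ka_uM=float(res.params["ka"].value),
        ka_se_uM=float(res.params["ka"].stderr or np.nan),
        kb_uM=float(res.params["kb"].value),
        kb_se_uM=float(res.params["kb"].stderr or np.nan),
        parallelism_stat=cv,
        ok=ok,
        flags=flags,
    )


def kcat_from_specific_activity(sa_umol_min_mg: float, subunit_mass_da: float) -> float:
    """Convert a specific activity (µmol min^-1 mg^-1) to kcat (s^-1).

    kcat = SA · M / 60000 with M the subunit molecular mass in Da; e.g.
    (1111, 21412) → 396.5 s^-1.
    """
    if sa_umol_min_mg < 0 or subunit_mass_da <= 0:
        raise ValueError("specific activity must be >= 0 and mass > 0")
    return sa_umol_min_mg * subunit_mass_da / 60000.0


def _ratio(num: float, den: float, num_se: float | None, den_se: float | None) -> RatioResult:
    if den == 0:
        raise ValueError("denominator rate must be nonzero")
    r = num / den
    if num_se is None and den_se is None:
        return RatioResult(r, None)
    ns = num_se or 0.0
    ds = den_se or 0.0
    se = abs(r) * np.sqrt((ns / num) ** 2 + (ds / den) ** 2)
    return RatioResult(r, float(se))


def kie(
    rate_h: float,
    rate_d: float,
    se_h: float | None = None,
    se_d: float | None = None,
) -> RatioResult:
    """Kinetic isotope effect k(light)/k(heavy), first-order SE propagation."""
    return _ratio(rate_h, rate_d, se_h, se_d)


def activity_ratio(
    kcat_a: float,
    kcat_b: float,
    se_a: float | None = None,
    se_b: float | None = None,
) -> RatioResult:
    """Ratio of two catalytic constants, kcat_a / kcat_b."""
    return _ratio(kcat_a, kcat_b, se_a, se_b)
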