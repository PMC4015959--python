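"""Solution oligomeric-state estimation from SEC and SAXS.

Two complementary routes:

* Analytical size-exclusion chromatography — a linear calibration of
  log10(molecular mass) against elution volume over marker proteins gives
  an apparent native mass, divided by the subunit mass to a subunit count.

* Small-angle X-ray scattering — the measured curve of an oligomer mixture
  is a weighted sum of component form factors; non-negative least squares
  over the weights (with an overall scale) yields the volume fractions of
  each assembly, assessed by the reduced chi-square against the per-point
  uncertainties.

Form factors are inputs: either supplied externally (e.g. computed from
atomic models) or generated analytically by the homogeneous-sphere model in
:func:`sphere_intensity`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SECMarkerTable",
    "SECCalibration",
    "ScatteringCurve",
    "FormFactorSet",
    "MixtureFit",
    "sec_calibrate",
    "apparent_mass",
    "subunit_count",
    "sphere_intensity",
    "fit_mixture",
]


@dataclass
class SECMarkerTable:
    """Size-exclusion marker proteins: (name, mass kDa, elution mL)."""

    markers: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        if len(self.markers) < 2:
            raise ValueError("need at least 2 markers for a calibration line")
        if len(self.markers) < 3:
            warnings.warn("fewer than 3 markers: calibration quality unchecked",
                          stacklevel=2)
        for name, mass, ve in self.markers:
            if mass <= 0 or ve <= 0:
                raise ValueError(f"marker {name!r}: mass and volume must be positive")

    @property
    def masses_kda(self) -> np.ndarray:
        return np.array([m for _, m, _ in self.markers])

    @property
    def volumes_ml(self) -> np.ndarray:
        return np.array([v for _, _, v in self.markers])


@dataclass
class SECCalibration:
    """log10(mass/kDa) = intercept + slope · Ve calibration line."""

    slope: float
    intercept: float
    r_squared: float
    ve_range_ml: tuple[float, float]
    flags: list[str] = field(default_factory=list)


@dataclass
class ScatteringCurve:
    """A 1-D SAXS curve: momentum transfer q (Å^-1), intensity, uncertainty."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.shape == self.intensity.shape == self.sigma.shape):
            raise ValueError("q, intensity and sigma must have equal length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be positive and strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")


@dataclass
class FormFactorSet:
    """Component scattering profiles sampled on a common q grid."""

    q: np.ndarray
    intensities: np.ndarray  # shape (n_components, n_q)
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape != (len(self.names), self.q.size):
            raise ValueError("intensities must be (n_components, n_q)")


@dataclass
class MixtureFit:
    """Component volume fractions from the scattering-mixture decomposition."""

    weights: np.ndarray
    weight_se: np.ndarray
    scale: float
    chi2: float  # reduced chi-square
    names: tuple[str, ...]
    interpolated: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def chi(self) -> float:
        return float(np.sqrt(self.chi2))


def sec_calibrate(markers: SECMarkerTable) -> SECCalibration:
    """Least-squares calibration of log10(mass) against elution volume."""
    ve = markers.volumes_ml
    logm = np.log10(markers.masses_kda)
    flags: list[str] = []
    order = np.argsort(ve)
    if np.any(np.diff(logm[order]) >= 0):
        flags.append("non_monotone_markers")
        warnings.warn("marker log-mass is not monotone decreasing in elution volume",
                      stacklevel=2)
    if ve.size == 2:
        slope = (logm[1] - logm[0]) / (ve[1] - ve[0])
        intercept = logm[0] - slope * ve[0]
        r2 = 1.0
    else:
        res = stats.linregress(ve, logm)
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
    return SECCalibration(
        slope=float(slope), intercept=float(intercept), r_squared=float(r2),
        ve_range_ml=(float(ve.min()), float(ve.max())), flags=flags,
    )


def apparent_mass(cal: SECCalibration, elution_ml: float) -> tuple[float, bool]:
    """Apparent native mass (Da) at an elution volume, with extrapolation flag."""
    mass_da = 10.0 ** (cal.intercept + cal.slope * elution_ml) * 1000.0
    lo, hi = cal.ve_range_ml
    extrapolated = not (lo <= elution_ml <= hi)
    return float(mass_da), extrapolated


def subunit_count(apparent_mass_da: float, monomer_mass_da: float) -> float:
    """Number of subunits per native particle, rounded to two decimals."""
    if apparent_mass_da <= 0 or monomer_mass_da <= 0:
        raise ValueError("masses must be positive")
    return round(apparent_mass_da / monomer_mass_da, 2)


def sphere_intensity(q: np.ndarray, radius_A: float) -> np.ndarray:
    """Homogeneous-sphere scattering intensity, scaled by R^6.

    I(q) = [3 (sin qR − qR cos qR) / (qR)^3]^2 · R^6; the R^6 factor keeps
    forward scattering proportional to the squared particle volume so that
    equal-weight mixtures of unequal spheres scatter unequally, as in real
    oligomer mixtures.
    """
    if radius_A <= 0:
        raise ValueError("radius must be positive")
    x = np.asarray(q, dtype=float) * radius_A
    amp = np.empty_like(x)
    small = np.abs(x) < 1e-2  # series branch: direct formula cancels badly
    xs = x[small]
    amp[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0
    xl = x[~small]
    amp[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return amp**2 * radius_A**6


def fit_mixture(curve: ScatteringCurve, components: FormFactorSet) -> MixtureFit:
    """Decompose a scattering curve over component form factors.

    Minimizes the sigma-weighted residual of
    ``I(q) ≈ c · Σ_i w_i I_i(q)`` with ``w_i ≥ 0, Σ w_i = 1`` by
    non-negative least squares on ``b_i = c·w_i`` followed by
    normalization.  Reports reduced chi-square
    ``χ² = Σ[(I − fit)/σ]² / (N − K)`` with K the number of components
    (one scale plus K−1 independent weights).

    Components sampled on a different q grid are linearly interpolated
    onto the curve's grid and the fit flagged ``interpolated``.  Nearly
    colinear components trigger an ill-conditioning warning; their weight
    uncertainties blow up accordingly.
    """
    interpolated = False
    if components.q.size != curve.q.size or not np.allclose(components.q, curve.q):
        if curve.q.min() < components.q.min() or curve.q.max() > components.q.max():
            raise ValueError("curve q range exceeds component form-factor range")
        comps = np.vstack([
            np.interp(curve.q, components.q, ci) for ci in components.intensities
        ])
        interpolated = True
    else:
        comps = components.intensities

    A = (comps / curve.sigma).T  # (N, K)
    b = curve.intensity / curve.sigma
    coef, _ = optimize.nnls(A, b)
    total = coef.sum()
    flags: list[str] = []
    if interpolated:
        flags.append("interpolated")
    if total <= 0:
        raise ValueError("mixture fit degenerate: all component weights zero")
    weights = coef / total
    resid = b - A @ coef
    n, k = b.size, coef.size
    dof = max(n - k, 1)
    chi2 = float(resid @ resid / dof)

    ata = A.T @ A
    cond = np.linalg.cond(ata)
    if cond > 1e10:
        flags.append("ill_conditioned")
        warnings.warn(
            f"component form factors nearly colinear (cond {cond:.3g}); "
            "weight uncertainties unreliable",
            stacklevel=2,
        )
    # asymptotic covariance of the unconstrained coefficients, then the
    # delta method for w_i = b_i / sum(b)
    try:
        cov_b = chi2 * np.linalg.pinv(ata)
        J = (np.eye(k) * total - np.outer(coef, np.ones(k))) / total**2
        cov_w = J @ cov_b @ J.T
        weight_se = np.sqrt(np.maximum(np.diag(cov_w), 0.0))
    except np.linalg.LinAlgError:
        weight_se = np.full(k, np.nan)
    return MixtureFit(
        weights=weights,
        weight_se=weight_se,
        scale=float(total),
        chi2=chi2,
        names=components.names,
        interpolated=interpolated,
        flags=flags,
    )
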