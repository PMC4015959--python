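"""Dye-coupled redox potentiometry of enzyme-bound flavin.

In the xanthine/xanthine-oxidase equilibration method a slow, constant
supply of reducing equivalents is delivered to a sealed cuvette containing
the flavoenzyme and a reference dye of known midpoint potential; a mediator
keeps the two couples at a common solution potential throughout.  Two-
wavelength absorbance readings are deconvolved into oxidized fractions of
each couple, and the Nernst relation links the two log ratios linearly:
plotted as log10([red]/[ox]) of the enzyme against that of the dye the
points fall on a line of slope n_F/n_D with intercept n_F(E_enz − E_dye)/ν,
so the enzyme midpoint potential follows from the intercept as

    E_enz = E_dye + (ν / n_F) · intercept

with ν the Nernst slope (59 mV per decade per electron at 25 °C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "NERNST_SLOPE_MV",
    "SPECIES",
    "ExtinctionMatrix",
    "AbsorbanceSeries",
    "FractionSeries",
    "NernstFit",
    "DyeRef",
    "dye_library",
    "get_dye",
    "deconvolve",
    "equilibration_fit",
    "potential_from_intercept",
]

#: default Nernst slope, mV per tenfold change of [ox]/[red] per electron
NERNST_SLOPE_MV = 59.0

#: canonical species order used throughout the module
SPECIES = ("flavin_ox", "flavin_red", "dye_ox", "dye_red")


@dataclass(frozen=True)
class ExtinctionMatrix:
    """Molar extinction coefficients (mM^-1 cm^-1) per species and wavelength.

    ``eps`` has shape (4, n_wavelengths) in the order
    (flavin_ox, flavin_red, dye_ox, dye_red).  The difference submatrix of
    the two couples must be non-singular for deconvolution.  Reduced flavin
    hydroquinone and leuco-dyes absorb weakly at the analysis wavelengths,
    so their rows default to zero.
    """

    wavelengths_nm: tuple[float, ...]
    eps: np.ndarray

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps, dtype=float)
        if eps.shape != (4, len(self.wavelengths_nm)):
            raise ValueError("eps must have shape (4, n_wavelengths)")
        if np.any(eps < 0):
            raise ValueError("extinction coefficients must be non-negative")
        object.__setattr__(self, "eps", eps)

    @classmethod
    def two_wavelength(
        cls,
        flavin_wl: float = 450.0,
        dye_wl: float = 610.0,
        eps_flavin_ox: tuple[float, float] = (12.5, 0.5),
        eps_dye_ox: tuple[float, float] = (1.0, 20.0),
        eps_flavin_red: tuple[float, float] = (0.0, 0.0),
        eps_dye_red: tuple[float, float] = (0.0, 0.0),
    ) -> "ExtinctionMatrix":
        """Convenience two-wavelength matrix (defaults: flavin 450 nm,
        indigo-carmine-like dye 610 nm; reduced species non-absorbing)."""
        return cls(
            wavelengths_nm=(flavin_wl, dye_wl),
            eps=np.array(
                [eps_flavin_ox, eps_flavin_red, eps_dye_ox, eps_dye_red],
                dtype=float,
            ),
        )


@dataclass
class AbsorbanceSeries:
    """Timed multi-wavelength absorbances from a reductive equilibration."""

    times_min: np.ndarray
    absorbance: np.ndarray  # shape (n_times, n_wavelengths)
    flavin_total_uM: float
    dye_total_uM: float
    path_cm: float = 1.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape[0] != self.times_min.size:
            raise ValueError("absorbance rows must match times")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.flavin_total_uM <= 0 or self.dye_total_uM <= 0:
            raise ValueError("totals must be positive")


@dataclass
class FractionSeries:
    """Oxidized fractions of the enzyme-flavin and dye couples over time."""

    times_min: np.ndarray
    f_ox_enzyme: np.ndarray
    f_ox_dye: np.ndarray
    clipped: np.ndarray  # bool mask: fraction fell outside [0, 1] pre-clip


@dataclass
class NernstFit:
    """Linear equilibration-plot fit and the derived midpoint potential."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    e_dye_mV: float
    n_F: int
    n_D: int
    e_m_mV: float
    nernst_slope_mv: float = NERNST_SLOPE_MV
    n_points: int = 0
    r_squared: float = np.nan
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class DyeRef:
    """Reference redox dye: midpoint potential (pH 7) and electron count."""

    name: str
    e0_mV: float
    n: int = 2


def dye_library() -> dict[str, DyeRef]:
    """Built-in reference dyes for potentiometric equilibration.

    Midpoints (pH 7.0): indigo carmine −125 mV, phenosafranin −252 mV,
    anthraquinone-2-sulfonate −225 mV.  All default to two-electron couples.
    """
    return {
        "indigo_carmine": DyeRef("indigo_carmine", -125.0, 2),
        "phenosafranin": DyeRef("phenosafranin", -252.0, 2),
        "anthraquinone_2_sulfonate": DyeRef("anthraquinone_2_sulfonate", -225.0, 2),
    }


def get_dye(name: str, library: dict[str, DyeRef] | None = None) -> DyeRef:
    """Look up a dye by name; user-supplied ``library`` overrides defaults."""
    lib = dye_library()
    if library:
        lib.update(library)
    try:
        return lib[name]
    except KeyError:
        raise KeyError(
            f"unknown reference dye {name!r}; known: {sorted(lib)}"
        ) from None


def deconvolve(series: AbsorbanceSeries, eps: ExtinctionMatrix) -> FractionSeries:
    """Resolve two-couple absorbances into per-couple oxidized fractions.

    At each time the system ``A(λ) = path · Σ_s ε[s,λ] c_s`` is solved for
    the two oxidized concentrations under the closure constraints
    ``[ox] + [red] = total`` for each couple.  Fractions are clipped to
    [0, 1]; clipping is flagged per time point.

    Raises ``ValueError`` (with the condition number) when the effective
    ox-minus-red extinction submatrix is singular.
    """
    if series.absorbance.shape[1] != len(eps.wavelengths_nm):
        raise ValueError("wavelength count mismatch between series and eps")
    e = eps.eps / 1000.0  # mM^-1 cm^-1 -> µM^-1 cm^-1
    totals = np.array([series.flavin_total_uM, series.dye_total_uM])
    # substitute red = total - ox; unknowns are the two ox concentrations
    d_flavin = e[0] - e[1]
    d_dye = e[2] - e[3]
    M = series.path_cm * np.column_stack([d_flavin, d_dye])  # (n_wl, 2)
    baseline = series.path_cm * (e[1] * totals[0] + e[3] * totals[1])
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"singular extinction configuration (condition number {cond:.3g})"
        )
    b = series.absorbance - baseline  # (n_t, n_wl)
    ox, *_ = np.linalg.lstsq(M, b.T, rcond=None)
    f = ox.T / totals  # (n_t, 2) oxidized fractions
    clipped = np.any((f < 0) | (f > 1), axis=1)
    f = np.clip(f, 0.0, 1.0)
    return FractionSeries(
        times_min=series.times_min,
        f_ox_enzyme=f[:, 0],
        f_ox_dye=f[:, 1],
        clipped=clipped,
    )


def potential_from_intercept(
    e_dye_mV: float,
    intercept: float,
    n_F: int,
    nernst_slope_mv: float = NERNST_SLOPE_MV,
) -> float:
    """Midpoint potential from the equilibration-plot intercept.

    E_m = E_dye + (ν / n_F) · intercept, in mV.  With the
    log10([red]/[ox])-on-both-axes orientation used by
    :func:`equilibration_fit` this is exact, e.g.
    ``potential_from_intercept(-125, -0.45, 2)`` → −138.275 mV.
    """
    if n_F not in (1, 2):
        raise ValueError("n_F must be 1 or 2")
    return e_dye_mV + (nernst_slope_mv / n_F) * intercept


def equilibration_fit(
    fractions: FractionSeries,
    e_dye_mV: float,
    n_F: int = 2,
    n_D: int = 2,
    window: tuple[float, float] = (0.1, 0.9),
    nernst_slope_mv: float = NERNST_SLOPE_MV,
) -> NernstFit:
    """Fit the Nernst equilibration plot and derive the enzyme midpoint.

    Ordinary least squares of the enzyme couple's log10([red]/[ox]) on the
    dye couple's, restricted to points where both oxidized fractions lie
    strictly inside ``window`` (the log ratio diverges at the ends).  The
    slope estimates n_F/n_D; the midpoint follows from the intercept via
    :func:`potential_from_intercept`.

    A slope deviating more than 25% from n_F/n_D is flagged
    (``slope_off_expected``): the couples may not have reached a true
    redox equilibrium.
    """
    lo, hi = window
    mask = (
        (fractions.f_ox_enzyme > lo)
        & (fractions.f_ox_enzyme < hi)
        & (fractions.f_ox_dye > lo)
        & (fractions.f_ox_dye < hi)
    )
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} usable points inside fraction window {window}; "
            "need at least 3"
        )
    fe = fractions.f_ox_enzyme[mask]
    fd = fractions.f_ox_dye[mask]
    y = np.log10((1.0 - fe) / fe)  # enzyme log([red]/[ox]), ordinate
    x = np.log10((1.0 - fd) / fd)  # dye log([red]/[ox]), abscissa
    res = stats.linregress(x, y)
    flags: list[str] = []
    expected = n_F / n_D
    if abs(res.slope - expected) > 0.25 * expected:
        flags.append("slope_off_expected")
        warnings.warn(
            f"equilibration-plot slope {res.slope:.3f} deviates >25% from "
            f"n_F/n_D = {expected:.2f}; equilibrium suspect",
            stacklevel=2,
        )
    e_m = potential_from_intercept(e_dye_mV, res.intercept, n_F, nernst_slope_mv)
    if not (0.3 <= res.slope <= 3.0):
        flags.append("slope_out_of_range")
    return NernstFit(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        intercept_se=float(res.intercept_stderr),
        e_dye_mV=e_dye_mV,
        n_F=n_F,
        n_D=n_D,
        e_m_mV=float(e_m),
        nernst_slope_mv=nernst_slope_mv,
        n_points=int(mask.sum()),
        r_squared=float(res.rvalue**2),
        flags=flags,
    )
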