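"""Flavin-binding thermodynamics from fluorescence-quenching titrations.

Apoflavoproteins quench the fluorescence of free flavin (FMN, riboflavin)
upon complex formation, so titrating apoprotein into a fixed, sub-micromolar
amount of flavin traces out the binding isotherm.  Because the flavin
concentration used in such experiments (~100 nM) is comparable to the
dissociation constant, the free-ligand ≈ total-ligand approximation fails
and the exact single-site ("tight-binding") quadratic mass balance must be
fitted instead.

The module fits that quadratic model, converts dissociation constants to
standard Gibbs binding energies (1 M standard state), and provides the
mutant-cycle arithmetic used to apportion binding energy among parts of the
ligand or residues of the protein.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

__all__ = [
    "GAS_CONSTANT",
    "TitrationCurve",
    "BindingFit",
    "GibbsResult",
    "bound_concentration",
    "fit_tight_binding",
    "gibbs_from_kd",
    "delta_delta_g",
    "fold_change",
    "additivity_check",
]

#: molar gas constant, J mol^-1 K^-1
GAS_CONSTANT = 8.314


@dataclass
class TitrationCurve:
    """A fluorescence titration of apoprotein into a fixed flavin solution.

    Parameters
    ----------
    protein_uM : array-like
        Total apoprotein concentration at each titration point, µM.
    emission : array-like
        Fluorescence emission intensity (arbitrary units) at each point.
    flavin_total_nM : float
        Fixed total flavin concentration, nM (default 100 nM).
    temperature_K : float
        Temperature of the titration, K.
    dilution_factor : array-like, optional
        Per-point cumulative dilution factor (≤ 1); when present the
        emission and concentrations are corrected before fitting.
    """

    protein_uM: np.ndarray
    emission: np.ndarray
    flavin_total_nM: float = 100.0
    temperature_K: float = 298.15
    dilution_factor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.protein_uM = np.asarray(self.protein_uM, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        if self.protein_uM.shape != self.emission.shape:
            raise ValueError("protein and emission series must have equal length")
        if self.protein_uM.size < 4:
            raise ValueError("at least 4 titration points are required")
        if np.any(self.protein_uM < 0):
            raise ValueError("protein concentrations must be non-negative")
        if self.flavin_total_nM <= 0:
            raise ValueError("flavin_total_nM must be positive")
        if np.any(np.diff(self.protein_uM) < 0):
            warnings.warn(
                "titrant series is not non-decreasing", stacklevel=2
            )
        if self.dilution_factor is not None:
            self.dilution_factor = np.asarray(self.dilution_factor, dtype=float)
            if self.dilution_factor.shape != self.protein_uM.shape:
                raise ValueError("dilution_factor must match series length")


@dataclass
class BindingFit:
    """Result of the tight-binding quadratic fit.

    ``kd_nM`` carries an asymptotic standard error; ``flags`` collects
    diagnostics such as ``kd_at_lower_bound`` (K_d is an upper limit only)
    or ``no_quenching`` (the curve carries no binding signal).
    """

    kd_nM: float
    kd_se_nM: float
    f_free: float
    f_bound: float
    residual_rms: float
    ok: bool = True
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class GibbsResult:
    """Standard Gibbs energy of binding, kJ mol^-1, at a stated temperature."""

    dg_kJ_mol: float
    temperature_K: float = 298.15
    gas_constant: float = GAS_CONSTANT


def bound_concentration(
    protein_nM: np.ndarray | float, ligand_total_nM: float, kd_nM: float
) -> np.ndarray | float:
    """Exact single-site bound-complex concentration from mass balance.

    Solves ``C^2 - (P + L + Kd) C + P L = 0`` for the physical root

    ``C = ((P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)) / 2``

    valid for any ratio of ligand to K_d (ligand depletion included).
    All concentrations share the same unit (nM here).
    """
    p = np.asarray(protein_nM, dtype=float)
    if np.any(p < 0) or ligand_total_nM < 0 or kd_nM < 0:
        raise ValueError("concentrations and kd must be non-negative")
    s = p + ligand_total_nM + kd_nM
    disc = s * s - 4.0 * p * ligand_total_nM
    c = (s - np.sqrt(np.maximum(disc, 0.0))) / 2.0
    # guard round-off: bound cannot exceed either total
    c = np.minimum(c, np.minimum(p, ligand_total_nM))
    if np.ndim(protein_nM) == 0:
        return float(c)
    return c


def _emission_model(protein_nM, kd_nM, f_free, f_bound, ligand_total_nM):
    c = bound_concentration(protein_nM, ligand_total_nM, kd_nM)
    return f_free * (ligand_total_nM - c) + f_bound * c


def fit_tight_binding(curve: TitrationCurve) -> BindingFit:
    """Fit the quadratic (ligand-depletion) binding model to a titration.

    The emission at each point is modelled as
    ``F = f_free (L_tot - C) + f_bound C`` with ``C`` the exact bound
    concentration; nonlinear least squares over ``(K_d, f_free, f_bound)``.

    Returns a :class:`BindingFit`; degenerate curves (no quenching) are
    returned with ``ok=False`` rather than a spurious finite K_d.
    """
    L = curve.flavin_total_nM
    p_nM = curve.protein_uM * 1000.0
    y = curve.emission.copy()
    if curve.dilution_factor is not None:
        y = y / curve.dilution_factor
        p_nM = p_nM / curve.dilution_factor

    span = y.max() - y.min()
    if span <= 1e-12 * max(abs(y).max(), 1.0):
        return BindingFit(
            kd_nM=np.inf, kd_se_nM=np.inf, f_free=y.mean() / L, f_bound=np.nan,
            residual_rms=0.0, ok=False, flags=["no_quenching"],
        )

    i0 = int(np.argmin(p_nM))
    f_free0 = max(y[i0] / L, 1e-12)
    f_bound0 = max(min(y.min() / L, f_free0), 0.0)
    params = lmfit.Parameters()
    params.add("kd_nM", value=max(L / 2.0, 1e-3), min=0.0)
    params.add("f_free", value=f_free0, min=0.0)
    params.add("f_bound", value=f_bound0, min=0.0)

    def residual(pars):
        return _emission_model(
            p_nM, pars["kd_nM"].value, pars["f_free"].value,
            pars["f_bound"].value, L,
        ) - y

    result = lmfit.minimize(residual, params, method="leastsq")
    flags: list[str] = []
    ok = bool(result.success)
    if not ok:
        flags.append("no_convergence")
    kd = float(result.params["kd_nM"].value)
    kd_se = result.params["kd_nM"].stderr
    if kd_se is None or not np.isfinite(kd_se):
        kd_se = np.nan
    if kd <= 1e-9 * L:
        flags.append("kd_at_lower_bound")  # report as upper-limit estimate
    fit = BindingFit(
        kd_nM=kd,
        kd_se_nM=float(kd_se),
        f_free=float(result.params["f_free"].value),
        f_bound=float(result.params["f_bound"].value),
        residual_rms=float(np.sqrt(np.mean(result.residual**2))),
        ok=ok,
        flags=flags,
    )
    if fit.f_bound > fit.f_free:
        fit.flags.append("enhancement_mode")  # quenching expected by default
    return fit


def gibbs_from_kd(kd_molar: float, temperature_K: float = 298.15) -> GibbsResult:
    """Standard Gibbs energy of binding from a dissociation constant.

    ΔG_b = -R T ln(1/K_d) = R T ln(K_d / 1 M), reported in kJ mol^-1.
    Negative whenever K_d < 1 M (the 1 M standard state).
    """
    if kd_molar <= 0:
        raise ValueError("kd must be positive")
    dg = GAS_CONSTANT * temperature_K * math.log(kd_molar) / 1000.0
    return GibbsResult(dg_kJ_mol=dg, temperature_K=temperature_K)


def delta_delta_g(mutant: GibbsResult, wild_type: GibbsResult) -> float:
    """Mutational shift in binding energy, ΔΔG_b = ΔG_b(mut) − ΔG_b(wt).

    Positive values mean the mutation (or ligand truncation) weakened
    binding.  Both results must share a temperature.
    """
    if abs(mutant.temperature_K - wild_type.temperature_K) > 1e-9:
        raise ValueError("temperature mismatch between Gibbs results")
    return mutant.dg_kJ_mol - wild_type.dg_kJ_mol


def fold_change(kd_a: float, kd_b: float) -> float:
    """Ratio of two dissociation constants (same units), kd_a / kd_b."""
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("dissociation constants must be positive")
    return kd_a / kd_b


def additivity_check(parts: list[GibbsResult], whole: GibbsResult) -> float:
    """Discrepancy Σ(parts) − whole, kJ mol^-1.

    Used to quantify cooperativity: when per-residue (or per-moiety) ΔΔG_b
    contributions do not sum to the independently measured total, the
    signed excess measures the non-additive coupling among them.
    """
    for p in parts:
        if abs(p.temperature_K - whole.temperature_K) > 1e-9:
            raise ValueError("temperature mismatch between Gibbs results")
    return sum(p.dg_kJ_mol for p in parts) - whole.dg_kJ_mol
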