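"""Synthetic instrument outputs with known ground truth.

Every input class the analysis pipeline consumes can be generated here with
configurable noise and a fixed seed, so each downstream fitter is testable
by parameter recovery:

* fluorescence-quenching titrations (single-site tight binding),
* two-wavelength absorbance series from dye-coupled reductive
  equilibrations (two Nernstian couples under constant electron influx),
* initial-rate tables (Michaelis–Menten and ping-pong bi-bi),
* stopped-flow single-exponential traces,
* SAXS curves of sphere-mixture models with per-point uncertainties.

The noise model is multiplicative Gaussian on the signal (instrument-like
relative error) with an optional absolute floor.  Identical seed and
parameters give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .binding_thermo import TitrationCurve, bound_concentration
from .oligomer_state import FormFactorSet, ScatteringCurve, sphere_intensity
from .redox_potentiometry import NERNST_SLOPE_MV, AbsorbanceSeries, ExtinctionMatrix
from .steady_state_kinetics import PingPongDataset, RateDataset
from .transient_kinetics import StoppedFlowTrace

__all__ = [
    "SimConfig",
    "EquilibrationTruth",
    "gen_titration",
    "gen_equilibration",
    "equilibrate_fractions",
    "solution_potential",
    "gen_rates_mm",
    "gen_rates_pingpong",
    "gen_rates_ternary",
    "gen_trace",
    "gen_saxs_mixture",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation plumbing: seed, relative noise level, points per curve."""

    seed: int = 0
    noise_rel: float = 0.02
    noise_abs: float = 0.0
    n_points: int = 12

    def __post_init__(self) -> None:
        if self.noise_rel < 0 or self.noise_abs < 0:
            raise ValueError("noise levels must be non-negative")
        if self.n_points < 4:
            raise ValueError("n_points must be at least 4")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _add_noise(signal: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    out = np.asarray(signal, dtype=float)
    if cfg.noise_rel > 0:
        out = out * (1.0 + cfg.noise_rel * rng.standard_normal(out.shape))
    if cfg.noise_abs > 0:
        out = out + cfg.noise_abs * rng.standard_normal(out.shape)
    return out


# ---------------------------------------------------------------------------
# fluorescence titration

def gen_titration(
    kd_nM: float,
    protein_series_uM: np.ndarray,
    cfg: SimConfig,
    flavin_total_nM: float = 100.0,
    f_free: float = 1.0,
    f_bound: float = 0.05,
    temperature_K: float = 298.15,
    quenching: bool = True,
) -> TitrationCurve:
    """Simulate a quenching titration of apoprotein into fixed flavin.

    Emission at each point is ``f_free·[flavin free] + f_bound·[bound]``
    with the bound concentration from the exact single-site quadratic mass
    balance; multiplicative Gaussian noise is applied afterwards.  In the
    default quenching mode ``f_bound < f_free`` is enforced.
    """
    protein_series_uM = np.asarray(protein_series_uM, dtype=float)
    if kd_nM < 0 or flavin_total_nM <= 0 or np.any(protein_series_uM < 0):
        raise ValueError("concentrations must be non-negative, flavin total positive")
    if quenching and f_bound > f_free:
        raise ValueError("quenching mode requires f_bound <= f_free")
    c = bound_concentration(protein_series_uM * 1000.0, flavin_total_nM, kd_nM)
    emission = f_free * (flavin_total_nM - c) + f_bound * c
    emission = _add_noise(emission, cfg, cfg.rng())
    return TitrationCurve(
        protein_uM=protein_series_uM,
        emission=emission,
        flavin_total_nM=flavin_total_nM,
        temperature_K=temperature_K,
    )


# ---------------------------------------------------------------------------
# reductive equilibration of two Nernstian couples

@dataclass(frozen=True)
class EquilibrationTruth:
    """Ground truth for a dye-coupled reductive equilibration.

    Midpoints in mV, totals in µM, influx in µM electron equivalents per
    minute (the constant delivery rate of the reducing system).
    """

    e_enzyme_mV: float = -138.0
    e_dye_mV: float = -125.0
    n_F: int = 2
    n_D: int = 2
    flavin_total_uM: float = 65.0
    dye_total_uM: float = 40.0
    influx_uM_eq_min: float = 5.0

    def __post_init__(self) -> None:
        if self.n_F not in (1, 2) or self.n_D not in (1, 2):
            raise ValueError("electron counts must be 1 or 2")
        if self.flavin_total_uM <= 0 or self.dye_total_uM <= 0:
            raise ValueError("totals must be positive")
        if self.influx_uM_eq_min <= 0:
            raise ValueError("influx must be positive")

    @property
    def capacity_uM_eq(self) -> float:
        return self.n_F * self.flavin_total_uM + self.n_D * self.dye_total_uM


def _fraction_reduced(e_h: float, e_mid: float, n: int, nu: float) -> float:
    # Nernst: [ox]/[red] = 10^(n (E_h - E_mid)/nu)
    return 1.0 / (1.0 + 10.0 ** (n * (e_h - e_mid) / nu))


def solution_potential(
    truth: EquilibrationTruth, q_uM_eq: float, nu: float = NERNST_SLOPE_MV
) -> float:
    """Common solution potential E_h (mV) at a given delivered charge.

    Solves ``n_F F_tot f_red(E) + n_D D_tot f_red(E) = Q`` by root
    bracketing; E_h is monotone non-increasing in Q.  Returns ±inf at the
    fully oxidized / fully reduced extremes.
    """
    cap = truth.capacity_uM_eq
    if q_uM_eq <= 0:
        return np.inf
    if q_uM_eq >= cap:
        return -np.inf

    def balance(e_h: float) -> float:
        return (
            truth.n_F * truth.flavin_total_uM
            * _fraction_reduced(e_h, truth.e_enzyme_mV, truth.n_F, nu)
            + truth.n_D * truth.dye_total_uM
            * _fraction_reduced(e_h, truth.e_dye_mV, truth.n_D, nu)
            - q_uM_eq
        )

    lo = min(truth.e_enzyme_mV, truth.e_dye_mV) - 2000.0
    hi = max(truth.e_enzyme_mV, truth.e_dye_mV) + 2000.0
    return float(optimize.brentq(balance, lo, hi, xtol=1e-10))


def equilibrate_fractions(
    truth: EquilibrationTruth,
    times_min: np.ndarray,
    nu: float = NERNST_SLOPE_MV,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless reduced fractions (enzyme, dye) at each time point.

    Delivered equivalents Q(t) = min(influx·t, capacity) are partitioned
    between the couples by the common solution potential.
    """
    times_min = np.asarray(times_min, dtype=float)
    f_red_e = np.empty_like(times_min)
    f_red_d = np.empty_like(times_min)
    for i, t in enumerate(times_min):
        q = min(truth.influx_uM_eq_min * t, truth.capacity_uM_eq)
        e_h = solution_potential(truth, q, nu)
        if np.isposinf(e_h):
            f_red_e[i] = f_red_d[i] = 0.0
        elif np.isneginf(e_h):
            f_red_e[i] = f_red_d[i] = 1.0
        else:
            f_red_e[i] = _fraction_reduced(e_h, truth.e_enzyme_mV, truth.n_F, nu)
            f_red_d[i] = _fraction_reduced(e_h, truth.e_dye_mV, truth.n_D, nu)
    return f_red_e, f_red_d


def gen_equilibration(
    truth: EquilibrationTruth,
    eps: ExtinctionMatrix,
    times_min: np.ndarray,
    cfg: SimConfig,
    path_cm: float = 1.0,
    nu: float = NERNST_SLOPE_MV,
) -> AbsorbanceSeries:
    """Simulate the two-wavelength absorbance record of an equilibration.

    Species concentrations at each time follow the instantaneous-
    equilibrium partitioning of the delivered charge; absorbances are the
    extinction-matrix linear combination of the four species plus noise.
    """
    times_min = np.asarray(times_min, dtype=float)
    if times_min[0] < 0 or np.any(np.diff(times_min) <= 0):
        raise ValueError("times must start at >= 0 and increase strictly")
    f_red_e, f_red_d = equilibrate_fractions(truth, times_min, nu)
    # concentrations µM, species order (flavin_ox, flavin_red, dye_ox, dye_red)
    conc = np.column_stack([
        truth.flavin_total_uM * (1.0 - f_red_e),
        truth.flavin_total_uM * f_red_e,
        truth.dye_total_uM * (1.0 - f_red_d),
        truth.dye_total_uM * f_red_d,
    ])
    absorbance = path_cm * conc @ (eps.eps / 1000.0)
    absorbance = _add_noise(absorbance, cfg, cfg.rng())
    return AbsorbanceSeries(
        times_min=times_min,
        absorbance=absorbance,
        flavin_total_uM=truth.flavin_total_uM,
        dye_total_uM=truth.dye_total_uM,
        path_cm=path_cm,
    )


# ---------------------------------------------------------------------------
# steady-state rate tables

def gen_rates_mm(
    km_uM: float,
    kcat_s: float,
    e_tot_uM: float,
    s_series_uM: np.ndarray,
    cfg: SimConfig,
) -> RateDataset:
    """Michaelis–Menten initial-rate table: v = kcat·E·S/(Km+S) + noise."""
    if km_uM <= 0 or kcat_s <= 0 or e_tot_uM <= 0:
        raise ValueError("km, kcat and enzyme total must be positive")
    s = np.asarray(s_series_uM, dtype=float)
    v = kcat_s * e_tot_uM * s / (km_uM + s)
    v = _add_noise(v, cfg, cfg.rng())
    return RateDataset(substrate_uM=s, velocity=v, enzyme_total_uM=e_tot_uM)


def gen_rates_pingpong(
    kcat_s: float,
    ka_uM: float,
    kb_uM: float,
    e_tot_uM: float,
    a_series_uM: np.ndarray,
    b_levels_uM: np.ndarray,
    cfg: SimConfig,
) -> PingPongDataset:
    """Ping-pong bi-bi design grid: every A level at every fixed B level.

    v = kcat·E·A·B/(Ka·B + Kb·A + A·B) + noise.  The default analysis
    design uses four fixed co-substrate (FMN) levels of 10/20/50/100 µM.
    """
    if min(kcat_s, ka_uM, kb_uM, e_tot_uM) <= 0:
        raise ValueError("all kinetic parameters must be positive")
    a_series_uM = np.asarray(a_series_uM, dtype=float)
    b_levels_uM = np.asarray(b_levels_uM, dtype=float)
    a, b = [x.ravel() for x in np.meshgrid(a_series_uM, b_levels_uM)]
    v = kcat_s * e_tot_uM * a * b / (ka_uM * b + kb_uM * a + a * b)
    v = _add_noise(v, cfg, cfg.rng())
    return PingPongDataset(a_uM=a, b_uM=b, velocity=v, enzyme_total_uM=e_tot_uM)


def gen_rates_ternary(
    kcat_s: float,
    ka_uM: float,
    kb_uM: float,
    e_tot_uM: float,
    a_series_uM: np.ndarray,
    b_levels_uM: np.ndarray,
    cfg: SimConfig,
    kia_uM: float | None = None,
) -> PingPongDataset:
    """Sequential (ternary-complex) rate-law grid, as a negative control.

    v = kcat·E·A·B/(Kia·Kb + Ka·B + Kb·A + A·B); its double-reciprocal
    lines intersect, so the ping-pong parallelism diagnostic should reject
    such data.
    """
    kia = ka_uM if kia_uM is None else kia_uM
    a_series_uM = np.asarray(a_series_uM, dtype=float)
    b_levels_uM = np.asarray(b_levels_uM, dtype=float)
    a, b = [x.ravel() for x in np.meshgrid(a_series_uM, b_levels_uM)]
    v = kcat_s * e_tot_uM * a * b / (kia * kb_uM + ka_uM * b + kb_uM * a + a * b)
    v = _add_noise(v, cfg, cfg.rng())
    return PingPongDataset(a_uM=a, b_uM=b, velocity=v, enzyme_total_uM=e_tot_uM)


# ---------------------------------------------------------------------------
# stopped-flow traces

def gen_trace(
    kobs_s: float,
    amplitude: float,
    offset: float,
    dt_s: float,
    n: int,
    cfg: SimConfig,
    nadh_uM: float = np.nan,
) -> StoppedFlowTrace:
    """Single-exponential stopped-flow trace A(t) = offset + amp·e^(−k t)."""
    if kobs_s < 0 or dt_s <= 0 or n < 20:
        raise ValueError("kobs >= 0, dt > 0 and n >= 20 required")
    t = np.arange(1, n + 1) * dt_s  # post dead time, t > 0
    a = offset + amplitude * np.exp(-kobs_s * t)
    a = _add_noise(a, cfg, cfg.rng())
    return StoppedFlowTrace(t_s=t, a450=a, nadh_uM=nadh_uM)


# ---------------------------------------------------------------------------
# SAXS mixtures of homogeneous spheres

def gen_saxs_mixture(
    weights: np.ndarray,
    radii_A: np.ndarray,
    q: np.ndarray,
    cfg: SimConfig,
    scale: float = 1.0,
    names: tuple[str, ...] | None = None,
) -> tuple[ScatteringCurve, FormFactorSet]:
    """Scattering curve of a weighted sphere mixture, with its form factors.

    I(q) = scale · Σ w_i I_sphere(q; R_i) + Gaussian noise; the per-point
    uncertainty actually used to perturb the curve is reported as sigma.
    Weights must be non-negative and sum to 1.
    """
    weights = np.asarray(weights, dtype=float)
    radii_A = np.asarray(radii_A, dtype=float)
    q = np.asarray(q, dtype=float)
    if weights.shape != radii_A.shape:
        raise ValueError("weights and radii must have equal length")
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    comps = np.vstack([sphere_intensity(q, r) for r in radii_A])
    clean = scale * weights @ comps
    sigma = cfg.noise_rel * clean + cfg.noise_abs
    if np.all(sigma <= 0):
        sigma = np.ones_like(clean)  # noiseless curve: unit uncertainties
    intensity = clean + sigma * cfg.rng().standard_normal(clean.shape) \
        if (cfg.noise_rel > 0 or cfg.noise_abs > 0) else clean
    if names is None:
        names = tuple(f"sphere_R{r:g}" for r in radii_A)
    curve = ScatteringCurve(q=q, intensity=intensity, sigma=sigma)
    ff = FormFactorSet(q=q, intensities=comps, names=names)
    return curve, ff
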