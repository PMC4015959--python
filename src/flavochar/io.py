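"""Plain-text readers and writers for the instrument-output formats.

Every dataset travels as a small CSV (or whitespace ``.dat`` for SAXS) with
a header row; experiment-level metadata (totals, temperature, ground truth
of a simulation) goes into a JSON manifest next to the data files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binding_thermo import TitrationCurve
from .oligomer_state import FormFactorSet, ScatteringCurve, SECMarkerTable
from .redox_potentiometry import AbsorbanceSeries
from .steady_state_kinetics import PingPongDataset, RateDataset
from .transient_kinetics import StoppedFlowTrace

__all__ = [
    "read_titration_csv", "write_titration_csv",
    "read_potentiometry_csv", "write_potentiometry_csv",
    "read_rates_csv", "write_rates_csv",
    "read_pingpong_csv", "write_pingpong_csv",
    "read_trace_csv", "write_trace_csv",
    "read_markers_csv", "write_markers_csv",
    "read_saxs_dat", "write_saxs_dat",
    "read_form_factors", "write_form_factors",
    "write_manifest", "read_manifest",
]


def write_manifest(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# -- titration --------------------------------------------------------------

def write_titration_csv(path: str | Path, curve: TitrationCurve) -> None:
    pd.DataFrame(
        {"protein_uM": curve.protein_uM, "emission": curve.emission}
    ).to_csv(path, index=False)


def read_titration_csv(
    path: str | Path,
    flavin_total_nM: float = 100.0,
    temperature_K: float = 298.15,
) -> TitrationCurve:
    df = pd.read_csv(path)
    return TitrationCurve(
        protein_uM=df["protein_uM"].to_numpy(),
        emission=df["emission"].to_numpy(),
        flavin_total_nM=flavin_total_nM,
        temperature_K=temperature_K,
        dilution_factor=(
            df["dilution_factor"].to_numpy() if "dilution_factor" in df else None
        ),
    )


# -- potentiometry ----------------------------------------------------------

def write_potentiometry_csv(path: str | Path, series: AbsorbanceSeries) -> None:
    df = pd.DataFrame({"t_min": series.times_min})
    df["A_450"] = series.absorbance[:, 0]
    df["A_dye"] = series.absorbance[:, 1]
    df.to_csv(path, index=False)


def read_potentiometry_csv(
    path: str | Path,
    flavin_total_uM: float,
    dye_total_uM: float,
    path_cm: float = 1.0,
) -> AbsorbanceSeries:
    df = pd.read_csv(path)
    return AbsorbanceSeries(
        times_min=df["t_min"].to_numpy(),
        absorbance=df[["A_450", "A_dye"]].to_numpy(),
        flavin_total_uM=flavin_total_uM,
        dye_total_uM=dye_total_uM,
        path_cm=path_cm,
    )


# -- steady-state rates -----------------------------------------------------

def write_rates_csv(path: str | Path, data: RateDataset) -> None:
    pd.DataFrame(
        {"S_uM": data.substrate_uM, "v_uM_per_s": data.velocity}
    ).to_csv(path, index=False)


def read_rates_csv(path: str | Path, enzyme_total_uM: float) -> RateDataset:
    df = pd.read_csv(path)
    return RateDataset(
        substrate_uM=df["S_uM"].to_numpy(),
        velocity=df["v_uM_per_s"].to_numpy(),
        enzyme_total_uM=enzyme_total_uM,
    )


def write_pingpong_csv(path: str | Path, data: PingPongDataset) -> None:
    pd.DataFrame(
        {"A_uM": data.a_uM, "B_uM": data.b_uM, "v_uM_per_s": data.velocity}
    ).to_csv(path, index=False)


def read_pingpong_csv(path: str | Path, enzyme_total_uM: float) -> PingPongDataset:
    df = pd.read_csv(path)
    return PingPongDataset(
        a_uM=df["A_uM"].to_numpy(),
        b_uM=df["B_uM"].to_numpy(),
        velocity=df["v_uM_per_s"].to_numpy(),
        enzyme_total_uM=enzyme_total_uM,
    )


# -- stopped flow -----------------------------------------------------------

def write_trace_csv(path: str | Path, trace: StoppedFlowTrace) -> None:
    pd.DataFrame({"t_s": trace.t_s, "A450": trace.a450}).to_csv(path, index=False)


def read_trace_csv(path: str | Path, nadh_uM: float = np.nan) -> StoppedFlowTrace:
    df = pd.read_csv(path)
    return StoppedFlowTrace(
        t_s=df["t_s"].to_numpy(), a450=df["A450"].to_numpy(), nadh_uM=nadh_uM
    )


# -- SEC markers ------------------------------------------------------------

def write_markers_csv(path: str | Path, table: SECMarkerTable) -> None:
    pd.DataFrame(table.markers, columns=["name", "kDa", "mL"]).to_csv(
        path, index=False
    )


def read_markers_csv(path: str | Path) -> SECMarkerTable:
    df = pd.read_csv(path)
    return SECMarkerTable(
        markers=[(str(r["name"]), float(r["kDa"]), float(r["mL"]))
                 for _, r in df.iterrows()]
    )


# -- SAXS -------------------------------------------------------------------

def write_saxs_dat(path: str | Path, curve: ScatteringCurve, header: str = "") -> None:
    """Three-column (q, I, sigma) whitespace file with '#' comments."""
    lines = [f"# {h}" for h in header.splitlines() if h]
    lines.append("# q_A^-1  I  sigma")
    for q, i, s in zip(curve.q, curve.intensity, curve.sigma):
        lines.append(f"{q:.8e} {i:.8e} {s:.8e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_saxs_dat(path: str | Path) -> ScatteringCurve:
    arr = np.loadtxt(path, comments="#")
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise ValueError("SAXS .dat file must have three columns (q, I, sigma)")
    return ScatteringCurve(q=arr[:, 0], intensity=arr[:, 1], sigma=arr[:, 2])


def write_form_factors(path: str | Path, ff: FormFactorSet) -> None:
    """Columns: q then one intensity column per component (named in header)."""
    lines = ["# q_A^-1 " + " ".join(ff.names)]
    for j in range(ff.q.size):
        row = " ".join(f"{ff.intensities[i, j]:.8e}" for i in range(len(ff.names)))
        lines.append(f"{ff.q[j]:.8e} {row}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_form_factors(path: str | Path) -> FormFactorSet:
    text = Path(path).read_text().splitlines()
    names: tuple[str, ...] = ()
    for line in text:
        if line.startswith("#"):
            toks = line.lstrip("# ").split()
            if len(toks) > 1 and toks[0].startswith("q"):
                names = tuple(toks[1:])
            break
    arr = np.loadtxt(path, comments="#")
    ncomp = arr.shape[1] - 1
    if not names or len(names) != ncomp:
        names = tuple(f"component_{i + 1}" for i in range(ncomp))
    return FormFactorSet(q=arr[:, 0], intensities=arr[:, 1:].T, names=names)
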