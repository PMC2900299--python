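"""Delimited-text I/O for every exchange format in the workflow.

All tables are plain CSV with headers.  Plate-reader data travels in long
format (strain, condition, moi, replicate, time_h, od600); trajectories as
(tau, E, Estar, lambda, total); derivative-profile heatmaps as a matrix
with the tau grid in the header; dendrograms as Newick.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterResult, linkage_to_newick, profile_matrix
from .curves import DerivativeProfile, GrowthCurve, NormalizedCurve
from .model import NondimParams, Trajectory
from .titer import PhageTimecourse

PLATE_COLUMNS = ["strain", "condition", "moi", "replicate", "time_h", "od600"]


def write_plate_curves(curves: list[GrowthCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, a in zip(c.t, c.A):
            rows.append((c.strain_id, c.condition,
                         "" if c.moi is None else c.moi,
                         c.replicate, t, a))
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def read_plate_curves(path: str | Path) -> list[GrowthCurve]:
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    curves = []
    for (strain, cond, rep), g in df.groupby(
            ["strain", "condition", "replicate"], sort=True):
        g = g.sort_values("time_h")
        moi = g["moi"].iloc[0]
        curves.append(GrowthCurve(
            strain_id=str(strain), condition=str(cond),
            t=g["time_h"].to_numpy(), A=g["od600"].to_numpy(),
            moi=None if pd.isna(moi) else float(moi), replicate=int(rep),
        ))
    return curves


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    traj.to_dataframe().to_csv(path, index=False)


def read_trajectory(path: str | Path,
                    params: NondimParams | None = None) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        tau=df["tau"].to_numpy(), E=df["E"].to_numpy(),
        Estar=df["Estar"].to_numpy(), lam=df["lambda"].to_numpy(),
        params=params or NondimParams(kappa=0.0, b=0.0, f=0.0),
    )


def write_normalized_curves(curves: list[NormalizedCurve],
                            path: str | Path) -> None:
    rows = []
    for c in curves:
        for tau, y in zip(c.tau, c.y):
            rows.append((c.strain_id, c.condition,
                         "" if c.moi is None else c.moi, tau, y))
    pd.DataFrame(rows, columns=["strain", "condition", "moi", "tau", "y"]) \
        .to_csv(path, index=False)


def write_profiles(profiles: list[DerivativeProfile], path: str | Path) -> None:
    """Profiles-by-grid matrix: one row per strain, tau values as columns."""
    ids, mat = profile_matrix(profiles)
    cols = [f"{t:.6g}" for t in profiles[0].tau_grid]
    df = pd.DataFrame(mat, columns=cols)
    df.insert(0, "strain", ids)
    df.to_csv(path, index=False)


def write_clusters(result: ClusterResult, path: str | Path) -> None:
    pd.DataFrame({"strain_id": result.ids, "cluster": result.labels}) \
        .to_csv(path, index=False)


def write_newick(result: ClusterResult, path: str | Path) -> None:
    Path(path).write_text(linkage_to_newick(result.linkage, result.ids) + "\n")


def write_titer(tc: PhageTimecourse, path: str | Path) -> None:
    df = pd.DataFrame({"strain": tc.strain_id, "t_min": tc.t_min,
                       "pfu_ml": tc.pfu_ml})
    if tc.counts is not None:
        df["count"] = tc.counts
        df["dilution"] = tc.dilutions
    df.to_csv(path, index=False)


def read_titer(path: str | Path) -> list[PhageTimecourse]:
    df = pd.read_csv(path)
    out = []
    for strain, g in df.groupby("strain", sort=True):
        g = g.sort_values("t_min")
        kwargs = {}
        if "count" in g.columns:
            kwargs = {"counts": g["count"].to_numpy(),
                      "dilutions": g["dilution"].to_numpy()}
        out.append(PhageTimecourse(
            strain_id=str(strain), t_min=g["t_min"].to_numpy(),
            pfu_ml=g["pfu_ml"].to_numpy(), **kwargs))
    return out
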