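"""Readers and writers for the pipeline's on-disk formats.

Trajectory CSV dialect (one file per condition, long format): columns
``molecule_id, frame, time_s, laser, i_dd, i_da, i_aa`` — intensity cells
are empty on frames where that channel is not read (ALEX).  Ground truth is
a long CSV of per-molecule events; dwell tables carry the condition fields
alongside each duration; manifests are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import Condition, DwellSample, Trajectory

__all__ = [
    "trajectories_to_frame",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "write_truth_csv",
    "read_truth_csv",
    "write_dwells_csv",
    "read_dwells_csv",
    "write_manifest",
    "read_manifest",
    "write_fit_json",
    "condition_to_dict",
    "condition_from_dict",
]


def condition_to_dict(cond: Condition) -> dict:
    return {
        "sen1_conc_nM": cond.sen1_conc * 1e9,
        "atp_conc_uM": cond.atp_conc,
        "rna_ext_length_nt": cond.rna_ext_length,
        "construct": cond.construct,
        "n_molecules": cond.n_molecules,
        "label_distance_bp": cond.label_distance_bp,
    }


def condition_from_dict(d: dict) -> Condition:
    return Condition(
        sen1_conc=float(d.get("sen1_conc_nM", 10.0)) * 1e-9,
        atp_conc=float(d.get("atp_conc_uM", 1100.0)),
        rna_ext_length=float(d.get("rna_ext_length_nt", 28.0)),
        construct=str(d.get("construct", "no_mismatch")),
        n_molecules=int(d.get("n_molecules", 1)),
        label_distance_bp=d.get("label_distance_bp"),
    )


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    rows = []
    for traj in trajectories:
        for i in range(traj.n_frames):
            rows.append(
                (
                    traj.molecule_id,
                    i,
                    traj.times[i],
                    traj.laser[i],
                    traj.i_dd[i],
                    traj.i_da[i],
                    traj.i_aa[i],
                )
            )
    return pd.DataFrame(
        rows, columns=["molecule_id", "frame", "time_s", "laser", "i_dd", "i_da", "i_aa"]
    )


def write_trajectories_csv(trajectories: Sequence[Trajectory], path) -> None:
    df = trajectories_to_frame(trajectories)
    # empty cells for channels not read on that frame
    df.to_csv(path, index=False, float_format="%.6g", na_rep="")


def read_trajectories_csv(
    path, condition: Optional[Condition] = None
) -> list[Trajectory]:
    """Read a long-format trajectory CSV back into Trajectory objects."""
    df = pd.read_csv(path)
    required = {"molecule_id", "frame", "time_s", "laser", "i_dd", "i_da", "i_aa"}
    if missing := required - set(df.columns):
        raise ValueError(f"trajectory CSV missing columns {sorted(missing)}")
    cond = condition or Condition()
    out = []
    for mol_id, g in df.groupby("molecule_id", sort=False):
        g = g.sort_values("frame")
        times = g["time_s"].to_numpy(dtype=float)
        if len(times) > 1:
            period = float(np.median(np.diff(times)))
            n_lasers = max(len(pd.unique(g["laser"])), 1)
        else:
            period, n_lasers = 0.02, 2
        out.append(
            Trajectory(
                times=times,
                laser=g["laser"].to_numpy(dtype=object),
                i_dd=g["i_dd"].to_numpy(dtype=float),
                i_da=g["i_da"].to_numpy(dtype=float),
                i_aa=g["i_aa"].to_numpy(dtype=float),
                condition=cond,
                molecule_id=str(mol_id),
                channel_period=period * n_lasers,
            )
        )
    return out


def write_truth_csv(truth_rows: Sequence[dict], path) -> None:
    pd.DataFrame(truth_rows).to_csv(path, index=False, float_format="%.9g")


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_dwells_csv(sample: DwellSample, path) -> None:
    cond = condition_to_dict(sample.condition)
    df = pd.DataFrame(
        {
            "duration_s": sample.durations,
            "censored": sample.censored_flags.astype(int),
        }
    )
    df["state"] = sample.state
    for k, v in cond.items():
        df[k] = v
    df.to_csv(path, index=False, float_format="%.9g")


def read_dwells_csv(path) -> DwellSample:
    df = pd.read_csv(path)
    cond = condition_from_dict(df.iloc[0].to_dict()) if len(df) else Condition()
    state = str(df["state"].iloc[0]) if len(df) else "stall"
    return DwellSample(
        durations=df["duration_s"].to_numpy(dtype=float),
        condition=cond,
        state=state,
        censored_flags=df["censored"].to_numpy(dtype=bool)
        if "censored" in df
        else None,
    )


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_fit_json(result, path) -> None:
    """Serialize a FitResult to JSON (estimates, ses, redchi, sizes)."""
    payload = {
        "model_id": result.model.model_id,
        "estimates": result.estimates,
        "ses": result.ses,
        "reduced_chisq": None
        if result.reduced_chisq != result.reduced_chisq
        else result.reduced_chisq,
        "n_points": result.n_points,
        "n_free": result.n_free,
        "success": result.success,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
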