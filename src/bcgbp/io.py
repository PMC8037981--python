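"""CSV / JSON readers and writers for the pipeline's intermediate files.

File formats (all plain text):

* recording: ``t,ch_back,ch_seat`` — seconds and signal units
* references: ``epoch_start_s,sbp,dbp`` — seconds and mmHg
* phase: ``t,phase_back,phase_seat`` — seconds and wrapped radians
* epoch bundle: one row per epoch — ``subject,session,sbp,dbp`` followed by
  the 2 x L phase samples (back channel then seat channel)
* sim config: flat ``key,value`` pairs mirroring SimConfig field names
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import PhaseEpoch
from .hht import PhaseSeries
from .synthbcg import BPReference, RawRecording, SimConfig

__all__ = [
    "write_recording", "read_recording",
    "write_refs", "read_refs",
    "write_phase", "read_phase",
    "write_epoch_bundle", "read_epoch_bundle",
    "write_sim_config", "read_sim_config",
]


def write_recording(rec: RawRecording, path: str | Path) -> None:
    df = pd.DataFrame({"t": rec.times, "ch_back": rec.ch_back, "ch_seat": rec.ch_seat})
    df.to_csv(path, index=False, float_format="%.10g")


def read_recording(path: str | Path, fs: float | None = None, session: str = "rest") -> RawRecording:
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    if fs is None:
        fs = float(np.round(1.0 / np.median(np.diff(t)), 6))
    return RawRecording(
        ch_back=df["ch_back"].to_numpy(),
        ch_seat=df["ch_seat"].to_numpy(),
        fs=fs,
        session=session,
        t0=float(t[0]),
    )


def write_refs(refs: list[BPReference], path: str | Path) -> None:
    pd.DataFrame(
        {
            "epoch_start_s": [r.epoch_start_s for r in refs],
            "sbp": [r.sbp for r in refs],
            "dbp": [r.dbp for r in refs],
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_refs(path: str | Path) -> list[BPReference]:
    df = pd.read_csv(path)
    return [
        BPReference(epoch_start_s=float(r.epoch_start_s), sbp=float(r.sbp), dbp=float(r.dbp))
        for r in df.itertuples()
    ]


def write_phase(back: PhaseSeries, seat: PhaseSeries, path: str | Path) -> None:
    if len(back) != len(seat) or back.fs != seat.fs:
        raise ValueError("phase channels must share length and sampling rate")
    t = np.arange(len(back)) / back.fs
    pd.DataFrame(
        {"t": t, "phase_back": back.phase, "phase_seat": seat.phase}
    ).to_csv(path, index=False, float_format="%.10g")


def read_phase(path: str | Path, fs: float | None = None) -> tuple[PhaseSeries, PhaseSeries]:
    df = pd.read_csv(path)
    if fs is None:
        fs = float(np.round(1.0 / np.median(np.diff(df["t"].to_numpy())), 6))
    return (
        PhaseSeries(phase=df["phase_back"].to_numpy(), fs=fs),
        PhaseSeries(phase=df["phase_seat"].to_numpy(), fs=fs),
    )


def write_epoch_bundle(epochs: list[PhaseEpoch], path: str | Path) -> None:
    if not epochs:
        raise ValueError("no epochs to write")
    n = epochs[0].n_samples
    rows = []
    for e in epochs:
        if e.n_samples != n:
            raise ValueError("epochs of mixed length in one bundle")
        rows.append(
            [e.subject_id, e.session, e.sbp, e.dbp, *e.phase_back, *e.phase_seat]
        )
    cols = (
        ["subject", "session", "sbp", "dbp"]
        + [f"pb{i}" for i in range(n)]
        + [f"ps{i}" for i in range(n)]
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.8g")


def read_epoch_bundle(path: str | Path) -> list[PhaseEpoch]:
    df = pd.read_csv(path)
    n = (df.shape[1] - 4) // 2
    pb = df[[f"pb{i}" for i in range(n)]].to_numpy()
    ps = df[[f"ps{i}" for i in range(n)]].to_numpy()
    return [
        PhaseEpoch(
            phase_back=pb[i],
            phase_seat=ps[i],
            sbp=float(df["sbp"].iloc[i]),
            dbp=float(df["dbp"].iloc[i]),
            session=str(df["session"].iloc[i]),
            subject_id=str(df["subject"].iloc[i]),
        )
        for i in range(df.shape[0])
    ]


def write_sim_config(cfg: SimConfig, path: str | Path) -> None:
    lines = ["key,value"]
    for f in dataclasses.fields(cfg):
        lines.append(f"{f.name},{getattr(cfg, f.name)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sim_config(path: str | Path) -> SimConfig:
    df = pd.read_csv(path)
    kw = {}
    for _, row in df.iterrows():
        key, value = str(row["key"]), row["value"]
        if key in ("session",):
            kw[key] = str(value)
        elif key in ("seed",):
            kw[key] = int(value)
        elif key == "delta_dbp":
            kw[key] = None if pd.isna(value) or str(value) == "None" else float(value)
        else:
            kw[key] = float(value)
    return SimConfig(**kw)
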