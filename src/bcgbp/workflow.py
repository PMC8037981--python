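"""End-to-end study orchestration: simulate -> filter -> EMD -> phase ->
epochs -> split -> train -> evaluate, from one config, with a manifest.

One top-level seed fans out deterministically (via ``numpy.random
.SeedSequence`` spawning) to the cohort sampler, the split and every CV
fold, so a single integer reproduces the whole study bit-for-bit on the
same platform.  Every intermediate file is checksummed into the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as bio
from .cnnreg import ArchitectureSpec, TrainSettings, predict_bp, train_model
from .dataset import PhaseEpoch, make_cv_folds, segment_epochs, split_train_test
from .evaluate import ErrorSummary, bland_altman_plot, bland_altman_table, error_summary
from .hht import PhaseSeries, SiftSettings, emd_decompose, hilbert_phase
from .preprocess import FilterSpec, bandpass_filter
from .synthbcg import RawRecording, sample_cohort, simulate_session

__all__ = ["StudyConfig", "run_study", "recording_to_phase", "subject_epochs"]

VERSION = "0.1.0"


@dataclass(frozen=True)
class StudyConfig:
    """One full study replica: cohort size, sessions, splits, training budget."""

    n_subjects: int = 30
    sessions: tuple[str, ...] = ("rest",)
    seed: int = 0
    split_mode: str = "epoch"
    split_ratio: float = 0.8
    cv_folds: int = 10
    batch_size: int = 16
    max_epochs: int = 25
    early_stop_patience: int = 7
    learning_rate: float = 0.001
    write_intermediates: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sessions" in raw:
            raw["sessions"] = tuple(raw["sessions"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sessions"] = list(d["sessions"])
        return d


def recording_to_phase(
    rec: RawRecording,
    filter_spec: FilterSpec | None = None,
    sift: SiftSettings = SiftSettings(),
) -> tuple[PhaseSeries, PhaseSeries]:
    """Band-pass both channels, take IMF(1) of each, return their phases."""
    filtered = bandpass_filter(rec, filter_spec)
    phases = []
    for chan in (filtered.ch_back, filtered.ch_seat):
        imfset = emd_decompose(chan, sift)
        if imfset.n == 0:
            raise ValueError("channel decomposed to zero IMFs; no oscillation present")
        phases.append(hilbert_phase(imfset.imfs[0], rec.fs))
    return phases[0], phases[1]


def subject_epochs(
    cfg, subject_id: str, out_dir: Path | None = None
) -> list[PhaseEpoch]:
    """Simulate one subject's session and run it to phase epochs."""
    rec, refs = simulate_session(cfg)
    back, seat = recording_to_phase(rec)
    if out_dir is not None:
        bio.write_recording(rec, out_dir / f"{subject_id}_{cfg.session}_rec.csv")
        bio.write_refs(refs, out_dir / f"{subject_id}_{cfg.session}_refs.csv")
        bio.write_phase(back, seat, out_dir / f"{subject_id}_{cfg.session}_phase.csv")
    return segment_epochs(back, seat, refs, session=cfg.session, subject_id=subject_id)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: StudyConfig, out_dir: str | Path) -> dict:
    """Run the complete replica and return the manifest (also written to disk).

    Produces, per session, one :class:`ErrorSummary` for SBP and one for DBP
    on the held-out test split, plus Bland–Altman tables and plots.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_dir = out / "data"
    report_dir = out / "report"
    data_dir.mkdir(exist_ok=True)
    report_dir.mkdir(exist_ok=True)

    master = np.random.SeedSequence(config.seed)
    # fixed fan-out: one child per stage, stable across runs
    cohort_seeds, split_seed, train_seed = master.spawn(3)
    split_seed = int(split_seed.generate_state(1)[0] % (2**31 - 1))
    train_seed = int(train_seed.generate_state(1)[0] % (2**31 - 1))

    summaries: list[ErrorSummary] = []
    files: dict[str, str] = {}
    session_seeds = cohort_seeds.spawn(len(config.sessions))
    for session, sseed in zip(config.sessions, session_seeds):
        cohort_seed = int(sseed.generate_state(1)[0] % (2**31 - 1))
        cohort = sample_cohort(config.n_subjects, session, seed=cohort_seed)
        epochs: list[PhaseEpoch] = []
        for i, cfg in enumerate(cohort):
            sid = f"s{i:02d}"
            epochs.extend(
                subject_epochs(
                    cfg, sid, data_dir if config.write_intermediates else None
                )
            )
        bundle_path = data_dir / f"{session}_epochs.csv"
        bio.write_epoch_bundle(epochs, bundle_path)

        plan = split_train_test(
            epochs, ratio=config.split_ratio, seed=split_seed, mode=config.split_mode
        )
        plan = make_cv_folds(plan, k=config.cv_folds)
        plan_path = data_dir / f"{session}_split.json"
        plan.to_json(plan_path)

        test_epochs = [epochs[i] for i in plan.test]
        for target in ("sbp", "dbp"):
            settings = TrainSettings(
                target=target,
                learning_rate=config.learning_rate,
                batch_size=config.batch_size,
                max_epochs=config.max_epochs,
                early_stop_patience=config.early_stop_patience,
                seed=train_seed,
            )
            model = train_model(epochs, plan, ArchitectureSpec(), settings)
            model_dir = out / f"model_{session}_{target}"
            model.save(model_dir)
            preds = predict_bp(model, test_epochs)
            refs = np.asarray([getattr(e, target) for e in test_epochs])
            summary = error_summary(preds, refs, target=target, session=session)
            summaries.append(summary)

            np.savetxt(
                report_dir / f"{session}_{target}_preds.csv",
                np.column_stack([preds, refs]),
                delimiter=",",
                header="estimate_mmhg,reference_mmhg",
                comments="",
            )
            table, _ = bland_altman_table(preds, refs)
            table.to_csv(report_dir / f"{session}_{target}_bland_altman.csv", index=False)
            bland_altman_plot(
                preds,
                refs,
                report_dir / f"{session}_{target}_bland_altman.png",
                title=f"{session} {target.upper()}",
            )

    summary_rows = [s.to_row() for s in summaries]
    import pandas as pd

    pd.DataFrame(summary_rows).to_csv(report_dir / "summary.csv", index=False)

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.suffix in (".csv", ".json", ".npz") and p.name != "manifest.json":
            files[str(p.relative_to(out))] = _sha256(p)
    manifest = {
        "tool_version": VERSION,
        "config": config.to_dict(),
        "stage_seeds": {"split": split_seed, "train": train_seed},
        "summaries": summary_rows,
        "checksums": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
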