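"""Phase epochs and leakage-safe train/test/CV bookkeeping.

The regression unit is a 10-s, two-channel wrapped-phase epoch paired with
one cuff reference (SBP, DBP).  Splits follow the study protocol: an 8:2
train/test division and a 10-fold partition of the training set for
cross-validated model selection.  Sessions (rest vs recovery) are never
mixed within one plan — pooling them is known to overfit — and a
subject-disjoint split mode is available for generalization claims.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hht import PhaseSeries
from .synthbcg import BPReference

__all__ = ["PhaseEpoch", "SplitPlan", "segment_epochs", "split_train_test", "make_cv_folds"]


@dataclass
class PhaseEpoch:
    """One 10-s two-channel phase window with its reference BP (mmHg)."""

    phase_back: np.ndarray
    phase_seat: np.ndarray
    sbp: float
    dbp: float
    session: str
    subject_id: str

    def __post_init__(self) -> None:
        self.phase_back = np.asarray(self.phase_back, dtype=float)
        self.phase_seat = np.asarray(self.phase_seat, dtype=float)
        if self.phase_back.shape != self.phase_seat.shape:
            raise ValueError("phase channels must have equal length")
        if not self.sbp > self.dbp:
            raise ValueError("sbp must exceed dbp")

    @property
    def n_samples(self) -> int:
        return self.phase_back.shape[0]


@dataclass
class SplitPlan:
    """Train/test indices plus optional CV folds over the train set."""

    train: np.ndarray
    test: np.ndarray
    seed: int
    mode: str
    folds: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=int)
        self.test = np.asarray(self.test, dtype=int)
        self.folds = [np.asarray(f, dtype=int) for f in self.folds]
        if np.intersect1d(self.train, self.test).size:
            raise ValueError("train and test sets overlap")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train": self.train.tolist(),
            "test": self.test.tolist(),
            "folds": [f.tolist() for f in self.folds],
            "seed": self.seed,
            "mode": self.mode,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            train=np.asarray(d["train"]),
            test=np.asarray(d["test"]),
            folds=[np.asarray(f) for f in d["folds"]],
            seed=d["seed"],
            mode=d["mode"],
        )


def segment_epochs(
    phase_back: PhaseSeries,
    phase_seat: PhaseSeries,
    refs: list[BPReference],
    epoch_s: float = 10.0,
    session: str = "rest",
    subject_id: str = "s0",
) -> list[PhaseEpoch]:
    """Cut one epoch per reference out of the two phase series.

    Each epoch starts at its reference's ``epoch_start_s`` and holds exactly
    ``round(epoch_s * fs)`` samples per channel.  A reference whose window
    leaves the recording is rejected with its index.
    """
    if phase_back.fs != phase_seat.fs or len(phase_back) != len(phase_seat):
        raise ValueError("phase channels must share length and sampling rate")
    fs = phase_back.fs
    n = len(phase_back)
    n_epoch = int(round(epoch_s * fs))
    epochs = []
    for k, ref in enumerate(refs):
        i0 = int(round(ref.epoch_start_s * fs))
        if i0 < 0 or i0 + n_epoch > n:
            raise ValueError(
                f"reference {k} at {ref.epoch_start_s} s: window of {epoch_s} s "
                f"does not fit in the {n / fs} s recording"
            )
        epochs.append(
            PhaseEpoch(
                phase_back=phase_back.phase[i0 : i0 + n_epoch].copy(),
                phase_seat=phase_seat.phase[i0 : i0 + n_epoch].copy(),
                sbp=ref.sbp,
                dbp=ref.dbp,
                session=session,
                subject_id=subject_id,
            )
        )
    return epochs


def _check_single_session(epochs: list[PhaseEpoch]) -> None:
    sessions = {e.session for e in epochs}
    if len(sessions) > 1:
        raise ValueError(f"epochs mix sessions {sorted(sessions)}; train per session")


def split_train_test(
    epochs: list[PhaseEpoch],
    ratio: float = 0.8,
    seed: int = 0,
    mode: str = "epoch",
) -> SplitPlan:
    """Random 8:2 train/test division, per-epoch or subject-disjoint.

    ``epoch`` mode shuffles epochs directly; ``subject`` mode shuffles
    subjects and assigns whole subjects to one side so no subject spans the
    split.  Deterministic for a fixed seed.
    """
    n = len(epochs)
    if n < 10:
        raise ValueError("need at least 10 epochs to split")
    _check_single_session(epochs)
    rng = np.random.default_rng(seed)
    n_train = int(round(ratio * n))
    if mode == "epoch":
        perm = rng.permutation(n)
        return SplitPlan(train=perm[:n_train], test=perm[n_train:], seed=seed, mode=mode)
    if mode == "subject":
        subjects = sorted({e.subject_id for e in epochs})
        if len(subjects) < 5:
            raise ValueError("subject mode needs at least 5 subjects")
        order = rng.permutation(len(subjects))
        train_idx: list[int] = []
        test_idx: list[int] = []
        count = 0
        for si in order:
            sid = subjects[si]
            members = [i for i, e in enumerate(epochs) if e.subject_id == sid]
            if count < n_train:
                train_idx.extend(members)
                count += len(members)
            else:
                test_idx.extend(members)
        return SplitPlan(
            train=np.asarray(train_idx), test=np.asarray(test_idx), seed=seed, mode=mode
        )
    raise ValueError(f"unknown split mode {mode!r}")


def make_cv_folds(plan: SplitPlan, k: int = 10, seed: int | None = None) -> SplitPlan:
    """Partition the train set into k disjoint folds of equal size +- 1."""
    if k > plan.train.size:
        raise ValueError(f"k={k} exceeds train set size {plan.train.size}")
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    shuffled = rng.permutation(plan.train)
    plan.folds = [np.sort(f) for f in np.array_split(shuffled, k)]
    return plan
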