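"""Timed experimental designs for neurofeedback and MID sessions.

A neurofeedback session consists of a pre-training baseline run without
feedback, two training runs with feedback, and a post-training transfer run
without feedback.  Every run alternates 20 s blocks of REST (neutral imagery)
and IMAGINE_REWARD (reward imagery); a short lead-in precedes the first block
so that the default run is 190 volumes at TR = 2 s.

The monetary incentive delay (MID) task presents cues signalling a large
(0-2.00 CHF), small (0-0.40 CHF) or zero reward, followed after a 2.5-3 s
delay by a speeded target.

Time convention: onsets in seconds, 0-based, half-open intervals
[onset, onset + duration).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

REST = "REST"
IMAGINE = "IMAGINE_REWARD"
LEAD_IN = "LEAD_IN"

CONDITIONS = (REST, IMAGINE, LEAD_IN)
RUN_TYPES = ("baseline", "training1", "training2", "transfer", "mid")
ARMS = ("standard", "inverted")
POLARITIES = ("standard", "inverted", "none")

#: reward-magnitude range (CHF) per MID cue type
MID_RANGES = {"large": (0.0, 2.00), "small": (0.0, 0.40), "none": (0.0, 0.0)}
MID_DELAY_RANGE = (2.5, 3.0)


class DesignError(ValueError):
    """Raised for malformed or inconsistent experimental designs."""


@dataclass(frozen=True)
class BlockSpec:
    """One condition block: half-open interval [onset, onset + duration)."""

    condition: str
    onset: float
    duration: float

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise DesignError(f"unknown condition {self.condition!r}")
        if self.duration <= 0:
            raise DesignError("block duration must be positive")
        if self.onset < 0:
            raise DesignError("block onset must be non-negative")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class RunDesign:
    """One run: ordered, non-overlapping blocks on a TR grid."""

    run_type: str
    tr: float
    n_volumes: int
    blocks: tuple[BlockSpec, ...]
    feedback_enabled: bool
    polarity: str

    def __post_init__(self):
        if self.run_type not in RUN_TYPES:
            raise DesignError(f"unknown run type {self.run_type!r}")
        if self.tr <= 0:
            raise DesignError("tr must be positive")
        if self.polarity not in POLARITIES:
            raise DesignError(f"unknown polarity {self.polarity!r}")
        expect_fb = self.run_type in ("training1", "training2")
        if self.feedback_enabled != expect_fb:
            raise DesignError(
                f"feedback_enabled must be {expect_fb} for run type {self.run_type}"
            )
        if self.feedback_enabled and self.polarity == "none":
            raise DesignError("feedback-enabled run needs a standard/inverted polarity")
        if not self.feedback_enabled and self.polarity != "none":
            raise DesignError("polarity must be 'none' when feedback is disabled")
        last_end = 0.0
        for blk in self.blocks:
            if blk.onset < last_end - 1e-9:
                raise DesignError("blocks overlap or onsets not increasing")
            last_end = blk.end
        covered = self.blocks[-1].end if self.blocks else 0.0
        if abs(self.n_volumes * self.tr - covered) > 1e-6:
            raise DesignError(
                f"n_volumes x tr ({self.n_volumes * self.tr}) != covered duration ({covered})"
            )

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr

    def volume_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr

    def condition_blocks(self, condition: str) -> list[BlockSpec]:
        return [b for b in self.blocks if b.condition == condition]


@dataclass(frozen=True)
class SessionDesign:
    """A full neurofeedback session for one subject."""

    subject_id: str
    arm: str
    study_id: str
    runs: tuple[RunDesign, ...]

    def __post_init__(self):
        if self.arm not in ARMS:
            raise DesignError(f"unknown arm {self.arm!r}")
        types = [r.run_type for r in self.runs]
        if types.count("baseline") != 1 or types.count("transfer") != 1:
            raise DesignError("session needs exactly one baseline and one transfer run")
        for r in self.runs:
            if r.feedback_enabled and r.polarity != self.arm:
                raise DesignError("training run polarity must match the session arm")

    def run(self, run_type: str) -> RunDesign:
        for r in self.runs:
            if r.run_type == run_type:
                return r
        raise DesignError(f"no run of type {run_type!r} in session")

    @property
    def training_runs(self) -> list[RunDesign]:
        return [r for r in self.runs if r.feedback_enabled]


@dataclass(frozen=True)
class MIDTrialSpec:
    """One MID trial: cue, reward magnitude, and cue-to-target delay."""

    cue_type: str
    magnitude: float
    cue_onset: float
    delay: float

    def __post_init__(self):
        if self.cue_type not in MID_RANGES:
            raise DesignError(f"unknown cue type {self.cue_type!r}")
        lo, hi = MID_RANGES[self.cue_type]
        if not (lo - 1e-12 <= self.magnitude <= hi + 1e-12):
            raise DesignError(
                f"magnitude {self.magnitude} outside [{lo}, {hi}] for cue {self.cue_type}"
            )
        if not (MID_DELAY_RANGE[0] - 1e-12 <= self.delay <= MID_DELAY_RANGE[1] + 1e-12):
            raise DesignError(f"delay {self.delay} outside {MID_DELAY_RANGE}")

    @property
    def target_onset(self) -> float:
        return self.cue_onset + self.delay


# ---------------------------------------------------------------------------
# construction


def _nf_run(run_type: str, polarity: str, *, tr: float, block_duration: float,
            n_block_pairs: int, lead_in_volumes: int) -> RunDesign:
    if block_duration <= 0 or abs(block_duration / tr - round(block_duration / tr)) > 1e-9:
        raise DesignError("block duration must be a positive multiple of tr")
    blocks = []
    t = lead_in_volumes * tr
    if lead_in_volumes:
        blocks.append(BlockSpec(LEAD_IN, 0.0, t))
    for _ in range(n_block_pairs):
        blocks.append(BlockSpec(REST, t, block_duration))
        t += block_duration
        blocks.append(BlockSpec(IMAGINE, t, block_duration))
        t += block_duration
    n_volumes = int(round(t / tr))
    return RunDesign(
        run_type=run_type,
        tr=tr,
        n_volumes=n_volumes,
        blocks=tuple(blocks),
        feedback_enabled=run_type in ("training1", "training2"),
        polarity=polarity,
    )


def build_session_design(subject_id: str = "sub-01", arm: str = "standard",
                         study_id: str = "study2", *, tr: float = 2.0,
                         block_duration: float = 20.0, n_block_pairs: int = 9,
                         lead_in_volumes: int = 10) -> SessionDesign:
    """Build the default session: baseline, two training runs, transfer.

    The default run is a 10-volume lead-in followed by 9 alternating
    REST / IMAGINE_REWARD block pairs of 20 s each at TR 2 s, i.e. 190
    volumes.  Runs begin with REST so the feedback reference (last five REST
    volumes) exists before the first IMAGINE_REWARD block.
    """
    if arm not in ARMS:
        raise DesignError(f"unknown arm {arm!r}")
    if tr <= 0:
        raise DesignError("tr must be positive")
    kwargs = dict(tr=tr, block_duration=block_duration,
                  n_block_pairs=n_block_pairs, lead_in_volumes=lead_in_volumes)
    runs = (
        _nf_run("baseline", "none", **kwargs),
        _nf_run("training1", arm, **kwargs),
        _nf_run("training2", arm, **kwargs),
        _nf_run("transfer", "none", **kwargs),
    )
    return SessionDesign(subject_id=subject_id, arm=arm, study_id=study_id, runs=runs)


def build_mid_design(seed: int, *, n_trials_per_cue: int = 24, tr: float = 2.0,
                     lead_in_volumes: int = 5, iti_volumes: Sequence[int] = (4, 5, 6),
                     ) -> list[MIDTrialSpec]:
    """Build a randomized MID trial list (seed-deterministic).

    Magnitudes are uniform within the cue-type range (large 0-2.00 CHF, small
    0-0.40 CHF, none 0); cue-to-target delays are uniform in 2.5-3.0 s; trial
    order is shuffled; cue onsets fall on the TR grid with inter-trial
    intervals drawn from ``iti_volumes`` (in volumes).
    """
    if n_trials_per_cue < 1:
        raise DesignError("need at least one trial per cue type")
    rng = np.random.default_rng(seed)
    cue_types = []
    for cue in ("large", "small", "none"):
        cue_types += [cue] * n_trials_per_cue
    rng.shuffle(cue_types)
    trials = []
    onset = lead_in_volumes * tr
    for cue in cue_types:
        lo, hi = MID_RANGES[cue]
        mag = float(rng.uniform(lo, hi)) if hi > lo else 0.0
        delay = float(rng.uniform(*MID_DELAY_RANGE))
        trials.append(MIDTrialSpec(cue_type=cue, magnitude=mag,
                                   cue_onset=onset, delay=delay))
        onset += float(rng.choice(list(iti_volumes))) * tr
    return trials


def mid_run_length(trials: Sequence[MIDTrialSpec], tr: float = 2.0,
                   tail_volumes: int = 12) -> int:
    """Number of volumes needed to cover the trial list plus an HRF tail."""
    last = max(t.target_onset for t in trials)
    return int(np.ceil(last / tr)) + tail_volumes


def labels_per_volume(run: RunDesign, hemodynamic_shift: float = 0.0) -> np.ndarray:
    """Label each volume with the condition of the block covering its
    (acquisition time - hemodynamic_shift); volumes before the first shifted
    block are labelled LEAD_IN.  The shift must sit on the TR grid."""
    if hemodynamic_shift < 0:
        raise DesignError("hemodynamic shift must be >= 0")
    if abs(hemodynamic_shift / run.tr - round(hemodynamic_shift / run.tr)) > 1e-9:
        raise DesignError("hemodynamic shift must be a multiple of tr")
    times = run.volume_times() - hemodynamic_shift
    labels = np.full(run.n_volumes, LEAD_IN, dtype=object)
    for blk in run.blocks:
        sel = (times >= blk.onset - 1e-9) & (times < blk.end - 1e-9)
        labels[sel] = blk.condition
    labels[times < -1e-9] = LEAD_IN
    return labels


# ---------------------------------------------------------------------------
# serialization

def session_to_dict(design: SessionDesign) -> dict:
    return asdict(design)


def session_from_dict(d: dict) -> SessionDesign:
    runs = tuple(
        RunDesign(
            run_type=r["run_type"], tr=r["tr"], n_volumes=r["n_volumes"],
            blocks=tuple(BlockSpec(**b) for b in r["blocks"]),
            feedback_enabled=r["feedback_enabled"], polarity=r["polarity"],
        )
        for r in d["runs"]
    )
    return SessionDesign(subject_id=d["subject_id"], arm=d["arm"],
                         study_id=d["study_id"], runs=runs)


def save_session(design: SessionDesign, path) -> None:
    with open(path, "w") as fh:
        json.dump(session_to_dict(design), fh, indent=2)


def load_session(path) -> SessionDesign:
    with open(path) as fh:
        return session_from_dict(json.load(fh))


def events_frame(run: RunDesign) -> pd.DataFrame:
    """BIDS-style events table (onset, duration, trial_type) for one run."""
    return pd.DataFrame(
        {"onset": [b.onset for b in run.blocks],
         "duration": [b.duration for b in run.blocks],
         "trial_type": [b.condition for b in run.blocks]}
    )


def mid_events_frame(trials: Sequence[MIDTrialSpec]) -> pd.DataFrame:
    """BIDS-style events table for a MID trial list (cue events)."""
    return pd.DataFrame(
        {"onset": [t.cue_onset for t in trials],
         "duration": [t.delay for t in trials],
         "trial_type": [f"cue_{t.cue_type}" for t in trials],
         "magnitude": [t.magnitude for t in trials]}
    )
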