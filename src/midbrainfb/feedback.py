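"""Online neurofeedback computation as a streaming state machine.

The displayed feedback is the percent signal change (PSC) of a 3-volume
moving average of the raw SN/VTA signal against a reference value, defined
as the mean of the last five volumes of the most recent completed REST
block.  The reference is (re)set whenever a REST block ends (detected at the
REST -> non-REST transition), which minimizes drift and motion effects; it
remains in force through the following blocks until the next REST block
completes.  In the inverted (control) arm the displayed value is the exact
negative of the standard display for the same input stream.  The display is
a linear map of PSC saturating at +/- `clamp_psc` percent.

Before the first REST block has completed no reference exists and the trace
rows are marked invalid.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import REST

#: PSC magnitude at which the display saturates (percent)
DEFAULT_CLAMP_PSC = 2.0
#: moving-average window in volumes (current + 2 preceding)
DEFAULT_WINDOW = 3
#: number of trailing REST volumes averaged into the reference
REFERENCE_TAIL = 5


class FeedbackError(ValueError):
    pass


def compute_reference(rest_tail) -> float:
    """Reference value: arithmetic mean of the last five REST volumes."""
    tail = np.asarray(rest_tail, dtype=float)
    if tail.shape != (REFERENCE_TAIL,):
        raise FeedbackError(
            f"reference needs exactly {REFERENCE_TAIL} REST samples, got {tail.shape}"
        )
    return float(tail.mean())


def moving_average(samples) -> float:
    """Mean of the current volume and up to two preceding volumes."""
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise FeedbackError("moving average of an empty stream")
    return float(arr[-DEFAULT_WINDOW:].mean())


def percent_signal_change(value: float, reference: float) -> float:
    """100 * (value - reference) / reference."""
    if reference == 0:
        raise FeedbackError("degenerate reference value 0")
    return 100.0 * (value - reference) / reference


@dataclass
class TraceRow:
    volume: int
    condition: str
    raw: float
    moving_average: float
    reference: float
    psc: float
    displayed: float
    valid: bool


class FeedbackEngine:
    """Streaming engine; feed one volume at a time with :meth:`step`."""

    def __init__(self, polarity: str = "standard", *,
                 clamp_psc: float = DEFAULT_CLAMP_PSC,
                 window: int = DEFAULT_WINDOW,
                 display_scale: float = 1.0):
        if polarity not in ("standard", "inverted"):
            raise FeedbackError(f"unknown polarity {polarity!r}")
        if clamp_psc <= 0:
            raise FeedbackError("clamp_psc must be positive")
        self.polarity = polarity
        self.clamp_psc = float(clamp_psc)
        self.window = int(window)
        self.display_scale = float(display_scale)
        self.reference: float | None = None
        self._recent: deque[float] = deque(maxlen=self.window)
        self._rest_tail: deque[float] = deque(maxlen=REFERENCE_TAIL)
        self._prev_condition: str | None = None
        self._volume = 0

    def step(self, raw: float, condition: str) -> TraceRow:
        raw = float(raw)
        # a REST block has just completed: lock in the new reference
        if (self._prev_condition == REST and condition != REST
                and len(self._rest_tail) == REFERENCE_TAIL):
            self.reference = compute_reference(list(self._rest_tail))
        if condition == REST:
            self._rest_tail.append(raw)
        else:
            self._rest_tail.clear()
        self._recent.append(raw)
        ma = float(np.mean(self._recent))

        valid = self.reference is not None
        if valid:
            psc = percent_signal_change(ma, self.reference)
            signed = -psc if self.polarity == "inverted" else psc
            displayed = self.display_scale * float(
                np.clip(signed, -self.clamp_psc, self.clamp_psc))
            ref = self.reference
        else:
            psc = np.nan
            displayed = np.nan
            ref = np.nan
        row = TraceRow(volume=self._volume, condition=condition, raw=raw,
                       moving_average=ma, reference=ref, psc=psc,
                       displayed=displayed, valid=valid)
        self._prev_condition = condition
        self._volume += 1
        return row


def replay(raw, conditions, polarity: str = "standard", **kwargs) -> pd.DataFrame:
    """Batch replay of a whole run; identical to streaming volume by volume."""
    raw = np.asarray(raw, dtype=float)
    conditions = list(conditions)
    if len(raw) != len(conditions):
        raise FeedbackError("raw series and condition labels differ in length")
    engine = FeedbackEngine(polarity, **kwargs)
    rows = [engine.step(x, c) for x, c in zip(raw, conditions)]
    return trace_frame(rows)


def trace_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def read_replay_tsv(path) -> tuple[np.ndarray, list[str]]:
    """Read a (volume, raw, condition) TSV for replay mode."""
    df = pd.read_csv(path, sep="\t")
    for col in ("raw", "condition"):
        if col not in df.columns:
            raise FeedbackError(f"replay TSV missing column {col!r}")
    return df["raw"].to_numpy(float), df["condition"].astype(str).tolist()
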