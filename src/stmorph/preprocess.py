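"""ECG conditioning: low-pass filtering, isoelectric estimation, baseline removal.

All amplitudes are in microvolts throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import numpy.typing as npt
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "Beat",
    "ECGRecord",
    "ConfigurationError",
    "lowpass_filter",
    "estimate_isoelectric",
    "remove_baseline",
    "select_normal_beats",
    "preprocess_record",
]

logger = logging.getLogger(__name__)

NORMAL_LABEL = "N"

# PQ flatness search: scan [F-120, F-20] ms with a 20 ms window
PQ_SEARCH_START_MS = 120.0
PQ_SEARCH_END_MS = 20.0
PQ_FLAT_WINDOW_MS = 20.0


class ConfigurationError(ValueError):
    pass


@dataclass
class Beat:
    """One heartbeat: fiducial sample index, label, per-lead isoelectric level."""

    fiducial: int
    label: str = NORMAL_LABEL
    isoelectric: npt.NDArray[np.float64] | None = None  # per lead, uV
    iso_center: npt.NDArray[np.int64] | None = None  # per lead, sample of PQ window center
    rr_prev_ms: float | None = None
    usable: bool = True

    @property
    def is_normal(self) -> bool:
        return self.label == NORMAL_LABEL


@dataclass
class ECGRecord:
    """Multi-lead ECG: signals (lead x sample, uV), sampling rate, beat table."""

    signals: npt.NDArray[np.float64]
    fs: float = 250.0
    beats: list[Beat] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.beats = sorted(self.beats, key=lambda b: b.fiducial)

    @property
    def lead_count(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "ECGRecord":
        return ECGRecord(
            signals=self.signals.copy(),
            fs=self.fs,
            beats=[replace(b) for b in self.beats],
        )


def lowpass_filter(record: ECGRecord, cutoff_hz: float = 55.0, order: int = 6) -> ECGRecord:
    """Zero-phase 6-pole Butterworth low-pass at 55 Hz on every lead.

    Applied forward-backward so ST timing relative to the fiducial point is
    preserved; effective attenuation is the squared single-pass magnitude.
    """
    if record.fs <= 2 * cutoff_hz:
        raise ConfigurationError(
            f"fs={record.fs} Hz too low for a {cutoff_hz} Hz low-pass"
        )
    sos = butter(order, cutoff_hz, btype="low", fs=record.fs, output="sos")
    out = record.copy()
    out.signals = sosfiltfilt(sos, out.signals, axis=1)
    return out


def estimate_isoelectric(
    record: ECGRecord, beat: Beat
) -> tuple[npt.NDArray[np.float64], npt.NDArray[np.int64]]:
    """Isoelectric level per lead from the flattest PQ window before the beat.

    A 20 ms window slides over [F-120 ms, F-20 ms]; flatness is the sum of
    absolute first differences inside the window; the level is the mean of
    the flattest window (ties broken by the window closest to F).  Returns
    the levels and the window-center sample index per lead.

    Raises ValueError when fewer than 120 ms of signal precede the fiducial;
    callers flag such beats unusable.
    """
    fs = record.fs
    f = beat.fiducial
    start = f - int(round(PQ_SEARCH_START_MS * fs / 1000.0))
    end = f - int(round(PQ_SEARCH_END_MS * fs / 1000.0))
    win = int(round(PQ_FLAT_WINDOW_MS * fs / 1000.0)) + 1  # samples spanning 20 ms
    if start < 0 or end - start + 1 < win:
        raise ValueError("insufficient pre-beat signal for isoelectric estimation")

    levels = np.empty(record.lead_count)
    centers = np.empty(record.lead_count, dtype=np.int64)
    n_starts = end - start + 1 - win + 1
    for lead in range(record.lead_count):
        seg = record.signals[lead, start : end + 1]
        absdiff = np.abs(np.diff(seg))
        # flatness of window starting at s: sum of the win-1 diffs inside it
        kernel = np.ones(win - 1)
        flat = np.convolve(absdiff, kernel, mode="valid")[:n_starts]
        best = 0
        for s in range(1, n_starts):
            if flat[s] <= flat[best]:  # '<=' prefers windows nearer F on ties
                best = s
        w0 = start + best
        levels[lead] = record.signals[lead, w0 : w0 + win].mean()
        centers[lead] = w0 + win // 2
    return levels, centers


def _fill_isoelectric(record: ECGRecord) -> None:
    for beat in record.beats:
        try:
            z, centers = estimate_isoelectric(record, beat)
        except ValueError:
            beat.usable = False
            beat.isoelectric = None
            beat.iso_center = None
            continue
        beat.isoelectric = z
        beat.iso_center = centers


def remove_baseline(record: ECGRecord) -> ECGRecord:
    """Subtract a natural cubic spline through the per-beat isoelectric knots.

    Knots are (PQ-window center time, isoelectric level) per lead.  With
    fewer than 3 knots the method falls back to linear interpolation with a
    warning.  Outside the knot span the edge value is held constant (cubic
    extrapolation of a natural spline diverges).
    """
    out = record.copy()
    t_all = np.arange(record.n_samples, dtype=float)
    for lead in range(record.lead_count):
        knots_t = []
        knots_z = []
        for beat in record.beats:
            if beat.isoelectric is None or beat.iso_center is None:
                continue
            knots_t.append(float(beat.iso_center[lead]))
            knots_z.append(float(beat.isoelectric[lead]))
        if len(knots_t) == 0:
            continue
        knots_t_arr = np.asarray(knots_t)
        knots_z_arr = np.asarray(knots_z)
        uniq, idx = np.unique(knots_t_arr, return_index=True)
        knots_t_arr, knots_z_arr = uniq, knots_z_arr[idx]
        if len(knots_t_arr) < 3:
            logger.warning(
                "lead %d: only %d isoelectric knots; linear baseline fallback",
                lead,
                len(knots_t_arr),
            )
            baseline = np.interp(t_all, knots_t_arr, knots_z_arr)
        else:
            spline = CubicSpline(knots_t_arr, knots_z_arr, bc_type="natural")
            t_clip = np.clip(t_all, knots_t_arr[0], knots_t_arr[-1])
            baseline = spline(t_clip)
        out.signals[lead] -= baseline
    # isoelectric levels are now stale; re-estimate
    _fill_isoelectric(out)
    return out


def select_normal_beats(beats: list[Beat]) -> list[Beat]:
    """Keep normal beats whose immediate neighbors are also normal.

    Abnormal beats and their direct neighbors are dropped; boundary beats
    are kept when their single neighbor is normal.
    """
    kept = []
    n = len(beats)
    for i, beat in enumerate(beats):
        if not beat.is_normal:
            continue
        if i > 0 and not beats[i - 1].is_normal:
            continue
        if i < n - 1 and not beats[i + 1].is_normal:
            continue
        kept.append(beat)
    return kept


def preprocess_record(record: ECGRecord) -> ECGRecord:
    """Full conditioning pipeline.

    Low-pass filter, estimate isoelectric levels, remove baseline wander by
    cubic-spline subtraction (which re-estimates the levels on the corrected
    signal).  Beat selection is left to the delineation stage so that the
    abnormal-beat context is preserved in the record.
    """
    out = lowpass_filter(record)
    _fill_isoelectric(out)
    return remove_baseline(out)
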