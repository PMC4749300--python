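"""Per-beat diagnostic and morphologic ST-segment feature time series.

Diagnostic features: instantaneous heart rate, ST level and ST slope, with
the ST measurement point rate-adjusted between F+160 ms (<= 100 bpm) and
F+120 ms (>= 120 bpm).  Morphologic features: projections of the 32-sample
isoelectric-corrected ST pattern vector onto the KLT and LPT bases, their
std-normalized counterparts, residual reconstruction errors, and compound
Mahalanobis distances to the first beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from stmorph.basis import BasisMatrix, STWindowSpec
from stmorph.klt import KLTModel
from stmorph.preprocess import Beat, ECGRecord, select_normal_beats

__all__ = [
    "NormalizationModel",
    "FeatureSeries",
    "EmptySeriesError",
    "instantaneous_heart_rate",
    "st_measurement_offset",
    "st_level",
    "st_slope",
    "extract_pattern_vector",
    "project",
    "normalize",
    "residual_error",
    "mahalanobis_series",
    "delineate_record",
]

N_COEFFS = 9
N_D_DEFAULT = 5


class EmptySeriesError(RuntimeError):
    """No usable beats in the record."""


@dataclass
class NormalizationModel:
    """Per-coefficient standard deviations (uV) used to normalize projections."""

    rho: npt.NDArray[np.float64]  # KLT coefficient stds
    theta: npt.NDArray[np.float64]  # LPT coefficient stds
    provenance: str = ""

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.rho <= 0) or np.any(self.theta <= 0):
            raise ValueError("normalization stds must be positive")

    def stds_for(self, transform: str) -> npt.NDArray[np.float64]:
        if transform.upper() == "KLT":
            return self.rho
        if transform.upper() == "LPT":
            return self.theta
        raise ValueError(f"unknown transform {transform!r}")


@dataclass
class FeatureSeries:
    """Aligned per-beat feature arrays in long format (one row per lead, beat).

    ``lead`` and ``beat_index`` identify each row; coefficient arrays are
    (n_rows, 9).  Mahalanobis distances are relative to the first beat of
    the same lead.
    """

    time_s: npt.NDArray[np.float64]
    lead: npt.NDArray[np.int64]
    beat_index: npt.NDArray[np.int64]
    heart_rate: npt.NDArray[np.float64]
    st_level: npt.NDArray[np.float64]
    st_slope: npt.NDArray[np.float64]
    klt_raw: npt.NDArray[np.float64]
    klt_norm: npt.NDArray[np.float64]
    klt_residual: npt.NDArray[np.float64]
    lpt_raw: npt.NDArray[np.float64]
    lpt_norm: npt.NDArray[np.float64]
    lpt_residual: npt.NDArray[np.float64]
    d_klt: npt.NDArray[np.float64]
    d_lpt: npt.NDArray[np.float64]
    n_d: int = N_D_DEFAULT
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.time_s)

    def for_lead(self, lead: int) -> "FeatureSeries":
        mask = self.lead == lead
        return FeatureSeries(
            **{
                name: (getattr(self, name)[mask] if name not in ("n_d", "meta") else getattr(self, name))
                for name in self.__dataclass_fields__
            }
        )

    def norm_coeffs(self, transform: str) -> npt.NDArray[np.float64]:
        return self.klt_norm if transform.upper() == "KLT" else self.lpt_norm


def instantaneous_heart_rate(beat_times_ms: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
    """h(j) = 60000 / RR(j) with RR(j) = t(j) - t(j-1); h(1) backfilled from h(2)."""
    t = np.asarray(beat_times_ms, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 beats for heart rate")
    rr = np.diff(t)
    if np.any(rr <= 0):
        raise ValueError("beat times must be strictly increasing")
    h = 60000.0 / rr
    return np.concatenate([[h[0]], h])


def st_measurement_offset(h: float) -> float:
    """ST measurement point (ms after F): 160 at <= 100 bpm, 120 at >= 120 bpm, linear between."""
    if h <= 0:
        raise ValueError("heart rate must be positive")
    if h <= 100.0:
        return 160.0
    if h >= 120.0:
        return 120.0
    return 160.0 - 2.0 * (h - 100.0)


def _amplitude_at(record: ECGRecord, lead: int, fiducial: int, offset_ms: float) -> float:
    """Signal amplitude at F + offset, linearly interpolated between samples."""
    pos = fiducial + offset_ms * record.fs / 1000.0
    if pos < 0 or pos > record.n_samples - 1:
        raise ValueError("measurement point outside record")
    i0 = int(np.floor(pos))
    frac = pos - i0
    sig = record.signals[lead]
    if frac == 0.0:
        return float(sig[i0])
    return float(sig[i0] * (1.0 - frac) + sig[i0 + 1] * frac)


def st_level(record: ECGRecord, beat: Beat, lead: int, h: float) -> float:
    """ST level: amplitude at the rate-adjusted point minus the isoelectric level (uV)."""
    if beat.isoelectric is None:
        raise ValueError("beat has no isoelectric estimate")
    a = _amplitude_at(record, lead, beat.fiducial, st_measurement_offset(h))
    return a - float(beat.isoelectric[lead])


def st_slope(record: ECGRecord, beat: Beat, lead: int, h: float) -> float:
    """ST slope: amplitude at the rate-adjusted point minus the amplitude at F+60 ms (uV)."""
    a_hi = _amplitude_at(record, lead, beat.fiducial, st_measurement_offset(h))
    a_lo = _amplitude_at(record, lead, beat.fiducial, 60.0)
    return a_hi - a_lo


def extract_pattern_vector(
    record: ECGRecord,
    beat: Beat,
    lead: int,
    window: STWindowSpec | None = None,
) -> npt.NDArray[np.float64]:
    """Isoelectric-corrected ST window resampled to the basis grid.

    The signal over [F+40, F+160] ms is linearly interpolated onto
    ``window.n_samples`` equally spaced points (endpoints included) and the
    beat's isoelectric level subtracted.
    """
    if window is None:
        window = STWindowSpec()
    if beat.isoelectric is None:
        raise ValueError("beat has no isoelectric estimate")
    positions = beat.fiducial + window.offsets_ms() * record.fs / 1000.0
    if positions[0] < 0 or positions[-1] > record.n_samples - 1:
        raise ValueError("ST window outside record")
    samples = np.interp(positions, np.arange(record.n_samples), record.signals[lead])
    return samples - float(beat.isoelectric[lead])


def project(x: npt.NDArray[np.float64], b: BasisMatrix, n: int = N_COEFFS) -> npt.NDArray[np.float64]:
    """First ``n`` transform coefficients: (B^T x)[:n]."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != b.M:
        raise ValueError(f"pattern length {x.shape[-1]} != basis dimension {b.M}")
    return x @ b.entries[:, :n]


def normalize(
    raw: npt.NDArray[np.float64], model: NormalizationModel, transform: str
) -> npt.NDArray[np.float64]:
    """Elementwise division by the transform's coefficient stds."""
    stds = model.stds_for(transform)
    raw = np.asarray(raw, dtype=float)
    n = raw.shape[-1]
    return raw / stds[:n]


def residual_error(x: npt.NDArray[np.float64], b: BasisMatrix, n: int) -> float:
    """RMS reconstruction error using the first ``n`` coefficients (uV)."""
    if n > b.M:
        raise ValueError("n exceeds basis dimension")
    x = np.asarray(x, dtype=float)
    coeffs = x @ b.entries[:, :n]
    recon = b.entries[:, :n] @ coeffs
    return float(np.sqrt(np.mean((x - recon) ** 2)))


def mahalanobis_series(
    normalized: npt.NDArray[np.float64], n_d: int = N_D_DEFAULT
) -> npt.NDArray[np.float64]:
    """Distance of each beat's normalized feature vector to the first beat's.

    Euclidean distance over the first ``n_d`` normalized coefficients;
    d(1) = 0 by construction.
    """
    normalized = np.atleast_2d(np.asarray(normalized, dtype=float))
    if normalized.shape[0] == 0:
        raise ValueError("empty series")
    if n_d > normalized.shape[1]:
        raise ValueError("n_d exceeds coefficient count")
    delta = normalized[:, :n_d] - normalized[0, :n_d]
    return np.sqrt(np.sum(delta**2, axis=1))


def delineate_record(
    record: ECGRecord,
    lpt: BasisMatrix,
    klt: KLTModel,
    norm: NormalizationModel,
    n_coeffs: int = N_COEFFS,
    n_d: int = N_D_DEFAULT,
    window: STWindowSpec | None = None,
) -> FeatureSeries:
    """Run every per-beat feature over the selected normal beats of all leads."""
    if window is None:
        window = STWindowSpec()
    beats = [b for b in select_normal_beats(record.beats) if b.usable and b.isoelectric is not None]
    # beats whose ST window would run off the record are dropped
    max_pos = record.n_samples - 1 - window.end_offset_ms * record.fs / 1000.0
    beats = [b for b in beats if 0 <= b.fiducial <= max_pos]
    if len(beats) == 0:
        raise EmptySeriesError("no usable beats after selection")

    times_ms = np.array([b.fiducial / record.fs * 1000.0 for b in beats])
    if len(beats) >= 2:
        h = instantaneous_heart_rate(times_ms)
    else:
        h = np.array([np.nan])

    rows: dict[str, list] = {k: [] for k in (
        "time_s", "lead", "beat_index", "heart_rate", "st_level", "st_slope",
        "klt_raw", "klt_norm", "klt_residual", "lpt_raw", "lpt_norm", "lpt_residual",
    )}
    for lead in range(record.lead_count):
        for j, beat in enumerate(beats):
            x = extract_pattern_vector(record, beat, lead, window)
            k_raw = project(x, klt.basis, n_coeffs)
            l_raw = project(x, lpt, n_coeffs)
            rows["time_s"].append(times_ms[j] / 1000.0)
            rows["lead"].append(lead)
            rows["beat_index"].append(j)
            hr = h[j] if np.isfinite(h[j]) else 60.0
            rows["heart_rate"].append(h[j])
            rows["st_level"].append(st_level(record, beat, lead, hr))
            rows["st_slope"].append(st_slope(record, beat, lead, hr))
            rows["klt_raw"].append(k_raw)
            rows["klt_norm"].append(normalize(k_raw, norm, "KLT"))
            rows["klt_residual"].append(residual_error(x, klt.basis, n_coeffs))
            rows["lpt_raw"].append(l_raw)
            rows["lpt_norm"].append(normalize(l_raw, norm, "LPT"))
            rows["lpt_residual"].append(residual_error(x, lpt, n_coeffs))

    lead_arr = np.array(rows["lead"], dtype=np.int64)
    klt_norm = np.array(rows["klt_norm"])
    lpt_norm = np.array(rows["lpt_norm"])
    d_klt = np.empty(len(lead_arr))
    d_lpt = np.empty(len(lead_arr))
    for lead in range(record.lead_count):
        mask = lead_arr == lead
        d_klt[mask] = mahalanobis_series(klt_norm[mask], n_d)
        d_lpt[mask] = mahalanobis_series(lpt_norm[mask], n_d)

    return FeatureSeries(
        time_s=np.array(rows["time_s"]),
        lead=lead_arr,
        beat_index=np.array(rows["beat_index"], dtype=np.int64),
        heart_rate=np.array(rows["heart_rate"]),
        st_level=np.array(rows["st_level"]),
        st_slope=np.array(rows["st_slope"]),
        klt_raw=np.array(rows["klt_raw"]),
        klt_norm=klt_norm,
        klt_residual=np.array(rows["klt_residual"]),
        lpt_raw=np.array(rows["lpt_raw"]),
        lpt_norm=lpt_norm,
        lpt_residual=np.array(rows["lpt_residual"]),
        d_klt=d_klt,
        d_lpt=d_lpt,
        n_d=n_d,
        meta={"fs": record.fs, "window": window.to_dict(), "n_coeffs": n_coeffs},
    )
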