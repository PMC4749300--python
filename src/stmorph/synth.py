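"""Synthetic annotated ambulatory ECG generator.

Produces deterministic (seeded) multi-lead records with parameterized ST
morphology, triangular ischaemic ST episodes, heart-rate-related T-wave
encroachment episodes, step axis shifts, baseline wander, noise and
labeled abnormal beats -- everything the rest of the package needs for
testing without real recordings.

Waveform anatomy (P wave, QRS, T wave) uses invented Gaussian/taper
primitives; only the ST window [F+40, F+160] ms carries an analytically
exact parametric shape (level + slope ramp + quadratic bowl), because that
window is what delineation reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from stmorph.preprocess import Beat, ECGRecord

__all__ = [
    "ISCHAEMIC",
    "HEART_RATE_RELATED",
    "BeatTemplateParams",
    "EpisodeSpec",
    "Episode",
    "SyntheticRecordConfig",
    "CorpusConfig",
    "make_beat",
    "make_record",
    "make_training_corpus",
]

ISCHAEMIC = "ischaemic"
HEART_RATE_RELATED = "heart_rate_related"

# ST plateau shape region (seconds after F); exact inside, tapered outside
_ST_T0 = 0.040
_ST_T1 = 0.160
_ST_MID = 0.100
_ST_HALF = 0.060
_T_CENTER = 0.300  # unshifted T wave center (s after F)
_T_SIGMA = 0.040
_T_AMP = 200.0

# The scoop primitive is the quadratic with zero *discrete* mean over the
# standard 32-point window grid (mean of u_i^2 = (M+1)/(3(M-1)) = 11/31, not
# the continuous 1/3), rescaled to peak deflection 1 at the window edges.
# This keeps a pure scoop orthogonal to the constant and linear basis
# functions under the delineation grid's inner product.
_SCOOP_MEAN_U2 = 11.0 / 31.0


def scoop_shape(u: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
    return (np.asarray(u, dtype=float) ** 2 - _SCOOP_MEAN_U2) / (1.0 - _SCOOP_MEAN_U2)


@dataclass(frozen=True)
class BeatTemplateParams:
    """Controls for a single synthetic heartbeat (amplitudes in uV)."""

    st_level: float = 0.0  # uV, uniform ST offset
    st_slope: float = 0.0  # uV per 100 ms linear ramp across the ST window
    st_scoop: float = 0.0  # uV, peak quadratic deflection at the window edges
    t_onset_shift: float = 0.0  # ms; negative moves the T wave into the ST window
    qrs_amplitude: float = 1000.0
    heart_rate: float = 70.0

    def __post_init__(self) -> None:
        if abs(self.st_level) > 500 or abs(self.st_slope) > 500 or abs(self.st_scoop) > 500:
            raise ValueError("ST morphology parameters limited to +/-500 uV")
        if abs(self.t_onset_shift) > 250:
            raise ValueError("t_onset_shift limited to +/-250 ms")
        if not (100 <= self.qrs_amplitude <= 4000):
            raise ValueError("qrs_amplitude outside 100..4000 uV")
        if not (20 <= self.heart_rate <= 240):
            raise ValueError("heart_rate outside 20..240 bpm")


def st_shape(t_rel_s: npt.NDArray[np.float64], params: BeatTemplateParams) -> npt.NDArray[np.float64]:
    """Exact parametric ST value at times relative to F (valid on [40, 160] ms).

    level + slope ramp + scoop quadratic, where the quadratic is the
    discretely-mean-free shape of :func:`scoop_shape` in the window
    coordinate u in [-1, 1] so that a pure scoop projects onto basis
    function 3 only.
    """
    u = (np.asarray(t_rel_s, dtype=float) - _ST_MID) / _ST_HALF
    ramp = params.st_slope * (np.asarray(t_rel_s) - _ST_MID) * 10.0  # uV/100ms * s * 1000/100
    bowl = params.st_scoop * scoop_shape(u)
    return params.st_level + ramp + bowl


def _gauss(t: npt.NDArray[np.float64], center: float, sigma: float) -> npt.NDArray[np.float64]:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def beat_waveform(
    t_rel_s: npt.NDArray[np.float64],
    params: BeatTemplateParams,
    abnormal: bool = False,
) -> npt.NDArray[np.float64]:
    """Evaluate one beat's waveform (uV) at times relative to its fiducial point F.

    The PQ segment ([F-120, F-20] ms) is flat at 0 (true isoelectric
    level); the ST plateau follows :func:`st_shape` exactly on
    [F+40, F+160] ms with linear tapers to the QRS end and the T wave.
    """
    t = np.asarray(t_rel_s, dtype=float)
    if abnormal:
        # wide, tall ectopic complex without a P wave
        v = 1.8 * params.qrs_amplitude * _gauss(t, 0.01, 0.030)
        v -= 350.0 * _gauss(t, 0.09, 0.035)
        v += 250.0 * _gauss(t, 0.32, 0.060)
        return v

    v = 90.0 * _gauss(t, -0.170, 0.013)  # P
    v += -80.0 * _gauss(t, -0.018, 0.004)  # Q
    v += params.qrs_amplitude * _gauss(t, 0.0, 0.007)  # R
    v += -150.0 * _gauss(t, 0.020, 0.004)  # S

    st = np.zeros_like(t)
    inside = (t >= _ST_T0) & (t <= _ST_T1)
    st[inside] = st_shape(t[inside], params)
    lead_in = (t >= 0.020) & (t < _ST_T0)
    st[lead_in] = st_shape(np.full(np.count_nonzero(lead_in), _ST_T0), params) * (
        (t[lead_in] - 0.020) / (_ST_T0 - 0.020)
    )
    lead_out = (t > _ST_T1) & (t <= 0.220)
    st[lead_out] = st_shape(np.full(np.count_nonzero(lead_out), _ST_T1), params) * (
        1.0 - (t[lead_out] - _ST_T1) / 0.060
    )
    v += st

    t_center = _T_CENTER + params.t_onset_shift / 1000.0
    v += _T_AMP * _gauss(t, t_center, _T_SIGMA)
    return v


def make_beat(
    params: BeatTemplateParams, fs: float = 250.0
) -> tuple[npt.NDArray[np.float64], int]:
    """One beat sampled at ``fs`` over [F-250 ms, F+450 ms]; returns (waveform, fiducial index)."""
    n_pre = int(round(0.250 * fs))
    n_post = int(round(0.450 * fs))
    idx = np.arange(-n_pre, n_post + 1)
    return beat_waveform(idx / fs, params), n_pre


@dataclass(frozen=True)
class EpisodeSpec:
    """A transient episode to inject: triangular trajectory onset -> extremum -> offset."""

    kind: str  # ISCHAEMIC | HEART_RATE_RELATED
    onset_s: float
    extremum_s: float
    offset_s: float
    extremum_magnitude: float = 0.0  # uV ST level at the extremum (ischaemic)
    hr_delta: float = 0.0  # bpm increase at the extremum
    affected_leads: tuple[int, ...] = (0,)
    slope_factor: float = 0.0  # ST slope at extremum = factor * magnitude (uV/100ms)
    scoop_factor: float = 0.0  # ST scoop at extremum = factor * magnitude (uV)

    def __post_init__(self) -> None:
        if not (self.onset_s < self.extremum_s < self.offset_s):
            raise ValueError("episode needs onset < extremum < offset")
        if self.kind == ISCHAEMIC and abs(self.extremum_magnitude) <= 50:
            raise ValueError("ischaemic episodes must deviate by more than 50 uV")
        if self.kind == HEART_RATE_RELATED and self.hr_delta <= 0:
            raise ValueError("heart-rate-related episodes need hr_delta > 0")
        if self.kind not in (ISCHAEMIC, HEART_RATE_RELATED):
            raise ValueError(f"unknown episode kind {self.kind!r}")

    def triangle(self, t_s) -> npt.NDArray[np.float64]:
        """Triangular activation in [0, 1]: 0 at onset/offset, 1 at the extremum."""
        t = np.asarray(t_s, dtype=float)
        up = (t - self.onset_s) / (self.extremum_s - self.onset_s)
        down = (self.offset_s - t) / (self.offset_s - self.extremum_s)
        return np.clip(np.minimum(up, down), 0.0, 1.0)


@dataclass
class Episode:
    """Ground-truth episode annotation attached to a generated record."""

    label: str
    lead: int
    onset_s: float
    extremum_s: float
    offset_s: float
    extremum_magnitude: float


@dataclass
class SyntheticRecordConfig:
    duration_s: float = 120.0
    fs: float = 250.0
    leads: int = 2
    base_hr: float = 70.0
    episodes: list[EpisodeSpec] = field(default_factory=list)
    axis_shifts: list[tuple[float, tuple[float, ...]]] = field(default_factory=list)
    noise_rms: float = 0.0  # uV additive white noise
    baseline_wander: tuple[float, float] = (0.0, 0.3)  # (amplitude uV, frequency Hz)
    abnormal_beat_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for lead in range(self.leads):
            spans = sorted(
                (e.onset_s, e.offset_s)
                for e in self.episodes
                if lead in e.affected_leads
            )
            for (a0, a1), (b0, _b1) in zip(spans, spans[1:]):
                if b0 < a1:
                    raise ValueError(f"overlapping episodes on lead {lead}")


# T-wave encroachment at the extremum of a heart-rate-related episode (ms)
def _hr_related_shift(hr_delta: float) -> float:
    return -(60.0 + 1.1 * hr_delta)


def make_record(
    config: SyntheticRecordConfig,
) -> tuple[ECGRecord, list[Episode], dict]:
    """Generate a synthetic record, its ground-truth episodes and per-beat truth.

    Identical configs (including seed) give bit-identical output.  The
    truth dict holds, per beat and lead, the injected ST parameters, the
    heart-rate trajectory and the beat labels.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))

    hr_eps = [e for e in config.episodes if e.kind == HEART_RATE_RELATED]
    isch_eps = [e for e in config.episodes if e.kind == ISCHAEMIC]

    def hr_at(t: float) -> float:
        h = config.base_hr
        for e in config.episodes:
            if e.hr_delta:
                h += e.hr_delta * float(e.triangle(t))
        return h

    # lay down the beat train
    beat_times: list[float] = []
    t = 0.4
    while t < config.duration_s - 0.6:
        beat_times.append(t)
        t += 60.0 / hr_at(t)
    n_beats = len(beat_times)
    if n_beats == 0:
        raise ValueError("record too short for any beat")

    labels = np.where(rng.random(n_beats) < config.abnormal_beat_rate, "V", "N")

    truth_level = np.zeros((config.leads, n_beats))
    truth_slope = np.zeros((config.leads, n_beats))
    truth_scoop = np.zeros((config.leads, n_beats))
    truth_shift = np.zeros((config.leads, n_beats))
    truth_hr = np.array([hr_at(tb) for tb in beat_times])

    signals = np.zeros((config.leads, n))
    sample_idx = np.arange(n)
    beats: list[Beat] = []
    prev_t: float | None = None
    for j, tb in enumerate(beat_times):
        fid = int(round(tb * fs))
        abnormal = labels[j] == "V"
        for lead in range(config.leads):
            level = slope = scoop = 0.0
            shift = 0.0
            for e in isch_eps:
                if lead in e.affected_leads:
                    tri = float(e.triangle(tb))
                    level += e.extremum_magnitude * tri
                    slope += e.slope_factor * e.extremum_magnitude * tri
                    scoop += e.scoop_factor * e.extremum_magnitude * tri
            for e in hr_eps:
                if lead in e.affected_leads:
                    shift += _hr_related_shift(e.hr_delta) * float(e.triangle(tb))
            for t_shift, offsets in config.axis_shifts:
                if tb >= t_shift:
                    level += offsets[lead]
            truth_level[lead, j] = level
            truth_slope[lead, j] = slope
            truth_scoop[lead, j] = scoop
            truth_shift[lead, j] = shift
            params = BeatTemplateParams(
                st_level=float(np.clip(level, -500, 500)),
                st_slope=float(np.clip(slope, -500, 500)),
                st_scoop=float(np.clip(scoop, -500, 500)),
                t_onset_shift=float(np.clip(shift, -250, 250)),
                heart_rate=float(np.clip(truth_hr[j], 20, 240)),
            )
            lo = max(0, fid - int(round(0.250 * fs)))
            hi = min(n - 1, fid + int(round(0.450 * fs)))
            seg = sample_idx[lo : hi + 1]
            signals[lead, lo : hi + 1] += beat_waveform(
                (seg - fid) / fs, params, abnormal=abnormal
            )
        rr_prev = None if prev_t is None else (tb - prev_t) * 1000.0
        beats.append(Beat(fiducial=fid, label=str(labels[j]), rr_prev_ms=rr_prev))
        prev_t = tb

    wander_amp, wander_freq = config.baseline_wander
    t_axis = sample_idx / fs
    for lead in range(config.leads):
        if wander_amp:
            phase = rng.uniform(0, 2 * np.pi)
            signals[lead] += wander_amp * np.sin(2 * np.pi * wander_freq * t_axis + phase)
        if config.noise_rms:
            signals[lead] += rng.normal(0.0, config.noise_rms, n)

    record = ECGRecord(signals=signals, fs=fs, beats=beats)
    episodes = [
        Episode(
            label=e.kind,
            lead=lead,
            onset_s=e.onset_s,
            extremum_s=e.extremum_s,
            offset_s=e.offset_s,
            extremum_magnitude=e.extremum_magnitude,
        )
        for e in config.episodes
        for lead in e.affected_leads
    ]
    truth = {
        "beat_times_s": np.asarray(beat_times),
        "labels": labels,
        "st_level": truth_level,
        "st_slope": truth_slope,
        "st_scoop": truth_scoop,
        "t_onset_shift": truth_shift,
        "heart_rate": truth_hr,
    }
    return record, episodes, truth


@dataclass
class CorpusConfig:
    """Class-conditional ST parameter distributions for training corpora (uV)."""

    beats_per_interval: int = 30
    noise_rms: float = 8.0  # per-sample noise inside a beat
    intra_interval_sigma: float = 5.0  # beat-to-beat parameter jitter
    no_dev_level_sigma: float = 15.0
    no_dev_slope_sigma: float = 5.0
    no_dev_scoop_sigma: float = 5.0
    isch_level_range: tuple[float, float] = (60.0, 250.0)
    isch_scoop_range: tuple[float, float] = (20.0, 100.0)
    isch_slope_sigma: float = 30.0
    isch_negative_fraction: float = 0.7
    hr_t_amp_range: tuple[float, float] = (150.0, 250.0)
    hr_shift_range: tuple[float, float] = (100.0, 160.0)


def _window_u(n_samples: int = 32) -> npt.NDArray[np.float64]:
    return np.linspace(-1.0, 1.0, n_samples)


def _pattern(level: float, slope: float, scoop: float, n_samples: int = 32) -> npt.NDArray[np.float64]:
    u = _window_u(n_samples)
    return level + slope * 0.6 * u + scoop * scoop_shape(u)


def _encroachment_pattern(t_amp: float, shift_ms: float, n_samples: int = 32) -> npt.NDArray[np.float64]:
    # T-wave Gaussian tail sampled over the ST window [40, 160] ms
    t_ms = np.linspace(40.0, 160.0, n_samples)
    center = _T_CENTER * 1000.0 + shift_ms
    return t_amp * np.exp(-0.5 * ((t_ms - center) / (_T_SIGMA * 1000.0)) ** 2)


def make_training_corpus(
    n_ischaemic: int,
    n_non_ischaemic: int,
    n_no_deviation: int,
    seed: int = 0,
    config: CorpusConfig | None = None,
    n_samples: int = 32,
) -> list[tuple[str, npt.NDArray[np.float64]]]:
    """Labeled interval corpus of ST pattern vectors for KLT training.

    One (label, patterns) pair per interval; patterns are drawn beat by beat
    from class-conditional parameter distributions with interval-level
    means, beat-level jitter and per-sample noise.  Leads are conceptually
    pooled: every pattern vector enters the same corpus.
    """
    if config is None:
        config = CorpusConfig()
    rng = np.random.default_rng(seed)
    corpus: list[tuple[str, npt.NDArray[np.float64]]] = []

    def interval(label: str, level: float, slope: float, scoop: float, extra=None):
        rows = []
        for _ in range(config.beats_per_interval):
            jl, js, jc = rng.normal(0.0, config.intra_interval_sigma, 3)
            p = _pattern(level + jl, slope + js, scoop + jc, n_samples)
            if extra is not None:
                p = p + extra
            if config.noise_rms:
                p = p + rng.normal(0.0, config.noise_rms, n_samples)
            rows.append(p)
        corpus.append((label, np.asarray(rows)))

    for _ in range(n_ischaemic):
        sign = -1.0 if rng.random() < config.isch_negative_fraction else 1.0
        level = sign * rng.uniform(*config.isch_level_range)
        scoop = sign * rng.uniform(*config.isch_scoop_range)
        slope = rng.normal(0.0, config.isch_slope_sigma)
        interval("ischaemic_deviation", level, slope, scoop)

    for _ in range(n_non_ischaemic):
        t_amp = rng.uniform(*config.hr_t_amp_range)
        shift = rng.uniform(*config.hr_shift_range)
        extra = _encroachment_pattern(t_amp, -shift, n_samples)
        interval("non_ischaemic_deviation", 0.0, 0.0, 0.0, extra=extra)

    for _ in range(n_no_deviation):
        level = rng.normal(0.0, config.no_dev_level_sigma)
        slope = rng.normal(0.0, config.no_dev_slope_sigma)
        scoop = rng.normal(0.0, config.no_dev_scoop_sigma)
        interval("no_deviation", level, slope, scoop)

    return corpus
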