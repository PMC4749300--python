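"""Readers and writers for the package's on-disk formats.

Formats are deliberately text-first: basis matrices and feature series as
TSV with JSON metadata, models and episodes as JSON.  Every file carries
explicit units (microvolts internally; the conventional display scale of
1 unit = 5 uV is recorded in headers).  A minimal native WFDB reader/
writer (format 16 only) covers signal exchange without extra dependencies.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from stmorph.basis import BasisMatrix, STWindowSpec, orthonormality_error
from stmorph.delineate import FeatureSeries, NormalizationModel
from stmorph.klt import KLTModel
from stmorph.preprocess import Beat, ECGRecord
from stmorph.synth import Episode

__all__ = [
    "UNIT_UV_PER_DISPLAY_UNIT",
    "FormatError",
    "write_basis",
    "read_basis",
    "write_klt_model",
    "read_klt_model",
    "write_normalization_model",
    "read_normalization_model",
    "write_feature_series",
    "read_feature_series",
    "write_episodes",
    "read_episodes",
    "save_bundle",
    "load_bundle",
    "write_wfdb",
    "read_wfdb",
]

# display convention: 20 units = 100 uV
UNIT_UV_PER_DISPLAY_UNIT = 5.0

FEATURE_FORMAT_VERSION = 1


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- basis TSV


def write_basis(basis: BasisMatrix, path: str | Path) -> None:
    """Basis matrix as TSV (rows = samples, columns = basis functions) + JSON sidecar."""
    path = Path(path)
    np.savetxt(path, basis.entries, delimiter="\t", fmt="%.12g")
    diag_err, off_err = orthonormality_error(basis, min(10, basis.M))
    sidecar = {
        "kind": basis.kind,
        "window": basis.window.to_dict(),
        "weights": basis.weights.tolist(),
        "orthonormality": {
            "first_k": min(10, basis.M),
            "max_diag_error": diag_err,
            "max_offdiag_error": off_err,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_basis(path: str | Path) -> BasisMatrix:
    path = Path(path)
    entries = np.loadtxt(path, delimiter="\t")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        return BasisMatrix(
            entries=entries,
            kind=meta["kind"],
            window=STWindowSpec.from_dict(meta["window"]),
            weights=np.asarray(meta["weights"]),
        )
    return BasisMatrix(entries=entries, kind="LPT", window=STWindowSpec(n_samples=entries.shape[0]))


# ---------------------------------------------------------------- models


def write_klt_model(model: KLTModel, path: str | Path) -> None:
    doc = {
        "kind": "KLT",
        "window": model.basis.window.to_dict(),
        "basis": model.basis.entries.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "stds_uv": None if model.stds is None else model.stds.tolist(),
        "units": {"amplitude": "uV", "display_unit_uv": UNIT_UV_PER_DISPLAY_UNIT},
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_klt_model(path: str | Path) -> KLTModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "KLT":
        raise FormatError(f"{path}: not a KLT model file")
    basis = BasisMatrix(
        entries=np.asarray(doc["basis"]),
        kind="KLT",
        window=STWindowSpec.from_dict(doc["window"]),
    )
    stds = doc.get("stds_uv")
    return KLTModel(
        basis=basis,
        eigenvalues=np.asarray(doc["eigenvalues"]),
        stds=None if stds is None else np.asarray(stds),
    )


def write_normalization_model(model: NormalizationModel, path: str | Path) -> None:
    doc = {
        "kind": "normalization",
        "rho_uv": model.rho.tolist(),
        "theta_uv": model.theta.tolist(),
        "provenance": model.provenance,
        "units": {"amplitude": "uV", "display_unit_uv": UNIT_UV_PER_DISPLAY_UNIT},
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_normalization_model(path: str | Path) -> NormalizationModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "normalization":
        raise FormatError(f"{path}: not a normalization model file")
    return NormalizationModel(
        rho=np.asarray(doc["rho_uv"]),
        theta=np.asarray(doc["theta_uv"]),
        provenance=doc.get("provenance", ""),
    )


# ---------------------------------------------------------------- feature series TSV


def _series_columns(n_coeffs: int) -> list[str]:
    cols = ["time_s", "lead", "beat_index", "heart_rate", "st_level", "st_slope"]
    for prefix in ("klt_raw", "klt_norm"):
        cols += [f"{prefix}_{k}" for k in range(1, n_coeffs + 1)]
    cols += ["klt_residual", "d_klt"]
    for prefix in ("lpt_raw", "lpt_norm"):
        cols += [f"{prefix}_{k}" for k in range(1, n_coeffs + 1)]
    cols += ["lpt_residual", "d_lpt"]
    return cols


def write_feature_series(series: FeatureSeries, path: str | Path) -> None:
    """Feature series as TSV with a JSON header comment; 9 significant digits."""
    n_coeffs = series.klt_raw.shape[1] if len(series) else 9
    header = {
        "format_version": FEATURE_FORMAT_VERSION,
        "n_coeffs": n_coeffs,
        "n_d": series.n_d,
        "units": {"amplitude": "uV", "display_unit_uv": UNIT_UV_PER_DISPLAY_UNIT},
        "meta": {k: v for k, v in series.meta.items()},
    }
    cols = _series_columns(n_coeffs)
    lines = ["# " + json.dumps(header), "\t".join(cols)]
    for i in range(len(series)):
        row = [
            f"{series.time_s[i]:.9g}",
            str(int(series.lead[i])),
            str(int(series.beat_index[i])),
            f"{series.heart_rate[i]:.9g}",
            f"{series.st_level[i]:.9g}",
            f"{series.st_slope[i]:.9g}",
        ]
        row += [f"{v:.9g}" for v in series.klt_raw[i]]
        row += [f"{v:.9g}" for v in series.klt_norm[i]]
        row += [f"{series.klt_residual[i]:.9g}", f"{series.d_klt[i]:.9g}"]
        row += [f"{v:.9g}" for v in series.lpt_raw[i]]
        row += [f"{v:.9g}" for v in series.lpt_norm[i]]
        row += [f"{series.lpt_residual[i]:.9g}", f"{series.d_lpt[i]:.9g}"]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_series(path: str | Path) -> FeatureSeries:
    text = Path(path).read_text().strip().split("\n")
    if not text or not text[0].startswith("# "):
        raise FormatError(f"{path}: missing JSON header line")
    header = json.loads(text[0][2:])
    if header.get("format_version") != FEATURE_FORMAT_VERSION:
        raise FormatError(
            f"{path}: unsupported format version {header.get('format_version')!r}"
        )
    n_coeffs = header["n_coeffs"]
    cols = _series_columns(n_coeffs)
    if text[1].split("\t") != cols:
        raise FormatError(f"{path}: column schema mismatch")
    body = text[2:]
    if body and body[-1] == "":
        body = body[:-1]
    data = (
        np.array([[float(v) for v in line.split("\t")] for line in body])
        if body
        else np.empty((0, len(cols)))
    )
    c = {name: i for i, name in enumerate(cols)}

    def block(prefix: str) -> np.ndarray:
        idx = [c[f"{prefix}_{k}"] for k in range(1, n_coeffs + 1)]
        return data[:, idx]

    return FeatureSeries(
        time_s=data[:, c["time_s"]],
        lead=data[:, c["lead"]].astype(np.int64),
        beat_index=data[:, c["beat_index"]].astype(np.int64),
        heart_rate=data[:, c["heart_rate"]],
        st_level=data[:, c["st_level"]],
        st_slope=data[:, c["st_slope"]],
        klt_raw=block("klt_raw"),
        klt_norm=block("klt_norm"),
        klt_residual=data[:, c["klt_residual"]],
        lpt_raw=block("lpt_raw"),
        lpt_norm=block("lpt_norm"),
        lpt_residual=data[:, c["lpt_residual"]],
        d_klt=data[:, c["d_klt"]],
        d_lpt=data[:, c["d_lpt"]],
        n_d=header["n_d"],
        meta=header.get("meta", {}),
    )


# ---------------------------------------------------------------- episodes JSON


def write_episodes(episodes: list[Episode], path: str | Path) -> None:
    Path(path).write_text(json.dumps([asdict(e) for e in episodes], indent=2))


def read_episodes(path: str | Path) -> list[Episode]:
    return [Episode(**d) for d in json.loads(Path(path).read_text())]


# ---------------------------------------------------------------- record bundle (NPZ)


def save_bundle(record: ECGRecord, path: str | Path) -> None:
    """Portable NPZ bundle: per-lead uV signals plus the beat table."""
    beats = record.beats
    has_iso = [b.isoelectric is not None for b in beats]
    np.savez(
        path,
        signals_uv=record.signals,
        fs=np.array([record.fs]),
        beat_fiducial=np.array([b.fiducial for b in beats], dtype=np.int64),
        beat_label=np.array([b.label for b in beats]),
        beat_rr_prev_ms=np.array(
            [b.rr_prev_ms if b.rr_prev_ms is not None else np.nan for b in beats]
        ),
        beat_has_iso=np.array(has_iso),
        beat_iso=np.array(
            [
                b.isoelectric if b.isoelectric is not None else np.full(record.lead_count, np.nan)
                for b in beats
            ]
        ).reshape(len(beats), record.lead_count) if beats else np.empty((0, record.lead_count)),
        beat_iso_center=np.array(
            [
                b.iso_center if b.iso_center is not None else np.full(record.lead_count, -1)
                for b in beats
            ],
            dtype=np.int64,
        ).reshape(len(beats), record.lead_count) if beats else np.empty((0, record.lead_count), dtype=np.int64),
        beat_usable=np.array([b.usable for b in beats]),
    )


def load_bundle(path: str | Path) -> ECGRecord:
    with np.load(path, allow_pickle=False) as z:
        beats = []
        for i in range(len(z["beat_fiducial"])):
            rr = float(z["beat_rr_prev_ms"][i])
            beats.append(
                Beat(
                    fiducial=int(z["beat_fiducial"][i]),
                    label=str(z["beat_label"][i]),
                    isoelectric=z["beat_iso"][i] if z["beat_has_iso"][i] else None,
                    iso_center=z["beat_iso_center"][i] if z["beat_has_iso"][i] else None,
                    rr_prev_ms=None if np.isnan(rr) else rr,
                    usable=bool(z["beat_usable"][i]),
                )
            )
        return ECGRecord(signals=z["signals_uv"], fs=float(z["fs"][0]), beats=beats)


# ---------------------------------------------------------------- minimal WFDB


def write_wfdb(
    record: ECGRecord,
    prefix: str | Path,
    gain_adu_per_mv: float = 200.0,
    annotations: bool = True,
) -> None:
    """Export as a WFDB format-16 record (<prefix>.hea, <prefix>.dat).

    Beat annotations go to a plain-text <prefix>.ann with one
    "sample<TAB>label" line per beat.
    """
    prefix = Path(prefix)
    name = prefix.name
    n_sig, n_samp = record.signals.shape
    digital = np.round(record.signals / 1000.0 * gain_adu_per_mv).astype(np.int16)
    interleaved = digital.T.reshape(-1)
    (prefix.parent / f"{name}.dat").write_bytes(interleaved.astype("<i2").tobytes())
    lines = [f"{name} {n_sig} {record.fs:g} {n_samp}"]
    for lead in range(n_sig):
        lines.append(f"{name}.dat 16 {gain_adu_per_mv:g}(0)/mV 16 0 0 0 0 ECG{lead}")
    (prefix.parent / f"{name}.hea").write_text("\n".join(lines) + "\n")
    if annotations and record.beats:
        ann = "\n".join(f"{b.fiducial}\t{b.label}" for b in record.beats)
        (prefix.parent / f"{name}.ann").write_text(ann + "\n")


def read_wfdb(prefix: str | Path) -> ECGRecord:
    """Read a WFDB record (format 16 only); annotations from <prefix>.ann if present.

    Signals are converted to uV with the header gain; annotation labels map
    to the beat table unchanged ('N' = normal, anything else abnormal).
    """
    prefix = Path(prefix)
    hea = prefix.parent / f"{prefix.name}.hea"
    if not hea.exists():
        raise FormatError(f"missing header file {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea}:1: malformed record line {lines[0]!r}")
    n_sig = int(head[1])
    fs = float(head[2])
    n_samp = int(head[3])

    gains = []
    units = []
    dat_name = None
    for k, ln in enumerate(lines[1 : 1 + n_sig], start=2):
        tok = ln.split()
        if len(tok) < 3:
            raise FormatError(f"{hea}:{k}: malformed signal line {ln!r}")
        dat_name = tok[0]
        fmt = tok[1].split("x")[0].split(":")[0]
        if fmt != "16":
            raise FormatError(f"{hea}:{k}: unsupported WFDB format {fmt!r} (only 16)")
        gspec = tok[2]
        unit = "mV"
        if "/" in gspec:
            gspec, unit = gspec.split("/", 1)
        if "(" in gspec:
            gspec = gspec.split("(")[0]
        gains.append(float(gspec) if float(gspec) != 0 else 200.0)
        units.append(unit)

    dat = prefix.parent / dat_name
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    raw = raw[: n_samp * n_sig].reshape(n_samp, n_sig).T.astype(float)
    signals = np.empty_like(raw)
    for lead in range(n_sig):
        scale = 1000.0 if units[lead].lower() == "mv" else 1.0
        signals[lead] = raw[lead] / gains[lead] * scale

    beats: list[Beat] = []
    ann = prefix.parent / f"{prefix.name}.ann"
    if ann.exists():
        prev = None
        for ln in ann.read_text().splitlines():
            if not ln.strip():
                continue
            sample_str, label = ln.split()[:2]
            sample = int(sample_str)
            rr = None if prev is None else (sample - prev) / fs * 1000.0
            beats.append(Beat(fiducial=sample, label=label, rr_prev_ms=rr))
            prev = sample
    return ECGRecord(signals=signals, fs=fs, beats=beats)
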