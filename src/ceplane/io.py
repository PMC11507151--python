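"""Reading and writing cohorts: metadata CSV, NPZ signal bundles, EDF.

A cohort on disk is a directory containing ``metadata.csv`` (one row per
channel: patient_id, sex, age, region, hemisphere, channel_id, fs_hz)
plus the signals, either as a single ``signals.npz`` bundle keyed by
channel_id or as one EDF file per patient.  EDF reading goes through MNE;
EDF writing uses a small built-in writer for the standard 16-bit EDF
layout (1 s data records, per-channel physical scaling).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .records import METADATA_COLUMNS, SignalRecord

__all__ = [
    "read_metadata",
    "read_signals",
    "write_cohort",
    "write_edf",
]

_SEX_ALIASES = {
    "f": "F", "female": "F", "woman": "F", "w": "F",
    "m": "M", "male": "M", "man": "M",
}


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Load and validate a channel-metadata CSV.

    Column order is irrelevant and extra columns are preserved.  Sex
    labels are normalized to {F, M} through a documented alias map
    (female/woman/w -> F, male/man -> M, case-insensitive).  Raises
    ``KeyError`` for missing required columns and ``ValueError`` for
    unparseable ages or unrecognized sex labels (with row indices).
    """
    df = pd.read_csv(path)
    required = [c for c in METADATA_COLUMNS if c != "fs_hz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"metadata file {path} is missing columns: {missing}")

    ages = pd.to_numeric(df["age"], errors="coerce")
    bad = df.index[ages.isna()].tolist()
    if bad:
        raise ValueError(f"unparseable age values at rows {bad} of {path}")
    df["age"] = ages

    def _norm_sex(value):
        s = str(value).strip()
        if s in ("F", "M"):
            return s
        return _SEX_ALIASES.get(s.lower())

    norm = df["sex"].map(_norm_sex)
    bad = df.index[norm.isna()].tolist()
    if bad:
        raise ValueError(
            f"unrecognized sex labels at rows {bad} of {path}: "
            f"{df.loc[bad, 'sex'].unique().tolist()}"
        )
    df["sex"] = norm
    df["patient_id"] = df["patient_id"].astype(str)
    df["channel_id"] = df["channel_id"].astype(str)
    return df


def _records_from_arrays(
    arrays: dict[str, np.ndarray],
    fs_by_channel: dict[str, float],
    metadata: pd.DataFrame,
    fs_expected: float | None,
) -> list[SignalRecord]:
    meta_by_channel = metadata.set_index("channel_id")
    orphans = sorted(set(arrays) - set(meta_by_channel.index))
    if orphans:
        raise KeyError(f"channels present in signals but absent from metadata: {orphans}")
    records = []
    for channel_id in sorted(arrays):
        row = meta_by_channel.loc[channel_id]
        x = np.asarray(arrays[channel_id], dtype=float)
        fs = float(fs_by_channel[channel_id])
        if fs_expected is not None and fs != fs_expected:
            warnings.warn(
                f"channel {channel_id}: resampling {fs} Hz -> {fs_expected} Hz",
                stacklevel=3,
            )
            up, down = (np.array([fs_expected, fs]) /
                        np.gcd(int(fs_expected), int(fs))).astype(int)
            x = resample_poly(x, up, down)
            fs = fs_expected
        records.append(
            SignalRecord(
                channel_id=channel_id,
                patient_id=str(row["patient_id"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                region=str(row["region"]),
                hemisphere=str(row["hemisphere"]),
                fs=fs,
                data=x,
            )
        )
    return records


def read_signals(
    path: str | Path,
    metadata: pd.DataFrame | None = None,
    fs_expected: float | None = 200.0,
) -> list[SignalRecord]:
    """Load all channels of a cohort directory (NPZ bundle or EDF files).

    ``path`` is a cohort directory, a ``signals.npz`` bundle, or a single
    EDF file.  ``metadata`` defaults to ``metadata.csv`` next to the
    signals.  Channels whose rate differs from ``fs_expected`` are
    resampled with a warning; pass ``fs_expected=None`` to keep native
    rates.  Raises ``FileNotFoundError``/``ValueError`` for unreadable
    inputs and ``KeyError`` for channels missing from the metadata.
    """
    path = Path(path)
    directory = path if path.is_dir() else path.parent
    if metadata is None:
        metadata = read_metadata(directory / "metadata.csv")

    if path.is_dir():
        npz = path / "signals.npz"
        edfs = sorted(path.glob("*.edf"))
        if npz.exists():
            sources = [npz]
        elif edfs:
            sources = edfs
        else:
            raise FileNotFoundError(f"no signals.npz or *.edf files under {path}")
    else:
        sources = [path]

    arrays: dict[str, np.ndarray] = {}
    fs_by_channel: dict[str, float] = {}
    for src in sources:
        if src.stat().st_size == 0:
            raise ValueError(f"signal file {src} is empty")
        if src.suffix == ".npz":
            with np.load(src) as bundle:
                fs_arr = bundle["__fs_hz__"]
                names = [k for k in bundle.files if k != "__fs_hz__"]
                fs_map = dict(zip(sorted(names), np.atleast_1d(fs_arr)))
                for name in names:
                    arrays[name] = bundle[name]
                    fs_by_channel[name] = float(fs_map[name])
        elif src.suffix.lower() == ".edf":
            import mne

            raw = mne.io.read_raw_edf(src, preload=True, verbose="error")
            for name, x in zip(raw.ch_names, raw.get_data()):
                arrays[name] = x
                fs_by_channel[name] = float(raw.info["sfreq"])
        else:
            raise ValueError(f"unsupported signal file type: {src}")
    return _records_from_arrays(arrays, fs_by_channel, metadata, fs_expected)


def write_cohort(
    records: list[SignalRecord],
    metadata: pd.DataFrame,
    directory: str | Path,
    fmt: str = "npz",
) -> Path:
    """Write a cohort directory: ``metadata.csv`` plus signals.

    ``fmt='npz'`` stores all channels in one lossless ``signals.npz``
    bundle; ``fmt='edf'`` writes one 16-bit EDF file per patient
    (quantized to the per-channel physical range, as EDF requires).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    metadata.to_csv(directory / "metadata.csv", index=False)
    if fmt == "npz":
        names = sorted(r.channel_id for r in records)
        by_id = {r.channel_id: r for r in records}
        arrays = {name: by_id[name].data for name in names}
        arrays["__fs_hz__"] = np.array([by_id[name].fs for name in names])
        np.savez(directory / "signals.npz", **arrays)
    elif fmt == "edf":
        by_patient: dict[str, list[SignalRecord]] = {}
        for r in records:
            by_patient.setdefault(r.patient_id, []).append(r)
        for patient_id, recs in sorted(by_patient.items()):
            write_edf(directory / f"{patient_id}.edf", recs)
    else:
        raise ValueError(f"fmt must be 'npz' or 'edf', got {fmt!r}")
    return directory


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, records: list[SignalRecord]) -> Path:
    """Write one standard EDF file holding the given channels.

    All channels must share one sampling rate and length.  Data are
    stored as little-endian int16 scaled to each channel's physical
    range, in 1 s data records.  Lengths that are not a whole number of
    seconds are zero-padded to the next full record.
    """
    if not records:
        raise ValueError("write_edf needs at least one channel")
    fs = records[0].fs
    if any(r.fs != fs for r in records):
        raise ValueError("all channels in one EDF file must share a sampling rate")
    if fs != int(fs):
        raise ValueError("the built-in EDF writer requires an integer sampling rate")
    spr = int(fs)  # samples per 1 s data record
    n_samples = max(len(r.data) for r in records)
    n_records = int(np.ceil(n_samples / spr))
    ns = len(records)

    path = Path(path)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(records[0].patient_id, 80),
            _edf_field("synthetic cohort", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (1 + ns), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(1, 8),
            _edf_field(ns, 4),
        ]
    )

    phys_min, phys_max, scaled = [], [], []
    dig_min, dig_max = -32768, 32767
    for r in records:
        x = np.zeros(n_records * spr)
        x[: len(r.data)] = r.data
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        gain = (dig_max - dig_min) / (hi - lo)
        scaled.append(
            np.round((x - lo) * gain + dig_min).clip(dig_min, dig_max).astype("<i2")
        )

    def sig_fields(width: int, values) -> bytes:
        return b"".join(_edf_field(v, width) for v in values)

    header += sig_fields(16, (r.channel_id for r in records))
    header += sig_fields(80, ("" for _ in records))
    header += sig_fields(8, ("uV" for _ in records))
    header += sig_fields(8, (f"{v:.6g}" for v in phys_min))
    header += sig_fields(8, (f"{v:.6g}" for v in phys_max))
    header += sig_fields(8, (dig_min for _ in records))
    header += sig_fields(8, (dig_max for _ in records))
    header += sig_fields(80, ("" for _ in records))
    header += sig_fields(8, (spr for _ in records))
    header += sig_fields(32, ("" for _ in records))

    with open(path, "wb") as fh:
        fh.write(header)
        for rec_idx in range(n_records):
            for ch in scaled:
                fh.write(ch[rec_idx * spr : (rec_idx + 1) * spr].tobytes())
    return path
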