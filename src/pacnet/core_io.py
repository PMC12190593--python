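"""Data model, file readers/writers and study configuration.

A :class:`Recording` is the atomic analysis unit: one subject in one state,
a channels x samples matrix in microvolts with 10-10 style channel labels.
Recordings round-trip through two on-disk formats:

* delimited text (CSV) — header row of channel labels, one column per
  channel, samples as rows; lossless;
* EDF — 16-bit European Data Format; read via :mod:`mne`, written by a
  minimal in-house writer (values survive within one quantization step of
  the per-channel physical range).

Feature values produced by the analysis stages live in a long-format
"study table": one row per subject x state x channel x feature x band.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

GROUPS = ("wm", "tdcs", "sham")
STATES = ("pre_rest", "task", "post_rest")

#: column order of the long-format feature table; stable across writes
FEATURE_COLUMNS = (
    "subject_id",
    "group",
    "state",
    "channel",
    "feature_name",
    "band",
    "value",
)


class PacnetError(Exception):
    """Base class for errors raised by this package."""


@dataclass(frozen=True)
class Band:
    """A frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"({self.f_lo}, {self.f_hi})"
            )

    def validate_for(self, fs: float) -> None:
        """Raise if the band is not strictly below the Nyquist frequency."""
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.f_hi} Hz is at or above "
                f"Nyquist ({fs / 2} Hz)"
            )


#: the two bands analysed throughout: slow modulating and fast modulated
DELTA = Band("delta", 0.5, 4.0)
GAMMA = Band("gamma", 30.0, 50.0)


@dataclass
class Recording:
    """One subject x state multichannel signal with metadata.

    data is channels x samples, microvolts. Channel order is preserved in
    every downstream per-channel output.
    """

    subject_id: str
    group: str
    state: str
    fs: float
    channels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel labels but data has "
                f"{self.data.shape[0]} rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel labels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in recording")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the signal of a single channel by label."""
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None
        return self.data[idx]


def rereference(rec: Recording, ref_labels: Sequence[str]) -> Recording:
    """Re-reference to the mean of ``ref_labels`` (e.g. mastoids M1/M2).

    Every non-reference channel has the sample-wise mean of the reference
    channels subtracted; the reference channels themselves are dropped from
    the output (they would be identically the negated mean).
    """
    missing = [l for l in ref_labels if l not in rec.channels]
    if missing:
        raise ValueError(f"reference channel(s) not present: {missing}")
    ref_idx = [rec.channels.index(l) for l in ref_labels]
    keep_idx = [i for i in range(rec.n_channels) if i not in ref_idx]
    ref_mean = rec.data[ref_idx].mean(axis=0)
    return Recording(
        subject_id=rec.subject_id,
        group=rec.group,
        state=rec.state,
        fs=rec.fs,
        channels=[rec.channels[i] for i in keep_idx],
        data=rec.data[keep_idx] - ref_mean,
    )


# ---------------------------------------------------------------------------
# recording I/O


def read_recording(
    path: str | Path,
    *,
    subject_id: str = "s01",
    group: str = "wm",
    state: str = "task",
    fs: float | None = None,
) -> Recording:
    """Read a Recording from an EDF file or a delimited channel matrix.

    Delimited input: first row = channel labels, one column per channel,
    samples as rows. ``fs`` is mandatory for delimited input; for EDF it is
    taken from the header and, if also passed, cross-checked against it.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        labels, header_fs, data = _read_edf(path)
        if fs is not None and not math.isclose(fs, header_fs, rel_tol=1e-9):
            raise ValueError(
                f"sampling rate mismatch: EDF header says {header_fs} Hz, "
                f"metadata says {fs} Hz"
            )
        return Recording(subject_id, group, state, header_fs, labels, data)
    if fs is None:
        raise ValueError("fs metadata is required for delimited input")
    with open(path) as fh:
        labels = [c.strip() for c in fh.readline().rstrip("\n").split(",")]
    frame = pd.read_csv(
        path, skiprows=1, header=None, float_precision="round_trip"
    )
    if frame.shape[1] != len(labels):
        raise ValueError(
            f"{len(labels)} header labels but {frame.shape[1]} data columns"
        )
    try:
        data = frame.to_numpy(dtype=float).T
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return Recording(subject_id, group, state, fs, labels, data)


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as CSV (lossless) or EDF (16-bit), by extension."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        _write_edf(rec, path)
    else:
        frame = pd.DataFrame(rec.data.T, columns=rec.channels)
        # %.17g round-trips IEEE doubles exactly
        frame.to_csv(path, index=False, float_format="%.17g")
    return path


def _read_edf(path: Path) -> tuple[list[str], float, np.ndarray]:
    import mne  # deferred: slow import, only needed for EDF

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne converts EEG to volts; we keep uV
    return list(raw.ch_names), float(raw.info["sfreq"]), data


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: 1-second data records, 16-bit samples.

    Requires an integer sampling rate and a whole number of seconds;
    per-channel physical scaling spans the observed range.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF output requires an integer sampling rate")
    fs = int(round(fs))
    n_records, rem = divmod(rec.n_samples, fs)
    if rem or n_records == 0:
        raise ValueError("EDF output requires a whole number of seconds of data")
    ns = rec.n_channels
    dig_min, dig_max = -32768, 32767

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii", "replace")[:width]
        return b.ljust(width)

    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            f("0", 8),
            f(rec.subject_id, 80),
            f(f"{rec.group} {rec.state}", 80),
            f(now.strftime("%d.%m.%y"), 8),
            f(now.strftime("%H.%M.%S"), 8),
            f(str(256 * (1 + ns)), 8),
            f("", 44),
            f(str(n_records), 8),
            f("1", 8),
            f(str(ns), 4),
        ]
    )
    pmins = rec.data.min(axis=1)
    pmaxs = rec.data.max(axis=1)
    flat = pmaxs - pmins <= 0
    pmins[flat] -= 1.0
    pmaxs[flat] += 1.0

    def num(x: float) -> str:
        s = f"{x:.6g}"
        return s if len(s) <= 8 else f"{x:.2e}"

    sig_fields: list[bytes] = []
    for maker, width in [
        (lambda i: rec.channels[i], 16),
        (lambda i: "", 80),
        (lambda i: "uV", 8),
        (lambda i: num(pmins[i]), 8),
        (lambda i: num(pmaxs[i]), 8),
        (lambda i: str(dig_min), 8),
        (lambda i: str(dig_max), 8),
        (lambda i: "", 80),
        (lambda i: str(fs), 8),
        (lambda i: "", 32),
    ]:
        sig_fields.extend(f(maker(i), width) for i in range(ns))
    # physical limits as re-parsed from their ascii fields, so scaling is
    # exactly invertible by any conforming reader
    pmins = np.array([float(num(v)) for v in pmins])
    pmaxs = np.array([float(num(v)) for v in pmaxs])
    scale = (pmaxs - pmins) / (dig_max - dig_min)
    digital = np.round((rec.data - pmins[:, None]) / scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")
    records = digital.reshape(ns, n_records, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(sig_fields))
        fh.write(records.tobytes())


# ---------------------------------------------------------------------------
# feature tables


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check study-table invariants: columns, finite values, unique keys."""
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    table = table.loc[:, list(FEATURE_COLUMNS)]
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValueError("non-finite feature values")
    keys = ["subject_id", "state", "channel", "feature_name", "band"]
    if table.duplicated(subset=keys).any():
        dup = table[table.duplicated(subset=keys)].iloc[0]
        raise ValueError(f"duplicate feature-table key: {dup[keys].to_dict()}")
    return table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a study table as CSV with the stable column order."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty feature table")
    validate_feature_table(table).to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        dtype={c: str for c in FEATURE_COLUMNS[:-1]},
        float_precision="round_trip",
    )
    return validate_feature_table(table)


# ---------------------------------------------------------------------------
# study configuration


@dataclass
class WelchParams:
    """Welch PSD settings: 2 s Hamming segments, 50% overlap by default.

    ``window_constant`` is the cosine coefficient a of the Hamming taper
    (1-a) - a*cos(2*pi*n/(N-1)); ``scale`` multiplies the band-mean density
    before taking 10*log10 (an overall amplification constant; only dB
    differences are comparable across choices of it).
    """

    segment_length: int = 2000
    overlap: float = 0.5
    window_constant: float = 0.46
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.segment_length < 2:
            raise ValueError("segment_length must be >= 2")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap fraction must be in [0, 1)")
        if not 0 < self.window_constant < 1:
            raise ValueError("window_constant must be in (0, 1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class NetworkParams:
    """Correlation-network settings.

    Default binarization thresholds are the working-memory study values
    (0.32 delta, 0.56 gamma); ``density_range`` drives data-driven
    threshold selection when no fixed threshold is given.
    """

    thresholds: dict[str, float] = field(
        default_factory=lambda: {"delta": 0.32, "gamma": 0.56}
    )
    density_range: tuple[float, float] = (0.05, 0.45)
    absolute: bool = False

    def __post_init__(self) -> None:
        self.density_range = tuple(self.density_range)  # type: ignore[assignment]
        lo, hi = self.density_range
        if not (0 < lo < hi <= 1):
            raise ValueError("density_range must satisfy 0 < lo < hi <= 1")
        for band, thr in self.thresholds.items():
            if not 0 < thr < 1:
                raise ValueError(f"threshold for {band!r} must be in (0, 1)")


@dataclass
class StudyConfig:
    """Everything a full study run needs; loadable from YAML."""

    bands: dict[str, Band] = field(
        default_factory=lambda: {"delta": DELTA, "gamma": GAMMA}
    )
    n_bins: int = 18
    welch: WelchParams = field(default_factory=WelchParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    alpha: float = 0.05
    seed: int = 0
    synthetic: dict | None = None
    input_dir: str | None = None
    output_dir: str = "pacnet_out"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.bands:
            raise ValueError("at least one band is required")

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bands" in raw:
            bands = {}
            for name, edges in raw["bands"].items():
                if isinstance(edges, dict):
                    bands[name] = Band(name, **_only(edges, {"f_lo", "f_hi"}))
                else:
                    lo, hi = edges
                    bands[name] = Band(name, float(lo), float(hi))
            raw["bands"] = bands
        if "welch" in raw:
            raw["welch"] = WelchParams(**_only(raw["welch"], None, WelchParams))
        if "network" in raw:
            raw["network"] = NetworkParams(**_only(raw["network"], None, NetworkParams))
        if raw.get("synthetic") is not None:
            # validated against the generator's own field set, lazily to
            # avoid a module cycle
            from .synthetic import GeneratorSpec

            spec_fields = {f.name for f in dataclasses.fields(GeneratorSpec)}
            extra = {"n_subjects_per_group", "groups", "states"}
            unknown = set(raw["synthetic"]) - spec_fields - extra
            if unknown:
                raise ValueError(f"unknown synthetic keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw)}")
        return cls.from_dict(raw)


def _only(raw: dict, allowed: set | None, klass=None) -> dict:
    if allowed is None:
        allowed = {f.name for f in dataclasses.fields(klass)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return raw
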