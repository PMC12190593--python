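"""End-to-end study runs: ingest -> features -> networks -> statistics.

``run_study`` executes the full analysis for a configuration: synthetic
recordings are generated (or real ones loaded), per-channel features are
extracted (modulation index, band log-power), correlation networks are
built and reduced to degree/clustering, and the study's comparison
structure (task vs rest within subjects; stimulated vs sham between
groups) is tested and reported. All outputs are plain text (CSV / JSON /
report) in the output directory; runs are deterministic given the
configuration and seed.

Stage handoffs inside ``run_study`` stay in memory by default for speed;
each stage is also exposed as a CLI subcommand operating on files so any
stage can be re-run independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    FEATURE_COLUMNS,
    Recording,
    StudyConfig,
    read_recording,
    validate_feature_table,
    write_feature_table,
)
from .network import (
    binarize,
    correlation_matrix,
    edges_dataframe,
    network_features,
    select_threshold,
)
from .pac import channel_mi
from .spectral import band_power_db, bandpass, welch_psd
from .stats import compare_groups, compare_states, results_to_dataframe
from .synthetic import GeneratorSpec, gen_study, write_study

__all__ = [
    "StageError",
    "run_study",
    "extract_features",
    "network_stage",
    "comparison_stage",
    "load_recordings",
    "build_generator",
]

log = logging.getLogger("pacnet")

STATE_PAIRS = (("pre_rest", "task"), ("post_rest", "task"), ("pre_rest", "post_rest"))
GROUP_PAIR = ("sham", "tdcs")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for exit codes."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def build_generator(config: StudyConfig) -> tuple[GeneratorSpec, dict]:
    """Split the config's synthetic block into a GeneratorSpec and study shape."""
    block = dict(config.synthetic or {})
    shape = {
        "n_subjects_per_group": block.pop("n_subjects_per_group", 12),
        "groups": tuple(block.pop("groups", ("wm", "tdcs", "sham"))),
        "states": tuple(block.pop("states", ("pre_rest", "task", "post_rest"))),
    }
    block.setdefault("seed", config.seed)
    return GeneratorSpec(**block), shape


def _pac_pair(config: StudyConfig):
    names = list(config.bands)
    phase = config.bands.get("delta", config.bands[names[0]])
    amp = config.bands.get("gamma", config.bands[names[-1]])
    return phase, amp


def extract_features(recordings: list[Recording], config: StudyConfig) -> pd.DataFrame:
    """Per-channel modulation index and band log-power for every recording."""
    phase_band, amp_band = _pac_pair(config)
    pac_label = f"{phase_band.name}-{amp_band.name}"
    rows = []
    for rec in recordings:
        for res in channel_mi(rec, phase_band, amp_band, config.n_bins):
            rows.append(
                (rec.subject_id, rec.group, rec.state, res.channel, "mi",
                 pac_label, res.mi)
            )
        w = config.welch
        seg = min(w.segment_length, rec.n_samples)
        for i, label in enumerate(rec.channels):
            psd = welch_psd(rec.data[i], rec.fs, seg, w.overlap, w.window_constant)
            for band in config.bands.values():
                rows.append(
                    (rec.subject_id, rec.group, rec.state, label, "band_power_db",
                     band.name, band_power_db(psd, band, w.scale))
                )
    return validate_feature_table(pd.DataFrame(rows, columns=list(FEATURE_COLUMNS)))


def network_stage(
    recordings: list[Recording],
    config: StudyConfig,
    edges_dir: Path | None = None,
) -> pd.DataFrame:
    """Band-filtered correlation networks and their graph-metric rows."""
    rows = []
    for rec in recordings:
        for band in config.bands.values():
            cm = correlation_matrix(bandpass(rec, band), band)
            thr = config.network.thresholds.get(band.name)
            if thr is None:
                thr = select_threshold(
                    cm, config.network.density_range, config.network.absolute
                )
            net = binarize(cm, thr, config.network.absolute)
            rows.append(
                network_features(net, rec.subject_id, rec.group, rec.state, band.name)
            )
            if edges_dir is not None:
                edges_dir.mkdir(parents=True, exist_ok=True)
                edges_dataframe(net).to_csv(
                    edges_dir / f"{rec.subject_id}_{rec.state}_{band.name}_edges.csv",
                    index=False,
                )
    return validate_feature_table(pd.concat(rows, ignore_index=True))


def comparison_stage(table: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """All state and group contrasts available in the feature table."""
    results = []
    combos = table[["feature_name", "band"]].drop_duplicates().itertuples(index=False)
    states_present = set(table["state"])
    groups_present = set(table["group"])
    for feature, band in combos:
        for pair in STATE_PAIRS:
            if set(pair) <= states_present:
                results.extend(
                    compare_states(table, feature, band, pair, config.alpha)
                )
        if set(GROUP_PAIR) <= groups_present and "task" in states_present:
            results.extend(
                compare_groups(table, feature, band, GROUP_PAIR, "task", config.alpha)
            )
    return results_to_dataframe(results)


def _report(comparisons: pd.DataFrame) -> str:
    lines = ["Whole-brain comparisons", "=" * 23, ""]
    whole = comparisons[comparisons["level"] == "whole_brain_mean"]
    for row in whole.itertuples(index=False):
        mark = "*" if row.significant else " "
        lines.append(
            f"{mark} {row.feature_name:>14s} [{row.band:>11s}] "
            f"{row.condition_a} vs {row.condition_b}: "
            f"{row.mean_a:.4g} ± {row.sd_a:.4g} vs {row.mean_b:.4g} ± {row.sd_b:.4g}; "
            f"p = {row.p_value:.3g} ({row.test_name})"
        )
    per = comparisons[comparisons["level"] == "per_channel"]
    lines += ["", "Per-channel significant nodes", "-" * 29, ""]
    for (feature, band, ca, cb), sub in per.groupby(
        ["feature_name", "band", "condition_a", "condition_b"], sort=False
    ):
        sig = sub[sub["significant"]]["channel"].tolist()
        lines.append(
            f"{feature} [{band}] {ca} vs {cb}: "
            f"{len(sig)}/{len(sub)} nodes significant"
            + (f" ({', '.join(sig)})" if 0 < len(sig) <= 15 else "")
        )
    return "\n".join(lines) + "\n"


def run_study(
    config: StudyConfig,
    out_dir: str | Path | None = None,
    write_recordings: bool = False,
) -> Path:
    """Run the full pipeline; returns the output directory.

    On stage failure every file written by this run is removed and a
    :class:`StageError` naming the stage is raised.
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - cleaned up and re-raised
            for p in written:
                p.unlink(missing_ok=True)
            raise StageError(name, exc) from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %-8s done in %.2f s", name, timings[name])
        return result

    def _ingest():
        if config.synthetic is not None:
            spec, shape = build_generator(config)
            log.info("generating synthetic study: %s, shape %s", spec, shape)
            recordings, manifest = gen_study(spec, **shape)
            manifest.to_csv(out / "synthetic_manifest.csv", index=False)
            written.append(out / "synthetic_manifest.csv")
            if write_recordings:
                written.extend(write_study(recordings, manifest, out / "recordings"))
            return recordings
        if config.input_dir is None:
            raise ValueError("config needs either a synthetic block or input_dir")
        return load_recordings(config.input_dir)

    recordings = _stage("simulate", _ingest)
    features = _stage("features", lambda: extract_features(recordings, config))
    networks = _stage(
        "network", lambda: network_stage(recordings, config, out / "networks")
    )
    table = pd.concat([features, networks], ignore_index=True)
    written.append(write_feature_table(table, out / "features.csv"))
    comparisons = _stage("compare", lambda: comparison_stage(table, config))
    comparisons.to_csv(out / "comparisons.csv", index=False)
    written.append(out / "comparisons.csv")

    def _report_stage():
        (out / "report.txt").write_text(_report(comparisons))
        manifest = {
            "pacnet_version": __version__,
            "config_hash": config_hash(config),
            "seed": config.seed,
            "n_recordings": len(recordings),
            "timings_s": timings,
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    _stage("report", _report_stage)
    return out


def config_hash(config: StudyConfig) -> str:
    """Stable short hash identifying a configuration."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    import dataclasses

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def load_recordings(input_dir: str | Path, fs: float | None = None) -> list[Recording]:
    """Load every recording in a directory.

    If ``metadata.csv`` (columns: filename, subject_id, group, state, and
    fs for delimited files) is present it is authoritative; otherwise
    filenames must follow ``<subject>_<state>.<ext>`` with the group being
    the leading alphabetic prefix of the subject id (the layout written by
    the simulator).
    """
    input_dir = Path(input_dir)
    meta_path = input_dir / "metadata.csv"
    recordings = []
    if meta_path.exists():
        meta = pd.read_csv(meta_path)
        for row in meta.itertuples(index=False):
            recordings.append(
                read_recording(
                    input_dir / row.filename,
                    subject_id=str(row.subject_id),
                    group=str(row.group),
                    state=str(row.state),
                    fs=float(row.fs) if "fs" in meta.columns else fs,
                )
            )
        return recordings
    paths = sorted(
        p for p in input_dir.iterdir() if p.suffix.lower() in (".csv", ".edf")
        and p.name != "manifest.csv"
    )
    if not paths:
        raise ValueError(f"no recordings found in {input_dir}")
    for p in paths:
        stem = p.stem
        subject, _, state = stem.partition("_")
        group = subject.rstrip("0123456789")
        recordings.append(
            read_recording(p, subject_id=subject, group=group, state=state, fs=fs)
        )
    return recordings
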