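"""Readers and writers for the pipeline's TSV/JSON/DOT artifacts.

Fixed dialect: tab-separated, UTF-8, Unix newlines, dot decimal separator,
floats serialized with 17 significant digits so write/read round trips are
exact. All readers validate shape and finiteness and report the offending
location on failure.
"""

from __future__ import annotations

import json
import hashlib
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionTaxonomy
from .scores import ROITimeSeriesSet
from .tracts import PathwayMeasure, StreamlineData

FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    pass


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT,
              lineterminator="\n", encoding="utf-8")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8",
                       float_precision="round_trip")


# ---------------------------------------------------------------------------
# ROI time series
# ---------------------------------------------------------------------------

def write_timeseries_tsv(matrix: np.ndarray, labels, path) -> None:
    write_tsv(pd.DataFrame(np.asarray(matrix, float), columns=list(labels)), path)


def read_timeseries_tsv(path, known_labels=None) -> tuple[np.ndarray, tuple[str, ...]]:
    """One subject's time x region matrix; header row gives region labels.

    Rejects ragged rows, non-numeric cells and NaN/inf, naming the location.
    Labels outside ``known_labels`` (when given) produce a warning on stderr
    but the columns are retained.
    """
    try:
        df = pd.read_csv(path, sep="\t", encoding="utf-8",
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    labels = tuple(str(c) for c in df.columns)
    try:
        mat = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from exc
    bad = np.argwhere(~np.isfinite(mat))
    if bad.size:
        r, c = bad[0]
        raise ParseError(f"{path}: non-finite value at data row {r + 1}, "
                         f"column {labels[c]!r}")
    if known_labels is not None:
        unknown = [l for l in labels if l not in known_labels]
        if unknown:
            print(f"warning: {path}: labels outside taxonomy: {unknown}",
                  file=sys.stderr)
    return mat, labels


def read_group_manifest(path) -> dict[str, dict[str, list[Path]]]:
    """Manifest JSON: {group: {hemisphere: [subject TSV paths]}}; paths are
    resolved relative to the manifest's directory."""
    base = Path(path).parent
    with open(path) as fh:
        raw = json.load(fh)
    out: dict[str, dict[str, list[Path]]] = {}
    for group, hemis in raw.items():
        out[group] = {h: [base / p for p in paths] for h, paths in hemis.items()}
        for h, paths in out[group].items():
            for p in paths:
                if not p.exists():
                    raise ParseError(f"manifest {path}: missing file {p}")
    return out


def load_timeseries_set(paths, subject_ids=None) -> ROITimeSeriesSet:
    subjects = []
    labels = None
    for i, p in enumerate(paths):
        mat, lab = read_timeseries_tsv(p)
        if labels is None:
            labels = lab
        elif lab != labels:
            raise ParseError(f"{p}: region labels differ from first subject")
        sid = subject_ids[i] if subject_ids else Path(p).stem
        subjects.append((sid, mat))
    return ROITimeSeriesSet(subjects, labels)


# ---------------------------------------------------------------------------
# Streamline data
# ---------------------------------------------------------------------------

STREAMLINE_COLUMNS = ["seed_label", "hemisphere", "n_seed_voxels",
                      "samples_per_voxel", "target_label", "streamline_count",
                      "mean_path_length_mm"]


def write_streamlines_tsv(streamlines: dict, path) -> None:
    """``streamlines`` maps (label, hemisphere) -> StreamlineData (one subject)."""
    rows = []
    for (label, hemi), data in sorted(streamlines.items()):
        for target in sorted(data.counts):
            rows.append((label, hemi, data.n_seed_voxels, data.samples_per_voxel,
                         target, data.counts[target],
                         data.mean_path_length.get(target, float("nan"))))
    write_tsv(pd.DataFrame(rows, columns=STREAMLINE_COLUMNS), path)


def read_streamlines_tsv(path, taxonomy: RegionTaxonomy) -> dict:
    df = read_tsv(path)
    missing = [c for c in STREAMLINE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}; "
                         f"found {list(df.columns)}")
    out: dict[tuple[str, str], StreamlineData] = {}
    for (label, hemi), sub in df.groupby(["seed_label", "hemisphere"], sort=True):
        counts = dict(zip(sub["target_label"], sub["streamline_count"].astype(int)))
        plens = {t: float(l) for t, l in zip(sub["target_label"],
                                             sub["mean_path_length_mm"])
                 if np.isfinite(l)}
        out[(label, hemi)] = StreamlineData(
            seed=taxonomy.get(label, hemi),
            n_seed_voxels=int(sub["n_seed_voxels"].iloc[0]),
            counts=counts,
            mean_path_length=plens,
            samples_per_voxel=int(sub["samples_per_voxel"].iloc[0]),
        )
    return out


def pathway_table_to_frame(measures: list[PathwayMeasure],
                           subject_id: str) -> pd.DataFrame:
    rows = [
        (subject_id, m.tract.hemisphere, m.tract.seed.label, m.tract.target.label,
         m.connection_strength, m.mean_fa if m.mean_fa is not None else float("nan"))
        for m in measures
    ]
    return pd.DataFrame(rows, columns=["subject_id", "hemisphere", "seed",
                                       "target", "connection_strength", "mean_fa"])


# ---------------------------------------------------------------------------
# Run metadata
# ---------------------------------------------------------------------------

def write_run_metadata(path, config: dict, seed: int | None = None,
                       warnings_seen: list[str] | None = None) -> None:
    import tastecircuit

    payload = {
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "tastecircuit": tastecircuit.__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "warnings": warnings_seen or [],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
        fh.write("\n")
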