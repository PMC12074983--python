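"""Readers and writers for the interchange formats, plus run configuration.

Conventions enforced here: positions in nm, genomic midpoints in bp,
TAD indices 1-based on disk and 0-based in memory. Writes are atomic
(temp file + rename) and every result directory gets a manifest with
file SHA-256 hashes and the provenance (config, seed, package version)
needed to reproduce deterministic stages byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .barcode import Codebook
from .traces import CompartmentProfile

logger = logging.getLogger("perturbtrace")


class SchemaError(ValueError):
    """A file violates its declared schema; the message names file/line/column."""


@dataclass
class RunConfig:
    """Thresholds and seeds echoed into every output's provenance record."""

    contact_threshold_nm: float = 500.0
    fdr_threshold: float = 0.1
    effect_floor: float = 0.05
    min_traces: int = 20
    min_cells: int = 10
    min_trace_observed_fraction: float = 0.6
    short_range_cutoff_bp: int = 3_000_000
    seed: int = 0
    control_selector: str = "NON_TARGETING"
    out_dir: str = "results"

    def to_json(self, path) -> None:
        atomic_write_text(path, json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def atomic_write_df(path, df: pd.DataFrame, **kwargs) -> None:
    kwargs.setdefault("sep", "\t")
    kwargs.setdefault("index", False)
    atomic_write_text(path, df.to_csv(**kwargs))


# ---------------------------------------------------------------------------
# Trace tables
# ---------------------------------------------------------------------------

TRACE_COLUMNS = ("cell_id", "trace_id", "tad_index", "x_nm", "y_nm", "z_nm")


def read_trace_table(path, n_tad: int | None = None) -> dict:
    """Read a long-format trace TSV into a dict trace_id -> (n_tad, 3)
    array (NaN = missing). Validates 1-based tad_index against ``n_tad``
    (inferred from the file when omitted)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        return {}
    idx = df["tad_index"]
    if (idx < 1).any():
        row = int(df.index[idx < 1][0]) + 2  # header + 1-based
        raise SchemaError(f"{path}: line {row}, column tad_index: must be >= 1")
    n_tad = n_tad or int(idx.max())
    if (idx > n_tad).any():
        row = int(df.index[idx > n_tad][0]) + 2
        raise SchemaError(f"{path}: line {row}, column tad_index: exceeds n_tad={n_tad}")
    out = {}
    for trace_id, grp in df.groupby("trace_id", sort=True):
        arr = np.full((n_tad, 3), np.nan)
        arr[grp["tad_index"].to_numpy() - 1] = grp[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
        out[trace_id] = arr
    return out


def write_trace_table(path, traces: dict) -> None:
    rows = []
    for trace_id in sorted(traces):
        arr = np.asarray(traces[trace_id], float)
        for k in range(arr.shape[0]):
            x, y, z = arr[k]
            rows.append((str(trace_id), str(trace_id), k + 1, x, y, z))
    df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    atomic_write_df(path, df)


# ---------------------------------------------------------------------------
# Compartment profiles
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ("tad_index", "chrom", "midpoint_bp", "label", "score")


def read_profile(path) -> CompartmentProfile:
    df = pd.read_csv(path, sep="\t")
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values("tad_index")
    expect = np.arange(1, len(df) + 1)
    if not (df["tad_index"].to_numpy() == expect).all():
        raise SchemaError(f"{path}: tad_index must be exactly 1..{len(df)}")
    bad = ~df["label"].isin(["A", "B"])
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise SchemaError(f"{path}: line {row}, column label: must be 'A' or 'B'")
    return CompartmentProfile(
        labels=tuple(df["label"]),
        scores=df["score"].to_numpy(float),
        midpoints_bp=df["midpoint_bp"].to_numpy(np.int64),
    )


def write_profile(path, profile: CompartmentProfile, chrom: str = "chr22") -> None:
    df = pd.DataFrame({
        "tad_index": np.arange(1, profile.n_tad + 1),
        "chrom": chrom,
        "midpoint_bp": profile.midpoints_bp,
        "label": list(profile.labels),
        "score": profile.scores,
    })
    atomic_write_df(path, df)


# ---------------------------------------------------------------------------
# Codebooks and readouts
# ---------------------------------------------------------------------------

def read_codebook(path) -> Codebook:
    return Codebook.from_json(path)


def write_codebook(path, codebook: Codebook) -> None:
    payload = {"good": dict(sorted(codebook.good.items())), "bad": sorted(codebook.bad)}
    atomic_write_text(path, json.dumps(payload, indent=1))


READOUT_COLUMNS = ("cell_id", "round", "channel_value", "intensity")


def read_readout_table(path, n_rounds: int = 10, n_values: int = 3) -> dict:
    """cell_id -> (rounds x channels) intensity matrix."""
    df = pd.read_csv(path)
    missing = set(READOUT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if ((df["round"] < 1) | (df["round"] > n_rounds)).any():
        raise SchemaError(f"{path}: round must lie in 1..{n_rounds}")
    if ((df["channel_value"] < 0) | (df["channel_value"] >= n_values)).any():
        raise SchemaError(f"{path}: channel_value must lie in 0..{n_values - 1}")
    if (df["intensity"] < 0).any():
        raise SchemaError(f"{path}: intensities must be non-negative")
    out = {}
    for cell_id, grp in df.groupby("cell_id", sort=True):
        m = np.zeros((n_rounds, n_values))
        m[grp["round"].to_numpy() - 1, grp["channel_value"].to_numpy()] = grp["intensity"].to_numpy(float)
        out[cell_id] = m
    return out


def write_readout_table(path, readouts: dict) -> None:
    rows = []
    for cell_id in sorted(readouts):
        m = np.asarray(readouts[cell_id], float)
        for r in range(m.shape[0]):
            for v in range(m.shape[1]):
                rows.append((str(cell_id), r + 1, v, m[r, v]))
    atomic_write_text(path, pd.DataFrame(rows, columns=READOUT_COLUMNS).to_csv(index=False))


# ---------------------------------------------------------------------------
# Nuclei (per-nucleus TIFF pairs)
# ---------------------------------------------------------------------------

def write_nucleus_tiffs(directory, name: str, nucleus) -> tuple:
    """Write (intensity, mask) TIFF stacks with voxel size metadata."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"voxel_size_nm_zyx": list(nucleus.voxel_size_nm)}
    ipath = directory / f"{name}_intensity.tiff"
    mpath = directory / f"{name}_mask.tiff"
    tifffile.imwrite(ipath, nucleus.intensity.astype(np.float32), metadata=meta)
    tifffile.imwrite(mpath, nucleus.mask.astype(np.uint8), metadata=meta)
    return ipath, mpath


def read_nucleus_tiffs(intensity_path, mask_path):
    import tifffile

    from .nucleus import NucleusImage

    with tifffile.TiffFile(intensity_path) as tf:
        intensity = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    mask = tifffile.imread(mask_path).astype(bool)
    voxel = tuple(meta.get("voxel_size_nm_zyx", (1.0, 1.0, 1.0)))
    return NucleusImage(intensity=intensity, mask=mask, voxel_size_nm=voxel)


# ---------------------------------------------------------------------------
# Conformations (XYZ) and result manifests
# ---------------------------------------------------------------------------

def write_xyz(path, positions: np.ndarray, comment: str = "") -> None:
    pos = np.asarray(positions, float)
    lines = [str(len(pos)), comment]
    lines += [f"C {x:.6f} {y:.6f} {z:.6f}" for x, y, z in pos]
    atomic_write_text(path, "\n".join(lines) + "\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(out_dir, tables: dict, config: RunConfig | None = None) -> Path:
    """Write a dict of name -> DataFrame (TSV) / dict (JSON) / str (as-is)
    into ``out_dir`` and a manifest.json listing hashes and provenance."""
    from importlib.metadata import version

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in sorted(tables.items()):
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{name}.tsv"
            atomic_write_df(path, obj)
        elif isinstance(obj, (dict, list)):
            path = out_dir / f"{name}.json"
            atomic_write_text(path, json.dumps(obj, indent=1, default=_jsonify))
        else:
            path = out_dir / name
            atomic_write_text(path, str(obj))
        written.append(path)
        logger.info("wrote %s", path)
    try:
        pkg_version = version("perturbtrace")
    except Exception:
        pkg_version = "unknown"
    manifest = {
        "package": "perturbtrace",
        "version": pkg_version,
        "config": dataclasses.asdict(config) if config else None,
        "files": {p.name: sha256_of(p) for p in written},
    }
    mpath = out_dir / "manifest.json"
    atomic_write_text(mpath, json.dumps(manifest, indent=1))
    return mpath


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
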