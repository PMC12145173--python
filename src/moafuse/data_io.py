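"""Reading and writing compound tables, fingerprint tables and image stacks,
and the compound-to-image matching that assembles training samples.

On-disk conventions
-------------------
* Compound table: delimited text (comma or tab, sniffed) with a header row;
  columns ``compound_id``, ``smiles`` (may be empty) and a label column
  (default ``moa``). Class names are mapped to contiguous indices in sorted
  order so the mapping is reproducible across runs.
* Images: either one multi-page TIFF per sample (pages = channels, in channel
  order) or a directory of single-page TIFFs named ``<stem>_<channel>.tif``.
* Fingerprint tables: CSV with ``compound_id`` plus either one hex-string
  column per fingerprint type (compact dialect) or one column per bit
  (``rdk_0`` ... ``maccs_166``; explicit dialect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datamodel import (
    DEFAULT_FP_LENGTHS,
    FINGERPRINT_TYPES,
    CellImage,
    CompoundRecord,
    ConfigurationError,
    Dataset,
    FingerprintSet,
    FormatError,
    Sample,
    ValidationError,
)

__all__ = [
    "load_compound_table",
    "load_image_stack",
    "save_image_stack",
    "read_fingerprint_table",
    "write_fingerprint_table",
    "match_samples",
    "MatchReport",
]


def load_compound_table(path, label_column: str = "moa"):
    """Read a compound table; returns (records, class_names).

    Labels are mapped to indices by lexicographic class-name order;
    ``class_names[i]`` is the name of class index ``i``.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except pd.errors.EmptyDataError:
        return [], []
    except Exception:
        # delimiter sniffing fails on degenerate files; retry as plain CSV
        try:
            df = pd.read_csv(path, dtype=str)
        except pd.errors.EmptyDataError:
            return [], []
    if df.empty and len(df.columns) == 0:
        return [], []
    for col in ("compound_id", label_column):
        if col not in df.columns:
            raise ConfigurationError(f"compound table missing column {col!r}")
    dup = df["compound_id"][df["compound_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate compound_id(s): {sorted(set(dup))}")
    class_names = sorted(df[label_column].dropna().unique())
    index = {name: i for i, name in enumerate(class_names)}
    smiles = df["smiles"] if "smiles" in df.columns else pd.Series("", index=df.index)
    records = [
        CompoundRecord(
            compound_id=row["compound_id"],
            smiles="" if pd.isna(sm) else str(sm),
            moa_label=index[row[label_column]],
        )
        for (_, row), sm in zip(df.iterrows(), smiles)
    ]
    return records, class_names


def load_image_stack(path, channel_names, compound_id: str = "") -> CellImage:
    """Load one multi-channel image (multi-page TIFF file, or a directory of
    per-channel TIFFs suffixed with the channel name)."""
    path = Path(path)
    if path.is_dir():
        planes = []
        for ch in channel_names:
            matches = sorted(path.glob(f"*_{ch}.tif*"))
            if len(matches) != 1:
                raise FormatError(
                    f"{path}: expected exactly one '*_{ch}.tif' file, found {len(matches)}"
                )
            planes.append(np.asarray(tifffile.imread(matches[0])))
        shapes = {p.shape for p in planes}
        if len(shapes) != 1:
            raise FormatError(f"{path}: channel planes differ in shape: {shapes}")
        pixels = np.stack(planes)
    else:
        arr = np.asarray(tifffile.imread(path))
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise FormatError(f"{path}: expected a C x H x W stack, got shape {arr.shape}")
        if arr.shape[0] != len(channel_names):
            raise FormatError(
                f"{path}: {arr.shape[0]} planes but {len(channel_names)} channel names"
            )
        pixels = arr
    return CellImage(pixels.astype(np.float32), tuple(channel_names), compound_id)


def save_image_stack(image: CellImage, path, dtype=None) -> None:
    """Write a CellImage as a multi-page TIFF (one page per channel)."""
    data = image.pixels if dtype is None else image.pixels.astype(dtype)
    tifffile.imwrite(path, data)


# -- fingerprint tables --------------------------------------------------------


def _bits_to_hex(bits: np.ndarray) -> str:
    return np.packbits(bits.astype(np.uint8)).tobytes().hex()


def _hex_to_bits(s: str, length: int) -> np.ndarray:
    raw = np.frombuffer(bytes.fromhex(s), dtype=np.uint8)
    bits = np.unpackbits(raw)
    if len(bits) < length:
        raise FormatError(f"hex fingerprint too short for declared length {length}")
    return bits[:length]


def write_fingerprint_table(fingerprints: dict, path, dialect: str = "hex") -> None:
    """Write a compound_id -> FingerprintSet map as CSV ('hex' or 'bits')."""
    rows = []
    for cid, fps in fingerprints.items():
        if dialect == "hex":
            row = {"compound_id": cid}
            for name, vec in zip(FINGERPRINT_TYPES, fps.as_tuple()):
                row[name] = _bits_to_hex(vec)
        elif dialect == "bits":
            row = {"compound_id": cid}
            for name, vec in zip(FINGERPRINT_TYPES, fps.as_tuple()):
                row.update({f"{name}_{i}": int(b) for i, b in enumerate(vec)})
        else:
            raise ConfigurationError(f"unknown fingerprint-table dialect {dialect!r}")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fingerprint_table(path, lengths: dict | None = None) -> dict:
    """Read a fingerprint CSV in either dialect; returns compound_id -> FingerprintSet."""
    lengths = dict(DEFAULT_FP_LENGTHS, **(lengths or {}))
    df = pd.read_csv(path, dtype={"compound_id": str})
    if "compound_id" not in df.columns:
        raise ConfigurationError("fingerprint table missing column 'compound_id'")
    out = {}
    if all(t in df.columns for t in FINGERPRINT_TYPES):  # hex dialect
        for _, row in df.iterrows():
            vecs = {t: _hex_to_bits(str(row[t]), lengths[t]) for t in FINGERPRINT_TYPES}
            out[row["compound_id"]] = FingerprintSet(**vecs)
    elif "rdk_0" in df.columns:  # per-bit dialect
        cols = {
            t: [f"{t}_{i}" for i in range(lengths[t])] for t in FINGERPRINT_TYPES
        }
        for t, names in cols.items():
            missing = [c for c in names if c not in df.columns]
            if missing:
                raise FormatError(f"fingerprint table missing bit columns for {t}")
        for _, row in df.iterrows():
            vecs = {
                t: row[names].to_numpy(dtype=np.uint8) for t, names in cols.items()
            }
            out[row["compound_id"]] = FingerprintSet(**vecs)
    else:
        raise FormatError(
            "fingerprint table matches neither the hex dialect (columns "
            f"{FINGERPRINT_TYPES}) nor the per-bit dialect (rdk_0, ...)"
        )
    return out


# -- sample assembly -----------------------------------------------------------


@dataclass
class MatchReport:
    """What happened during compound-image matching."""

    n_samples: int = 0
    images_per_compound: dict = field(default_factory=dict)
    compounds_without_images: list = field(default_factory=list)


def match_samples(compounds, images, fingerprints, class_names=None):
    """Pair every image with its compound's single FingerprintSet.

    Returns ``(dataset, report)``; compounds with zero images contribute no
    samples and are listed in the report.
    """
    by_id = {c.compound_id: c for c in compounds}
    samples = []
    counts = {c.compound_id: 0 for c in compounds}
    for img in images:
        cid = img.compound_id
        if cid not in by_id:
            raise ValidationError(f"image references unknown compound {cid!r}")
        if cid not in fingerprints:
            raise ValidationError(f"compound {cid!r} has no fingerprints")
        rec = by_id[cid]
        samples.append(
            Sample(
                compound_id=cid,
                image=img,
                fingerprints=fingerprints[cid],
                moa_label=rec.moa_label,
            )
        )
        counts[cid] += 1
    missing_fp = [c.compound_id for c in compounds if c.compound_id not in fingerprints]
    if missing_fp:
        raise ValidationError(f"compounds missing fingerprints: {missing_fp}")
    n_classes = 1 + max((c.moa_label for c in compounds), default=-1)
    if class_names is None:
        class_names = [str(i) for i in range(n_classes)]
    report = MatchReport(
        n_samples=len(samples),
        images_per_compound=counts,
        compounds_without_images=[cid for cid, n in counts.items() if n == 0],
    )
    return Dataset(samples, n_classes=len(class_names) or n_classes, class_names=list(class_names)), report
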