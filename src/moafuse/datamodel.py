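"""Shared data model for compound mechanism-of-action (MoA) classification.

A dataset couples each compound (one SMILES string, one MoA class label, one
set of four molecular fingerprints) with many five-channel cell-morphology
images; the compound is the unit of cross-validation splitting and of
test-time voting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_CHANNELS = ("DNA", "Mito", "AGP", "RNA", "ER")

FINGERPRINT_TYPES = ("rdk", "ecfp", "pubchem", "maccs")

DEFAULT_FP_LENGTHS = {"rdk": 2048, "ecfp": 2048, "pubchem": 881, "maccs": 167}


class MoafuseError(Exception):
    """Base class for package errors."""


class ValidationError(MoafuseError):
    """Input data violates a dataset invariant."""


class ConfigurationError(MoafuseError):
    """Invalid configuration (missing column, bad hyperparameter, ...)."""


class FormatError(MoafuseError):
    """On-disk container does not match the declared layout."""


class FeaturizationError(MoafuseError):
    """A SMILES string could not be converted to fingerprints."""


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: identifier, structure, and MoA class index."""

    compound_id: str
    smiles: str
    moa_label: int


@dataclass(frozen=True)
class FingerprintSet:
    """Four binary fingerprint vectors for one compound.

    Types, in the fixed slot order used throughout the package:
    RDK (path-based), ECFP (circular, radius 2), PubChem (881 substructure
    keys), MACCS (167 structural keys).
    """

    rdk: np.ndarray
    ecfp: np.ndarray
    pubchem: np.ndarray
    maccs: np.ndarray

    def __post_init__(self):
        for name in FINGERPRINT_TYPES:
            vec = np.asarray(getattr(self, name), dtype=np.uint8)
            if vec.ndim != 1 or not np.isin(vec, (0, 1)).all():
                raise ValidationError(f"{name} fingerprint must be a 1-D binary vector")
            object.__setattr__(self, name, vec)

    def as_tuple(self):
        return (self.rdk, self.ecfp, self.pubchem, self.maccs)

    def lengths(self):
        return tuple(len(v) for v in self.as_tuple())

    def __eq__(self, other):
        if not isinstance(other, FingerprintSet):
            return NotImplemented
        return all(
            np.array_equal(a, b) for a, b in zip(self.as_tuple(), other.as_tuple())
        )


@dataclass
class CellImage:
    """A C x H x W intensity stack with named channels."""

    pixels: np.ndarray
    channel_names: tuple = DEFAULT_CHANNELS
    compound_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        self.channel_names = tuple(self.channel_names)
        if self.pixels.ndim != 3:
            raise ValidationError("pixels must be a C x H x W array")
        if self.pixels.shape[0] != len(self.channel_names):
            raise ValidationError(
                f"{self.pixels.shape[0]} planes but {len(self.channel_names)} channel names"
            )
        if (self.pixels < 0).any():
            raise ValidationError("intensities must be non-negative")

    def select_channels(self, wanted) -> "CellImage":
        """Restrict to `wanted` channels, in the requested order."""
        unknown = [w for w in wanted if w not in self.channel_names]
        if unknown:
            raise ValidationError(f"unknown channel name(s): {unknown}")
        idx = [self.channel_names.index(w) for w in wanted]
        return CellImage(self.pixels[idx], tuple(wanted), self.compound_id)


@dataclass(frozen=True)
class Sample:
    """One training sample: a single image plus its compound's fingerprints."""

    compound_id: str
    image: CellImage
    fingerprints: FingerprintSet
    moa_label: int

    def __post_init__(self):
        if self.image.compound_id != self.compound_id:
            raise ValidationError(
                f"image compound_id {self.image.compound_id!r} != {self.compound_id!r}"
            )


@dataclass
class Dataset:
    samples: list = field(default_factory=list)
    n_classes: int = 0
    class_names: list = field(default_factory=list)

    def __post_init__(self):
        for s in self.samples:
            if s.moa_label >= self.n_classes:
                raise ValidationError(
                    f"label {s.moa_label} out of range for {self.n_classes} classes"
                )

    def __len__(self):
        return len(self.samples)

    def compound_ids(self):
        seen = dict.fromkeys(s.compound_id for s in self.samples)
        return list(seen)

    def labels_by_compound(self):
        out = {}
        for s in self.samples:
            out[s.compound_id] = s.moa_label
        return out

    def subset(self, compound_ids) -> "Dataset":
        wanted = set(compound_ids)
        return Dataset(
            [s for s in self.samples if s.compound_id in wanted],
            self.n_classes,
            list(self.class_names),
        )
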