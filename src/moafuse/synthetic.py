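"""Seeded synthetic datasets: class-conditioned five-channel cell images and
four coupled fingerprint types with compound-level shared structure.

The generator emulates the statistical structure the classifier exploits,
not microscopy realism:

* Each compound has a latent vector ``z`` = class centroid + compound-level
  perturbation. The four fingerprint types threshold four *different* fixed
  random projections of the *same* ``z`` — a shared compound-level signal
  (commonality across types) expressed through type-specific axes
  (specificity) — then suffer independent bit flips with probability
  ``p_flip``.
* Each image draws per-class morphology per channel: DNA carries nuclei
  (disks) whose radius grows with the class index; Mito carries an oriented
  band-pass texture whose spatial frequency and amplitude are
  class-conditioned (the largest effect, by design); AGP (rings) and RNA
  (speckles) carry class-conditioned intensity scales under distinct class
  orderings; ER (smooth gradient) carries an almost class-independent scale
  and is deliberately the weakest channel, giving the single-channel
  ablation non-trivial structure. Position / count / intensity jitter is
  seeded per image.

Pixel intensities are quantized to integers (stored as float32) so a write
to uint16 TIFF and re-read reproduces them exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data_io import (
    load_compound_table,
    load_image_stack,
    match_samples,
    read_fingerprint_table,
    save_image_stack,
    write_fingerprint_table,
)
from .datamodel import (
    DEFAULT_CHANNELS,
    CellImage,
    CompoundRecord,
    Dataset,
    FingerprintSet,
)

__all__ = ["SynthConfig", "SynthCompound", "generate_fingerprints", "generate_images", "generate_dataset", "PRESETS"]


@dataclass
class SynthConfig:
    n_classes: int = 10
    compounds_per_class: int = 20
    images_per_compound: int = 4
    image_size: int = 64
    p_flip: float = 0.05  # independent fingerprint bit-flip probability
    latent_dim: int = 32
    compound_spread: float = 0.35  # sd of the compound-level latent perturbation
    fp_lengths: dict = field(
        default_factory=lambda: {"rdk": 2048, "ecfp": 2048, "pubchem": 881, "maccs": 167}
    )
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_flip < 0.5):
            raise ValueError("p_flip must lie in [0, 0.5)")
        for name in ("n_classes", "compounds_per_class", "images_per_compound", "image_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _coprime_perm(n: int, k: int) -> np.ndarray:
    """Deterministic permutation of range(n): multiply by the k-th unit coprime."""
    cands = [m for m in range(2, n + 2) if math.gcd(m, n) == 1]
    mult = cands[k % len(cands)]
    return np.array([(c * mult) % n for c in range(n)])


def class_morphology(config: SynthConfig) -> dict:
    """Per-class channel parameters (deterministic functions of n_classes)."""
    n = config.n_classes
    lin = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    return {
        "nucleus_radius": 3.0 + 6.0 * lin,  # px
        "mito_freq": 0.12 + 0.33 * lin,  # cycles / px
        "mito_amp": 0.5 + 2.5 * lin[_coprime_perm(n, 0)],
        "agp_amp": 0.3 + 1.7 * lin[_coprime_perm(n, 1)],
        "rna_amp": 0.3 + 1.7 * lin[_coprime_perm(n, 2)],
        "er_amp": 0.95 + 0.1 * lin[_coprime_perm(n, 3)],  # weakest effect
    }


@dataclass
class SynthCompound:
    compound_id: str
    class_index: int
    z: np.ndarray
    fingerprints: FingerprintSet | None = None
    images: list = field(default_factory=list)


def _fingerprint_projections(config: SynthConfig, rng: np.random.Generator) -> dict:
    return {
        t: rng.normal(size=(length, config.latent_dim))
        for t, length in config.fp_lengths.items()
    }


def generate_fingerprints(z, config: SynthConfig, projections: dict, rng) -> FingerprintSet:
    """Threshold type-specific projections of the shared latent, then flip bits."""
    vecs = {}
    for t, proj in projections.items():
        bits = (proj @ np.asarray(z) > 0).astype(np.uint8)
        if config.p_flip > 0:
            flips = rng.random(len(bits)) < config.p_flip
            bits = bits ^ flips.astype(np.uint8)
        vecs[t] = bits
    return FingerprintSet(**vecs)


# -- image rendering -----------------------------------------------------------


def _render_channel(ch: str, cls: int, morph: dict, size: int, rng) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    img = np.clip(rng.normal(0.08, 0.04, size=(size, size)), 0.0, None)
    if ch == "DNA":
        radius = morph["nucleus_radius"][cls]
        for _ in range(int(rng.integers(4, 8))):
            cy, cx = rng.uniform(0, size, size=2)
            r = radius * rng.uniform(0.9, 1.1)
            img += 1.0 * ((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r)
    elif ch == "Mito":
        freq, amp = morph["mito_freq"][cls], morph["mito_amp"][cls]
        for _ in range(2):
            theta = rng.uniform(0, np.pi)
            phase = rng.uniform(0, 2 * np.pi)
            wave = np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) + phase)
            img += 0.5 * amp * (0.5 + 0.5 * wave)
    elif ch == "AGP":
        amp = morph["agp_amp"][cls]
        for _ in range(3):
            cy, cx = rng.uniform(0, size, size=2)
            r0 = rng.uniform(5, 11)
            d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
            img += amp * (np.abs(d - r0) <= 1.5)
    elif ch == "RNA":
        amp = morph["rna_amp"][cls]
        speck = np.zeros((size, size))
        k = int(rng.integers(25, 45))
        ys, xs = rng.integers(0, size, k), rng.integers(0, size, k)
        speck[ys, xs] = amp * 4.0
        img += ndimage.gaussian_filter(speck, sigma=1.0)
    elif ch == "ER":
        amp = morph["er_amp"][cls]
        theta = rng.uniform(0, 2 * np.pi)
        grad = (xx * np.cos(theta) + yy * np.sin(theta)) / size
        img += amp * (0.4 + 0.6 * (grad - grad.min()) / (np.ptp(grad) + 1e-9))
    # quantize so uint16 round-trips exactly
    return np.round(np.clip(img, 0.0, 60.0) * 1000.0).astype(np.float32)


def generate_images(compound: SynthCompound, config: SynthConfig, morph=None) -> list:
    """Render the compound's images; deterministic in (compound, config, seed)."""
    morph = morph or class_morphology(config)
    out = []
    for k in range(config.images_per_compound):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7, _stable_id(compound.compound_id), k])
        )
        planes = [
            _render_channel(ch, compound.class_index, morph, config.image_size, rng)
            for ch in DEFAULT_CHANNELS
        ]
        out.append(CellImage(np.stack(planes), DEFAULT_CHANNELS, compound.compound_id))
    return out


def _stable_id(compound_id: str) -> int:
    return int(compound_id.rsplit("-", 1)[-1])


def _build_compounds(config: SynthConfig):
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    centroids = rng.normal(size=(config.n_classes, config.latent_dim))
    compounds = []
    idx = 0
    for cls in range(config.n_classes):
        for _ in range(config.compounds_per_class):
            z = centroids[cls] + config.compound_spread * rng.normal(size=config.latent_dim)
            compounds.append(SynthCompound(f"SYN-{idx:04d}", cls, z))
            idx += 1
    return compounds


def generate_dataset(config: SynthConfig | None = None, out_dir=None):
    """Build the full synthetic dataset.

    In-memory when ``out_dir`` is None; otherwise the compound CSV (blank
    SMILES), hex fingerprint CSV, per-sample multi-page TIFFs and a manifest
    JSON are written, then read back through the regular data_io path, so the
    on-disk formats are exercised end to end. Returns ``(dataset, report)``.
    """
    config = config or SynthConfig()
    morph = class_morphology(config)
    compounds = _build_compounds(config)
    proj = _fingerprint_projections(
        config, np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    )
    fingerprints = {}
    for comp in compounds:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 3, _stable_id(comp.compound_id)])
        )
        comp.fingerprints = generate_fingerprints(comp.z, config, proj, rng)
        fingerprints[comp.compound_id] = comp.fingerprints
        comp.images = generate_images(comp, config, morph)

    class_names = [f"MoA_{c:02d}" for c in range(config.n_classes)]
    records = [
        CompoundRecord(c.compound_id, "", c.class_index) for c in compounds
    ]
    images = [img for c in compounds for img in c.images]

    if out_dir is None:
        return match_samples(records, images, fingerprints, class_names)

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    import pandas as pd

    pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in compounds],
            "smiles": ["" for _ in compounds],
            "moa": [class_names[c.class_index] for c in compounds],
        }
    ).to_csv(out_dir / "compounds.csv", index=False)
    write_fingerprint_table(fingerprints, out_dir / "fingerprints.csv", dialect="hex")
    image_index = []
    for comp in compounds:
        for k, img in enumerate(comp.images):
            rel = f"images/{comp.compound_id}_{k}.tif"
            save_image_stack(img, out_dir / rel, dtype=np.uint16)
            image_index.append({"compound_id": comp.compound_id, "path": rel})
    (out_dir / "manifest.json").write_text(
        json.dumps(
            {
                "config": {
                    k: (v if not isinstance(v, dict) else dict(v))
                    for k, v in vars(config).items()
                },
                "class_names": class_names,
                "images": image_index,
            },
            indent=2,
        )
    )
    # reload through the regular I/O path
    recs, names = load_compound_table(out_dir / "compounds.csv")
    fps = read_fingerprint_table(out_dir / "fingerprints.csv", config.fp_lengths)
    imgs = [
        load_image_stack(out_dir / entry["path"], DEFAULT_CHANNELS, entry["compound_id"])
        for entry in image_index
    ]
    return match_samples(recs, imgs, fps, names)


PRESETS = {
    "smoke": dict(n_classes=3, compounds_per_class=10, images_per_compound=2, image_size=32),
    "default": {},
    "hard": dict(p_flip=0.25, compound_spread=0.6),
}
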