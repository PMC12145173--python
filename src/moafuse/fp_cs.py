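"""Fingerprint branch: common/specific representation learning over four
fingerprint views of one compound.

Pipeline (slot order fixed throughout: RDK=0, ECFP=1, PubChem=2, MACCS=3):

1. per-type affine embedders map each fingerprint to a shared width ``d``;
2. each embedding is zero-padded into its block of a ``4 d`` vector so the
   four padded vectors live in one dimension-aligned space;
3. a single shared two-layer encoder (FPC) maps the padded vectors to the
   common space; the alignment loss ``Lc`` pulls the four common encodings
   toward their mean (their per-sample centroid);
4. four independent two-layer ReLU encoders (FPS) map the *un-padded*
   embeddings to the specific space; the decorrelation loss ``Ls`` pushes the
   4 x 4 Gram matrix of the stacked specific encodings toward the identity;
5. common feature (sum of the four common encodings) and specific feature
   (concatenation of the four specific encodings) are fused by a two-layer
   network into a compact fingerprint feature, classified by a linear +
   softmax head.

``Lc`` and ``Ls`` are squared Euclidean / Frobenius norms, written per sample
and averaged over a batch. Rows of the stacked specific matrix are not
L2-normalized before the Gram product by default (so ``Ls`` also drives row
norms toward 1); ``normalize_rows=True`` enables the normalized variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .datamodel import DEFAULT_FP_LENGTHS, FINGERPRINT_TYPES
from .nn import Tensor, concat

__all__ = [
    "FPBranchConfig",
    "pad_quad",
    "common_target",
    "common_loss",
    "common_feature",
    "specific_loss",
    "specific_feature",
    "FingerprintEmbedder",
    "FingerprintBranch",
]

N_VIEWS = 4


@dataclass
class FPBranchConfig:
    d: int = 512  # per-type embedding width
    d_c: int = 512  # common-space width
    d_s: int = 512  # specific-space width
    d_f: int = 64  # fused fingerprint feature width
    fpc_hidden: int = 1024
    fps_hidden: int = 512
    fusion_hidden: int = 256
    lambda_c: float = 1.0
    lambda_s: float = 1.0
    normalize_rows: bool = False


def _as_batch(v) -> tuple[Tensor, bool]:
    t = Tensor.as_tensor(v)
    if t.ndim == 1:
        return t.reshape(1, -1), True
    return t, False


def pad_quad(quad):
    """Zero-pad each width-d embedding into its slot of a width-4d vector.

    Slot order R, E, P, M: the padded vector for view ``t`` has the embedding
    in block ``t`` and zeros elsewhere.
    """
    out = []
    for slot, v in enumerate(quad):
        t, single = _as_batch(v)
        n, d = t.shape
        blocks = []
        for k in range(N_VIEWS):
            if k == slot:
                blocks.append(t)
            else:
                blocks.append(Tensor(np.zeros((n, d), dtype=t.data.dtype)))
        padded = concat(blocks, axis=1)
        out.append(padded.reshape(-1) if single else padded)
    return tuple(out)


def common_target(cq) -> Tensor:
    """Per-sample centroid of the four common encodings."""
    total = Tensor.as_tensor(cq[0])
    for v in cq[1:]:
        total = total + Tensor.as_tensor(v)
    return total * 0.25


def common_loss(cq) -> Tensor:
    """Alignment loss: sum over views of squared distance to the centroid,
    averaged over the batch."""
    batched = [_as_batch(v)[0] for v in cq]
    target = common_target(batched)
    per_sample = None
    for v in batched:
        term = ((v - target) ** 2.0).sum(axis=1)
        per_sample = term if per_sample is None else per_sample + term
    return per_sample.mean()


def common_feature(cq) -> Tensor:
    """Common feature: the sum of the four common encodings (= 4 x centroid)."""
    total = Tensor.as_tensor(cq[0])
    for v in cq[1:]:
        total = total + Tensor.as_tensor(v)
    return total


def _stack_views(sq) -> Tensor:
    """Stack a quad of (N, d) tensors into (N, 4, d)."""
    batched = [_as_batch(v)[0] for v in sq]
    n, d = batched[0].shape
    return concat([v.reshape(n, 1, d) for v in batched], axis=1)


def gram_matrix(sq, normalize_rows: bool = False) -> Tensor:
    """Per-sample 4 x 4 Gram matrix of the stacked specific encodings."""
    h = _stack_views(sq)
    if normalize_rows:
        norms = ((h**2.0).sum(axis=2, keepdims=True) + 1e-12) ** 0.5
        h = h / norms
    return h @ h.transpose(0, 2, 1)


def specific_loss(sq, normalize_rows: bool = False) -> Tensor:
    """Decorrelation loss: squared Frobenius distance between the Gram matrix
    of the four specific encodings and the 4 x 4 identity, batch-averaged."""
    icm = gram_matrix(sq, normalize_rows=normalize_rows)
    eye = Tensor(np.eye(N_VIEWS, dtype=icm.data.dtype))
    return (((icm - eye) ** 2.0).sum(axis=(1, 2))).mean()


def specific_feature(sq) -> Tensor:
    """Specific feature: in-order concatenation of the four encodings."""
    batched_flags = [_as_batch(v) for v in sq]
    out = concat([t for t, _ in batched_flags], axis=1)
    if all(flag for _, flag in batched_flags):
        return out.reshape(-1)
    return out


class FingerprintEmbedder(nn.Module):
    """Four independent affine maps, one per fingerprint type, to width d."""

    def __init__(self, fp_lengths, d, rng, dtype=np.float32):
        super().__init__()
        self.linears = [
            nn.Linear(fp_lengths[t], d, rng, dtype=dtype) for t in FINGERPRINT_TYPES
        ]

    def forward(self, quad):
        return tuple(lin(Tensor.as_tensor(v)) for lin, v in zip(self.linears, quad))


def _two_layer(i, h, o, rng, dtype, final_relu):
    layers = [nn.Linear(i, h, rng, dtype=dtype), nn.ReLU(), nn.Linear(h, o, rng, dtype=dtype)]
    if final_relu:
        layers.append(nn.ReLU())
    return nn.Sequential(*layers)


class FingerprintBranch(nn.Module):
    """Full fingerprint branch: embed, pad, FPC/FPS encoders, fusion, classifier."""

    def __init__(
        self,
        n_classes: int,
        fp_lengths: dict | None = None,
        config: FPBranchConfig | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        self.config = cfg = config or FPBranchConfig()
        fp_lengths = dict(DEFAULT_FP_LENGTHS, **(fp_lengths or {}))
        rng = rng or np.random.default_rng(0)
        self.embedder = FingerprintEmbedder(fp_lengths, cfg.d, rng, dtype)
        self.fpc = _two_layer(N_VIEWS * cfg.d, cfg.fpc_hidden, cfg.d_c, rng, dtype, final_relu=False)
        self.fps = [
            _two_layer(cfg.d, cfg.fps_hidden, cfg.d_s, rng, dtype, final_relu=True)
            for _ in range(N_VIEWS)
        ]
        self.fusion = _two_layer(
            cfg.d_c + N_VIEWS * cfg.d_s, cfg.fusion_hidden, cfg.d_f, rng, dtype, final_relu=False
        )
        self.classifier = nn.Linear(cfg.d_f, n_classes, rng, dtype=dtype)

    def forward(self, quad):
        """quad: four (N, L_t) binary arrays in slot order; returns a dict of
        every intermediate the losses and the export hook need."""
        emb = self.embedder(quad)
        padded = pad_quad(emb)
        cq = tuple(self.fpc(p) for p in padded)
        sq = tuple(enc(e) for enc, e in zip(self.fps, emb))
        c_feat = common_feature(cq)
        s_feat = specific_feature(sq)
        fused = self.fusion(concat([c_feat, s_feat], axis=1))
        logits = self.classifier(fused)
        return {
            "embeddings": emb,
            "common": cq,
            "specific": sq,
            "common_feature": c_feat,
            "specific_feature": s_feat,
            "fused": fused,
            "logits": logits,
            "lc": common_loss(cq),
            "ls": specific_loss(sq, normalize_rows=self.config.normalize_rows),
        }

    def predict_scores(self, quad) -> np.ndarray:
        """Softmax class probabilities, (N, n_classes)."""
        out = self.forward(quad)
        return out["logits"].softmax(axis=1).data

    def representation_stats(self, quad) -> dict:
        """Diagnostics for the common/specific structure: mean pairwise cosine
        similarity among the four common encodings and mean |off-diagonal| of
        the specific Gram matrix (row-normalized for comparability)."""
        out = self.forward(quad)
        cs = [c.data for c in out["common"]]
        sims = []
        for j in range(N_VIEWS):
            for k in range(j + 1, N_VIEWS):
                num = (cs[j] * cs[k]).sum(axis=1)
                den = np.linalg.norm(cs[j], axis=1) * np.linalg.norm(cs[k], axis=1) + 1e-12
                sims.append(num / den)
        icm = gram_matrix(out["specific"], normalize_rows=True).data
        off = icm[:, ~np.eye(N_VIEWS, dtype=bool)]
        return {
            "mean_common_cosine": float(np.mean(sims)),
            "mean_abs_offdiag": float(np.mean(np.abs(off))),
        }


def export_embeddings(model: FingerprintBranch, quad, compound_ids, path) -> None:
    """Write per-sample common, specific and fused features to CSV."""
    import pandas as pd

    out = model.forward(quad)
    frames = {"compound_id": list(compound_ids)}
    for key, prefix in (("common_feature", "C"), ("specific_feature", "S"), ("fused", "F")):
        arr = out[key].data
        for i in range(arr.shape[1]):
            frames[f"{prefix}{i}"] = arr[:, i]
    pd.DataFrame(frames).to_csv(path, index=False)
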