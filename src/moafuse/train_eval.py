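"""Training, cross-validation protocol, score fusion and metrics.

The two branches are trained independently: the image branch minimizes the
classification cross-entropy; the fingerprint branch minimizes
cross-entropy + lambda_c * Lc + lambda_s * Ls. Both use an adaptive-moment
optimizer with plateau learning-rate reduction on the validation loss.

Protocol: compounds (never individual images) are dealt into 10 stratified
subsets; one subset is held out for final testing and the remaining nine
supply 5 cross-validation folds of 8 training + 1 validation subsets. The
fusion weight beta of ``score = beta * score_CI + (1 - beta) * score_FP`` is
chosen on the validation folds by a grid search over {0.0, 0.1, ..., 1.0}.
Test evaluation is reported at sample level and at compound level (majority
vote over a compound's samples).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, f1_score

from .datamodel import ConfigurationError, Dataset
from .fp_cs import FingerprintBranch, FPBranchConfig
from .mresnet import BackboneConfig, ImageBranch
from .nn import Adam, ReduceLROnPlateau, Tensor, gather_rows

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "Metrics",
    "stratified_split",
    "cross_entropy",
    "train_branch",
    "fuse_scores",
    "compound_vote",
    "compute_metrics",
    "run_protocol",
]


# -- splitting -----------------------------------------------------------------


@dataclass
class SplitPlan:
    """Compound-level subset assignment plus the CV fold layout."""

    assignment: dict  # compound_id -> subset index
    test_subset: int
    folds: list  # (train_subset_tuple, val_subset) pairs

    def ids_in(self, subsets) -> list:
        wanted = {subsets} if np.isscalar(subsets) else set(subsets)
        return [cid for cid, s in self.assignment.items() if s in wanted]


def stratified_split(compounds, k: int = 10, seed: int = 0, test_subset: int = 0,
                     n_folds: int = 5) -> SplitPlan:
    """Deal compounds round-robin into k subsets within each class.

    Per-class subset counts differ by at most one; all images of a compound
    follow it into its subset because splitting is by compound.
    """
    if k <= 1:
        raise ConfigurationError("k must be at least 2")
    rng = np.random.default_rng(seed)
    by_class = defaultdict(list)
    for rec in compounds:
        by_class[rec.moa_label].append(rec.compound_id)
    assignment = {}
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        rng.shuffle(ids)
        for i, cid in enumerate(ids):
            assignment[cid] = i % k
    cv_subsets = [s for s in range(k) if s != test_subset]
    folds = []
    for f in range(n_folds):
        val = cv_subsets[f % len(cv_subsets)]
        train = tuple(s for s in cv_subsets if s != val)
        folds.append((train, val))
    return SplitPlan(assignment=assignment, test_subset=test_subset, folds=folds)


# -- losses / metrics ----------------------------------------------------------


def cross_entropy(scores, true_label, eps: float = 1e-12) -> float:
    """-log p(true class) from a probability vector (or batch of them);
    batch value is the mean. Probabilities are clamped at ``eps``."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim == 1:
        scores, true_label = scores[None], np.asarray([true_label])
    p = scores[np.arange(len(scores)), np.asarray(true_label)]
    return float(-np.log(np.clip(p, eps, None)).mean())


def fuse_scores(score_ci, score_fp, beta: float):
    """Late fusion: beta * score_CI + (1 - beta) * score_FP."""
    if not (0.0 <= beta <= 1.0):
        raise ConfigurationError(f"beta must lie in [0, 1], got {beta}")
    score_ci, score_fp = np.asarray(score_ci), np.asarray(score_fp)
    if beta == 1.0:
        return score_ci.copy()
    if beta == 0.0:
        return score_fp.copy()
    return beta * score_ci + (1.0 - beta) * score_fp


def compound_vote(sample_predictions) -> dict:
    """Majority vote of per-sample argmax classes within each compound.

    Ties are broken by the highest mean score among the tied classes, then by
    the lowest class index.
    """
    scores_by_cid = defaultdict(list)
    for cid, scores in sample_predictions:
        scores_by_cid[cid].append(np.asarray(scores))
    out = {}
    for cid, score_list in scores_by_cid.items():
        votes = Counter(int(np.argmax(s)) for s in score_list)
        top = max(votes.values())
        tied = sorted(c for c, v in votes.items() if v == top)
        if len(tied) == 1:
            out[cid] = tied[0]
        else:
            means = np.mean(score_list, axis=0)
            best = max(tied, key=lambda c: (means[c], -c))
            out[cid] = best
    return out


@dataclass
class Metrics:
    accuracy: float
    macro_f1: float
    weighted_f1: float
    per_class_accuracy: list

    def as_dict(self):
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "per_class_accuracy": list(self.per_class_accuracy),
        }


def compute_metrics(y_true, y_pred, n_classes: int) -> Metrics:
    """Accuracy, macro-F1, weighted-F1 and per-class accuracy (recall).

    Classes absent from ``y_true`` contribute F1 = 0 to the macro average.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    labels = list(range(n_classes))
    per_class = []
    for c in labels:
        mask = y_true == c
        per_class.append(float((y_pred[mask] == c).mean()) if mask.any() else 0.0)
    return Metrics(
        accuracy=float(accuracy_score(y_true, y_pred)),
        macro_f1=float(f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)),
        weighted_f1=float(
            f1_score(y_true, y_pred, labels=labels, average="weighted", zero_division=0)
        ),
        per_class_accuracy=per_class,
    )


# -- training ------------------------------------------------------------------


@dataclass
class TrainConfig:
    epochs: int = 100
    lr_ci: float = 1e-3
    lr_fp: float = 1e-5
    batch_size: int = 32
    seed: int = 0
    plateau_patience: int = 10
    plateau_factor: float = 0.1
    min_lr: float = 1e-8
    beta: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.beta <= 1.0):
            raise ConfigurationError("beta must lie in [0, 1]")


@dataclass
class ChannelNormalizer:
    """Per-channel z-score statistics computed on the training images."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, images: np.ndarray) -> "ChannelNormalizer":
        mean = images.mean(axis=(0, 2, 3))
        std = images.std(axis=(0, 2, 3))
        return cls(mean=mean, std=np.where(std > 0, std, 1.0))

    def __call__(self, images: np.ndarray) -> np.ndarray:
        return (images - self.mean[None, :, None, None]) / self.std[None, :, None, None]


def _image_array(dataset: Dataset, channels=None) -> np.ndarray:
    imgs = []
    for s in dataset.samples:
        img = s.image if channels is None else s.image.select_channels(channels)
        imgs.append(img.pixels)
    return np.stack(imgs).astype(np.float32)


def _fp_quad(dataset: Dataset):
    return tuple(
        np.stack([s.fingerprints.as_tuple()[i] for s in dataset.samples]).astype(np.float32)
        for i in range(4)
    )


def _labels(dataset: Dataset) -> np.ndarray:
    return np.array([s.moa_label for s in dataset.samples], dtype=np.int64)


def _ce_from_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    return -gather_rows(logits.log_softmax(axis=1), y).mean()


@dataclass
class TrainResult:
    model: object
    history: list
    normalizer: ChannelNormalizer | None
    lr_drops: list
    branch: str
    # fingerprint branch only: common/specific representation diagnostics on
    # the validation set at initialization and after training
    repr_stats: dict = field(default_factory=dict)


def _batched_scores(predict, inputs, n, batch=64):
    chunks = []
    for lo in range(0, n, batch):
        sel = slice(lo, lo + batch)
        chunks.append(predict(_take(inputs, sel)))
    return np.concatenate(chunks)


def _take(inputs, sel):
    if isinstance(inputs, tuple):
        return tuple(a[sel] for a in inputs)
    return inputs[sel]


def train_branch(
    dataset: Dataset,
    branch: str,
    config: TrainConfig,
    train_ids=None,
    val_ids=None,
    backbone: BackboneConfig | None = None,
    fp_config: FPBranchConfig | None = None,
    channels=None,
) -> TrainResult:
    """Train one branch ('ci' or 'fp') on the compounds in ``train_ids``,
    validating on ``val_ids`` (defaults: an internal 9-to-1 compound split).

    Returns the trained model with its per-epoch history (train/val loss,
    validation accuracy, learning rate) and any plateau LR reductions.
    """
    if len(dataset) == 0:
        raise ConfigurationError("dataset is empty")
    if train_ids is None or val_ids is None:
        labels = dataset.labels_by_compound()
        recs = [type("R", (), {"compound_id": c, "moa_label": l})() for c, l in labels.items()]
        plan = stratified_split(recs, k=10, seed=config.seed, test_subset=0, n_folds=1)
        train_subs, val_sub = plan.folds[0]
        train_ids = plan.ids_in(train_subs)
        val_ids = plan.ids_in(val_sub)
    train_ds, val_ds = dataset.subset(train_ids), dataset.subset(val_ids)
    if len(train_ds) == 0:
        raise ConfigurationError("empty training fold")
    y_tr, y_va = _labels(train_ds), _labels(val_ds)
    seedseq = np.random.SeedSequence([config.seed, 0 if branch == "ci" else 1])
    init_rng, shuffle_rng = (np.random.default_rng(s) for s in seedseq.spawn(2))

    normalizer = None
    if branch == "ci":
        bcfg = backbone or BackboneConfig.tiny()
        if channels is not None:
            bcfg.in_channels = len(channels)
            bcfg.channel_names = tuple(channels)
        x_tr = _image_array(train_ds, channels)
        x_va = _image_array(val_ds, channels)
        normalizer = ChannelNormalizer.fit(x_tr)
        x_tr, x_va = normalizer(x_tr), normalizer(x_va)
        bcfg.n_classes = dataset.n_classes
        model = ImageBranch(bcfg, rng=init_rng)
        lr = config.lr_ci

        def batch_loss(sel):
            out = model(Tensor(x_tr[sel]))
            return _ce_from_logits(out["logits"], y_tr[sel])

        def eval_scores(inputs):
            return model.predict_scores(Tensor(inputs))

        tr_inputs, va_inputs = x_tr, x_va
    elif branch == "fp":
        lengths = dict(
            zip(("rdk", "ecfp", "pubchem", "maccs"), dataset.samples[0].fingerprints.lengths())
        )
        fcfg = fp_config or FPBranchConfig()
        model = FingerprintBranch(dataset.n_classes, lengths, fcfg, rng=init_rng)
        q_tr, q_va = _fp_quad(train_ds), _fp_quad(val_ds)
        lr = config.lr_fp

        def batch_loss(sel):
            out = model(tuple(a[sel] for a in q_tr))
            ce = _ce_from_logits(out["logits"], y_tr[sel])
            return ce + fcfg.lambda_c * out["lc"] + fcfg.lambda_s * out["ls"]

        def eval_scores(inputs):
            return model.predict_scores(inputs)

        tr_inputs, va_inputs = q_tr, q_va
    else:
        raise ConfigurationError(f"unknown branch {branch!r} (expected 'ci' or 'fp')")

    repr_stats = {}
    if branch == "fp" and len(y_va):
        model.eval()
        repr_stats["init"] = model.representation_stats(va_inputs)
    optimizer = Adam(model.parameters(), lr=lr)
    scheduler = ReduceLROnPlateau(
        optimizer,
        factor=config.plateau_factor,
        patience=config.plateau_patience,
        min_lr=config.min_lr,
    )
    n = len(y_tr)
    history = []
    for epoch in range(config.epochs):
        model.train()
        order = shuffle_rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            sel = order[lo : lo + config.batch_size]
            optimizer.zero_grad()
            loss = batch_loss(sel)
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        model.eval()
        va_scores = _batched_scores(eval_scores, va_inputs, len(y_va))
        val_loss = cross_entropy(va_scores, y_va) if len(y_va) else float("nan")
        val_acc = float((va_scores.argmax(axis=1) == y_va).mean()) if len(y_va) else float("nan")
        scheduler.step(val_loss, epoch=epoch)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "val_accuracy": val_acc,
                "lr": optimizer.lr,
            }
        )
    model.eval()
    if branch == "fp" and len(y_va):
        repr_stats["trained"] = model.representation_stats(va_inputs)
    return TrainResult(
        model=model,
        history=history,
        normalizer=normalizer,
        lr_drops=list(scheduler.events),
        branch=branch,
        repr_stats=repr_stats,
    )


def predict_branch(result: TrainResult, dataset: Dataset, channels=None) -> np.ndarray:
    """Sample-level softmax scores of a trained branch on a dataset."""
    if result.branch == "ci":
        x = _image_array(dataset, channels)
        x = result.normalizer(x)
        return _batched_scores(lambda a: result.model.predict_scores(Tensor(a)), x, len(x))
    quad = _fp_quad(dataset)
    return _batched_scores(result.model.predict_scores, quad, len(dataset))


# -- full protocol -------------------------------------------------------------


def run_protocol(
    dataset: Dataset,
    config: TrainConfig,
    backbone: BackboneConfig | None = None,
    fp_config: FPBranchConfig | None = None,
    n_folds: int | None = None,
    channels=None,
    beta_grid=None,
) -> dict:
    """The full split / train / fuse / evaluate pipeline; returns the report.

    Trains both branches on every fold, picks the fusion weight beta by grid
    search on mean validation accuracy, ensembles the fold models (mean score
    vector) on the held-out test subset and reports sample-level and
    compound-level (voting) metrics.
    """
    labels = dataset.labels_by_compound()
    recs = [type("R", (), {"compound_id": c, "moa_label": l})() for c, l in labels.items()]
    plan = stratified_split(recs, k=10, seed=config.seed)
    folds = plan.folds if n_folds is None else plan.folds[:n_folds]
    beta_grid = [round(b, 1) for b in np.arange(0.0, 1.01, 0.1)] if beta_grid is None else beta_grid

    test_ids = plan.ids_in(plan.test_subset)
    test_ds = dataset.subset(test_ids)
    y_test = _labels(test_ds)

    fold_records = []
    val_sets = []
    test_ci, test_fp = [], []
    for fold_idx, (train_subs, val_sub) in enumerate(folds):
        train_ids, val_ids = plan.ids_in(train_subs), plan.ids_in(val_sub)
        res_ci = train_branch(
            dataset, "ci", config, train_ids, val_ids, backbone=backbone, channels=channels
        )
        res_fp = train_branch(dataset, "fp", config, train_ids, val_ids, fp_config=fp_config)
        val_ds = dataset.subset(val_ids)
        val_sets.append(
            {
                "y": _labels(val_ds),
                "ci": predict_branch(res_ci, val_ds, channels),
                "fp": predict_branch(res_fp, val_ds),
            }
        )
        test_ci.append(predict_branch(res_ci, test_ds, channels))
        test_fp.append(predict_branch(res_fp, test_ds))
        fold_records.append(
            {
                "fold": fold_idx,
                "val_subset": val_sub,
                "history_ci": res_ci.history,
                "history_fp": res_fp.history,
            }
        )

    beta_scores = {}
    for beta in beta_grid:
        accs = [
            float(
                (fuse_scores(v["ci"], v["fp"], beta).argmax(axis=1) == v["y"]).mean()
            )
            for v in val_sets
        ]
        beta_scores[beta] = float(np.mean(accs))
    best_beta = max(beta_grid, key=lambda b: beta_scores[b])

    mean_ci = np.mean(test_ci, axis=0)
    mean_fp = np.mean(test_fp, axis=0)
    fused = fuse_scores(mean_ci, mean_fp, best_beta)
    sample_metrics = {
        "ci": compute_metrics(y_test, mean_ci.argmax(axis=1), dataset.n_classes).as_dict(),
        "fp": compute_metrics(y_test, mean_fp.argmax(axis=1), dataset.n_classes).as_dict(),
        "fused": compute_metrics(y_test, fused.argmax(axis=1), dataset.n_classes).as_dict(),
    }
    cids = [s.compound_id for s in test_ds.samples]
    votes = compound_vote(list(zip(cids, fused)))
    compound_labels = test_ds.labels_by_compound()
    vote_ids = sorted(votes)
    compound_metrics = compute_metrics(
        [compound_labels[c] for c in vote_ids],
        [votes[c] for c in vote_ids],
        dataset.n_classes,
    ).as_dict()

    per_fold_test = [
        {
            "fold": i,
            "fused": compute_metrics(
                y_test,
                fuse_scores(test_ci[i], test_fp[i], best_beta).argmax(axis=1),
                dataset.n_classes,
            ).as_dict(),
        }
        for i in range(len(folds))
    ]

    return {
        "seed": config.seed,
        "n_folds": len(folds),
        "test_subset": plan.test_subset,
        "assignment": plan.assignment,
        "folds": fold_records,
        "beta_grid": beta_scores,
        "beta": best_beta,
        "test_sample_metrics": sample_metrics,
        "test_compound_metrics": compound_metrics,
        "per_fold_test": per_fold_test,
    }
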