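"""Episodic training with the binary cross-entropy objective.

Every iteration samples a fresh C-way K-shot episode from the training
classes, runs the episode forward pass, and takes one Adam step on the
loss

    L = -(1 / (C*K)) * sum_j sum_k mean_pixels[ y log p + (1-y) log(1-p) ]

where the inner mean over pixels makes the loss patch-size invariant and
the printed 1/(C*K) outer normalization is kept exactly.  After each epoch
the model is scored on fixed validation episodes and the weights with the
best validation accuracy are retained.

Study-scale defaults follow the reference protocol (Adam, learning rate
1e-4, 30 epochs of 100 iterations); desk-scale runs shrink all of these.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from . import evaluation as ev
from . import nn
from . import preprocessing as pp
from .autograd import Tensor
from .episodes import ClassRecord, Episode, SplitSpec, sample_episode, test_support_provider
from .exceptions import ConfigurationError, ShapeError
from .model_core import FewShotSegmenter

__all__ = ["TrainConfig", "LossValue", "TrainResult", "sigmoid_map",
           "bce_loss", "train", "evaluate_split", "predict_with_support",
           "predict_image"]

EPS = 1e-7  # probability clamp before logs


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 30
    iterations_per_epoch: int = 100
    optimizer: str = "adam"
    C: int = 3
    K: int = 3
    seed: int = 0
    val_episodes: int = 2
    threshold: float = 0.5

    def __post_init__(self):
        if min(self.learning_rate, self.epochs, self.iterations_per_epoch,
               self.C, self.K) <= 0:
            raise ConfigurationError("all training settings must be positive")
        if self.optimizer.lower() != "adam":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class LossValue:
    value: float
    epoch: int
    iteration: int


def sigmoid_map(logits: np.ndarray) -> np.ndarray:
    """Element-wise logistic function, numerically stable for large |x|."""
    x = np.asarray(logits, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def bce_loss(prob_maps, truths, eps: float = EPS) -> float:
    """Binary cross-entropy over C*K probability maps.

    Probabilities are clamped to [eps, 1-eps]; each map contributes its
    pixel mean and the maps are averaged (the 1/(C*K) normalization).
    """
    probs = np.asarray(prob_maps, dtype=np.float64)
    ys = np.asarray(truths, dtype=np.float64)
    if probs.shape != ys.shape:
        raise ShapeError(f"probabilities {probs.shape} vs truths {ys.shape}")
    if probs.ndim < 2:
        raise ShapeError("expected a batch of 2-D maps")
    flat_p = probs.reshape(-1, probs.shape[-2] * probs.shape[-1])
    flat_y = ys.reshape(flat_p.shape)
    p = np.clip(flat_p, eps, 1.0 - eps)
    per_map = -(flat_y * np.log(p) + (1 - flat_y) * np.log(1 - p)).mean(axis=1)
    return float(per_map.mean())


def bce_loss_tensor(probs: Tensor, truths: np.ndarray, eps: float = EPS) -> Tensor:
    """Differentiable version of :func:`bce_loss` for (N,1,H,W) tensors."""
    y = np.asarray(truths, dtype=probs.dtype)
    if y.shape != probs.shape:
        raise ShapeError(f"probabilities {probs.shape} vs truths {y.shape}")
    p = ag.clip(probs, eps, 1.0 - eps)
    ll = ag.add(ag.mul(y, ag.log(p)),
                ag.mul(1.0 - y, ag.log(ag.sub(1.0, p))))
    return ag.neg(ag.tmean(ll))


def episode_arrays(episode: Episode):
    """Stack an episode into (C,K,t,t) support and (C,Q,t,t) query arrays."""
    cids = episode.class_ids
    sp = np.stack([[m.patch for m in episode.support[c]] for c in cids])
    sm = np.stack([[m.mask for m in episode.support[c]] for c in cids])
    qp = np.stack([[m.patch for m in episode.query[c]] for c in cids])
    qm = np.stack([[m.mask for m in episode.query[c]] for c in cids])
    qf = np.stack([[m.fov for m in episode.query[c]] for c in cids])
    return sp, sm, qp, qm, qf


@dataclass
class TrainResult:
    """Outcome of a training run: histories, best weights, diagnostics."""

    config: TrainConfig
    history: list = field(default_factory=list)       # LossValue rows
    val_history: list = field(default_factory=list)   # per-epoch dicts
    best_state: dict | None = None
    best_epoch: int = -1
    best_val_acc: float = float("-inf")
    wall_time_s: float = 0.0

    def restore_best(self, model: FewShotSegmenter) -> None:
        if self.best_state is not None:
            model.load_state_dict(self.best_state)

    def epoch_losses(self) -> list[float]:
        out: dict[int, list] = {}
        for row in self.history:
            out.setdefault(row.epoch, []).append(row.value)
        return [float(np.mean(out[e])) for e in sorted(out)]

    def save_history(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["kind", "epoch", "iteration", "loss",
                             "val_acc", "val_sen", "val_spe", "val_f1"])
            for row in self.history:
                writer.writerow(["loss", row.epoch, row.iteration,
                                 f"{row.value:.6f}", "", "", "", ""])
            for row in self.val_history:
                writer.writerow(["val", row["epoch"], "", "",
                                 f"{row['acc']:.6f}", f"{row['sen']:.6f}",
                                 f"{row['spe']:.6f}", f"{row['f1']:.6f}"])

    def summary(self) -> str:
        losses = self.epoch_losses()
        lines = [
            "Episodic training summary",
            "=" * 41,
            f"episodes per epoch : {self.config.iterations_per_epoch}",
            f"epochs             : {self.config.epochs}",
            f"task               : {self.config.C}-way {self.config.K}-shot",
            f"optimizer          : {self.config.optimizer} "
            f"(lr={self.config.learning_rate:g})",
            f"first-epoch loss   : {losses[0]:.4f}" if losses else "",
            f"last-epoch loss    : {losses[-1]:.4f}" if losses else "",
            f"best val accuracy  : {self.best_val_acc:.4f} "
            f"(epoch {self.best_epoch})",
            f"wall time          : {self.wall_time_s:.1f} s",
        ]
        return "\n".join(line for line in lines if line)


def train(model: FewShotSegmenter, library: list[ClassRecord],
          split: SplitSpec, config: TrainConfig,
          progress: bool = False) -> TrainResult:
    """Run episodic training; returns histories and the best-epoch weights.

    Raises ``RuntimeError`` with diagnostics if the loss turns NaN.
    """
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    result = TrainResult(config=config)
    t0 = time.perf_counter()
    for epoch in range(config.epochs):
        for it in range(config.iterations_per_epoch):
            episode = sample_episode(library, config.C, config.K, rng,
                                     class_ids=split.train_ids)
            sp, sm, qp, qm, _ = episode_arrays(episode)
            probs = model.episode_forward(sp, sm, qp)
            truths = qm.reshape(-1, 1, *qm.shape[-2:])
            loss = bce_loss_tensor(probs, truths)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"loss became non-finite at epoch {epoch} iteration {it} "
                    f"(lr={config.learning_rate}, classes={episode.class_ids})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            result.history.append(LossValue(value, epoch, it))
        val = evaluate_split(model, library, split, config.C, config.K,
                             n_episodes=config.val_episodes,
                             seed=config.seed + 7919, scope="valid",
                             threshold=config.threshold)
        row = {"epoch": epoch, **{k: val.as_dict()[k]
                                  for k in ("acc", "sen", "spe", "f1")}}
        result.val_history.append(row)
        if val.acc > result.best_val_acc:
            result.best_val_acc = val.acc
            result.best_epoch = epoch
            result.best_state = model.state_dict()
        if progress:  # pragma: no cover - logging only
            print(f"epoch {epoch:3d}  loss {value:.4f}  "
                  f"val acc {val.acc:.4f}")
    result.wall_time_s = time.perf_counter() - t0
    return result


def predict_with_support(model: FewShotSegmenter, support_members,
                         query_patches, chunk: int = 16) -> np.ndarray:
    """Segment query patches guided by a pooled (shared) support set.

    ``support_members`` is a flat list of PatchMember-like objects whose
    prototypes are averaged into one class (the shared-support inference
    used for test images).  Returns (N, t, t) probabilities.
    """
    sp = np.stack([np.asarray(m.patch) for m in support_members])[None]
    sm = np.stack([np.asarray(m.mask) for m in support_members])[None]
    queries = np.asarray(query_patches)
    if queries.ndim == 2:
        queries = queries[None]
    out = []
    for start in range(0, len(queries), chunk):
        batch = queries[start:start + chunk]
        probs = model.episode_forward(sp, sm, batch[None])
        out.append(probs.data[:, 0])
    return np.concatenate(out).astype(np.float64)


def predict_image(model: FewShotSegmenter, record: ClassRecord,
                  support_members) -> np.ndarray:
    """Vessel probabilities for a whole image.

    Every member patch of the record is segmented under the given (shared)
    support and the patch maps are stitched back to image extent, averaging
    where patches overlap.
    """
    queries = np.stack([m.patch for m in record.members])
    probs = predict_with_support(model, support_members, queries)
    return pp.reassemble(list(probs), record.grid, record.extent)


def evaluate_split(model: FewShotSegmenter, library: list[ClassRecord],
                   split: SplitSpec, C: int, K: int, n_episodes: int = 2,
                   seed: int = 0, scope: str = "valid",
                   threshold: float = 0.5) -> ev.MetricReport:
    """Micro-averaged metrics over sampled held-out episodes.

    scope="valid": standard episodes from the validation classes, each
    query guided by its own class support.  scope="test": the test queries
    are guided by the fixed validation support set (support sharing); all
    validation support shots are pooled into a single prototype class.
    """
    rng = np.random.default_rng(seed)
    counts = ev.ConfusionCounts()
    probs_all, truth_all, fov_all = [], [], []

    def accumulate(probs, masks, fovs):
        nonlocal counts
        for p, m, f in zip(probs, masks, fovs):
            counts = counts + ev.confusion(p, m, f, threshold)
            keep = np.asarray(f) > 0
            probs_all.append(np.asarray(p)[keep])
            truth_all.append(np.asarray(m)[keep])
            fov_all.append(None)

    if scope == "valid":
        ids = split.valid_ids
        c_eff = min(C, len(ids))
        for _ in range(n_episodes):
            episode = sample_episode(library, c_eff, K, rng, class_ids=ids)
            sp, sm, qp, qm, qf = episode_arrays(episode)
            probs = model.episode_forward(sp, sm, qp).data[:, 0]
            accumulate(probs, qm.reshape(-1, *qm.shape[-2:]),
                       qf.reshape(-1, *qf.shape[-2:]))
    elif scope == "test":
        c_eff = min(C, len(split.valid_ids))
        valid_ep = sample_episode(library, c_eff, K, rng,
                                  class_ids=split.valid_ids)
        provider = test_support_provider(valid_ep.support, split.test_ids)
        by_id = {rec.class_id: rec for rec in library}
        for _ in range(n_episodes):
            for tid in split.test_ids:
                rec = by_id[tid]
                shared = [m for members in provider[tid].values()
                          for m in members]
                picks = rng.choice(len(rec), size=min(K, len(rec)),
                                   replace=False)
                queries = np.stack([rec.members[i].patch for i in picks])
                probs = predict_with_support(model, shared, queries)
                accumulate(probs,
                           [rec.members[i].mask for i in picks],
                           [rec.members[i].fov for i in picks])
    else:
        raise ConfigurationError(f"unknown scope {scope!r}")

    report = ev.metrics(counts, scope=scope)
    scores = np.concatenate(probs_all)
    labels = np.concatenate(truth_all)
    report.auc = ev.auc(scores, labels)
    return report
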