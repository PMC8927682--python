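"""Desk-scale reference experiments on the synthetic corpus.

These are the package's standard CPU-sized study conditions: a 10-class
synthetic corpus of 160x160 images cut into 64x64 patches (stride 48),
models at 1/8 of the reference channel widths, and 3-way 3-shot episodic
training for 10 epochs of 20 episodes at learning rate 3e-3.  Held-out
evaluation follows the study protocol: test-class queries are guided by
the validation split's shared support set.

The cross-domain experiment trains one member per synthetic domain
(distinct vessel-width/contrast/noise regimes) with a shorter schedule
(8 epochs x 15 episodes), then fuses the members by pixel-wise majority
vote on the held-out target domain.  Member seeds are decorrelated from
the run seed so the members are independently initialized.
"""

from __future__ import annotations

import numpy as np

from . import ensemble as ens
from . import evaluation as ev
from . import synthetic as syn
from . import training as tr
from .episodes import SplitSpec, sample_episode
from .model_core import FewShotSegmenter, ModelConfig
from .preprocessing import PatchGrid

__all__ = ["desk_library", "desk_train_config", "run_desk_training",
           "run_domain_ensemble", "DESK_CHANNEL_SCALE", "DESK_LR"]

DESK_CHANNEL_SCALE = 0.125
DESK_LR = 3e-3
DESK_EPOCHS = 10
DESK_ITERATIONS = 20


def desk_library(spec: syn.SyntheticSpec | None = None):
    """The desk corpus: 10 classes x 9 members of 64x64 patches."""
    spec = spec or syn.SyntheticSpec(seed=0)
    grid = PatchGrid.for_extent((spec.image_size, spec.image_size),
                                template=64, stride=48)
    return syn.generate_library(spec, grid)


def desk_train_config(seed: int, epochs: int = DESK_EPOCHS,
                      iterations: int = DESK_ITERATIONS) -> tr.TrainConfig:
    return tr.TrainConfig(learning_rate=DESK_LR, epochs=epochs,
                          iterations_per_epoch=iterations, C=3, K=3,
                          seed=seed)


def run_desk_training(variant: str, seed: int,
                      spec: syn.SyntheticSpec | None = None,
                      epochs: int = DESK_EPOCHS,
                      iterations: int = DESK_ITERATIONS):
    """Train one variant under the desk protocol and score it held-out.

    Returns (model, TrainResult, test MetricReport); the model carries the
    best-validation-accuracy weights and the report uses shared-support
    inference on the test classes.
    """
    library = desk_library(spec)
    split = SplitSpec.default([r.class_id for r in library], n_train=3,
                              seed=seed)
    model = FewShotSegmenter(
        ModelConfig(channel_scale=DESK_CHANNEL_SCALE, variant=variant),
        seed=seed)
    result = tr.train(model, library, split,
                      desk_train_config(seed, epochs, iterations))
    result.restore_best(model)
    report = tr.evaluate_split(model, library, split, C=3, K=3,
                               n_episodes=2, seed=99, scope="test")
    return model, result, report


def run_domain_ensemble(seed: int, epochs: int = 8, iterations: int = 15,
                        queries_per_class: int = 3) -> dict:
    """Cross-domain ensemble experiment for one run seed.

    Trains an upgraded member on each of the three source domains, then
    scores each member and their majority-vote fusion on the held-out
    target domain (shared support from the target's validation split).
    Returns the member and fused F1/AUC values.
    """
    domains = syn.domain_specs(seed=seed)
    members = []
    for i, name in enumerate(("thin", "thick", "noisy")):
        member_seed = 100 * seed + i + 1
        library = desk_library(domains[name])
        split = SplitSpec.default([r.class_id for r in library], n_train=3,
                                  seed=member_seed)
        model = FewShotSegmenter(
            ModelConfig(channel_scale=DESK_CHANNEL_SCALE), seed=member_seed)
        result = tr.train(model, library, split,
                          desk_train_config(member_seed, epochs, iterations))
        result.restore_best(model)
        members.append(model)

    target_library = desk_library(domains["target"])
    split = SplitSpec.default([r.class_id for r in target_library],
                              n_train=3, seed=seed)
    rng = np.random.default_rng(seed + 500)
    valid_ep = sample_episode(target_library, 3, 3, rng,
                              class_ids=split.valid_ids)
    shared = [m for ms in valid_ep.support.values() for m in ms]
    by_id = {r.class_id: r for r in target_library}
    queries, masks, fovs = [], [], []
    for tid in split.test_ids:
        rec = by_id[tid]
        picks = rng.choice(len(rec), size=min(queries_per_class, len(rec)),
                           replace=False)
        for i in picks:
            queries.append(rec.members[i].patch)
            masks.append(rec.members[i].mask)
            fovs.append(rec.members[i].fov)
    queries = np.stack(queries)

    maps = ens.member_predict(members, shared, queries)
    fused = ens.fuse(maps, ens.vote(maps, T=0.5, T1=1))

    def score(probs):
        counts = ev.ConfusionCounts()
        for p, m, f in zip(probs, masks, fovs):
            counts = counts + ev.confusion(p, m, f)
        report = ev.metrics(counts, scope="split")
        keep = np.concatenate([np.asarray(p)[np.asarray(f) > 0]
                               for p, f in zip(probs, fovs)])
        labels = np.concatenate([np.asarray(m)[np.asarray(f) > 0]
                                 for m, f in zip(masks, fovs)])
        report.auc = ev.auc(keep, labels)
        return report

    member_reports = [score(m) for m in maps]
    fused_report = score(fused)
    return {
        "member_f1": [r.f1 for r in member_reports],
        "member_auc": [r.auc for r in member_reports],
        "fused_f1": fused_report.f1,
        "fused_auc": fused_report.auc,
    }
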