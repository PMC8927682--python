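"""Scene-to-episode transformation for few-shot vessel segmentation.

Each annotated retinal image is treated as its own class (vascular trees
differ between people) and its overlapping patches are the class members.
A C-way K-shot episode draws C classes and, per class, K support and K
query members, all without replacement.  Test-time inference has no
annotated support of its own: test images share the fixed support set of
the validation split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from . import preprocessing as pp
from .exceptions import (ConfigurationError, MissingAnnotationError,
                         SamplingError)

__all__ = [
    "PatchMember", "ClassRecord", "Episode", "SplitSpec",
    "build_class_library", "sample_episode", "test_support_provider",
]


class PatchMember(NamedTuple):
    """One class member: a preprocessed patch with its aligned crops."""

    patch: np.ndarray  # (t, t) preprocessed plane
    mask: np.ndarray   # (t, t) vessel annotation crop, {0,1}
    fov: np.ndarray    # (t, t) field-of-view crop, {0,1}
    origin: tuple      # (row, col) top-left in the source image


@dataclass
class ClassRecord:
    class_id: str
    members: list[PatchMember]
    extent: tuple = ()
    grid: pp.PatchGrid | None = None

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Episode:
    """One C-way K-shot task: per-class support and query member lists."""

    support: dict[str, list[PatchMember]]
    query: dict[str, list[PatchMember]]
    C: int
    K: int
    support_indices: dict[str, list[int]] = field(default_factory=dict)
    query_indices: dict[str, list[int]] = field(default_factory=dict)

    @property
    def class_ids(self) -> list[str]:
        return list(self.support.keys())

    def to_manifest(self) -> dict:
        """JSON-serializable replay record (ids and member indices only)."""
        return {
            "C": self.C, "K": self.K,
            "support": {cid: idx for cid, idx in self.support_indices.items()},
            "query": {cid: idx for cid, idx in self.query_indices.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_manifest(), sort_keys=True)


@dataclass
class SplitSpec:
    """Disjoint train/validation/test class-id lists."""

    train_ids: list[str]
    valid_ids: list[str]
    test_ids: list[str]
    seed: int = 0

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.valid_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ConfigurationError("split id lists must be pairwise disjoint")

    @classmethod
    def default(cls, class_ids: Sequence[str], n_train: int, seed: int = 0
                ) -> "SplitSpec":
        """Shuffle ids by seed; n_train go to training, the remainder is
        split (validation gets the ceiling half)."""
        ids = list(class_ids)
        if n_train >= len(ids):
            raise ConfigurationError(
                f"n_train={n_train} leaves no held-out classes of {len(ids)}")
        rng = np.random.default_rng(seed)
        rng.shuffle(ids)
        rest = ids[n_train:]
        n_valid = (len(rest) + 1) // 2
        return cls(train_ids=ids[:n_train], valid_ids=rest[:n_valid],
                   test_ids=rest[n_valid:], seed=seed)


def build_class_library(samples, grid: pp.PatchGrid | None = None,
                        config: pp.PreprocessConfig | None = None
                        ) -> list[ClassRecord]:
    """Preprocess annotated images into a library of patch classes.

    ``samples`` is an iterable of (FundusImage, vessel BinaryMask,
    fov BinaryMask) triples; each yields one :class:`ClassRecord` whose
    members come from the overlapping patch grid.
    """
    library: list[ClassRecord] = []
    for item in samples:
        try:
            image, vessel, fov = item
        except (TypeError, ValueError) as exc:
            raise MissingAnnotationError(
                "each sample must be (image, vessel_mask, fov_mask)") from exc
        if vessel is None or fov is None:
            raise MissingAnnotationError(
                f"image {getattr(image, 'id', '?')} lacks a mask")
        extent = image.pixels.shape[:2]
        g = grid or pp.PatchGrid.for_extent(extent)
        if not g.origins or max(o[0] for o in g.origins) + g.template > extent[0]:
            g = pp.PatchGrid.for_extent(extent, g.template, g.stride)
        plane = pp.preprocess_image(image, fov, config)
        patch_pairs = pp.extract_patches(plane, vessel, g)
        fov_pairs = pp.extract_patches(fov.pixels, fov, g)
        members = [
            PatchMember(patch, mask, fov_patch, origin)
            for (patch, mask), (fov_patch, _), origin
            in zip(patch_pairs, fov_pairs, g.origins)
        ]
        library.append(ClassRecord(class_id=image.id, members=members,
                                   extent=tuple(extent), grid=g))
    return library


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_episode(library: Sequence[ClassRecord], C: int, K: int,
                   rng_seed=0, class_ids: Sequence[str] | None = None
                   ) -> Episode:
    """Draw a C-way K-shot episode, support and query disjoint per class.

    ``class_ids`` restricts the candidate classes (e.g. to a training
    split).  Sampling is without replacement at both levels and fully
    reproducible from ``rng_seed``.
    """
    rng = _as_rng(rng_seed)
    by_id = {rec.class_id: rec for rec in library}
    pool = list(class_ids) if class_ids is not None else list(by_id)
    missing = [cid for cid in pool if cid not in by_id]
    if missing:
        raise SamplingError(f"unknown class ids {missing}")
    if len(pool) < C:
        raise SamplingError(f"need {C} classes, library split has {len(pool)}")
    chosen = [pool[i] for i in rng.choice(len(pool), size=C, replace=False)]
    support, query = {}, {}
    support_idx, query_idx = {}, {}
    for cid in chosen:
        rec = by_id[cid]
        if len(rec) < 2 * K:
            raise SamplingError(
                f"class {cid!r} has {len(rec)} members, needs {2 * K} "
                f"for disjoint {K}-shot support and query")
        picks = rng.choice(len(rec), size=2 * K, replace=False)
        support_idx[cid] = [int(i) for i in picks[:K]]
        query_idx[cid] = [int(i) for i in picks[K:]]
        support[cid] = [rec.members[i] for i in support_idx[cid]]
        query[cid] = [rec.members[i] for i in query_idx[cid]]
    return Episode(support=support, query=query, C=C, K=K,
                   support_indices=support_idx, query_indices=query_idx)


def test_support_provider(valid_support: dict[str, list[PatchMember]],
                          test_ids: Sequence[str]
                          ) -> dict[str, dict[str, list[PatchMember]]]:
    """Pair every test class with the fixed validation support set.

    Test images have no annotated support of their own; their queries are
    guided by prototypes computed from the validation split's support
    patches, so the returned mapping is constant across test classes.
    """
    if not valid_support or all(len(v) == 0 for v in valid_support.values()):
        raise ConfigurationError("validation support set is empty")
    return {tid: valid_support for tid in test_ids}
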