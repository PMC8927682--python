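"""Pixel-wise majority-vote ensembling of independently trained models.

Given N1 member probability maps for the same query, a pixel is voted
vessel when strictly more than T1 members assign it probability strictly
above T (defaults T=0.5, T1=1, i.e. "at least 2 of 3").  The fused
probability is the member maximum where the vote is 1 and the member
minimum elsewhere, which sharpens agreement in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, ShapeError
from .training import predict_with_support

__all__ = ["EnsembleConfig", "member_predict", "vote", "fuse",
           "ensemble_predict"]


@dataclass
class EnsembleConfig:
    """Voting thresholds and the member checkpoint list.

    T is the per-member binarization threshold (0 < T < 1); T1 is the vote
    count that must be strictly exceeded (defaults to floor(N1/2), which
    for three members is the printed value 1).
    """

    members: list = field(default_factory=list)
    T: float = 0.5
    T1: float | None = None

    def __post_init__(self):
        if len(self.members) < 2:
            raise ConfigurationError("an ensemble needs at least 2 members")
        if not (0 < self.T < 1):
            raise ConfigurationError(f"T must be in (0, 1), got {self.T}")
        if self.T1 is None:
            self.T1 = len(self.members) // 2
        if not (0 <= self.T1 < len(self.members)):
            raise ConfigurationError(
                f"T1 must satisfy 0 <= T1 < N1={len(self.members)}")


def _stack(maps) -> np.ndarray:
    arrs = [np.asarray(m, dtype=np.float64) for m in maps]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ShapeError(f"member maps differ in shape: {sorted(shapes)}")
    return np.stack(arrs)


def member_predict(models, support_members, query_patches) -> list[np.ndarray]:
    """One probability map batch per member model, in config order."""
    out = []
    for idx, model in enumerate(models):
        try:
            out.append(predict_with_support(model, support_members,
                                            query_patches))
        except Exception as exc:
            raise RuntimeError(f"ensemble member {idx} failed: {exc}") from exc
    return out


def vote(maps, T: float = 0.5, T1: float = 1) -> np.ndarray:
    """Indicator vote map: 1 where #{members with p > T} > T1 (both strict)."""
    stacked = _stack(maps)
    votes = (stacked > T).sum(axis=0)
    return (votes > T1).astype(np.uint8)


def fuse(maps, vote_map) -> np.ndarray:
    """Max over members where voted vessel, min over members elsewhere."""
    stacked = _stack(maps)
    vote_map = np.asarray(vote_map)
    if vote_map.shape != stacked.shape[1:]:
        raise ShapeError(
            f"vote map {vote_map.shape} vs members {stacked.shape[1:]}")
    return np.where(vote_map > 0, stacked.max(axis=0), stacked.min(axis=0))


def ensemble_predict(models, support_members, query_patches,
                     T: float = 0.5, T1: float | None = None) -> np.ndarray:
    """Full pipeline: member prediction, voting, max/min fusion."""
    if T1 is None:
        T1 = len(list(models)) // 2
    maps = member_predict(models, support_members, query_patches)
    return fuse(maps, vote(maps, T, T1))
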