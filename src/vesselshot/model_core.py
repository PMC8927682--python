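"""Prototype-guided segmentation networks.

Two variants share one encoder/decoder configuration:

* **baseline** — the class prototype is extracted by mask average pooling
  only at the deepest encoder position (l=5); its inner-product guidance
  map is concatenated with the deepest query feature and decoded back to
  patch resolution.
* **upgraded** — prototypes are extracted at all five positions (the four
  block outputs before pooling plus the post-final-pool map), each
  guidance map is fused into the matching decoder stage together with a
  skip-connected query feature, and two-scale non-local attention (MSA) is
  applied to the deepest query feature first.

The encoder is the first four convolution modules of VGG16 with ordinary
(non-dilated) 3x3 kernels; the decoder mirrors it with four bilinear
up-samplings.  ``channel_scale`` shrinks every width uniformly so the same
graph trains on a CPU in minutes; the architecture is scale-invariant.

Mask average pooling normalizes by the full spatial area W*H (not by the
mask sum), so an all-zero vessel mask yields a zero prototype.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autograd as ag
from . import nn
from . import preprocessing as pp
from .autograd import Tensor
from .exceptions import ConfigurationError, ConsistencyError, ShapeError

__all__ = [
    "ENCODER_WIDTHS", "DECODER_WIDTHS", "ModelConfig", "Prototype",
    "FewShotSegmenter", "mask_average_pool", "combine_shots",
    "prototype_guidance", "save_checkpoint", "load_checkpoint",
]

# Layer widths of the reference architecture (channel_scale = 1).
ENCODER_WIDTHS: tuple = (64, 64, 128, 128, 256, 256, 256, 512, 512, 512)
DECODER_WIDTHS: tuple = (512, 256, 256, 128, 128, 64, 64, 32, 3, 1)

_ENC_BLOCKS = ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512))


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    channel_scale uniformly shrinks the reference widths (1.0 keeps them);
    the final two decoder convolutions (widths 3 and 1) form the output
    head and are never scaled.  attention_scales are the MSA down-sampling
    factors.  variant selects the forward pass.
    """

    channel_scale: float = 1.0
    attention_scales: tuple = (1, 2)
    variant: str = "upgraded"
    leaky_slope: float = 0.1
    foreground_prior: float = 0.1
    pretrained_encoder: bool = False

    def __post_init__(self):
        if not (0 < self.channel_scale <= 1):
            raise ConfigurationError(
                f"channel_scale must be in (0, 1], got {self.channel_scale}")
        if self.variant not in ("baseline", "upgraded"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.pretrained_encoder:
            raise ConfigurationError(
                "no pretrained encoder weights are bundled; "
                "set pretrained_encoder=False")

    def scaled(self, width: int) -> int:
        return max(1, int(round(width * self.channel_scale)))


@dataclass
class Prototype:
    """Per-class, per-position channel summary of support features."""

    vector: np.ndarray
    position: int = 5
    class_id: str = ""

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if self.vector.ndim != 1 or not np.all(np.isfinite(self.vector)):
            raise ShapeError("prototype must be a finite 1-D channel vector")


# -- functional ops (numpy reference surface) -----------------------------

def mask_average_pool(feature: np.ndarray, mask: np.ndarray,
                      position: int = 5, class_id: str = "") -> Prototype:
    """Masked spatial mean of a (H, W, C) feature map.

    vector[c] = (1 / (W*H)) * sum_{h,w} feature[h, w, c] * mask[h, w]

    The normalizer is the full spatial area, so sparse masks produce
    proportionally small prototypes.
    """
    feature = np.asarray(feature, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if feature.ndim != 3:
        raise ShapeError(f"expected (H, W, C) feature, got {feature.shape}")
    if mask.shape != feature.shape[:2]:
        raise ShapeError(
            f"mask {mask.shape} does not match feature plane {feature.shape[:2]}")
    vector = (feature * mask[:, :, None]).mean(axis=(0, 1))
    return Prototype(vector=vector, position=position, class_id=class_id)


def combine_shots(prototypes) -> Prototype:
    """Element-wise mean of K same-class, same-position prototypes."""
    protos = list(prototypes)
    if not protos:
        raise ConsistencyError("cannot combine zero prototypes")
    positions = {p.position for p in protos}
    if len(positions) > 1:
        raise ConsistencyError(f"mixed prototype positions {sorted(positions)}")
    vectors = np.stack([p.vector for p in protos])
    return Prototype(vector=vectors.mean(axis=0),
                     position=protos[0].position,
                     class_id=protos[0].class_id)


def prototype_guidance(prototype: Prototype | np.ndarray,
                       query_feature: np.ndarray) -> np.ndarray:
    """Inner-product guidance grid of a prototype over a (H, W, C) query map.

    The prototype acts as a 1x1 convolution kernel: each output location is
    the dot product of the prototype with the query feature vector there.
    """
    vec = prototype.vector if isinstance(prototype, Prototype) else np.asarray(prototype)
    query_feature = np.asarray(query_feature, dtype=np.float64)
    if query_feature.ndim != 3:
        raise ShapeError(f"expected (H, W, C) query feature, got {query_feature.shape}")
    if query_feature.shape[2] != vec.shape[0]:
        raise ShapeError(
            f"prototype has {vec.shape[0]} channels, query feature "
            f"has {query_feature.shape[2]}")
    return query_feature @ vec


# -- the network ----------------------------------------------------------

class FewShotSegmenter(nn.Module):
    """Baseline or upgraded prototype-guided segmentation network.

    Weights are He-normal initialized from ``seed``.  Input patches are
    single-channel preprocessed planes whose side must divide by 16 (four
    max-poolings).
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0,
                 dtype=nn.DEFAULT_DTYPE):
        self.config = config or ModelConfig()
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        sw = self.config.scaled
        leak = self.config.leaky_slope
        self.enc_blocks = []
        cin = 1
        for block in _ENC_BLOCKS:
            convs = []
            for w in block:
                convs.append(nn.Conv2d(cin, sw(w), rng, leak=leak, dtype=dtype))
                cin = sw(w)
            self.enc_blocks.append(convs)
        self._enc_out = [sw(b[-1]) for b in _ENC_BLOCKS]  # l1..l4 channels
        e1, e2, e3, e4 = self._enc_out
        e5 = e4
        upgraded = self.config.variant == "upgraded"
        self.msa = (nn.MultiScaleAttention(e5, rng,
                                           scales=self.config.attention_scales,
                                           dtype=dtype)
                    if upgraded else None)
        skip = lambda c: (c + 1) if upgraded else 0  # noqa: E731
        d0 = e5 + 1  # deepest query feature + its guidance grid
        self.dec_convs = [
            nn.Conv2d(d0 + skip(e4), sw(512), rng, leak=leak, dtype=dtype),
            nn.Conv2d(sw(512), sw(256), rng, leak=leak, dtype=dtype),
            nn.Conv2d(sw(256) + skip(e3), sw(256), rng, leak=leak, dtype=dtype),
            nn.Conv2d(sw(256), sw(128), rng, leak=leak, dtype=dtype),
            nn.Conv2d(sw(128) + skip(e2), sw(128), rng, leak=leak, dtype=dtype),
            nn.Conv2d(sw(128), sw(64), rng, leak=leak, dtype=dtype),
            nn.Conv2d(sw(64) + skip(e1), sw(64), rng, leak=leak, dtype=dtype),
            nn.Conv2d(sw(64), sw(32), rng, leak=leak, dtype=dtype),
            nn.Conv2d(sw(32), 3, rng, leak=leak, dtype=dtype),
            nn.Conv2d(3, 1, rng, relu=False, dtype=dtype),  # logits head
        ]
        # start at the foreground prior's log-odds so early training does
        # not spend its first epochs fitting the class base rate
        prior = float(np.clip(self.config.foreground_prior, 1e-4, 1 - 1e-4))
        self.dec_convs[-1].bias.data[:] = np.log(prior / (1 - prior))
        self.dtype = dtype

    # -- encoder ----------------------------------------------------------
    def encode(self, patches) -> list[Tensor]:
        """Five-scale feature pyramid for a (N, H, W) or (H, W) patch batch."""
        x = np.asarray(patches, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3:
            raise ShapeError(f"expected (N, H, W) patches, got {x.shape}")
        n, h, w = x.shape
        if h % 16 or w % 16:
            raise ShapeError(
                f"patch side must divide by 16 (four poolings), got {h}x{w}")
        t = Tensor(x[:, None, :, :])
        feats: list[Tensor] = []
        for convs in self.enc_blocks:
            for conv in convs:
                t = conv(t)
            feats.append(t)          # l = 1..4, before pooling
            t = ag.maxpool2x2(t)
        feats.append(t)              # l = 5, after the fourth pooling
        return feats

    # -- episode forward ---------------------------------------------------
    def episode_forward(self, support_patches, support_masks, query_patches,
                        zero_upper_guidance: bool = False,
                        return_internals: bool = False):
        """Segment query patches guided by per-class support prototypes.

        Parameters are grouped per class: support (C, K, t, t) patches and
        masks, queries (C, Q, t, t).  Returns the probability Tensor of
        shape (C*Q, 1, t, t) in class-major order (and an internals dict
        when requested).  All-zero support masks produce a zero prototype
        and therefore a zero guidance grid.
        """
        sp = np.asarray(support_patches, dtype=self.dtype)
        sm = np.asarray(support_masks, dtype=self.dtype)
        qp = np.asarray(query_patches, dtype=self.dtype)
        if sp.ndim != 4 or sm.shape != sp.shape:
            raise ShapeError("support patches/masks must both be (C, K, t, t)")
        if qp.ndim != 4 or qp.shape[0] != sp.shape[0]:
            raise ShapeError("query patches must be (C, Q, t, t) with the "
                             "same C as the support")
        C, K, th, tw = sp.shape
        Q = qp.shape[1]
        feats_s = self.encode(sp.reshape(C * K, th, tw))
        feats_q = self.encode(qp.reshape(C * Q, th, tw))
        upgraded = self.config.variant == "upgraded"
        levels = [0, 1, 2, 3, 4] if upgraded else [4]

        # averaging matrix over shots and one-hot expansion over queries
        avg = np.kron(np.eye(C), np.full((1, K), 1.0 / K)).astype(self.dtype)
        expand = np.kron(np.eye(C), np.ones((Q, 1))).astype(self.dtype)

        q5 = self.msa(feats_q[4]) if upgraded else feats_q[4]
        guidance: dict[int, Tensor] = {}
        protos: dict[int, Tensor] = {}
        for lv in levels:
            fs = feats_s[lv]
            hl, wl = fs.shape[2], fs.shape[3]
            masks_l = np.stack([
                pp.resize_mask(sm.reshape(C * K, th, tw)[i], (hl, wl))
                for i in range(C * K)
            ]).astype(self.dtype)
            pooled = ag.tmean(ag.mul(fs, masks_l[:, None]), axis=(2, 3))
            proto = ag.matmul(Tensor(avg), pooled)            # (C, C_l)
            protos[lv + 1] = proto
            proto_q = ag.matmul(Tensor(expand), proto)        # (C*Q, C_l)
            qf = q5 if lv == 4 else feats_q[lv]
            grid = ag.tsum(
                ag.mul(ag.reshape(proto_q, (C * Q, qf.shape[1], 1, 1)), qf),
                axis=1, keepdims=True)                        # (C*Q, 1, h, w)
            if zero_upper_guidance and lv != 4:
                grid = Tensor(np.zeros_like(grid.data))
            guidance[lv + 1] = grid

        logits = self._decode(q5, feats_q, guidance, upgraded)
        probs = ag.sigmoid(logits)
        if return_internals:
            internals = {
                "prototypes": protos,
                "guidance": guidance,
                "query_l5": q5,
                "logits": logits,
            }
            return probs, internals
        return probs

    def _decode(self, q5: Tensor, feats_q: list[Tensor],
                guidance: dict[int, Tensor], upgraded: bool) -> Tensor:
        t = ag.concat([q5, guidance[5]], axis=1)
        stages = ((0, 1, 3), (2, 3, 2), (4, 5, 1), (6, 7, 0))
        for conv_a, conv_b, skip_lv in stages:
            hl, wl = feats_q[skip_lv].shape[2], feats_q[skip_lv].shape[3]
            t = ag.bilinear_resize(t, hl, wl)
            if upgraded:
                t = ag.concat([t, feats_q[skip_lv], guidance[skip_lv + 1]],
                              axis=1)
            t = self.dec_convs[conv_a](t)
            t = self.dec_convs[conv_b](t)
        t = self.dec_convs[8](t)
        return self.dec_convs[9](t)

    # -- single-class convenience (spec-style forward) ---------------------
    def forward(self, support_pairs, query_patch, **kwargs) -> np.ndarray:
        """Segment one query patch from K (patch, mask) support pairs.

        Returns a (t, t) vessel-probability map in [0, 1].
        """
        patches = np.stack([np.asarray(p) for p, _ in support_pairs])
        masks = np.stack([np.asarray(m) for _, m in support_pairs])
        probs = self.episode_forward(patches[None], masks[None],
                                     np.asarray(query_patch)[None, None],
                                     **kwargs)
        return probs.data[0, 0].astype(np.float64)

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        if set(params) != set(state):
            raise ConsistencyError("checkpoint parameter names do not match")
        for k, v in params.items():
            if v.data.shape != state[k].shape:
                raise ShapeError(f"shape mismatch for {k}")
            v.data = np.asarray(state[k], dtype=v.data.dtype).copy()

    def encoder_widths(self) -> list[int]:
        return [c.cout for convs in self.enc_blocks for c in convs]

    def decoder_widths(self) -> list[int]:
        return [c.cout for c in self.dec_convs]


def forward_baseline(model: FewShotSegmenter, support_pairs, query_patch
                     ) -> np.ndarray:
    """Baseline forward pass (prototype at l=5 only)."""
    if model.config.variant != "baseline":
        raise ConfigurationError("model variant is not 'baseline'")
    return model.forward(support_pairs, query_patch)


def forward_upgraded(model: FewShotSegmenter, support_pairs, query_patch,
                     zero_upper_guidance: bool = False) -> np.ndarray:
    """Upgraded forward pass (multi-scale prototypes, skips, MSA).

    ``zero_upper_guidance`` zeroes the guidance grids at l=1..4, reducing
    the pass to a baseline-like one (ablation hook).
    """
    if model.config.variant != "upgraded":
        raise ConfigurationError("model variant is not 'upgraded'")
    return model.forward(support_pairs, query_patch,
                         zero_upper_guidance=zero_upper_guidance)


# -- checkpoints ----------------------------------------------------------

def save_checkpoint(model: FewShotSegmenter, path: str | Path,
                    rng_state: dict | None = None,
                    extra: dict | None = None) -> None:
    """Single-archive checkpoint: weights + ModelConfig + RNG state."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": asdict(model.config),
        "seed": model.seed,
        "rng_state": rng_state,
        "extra": extra or {},
        "format_version": 1,
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta, default=list).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[FewShotSegmenter, dict]:
    """Restore a model (and its metadata) from :func:`save_checkpoint`."""
    with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz")
                 else path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_dict = dict(meta["config"])
        cfg_dict["attention_scales"] = tuple(cfg_dict["attention_scales"])
        config = ModelConfig(**cfg_dict)
        model = FewShotSegmenter(config, seed=meta["seed"])
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    model.load_state_dict(state)
    return model, meta
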