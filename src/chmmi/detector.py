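"""The three-scale anchor detector.

Backbone: a YOLOv5-style CSP stack (CBS + C3 stages) with squeeze-excitation
gates after the shallow stages, finishing in SPPF at stride 32.  Neck:
top-down (FPN) then bottom-up (PAN) fusion by channel concatenation and
CBS/C3 blocks.  Each of the three fused outputs (strides 8/16/32) passes
through an efficient-channel-attention gate before a 1x1 prediction
convolution that emits, per grid cell and per anchor, the raw
(t_x, t_y, t_w, t_h, t_conf, class logits) vector.

Widths are configurable; the default is a deliberately narrow CPU-scale
plan.  Anchors default to k-means over a dataset's box dimensions, three per
scale ordered small to large.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster.vq import kmeans2

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

STRIDES = (8, 16, 32)

# fallback anchors (pixels, per scale small->large) for a 320px input
FALLBACK_ANCHORS = (
    ((20.0, 20.0), (34.0, 22.0), (22.0, 34.0)),
    ((48.0, 48.0), (80.0, 48.0), (48.0, 80.0)),
    ((112.0, 112.0), (176.0, 112.0), (112.0, 176.0)),
)


class DetectorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DetectorConfig:
    n_classes: int
    input_size: tuple[int, int] = (320, 320)
    widths: tuple[int, int, int, int, int] = (8, 16, 24, 32, 48)
    anchors: tuple = FALLBACK_ANCHORS
    use_scam: bool = True
    use_dcam: bool = True
    scam_stages: tuple[int, ...] = (1, 2)
    seed: int = 0

    def validate(self) -> None:
        h, w = self.input_size
        if h % 32 or w % 32 or h < 32 or w < 32:
            raise DetectorConfigError(
                f"input_size must be divisible by 32, got {self.input_size}"
            )
        if self.n_classes < 1:
            raise DetectorConfigError("n_classes must be >= 1")
        if len(self.anchors) != 3 or any(len(a) != 3 for a in self.anchors):
            raise DetectorConfigError("anchors must be 3 scales x 3 (w,h) pairs")
        if any(w_ < 2 for w_ in self.widths):
            raise DetectorConfigError("channel widths must be >= 2")
        for scale in self.anchors:
            for (aw, ah) in scale:
                if aw <= 0 or ah <= 0:
                    raise DetectorConfigError("anchor dims must be positive")

    def grid_sizes(self) -> list[tuple[int, int]]:
        h, w = self.input_size
        return [(h // s, w // s) for s in STRIDES]

    def anchors_array(self) -> np.ndarray:
        return np.asarray(self.anchors, dtype=float)  # (3, 3, 2)


def kmeans_anchors(box_whs: np.ndarray, input_size: tuple[int, int],
                   seed: int = 0) -> tuple:
    """Cluster normalized box (w, h) pairs into 9 anchors (pixels), ordered
    by area and grouped 3 per scale (small -> P3, large -> P5)."""
    wh = np.asarray(box_whs, dtype=float)
    if wh.ndim != 2 or wh.shape[1] != 2 or len(wh) == 0:
        raise ValueError("box_whs must be a non-empty (n, 2) array")
    h, w = input_size
    px = wh * np.array([w, h])
    if len(px) < 9:
        px = np.concatenate([px * s for s in (0.7, 1.0, 1.4)])
    centroids, _ = kmeans2(px, 9, minit="++", seed=seed)
    centroids = np.clip(centroids, 2.0, max(h, w))
    order = np.argsort(centroids.prod(axis=1))
    c = centroids[order]
    return tuple(tuple((float(a), float(b)) for a, b in c[3 * i:3 * i + 3])
                 for i in range(3))


class DetectorModel(nn.Module):
    """Assembled network; ``forward`` returns one raw grid per scale."""

    def __init__(self, config: DetectorConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        w1, w2, w3, w4, w5 = config.widths
        nc = config.n_classes
        self.no = 5 + nc

        # backbone (stage index -> stride): 0->2, 1->4, 2->8, 3->16, 4->32
        self.b0 = nn.CBS(3, w1, 3, 2, rng)
        self.b1 = nn.CBS(w1, w2, 3, 2, rng)
        self.c1 = nn.C3(w2, w2, rng)
        self.se1 = nn.SEGate(w2, rng) if config.use_scam and 1 in config.scam_stages else None
        self.b2 = nn.CBS(w2, w3, 3, 2, rng)
        self.c2 = nn.C3(w3, w3, rng)
        self.se2 = nn.SEGate(w3, rng) if config.use_scam and 2 in config.scam_stages else None
        self.b3 = nn.CBS(w3, w4, 3, 2, rng)
        self.c3_ = nn.C3(w4, w4, rng)
        self.b4 = nn.CBS(w4, w5, 3, 2, rng)
        self.c4 = nn.C3(w5, w5, rng)
        self.sppf = nn.SPPF(w5, w5, rng)

        # neck: FPN top-down then PAN bottom-up
        self.lat5 = nn.CBS(w5, w4, 1, 1, rng)
        self.f4 = nn.C3(w4 + w4, w4, rng)
        self.lat4 = nn.CBS(w4, w3, 1, 1, rng)
        self.f3 = nn.C3(w3 + w3, w3, rng)
        self.d3 = nn.CBS(w3, w3, 3, 2, rng)
        self.f4b = nn.C3(w3 + w3, w4, rng)
        self.d4 = nn.CBS(w4, w4, 3, 2, rng)
        self.f5b = nn.C3(w4 + w4, w5, rng)

        self.eca_l = nn.ECAGate(w3, rng) if config.use_dcam else None
        self.eca_m = nn.ECAGate(w4, rng) if config.use_dcam else None
        self.eca_h = nn.ECAGate(w5, rng) if config.use_dcam else None

        self.head_l = nn.Conv2d(w3, 3 * self.no, 1, 1, rng, bias=True)
        self.head_m = nn.Conv2d(w4, 3 * self.no, 1, 1, rng, bias=True)
        self.head_h = nn.Conv2d(w5, 3 * self.no, 1, 1, rng, bias=True)
        # start objectness strongly negative so early training is not swamped
        # by false positives on the dense no-object grid
        for head in (self.head_l, self.head_m, self.head_h):
            bias = head.bias.data.reshape(3, self.no)
            bias[:, 4] = -4.0

        self.attention_bypass = False  # gates forced to identity when True

    # -- forward -----------------------------------------------------------
    def forward(self, images: np.ndarray, training: bool = False
                ) -> tuple[list[Tensor], list[Tensor]]:
        """Run the network.

        ``images``: (N, H, W, 3) uint8 or float in [0,1].  Returns
        ``(raw_heads, grids)`` where each grid Tensor has data of shape
        (N, 3, S, S, 5+nc); ``raw_heads`` are the head conv outputs kept for
        backward.
        """
        x = np.asarray(images)
        if x.ndim == 3:
            x = x[None]
        if x.dtype == np.uint8:
            x = x.astype(np.float32) / 255.0
        H, W = self.config.input_size
        if x.shape[1:] != (H, W, 3):
            raise ValueError(
                f"expected input (N, {H}, {W}, 3), got {x.shape}"
            )
        t = Tensor(x.transpose(0, 3, 1, 2))
        byp = self.attention_bypass

        y = self.b0(t, training)
        y = self.c1(self.b1(y, training), training)
        if self.se1 is not None:
            y = self.se1(y, training, bypass=byp)
        p3 = self.c2(self.b2(y, training), training)
        if self.se2 is not None:
            p3 = self.se2(p3, training, bypass=byp)
        p4 = self.c3_(self.b3(p3, training), training)
        p5 = self.sppf(self.c4(self.b4(p4, training), training), training)

        h5 = self.lat5(p5, training)
        m4 = self.f4(ad.concat([ad.upsample2(h5), p4], axis=1), training)
        h4 = self.lat4(m4, training)
        out_l = self.f3(ad.concat([ad.upsample2(h4), p3], axis=1), training)
        out_m = self.f4b(ad.concat([self.d3(out_l, training), h4], axis=1), training)
        out_h = self.f5b(ad.concat([self.d4(out_m, training), h5], axis=1), training)

        if self.eca_l is not None:
            out_l = self.eca_l(out_l, training, bypass=byp)
            out_m = self.eca_m(out_m, training, bypass=byp)
            out_h = self.eca_h(out_h, training, bypass=byp)

        heads = [self.head_l(out_l), self.head_m(out_m), self.head_h(out_h)]
        grids = []
        for head, (gh, gw) in zip(heads, self.config.grid_sizes()):
            n = head.shape[0]
            grids.append(head.data.reshape(n, 3, self.no, gh, gw)
                         .transpose(0, 1, 3, 4, 2))
        return heads, grids

    def backward_from_grids(self, heads: list[Tensor],
                            grid_grads: list[np.ndarray]) -> None:
        """Push per-scale gradients (in grid layout) back through the tape.

        All three head gradients are injected through one virtual root so the
        shared tape is traversed exactly once.
        """
        head_grads = []
        for g in grid_grads:
            n, a, gh, gw, no = g.shape
            head_grads.append(
                np.ascontiguousarray(g.transpose(0, 1, 4, 2, 3)
                                     .reshape(n, a * no, gh, gw))
            )

        def inject(_):
            for head, gg in zip(heads, head_grads):
                head._accum(gg)

        root = Tensor(0.0, parents=tuple(heads), backward=inject)
        root.backward(np.zeros(()))

    def predict(self, images: np.ndarray) -> list[np.ndarray]:
        """Eval-mode forward returning only the numpy grids."""
        _, grids = self.forward(images, training=False)
        return grids

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = self.state_arrays()
        with open(path, "wb") as fh:
            pickle.dump({"config": self.config, "arrays": arrays}, fh)

    @staticmethod
    def load(path: str | Path) -> "DetectorModel":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        model = DetectorModel(blob["config"])
        for tgt, src in zip(model.state_arrays(), blob["arrays"]):
            if tgt.shape != src.shape:
                raise ValueError("checkpoint does not match config")
            tgt[...] = src
        return model


def build_detector(config: DetectorConfig) -> DetectorModel:
    """Construct the detector; parameter initialization is seeded by
    ``config.seed`` so identical configs build identical models."""
    return DetectorModel(config)
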