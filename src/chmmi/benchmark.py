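"""The CPU-scale end-to-end synthetic benchmark.

A scaled-down rendition of the full experimental protocol: a two-class
imbalanced synthetic slide set (a rounded stone-cell-like majority class and
an elongated fiber-like minority class, 70/30 box mix), an 8:2 split,
cut-and-recombine balancing of the training split, five-fold cross-
validation of the attention detector, and 3-of-5 box-cluster voting on the
held-out images.

Problem sizes (120 slides of 128x128 px, 14 epochs per fold, batch 8) are
chosen so one full run completes in a few minutes on a single CPU core while
leaving enough signal to separate the full method from the bare detector.
The box/class/confidence loss weighting (5, 1, 1) compensates for the box
term being expressed in squared *normalized* coordinates, which are orders
of magnitude smaller than the confidence term.
"""

from __future__ import annotations

import copy

_BASE = {
    "generate": {
        "n_images": 120,
        "n_classes": 2,
        "image_size": [128, 128],
        "cells_per_image": [1, 3],
        "class_weights": [0.7, 0.3],
        "blur_sigma": [0.0, 0.8],
        "edge_truncation_prob": 0.15,
        "cell_size": [0.2, 0.45],
        "seed": 7,
    },
    "split": {"ratio": 0.8, "seed": 0},
    "augment": {"enabled": True, "balance_ratio": 0.5,
                "max_new_images": 60, "seed": 0},
    "model": {"input_size": [128, 128], "seed": 0,
              "use_scam": True, "use_dcam": True},
    "train": {"preset": "desk", "epochs": 14, "batch_size": 8,
              "learning_rate": 0.01, "seed": 0,
              "loss_weights": {"alpha": 5.0, "beta": 1.0, "gamma": 1.0}},
    "cv": {"k": 5, "seed": 0},
    "vote": {"min_votes": 3},
    "eval": {"score_thresh": 0.25},
}


def benchmark_config(seed: int = 0, full: bool = True) -> dict:
    """Experiment configuration for one benchmark replicate.

    ``full=True`` enables augmentation and both attention gates;
    ``full=False`` is the bare three-scale detector without augmentation.
    ``seed`` shifts every stochastic component (data, split, augmentation,
    fold plan, initialization, training order).
    """
    cfg = copy.deepcopy(_BASE)
    cfg["generate"]["seed"] = 7 + 1000 * seed
    cfg["split"]["seed"] = seed
    cfg["augment"]["seed"] = seed
    cfg["model"]["seed"] = seed
    cfg["train"]["seed"] = seed
    cfg["cv"]["seed"] = seed
    if not full:
        cfg["augment"]["enabled"] = False
        cfg["model"]["use_scam"] = False
        cfg["model"]["use_dcam"] = False
    return cfg
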