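"""Experimental protocol: 8:2 split, five-fold cross-validation producing
models M1..Mk, per-model test predictions, and box-cluster majority voting.

The voting rule generalizes label voting to detection output: detections
from the k models are greedily clustered by overlap (each model contributes
at most one member per cluster), clusters backed by at least ``min_votes``
distinct models survive, and each surviving cluster is emitted with the
majority class, the mean box and the mean score of its members.  With one
model and ``min_votes=1`` the rule is the identity.

Augmentation discipline: cut-and-recombine products are created from the
training split only, and each product records its two source slides; a fold
uses an augmented image only when *both* sources sit in that fold's training
portion, so no half of a validation image is ever seen in training.
"""

from __future__ import annotations

import csv
import json
import sys
import time
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .augment import AugmentationPolicy, balance_dataset
from .boxes import BBox, iou
from .detector import (DetectorConfig, DetectorModel, build_detector,
                       kmeans_anchors)
from .labels import DatasetIndex, load_index
from .losses import LossWeights, assign_targets, detection_loss
from .metrics import (Detection, EvalReport, anchor_cell_count,
                      decode_predictions, map_suite, nms)
from .synthetic import SlideSpec, generate_dataset
from . import autodiff as ad


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 16
    loss_weights: LossWeights = field(default_factory=LossWeights)
    box_loss: str = "sse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")


def desk_train_config(**overrides) -> TrainConfig:
    """CPU-scale defaults shipped alongside the full-scale configuration."""
    base = dict(epochs=8, batch_size=8, learning_rate=0.01)
    base.update(overrides)
    return TrainConfig(**base)


@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignment: dict[str, int]  # image_id -> fold
    seed: int = 0

    def validate(self) -> None:
        sizes = Counter(self.assignment.values())
        if set(sizes) != set(range(self.k)):
            raise ValueError("folds must be 0..k-1 and non-empty")
        if max(sizes.values()) - min(sizes.values()) > 1:
            raise ValueError("fold sizes must differ by at most 1")


@dataclass(frozen=True)
class VotePolicy:
    iou_thresh: float = 0.5
    min_votes: int = 3
    k: int = 5

    def __post_init__(self) -> None:
        if not (1 <= self.min_votes <= self.k):
            raise ValueError(f"min_votes {self.min_votes} outside [1, k={self.k}]")


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _majority_class(boxes: list[BBox]) -> int:
    if not boxes:
        return -1
    return Counter(b.class_id for b in boxes).most_common(1)[0][0]


def split_dataset(index: DatasetIndex, ratio: float = 0.8, seed: int = 0
                  ) -> tuple[list[int], list[int], str | None]:
    """Split image indices into (train, test) with |test| = round((1-ratio) N),
    stratified by each image's majority class.  Below 5 images the split
    falls back to plain random sampling and a warning is returned."""
    if not (0.0 < ratio < 1.0):
        raise ValueError(f"ratio {ratio} outside (0,1)")
    n = len(index)
    if n == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    n_test = int(round((1.0 - ratio) * n))
    warning = None
    if n < 5:
        warning = "fewer than 5 images: plain random split, no stratification"
        perm = rng.permutation(n)
        return sorted(perm[n_test:].tolist()), sorted(perm[:n_test].tolist()), warning

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[_majority_class(index.boxes_for(i))].append(i)
    quotas = {}
    fractions = []
    total = 0
    for c, items in sorted(groups.items()):
        exact = len(items) * n_test / n
        quotas[c] = int(exact)
        total += quotas[c]
        fractions.append((exact - quotas[c], c))
    for _, c in sorted(fractions, reverse=True):
        if total >= n_test:
            break
        if quotas[c] < len(groups[c]):
            quotas[c] += 1
            total += 1
    test: list[int] = []
    for c, items in sorted(groups.items()):
        perm = rng.permutation(len(items))
        test.extend(items[j] for j in perm[:quotas[c]])
    # largest-remainder rounding can fall one short when groups saturate
    remaining = [i for i in range(n) if i not in set(test)]
    while len(test) < n_test and remaining:
        j = int(rng.integers(len(remaining)))
        test.append(remaining.pop(j))
    test = sorted(test)
    train = sorted(set(range(n)) - set(test))
    return train, test, warning


def make_fold_plan(image_ids: list[str], k: int = 5, seed: int = 0) -> FoldPlan:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(image_ids))
    assignment = {image_ids[j]: int(f % k) for f, j in enumerate(order)}
    plan = FoldPlan(k=k, assignment=assignment, seed=seed)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _load_images(index: DatasetIndex, ids: list[int]):
    imgs, boxes, names = [], [], []
    for i in ids:
        imgs.append(np.asarray(Image.open(index.image_paths[i]).convert("RGB")))
        boxes.append(index.boxes_for(i))
        names.append(index.image_paths[i].stem)
    return imgs, boxes, names


def train_model(images: list[np.ndarray], gt_boxes: list[list[BBox]],
                det_config: DetectorConfig, cfg: TrainConfig,
                val: tuple | None = None, log_rows: list | None = None,
                tag: str = "M") -> DetectorModel:
    """Train one detector with Adam on the given in-memory set.

    Losses are averaged per image inside a batch before the gradient step.
    A NaN loss aborts with a diagnostic.  Per-epoch loss components (and
    validation mAP@.5 when ``val`` is provided) are appended to
    ``log_rows``.
    """
    if cfg.optimizer.lower() != "adam":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    model = build_detector(det_config)
    opt = ad.Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    masks_all = [assign_targets(bs, det_config) for bs in gt_boxes]
    n = len(images)
    for epoch in range(cfg.epochs):
        # cosine decay to 10% of the base rate over the run
        frac = epoch / max(1, cfg.epochs - 1)
        opt.lr = cfg.learning_rate * (0.55 + 0.45 * np.cos(np.pi * frac))
        order = rng.permutation(n)
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = np.stack([images[i] for i in idx])
            masks = [masks_all[i] for i in idx]
            heads, grids = model.forward(batch, training=True)
            breakdown, grads = detection_loss(
                grids, masks, cfg.loss_weights, det_config,
                box_loss=cfg.box_loss, compute_grad=True)
            if not np.isfinite(breakdown.total):
                raise FloatingPointError(
                    f"{tag}: loss diverged (NaN/Inf) at epoch {epoch}"
                )
            opt.zero_grad()
            model.backward_from_grids(heads, [g / len(idx) for g in grads])
            opt.step()
            sums += np.array([breakdown.l_obj, breakdown.l_cls,
                              breakdown.l_conf, breakdown.total]) / len(idx)
            n_batches += 1
        row = {
            "model": tag, "epoch": epoch,
            "l_obj": sums[0] / n_batches, "l_cls": sums[1] / n_batches,
            "l_conf": sums[2] / n_batches, "total": sums[3] / n_batches,
        }
        if val is not None:
            row["val_map50"] = evaluate_model(model, *val).map50
        if log_rows is not None:
            log_rows.append(row)
    return model


def predict_model(model: DetectorModel, images: list[np.ndarray],
                  image_ids: list[str], score_thresh: float = 0.05,
                  nms_iou: float = 0.45, batch_size: int = 16
                  ) -> list[Detection]:
    dets: list[Detection] = []
    for start in range(0, len(images), batch_size):
        chunk = images[start:start + batch_size]
        grids = model.predict(np.stack(chunk))
        raw = decode_predictions(grids, model.config, score_thresh,
                                 image_ids[start:start + batch_size])
        by_img: dict[str, list[Detection]] = defaultdict(list)
        for d in raw:
            by_img[d.image_id].append(d)
        for ds in by_img.values():
            dets.extend(nms(ds, nms_iou))
    return dets


def evaluate_model(model: DetectorModel, images, gt_boxes, image_ids,
                   score_thresh: float = 0.25) -> EvalReport:
    dets = predict_model(model, images, image_ids)
    gts = {iid: bs for iid, bs in zip(image_ids, gt_boxes)}
    return map_suite(dets, gts, model.config.n_classes, score_thresh,
                     anchor_cell_count(model.config, len(images)))


def kfold_train(index: DatasetIndex, train_ids: list[int], plan: FoldPlan,
                det_config: DetectorConfig, cfg: TrainConfig,
                aug_sources: dict[str, tuple[str, str]] | None = None,
                aug_ids: list[int] | None = None,
                log_rows: list | None = None) -> list[DetectorModel]:
    """Train k models, fold f validating on fold f and training on the rest.

    ``train_ids`` index the original training images; ``aug_ids`` (optional)
    index augmented images inside the same DatasetIndex, each of which is
    used only when both of its source images (``aug_sources``) lie outside
    the validation fold.
    """
    plan.validate()
    id_of = index.image_ids()
    models = []
    for f in range(plan.k):
        train_orig = [i for i in train_ids if plan.assignment[id_of[i]] != f]
        val_ids = [i for i in train_ids if plan.assignment[id_of[i]] == f]
        chosen = list(train_orig)
        if aug_ids:
            for i in aug_ids:
                s1, s2 = aug_sources[id_of[i]]
                if (plan.assignment.get(s1, -1) != f
                        and plan.assignment.get(s2, -1) != f):
                    chosen.append(i)
        imgs, boxes, _ = _load_images(index, chosen)
        v_imgs, v_boxes, v_names = _load_images(index, val_ids)
        fold_cfg = replace(cfg, seed=cfg.seed + 1000 * (f + 1))
        model = train_model(
            imgs, boxes, det_config, fold_cfg,
            val=(v_imgs, v_boxes, v_names) if val_ids else None,
            log_rows=log_rows, tag=f"M{f + 1}")
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# voting
# ---------------------------------------------------------------------------

def ensemble_vote(pred_sets: list[list[Detection]],
                  policy: VotePolicy) -> list[Detection]:
    """Fuse the k models' detections by box-cluster majority voting."""
    pool = []
    for m, dets in enumerate(pred_sets):
        for d in dets:
            pool.append((m, d))
    pool.sort(key=lambda md: (-md[1].score, md[1].box.cx, md[1].box.cy,
                              md[1].box.w, md[1].box.h, md[1].class_id, md[0]))
    assigned = [False] * len(pool)
    fused: list[Detection] = []
    for i, (mi, seed_det) in enumerate(pool):
        if assigned[i]:
            continue
        members = [(mi, seed_det)]
        assigned[i] = True
        models_in = {mi}
        for j in range(i + 1, len(pool)):
            if assigned[j]:
                continue
            mj, d = pool[j]
            if mj in models_in or d.image_id != seed_det.image_id:
                continue
            if iou(d.box, seed_det.box) >= policy.iou_thresh:
                members.append((mj, d))
                assigned[j] = True
                models_in.add(mj)
        if len(models_in) < policy.min_votes:
            continue
        votes = Counter(d.class_id for _, d in members)
        top = votes.most_common()
        best_n = top[0][1]
        tied = [c for c, v in top if v == best_n]
        if len(tied) > 1:
            score_sum = {c: sum(d.score for _, d in members if d.class_id == c)
                         for c in tied}
            cls = max(tied, key=lambda c: score_sum[c])
        else:
            cls = tied[0]
        corners = np.array([d.box.corners() for _, d in members])
        mean_c = corners.mean(axis=0)
        fused.append(Detection(
            image_id=seed_det.image_id, class_id=cls,
            score=float(np.mean([d.score for _, d in members])),
            box=BBox.from_corners(cls, *mean_c),
        ))
    fused.sort(key=_vote_sort_key)
    return fused


def _vote_sort_key(d: Detection):
    return (-d.score, d.box.cx, d.box.cy, d.box.w, d.box.h, d.class_id)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_experiment(config: dict | str | Path, out_dir: str | Path | None = None
                   ) -> EvalReport:
    """Execute generate -> split -> augment -> k-fold train -> predict ->
    vote -> evaluate, writing all artifacts under ``out_dir``.

    ``config`` is a dict or a YAML path; see README for the schema.  Any
    stage failure raises :class:`StageError` naming the stage.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir or config.get("out_dir", "experiment_out"))
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name):
        print(f"[chmmi] stage {name} (+{time.time() - t0:.1f}s)",
              file=sys.stderr, flush=True)

    try:
        stage("dataset")
        if "generate" in config:
            g = dict(config["generate"])
            n_images = int(g.pop("n_images"))
            spec = SlideSpec(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in g.items()})
            index = generate_dataset(spec, n_images, out / "data")
        else:
            index = load_index(config["dataset"])
    except Exception as exc:
        raise StageError("dataset", exc) from exc

    try:
        stage("split")
        sp = config.get("split", {})
        train_ids, test_ids, warn = split_dataset(
            index, float(sp.get("ratio", 0.8)), int(sp.get("seed", 0)))
    except Exception as exc:
        raise StageError("split", exc) from exc

    try:
        stage("augment")
        aug = config.get("augment", {})
        aug_sources: dict[str, tuple[str, str]] = {}
        aug_ids: list[int] = []
        work_index = index
        if aug.get("enabled", True):
            policy = AugmentationPolicy(
                clip_keep_fraction=float(aug.get("clip_keep_fraction", 0.2)),
                balance_ratio=float(aug.get("balance_ratio", 0.5)),
                max_new_images=int(aug.get("max_new_images", 200)),
                seed=int(aug.get("seed", 0)),
            )
            train_index = DatasetIndex(
                root=index.root,
                image_paths=[index.image_paths[i] for i in train_ids],
                label_paths=[index.label_paths[i] for i in train_ids],
                n_classes=index.n_classes, class_names=index.class_names,
            )
            aug_index = balance_dataset(train_index, policy,
                                        out_dir=out / "data_aug",
                                        pair_sources=aug_sources)
            work_index = aug_index
            # remap: only the training images were copied into the augmented
            # directory, so translate training ids into the new index
            name_to_new = {p.stem: i for i, p in enumerate(aug_index.image_paths)}
            train_ids_w = [name_to_new[index.image_paths[i].stem]
                           for i in train_ids]
            aug_ids = sorted(i for n_, i in name_to_new.items()
                             if n_.startswith("aug_"))
        else:
            train_ids_w = train_ids
    except Exception as exc:
        raise StageError("augment", exc) from exc

    try:
        stage("model-config")
        mc = dict(config.get("model", {}))
        anchors_mode = mc.pop("anchors", "kmeans")
        det_config = DetectorConfig(
            n_classes=index.n_classes,
            input_size=tuple(mc.get("input_size", (320, 320))),
            widths=tuple(mc.get("widths", (8, 16, 24, 32, 48))),
            use_scam=bool(mc.get("use_scam", True)),
            use_dcam=bool(mc.get("use_dcam", True)),
            seed=int(mc.get("seed", 0)),
        )
        if anchors_mode == "kmeans":
            whs = []
            for i in train_ids:
                whs.extend([(b.w, b.h) for b in index.boxes_for(i)])
            if whs:
                det_config = replace(
                    det_config,
                    anchors=kmeans_anchors(np.array(whs), det_config.input_size,
                                           seed=int(mc.get("seed", 0))))
        det_config.validate()
    except Exception as exc:
        raise StageError("model-config", exc) from exc

    try:
        stage("kfold-train")
        tc = dict(config.get("train", {}))
        preset = tc.pop("preset", "desk")
        lw = tc.pop("loss_weights", None)
        if lw:
            tc["loss_weights"] = LossWeights(**lw)
        cfg = desk_train_config(**tc) if preset == "desk" else TrainConfig(**tc)
        k = int(config.get("cv", {}).get("k", 5))
        plan = make_fold_plan([work_index.image_ids()[i] for i in train_ids_w],
                              k=k, seed=int(config.get("cv", {}).get("seed", 0)))
        with open(out / "folds.json", "w") as fh:
            json.dump({"k": plan.k, "assignment": plan.assignment}, fh, indent=1)
        log_rows: list[dict] = []
        models = kfold_train(work_index, train_ids_w, plan, det_config, cfg,
                             aug_sources=aug_sources, aug_ids=aug_ids,
                             log_rows=log_rows)
        with open(out / "train_log.csv", "w", newline="") as fh:
            cols = ["model", "epoch", "l_obj", "l_cls", "l_conf", "total",
                    "val_map50"]
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            for row in log_rows:
                writer.writerow(row)
        for i, m in enumerate(models, start=1):
            m.save(out / f"M{i}.ckpt")
    except Exception as exc:
        raise StageError("kfold-train", exc) from exc

    try:
        stage("predict-vote-evaluate")
        t_imgs, t_boxes, t_names = _load_images(index, test_ids)
        ev = config.get("eval", {})
        score_thresh = float(ev.get("score_thresh", 0.25))
        pred_sets = []
        for i, m in enumerate(models, start=1):
            dets = predict_model(m, t_imgs, t_names)
            pred_sets.append(dets)
            _dump_dets(dets, out / f"preds_M{i}.json")
        vp = VotePolicy(
            iou_thresh=float(config.get("vote", {}).get("iou_thresh", 0.5)),
            min_votes=int(config.get("vote", {}).get("min_votes",
                                                     max(1, (k + 1) // 2))),
            k=k)
        voted = ensemble_vote(pred_sets, vp)
        _dump_dets(voted, out / "preds_vote.json")
        gts = {n: b for n, b in zip(t_names, t_boxes)}
        cells = anchor_cell_count(det_config, len(t_imgs))
        report = map_suite(voted, gts, index.n_classes, score_thresh, cells)
        per_model = [map_suite(ds, gts, index.n_classes, score_thresh, cells)
                     for ds in pred_sets]
        with open(out / "report.json", "w") as fh:
            json.dump({
                "split_warning": warn,
                "ensemble": _report_dict(report),
                "per_model": [_report_dict(r) for r in per_model],
            }, fh, indent=1)
        return report
    except Exception as exc:
        raise StageError("predict-vote-evaluate", exc) from exc


def _dump_dets(dets: list[Detection], path: Path) -> None:
    with open(path, "w") as fh:
        json.dump([{"image_id": d.image_id, "class": d.class_id,
                    "score": d.score,
                    "box": [d.box.cx, d.box.cy, d.box.w, d.box.h]}
                   for d in dets], fh)


def _report_dict(r: EvalReport) -> dict:
    return {
        "map50": r.map50, "map50_95": r.map50_95, "mcc": r.mcc, "auc": r.auc,
        "per_class_ap": {str(k): v for k, v in r.per_class_ap.items()},
        "per_class_precision": {str(k): v for k, v in r.per_class_precision.items()},
        "per_class_recall": {str(k): v for k, v in r.per_class_recall.items()},
        "roc_degenerate": r.roc_degenerate,
    }
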