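"""YOLO-dialect label files and the images/labels/dataset.yaml layout.

One text file per image, one line per box::

    class_id cx cy w h

with coordinates normalized to [0, 1].  ``dataset.yaml`` records the class
count, class names, and the image/label directories.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .boxes import BBox


class LabelParseError(ValueError):
    pass


def read_yolo_labels(path: str | os.PathLike) -> list[BBox]:
    """Parse a YOLO label file.  Empty file -> empty list.

    Malformed lines raise :class:`LabelParseError` naming the line number;
    out-of-range coordinates raise ``ValueError`` from box validation.
    """
    boxes: list[BBox] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise LabelParseError(
                    f"{path}:{lineno}: expected 5 fields, got {len(parts)}"
                )
            try:
                cid = int(parts[0])
                vals = [float(p) for p in parts[1:]]
            except ValueError as exc:
                raise LabelParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                boxes.append(BBox(cid, *vals))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return boxes


def write_yolo_labels(boxes: list[BBox], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for b in boxes:
            fh.write(f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}\n")


@dataclass
class DatasetIndex:
    """Index of an on-disk detection dataset (images + YOLO labels)."""

    root: Path
    image_paths: list[Path]
    label_paths: list[Path]
    n_classes: int
    class_names: list[str]
    class_box_counts: dict[int, int] = field(default_factory=dict)
    warning: str | None = None

    def __len__(self) -> int:
        return len(self.image_paths)

    def image_ids(self) -> list[str]:
        return [p.stem for p in self.image_paths]

    def boxes_for(self, i: int) -> list[BBox]:
        return read_yolo_labels(self.label_paths[i])

    def recount(self) -> dict[int, int]:
        counts = {c: 0 for c in range(self.n_classes)}
        for lp in self.label_paths:
            for b in read_yolo_labels(lp):
                counts[b.class_id] += 1
        self.class_box_counts = counts
        return counts

    def save_yaml(self) -> Path:
        path = self.root / "dataset.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "n_classes": self.n_classes,
                    "names": list(self.class_names),
                    "images": "images",
                    "labels": "labels",
                },
                fh,
            )
        return path


def load_index(root: str | os.PathLike) -> DatasetIndex:
    """Load a dataset directory written by ``generate_dataset`` / augmentation."""
    root = Path(root)
    meta_path = root / "dataset.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"no dataset.yaml under {root}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    img_dir = root / meta.get("images", "images")
    lbl_dir = root / meta.get("labels", "labels")
    image_paths = sorted(img_dir.glob("*.png")) + sorted(img_dir.glob("*.jpg"))
    label_paths = [lbl_dir / f"{p.stem}.txt" for p in image_paths]
    missing = [str(l) for l in label_paths if not l.exists()]
    if missing:
        raise FileNotFoundError(f"missing label files: {missing[:3]}")
    idx = DatasetIndex(
        root=root,
        image_paths=image_paths,
        label_paths=label_paths,
        n_classes=int(meta["n_classes"]),
        class_names=[str(n) for n in meta["names"]],
    )
    idx.recount()
    return idx
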