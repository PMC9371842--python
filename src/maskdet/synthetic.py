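"""Synthetic noisy low-resolution images with small elliptical targets.

Emulates the regime the detector is built for: a smoothly varying background
(low-frequency cosine mixture), additive Gaussian pixel noise, and a handful
(0-5) of small elliptical lesions per image, each annotated with the tight
bounding box of its rendered mask.  Everything is deterministic given the
seed; per-image seeds are spawned from a master seed so datasets are
reproducible image-by-image.

Two lesion-size modes mirror the small/medium object-area bands used in the
size-stratified average-precision metrics: ``small`` guarantees box area
< 32^2 pixels, ``medium`` guarantees 32^2 <= area < 96^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "LesionSpec",
    "AnnotatedImage",
    "DatasetBundle",
    "GeneratorConfig",
    "PlacementError",
    "generate_image",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

# semi-axis ranges guaranteeing the rendered tight box stays in each area band
# (max half-extent of a rotated ellipse is max(a, b); rendered extent adds <= 1 px)
_SIZE_MODES = {
    "small": (2.0, 13.0),    # box <= 27x27 = 729 < 1024 = 32^2
    "medium": (17.0, 40.0),  # box in [33, 81] per side -> [1089, 6561) in [32^2, 96^2)
}


class PlacementError(RuntimeError):
    """Raised when a lesion cannot be placed within the rejection budget."""


@dataclass(frozen=True)
class LesionSpec:
    """One elliptical target: where it is, how big, how bright."""

    class_id: int
    center_xy: tuple[float, float]
    axes: tuple[float, float]          # semi-axes, pixels
    intensity_delta: float             # signed contrast against background
    rotation: float                    # radians

    def __post_init__(self):
        if min(self.axes) < 1.0:
            raise ValueError("ellipse semi-axes must be >= 1 px")
        if self.intensity_delta == 0.0:
            raise ValueError("intensity_delta must be nonzero")


@dataclass
class AnnotatedImage:
    """Image pixels in [0,1] plus 0-based half-open pixel boxes and labels.

    ``lesions`` carries the generating ellipse specs when the image came from
    the synthetic generator (None for images read from disk)."""

    pixels: np.ndarray                 # (H, W) or (H, W, C) float in [0,1]
    boxes: np.ndarray                  # (n, 4) float: x_min, y_min, x_max, y_max
    labels: np.ndarray                 # (n,) int
    lesions: list["LesionSpec"] | None = None

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=float).reshape(-1, 4)
        self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
        if len(self.boxes) != len(self.labels):
            raise ValueError("boxes and labels length mismatch")
        h, w = self.pixels.shape[:2]
        for x0, y0, x1, y1 in self.boxes:
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError(f"box ({x0},{y0},{x1},{y1}) invalid for {w}x{h} image")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class DatasetBundle:
    train: list[AnnotatedImage]
    val: list[AnnotatedImage]
    test: list[AnnotatedImage]
    class_names: list[str]
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)

    def split(self, name: str) -> list[AnnotatedImage]:
        return {"train": self.train, "val": self.val, "test": self.test}[name]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the image generator.

    noise_sigma is the std of the additive Gaussian pixel noise on a [0,1]
    intensity scale; 0.05 is clearly visible grain at 8 bits.
    """

    width: int = 64
    height: int = 64
    n_classes: int = 2
    lesions_per_image: tuple[int, int] = (1, 3)
    noise_sigma: float = 0.05
    size_mode: str = "small"
    intensity_delta_range: tuple[float, float] = (0.25, 0.55)
    max_overlap_iou: float = 0.3
    max_placement_attempts: int = 100
    class_names: tuple[str, ...] | None = None

    def resolved_class_names(self) -> list[str]:
        if self.class_names is not None:
            return list(self.class_names)
        return [f"lesion_{i}" for i in range(self.n_classes)]


def _background(width: int, height: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency 2-D cosine mixture, scaled into [0.3, 0.7]."""
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    bg = np.zeros((height, width))
    for _ in range(3):
        fx = rng.uniform(0.5, 2.0) / width
        fy = rng.uniform(0.5, 2.0) / height
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.3, 1.0)
        bg += amp * np.cos(2 * np.pi * (fx * xx + fy * yy) + phase)
    lo, hi = bg.min(), bg.max()
    if hi - lo < 1e-12:
        return np.full_like(bg, 0.5)
    return 0.3 + 0.4 * (bg - lo) / (hi - lo)


def _render_ellipse(spec: LesionSpec, width: int, height: int) -> np.ndarray:
    """Coverage map in [0,1] via 4x supersampling of the ellipse indicator."""
    cx, cy = spec.center_xy
    a, b = spec.axes
    ext = max(a, b) + 1.0
    x0 = max(int(np.floor(cx - ext)), 0)
    x1 = min(int(np.ceil(cx + ext)) + 1, width)
    y0 = max(int(np.floor(cy - ext)), 0)
    y1 = min(int(np.ceil(cy + ext)) + 1, height)
    cov = np.zeros((height, width))
    if x0 >= x1 or y0 >= y1:
        return cov
    sub = (np.arange(4) + 0.5) / 4.0  # supersample offsets within a pixel
    xs = x0 + np.add.outer(np.arange(x1 - x0), sub).reshape(-1)
    ys = y0 + np.add.outer(np.arange(y1 - y0), sub).reshape(-1)
    dx = xs[None, :] - cx
    dy = ys[:, None] - cy
    c, s = np.cos(spec.rotation), np.sin(spec.rotation)
    xr = c * dx + s * dy
    yr = -s * dx + c * dy
    inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    block = inside.reshape(y1 - y0, 4, (x1 - x0) * 4).reshape(
        y1 - y0, 4, x1 - x0, 4
    )
    cov[y0:y1, x0:x1] = block.mean(axis=(1, 3))
    return cov


def _tight_box(mask: np.ndarray) -> tuple[int, int, int, int] | None:
    """Half-open tight bounding box of the nonzero pixels, or None if empty."""
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        return None
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


def _box_iou(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def generate_image(
    width: int,
    height: int,
    n_lesions: int,
    classes: int,
    noise_sigma: float,
    seed: int,
    *,
    config: GeneratorConfig | None = None,
) -> AnnotatedImage:
    """Render one annotated image.

    Lesion geometry is rejection-sampled so every ellipse bounding circle fits
    inside the image and pairwise box IoU stays below the configured cap;
    exceeding the attempt budget raises :class:`PlacementError`.
    """
    if not (0 <= n_lesions <= 5):
        raise ValueError("n_lesions must be in [0, 5]")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if min(width, height) < 16:
        raise ValueError("image must be at least 16x16")
    cfg = config or GeneratorConfig(
        width=width, height=height, n_classes=classes, noise_sigma=noise_sigma
    )
    ax_lo, ax_hi = _SIZE_MODES[cfg.size_mode]
    ax_hi = min(ax_hi, (min(width, height) - 4) / 2.0)
    if ax_hi < ax_lo:
        raise ValueError(
            f"image {width}x{height} too small for size_mode={cfg.size_mode!r}"
        )

    rng = np.random.default_rng(seed)
    img = _background(width, height, rng)

    specs: list[LesionSpec] = []
    boxes: list[tuple[int, int, int, int]] = []
    labels: list[int] = []
    for _ in range(n_lesions):
        placed = False
        for _attempt in range(cfg.max_placement_attempts):
            a = rng.uniform(ax_lo, ax_hi)
            b = rng.uniform(ax_lo, min(a, ax_hi))
            ext = max(a, b) + 1.0
            if width - 2 * ext <= 0 or height - 2 * ext <= 0:
                continue
            cx = rng.uniform(ext, width - ext)
            cy = rng.uniform(ext, height - ext)
            rot = rng.uniform(0, np.pi)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            delta = sign * rng.uniform(*cfg.intensity_delta_range)
            cls = int(rng.integers(0, classes))
            spec = LesionSpec(cls, (cx, cy), (a, b), delta, rot)
            cov = _render_ellipse(spec, width, height)
            box = _tight_box(cov)
            if box is None:
                continue
            if any(_box_iou(box, other) > cfg.max_overlap_iou for other in boxes):
                continue
            img = img + spec.intensity_delta * cov
            specs.append(spec)
            boxes.append(box)
            labels.append(cls)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place lesion {len(specs)} within "
                f"{cfg.max_placement_attempts} attempts"
            )

    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return AnnotatedImage(
        pixels=img,
        boxes=np.asarray(boxes, dtype=float).reshape(-1, 4),
        labels=np.asarray(labels, dtype=int),
        lesions=specs,
    )


def _child_seed(master: int, index: int) -> int:
    """Deterministic per-image seed derived from the master seed."""
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % (2**31))


def split_sizes(n_images: int, fractions=(0.70, 0.15, 0.15)) -> tuple[int, int, int]:
    n_train = round(fractions[0] * n_images)
    n_val = round(fractions[1] * n_images)
    n_test = n_images - n_train - n_val
    return n_train, n_val, n_test


def generate_dataset(
    n_images: int, config: GeneratorConfig, seed: int
) -> DatasetBundle:
    """Generate a 70/15/15-split dataset of annotated images."""
    if n_images < 10:
        raise ValueError("need at least 10 images for nonempty 70/15/15 splits")
    n_train, n_val, n_test = split_sizes(n_images)
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("splits would be empty at this n_images")
    rng = np.random.default_rng(seed)
    lo, hi = config.lesions_per_image
    images = []
    for i in range(n_images):
        n_lesions = int(rng.integers(lo, hi + 1))
        images.append(
            generate_image(
                config.width,
                config.height,
                n_lesions,
                config.n_classes,
                config.noise_sigma,
                _child_seed(seed, i),
                config=config,
            )
        )
    return DatasetBundle(
        train=images[:n_train],
        val=images[n_train : n_train + n_val],
        test=images[n_train + n_val :],
        class_names=config.resolved_class_names(),
    )


# -- on-disk formats ----------------------------------------------------------
def _to_png(img: AnnotatedImage, path: Path) -> None:
    arr = np.round(img.pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr).save(path)


def _boxes_to_yolo(img: AnnotatedImage) -> list[str]:
    h, w = img.pixels.shape[:2]
    lines = []
    for (x0, y0, x1, y1), cls in zip(img.boxes, img.labels):
        cx, cy = (x0 + x1) / 2 / w, (y0 + y1) / 2 / h
        bw, bh = (x1 - x0) / w, (y1 - y0) / h
        lines.append(f"{cls} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
    return lines


def write_dataset(bundle: DatasetBundle, directory, format: str = "yolo") -> dict:
    """Write PNGs plus YOLO .txt or COCO JSON annotations; returns a manifest."""
    if format not in ("yolo", "coco"):
        raise ValueError(f"unknown format {format!r}")
    root = Path(directory)
    manifest = {
        "format": format,
        "class_names": bundle.class_names,
        "splits": {},
    }
    for split in ("train", "val", "test"):
        images = bundle.split(split)
        img_dir = root / "images" / split
        img_dir.mkdir(parents=True, exist_ok=True)
        names = []
        coco = {"images": [], "annotations": [], "categories": [
            {"id": i, "name": n} for i, n in enumerate(bundle.class_names)
        ]}
        ann_id = 0
        for i, img in enumerate(images):
            name = f"img_{i:05d}"
            names.append(name)
            _to_png(img, img_dir / f"{name}.png")
            if format == "yolo":
                lbl_dir = root / "labels" / split
                lbl_dir.mkdir(parents=True, exist_ok=True)
                (lbl_dir / f"{name}.txt").write_text(
                    "\n".join(_boxes_to_yolo(img)) + ("\n" if len(img.boxes) else "")
                )
            else:
                h, w = img.pixels.shape[:2]
                coco["images"].append(
                    {"id": i, "file_name": f"{name}.png", "width": w, "height": h}
                )
                for (x0, y0, x1, y1), cls in zip(img.boxes, img.labels):
                    coco["annotations"].append(
                        {
                            "id": ann_id,
                            "image_id": i,
                            "category_id": int(cls),
                            "bbox": [x0, y0, x1 - x0, y1 - y0],
                            "area": (x1 - x0) * (y1 - y0),
                            "iscrowd": 0,
                        }
                    )
                    ann_id += 1
        if format == "coco":
            ann_path = root / "annotations" / f"{split}.json"
            ann_path.parent.mkdir(parents=True, exist_ok=True)
            ann_path.write_text(json.dumps(coco, indent=1))
        manifest["splits"][split] = names
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _read_split(root: Path, split: str, names: list[str], fmt: str,
                n_classes: int) -> list[AnnotatedImage]:
    images = []
    coco_by_image: dict[str, list] = {}
    if fmt == "coco":
        coco = json.loads((root / "annotations" / f"{split}.json").read_text())
        id_to_name = {im["id"]: im["file_name"] for im in coco["images"]}
        for ann in coco["annotations"]:
            coco_by_image.setdefault(id_to_name[ann["image_id"]], []).append(ann)
    for name in names:
        arr = np.asarray(Image.open(root / "images" / split / f"{name}.png"))
        pixels = arr.astype(float) / 255.0
        h, w = pixels.shape[:2]
        boxes, labels = [], []
        if fmt == "yolo":
            text = (root / "labels" / split / f"{name}.txt").read_text()
            for line in text.splitlines():
                if not line.strip():
                    continue
                cls, cx, cy, bw, bh = line.split()
                cx, cy, bw, bh = (float(v) for v in (cx, cy, bw, bh))
                boxes.append(
                    [(cx - bw / 2) * w, (cy - bh / 2) * h,
                     (cx + bw / 2) * w, (cy + bh / 2) * h]
                )
                labels.append(int(cls))
        else:
            for ann in coco_by_image.get(f"{name}.png", []):
                x, y, bw, bh = ann["bbox"]
                boxes.append([x, y, x + bw, y + bh])
                labels.append(int(ann["category_id"]))
        b = np.asarray(boxes, dtype=float).reshape(-1, 4)
        # guard against float round-off pushing normalized coords out of bounds
        b[:, 0::2] = np.clip(b[:, 0::2], 0, w)
        b[:, 1::2] = np.clip(b[:, 1::2], 0, h)
        images.append(AnnotatedImage(pixels=pixels, boxes=b, labels=labels))
    return images


def read_dataset(directory) -> DatasetBundle:
    """Inverse of :func:`write_dataset` (boxes recovered to float precision)."""
    root = Path(directory)
    manifest = json.loads((root / "manifest.json").read_text())
    fmt = manifest["format"]
    names = manifest["class_names"]
    splits = {
        s: _read_split(root, s, manifest["splits"][s], fmt, len(names))
        for s in ("train", "val", "test")
    }
    return DatasetBundle(
        train=splits["train"], val=splits["val"], test=splits["test"],
        class_names=names,
    )
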