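"""Pipeline orchestration: generate -> pretrain -> train -> evaluate/detect.

Every run writes a manifest (config, seed, package version, key metrics) next
to its artifacts so any checkpoint can be regenerated from the manifest
alone.  Checkpoints are self-describing .npz containers embedding the
estimator's configuration, so evaluation and detection never need the
original YAML.
"""

from __future__ import annotations

import json
import time

from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .detection import Detection, WindowDetector
from .metrics import EvalReport, evaluate_detections
from .reconstruction import MaskedAutoencoder
from .synthetic import DatasetBundle, GeneratorConfig, generate_dataset

__all__ = [
    "build_dataset",
    "run_pretrain",
    "run_train",
    "run_evaluate",
    "run_detect",
    "run_ablation",
    "write_detections_yolo",
    "evaluate_files",
    "save_mae",
    "load_mae",
    "save_detector",
    "load_detector",
]


def _write_manifest(path: Path, payload: dict) -> None:
    payload = dict(payload)
    payload.setdefault("version", __version__)
    payload.setdefault("written_at", time.strftime("%Y-%m-%dT%H:%M:%S"))
    path.write_text(json.dumps(payload, indent=1, default=float))


def build_dataset(cfg: RunConfig) -> DatasetBundle:
    g = cfg.generator
    gen_cfg = GeneratorConfig(
        width=g.width, height=g.height, n_classes=g.n_classes,
        lesions_per_image=(g.lesions_min, g.lesions_max),
        noise_sigma=g.noise_sigma, size_mode=g.size_mode,
    )
    return generate_dataset(g.n_images, gen_cfg, cfg.seed)


# -- checkpoint containers ----------------------------------------------------
def save_mae(est: MaskedAutoencoder, path) -> None:
    est._check_fitted()
    meta = {
        "kind": "mae",
        "params": est.get_params(),
        "grid_shape": list(est.template_.grid_shape),
        "patch_dim": est.template_.tokens.shape[1],
        "orig_hw": list(est.template_.orig_hw),
        "channels": est.template_.channels,
        "loss_trace": est.loss_trace_,
    }
    arrays = {f"w_{i}": a for i, (_, a) in
              enumerate(sorted(est.model_.state_dict().items()))}
    names = sorted(est.model_.state_dict())
    np.savez(path, __meta__=np.frombuffer(
        json.dumps({**meta, "names": names}).encode(), dtype=np.uint8),
        **arrays)


def load_mae(path) -> MaskedAutoencoder:
    from .patching import PatchSequence
    from .reconstruction import MaeModel

    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = {n: z[f"w_{i}"] for i, n in enumerate(meta["names"])}
    est = MaskedAutoencoder(**meta["params"])
    grid = tuple(meta["grid_shape"])
    est.model_ = MaeModel(
        meta["patch_dim"], grid, est.width, est.depth, est.heads,
        est.dec_width, est.dec_depth, est.heads, est.mlp_ratio, est.scale_mode,
    )
    est.model_.load_state_dict(arrays)
    est.template_ = PatchSequence(
        np.zeros((grid[0] * grid[1], meta["patch_dim"])), grid,
        est.patch_size, meta["channels"], tuple(meta["orig_hw"]),
    )
    est.loss_trace_ = list(meta["loss_trace"])
    return est


def save_detector(est: WindowDetector, path) -> None:
    est._check_fitted()
    params = est.get_params()
    params["backbone_init"] = None  # weights already merged into the state
    state = {}
    for tag, mod in (("bb", est.backbone_), ("nk", est.neck_), ("hd", est.head_)):
        for name, arr in mod.state_dict().items():
            state[f"{tag}.{name}"] = arr
    meta = {
        "kind": "detector",
        "params": params,
        "grid": list(est._grid),
        "img_hw": list(est._img_hw),
        "n_classes": est.n_classes_,
        "anchors": [a.tolist() for a in est.anchors_],
        "loss_trace": est.loss_trace_,
        "names": sorted(state),
    }
    arrays = {f"w_{i}": state[n] for i, n in enumerate(meta["names"])}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_detector(path) -> WindowDetector:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = {n: z[f"w_{i}"] for i, n in enumerate(meta["names"])}
    params = meta["params"]
    params["stage_depths"] = tuple(params["stage_depths"])
    est = WindowDetector(**params)
    est._grid = tuple(meta["grid"])
    est._img_hw = tuple(meta["img_hw"])
    est.n_classes_ = int(meta["n_classes"])
    est.anchors_ = [np.asarray(a, dtype=float) for a in meta["anchors"]]
    patch_dim = est.patch_size**2
    rng = np.random.default_rng(est.random_state)
    est._build(patch_dim, est.n_classes_, rng)
    for tag, mod in (("bb", est.backbone_), ("nk", est.neck_), ("hd", est.head_)):
        sub = {n[len(tag) + 1:]: a for n, a in arrays.items()
               if n.startswith(tag + ".")}
        mod.load_state_dict(sub)
    est.loss_trace_ = list(meta["loss_trace"])
    return est


def evaluate_files(gt_json, dets_json, report_out=None) -> EvalReport:
    """Evaluate a COCO-results detections file against COCO ground truth."""
    gt = json.loads(Path(gt_json).read_text())
    det_records = json.loads(Path(dets_json).read_text())
    image_ids = sorted(im["id"] for im in gt["images"])
    index = {img_id: k for k, img_id in enumerate(image_ids)}
    gts = [[[], []] for _ in image_ids]
    for ann in gt["annotations"]:
        x, y, w, h = ann["bbox"]
        k = index[ann["image_id"]]
        gts[k][0].append([x, y, x + w, y + h])
        gts[k][1].append(int(ann["category_id"]))
    gts = [(np.asarray(b, dtype=float).reshape(-1, 4), np.asarray(l, int))
           for b, l in gts]
    dets = [[] for _ in image_ids]
    for rec in det_records:
        x, y, w, h = rec["bbox"]
        dets[index[rec["image_id"]]].append(
            (np.array([x, y, x + w, y + h]), float(rec["score"]),
             int(rec["category_id"])))
    report = evaluate_detections(dets, gts)
    if report_out is not None:
        Path(report_out).parent.mkdir(parents=True, exist_ok=True)
        _write_manifest(Path(report_out),
                        {"stage": "evaluate", "report": report.to_dict()})
    return report


# -- pipeline stages ----------------------------------------------------------
def run_pretrain(cfg: RunConfig, bundle: DatasetBundle | None = None,
                 out: Path | str | None = None) -> tuple[MaskedAutoencoder, Path]:
    cfg.validate()
    bundle = bundle or build_dataset(cfg)
    p = cfg.pretrain
    est = MaskedAutoencoder(
        patch_size=p.patch_size, mask_ratio=p.mask_ratio, width=p.width,
        depth=p.depth, heads=p.heads, dec_width=p.dec_width,
        dec_depth=p.dec_depth, mlp_ratio=p.mlp_ratio, loss_on=p.loss_on,
        epochs=p.epochs, batch_size=p.batch_size, lr=p.lr,
        weight_decay=p.weight_decay, dropout=p.dropout,
        random_state=cfg.seed,
    )
    est.fit([im.pixels for im in bundle.train])
    out_dir = Path(out or cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ckpt = out_dir / "mae.npz"
    save_mae(est, ckpt)
    _write_manifest(out_dir / "pretrain_manifest.json", {
        "stage": "pretrain", "seed": cfg.seed, "config": cfg.to_dict(),
        "final_loss": est.loss_trace_[-1], "initial_loss": est.loss_trace_[0],
        "checkpoint": ckpt.name,
    })
    return est, ckpt


def run_train(cfg: RunConfig, pretrain_ckpt=None,
              bundle: DatasetBundle | None = None,
              out: Path | str | None = None) -> tuple[WindowDetector, Path]:
    cfg.validate()
    bundle = bundle or build_dataset(cfg)
    d = cfg.detector
    mae = None
    if d.backbone_init != "none":
        if pretrain_ckpt is None:
            raise ValueError(
                f"backbone_init={d.backbone_init!r} needs a pretraining checkpoint"
            )
        mae = (pretrain_ckpt if isinstance(pretrain_ckpt, MaskedAutoencoder)
               else load_mae(pretrain_ckpt))
    X, y = WindowDetector.targets_from_images(bundle.train)
    if d.backbone_init == "denoised":
        X = mae.transform(X)
    est = WindowDetector(
        patch_size=d.patch_size, base_channels=d.base_channels,
        stage_depths=d.stage_depths, n_heads=d.heads,
        window_size=d.window_size, mlp_ratio=d.mlp_ratio,
        neck_width=d.neck_width, n_anchors=d.n_anchors, epochs=d.epochs,
        batch_size=d.batch_size, lr=d.lr, weight_decay=d.weight_decay,
        dropout=d.dropout, conf_thr=d.conf_thr, nms_iou=d.nms_iou,
        iou_weight=d.iou_weight, noobj_weight=d.noobj_weight,
        backbone_init=mae if d.backbone_init == "weights" else None,
        random_state=cfg.seed,
    )
    est.fit(X, y)
    out_dir = Path(out or cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ckpt = out_dir / "detector.npz"
    save_detector(est, ckpt)
    Xv, yv = WindowDetector.targets_from_images(bundle.val)
    if d.backbone_init == "denoised":
        Xv = mae.transform(Xv)
    val_report = evaluate_detections(est.predict(Xv), yv)
    _write_manifest(out_dir / "train_manifest.json", {
        "stage": "train", "seed": cfg.seed, "config": cfg.to_dict(),
        "final_loss": est.loss_trace_[-1],
        "val": val_report.to_dict(), "checkpoint": ckpt.name,
    })
    return est, ckpt


def run_evaluate(cfg: RunConfig, ckpt, bundle: DatasetBundle | None = None,
                 split: str = "test", mae=None,
                 out: Path | str | None = None) -> EvalReport:
    cfg.validate()
    bundle = bundle or build_dataset(cfg)
    est = ckpt if isinstance(ckpt, WindowDetector) else load_detector(ckpt)
    X, y = WindowDetector.targets_from_images(bundle.split(split))
    if cfg.detector.backbone_init == "denoised":
        if mae is None:
            raise ValueError("denoised evaluation needs the pretrained model")
        X = mae.transform(X)
    report = evaluate_detections(est.predict(X), y)
    if out is not None:
        out = Path(out)
        out.parent.mkdir(parents=True, exist_ok=True)
        _write_manifest(out, {"stage": "evaluate", "split": split,
                              "seed": cfg.seed, "report": report.to_dict()})
    return report


def write_detections_yolo(dets, image_hws, directory) -> None:
    """One text file per image: `class conf cx cy w h` (normalized)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for img_id, (per_img, (h, w)) in enumerate(zip(dets, image_hws)):
        lines = []
        for d in per_img:
            x0, y0, x1, y1 = d.box
            lines.append(
                f"{d.class_id} {d.score:.6f} {(x0 + x1) / 2 / w:.6f} "
                f"{(y0 + y1) / 2 / h:.6f} {(x1 - x0) / w:.6f} "
                f"{(y1 - y0) / h:.6f}"
            )
        (directory / f"img_{img_id:05d}.txt").write_text(
            "\n".join(lines) + ("\n" if lines else ""))


def run_detect(cfg: RunConfig, ckpt, images: list[np.ndarray],
               out: Path | str) -> list[list[Detection]]:
    """Run inference; writes COCO-results JSON to ``out`` and YOLO-style
    text files next to it."""
    est = ckpt if isinstance(ckpt, WindowDetector) else load_detector(ckpt)
    dets = est.predict(images)
    records = []
    for img_id, per_img in enumerate(dets):
        for d in per_img:
            records.append({
                "image_id": img_id,
                "bbox": [float(v) for v in
                         (d.box[0], d.box[1], d.box[2] - d.box[0],
                          d.box[3] - d.box[1])],
                "category_id": int(d.class_id),
                "score": d.score,
            })
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(records, indent=1))
    write_detections_yolo(dets, [im.shape[:2] for im in images],
                          out.parent / (out.stem + "_txt"))
    return dets


def run_ablation(mask_ratios=None, cfg: RunConfig | None = None, seeds=(0,),
                 out: Path | str | None = None) -> list[dict]:
    """Full pretrain+train+evaluate per (mask ratio, seed); returns rows of
    validation metrics.  Ratios must be strictly increasing in (0,1);
    default grid 0.10 .. 0.80 in steps of 0.05."""
    if mask_ratios is None:
        mask_ratios = np.round(np.arange(0.10, 0.801, 0.05), 2).tolist()
    cfg = cfg if cfg is not None else RunConfig()
    ratios = list(mask_ratios)
    if len(ratios) < 2:
        raise ValueError("ablation needs at least two mask ratios")
    if any(not (0 < r < 1) for r in ratios) or any(
            b <= a for a, b in zip(ratios, ratios[1:])):
        raise ValueError("mask ratios must be strictly increasing within (0,1)")
    from .config import DetectorSection, GeneratorSection, PretrainSection

    rows = []
    for seed in seeds:
        run_cfg = RunConfig(
            seed=int(seed), out_dir=cfg.out_dir,
            generator=GeneratorSection(**cfg.to_dict()["generator"]),
            pretrain=PretrainSection(**cfg.to_dict()["pretrain"]),
            detector=DetectorSection(**{
                **cfg.to_dict()["detector"],
                "stage_depths": tuple(cfg.detector.stage_depths),
            }),
        )
        bundle = build_dataset(run_cfg)
        for ratio in ratios:
            run_cfg.pretrain.mask_ratio = float(ratio)
            mae, _ = run_pretrain(run_cfg, bundle,
                                  out=Path(run_cfg.out_dir) / f"ablate_{seed}_{ratio}")
            est, _ = run_train(run_cfg, mae, bundle,
                               out=Path(run_cfg.out_dir) / f"ablate_{seed}_{ratio}")
            report = run_evaluate(run_cfg, est, bundle, split="val", mae=mae)
            rows.append({
                "mask_ratio": float(ratio), "seed": int(seed),
                "val_ap50": report.ap50, "val_accuracy": report.accuracy,
                "val_map_composite": report.map_composite,
            })
    if out is not None:
        out = Path(out)
        out.parent.mkdir(parents=True, exist_ok=True)
        header = "mask_ratio,seed,val_ap50,val_accuracy,val_map_composite"
        lines = [header] + [
            f"{r['mask_ratio']},{r['seed']},{r['val_ap50']:.6f},"
            f"{r['val_accuracy']:.6f},{r['val_map_composite']:.6f}"
            for r in rows
        ]
        out.write_text("\n".join(lines) + "\n")
    return rows
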