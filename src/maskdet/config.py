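"""Run configuration: dataclasses with YAML round-trip and validation.

Optimizer defaults follow the training recipe the pipeline is built around:
Adam, learning rate 1e-4, batch size 32, dropout 0.5, L2 weight 5e-4.  Epoch
defaults are desk-scale (20 pretrain / 40 detector); production-scale values
are one config key away.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["GeneratorSection", "PretrainSection", "DetectorSection",
           "RunConfig", "load_config", "save_config"]


@dataclass
class GeneratorSection:
    n_images: int = 200
    width: int = 64
    height: int = 64
    n_classes: int = 1
    lesions_min: int = 1
    lesions_max: int = 3
    noise_sigma: float = 0.05
    size_mode: str = "small"


@dataclass
class PretrainSection:
    patch_size: int = 8
    mask_ratio: float = 0.75
    width: int = 64
    depth: int = 2
    heads: int = 4
    dec_width: int = 32
    dec_depth: int = 1
    mlp_ratio: float = 2.0
    loss_on: str = "all"
    epochs: int = 20
    batch_size: int = 32
    lr: float = 1e-4
    weight_decay: float = 5e-4
    dropout: float = 0.5


@dataclass
class DetectorSection:
    patch_size: int = 8
    base_channels: int = 64
    stage_depths: tuple[int, ...] = (1, 1)
    heads: int = 4
    window_size: int = 4
    mlp_ratio: float = 2.0
    neck_width: int = 64
    n_anchors: int = 3
    epochs: int = 40
    batch_size: int = 32
    lr: float = 1e-4
    weight_decay: float = 5e-4
    dropout: float = 0.5
    conf_thr: float = 0.25
    nms_iou: float = 0.45
    iou_weight: float = 1.0
    noobj_weight: float = 0.5
    backbone_init: str = "weights"  # weights | denoised | none


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    generator: GeneratorSection = field(default_factory=GeneratorSection)
    pretrain: PretrainSection = field(default_factory=PretrainSection)
    detector: DetectorSection = field(default_factory=DetectorSection)

    def validate(self) -> "RunConfig":
        g, p, d = self.generator, self.pretrain, self.detector
        if not (0.0 < p.mask_ratio < 1.0):
            raise ValueError(f"mask_ratio {p.mask_ratio} outside (0,1)")
        if p.lr <= 0 or d.lr <= 0:
            raise ValueError("learning rates must be positive")
        if g.n_images < 10:
            raise ValueError("generator.n_images must be >= 10")
        if not (0 <= g.lesions_min <= g.lesions_max <= 5):
            raise ValueError("lesions_min/max must satisfy 0<=min<=max<=5")
        if d.backbone_init not in ("weights", "denoised", "none"):
            raise ValueError(f"unknown backbone_init {d.backbone_init!r}")
        if p.patch_size != d.patch_size and d.backbone_init == "weights":
            raise ValueError(
                "weight-transfer init needs matching pretrain/detector patch size"
            )
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["detector"]["stage_depths"] = list(self.detector.stage_depths)
        return d


def _section(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "runs")),
        generator=_section(GeneratorSection, raw.get("generator", {})),
        pretrain=_section(PretrainSection, raw.get("pretrain", {})),
        detector=_section(DetectorSection, raw.get("detector", {})),
    )
    if "stage_depths" in raw.get("detector", {}):
        cfg.detector.stage_depths = tuple(raw["detector"]["stage_depths"])
    return cfg.validate()


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
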