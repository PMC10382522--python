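"""TIFF, YAML and CSV input/output for stacks, masks and configs."""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .focusmap import FocalStack, FocusScoreMap, ScanConfig
from .masking import InFocusMask
from .metrics import MetricParams
from .surrogate import TrainConfig, UNetSpec
from .synthetic import SyntheticStackSpec

__all__ = [
    "PipelineConfig",
    "read_stack",
    "write_stack",
    "write_score_maps",
    "read_score_maps",
    "write_mask_stack",
    "read_mask_stack",
    "write_history_csv",
    "write_profile_csv",
]

_SUPPORTED_DTYPES = ("uint8", "uint16", "float32", "float64")


def read_stack(path, pixel_size_um: float = 0.79, z_step_um: float = 8.55) -> FocalStack:
    """Read a multi-page grayscale TIFF as a focal stack.

    Z equals the page count (a single-page file gives Z = 1).  Physical
    metadata is taken from the JSON image description written by
    :func:`write_stack` when present, else from the keyword defaults.
    RGB / multi-sample files are rejected.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            axes = series.axes
            if "S" in axes or "C" in axes:
                raise ValueError(f"{path}: RGB/multi-channel TIFF is not supported; provide grayscale pages")
            data = series.asarray()
            desc = tif.pages[0].description
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF stack {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected Z x H x W grayscale pages, got shape {data.shape}")
    if desc:
        try:
            meta = json.loads(desc)
            pixel_size_um = float(meta.get("pixel_size_um", pixel_size_um))
            z_step_um = float(meta.get("z_step_um", z_step_um))
        except (ValueError, TypeError):
            pass
    return FocalStack(data, pixel_size_um=pixel_size_um, z_step_um=z_step_um, source_path=str(path))


def write_stack(stack: FocalStack, path, dtype=None) -> None:
    """Write a focal stack as a multi-page TIFF (one page per slice)."""
    data = stack.voxels if dtype is None else np.asarray(stack.voxels, dtype=dtype)
    if data.dtype.name not in _SUPPORTED_DTYPES:
        data = data.astype(np.float32)
    desc = json.dumps({"pixel_size_um": stack.pixel_size_um, "z_step_um": stack.z_step_um})
    # photometric is explicit so 3/4-slice uint8 stacks are not stored as RGB
    tifffile.imwrite(path, data, description=desc, photometric="minisblack")


def write_score_maps(maps: list, path) -> None:
    """Write per-slice focus-score maps as a float32 multi-page TIFF."""
    if not maps:
        raise ValueError("no maps to write")
    tifffile.imwrite(path, np.stack([m.values for m in maps]).astype(np.float32), photometric="minisblack")


def read_score_maps(path) -> list:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis]
    return [FocusScoreMap(data[z].astype(np.float64), slice_index=z) for z in range(data.shape[0])]


def write_mask_stack(masks: list, path) -> None:
    """Write masks as an 8-bit multi-page TIFF with values {0, 255}."""
    if not masks:
        raise ValueError("no masks to write")
    shape = masks[0].values.shape
    if any(m.values.shape != shape for m in masks):
        raise ValueError("all masks must share the same shape")
    tifffile.imwrite(path, np.stack([m.values for m in masks]).astype(np.uint8) * 255, photometric="minisblack")


def read_mask_stack(path, origin: str = "rule_based") -> list:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis]
    return [InFocusMask(data[z] > 0, slice_index=z, origin=origin) for z in range(data.shape[0])]


def write_history_csv(history: dict, path) -> None:
    """Per-epoch training curves as CSV (one row per epoch)."""
    keys = [k for k in ("train_loss", "train_iou", "val_loss", "val_iou") if history.get(k)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", *keys])
        for i in range(len(history["train_loss"])):
            writer.writerow([i, *[history[k][i] for k in keys]])


def write_profile_csv(profiles: dict, path) -> None:
    """Axial focus profiles (one column per metric, one row per slice)."""
    metrics = list(profiles)
    n = len(profiles[metrics[0]])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slice", *metrics])
        for z in range(n):
            writer.writerow([z, *[float(profiles[m][z]) for m in metrics]])


@dataclass
class PipelineConfig:
    """Bundle of all pipeline settings; round-trips losslessly via YAML."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    masking_nbins: int = 256
    training: TrainConfig = field(default_factory=TrainConfig)
    unet: UNetSpec = field(default_factory=UNetSpec)
    synthetic: SyntheticStackSpec = field(default_factory=SyntheticStackSpec)
    io: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)

        def listify(obj):
            if isinstance(obj, tuple):
                return [listify(v) for v in obj]
            if isinstance(obj, list):
                return [listify(v) for v in obj]
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            return obj

        return listify(d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        scan = d.get("scan", {})
        mp = scan.pop("metric_params", None) or {}
        if "laplacian_kernel" in mp:
            mp["laplacian_kernel"] = tuple(mp["laplacian_kernel"])
        scan = {
            **scan,
            **{k: tuple(scan[k]) for k in ("window_sizes", "strides") if k in scan},
            "metric_params": MetricParams(**mp),
        }
        training = dict(d.get("training", {}))
        if "loss_weights" in training:
            training["loss_weights"] = tuple(training["loss_weights"])
        unet = dict(d.get("unet", {}))
        for k in ("encoder_channels", "decoder_channels"):
            if k in unet:
                unet[k] = tuple(unet[k])
        return cls(
            scan=ScanConfig(**scan),
            masking_nbins=int(d.get("masking_nbins", 256)),
            training=TrainConfig(**training),
            unet=UNetSpec(**unet),
            synthetic=SyntheticStackSpec(**d.get("synthetic", {})),
            io=dict(d.get("io", {})),
            log_level=str(d.get("log_level", "INFO")),
        )

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
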