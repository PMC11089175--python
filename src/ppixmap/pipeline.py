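"""End-to-end orchestration: blue-light image(s) in, overlays + report out.

``process_image`` is the pure per-frame function (arrays in, arrays +
statistics out); ``run_pipeline`` wraps it with file I/O for a single image
or a directory (processed in lexicographic order). Every report embeds the
complete effective configuration and the package version, so any result is
reproducible from its own report file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .colorimetry import ColorimetryParams, extract_fluorescence, extract_fluorescence_hsv
from .imaging import read_image, write_gray, write_image, write_rgba
from .mapping import build_intensity_map, region_stats
from .margins import extract_safety_margin, overlay
from .masking import MaskParams, compute_mask, label_components
from .phantom import load_spec, render_phantom, save_spec

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "process_image", "run_pipeline", "run_phantom"]

IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


@dataclass
class PipelineConfig:
    """Full effective configuration of one pipeline run.

    Precedence when assembled by the CLI: command-line flags > config file >
    these defaults.
    """

    backend: str = "sub"  # "sub" (excitation subtraction) or "hsv" (hue-band gate)
    alpha: float = 1.0
    gain: float = 1.0
    hue_band: tuple[float, float] = (320.0, 30.0)
    sat_min: float = 0.3
    val_min: float = 0.1
    threshold: int = 30
    min_area: int = 25
    morph_radius: int = 1
    gamma: float = 0.6
    colormap: str = "inferno"
    im_alpha: float = 0.5
    sm_color: tuple[int, int, int] = (0, 255, 0)
    sm_width: int = 2
    sm_dilation: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.backend not in ("sub", "hsv"):
            raise ValueError(f"backend must be 'sub' or 'hsv', got {self.backend!r}")
        # delegate range checks to the stage parameter types
        ColorimetryParams(alpha=self.alpha, gain=self.gain)
        MaskParams(threshold=self.threshold, min_area=self.min_area,
                   morph_radius=self.morph_radius)
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hue_band"] = list(self.hue_band)
        d["sm_color"] = list(self.sm_color)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "hue_band" in d:
            d["hue_band"] = tuple(float(x) for x in d["hue_band"])
        if "sm_color" in d:
            d["sm_color"] = tuple(int(x) for x in d["sm_color"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def process_image(oi: np.ndarray, config: PipelineConfig | None = None) -> dict:
    """Run the full chain on one blue-light RGB frame.

    Returns a dict with keys ``afi`` (uint8 au image), ``mask`` (bool),
    ``labels`` (int32), ``intensity_map`` (IntensityMap), ``safety_margin``
    (SafetyMargin), ``overlay_im``/``overlay_sm``/``overlay`` (uint8 RGB
    composites) and ``regions`` (list of RegionStats).
    """
    if config is None:
        config = PipelineConfig()
    if config.backend == "sub":
        afi = extract_fluorescence(oi, ColorimetryParams(alpha=config.alpha, gain=config.gain))
    else:
        afi = extract_fluorescence_hsv(
            oi, hue_band=config.hue_band, sat_min=config.sat_min, val_min=config.val_min
        )
    mask = compute_mask(afi, MaskParams(threshold=config.threshold,
                                        min_area=config.min_area,
                                        morph_radius=config.morph_radius))
    labels, _ = label_components(mask)
    im = build_intensity_map(afi, mask, gamma=config.gamma, colormap=config.colormap)
    sm = extract_safety_margin(mask, dilation_radius=config.sm_dilation)
    common = dict(im_alpha=config.im_alpha, sm_color=config.sm_color, sm_width=config.sm_width)
    return {
        "afi": afi,
        "mask": mask,
        "labels": labels,
        "intensity_map": im,
        "safety_margin": sm,
        "overlay_im": overlay(oi, im, None, **common),
        "overlay_sm": overlay(oi, None, sm, **common),
        "overlay": overlay(oi, im, sm, **common),
        "regions": region_stats(afi, labels),
    }


def _write_bundle(oi: np.ndarray, result: dict, out_dir: Path, stem: str,
                  config: PipelineConfig) -> None:
    write_gray(result["afi"], out_dir / f"{stem}.afi.png")
    write_gray((result["mask"].astype(np.uint8) * 255), out_dir / f"{stem}.bmi.png")
    write_rgba(result["intensity_map"].rgba, out_dir / f"{stem}.im.png")
    write_image(result["overlay_im"], out_dir / f"{stem}.overlay_im.png")
    write_image(result["overlay_sm"], out_dir / f"{stem}.overlay_sm.png")
    write_image(result["overlay"], out_dir / f"{stem}.overlay.png")
    report = {
        "image": stem,
        "version": __version__,
        "config": config.to_dict(),
        "regions": [r.to_dict() for r in result["regions"]],
    }
    (out_dir / f"{stem}.regions.json").write_text(json.dumps(report, indent=2) + "\n")
    (out_dir / f"{stem}.margins.json").write_text(
        json.dumps(result["safety_margin"].to_geojson_dict()) + "\n"
    )


def run_pipeline(input_path: str | Path, out_dir: str | Path,
                 config: PipelineConfig | None = None) -> int:
    """Process one image or every image in a directory; return failure count.

    Raises FileNotFoundError when no image is found at all. Per-image read
    failures are logged and processing continues with the remaining images.
    """
    if config is None:
        config = PipelineConfig()
    input_path = Path(input_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if input_path.is_dir():
        images = sorted(p for p in input_path.iterdir()
                        if p.suffix.lower() in IMAGE_SUFFIXES)
    elif input_path.exists():
        images = [input_path]
    else:
        raise FileNotFoundError(f"no such input: {input_path}")
    if not images:
        raise FileNotFoundError(f"no images found in {input_path}")

    failures = 0
    for path in images:
        try:
            oi = read_image(path)
            result = process_image(oi, config)
            _write_bundle(oi, result, out_dir, path.stem, config)
            log.info("processed %s: %d region(s)", path.name, len(result["regions"]))
        except Exception:
            failures += 1
            log.exception("failed to process %s", path)
    return failures


def run_phantom(spec_path: str | Path, out_dir: str | Path) -> None:
    """Render a phantom spec file to white.png / blue.png / truth.png.

    The fully-resolved spec (defaults filled) is echoed to
    ``spec.resolved.yaml`` next to the images.
    """
    spec = load_spec(spec_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    white, blue, truth = render_phantom(spec)
    write_image(white, out_dir / "white.png")
    write_image(blue, out_dir / "blue.png")
    if truth.max() > 255:
        raise ValueError("more than 255 lesions cannot be stored in an 8-bit truth image")
    write_gray(truth.astype(np.uint8), out_dir / "truth.png")
    save_spec(spec, out_dir / "spec.resolved.yaml")
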