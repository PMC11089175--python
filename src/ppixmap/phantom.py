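"""Synthetic gelatin brain-phantom renderer with ground truth.

The generator emulates gel-based brain phantoms used to validate
fluorescence quantification at the bench: a gelatin background with embedded
agarose tumor-surrogate masses of known PpIX concentration, photographed
under white and blue illumination. It exists so the whole pipeline can be
exercised against known ground truth without any real surgical images.

Emission model
--------------
Per lesion, the red-channel signal at the lesion core is

    emission(c, d) = 255 * (1 - exp(-k_sat * c)) * exp(-mu * d)   [au]

a saturating exponential in concentration ``c`` (µg/mL) times Beer-Lambert
attenuation through ``d`` mm of overlying gelatin. This minimal form
reproduces the two phenomena that matter for testing: the camera's top of
scale saturates at high concentration, and a deeper, more concentrated
lesion can quantify *below* a shallower, weaker one (the depth confound).
The constants are nominal, not fitted to any physical gel: k_sat = 0.5
(µg/mL)^-1 puts 5 µg/mL — the upper end of intratumoral PpIX — near 92% of
full scale; mu = 0.6 mm^-1 makes a few millimetres of gelatin visibly
attenuating.

Rendering
---------
Blue-light frame: a bluish background (reflected excitation; translucent
yellowish gelatin or the opaque pinkish variant), with each lesion blended
in as pure red emission using a smooth elliptical edge falloff; overlapping
lesions resolve to the maximum emission per pixel. Optional specular
highlight blobs (translucent style) stress-test the colorimetry's blue
rejection. White-light frame: lesions appear only as subtle texture —
fluorescence is invisible under white light. Gaussian pixel noise is added
per channel and clamped. All randomness derives from the spec seed;
identical spec gives bit-identical images.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .imaging import round_half_up

__all__ = [
    "Lesion",
    "PhantomSpec",
    "ppix_emission",
    "render_phantom",
    "load_spec",
    "save_spec",
    "BACKGROUND_STYLES",
]

# (blue-light color, white-light color) per background style, RGB uint8.
# Blue-light backgrounds keep R below max(G, B) so background fluorescence
# reads exactly 0 au under the default subtraction backend.
BACKGROUND_STYLES: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]] = {
    "translucent-yellowish": ((18, 32, 150), (225, 205, 150)),
    "opaque-pinkish": ((55, 38, 165), (230, 170, 170)),
}


@dataclass(frozen=True)
class Lesion:
    """An elliptical tumor-surrogate mass.

    center        : (row, col) pixels.
    radii         : (r1, r2) ellipse semi-axes in pixels, each >= 1.
    angle         : ellipse rotation, degrees.
    concentration : PpIX concentration, µg/mL, >= 0.
    depth         : thickness of overlying gelatin, mm, >= 0.
    """

    center: tuple[float, float]
    radii: tuple[float, float]
    angle: float = 0.0
    concentration: float = 0.0
    depth: float = 0.0

    def __post_init__(self) -> None:
        if min(self.radii) < 1:
            raise ValueError(f"lesion radii must be >= 1 pixel, got {self.radii}")
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic phantom scene.

    shape          : (height, width) pixels.
    background     : one of BACKGROUND_STYLES.
    lesions        : tumor-surrogate masses, labelled 1..N in list order.
    k_sat          : emission saturation constant, (µg/mL)^-1, > 0.
    mu             : gelatin attenuation coefficient, mm^-1, >= 0.
    noise_sd       : Gaussian camera-noise standard deviation, au, >= 0.
    seed           : integer seed driving all randomness.
    edge_softness  : fractional width of the lesion edge falloff band (of the
                     normalized ellipse radius).
    n_highlights   : specular highlight blobs (translucent style only).
    model_scale    : cosmetic metadata ("1:25", "1:1"); geometry is fully
                     determined by the pixel parameters.
    """

    shape: tuple[int, int] = (256, 256)
    background: str = "translucent-yellowish"
    lesions: list[Lesion] = field(default_factory=list)
    k_sat: float = 0.5
    mu: float = 0.6
    noise_sd: float = 3.0
    seed: int = 0
    edge_softness: float = 0.05
    n_highlights: int = 0
    model_scale: str = "1:1"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.background not in BACKGROUND_STYLES:
            raise ValueError(
                f"background: unknown style {self.background!r}; "
                f"expected one of {sorted(BACKGROUND_STYLES)}"
            )
        if self.k_sat <= 0:
            raise ValueError(f"k_sat: must be > 0, got {self.k_sat}")
        if self.mu < 0:
            raise ValueError(f"mu: must be >= 0, got {self.mu}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd: must be >= 0, got {self.noise_sd}")
        if not 0 < self.edge_softness < 1:
            raise ValueError(f"edge_softness: must be in (0, 1), got {self.edge_softness}")
        if min(self.shape) < 1:
            raise ValueError(f"shape: dimensions must be >= 1, got {self.shape}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["lesions"] = [
            {
                "center": list(l.center),
                "radii": list(l.radii),
                "angle": l.angle,
                "concentration": l.concentration,
                "depth": l.depth,
            }
            for l in self.lesions
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        lesions = [
            Lesion(
                center=tuple(l["center"]),
                radii=tuple(l["radii"]),
                angle=float(l.get("angle", 0.0)),
                concentration=float(l.get("concentration", 0.0)),
                depth=float(l.get("depth", 0.0)),
            )
            for l in d.pop("lesions", [])
        ]
        if "shape" in d:
            d["shape"] = tuple(int(x) for x in d["shape"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown phantom spec field(s): {sorted(unknown)}")
        return cls(lesions=lesions, **d)


def load_spec(path: str | Path) -> PhantomSpec:
    """Load a PhantomSpec from a YAML (or JSON, a YAML subset) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: phantom spec must be a mapping, got {type(data).__name__}")
    return PhantomSpec.from_dict(data)


def save_spec(spec: PhantomSpec, path: str | Path) -> None:
    """Write a spec, with all defaults filled in, as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def ppix_emission(
    concentration: float, depth: float, k_sat: float = 0.5, mu: float = 0.6
) -> float:
    """Core emission in au: 255 * (1 - exp(-k_sat*c)) * exp(-mu*d), in [0, 255)."""
    if concentration < 0 or depth < 0:
        raise ValueError("concentration and depth must be >= 0")
    return 255.0 * (1.0 - math.exp(-k_sat * concentration)) * math.exp(-mu * depth)


def _lesion_falloff(spec: PhantomSpec, lesion: Lesion) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel edge falloff weight in [0, 1] and the inside-ellipse truth."""
    h, w = spec.shape
    rows, cols = np.indices((h, w), dtype=np.float64)
    dr = rows - lesion.center[0]
    dc = cols - lesion.center[1]
    th = math.radians(lesion.angle)
    u = dr * math.cos(th) + dc * math.sin(th)
    v = -dr * math.sin(th) + dc * math.cos(th)
    rho = np.sqrt((u / lesion.radii[0]) ** 2 + (v / lesion.radii[1]) ** 2)
    inside = rho <= 1.0
    s = spec.edge_softness
    t = np.clip((1.0 - rho) / s, 0.0, 1.0)  # 0 at the rim, 1 at rho <= 1 - s
    weight = t * t * (3.0 - 2.0 * t)  # cubic smoothstep
    return weight, inside


def render_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render (white-light image, blue-light image, ground-truth labels).

    Images are (H, W, 3) uint8; truth is (H, W) int32 with lesion pixels
    labelled 1..N in list order (overlaps resolved to the lesion with the
    stronger emission at that pixel) and background 0.
    """
    spec.validate()
    h, w = spec.shape
    for i, les in enumerate(spec.lesions):
        r, c = les.center
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"lesion {i + 1} center {les.center} outside image bounds {spec.shape}")

    bg_blue, bg_white = (np.array(c, dtype=np.float64) for c in BACKGROUND_STYLES[spec.background])
    blue = np.broadcast_to(bg_blue, (h, w, 3)).copy()
    white = np.broadcast_to(bg_white, (h, w, 3)).copy()
    truth = np.zeros((h, w), dtype=np.int32)

    best_em = np.zeros((h, w), dtype=np.float64)  # winning emission * falloff
    best_w = np.zeros((h, w), dtype=np.float64)
    for i, les in enumerate(spec.lesions):
        weight, inside = _lesion_falloff(spec, les)
        em = ppix_emission(les.concentration, les.depth, spec.k_sat, spec.mu)
        signal = weight * em
        win = signal > best_em
        best_em = np.where(win, signal, best_em)
        best_w = np.where(win, weight, best_w)
        # truth is geometric (the mass itself), independent of emission strength
        claim = inside & (win | (truth == 0))
        truth[claim] = i + 1

    # Blue light: blend toward pure red emission; strong PpIX emission
    # replaces the reflected excitation at the lesion core.
    wgt = best_w[:, :, None]
    target = np.zeros((h, w, 3), dtype=np.float64)
    target[:, :, 0] = np.where(best_w > 0, best_em / np.maximum(best_w, 1e-12), 0.0)
    blue = (1.0 - wgt) * blue + wgt * target
    # White light: lesions only as subtle darker texture, no fluorescence.
    white = white - wgt * 0.12 * bg_white

    rng = np.random.default_rng(spec.seed)
    if spec.background == "translucent-yellowish" and spec.n_highlights > 0:
        rows, cols = np.indices((h, w), dtype=np.float64)
        for _ in range(spec.n_highlights):
            cr = rng.uniform(0, h)
            cc = rng.uniform(0, w)
            rad = rng.uniform(2.0, max(3.0, 0.03 * min(h, w)))
            blob = np.clip(1.0 - np.hypot(rows - cr, cols - cc) / rad, 0.0, 1.0)[:, :, None]
            blue = (1.0 - blob) * blue + blob * np.array([205.0, 215.0, 255.0])
            white = (1.0 - blob) * white + blob * np.array([250.0, 250.0, 250.0])
    if spec.noise_sd > 0:
        blue = blue + rng.normal(0.0, spec.noise_sd, size=blue.shape)
        white = white + rng.normal(0.0, spec.noise_sd, size=white.shape)

    blue_u8 = round_half_up(np.clip(blue, 0.0, 255.0)).astype(np.uint8)
    white_u8 = round_half_up(np.clip(white, 0.0, 255.0)).astype(np.uint8)
    return white_u8, blue_u8, truth
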