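"""Synthetic stimulus generation.

Three stimulus families drive the probing experiments:

* colored-word rasters -- the word "color" in a random font at a random
  position on a mid-grey background, glyph pixels carrying a single
  spectrum hue;
* multi-word scenes -- three target words sharing one hue plus two
  randomly colored distractor words on a half-brightness random-hue
  background;
* enclosure-filled outline shapes -- closed line drawings whose
  "enclosed" pixels (a drawn line to the left, right, above and below)
  are flooded with a single hue, lines redrawn on top.

Glyphs are rendered with binary (non-anti-aliased) coverage so that glyph
pixels carry exactly the target color; all generators are pure functions
of (config, rng state).
"""

from __future__ import annotations

import functools
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .colorspace import hue_to_rgb, rgb8

__all__ = [
    "RASTER_SIZE",
    "MID_GREY",
    "IMAGENET_MEAN",
    "IMAGENET_SD",
    "default_font_pool",
    "WordStimulusConfig",
    "render_word_stimulus",
    "render_multiword_stimulus",
    "enclosure_mask",
    "render_filled_shape",
    "generate_synthetic_outline",
    "OUTLINE_FAMILIES",
    "normalize_image",
    "denormalize_image",
    "save_png",
    "load_png",
]

RASTER_SIZE = 224
MID_GREY = (128, 128, 128)

# conventional per-channel normalization constants (configurable)
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_SD = (0.229, 0.224, 0.225)


def default_font_pool() -> tuple:
    """Five scalable font faces resolved from matplotlib's bundled set."""
    import matplotlib

    ttf = os.path.join(matplotlib.get_data_path(), "fonts", "ttf")
    names = (
        "DejaVuSans.ttf",
        "DejaVuSans-Bold.ttf",
        "DejaVuSans-Oblique.ttf",
        "DejaVuSerif.ttf",
        "DejaVuSerif-Bold.ttf",
    )
    return tuple(os.path.join(ttf, n) for n in names)


@functools.lru_cache(maxsize=128)
def _glyph_mask(font_path: str, word: str, font_size: int) -> np.ndarray:
    """Boolean coverage mask of ``word`` at ``font_size`` (binary rendering)."""
    font = ImageFont.truetype(font_path, font_size)
    mask = font.getmask(word, mode="1")
    w, h = mask.size
    arr = np.asarray(mask, dtype=np.uint8).reshape(h, w)
    return arr > 0


@dataclass(frozen=True)
class WordStimulusConfig:
    word: str = "color"
    font_size: int = 40
    fonts: tuple = field(default_factory=default_font_pool)
    background: tuple = MID_GREY
    size: int = RASTER_SIZE

    def __post_init__(self):
        if len(self.fonts) < 1:
            raise ValueError("font pool must contain at least one font")


def _place_word(
    img: np.ndarray,
    hue: float,
    cfg: WordStimulusConfig,
    rng: np.random.Generator,
    value: float = 1.0,
) -> np.ndarray:
    """Draw one word in-place; returns the boolean glyph mask in image coords."""
    font = cfg.fonts[rng.integers(len(cfg.fonts))]
    mask = _glyph_mask(font, cfg.word, cfg.font_size)
    mh, mw = mask.shape
    if mh > cfg.size or mw > cfg.size:
        raise ValueError(
            f"word {cfg.word!r} at size {cfg.font_size} does not fit the raster"
        )
    y0 = int(rng.integers(cfg.size - mh + 1))
    x0 = int(rng.integers(cfg.size - mw + 1))
    color = rgb8(hue, value)
    img[y0 : y0 + mh, x0 : x0 + mw][mask] = color
    full = np.zeros(img.shape[:2], dtype=bool)
    full[y0 : y0 + mh, x0 : x0 + mw] = mask
    return full


def render_word_stimulus(
    hue: float, cfg: WordStimulusConfig | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Single word of the given hue, randomly positioned on the background.

    Returns an ``(size, size, 3)`` uint8 raster containing exactly two
    colors: the glyph color and the background.
    """
    cfg = cfg or WordStimulusConfig()
    rng = rng if rng is not None else np.random.default_rng()
    img = np.empty((cfg.size, cfg.size, 3), dtype=np.uint8)
    img[...] = np.asarray(cfg.background, dtype=np.uint8)
    _place_word(img, hue, cfg, rng)
    return img


def render_multiword_stimulus(
    target_hue: float,
    cfg: WordStimulusConfig | None = None,
    rng: np.random.Generator | None = None,
    n_targets: int = 3,
    n_distractors: int = 2,
    background_value: float = 0.5,
    grey_distractors: bool = False,
    background_value_range: tuple | None = None,
    return_info: bool = False,
):
    """Three target words plus two random distractors on a dimmed random background.

    Target words carry ``target_hue`` at full saturation/brightness; the
    two distractor hues and the background hue are drawn uniformly from
    the spectrum (background at 50% brightness).  Distractors are drawn
    last, on top of the targets.

    Two experimental luminance-variation flags decouple color from
    luminance cues: ``grey_distractors`` renders the distractor words as
    achromatic greys at random luminances, and ``background_value_range``
    draws the background brightness uniformly from ``(lo, hi)`` instead
    of fixing it.
    """
    cfg = cfg or WordStimulusConfig()
    rng = rng if rng is not None else np.random.default_rng()
    bg_hue = float(rng.uniform())
    if background_value_range is not None:
        background_value = float(rng.uniform(*background_value_range))
    img = np.empty((cfg.size, cfg.size, 3), dtype=np.uint8)
    img[...] = rgb8(bg_hue, background_value)
    for _ in range(n_targets):
        _place_word(img, target_hue, cfg, rng)
    distractor_hues = []
    for _ in range(n_distractors):
        if grey_distractors:
            v = float(rng.uniform(0.2, 0.9))
            grey = int(np.floor(v * 255 + 0.5))
            mask_img = np.zeros_like(img)
            glyph = _place_word(mask_img, 0.0, cfg, rng)
            img[glyph] = grey
            distractor_hues.append(None)
        else:
            dh = float(rng.uniform())
            distractor_hues.append(dh)
            _place_word(img, dh, cfg, rng)
    if return_info:
        return img, {"background_hue": bg_hue, "background_value": background_value,
                     "distractor_hues": distractor_hues}
    return img


def enclosure_mask(outline: np.ndarray) -> np.ndarray:
    """Pixels enclosed by drawn lines on all four sides.

    A pixel (x, y) is enclosed iff some line pixel exists strictly to its
    left in its row, strictly to its right, strictly above in its column
    and strictly below.  Line pixels themselves are excluded.
    """
    line = np.asarray(outline, dtype=bool)
    if line.ndim != 2:
        raise ValueError("outline must be a 2D boolean raster")
    acc_l = np.logical_or.accumulate(line, axis=1)
    acc_r = np.logical_or.accumulate(line[:, ::-1], axis=1)[:, ::-1]
    acc_u = np.logical_or.accumulate(line, axis=0)
    acc_d = np.logical_or.accumulate(line[::-1, :], axis=0)[::-1, :]
    # strict: shift the accumulations by one pixel away from the border
    left = np.zeros_like(line)
    left[:, 1:] = acc_l[:, :-1]
    right = np.zeros_like(line)
    right[:, :-1] = acc_r[:, 1:]
    above = np.zeros_like(line)
    above[1:, :] = acc_u[:-1, :]
    below = np.zeros_like(line)
    below[:-1, :] = acc_d[1:, :]
    return left & right & above & below & ~line


def render_filled_shape(
    outline: np.ndarray,
    fill_hue: float,
    line_color: tuple = (0, 0, 0),
    background: tuple = MID_GREY,
) -> np.ndarray:
    """Fill the enclosed area with ``fill_hue`` and redraw the lines on top."""
    line = np.asarray(outline, dtype=bool)
    mask = enclosure_mask(line)
    img = np.empty((*line.shape, 3), dtype=np.uint8)
    img[...] = np.asarray(background, dtype=np.uint8)
    img[mask] = rgb8(fill_hue)
    img[line] = np.asarray(line_color, dtype=np.uint8)
    return img


# 14 parametric closed-outline families: one per object class in the
# colored-objects experiment.  The geometry itself is incidental; what
# matters is a closed stroke with a large enclosed interior.
OUTLINE_FAMILIES = (
    "ellipse",
    "rectangle",
    "triangle",
    "diamond",
    "pentagon",
    "hexagon",
    "star5",
    "star6",
    "blob3",
    "blob4",
    "blob5",
    "flower4",
    "flower5",
    "heart",
)


def _family_points(family: str, rng: np.random.Generator, n: int = 180) -> np.ndarray:
    """Closed path vertices in unit coordinates, mildly randomized per draw."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    rot = rng.uniform(0, 2 * np.pi)
    if family == "ellipse":
        a, b = rng.uniform(0.55, 0.95), rng.uniform(0.35, 0.7)
        x, y = a * np.cos(t), b * np.sin(t)
    elif family in ("rectangle", "triangle", "diamond", "pentagon", "hexagon"):
        k = {"rectangle": 4, "triangle": 3, "diamond": 4, "pentagon": 5, "hexagon": 6}[family]
        phase = np.pi / 4 if family == "rectangle" else np.pi / 2
        verts = np.stack(
            [np.cos(2 * np.pi * np.arange(k) / k + phase),
             np.sin(2 * np.pi * np.arange(k) / k + phase)],
            axis=1,
        ) * rng.uniform(0.6, 0.95)
        if family == "rectangle":
            verts[:, 1] *= rng.uniform(0.5, 0.8)
        pts = []
        for i in range(k):
            p, q = verts[i], verts[(i + 1) % k]
            for s in np.linspace(0, 1, n // k, endpoint=False):
                pts.append(p + s * (q - p))
        x, y = np.array(pts).T
    elif family.startswith("star"):
        k = int(family[4:])
        r = np.where(np.floor(k * t / np.pi).astype(int) % 2 == 0,
                     rng.uniform(0.8, 0.95), rng.uniform(0.4, 0.55))
        x, y = r * np.cos(t), r * np.sin(t)
    elif family.startswith("blob"):
        k = int(family[4:])
        amp = rng.uniform(0.08, 0.18)
        phase = rng.uniform(0, 2 * np.pi)
        r = 0.7 * (1.0 + amp * np.cos(k * t + phase))
        x, y = r * np.cos(t), r * np.sin(t)
    elif family.startswith("flower"):
        k = int(family[6:])
        amp = rng.uniform(0.2, 0.3)
        r = 0.62 * (1.0 + amp * np.cos(k * t))
        x, y = r * np.cos(t), r * np.sin(t)
    elif family == "heart":
        x = 0.05 * (16 * np.sin(t) ** 3)
        y = 0.05 * (13 * np.cos(t) - 5 * np.cos(2 * t) - 2 * np.cos(3 * t) - np.cos(4 * t))
    else:
        raise ValueError(f"unknown shape family {family!r}")
    c, s = np.cos(rot), np.sin(rot)
    return np.stack([c * x - s * y, s * x + c * y], axis=1)


def generate_synthetic_outline(
    family: str,
    rng: np.random.Generator,
    size: int = RASTER_SIZE,
    thickness: int = 4,
    max_retries: int = 10,
) -> np.ndarray:
    """Rasterize a closed stroke from a shape family at the given thickness.

    Guarantees that at least 5% (and at most 80%) of the raster becomes
    enclosed, regenerating internally up to ``max_retries``.
    """
    if family not in OUTLINE_FAMILIES:
        raise ValueError(f"unknown shape family {family!r}")
    for _ in range(max_retries):
        pts = _family_points(family, rng)
        scale = size * rng.uniform(0.32, 0.44)
        cx = size / 2 + rng.uniform(-0.05, 0.05) * size
        cy = size / 2 + rng.uniform(-0.05, 0.05) * size
        xy = np.clip(pts * scale + [cx, cy], thickness, size - 1 - thickness)
        im = Image.new("L", (size, size), 0)
        draw = ImageDraw.Draw(im)
        coords = [tuple(p) for p in xy] + [tuple(xy[0])]
        draw.line(coords, fill=255, width=thickness, joint="curve")
        line = np.asarray(im) > 0
        area = enclosure_mask(line).mean()
        if 0.05 <= area <= 0.80:
            return line
    raise RuntimeError(f"could not generate a valid {family!r} outline")


def normalize_image(img: np.ndarray, mean=IMAGENET_MEAN, sd=IMAGENET_SD) -> np.ndarray:
    """Per-channel ``(value/255 - mean)/sd``; invertible given the constants."""
    mean = np.asarray(mean, dtype=np.float32)
    sd = np.asarray(sd, dtype=np.float32)
    if np.any(sd == 0):
        raise ValueError("zero standard deviation in normalization constants")
    return (np.asarray(img, dtype=np.float32) / 255.0 - mean) / sd


def denormalize_image(arr: np.ndarray, mean=IMAGENET_MEAN, sd=IMAGENET_SD) -> np.ndarray:
    mean = np.asarray(mean, dtype=np.float32)
    sd = np.asarray(sd, dtype=np.float32)
    return (np.asarray(arr, dtype=np.float32) * sd + mean) * 255.0


def render_word_batch(outdir, bands, n_per_class: int, seed: int = 0,
                      cfg: WordStimulusConfig | None = None):
    """Render a labeled word-stimulus batch to PNG files with a CSV manifest.

    ``bands`` is any object with a ``bands`` sequence (e.g. a band set);
    the manifest records filename, class index, sampled hue and the seed.
    Returns the manifest as a DataFrame.
    """
    import pandas as pd

    cfg = cfg or WordStimulusConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    records = []
    for cls, band in enumerate(bands.bands):
        for j in range(n_per_class):
            hue = float(band.sample(rng))
            img = render_word_stimulus(hue, cfg, rng)
            name = f"word_c{cls}_{j:04d}.png"
            save_png(img, outdir / name)
            records.append({"filename": name, "class_index": cls,
                            "hue": hue, "seed": seed})
    manifest = pd.DataFrame(records)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def save_png(img: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8)).save(path)


def load_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))
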