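"""Image pre-processing variants feeding the OCR ensemble.

Four cumulative variants of each label image are produced, each of which can
help (or hurt) a given OCR engine on a given label:

* ``V1_none``     — the unmodified grayscale image;
* ``V2_deskew``   — slight Gaussian blur, isotropic rescale, upright
  orientation (multiples of 90°), then fine deskew;
* ``V3_binarize`` — all of V2, then Sauvola adaptive binarization;
* ``V4_denoise``  — all of V3, then speck removal and small-hole filling.

Grayscale pixels are intensities in [0, 255] (dark ink on light paper);
binary images hold {0, 1} with 1 = ink.  Every transform appends an entry to
the image's provenance list so any output can be audited.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_sauvola
from skimage.morphology import remove_small_objects

__all__ = [
    "PreprocVariant",
    "PreprocParams",
    "LabelImage",
    "apply_variant",
    "blur_scale",
    "orient_upright",
    "deskew",
    "sauvola_binarize",
    "despeckle_fill",
]


class PreprocVariant(str, Enum):
    V1_none = "V1_none"
    V2_deskew = "V2_deskew"
    V3_binarize = "V3_binarize"
    V4_denoise = "V4_denoise"


@dataclass(frozen=True)
class PreprocParams:
    """Tunable knobs for the pre-processing chain (all configurable).

    ``blur_sigma`` is the Gaussian sigma in pixels; ``target_long_side`` the
    rescale target many OCR engines prefer; Sauvola's ``window``/``k``/``r``
    follow the usual adaptive-threshold parametrization; ``min_speck`` /
    ``min_hole`` are component areas in pixels; deskew searches
    ±``max_skew_deg`` at ``skew_step_deg`` resolution.
    """

    blur_sigma: float = 0.5
    target_long_side: int = 4096
    sauvola_window: int = 31
    sauvola_k: float = 0.2
    sauvola_r: float = 128.0
    min_speck: int = 4
    min_hole: int = 4
    max_skew_deg: float = 10.0
    skew_step_deg: float = 0.1


@dataclass
class LabelImage:
    """A (possibly pre-processed) label image plus its transform provenance.

    ``pixels`` is a 2-D float array: grayscale intensities in [0, 255], or
    {0, 1} after binarization.  ``meta`` carries fixture ground truth
    (rendered text, skew, speckle count) when the image came from the
    synthetic renderer.
    """

    pixels: np.ndarray
    label_id: str = ""
    variant_applied: PreprocVariant = PreprocVariant.V1_none
    provenance: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a non-empty 2-D array")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(np.unique(self.pixels), (0.0, 1.0)).all())

    def with_pixels(self, pixels: np.ndarray, step: str, **params) -> "LabelImage":
        """Copy with new pixels and one provenance entry appended."""
        return LabelImage(
            pixels=pixels,
            label_id=self.label_id,
            variant_applied=self.variant_applied,
            provenance=self.provenance + [{"step": step, **params}],
            meta=dict(self.meta),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "LabelImage":
        """Read PNG/JPEG/TIFF, converting color to luminance."""
        with Image.open(path) as im:
            gray = im.convert("L")
            arr = np.asarray(gray, dtype=float)
        return cls(arr, label_id=Path(path).stem,
                   provenance=[{"step": "load", "path": str(path)}])

    def to_file(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the image (and a provenance JSON sidecar for audit)."""
        arr = self.pixels
        if self.is_binary:
            arr = (1 - arr) * 255  # ink back to dark-on-light for viewing
        Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8)).save(path)
        if sidecar:
            side = Path(path).with_suffix(Path(path).suffix + ".provenance.json")
            side.write_text(json.dumps(
                {"label_id": self.label_id,
                 "variant": self.variant_applied.value,
                 "provenance": self.provenance}, indent=2))


def _ink(img: LabelImage) -> np.ndarray:
    """Foreground (ink) weight map: high where the page is dark."""
    if img.is_binary:
        return img.pixels.astype(float)
    return (255.0 - img.pixels) / 255.0


def blur_scale(
    img: LabelImage,
    blur_sigma: float = 0.5,
    target_long_side: int = 4096,
) -> LabelImage:
    """Gaussian blur then isotropic rescale of the longer side.

    Zero sigma skips the blur; a target equal to the current long side skips
    the resize, so the operation degrades to the identity.
    """
    if blur_sigma < 0 or target_long_side <= 0:
        raise ValueError("blur_sigma must be >= 0 and target_long_side > 0")
    out = img.pixels
    if blur_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=blur_sigma, mode="reflect")
    long_side = max(out.shape)
    if long_side != target_long_side:
        scale = target_long_side / long_side
        new_w = max(1, round(out.shape[1] * scale))
        new_h = max(1, round(out.shape[0] * scale))
        pil = Image.fromarray(np.clip(out, 0, 255).astype(np.uint8))
        out = np.asarray(pil.resize((new_w, new_h), Image.LANCZOS), dtype=float)
    return img.with_pixels(out, "blur_scale", blur_sigma=blur_sigma,
                           target_long_side=target_long_side)


def _row_profile_scores(ink: np.ndarray) -> tuple[float, float]:
    """(line contrast, bottom-heaviness) of the horizontal text-line profile.

    Line contrast is the variance of row sums — maximal when text lines run
    horizontally.  Bottom-heaviness exploits Latin typography: within a text
    line most mass sits between baseline and x-height with ascenders above,
    so in an upright image the lower half of each line run carries more ink
    than the upper half.
    """
    rows = ink.sum(axis=1)
    contrast = float(np.var(rows))
    if rows.max() <= 0:
        return contrast, 0.0
    thresh = 0.2 * rows.max()
    on = rows > thresh
    heaviness = 0.0
    i = 0
    n = len(on)
    while i < n:
        if not on[i]:
            i += 1
            continue
        j = i
        while j < n and on[j]:
            j += 1
        run = rows[i:j]
        mid = len(run) // 2
        heaviness += float(run[mid:].sum() - run[:mid].sum())
        i = j
    return contrast, heaviness


def orient_upright(img: LabelImage) -> tuple[LabelImage, int, bool]:
    """Rotate by a multiple of 90° so text reads left-to-right, upright.

    Returns ``(rotated image, rotation, low_confidence)`` where ``rotation``
    in {0, 90, 180, 270} is the clockwise rotation the input had relative to
    upright (so the output is the input rotated counterclockwise by it... in
    array terms, ``np.rot90`` applied ``rotation/90`` times).  A blank page
    yields rotation 0 with the low-confidence flag set.
    """
    ink0 = _ink(img)
    if ink0.sum() < 1e-9:
        return img.with_pixels(img.pixels, "orient", rotation=0), 0, True
    cands = {}
    for k in range(4):
        rotated = np.rot90(ink0, k)
        cands[k] = _row_profile_scores(rotated)
    # pick the axis (0/180 vs 90/270) by line contrast, then the direction
    # within the axis by bottom-heaviness of the line runs
    axis0 = max(cands[0][0], cands[2][0])
    axis1 = max(cands[1][0], cands[3][0])
    ks = (0, 2) if axis0 >= axis1 else (1, 3)
    k = max(ks, key=lambda q: cands[q][1])
    out = np.rot90(img.pixels, k)
    rotation = (k * 90) % 360
    low_conf = max(axis0, axis1) <= 0
    return img.with_pixels(out, "orient", rotation=rotation), rotation, low_conf


def _rotate_keep(arr: np.ndarray, angle_deg: float, cval: float) -> np.ndarray:
    return ndimage.rotate(arr, angle_deg, reshape=False, order=1,
                          mode="constant", cval=cval)


def deskew(
    img: LabelImage,
    max_angle: float = 10.0,
    step: float = 0.1,
) -> tuple[LabelImage, float]:
    """Estimate and undo small text-line skew.

    The skew estimate maximizes the variance of the row-projection profile
    over a candidate-angle grid (coarse 1° pass, then ``step``-resolution
    refinement), evaluated on a downsampled copy for speed.  Returns the
    corrected image and the estimated skew in degrees (positive =
    counterclockwise, matching PIL's rotation convention).  A blank image
    reports 0°.
    """
    ink = _ink(img)
    if ink.sum() < 1e-9:
        return img.with_pixels(img.pixels, "deskew", angle=0.0), 0.0
    # search on a copy no larger than ~512 px on the long side
    factor = max(1, int(np.ceil(max(ink.shape) / 512)))
    small = ink[::factor, ::factor] if factor > 1 else ink
    fill = float(small.mean())  # neutral corner fill: no artificial contrast

    def score(theta: float) -> float:
        if theta == 0.0:
            return float(np.var(small.sum(axis=1)))
        return float(np.var(_rotate_keep(small, theta, fill).sum(axis=1)))

    def argbest(angles) -> float:
        scored = [(score(t), t) for t in angles]
        top = max(s for s, _ in scored)
        # among near-ties (featureless images score ~equal everywhere),
        # prefer the smallest rotation
        return min((t for s, t in scored if s >= top - 1e-9 * max(top, 1.0)),
                   key=abs)

    coarse = np.arange(-max_angle, max_angle + 1e-9, 1.0)
    best = argbest(coarse)
    fine = np.arange(best - 1.0, best + 1.0 + 1e-9, step)
    best = float(argbest(fine))
    # ndimage rotates the opposite way from PIL's on-screen convention, so
    # an image rendered with skew s is re-aligned by ndimage-rotating by -s;
    # the estimated skew (PIL convention, positive = CCW) is -best.
    angle = -best
    if abs(angle) < step / 2:
        return img.with_pixels(img.pixels, "deskew", angle=0.0), 0.0
    cval = 255.0 if not img.is_binary else 0.0
    fixed = _rotate_keep(img.pixels, best, cval)
    if img.is_binary:
        fixed = (fixed > 0.5).astype(float)
    return img.with_pixels(fixed, "deskew", angle=angle), angle


def sauvola_binarize(
    img: LabelImage,
    window_size: int = 31,
    k: float = 0.2,
    r: float = 128.0,
) -> LabelImage:
    """Sauvola adaptive binarization: T = m·(1 + k·(s/R − 1)).

    ``m`` and ``s`` are the local window mean and standard deviation; a pixel
    is foreground (ink, value 1) iff its intensity is below its threshold.
    The window is clamped (with a warning) when larger than the image.
    """
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError("window_size must be odd and >= 3")
    if not (0 < k < 1):
        raise ValueError("k must be in (0, 1)")
    short = min(img.pixels.shape)
    if window_size > short:
        clamped = short if short % 2 == 1 else short - 1
        warnings.warn(
            f"Sauvola window {window_size} larger than image; clamping to {clamped}"
        )
        window_size = max(3, clamped)
    t = threshold_sauvola(img.pixels, window_size=window_size, k=k, r=r)
    binary = (img.pixels < t).astype(float)
    return img.with_pixels(binary, "sauvola", window_size=window_size, k=k, r=r)


def despeckle_fill(
    img: LabelImage,
    min_speck: int = 4,
    min_hole: int = 4,
) -> LabelImage:
    """Remove small ink specks ("snow") and fill small enclosed holes.

    Foreground components (8-connectivity) with area < ``min_speck`` are
    erased; background components (4-connectivity) fully enclosed by ink
    with area < ``min_hole`` are filled.  Idempotent.
    """
    if not img.is_binary:
        raise ValueError("despeckle_fill requires a binary image")
    fg = img.pixels.astype(bool)
    if min_speck > 1:
        # area < min_speck, i.e. remove components of size <= min_speck - 1
        fg = remove_small_objects(fg, max_size=min_speck - 1, connectivity=2)
    # fill only fully-enclosed small background components
    bg_labels, n = ndimage.label(~fg)  # default structure = 4-connectivity
    if n:
        border = np.zeros_like(fg, dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        border_ids = np.unique(bg_labels[border & (bg_labels > 0)])
        areas = np.bincount(bg_labels.ravel(), minlength=n + 1)
        fill_ids = np.array([
            i for i in range(1, n + 1)
            if areas[i] < min_hole and i not in set(border_ids)
        ], dtype=int)
        if fill_ids.size:
            fg |= np.isin(bg_labels, fill_ids)
    return img.with_pixels(fg.astype(float), "despeckle_fill",
                           min_speck=min_speck, min_hole=min_hole)


def apply_variant(
    img: LabelImage,
    variant: PreprocVariant | str,
    params: Optional[PreprocParams] = None,
) -> LabelImage:
    """Apply one of the four cumulative pre-processing variants.

    V1 is the identity; V2 = blur → scale → orient → deskew; V3 = V2 then
    Sauvola; V4 = V3 then despeckle/fill.
    """
    variant = PreprocVariant(variant)
    p = params or PreprocParams()
    if variant is PreprocVariant.V1_none:
        out = img.with_pixels(img.pixels.copy(), "identity")
    elif variant is PreprocVariant.V2_deskew:
        out = blur_scale(img, p.blur_sigma, p.target_long_side)
        out, _, _ = orient_upright(out)
        out, _ = deskew(out, p.max_skew_deg, p.skew_step_deg)
    elif variant is PreprocVariant.V3_binarize:
        out = apply_variant(img, PreprocVariant.V2_deskew, p)
        out = sauvola_binarize(out, p.sauvola_window, p.sauvola_k, p.sauvola_r)
    elif variant is PreprocVariant.V4_denoise:
        out = apply_variant(img, PreprocVariant.V3_binarize, p)
        out = despeckle_fill(out, p.min_speck, p.min_hole)
    else:  # pragma: no cover - Enum() above already rejects unknown ids
        raise ValueError(f"unknown variant {variant!r}")
    out.variant_applied = variant
    return out
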