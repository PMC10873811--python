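"""OCR engine adapters and the synthetic fixtures that stand in for them.

Real deployments run Tesseract and/or EasyOCR over each pre-processed image
variant, yielding up to eight text streams per label.  Engine output is
environment-dependent, so the test bed instead uses two first-class synthetic
components:

* :func:`render_label` rasterizes label text with known skew and speckle
  density, returning the ground truth alongside the image, and
* :class:`SimulatedEngine` / :func:`simulate_ocr` corrupt the ground truth
  with a seeded character-level noise model (substitutions biased toward
  visually confusable characters, insertions, deletions).

Real-engine adapters are thin wrappers that fail loudly when the engine is
not installed — an unavailable engine never silently returns empty text.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .preproc import LabelImage, PreprocVariant

__all__ = [
    "DEFAULT_CONFUSION_CLASSES",
    "OCRStream",
    "NoiseModel",
    "EngineAdapter",
    "EngineUnavailableError",
    "TesseractAdapter",
    "EasyOCRAdapter",
    "SimulatedEngine",
    "run_engine",
    "simulate_ocr",
    "render_label",
    "LabelStyle",
    "random_label_text",
]

#: Groups of visually confusable Latin-script characters (lookalikes).
DEFAULT_CONFUSION_CLASSES = (
    "l1I|!",
    "O0o",
    "S5s",
    "Z2z",
    "B8",
    "G6",
    "mn",
    "rn",  # not pairwise-substitutable glyphs but a classic OCR merge
    "cC",
    "uv",
    "E3",
)

_INSERT_POOL = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789.,- "


class EngineUnavailableError(RuntimeError):
    """Raised when a required OCR engine is not installed."""


@dataclass(frozen=True)
class OCRStream:
    """One engine's transcription of one pre-processed variant of a label."""

    text: str
    engine_id: str
    variant_id: str
    label_id: str = ""


@dataclass(frozen=True)
class NoiseModel:
    """Per-character OCR error model for the simulator.

    Each truth character is substituted with probability ``sub_rate``
    (preferring a lookalike from its confusion class), deleted with
    ``del_rate``, otherwise kept; spurious characters are inserted between
    positions with probability ``ins_rate``.  Fully deterministic given
    ``seed``.
    """

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    confusion_classes: tuple[str, ...] = DEFAULT_CONFUSION_CLASSES
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r <= 1:
                raise ValueError("noise rates must be in [0, 1]")
        if self.sub_rate + self.del_rate > 1:
            raise ValueError("sub_rate + del_rate must be <= 1")


def simulate_ocr(
    truth: str,
    model: NoiseModel,
    engine_id: str = "simulated:noise",
    variant_id: str = PreprocVariant.V1_none.value,
    label_id: str = "",
) -> OCRStream:
    """Corrupt ``truth`` according to ``model`` (deterministic given seed).

    Expected number of edit events ≈ (sub + ins + del) · len(truth).
    """
    rng = np.random.default_rng(model.seed)
    by_char = {c: cls for cls in model.confusion_classes for c in cls}
    out: list[str] = []
    for i in range(len(truth) + 1):
        if model.ins_rate and rng.random() < model.ins_rate:
            out.append(_INSERT_POOL[rng.integers(len(_INSERT_POOL))])
        if i == len(truth):
            break
        c = truth[i]
        u = rng.random()
        if u < model.sub_rate:
            cls = by_char.get(c)
            choices = [x for x in (cls or "") if x != c]
            if not choices:
                choices = [x for x in _INSERT_POOL if x != c]
            out.append(choices[rng.integers(len(choices))])
        elif u < model.sub_rate + model.del_rate:
            continue
        else:
            out.append(c)
    return OCRStream("".join(out), engine_id, variant_id, label_id)


@runtime_checkable
class EngineAdapter(Protocol):
    """Contract every OCR engine plugs into."""

    engine_id: str

    def available(self) -> bool: ...

    def transcribe(self, img: LabelImage) -> str: ...


def run_engine(adapter: EngineAdapter, img: LabelImage) -> OCRStream:
    """Run one adapter on one image, tagging the stream with its origin."""
    if not adapter.available():
        raise EngineUnavailableError(
            f"OCR engine {adapter.engine_id!r} is not installed/available"
        )
    text = adapter.transcribe(img)
    return OCRStream(
        text=text,
        engine_id=adapter.engine_id,
        variant_id=img.variant_applied.value,
        label_id=img.label_id,
    )


def _img_to_pil(img: LabelImage) -> Image.Image:
    arr = img.pixels
    if img.is_binary:
        arr = (1 - arr) * 255.0
    return Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8))


@dataclass
class TesseractAdapter:
    """pytesseract wrapper; pass-through engine options, no added defaults."""

    engine_id: str = "tesseract"
    config: str = ""

    def available(self) -> bool:
        try:
            import pytesseract  # noqa: F401

            pytesseract.get_tesseract_version()
            return True
        except Exception:
            return False

    def transcribe(self, img: LabelImage) -> str:
        import pytesseract

        return pytesseract.image_to_string(_img_to_pil(img), config=self.config)


@dataclass
class EasyOCRAdapter:
    """easyocr wrapper; languages configurable, engine defaults otherwise."""

    engine_id: str = "easyocr"
    languages: tuple[str, ...] = ("en",)
    _reader: object = field(default=None, repr=False, compare=False)

    def available(self) -> bool:
        try:
            import easyocr  # noqa: F401

            return True
        except Exception:
            return False

    def transcribe(self, img: LabelImage) -> str:
        import easyocr

        if self._reader is None:
            self._reader = easyocr.Reader(list(self.languages), verbose=False)
        arr = np.asarray(_img_to_pil(img))
        return "\n".join(self._reader.readtext(arr, detail=0))


@dataclass
class SimulatedEngine:
    """Test double for a real engine: corrupts the image's ground truth.

    The image must carry its rendered ground truth in ``meta['truth']``
    (fixtures from :func:`render_label` do).  A per-call seed is derived
    from the model seed, the engine id, the label id and the variant, so
    different streams of the same label get independent (but reproducible)
    errors.
    """

    model: NoiseModel
    engine_id: str = "simulated:noise"

    def available(self) -> bool:
        return True

    def transcribe(self, img: LabelImage) -> str:
        if "truth" not in img.meta:
            raise ValueError(
                "SimulatedEngine needs ground truth in image.meta['truth']"
            )
        key = f"{self.model.seed}:{self.engine_id}:{img.label_id}:{img.variant_applied.value}"
        child = zlib.crc32(key.encode()) & 0x7FFFFFFF
        stream = simulate_ocr(
            img.meta["truth"],
            NoiseModel(
                sub_rate=self.model.sub_rate,
                ins_rate=self.model.ins_rate,
                del_rate=self.model.del_rate,
                confusion_classes=self.model.confusion_classes,
                seed=child,
            ),
            engine_id=self.engine_id,
            variant_id=img.variant_applied.value,
            label_id=img.label_id,
        )
        return stream.text


def load_simulation_config(path) -> tuple["NoiseModel", "LabelStyle"]:
    """Read simulator settings from a key-value config file.

    One ``key = value`` pair per line (``#`` comments allowed).  Keys are
    the field names of :class:`NoiseModel` (``sub_rate``, ``ins_rate``,
    ``del_rate``, ``seed``) and :class:`LabelStyle` (``font_size``,
    ``skew_deg``, ``speckle_density``, ``margin``, ``line_spacing``);
    unknown keys are rejected.
    """
    from pathlib import Path

    noise_fields = {"sub_rate": float, "ins_rate": float, "del_rate": float,
                    "seed": int}
    style_fields = {"font_size": int, "skew_deg": float,
                    "speckle_density": float, "margin": int,
                    "line_spacing": int}
    noise_kw: dict = {}
    style_kw: dict = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, sep, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if not sep:
            raise ValueError(f"expected 'key = value', got {raw!r}")
        if key in noise_fields:
            noise_kw[key] = noise_fields[key](value)
        elif key in style_fields:
            style_kw[key] = style_fields[key](value)
        else:
            raise ValueError(f"unknown simulation config key {key!r}")
    return NoiseModel(**noise_kw), LabelStyle(**style_kw)


# --- synthetic label rendering ---------------------------------------------


@dataclass(frozen=True)
class LabelStyle:
    """Rendering parameters for synthetic label fixtures."""

    font_size: int = 16
    skew_deg: float = 0.0
    speckle_density: float = 0.0  # expected isolated specks per pixel
    margin: int = 12
    line_spacing: int = 4
    ink: int = 0
    paper: int = 255


def render_label(
    text: str,
    style: LabelStyle = LabelStyle(),
    seed: int = 0,
    label_id: str = "",
) -> LabelImage:
    """Rasterize label text with known skew and speckle noise.

    Returns a grayscale :class:`LabelImage` whose ``meta`` records the
    ground truth (``truth``, ``skew_deg``, ``n_specks``) for oracle use.
    Speckles are single isolated ink pixels placed only where their 3×3
    neighbourhood is clear, so the placed count is exact.  Deterministic
    given ``seed``.
    """
    if not text.isprintable() and "\n" not in text:
        raise ValueError("text contains unprintable characters")
    for ch in text:
        if ch != "\n" and not ch.isprintable():
            raise ValueError(f"unprintable character {ch!r} in label text")
    font = ImageFont.load_default(size=style.font_size)
    probe = ImageDraw.Draw(Image.new("L", (1, 1)))
    bbox = probe.multiline_textbbox((0, 0), text, font=font,
                                    spacing=style.line_spacing)
    w = bbox[2] - bbox[0] + 2 * style.margin
    h = bbox[3] - bbox[1] + 2 * style.margin
    im = Image.new("L", (max(w, 8), max(h, 8)), color=style.paper)
    draw = ImageDraw.Draw(im)
    draw.multiline_text(
        (style.margin - bbox[0], style.margin - bbox[1]),
        text, fill=style.ink, font=font, spacing=style.line_spacing,
    )
    if style.skew_deg:
        im = im.rotate(style.skew_deg, expand=True, resample=Image.BICUBIC,
                       fillcolor=style.paper)
    arr = np.asarray(im, dtype=float)
    rng = np.random.default_rng(seed)
    n_specks = 0
    if style.speckle_density > 0:
        target = int(round(style.speckle_density * arr.size))
        ink_thresh = (style.ink + style.paper) / 2
        tries = 0
        while n_specks < target and tries < 50 * max(target, 1):
            tries += 1
            y = int(rng.integers(2, arr.shape[0] - 2))
            x = int(rng.integers(2, arr.shape[1] - 2))
            if (arr[y - 2:y + 3, x - 2:x + 3] > ink_thresh).all():
                arr[y, x] = style.ink
                n_specks += 1
    return LabelImage(
        arr,
        label_id=label_id,
        provenance=[{"step": "render", "font_size": style.font_size,
                     "skew_deg": style.skew_deg,
                     "speckle_density": style.speckle_density, "seed": seed}],
        meta={"truth": text, "skew_deg": style.skew_deg, "n_specks": n_specks},
    )


# --- synthetic label text ---------------------------------------------------

_GENERA = ["Quercus", "Carex", "Solidago", "Aster", "Panicum", "Salix",
           "Juncus", "Viola", "Rubus", "Acer", "Pinus", "Eupatorium"]
_EPITHETS = ["alba", "virginiana", "canadensis", "occidentalis", "vulgaris",
             "glabra", "hirsuta", "laevis", "rigida", "tenuifolia"]
_STATES = ["Texas", "Florida", "Georgia", "Alabama", "Virginia",
           "Tennessee", "Carolina", "Kentucky", "Arkansas", "Louisiana"]
_COUNTIES = ["Travis", "Leon", "Madison", "Clay", "Marion", "Walker",
             "Greene", "Jackson", "Monroe", "Lawrence"]
_HABITATS = ["Moist roadside ditch", "Dry sandy pineland", "Open pasture",
             "Rocky limestone slope", "Edge of mixed hardwood forest",
             "Stream bank in ravine", "Disturbed field margin",
             "Low wet meadow", "Granite outcrop", "Old field near fencerow"]
_COLLECTORS = ["J. K. Small", "A. H. Curtiss", "R. Kral", "D. S. Correll",
               "L. H. Shinners", "W. H. Duncan", "S. B. Jones", "C. Mohr"]
_MONTHS = ["Jan", "Feb", "Mar", "Apr", "May", "Jun", "Jul", "Aug",
           "Sep", "Oct", "Nov", "Dec"]


def random_label_text(
    rng: np.random.Generator,
    min_chars: int = 200,
    max_chars: int = 600,
) -> str:
    """Compose a realistic multi-line herbarium label transcription.

    Lines mimic the usual label layout — herbarium header, scientific name,
    locality, habitat, collector, number, date — and are repeated/extended
    until the requested length window is reached.
    """
    target = int(rng.integers(min_chars, max_chars + 1))
    lines: list[str] = []

    def sample(seq: Sequence[str]) -> str:
        return seq[int(rng.integers(len(seq)))]

    lines.append(f"Flora of {sample(_STATES)}")
    lines.append(f"Herbarium of the University of {sample(_STATES)}")
    while sum(len(x) + 1 for x in lines) < target:
        genus, epi = sample(_GENERA), sample(_EPITHETS)
        lines.append(f"{genus} {epi} L.")
        lines.append(f"{sample(_COUNTIES)} County, {sample(_STATES)}")
        lines.append(f"{sample(_HABITATS)}, elev. {int(rng.integers(10, 900))} m.")
        lines.append(
            f"{sample(_COLLECTORS)} No. {int(rng.integers(100, 99999))}, "
            f"{int(rng.integers(1, 29))} {sample(_MONTHS)} "
            f"{int(rng.integers(1880, 1990))}"
        )
    text = "\n".join(lines)
    return text[:target].rstrip() or text[:target]
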