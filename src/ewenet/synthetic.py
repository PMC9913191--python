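"""Deterministic generator of barn-like surveillance scenes.

The real footage — a fixed overhead camera over a shaded sheep pen —
cannot be redistributed, so this module fabricates geometrically faithful
stand-ins: 2560x1440 frames in which a *mounting event* is rendered as two
overlapping ellipses with distinct shading (the mounted animal drawn
brighter and offset onto the other's hindquarters) and annotated with one
bounding box, while single-animal *distractors* (feeding, standing, lying
ewes) are single ellipses with no annotation.

Two properties of the real data are reproduced because the detector's
design depends on them:

* a perspective size gradient — animals higher in the frame (farther from
  the camera) are drawn smaller, so the finest detection head has
  genuinely small targets to learn;
* the event-box width/height distribution is planted on four prototype
  shapes that straddle the four head scales after letterboxing, so anchor
  clustering has recoverable structure and target assignment exercises
  every head.

Appearance is deliberately schematic: the test surface is geometry and
learnability, not photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .geometry import BoundingBox
from .imaging import MaskSpec, letterbox_params
from .voc import Annotation, VocObject, write_voc

__all__ = ["SceneConfig", "generate_scene", "generate_dataset", "load_dataset"]

#: Planted event-shape prototypes, normalized to the letterboxed input;
#: one per detection head, smallest (most distant) first.  They span the
#: anchor range of the surveillance dataset (roughly 19x34 .. 92x122 at
#: 416 input).
DEFAULT_PROTOTYPES: tuple[tuple[float, float], ...] = (
    (0.0455, 0.0815),
    (0.0955, 0.1410),
    (0.1485, 0.2470),
    (0.2210, 0.2945),
)


@dataclass(frozen=True)
class SceneConfig:
    """Generator parameters.

    ``prototypes`` are normalized to ``input_size`` after letterboxing
    from ``canvas``; band placement couples shape to height in the frame
    (smallest prototype in the top band) which yields the perspective
    size gradient.  ``size_jitter`` multiplies each prototype dimension by
    U(1-j, 1+j).
    """

    canvas: tuple[int, int] = (2560, 1440)
    n_events: int = 2
    n_distractors: int = 6
    input_size: int = 416
    prototypes: tuple[tuple[float, float], ...] = DEFAULT_PROTOTYPES
    size_jitter: float = 0.08
    brightness_jitter: float = 0.1
    mask: MaskSpec | None = None
    seed: int = 0

    def source_prototypes(self) -> np.ndarray:
        """Prototype sizes in source pixels (inverse of the letterbox map)."""
        s = letterbox_params(self.canvas, (self.input_size, self.input_size)).scale
        return np.asarray(self.prototypes, dtype=float) * self.input_size / s


def _rng_for(config: SceneConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, index]))


def _place_box(
    rng: np.random.Generator,
    w: float,
    h: float,
    band: tuple[float, float],
    canvas: tuple[int, int],
    taken: list[tuple[float, float, float, float]],
    max_tries: int = 100,
) -> tuple[float, float, float, float] | None:
    cw, ch = canvas
    feas_lo, feas_hi = h / 2 + 2, ch - h / 2 - 2
    if feas_hi <= feas_lo or cw - w - 4 <= 0:
        return None  # box larger than the canvas
    y_lo = max(band[0] * ch, feas_lo)
    y_hi = min(band[1] * ch, feas_hi)
    if y_hi <= y_lo:
        # band unreachable for a box this tall: snap to the nearest
        # feasible sliver so the vertical size ordering is preserved
        if band[0] * ch >= feas_hi:
            y_lo, y_hi = max(feas_lo, feas_hi - 0.05 * ch), feas_hi
        else:
            y_lo, y_hi = feas_lo, min(feas_hi, feas_lo + 0.05 * ch)
    for _ in range(max_tries):
        cx = rng.uniform(w / 2 + 2, cw - w / 2 - 2)
        cy = rng.uniform(y_lo, y_hi)
        x0, y0, x1, y1 = cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2
        ok = True
        for tx0, ty0, tx1, ty1 in taken:
            iw = min(x1, tx1) - max(x0, tx0)
            ih = min(y1, ty1) - max(y0, ty0)
            if iw > 0 and ih > 0:
                ok = False
                break
        if ok:
            return (x0, y0, x1, y1)
    return None


def _draw_event(draw: ImageDraw.ImageDraw, box: tuple[float, float, float, float],
                rng: np.random.Generator) -> None:
    """Two overlapping ellipses: mount-ee below, brighter mounter on top."""
    x0, y0, x1, y1 = box
    w, h = x1 - x0, y1 - y0
    # lower animal occupies the bottom ~70% of the box
    draw.ellipse([x0, y0 + 0.30 * h, x1, y1], fill=(198, 192, 180), outline=(90, 85, 75))
    # mounted animal overlaps the top, brighter, slightly narrower
    inset = 0.12 * w
    draw.ellipse(
        [x0 + inset, y0, x1 - inset, y0 + 0.62 * h],
        fill=(238, 234, 224),
        outline=(110, 105, 95),
    )


def _draw_distractor(draw: ImageDraw.ImageDraw, box: tuple[float, float, float, float]) -> None:
    draw.ellipse(list(box), fill=(198, 192, 180), outline=(90, 85, 75))


def generate_scene(config: SceneConfig, index: int) -> tuple[np.ndarray, Annotation]:
    """Render scene ``index``; bit-identical for a fixed (seed, index).

    Mounting events are placed in vertical bands matched to their
    prototype (small shapes near the top of the frame), distractors
    anywhere free.  Raises if an event cannot be placed after bounded
    retries.
    """
    rng = _rng_for(config, index)
    cw, ch = config.canvas
    base = np.array([104, 100, 92], dtype=float)
    base = np.clip(base * (1 + rng.uniform(-config.brightness_jitter,
                                           config.brightness_jitter)), 0, 255)
    img = Image.new("RGB", (cw, ch), tuple(int(v) for v in base))
    draw = ImageDraw.Draw(img)

    # sparse ground texture
    for _ in range(60):
        x = rng.uniform(0, cw)
        y = rng.uniform(0, ch)
        r = rng.uniform(1, 4) * cw / 416
        shade = int(np.clip(base[0] + rng.uniform(-18, 18), 0, 255))
        draw.ellipse([x - r, y - r, x + r, y + r], fill=(shade, shade, shade))

    protos = config.source_prototypes()
    n_proto = len(protos)
    bands = [(i / n_proto, (i + 1) / n_proto) for i in range(n_proto)]
    taken: list[tuple[float, float, float, float]] = []
    objects: list[VocObject] = []

    for e in range(config.n_events):
        box = None
        # crowded canvases may not fit the first prototype drawn; redraw
        # a few times before declaring the scene unplaceable
        for _ in range(4 * n_proto):
            p = int(rng.integers(n_proto))
            jw, jh = 1 + rng.uniform(-config.size_jitter, config.size_jitter, size=2)
            w = protos[p, 0] * jw
            h = protos[p, 1] * jh
            box = _place_box(rng, w, h, bands[p], config.canvas, taken)
            if box is not None:
                break
        if box is None:
            raise RuntimeError(
                f"could not place mounting event {e} (scene {index}); "
                "reduce n_events or box sizes"
            )
        taken.append(box)
        _draw_event(draw, box, rng)
        objects.append(
            VocObject(class_name="mounting", xmin=box[0], ymin=box[1],
                      xmax=box[2], ymax=box[3])
        )

    for _ in range(config.n_distractors):
        p = int(rng.integers(n_proto))
        # a single animal: roughly the lower ellipse of an event
        w = protos[p, 0] * 0.8
        h = protos[p, 1] * 0.55
        box = _place_box(rng, w, h, bands[p], config.canvas, taken)
        if box is None:
            continue  # distractors are best-effort
        taken.append(box)
        _draw_distractor(draw, box)

    arr = np.asarray(img, dtype=np.uint8).copy()
    if config.mask is not None:
        from .imaging import apply_mask

        arr = apply_mask(arr, config.mask)
    ann = Annotation(image_path=f"scene_{index:05d}.png", image_size=(cw, ch),
                     objects=objects)
    return arr, ann


def generate_dataset(
    n_images: int, config: SceneConfig, out_dir: str | Path
) -> list[tuple[Path, Path]]:
    """Write ``n_images`` scenes as images/ + annotations/ + a manifest.

    Returns the (image, xml) path pairs; the layout is exactly what
    :mod:`ewenet.voc` consumes.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    pairs: list[tuple[Path, Path]] = []
    names: list[str] = []
    for i in range(n_images):
        img, ann = generate_scene(config, i)
        img_path = out / "images" / ann.image_path
        xml_path = out / "annotations" / f"{Path(ann.image_path).stem}.xml"
        Image.fromarray(img).save(img_path)
        write_voc(ann, xml_path)
        pairs.append((img_path, xml_path))
        names.append(Path(ann.image_path).stem)
    (out / "manifest.txt").write_text("\n".join(names) + "\n")
    return pairs


def load_dataset(root: str | Path) -> list[tuple[Path, Annotation]]:
    """Read back a generated (or hand-labelled) images/ + annotations/ tree."""
    from .voc import read_voc

    root = Path(root)
    manifest = root / "manifest.txt"
    if manifest.exists():
        stems = [s for s in manifest.read_text().splitlines() if s]
    else:
        stems = sorted(p.stem for p in (root / "annotations").glob("*.xml"))
    out = []
    for stem in stems:
        ann = read_voc(root / "annotations" / f"{stem}.xml")
        img_path = root / "images" / ann.image_path
        out.append((img_path, ann))
    return out
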