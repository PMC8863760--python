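"""Rasterisation and serialization of stimulus sets.

Rendering is pure: no randomness, so identical inputs give byte-identical
PNGs.  The canvas is described both in pixels and in physical centimetres,
and the arena's desired on-screen size in centimetres fixes the
units-to-pixel scale, so a stimulus computed in abstract units ends up with
an exact physical size on a calibrated display.  Anti-aliasing is done by
supersampling (draw at Nx, box-filter down), with a hard-edge mode for
users who need exact binary masks.

A stimulus *set* — the constraint set, every generated array with its
achieved descriptor audit, and the software version — serializes to a JSON
file that round-trips exactly; :func:`save_set` additionally writes one PNG
per array and a CSV metadata table (one row per stimulus) mirroring the
spreadsheet an experimenter keeps next to the images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from . import __version__
from .constraints import ConstraintSet, constraint_from_dict, constraint_to_dict
from .descriptors import Arena, Element, ShapeKind, StimulusArray, element_vertices
from .errors import InvalidParameterError

__all__ = [
    "RenderSpec",
    "StimulusSetFile",
    "render",
    "save_set",
    "load_set",
    "metadata_table",
]

METADATA_COLUMNS = [
    "id", "n", "shape", "ID", "CH", "D", "TA", "TP", "Rmin", "Rmax",
    "err_ID", "err_CH", "err_D", "err_TA", "err_TP", "seed", "file",
]


@dataclass(frozen=True)
class RenderSpec:
    """How to map stimulus units onto canvas pixels.

    ``canvas_cm`` is the physical width the full canvas occupies on screen;
    ``arena_cm`` the physical diameter (or side) the arena should have.
    When ``arena_cm`` is None the arena auto-fills 90% of its panel's
    shorter side.
    """

    canvas_px: tuple[int, int] = (800, 600)
    canvas_cm: float = 20.0
    arena_cm: float | None = None
    background_rgb: tuple[int, int, int] = (0, 0, 0)
    arena_rgb: tuple[int, int, int] | None = None  # None: use each arena's colour
    element_rgb: tuple[int, int, int] = (255, 255, 255)
    layout: str = "single"  # single | pair_horizontal | pair_vertical
    gap_px: int = 0
    antialias: bool = True
    supersample: int = 4

    def __post_init__(self):
        if self.canvas_px[0] <= 0 or self.canvas_px[1] <= 0:
            raise InvalidParameterError("canvas dimensions must be positive")
        if self.layout not in ("single", "pair_horizontal", "pair_vertical"):
            raise InvalidParameterError(f"unknown layout {self.layout!r}")
        if self.canvas_cm <= 0:
            raise InvalidParameterError("canvas_cm must be positive")

    def px_per_unit(self, arena: Arena, panel_px: tuple[int, int]) -> float:
        if self.arena_cm is not None:
            px_per_cm = self.canvas_px[0] / self.canvas_cm
            arena_diameter_px = self.arena_cm * px_per_cm
        else:
            arena_diameter_px = 0.9 * min(panel_px)
        return arena_diameter_px / (2.0 * arena.radius)


def _panels(spec: RenderSpec) -> list[tuple[int, int, int, int]]:
    """Panel boxes (x0, y0, w, h) on the canvas for the configured layout."""
    w, h = spec.canvas_px
    if spec.layout == "single":
        return [(0, 0, w, h)]
    g = spec.gap_px
    if spec.layout == "pair_horizontal":
        pw = (w - g) // 2
        return [(0, 0, pw, h), (w - pw, 0, pw, h)]
    ph = (h - g) // 2
    return [(0, 0, w, ph), (0, h - ph, w, ph)]


def _draw_array(
    draw: ImageDraw.ImageDraw,
    array: StimulusArray,
    panel: tuple[int, int, int, int],
    spec: RenderSpec,
    S: int,
):
    x0, y0, pw, ph = panel
    s = spec.px_per_unit(array.arena, (pw, ph)) * S
    # panel centre, half-pixel aligned on the final grid
    cx = (x0 + pw / 2.0) * S
    cy = (y0 + ph / 2.0) * S

    def to_px(x: float, y: float) -> tuple[float, float]:
        return (cx + x * s, cy - y * s)

    arena = array.arena
    arena_colour = spec.arena_rgb if spec.arena_rgb is not None else tuple(arena.colour)
    r_px = arena.radius * s
    if arena.kind == "circular":
        draw.ellipse([cx - r_px, cy - r_px, cx + r_px, cy + r_px], fill=arena_colour)
    else:
        draw.rectangle([cx - r_px, cy - r_px, cx + r_px, cy + r_px], fill=arena_colour)
    for el in array.elements:
        if el.shape == ShapeKind.CIRCLE:
            ex, ey = to_px(*el.centre)
            # PIL's filled ellipse covers ~half a pixel beyond the box
            rr = el.R * s - 0.5
            draw.ellipse([ex - rr, ey - rr, ex + rr, ey + rr], fill=spec.element_rgb)
        else:
            verts = [to_px(x, y) for x, y in element_vertices(el)]
            draw.polygon(verts, fill=spec.element_rgb)


def render(arrays, spec: RenderSpec = RenderSpec()) -> Image.Image:
    """Rasterise one array (or a pair, for the paired layouts) to an image."""
    if isinstance(arrays, StimulusArray):
        arrays = [arrays]
    arrays = list(arrays)
    panels = _panels(spec)
    if len(arrays) != len(panels):
        raise InvalidParameterError(
            f"layout {spec.layout!r} needs {len(panels)} array(s), got {len(arrays)}"
        )
    S = spec.supersample if spec.antialias else 1
    w, h = spec.canvas_px
    img = Image.new("RGB", (w * S, h * S), tuple(spec.background_rgb))
    draw = ImageDraw.Draw(img)
    for array, panel in zip(arrays, panels):
        _draw_array(draw, array, panel, spec, S)
    if S > 1:
        img = img.resize((w, h), Image.Resampling.BOX)
    return img


# ---------------------------------------------------------------------------
# stimulus set files


@dataclass
class StimulusSetFile:
    """A serializable pool of generated stimuli plus their provenance."""

    constraints: ConstraintSet
    arrays: list[StimulusArray]
    version: str = __version__

    @property
    def name(self) -> str:
        return self.constraints.ref or "stimulus_set"


def _array_to_dict(a: StimulusArray) -> dict:
    return {
        "elements": [
            {"shape": el.shape.value, "x": el.centre[0], "y": el.centre[1], "R": el.R}
            for el in a.elements
        ],
        "arena": {"kind": a.arena.kind, "radius": a.arena.radius, "colour": list(a.arena.colour)},
        "achieved": dict(a.achieved),
        "errors": dict(a.errors),
        "seed": a.seed,
        "constraint_ref": a.constraint_ref,
    }


def _array_from_dict(d: dict) -> StimulusArray:
    arena = Arena(
        kind=d["arena"]["kind"],
        radius=d["arena"]["radius"],
        colour=tuple(d["arena"].get("colour", (0, 0, 0))),
    )
    elements = [
        Element(ShapeKind(e["shape"]), (e["x"], e["y"]), e["R"]) for e in d["elements"]
    ]
    return StimulusArray(
        elements=elements,
        arena=arena,
        achieved=dict(d.get("achieved", {})),
        errors=dict(d.get("errors", {})),
        seed=d.get("seed"),
        constraint_ref=d.get("constraint_ref"),
    )


def set_to_dict(sset: StimulusSetFile) -> dict:
    return {
        "version": sset.version,
        "constraints": constraint_to_dict(sset.constraints),
        "arrays": [_array_to_dict(a) for a in sset.arrays],
    }


def set_from_dict(d: dict) -> StimulusSetFile:
    return StimulusSetFile(
        constraints=constraint_from_dict(d["constraints"]),
        arrays=[_array_from_dict(a) for a in d["arrays"]],
        version=d.get("version", __version__),
    )


def metadata_table(sset: StimulusSetFile, filenames: list[str] | None = None) -> pd.DataFrame:
    """One row per stimulus with its achieved descriptors and errors."""
    rows = []
    for i, a in enumerate(sset.arrays):
        row = {
            "id": i,
            "n": a.n,
            "shape": a.elements[0].shape.value,
            "seed": a.seed,
            "file": filenames[i] if filenames else "",
        }
        for key in ("ID", "CH", "D", "TA", "TP", "Rmin", "Rmax"):
            row[key] = a.achieved.get(key, np.nan)
        for key in ("ID", "CH", "D", "TA", "TP"):
            row[f"err_{key}"] = a.errors.get(key, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def save_set(
    sset: StimulusSetFile,
    directory: str | Path,
    render_spec: RenderSpec | None = None,
    images: bool = True,
    spreadsheet: bool = False,
) -> dict[str, Path]:
    """Write images, metadata and the serialized set under ``directory``.

    Returns the paths written ({'set', 'metadata', 'images': [...]}).
    The JSON set file is canonical; ``spreadsheet=True`` additionally
    exports the metadata as ``.xlsx`` when openpyxl is available.
    """
    if not sset.arrays:
        raise InvalidParameterError("cannot save an empty stimulus set")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = render_spec or RenderSpec()
    if spec.layout != "single":
        spec = replace(spec, layout="single")
    filenames = []
    image_paths = []
    if images:
        for i, a in enumerate(sset.arrays):
            fname = f"{sset.name}_{i:04d}.png"
            render(a, spec).save(directory / fname)
            filenames.append(fname)
            image_paths.append(directory / fname)
    meta = metadata_table(sset, filenames or None)
    meta_path = directory / f"{sset.name}_metadata.csv"
    meta.to_csv(meta_path, index=False)
    if spreadsheet:
        meta.to_excel(directory / f"{sset.name}_metadata.xlsx", index=False)
    set_path = directory / f"{sset.name}.json"
    set_path.write_text(json.dumps(set_to_dict(sset), indent=1))
    return {"set": set_path, "metadata": meta_path, "images": image_paths}


def load_set(path: str | Path) -> StimulusSetFile:
    return set_from_dict(json.loads(Path(path).read_text()))
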