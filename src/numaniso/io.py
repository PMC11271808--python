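"""Serialization and rendering of displays and trial tables.

Displays are stored as JSON (one object per display, degrees,
fixation-origin); trial tables as long-format CSV with empty cells for
invalid responses.  Rendering uses the experiment's palette: gray #B6B6B6
background, dark discs #000000, light discs #FFFFFF, 0.04 degrees per
pixel, no anti-aliasing so color assertions are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from PIL import Image, ImageDraw

from .generator import Disc, Display
from .geometry import Point

__all__ = [
    "DisplayParseError",
    "display_to_dict",
    "display_from_dict",
    "write_display",
    "read_display",
    "write_pool",
    "read_pool",
    "render_display",
    "write_trials",
    "read_trials",
]

BACKGROUND_HEX = "#B6B6B6"
DARK_HEX = "#000000"
LIGHT_HEX = "#FFFFFF"
DEFAULT_SCALE = 0.04  # degrees per pixel

_REQUIRED_KEYS = (
    "seed",
    "arrangement",
    "mode",
    "percent_pairs",
    "polarity_scheme",
    "field",
    "disc_radius",
    "discs",
)


class DisplayParseError(ValueError):
    """A display JSON document violates the schema."""


def display_to_dict(d: Display) -> dict:
    return {
        "seed": d.seed,
        "arrangement": d.arrangement,
        "mode": d.mode,
        "percent_pairs": d.percent_pairs,
        "polarity_scheme": d.polarity_scheme,
        "field": {"w": d.field[0], "h": d.field[1]},
        "disc_radius": d.disc_radius,
        "fixation_exclusion_radius": d.fixation_exclusion_radius,
        "zone_major_factor": d.zone_major_factor,
        "zone_minor_factor": d.zone_minor_factor,
        "zones_within_field": d.zones_within_field,
        "base_count": d.base_count,
        "demotions": list(d.demotions),
        "side_fallbacks": list(d.side_fallbacks),
        "discs": [
            {
                "id": disc.id,
                "role": disc.role,
                "parent_id": disc.parent_id,
                "x": disc.center.x,
                "y": disc.center.y,
                "polarity": disc.polarity,
            }
            for disc in d.discs
        ],
    }


def display_from_dict(doc: dict) -> Display:
    for key in _REQUIRED_KEYS:
        if key not in doc:
            raise DisplayParseError(f"display document is missing key {key!r}")
    discs = tuple(
        Disc(
            id=int(entry["id"]),
            center=Point(float(entry["x"]), float(entry["y"])),
            radius=float(doc["disc_radius"]),
            polarity=entry["polarity"],
            role=entry["role"],
            parent_id=int(entry["parent_id"]),
        )
        for entry in doc["discs"]
    )
    return Display(
        discs=discs,
        arrangement=doc["arrangement"],
        mode=doc["mode"],
        percent_pairs=doc["percent_pairs"],
        polarity_scheme=doc["polarity_scheme"],
        base_count=int(doc.get("base_count", sum(1 for x in discs if x.role == "base"))),
        seed=int(doc["seed"]),
        field=(float(doc["field"]["w"]), float(doc["field"]["h"])),
        disc_radius=float(doc["disc_radius"]),
        fixation_exclusion_radius=float(doc.get("fixation_exclusion_radius", 4.0)),
        zone_major_factor=float(doc.get("zone_major_factor", 0.5)),
        zone_minor_factor=float(doc.get("zone_minor_factor", 0.2)),
        zones_within_field=bool(doc.get("zones_within_field", True)),
        demotions=tuple(doc.get("demotions", ())),
        side_fallbacks=tuple(doc.get("side_fallbacks", ())),
    )


def write_display(path: str | Path, d: Display) -> None:
    Path(path).write_text(json.dumps(display_to_dict(d), indent=1))


def read_display(path: str | Path) -> Display:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise DisplayParseError(f"not valid JSON: {exc}") from exc
    return display_from_dict(doc)


def write_pool(path: str | Path, displays: list[Display]) -> None:
    Path(path).write_text(
        json.dumps([display_to_dict(d) for d in displays], indent=1)
    )


def read_pool(path: str | Path) -> list[Display]:
    docs = json.loads(Path(path).read_text())
    return [display_from_dict(doc) for doc in docs]


def render_display(d: Display, scale: float = DEFAULT_SCALE) -> Image.Image:
    """Rasterize a display with fixation at the image center."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    w_px = int(round(d.field[0] / scale))
    h_px = int(round(d.field[1] / scale))
    img = Image.new("RGB", (w_px, h_px), BACKGROUND_HEX)
    draw = ImageDraw.Draw(img)
    r_px = d.disc_radius / scale
    for disc in d.discs:
        cx = w_px / 2 + disc.center.x / scale
        cy = h_px / 2 - disc.center.y / scale  # +y is up
        color = DARK_HEX if disc.polarity == "dark" else LIGHT_HEX
        draw.ellipse(
            [cx - r_px, cy - r_px, cx + r_px, cy + r_px], fill=color
        )
    return img


def write_trials(path: str | Path, trials: pd.DataFrame) -> None:
    """Write a long-format trial CSV; NaN responses become empty cells."""
    trials.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["response"] = pd.to_numeric(df["response"], errors="coerce")
    return df
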