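"""Color-coded timeline bars ("visual maps") for scored trials.

Each trial renders as a single horizontal bar whose length is proportional
to the trial duration.  Bouts are drawn as runs of their behavior's color,
unscored gaps in a neutral gap color, and point occurrences as full-height
vertical ticks overlaid on the state colors.  Multiple trials (e.g. the
same animal scored by a trainer and a trainee) stack into rows for
side-by-side comparison.

Pixel mapping uses round-half-up on cumulative positions, so adjacent
bouts never overlap and never leave seams; the bar region is deterministic
(byte-identical for identical inputs).  Labels in the left gutter are
best-effort and kept out of the bar region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from PIL import Image, ImageDraw

from .errors import StyleError
from .ethogram import Ethogram
from .timeline import ScoredTrial

__all__ = ["MapStyle", "render_map", "collate_maps", "save_map"]


@dataclass(frozen=True)
class MapStyle:
    """Rendering parameters for visual maps."""

    px_per_second: float = 2.0
    bar_height_px: int = 40
    gap_color: str = "#D3D3D3"
    tick_width_px: int = 1
    label_gutter_px: int = 0
    row_spacing_px: int = 8

    def __post_init__(self) -> None:
        if not self.px_per_second > 0:
            raise StyleError("px_per_second must be > 0")
        if self.bar_height_px < 1:
            raise StyleError("bar_height_px must be >= 1")
        if self.tick_width_px < 1:
            raise StyleError("tick_width_px must be >= 1")
        if self.label_gutter_px < 0 or self.row_spacing_px < 0:
            raise StyleError("gutter and spacing must be >= 0")


def _px(t: float, pps: float) -> int:
    # round-half-up on the cumulative pixel position
    return int(math.floor(t * pps + 0.5))


def _hex_rgb(color: str) -> tuple[int, int, int]:
    c = color.lstrip("#")
    return (int(c[0:2], 16), int(c[2:4], 16), int(c[4:6], 16))


def render_map(
    trial: ScoredTrial, etho: Ethogram, style: MapStyle = MapStyle()
) -> Image.Image:
    """Render one trial as a horizontal color-coded bar (RGB image).

    Bar width is ``round(duration * px_per_second)``; each bout occupies a
    color run whose length matches ``duration * px_per_second`` within the
    +/-1 px implied by rounding.  Point ticks overdraw state colors; when
    two ticks collide in one column, the behavior later in ethogram order
    wins.
    """
    width = _px(trial.duration_s, style.px_per_second)
    if width < 1:
        raise StyleError(
            f"bar width rounds to {width} px "
            f"(duration {trial.duration_s:g} s at {style.px_per_second:g} px/s)"
        )
    colors = {b.name: _hex_rgb(b.color) for b in etho.behaviors}
    img = Image.new("RGB", (width, style.bar_height_px), _hex_rgb(style.gap_color))
    draw = ImageDraw.Draw(img)

    for bout in trial.bouts:
        x0 = _px(bout.start, style.px_per_second)
        x1 = _px(bout.end, style.px_per_second)
        if x1 > x0:
            draw.rectangle([x0, 0, x1 - 1, style.bar_height_px - 1], fill=colors[bout.behavior])

    # draw ticks in ethogram order so later behaviors overdraw earlier ones
    for beh in etho.point_behaviors:
        for p in trial.points:
            if p.behavior != beh.name:
                continue
            x0 = min(_px(p.t, style.px_per_second), width - style.tick_width_px)
            x0 = max(x0, 0)
            draw.rectangle(
                [x0, 0, x0 + style.tick_width_px - 1, style.bar_height_px - 1],
                fill=colors[beh.name],
            )
    return img


def collate_maps(
    trials: Sequence[ScoredTrial],
    etho: Ethogram,
    style: MapStyle = MapStyle(),
    labels: Sequence[str] | None = None,
) -> Image.Image:
    """Stack per-trial bars into rows (one animal/rater per row).

    Rows keep input order and are left-aligned after the label gutter, so
    row widths stay proportional to trial durations.  Image height is
    ``n_rows * (bar_height_px + row_spacing_px)``.
    """
    if not trials:
        raise ValueError("collate_maps needs at least one trial")
    if labels is not None and len(labels) != len(trials):
        raise ValueError("labels must match trials in length")

    rows = [render_map(t, etho, style) for t in trials]
    row_h = style.bar_height_px + style.row_spacing_px
    width = style.label_gutter_px + max(r.width for r in rows)
    height = len(rows) * row_h
    img = Image.new("RGB", (width, height), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    for i, row in enumerate(rows):
        y = i * row_h
        img.paste(row, (style.label_gutter_px, y))
        if labels is not None and style.label_gutter_px > 0:
            draw.text((2, y + 2), labels[i], fill=(0, 0, 0))
    return img


def save_map(img: Image.Image, path) -> None:
    """Write a rendered map to disk as png."""
    img.save(path, format="PNG")
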