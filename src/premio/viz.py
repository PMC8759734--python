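"""Parallel-coordinate rendering of a selection round.

Each shown alternative is a polyline across one vertical axis per
objective.  Group I members (all preferred ranges met) are drawn in
full-opacity distinct colors; group II members are shaded low-opacity
gray.  The decision-maker's preferred range is drawn as a band on every
axis.

Axis scaling uses the dataset's observed ideal–nadir range: by default
each axis is oriented so *better* points up (minimized objectives are
inverted), which makes group I polylines cluster near the top.  Set
``orient_better_up=False`` for raw low-to-high axes.

The renderer returns a :class:`DrawManifest` — the exact polyline
coordinates, styles and axis endpoints it drew — so tests can assert on
the drawing without pixel comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering; no display required

import matplotlib.pyplot as plt

from .preference_core import IterationResult, aspiration_bound, reservation_bound
from .therapy_data import ObjectiveSpec, ValidationError

__all__ = ["PlotConfig", "DrawManifest", "render_parallel_coordinates"]

_HIGHLIGHT_CYCLE = ("#d62728", "#1f77b4", "#2ca02c", "#9467bd", "#ff7f0e", "#17becf")
_SUPPORTED_FORMATS = {".svg", ".png"}


@dataclass
class PlotConfig:
    """Rendering options for the parallel-coordinate plot."""

    axis_order: Sequence[str] | None = None  # default: spec order
    orient_better_up: bool = True
    highlight_colors: Sequence[str] = _HIGHLIGHT_CYCLE
    shade_color: str = "0.55"
    shade_alpha: float = 0.35
    band_color: str = "#a6d8a8"
    band_alpha: float = 0.4
    figsize: tuple[float, float] = (9.0, 5.0)


@dataclass
class DrawManifest:
    """What the renderer drew, for programmatic inspection."""

    axes: list[dict]        # per axis: key, label, top_value, bottom_value, band_y
    polylines: list[dict]   # per alternative: id, group, ys, color, alpha, highlighted
    path: str | None

    @property
    def n_highlighted(self) -> int:
        return sum(1 for p in self.polylines if p["highlighted"])

    @property
    def n_shaded(self) -> int:
        return sum(1 for p in self.polylines if not p["highlighted"])


def _axis_position(value: float, ideal: float, nadir: float, better_up: bool) -> float:
    """Map a raw objective value to [0, 1] axis coordinates."""
    span = ideal - nadir
    if span == 0:
        return 0.5
    pos = (value - nadir) / span  # 1 at ideal, 0 at nadir
    return pos if better_up else (1.0 - pos if ideal < nadir else pos)


def render_parallel_coordinates(
    result: IterationResult,
    config: PlotConfig | None = None,
    path: str | Path | None = None,
) -> DrawManifest:
    """Draw one selection round as a parallel-coordinate plot.

    Writes SVG or PNG when ``path`` is given (format inferred from the
    suffix) and always returns the draw manifest.
    """
    config = config or PlotConfig()
    if not result.selection:
        raise ValidationError("cannot render an empty selection")
    if path is not None:
        suffix = Path(path).suffix.lower()
        if suffix not in _SUPPORTED_FORMATS:
            raise ValueError(
                f"unsupported output format {suffix!r}; use one of "
                f"{sorted(_SUPPORTED_FORMATS)}"
            )

    known_keys = list(result.ideal_nadir.ideal.keys())
    order = list(config.axis_order) if config.axis_order else known_keys
    if sorted(order) != sorted(known_keys):
        raise ValidationError(
            f"axis_order {order} is not a permutation of objectives {known_keys}"
        )

    inad = result.ideal_nadir
    axes_manifest: list[dict] = []
    for k in order:
        ideal, nadir = inad.ideal[k], inad.nadir[k]
        rng = result.prefs.ranges[k]
        band = sorted(
            (
                _axis_position(rng.lower, ideal, nadir, config.orient_better_up),
                _axis_position(rng.upper, ideal, nadir, config.orient_better_up),
            )
        )
        top, bottom = (ideal, nadir) if config.orient_better_up else (
            (max(ideal, nadir), min(ideal, nadir))
        )
        axes_manifest.append(
            {
                "key": k,
                "top_value": top,
                "bottom_value": bottom,
                "band_y": [max(0.0, band[0]), min(1.0, band[1])],
            }
        )

    polylines: list[dict] = []
    highlight_idx = 0
    for cls in result.selection:
        ys = [
            _axis_position(
                cls.record.objectives[k], inad.ideal[k], inad.nadir[k],
                config.orient_better_up,
            )
            for k in order
        ]
        if cls.group == "I":
            color = config.highlight_colors[highlight_idx % len(config.highlight_colors)]
            highlight_idx += 1
            alpha, highlighted = 1.0, True
        else:
            color, alpha, highlighted = config.shade_color, config.shade_alpha, False
        polylines.append(
            {
                "id": cls.record.id,
                "label": cls.record.study,
                "group": cls.group,
                "ys": ys,
                "color": color,
                "alpha": alpha,
                "highlighted": highlighted,
            }
        )

    fig, ax = plt.subplots(figsize=config.figsize)
    xs = list(range(len(order)))
    band_half_width = 0.06
    for x, axis in zip(xs, axes_manifest):
        ax.plot([x, x], [0, 1], color="0.2", lw=1)
        y0, y1 = axis["band_y"]
        if y1 > y0:
            ax.fill_betweenx(
                [y0, y1], x - band_half_width, x + band_half_width,
                color=config.band_color, alpha=config.band_alpha, zorder=0,
            )
        ax.annotate(
            f"{axis['top_value']:g}", (x, 1.02), ha="center", fontsize=8
        )
        ax.annotate(
            f"{axis['bottom_value']:g}", (x, -0.05), ha="center", fontsize=8
        )
    # shaded lines first so highlights draw on top
    for poly in sorted(polylines, key=lambda p: p["highlighted"]):
        ax.plot(
            xs,
            poly["ys"],
            color=poly["color"],
            alpha=poly["alpha"],
            lw=2.2 if poly["highlighted"] else 1.6,
            label=f"{poly['label']} (group {poly['group']})",
        )
    ax.set_xticks(xs)
    ax.set_xticklabels(order, fontsize=8)
    ax.set_yticks([])
    ax.set_ylim(-0.1, 1.1)
    ax.set_title(f"Iteration {result.index or '-'}: compromise therapies")
    ax.legend(fontsize=7, loc="upper center", bbox_to_anchor=(0.5, -0.08), ncol=2)
    for spine in ax.spines.values():
        spine.set_visible(False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
    plt.close(fig)

    return DrawManifest(
        axes=axes_manifest, polylines=polylines, path=None if path is None else str(path)
    )
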