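"""Publication-style SVG idiograms of aggregated karyotypes.

One vertical bar per chromosome pair, short arm up, all centromeres
aligned on a common baseline; marker glyphs are placed at their
di-derived positions with heights proportional to their size percent (a
percent of the haploid complement equals one RL unit, so chromosome
height and glyph height share the ordinate scale).  Output is SVG 1.1
assembled deterministically: identical input yields a byte-identical
document.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .measurements import Karyotype, ValidationError

__all__ = ["IdiogramStyle", "IdiogramMarker", "render_idiogram", "DEFAULT_PALETTE"]

DEFAULT_PALETTE = {
    "rDNA5S": "#d62728",   # red
    "rDNA45S": "#2ca02c",  # green
    "CPD": "#9467bd",      # purple
    "sGISH": "#ff7f0e",    # orange
}


@dataclass(frozen=True)
class IdiogramStyle:
    """Layout parameters; ``scale`` is display units per RL percent."""

    bar_width: float = 18.0
    scale: float = 22.0
    gap: float = 26.0
    margin: float = 48.0
    marker_palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    show_sd_whiskers: bool = True
    ordinate_ticks: tuple = (0, 2, 4, 6, 8)
    satellite_fraction: float = 0.15  # arm fraction drawn as a detached satellite
    sc_gap: float = 0.35  # RL units of secondary-constriction gap

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError(f"scale must be > 0, got {self.scale}")
        missing = set(DEFAULT_PALETTE) - set(self.marker_palette)
        if missing:
            raise ValidationError(f"palette missing marker kinds: {sorted(missing)}")


@dataclass(frozen=True)
class IdiogramMarker:
    """A marker glyph in RL coordinates: di along the arm, size as height."""

    pair_id: int
    kind: str
    arm: str  # short | long | centromere
    di: float | None  # percent along the arm; None for centromeric
    size_percent: float


def _f(v: float) -> str:
    """Fixed-precision float formatting keeps the byte stream reproducible."""
    return f"{v:.3f}".rstrip("0").rstrip(".")


def render_idiogram(
    karyotype: Karyotype,
    markers: list[IdiogramMarker] | None = None,
    style: IdiogramStyle | None = None,
) -> str:
    """Render a karyotype (optionally with marker glyphs) to an SVG string."""
    style = style or IdiogramStyle()
    markers = markers or []
    pairs = karyotype.pairs
    by_id = {p.pair_id: p for p in pairs}

    for m in markers:
        if m.pair_id not in by_id:
            raise ValidationError(f"marker {m.kind} references unknown pair {m.pair_id}")
        if m.arm != "centromere":
            if m.di is None or not (0.0 <= m.di <= 100.0):
                raise ValidationError(
                    f"marker {m.kind} outside its arm on pair {m.pair_id} (di = {m.di})"
                )

    s = style.scale
    max_short = max(p.rl_short_mean for p in pairs)
    max_long = max(p.rl_long_mean for p in pairs)
    baseline = style.margin + max_short * s
    height = baseline + max_long * s + style.margin
    width = style.margin * 2 + len(pairs) * (style.bar_width + style.gap)

    el: list[str] = []
    el.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_f(width)}" height="{_f(height)}" '
        f'viewBox="0 0 {_f(width)} {_f(height)}">'
    )
    el.append(f'<title>{karyotype.label or "karyotype"}</title>')

    # ordinate axis: RL percent, increasing upward from the baseline
    ax = style.margin * 0.5
    top_tick = max(style.ordinate_ticks)
    el.append(
        f'<line class="axis" x1="{_f(ax)}" y1="{_f(baseline)}" '
        f'x2="{_f(ax)}" y2="{_f(baseline - top_tick * s)}" '
        f'stroke="black" stroke-width="1"/>'
    )
    for t in style.ordinate_ticks:
        y = baseline - t * s
        el.append(
            f'<line class="tick" x1="{_f(ax - 4)}" y1="{_f(y)}" '
            f'x2="{_f(ax)}" y2="{_f(y)}" stroke="black" stroke-width="1"/>'
        )
        el.append(
            f'<text class="tick-label" x="{_f(ax - 7)}" y="{_f(y + 3)}" '
            f'font-size="10" text-anchor="end">{t}</text>'
        )

    for i, p in enumerate(pairs):
        x = style.margin + i * (style.bar_width + style.gap) + style.gap
        short_h = p.rl_short_mean * s
        long_h = p.rl_long_mean * s

        def bar(y0: float, h: float, cls: str) -> str:
            return (
                f'<rect class="{cls}" x="{_f(x)}" y="{_f(y0)}" '
                f'width="{_f(style.bar_width)}" height="{_f(h)}" '
                f'fill="none" stroke="black" stroke-width="1.2"/>'
            )

        # short arm above the baseline, satellite detached when flagged
        if p.satellite_arm == "short":
            sat_h = short_h * style.satellite_fraction
            body_h = short_h - sat_h - style.sc_gap * s
            el.append(bar(baseline - short_h, sat_h, f"satellite pair-{p.pair_id}"))
            el.append(bar(baseline - body_h, body_h, f"arm-short pair-{p.pair_id}"))
        else:
            el.append(bar(baseline - short_h, short_h, f"arm-short pair-{p.pair_id}"))
        if p.satellite_arm == "long":
            sat_h = long_h * style.satellite_fraction
            body_h = long_h - sat_h - style.sc_gap * s
            el.append(bar(baseline, body_h, f"arm-long pair-{p.pair_id}"))
            el.append(bar(baseline + long_h - sat_h, sat_h, f"satellite pair-{p.pair_id}"))
        else:
            el.append(bar(baseline, long_h, f"arm-long pair-{p.pair_id}"))

        # centromere mark on the common baseline
        el.append(
            f'<line class="centromere pair-{p.pair_id}" '
            f'x1="{_f(x - 2)}" y1="{_f(baseline)}" '
            f'x2="{_f(x + style.bar_width + 2)}" y2="{_f(baseline)}" '
            f'stroke="black" stroke-width="2"/>'
        )

        if style.show_sd_whiskers and p.rl_total_sd > 0:
            wy0 = baseline + long_h - p.rl_total_sd * s
            wy1 = baseline + long_h + p.rl_total_sd * s
            wx = x + style.bar_width / 2
            el.append(
                f'<line class="sd-whisker pair-{p.pair_id}" '
                f'x1="{_f(wx)}" y1="{_f(wy0)}" x2="{_f(wx)}" y2="{_f(wy1)}" '
                f'stroke="gray" stroke-width="1"/>'
            )

        el.append(
            f'<text class="pair-label" x="{_f(x + style.bar_width / 2)}" '
            f'y="{_f(style.margin - 12 + (max_short - p.rl_short_mean) * 0)}" '
            f'font-size="11" text-anchor="middle">{p.pair_id}</text>'
        )

    # marker glyphs: wider than the bar, centred at the di position
    for m in markers:
        p = by_id[m.pair_id]
        i = next(j for j, q in enumerate(pairs) if q.pair_id == m.pair_id)
        x = style.margin + i * (style.bar_width + style.gap) + style.gap
        h = m.size_percent * s
        if m.arm == "centromere":
            cy = baseline
        else:
            arm_rl = p.rl_short_mean if m.arm == "short" else p.rl_long_mean
            offset = m.di / 100.0 * arm_rl * s
            cy = baseline - offset if m.arm == "short" else baseline + offset
        color = style.marker_palette.get(m.kind, "#000000")
        el.append(
            f'<rect class="marker {m.kind} pair-{m.pair_id}" '
            f'x="{_f(x - 2)}" y="{_f(cy - h / 2)}" '
            f'width="{_f(style.bar_width + 4)}" height="{_f(h)}" '
            f'fill="{color}" fill-opacity="0.65" stroke="none"/>'
        )

    el.append("</svg>")
    return "\n".join(el)
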