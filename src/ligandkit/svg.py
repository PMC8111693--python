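"""Minimal SVG rendering for logos, Venn counts and convergence curves.

A deliberately thin layer over the numeric result types: nothing here feeds
back into any computation, and numeric tests never touch it. Output is
plain hand-assembled SVG text.
"""

from __future__ import annotations

from .convergence import ConvergenceCurve
from .motif import AMINO_ACIDS, LogoMatrix
from .overlap import VennDomains

_CHEMISTRY_COLORS = {
    **{a: "#2c7fb8" for a in "RHK"},        # basic
    **{a: "#d7301f" for a in "DE"},          # acidic
    **{a: "#31a354" for a in "STNQ"},        # polar
    **{a: "#636363" for a in "AVLIMFWPGC"},  # hydrophobic / other
    "Y": "#31a354",
}


def _svg(width: float, height: float, body: list[str]) -> str:
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" viewBox="0 0 {width:.0f} {height:.0f}">\n'
        + "\n".join(body)
        + "\n</svg>\n"
    )


def logo_svg(logo: LogoMatrix, col_width: float = 40.0, bits_px: float = 60.0) -> str:
    """Stacked-letter logo: per position, letters ordered by |height|,
    tallest furthest from the axis; depleted letters hang below it."""
    max_pos = max(float(logo.heights.max(initial=0.0)), 0.1)
    max_neg = max(float(-logo.heights.min(initial=0.0)), 0.1)
    axis_y = 20 + max_pos * bits_px
    height = axis_y + max_neg * bits_px + 30
    width = 40 + col_width * logo.length
    body = [
        f'<line x1="40" y1="{axis_y:.1f}" x2="{width:.1f}" y2="{axis_y:.1f}" '
        'stroke="black" stroke-width="1"/>'
    ]
    for i in range(logo.length):
        x = 40 + i * col_width
        up = axis_y
        down = axis_y
        # stack letters: most deviant nearest the axis end (furthest from axis)
        letters = [a for a in logo.rank_by_height[i]]
        pos_letters = [a for a in letters if logo.heights[i][AMINO_ACIDS.index(a)] > 1e-9]
        neg_letters = [a for a in letters if logo.heights[i][AMINO_ACIDS.index(a)] < -1e-9]
        for a in reversed(pos_letters):  # least deviant drawn first, closest to axis
            h = logo.heights[i][AMINO_ACIDS.index(a)] * bits_px
            up -= h
            body.append(
                f'<text x="{x + col_width / 2:.1f}" y="{up + h - 2:.1f}" '
                f'font-family="monospace" text-anchor="middle" '
                f'font-size="{max(h, 1.0):.1f}" fill="{_CHEMISTRY_COLORS[a]}">{a}</text>'
            )
        for a in reversed(neg_letters):
            h = -logo.heights[i][AMINO_ACIDS.index(a)] * bits_px
            body.append(
                f'<text x="{x + col_width / 2:.1f}" y="{down + h - 2:.1f}" '
                f'font-family="monospace" text-anchor="middle" '
                f'font-size="{max(h, 1.0):.1f}" fill="{_CHEMISTRY_COLORS[a]}" '
                f'opacity="0.7">{a}</text>'
            )
            down += h
        body.append(
            f'<text x="{x + col_width / 2:.1f}" y="{height - 8:.1f}" '
            f'font-family="sans-serif" text-anchor="middle" font-size="12">P{i + 1}</text>'
        )
    return _svg(width, height, body)


def venn2_svg(v: VennDomains, label1: str = "set 1", label2: str = "set 2") -> str:
    """Two overlapping circles with domain counts (not area-proportional)."""
    body = [
        '<circle cx="150" cy="120" r="90" fill="#1f78b4" fill-opacity="0.4"/>',
        '<circle cx="250" cy="120" r="90" fill="#33a02c" fill-opacity="0.4"/>',
        f'<text x="110" y="125" text-anchor="middle" font-family="sans-serif">{v.a1}</text>',
        f'<text x="200" y="125" text-anchor="middle" font-family="sans-serif">{v.a2}</text>',
        f'<text x="290" y="125" text-anchor="middle" font-family="sans-serif">{v.a3}</text>',
        f'<text x="110" y="235" text-anchor="middle" font-family="sans-serif" font-size="12">{label1}</text>',
        f'<text x="290" y="235" text-anchor="middle" font-family="sans-serif" font-size="12">{label2}</text>',
    ]
    return _svg(400, 250, body)


_POSITION_COLORS = [
    "#a6cee3", "#1f78b4", "#b2df8a", "#33a02c", "#fb9a99",
    "#e31a1c", "#fdbf6f", "#ff7f00", "#cab2d6", "#6a3d9a",
    "#ffff99", "#b15928", "#8dd3c7", "#bebada",
]


def convergence_svg(curve: ConvergenceCurve, width: float = 520, height: float = 320) -> str:
    """Per-position convergence vs subsample size, one colored line per position."""
    left, bottom, top, right = 50, height - 40, 20, width - 90
    n_max = max(curve.n_grid)
    body = [
        f'<line x1="{left}" y1="{bottom}" x2="{right}" y2="{bottom}" stroke="black"/>',
        f'<line x1="{left}" y1="{bottom}" x2="{left}" y2="{top}" stroke="black"/>',
        f'<text x="{(left + right) / 2}" y="{height - 10}" text-anchor="middle" '
        'font-family="sans-serif" font-size="12">peptides subsampled (N_A)</text>',
        f'<text x="14" y="{(top + bottom) / 2}" text-anchor="middle" font-family="sans-serif" '
        f'font-size="12" transform="rotate(-90 14 {(top + bottom) / 2})">convergence</text>',
    ]
    for i in range(curve.length):
        pts = []
        for gi, n in enumerate(curve.n_grid):
            x = left + (right - left) * n / n_max
            y = bottom - (bottom - top) * float(curve.values[gi, i])
            pts.append(f"{x:.1f},{y:.1f}")
        color = _POSITION_COLORS[i % len(_POSITION_COLORS)]
        body.append(
            f'<polyline points="{" ".join(pts)}" fill="none" stroke="{color}" stroke-width="1.5"/>'
        )
        body.append(
            f'<text x="{right + 8}" y="{top + 14 * i + 10}" font-family="sans-serif" '
            f'font-size="11" fill="{color}">P{i + 1}</text>'
        )
    return _svg(width, height, body)
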