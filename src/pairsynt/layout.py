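"""Static SVG rendering of one pairwise comparison.

The genomic organization display combines two complementary views in a
single figure:

* a *symbolic* track — one fixed-width glyph per annotation event, ordered
  by start position on the reference genome: a rectangle for conserved
  synteny, a bowtie when the synteny is reversed, a single-gene homology
  glyph for one-anchor blocks, and (at half height, below) rectangles or
  plain lines for genome-specific regions with or without genes;
* a *proportional* view — two horizontal tracks whose x-axes are affine
  images of concatenated bp coordinates (replicons consecutive, in file
  order), with a trapezoid joining the reference and compared spans of each
  synteny block and a triangular marker tying every symbol to its
  proportional location.

Rendering is deterministic: the same model always yields the same bytes.
Glyph kinds are exposed as CSS classes so the output is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .genome_io import GenomeCatalog, ValidationError
from .synteny import AnnotationEvent, REVERSED

GLYPH_SYNTENY = "synteny-rect"
GLYPH_BOWTIE = "bowtie"
GLYPH_GENE_HOMOLOGY = "gene-homology"
GLYPH_EMPTY_REGION = "empty-region-line"
GLYPH_GENE_REGION = "gene-region-rect"

_SYMBOL_W = 26.0
_SYMBOL_H = 22.0
_GAP = 6.0
_TRACK_W = 640.0


@dataclass(frozen=True)
class Symbol:
    glyph: str
    ordinal: int
    kind: str           # event kind
    x: float            # symbolic-track x of the left edge
    half_scale: bool    # compared-genome-specific regions draw at half size
    ref_span: Optional[tuple]   # (start, end) concatenated ref bp, if any
    cmp_span: Optional[tuple]


@dataclass
class LayoutModel:
    """Placed symbols, proportional track transforms and trapezoids."""

    symbols: list
    ref_track: tuple     # (bp_lo, bp_hi, x0, x1) affine map of the ref track
    cmp_track: tuple
    trapezoids: list     # (symbol index, ref x0, ref x1, cmp x0, cmp x1)

    def ref_x(self, bp: float) -> float:
        return _affine(self.ref_track, bp)

    def cmp_x(self, bp: float) -> float:
        return _affine(self.cmp_track, bp)


def _affine(track, bp):
    lo, hi, x0, x1 = track
    if hi == lo:
        return x0
    return x0 + (min(max(bp, lo), hi) - lo) * (x1 - x0) / (hi - lo)


def _glyph_for(ev: AnnotationEvent) -> tuple:
    if ev.kind == "synteny":
        b = ev.block
        if b.orientation == REVERSED:
            return GLYPH_BOWTIE, False
        if b.n_anchors == 1:
            return GLYPH_GENE_HOMOLOGY, False
        return GLYPH_SYNTENY, False
    half = ev.kind == "cmp_specific"
    if ev.gene_ids:
        return GLYPH_GENE_REGION, half
    return GLYPH_EMPTY_REGION, half


def build_layout(events, ref: GenomeCatalog = None, cmp: GenomeCatalog = None,
                 window: tuple = None) -> LayoutModel:
    """Build the deterministic layout model of an event chain.

    *window* is an optional (start, end) bp range on the concatenated
    reference coordinates; symbols whose reference span falls wholly
    outside it are dropped and the proportional tracks are clipped to it.
    Catalogs, when given, supply replicon offsets and total lengths for the
    proportional tracks; otherwise spans in the events are used as-is.
    """
    ref_off = ref.cumulative_offsets if ref else {}
    cmp_off = cmp.cumulative_offsets if cmp else {}

    def ref_bp(ev):
        off = ref_off.get(ev.replicon_id, 0)
        return (ev.start + off, ev.end + off)

    def cmp_bp(ev):
        if ev.kind == "synteny":
            b = ev.block
            off = cmp_off.get(b.cmp_replicon, 0)
            return (b.cmp_start + off, b.cmp_end + off)
        if ev.kind == "cmp_specific":
            off = cmp_off.get(ev.replicon_id, 0)
            return (ev.start + off, ev.end + off)
        return None

    placed = []
    for ev in events:
        glyph, half = _glyph_for(ev)
        rspan = ref_bp(ev) if ev.kind != "cmp_specific" else None
        cspan = cmp_bp(ev)
        if window is not None and rspan is not None:
            if rspan[1] < window[0] or rspan[0] > window[1]:
                continue
        placed.append((ev, glyph, half, rspan, cspan))

    ref_total = ref.total_bp if ref else max((s[1] for _, _, _, s, _ in placed if s),
                                             default=1)
    cmp_total = cmp.total_bp if cmp else max((s[1] for *_, s in placed if s),
                                             default=1)
    ref_lo, ref_hi = (window if window is not None else (0, ref_total))
    ref_track = (float(ref_lo), float(ref_hi), 40.0, 40.0 + _TRACK_W)
    cmp_track = (0.0, float(cmp_total), 40.0, 40.0 + _TRACK_W)
    model = LayoutModel([], ref_track, cmp_track, [])

    x = 40.0
    for ev, glyph, half, rspan, cspan in placed:
        w = _SYMBOL_W / (2 if half else 1)
        model.symbols.append(Symbol(glyph, ev.ordinal, ev.kind, x, half, rspan, cspan))
        if ev.kind == "synteny" and rspan and cspan:
            model.trapezoids.append((
                len(model.symbols) - 1,
                model.ref_x(rspan[0]), model.ref_x(rspan[1]),
                model.cmp_x(cspan[0]), model.cmp_x(cspan[1]),
            ))
        x += w + _GAP
    return model


# ---------------------------------------------------------------------------
# SVG output
# ---------------------------------------------------------------------------

_CSS = """
.synteny-rect{fill:#7fb2e5;stroke:#2c5f8a}
.bowtie{fill:#e5a77f;stroke:#8a522c}
.gene-homology{fill:#9fd49f;stroke:#3a7a3a}
.gene-region-rect{fill:#d9d9d9;stroke:#777}
.empty-region-line{stroke:#777;stroke-width:1.5}
.track{stroke:#333;stroke-width:2}
.trapezoid{fill:#7fb2e5;fill-opacity:0.35;stroke:#2c5f8a;stroke-width:0.5}
.marker{fill:#444}
""".strip()

_Y_SYMBOL = 40.0
_Y_REF = 120.0
_Y_CMP = 200.0


def _rect(x, y, w, h, cls):
    return (f'<rect class="{cls}" x="{x:.2f}" y="{y:.2f}" '
            f'width="{w:.2f}" height="{h:.2f}"/>')


def _bowtie(x, y, w, h, cls):
    pts = [(x, y), (x + w, y + h), (x + w, y), (x, y + h)]
    p = " ".join(f"{px:.2f},{py:.2f}" for px, py in pts)
    return f'<polygon class="{cls}" points="{p}"/>'


def render_svg(model: LayoutModel, path) -> None:
    """Write the model as a standalone SVG 1.1 document (deterministic)."""
    width = max(720.0, (model.symbols[-1].x + _SYMBOL_W + 40.0) if model.symbols
                else 720.0)
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width:.0f}" height="260">',
        f"<style>{_CSS}</style>",
        # proportional track backbones
        f'<line class="track" x1="{model.ref_track[2]:.2f}" y1="{_Y_REF:.2f}" '
        f'x2="{model.ref_track[3]:.2f}" y2="{_Y_REF:.2f}"/>',
        f'<line class="track" x1="{model.cmp_track[2]:.2f}" y1="{_Y_CMP:.2f}" '
        f'x2="{model.cmp_track[3]:.2f}" y2="{_Y_CMP:.2f}"/>',
    ]
    for idx, rx0, rx1, cx0, cx1 in model.trapezoids:
        p = (f"{rx0:.2f},{_Y_REF:.2f} {rx1:.2f},{_Y_REF:.2f} "
             f"{cx1:.2f},{_Y_CMP:.2f} {cx0:.2f},{_Y_CMP:.2f}")
        parts.append(f'<polygon class="trapezoid" points="{p}"/>')
    for s in model.symbols:
        h = _SYMBOL_H / (2 if s.half_scale else 1)
        w = _SYMBOL_W / (2 if s.half_scale else 1)
        y = _Y_SYMBOL + (_SYMBOL_H - h)  # half-size glyphs hug the bottom edge
        if s.glyph == GLYPH_BOWTIE:
            parts.append(_bowtie(s.x, y, w, h, s.glyph))
        elif s.glyph == GLYPH_EMPTY_REGION:
            ym = y + h / 2
            parts.append(f'<line class="{s.glyph}" x1="{s.x:.2f}" y1="{ym:.2f}" '
                         f'x2="{s.x + w:.2f}" y2="{ym:.2f}"/>')
        else:
            parts.append(_rect(s.x, y, w, h, s.glyph))
        # triangular marker at the proportional location of the symbol
        span = s.ref_span if s.ref_span is not None else s.cmp_span
        if span is not None:
            xm = (model.ref_x if s.ref_span is not None else model.cmp_x)(
                (span[0] + span[1]) / 2)
            ym = _Y_REF if s.ref_span is not None else _Y_CMP
            parts.append(
                f'<polygon class="marker" points="{xm:.2f},{ym - 8:.2f} '
                f"{xm - 4:.2f},{ym - 2:.2f} {xm + 4:.2f},{ym - 2:.2f}\"/>")
    parts.append("</svg>")
    try:
        Path(path).write_text("\n".join(parts) + "\n")
    except OSError as exc:
        raise ValidationError(f"cannot write SVG to {path}: {exc}") from exc
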