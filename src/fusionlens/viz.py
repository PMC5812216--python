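"""Static evidence plots: color-coded read tracks around the junction.

Each panel reference gets a deterministic color; a read takes the color of the
reference it aligned to, so a junction-crossing read shows two colors meeting
at the dashed breakpoint guide.  Mates are co-plotted on one row joined by a
thin connector.  Output is a standalone SVG, a single-file HTML report with an
embedded sortable table, and machine-readable TSV/JSON tables; all outputs are
byte-stable for identical inputs.
"""
from __future__ import annotations

import dataclasses
import html
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .alignment import AlignmentResult, ReferencePanel
from .filters import FilterSettings, group_pairs

logger = logging.getLogger("fusionlens")

# Okabe-Ito colorblind-safe palette, extended
PALETTE = [
    "#0072B2", "#E69F00", "#009E73", "#D55E00",
    "#CC79A7", "#56B4E9", "#F0E442", "#999999",
    "#332288", "#44AA99", "#882255", "#117733",
]


def _shade(color: str, step: int) -> str:
    """Darken a hex color by 18% per step (palette overflow)."""
    r, g, b = (int(color[i:i + 2], 16) for i in (1, 3, 5))
    factor = 0.82 ** step
    return "#{:02X}{:02X}{:02X}".format(*(max(0, int(c * factor)) for c in (r, g, b)))


def assign_colors(panel: ReferencePanel) -> Dict[str, str]:
    """Deterministic label -> color map; colors follow labels, not positions."""
    labels = sorted(ref.label for ref in panel.left_refs + panel.right_refs)
    if len(labels) > len(PALETTE):
        logger.warning("panel has %d references but palette only %d colors; "
                       "cycling with shade variation", len(labels), len(PALETTE))
    mapping = {}
    for k, label in enumerate(labels):
        mapping[label] = _shade(PALETTE[k % len(PALETTE)], k // len(PALETTE))
    return mapping


@dataclass
class Segment:
    label: str
    color: str
    x0: float  # junction-relative offsets; left refs end at 0, right start at 0
    x1: float


@dataclass
class ReadTrack:
    row: int
    name: str
    segments: List[Segment]
    strands: List[str]
    alphas: List[float]
    spanning: bool
    mate_indices: List[Optional[int]]
    connector: Optional[Tuple[float, float]] = None


@dataclass
class PlotModel:
    tracks: List[ReadTrack]
    legend: List[Tuple[str, str]]  # (label, color)
    xmin: float
    xmax: float


def _result_segments(res: AlignmentResult, panel: ReferencePanel,
                     colors: Dict[str, str]) -> List[Segment]:
    segs = []
    if res.left_ref_index is not None:
        n_f = len(panel.left_refs[res.left_ref_index])
        # ref position p (1-based) sits at junction offset p - n_f - 1 in [-n_f, -1]
        segs.append(Segment(res.left_ref_label, colors[res.left_ref_label],
                            res.left_ref_start - n_f - 1,
                            res.left_ref_end - n_f))
    if res.right_ref_index is not None:
        segs.append(Segment(res.right_ref_label, colors[res.right_ref_label],
                            res.right_ref_start - 1, res.right_ref_end))
    return segs


def _group_sort_key(group: List[AlignmentResult]) -> Tuple[int, float, str]:
    spanning = any(r.spanning for r in group)
    left_only = all(r.right_ref_index is None for r in group)
    if spanning:
        cat = 0
    elif left_only:
        cat = 1
    else:
        cat = 2
    return (cat, -max(r.alpha for r in group), group[0].name)


def layout_tracks(results: List[AlignmentResult], panel: ReferencePanel,
                  settings: FilterSettings) -> PlotModel:
    """Arrange (already filtered) results into ordered read tracks.

    Spanning reads come first, then left-only, then right-only, each by
    descending score; mates share a row with a connector.
    """
    colors = assign_colors(panel)
    groups = group_pairs(results) if settings.paired else [[r] for r in results]
    groups.sort(key=_group_sort_key)
    tracks: List[ReadTrack] = []
    xmin, xmax = -1.0, 1.0
    for row, group in enumerate(groups):
        segs: List[Segment] = []
        extents: List[Tuple[float, float]] = []
        for res in group:
            rsegs = _result_segments(res, panel, colors)
            segs.extend(rsegs)
            if rsegs:
                extents.append((min(s.x0 for s in rsegs), max(s.x1 for s in rsegs)))
        connector = None
        if len(extents) > 1:
            spans = sorted(extents)
            connector = (spans[0][1], spans[-1][0])
        for s in segs:
            xmin, xmax = min(xmin, s.x0), max(xmax, s.x1)
        tracks.append(ReadTrack(
            row=row, name=group[0].name, segments=segs,
            strands=[r.strand for r in group],
            alphas=[r.alpha for r in group],
            spanning=any(r.spanning for r in group),
            mate_indices=[r.mate_index for r in group],
            connector=connector))
    legend = sorted(colors.items())
    return PlotModel(tracks=tracks, legend=legend, xmin=xmin, xmax=xmax)


_TRACK_H = 10
_LEGEND_H = 16
_MARGIN = 40


def render_svg(plot: PlotModel) -> str:
    """Standalone SVG: one glyph group per track, legend entries, junction guide."""
    width = 800
    span = plot.xmax - plot.xmin or 1.0
    scale = (width - 2 * _MARGIN) / span

    def x(off: float) -> float:
        return _MARGIN + (off - plot.xmin) * scale

    legend_rows = (len(plot.legend) + 1) // 2
    top = 10 + legend_rows * _LEGEND_H + 10
    height = top + max(1, len(plot.tracks)) * _TRACK_H + 20
    out = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
           f'height="{height}" font-family="sans-serif" font-size="9">']
    for k, (label, color) in enumerate(plot.legend):
        lx = 10 + (k % 2) * (width // 2)
        ly = 10 + (k // 2) * _LEGEND_H
        out.append(f'<g class="legend"><rect x="{lx}" y="{ly}" width="10" '
                   f'height="10" fill="{color}"/>'
                   f'<text x="{lx + 14}" y="{ly + 9}">{html.escape(label)}</text></g>')
    guide_x = f"{x(0.0):.1f}"
    out.append(f'<line class="guide" x1="{guide_x}" y1="{top - 5}" x2="{guide_x}" '
               f'y2="{height - 10}" stroke="#000" stroke-dasharray="4,3"/>')
    for track in plot.tracks:
        y = top + track.row * _TRACK_H
        meta = " ".join(
            f"mate{m or 1}:alpha={a:.2f},strand={s}"
            for m, a, s in zip(track.mate_indices, track.alphas, track.strands))
        out.append(f'<g class="read"><title>{html.escape(track.name)} '
                   f'{html.escape(meta)} spanning={str(track.spanning).lower()}</title>')
        if track.connector is not None:
            cx0, cx1 = sorted(track.connector)
            out.append(f'<line x1="{x(cx0):.1f}" y1="{y + 3}" x2="{x(cx1):.1f}" '
                       f'y2="{y + 3}" stroke="#bbb" stroke-width="1"/>')
        for seg in track.segments:
            out.append(f'<rect x="{x(seg.x0):.1f}" y="{y}" '
                       f'width="{max(1.0, (seg.x1 - seg.x0) * scale):.1f}" height="6" '
                       f'fill="{seg.color}"/>')
        out.append("</g>")
    out.append("</svg>")
    return "\n".join(out)


def results_table(results: List[AlignmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "read": r.name,
            "mate": r.mate_index if r.mate_index is not None else 0,
            "strand": r.strand,
            "alpha": round(r.alpha, 2),
            "left_ref": r.left_ref_label or ".",
            "right_ref": r.right_ref_label or ".",
            "spanning": r.spanning,
            "anchor": r.anchor_length,
            "cigar": r.cigar() or ".",
        })
    return pd.DataFrame(rows, columns=["read", "mate", "strand", "alpha",
                                       "left_ref", "right_ref", "spanning",
                                       "anchor", "cigar"])


def _result_json(r: AlignmentResult) -> dict:
    d = dataclasses.asdict(r)
    d["path"] = [list(step) for step in d["path"]]
    d["alpha"] = round(r.alpha, 2)
    return d


def render(plot: PlotModel, results: List[AlignmentResult], out_dir: str,
           basename: str = "fusion_evidence") -> Dict[str, str]:
    """Write SVG, HTML report, TSV and JSON; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    svg = render_svg(plot)
    table = results_table(results)
    paths = {
        "svg": os.path.join(out_dir, f"{basename}.svg"),
        "html": os.path.join(out_dir, f"{basename}.html"),
        "tsv": os.path.join(out_dir, f"{basename}.tsv"),
        "json": os.path.join(out_dir, f"{basename}.json"),
    }
    try:
        with open(paths["svg"], "w") as fh:
            fh.write(svg)
        table.to_csv(paths["tsv"], sep="\t", index=False)
        with open(paths["json"], "w") as fh:
            json.dump([_result_json(r) for r in results], fh, indent=1,
                      sort_keys=True)
        table_html = table.to_html(index=False, border=0)
        with open(paths["html"], "w") as fh:
            fh.write("<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
                     "<title>Fusion breakpoint evidence</title></head><body>\n"
                     "<h1>Fusion breakpoint evidence</h1>\n"
                     f"{svg}\n<h2>Retained reads</h2>\n{table_html}\n"
                     "</body></html>\n")
    except OSError as exc:
        raise OSError(f"failed writing report under {out_dir}: {exc}") from exc
    return paths
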