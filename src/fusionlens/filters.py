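"""Score and spanning filters over realignment results.

The minimum-score filter is inclusive (alpha >= min_alpha keeps the read), so
a threshold of 95 retains reads scoring exactly 95.  In paired mode both mates
must pass the score threshold for the pair to be kept, and under the spanning
filter a pair survives when at least one mate spans the junction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from .alignment import AlignmentResult


@dataclass
class FilterSettings:
    min_alpha: float = 0.0
    spanning_only: bool = False
    paired: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_alpha <= 100.0:
            raise ValueError("min_alpha must be within [0, 100]")


def group_pairs(results: List[AlignmentResult]) -> List[List[AlignmentResult]]:
    """Group results by read name, preserving first-seen order; mates sorted."""
    groups: Dict[str, List[AlignmentResult]] = {}
    order: List[str] = []
    for res in results:
        if res.name not in groups:
            groups[res.name] = []
            order.append(res.name)
        groups[res.name].append(res)
    out = []
    for name in order:
        out.append(sorted(groups[name], key=lambda r: r.mate_index or 0))
    return out


def apply_filters(results: List[AlignmentResult],
                  settings: FilterSettings) -> List[AlignmentResult]:
    """Retained results, flat, in input order (pairs kept or dropped whole)."""
    if not settings.paired:
        return [r for r in results
                if r.alpha >= settings.min_alpha
                and (not settings.spanning_only or r.spanning)]
    kept: List[AlignmentResult] = []
    for group in group_pairs(results):
        if all(r.alpha >= settings.min_alpha for r in group) and (
                not settings.spanning_only or any(r.spanning for r in group)):
            kept.extend(group)
    return kept
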