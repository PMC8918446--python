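"""Figural and textual output: the traffic-light grid and score reports.

The grid follows the risk-of-bias "traffic light" idiom: one row per
instrument item (grouped by content domain), one column per agent, each
cell red / yellow / green for a score of 0 / 1 / 2 with the numeral
overlaid.  Cells whose score is unknown (partial profiles transcribed from
published prose) are rendered grey.  Rendering is deterministic: identical
inputs give byte-identical SVG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union
from xml.sax.saxutils import escape

import yaml

from .scoring_engine import ITEM_GROUPS, ITEM_IDS, ScoreProfile

__all__ = [
    "DEFAULT_COLORS",
    "UNKNOWN_COLOR",
    "TOTAL_CAUTION",
    "PartialProfile",
    "load_profiles",
    "render_grid",
    "render_report",
]

#: Score → fill colour (colour-blind-considered red/yellow/green).
DEFAULT_COLORS: dict[int, str] = {0: "#d73027", 1: "#fec44f", 2: "#1a9850"}

#: Fill for cells whose score is not known.
UNKNOWN_COLOR = "#bdbdbd"

#: Wording attached to every printed summary total.
TOTAL_CAUTION = (
    "Use the summary total with caution: it fails to convey the granular "
    "information of each scale item."
)


@dataclass
class PartialProfile:
    """An 11-item profile in which some cells may be unknown (None)."""

    agent_id: str
    agent_name: str = ""
    scores: dict[str, Optional[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown_items = set(self.scores) - set(ITEM_IDS)
        if unknown_items:
            raise ValueError(f"unknown item ids: {sorted(unknown_items)}")
        for item in ITEM_IDS:
            self.scores.setdefault(item, None)
        for item, score in self.scores.items():
            if score is not None and score not in (0, 1, 2):
                raise ValueError(f"{item}: score must be 0, 1, 2 or unknown")

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.scores.values())

    @property
    def total(self) -> Optional[int]:
        if not self.complete:
            return None
        return sum(self.scores.values())  # type: ignore[arg-type]


ProfileLike = Union[ScoreProfile, PartialProfile]


def _as_partial(profile: ProfileLike) -> PartialProfile:
    if isinstance(profile, PartialProfile):
        return profile
    return PartialProfile(
        agent_id=profile.agent_id,
        scores={item.item_id: item.score for item in profile.items},
    )


def load_profiles(path) -> list[PartialProfile]:
    """Load a YAML score-profile sheet (one entry per agent).

    Layout::

        agents:
          - agent_id: nerinetide
            agent_name: "Nerinetide (NA1)"
            items: {age: 2, sex: 0, ..., behavioral: ~}

    ``~`` (null) marks a cell whose score is unknown; it renders grey.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "agents" not in doc:
        raise ValueError("profile sheet must be a mapping with an 'agents' list")
    out = []
    for entry in doc["agents"]:
        out.append(PartialProfile(
            agent_id=str(entry["agent_id"]),
            agent_name=str(entry.get("agent_name", "")),
            scores=dict(entry.get("items", {})),
        ))
    return out


_CELL_W = 64
_CELL_H = 26
_LABEL_W = 170
_HEADER_H = 34
_GROUP_GAP = 8
_FONT = "font-family=\"Helvetica, Arial, sans-serif\""


def render_grid(
    profiles: Sequence[ProfileLike],
    colors: Optional[dict[int, str]] = None,
    item_order: Optional[Sequence[str]] = None,
    agent_order: Optional[Sequence[str]] = None,
    show_totals: bool = True,
) -> str:
    """Render profiles as a traffic-light SVG grid (returned as text).

    One row per item in ``item_order`` (default: the instrument order,
    grouped by domain with separator gaps), one column per agent.  A totals
    row is appended when every profile is complete and ``show_totals`` is
    set.  Data cells carry ``data-item`` / ``data-agent`` / ``data-score``
    attributes for downstream tooling.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    partials = [_as_partial(p) for p in profiles]
    item_sets = {frozenset(p.scores) for p in partials}
    if len(item_sets) != 1:
        raise ValueError("all profiles must carry the same item set")
    colors = dict(DEFAULT_COLORS if colors is None else colors)
    if agent_order is not None:
        by_id = {p.agent_id: p for p in partials}
        missing = [a for a in agent_order if a not in by_id]
        if missing:
            raise ValueError(f"agent_order names unknown agents: {missing}")
        partials = [by_id[a] for a in agent_order]
    items = list(item_order) if item_order is not None else list(ITEM_IDS)
    if sorted(items) != sorted(ITEM_IDS):
        raise ValueError("item_order must be a permutation of the 11 items")

    # rows follow domain grouping when the default order is used
    group_after: set[str] = set()
    if item_order is None:
        for _, group_items in ITEM_GROUPS[:-1]:
            group_after.add(group_items[-1])

    totals = show_totals and all(p.complete for p in partials)
    width = _LABEL_W + _CELL_W * len(partials) + 10
    n_gaps = len(group_after)
    n_rows = len(items) + (1 if totals else 0)
    height = _HEADER_H + _CELL_H * n_rows + _GROUP_GAP * n_gaps + 10

    parts: list[str] = []
    parts.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">')
    parts.append(f'<rect width="{width}" height="{height}" fill="#ffffff"/>')
    for col, prof in enumerate(partials):
        x = _LABEL_W + col * _CELL_W + _CELL_W / 2
        label = escape(prof.agent_name or prof.agent_id)
        parts.append(
            f'<text x="{x:g}" y="{_HEADER_H - 12}" text-anchor="middle" '
            f'font-size="11" {_FONT}>{label}</text>')
    y = _HEADER_H
    for item in items:
        parts.append(
            f'<text x="{_LABEL_W - 8}" y="{y + _CELL_H / 2 + 4:g}" '
            f'text-anchor="end" font-size="11" {_FONT}>{escape(item)}</text>')
        for col, prof in enumerate(partials):
            x = _LABEL_W + col * _CELL_W
            score = prof.scores[item]
            fill = UNKNOWN_COLOR if score is None else colors[score]
            parts.append(
                f'<rect x="{x}" y="{y}" width="{_CELL_W}" height="{_CELL_H}" '
                f'fill="{fill}" stroke="#ffffff" stroke-width="2" '
                f'data-item="{escape(item)}" data-agent="{escape(prof.agent_id)}" '
                f'data-score="{"" if score is None else score}"/>')
            if score is not None:
                parts.append(
                    f'<text x="{x + _CELL_W / 2:g}" y="{y + _CELL_H / 2 + 4:g}" '
                    f'text-anchor="middle" font-size="12" fill="#ffffff" '
                    f'{_FONT}>{score}</text>')
        y += _CELL_H
        if item in group_after:
            y += _GROUP_GAP
    if totals:
        parts.append(
            f'<text x="{_LABEL_W - 8}" y="{y + _CELL_H / 2 + 4:g}" '
            f'text-anchor="end" font-size="11" font-weight="bold" '
            f'{_FONT}>total</text>')
        for col, prof in enumerate(partials):
            x = _LABEL_W + col * _CELL_W
            parts.append(
                f'<text x="{x + _CELL_W / 2:g}" y="{y + _CELL_H / 2 + 4:g}" '
                f'text-anchor="middle" font-size="12" font-weight="bold" '
                f'{_FONT}>{prof.total}</text>')
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render_report(profile: ScoreProfile) -> str:
    """Render a per-agent markdown report: item table, rationale, total."""
    lines = [
        f"# PRIMED² readiness profile: {profile.agent_id}",
        "",
        "| item | score | contributing studies | rationale |",
        "| --- | ---: | --- | --- |",
    ]
    for item in profile.items:
        studies = ", ".join(item.contributing_study_ids) or "—"
        lines.append(
            f"| {item.item_id} | {item.score} | {studies} | {item.rationale} |")
    lines += [
        "",
        f"**Summary total: {profile.total} / 22.** {TOTAL_CAUTION}",
        "",
    ]
    return "\n".join(lines)
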