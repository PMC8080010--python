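"""Mapping independent complex I losses onto a species tree.

An *independent loss event* is a maximal clade whose known-status tips
are all CI-absent while the surrounding tree still contains CI-present
tips; under parsimony with irreversible loss each such clade corresponds
to exactly one loss on the branch leading to it. Events are classified
as *ancient* (tips span several genera) or *recent* (confined to one
genus that still contains a CI-bearing congener elsewhere in the tree).

Tips with ``unknown`` or ``conflicting`` status are ignored when
evaluating clade uniformity: species without usable mitochondrial data
cannot distinguish CI loss from missing data and are excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .trees import ABSENT, PRESENT, SpeciesTree

__all__ = [
    "LossEvent",
    "find_independent_losses",
    "classify_recency",
    "count_events_per_supergroup",
    "map_losses",
    "write_events_tsv",
]

RECENT = "recent"
ANCIENT = "ancient"
RECENT_UNCONFIRMED = "recent_unconfirmed"


@dataclass(frozen=True)
class LossEvent:
    """One independent CI loss: a maximal clade of CI-absent species."""

    clade_node_id: str
    tip_set: frozenset[str]
    n_genera: int | None = None
    recency: str | None = None


def find_independent_losses(stree: SpeciesTree) -> list[LossEvent]:
    """Enumerate maximal CI-absent clades as independent loss events.

    Returns events in preorder; their tip sets are pairwise disjoint.
    Raises ``ValueError`` if no tip has a known status.
    """
    known = [t for t, s in stree.status.items() if s in (PRESENT, ABSENT)]
    if not known:
        raise ValueError("no tip has a known CI status")

    # Postorder tally of known present/absent tips below each node.
    tallies: dict[int, tuple[int, int]] = {}
    for node in stree.tree.postorder_node_iter():
        if node.is_leaf():
            s = stree.status[node.taxon.label]
            tallies[id(node)] = (int(s == PRESENT), int(s == ABSENT))
        else:
            p = sum(tallies[id(c)][0] for c in node.child_nodes())
            a = sum(tallies[id(c)][1] for c in node.child_nodes())
            tallies[id(node)] = (p, a)

    def qualifies(node) -> bool:
        p, a = tallies[id(node)]
        return p == 0 and a > 0

    events: list[LossEvent] = []
    for node in stree.tree.preorder_node_iter():
        if not qualifies(node):
            continue
        parent = node.parent_node
        if parent is not None and qualifies(parent):
            continue  # not maximal
        tips = frozenset(
            t for t in stree.leafset(node) if stree.status[t] == ABSENT
        )
        n_genera = None
        if stree.genus:
            n_genera = len({stree.genus[t] for t in tips if t in stree.genus})
        events.append(
            LossEvent(
                clade_node_id=SpeciesTree._node_id(node),
                tip_set=tips,
                n_genera=n_genera,
            )
        )
    return events


def classify_recency(event: LossEvent, stree: SpeciesTree) -> str:
    """Classify a loss event as ancient, recent or recent_unconfirmed.

    *Ancient* losses span several genera. A single-genus loss is
    *recent* when the genus still contains a CI-present species outside
    the event; when no such congener exists the classification cannot be
    confirmed and ``recent_unconfirmed`` is returned rather than a
    guess.
    """
    try:
        genera = {stree.genus[t] for t in event.tip_set}
    except KeyError as exc:
        raise ValueError(f"missing genus label for tip {exc.args[0]!r}") from exc
    if len(genera) >= 2:
        return ANCIENT
    (genus,) = genera
    congeners = [
        t
        for t in stree.tip_labels()
        if stree.genus.get(t) == genus and t not in event.tip_set
    ]
    if any(stree.status[t] == PRESENT for t in congeners):
        return RECENT
    return RECENT_UNCONFIRMED


def map_losses(stree: SpeciesTree) -> list[LossEvent]:
    """Find independent losses and classify their recency in one pass."""
    events = find_independent_losses(stree)
    if not stree.genus:
        return events
    return [replace(ev, recency=classify_recency(ev, stree)) for ev in events]


def count_events_per_supergroup(
    events: Sequence[LossEvent], tip_to_group: Mapping[str, str]
) -> dict[str, int]:
    """Count loss events per taxonomic supergroup.

    Each event is assigned to the modal supergroup of its tips (ties are
    broken alphabetically, and a mixed-group event triggers no error:
    taxonomy supergroups are normally much deeper than loss clades).
    Raises ``ValueError`` for tips absent from the mapping.
    """
    counts: dict[str, int] = {}
    for ev in events:
        groups = []
        for tip in sorted(ev.tip_set):
            if tip not in tip_to_group:
                raise ValueError(f"tip {tip!r} has no supergroup mapping")
            groups.append(tip_to_group[tip])
        tally = Counter(groups)
        top = max(tally.values())
        group = min(g for g, n in tally.items() if n == top)
        counts[group] = counts.get(group, 0) + 1
    return counts


def write_events_tsv(events: Sequence[LossEvent], path: str | Path) -> None:
    rows = [
        {
            "event_id": f"loss{i:02d}",
            "node": ev.clade_node_id,
            "tips": ",".join(sorted(ev.tip_set)),
            "n_genera": "" if ev.n_genera is None else ev.n_genera,
            "recency": ev.recency or "",
        }
        for i, ev in enumerate(events)
    ]
    pd.DataFrame(
        rows, columns=["event_id", "node", "tips", "n_genera", "recency"]
    ).to_csv(path, sep="\t", index=False)
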