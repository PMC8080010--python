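"""Rooted species trees with per-tip complex I state.

A :class:`SpeciesTree` wraps a rooted (possibly non-binary) dendropy tree
together with per-tip metadata: the complex I (CI) state of every species
(``present``/``absent``/``unknown``), and optional genus and supergroup
labels used to classify loss events and summarise them taxonomically.

Trees are exchanged as Newick plus a tip-metadata TSV with columns
``species_id``, ``status`` and optionally ``genus`` and ``supergroup``.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import dendropy
import pandas as pd

__all__ = [
    "PRESENT",
    "ABSENT",
    "UNKNOWN",
    "SpeciesTree",
    "monophyletic_state_nodes",
]

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"

_VALID_STATES = frozenset({PRESENT, ABSENT, UNKNOWN})


class SpeciesTree:
    """A rooted species tree whose tips carry a CI presence state.

    Parameters
    ----------
    tree:
        Rooted dendropy tree. Tip taxon labels are the species ids.
    status:
        Mapping species id -> ``present`` / ``absent`` / ``unknown``.
        Species not listed are treated as ``unknown``.
    genus, supergroup:
        Optional per-species taxonomy labels.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        status: Mapping[str, str],
        genus: Mapping[str, str] | None = None,
        supergroup: Mapping[str, str] | None = None,
    ) -> None:
        self.tree = tree
        tips = self.tip_labels()
        if len(tips) != len(set(tips)):
            raise ValueError("tip labels must be unique")
        self.status: dict[str, str] = {}
        for tip in tips:
            state = status.get(tip, UNKNOWN)
            if state not in _VALID_STATES:
                raise ValueError(f"invalid CI status {state!r} for tip {tip!r}")
            self.status[tip] = state
        self.genus = dict(genus) if genus is not None else {}
        self.supergroup = dict(supergroup) if supergroup is not None else {}
        self._label_nodes()

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        newick: str,
        status: Mapping[str, str],
        genus: Mapping[str, str] | None = None,
        supergroup: Mapping[str, str] | None = None,
    ) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree, status, genus=genus, supergroup=supergroup)

    @classmethod
    def read(cls, newick_path: str | Path, states_path: str | Path) -> "SpeciesTree":
        """Load from a Newick file plus a tip-metadata TSV."""
        newick = Path(newick_path).read_text()
        meta = pd.read_csv(states_path, sep="\t", dtype=str)
        status = dict(zip(meta["species_id"], meta["status"]))
        genus = (
            dict(zip(meta["species_id"], meta["genus"]))
            if "genus" in meta.columns
            else None
        )
        supergroup = (
            dict(zip(meta["species_id"], meta["supergroup"]))
            if "supergroup" in meta.columns
            else None
        )
        return cls.from_newick(newick, status, genus=genus, supergroup=supergroup)

    # -- serialisation --------------------------------------------------

    def to_newick(self) -> str:
        out = io.StringIO()
        self.tree.write(
            file=out,
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return out.getvalue().strip()

    def write(self, newick_path: str | Path, states_path: str | Path) -> None:
        Path(newick_path).write_text(self.to_newick() + "\n")
        rows = []
        for tip in self.tip_labels():
            rows.append(
                {
                    "species_id": tip,
                    "status": self.status[tip],
                    "genus": self.genus.get(tip, ""),
                    "supergroup": self.supergroup.get(tip, ""),
                }
            )
        pd.DataFrame(rows).to_csv(states_path, sep="\t", index=False)

    # -- queries --------------------------------------------------------

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def tips_with_status(self, state: str) -> list[str]:
        return [t for t in self.tip_labels() if self.status[t] == state]

    def node_by_id(self, node_id: str) -> dendropy.Node:
        for node in self.tree.preorder_node_iter():
            if self._node_id(node) == node_id:
                return node
        raise KeyError(node_id)

    def leafset(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(leaf.taxon.label for leaf in node.leaf_iter())

    def is_monophyletic(self, tips: Iterable[str], ignore: Iterable[str] = ()) -> bool:
        """True if ``tips`` form a clade, ignoring ``ignore`` tips.

        A tip set is treated as monophyletic when some node's leaf set,
        after removing ignored tips, equals the set exactly.
        """
        target = frozenset(tips)
        skip = frozenset(ignore)
        for node in self.tree.preorder_node_iter():
            if self.leafset(node) - skip == target:
                return True
        return False

    def _label_nodes(self) -> None:
        for i, node in enumerate(self.tree.preorder_node_iter()):
            node._ciloss_id = f"n{i}" if node.taxon is None else node.taxon.label

    @staticmethod
    def _node_id(node: dendropy.Node) -> str:
        return node._ciloss_id

    def iter_nodes(self) -> Iterator[dendropy.Node]:
        return self.tree.preorder_node_iter()


def monophyletic_state_nodes(
    stree: SpeciesTree, maximal_only: bool = True, include_leaves: bool = True
) -> list[tuple[str, frozenset[str], str]]:
    """Enumerate nodes whose known-status tips share one CI state.

    Tips with ``unknown`` status are ignored when evaluating uniformity.
    With ``maximal_only`` each uniform clade is reported once, at the
    deepest node not contained in a larger uniform clade of the same
    state; otherwise every uniform node (optionally including leaves)
    is reported.

    Returns
    -------
    list of (node_id, known tips of the clade, state) tuples.
    """
    annotated: list[tuple[dendropy.Node, frozenset[str], str]] = []
    state_of: dict[int, str | None] = {}
    for node in stree.tree.postorder_node_iter():
        if node.is_leaf():
            tip = node.taxon.label
            state_of[id(node)] = stree.status[tip]
        else:
            child_states = {state_of[id(c)] for c in node.child_nodes()}
            child_states.discard(UNKNOWN)
            if len(child_states) == 1:
                state_of[id(node)] = next(iter(child_states))
            elif len(child_states) == 0:
                state_of[id(node)] = UNKNOWN
            else:
                state_of[id(node)] = None  # mixed
    for node in stree.tree.preorder_node_iter():
        state = state_of[id(node)]
        if state in (None, UNKNOWN):
            continue
        if not include_leaves and node.is_leaf():
            continue
        parent = node.parent_node
        if maximal_only and parent is not None and state_of[id(parent)] == state:
            continue
        tips = frozenset(
            t for t in stree.leafset(node) if stree.status[t] == state
        )
        annotated.append((SpeciesTree._node_id(node), tips, state))
    return annotated
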