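"""Gene-family evolutionary events and copy-number association with CI loss.

This module derives per-family event flags from gene trees and
orthologue-count matrices and tests whether a family's copy number is
associated with complex I (CI) loss:

* duplications are called on gene trees with the *species-overlap*
  criterion (a node is a duplication when the species sets of its child
  subtrees intersect);
* a family is flagged as lost in a focal CI-absent species when it has
  zero orthologues there while at least one species of the CI-bearing
  sister group retains the family;
* families whose events are shared with the sister group are discarded
  (such changes are not specific to CI loss);
* the association test compares, per family, the median orthologue
  count over clades monophyletic for CI presence against clades
  monophyletic for CI absence with a two-sample two-sided
  Kolmogorov-Smirnov test at p < 0.05.

Event tables are tidy DataFrames with columns ``family_id``,
``species_id`` and boolean columns ``L``, ``D``, ``PS``, ``MR``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trees import ABSENT, PRESENT, SpeciesTree, monophyletic_state_nodes

__all__ = [
    "EVENT_TYPES",
    "AssociationResult",
    "annotate_duplications",
    "infer_family_loss",
    "filter_shared_with_sister",
    "node_medians",
    "ks_association",
    "ks_scan",
    "ancestral_copy_number",
]

EVENT_TYPES = ("L", "D", "PS", "MR")

#: Use the exact two-sample KS null when n*m is at most this large.
EXACT_KS_LIMIT = 10_000

ALPHA = 0.05


@dataclass(frozen=True)
class AssociationResult:
    """Copy-number association of one family with CI state."""

    family_id: str
    statistic: float
    pvalue: float
    significant: bool
    direction: str  # 'higher' / 'lower' (in CI- clades) / 'none'


# -- duplication calling ------------------------------------------------


def _default_species_of(label: str) -> str:
    """Extract the species from a ``gene@species`` tip label."""
    if "@" not in label:
        raise ValueError(
            f"tip label {label!r} has no '@species' suffix and no mapping "
            "was provided"
        )
    return label.rsplit("@", 1)[1]


def annotate_duplications(
    gene_tree,
    species_of: Callable[[str], str] | Mapping[str, str] | None = None,
) -> tuple[set[str], dict[str, bool]]:
    """Call duplication nodes on a rooted gene tree by species overlap.

    Parameters
    ----------
    gene_tree:
        A rooted dendropy tree whose tips are genes. Tip labels follow
        the ``gene@species`` convention unless ``species_of`` (callable
        or mapping) translates labels to species.

    Returns
    -------
    (duplication node ids, per-species D flags). A species is flagged
    when at least two of its genes descend from one duplication node.
    """
    if species_of is None:
        lookup: Callable[[str], str] = _default_species_of
    elif callable(species_of):
        lookup = species_of
    else:
        mapping = dict(species_of)

        def lookup(label: str, _m=mapping) -> str:
            if label not in _m:
                raise ValueError(f"tip {label!r} missing from species mapping")
            return _m[label]

    species_below: dict[int, frozenset[str]] = {}
    genes_per_species: dict[int, pd.Series] = {}
    dup_nodes: set[str] = set()
    d_flags: dict[str, bool] = {}

    for i, node in enumerate(gene_tree.preorder_node_iter()):
        if getattr(node, "_ciloss_id", None) is None:
            node._ciloss_id = f"g{i}"

    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            sp = lookup(node.taxon.label)
            species_below[id(node)] = frozenset([sp])
            genes_per_species[id(node)] = pd.Series({sp: 1})
        else:
            children = node.child_nodes()
            sets = [species_below[id(c)] for c in children]
            species_below[id(node)] = frozenset().union(*sets)
            tally = (
                pd.concat([genes_per_species[id(c)] for c in children])
                .groupby(level=0)
                .sum()
            )
            genes_per_species[id(node)] = tally
            overlap = False
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    if sets[a] & sets[b]:
                        overlap = True
            if overlap:
                dup_nodes.add(node._ciloss_id)
                for sp, n in tally.items():
                    if n >= 2:
                        d_flags[sp] = True
    for sp in species_below[id(gene_tree.seed_node)]:
        d_flags.setdefault(sp, False)
    return dup_nodes, d_flags


# -- loss calling and the sister filter ---------------------------------


def infer_family_loss(
    counts_row: Mapping[str, int],
    focal_species: str,
    sister_species: Sequence[str],
) -> bool:
    """Family lost in the focal species but retained in the sister group.

    True iff the focal species has zero orthologues and at least one
    sister species has one or more. A family absent from the whole
    sister group as well predates the focal lineage and is not counted.
    """
    if not sister_species:
        raise ValueError("sister species set must be non-empty")
    if focal_species not in counts_row:
        raise ValueError(f"focal species {focal_species!r} not in count matrix")
    if counts_row[focal_species] != 0:
        return False
    return any(counts_row.get(s, 0) >= 1 for s in sister_species)


def filter_shared_with_sister(
    focal_events: pd.DataFrame, sister_events: pd.DataFrame
) -> pd.Series:
    """Keep families whose events are specific to the CI-absent species.

    A family is discarded when any event type flagged in a focal
    (CI-absent) species is also flagged, for the same event type, in at
    least one sister-group CI-present species. Returns a boolean Series
    indexed by family id (True = keep). Families present only in the
    focal table are kept.
    """
    cols = [c for c in EVENT_TYPES if c in focal_events.columns]
    focal_any = focal_events.groupby("family_id")[cols].any()
    if sister_events.empty:
        return pd.Series(True, index=focal_any.index)
    sister_any = sister_events.groupby("family_id")[cols].any()
    sister_any = sister_any.reindex(focal_any.index, fill_value=False)
    shared = (focal_any & sister_any).any(axis=1)
    return ~shared


# -- clade medians and the KS association test --------------------------


def node_medians(
    counts: pd.DataFrame,
    nodes: Sequence[tuple[str, frozenset[str] | Sequence[str], str]],
) -> pd.DataFrame:
    """Median orthologue count per family at each monophyletic node.

    ``counts`` is a family x species matrix; ``nodes`` are
    ``(node_id, member species, state)`` tuples as produced by
    :func:`ciloss.trees.monophyletic_state_nodes`. The median of an
    even-sized clade is the mean of the two central values.
    """
    records = []
    for node_id, tips, state in nodes:
        members = [t for t in tips if t in counts.columns]
        if not members:
            raise ValueError(f"node {node_id!r} has no species in the matrix")
        med = counts[members].median(axis=1)
        for family_id, value in med.items():
            records.append(
                {
                    "family_id": family_id,
                    "node_id": node_id,
                    "state": state,
                    "median": float(value),
                }
            )
    return pd.DataFrame(records)


def ks_association(
    family_id: str,
    plus_medians: Sequence[float],
    minus_medians: Sequence[float],
    alpha: float = ALPHA,
) -> AssociationResult:
    """Two-sided two-sample KS test of CI+ vs CI- node medians.

    The exact small-sample null is used whenever ``n * m`` does not
    exceed 10,000, the asymptotic approximation otherwise.
    """
    plus = np.asarray(list(plus_medians), dtype=float)
    minus = np.asarray(list(minus_medians), dtype=float)
    if plus.size == 0 or minus.size == 0:
        raise ValueError("both CI+ and CI- node medians are required")
    method = "exact" if plus.size * minus.size <= EXACT_KS_LIMIT else "asymp"
    res = stats.ks_2samp(minus, plus, alternative="two-sided", method=method)
    diff = float(np.median(minus) - np.median(plus))
    direction = "higher" if diff > 0 else ("lower" if diff < 0 else "none")
    return AssociationResult(
        family_id=family_id,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
        direction=direction,
    )


def ks_scan(
    counts: pd.DataFrame,
    stree: SpeciesTree,
    nodes: str = "pooled",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Run the KS association test for every family in the matrix.

    ``nodes`` selects the sampling unit of the test:

    ``"pooled"`` (default)
        raw per-species counts pooled by CI state. Under the null the
        two samples are draws from one distribution, so the test keeps
        its nominal (slightly conservative, because counts are
        discrete) type-I error while retaining power;
    ``"maximal"``
        one median per maximal clade monophyletic for CI+ or CI-.
        Faithful to a per-clade reading but weak when only a handful of
        clades exist: the exact test then needs near-complete
        separation of the medians;
    ``"all"``
        one median per monophyletic node, nested nodes and tips
        included. The medians of nested clades are strongly dependent
        and differently dispersed on the two sides, which inflates the
        false-positive rate; provided for comparison only.
    """
    if nodes in ("maximal", "all"):
        node_list = monophyletic_state_nodes(
            stree, maximal_only=(nodes == "maximal"), include_leaves=True
        )
        profile = node_medians(counts, node_list)
        values = profile.pivot_table(
            index="family_id", columns="node_id", values="median", sort=False
        )
        state_of = {node_id: state for node_id, _, state in node_list}
        plus_cols = [c for c in values.columns if state_of[c] == PRESENT]
        minus_cols = [c for c in values.columns if state_of[c] == ABSENT]
    elif nodes == "pooled":
        values = counts
        plus_cols = [
            s for s in counts.columns if stree.status.get(s) == PRESENT
        ]
        minus_cols = [
            s for s in counts.columns if stree.status.get(s) == ABSENT
        ]
    else:
        raise ValueError(f"unknown node sampling mode {nodes!r}")

    results = []
    for family_id, row in values.iterrows():
        res = ks_association(
            str(family_id),
            row[plus_cols].to_numpy(dtype=float),
            row[minus_cols].to_numpy(dtype=float),
            alpha=alpha,
        )
        results.append(
            {
                "family_id": res.family_id,
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "significant": res.significant,
                "direction": res.direction,
            }
        )
    return pd.DataFrame(results)


def ancestral_copy_number(
    clade_tips: Sequence[str], counts_row: Mapping[str, float]
) -> float:
    """Ancestral copy number of a clade: median over its extant species."""
    tips = list(clade_tips)
    if not tips:
        raise ValueError("clade is empty")
    return float(np.median([counts_row[t] for t in tips]))
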