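"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — exhaustive enumeration or direct
rule application — and shares no code with the package internals.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np

PRESENT = "present"
ABSENT = "absent"


def camin_sokal_min_losses(stree) -> int:
    """Minimum number of present->absent transitions, loss irreversible.

    Exhaustive search over all internal-node state assignments (and over
    both states for unknown-status tips). The ancestral state is
    CI-present; a CI-absent root counts as one loss on the root branch.
    Edges from an absent parent to a present child are forbidden.
    """
    nodes = list(stree.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    free_leaves = [
        n for n in leaves if stree.status[n.taxon.label] not in (PRESENT, ABSENT)
    ]
    fixed = {
        id(n): stree.status[n.taxon.label]
        for n in leaves
        if n not in free_leaves
    }
    root = stree.tree.seed_node
    best = math.inf
    for internal_states in itertools.product(
        (PRESENT, ABSENT), repeat=len(internal)
    ):
        for leaf_states in itertools.product(
            (PRESENT, ABSENT), repeat=len(free_leaves)
        ):
            state = dict(fixed)
            state.update(
                {id(n): s for n, s in zip(internal, internal_states)}
            )
            state.update(
                {id(n): s for n, s in zip(free_leaves, leaf_states)}
            )
            cost = 1 if state[id(root)] == ABSENT else 0
            valid = True
            for node in nodes:
                if node is root:
                    continue
                parent = node.parent_node
                if state[id(parent)] == ABSENT and state[id(node)] == PRESENT:
                    valid = False
                    break
                if state[id(parent)] == PRESENT and state[id(node)] == ABSENT:
                    cost += 1
            if valid and cost < best:
                best = cost
    return int(best)


def ks_two_sample_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact permutation two-sample KS: statistic and P(D >= observed).

    Enumerates every split of the pooled sample into groups of sizes
    len(x) and len(y); ties are handled by treating values at identical
    positions as exchangeable, which matches the continuous-null
    convention for the observed statistic.
    """

    def d_stat(a: np.ndarray, b: np.ndarray) -> float:
        grid = np.unique(np.concatenate([a, b]))
        fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
        fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
        return float(np.abs(fa - fb).max())

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    observed = d_stat(x, y)
    pooled = np.concatenate([x, y])
    n = x.size
    idx = range(pooled.size)
    count = total = 0
    for combo in itertools.combinations(idx, n):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(combo)] = True
        d = d_stat(pooled[mask], pooled[~mask])
        total += 1
        if d >= observed - 1e-12:
            count += 1
    return observed, count / total


def exact_overlap_tail(
    tested_genes: Mapping[str, Sequence[str]],
    ps_counts: Mapping[str, int],
    gene_to_family: Mapping[str, str],
    observed: int,
) -> float:
    """P(all-species family overlap >= observed) by full enumeration.

    Enumerates, per species, every way of assigning its number of PS
    calls to its tested genes, and averages the overlap indicator over
    the product space.
    """
    per_species: list[list[frozenset[str]]] = []
    for sp in sorted(tested_genes):
        genes = list(tested_genes[sp])
        k = ps_counts[sp]
        options = [
            frozenset(gene_to_family[genes[i]] for i in combo)
            for combo in itertools.combinations(range(len(genes)), k)
        ]
        per_species.append(options)
    total = math.prod(len(o) for o in per_species)
    hits = 0
    for choice in itertools.product(*per_species):
        overlap = set(choice[0]).intersection(*choice[1:])
        if len(overlap) >= observed:
            hits += 1
    return hits / total


def hypergeom_tail_by_enumeration(
    population: Sequence[str],
    term_genes: set[str],
    study_size: int,
    observed: int,
) -> float:
    """P(study of this size hits >= observed term genes), enumerated."""
    hits = total = 0
    for combo in itertools.combinations(population, study_size):
        total += 1
        if len(set(combo) & term_genes) >= observed:
            hits += 1
    return hits / total


def confusion_matrix_curve(
    labels: Sequence[bool], deltas: Sequence[float], thresholds: Sequence[float]
) -> list[tuple[float, float, float]]:
    """(threshold, precision, sensitivity) by direct counting."""
    out = []
    for t in thresholds:
        tp = sum(1 for l, d in zip(labels, deltas) if l and d > t)
        fp = sum(1 for l, d in zip(labels, deltas) if not l and d > t)
        fn = sum(1 for l, d in zip(labels, deltas) if l and d <= t)
        precision = tp / (tp + fp) if tp + fp else float("nan")
        sensitivity = tp / (tp + fn)
        out.append((float(t), precision, sensitivity))
    return out
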