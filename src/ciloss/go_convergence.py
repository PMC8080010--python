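"""GO enrichment per CI-absent species and convergently enriched terms.

Per species and gene category (loss, duplication, positive selection,
mitochondrial retargeting, and their intersections), over-representation
of each GO term in the study set against the species' annotated
background is tested with a one-sided hypergeometric test, followed by
Benjamini-Hochberg FDR across terms. A term is *convergently* enriched
when its raw p-value is below 0.05 in every species with a CI loss
(level ``X``); when the FDR-adjusted p-value is also below 0.05 in every
species the term is flagged ``XX``. The raw-p intersection deliberately
skips multiple-testing correction within species — requiring the signal
in every independent loss already suppresses false positives while
keeping sensitivity in small categories.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "enrich",
    "convergent_terms",
    "propagate_annotations",
    "load_obo_ancestors",
]

ALPHA = 0.05


def load_obo_ancestors(
    path, relations: tuple[str, ...] = ("is_a", "part_of")
) -> dict[str, set[str]]:
    """Term -> ancestor set from an OBO ontology (is_a/part_of closure)."""
    import networkx as nx
    import obonet

    graph = obonet.read_obo(path)
    # obonet edges run child -> parent keyed by relation type.
    sub = nx.MultiDiGraph(
        (u, v, k) for u, v, k in graph.edges(keys=True) if k in relations
    )
    ancestors: dict[str, set[str]] = {}
    for term in graph.nodes:
        if term in sub:
            ancestors[term] = set(nx.descendants(sub, term))
        else:
            ancestors[term] = set()
    return ancestors


def propagate_annotations(
    term_to_genes: Mapping[str, Iterable[str]],
    ancestors: Mapping[str, Iterable[str]],
) -> dict[str, set[str]]:
    """Propagate gene annotations up the ontology graph.

    Every gene annotated to a term is also annotated to all the term's
    ancestors (the true-path rule).
    """
    out: dict[str, set[str]] = {t: set(g) for t, g in term_to_genes.items()}
    for term, genes in term_to_genes.items():
        for anc in ancestors.get(term, ()):
            out.setdefault(anc, set()).update(genes)
    return out


def enrich(
    study_genes: Iterable[str],
    population_genes: Iterable[str],
    term_to_genes: Mapping[str, Iterable[str]],
    ancestors: Mapping[str, Iterable[str]] | None = None,
    namespaces: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per GO term.

    Parameters
    ----------
    study_genes:
        Genes of interest; must be a subset of the population.
    population_genes:
        The background (typically the species' annotated proteome).
    term_to_genes:
        GO annotation; propagated up the ontology first when
        ``ancestors`` is given.
    namespaces:
        Optional term -> namespace (BP/CC/MF) labels copied to the
        output.

    Returns a DataFrame with one row per term annotating at least one
    population gene: study/population counts, the raw hypergeometric
    tail p-value P(X >= k), and the BH-adjusted value across terms.
    """
    study = set(study_genes)
    population = set(population_genes)
    if not study:
        raise ValueError("study set is empty")
    stray = study - population
    if stray:
        raise ValueError(
            f"study genes missing from the population: {sorted(stray)[:3]}"
        )
    annot = (
        propagate_annotations(term_to_genes, ancestors)
        if ancestors is not None
        else {t: set(g) for t, g in term_to_genes.items()}
    )
    N = len(population)
    n = len(study)
    rows = []
    for term in sorted(annot):
        term_genes = annot[term] & population
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "study_count": k,
                "study_n": n,
                "population_count": K,
                "population_n": N,
                "p_raw": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_fdr"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    if namespaces is not None:
        df["namespace"] = df["term_id"].map(namespaces)
    return df


def convergent_terms(results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Terms enriched in every CI-absent species, with X/XX levels.

    ``results`` maps each focal species to its :func:`enrich` output.
    A term reaches level ``X`` when its raw p-value is below 0.05 in
    every species, and ``XX`` when its FDR-adjusted p-value is also
    below 0.05 in every species (XX implies X).
    """
    if not results:
        raise ValueError("enrichment results for at least one species required")
    raw_ok: dict[str, int] = {}
    fdr_ok: dict[str, int] = {}
    seen: dict[str, int] = {}
    for species, df in results.items():
        if df.empty:
            return pd.DataFrame(columns=["term_id", "level"])
        for row in df.itertuples():
            seen[row.term_id] = seen.get(row.term_id, 0) + 1
            if row.p_raw < ALPHA:
                raw_ok[row.term_id] = raw_ok.get(row.term_id, 0) + 1
            if row.p_fdr < ALPHA:
                fdr_ok[row.term_id] = fdr_ok.get(row.term_id, 0) + 1
    n_species = len(results)
    rows = []
    for term in sorted(seen):
        if raw_ok.get(term, 0) == n_species:
            level = "XX" if fdr_ok.get(term, 0) == n_species else "X"
            rows.append({"term_id": term, "level": level})
    return pd.DataFrame(rows, columns=["term_id", "level"])
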