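"""Pathway-level scoring of convergent evolutionary change after CI loss.

Each gene mapped to a KEGG enzyme carries event flags — duplication (D),
positive selection (PS), mitochondrial retargeting (MR), loss (L) — in
each CI-absent (CI-) species. Scores roll up gene -> enzyme -> pathway
under six positive parameters ``p1..p6``:

* gene score: ``p4`` for genes under PS, MR or D (innovation), ``p5``
  (lower) for genes under loss only, ``-p6`` otherwise; multiplied by 10
  for high-identity gene-to-orthologue mappings and by 1 for low;
* enzyme score: ``p1`` when exactly two CI- species have an innovation
  in the enzyme's genes, ``p2`` when all of them do, ``p3`` when the
  enzyme was gained or lost together with CI (present in every CI-
  species but no close CI+ relative, or vice versa), plus the summed
  gene scores;
* pathway score (per species): sum of its enzyme scores, with ``-p6``
  for every enzyme with no mapped gene in that species.

No principled choice of ``p1..p6`` exists, so pathways are scored under
a grid of 729 parameter combinations spanning the admissible region

    p5 in [0.5, 5];  p4, p6 in [p5+1, 10];  p3 in [p4+5, 50];
    p1 in [p3+10, 100];  p2 in [p1+20, 200]

(three values — lower bound, midpoint, upper bound — per parameter,
dependent bounds evaluated at the parent's sampled value). For each
parameter set and species, pathway scores are z-scored across pathways;
the per-species *final* score is the mean z over the grid, and pathways
are ranked by the mean final score across species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoreParams",
    "PathwayScores",
    "gene_score",
    "enzyme_score",
    "pathway_raw_score",
    "parameter_grid",
    "final_scores",
    "score_pathways",
]

logger = logging.getLogger(__name__)

#: Identity multiplier applied to individual gene scores.
IDENTITY_MULTIPLIER = {"high": 10.0, "low": 1.0}

_TOL = 1e-9


@dataclass(frozen=True)
class ScoreParams:
    """One admissible point of the six-parameter scoring space."""

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float

    def __post_init__(self) -> None:
        checks = [
            ("p5", 0.5, 5.0, self.p5),
            ("p4", self.p5 + 1.0, 10.0, self.p4),
            ("p6", self.p5 + 1.0, 10.0, self.p6),
            ("p3", self.p4 + 5.0, 50.0, self.p3),
            ("p1", self.p3 + 10.0, 100.0, self.p1),
            ("p2", self.p1 + 20.0, 200.0, self.p2),
        ]
        for name, lo, hi, value in checks:
            if not (lo - _TOL <= value <= hi + _TOL):
                raise ValueError(
                    f"{name}={value} outside its admissible range "
                    f"[{lo}, {hi}]"
                )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.p1, self.p2, self.p3, self.p4, self.p5, self.p6], dtype=float
        )


def gene_score(
    events: Mapping[str, bool], params: ScoreParams, identity_class: str
) -> float:
    """Score one gene from its event flags and mapping confidence.

    Innovation events (PS, MR, D) dominate loss: a gene with any of them
    scores ``p4`` regardless of its L flag; a gene under loss only
    scores ``p5``; a gene with no event scores ``-p6``. The result is
    multiplied by 10 (high-identity mapping) or 1 (low).
    """
    try:
        mult = IDENTITY_MULTIPLIER[identity_class]
    except KeyError:
        raise ValueError(f"identity_class must be 'high' or 'low', got {identity_class!r}")
    if events.get("PS") or events.get("MR") or events.get("D"):
        base = params.p4
    elif events.get("L"):
        base = params.p5
    else:
        base = -params.p6
    return base * mult


def enzyme_score(
    genes: pd.DataFrame,
    params: ScoreParams,
    n_ci_species: int = 3,
    unique_with_loss: bool = False,
) -> float:
    """Score one enzyme from the genes mapping to it across CI- species.

    ``genes`` has one row per (gene, species) with boolean columns
    ``PS``, ``MR``, ``D``, ``L`` and an ``identity_class`` column. The
    score is the co-occurrence bonus (``p1`` for innovation in exactly
    two species, ``p2`` for all ``n_ci_species``), the uniqueness bonus
    ``p3`` when the enzyme was gained/lost together with CI, plus the
    sum of the individual gene scores.
    """
    score = 0.0
    innovating = genes.loc[genes[["PS", "MR", "D"]].any(axis=1), "species_id"]
    n_innov = innovating.nunique()
    if n_innov == n_ci_species:
        score += params.p2
    elif n_innov == 2:
        score += params.p1
    if unique_with_loss:
        score += params.p3
    for row in genes.itertuples():
        score += gene_score(
            {"PS": row.PS, "MR": row.MR, "D": row.D, "L": row.L},
            params,
            row.identity_class,
        )
    return score


def pathway_raw_score(
    enzymes: Mapping[str, pd.DataFrame],
    species_id: str,
    params: ScoreParams,
    n_ci_species: int = 3,
    unique_enzymes: Iterable[str] = (),
) -> float:
    """Raw score of one pathway for one species.

    ``enzymes`` maps each enzyme of the pathway to its gene table (as in
    :func:`enzyme_score`; may be empty). Enzymes with no gene mapped in
    ``species_id`` contribute ``-p6``; mapped enzymes contribute their
    full enzyme score.
    """
    if not enzymes:
        raise ValueError("pathway has no enzymes")
    unique = set(unique_enzymes)
    total = 0.0
    for enzyme_id, genes in enzymes.items():
        mapped = (
            not genes.empty and (genes["species_id"] == species_id).any()
        )
        if not mapped:
            total -= params.p6
            if genes.empty and enzyme_id in unique:
                # Enzyme lost together with CI: the uniqueness bonus still
                # applies even though no CI- gene maps to it.
                total += params.p3
        else:
            total += enzyme_score(
                genes,
                params,
                n_ci_species=n_ci_species,
                unique_with_loss=enzyme_id in unique,
            )
    return total


def parameter_grid() -> list[ScoreParams]:
    """The 729-point parameter grid (3 values per parameter).

    Each parameter takes the lower bound, midpoint and upper bound of
    its interval; dependent bounds are evaluated at the sampled value of
    the parent parameter, following the dependency chain
    p5 -> p4 -> p6 -> p3 -> p1 -> p2.
    """

    def three(lo: float, hi: float) -> tuple[float, float, float]:
        return (lo, (lo + hi) / 2.0, hi)

    grid: list[ScoreParams] = []
    for p5 in three(0.5, 5.0):
        for p4 in three(p5 + 1.0, 10.0):
            for p6 in three(p5 + 1.0, 10.0):
                for p3 in three(p4 + 5.0, 50.0):
                    for p1 in three(p3 + 10.0, 100.0):
                        for p2 in three(p1 + 20.0, 200.0):
                            grid.append(
                                ScoreParams(
                                    p1=p1, p2=p2, p3=p3, p4=p4, p5=p5, p6=p6
                                )
                            )
    return grid


@dataclass(frozen=True)
class PathwayScores:
    """Scores of all pathways under the parameter grid."""

    pathway_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    raw: np.ndarray  # (pathway, species, params)
    z: np.ndarray  # (pathway, species, params)
    final_per_species: np.ndarray  # (pathway, species): mean z over params
    mean_final: np.ndarray  # (pathway,): mean over species
    rank: np.ndarray  # (pathway,): 1 = highest mean final score

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "pathway_id": self.pathway_ids,
                "mean_final_score": self.mean_final,
                "rank": self.rank,
            }
        )
        for j, sp in enumerate(self.species_ids):
            df[f"final_{sp}"] = self.final_per_species[:, j]
        return df.sort_values("rank").reset_index(drop=True)

    def top(self, n: int = 10) -> list[str]:
        order = np.argsort(self.rank)
        return [self.pathway_ids[i] for i in order[:n]]


def final_scores(
    raw: np.ndarray,
    pathway_ids: Sequence[str],
    species_ids: Sequence[str],
) -> PathwayScores:
    """Z-score raw pathway scores and aggregate them into final ranks.

    ``raw`` has shape (pathway, species, parameter set). For each
    (species, parameter set) the scores are standardized across
    pathways (population sd); a zero-variance slice yields z = 0 with a
    warning. The per-species final score is the mean z over parameter
    sets, the overall score the mean across species, and ranks are
    assigned in descending order of the overall score (ties broken by
    pathway id order).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape[0] < 2:
        raise ValueError("z-scores need at least two pathways")
    mean = raw.mean(axis=0, keepdims=True)
    sd = raw.std(axis=0, keepdims=True)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d (species, parameter set) slices have zero variance across "
            "pathways; their z-scores are set to 0",
            int(degenerate.sum()),
        )
    safe_sd = np.where(degenerate, 1.0, sd)
    z = (raw - mean) / safe_sd
    z = np.where(degenerate, 0.0, z)
    final_per_species = z.mean(axis=2)
    mean_final = final_per_species.mean(axis=1)
    order = np.lexsort((np.arange(len(pathway_ids)), -mean_final))
    rank = np.empty(len(pathway_ids), dtype=int)
    rank[order] = np.arange(1, len(pathway_ids) + 1)
    return PathwayScores(
        pathway_ids=tuple(pathway_ids),
        species_ids=tuple(species_ids),
        raw=raw,
        z=z,
        final_per_species=final_per_species,
        mean_final=mean_final,
        rank=rank,
    )


def _score_coefficients(
    pathway_map: pd.DataFrame,
    gene_events: pd.DataFrame,
    ci_species: Sequence[str],
    sister_enzymes: Iterable[str] = (),
    pathway_enzymes: pd.DataFrame | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Linear coefficients of the raw score in (p1..p6).

    The raw pathway score is linear in the parameter vector, which lets
    the whole 729-point grid be evaluated as one matrix product.
    Returns (coefficients of shape (pathway, species, 6), pathway ids,
    species ids).
    """
    species = list(ci_species)
    n_ci = len(species)
    sister = set(sister_enzymes)

    cols = ["gene_id", "species_id", "enzyme_id", "identity_class"]
    genes = pathway_map[cols].drop_duplicates()
    genes = genes.merge(gene_events, on=["gene_id", "species_id"], how="left")
    for c in ("PS", "MR", "D", "L"):
        if c not in genes.columns:
            genes[c] = False
        col = genes[c]
        genes[c] = col.where(col.notna(), other=False).astype(bool)
    genes["mult"] = genes["identity_class"].map(IDENTITY_MULTIPLIER)
    if genes["mult"].isna().any():
        bad = genes.loc[genes["mult"].isna(), "identity_class"].unique()
        raise ValueError(f"unknown identity_class values: {list(bad)}")
    genes["innov"] = genes[["PS", "MR", "D"]].any(axis=1)
    genes["loss_only"] = genes["L"] & ~genes["innov"]
    genes["neutral"] = ~genes["innov"] & ~genes["L"]

    # Per-enzyme, species-independent quantities.
    by_enzyme = genes.groupby("enzyme_id")
    enz = pd.DataFrame(
        {
            "n_innov_species": by_enzyme.apply(
                lambda g: g.loc[g["innov"], "species_id"].nunique(),
                include_groups=False,
            ),
            "g4": by_enzyme.apply(
                lambda g: (g["mult"] * g["innov"]).sum(), include_groups=False
            ),
            "g5": by_enzyme.apply(
                lambda g: (g["mult"] * g["loss_only"]).sum(),
                include_groups=False,
            ),
            "g6": by_enzyme.apply(
                lambda g: (g["mult"] * g["neutral"]).sum(),
                include_groups=False,
            ),
        }
    )
    enz["a"] = (enz["n_innov_species"] == 2).astype(float)
    enz["b"] = (enz["n_innov_species"] == n_ci).astype(float)
    if n_ci == 2:
        enz["a"] = 0.0  # with two CI- species, full co-occurrence is p2
    mapped_species = by_enzyme["species_id"].agg(lambda s: frozenset(s))
    enz["unique"] = [
        float(
            (len(mapped_species[e]) == n_ci and e not in sister)
            or (len(mapped_species[e]) == 0 and e in sister)
        )
        for e in enz.index
    ]

    if pathway_enzymes is None:
        pathway_enzymes = pathway_map[["pathway_id", "enzyme_id"]].drop_duplicates()
    else:
        pathway_enzymes = pathway_enzymes[["pathway_id", "enzyme_id"]].drop_duplicates()
    pathways = sorted(pathway_enzymes["pathway_id"].unique())
    pw_index = {p: i for i, p in enumerate(pathways)}
    sp_index = {s: j for j, s in enumerate(species)}

    coeff = np.zeros((len(pathways), n_ci, 6), dtype=float)
    for row in pathway_enzymes.itertuples():
        i = pw_index[row.pathway_id]
        e = row.enzyme_id
        if e in enz.index:
            stats_ = enz.loc[e]
            members = mapped_species[e]
        else:  # enzyme known to the pathway but with no CI- gene at all
            stats_ = None
            members = frozenset()
        for s in species:
            j = sp_index[s]
            if s in members:
                coeff[i, j, 0] += stats_["a"]
                coeff[i, j, 1] += stats_["b"]
                coeff[i, j, 2] += stats_["unique"]
                coeff[i, j, 3] += stats_["g4"]
                coeff[i, j, 4] += stats_["g5"]
                coeff[i, j, 5] -= stats_["g6"]
            else:
                unique = 0.0
                if stats_ is None:
                    unique = float(e in sister)  # lost with CI
                coeff[i, j, 2] += unique
                coeff[i, j, 5] -= 1.0
    return coeff, pathways, species


def score_pathways(
    pathway_map: pd.DataFrame,
    gene_events: pd.DataFrame,
    ci_species: Sequence[str],
    sister_enzymes: Iterable[str] = (),
    pathway_enzymes: pd.DataFrame | None = None,
    params_list: Sequence[ScoreParams] | None = None,
) -> PathwayScores:
    """Score every pathway under the full parameter grid.

    Parameters
    ----------
    pathway_map:
        One row per gene-to-pathway mapping with columns ``gene_id``,
        ``species_id``, ``enzyme_id``, ``pathway_id``,
        ``identity_class`` ('high'/'low').
    gene_events:
        One row per (gene, species) with boolean columns ``PS``,
        ``MR``, ``D``, ``L``.
    ci_species:
        The focal CI-absent species (order fixes the species axis).
    sister_enzymes:
        Enzymes with mapped genes in the close CI+ relatives, used for
        the uniqueness bonus p3.
    pathway_enzymes:
        Optional explicit pathway composition (columns ``pathway_id``,
        ``enzyme_id``); defaults to the enzymes seen in the map.
    params_list:
        Parameter sets to evaluate; defaults to :func:`parameter_grid`.
    """
    if params_list is None:
        params_list = parameter_grid()
    coeff, pathways, species = _score_coefficients(
        pathway_map,
        gene_events,
        ci_species,
        sister_enzymes=sister_enzymes,
        pathway_enzymes=pathway_enzymes,
    )
    pmat = np.stack([p.as_array() for p in params_list])  # (K, 6)
    raw = np.einsum("ijc,kc->ijk", coeff, pmat)
    return final_scores(raw, pathways, species)
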