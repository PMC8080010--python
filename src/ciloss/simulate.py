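"""Synthetic datasets with planted truth for the CI-loss pipeline.

Every pipeline stage can be exercised without any external database:
the generator emits a random rooted species tree with planted
monophyletic CI-loss clades (single-genus "recent" losses and
multi-genus "ancient" ones), per-species mitochondrial genome records
with the bimodal subunit-count structure seen in real screens,
orthologue-count matrices with copy-number shifts planted in CI-absent
clades, branch-site p-value tables with a planted all-species
positive-selection overlap, localization profiles for paralogue pairs
with and without planted mitochondrial retargeting, and a gene/enzyme/
pathway map with planted convergently altered pathways.

All randomness flows from one integer seed through per-stage derived
streams (CRC-hashed stage names), so the same configuration reproduces
byte-identical output while stages remain independently perturbable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mito_screen import SUBUNITS, GenomeRecord, SubunitEvidence
from .retargeting import LocalizationProfile
from .trees import ABSENT, PRESENT, SpeciesTree

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "FamilyData",
    "SyntheticDataset",
    "simulate_species_tree",
    "simulate_mito_dataset",
    "simulate_family_data",
    "simulate_go_annotations",
    "simulate_all",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    The defaults emulate the scale of the real analysis: a few dozen
    yeast-like species, five independent CI losses of which three are
    recent single-genus events used as the focal comparative set, an
    eight-family planted positive-selection overlap, and a handful of
    convergently altered pathways among a few dozen mapped ones.
    """

    seed: int = 0
    n_species: int = 40
    n_loss_events: int = 5
    n_genomes_per_species: int = 4
    n_families: int = 60
    n_planted_assoc_families: int = 6
    n_planted_overlap_families: int = 8
    n_pathways: int = 20
    n_planted_pathways: int = 3
    n_retarget_pairs: int = 24
    n_planted_retargeted: int = 8
    misannotation_prob: float = 0.02
    incomplete_genome_prob: float = 0.05
    copy_number_shift: float = 3.0
    retargeting_delta: float = 0.6
    background_event_rate: float = 0.05
    genus_max_size: int = 3
    n_enzymes_per_pathway: int = 4

    def __post_init__(self) -> None:
        positive = (
            "n_species",
            "n_genomes_per_species",
            "n_families",
            "n_pathways",
            "genus_max_size",
            "n_enzymes_per_pathway",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        non_negative = (
            "n_loss_events",
            "n_planted_assoc_families",
            "n_planted_overlap_families",
            "n_planted_pathways",
            "n_retarget_pairs",
            "n_planted_retargeted",
        )
        for name in non_negative:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "misannotation_prob",
            "incomplete_genome_prob",
            "background_event_rate",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_loss_events >= self.n_species:
            raise ValueError("n_loss_events must be smaller than n_species")
        if self.n_planted_pathways > self.n_pathways:
            raise ValueError("n_planted_pathways exceeds n_pathways")
        if self.n_planted_retargeted > self.n_retarget_pairs:
            raise ValueError("n_planted_retargeted exceeds n_retarget_pairs")
        reserved = (
            self.n_planted_assoc_families
            + self.n_planted_overlap_families
            + 2 * self.n_planted_pathways
            + self.n_planted_retargeted
        )
        if reserved > self.n_families:
            raise ValueError(
                "n_families too small for the requested planted families"
            )
        if self.copy_number_shift < 0:
            raise ValueError("copy_number_shift must be non-negative")
        if self.n_planted_retargeted > 0 and not 0.0 < self.retargeting_delta <= 0.8:
            raise ValueError(
                "retargeting_delta must lie in (0, 0.8] when retargeted "
                "pairs are planted"
            )


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted by the generator."""

    loss_clades: tuple[frozenset[str], ...] = ()
    assoc_family_ids: frozenset[str] = frozenset()
    overlap_family_ids: frozenset[str] = frozenset()
    retargeted_pair_ids: frozenset[str] = frozenset()
    altered_pathway_ids: frozenset[str] = frozenset()


@dataclass(frozen=True)
class FamilyData:
    """Per-family inputs of the downstream association analyses."""

    counts: pd.DataFrame  # families x species orthologue counts
    events: pd.DataFrame  # family_id, species_id, L, D, PS, MR
    ps_pvalues: pd.DataFrame  # species_id, gene_id, family_id, pvalue
    profiles: tuple[LocalizationProfile, ...]
    pairs: pd.DataFrame  # pair_id, retargeted, target/sister proteins
    pathway_map: pd.DataFrame  # gene_id, species_id, ko_id, enzyme_id, ...
    pathway_enzymes: pd.DataFrame  # pathway_id, enzyme_id
    sister_enzymes: frozenset[str]
    focal_species: tuple[str, ...]
    sister_species: dict[str, tuple[str, ...]]
    truth: PlantedTruth


@dataclass(frozen=True)
class SyntheticDataset:
    config: SimulationConfig
    tree: SpeciesTree
    genomes: tuple[GenomeRecord, ...]
    family_data: FamilyData
    truth: PlantedTruth


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    )


# ---------------------------------------------------------------------
# Species tree with planted losses
# ---------------------------------------------------------------------


class _Node:
    __slots__ = ("children", "tip", "parent")

    def __init__(self, tip: str | None = None):
        self.children: list["_Node"] = []
        self.tip = tip
        self.parent: "_Node" | None = None


def _random_topology(tips: Sequence[str], rng: np.random.Generator) -> _Node:
    if len(tips) == 1:
        return _Node(tip=tips[0])
    k = int(rng.integers(1, len(tips)))
    node = _Node()
    for part in (tips[:k], tips[k:]):
        child = _random_topology(part, rng)
        child.parent = node
        node.children.append(child)
    return node


def _leafset(node: _Node) -> frozenset[str]:
    if node.tip is not None:
        return frozenset([node.tip])
    return frozenset().union(*(_leafset(c) for c in node.children))


def _postorder(node: _Node):
    for c in node.children:
        yield from _postorder(c)
    yield node


def _to_newick(node: _Node) -> str:
    if node.tip is not None:
        return node.tip
    return "(" + ",".join(_to_newick(c) for c in node.children) + ")"


def simulate_species_tree(
    config: SimulationConfig,
) -> tuple[SpeciesTree, PlantedTruth]:
    """Random rooted binary species tree with planted CI-loss clades.

    Losses alternate between *recent* (a single species whose genus
    retains CI-bearing congeners) and *ancient* (a clade spanning at
    least two genera). Planted clades are pairwise disjoint,
    monophyletic by construction, and never exhaust the tree, so every
    loss clade has CI-present species outside it.
    """
    rng = _stage_rng(config.seed, "tree")
    tips = [f"s{i:03d}" for i in range(config.n_species)]
    order = list(rng.permutation(len(tips)))
    shuffled = [tips[i] for i in order]
    root = _random_topology(shuffled, rng)

    leafsets = {id(n): _leafset(n) for n in _postorder(root)}

    # Genus labels: maximal clades of at most genus_max_size tips.
    genus: dict[str, str] = {}
    counter = 0

    def assign_genus(node: _Node) -> None:
        nonlocal counter
        if len(leafsets[id(node)]) <= config.genus_max_size:
            for t in leafsets[id(node)]:
                genus[t] = f"G{counter:02d}"
            counter += 1
            return
        for c in node.children:
            assign_genus(c)

    assign_genus(root)
    genus_members: dict[str, set[str]] = {}
    for t, g in genus.items():
        genus_members.setdefault(g, set()).add(t)

    # Supergroup labels from the deepest splits of the tree.
    group_names = ("fungi", "viridiplantae", "alveolata")
    top = root.children if root.children else [root]
    supergroup: dict[str, str] = {}
    for i, child in enumerate(top):
        for t in leafsets[id(child)]:
            supergroup[t] = group_names[i % len(group_names)]

    nodes = list(_postorder(root))
    internal = [n for n in nodes if n.tip is None and n is not root]
    leaf_nodes = {n.tip: n for n in nodes if n.tip is not None}

    def n_genera(node: _Node) -> int:
        return len({genus[t] for t in leafsets[id(node)]})

    recent_pool = sorted(
        t for t in tips if len(genus_members[genus[t]]) >= 2
    )
    ancient_pool = sorted(
        (n for n in internal if 2 <= n_genera(n) <= 3),
        key=lambda n: min(leafsets[id(n)]),
    )

    chosen: list[tuple[_Node, frozenset[str]]] = []
    if config.n_loss_events > 0:
        ok = False
        for _attempt in range(500):
            chosen = []
            used: set[str] = set()
            feasible = True
            for i in range(config.n_loss_events):
                prefer_recent = i % 2 == 0
                pools = (
                    ["recent", "ancient"] if prefer_recent else ["ancient", "recent"]
                )
                picked = None
                for kind in pools:
                    if kind == "recent":
                        cands = [
                            t
                            for t in recent_pool
                            if t not in used
                            and (genus_members[genus[t]] - used - {t})
                        ]
                        if cands:
                            t = cands[int(rng.integers(len(cands)))]
                            picked = (leaf_nodes[t], frozenset([t]))
                    else:
                        cands = [
                            n
                            for n in ancient_pool
                            if not (leafsets[id(n)] & used)
                        ]
                        if cands:
                            n = cands[int(rng.integers(len(cands)))]
                            picked = (n, leafsets[id(n)])
                    if picked is not None:
                        break
                if picked is None:
                    feasible = False
                    break
                chosen.append(picked)
                used |= picked[1]
            if not feasible:
                continue
            if used == set(tips):
                continue
            # Maximality: each planted clade must have a CI+ tip in its
            # parent clade, and recent losses a CI+ congener.
            valid = True
            for node, clade in chosen:
                parent = node.parent
                if parent is None or not (
                    leafsets[id(parent)] - clade - used
                ):
                    valid = False
                    break
                if len(clade) == 1:
                    (t,) = clade
                    if not (genus_members[genus[t]] - used):
                        valid = False
                        break
            if valid:
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place {config.n_loss_events} disjoint loss "
                f"clades on a tree of {config.n_species} species"
            )

    lost_tips = frozenset().union(*(c for _, c in chosen)) if chosen else frozenset()
    status = {t: (ABSENT if t in lost_tips else PRESENT) for t in tips}
    newick = _to_newick(root) + ";"
    stree = SpeciesTree.from_newick(
        newick, status, genus=genus, supergroup=supergroup
    )
    clades = tuple(
        sorted((c for _, c in chosen), key=lambda s: min(s))
    )
    return stree, PlantedTruth(loss_clades=clades)


# ---------------------------------------------------------------------
# Mitochondrial genome records
# ---------------------------------------------------------------------


def simulate_mito_dataset(
    config: SimulationConfig,
) -> tuple[list[GenomeRecord], PlantedTruth]:
    """Mitochondrial genome records with bimodal subunit counts.

    CI-bearing species carry 6-7 of the 7 subunits with annotation or
    high-coverage homology evidence; CI-lacking species carry 0-2.
    ``incomplete_genome_prob`` controls the fraction of genomes with
    fewer than three CDS annotations (filtered as incomplete
    downstream) and ``misannotation_prob`` flips individual subunit
    evidence in either direction.
    """
    stree, truth = simulate_species_tree(config)
    rng = _stage_rng(config.seed, "genomes")
    records: list[GenomeRecord] = []
    for species in sorted(stree.tip_labels()):
        ci_present = stree.status[species] == PRESENT
        for g in range(config.n_genomes_per_species):
            if rng.random() < config.incomplete_genome_prob:
                n_cds = int(rng.integers(0, 3))
            else:
                n_cds = int(rng.integers(10, 16))
            if ci_present:
                n_present = int(rng.choice([6, 7], p=[0.3, 0.7]))
            else:
                n_present = int(rng.choice([0, 1, 2], p=[0.5, 0.35, 0.15]))
            present_idx = set(
                int(i)
                for i in rng.choice(len(SUBUNITS), size=n_present, replace=False)
            )
            evidence = []
            for i, subunit in enumerate(SUBUNITS):
                present = i in present_idx
                if rng.random() < config.misannotation_prob:
                    present = not present
                if present:
                    annotated = bool(rng.random() < 0.9)
                    coverage = float(rng.uniform(0.5, 1.0))
                else:
                    annotated = False
                    coverage = float(rng.uniform(0.0, 0.45))
                evidence.append(
                    SubunitEvidence(
                        subunit_id=subunit,
                        annotated=annotated,
                        prediction_coverage=round(coverage, 6),
                    )
                )
            records.append(
                GenomeRecord(
                    genome_id=f"{species}_g{g}",
                    species_id=species,
                    n_cds=n_cds,
                    evidence=tuple(evidence),
                )
            )
    return records, truth


# ---------------------------------------------------------------------
# Family-level data
# ---------------------------------------------------------------------


def _maximal_absent_clades(
    stree: SpeciesTree,
) -> list[tuple[object, frozenset[str]]]:
    """(node, tips) of each maximal CI-absent clade, by direct traversal."""
    tally: dict[int, tuple[int, int]] = {}
    for node in stree.tree.postorder_node_iter():
        if node.is_leaf():
            s = stree.status[node.taxon.label]
            tally[id(node)] = (int(s == PRESENT), int(s == ABSENT))
        else:
            ps = sum(tally[id(c)][0] for c in node.child_nodes())
            ab = sum(tally[id(c)][1] for c in node.child_nodes())
            tally[id(node)] = (ps, ab)
    clades = []
    for node in stree.tree.preorder_node_iter():
        p, a = tally[id(node)]
        if p == 0 and a > 0:
            parent = node.parent_node
            if parent is None or tally[id(parent)][0] > 0:
                clades.append((node, stree.leafset(node)))
    clades.sort(key=lambda item: min(item[1]))
    return clades


def _sister_species(stree: SpeciesTree, node, clade: frozenset[str]) -> tuple[str, ...]:
    """Closest CI-present species outside the clade, walking rootwards."""
    current = node.parent_node
    while current is not None:
        sisters = [
            t
            for t in stree.leafset(current) - clade
            if stree.status[t] == PRESENT
        ]
        if sisters:
            return tuple(sorted(sisters))
        current = current.parent_node
    return ()


def _make_profile(
    protein_id: str,
    species_id: str,
    p_mito: float,
    rng: np.random.Generator,
) -> LocalizationProfile:
    others = rng.dirichlet([5.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
    probs = (p_mito, *(float(x * (1.0 - p_mito)) for x in others))
    return LocalizationProfile(
        protein_id=protein_id,
        species_id=species_id,
        probabilities=probs,
        membrane=float(rng.uniform(0.0, 0.5)),
    )


def simulate_family_data(
    config: SimulationConfig, stree: SpeciesTree
) -> FamilyData:
    """Per-family inputs with planted associations, overlap, MR and pathways.

    The focal comparative set is one representative species per
    *recent* (single-genus) loss clade, mirroring an analysis centred
    on recent losses with close CI-bearing relatives; when fewer than
    two recent clades exist, all loss clades contribute a
    representative.
    """
    absent = stree.tips_with_status(ABSENT)
    present = stree.tips_with_status(PRESENT)
    if not absent or not present:
        raise ValueError("tree must contain both CI-present and CI-absent tips")

    rng = _stage_rng(config.seed, "families")
    clades = _maximal_absent_clades(stree)
    recent = [
        (node, tips)
        for node, tips in clades
        if len({stree.genus.get(t) for t in tips}) == 1
    ]
    chosen_clades = recent if len(recent) >= 2 else clades
    focal = tuple(sorted(min(tips) for _, tips in chosen_clades))
    sister_map = {
        min(tips): _sister_species(stree, node, tips)
        for node, tips in chosen_clades
    }

    families = [f"fam{i:04d}" for i in range(config.n_families)]
    cursor = 0
    assoc = families[cursor : cursor + config.n_planted_assoc_families]
    cursor += len(assoc)
    overlap = families[cursor : cursor + config.n_planted_overlap_families]
    cursor += len(overlap)
    hot = families[cursor : cursor + 2 * config.n_planted_pathways]
    cursor += len(hot)
    mr_fams = families[cursor : cursor + config.n_planted_retargeted]
    cursor += len(mr_fams)
    background = families[cursor:]

    species = sorted(stree.tip_labels())
    base_lambda = 2.0

    # Orthologue counts; planted associated families are shifted in all
    # CI-absent species.
    counts = pd.DataFrame(
        rng.poisson(base_lambda, size=(len(families), len(species))),
        index=families,
        columns=species,
    )
    absent_set = set(absent)
    shifted_cols = [s for s in species if s in absent_set]
    if assoc and shifted_cols:
        counts.loc[assoc, shifted_cols] = rng.poisson(
            base_lambda + config.copy_number_shift,
            size=(len(assoc), len(shifted_cols)),
        )

    # Branch-site p-values: planted overlap families are tiny in every
    # focal species; a sprinkling of species-private PS calls is added.
    ps_rows = []
    extras: dict[str, set[str]] = {}
    for sp in focal:
        pool = [f for f in families if f not in overlap]
        n_extra = rng.binomial(len(pool), config.background_event_rate)
        chosen = rng.choice(len(pool), size=n_extra, replace=False)
        extras[sp] = {pool[int(i)] for i in chosen}
        for fam in families:
            if fam in overlap:
                p = 10.0 ** rng.uniform(-6.0, -4.0)
            elif fam in extras[sp]:
                p = 10.0 ** rng.uniform(-5.0, -3.5)
            else:
                p = rng.uniform(0.05, 1.0)
            ps_rows.append(
                {
                    "species_id": sp,
                    "gene_id": f"{fam}@{sp}",
                    "family_id": fam,
                    "pvalue": float(p),
                }
            )
    ps_pvalues = pd.DataFrame(ps_rows)

    # Localization profiles for paralogue pairs.
    profiles: list[LocalizationProfile] = []
    pair_rows = []
    for i in range(config.n_retarget_pairs):
        pair_id = f"pair{i:03d}"
        planted = i < config.n_planted_retargeted
        target_sp = focal[i % len(focal)]
        sisters = sister_map[target_sp]
        sister_sp = [
            sisters[int(rng.integers(len(sisters)))] for _ in range(2)
        ] if sisters else [present[0], present[0]]
        if planted:
            sister_mito = rng.uniform(0.05, 0.15, size=2)
            target_mito = float(sister_mito.max() + config.retargeting_delta)
        else:
            sister_mito = rng.uniform(0.05, 0.2, size=2)
            target_mito = float(rng.uniform(0.05, 0.2))
        target = _make_profile(f"{pair_id}_t", target_sp, target_mito, rng)
        sis_profiles = [
            _make_profile(f"{pair_id}_s{k}", sp, float(m), rng)
            for k, (sp, m) in enumerate(zip(sister_sp, sister_mito))
        ]
        profiles.append(target)
        profiles.extend(sis_profiles)
        pair_rows.append(
            {
                "pair_id": pair_id,
                "retargeted": planted,
                "family_id": mr_fams[i] if planted else "",
                "target_protein": target.protein_id,
                "target_species": target_sp,
                "sister_proteins": ",".join(p.protein_id for p in sis_profiles),
            }
        )
    pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "pair_id",
            "retargeted",
            "family_id",
            "target_protein",
            "target_species",
            "sister_proteins",
        ],
    )

    # Event table over (family, focal species).
    event_rows = []
    planted_mr = {
        (row["family_id"], row["target_species"])
        for row in pair_rows
        if row["retargeted"]
    }
    for fam in families:
        for sp in focal:
            d_flag = bool(rng.random() < config.background_event_rate)
            mr_flag = bool(rng.random() < config.background_event_rate / 2.0)
            if fam in hot:
                d_flag = True
            if (fam, sp) in planted_mr:
                mr_flag = True
            ps_flag = fam in overlap or fam in extras[sp]
            if fam in hot:
                ps_flag = True
            sisters = sister_map[sp]
            l_flag = counts.at[fam, sp] == 0 and any(
                counts.at[fam, s] >= 1 for s in sisters
            )
            event_rows.append(
                {
                    "family_id": fam,
                    "species_id": sp,
                    "L": bool(l_flag),
                    "D": d_flag,
                    "PS": ps_flag,
                    "MR": mr_flag,
                }
            )
    events = pd.DataFrame(event_rows)

    # Pathway map: planted pathways carry two "hot" enzymes whose genes
    # are under innovation in every focal species.
    pathway_ids = [f"pw{i:02d}" for i in range(config.n_pathways)]
    planted_pathways = pathway_ids[: config.n_planted_pathways]
    map_rows = []
    pw_enzyme_rows = []
    sister_enzymes: set[str] = set()
    hot_iter = iter(hot)
    for pw in pathway_ids:
        for j in range(config.n_enzymes_per_pathway):
            enzyme_id = f"{pw}:e{j}"
            is_hot = pw in planted_pathways and j < 2
            if is_hot:
                fam = next(hot_iter)
            else:
                fam = background[int(rng.integers(len(background)))]
            pw_enzyme_rows.append({"pathway_id": pw, "enzyme_id": enzyme_id})
            if rng.random() < 0.8 or is_hot:
                sister_enzymes.add(enzyme_id)
            for sp in focal:
                if not is_hot and rng.random() > 0.9:
                    continue  # enzyme unmapped in this species
                map_rows.append(
                    {
                        "gene_id": f"{fam}@{sp}",
                        "species_id": sp,
                        "ko_id": f"K{10000 + len(pw_enzyme_rows):05d}",
                        "enzyme_id": enzyme_id,
                        "pathway_id": pw,
                        "identity_class": "high"
                        if is_hot or rng.random() < 0.5
                        else "low",
                    }
                )
    pathway_map = pd.DataFrame(map_rows)
    pathway_enzymes = pd.DataFrame(pw_enzyme_rows)

    truth = PlantedTruth(
        loss_clades=tuple(sorted((t for _, t in clades), key=min)),
        assoc_family_ids=frozenset(assoc),
        overlap_family_ids=frozenset(overlap),
        retargeted_pair_ids=frozenset(
            row["pair_id"] for row in pair_rows if row["retargeted"]
        ),
        altered_pathway_ids=frozenset(planted_pathways),
    )
    return FamilyData(
        counts=counts,
        events=events,
        ps_pvalues=ps_pvalues,
        profiles=tuple(profiles),
        pairs=pairs,
        pathway_map=pathway_map,
        pathway_enzymes=pathway_enzymes,
        sister_enzymes=frozenset(sister_enzymes),
        focal_species=focal,
        sister_species=sister_map,
        truth=truth,
    )


def simulate_go_annotations(
    config: SimulationConfig, data: FamilyData
) -> tuple[dict[str, set[str]], dict[str, set[str]], dict[str, set[str]], str]:
    """GO-style annotations with one term planted as convergently enriched.

    Families flagged as duplicated in *every* focal species are
    annotated to a dedicated term; the per-species study sets are the
    duplicated genes of that species. Returns (term -> genes,
    species -> study genes, species -> population genes, planted term).
    """
    rng = _stage_rng(config.seed, "go")
    families = list(data.counts.index)
    terms = [f"GO:{7000000 + i}" for i in range(15)]
    planted_term = terms[0]
    term_to_families: dict[str, set[str]] = {t: set() for t in terms}
    for fam in families:
        n_terms = int(rng.integers(1, 4))
        chosen = rng.choice(len(terms) - 1, size=n_terms, replace=False)
        for i in chosen:
            term_to_families[terms[int(i) + 1]].add(fam)
    d_wide = data.events.pivot(
        index="family_id", columns="species_id", values="D"
    )
    convergent_d = set(d_wide.index[d_wide.all(axis=1)])
    term_to_families[planted_term] = set(convergent_d)
    # a couple of background annotations keep the planted term imperfect
    others = [f for f in families if f not in convergent_d]
    for i in rng.choice(len(others), size=min(2, len(others)), replace=False):
        term_to_families[planted_term].add(others[int(i)])

    term_to_genes: dict[str, set[str]] = {t: set() for t in terms}
    study_sets: dict[str, set[str]] = {}
    population_sets: dict[str, set[str]] = {}
    for sp in data.focal_species:
        population_sets[sp] = {f"{fam}@{sp}" for fam in families}
        d_fams = set(
            data.events.loc[
                (data.events["species_id"] == sp) & data.events["D"],
                "family_id",
            ]
        )
        study_sets[sp] = {f"{fam}@{sp}" for fam in d_fams}
        for t in terms:
            term_to_genes[t].update(
                f"{fam}@{sp}" for fam in term_to_families[t]
            )
    return term_to_genes, study_sets, population_sets, planted_term


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Generate every pipeline input for one configuration."""
    stree, tree_truth = simulate_species_tree(config)
    genomes, _ = simulate_mito_dataset(config)
    family_data = simulate_family_data(config, stree)
    truth = replace(
        family_data.truth, loss_clades=tree_truth.loss_clades
    )
    return SyntheticDataset(
        config=config,
        tree=stree,
        genomes=tuple(genomes),
        family_data=replace(family_data, truth=truth),
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write all synthetic inputs as TSV/Newick files."""
    from .mito_screen import write_genomes_tsv
    from .retargeting import write_profiles_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.tree.write(out / "species_tree.nwk", out / "tip_states.tsv")
    write_genomes_tsv(dataset.genomes, out / "genomes.tsv")
    fd = dataset.family_data
    fd.counts.rename_axis("family_id").to_csv(out / "ortholog_counts.tsv", sep="\t")
    fd.events.to_csv(out / "family_events.tsv", sep="\t", index=False)
    fd.ps_pvalues.to_csv(out / "ps_pvalues.tsv", sep="\t", index=False)
    write_profiles_tsv(fd.profiles, out / "localization.tsv")
    fd.pairs.to_csv(out / "retarget_pairs.tsv", sep="\t", index=False)
    fd.pathway_map.to_csv(out / "pathway_map.tsv", sep="\t", index=False)
    fd.pathway_enzymes.to_csv(out / "pathway_enzymes.tsv", sep="\t", index=False)
    truth_rows = [
        {"kind": "loss_clade", "id": f"clade{i}", "members": ",".join(sorted(c))}
        for i, c in enumerate(dataset.truth.loss_clades)
    ]
    for kind, ids in (
        ("assoc_family", dataset.truth.assoc_family_ids),
        ("overlap_family", dataset.truth.overlap_family_ids),
        ("retargeted_pair", dataset.truth.retargeted_pair_ids),
        ("altered_pathway", dataset.truth.altered_pathway_ids),
    ):
        for x in sorted(ids):
            truth_rows.append({"kind": kind, "id": x, "members": ""})
    pd.DataFrame(truth_rows, columns=["kind", "id", "members"]).to_csv(
        out / "planted_truth.tsv", sep="\t", index=False
    )
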