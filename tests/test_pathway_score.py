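"""Gene/enzyme/pathway scores, the 729-point grid, z-score aggregation."""

import numpy as np
import pandas as pd
import pytest

from ciloss.pathway_score import (
    ScoreParams,
    enzyme_score,
    final_scores,
    gene_score,
    parameter_grid,
    pathway_raw_score,
    score_pathways,
)

PARAMS = ScoreParams(p1=60.0, p2=120.0, p3=30.0, p4=5.0, p5=2.0, p6=4.0)


def gene_table(rows):
    cols = ["species_id", "PS", "MR", "D", "L", "identity_class"]
    return pd.DataFrame(rows, columns=cols)


class TestScoreParams:
    def test_valid(self):
        ScoreParams(p1=100, p2=200, p3=50, p4=10, p5=5, p6=10)

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(p1=60, p2=120, p3=30, p4=5, p5=0.4, p6=4), "p5"),
            (dict(p1=60, p2=120, p3=30, p4=2.5, p5=2, p6=4), "p4"),
            (dict(p1=60, p2=120, p3=9, p4=5, p5=2, p6=4), "p3"),
            (dict(p1=39, p2=120, p3=30, p4=5, p5=2, p6=4), "p1"),
            (dict(p1=60, p2=79, p3=30, p4=5, p5=2, p6=4), "p2"),
            (dict(p1=60, p2=120, p3=30, p4=5, p5=2, p6=11), "p6"),
        ],
    )
    def test_constraint_chain(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            ScoreParams(**kwargs)


class TestGeneScore:
    def test_duplication_high_identity(self):
        assert gene_score({"D": True}, PARAMS, "high") == 50.0  # p4 * 10

    def test_no_events_low_identity(self):
        assert gene_score({}, PARAMS, "low") == -4.0  # -p6

    def test_loss_only_uses_lower_score(self):
        assert gene_score({"L": True}, PARAMS, "low") == 2.0  # p5

    def test_innovation_dominates_loss(self):
        assert gene_score({"L": True, "PS": True}, PARAMS, "low") == 5.0

    def test_unknown_identity_raises(self):
        with pytest.raises(ValueError, match="identity_class"):
            gene_score({}, PARAMS, "medium")


class TestEnzymeScore:
    def test_three_species_cooccurrence(self):
        genes = gene_table(
            [[f"sp{i}", True, False, False, False, "low"] for i in range(3)]
        )
        expected = PARAMS.p2 + 3 * PARAMS.p4
        assert enzyme_score(genes, PARAMS) == pytest.approx(expected)

    def test_two_species_cooccurrence_gets_p1_not_p2(self):
        genes = gene_table(
            [
                ["sp0", True, False, False, False, "low"],
                ["sp1", False, True, False, False, "low"],
                ["sp2", False, False, False, False, "low"],
            ]
        )
        expected = PARAMS.p1 + 2 * PARAMS.p4 - PARAMS.p6
        assert enzyme_score(genes, PARAMS) == pytest.approx(expected)

    def test_no_events_all_negative(self):
        genes = gene_table(
            [[f"sp{i}", False, False, False, False, "low"] for i in range(3)]
        )
        assert enzyme_score(genes, PARAMS) == pytest.approx(-3 * PARAMS.p6)

    def test_uniqueness_bonus(self):
        genes = gene_table([["sp0", False, False, False, True, "low"]])
        with_u = enzyme_score(genes, PARAMS, unique_with_loss=True)
        without = enzyme_score(genes, PARAMS, unique_with_loss=False)
        assert with_u - without == pytest.approx(PARAMS.p3)


class TestPathwayRawScore:
    def test_all_enzymes_unmapped(self):
        enzymes = {f"e{i}": gene_table([]) for i in range(4)}
        score = pathway_raw_score(enzymes, "sp0", PARAMS)
        assert score == pytest.approx(-4 * PARAMS.p6)

    def test_single_enzyme_pathway(self):
        genes = gene_table([["sp0", True, False, False, False, "high"]])
        score = pathway_raw_score({"e0": genes}, "sp0", PARAMS)
        assert score == pytest.approx(enzyme_score(genes, PARAMS))

    def test_adding_innovation_never_lowers_score(self):
        base = gene_table([["sp0", False, False, False, False, "low"]])
        upgraded = gene_table([["sp0", False, False, True, False, "low"]])
        for params in parameter_grid()[::73]:
            low = pathway_raw_score({"e0": base}, "sp0", params)
            high = pathway_raw_score({"e0": upgraded}, "sp0", params)
            assert high > low

    def test_empty_pathway_raises(self):
        with pytest.raises(ValueError, match="no enzymes"):
            pathway_raw_score({}, "sp0", PARAMS)


class TestParameterGrid:
    def test_exactly_729_combinations(self):
        grid = parameter_grid()
        assert len(grid) == 729
        assert len(set(grid)) == 729

    def test_all_satisfy_constraints(self):
        for p in parameter_grid():
            # ScoreParams validates on construction; re-check explicitly
            assert 0.5 <= p.p5 <= 5
            assert p.p5 + 1 <= p.p4 <= 10
            assert p.p5 + 1 <= p.p6 <= 10
            assert p.p4 + 5 <= p.p3 <= 50
            assert p.p3 + 10 <= p.p1 <= 100
            assert p.p1 + 20 <= p.p2 <= 200

    def test_p5_levels(self):
        grid = parameter_grid()
        assert sorted({p.p5 for p in grid}) == [0.5, 2.75, 5.0]

    def test_deterministic(self):
        assert parameter_grid() == parameter_grid()


class TestFinalScores:
    def test_z_invariants(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(8, 3, 5))
        scores = final_scores(raw, [f"pw{i}" for i in range(8)], ["a", "b", "c"])
        assert np.allclose(scores.z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(scores.z.std(axis=0), 1, atol=1e-9)
        assert sorted(scores.rank) == list(range(1, 9))

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(6, 2, 4))
        shifted = raw + rng.normal(size=(1, 2, 4))  # constant per slice
        a = final_scores(raw, list("abcdef"), ["x", "y"])
        b = final_scores(shifted, list("abcdef"), ["x", "y"])
        assert np.allclose(a.z, b.z)

    def test_zero_variance_slice_handled(self, caplog):
        raw = np.ones((3, 1, 2))
        with caplog.at_level("WARNING"):
            scores = final_scores(raw, ["a", "b", "c"], ["x"])
        assert "zero variance" in caplog.text
        assert np.allclose(scores.z, 0)

    def test_single_pathway_raises(self):
        with pytest.raises(ValueError, match="two pathways"):
            final_scores(np.ones((1, 2, 3)), ["a"], ["x", "y"])


def test_score_pathways_matches_explicit_rules():
    """The vectorized grid scorer agrees with direct rule application."""
    species = ["sp0", "sp1", "sp2"]
    pathway_map = pd.DataFrame(
        [
            # pwA:e0 — innovation in all three species, high identity
            *[
                {
                    "gene_id": f"famH@{sp}",
                    "species_id": sp,
                    "enzyme_id": "e0",
                    "pathway_id": "pwA",
                    "identity_class": "high",
                }
                for sp in species
            ],
            # pwA:e1 — mapped in sp0 only
            {
                "gene_id": "famX@sp0",
                "species_id": "sp0",
                "enzyme_id": "e1",
                "pathway_id": "pwA",
                "identity_class": "low",
            },
            # pwB:e2 — no events
            *[
                {
                    "gene_id": f"famN@{sp}",
                    "species_id": sp,
                    "enzyme_id": "e2",
                    "pathway_id": "pwB",
                    "identity_class": "low",
                }
                for sp in species
            ],
        ]
    )
    gene_events = pd.DataFrame(
        [
            {"gene_id": f"famH@{sp}", "species_id": sp, "PS": True, "MR": False,
             "D": False, "L": False}
            for sp in species
        ]
        + [
            {"gene_id": "famX@sp0", "species_id": "sp0", "PS": False, "MR": False,
             "D": False, "L": True}
        ]
    )
    grid = [PARAMS]
    # all enzymes also occur in the CI+ sister group: no uniqueness bonus
    scores = score_pathways(
        pathway_map,
        gene_events,
        species,
        sister_enzymes={"e0", "e1", "e2"},
        params_list=grid,
    )

    # explicit computation via the rule functions
    e0 = gene_table([[sp, True, False, False, False, "high"] for sp in species])
    e1 = gene_table([["sp0", False, False, False, True, "low"]])
    e2 = gene_table([[sp, False, False, False, False, "low"] for sp in species])
    for j, sp in enumerate(species):
        expected_a = pathway_raw_score({"e0": e0, "e1": e1}, sp, PARAMS)
        expected_b = pathway_raw_score({"e2": e2}, sp, PARAMS)
        i_a = scores.pathway_ids.index("pwA")
        i_b = scores.pathway_ids.index("pwB")
        assert scores.raw[i_a, j, 0] == pytest.approx(expected_a)
        assert scores.raw[i_b, j, 0] == pytest.approx(expected_b)
    assert scores.rank[scores.pathway_ids.index("pwA")] == 1


def test_planted_pathways_rank_top(default_dataset):
    ds = default_dataset
    fd = ds.family_data
    events = fd.events.assign(gene_id=fd.events["family_id"] + "@" + fd.events["species_id"])
    scores = score_pathways(
        fd.pathway_map,
        events,
        list(fd.focal_species),
        sister_enzymes=fd.sister_enzymes,
        pathway_enzymes=fd.pathway_enzymes,
    )
    ranks = dict(zip(scores.pathway_ids, scores.rank))
    planted = ds.truth.altered_pathway_ids
    # On any single seed the planted pathways dominate the ranking;
    # the stricter top-n_planted recovery rate is checked over many
    # seeds in the acceptance suite.
    assert scores.top(1)[0] in planted
    assert all(ranks[p] <= 2 * len(planted) for p in planted)
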