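"""B-vitamin pathway scoring rules."""

import numpy as np
import pytest

from cimsym.errors import InvalidParameterError
from cimsym.synthetic_data import SimConfig, reference_pathway_calls, simulate_gene_matrix
from cimsym.vitamin_pathways import (
    ABSENT,
    ALT_ENZYME,
    COHORT_ABSENT,
    DISRUPTED,
    FUNCTIONAL,
    INTACT,
    NONFUNCTIONAL,
    PUTATIVELY_FUNCTIONAL,
    GeneCopyMatrix,
    PathwayDefinition,
    PathwayStep,
    cohort_absence_profile,
    complementation_call,
    gene_status,
    load_pathway_definitions,
    score_pathway,
    step_satisfied,
    vitamin_matrix,
)

RIBO = PathwayDefinition(
    "riboflavin",
    (
        PathwayStep("ribA", frozenset({"ribA"})),
        PathwayStep("dephosphorylation", frozenset({"yigB"}),
                    has_known_alternative_enzymes=True),
        PathwayStep("ribE", frozenset({"ribE"})),
    ),
)

THREE_STEP = PathwayDefinition(
    "thiamine",
    (
        PathwayStep("s1", frozenset({"thiC"})),
        PathwayStep("s2", frozenset({"thiD"})),
        PathwayStep("s3", frozenset({"thiE"})),
    ),
)


def matrix_of(**genomes):
    """matrix_of(g1={"ribA": ["INTACT"]}, ...)"""
    return GeneCopyMatrix(
        {(g, gene): copies for g, genes in genomes.items()
         for gene, copies in genes.items()}
    )


class TestGeneStatus:
    @pytest.mark.parametrize(
        "copies,status",
        [
            ([DISRUPTED, INTACT], INTACT),  # duplicated-operon complementation
            ([ABSENT], ABSENT),
            ([DISRUPTED, DISRUPTED], DISRUPTED),
            ([INTACT], INTACT),
        ],
    )
    def test_copy_collapse(self, copies, status):
        assert gene_status(copies) == status

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            gene_status([])


class TestStepSatisfied:
    step = PathwayStep("panE", frozenset({"panD", "panE"}))

    def test_any_alternative_gene_suffices(self):
        m = matrix_of(g={"panE": [INTACT]})
        assert step_satisfied("g", self.step, m)

    def test_disrupted_does_not_satisfy(self):
        m = matrix_of(g={"panD": [DISRUPTED], "panE": [DISRUPTED]})
        assert not step_satisfied("g", self.step, m)

    def test_unlisted_gene_is_absent(self):
        m = matrix_of(g={"ribA": [INTACT]})
        assert not step_satisfied("g", self.step, m)


class TestCohortProfile:
    def build(self, n_missing, n_total):
        genomes = {}
        for i in range(n_total):
            has = i >= n_missing
            genomes[f"g{i}"] = {"thiC": [INTACT if has else ABSENT],
                                "thiD": [INTACT], "thiE": [INTACT]}
        return matrix_of(**genomes)

    def test_majority_absence_enters_profile(self):
        # 13 of 22 genomes lack the step: 13/22 > 0.5
        m = self.build(13, 22)
        profile = cohort_absence_profile(m, [THREE_STEP])
        assert ("thiamine", "s1") in profile

    def test_universally_satisfied_step_not_in_profile(self):
        m = self.build(0, 10)
        assert cohort_absence_profile(m, [THREE_STEP]) == set()

    def test_exactly_half_is_not_majority(self):
        m = self.build(5, 10)
        assert cohort_absence_profile(m, [THREE_STEP]) == set()

    def test_single_genome_cohort_empty(self):
        m = self.build(1, 1)
        assert cohort_absence_profile(m, [THREE_STEP]) == set()


class TestScorePathway:
    def test_all_steps_satisfied_functional(self):
        m = matrix_of(g={"ribA": [INTACT], "yigB": [INTACT], "ribE": [INTACT]})
        assert score_pathway("g", RIBO, m).call == FUNCTIONAL

    def test_missing_alternative_enzyme_step_putative(self):
        # the canonical dephosphorylation gene is absent but alternative
        # enzymes exist: the pathway stays putatively functional
        m = matrix_of(g={"ribA": [INTACT], "ribE": [INTACT]})
        call = score_pathway("g", RIBO, m)
        assert call.call == PUTATIVELY_FUNCTIONAL
        assert call.excusals == {"dephosphorylation": ALT_ENZYME}

    def test_two_unexcusable_missing_steps_nonfunctional(self):
        m = matrix_of(g={"thiE": [INTACT]})
        call = score_pathway("g", THREE_STEP, m)
        assert call.call == NONFUNCTIONAL
        assert set(call.missing_steps) == {"s1", "s2"}

    def test_cohort_absent_step_excused_when_otherwise_intact(self):
        m = matrix_of(g={"thiD": [INTACT], "thiE": [INTACT]})
        profile = {("thiamine", "s1")}
        call = score_pathway("g", THREE_STEP, m, profile)
        assert call.call == PUTATIVELY_FUNCTIONAL
        assert call.excusals["s1"] == COHORT_ABSENT

    def test_cohort_excusal_needs_otherwise_intact(self):
        # an extra idiosyncratic hole voids the cohort-absence excusal
        m = matrix_of(g={"thiE": [INTACT]})
        profile = {("thiamine", "s1")}
        assert score_pathway("g", THREE_STEP, m, profile).call == NONFUNCTIONAL

    def test_monotone_under_copy_upgrades(self):
        """Upgrading any copy (ABSENT->DISRUPTED->INTACT) never
        downgrades the pathway call."""
        order = {NONFUNCTIONAL: 0, PUTATIVELY_FUNCTIONAL: 1, FUNCTIONAL: 2}
        upgrade = {ABSENT: DISRUPTED, DISRUPTED: INTACT}
        rng = np.random.default_rng(21)
        statuses = [INTACT, DISRUPTED, ABSENT]
        for _ in range(200):
            genes = {g: [statuses[int(rng.integers(3))]]
                     for g in ("thiC", "thiD", "thiE")}
            m = matrix_of(g=genes)
            base = score_pathway("g", THREE_STEP, m).call
            for gene, copies in genes.items():
                if copies[0] == INTACT:
                    continue
                up = dict(genes)
                up[gene] = [upgrade[copies[0]]]
                upped = score_pathway("g", THREE_STEP, matrix_of(g=up)).call
                assert order[upped] >= order[base]


class TestComplementation:
    def test_union_of_partial_capacities(self):
        # residents satisfying steps {1,2} and {3} combine to FUNCTIONAL
        # though each alone is NONFUNCTIONAL
        m = matrix_of(
            wolb={"thiC": [INTACT], "thiD": [INTACT]},
            symbio={"thiE": [INTACT]},
        )
        assert score_pathway("wolb", THREE_STEP, m).call == NONFUNCTIONAL
        assert score_pathway("symbio", THREE_STEP, m).call == NONFUNCTIONAL
        combined = complementation_call(["wolb", "symbio"], THREE_STEP, m)
        assert combined.call == FUNCTIONAL

    def test_single_resident_identity(self):
        m = matrix_of(g={"thiC": [INTACT], "thiD": [INTACT], "thiE": [INTACT]})
        assert complementation_call(["g"], THREE_STEP, m).call == \
            score_pathway("g", THREE_STEP, m).call

    def test_dominance_over_best_resident(self):
        rng = np.random.default_rng(8)
        order = {NONFUNCTIONAL: 0, PUTATIVELY_FUNCTIONAL: 1, FUNCTIONAL: 2}
        statuses = [INTACT, DISRUPTED, ABSENT]
        for _ in range(100):
            m = matrix_of(
                a={g: [statuses[int(rng.integers(3))]] for g in ("thiC", "thiD", "thiE")},
                b={g: [statuses[int(rng.integers(3))]] for g in ("thiC", "thiD", "thiE")},
            )
            best = max(
                order[score_pathway(g, THREE_STEP, m).call] for g in ("a", "b")
            )
            combined = complementation_call(["a", "b"], THREE_STEP, m)
            assert order[combined.call] >= best


class TestVitaminMatrix:
    def test_pristine_cohort_all_functional(self):
        defs = load_pathway_definitions()
        cfg = SimConfig(seed=1, pathway_loss_rate=0.0, pseudogene_rate=0.0)
        matrix, truth = simulate_gene_matrix([f"g{i}" for i in range(4)], defs, cfg)
        calls, _ = vitamin_matrix(matrix, defs)
        assert (calls.values == FUNCTIONAL).all()
        assert all(v == FUNCTIONAL for v in truth.true_pathway_calls.values())

    def test_total_loss_all_nonfunctional(self):
        defs = load_pathway_definitions()
        cfg = SimConfig(seed=1, pathway_loss_rate=1.0)
        matrix, truth = simulate_gene_matrix(["g0", "g1"], defs, cfg)
        assert all(v == NONFUNCTIONAL for v in truth.true_pathway_calls.values())

    def test_matches_reference_scorer_on_degraded_cohorts(self):
        """Production scorer vs the straight-line reference scorer on
        random degraded gene matrices (cell-wise exact)."""
        defs = load_pathway_definitions()
        genomes = [f"g{i}" for i in range(6)]
        for seed in range(25):
            cfg = SimConfig(seed=seed, pathway_loss_rate=0.3, pseudogene_rate=0.2)
            matrix, truth = simulate_gene_matrix(genomes, defs, cfg)
            calls, _ = vitamin_matrix(matrix, defs)
            for g in genomes:
                for d in defs:
                    assert calls.loc[g, d.pathway_id] == \
                        truth.true_pathway_calls[f"{g}|{d.pathway_id}"]

    def test_iteration_order_invariance(self):
        defs = load_pathway_definitions()
        cfg = SimConfig(seed=7, pathway_loss_rate=0.3)
        matrix, _ = simulate_gene_matrix(["b", "a", "c"], defs, cfg)
        calls1, _ = vitamin_matrix(matrix, defs)
        calls2, _ = vitamin_matrix(matrix, list(reversed(defs)))
        assert (calls1[sorted(calls1.columns)]
                .equals(calls2[sorted(calls2.columns)]))

    def test_composite_pooling_improves_call(self):
        defs = [THREE_STEP]
        m = matrix_of(
            w_high={"thiC": [INTACT]},
            w_low={"thiD": [INTACT], "thiE": [INTACT]},
            other={"thiC": [INTACT], "thiD": [INTACT], "thiE": [INTACT]},
        )
        calls, _ = vitamin_matrix(m, defs, composites={"w": ["w_high", "w_low"]})
        assert set(calls.index) == {"w", "other"}
        assert calls.loc["w", "thiamine"] == FUNCTIONAL
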