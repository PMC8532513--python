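"""FBA core: LP solutions, pFBA, substrate tests, essentiality, metrics."""

import math

import numpy as np
import pytest

from evogem.fba import (
    ConfusionCounts,
    MediaSpec,
    confusion_metrics,
    pfba,
    single_gene_deletions,
    solve_fba,
)
from evogem.fba import test_substrate_utilization as check_utilization
from evogem.gpr import parse_gpr
from evogem.panmodel import Metabolite, PanModel, Reaction
from evogem.ssmodel import derive_species_model


class TestSolveFba:
    def test_hand_solved_chain(self, chain_model, chain_media):
        # uptake 10, biomass consumes 2 P per unit -> optimum 5
        result = solve_fba(chain_model, chain_media)
        assert result.optimal
        assert result.objective == pytest.approx(5.0, abs=1e-8)

    def test_closed_exchanges_give_zero(self, chain_model):
        result = solve_fba(chain_model, MediaSpec({}, name="empty"))
        assert result.optimal
        assert result.objective == pytest.approx(0.0, abs=1e-9)

    def test_invalid_media_bounds_rejected(self, chain_model):
        with pytest.raises(ValueError):
            MediaSpec({"EX_S": (5.0, -5.0)})

    def test_unknown_objective_rejected(self, chain_model, chain_media):
        with pytest.raises(KeyError):
            solve_fba(chain_model, chain_media, objective_reaction="nope")

    def test_steady_state_and_bounds_hold(self, world):
        model = world.species_model("sp00")
        result = solve_fba(model, world.media)
        assert result.optimal
        flux = np.array([result.fluxes[r.id] for r in model.reactions])
        from evogem.fba import apply_media, build_stoichiometry

        _, _, s = build_stoichiometry(model)
        lb, ub = apply_media(model, world.media)
        assert np.abs(s @ flux).max() < 1e-6
        assert (flux >= lb - 1e-6).all() and (flux <= ub + 1e-6).all()

    def test_objective_invariant_under_reordering(self, world):
        model = world.species_model("sp00")
        base = solve_fba(model, world.media).objective
        rng = np.random.default_rng(0)
        for _ in range(3):
            perm_r = list(rng.permutation(len(model.reactions)))
            perm_m = list(rng.permutation(len(model.metabolites)))
            shuffled = PanModel(
                [model.metabolites[i] for i in perm_m],
                [model.reactions[i] for i in perm_r],
                model.biomass_id,
            )
            assert solve_fba(shuffled, world.media).objective == pytest.approx(
                base, rel=1e-9
            )

    def test_relaxing_bounds_never_decreases_optimum(self, world):
        model = world.species_model("sp00")
        base = solve_fba(model, world.media).objective
        rng = np.random.default_rng(1)
        for _ in range(5):
            rxn = model.reactions[int(rng.integers(len(model.reactions)))]
            relaxed = solve_fba(
                model,
                world.media,
                bound_overrides={
                    rxn.id: (rxn.lower_bound - 10.0, rxn.upper_bound + 10.0)
                },
            )
            assert relaxed.objective >= base - 1e-9


def _cycle_model():
    """Optimal path plus a parallel futile cycle A<->B."""
    mets = [Metabolite("s_e", compartment="e"), Metabolite("a_c"), Metabolite("b_c")]
    reactions = [
        Reaction("EX_S", {"s_e": -1.0}, -10.0, 1000.0),
        Reaction("T", {"s_e": -1.0, "a_c": 1.0}),
        Reaction("AB", {"a_c": -1.0, "b_c": 1.0}, -1000.0, 1000.0),
        Reaction("BA", {"b_c": -1.0, "a_c": 1.0}, -1000.0, 1000.0),
        Reaction("BIO", {"b_c": -1.0}),
    ]
    return PanModel(mets, reactions, "BIO")


class TestPfba:
    def test_futile_cycle_carries_no_flux(self):
        model = _cycle_model()
        media = MediaSpec({"EX_S": (-10.0, 1000.0)})
        result = pfba(model, media)
        assert result.objective == pytest.approx(10.0, abs=1e-8)
        # the A->B conversion needs 10 units net; the shortest assignment
        # uses one direction only
        assert abs(result.fluxes["AB"]) + abs(result.fluxes["BA"]) == pytest.approx(
            10.0, abs=1e-6
        )

    def test_objective_matches_plain_fba(self, chain_model, chain_media):
        assert pfba(chain_model, chain_media).objective == pytest.approx(
            solve_fba(chain_model, chain_media).objective, rel=1e-9
        )

    def test_total_flux_is_minimal_on_toy(self):
        # brute force: on the cycle toy the optimal face fixes EX_S=-10,
        # T=10, BIO=10 and net AB-BA=10, so min sum|v| = 40
        model = _cycle_model()
        media = MediaSpec({"EX_S": (-10.0, 1000.0)})
        result = pfba(model, media)
        total = sum(abs(v) for v in result.fluxes.values())
        assert total == pytest.approx(40.0, abs=1e-6)


class TestAgainstCobra:
    def test_objective_matches_cobrapy(self, chain_model, chain_media):
        cobra = pytest.importorskip("cobra")
        m = cobra.Model("chain")
        mets = {x.id: cobra.Metabolite(x.id) for x in chain_model.metabolites}
        for rxn in chain_model.reactions:
            cr = cobra.Reaction(rxn.id)
            m.add_reactions([cr])
            cr.add_metabolites(
                {mets[k]: v for k, v in rxn.stoichiometry.items()}
            )
            lo, hi = rxn.lower_bound, rxn.upper_bound
            if rxn.id in chain_media.bounds:
                lo, hi = chain_media.bounds[rxn.id]
            elif rxn.id == "EX_S":
                lo = 0.0
            cr.bounds = (lo, hi)
        m.objective = "BIO"
        assert m.optimize().objective_value == pytest.approx(
            solve_fba(chain_model, chain_media).objective, abs=1e-6
        )


class TestSubstrateUtilization:
    def test_complete_species_uses_all_substrates(self, world):
        model = world.species_model(world.truth["complete_species"])
        for trait, ex in world.truth["substrate_exchanges"].items():
            assert check_utilization(model, ex, world.media, "EX_s0")

    def test_species_missing_branch_fails(self, world, world_traits):
        # any planted catabolic-loss species must not utilize its trait
        for trait, labels in world.truth["loss_labels"].items():
            ex = world.truth["substrate_exchanges"][trait]
            for sp, label in labels.items():
                if label != "correlated_reaction_loss":
                    continue
                model = world.species_model(sp)
                assert not check_utilization(model, ex, world.media, "EX_s0")

    def test_absent_exchange_scores_as_non_utilizer(self, chain_model, chain_media):
        species = derive_species_model(chain_model, {"G_T": 1})
        assert not check_utilization(
            species, "EX_missing", chain_media, "EX_S"
        )

    def test_growth_exactly_at_threshold_counts(self):
        mets = [Metabolite("s_e", compartment="e")]
        reactions = [
            Reaction("EX_S", {"s_e": -1.0}, -1e-6, 1000.0),
            Reaction("BIO", {"s_e": -1.0}),
        ]
        model = PanModel(mets, reactions, "BIO")
        media = MediaSpec({"EX_S": (-1e-6, 1000.0)})
        # uptake capped exactly at the growth threshold: still counts
        assert check_utilization(model, "EX_S", media, "EX_S", uptake_rate=1e-6)


class TestEssentiality:
    def test_sole_route_gene_is_essential(self, chain_model, chain_media):
        species = derive_species_model(chain_model, {"G_T": 1})
        calls = single_gene_deletions(species, chain_media)
        assert calls["G_T"] == "essential"

    def test_isozyme_members_are_dispensable(self, chain_media):
        mets = [Metabolite("s_e", compartment="e"), Metabolite("p_c")]
        reactions = [
            Reaction("EX_S", {"s_e": -1.0}, -10.0, 1000.0),
            Reaction("T", {"s_e": -1.0, "p_c": 1.0}, gpr=parse_gpr("G1 or G2")),
            Reaction("BIO", {"p_c": -1.0}),
        ]
        pan = PanModel(mets, reactions, "BIO")
        species = derive_species_model(pan, {"G1": 1, "G2": 1})
        calls = single_gene_deletions(species, MediaSpec({"EX_S": (-10.0, 1000.0)}))
        assert calls == {"G1": "non_essential", "G2": "non_essential"}

    def test_adding_isozyme_never_creates_essentiality(self, chain_model, chain_media):
        species = derive_species_model(chain_model, {"G_T": 1})
        before = single_gene_deletions(species, chain_media)
        with_iso = PanModel(
            chain_model.metabolites,
            [
                Reaction(
                    r.id, r.stoichiometry, r.lower_bound, r.upper_bound,
                    parse_gpr("G_T or G_ISO") if r.id == "T" else r.gpr,
                )
                for r in chain_model.reactions
            ],
            "BIO",
        )
        species2 = derive_species_model(with_iso, {"G_T": 1, "G_ISO": 1})
        after = single_gene_deletions(species2, chain_media)
        for gene, call in before.items():
            if call == "non_essential":
                assert after[gene] == "non_essential"
        assert after["G_T"] == "non_essential"

    def test_matches_rebuild_oracle_on_world(self, world):
        sp = world.truth["complete_species"]
        model = world.species_model(sp)
        calls = single_gene_deletions(model, world.media)
        row = world.existence.row(sp)
        for gene, call in calls.items():
            knocked = dict(row)
            knocked[gene] = 0
            rebuilt = derive_species_model(world.pan_model, knocked, sp)
            result = solve_fba(rebuilt, world.media)
            grows = result.optimal and result.objective >= 1e-6
            assert call == ("non_essential" if grows else "essential"), gene


class TestConfusionMetrics:
    def test_published_definitions(self):
        m = confusion_metrics(ConfusionCounts(TP=9, TN=0, FP=2, FN=1))
        assert m.sensitivity == pytest.approx(0.9)
        assert m.accuracy == pytest.approx(0.75)

    def test_perfect_predictions(self):
        m = confusion_metrics(ConfusionCounts(TP=5, TN=7, FP=0, FN=0))
        assert (
            m.accuracy == m.sensitivity == m.specificity == m.precision == m.f1 == 1.0
        )
        assert m.fpr == 0.0

    def test_matches_first_principles_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 21, size=4))
            if tp + tn + fp + fn == 0:
                continue
            m = confusion_metrics(ConfusionCounts(tp, tn, fp, fn))
            assert m.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))
            for value, num, den in [
                (m.sensitivity, tp, tp + fn),
                (m.specificity, tn, tn + fp),
                (m.precision, tp, tp + fp),
            ]:
                if den == 0:
                    assert math.isnan(value)
                else:
                    assert value == pytest.approx(num / den)

    def test_zero_denominators_are_nan_not_zero(self):
        m = confusion_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert math.isnan(m.sensitivity) and math.isnan(m.precision)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts())
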