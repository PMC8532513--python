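"""Trait-reaction correlation, gain/loss classification, attribution."""

import numpy as np
import pandas as pd
import pytest

from evogem.fba import ConfusionCounts, confusion_metrics
from evogem.traitevo import (
    TraitTable,
    attribute_loss_mechanism,
    classify_trait_changes,
    find_correlated_reactions,
    gain_mechanism_tally,
    reaction_trait_metrics,
)


class TestReactionTraitMetrics:
    def test_perfect_predictor(self):
        v = [1, 0, 1, 1, 0, 1, 0, 0, 1, 1]
        assert reaction_trait_metrics(v, v) == (1.0, 1.0)

    def test_complement_predictor(self):
        trait = [1, 0, 1, 0]
        presence = [0, 1, 0, 1]
        acc, sens = reaction_trait_metrics(presence, trait)
        assert acc == 0.0 and sens == 0.0

    def test_na_excluded_and_matches_hand_counts(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            presence = rng.integers(0, 2, size=20)
            trait = rng.integers(0, 2, size=20).astype(float)
            trait[rng.random(20) < 0.2] = np.nan
            if np.isnan(trait).all() or not (trait == 1).any():
                continue
            tp = fp = fn = tn = 0
            for p, t in zip(presence, trait):
                if np.isnan(t):
                    continue
                if p and t == 1:
                    tp += 1
                elif p and t == 0:
                    fp += 1
                elif not p and t == 1:
                    fn += 1
                else:
                    tn += 1
            m = confusion_metrics(ConfusionCounts(tp, tn, fp, fn))
            acc, sens = reaction_trait_metrics(presence, trait)
            assert acc == pytest.approx(m.accuracy)
            if not np.isnan(m.sensitivity):
                assert sens == pytest.approx(m.sensitivity)

    def test_all_na_rejected(self):
        with pytest.raises(ValueError):
            reaction_trait_metrics([1, 0], [np.nan, np.nan])


class TestFindCorrelated:
    def test_threshold_is_strict(self):
        # 100-species vector engineered to accuracy exactly 0.83: excluded
        trait = np.array([1.0] * 50 + [0.0] * 50)
        presence = np.array([1] * 50 + [1] * 17 + [0] * 33)
        acc, sens = reaction_trait_metrics(presence, trait)
        assert acc == pytest.approx(0.83)
        existence = pd.DataFrame({"rxn": presence})
        assert find_correlated_reactions(existence, trait) == []

    def test_constant_reaction_excluded_at_half_prevalence(self):
        trait = np.array([1.0, 0.0] * 10)
        existence = pd.DataFrame({"rxn": np.ones(20, dtype=int)})
        assert find_correlated_reactions(existence, trait) == []

    def test_monotone_in_thresholds(self, world, world_traits):
        existence = world.reaction_existence()
        trait = world_traits.table[world.truth["loss_traits"][0]].to_numpy()
        loose = set(find_correlated_reactions(existence, trait, 0.0, 0.0))
        default = set(find_correlated_reactions(existence, trait))
        strict = set(find_correlated_reactions(existence, trait, 1.0, 1.0))
        assert strict <= default <= loose

    def test_planted_causal_reactions_recovered(self, world, world_traits):
        existence = world.reaction_existence()
        for trait in world.truth["loss_traits"]:
            got = find_correlated_reactions(
                existence, world_traits.table[trait].to_numpy()
            )
            assert got == world.truth["trait_causal_reactions"][trait]


class TestClassifyChanges:
    @pytest.mark.parametrize(
        "posterior, value, expected",
        [
            (0.90, 0, "loss"),
            (0.10, 1, "gain"),
            (0.50, 1, "undetermined"),
            (0.90, 1, "retained_present"),
            (0.10, 0, "retained_absent"),
            (0.85, 0, "loss"),  # boundary: >= 0.85 is ancestrally present
            (0.15, 1, "undetermined"),  # boundary: 0.15 is not < 0.15
        ],
    )
    def test_cutoff_semantics(self, posterior, value, expected):
        table = TraitTable(pd.DataFrame({"t": [float(value)]}, index=["sp"]))
        labels = classify_trait_changes(table, {"t": posterior})
        assert labels.loc["sp", "t"] == expected

    def test_na_cells_are_undetermined(self):
        table = TraitTable(pd.DataFrame({"t": [np.nan, 1.0]}, index=["a", "b"]))
        labels = classify_trait_changes(table, {"t": 0.9})
        assert labels.loc["a", "t"] == "undetermined"

    def test_invariant_to_species_order(self, world_traits, world):
        anc = world.truth["ancestral_posterior"]
        base = classify_trait_changes(world_traits, anc)
        shuffled = TraitTable(world_traits.table.iloc[::-1])
        flipped = classify_trait_changes(shuffled, anc)
        assert base.sort_index().equals(flipped.sort_index())

    def test_every_cell_is_labelled(self, world_traits, world):
        labels = classify_trait_changes(
            world_traits, world.truth["ancestral_posterior"]
        )
        assert labels.shape == world_traits.table.shape
        assert labels.isin(
            ["gain", "loss", "retained_present", "retained_absent", "undetermined"]
        ).all().all()

    def test_planted_gains_recovered(self, world, world_traits):
        labels = classify_trait_changes(
            world_traits, world.truth["ancestral_posterior"]
        )
        for trait in world.truth["gain_traits"]:
            gained = sorted(labels.index[labels[trait] == "gain"])
            assert gained == world.truth["gain_species"]


class TestAttribution:
    def test_growing_species_rejected(self, world):
        trait = world.truth["loss_traits"][0]
        ex = world.truth["substrate_exchanges"][trait]
        model = world.species_model(world.truth["complete_species"])
        with pytest.raises(ValueError, match="no loss"):
            attribute_loss_mechanism(
                model, world.pan_model, trait,
                set(world.truth["direct_pathway_reactions"][trait]),
                set(), world.media, ex, "EX_s0",
            )

    def test_no_loss_is_unexplained_on_noiseless_world(self, world, world_traits):
        existence = world.reaction_existence()
        for trait, labels in world.truth["loss_labels"].items():
            ex = world.truth["substrate_exchanges"][trait]
            direct = set(world.truth["direct_pathway_reactions"][trait])
            correlated = set(
                find_correlated_reactions(
                    existence, world_traits.table[trait].to_numpy()
                )
            )
            for sp, expected in labels.items():
                got = attribute_loss_mechanism(
                    world.species_model(sp), world.pan_model, trait,
                    direct, correlated, world.media, ex, "EX_s0",
                )
                assert got == expected, (trait, sp)


class TestGainTally:
    def test_mechanism_counting(self):
        tally = gain_mechanism_tally(
            gains={"spA": ["t1", "t2"], "spB": []},
            pathway_genes={"t1": {"g1", "g2"}, "t2": {"g3"}},
            hgt_genes={"g1"},
            expanded_family_genes={"g3"},
            promiscuous_genes={"g2", "g3"},
        )
        assert tally.loc["spA", "hgt"] == 1
        assert tally.loc["spA", "expanded_family"] == 1
        assert tally.loc["spA", "promiscuity"] == 2  # categories overlap
        assert (tally.loc["spB"] == 0).all()

    def test_unknown_trait_rejected(self):
        with pytest.raises(KeyError):
            gain_mechanism_tally({"sp": ["mystery"]}, {}, set(), set(), set())

    def test_planted_hgt_gain_counted(self, world, world_traits):
        labels = classify_trait_changes(
            world_traits, world.truth["ancestral_posterior"]
        )
        gains = {
            sp: [t for t in labels.columns if labels.loc[sp, t] == "gain"]
            for sp in labels.index
        }
        tally = gain_mechanism_tally(
            gains,
            {t: set(g) for t, g in world.truth["pathway_genes"].items()},
            set(world.truth["hgt_genes"]),
            set(world.truth["expanded_family_genes"]),
            set(world.truth["promiscuous_genes"]),
        )
        for sp in world.truth["gain_species"]:
            assert tally.loc[sp, "hgt"] >= 1
            assert tally.loc[sp, "promiscuity"] >= 1
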