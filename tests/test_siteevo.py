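"""Conservation, unique mutations, functional-site distances, CLUMPS."""

import math

import numpy as np
import pytest

from evogem.siteevo import (
    AMINO_ACIDS,
    AlignmentBlock,
    StructureModel,
    clumps_test,
    distance_to_functional_sites,
    jsd_conservation,
    read_ca_structure,
    unique_mutations,
    write_ca_structure,
)
from evogem.synthetic import generate_structure_alignment


def _literal_jsd(p, q):
    """Independent literal Jensen-Shannon divergence, base 2."""
    m = 0.5 * (p + q)

    def kl(a, b):
        total = 0.0
        for x, y in zip(a, b):
            if x > 0:
                total += x * math.log2(x / y)
        return total

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def _block(columns, species=None):
    """Build an alignment from per-column character lists."""
    n = len(columns[0])
    species = species or [f"sp{i}" for i in range(n)]
    seqs = ["".join(col[i] for col in columns) for i in range(n)]
    return AlignmentBlock(list(zip(species, seqs)), reference_id=species[0])


class TestJsdConservation:
    def test_invariant_column_is_maximal(self):
        block = _block([list("AAAA"), list("ARND")])
        scores = jsd_conservation(block)
        assert scores.loc[0, "score"] > scores.loc[1, "score"]
        # matches the independent literal computation
        p = np.zeros(20)
        p[AMINO_ACIDS.index("A")] = 1.0
        expected = _literal_jsd(p, np.full(20, 0.05))
        assert scores.loc[0, "score"] == pytest.approx(expected, abs=1e-12)

    def test_column_equal_to_background_scores_zero(self):
        # 20 species, one of each residue, uniform background
        block = _block([list(AMINO_ACIDS)])
        scores = jsd_conservation(block)
        assert scores.loc[0, "score"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_literal_oracle_on_random_columns(self):
        rng = np.random.default_rng(3)
        cols = [
            [AMINO_ACIDS[int(rng.integers(20))] for _ in range(12)] for _ in range(30)
        ]
        block = _block(cols)
        scores = jsd_conservation(block)
        bg = np.full(20, 0.05)
        for c, col in enumerate(cols):
            counts = np.zeros(20)
            for ch in col:
                counts[AMINO_ACIDS.index(ch)] += 1
            p = counts / counts.sum()
            assert scores.loc[c, "score"] == pytest.approx(
                _literal_jsd(p, bg), abs=1e-12
            )

    def test_gap_penalty_and_flagging(self):
        col_gappy = list("AAA") + ["-"] * 7  # 70% gaps
        col_clean = list("AAAAAAAAAA")
        block = _block([col_clean, col_gappy])
        scores = jsd_conservation(block)
        assert not scores.loc[0, "low_confidence"]
        assert scores.loc[1, "low_confidence"]  # gap fraction 0.7 > 0.3
        assert scores.loc[1, "score"] == pytest.approx(
            scores.loc[0, "score"] * 0.3, abs=1e-12
        )

    def test_all_gap_column_scores_zero(self):
        block = AlignmentBlock([("a", "A-"), ("b", "A-")], "a")
        scores = jsd_conservation(block)
        assert scores.loc[1, "score"] == 0.0
        assert scores.loc[1, "low_confidence"]

    def test_invariant_to_sequence_order(self):
        rng = np.random.default_rng(6)
        cols = [[AMINO_ACIDS[int(rng.integers(20))] for _ in range(8)] for _ in range(10)]
        block = _block(cols)
        reversed_block = AlignmentBlock(block.records[::-1], block.records[0][0])
        a = jsd_conservation(block)["score"]
        b = jsd_conservation(reversed_block)["score"]
        assert np.allclose(a, b)


class TestUniqueMutations:
    def _make(self, tol_chars, non_chars):
        cols = [[*tol_chars, *non_chars]]
        species = [f"t{i}" for i in range(len(tol_chars))] + [
            f"n{i}" for i in range(len(non_chars))
        ]
        block = _block(cols, species)
        tol = {s for s in species if s.startswith("t")}
        non = {s for s in species if s.startswith("n")}
        return block, tol, non

    def test_conserved_novel_residue_reported(self):
        # K in 9/10 tolerant (90%), 1/20 non-tolerant (5%)
        block, tol, non = self._make("KKKKKKKKKR", "K" + "A" * 19)
        assert unique_mutations(block, tol, non) == [(1, "K")]

    def test_residue_in_reference_set_not_reported(self):
        # 85% tolerant but 25% of non-tolerant carry it
        block, tol, non = self._make("KKKKKKKKKKKKKKKKKRRR", "KKKKK" + "A" * 15)
        assert unique_mutations(block, tol, non) == []

    def test_insufficiently_conserved_not_reported(self):
        block, tol, non = self._make("KKKKKKKRRR", "A" * 20)  # 70% < 80%
        assert unique_mutations(block, tol, non) == []

    def test_gaps_are_not_residues(self):
        block, tol, non = self._make("----------", "A" * 10)
        assert unique_mutations(block, tol, non) == []

    def test_overlapping_sets_rejected(self):
        block, tol, non = self._make("KKKK", "AAAA")
        with pytest.raises(ValueError):
            unique_mutations(block, tol, tol | non)

    def test_monotone_in_thresholds(self):
        block, tol, non = self._make("KKKKKKKKKR", "K" + "A" * 19)
        loose = unique_mutations(block, tol, non, 0.5, 0.3)
        default = unique_mutations(block, tol, non)
        strict = unique_mutations(block, tol, non, 0.95, 0.01)
        assert set(strict) <= set(default) <= set(loose)


class TestStructureDistances:
    def test_site_on_functional_residue(self):
        structure = StructureModel(
            {1: [0, 0, 0], 2: [20, 0, 0]}, {"active_site": {1}}
        )
        out = distance_to_functional_sites([1, 2], structure)
        assert out.loc[0, "min_distance"] == 0.0 and out.loc[0, "adjacent"]
        assert out.loc[1, "min_distance"] == 20.0 and not out.loc[1, "adjacent"]

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(10)
        coords = {i + 1: rng.normal(0, 10, 3) for i in range(25)}
        annotated = {3, 9, 17}
        structure = StructureModel(dict(coords), {"site": set(annotated)})
        sites = [1, 5, 12, 20]
        out = distance_to_functional_sites(sites, structure, ["site"])
        for row, site in zip(out.itertuples(), sites):
            naive = min(
                float(np.linalg.norm(np.asarray(coords[site]) - np.asarray(coords[a])))
                for a in annotated
            )
            assert row.min_distance == pytest.approx(naive, abs=1e-9)

    def test_planted_fast_sites_far_from_functional(self):
        block, structure, truth = generate_structure_alignment(seed=2)
        out = distance_to_functional_sites(truth["cluster_sites"], structure)
        assert (out["min_distance"] >= 10.0).all()
        assert not out["adjacent"].any()

    def test_no_annotations_rejected(self):
        structure = StructureModel({1: [0, 0, 0]})
        with pytest.raises(ValueError):
            distance_to_functional_sites([1], structure)


class TestClumps:
    def test_planted_cluster_is_significant(self):
        block, structure, truth = generate_structure_alignment(seed=4)
        score, p = clumps_test(
            truth["cluster_sites"], structure, n_permutations=10_000, seed=0
        )
        assert p < 0.05

    def test_identical_coordinates_score_one_per_pair(self):
        structure = StructureModel({1: [1.0, 2.0, 3.0], 2: [1.0, 2.0, 3.0]})
        score, _ = clumps_test([1, 2], structure, n_permutations=100, seed=0)
        assert score == pytest.approx(1.0)

    def test_reproducible_under_seed_and_p_in_unit_interval(self):
        _, structure, truth = generate_structure_alignment(seed=4)
        a = clumps_test(truth["cluster_sites"], structure, 500, seed=3)
        b = clumps_test(truth["cluster_sites"], structure, 500, seed=3)
        assert a == b
        assert 0.0 < a[1] <= 1.0

    def test_too_few_sites_rejected(self):
        structure = StructureModel({1: [0, 0, 0], 2: [1, 1, 1]})
        with pytest.raises(ValueError):
            clumps_test([1], structure, 1000, seed=0)

    def test_null_pvalues_approximately_uniform(self):
        # sites drawn from the null itself: p should be uniform
        from scipy.stats import kstest

        _, structure, _ = generate_structure_alignment(seed=1)
        rng = np.random.default_rng(0)
        positions = structure.positions
        pvals = []
        for _ in range(100):
            sites = list(rng.choice(positions, size=4, replace=False))
            _, p = clumps_test(sites, structure, n_permutations=1000, seed=int(rng.integers(2**31)))
            pvals.append(p)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestPdbIo:
    def test_ca_round_trip(self, tmp_path):
        _, structure, _ = generate_structure_alignment(seed=6)
        path = tmp_path / "model.pdb"
        write_ca_structure(structure, path)
        back = read_ca_structure(path)
        assert back.positions == structure.positions
        for pos in structure.positions:
            assert np.allclose(back.coordinates[pos], structure.coordinates[pos], atol=1e-2)
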