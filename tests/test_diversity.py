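"""Allele statistics, Fst, Nei distances and neighbor joining."""

import io

import numpy as np
import pandas as pd
import pytest
import skbio

from bridgemark import (
    GenotypeMatrix,
    SimulationConfig,
    allele_stats,
    distance_matrix,
    fst,
    nei_da_distance,
    nei_distance,
    nei_standard_distance,
    nj_tree,
    simulate_panel,
    species_cluster_purity,
)
from bridgemark.diversity import HeterozygousPatternError, write_phylip


def matrix_from_alleles(assignments, n_alleles, locus="L1", species=None):
    """One-locus band matrix from an allele index per accession."""
    rows = {}
    for i, al in enumerate(assignments):
        rows[f"acc{i:02d}"] = {
            f"{locus}:a{k}": int(k == al) for k in range(n_alleles)
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    sp = None
    if species is not None:
        sp = pd.Series(dict(zip(frame.index, species)))
    return GenotypeMatrix(frame, species=sp)


def freqs(d):
    return {locus: pd.Series(v) for locus, v in d.items()}


class TestAlleleStats:
    def test_monomorphic_locus(self):
        m = matrix_from_alleles([0, 0, 0, 0], 1)
        row = allele_stats(m).loc["L1"]
        assert row["n_alleles"] == 1
        assert row["maf"] == 1.0
        assert row["gene_diversity"] == 0.0 and row["pic"] == 0.0

    def test_balanced_biallelic_closed_form(self):
        m = matrix_from_alleles([0, 0, 1, 1], 2)
        row = allele_stats(m).loc["L1"]
        assert row["gene_diversity"] == pytest.approx(0.5)
        assert row["pic"] == pytest.approx(0.375)  # 1 - 0.5 - 2(0.25*0.25)
        assert row["maf"] == pytest.approx(0.5)

    def test_pic_bounds_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = int(rng.integers(2, 7))
            n = int(rng.integers(4, 30))
            m = matrix_from_alleles(rng.integers(0, k, n), k)
            row = allele_stats(m).loc["L1"]
            k_obs = row["n_alleles"]
            assert 0 <= row["pic"] <= row["gene_diversity"] <= 1 - 1 / k_obs + 1e-12

    def test_heterozygous_pattern_rejected(self):
        frame = pd.DataFrame(
            {"L1:a0": [1, 1], "L1:a1": [1, 0]}, index=["x", "y"]
        )
        with pytest.raises(HeterozygousPatternError):
            GenotypeMatrix(frame)

    def test_missing_locus_reported_nan(self):
        frame = pd.DataFrame(
            {"L1:a0": [1.0, np.nan], "L1:a1": [0.0, np.nan],
             "L2:a0": [1.0, 0.0], "L2:a1": [0.0, 1.0]},
            index=["x", "y"],
        )
        m = GenotypeMatrix(frame)
        stats = allele_stats(m)
        assert stats.loc["L1", "n"] == 1
        assert stats.loc["L2", "n"] == 2


class TestFst:
    def test_fixed_differences_give_one(self):
        m = matrix_from_alleles(
            [0, 0, 0, 1, 1, 1], 2, species=["A", "A", "A", "B", "B", "B"]
        )
        per_locus, mean = fst(m)
        assert per_locus["L1"] == pytest.approx(1.0)
        assert mean == pytest.approx(1.0)

    def test_identical_frequencies_give_zero(self):
        m = matrix_from_alleles(
            [0, 1, 0, 1], 2, species=["A", "A", "B", "B"]
        )
        per_locus, mean = fst(m)
        assert per_locus["L1"] == pytest.approx(0.0)

    def test_hand_case_point_thirty_six(self):
        # groups with p=(0.8,0.2) and (0.2,0.8): H_S=0.32, H_T=0.5
        m = matrix_from_alleles(
            [0, 0, 0, 0, 1] + [1, 1, 1, 1, 0], 2, species=["A"] * 5 + ["B"] * 5
        )
        per_locus, mean = fst(m)
        assert per_locus["L1"] == pytest.approx(0.36)
        assert mean == pytest.approx(0.36)

    def test_monomorphic_locus_excluded_from_mean(self):
        frame = pd.DataFrame(
            {
                "L1:a0": [1, 1, 1, 1], "L1:a1": [0, 0, 0, 0],
                "L2:a0": [1, 1, 0, 0], "L2:a1": [0, 0, 1, 1],
            },
            index=["w", "x", "y", "z"],
        )
        m = GenotypeMatrix(frame, species=pd.Series(
            ["A", "A", "B", "B"], index=["w", "x", "y", "z"]))
        per_locus, mean = fst(m)
        assert np.isnan(per_locus["L1"])
        assert mean == pytest.approx(per_locus["L2"])

    def test_single_group_rejected(self):
        m = matrix_from_alleles([0, 1], 2, species=["A", "A"])
        with pytest.raises(ValueError, match="two species"):
            fst(m)


class TestNeiDistances:
    def test_identical_profiles_zero(self):
        x = freqs({"L1": {"a": 0.5, "b": 0.5}})
        assert nei_distance(x, x) == pytest.approx(0.0)

    def test_fixed_difference_one(self):
        x = freqs({"L1": {"a": 1.0, "b": 0.0}})
        y = freqs({"L1": {"a": 0.0, "b": 1.0}})
        assert nei_distance(x, y) == pytest.approx(1.0)

    def test_hand_case_quarter(self):
        x = freqs({"L1": {"a": 0.5, "b": 0.5}})
        y = freqs({"L1": {"a": 1.0, "b": 0.0}})
        assert nei_distance(x, y) == pytest.approx(0.25)

    def test_symmetry_and_zero_iff_identical(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            k = int(rng.integers(2, 6))
            px = rng.dirichlet(np.ones(k))
            py = rng.dirichlet(np.ones(k))
            x = freqs({"L1": dict(zip("abcdef", px))})
            y = freqs({"L1": dict(zip("abcdef", py))})
            assert nei_distance(x, y) == pytest.approx(nei_distance(y, x))
            assert nei_distance(x, y) >= 0
            if not np.allclose(px, py):
                assert nei_distance(x, y) > 0

    def test_alternative_distances(self):
        x = freqs({"L1": {"a": 1.0, "b": 0.0}})
        y = freqs({"L1": {"a": 0.0, "b": 1.0}})
        assert nei_standard_distance(x, x) == pytest.approx(0.0)
        assert nei_standard_distance(x, y) == np.inf
        assert nei_da_distance(x, y) == pytest.approx(1.0)

    def test_locus_mismatch_rejected(self):
        x = freqs({"L1": {"a": 1.0}})
        y = freqs({"L2": {"a": 1.0}})
        with pytest.raises(ValueError, match="locus"):
            nei_distance(x, y)


def random_additive_tree(rng, n_taxa):
    """Random binary topology with branch lengths in [0.1, 1]; returns the
    skbio tree and its exact leaf-to-leaf distance matrix."""
    names = [f"t{i}" for i in range(n_taxa)]
    nodes = [skbio.TreeNode(name=n, length=float(rng.uniform(0.1, 1))) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = skbio.TreeNode(length=float(rng.uniform(0.1, 1)))
        parent.extend([nodes[i], nodes[j]])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    tree = nodes[0]
    tree.length = None
    dm = tree.tip_tip_distances()
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    return tree, df.loc[names, names]


def nj_tip_distances(newick):
    t = skbio.TreeNode.read(io.StringIO(newick))
    dm = t.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = nj_tree(d)
        t = skbio.TreeNode.read(io.StringIO(tree.newick))
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths == {"A": pytest.approx(1), "B": pytest.approx(2),
                           "C": pytest.approx(3)}

    def test_four_taxon_additive_matrix_recovered(self):
        # tree ((A:1,B:2):1,(C:3,D:1)); AB|CD split with those lengths
        d = pd.DataFrame(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        tree = nj_tree(d)
        got = nj_tip_distances(tree.newick)
        assert np.allclose(got.loc[list("ABCD"), list("ABCD")].to_numpy(), d.to_numpy())
        t = skbio.TreeNode.read(io.StringIO(tree.newick))
        a = t.find("A")
        siblings = {tip.name for tip in a.parent.tips()}
        assert siblings == {"A", "B"}

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_random_additive_matrices(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 13))
        _, d = random_additive_tree(rng, n)
        tree = nj_tree(d)
        got = nj_tip_distances(tree.newick).loc[d.index, d.columns]
        assert np.allclose(got.to_numpy(), d.to_numpy(), atol=1e-9)

    def test_agrees_with_skbio_topology(self):
        """Independent cross-check: same unrooted topology as scikit-bio's
        neighbor joining on an additive matrix."""
        rng = np.random.default_rng(7)
        _, d = random_additive_tree(rng, 8)
        ours = skbio.TreeNode.read(io.StringIO(nj_tree(d).newick))
        dm = skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        theirs = skbio.tree.nj(dm)
        assert ours.compare_rfd(theirs) == 0.0

    def test_non_symmetric_rejected(self):
        d = pd.DataFrame(
            [[0, 1, 2], [9, 0, 1], [2, 1, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d)

    def test_clamped_lengths_non_negative(self):
        rng = np.random.default_rng(8)
        _, d = random_additive_tree(rng, 7)
        noisy = d + rng.uniform(0, 0.5, d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy.values, 0.0)
        t = skbio.TreeNode.read(io.StringIO(nj_tree(noisy).newick))
        for node in t.traverse(include_self=False):
            assert node.length >= 0


class TestPanelRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_species_form_pure_clusters(self, seed):
        config = SimulationConfig(seed=seed)
        panel = simulate_panel({"Chr01": "ACGT"}, config)
        dist = distance_matrix(panel)
        tree = nj_tree(dist)
        assert species_cluster_purity(tree, panel.species.to_dict()) == 1.0

    def test_accession_and_species_levels(self, truth):
        acc = distance_matrix(truth.panel, level="accession")
        sp = distance_matrix(truth.panel, level="species")
        assert len(acc) == 63 and len(sp) == 5
        for d in (acc, sp):
            assert np.allclose(d, d.T)
            assert (np.diag(d) == 0).all()

    def test_phylip_output(self, truth, tmp_path):
        d = distance_matrix(truth.panel, level="species")
        path = tmp_path / "d.phy"
        write_phylip(path, d)
        lines = path.read_text().splitlines()
        assert lines[0] == "5" and len(lines) == 6
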