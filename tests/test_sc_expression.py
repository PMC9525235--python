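"""UMI normalization, cluster summaries and peptide target mapping."""

import numpy as np
import pandas as pd
import pytest

from neuropep.sc_expression import (
    ClusterExpression,
    UMIMatrix,
    cluster_means,
    filter_genes,
    normalize_cells,
    peptide_cell_targets,
    read_umi_matrix,
    scale_by_gene,
    top_homologue_per_family,
    write_umi_matrix,
)


def make_matrix(counts, clusters=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    counts.columns = [f"c{i}" for i in range(counts.shape[1])]
    if clusters is None:
        clusters = ["K0"] * counts.shape[1]
    return UMIMatrix(counts=counts, cluster_of=pd.Series(clusters, index=counts.columns))


class TestFilterGenes:
    def test_boundary_totals(self):
        m = make_matrix([[9], [10], [11]])
        kept = filter_genes(m, min_total=10)
        assert kept.genes == ["g1", "g2"]

    def test_zero_threshold_is_identity(self):
        m = make_matrix([[0, 1], [3, 2]])
        assert filter_genes(m, min_total=0).genes == m.genes

    def test_random_matches_row_sum_oracle(self, rng):
        counts = rng.integers(0, 6, size=(30, 12))
        m = make_matrix(counts)
        kept = filter_genes(m, min_total=10)
        expected = [f"g{i}" for i in range(30) if counts[i].sum() >= 10]
        assert kept.genes == expected

    def test_all_removed_warns(self):
        m = make_matrix([[1]])
        with pytest.warns(UserWarning):
            out = filter_genes(m, min_total=100)
        assert out.genes == []


class TestNormalizeCells:
    def test_single_gene_cell_hits_scale_factor(self):
        m = make_matrix([[7]])
        norm = normalize_cells(m, scale_factor=10_000)
        assert norm.iloc[0, 0] == 10_000

    def test_column_sums_equal_scale_factor(self, rng):
        m = make_matrix(rng.integers(1, 9, size=(20, 8)))
        norm = normalize_cells(m, scale_factor=1000)
        assert np.allclose(norm.sum(axis=0), 1000.0)

    def test_random_matches_division_oracle(self, rng):
        counts = rng.integers(0, 9, size=(10, 5)) + 1
        m = make_matrix(counts)
        norm = normalize_cells(m, scale_factor=100)
        expected = counts / counts.sum(axis=0, keepdims=True) * 100
        assert np.allclose(norm.values, expected)

    def test_zero_total_cell_dropped_with_warning(self):
        m = make_matrix([[1, 0], [2, 0]])
        with pytest.warns(UserWarning):
            norm = normalize_cells(m, scale_factor=10)
        assert list(norm.columns) == ["c0"]


class TestClusterMeans:
    def test_single_cell_clusters_equal_cell_values(self):
        m = make_matrix([[1, 4], [2, 8]], clusters=["K0", "K1"])
        norm = normalize_cells(m, scale_factor=100)
        ce = cluster_means(norm, m.cluster_of)
        assert np.allclose(ce.normalized_mean["K0"], norm["c0"])
        assert np.allclose(ce.normalized_mean["K1"], norm["c1"])

    def test_cell_permutation_invariance(self, rng):
        counts = rng.integers(1, 9, size=(6, 10))
        clusters = [f"K{i % 3}" for i in range(10)]
        m = make_matrix(counts, clusters)
        norm = normalize_cells(m, scale_factor=100)
        ce = cluster_means(norm, m.cluster_of)
        perm = rng.permutation(norm.columns)
        ce_p = cluster_means(norm[perm], m.cluster_of)
        assert np.allclose(ce.normalized_mean.values, ce_p.normalized_mean.values)

    def test_random_matches_group_by_oracle(self, rng):
        counts = rng.integers(1, 9, size=(4, 9))
        clusters = [f"K{i % 3}" for i in range(9)]
        m = make_matrix(counts, clusters)
        norm = normalize_cells(m, scale_factor=10)
        ce = cluster_means(norm, m.cluster_of)
        for k in ("K0", "K1", "K2"):
            cols = [c for c, lbl in m.cluster_of.items() if lbl == k]
            assert np.allclose(ce.normalized_mean[k], norm[cols].mean(axis=1))

    def test_median_summary_flag(self):
        m = make_matrix([[1, 2, 9]], clusters=["K0"] * 3)
        norm = m.counts.astype(float)
        ce = cluster_means(norm, m.cluster_of, summary="median")
        assert ce.normalized_mean.loc["g0", "K0"] == 2.0


class TestScaleByGene:
    def test_row_scaling(self):
        ce = ClusterExpression(
            normalized_mean=pd.DataFrame({"K0": [2.0, 0.0], "K1": [4.0, 0.0]},
                                         index=["g0", "g1"])
        )
        out = scale_by_gene(ce)
        assert list(out.scaled.loc["g0"]) == [0.5, 1.0]
        assert list(out.scaled.loc["g1"]) == [0.0, 0.0]  # all-zero row stays zero

    def test_bounded_in_unit_interval(self, rng):
        ce = ClusterExpression(
            normalized_mean=pd.DataFrame(rng.uniform(0, 50, size=(20, 6)))
        )
        out = scale_by_gene(ce)
        assert ((out.scaled.values >= 0) & (out.scaled.values <= 1)).all()


class TestTopHomologue:
    def _ce(self, rows):
        return ClusterExpression(normalized_mean=pd.DataFrame(rows).T)

    def test_highest_sum_wins(self):
        ce = self._ce({"g0": [2, 3], "g1": [4, 5]})
        chosen, missing = top_homologue_per_family(ce, {"fam": ["g0", "g1"]})
        assert chosen == {"fam": "g1"} and missing == []

    def test_singleton_family(self):
        ce = self._ce({"g0": [1, 1]})
        chosen, _ = top_homologue_per_family(ce, {"fam": ["g0"]})
        assert chosen["fam"] == "g0"

    def test_family_with_no_genes_reported(self):
        ce = self._ce({"g0": [1, 1]})
        chosen, missing = top_homologue_per_family(ce, {"fam": ["absent"]})
        assert chosen == {} and missing == ["fam"]

    def test_random_families_match_argmax_oracle(self, rng):
        genes = [f"g{i}" for i in range(12)]
        ce = ClusterExpression(
            normalized_mean=pd.DataFrame(rng.uniform(size=(12, 4)), index=genes)
        )
        fams = {f"f{k}": genes[3 * k:3 * k + 3] for k in range(4)}
        chosen, _ = top_homologue_per_family(ce, fams)
        sums = ce.normalized_mean.sum(axis=1)
        for fam, members in fams.items():
            assert chosen[fam] == max(members, key=lambda g: sums[g])


class TestPeptideTargets:
    def _ce(self):
        return ClusterExpression(
            normalized_mean=pd.DataFrame(
                {"K0": [1.0, 10.0, 5.0], "K1": [2.0, 20.0, 6.0]},
                index=["r0", "r1", "r2"],
            )
        )

    def test_single_receptor_equals_its_row(self):
        assign = pd.DataFrame({"peptide_id": ["A"], "receptor_id": ["r1"]})
        targets, unmapped = peptide_cell_targets(assign, self._ce())
        assert np.allclose(targets.loc["A"], [10.0, 20.0])
        assert unmapped == {}

    def test_two_receptors_sum(self):
        assign = pd.DataFrame({"peptide_id": ["A", "A"], "receptor_id": ["r0", "r2"]})
        targets, _ = peptide_cell_targets(assign, self._ce())
        assert np.allclose(targets.loc["A"], [6.0, 8.0])

    def test_additive_in_receptor_set(self):
        # split/merge property: targets(r0+r1) = targets(r0) + targets(r1)
        ce = self._ce()
        both = pd.DataFrame({"peptide_id": ["A", "A"], "receptor_id": ["r0", "r1"]})
        one = pd.DataFrame({"peptide_id": ["A"], "receptor_id": ["r0"]})
        other = pd.DataFrame({"peptide_id": ["A"], "receptor_id": ["r1"]})
        t = peptide_cell_targets(both, ce)[0]
        t1 = peptide_cell_targets(one, ce)[0]
        t2 = peptide_cell_targets(other, ce)[0]
        assert np.allclose(t.loc["A"], t1.loc["A"] + t2.loc["A"])

    def test_missing_receptor_reported_zero_row(self):
        assign = pd.DataFrame({"peptide_id": ["A"], "receptor_id": ["ghost"]})
        targets, unmapped = peptide_cell_targets(assign, self._ce())
        assert unmapped == {"A": ["ghost"]}
        assert (targets.loc["A"] == 0).all()


def test_mtx_round_trip(tmp_path, rng):
    counts = rng.integers(0, 5, size=(8, 6))
    m = make_matrix(counts, clusters=[f"K{i % 2}" for i in range(6)])
    write_umi_matrix(m, tmp_path / "umi")
    back = read_umi_matrix(tmp_path / "umi")
    assert back.genes == m.genes and back.cells == m.cells
    assert (back.counts.values == m.counts.values).all()
    assert (back.cluster_of == m.cluster_of).all()
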