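import numpy as np
import pandas as pd
import pytest

from immunoruler.heterogeneity import (
    hierarchical_cluster,
    map_antigen_to_protein,
    per_sample_concordance,
    variability_concordance,
    variability_score,
)
from immunoruler.quantify import CopyNumberMatrix, PseudocountMatrix


def _frame(rows, samples=None, prefix="f"):
    rows = np.asarray(rows, dtype=float)
    samples = samples or [f"s{j + 1}" for j in range(rows.shape[1])]
    return pd.DataFrame(
        rows, columns=samples,
        index=pd.Index([f"{prefix}{i}" for i in range(len(rows))], name="feature"),
    )


class TestVariabilityScore:
    def test_worked_type7_example(self):
        out = variability_score(_frame([[1, 2, 3, 4]]), min_samples=2)
        row = out.iloc[0]
        assert row["iqr"] == pytest.approx(1.5)
        assert row["mean"] == pytest.approx(2.5)
        assert row["score"] == pytest.approx(0.6)

    def test_constant_feature_scores_zero(self):
        out = variability_score(_frame([[5, 5, 5, 5]]), min_samples=2)
        assert out["score"].iloc[0] == 0.0

    def test_scale_free(self):
        a = variability_score(_frame([[1, 3, 7, 2, 9]]), min_samples=2)
        b = variability_score(_frame([[17, 51, 119, 34, 153]]), min_samples=2)
        assert a["score"].iloc[0] == pytest.approx(b["score"].iloc[0], rel=1e-12)

    def test_under_observed_feature_missing(self):
        mat = _frame([[1, 2, np.nan, np.nan]])
        out = variability_score(mat, min_samples=3)
        assert np.isnan(out["score"].iloc[0]) and out["n_observed"].iloc[0] == 2

    def test_brute_force_quantile_oracle(self):
        """Scores match manual linear-interpolation quantiles on random
        subsets up to 8 samples."""
        rng = np.random.default_rng(9)
        for n in range(2, 9):
            vals = rng.lognormal(3, 1, size=n)
            out = variability_score(_frame([vals]), min_samples=2)
            srt = np.sort(vals)
            def q(p):
                h = (n - 1) * p
                lo = int(np.floor(h))
                hi = min(lo + 1, n - 1)
                return srt[lo] + (h - lo) * (srt[hi] - srt[lo])
            expected = (q(0.75) - q(0.25)) / vals.mean()
            assert out["score"].iloc[0] == pytest.approx(expected, rel=1e-12)


def _copies(rows, samples, genes):
    df = _frame(rows, samples, prefix="P")
    return CopyNumberMatrix(
        copies=df,
        molar_mass=pd.Series(10000.0, index=df.index),
        feature_meta=pd.DataFrame({"gene": genes}, index=df.index),
    )


def _pseudo(rows, samples, genes):
    df = _frame(rows, samples, prefix="PEP")
    frac = df.div(df.sum(axis=0), axis=1)
    return PseudocountMatrix(
        pseudocounts=df,
        fraction=frac,
        b2m_copies=df.sum(axis=0),
        feature_meta=pd.DataFrame({"gene": genes}, index=df.index),
    )


class TestMapping:
    def test_mapping_statuses(self):
        copies = _copies([[1, 1], [2, 2]], ["s1", "s2"], ["TPP1", "CTSD"])
        meta = pd.DataFrame(
            {"gene": ["TPP1", "TPP1;CTSD", "", "ABSENT"]},
            index=["a1", "a2", "a3", "a4"],
        )
        m = map_antigen_to_protein(meta, copies)
        assert m.loc["a1", "status"] == "mapped" and m.loc["a1", "protein_id"] == "P0"
        assert m.loc["a2", "status"] == "multi_mapping"
        assert m.loc["a3", "status"] == "unannotated"
        assert m.loc["a4", "status"] == "not_in_proteome"


class TestVariabilityConcordance:
    def _setup(self, antigen_rows, protein_rows, genes):
        samples = [f"s{j}" for j in range(len(antigen_rows[0]))]
        copies = _copies(protein_rows, samples, genes)
        pseudo = _pseudo(antigen_rows, samples, genes)
        av = variability_score(pseudo, min_samples=2)
        pv = variability_score(copies, min_samples=2)
        mapping = map_antigen_to_protein(pseudo.feature_meta, copies)
        return av, pv, mapping

    def test_identical_scores_give_r1(self):
        rows = [[1, 2, 3, 4], [2, 8, 4, 6], [10, 10, 30, 20]]
        av, pv, mapping = self._setup(rows, rows, ["G0", "G1", "G2"])
        pairs, stats = variability_concordance(av, pv, mapping)
        assert stats["pearson_r"] == pytest.approx(1.0)
        assert stats["spearman_r"] == pytest.approx(1.0)

    def test_two_pairs_error(self):
        rows = [[1, 2, 3], [2, 8, 4]]
        av, pv, mapping = self._setup(rows, rows, ["G0", "G1"])
        with pytest.raises(ValueError, match="3"):
            variability_concordance(av, pv, mapping)


class TestPerSampleConcordance:
    def test_copy_of_protein_matrix_gives_r1(self):
        rng = np.random.default_rng(4)
        rows = rng.lognormal(8, 1, size=(6, 4))
        samples = ["s1", "s2", "s3", "s4"]
        genes = [f"G{i}" for i in range(6)]
        copies = _copies(rows, samples, genes)
        pseudo = _pseudo(rows, samples, genes)
        mapping = map_antigen_to_protein(pseudo.feature_meta, copies)
        rep = per_sample_concordance(pseudo, copies, mapping)
        assert np.allclose(rep.per_sample_r, 1.0)

    def test_negated_z_pattern_gives_minus1(self):
        rng = np.random.default_rng(5)
        prot = rng.lognormal(8, 1, size=(6, 4))
        z = (prot - prot.mean(axis=1, keepdims=True)) / prot.std(axis=1, ddof=1, keepdims=True)
        ant = 1e4 - 1e3 * z  # positively valued, z-pattern exactly negated
        assert (ant > 0).all()
        samples = ["s1", "s2", "s3", "s4"]
        genes = [f"G{i}" for i in range(6)]
        rep = per_sample_concordance(
            _pseudo(ant, samples, genes),
            _copies(prot, samples, genes),
            map_antigen_to_protein(pd.DataFrame({"gene": genes},
                                                index=[f"PEP{i}" for i in range(6)]),
                                   _copies(prot, samples, genes)),
        )
        assert np.allclose(rep.per_sample_r, -1.0)

    def test_three_pair_hand_computed(self):
        """r per sample matches a direct Pearson computation on z-scores."""
        prot = np.array([[1.0, 2.0, 6.0], [10.0, 30.0, 20.0], [5.0, 4.0, 3.0]])
        ant = np.array([[2.0, 3.0, 4.0], [8.0, 7.0, 9.0], [1.0, 5.0, 2.0]])
        samples = ["s1", "s2", "s3"]
        genes = ["G0", "G1", "G2"]
        copies = _copies(prot, samples, genes)
        pseudo = _pseudo(ant, samples, genes)
        mapping = map_antigen_to_protein(pseudo.feature_meta, copies)
        rep = per_sample_concordance(pseudo, copies, mapping)

        def z(m):
            return (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, ddof=1, keepdims=True)

        pz, az = z(prot), z(ant)
        for j, s in enumerate(samples):
            x, y = pz[:, j], az[:, j]
            expected = np.corrcoef(x, y)[0, 1]
            assert rep.per_sample_r[s] == pytest.approx(expected, rel=1e-12)


class TestHierarchicalCluster:
    def test_identical_rows_merge_at_zero(self):
        mat = _frame([[1, 2, 3], [1, 2, 3], [9, 1, 5]])
        res = hierarchical_cluster(mat, zscore=False)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert set(res.linkage_matrix[0, :2].astype(int)) == {0, 1}

    def test_closest_pair_merges_first(self):
        # points on a line at 0, 1, 3: pairwise distances 1, 2, 3
        mat = _frame([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        res = hierarchical_cluster(mat, zscore=False)
        assert set(res.linkage_matrix[0, :2].astype(int)) == {0, 1}

    def test_single_item_trivial_tree(self):
        res = hierarchical_cluster(_frame([[1, 2]]), zscore=False)
        assert res.leaf_order == ["f0"] and len(res.linkage_matrix) == 0

    def test_missing_values_error(self):
        with pytest.raises(ValueError, match="impute"):
            hierarchical_cluster(_frame([[1, np.nan], [2, 3]]), zscore=False)

    def test_average_linkage_brute_force_oracle(self):
        """scipy's average-linkage tree matches naive agglomeration on a
        random 6-point instance (merge heights compared)."""
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 3))
        res = hierarchical_cluster(_frame(pts), zscore=False)

        # naive average-linkage agglomeration
        clusters = {i: [i] for i in range(6)}
        dist = {
            (i, j): float(np.linalg.norm(pts[i] - pts[j]))
            for i in range(6)
            for j in range(i + 1, 6)
        }
        def cdist(a, b):
            return np.mean([
                np.linalg.norm(pts[i] - pts[j]) for i in clusters[a] for j in clusters[b]
            ])
        heights = []
        next_id = 6
        while len(clusters) > 1:
            keys = sorted(clusters)
            best = min(
                ((a, b) for ai, a in enumerate(keys) for b in keys[ai + 1:]),
                key=lambda ab: cdist(*ab),
            )
            heights.append(cdist(*best))
            clusters[next_id] = clusters.pop(best[0]) + clusters.pop(best[1])
            next_id += 1
        assert np.allclose(res.linkage_matrix[:, 2], heights, rtol=1e-12)

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(8)
        res = hierarchical_cluster(_frame(rng.normal(size=(10, 4))), zscore=False)
        assert (np.diff(res.linkage_matrix[:, 2]) >= -1e-12).all()
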