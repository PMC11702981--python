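"""Composite-score engine: formula identities and brute-force oracles.

The ssGSEA and GSVA checks re-enumerate the published running-sum
algorithms with plain Python loops on packaged <=10-gene fixtures and
require agreement to 1e-9; the PC1 check solves the small eigenproblem
directly with numpy.
"""

import numpy as np
import pandas as pd
import pytest

from p53func.ces import (
    CES_COLUMNS,
    CESModel,
    build_ces_table,
    combined_zscore,
    gsva_score,
    pc1_score,
    ssgsea_score,
)
from p53func.fixtures import list_fixtures


# ---------------------------------------------------------------- oracles


def ssgsea_brute(df: pd.DataFrame, geneset: set, alpha: float) -> pd.Series:
    """Loop re-enumeration of the weighted running-sum integral."""
    genes = list(df.index)
    p, k = len(genes), len(geneset)
    scores = {}
    for s in df.columns:
        vals = df[s]
        sorted_vals = sorted(vals)
        ranks = {
            g: np.mean([i + 1 for i, v in enumerate(sorted_vals) if v == vals[g]])
            for g in genes
        }
        order = sorted(genes, key=lambda g: (-ranks[g], genes.index(g)))
        wsum = sum(ranks[g] ** alpha for g in order if g in geneset)
        cum_in = cum_out = total = 0.0
        for g in order:
            if g in geneset:
                cum_in += ranks[g] ** alpha / wsum
            else:
                cum_out += 1.0 / (p - k)
            total += cum_in - cum_out
        scores[s] = total
    return pd.Series(scores)


def gsva_brute_ecdf(df: pd.DataFrame, geneset: set, tau: float = 1.0) -> pd.Series:
    """Loop re-enumeration of the kernel-CDF / rank-statistic walk (ecdf)."""
    genes = list(df.index)
    p, k = len(genes), len(geneset)
    z = {
        (g, s): np.mean([v <= df.loc[g, s] for v in df.loc[g]])
        for g in genes
        for s in df.columns
    }
    scores = {}
    for s in df.columns:
        order = sorted(genes, key=lambda g: (-z[(g, s)], genes.index(g)))
        rstat = {g: abs((p - t) - p / 2) for t, g in enumerate(order)}
        wsum = sum(rstat[g] ** tau for g in geneset)
        walk, cum_in, cum_out = [], 0.0, 0.0
        for g in order:
            if g in geneset:
                cum_in += rstat[g] ** tau / wsum
            else:
                cum_out += 1.0 / (p - k)
            walk.append(cum_in - cum_out)
        scores[s] = max(max(walk), 0.0) + min(min(walk), 0.0)
    return pd.Series(scores)


# ---------------------------------------------------------------- tests


class TestCombinedZscore:
    def test_known_z_values_sum_to_two(self):
        """A sample with set z-scores {1, -1, 2, 2} scores 4/sqrt(4) = 2."""
        # rows engineered to have mean 0 and sample sd 1 with the target
        # z-value in the first column (n = 10 per gene)
        def row(t):
            h = np.sqrt((9.0 - 2.0 * t * t) / 8.0)
            return [t, -t] + [h] * 4 + [-h] * 4

        df = pd.DataFrame(
            [row(1.0), row(-1.0), row(2.0), row(2.0)],
            index=["a", "b", "c", "d"],
            columns=[f"s{i}" for i in range(10)],
        )
        scores = combined_zscore(df, ["a", "b", "c", "d"])
        assert scores["s0"] == pytest.approx(2.0, abs=1e-12)

    def test_sample_at_gene_means_scores_zero(self):
        """A probe sitting at every gene's cross-sample mean gets Z = 0."""
        rng = np.random.default_rng(3)
        half = rng.normal(5, 2, (6, 4))
        # mirror the samples around 5 so each gene's mean is exactly 5,
        # then add a probe sample at the means
        mat = pd.DataFrame(
            np.hstack([half, 10.0 - half, np.full((6, 1), 5.0)]),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(8)] + ["probe"],
        )
        assert combined_zscore(mat, list(mat.index))["probe"] == pytest.approx(0.0, abs=1e-12)

    def test_single_gene_set_equals_gene_z(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(0, 1, (3, 8)), index=list("abc"))
        z = (df.loc["b"] - df.loc["b"].mean()) / df.loc["b"].std(ddof=1)
        pd.testing.assert_series_equal(combined_zscore(df, ["b"]), z, check_names=False)

    def test_zero_variance_genes_dropped_with_warning(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["var", "flat"]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            scores = combined_zscore(df, ["var", "flat"])
        pd.testing.assert_series_equal(scores, combined_zscore(df, ["var"]))

    def test_all_flat_set_errors(self):
        df = pd.DataFrame([[1.0, 1.0], [2.0, 2.0], [0.0, 3.0]], index=list("abc"))
        with pytest.raises(ValueError, match="zero variance"):
            combined_zscore(df, ["a", "b"])


class TestSsgsea:
    def test_matches_brute_force_oracle(self):
        fx = list_fixtures()["ssgsea_oracle_matrix"]
        df, gs = fx.payload, fx.expected["geneset"]
        mine = ssgsea_score(df, gs, alpha=0.25, rescale=False)
        oracle = ssgsea_brute(df, set(gs), 0.25)
        assert np.allclose(mine, oracle.loc[mine.index], atol=1e-9)

    def test_top_genes_give_maximal_score(self):
        """With alpha=0, the set of a sample's top-m genes maximizes its score."""
        from itertools import combinations

        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(0, 1, (7, 3)), index=[f"g{i}" for i in range(7)])
        sample = df.columns[1]
        top2 = list(df[sample].nlargest(2).index)
        best = ssgsea_score(df, top2, alpha=0.0, rescale=False)[sample]
        for pair in combinations(df.index, 2):
            other = ssgsea_score(df, list(pair), alpha=0.0, rescale=False)[sample]
            assert other <= best + 1e-12

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.uniform(1, 9, (8, 4)), index=[f"g{i}" for i in range(8)])
        warped = df.copy()
        warped.iloc[:, 2] = np.exp(warped.iloc[:, 2] / 3.0)
        a = ssgsea_score(df, ["g1", "g4"], rescale=False)
        b = ssgsea_score(warped, ["g1", "g4"], rescale=False)
        # unscaled per-sample scores depend only on within-sample ranks
        pd.testing.assert_series_equal(a, b, atol=1e-12)

    def test_full_universe_set_rejected(self):
        df = pd.DataFrame(np.arange(6.0).reshape(3, 2), index=list("abc"))
        with pytest.raises(ValueError, match="out-of-set"):
            ssgsea_score(df, ["a", "b", "c"])


class TestGsva:
    def test_matches_brute_force_oracle_ecdf(self):
        fx = list_fixtures()["gsva_oracle_matrix"]
        df, gs = fx.payload, fx.expected["geneset"]
        mine = gsva_score(df, gs, kcdf="ecdf")
        oracle = gsva_brute_ecdf(df, set(gs))
        assert np.allclose(mine, oracle.loc[mine.index], atol=1e-9)

    def test_duplicated_samples_score_identically(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(4, 1, (10, 5)), index=[f"g{i}" for i in range(10)])
        df["dup"] = df.iloc[:, 0]
        scores = gsva_score(df, ["g2", "g5", "g8"])
        assert scores.iloc[0] == pytest.approx(scores["dup"], abs=1e-12)

    def test_dr_ur_anticorrelated_on_defaults(self, small_cohort, small_pair):
        lf = small_cohort["log2fpkm"]
        dr = gsva_score(lf.matrix, small_pair.dr)
        ur = gsva_score(lf.matrix, small_pair.ur)
        assert np.corrcoef(dr, ur)[0, 1] <= -0.9

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0], [5.0, 0.0]], index=list("abc"))
        with pytest.raises(ValueError, match="3 reference samples"):
            gsva_score(df, ["a"])


class TestPc1:
    def test_matches_eigendecomposition(self):
        """PC1 of a 3-gene fixture equals the top correlation eigenvector."""
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(0, 1, (3, 5)), index=list("abc"),
                          columns=[f"s{i}" for i in range(5)])
        nt, tm = ["s0"], ["s4"]
        scores = pc1_score(df, list("abc"), nt, tm)
        x = df.to_numpy()
        std = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
        evals, evecs = np.linalg.eigh(np.cov(std, ddof=1))
        axis = evecs[:, np.argmax(evals)]
        proj = std.T @ axis
        if proj[0] < proj[4]:
            proj = -proj
        # same up to overall sign fixed by the orientation rule
        assert np.allclose(np.abs(scores.to_numpy()), np.abs(proj), atol=1e-9)
        assert scores["s0"] > scores["s4"]

    def test_orientation_rule_fixes_sign(self, small_cohort, small_pair):
        lf = small_cohort["log2fpkm"]
        nt = lf.group_samples("NT")
        tm = lf.group_samples("TM")
        scores = pc1_score(lf.matrix, small_pair.all_genes, nt, tm)
        assert scores[nt].mean() > scores[tm].mean()

    def test_separated_clusters_fully_ranked(self):
        rng = np.random.default_rng(12)
        base = rng.normal(0, 0.1, (4, 10))
        base[:, 5:] += 3.0  # second cluster shifted along all genes
        df = pd.DataFrame(base, index=list("abcd"), columns=[f"s{i}" for i in range(10)])
        scores = pc1_score(df, list("abcd"), ["s0"], ["s9"])
        assert scores[:5].min() > scores[5:].max()

    def test_degenerate_input_rejected(self):
        df = pd.DataFrame(np.ones((3, 4)), index=list("abc"))
        with pytest.raises(ValueError):
            pc1_score(df, list("abc"), [0], [1])


class TestBuildCesTable:
    def test_exactly_seven_scores_in_fixed_order(self, small_ces):
        table = small_ces["table"]
        assert list(table.columns) == list(CES_COLUMNS)
        assert table.notna().all().all()

    def test_sample_order_preserved(self, small_cohort, small_ces):
        assert list(small_ces["table"].index) == list(small_cohort["log2fpkm"].matrix.columns)

    def test_zscore_column_matches_standalone(self, small_cohort, small_pair, small_ces):
        counts = small_cohort["counts"]
        nt, tm = counts.group_samples("NT"), counts.group_samples("TM")
        ref = small_cohort["log2fpkm"].matrix[nt + tm]
        standalone = combined_zscore(small_cohort["log2fpkm"].matrix, small_pair.dr, ref=ref)
        pd.testing.assert_series_equal(
            small_ces["table"]["zscore_dr"], standalone, check_names=False
        )

    def test_group_ordering_of_zscore_dr(self, small_cohort, small_ces):
        by_group = small_ces["table"]["zscore_dr"].groupby(
            small_cohort["counts"].samples["group"]
        ).mean()
        assert by_group["NT"] > by_group["WT"] > by_group["TM"]

    def test_score_concordance_within_direction(self, small_ces):
        sub = small_ces["table"][["gsva_dr", "ssgsea_dr", "zscore_dr"]]
        assert sub.corr().to_numpy().min() >= 0.8

    def test_failing_sub_score_names_the_culprit(self, small_cohort):
        from p53func.feature_selection import GeneSetPair

        pair = GeneSetPair(("NOT_A_GENE",), ("ALSO_MISSING",))
        lf = small_cohort["log2fpkm"]
        nt, tm = lf.group_samples("NT"), lf.group_samples("TM")
        with pytest.raises(ValueError, match="DR set"), pytest.warns(UserWarning):
            build_ces_table(lf.matrix, pair, nt, tm)
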