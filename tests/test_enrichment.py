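"""Single-sample pathway scoring: kernel CDF, random walk, log odds."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from sklearn.base import clone

from progscape import (EnrichmentConfig, GSVAScorer, LogOddsScorer,
                       OmicsMatrix, PathwayCollection, gsva_enrichment,
                       kernel_cdf_transform, log_odds_enrichment)
from progscape.enrichment import _walk_scores


def brute_walk(z_col, member, tau=1.0, mode="max_diff"):
    """Independent step-by-step walk used as the oracle for _walk_scores."""
    n = len(z_col)
    order = sorted(range(n), key=lambda i: (-z_col[i], i))
    ranks = {g: pos + 1 for pos, g in enumerate(order)}
    weights = [abs(n / 2 - ranks[g]) ** tau for g in range(n)]
    denom = sum(weights[g] for g in range(n) if member[g])
    n_non = n - sum(member)
    cum, pos_max, neg_min = 0.0, 0.0, 0.0
    for g in order:
        if member[g]:
            cum += weights[g] / denom if denom > 0 else 0.0
        else:
            cum -= 1.0 / n_non
        pos_max = max(pos_max, cum)
        neg_min = min(neg_min, cum)
    if mode == "max_diff":
        return pos_max + neg_min
    return pos_max if pos_max > -neg_min else neg_min


class TestKernelCDF:
    def test_two_equal_values_map_to_half(self):
        om = OmicsMatrix(pd.DataFrame([[2.0, 2.0], [1.0, 0.0]],
                                      index=["G1", "G2"],
                                      columns=["S1", "S2"]))
        with pytest.warns(UserWarning, match="zero-variance"):
            z = kernel_cdf_transform(om)
        assert (z.loc["G1"] == 0.5).all()

    def test_two_point_gene_matches_closed_form(self):
        om = OmicsMatrix(pd.DataFrame([[-1.0, 1.0]], index=["G1"],
                                      columns=["S1", "S2"]))
        z = kernel_cdf_transform(om)
        h = np.std([-1.0, 1.0], ddof=1) / 4.0
        expected_high = (norm.cdf(0.0) + norm.cdf(2.0 / h)) / 2.0
        assert z.loc["G1", "S2"] == pytest.approx(expected_high, abs=1e-9)
        assert expected_high == pytest.approx(0.75, abs=1e-6)

    @pytest.mark.parametrize("scale,shift", [(3.0, 0.0), (0.5, -7.0),
                                             (10.0, 100.0)])
    def test_positive_affine_invariance(self, scale, shift, small_matrix):
        z0 = kernel_cdf_transform(small_matrix)
        om2 = OmicsMatrix(small_matrix.values * scale + shift)
        np.testing.assert_allclose(kernel_cdf_transform(om2), z0, atol=1e-10)

    def test_single_sample_is_rejected(self):
        om = OmicsMatrix(pd.DataFrame([[1.0]], index=["G1"], columns=["S1"]))
        with pytest.raises(ValueError, match="2 samples"):
            kernel_cdf_transform(om)

    def test_values_in_open_unit_interval(self, small_matrix):
        z = kernel_cdf_transform(small_matrix).to_numpy()
        assert (z > 0).all() and (z < 1).all()


class TestRandomWalk:
    def test_matches_oracle_on_all_orders_small(self):
        """Every rank order of up to 6 genes, single-member and mixed
        memberships, must agree exactly with the step-by-step oracle."""
        for n in (3, 5, 6):
            member = np.zeros(n, dtype=bool)
            member[0] = True
            if n > 3:
                member[2] = True
            perms = list(itertools.permutations(range(n)))
            Z = np.array([[n - p.index(g) for p in perms]
                          for g in range(n)], dtype=float)
            got = _walk_scores(Z, member, tau=1.0, mode="max_diff")
            for ci, p in enumerate(perms):
                z_col = [n - p.index(g) for g in range(n)]
                assert got[ci] == pytest.approx(brute_walk(z_col, member))

    def test_max_abs_mode_matches_oracle(self):
        rng = np.random.default_rng(5)
        n = 7
        Z = rng.standard_normal((n, 50))
        member = np.array([True, True, False, False, False, True, False])
        got = _walk_scores(Z, member, tau=1.0, mode="max_abs")
        for ci in range(50):
            assert got[ci] == pytest.approx(
                brute_walk(Z[:, ci], member, mode="max_abs"))

    def test_top_rank_member_scores_positive(self):
        Z = np.array([[3.0], [2.0], [1.0]])
        member = np.array([True, False, False])
        assert _walk_scores(Z, member, 1.0, "max_diff")[0] > 0

    def test_members_at_top_ranks_maximize_score(self):
        """Over all placements of k member genes among n ranks, putting the
        members at the top-k ranks yields the maximal walk score (tau=1)."""
        n, k = 8, 3
        Z = np.arange(n, 0, -1, dtype=float)[:, None]
        scores = {}
        for placement in itertools.combinations(range(n), k):
            member = np.zeros(n, dtype=bool)
            member[list(placement)] = True
            scores[placement] = _walk_scores(Z, member, 1.0, "max_diff")[0]
        top = tuple(range(k))
        assert scores[top] == pytest.approx(max(scores.values()))


class TestGSVAEnrichment:
    def test_output_dimensions(self, small_matrix, tiny_pathways):
        scores = gsva_enrichment(small_matrix, tiny_pathways)
        assert scores.values.shape == (3, 6)
        assert scores.provenance == "gsva"

    def test_small_and_universe_spanning_pathways_excluded(self):
        rng = np.random.default_rng(0)
        om = OmicsMatrix(pd.DataFrame(rng.standard_normal((4, 5)),
                                      index=["G1", "G2", "G3", "G4"],
                                      columns=[f"S{i}" for i in range(5)]))
        coll = PathwayCollection(
            ["TINY", "ALL", "OK"],
            {"TINY": ("G1",), "ALL": ("G1", "G2", "G3", "G4"),
             "OK": ("G1", "G2")})
        with pytest.warns(UserWarning):
            scores = gsva_enrichment(om, coll)
        assert scores.pathways == ["OK"]

    def test_null_scores_center_near_zero(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(100)]
        om = OmicsMatrix(pd.DataFrame(rng.standard_normal((100, 500)),
                                      index=genes,
                                      columns=[f"S{i}" for i in range(500)]))
        coll = PathwayCollection(["P1"], {"P1": tuple(genes[:20])})
        scores = gsva_enrichment(om, coll)
        assert abs(float(scores.values.loc["P1"].mean())) < 0.05

    def test_agrees_with_gseapy_reference(self):
        """Cross-check against the independent gseapy GSVA implementation
        (conventions differ slightly in tie/rank details, so correlation,
        not equality)."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(60)]
        om = OmicsMatrix(pd.DataFrame(rng.standard_normal((60, 40)),
                                      index=genes,
                                      columns=[f"S{i}" for i in range(40)]))
        sets = {f"P{k}": genes[10 * k:10 * (k + 1)] for k in range(5)}
        mine = gsva_enrichment(om, PathwayCollection(list(sets),
                                                     {k: tuple(v) for k, v
                                                      in sets.items()}))
        ref = gseapy.gsva(data=om.values, gene_sets=sets, outdir=None,
                          kcdf="Gaussian", weight=1, mx_diff=True,
                          min_size=2)
        piv = ref.res2d.pivot(index="Term", columns="Name",
                              values="ES").astype(float)
        piv = piv.loc[mine.values.index, mine.values.columns]
        r = np.corrcoef(piv.to_numpy().ravel(),
                        mine.values.to_numpy().ravel())[0, 1]
        assert r > 0.99


class TestLogOdds:
    def _score(self, a, b, c, d):
        return math.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))

    def test_worked_two_by_two_cases(self):
        """Universe of 100 genes, pathway of 10. A sample with 10 mutations,
        4 inside the pathway, scores ln 9; a mutation-free sample still
        scores positive because of the continuity correction."""
        genes = [f"G{i}" for i in range(100)]
        coll = PathwayCollection(["P"], {"P": tuple(genes[:10])})
        vals = np.zeros((100, 2))
        vals[[0, 1, 2, 3], 0] = 1          # 4 mutations inside the pathway
        vals[[20, 30, 40, 50, 60, 70], 0] = 1  # 6 outside
        om = OmicsMatrix(pd.DataFrame(vals, index=genes,
                                      columns=["mutated", "clean"]),
                         "SPM", "binary")
        scores = log_odds_enrichment(om, coll)
        assert scores.values.loc["P", "mutated"] == \
            pytest.approx(math.log(9.0), abs=1e-12)
        assert scores.values.loc["P", "mutated"] == pytest.approx(2.1972,
                                                                  abs=1e-4)
        assert scores.values.loc["P", "clean"] == \
            pytest.approx(self._score(0, 10, 0, 90), abs=1e-12)
        assert scores.values.loc["P", "clean"] == pytest.approx(2.154,
                                                                abs=1e-3)

    def test_balanced_table_scores_zero(self):
        genes = ["G1", "G2", "G3", "G4"]
        coll = PathwayCollection(["P"], {"P": ("G1", "G2")})
        vals = np.array([[1.0], [0.0], [1.0], [0.0]])  # a=b=c=d=1
        om = OmicsMatrix(pd.DataFrame(vals, index=genes, columns=["S1"]),
                         "SPM", "binary")
        assert log_odds_enrichment(om, coll).values.loc["P", "S1"] == 0.0

    def test_membership_complement_negates_score(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(30)]
        vals = (rng.uniform(size=(30, 8)) < 0.2).astype(float)
        om = OmicsMatrix(pd.DataFrame(vals, index=genes,
                                      columns=[f"S{i}" for i in range(8)]),
                         "SPM", "binary")
        coll = PathwayCollection(["P"], {"P": tuple(genes[:12])})
        coll_c = PathwayCollection(["P"], {"P": tuple(genes[12:])})
        s = log_odds_enrichment(om, coll).values.to_numpy()
        s_c = log_odds_enrichment(om, coll_c).values.to_numpy()
        np.testing.assert_allclose(s_c, -s, atol=1e-12)

    def test_sample_permutation_permutes_columns(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(20)]
        vals = (rng.uniform(size=(20, 6)) < 0.3).astype(float)
        om = OmicsMatrix(pd.DataFrame(vals, index=genes,
                                      columns=[f"S{i}" for i in range(6)]),
                         "SPM", "binary")
        coll = PathwayCollection(["P"], {"P": tuple(genes[:7])})
        s = log_odds_enrichment(om, coll)
        perm = ["S3", "S0", "S5", "S1", "S4", "S2"]
        om_p = OmicsMatrix(om.values[perm], "SPM", "binary")
        s_p = log_odds_enrichment(om_p, coll)
        pd.testing.assert_frame_equal(s_p.values, s.values[perm])

    def test_continuous_matrix_is_rejected(self, small_matrix, tiny_pathways):
        with pytest.raises(ValueError, match="binary"):
            log_odds_enrichment(small_matrix, tiny_pathways)


class TestTransformers:
    def test_gsva_scorer_matches_function(self, small_matrix, tiny_pathways):
        scorer = GSVAScorer(gene_sets=tiny_pathways)
        out = scorer.fit_transform(small_matrix.values.T)
        ref = gsva_enrichment(small_matrix, tiny_pathways).values.T
        pd.testing.assert_frame_equal(out, ref)

    def test_clone_round_trip(self, tiny_pathways):
        scorer = GSVAScorer(gene_sets=tiny_pathways, tau=0.5)
        assert clone(scorer).get_params()["tau"] == 0.5

    def test_log_odds_scorer_orientation(self, tiny_pathways):
        rng = np.random.default_rng(6)
        genes = [f"G{i}" for i in range(1, 11)]
        frame = pd.DataFrame((rng.uniform(size=(5, 10)) < 0.3).astype(float),
                             index=[f"S{i}" for i in range(5)],
                             columns=genes)
        out = LogOddsScorer(gene_sets=tiny_pathways).fit_transform(frame)
        assert out.shape[0] == 5
        assert set(out.columns) <= set(tiny_pathways.names)


def test_enrichment_config_validation():
    with pytest.raises(ValueError):
        EnrichmentConfig(kernel_bandwidth_factor=0.0)
    with pytest.raises(ValueError):
        EnrichmentConfig(statistic_mode="median")
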