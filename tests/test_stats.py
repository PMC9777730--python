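import itertools
import json
import math

import numpy as np
import pytest
import scipy.stats

from swehist.histograms import Elastogram, compute_features, extract_histograms, features_to_frame
from swehist.stats import (
    compare_cohorts,
    dunn_posthoc,
    kruskal_wallis,
    ks_two_sample,
    mann_whitney,
    roc_analysis,
    shapiro_wilk,
)


# ---------------------------------------------------------------- oracles
def ks_d_oracle(x, y):
    """Brute-force sup of |ECDF_x - ECDF_y| over all sample points."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    d = 0.0
    for t in np.concatenate([x, y]):
        d = max(d, abs((x <= t).mean() - (y <= t).mean()))
    return d


def mw_exact_oracle(x, y, alternative="two-sided"):
    """Full enumeration of group assignments over the pooled sample."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    mu = n1 * len(y) / 2.0

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    eps = 1e-9
    if alternative == "two-sided":
        hits = sum(abs(u - mu) >= abs(u_obs - mu) - eps for u in us)
    elif alternative == "greater":
        hits = sum(u >= u_obs - eps for u in us)
    else:
        hits = sum(u <= u_obs + eps for u in us)
    return hits / len(us)


# ------------------------------------------------------------------- KS
class TestKsTwoSample:
    def test_identical_samples_d_zero(self, rng):
        x = rng.normal(size=20)
        res = ks_two_sample(x, x)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_disjoint_supports_d_one(self):
        res = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert res.statistic == 1.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            x = np.round(rng.normal(size=5), 1)  # rounding forces ties
            y = np.round(rng.normal(size=5), 1)
            assert ks_two_sample(x, y).statistic == pytest.approx(
                ks_d_oracle(x, y), abs=1e-12
            )

    def test_matches_scipy_asymptotic(self, rng):
        x, y = rng.normal(size=40), rng.normal(0.5, size=60)
        res = ks_two_sample(x, y)
        ref = scipy.stats.ks_2samp(x, y, method="asymp")
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


# ------------------------------------------------------------ Mann-Whitney
class TestMannWhitney:
    def test_identical_multisets_u_half(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(x, x)
        assert res.statistic == len(x) ** 2 / 2

    def test_complete_separation_extremes(self):
        lo, hi = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        assert mann_whitney(lo, hi).statistic == 0.0
        assert mann_whitney(hi, lo).statistic == 9.0

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_matches_enumeration_oracle(self, rng, alternative):
        for _ in range(8):
            x = np.round(rng.normal(size=4), 1)
            y = np.round(rng.normal(0.7, size=4), 1)
            res = mann_whitney(x, y, alternative=alternative)
            assert res.method == "mann-whitney-exact"
            assert res.p_value == pytest.approx(
                mw_exact_oracle(x, y, alternative), abs=1e-12
            )

    def test_degenerate_constant_data(self):
        res = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0
        assert res.degenerate

    def test_normal_approx_close_to_scipy(self, rng):
        x, y = rng.normal(size=30), rng.normal(0.4, size=40)
        res = mann_whitney(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_p_in_unit_interval(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 25))
            y = rng.normal(size=rng.integers(2, 25))
            assert 0.0 <= mann_whitney(x, y).p_value <= 1.0


# ---------------------------------------------------------- Kruskal-Wallis
class TestKruskalWallis:
    def test_identical_constant_groups_degenerate(self):
        res = kruskal_wallis([[3.0, 3.0], [3.0, 3.0], [3.0, 3.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.degenerate

    def test_two_groups_matches_mw_z_squared(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(0.8, size=15)  # continuous -> no ties
        h = kruskal_wallis([x, y]).statistic
        u = mann_whitney(x, y).statistic
        mu = len(x) * len(y) / 2
        sigma = math.sqrt(len(x) * len(y) * (len(x) + len(y) + 1) / 12)
        z = (u - mu) / sigma
        assert h == pytest.approx(z**2, abs=1e-9)

    def test_matches_direct_rank_computation(self):
        groups = [[1.0, 5.0, 8.0, 2.0], [3.0, 3.0, 9.0, 4.0], [7.0, 6.0, 10.0, 11.0]]
        res = kruskal_wallis(groups)
        ref = scipy.stats.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


# ------------------------------------------------------------------ Dunn
class TestDunnPosthoc:
    def test_identical_groups_z_zero(self):
        g = [1.0, 2.0, 3.0]
        res = dunn_posthoc([g, g, g])
        for r in res.values():
            assert r.statistic == pytest.approx(0.0)
            assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_no_ties(self):
        # groups [1,2,3], [4,5,6], [7,8,9]: mean ranks 2, 5, 8; N=9
        # var = (9*10/12) * (2/3) = 5 -> sd = sqrt(5)
        res = dunn_posthoc([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
        sd = math.sqrt(5.0)
        assert res[(0, 1)].statistic == pytest.approx(-3.0 / sd, abs=1e-12)
        assert res[(0, 2)].statistic == pytest.approx(-6.0 / sd, abs=1e-12)
        assert res[(1, 2)].statistic == pytest.approx(-3.0 / sd, abs=1e-12)
        assert res[(0, 1)].p_value == pytest.approx(
            2 * scipy.stats.norm.sf(3.0 / sd), abs=1e-12
        )

    def test_bonferroni_contract(self, rng):
        groups = [rng.normal(size=6), rng.normal(1, size=6), rng.normal(2, size=6)]
        raw = dunn_posthoc(groups, adjustment="none")
        adj = dunn_posthoc(groups, adjustment="bonferroni")
        for key in raw:
            assert adj[key].p_value == pytest.approx(min(1.0, 3 * raw[key].p_value))

    def test_bad_adjustment_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc([[1.0], [2.0]], adjustment="holm")


# --------------------------------------------------------------- Shapiro
class TestShapiroWilk:
    def test_exact_normal_quantiles_w_near_one(self):
        q = scipy.stats.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        res = shapiro_wilk(q)
        assert res.statistic > 0.99

    def test_constant_sample_degenerate(self):
        res = shapiro_wilk([5.0] * 10)
        assert res.degenerate
        assert np.isnan(res.statistic)

    def test_bimodal_rejected(self):
        x = np.concatenate([np.zeros(25), np.ones(25)]) + np.linspace(0, 1e-6, 50)
        assert shapiro_wilk(x).p_value < 0.01

    @pytest.mark.parametrize("n", [2, 5001])
    def test_out_of_range_n_rejected(self, n):
        with pytest.raises(ValueError):
            shapiro_wilk(np.arange(n, dtype=float))


# ------------------------------------------------------------------- ROC
class TestRocAnalysis:
    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.3, 0.8, 0.9, 1.0]
        labels = ["benign"] * 3 + ["malignant"] * 3
        res = roc_analysis(scores, labels)
        assert res.auc == 1.0
        assert res.youden == 1.0

    def test_lower_direction(self):
        scores = [0.9, 0.8, 0.7, 0.2, 0.1, 0.0]
        labels = ["benign"] * 3 + ["malignant"] * 3
        res = roc_analysis(scores, labels, positive_direction="lower")
        assert res.auc == 1.0

    def test_permutation_average_is_half(self):
        # symmetry oracle: mean AUC over all label assignments is exactly 0.5
        scores = np.array([0.1, 0.5, 0.3, 0.9, 0.7, 0.2])
        aucs = []
        for pos in itertools.combinations(range(6), 3):
            labels = ["malignant" if i in pos else "benign" for i in range(6)]
            aucs.append(roc_analysis(scores, labels).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=1e-12)

    def test_auc_equals_u_identity_with_ties(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(3, 12, size=2)
            scores = np.round(rng.normal(size=n1 + n2), 1)
            labels = ["malignant"] * n1 + ["benign"] * n2
            auc = roc_analysis(scores, labels).auc
            u = mann_whitney(scores[:n1], scores[n1:]).statistic
            assert auc == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_curve_invariants(self, rng):
        scores = np.round(rng.normal(size=30), 1)
        labels = rng.choice(["benign", "malignant"], size=30).tolist()
        if len(set(labels)) < 2:
            labels[0], labels[1] = "benign", "malignant"
        res = roc_analysis(scores, labels)
        pts = res.points
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()
        assert res.auc == pytest.approx(np.trapezoid(pts[:, 1], pts[:, 0]))

    def test_sens_at_spec_conservative(self):
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2, 0.1, 0.05]
        labels = ["malignant"] * 3 + ["benign"] * 5
        res = roc_analysis(scores, labels, spec_targets=(0.9, 0.8))
        # spec 0.9 requires fpr <= 0.1 -> only fpr=0 points: sens 2/3;
        # spec 0.8 admits the fpr=0.2 point at threshold 0.4: sens 1.0
        assert res.sens_at_spec[0.9] == pytest.approx(2 / 3)
        assert res.sens_at_spec[0.8] == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], ["benign", "benign"])


# --------------------------------------------------------- compare_cohorts
def _cohort_from_images(images):
    feats = features_to_frame([compute_features(im) for im in images])
    hists = [extract_histograms(im) for im in images]
    return feats, hists


def _random_image(rng, label):
    px = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
    px[..., 0] = 0  # keep chromatic spread
    px[..., 2] = 255
    return Elastogram(pixels=px, valid_mask=np.ones((16, 16), dtype=bool), label=label)


class TestCompareCohorts:
    def test_identical_cohorts_degenerate(self, rng):
        base = _random_image(rng, "benign")
        images = []
        for label in ("benign", "malignant"):
            for i in range(3):
                images.append(
                    Elastogram(
                        pixels=base.pixels,
                        valid_mask=base.valid_mask,
                        source_id=f"{label}{i}",
                        label=label,
                    )
                )
        feats, hists = _cohort_from_images(images)
        report = compare_cohorts(feats, hists)
        for ch, res in report.ks.items():
            assert res.statistic == 0.0
        for res in report.rank_sum.values():
            assert res.degenerate
            # p = 1 where the descriptor is defined; NaN when it is
            # missing in both groups (constant-channel skewness)
            assert res.p_value == 1.0 or np.isnan(res.p_value)

    def test_row_order_invariance(self, rng):
        images = [_random_image(rng, "benign") for _ in range(4)] + [
            _random_image(rng, "malignant") for _ in range(4)
        ]
        for i, im in enumerate(images):
            im.source_id = f"im{i}"
        feats, hists = _cohort_from_images(images)
        r1 = compare_cohorts(feats, hists)
        perm = list(np.random.default_rng(0).permutation(len(images)))
        feats2 = feats.iloc[perm].reset_index(drop=True)
        hists2 = [hists[i] for i in perm]
        r2 = compare_cohorts(feats2, hists2)
        assert r1.to_json() == r2.to_json()

    def test_pooled_mode_runs(self, rng):
        images = [_random_image(rng, "benign") for _ in range(3)] + [
            _random_image(rng, "malignant") for _ in range(3)
        ]
        feats, hists = _cohort_from_images(images)
        report = compare_cohorts(feats, hists, ks_mode="pooled")
        assert report.ks_mode == "pooled"
        for res in report.ks.values():
            assert res.n1 == 3 * 250

    def test_single_label_rejected(self, rng):
        images = [_random_image(rng, "benign") for _ in range(4)]
        feats, hists = _cohort_from_images(images)
        with pytest.raises(ValueError):
            compare_cohorts(feats, hists)

    def test_report_json_schema(self, rng):
        images = [_random_image(rng, "benign") for _ in range(3)] + [
            _random_image(rng, "malignant") for _ in range(3)
        ]
        feats, hists = _cohort_from_images(images)
        d = json.loads(compare_cohorts(feats, hists).to_json())
        assert set(d) == {
            "n_benign",
            "n_malignant",
            "ks_mode",
            "ks",
            "rank_sum",
            "roc_feature",
            "roc",
        }
        assert set(d["ks"]) == {"warm", "intermediate", "cool"}
        assert d["roc_feature"] == "auc_low_cool"
        assert 0.0 <= d["roc"]["auc"] <= 1.0
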