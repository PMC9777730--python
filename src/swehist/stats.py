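"""Statistical layer: two-sample KS, rank tests, normality screen, ROC.

The cohort comparison mirrors the original analysis pipeline: histograms
are vectorized and compared channel-wise with a two-sample
Kolmogorov-Smirnov test, descriptors are compared with Mann-Whitney rank
sums, and the cool-channel low-bin AUC descriptor is evaluated by ROC
analysis with the Youden index and sensitivity at fixed specificity.

.. warning::
   The default ``faithful`` KS mode treats the two groups' mean normalized
   histograms as value samples (bin heights as observations). This follows
   the source workflow but is statistically unorthodox: the 250 bin heights
   of one histogram are not independent draws. A conventional ``pooled``
   mode (concatenating per-image normalized histograms) is also provided.
"""
from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from .histograms import CHANNELS, ChannelHistogramSet, cohort_mean_histogram

__all__ = [
    "TestResult",
    "RocResult",
    "CohortReport",
    "ks_two_sample",
    "mann_whitney",
    "kruskal_wallis",
    "dunn_posthoc",
    "shapiro_wilk",
    "roc_analysis",
    "compare_cohorts",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "n1": self.n1,
            "n2": self.n2,
            "degenerate": self.degenerate,
        }


def _as_sample(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("sample must be nonempty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("sample must be finite")
    return arr


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    D = sup_t |ECDF_x(t) - ECDF_y(t)|; the p-value comes from the
    asymptotic Kolmogorov distribution at effective size n1*n2/(n1+n2).
    """
    x = np.sort(_as_sample(x))
    y = np.sort(_as_sample(y))
    n1, n2 = x.size, y.size
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / n1
    cdf_y = np.searchsorted(y, grid, side="right") / n2
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = n1 * n2 / (n1 + n2)
    p = float(np.clip(scipy.special.kolmogorov(math.sqrt(en) * d), 0.0, 1.0))
    return TestResult(statistic=d, p_value=p, method="ks-two-sample-asymp", n1=n1, n2=n2)


def _rank_sum_u(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)  # midranks
    n1 = x.size
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    return u, ranks


def mann_whitney(x, y, alternative: str = "two-sided", exact: bool | None = None) -> TestResult:
    """Mann-Whitney U test (U of x relative to y) with midranks for ties.

    Small samples (n1+n2 <= 12, or ``exact=True``) use full enumeration of
    the C(N, n1) group assignments; otherwise the normal approximation with
    tie and continuity corrections is used. Fully degenerate data (all
    values identical) reports p = 1 with the degenerate flag set.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be two-sided, greater or less")
    x = _as_sample(x)
    y = _as_sample(y)
    n1, n2 = x.size, y.size
    u, ranks = _rank_sum_u(x, y)
    mu = n1 * n2 / 2.0

    if np.unique(np.concatenate([x, y])).size == 1:
        return TestResult(u, 1.0, "mann-whitney-degenerate", n1, n2, degenerate=True)

    if exact is None:
        exact = (n1 + n2) <= 12
    eps = 1e-9
    if exact:
        total = 0
        hits = 0
        idx_all = range(n1 + n2)
        for comb in itertools.combinations(idx_all, n1):
            u_perm = float(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0)
            total += 1
            if alternative == "two-sided":
                hits += abs(u_perm - mu) >= abs(u - mu) - eps
            elif alternative == "greater":
                hits += u_perm >= u - eps
            else:
                hits += u_perm <= u + eps
        return TestResult(u, hits / total, "mann-whitney-exact", n1, n2)

    n = n1 + n2
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return TestResult(u, 1.0, "mann-whitney-normal", n1, n2, degenerate=True)
    sigma = math.sqrt(sigma2)
    if alternative == "two-sided":
        z = (abs(u - mu) - 0.5) / sigma
        p = 2.0 * scipy.stats.norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (u - mu - 0.5) / sigma
        p = scipy.stats.norm.sf(z)
    else:
        z = (u - mu + 0.5) / sigma
        p = scipy.stats.norm.cdf(z)
    return TestResult(u, float(min(p, 1.0)), "mann-whitney-normal", n1, n2)


def kruskal_wallis(groups: Sequence) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi2 with k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = [_as_sample(g) for g in groups]
    sizes = np.array([s.size for s in samples])
    n = int(sizes.sum())
    pooled = np.concatenate(samples)
    ranks = scipy.stats.rankdata(pooled)
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_corr = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (n**3 - n)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    rank_sums = np.array(
        [ranks[offsets[i] : offsets[i + 1]].sum() for i in range(len(samples))]
    )
    h = 12.0 / (n * (n + 1)) * float(np.sum(rank_sums**2 / sizes)) - 3 * (n + 1)
    if tie_corr == 0.0:  # every value identical
        return TestResult(0.0, 1.0, "kruskal-wallis", n, len(samples), degenerate=True)
    h /= tie_corr
    p = float(scipy.stats.chi2.sf(h, df=len(samples) - 1))
    return TestResult(float(h), p, "kruskal-wallis", n, len(samples))


def dunn_posthoc(
    groups: Sequence, adjustment: str = "none"
) -> dict[tuple[int, int], TestResult]:
    """Pairwise Dunn z tests on mean ranks after Kruskal-Wallis.

    Returns a dict keyed by (i, j) group-index pairs, i < j. Bonferroni
    adjustment multiplies each raw p by the number of pairs.
    """
    if adjustment not in ("none", "bonferroni"):
        raise ValueError("adjustment must be 'none' or 'bonferroni'")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = [_as_sample(g) for g in groups]
    sizes = np.array([s.size for s in samples])
    n = int(sizes.sum())
    ranks = scipy.stats.rankdata(np.concatenate(samples))
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[offsets[i] : offsets[i + 1]].mean() for i in range(len(samples))]
    )
    m = len(samples) * (len(samples) - 1) // 2
    out: dict[tuple[int, int], TestResult] = {}
    for i, j in itertools.combinations(range(len(samples)), 2):
        var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:
            out[(i, j)] = TestResult(
                0.0, 1.0, "dunn", int(sizes[i]), int(sizes[j]), degenerate=True
            )
            continue
        z = float((mean_ranks[i] - mean_ranks[j]) / math.sqrt(var))
        p = float(2.0 * scipy.stats.norm.sf(abs(z)))
        if adjustment == "bonferroni":
            p = min(1.0, m * p)
        out[(i, j)] = TestResult(z, p, f"dunn-{adjustment}", int(sizes[i]), int(sizes[j]))
    return out


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality screen (Royston approximation, 3 <= n <= 5000).

    Zero-variance samples return a degenerate NaN result rather than a
    misleading statistic.
    """
    x = _as_sample(x)
    n = x.size
    if not 3 <= n <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.unique(x).size == 1:
        return TestResult(float("nan"), float("nan"), "shapiro-wilk", n, n, degenerate=True)
    w, p = scipy.stats.shapiro(x)
    return TestResult(float(w), float(p), "shapiro-wilk", n, n)


@dataclass(frozen=True)
class RocResult:
    """ROC curve in (1-specificity, sensitivity) space with summaries."""

    points: np.ndarray  # (m, 2) ordered, starts (0,0) ends (1,1)
    thresholds: np.ndarray  # score threshold per point (NaN at endpoints)
    auc: float
    youden: float
    youden_threshold: float
    sens_at_spec: dict[float, float]
    positive_direction: str = "higher"

    def to_dict(self) -> dict:
        return {
            "points": [[float(a), float(b)] for a, b in self.points],
            "auc": self.auc,
            "youden": self.youden,
            "youden_threshold": self.youden_threshold,
            "sens_at_spec": {f"{k:.4f}": v for k, v in self.sens_at_spec.items()},
            "positive_direction": self.positive_direction,
        }


def roc_analysis(
    scores,
    labels,
    positive_direction: str = "higher",
    positive_label: str = "malignant",
    spec_targets: Sequence[float] = (0.90,),
) -> RocResult:
    """ROC over the unique score thresholds.

    ``sens_at_spec`` is conservative: for each requested specificity it
    returns the best sensitivity among operating points whose specificity
    is at least the request (no interpolation).
    """
    if positive_direction not in ("higher", "lower"):
        raise ValueError("positive_direction must be 'higher' or 'lower'")
    scores = _as_sample(scores)
    y = np.asarray([lab == positive_label for lab in labels], dtype=bool)
    if y.size != scores.size:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    s = scores if positive_direction == "higher" else -scores

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # operating points at the last occurrence of each distinct score
    last = np.nonzero(np.diff(s_sorted, append=-np.inf))[0]
    sens = tp[last] / n_pos
    fpr = fp[last] / n_neg
    thr = s_sorted[last]
    points = np.vstack([[0.0, 0.0], np.column_stack([fpr, sens])])
    thresholds = np.concatenate([[np.nan], thr if positive_direction == "higher" else -thr])
    if points[-1, 0] != 1.0 or points[-1, 1] != 1.0:
        points = np.vstack([points, [1.0, 1.0]])
        thresholds = np.concatenate([thresholds, [np.nan]])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))

    spec = 1.0 - points[:, 0]
    j = points[:, 1] + spec - 1.0
    interior = ~np.isnan(thresholds)
    if interior.any():
        best = int(np.flatnonzero(interior)[np.argmax(j[interior])])
    else:  # pragma: no cover - at least one threshold always exists
        best = int(np.argmax(j))
    sens_at_spec: dict[float, float] = {}
    for target in spec_targets:
        ok = spec >= target - 1e-12
        sens_at_spec[float(target)] = float(points[ok, 1].max()) if ok.any() else 0.0
    return RocResult(
        points=points,
        thresholds=thresholds,
        auc=auc,
        youden=float(j[best]),
        youden_threshold=float(thresholds[best]),
        sens_at_spec=sens_at_spec,
        positive_direction=positive_direction,
    )


DEFAULT_ROC_FEATURE = "auc_low_cool"


@dataclass
class CohortReport:
    """Group-level comparison of benign vs malignant elastogram cohorts."""

    ks: dict[str, TestResult]
    ks_mode: str
    rank_sum: dict[str, TestResult]
    roc: RocResult
    roc_feature: str
    n_benign: int
    n_malignant: int

    def to_dict(self) -> dict:
        return {
            "n_benign": self.n_benign,
            "n_malignant": self.n_malignant,
            "ks_mode": self.ks_mode,
            "ks": {ch: r.to_dict() for ch, r in self.ks.items()},
            "rank_sum": {k: r.to_dict() for k, r in self.rank_sum.items()},
            "roc_feature": self.roc_feature,
            "roc": self.roc.to_dict(),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def compare_cohorts(
    features: pd.DataFrame,
    hists: Sequence[ChannelHistogramSet],
    ks_mode: str = "faithful",
    spec_targets: Sequence[float] = (0.90,),
    roc_feature: str = DEFAULT_ROC_FEATURE,
) -> CohortReport:
    """Full benign-vs-malignant comparison.

    ``features`` is the per-image descriptor table (one row per image,
    columns as written by :func:`swehist.histograms.features_to_frame`);
    ``hists`` is the aligned list of per-image histogram sets.

    KS modes: ``faithful`` compares the two groups' mean normalized
    histograms as 250-value vectors (see module warning); ``pooled``
    concatenates the per-image normalized histograms of each group.
    """
    if ks_mode not in ("faithful", "pooled"):
        raise ValueError("ks_mode must be 'faithful' or 'pooled'")
    if len(hists) != len(features):
        raise ValueError("hists must align with feature rows")
    labels = features["label"].to_numpy()
    benign = labels == "benign"
    malignant = labels == "malignant"
    if not benign.any() or not malignant.any():
        raise ValueError("both benign and malignant images are required")

    hists = list(hists)
    ks: dict[str, TestResult] = {}
    for ch in CHANNELS:
        hb = [h for h, b in zip(hists, benign) if b]
        hm = [h for h, m in zip(hists, malignant) if m]
        if ks_mode == "faithful":
            xb = cohort_mean_histogram(hb, ch)
            xm = cohort_mean_histogram(hm, ch)
        else:
            ci = CHANNELS.index(ch)
            xb = np.concatenate([h.normalized[ci] for h in hb])
            xm = np.concatenate([h.normalized[ci] for h in hm])
        ks[ch] = ks_two_sample(xb, xm)

    descriptors = [c for c in features.columns if c.startswith(("auc_", "skew_"))]
    rank_sum: dict[str, TestResult] = {}
    for col in descriptors:
        vals = features[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        xb, xm = vals[benign & ok], vals[malignant & ok]
        if xb.size == 0 or xm.size == 0:
            # descriptor undefined (e.g. zero-variance skewness) in a group
            rank_sum[col] = TestResult(
                float("nan"), float("nan"), "mann-whitney-missing",
                max(int(xb.size), 1), max(int(xm.size), 1), degenerate=True,
            )
            continue
        rank_sum[col] = mann_whitney(xb, xm)

    scores = features[roc_feature].to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError(f"ROC feature {roc_feature!r} contains missing values")
    roc = roc_analysis(
        scores, labels, positive_direction="higher", spec_targets=spec_targets
    )
    return CohortReport(
        ks=ks,
        ks_mode=ks_mode,
        rank_sum=rank_sum,
        roc=roc,
        roc_feature=roc_feature,
        n_benign=int(benign.sum()),
        n_malignant=int(malignant.sum()),
    )
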