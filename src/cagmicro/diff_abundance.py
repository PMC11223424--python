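"""Nonparametric group tests and the LDA-effect-size discriminant-taxa procedure.

The rank tests wrap scipy.stats with explicit exact/approximate mode logic:
exact enumeration where feasible (small samples, no ties), normal
approximation with tie and continuity corrections otherwise.

The discriminant-taxa procedure (LEfSe-style) is reimplemented here: a
Kruskal-Wallis screen at ``alpha``, then bootstrap rounds that fit a
one-discriminant LDA on the surviving features (samples scaled to sum
100,000, the conventional scale) and average a per-feature effect size; the
reported score is log10(effect + 1). In the two-class tumor/normal setting
the subclass (within-class) stage of the original procedure is a no-op and
is omitted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .data_io import AbundanceTable, DataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    """One feature's test outcome with per-group medians (fractional scale)."""

    feature: str
    test: str
    statistic: float
    p_value: float
    group_medians: dict = field(default_factory=dict)
    n: int = 0
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rank tests

def mann_whitney(x, y, mode: str = "auto", feature: str = "") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode="auto"`` uses exact enumeration when min(n) <= 8 and the pooled
    data are tie-free, else the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("mann_whitney requires non-empty groups")
    if mode not in ("exact", "normal_approx", "auto"):
        raise DataError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (min(len(x), len(y)) <= 8 and not ties) else "normal_approx"
    if mode == "exact" and ties:
        raise DataError("exact Mann-Whitney is undefined with ties")
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(feature, "mann_whitney", float(res.statistic),
                      float(min(res.pvalue, 1.0)),
                      {"x": float(np.median(x)), "y": float(np.median(y))},
                      n=len(pooled))


def wilcoxon_signed_rank(paired_diffs, feature: str = "") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon convention); exact for n <= 15
    without ties in |differences|, else normal approximation with continuity
    correction.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        raise DataError("all paired differences are zero")
    ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 15 and not ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method=method, correction=(method == "approx"))
    return TestResult(feature, "wilcoxon_signed_rank", float(res.statistic),
                      float(min(res.pvalue, 1.0)),
                      {"diff": float(np.median(d))}, n=len(d))


def spearman(x, y, feature: str = "") -> TestResult:
    """Spearman rank correlation (pairwise-complete); p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise DataError("spearman needs at least 3 complete pairs")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise DataError("spearman undefined for a constant variable")
    rho, p = stats.spearmanr(x, y)
    return TestResult(feature, "spearman", float(rho), float(min(p, 1.0)), n=len(x),
                      extra={"rho": float(rho)})


def kruskal_wallis(groups: list, feature: str = "") -> TestResult:
    """Kruskal-Wallis H test across 2+ groups (tie-corrected chi-square p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise DataError("kruskal_wallis needs >= 2 non-empty groups")
    h, p = stats.kruskal(*groups)
    medians = {str(i): float(np.median(g)) for i, g in enumerate(groups)}
    return TestResult(feature, "kruskal_wallis", float(h), float(min(p, 1.0)),
                      medians, n=sum(len(g) for g in groups))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# LEfSe-style discriminant taxa

LEFSE_SCALE = 100_000.0  # per-sample sum used by the conventional implementation


@dataclass(frozen=True)
class LefseResult:
    feature: str
    enriched_class: str
    kw_p: float
    lda_score: float  # log10 scale; NaN if the feature failed the screen
    passes: bool


def lefse_score(t: AbundanceTable, labels, alpha: float = 0.05, n_boot: int = 30,
                boot_fraction: float = 2 / 3, threshold: float = 3.5,
                seed: int | None = None) -> list[LefseResult]:
    """Score features discriminating two classes (e.g. tumor vs normal tissue).

    Step 1: Kruskal-Wallis screen at ``alpha`` per feature. Step 2: over
    ``n_boot`` bootstrap rounds, subsample ``boot_fraction`` of each class,
    fit a one-discriminant LDA on the surviving features, and take the
    per-feature effect 0.5*(|class-mean difference along the discriminant,
    back-projected to the feature| + |raw class-mean difference|) on the
    100,000-sum scale; the score is log10(mean effect + 1). A feature passes
    when kw_p < alpha and score >= threshold (boundary inclusive).
    """
    if t.kind == "counts":
        raise DataError("lefse_score expects relative abundances")
    labels = np.asarray(labels).astype(str)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise DataError(f"lefse_score requires exactly 2 classes, got {list(classes)}")
    x = t.values().T * LEFSE_SCALE  # samples × features
    n0, n1 = int((labels == classes[0]).sum()), int((labels == classes[1]).sum())
    if min(n0, n1) < 5:
        raise DataError("each class needs at least 5 samples")
    features = t.taxa
    idx0 = np.flatnonzero(labels == classes[0])
    idx1 = np.flatnonzero(labels == classes[1])

    kw_p = np.empty(len(features))
    enriched = []
    for j in range(len(features)):
        a, b = x[idx0, j], x[idx1, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            kw_p[j] = 1.0
        else:
            kw_p[j] = stats.kruskal(a, b)[1]
        enriched.append(str(classes[0]) if a.mean() >= b.mean() else str(classes[1]))

    surviving = np.flatnonzero(kw_p < alpha)
    scores = np.full(len(features), np.nan)
    if len(surviving) > 0:
        rng = np.random.default_rng(seed)
        effects = np.zeros(len(surviving))
        rounds = 0
        for _ in range(n_boot):
            s0 = rng.choice(idx0, size=max(int(round(boot_fraction * n0)), 1), replace=False)
            s1 = rng.choice(idx1, size=max(int(round(boot_fraction * n1)), 1), replace=False)
            if len(s0) < 2 or len(s1) < 2:
                logger.info("lefse: bootstrap round skipped (class too small)")
                continue
            sub = np.concatenate([s0, s1])
            xs = x[np.ix_(sub, surviving)]
            ys = np.concatenate([np.zeros(len(s0)), np.ones(len(s1))])
            m_diff = xs[ys == 1].mean(axis=0) - xs[ys == 0].mean(axis=0)
            if len(surviving) == 1:
                lda_part = np.abs(m_diff)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # collinear features are routine
                    lda = LinearDiscriminantAnalysis(solver="svd", n_components=1)
                    try:
                        lda.fit(xs, ys)
                        w = lda.scalings_[:, 0]
                        w = w / (np.linalg.norm(w) or 1.0)
                        delta = float(m_diff @ w)
                        lda_part = np.abs(w * delta)
                    except np.linalg.LinAlgError:
                        logger.info("lefse: bootstrap round skipped (singular fit)")
                        continue
            effects += 0.5 * (lda_part + np.abs(m_diff))
            rounds += 1
        if rounds > 0:
            scores[surviving] = np.log10(np.maximum(effects / rounds, 1e-10) + 1.0)

    out = []
    for j, f in enumerate(features):
        s = scores[j]
        passes = bool(kw_p[j] < alpha and not np.isnan(s) and s >= threshold)
        out.append(LefseResult(f, enriched[j], float(kw_p[j]), float(s), passes))
    return out


def lefse_table(results: list[LefseResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in results])
    return df.sort_values("lda_score", ascending=False, na_position="last").reset_index(drop=True)
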