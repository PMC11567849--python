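"""Behavioral composites and covariate-adjusted correlations.

Two composites mirror the cohort's phenotyping: an episodic-memory z-sum over
four tests (AVLT immediate/short/long recall and visual-reproduction delayed
recall), and a sleep-quality index — the first principal component of five
standardized sleep scales (ISI, AIS, PSQI, SRSS, ESS), oriented so that
higher scores mean better sleep, with a median split defining the low- and
high-sleep-quality groups (CI+LSQ / CI+HSQ).  Brain-behavior associations are
Pearson correlations of residuals after regressing out covariates (age,
education, sex, sleep status), which is the partial correlation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

LOW_QUALITY_LABEL = "CI+LSQ"
HIGH_QUALITY_LABEL = "CI+HSQ"


def composite_memory_z(test_scores: pd.DataFrame) -> pd.Series:
    """Sum of per-test z-scores, referenced to all rows of ``test_scores``.

    The reference population is every row passed in — in the intended use all
    subjects at both sessions pooled, which keeps pre and post scores on one
    scale.  Raises if any test has zero variance (z undefined).
    """
    scores = test_scores.astype(float)
    if len(scores) < 3:
        raise ValueError("need at least 3 subjects to form z-scores")
    sd = scores.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"test(s) with zero variance: {list(zero.index)}")
    z = (scores - scores.mean(axis=0)) / sd
    out = z.sum(axis=1)
    out.name = "memory_composite"
    return out


def sleep_pca_split(
    scale_totals: pd.DataFrame, orient_scale: str = "ISI"
) -> pd.DataFrame:
    """PC1 sleep-quality index and median-split group labels.

    Scales are standardized before PCA; constant scales are dropped with a
    warning (at least two must remain).  PC1's sign is fixed so that the
    loading on ``orient_scale`` (the Insomnia Severity Index by default; the
    first column if absent) is negative — all five scales score sleep
    *badness*, so higher PC1 then means better sleep.  Subjects strictly
    below the median PC1 score are labelled CI+LSQ, the rest CI+HSQ; with an
    even number of distinct scores this splits the cohort in half.
    """
    scales = scale_totals.astype(float)
    if len(scales) < 4:
        raise ValueError("need at least 4 subjects for the PCA split")
    sd = scales.std(axis=0, ddof=1)
    constant = list(sd[sd == 0].index)
    if constant:
        warnings.warn(f"dropping constant scale(s): {constant}", stacklevel=2)
        scales = scales.drop(columns=constant)
        sd = sd.drop(index=constant)
    if scales.shape[1] < 2:
        raise ValueError("fewer than two non-constant scales remain")
    z = (scales - scales.mean(axis=0)) / sd
    pca = PCA(n_components=1)
    scores = pca.fit_transform(z.to_numpy())[:, 0]
    loadings = pca.components_[0]
    col = orient_scale if orient_scale in scales.columns else scales.columns[0]
    if loadings[scales.columns.get_loc(col)] > 0:
        scores = -scores
        loadings = -loadings
    median = np.median(scores)
    group = np.where(scores < median, LOW_QUALITY_LABEL, HIGH_QUALITY_LABEL)
    return pd.DataFrame(
        {"pc1_score": scores, "group": group}, index=scale_totals.index
    )


def adjusted_correlation(
    x, y, covariates=None
) -> tuple[float, float, int]:
    """Pearson correlation of x and y after residualizing both on covariates.

    Returns ``(r, p, df)`` with df = n - k - 2 for k covariates; with no
    covariates this is the plain Pearson correlation.  The residualized
    Pearson r equals the partial correlation of x and y given the covariates.
    Raises if a covariate is collinear with x or y to machine precision.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have the same length")
    if covariates is None:
        c = np.empty((n, 0))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
    k = c.shape[1]
    if n <= k + 3:
        raise ValueError(f"need more than k + 3 = {k + 3} observations")
    design = np.column_stack([np.ones(n), c])

    def _resid(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    rx, ry = _resid(x), _resid(y)
    tol = np.finfo(float).eps * n * 100
    if np.var(rx) <= tol * max(np.var(x), 1.0) or np.var(ry) <= tol * max(np.var(y), 1.0):
        raise ValueError("a covariate is collinear with x or y")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    r_ = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p, df
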