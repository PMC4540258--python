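"""Ordination of FA signatures: standardized PCA and per-component group tests.

Each FA bin's proportion is treated as a variable. By default the PCA is on
the correlation matrix (variables centred and scaled to unit variance), the
default of the common reference implementations; covariance-matrix PCA is
available with ``standardize=False``. Group structure on each retained
component is tested by one-way ANOVA with Tukey's Honest Significant
Differences (Tukey–Kramer for unequal group sizes) for all pairwise
comparisons, using the studentized-range distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import SignatureLibrary

__all__ = ["PCAResult", "run_pca", "fa_component_correlation", "anova_tukey"]

logger = logging.getLogger(__name__)

#: Reporting floor for adjusted p-values (tail accuracy of the
#: studentized-range CDF).
P_FLOOR = 1e-16


@dataclass
class PCAResult:
    """Scores, explained-variance fractions and loadings of a PCA.

    ``loadings`` are unit-norm eigenvectors (columns = components), with the
    sign of each component fixed so its largest-|loading| FA loads
    positively. ``dropped_bins`` lists constant FA columns removed before
    standardization.
    """

    scores: pd.DataFrame  # samples × components
    explained: np.ndarray  # fraction of retained variance per component
    loadings: pd.DataFrame  # FA × components
    eigenvalues: np.ndarray
    standardized: bool
    dropped_bins: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def run_pca(lib: SignatureLibrary, standardize: bool = True) -> PCAResult:
    """PCA of a signature library, one variable per FA bin.

    Constant (zero-variance) bins are dropped with a logged notice — they
    carry no ordination information and break unit scaling. Scores are the
    projections of the centred (and, if ``standardize``, scaled with the n−1
    denominator) data onto the eigenvectors.
    """
    X = lib.matrix()
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    names = list(lib.bin_set.names)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [names[j] for j in np.flatnonzero(~keep)]
    if dropped:
        logger.info("dropping %d constant FA bins before PCA: %s", len(dropped), dropped)
    Xk = X[:, keep]
    kept_names = [names[j] for j in np.flatnonzero(keep)]
    Xc = Xk - Xk.mean(axis=0)
    if standardize:
        Xc = Xc / sd[keep]

    # SVD of the centred/scaled matrix: eigendecomposition of the
    # correlation (or covariance) matrix without forming it.
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S**2 / (n - 1)
    explained = eigvals / eigvals.sum()

    V = Vt.T  # FA × components
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    scores = Xc @ V

    comp_names = [f"PC{k + 1}" for k in range(V.shape[1])]
    ids = [s.sample_id for s in lib.signatures]
    return PCAResult(
        scores=pd.DataFrame(scores, index=ids, columns=comp_names),
        explained=explained,
        loadings=pd.DataFrame(V, index=kept_names, columns=comp_names),
        eigenvalues=eigvals,
        standardized=standardize,
        dropped_bins=dropped,
    )


def fa_component_correlation(pca: PCAResult, lib: SignatureLibrary) -> pd.DataFrame:
    """Pearson correlation of each FA proportion with each component score.

    The correlation quantifies how strongly an FA drives a component (for
    standardized PCA it equals loading × √eigenvalue). Constant FA columns
    get correlation 0 with a logged notice.
    """
    X = lib.matrix()
    S = pca.scores.to_numpy()
    out = np.zeros((X.shape[1], S.shape[1]))
    xsd = X.std(axis=0, ddof=1)
    ssd = S.std(axis=0, ddof=1)
    xc = X - X.mean(axis=0)
    sc = S - S.mean(axis=0)
    n = X.shape[0]
    # score columns of (numerically) zero eigenvalue are closure-induced
    # null directions; their correlations are noise and reported as 0
    score_ok = ssd > 1e-9 * ssd.max()
    for j in range(X.shape[1]):
        if xsd[j] == 0:
            logger.info("FA %s is constant; correlation reported as 0",
                        lib.bin_set.names[j])
            continue
        for k in range(S.shape[1]):
            if not score_ok[k]:
                continue
            out[j, k] = (xc[:, j] @ sc[:, k]) / ((n - 1) * xsd[j] * ssd[k])
    return pd.DataFrame(
        np.clip(out, -1, 1), index=list(lib.bin_set.names), columns=pca.scores.columns
    )


def anova_tukey(
    scores: pd.DataFrame,
    groups: list[str] | np.ndarray,
    n_components: int = 5,
) -> pd.DataFrame:
    """One-way ANOVA per component with Tukey HSD pairwise comparisons.

    For each of the first ``n_components`` score columns, computes the
    pooled within-group mean square and, for every group pair (a, b), the
    Tukey–Kramer statistic

        q = |mean_a − mean_b| / sqrt(MSW/2 · (1/n_a + 1/n_b))

    with adjusted p = P(Q_{k,df} > q) from the studentized-range
    distribution (k groups, df = N − k residual degrees of freedom).
    Singleton groups are allowed; they contribute no residual df. Returns a
    table with columns component, group_a, group_b, mean_diff, p_adj, plus
    per-component F and ANOVA p.
    """
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != scores.shape[0]:
        raise ValueError("one group label per score row required")
    uniq = list(dict.fromkeys(groups))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    ncomp = min(n_components, scores.shape[1])

    ns = np.array([np.sum(groups == g) for g in uniq])
    N, k = len(groups), len(uniq)
    df_resid = N - k
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom (all groups singleton)")

    rows = []
    for comp in scores.columns[:ncomp]:
        y = scores[comp].to_numpy(float)
        means = np.array([y[groups == g].mean() for g in uniq])
        ssw = sum(np.sum((y[groups == g] - m) ** 2) for g, m in zip(uniq, means))
        msw = ssw / df_resid
        grand = y.mean()
        ssb = float(np.sum(ns * (means - grand) ** 2))
        if msw > 0:
            f_stat = (ssb / (k - 1)) / msw
            p_anova = float(stats.f.sf(f_stat, k - 1, df_resid))
        else:  # zero within-group variance: groups either identical or separated
            f_stat = np.inf if ssb > 0 else 0.0
            p_anova = 0.0 if ssb > 0 else 1.0
        for i in range(k):
            for j in range(i + 1, k):
                diff = means[i] - means[j]
                if msw > 0:
                    se = np.sqrt(msw / 2 * (1 / ns[i] + 1 / ns[j]))
                    q = abs(diff) / se
                    p = float(stats.studentized_range.sf(q, k, df_resid))
                else:
                    p = 0.0 if diff != 0 else 1.0
                rows.append(
                    {
                        "component": comp,
                        "group_a": uniq[i],
                        "group_b": uniq[j],
                        "mean_diff": diff,
                        "p_adj": min(max(p, P_FLOOR), 1.0),
                        "F": f_stat,
                        "p_anova": min(max(p_anova, P_FLOOR), 1.0),
                    }
                )
    return pd.DataFrame(rows)
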