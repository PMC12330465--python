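"""Differential presentation/expression testing with mixed imputation.

Missing values in label-free proteomics arise from two mechanisms: features
below the detection limit in a whole condition (missing not at random,
MNAR) and sporadic dropouts (missing at random, MAR). The two are imputed
differently — MNAR cells by random draws from a left-censored normal
(down-shifted, narrowed per-sample distribution; the Perseus/DEP
convention, shift 1.8 sd, width 0.3 sd) and MAR cells by k-nearest
neighbours over feature profiles. Testing uses a moderated two-sample t
statistic with empirical-Bayes variance shrinkage (limma-style), BH FDR
control, and the significance rule fdr < alpha AND |log2FC| > lfc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.impute import KNNImputer
from statsmodels.stats.multitest import multipletests

from .io_formats import SampleSheet

__all__ = [
    "ImputationPlan",
    "classify_missingness",
    "impute_mixed",
    "moderated_t_test",
    "test_differential",
]


@dataclass
class ImputationPlan:
    """Per (feature, condition) missingness class and imputation parameters.

    ``classes`` is a feature x condition frame of {"observed", "MAR",
    "MNAR"}; MNAR means missing in *all* replicates of that condition, MAR
    missing in some but not all.
    """

    classes: pd.DataFrame
    knn_k: int = 10
    shift: float = 1.8
    width: float = 0.3
    seed: int = 0
    dropped_features: list = field(default_factory=list)


def classify_missingness(matrix: pd.DataFrame, sample_sheet: SampleSheet) -> ImputationPlan:
    """Classify each feature x condition cell pattern as observed/MAR/MNAR."""
    cols = {}
    for cond in sample_sheet.conditions:
        samples = sample_sheet.samples_for(cond)
        if len(samples) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
        block = matrix[samples]
        n_missing = block.isna().sum(axis=1)
        cls = pd.Series("observed", index=matrix.index)
        cls[n_missing == len(samples)] = "MNAR"
        cls[(n_missing > 0) & (n_missing < len(samples))] = "MAR"
        cols[cond] = cls
    return ImputationPlan(classes=pd.DataFrame(cols))


def impute_mixed(
    matrix: pd.DataFrame,
    sample_sheet: SampleSheet,
    plan: ImputationPlan | None = None,
    knn_only: bool = False,
) -> tuple[pd.DataFrame, ImputationPlan]:
    """Impute a log2 intensity matrix according to the mixed MNAR/MAR plan.

    MNAR cells are drawn from ``Normal(mu_s - shift*sigma_s,
    (width*sigma_s)^2)`` where ``mu_s, sigma_s`` are the mean and sd of the
    observed log2 values of sample ``s``; MAR cells are filled by k-nearest
    neighbours over feature profiles (features as rows, shared observed
    entries, Euclidean). ``knn_only=True`` routes every missing cell through
    kNN, the mode used for proteome-wide runs. Features missing everywhere
    are dropped and recorded. Deterministic under the plan's seed.
    """
    if plan is None:
        plan = classify_missingness(matrix, sample_sheet)

    all_missing = matrix.isna().all(axis=1)
    dropped = list(matrix.index[all_missing])
    plan.dropped_features = dropped
    work = matrix.loc[~all_missing].copy()
    if not work.isna().any().any():
        return work, plan

    rng = np.random.default_rng(plan.seed)

    if not knn_only:
        mu = work.mean(axis=0, skipna=True)
        sd = work.std(axis=0, ddof=1, skipna=True)
        for cond in sample_sheet.conditions:
            samples = sample_sheet.samples_for(cond)
            mnar_features = plan.classes.index[plan.classes[cond] == "MNAR"]
            mnar_features = mnar_features.intersection(work.index)
            for s in samples:
                k = len(mnar_features)
                if k == 0:
                    continue
                draws = rng.normal(
                    loc=mu[s] - plan.shift * sd[s],
                    scale=plan.width * sd[s],
                    size=k,
                )
                # left-censored draws must stay below the observed range
                draws = np.minimum(draws, work[s].max(skipna=True))
                work.loc[mnar_features, s] = draws

    if work.isna().any().any():
        imputer = KNNImputer(n_neighbors=plan.knn_k, weights="uniform")
        filled = imputer.fit_transform(work.to_numpy(dtype=float))
        work = pd.DataFrame(filled, index=work.index, columns=work.columns)
    return work, plan


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif / x) < 1e-10):
            break
    return x


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-feature variances toward a pooled
    prior (method-of-moments fit of a scaled inverse-chi-square prior on the
    log variances). Returns (posterior variances, prior df, prior var)."""
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = (e.var(ddof=1) if e.size > 1 else 0.0) - special.polygamma(1, df / 2.0)
    if evar > 0:
        df_prior = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
        s2_prior = float(np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)))
        s2_post = (df_prior * s2_prior + df * s2) / (df_prior + df)
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(emean))
        s2_post = np.full_like(s2, s2_prior)
    return s2_post, df_prior, s2_prior


def moderated_t_test(
    x1: np.ndarray, x2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated two-sample t test per feature (rows), groups in columns.

    Pooled per-feature variances are shrunk toward an empirical-Bayes prior
    before forming the t statistic; p-values use the augmented degrees of
    freedom. Returns (log2 fold change x2-x1, t, p)."""
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 replicates")
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    df = float(n1 + n2 - 2)
    s2 = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 /= df
    s2_post, df_prior, _ = _squeeze_var(s2, df)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    lfc = m2 - m1
    t = lfc / se
    df_total = df + (df_prior if np.isfinite(df_prior) else 0.0)
    if not np.isfinite(df_prior):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return lfc, t, p


def test_differential(
    matrix: pd.DataFrame,
    sample_sheet: SampleSheet,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    method: str = "moderated",
) -> pd.DataFrame:
    """Two-condition differential test on a complete log2 matrix.

    ``log2_fc`` is mean(second condition) - mean(first condition) in the
    sample sheet's condition order. ``method`` is ``"moderated"``
    (empirical-Bayes pooled variance) or ``"welch"``. Significance requires
    ``fdr < alpha`` and ``|log2_fc| > lfc_threshold``.
    """
    conds = sample_sheet.conditions
    if len(conds) != 2:
        raise ValueError(f"exactly 2 conditions required, got {conds}")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values: impute first")
    g1 = matrix[sample_sheet.samples_for(conds[0])].to_numpy(dtype=float)
    g2 = matrix[sample_sheet.samples_for(conds[1])].to_numpy(dtype=float)

    if method == "moderated":
        lfc, t, p = moderated_t_test(g1, g2)
    elif method == "welch":
        res = stats.ttest_ind(g2, g1, axis=1, equal_var=False)
        t, p = res.statistic, res.pvalue
        lfc = g2.mean(axis=1) - g1.mean(axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")

    p = np.clip(p, np.nextafter(0, 1), 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2_fc": lfc,
            "t": t,
            "p_value": p,
            "fdr": fdr,
        },
        index=matrix.index,
    )
    out["significant"] = (out["fdr"] < alpha) & (out["log2_fc"].abs() > lfc_threshold)
    return out
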