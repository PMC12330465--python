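"""Intratumoral heterogeneity of antigen presentation.

Per-feature variability across samples is scored as IQR/mean (scale-free,
so it is insensitive to the absolute pseudocount or copy-number level); the
relation between antigen variability and the variability of the matched
source proteins, and the per-sample concordance between z-scored protein
copies and antigen pseudocounts, quantify how much of the presentation
heterogeneity is explained by protein expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import pearsonr, spearmanr

from .quantify import CopyNumberMatrix, PseudocountMatrix

__all__ = [
    "variability_score",
    "map_antigen_to_protein",
    "variability_concordance",
    "per_sample_concordance",
    "hierarchical_cluster",
    "ConcordanceReport",
    "ClusterResult",
]


def _values(matrix) -> pd.DataFrame:
    if isinstance(matrix, PseudocountMatrix):
        return matrix.pseudocounts
    if isinstance(matrix, CopyNumberMatrix):
        return matrix.copies
    return matrix


def variability_score(
    matrix, min_samples: int = 8, log_space: bool = False
) -> pd.DataFrame:
    """Per-feature IQR divided by mean across the samples where observed.

    Quantiles use linear interpolation between order statistics (the
    ubiquitous "type 7" convention). Features observed in fewer than
    ``min_samples`` samples get a missing score: the IQR of a handful of
    values is unstable.

    Returns a table with columns ``n_observed, mean, iqr, score``.
    """
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    values = _values(matrix)
    if log_space:
        values = np.log2(values)
    arr = values.to_numpy(dtype=float)
    rows = []
    for i, fid in enumerate(values.index):
        v = arr[i]
        v = v[~np.isnan(v)]
        n = v.size
        if n < min_samples:
            rows.append((fid, n, np.nan, np.nan, np.nan))
            continue
        q1, q3 = np.quantile(v, [0.25, 0.75])  # linear interpolation
        mean = float(v.mean())
        iqr = float(q3 - q1)
        score = iqr / mean if mean != 0 else np.nan
        rows.append((fid, n, mean, iqr, score))
    out = pd.DataFrame(
        rows, columns=["feature_id", "n_observed", "mean", "iqr", "score"]
    ).set_index("feature_id")
    return out


def map_antigen_to_protein(
    antigen_meta: pd.DataFrame,
    copies: CopyNumberMatrix,
    by: str = "gene",
) -> pd.DataFrame:
    """Map each antigen to its source protein-group row in the proteome.

    ``antigen_meta`` must carry the search engine's gene (or protein group)
    annotation per antigen. Antigens with no annotation, with a
    multi-mapping annotation (``;``-separated), or whose gene is absent from
    the proteome matrix are excluded and counted.

    Returns a table indexed by antigen with columns ``protein_id, gene,
    status`` where status is one of mapped/unannotated/multi_mapping/
    not_in_proteome — only ``mapped`` rows enter concordance analyses.
    """
    if by not in antigen_meta.columns:
        raise ValueError(f"antigen annotation column {by!r} missing")
    gene_to_pid: dict[str, list[str]] = {}
    meta = copies.feature_meta
    for pid in copies.copies.index:
        g = meta.loc[pid, by] if by in meta.columns else pid
        gene_to_pid.setdefault(str(g), []).append(pid)

    rows = []
    for antigen, g in antigen_meta[by].items():
        g = "" if g is None or (isinstance(g, float) and np.isnan(g)) else str(g)
        if not g:
            rows.append((antigen, None, g, "unannotated"))
        elif ";" in g:
            rows.append((antigen, None, g, "multi_mapping"))
        else:
            pids = gene_to_pid.get(g, [])
            if len(pids) == 1:
                rows.append((antigen, pids[0], g, "mapped"))
            elif len(pids) == 0:
                rows.append((antigen, None, g, "not_in_proteome"))
            else:
                rows.append((antigen, None, g, "multi_mapping"))
    return pd.DataFrame(
        rows, columns=["antigen", "protein_id", "gene", "status"]
    ).set_index("antigen")


@dataclass
class ConcordanceReport:
    per_sample_r: pd.Series  # Pearson r per sample (NaN when < 3 pairs)
    n_pairs: pd.Series


def variability_concordance(
    antigen_var: pd.DataFrame,
    protein_var: pd.DataFrame,
    mapping: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Relate antigen variability scores to source-protein variability.

    Returns the paired table (one row per mapped antigen with both scores
    defined) and both Pearson and Spearman correlations over the pairs.
    """
    mapped = mapping[mapping["status"] == "mapped"]
    rows = []
    for antigen, rec in mapped.iterrows():
        a = antigen_var["score"].get(antigen, np.nan)
        p = protein_var["score"].get(rec["protein_id"], np.nan)
        if np.isfinite(a) and np.isfinite(p):
            rows.append((antigen, rec["protein_id"], rec["gene"], a, p))
    pairs = pd.DataFrame(
        rows, columns=["antigen", "protein_id", "gene", "antigen_score", "protein_score"]
    ).set_index("antigen")
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 mapped pairs, got {len(pairs)}")
    pr = pearsonr(pairs["antigen_score"], pairs["protein_score"])
    sr = spearmanr(pairs["antigen_score"], pairs["protein_score"])
    stats = {
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman_r": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
        "n_pairs": float(len(pairs)),
    }
    return pairs, stats


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row across samples; zero-variance rows are dropped."""
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    keep = sd > 0
    return df.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)


def per_sample_concordance(
    pseudocounts: PseudocountMatrix,
    copies: CopyNumberMatrix,
    mapping: pd.DataFrame,
) -> ConcordanceReport:
    """Within-sample Pearson correlation between z-scored protein copies and
    z-scored antigen pseudocounts over mapped antigen-protein pairs.

    Every feature is z-scored across samples first, so the per-sample r asks
    whether the antigens that are *relatively* high in this sample come from
    proteins that are also relatively high there. Samples with fewer than 3
    complete pairs get a missing r.
    """
    if len(pseudocounts.samples) < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mapped = mapping[mapping["status"] == "mapped"]
    az = _zscore_rows(pseudocounts.pseudocounts)
    pz = _zscore_rows(copies.copies[pseudocounts.samples])

    pairs = [
        (a, rec["protein_id"])
        for a, rec in mapped.iterrows()
        if a in az.index and rec["protein_id"] in pz.index
    ]
    r_out, n_out = {}, {}
    for s in pseudocounts.samples:
        xs, ys = [], []
        for a, pid in pairs:
            x = pz.at[pid, s]
            y = az.at[a, s]
            if np.isfinite(x) and np.isfinite(y):
                xs.append(x)
                ys.append(y)
        n_out[s] = len(xs)
        if len(xs) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
            r_out[s] = float(pearsonr(xs, ys).statistic)
        else:
            r_out[s] = np.nan
    return ConcordanceReport(
        per_sample_r=pd.Series(r_out, name="pearson_r"),
        n_pairs=pd.Series(n_out, name="n_pairs"),
    )


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray  # scipy (n-1, 4) merge table
    leaf_order: list
    labels: list


def hierarchical_cluster(
    matrix: pd.DataFrame,
    axis: int = 0,
    zscore: bool = True,
    method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering (euclidean distance, average linkage).

    ``axis=0`` clusters rows (features), ``axis=1`` clusters columns
    (samples); rows are z-scored first by default, mirroring heatmap
    practice. Missing values must be imputed or filtered beforehand.
    """
    df = matrix if axis == 0 else matrix.T
    if zscore:
        mean = df.mean(axis=1)
        sd = df.std(axis=1, ddof=1).replace(0, 1.0)
        df = df.sub(mean, axis=0).div(sd, axis=0)
    arr = df.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing values present: impute or filter before clustering")
    labels = list(df.index)
    if len(labels) < 2:
        return ClusterResult(np.empty((0, 4)), leaf_order=labels, labels=labels)
    Z = linkage(arr, method=method, metric="euclidean")
    order = [labels[i] for i in leaves_list(Z)]
    return ClusterResult(linkage_matrix=Z, leaf_order=order, labels=labels)
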