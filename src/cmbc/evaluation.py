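"""Bias / SD / rmse summaries of replicated cluster-specific estimates.

For each cluster and estimator (naive c-index, c-mbc) across the R
replications of an experiment:

* bias = mean(estimate - truth)
* sd   = standard deviation of the estimates (R - 1 denominator)
* rmse = sqrt(mean((estimate - truth)^2))   (R denominator)

so that the identity ``rmse^2 = bias^2 + sd^2 (R-1)/R`` holds exactly
per cluster.  Clusters are reported sorted by true concordance, with an
unweighted average row appended.  Replications in which a cluster's
c-index is undefined (single outcome class) are excluded pairwise for
that cluster's c-index summaries only, with the count retained.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = ["summarize", "compare_rmse", "format_table"]

AVERAGE_LABEL = "Average"


def _stats(est: np.ndarray, truth: float):
    est = est[np.isfinite(est)]
    r = est.size
    if r == 0:
        return np.nan, np.nan, np.nan, 0
    bias = float(np.mean(est) - truth)
    sd = float(np.std(est, ddof=1)) if r > 1 else 0.0
    rmse = float(np.sqrt(np.mean((est - truth) ** 2)))
    return bias, sd, rmse, r


def summarize(estimates: pd.DataFrame, truths: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster bias/SD/rmse of c-index and c-mbc plus an average row.

    Parameters
    ----------
    estimates : tidy frame with columns ``replication, cluster, c_index,
        c_mbc`` (extra columns ignored).
    truths : frame with columns ``cluster, true_concordance``.
    """
    tmap = truths.set_index("cluster")["true_concordance"]
    rows = []
    for cid, grp in estimates.groupby("cluster", sort=False):
        truth = float(tmap.loc[cid])
        b_ci, sd_ci, rm_ci, r_ci = _stats(grp["c_index"].to_numpy(float), truth)
        b_cm, sd_cm, rm_cm, r_cm = _stats(grp["c_mbc"].to_numpy(float), truth)
        rows.append({
            "cluster": cid, "true_concordance": truth,
            "bias_cindex": b_ci, "bias_cmbc": b_cm,
            "sd_cindex": sd_ci, "sd_cmbc": sd_cm,
            "rmse_cindex": rm_ci, "rmse_cmbc": rm_cm,
            "n_replications_used": r_cm,
            "n_missing_cindex": r_cm - r_ci,
        })
    out = pd.DataFrame(rows).sort_values("true_concordance",
                                         ignore_index=True)
    avg = out.drop(columns=["cluster"]).mean(numeric_only=True)
    avg_row = {"cluster": AVERAGE_LABEL, **avg.to_dict()}
    avg_row["n_replications_used"] = int(out["n_replications_used"].mean())
    avg_row["n_missing_cindex"] = int(out["n_missing_cindex"].sum())
    return pd.concat([out, pd.DataFrame([avg_row])], ignore_index=True)


def compare_rmse(summaries: pd.DataFrame) -> dict:
    """Head-to-head rmse comparison and the shrinkage bias diagnostic.

    Returns per-cluster rmse differences (c-index minus c-mbc, positive
    means the c-mbc wins), the number of clusters the c-mbc wins, and
    the Spearman correlation between the c-mbc bias and the deviation of
    the cluster truth from the average truth — shrinkage pulls estimates
    toward the overall mean, so this correlation is expected negative.
    """
    per = summaries[summaries["cluster"] != AVERAGE_LABEL].copy()
    per["rmse_diff"] = per["rmse_cindex"] - per["rmse_cmbc"]
    mean_truth = per["true_concordance"].mean()
    dev = per["true_concordance"] - mean_truth
    if per["bias_cmbc"].nunique() > 1 and dev.nunique() > 1:
        corr = float(spearmanr(per["bias_cmbc"], dev).statistic)
    else:
        corr = np.nan
    return {
        "per_cluster": per[["cluster", "true_concordance", "rmse_cindex",
                            "rmse_cmbc", "rmse_diff", "bias_cmbc"]],
        "avg_rmse_cindex": float(per["rmse_cindex"].mean()),
        "avg_rmse_cmbc": float(per["rmse_cmbc"].mean()),
        "avg_rmse_diff": float(per["rmse_diff"].mean()),
        "n_clusters_cmbc_wins": int((per["rmse_diff"] > 0).sum()),
        "n_clusters": int(len(per)),
        "bias_truth_spearman": corr,
    }


def format_table(summaries: pd.DataFrame, decimals: int = 3) -> str:
    """Aligned text rendering of the summary, 3 decimals like the reports."""
    df = summaries.copy()
    num = [c for c in df.columns if c.startswith(("true", "bias", "sd", "rmse"))]
    df[num] = df[num].round(decimals)
    return df.to_string(index=False)
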