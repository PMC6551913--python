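"""Three-panel forest plots of per-cluster calibration and discrimination.

Closed dots: independent (fixed-effect) per-cluster estimates with 95%
intervals.  Open dots: shrunken random-effect estimates (conditional
modes) and the c-mbc.  Optional gray squares mark simulation truths.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["forest_panels"]


def _panel(ax, ypos, point_a, lo_a, hi_a, point_b, lo_b, hi_b, truth,
           vline, title):
    ax.errorbar(point_a, ypos + 0.18,
                xerr=[point_a - lo_a, hi_a - point_a], fmt="o", color="black",
                markersize=3.5, elinewidth=0.8, capsize=0, label="fixed")
    ax.errorbar(point_b, ypos - 0.18,
                xerr=[point_b - lo_b, hi_b - point_b], fmt="o", color="black",
                markerfacecolor="white", markersize=3.5, elinewidth=0.8,
                capsize=0, label="random")
    if truth is not None:
        ax.plot(truth, ypos, "s", color="0.6", markersize=3, label="truth")
    if vline is not None:
        ax.axvline(vline, color="0.4", linewidth=0.8)
    ax.set_title(title, fontsize=10)
    ax.invert_yaxis()


def forest_panels(fixed_df, random_df, disc_df, truths_df=None, path=None,
                  pooled=None):
    """Write a three-panel (intercept, slope, concordance) forest plot.

    Parameters
    ----------
    fixed_df, random_df : frames with ``cluster, gamma0, gamma1, se0, se1``.
    disc_df : frame with ``cluster, n, c_index, c_index_lo/hi, c_mbc,
        c_mbc_lo/hi``.
    truths_df : optional frame with ``cluster, gamma0_true, gamma1_true,
        true_concordance``.
    pooled : optional dict with ``gamma0, gamma1, concordance`` vertical
        reference lines.
    """
    f = fixed_df.set_index("cluster")
    r = random_df.set_index("cluster")
    d = disc_df.set_index("cluster")
    clusters = list(d.index)
    ypos = np.arange(len(clusters), dtype=float)
    t = truths_df.set_index("cluster") if truths_df is not None else None
    pooled = pooled or {}

    fig, axes = plt.subplots(1, 3, figsize=(10, max(3.0, 0.22 * len(clusters))),
                             sharey=True)
    for ax, (col, se, dcol, title) in zip(axes, [
        ("gamma0", "se0", None, "calibration intercept"),
        ("gamma1", "se1", None, "calibration slope"),
        (None, None, ("c_index", "c_mbc"), "concordance"),
    ]):
        if col is not None:
            pa = f.loc[clusters, col].to_numpy(float)
            sa = f.loc[clusters, se].to_numpy(float)
            pb = r.loc[clusters, col].to_numpy(float)
            sb = r.loc[clusters, se].to_numpy(float)
            truth = (t[f"{col}_true"].loc[clusters].to_numpy(float)
                     if t is not None else None)
            _panel(ax, ypos, pa, pa - 1.96 * sa, pa + 1.96 * sa,
                   pb, pb - 1.96 * sb, pb + 1.96 * sb, truth,
                   pooled.get(col), title)
        else:
            ca, cb = dcol
            pa = d.loc[clusters, ca].to_numpy(float)
            la = d.loc[clusters, f"{ca}_lo"].to_numpy(float)
            ha = d.loc[clusters, f"{ca}_hi"].to_numpy(float)
            pb = d.loc[clusters, cb].to_numpy(float)
            lb = d.loc[clusters, f"{cb}_lo"].to_numpy(float)
            hb = d.loc[clusters, f"{cb}_hi"].to_numpy(float)
            truth = (t["true_concordance"].loc[clusters].to_numpy(float)
                     if t is not None and "true_concordance" in t else None)
            _panel(ax, ypos, pa, np.where(np.isfinite(la), la, pa),
                   np.where(np.isfinite(ha), ha, pa), pb,
                   np.where(np.isfinite(lb), lb, pb),
                   np.where(np.isfinite(hb), hb, pb), truth,
                   pooled.get("concordance"), title)
    axes[0].set_yticks(ypos)
    axes[0].set_yticklabels([str(c) for c in clusters], fontsize=7)
    axes[0].set_ylabel("cluster")
    if "n" in d.columns:
        ax2 = axes[2].twinx()
        ax2.set_ylim(axes[2].get_ylim())
        ax2.set_yticks(ypos)
        ax2.set_yticklabels([str(int(v)) for v in d.loc[clusters, "n"]],
                            fontsize=7)
        ax2.set_ylabel("n")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
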