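"""Clustered validation data: container, validation and CSV/TSV I/O.

The unit of analysis is a patient row with a cluster label (e.g. the
treating center), the linear predictor ``z`` of an existing logistic
prediction model on the log-odds scale *excluding* the model intercept,
and a binary outcome ``y``.  The original model intercept ``beta0``
travels with the dataset because it enters every downstream fit as a
fixed offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClusteredDataset", "read_clustered_csv"]


@dataclass
class ClusteredDataset:
    """Patient-level validation data grouped in clusters.

    Parameters
    ----------
    cluster : array-like
        Cluster label per row (any hashable labels).
    z : array-like of float
        Linear predictor per row, log-odds scale, excluding the model
        intercept.
    y : array-like of {0, 1}
        Binary outcome per row.
    beta0 : float
        Intercept of the original prediction model (log-odds), used as a
        fixed offset in all recalibration fits.
    """

    cluster: np.ndarray
    z: np.ndarray
    y: np.ndarray
    beta0: float = 0.0

    # derived, set in __post_init__
    clusters_: np.ndarray = field(init=False, repr=False)
    _codes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        self.y = np.asarray(self.y).ravel()
        self.cluster = np.asarray(self.cluster).ravel()
        if not (len(self.cluster) == len(self.z) == len(self.y)):
            raise ValueError("cluster, z and y must have equal length")
        if len(self.z) == 0:
            raise ValueError("empty dataset")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("linear predictors must be finite")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("outcomes must be binary (0/1)")
        self.y = self.y.astype(np.int8)
        if not np.isfinite(self.beta0):
            raise ValueError("beta0 must be finite")
        self.clusters_, self._codes = np.unique(self.cluster, return_inverse=True)
        sizes = np.bincount(self._codes)
        if sizes.min() < 2:
            small = self.clusters_[sizes < 2]
            raise ValueError(f"every cluster needs >= 2 rows; too small: {list(small)}")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters_)

    @property
    def n(self) -> int:
        return len(self.z)

    def cluster_sizes(self) -> pd.Series:
        return pd.Series(np.bincount(self._codes), index=self.clusters_, name="n")

    def cluster_events(self) -> pd.Series:
        ev = np.bincount(self._codes, weights=self.y.astype(float)).astype(int)
        return pd.Series(ev, index=self.clusters_, name="n_events")

    def sorted_by_cluster(self):
        """Rows sorted by cluster code plus reduceat group starts.

        Returns ``(codes, z, y, starts)`` with ``starts`` the first row
        index of each cluster in the sorted arrays; the fitting routines
        consume this layout directly.
        """
        order = np.argsort(self._codes, kind="stable")
        codes = self._codes[order]
        starts = np.concatenate(([0], np.flatnonzero(np.diff(codes)) + 1))
        return codes, self.z[order], self.y[order], starts

    def subset(self, keep_clusters) -> "ClusteredDataset":
        keep = np.isin(self.cluster, np.asarray(list(keep_clusters)))
        return ClusteredDataset(self.cluster[keep], self.z[keep], self.y[keep], self.beta0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cluster": self.cluster, "lp": self.z, "y": self.y})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, beta0: float = 0.0,
                   cluster_col: str = "cluster", lp_col: str = "lp",
                   y_col: str = "y") -> "ClusteredDataset":
        missing = [c for c in (cluster_col, lp_col, y_col) if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}; present: {list(df.columns)}")
        return cls(df[cluster_col].to_numpy(), df[lp_col].to_numpy(),
                   df[y_col].to_numpy(), beta0)


def read_clustered_csv(path, beta0: float = 0.0, cluster_col: str = "cluster",
                       lp_col: str = "lp", y_col: str = "y") -> ClusteredDataset:
    """Read a clustered validation dataset from delimited text.

    The delimiter is auto-detected between comma and tab from the header
    line.  Unparseable numeric entries are reported with their line
    numbers (1-based, header included).
    """
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty file")
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={cluster_col: str}, skip_blank_lines=False)
    for col, kind in ((lp_col, float), (y_col, int)):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}'; found {list(df.columns)}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna().to_numpy() & df[col].notna().to_numpy())
        bad = np.union1d(bad, np.flatnonzero(df[col].isna().to_numpy()))
        if bad.size:
            lines = (bad + 2).tolist()  # +1 header, +1 one-based
            raise ValueError(f"{path}: unparseable '{col}' values on lines {lines[:20]}")
        df[col] = coerced
    return ClusteredDataset.from_frame(df, beta0, cluster_col, lp_col, y_col)
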