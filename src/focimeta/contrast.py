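"""Cluster-by-label contingency analysis.

After the pooled foci are partitioned into K spatial clusters, the question is
which clusters are biased toward one condition.  The stage cross-tabulates
cluster membership against the binary condition label, tests independence with
Pearson's chi-square (no continuity correction, df = K-1), and characterises
each cluster with its Haberman adjusted standardized residual

    r = (O - E) / sqrt(E (1 - row_total/N) (1 - col_total/N)),

which is approximately standard normal per cell under independence.  For a
two-column table the two cells of a row carry the same |r| with opposite
signs, so one two-sided normal p-value per cluster summarises it.  Clusters
are then tagged:

* ``label1_dominant`` / ``label0_dominant`` - p below ``sig_alpha`` (default
  0.1), sign of the label-1 residual deciding the direction;
* ``overlapped`` - p above ``overlap_p`` (default 0.45): the two conditions
  are statistically indistinguishable there, and such clusters' foci are
  removed ("flag 2") before classification;
* ``undetermined`` - everything in between.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import (
    ConfigError,
    DegenerateTableError,
    EmptyInputError,
    ValidationError,
)

logger = logging.getLogger(__name__)

ROLES = ("label1_dominant", "label0_dominant", "overlapped", "undetermined")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    dof: int
    pvalue: float


def make_contingency(cluster_ids, n_label1, n_label0) -> pd.DataFrame:
    """Assemble a K x 2 count table (index cluster id, columns label1/label0)."""
    table = pd.DataFrame(
        {"label1": np.asarray(n_label1, dtype=int),
         "label0": np.asarray(n_label0, dtype=int)},
        index=pd.Index(cluster_ids, name="cluster_id"),
    )
    if (table.to_numpy() < 0).any():
        raise ValidationError("contingency counts must be non-negative")
    return table


def build_contingency(assignments, labels) -> pd.DataFrame:
    """Cross-tabulate per-focus cluster assignments against binary labels.

    Cluster ids appear in order of first appearance; clusters may have a zero
    total only if explicitly present in a categorical input (a warning is
    logged).
    """
    assignments = pd.Series(assignments)
    labels = pd.Series(labels)
    if len(assignments) != len(labels):
        raise ValidationError(
            f"length mismatch: {len(assignments)} assignments vs {len(labels)} labels"
        )
    if len(assignments) == 0:
        raise EmptyInputError("no foci to tabulate")
    if not labels.isin([0, 1]).all():
        raise ValidationError("labels must be binary (0 or 1)")
    order = assignments.drop_duplicates().tolist()
    ct = pd.crosstab(assignments, labels).reindex(order, fill_value=0)
    for lab in (0, 1):
        if lab not in ct.columns:
            ct[lab] = 0
    table = make_contingency(ct.index, ct[1].to_numpy(), ct[0].to_numpy())
    empty = table.index[table.sum(axis=1) == 0]
    if len(empty):
        logger.warning("clusters with zero total retained: %s", list(empty))
    return table


def _check_margins(table: pd.DataFrame) -> pd.DataFrame:
    if table[["label1", "label0"]].to_numpy().sum() == 0:
        raise DegenerateTableError("empty contingency table")
    col = table[["label1", "label0"]].sum(axis=0)
    if (col == 0).any():
        raise DegenerateTableError(f"zero column total for {col.index[col == 0].tolist()}")
    nonzero = table[table.sum(axis=1) > 0]
    if len(nonzero) < len(table):
        logger.warning("dropping %d zero-total cluster(s) from the test",
                       len(table) - len(nonzero))
    return nonzero


def expected_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Independence-model expected counts E = row_total * col_total / N."""
    table = _check_margins(table)
    obs = table[["label1", "label0"]].to_numpy(dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return pd.DataFrame(exp, index=table.index, columns=["label1", "label0"])


def chi_square_test(table: pd.DataFrame) -> ChiSquareResult:
    """Pearson chi-square test of cluster/label independence.

    X^2 = sum (O-E)^2/E with no continuity correction; df = K - 1 for a K x 2
    table; upper-tail chi-square p-value.
    """
    table = _check_margins(table)
    obs = table[["label1", "label0"]].to_numpy(dtype=float)
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(statistic=float(stat), dof=int(dof), pvalue=float(p))


def adjusted_residuals(table: pd.DataFrame) -> pd.DataFrame:
    """Haberman adjusted standardized residuals and per-cluster p-values.

    Returns a frame indexed by cluster id with ``residual_label1``,
    ``residual_label0`` (equal magnitude, opposite sign) and the two-sided
    normal ``p_value`` of the label-1 cell.
    """
    table = _check_margins(table)
    obs = table[["label1", "label0"]].to_numpy(dtype=float)
    n = obs.sum()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    exp = np.outer(row, col) / n
    denom = np.sqrt(exp * (1 - row[:, None] / n) * (1 - col[None, :] / n))
    res = (obs - exp) / denom
    p = 2 * stats.norm.sf(np.abs(res[:, 0]))
    return pd.DataFrame(
        {"residual_label1": res[:, 0], "residual_label0": res[:, 1], "p_value": p},
        index=table.index,
    )


def classify_clusters(report: pd.DataFrame, sig_alpha: float = 0.1,
                      overlap_p: float = 0.45) -> pd.DataFrame:
    """Fill the per-cluster role tag from residual p-values and signs."""
    if overlap_p <= sig_alpha:
        raise ConfigError(
            f"overlap_p ({overlap_p}) must exceed sig_alpha ({sig_alpha})"
        )
    out = report.copy()
    p = out["p_value"].to_numpy()
    r1 = out["residual_label1"].to_numpy()
    role = np.where(
        (p < sig_alpha) & (r1 > 0), "label1_dominant",
        np.where((p < sig_alpha) & (r1 < 0), "label0_dominant",
                 np.where(p > overlap_p, "overlapped", "undetermined")),
    )
    out["role"] = role
    return out


def filter_overlapped(foci: pd.DataFrame, report: pd.DataFrame) -> pd.DataFrame:
    """Drop foci belonging to overlapped clusters (the "flag 2" elimination).

    ``foci`` must carry a ``cluster_id`` column; the returned copy keeps only
    rows whose cluster is not tagged ``overlapped``.  The removed rows are
    available via ``result.attrs['removed']`` and surviving per-label counts
    are logged.
    """
    if "role" not in report.columns:
        raise ValidationError("report has no role tags; run classify_clusters first")
    if "cluster_id" not in foci.columns:
        raise ValidationError("foci table has no cluster_id column")
    overlapped = set(report.index[report["role"] == "overlapped"])
    flagged = foci["cluster_id"].isin(overlapped)
    out = foci.loc[~flagged].copy()
    if len(out) == 0:
        raise EmptyInputError("all clusters are overlapped; nothing survives")
    removed = foci.loc[flagged].copy()
    removed["flag"] = 2
    out.attrs["removed"] = removed
    if "label" in out.columns:
        logger.info(
            "overlap filter: %d foci survive (%d label-1, %d label-0), %d removed",
            len(out), int((out["label"] == 1).sum()), int((out["label"] == 0).sum()),
            len(removed),
        )
    return out


class ClusterContrast(BaseEstimator):
    """Cluster-by-label independence analysis as a scikit-learn estimator.

    ``fit(assignments, labels)`` cross-tabulates, tests independence and tags
    every cluster; ``transform(foci)`` then removes the overlapped clusters'
    rows.  All results live in trailing-underscore attributes.

    Parameters
    ----------
    sig_alpha : float, default 0.1
        Two-sided significance level below which a cluster is label-dominant.
    overlap_p : float, default 0.45
        p-value above which a cluster counts as overlapped (condition mix
        indistinguishable) and is eliminated.

    Attributes
    ----------
    contingency_ : pandas.DataFrame
        K x 2 count table.
    chi2_, dof_, pvalue_ : float, int, float
        Pearson test of independence.
    report_ : pandas.DataFrame
        Adjusted residuals, per-cluster p-values and role tags.
    """

    def __init__(self, sig_alpha: float = 0.1, overlap_p: float = 0.45):
        self.sig_alpha = sig_alpha
        self.overlap_p = overlap_p

    def fit(self, X, y):
        """Fit from per-focus cluster assignments X and binary labels y."""
        table = build_contingency(np.asarray(X).ravel(), np.asarray(y).ravel())
        return self.fit_table(table)

    def fit_table(self, table: pd.DataFrame):
        """Fit directly from a K x 2 count table (index cluster_id)."""
        result = chi_square_test(table)
        report = classify_clusters(
            adjusted_residuals(table), self.sig_alpha, self.overlap_p
        )
        self.contingency_ = table
        self.chi2_ = result.statistic
        self.dof_ = result.dof
        self.pvalue_ = result.pvalue
        self.report_ = report
        return self

    def transform(self, foci: pd.DataFrame) -> pd.DataFrame:
        """Remove foci that fall in overlapped clusters."""
        return filter_overlapped(foci, self.report_)

    def roles(self, role: str) -> list:
        """Cluster ids carrying a given role tag."""
        if role not in ROLES:
            raise ConfigError(f"unknown role {role!r}; one of {ROLES}")
        return list(self.report_.index[self.report_["role"] == role])
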