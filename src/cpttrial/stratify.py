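"""Responder stratification: cutoff classes, Ward clustering, agreement.

Subjects are labeled by a quadrant rule on their (untreated, treated)
severity pair, then independently clustered with Ward's minimum-variance
method (the squared-distance "D2" convention) so the two labelings can
be cross-tabulated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "CLASS_NAMES",
    "StratificationResult",
    "classify_manual",
    "classify_table",
    "ward_cluster",
    "compare_classifications",
    "stratify_trial",
]

#: Canonical order of the four response classes.
CLASS_NAMES = ("adverse_responder", "non_responder", "asymptomatic", "responder")

DEFAULT_CUTOFF = 0.5
DEFAULT_K = 3


def classify_manual(
    ci_untreated: float, ci_treated: float, cutoff: float = DEFAULT_CUTOFF
) -> str:
    """Quadrant rule on the paired severity scores.

    "High" means CI >= cutoff (the boundary counts as high).  Low/low is
    asymptomatic, high/low a responder, high/high a non-responder and
    low/high an adverse responder.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff {cutoff} outside (0, 1)")
    for name, val in (("ci_untreated", ci_untreated), ("ci_treated", ci_treated)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name}={val} outside [0, 1]")
    high_u = ci_untreated >= cutoff
    high_t = ci_treated >= cutoff
    if high_u and high_t:
        return "non_responder"
    if high_u:
        return "responder"
    if high_t:
        return "adverse_responder"
    return "asymptomatic"


def classify_table(trial: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> pd.Series:
    """Apply :func:`classify_manual` to every row of a trial table."""
    return pd.Series(
        [
            classify_manual(u, t, cutoff)
            for u, t in zip(trial["ci_u"], trial["ci_t"])
        ],
        index=trial.index,
        name="manual_class",
    )


def ward_cluster(points: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative Ward clustering of 2-D severity pairs.

    Returns ``(labels, merge_history)`` where labels are 1..k and the
    merge history is the standard (n-1) x 4 linkage matrix.  Uses
    Euclidean distances with the Ward criterion (merge cost equals the
    increase in within-cluster sum of squares).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    if not np.all(np.isfinite(points)):
        raise ValueError("non-finite coordinates in clustering input")
    if k < 1 or k > n:
        raise ValueError(f"cluster count k={k} outside 1..{n}")
    if n == 1:
        return np.array([1]), np.empty((0, 4))
    Z = linkage(points, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return labels, Z


@dataclass(frozen=True)
class StratificationResult:
    table: pd.DataFrame          # trial table + manual_class + cluster_label
    cutoff: float
    k: int
    merge_history: np.ndarray    # scipy linkage matrix
    confusion: pd.DataFrame      # clusters x manual classes
    cluster_to_class: dict[int, str]

    @property
    def class_counts(self) -> dict[str, int]:
        counts = Counter(self.table["manual_class"])
        return {name: int(counts.get(name, 0)) for name in CLASS_NAMES}


def compare_classifications(
    manual: pd.Series | np.ndarray, clusters: np.ndarray
) -> tuple[pd.DataFrame, dict[int, str], int]:
    """Cross-tabulate cluster labels against manual classes.

    Each cluster is matched to its majority manual class (ties broken
    toward the larger manual class overall); returns the contingency
    table, the cluster-to-class map, and the count of subjects whose
    manual class differs from their cluster's majority class.
    """
    manual = np.asarray(manual)
    clusters = np.asarray(clusters)
    if len(manual) != len(clusters):
        raise ValueError("label vectors differ in length")
    confusion = pd.crosstab(
        pd.Series(clusters, name="cluster"), pd.Series(manual, name="manual_class")
    )
    class_sizes = Counter(manual)
    mapping: dict[int, str] = {}
    for cluster in confusion.index:
        row = confusion.loc[cluster]
        top = row.max()
        candidates = [c for c in row.index if row[c] == top]
        mapping[int(cluster)] = max(candidates, key=lambda c: class_sizes[c])
    mismatches = int(
        sum(m != mapping[int(c)] for m, c in zip(manual, clusters))
    )
    return confusion, mapping, mismatches


def stratify_trial(
    trial: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    k: int = DEFAULT_K,
) -> StratificationResult:
    """Label, cluster, and cross-tabulate a completed trial table."""
    table = trial.copy()
    table["manual_class"] = classify_table(table, cutoff)
    points = table[["ci_u", "ci_t"]].to_numpy()
    labels, Z = ward_cluster(points, k)
    table["cluster_label"] = labels
    confusion, mapping, _ = compare_classifications(table["manual_class"], labels)
    return StratificationResult(
        table=table,
        cutoff=cutoff,
        k=k,
        merge_history=Z,
        confusion=confusion,
        cluster_to_class=mapping,
    )
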