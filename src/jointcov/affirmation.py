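"""Candidate affirmation by hierarchical clustering and correlation cliques.

Candidate probes (the union of selected individuals and pair members) are
characterised by their combined-projection values across patients.  After
per-row z-scoring, probes are clustered by complete-linkage agglomeration
under the centred-Pearson distance d = 1 - r, and the tree is cut into k
cliques (default 4).  Samples can be clustered the same way on the sample
axis (k = 2) to count how many patients land in the wrong phenotype
cluster.  Candidate pairs are then annotated by whether their two members
fall in different cliques — the cross-clique pairs are the interesting
ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .io import PhenotypeLabels


@dataclass
class CliqueAssignment:
    """Probe clique membership plus the clustering evidence behind it."""

    probe_ids: list[str]
    cluster_of: np.ndarray          # 1-based clique index per probe
    merge_tree: np.ndarray          # scipy linkage matrix, (n-1, 4)
    correlations: np.ndarray        # probe x probe centred-Pearson matrix

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for pid, c in zip(self.probe_ids, self.cluster_of):
            out.setdefault(int(c), []).append(pid)
        return out

    def clique_of(self, probe_id: str) -> int:
        try:
            return int(self.cluster_of[self.probe_ids.index(probe_id)])
        except ValueError:
            raise KeyError(f"probe {probe_id!r} not in assignment") from None


def zscore_rows(matrix: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Standardise each row to mean 0, sample (ddof=1) standard deviation 1.

    Zero-variance rows are centred only and reported in the returned flag
    list rather than raising.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2:
        raise ValidationError("expected a 2D matrix")
    means = M.mean(axis=1, keepdims=True)
    sds = M.std(axis=1, ddof=1, keepdims=True)
    flagged = [int(i) for i in np.flatnonzero(sds.ravel() == 0.0)]
    safe = np.where(sds == 0.0, 1.0, sds)
    return (M - means) / safe, flagged


def centered_pearson_distance(a: np.ndarray, b: np.ndarray) -> float:
    """d = 1 - r with r the Pearson correlation of the mean-centred vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.sqrt(ac @ ac)
    nb = np.sqrt(bc @ bc)
    if na == 0.0 or nb == 0.0:
        raise ValidationError("centred-Pearson distance undefined for constant input")
    return float(1.0 - (ac @ bc) / (na * nb))


def correlation_matrix(rows: np.ndarray) -> np.ndarray:
    R = np.corrcoef(np.asarray(rows, dtype=float))
    return np.clip(np.atleast_2d(R), -1.0, 1.0)


def hcluster_complete(
    matrix: np.ndarray,
    ids: list[str] | None = None,
    n_clusters: int = 4,
    axis: str = "rows",
) -> CliqueAssignment:
    """Complete-linkage tree over centred-Pearson distances, cut at k clusters.

    ``axis='columns'`` clusters the column profiles instead (used for the
    sample-axis clustering).  Requires at least 2 items and non-constant
    profiles.
    """
    M = np.asarray(matrix, dtype=float)
    if axis == "columns":
        M = M.T
    elif axis != "rows":
        raise ValidationError("axis must be 'rows' or 'columns'")
    n = M.shape[0]
    if n < 2:
        raise ValidationError("clustering needs at least 2 items")
    if (M.std(axis=1) == 0.0).any():
        raise ValidationError("constant profile: centred-Pearson distance undefined")
    if not 1 <= n_clusters <= n:
        raise ValidationError(f"cannot cut {n} items into {n_clusters} clusters")
    R = correlation_matrix(M)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="complete")
    labels_ = fcluster(Z, t=n_clusters, criterion="maxclust")
    if ids is None:
        ids = [str(i) for i in range(n)]
    return CliqueAssignment(list(ids), labels_, Z, R)


def cross_clique_pairs(
    candidate_pairs: list[tuple[str, str]],
    assignment: CliqueAssignment,
    scores: list | np.ndarray | None = None,
) -> pd.DataFrame:
    """Annotate candidate pairs with their members' cliques.

    Returns a frame sorted with cross-clique pairs first, then by total
    score descending (when given).  Every pair member must appear in the
    assignment; unknown probes raise ``KeyError``.
    """
    rows = []
    for i, (a, b) in enumerate(candidate_pairs):
        ca = assignment.clique_of(a)
        cb = assignment.clique_of(b)
        rows.append({
            "feature_a": a, "feature_b": b,
            "clique_a": ca, "clique_b": cb,
            "is_cross_clique": ca != cb,
            "total_score": (scores[i] if scores is not None else np.nan),
        })
    df = pd.DataFrame(rows, columns=["feature_a", "feature_b", "clique_a",
                                     "clique_b", "is_cross_clique", "total_score"])
    return df.sort_values(
        ["is_cross_clique", "total_score"], ascending=[False, False], kind="stable"
    ).reset_index(drop=True)


def sample_separation_report(
    matrix: np.ndarray, labels: PhenotypeLabels
) -> int:
    """Misclassified-sample count under the sample-axis clustering.

    Columns of ``matrix`` (features x samples) are clustered into two groups
    and matched to the phenotype labels in whichever of the two ways gives
    fewer mismatches; the mismatch count is returned.
    """
    assign = hcluster_complete(matrix, n_clusters=2, axis="columns")
    c = assign.cluster_of
    y = labels.y
    mis_a = int(((c == 1) & (y == 1)).sum() + ((c == 2) & (y == 0)).sum())
    mis_b = int(((c == 1) & (y == 0)).sum() + ((c == 2) & (y == 1)).sum())
    return min(mis_a, mis_b)


def merge_tree_frame(assignment: CliqueAssignment) -> pd.DataFrame:
    """Merge sequence as a (node, node, height, size) table for TSV export."""
    Z = assignment.merge_tree
    return pd.DataFrame({
        "node_a": Z[:, 0].astype(int),
        "node_b": Z[:, 1].astype(int),
        "height": Z[:, 2],
        "n_members": Z[:, 3].astype(int),
    })


def to_newick(assignment: CliqueAssignment) -> str:
    """Merge tree as a Newick string with heights as branch lengths."""
    Z = assignment.merge_tree
    names = assignment.probe_ids
    n = len(names)
    height = {i: 0.0 for i in range(n)}
    rep = {i: names[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        rep[n + k] = f"({rep[a]}:{la:g},{rep[b]}:{lb:g})"
        height[n + k] = h
    return rep[n + len(Z) - 1] + ";"
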