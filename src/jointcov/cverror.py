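"""Repeated stratified 70/30 cross-validation of the Fisher classifiers.

The boundary-based half of the integrative hypothesis test: for every probe
(2D tumour/normal classifier) and every probe pair (second-stage classifier
on combined-projection scalars), the mean balanced classification error over
many random stratified splits is computed.  Per split, floor(0.7 * n_g)
patients of each group train and the rest test; the split sequence is shared
across features within a run so feature errors are comparable.

Two evaluation modes exist for individual probes.  In the default
("faithful") mode the combined-projection classifier is the one fitted once
on all patients, and cross-validation only averages its balanced error over
the random test subsets.  With ``refit_combined=True`` the 2D discriminant
is refitted inside each training split for leakage-free evaluation.  Pair
classifiers always refit the second stage on the training split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import SplitError, ValidationError
from .io import ExpressionTriplet, PhenotypeLabels
from .projection import ProjectionModel, combined_projection, fisher_batch


@dataclass
class CvConfig:
    n_splits: int = 500
    train_fraction: float = 0.7
    seed: int = 0
    refit_combined: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction must lie in (0, 1)")
        if self.n_splits < 1:
            raise ValidationError("n_splits must be >= 1")


class CvResult(NamedTuple):
    mean_error: float
    n_effective: int
    skip_ratio: float


class SplitMatrices(NamedTuple):
    """Per-group train/test index matrices, one row per split."""

    train_g1: np.ndarray
    train_g2: np.ndarray
    test_g1: np.ndarray
    test_g2: np.ndarray


def split_matrices(labels: PhenotypeLabels, config: CvConfig) -> SplitMatrices:
    """Stratified split index matrices shared by all features of a run."""
    g1 = labels.g1_indices
    g2 = labels.g2_indices
    a = int(np.floor(config.train_fraction * len(g1)))
    b = int(np.floor(config.train_fraction * len(g2)))
    if min(a, b) < 1 or a >= len(g1) or b >= len(g2):
        raise SplitError(
            f"groups of size {len(g1)}/{len(g2)} cannot form non-empty "
            f"train and test sets at fraction {config.train_fraction}"
        )
    rng = np.random.default_rng(config.seed)
    S = config.n_splits
    tr1 = np.empty((S, a), dtype=int)
    tr2 = np.empty((S, b), dtype=int)
    te1 = np.empty((S, len(g1) - a), dtype=int)
    te2 = np.empty((S, len(g2) - b), dtype=int)
    for s in range(S):
        p1 = rng.permutation(g1)
        p2 = rng.permutation(g2)
        tr1[s], te1[s] = p1[:a], p1[a:]
        tr2[s], te2[s] = p2[:b], p2[b:]
    return SplitMatrices(tr1, tr2, te1, te2)


def stratified_splits(labels: PhenotypeLabels, config: CvConfig):
    """Sequence of (train indices, test indices) per split, patient-indexed."""
    m = split_matrices(labels, config)
    return [
        (np.concatenate([m.train_g1[s], m.train_g2[s]]),
         np.concatenate([m.test_g1[s], m.test_g2[s]]))
        for s in range(m.train_g1.shape[0])
    ]


def batched_fisher_errors(
    X: np.ndarray, splits: SplitMatrices
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced test error of a refitted 2D Fisher classifier per split.

    ``X`` (n, 2) holds one 2D point per patient.  Returns ``(errors,
    valid)``; splits whose training fit is degenerate (equal group means)
    are marked invalid.
    """
    X = np.asarray(X, dtype=float)
    W, thr, sgn, degenerate, _ = fisher_batch(X[splits.train_g1], X[splits.train_g2])
    p1 = np.einsum("sij,sj->si", X[splits.test_g1], W)
    p2 = np.einsum("sij,sj->si", X[splits.test_g2], W)
    to_g1_1 = (p1 - thr[:, None]) * sgn[:, None] > 0
    to_g1_2 = (p2 - thr[:, None]) * sgn[:, None] > 0
    er = (1.0 - to_g1_1.mean(axis=1) + to_g1_2.mean(axis=1)) / 2.0
    return er, ~degenerate


def fixed_model_errors(
    model: ProjectionModel, X: np.ndarray, splits: SplitMatrices
) -> np.ndarray:
    """Balanced test error per split of one fixed (pre-fitted) classifier."""
    if model.degenerate:
        return np.full(splits.test_g1.shape[0], 0.5)
    mu1 = float(model.w @ model.m1)
    mu2 = float(model.w @ model.m2)
    thr = (mu1 + mu2) / 2.0
    sgn = np.sign(mu1 - thr)
    if sgn == 0:
        return np.full(splits.test_g1.shape[0], 0.5)
    to_g1 = (np.asarray(X, float) @ model.w - thr) * sgn > 0
    er1 = 1.0 - to_g1[splits.test_g1].mean(axis=1)
    er2 = to_g1[splits.test_g2].mean(axis=1)
    return (er1 + er2) / 2.0


def _summarise(errors: np.ndarray, valid: np.ndarray) -> CvResult:
    n_total = len(errors)
    n_eff = int(valid.sum())
    skip = 1.0 - n_eff / n_total
    if skip > 0.5:
        raise SplitError(f"{skip:.0%} of splits degenerate")
    return CvResult(float(errors[valid].mean()), n_eff, skip)


def cv_error_individual(
    triplet: ExpressionTriplet,
    labels: PhenotypeLabels,
    probe: int | str,
    config: CvConfig,
    splits: SplitMatrices | None = None,
    model: ProjectionModel | None = None,
) -> CvResult:
    """Mean balanced error of one probe's (tumour, normal) classifier.

    Pass precomputed ``splits`` to share the split stream across probes and
    ``model`` to reuse an already-fitted combined projection in faithful
    mode.
    """
    idx = triplet.probe_index(probe) if isinstance(probe, str) else int(probe)
    labels.check_matches(triplet)
    X = np.column_stack([triplet.tumor[idx], triplet.normal[idx]])
    if splits is None:
        splits = split_matrices(labels, config)
    if config.refit_combined:
        errors, valid = batched_fisher_errors(X, splits)
    else:
        if model is None:
            model, _ = combined_projection(triplet, labels, idx)
        errors = fixed_model_errors(model, X, splits)
        valid = np.ones(len(errors), dtype=bool)
    return _summarise(errors, valid)


def cv_error_pair(
    triplet: ExpressionTriplet,
    labels: PhenotypeLabels,
    probe_a: int | str,
    probe_b: int | str,
    config: CvConfig,
    splits: SplitMatrices | None = None,
    combined: tuple[np.ndarray, np.ndarray] | None = None,
) -> CvResult:
    """Mean balanced error of a pair's dimension-reduction classifier.

    The second-stage discriminant is refitted on each training split's
    combined-projection values; the combined projections themselves come
    from the global (all-patient) first-stage fit unless ``combined`` is
    supplied.
    """
    ia = triplet.probe_index(probe_a) if isinstance(probe_a, str) else int(probe_a)
    ib = triplet.probe_index(probe_b) if isinstance(probe_b, str) else int(probe_b)
    if ia == ib:
        raise ValidationError("a pair requires two distinct probes")
    labels.check_matches(triplet)
    if combined is None:
        _, ca = combined_projection(triplet, labels, ia)
        _, cb = combined_projection(triplet, labels, ib)
    else:
        ca, cb = combined
    X = np.column_stack([ca, cb])
    if splits is None:
        splits = split_matrices(labels, config)
    errors, valid = batched_fisher_errors(X, splits)
    return _summarise(errors, valid)
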