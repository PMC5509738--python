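"""Fisher's linear discriminant projections over the tissue and probe-pair axes.

Each probe gives every patient a 2-vector x = (tumour, normal).  The
*combined projection* is a Fisher discriminant fitted on those 2-vectors over
all patients, with the tumour weight constrained non-negative, mapping each
patient to a scalar.  For a probe pair, the *dimension-reduction projection*
is a second Fisher discriminant on the pair of combined-projection scalars —
together the two stages approximate a rank-1 bilinear (matrix-variate)
discriminant u'Xv on the per-patient 2x2 tissue-by-probe matrix.

The discriminant weight is w = Sw^{-1}(m1 - m2) with the within-class
scatter Sw built from group-size-weighted scatter sums divided by n1 + n2.
Classification assigns a sample to the group whose projected mean is nearer
(midpoint threshold); the balanced error Er = (Er1 + Er2)/2 averages the two
per-group misclassification fractions to compensate group imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError, ValidationError
from .io import ExpressionTriplet, PhenotypeLabels

#: relative ridge added to a singular within-class scatter before inversion
RIDGE = 1e-8


@dataclass
class ProjectionModel:
    """A fitted 2D Fisher discriminant.

    ``w`` is the weight 2-vector, ``w0`` the bias of the decision boundary
    w'x + w0 = 0 (midpoint rule: w0 = -w'(m1+m2)/2), ``m1``/``m2`` the group
    means (group 1 = metastasis-free) and ``Sw`` the within-class scatter
    the fit used.  ``degenerate`` flags m1 == m2 fits, which are returned as
    w = (1, 0) with chance-level classification rather than raised, so
    enumeration loops survive pathological probes.
    """

    w: np.ndarray
    w0: float
    m1: np.ndarray
    m2: np.ndarray
    Sw: np.ndarray
    degenerate: bool = False
    ridged: bool = False

    def project(self, X: np.ndarray) -> np.ndarray:
        """Scalar projections w'x for samples in rows of X (n, 2)."""
        return np.asarray(X, dtype=float) @ self.w

    def to_dict(self) -> dict:
        return {
            "w": self.w.tolist(), "w0": float(self.w0),
            "m1": self.m1.tolist(), "m2": self.m2.tolist(),
            "Sw": self.Sw.tolist(), "degenerate": self.degenerate,
            "ridged": self.ridged,
        }


@dataclass
class ErrorRates:
    """Per-group misclassification fractions and their balanced mean."""

    er1: float
    er2: float

    @property
    def er(self) -> float:
        return (self.er1 + self.er2) / 2.0


def within_class_scatter(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Group-size-weighted within-class scatter (n1*S1 + n2*S2)/(n1 + n2)."""
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    n1, n2 = len(X1), len(X2)
    d1 = X1 - X1.mean(axis=0)
    d2 = X2 - X2.mean(axis=0)
    return (n1 * d1.T @ d1 + n2 * d2.T @ d2) / (n1 + n2)


def _solve_2x2(Sw: np.ndarray, rhs: np.ndarray) -> tuple[np.ndarray, bool]:
    """Solve Sw w = rhs for a 2x2 scatter, ridging if (near-)singular."""
    tr = Sw[0, 0] + Sw[1, 1]
    det = Sw[0, 0] * Sw[1, 1] - Sw[0, 1] * Sw[1, 0]
    ridged = False
    if det <= RIDGE * max(tr / 2.0, np.finfo(float).tiny) ** 2:
        lam = RIDGE * tr / 2.0 if tr > 0 else RIDGE
        Sw = Sw + lam * np.eye(2)
        det = Sw[0, 0] * Sw[1, 1] - Sw[0, 1] * Sw[1, 0]
        ridged = True
    w = np.array([
        (Sw[1, 1] * rhs[0] - Sw[0, 1] * rhs[1]) / det,
        (Sw[0, 0] * rhs[1] - Sw[1, 0] * rhs[0]) / det,
    ])
    return w, ridged


def fit_fisher(samples_g1: np.ndarray, samples_g2: np.ndarray) -> ProjectionModel:
    """Fit the 2D Fisher discriminant w = Sw^{-1}(m1 - m2).

    Each group needs >= 2 samples.  A singular scatter is ridge-regularised
    (RIDGE * trace/2 on the diagonal); identical group means yield a flagged
    degenerate model instead of an error.
    """
    X1 = np.atleast_2d(np.asarray(samples_g1, dtype=float))
    X2 = np.atleast_2d(np.asarray(samples_g2, dtype=float))
    if X1.shape[0] < 2 or X2.shape[0] < 2:
        raise FitError("each group needs at least 2 samples")
    if X1.shape[1] != 2 or X2.shape[1] != 2:
        raise ValidationError("samples must be 2-vectors")
    if not (np.isfinite(X1).all() and np.isfinite(X2).all()):
        raise ValidationError("non-finite values in discriminant inputs")
    m1 = X1.mean(axis=0)
    m2 = X2.mean(axis=0)
    Sw = within_class_scatter(X1, X2)
    if np.array_equal(m1, m2):
        w = np.array([1.0, 0.0])
        return ProjectionModel(w, -float(w @ (m1 + m2) / 2), m1, m2, Sw,
                               degenerate=True)
    w, ridged = _solve_2x2(Sw, m1 - m2)
    w0 = -float(w @ (m1 + m2) / 2.0)
    return ProjectionModel(w, w0, m1, m2, Sw, ridged=ridged)


def classify_and_error(model: ProjectionModel, samples_g1, samples_g2) -> ErrorRates:
    """Balanced classification error of a fitted discriminant.

    A sample goes to the group whose projected mean is nearer on the w axis
    (threshold at the midpoint of the projected means); a sample exactly on
    the boundary is assigned to group 2, matching the >= convention of the
    boundary rule.  ``er1`` is the fraction of group-1 samples sent to group
    2 and vice versa.
    """
    X1 = np.atleast_2d(np.asarray(samples_g1, dtype=float))
    X2 = np.atleast_2d(np.asarray(samples_g2, dtype=float))
    if X1.size == 0 or X2.size == 0:
        raise ValidationError("empty sample list")
    if model.degenerate:
        return ErrorRates(0.5, 0.5)
    mu1 = float(model.w @ model.m1)
    mu2 = float(model.w @ model.m2)
    thr = (mu1 + mu2) / 2.0
    sgn = np.sign(mu1 - thr)
    if sgn == 0:
        return ErrorRates(0.5, 0.5)
    to_g1_1 = (X1 @ model.w - thr) * sgn > 0
    to_g1_2 = (X2 @ model.w - thr) * sgn > 0
    return ErrorRates(float(1.0 - to_g1_1.mean()), float(to_g1_2.mean()))


def combined_projection(
    triplet: ExpressionTriplet, labels: PhenotypeLabels, probe: int | str
) -> tuple[ProjectionModel, np.ndarray]:
    """First-stage projection of one probe's (tumour, normal) pairs.

    Fits Fisher's discriminant on all patients and flips the sign of
    (w, w0) if the tumour component is negative, so that tumour expression
    always enters with a non-negative weight.  Returns the model and the
    per-patient scalar projections in patient order.
    """
    idx = triplet.probe_index(probe) if isinstance(probe, str) else int(probe)
    X = np.column_stack([triplet.tumor[idx], triplet.normal[idx]])
    model = fit_fisher(X[labels.g1_indices], X[labels.g2_indices])
    if model.w[0] < 0:
        model.w = -model.w
        model.w0 = -model.w0
    return model, model.project(X)


def dimension_reduction_projection(
    combined_a: np.ndarray, combined_b: np.ndarray, labels: PhenotypeLabels
) -> tuple[ProjectionModel, np.ndarray]:
    """Second-stage projection over a probe pair's combined scalars.

    No sign convention is imposed here: downstream statistics (|t| and
    balanced error) are invariant to the projection sign.
    """
    ca = np.asarray(combined_a, dtype=float)
    cb = np.asarray(combined_b, dtype=float)
    if ca.shape != cb.shape or ca.ndim != 1:
        raise ValidationError("combined projections must be equal-length vectors")
    if len(ca) != len(labels.y):
        raise ValidationError("projection length does not match patient count")
    X = np.column_stack([ca, cb])
    model = fit_fisher(X[labels.g1_indices], X[labels.g2_indices])
    return model, model.project(X)


# ---------------------------------------------------------------------------
# Batched fits: one Fisher discriminant per row of a stack of 2D datasets.
# Used by per-probe screening (F probes at once) and by cross-validation
# (S splits at once); closed-form 2x2 algebra keeps this pure numpy.
# ---------------------------------------------------------------------------

def fisher_batch(
    X1: np.ndarray, X2: np.ndarray, ridge: float = RIDGE
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit B independent 2D Fisher discriminants at once.

    ``X1`` (B, n1, 2) and ``X2`` (B, n2, 2) hold the two groups of each
    dataset.  Returns ``(W, thr, sgn, degenerate, ridged)`` where ``W``
    (B, 2) are the weights, ``thr`` the midpoint thresholds on the w axis,
    ``sgn`` the side of the group-1 projected mean (0 when degenerate) and
    the two flag vectors mark m1 == m2 fits and ridged scatters.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    n1, n2 = X1.shape[1], X2.shape[1]
    m1 = X1.mean(axis=1)
    m2 = X2.mean(axis=1)
    d1 = X1 - m1[:, None, :]
    d2 = X2 - m2[:, None, :]
    S1 = np.einsum("bij,bik->bjk", d1, d1)
    S2 = np.einsum("bij,bik->bjk", d2, d2)
    Sw = (n1 * S1 + n2 * S2) / (n1 + n2)
    tr = Sw[:, 0, 0] + Sw[:, 1, 1]
    det = Sw[:, 0, 0] * Sw[:, 1, 1] - Sw[:, 0, 1] * Sw[:, 1, 0]
    tiny = np.finfo(float).tiny
    ridged = det <= ridge * np.maximum(tr / 2.0, tiny) ** 2
    lam = np.where(ridged, np.where(tr > 0, ridge * tr / 2.0, ridge), 0.0)
    a = Sw[:, 0, 0] + lam
    b = Sw[:, 0, 1]
    c = Sw[:, 1, 1] + lam
    det = a * c - b * b
    diff = m1 - m2
    W = np.empty_like(diff)
    W[:, 0] = (c * diff[:, 0] - b * diff[:, 1]) / det
    W[:, 1] = (a * diff[:, 1] - b * diff[:, 0]) / det
    degenerate = (diff == 0).all(axis=1)
    W[degenerate] = (1.0, 0.0)
    mu1 = np.einsum("bj,bj->b", W, m1)
    mu2 = np.einsum("bj,bj->b", W, m2)
    thr = (mu1 + mu2) / 2.0
    sgn = np.sign(mu1 - thr)
    sgn[degenerate] = 0.0
    return W, thr, sgn, degenerate, ridged


def combined_projection_batch(
    tumor: np.ndarray, normal: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Combined projections for many probes at once.

    ``tumor``/``normal`` are (F, n) matrices over the same patients and
    ``y`` the 0/1 group labels.  Applies the tumour-non-negative sign
    convention per probe and returns ``(W, projections)`` with shapes
    (F, 2) and (F, n).
    """
    y = np.asarray(y)
    X = np.stack([tumor, normal], axis=-1)  # (F, n, 2)
    W, _, _, _, _ = fisher_batch(X[:, y == 0, :], X[:, y == 1, :])
    flip = W[:, 0] < 0
    W[flip] = -W[flip]
    return W, np.einsum("fnj,fj->fn", X, W)
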