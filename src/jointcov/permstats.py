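"""Welch's t, permutation p-values and the stepwise escalation schedule.

The model-based half of the integrative hypothesis test: projected values
are compared between metastasis-free (group 1) and metastasis (group 2)
patients with Welch's unequal-variance t-statistic, and significance is
assessed by permuting group labels (group sizes preserved) over the fixed
projection values.  p-values use the add-one estimator
p = (1 + #{|t0| >= |t|}) / (B + 1), whose smallest attainable value
1/(B + 1) is the "permutation floor" that drives the escalation schedule
for probe pairs (features at the floor are re-tested at the next, larger
permutation count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import PhenotypeLabels

_CHUNK = 4096  # permutation rows materialised at a time


@dataclass
class WelchResult:
    t: float
    df: float
    m1: float
    m2: float
    s1sq: float
    s2sq: float
    p_perm: float | None = None
    B: int | None = None
    flag: str | None = None


def welch_t(values_g1, values_g2) -> WelchResult:
    """Welch's t = (m2 - m1) / sqrt(s1^2/n1 + s2^2/n2) and its
    Welch–Satterthwaite degrees of freedom.

    Sample (n-1 denominator) variances.  Zero variance in both groups with
    equal means yields t = 0 with df = n1 + n2 - 2 (flagged); zero pooled
    scale with unequal means yields a signed-infinity flag.
    """
    g1 = np.asarray(values_g1, dtype=float)
    g2 = np.asarray(values_g2, dtype=float)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs >= 2 values")
    if not (np.isfinite(g1).all() and np.isfinite(g2).all()):
        raise ValidationError("non-finite values")
    m1, m2 = g1.mean(), g2.mean()
    s1, s2 = g1.var(ddof=1), g2.var(ddof=1)
    denom_sq = s1 / n1 + s2 / n2
    if denom_sq == 0.0:
        if m1 == m2:
            return WelchResult(0.0, float(n1 + n2 - 2), m1, m2, s1, s2,
                               flag="zero-variance")
        t = np.inf if m2 > m1 else -np.inf
        return WelchResult(t, float(n1 + n2 - 2), m1, m2, s1, s2,
                           flag="zero-scale-unequal-means")
    t = (m2 - m1) / np.sqrt(denom_sq)
    df = denom_sq**2 / (
        s1**2 / (n1**2 * (n1 - 1)) + s2**2 / (n2**2 * (n2 - 1))
    )
    return WelchResult(float(t), float(df), m1, m2, s1, s2)


def _abs_t_rows(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """|Welch t| per row for row-aligned group blocks (B, n1), (B, n2)."""
    n1, n2 = g1.shape[1], g2.shape[1]
    m1 = g1.mean(axis=1)
    m2 = g2.mean(axis=1)
    s1 = g1.var(axis=1, ddof=1)
    s2 = g2.var(axis=1, ddof=1)
    denom_sq = s1 / n1 + s2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m2 - m1) / np.sqrt(denom_sq)
    zero = denom_sq == 0.0
    t[zero & (m1 == m2)] = 0.0
    t[zero & (m1 != m2)] = np.inf
    return t


def count_ge(nulls: np.ndarray, t_abs: float) -> int:
    """#{|t0| >= |t|} with a relative guard for floating-point ties.

    Permutations that are mathematically tied with the observed statistic
    can differ in the last bits depending on summation order; the guard
    keeps such ties counted, as exact enumeration would.
    """
    if np.isinf(t_abs):
        return int(np.isinf(nulls).sum())
    tol = 1e-9 * max(t_abs, 1.0)
    return int((nulls >= t_abs - tol).sum())


def null_abs_t(values: np.ndarray, n1: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """B null |t| statistics from random label rearrangements.

    Labels are reassigned by permuting the pooled values and splitting the
    first n1 into group 1, preserving group sizes.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    out = np.empty(B)
    for start in range(0, B, _CHUNK):
        m = min(_CHUNK, B - start)
        block = np.broadcast_to(values, (m, n)).copy()
        rng.permuted(block, axis=1, out=block)
        out[start:start + m] = _abs_t_rows(block[:, :n1], block[:, n1:])
    return out


def permutation_pvalue(
    values_g1, values_g2, B: int, seed: int | np.random.Generator = 0
) -> WelchResult:
    """Two-sided permutation p-value for Welch's t with add-one correction.

    p = (1 + #{b : |t0(b)| >= |t|}) / (B + 1); deterministic given the seed.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    res = welch_t(values_g1, values_g2)
    pooled = np.concatenate([np.asarray(values_g1, float),
                             np.asarray(values_g2, float)])
    nulls = null_abs_t(pooled, len(values_g1), B, rng)
    count = count_ge(nulls, abs(res.t))
    res.p_perm = (1 + count) / (B + 1)
    res.B = B
    return res


def exact_permutation_pvalue(values_g1, values_g2) -> WelchResult:
    """Exact two-sided permutation p-value by full label enumeration.

    Enumerates every C(n1+n2, n1) assignment of the pooled values to group
    sizes (n1, n2); p = #{|t0| >= |t|} / C(n1+n2, n1).  The identity
    assignment is part of the enumeration, so p >= 1/C(n1+n2, n1) — the
    exact counterpart of the add-one floor.  Only feasible for small
    cohorts (n1 + n2 <= ~14).
    """
    from itertools import combinations

    g1 = np.asarray(values_g1, dtype=float)
    g2 = np.asarray(values_g2, dtype=float)
    n1 = len(g1)
    pooled = np.concatenate([g1, g2])
    n = len(pooled)
    res = welch_t(g1, g2)
    count = 0
    total = 0
    for pick in combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(pick)] = True
        a, b = pooled[mask], pooled[~mask]
        m1, m2 = a.mean(), b.mean()
        s1, s2 = a.var(ddof=1), b.var(ddof=1)
        denom_sq = s1 / n1 + s2 / (n - n1)
        if denom_sq == 0.0:
            t0 = 0.0 if m1 == m2 else np.inf
        else:
            t0 = (m2 - m1) / np.sqrt(denom_sq)
        if abs(t0) >= abs(res.t):
            count += 1
        total += 1
    res.p_perm = count / total
    res.B = total
    return res


def stepwise_pair_permutation(
    pair_projections: np.ndarray,
    labels: PhenotypeLabels,
    schedule=(10_000, 100_000, 1_000_000),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Escalating permutation testing over many features.

    ``pair_projections`` is an (F, n) matrix of per-feature scalar values
    over the patients.  Every feature is tested at ``schedule[0]``
    permutations; only features whose p-value sits at the current stage's
    permutation floor 1/(B + 1) are re-tested at the next stage.  Returns
    each feature's final p and the B at which it stopped.

    Each (feature, stage) gets its own seeded generator stream,
    ``default_rng([seed, feature, B])``, so a feature's p at a given B is
    identical whether reached by escalation or tested directly.
    """
    P = np.asarray(pair_projections, dtype=float)
    if P.ndim != 2 or P.shape[1] != len(labels.y):
        raise ValidationError("pair_projections must be (features, patients)")
    schedule = [int(b) for b in schedule]
    if not schedule:
        raise ValidationError("schedule must be non-empty")
    if any(b2 <= b1 for b1, b2 in zip(schedule, schedule[1:])):
        raise ValidationError("schedule must be strictly increasing")
    g1 = labels.g1_indices
    g2 = labels.g2_indices
    F = P.shape[0]
    p_final = np.empty(F)
    b_final = np.empty(F, dtype=int)
    active = np.arange(F)
    for stage, B in enumerate(schedule):
        floor = 1.0 / (B + 1)
        still = []
        for f in active:
            rng = np.random.default_rng([seed, int(f), B])
            res = permutation_pvalue(P[f, g1], P[f, g2], B, rng)
            p_final[f] = res.p_perm
            b_final[f] = B
            if res.p_perm <= floor and stage + 1 < len(schedule):
                still.append(f)
        active = np.array(still, dtype=int)
        if active.size == 0:
            break
    return p_final, b_final
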