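"""Rank voting and bootstrap score accumulation.

Each bootstrap round draws a stratified 90% patient subsample, recomputes
every feature's permutation p-value and mean cross-validated balanced error
on that subsample, ranks features ascending on both statistics, and assigns
votes by rank band:

    rank 1-3 -> 20, 4-5 -> 15, 6-10 -> 10, 11-15 -> 5, 16-20 -> 1, else 0.

A feature scores vote(rank_p) + vote(rank_err) in a round only when BOTH
ranks are <= 20; otherwise it scores nothing that round.  Scores accumulate
over rounds, and candidates are the features whose total exceeds a
threshold of two points per round on average (strictly greater than
2 x rounds; 200 for the canonical 100-round run).

Individuals (probes) and pairs are ranked in separate pools by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ScreenError, ValidationError
from .io import ExpressionTriplet, PhenotypeLabels
from .permstats import count_ge, null_abs_t, welch_t
from .projection import combined_projection_batch, fisher_batch
from .cverror import (CvConfig, SplitMatrices, batched_fisher_errors,
                      fixed_model_errors, split_matrices)


@dataclass(frozen=True)
class VoteTable:
    """Rank-band -> vote map; bands are inclusive (lo, hi, votes) triples."""

    bands: tuple = ((1, 3, 20), (4, 5, 15), (6, 10, 10), (11, 15, 5), (16, 20, 1))

    @property
    def gate(self) -> int:
        """Largest rank that earns any votes; both ranks must be <= gate."""
        return max(hi for _, hi, _ in self.bands)


DEFAULT_VOTE_TABLE = VoteTable()


def vote(rank: int, table: VoteTable = DEFAULT_VOTE_TABLE) -> int:
    """Votes earned by one ascending rank (1 = best)."""
    if rank < 1:
        raise ValidationError("ranks are 1-based")
    for lo, hi, v in table.bands:
        if lo <= rank <= hi:
            return v
    return 0


def ascending_ranks(
    primary: np.ndarray, secondary: np.ndarray, ids=None
) -> np.ndarray:
    """1-based ascending ranks of ``primary``.

    Ties on the primary statistic break on the secondary statistic, then on
    lexicographic feature-id order (input position when no ids are given),
    so the ranking is a deterministic permutation and, given ids, invariant
    to the input ordering of the features.
    """
    primary = np.asarray(primary, dtype=float)
    secondary = np.asarray(secondary, dtype=float)
    if ids is None:
        key = np.arange(len(primary))
    else:
        key = np.empty(len(primary), dtype=int)
        key[np.argsort(np.asarray(ids, dtype=object), kind="stable")] = \
            np.arange(len(primary))
    order = np.lexsort((key, secondary, primary))
    ranks = np.empty(len(primary), dtype=int)
    ranks[order] = np.arange(1, len(primary) + 1)
    return ranks


def round_scores(
    p: np.ndarray, err: np.ndarray, table: VoteTable = DEFAULT_VOTE_TABLE,
    ids=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Votes per feature for one round.

    Returns ``(scores, rank_p, rank_err)``; a feature scores
    vote(rank_p) + vote(rank_err) if both ranks are within the vote table's
    gate, else 0.
    """
    rank_p = ascending_ranks(p, err, ids)
    rank_err = ascending_ranks(err, p, ids)
    vp = np.array([vote(r, table) for r in rank_p])
    ve = np.array([vote(r, table) for r in rank_err])
    gate = (rank_p <= table.gate) & (rank_err <= table.gate)
    return np.where(gate, vp + ve, 0), rank_p, rank_err


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _subsample(labels: PhenotypeLabels, fraction: float, rng) -> np.ndarray:
    """Stratified without-replacement subsample of round(fraction*n_g) per group."""
    idx = []
    for g in (labels.g1_indices, labels.g2_indices):
        size = _round_half_up(fraction * len(g))
        if size < 3:
            raise ScreenError(f"subsample leaves a group with {size} < 3 patients")
        idx.append(np.sort(rng.choice(g, size=size, replace=False)))
    return np.concatenate(idx)


def _pool_stats(
    values: np.ndarray,
    y: np.ndarray,
    B: int,
    splits: SplitMatrices,
    seeds: list,
    models_2d: np.ndarray | None = None,
    points_2d: np.ndarray | None = None,
    refit: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p and mean balanced CV error for each feature of a pool.

    ``values`` (F, n) are the fixed per-patient scalar projections used by
    the permutation test.  The classifier evaluated by cross-validation is
    either refitted per split on ``points_2d`` (F, n, 2) or, for the
    faithful individual mode, the fixed per-feature linear rule given by
    ``models_2d`` = (W (F, 2), thr (F,), sgn (F,)) applied to ``points_2d``.
    """
    F, n = values.shape
    g1 = np.flatnonzero(y == 0)
    g2 = np.flatnonzero(y == 1)
    p = np.empty(F)
    for f in range(F):
        rng = np.random.default_rng(seeds[f])
        res = welch_t(values[f, g1], values[f, g2])
        pooled = np.concatenate([values[f, g1], values[f, g2]])
        nulls = null_abs_t(pooled, len(g1), B, rng)
        p[f] = (1 + count_ge(nulls, abs(res.t))) / (B + 1)
    err = np.empty(F)
    for f in range(F):
        X = points_2d[f]
        if refit or models_2d is None:
            errors, valid = batched_fisher_errors(X, splits)
            err[f] = errors[valid].mean() if valid.any() else 0.5
        else:
            W, thr, sgn = models_2d
            if sgn[f] == 0:
                err[f] = 0.5
                continue
            to_g1 = (X @ W[f] - thr[f]) * sgn[f] > 0
            er1 = 1.0 - to_g1[splits.test_g1].mean(axis=1)
            er2 = to_g1[splits.test_g2].mean(axis=1)
            err[f] = ((er1 + er2) / 2.0).mean()
    return p, err


def accumulate(
    triplet: ExpressionTriplet,
    labels: PhenotypeLabels,
    individuals: list | None = None,
    pairs: list | None = None,
    rounds: int = 20,
    fraction: float = 0.9,
    B: int = 199,
    n_splits: int = 100,
    seed: int = 0,
    table: VoteTable = DEFAULT_VOTE_TABLE,
    refit_in_cv: bool = False,
    train_fraction: float = 0.7,
    keep_round_scores: bool = False,
) -> dict[str, pd.DataFrame]:
    """Run the bootstrap vote-accumulation cycle.

    Per round: stratified subsample of ``fraction`` of each group, a fresh
    first-stage combined projection on the subsample, then per-feature
    permutation p (``B`` permutations) and mean balanced CV error
    (``n_splits`` splits) on the subsample, separate ascending rankings for
    the individual and pair pools, vote assignment and accumulation.

    Returns ``{"individuals": df, "pairs": df}`` sorted by total score
    descending, with the last round's statistics and, if requested, the
    full per-round score matrix under ``df.attrs["round_scores"]``.
    """
    if rounds < 1:
        raise ValidationError("rounds must be >= 1")
    if not (0.0 < fraction <= 1.0):
        raise ValidationError("fraction must lie in (0, 1]")
    labels.check_matches(triplet)
    individuals = list(individuals) if individuals else []
    pairs = [tuple(p) for p in pairs] if pairs else []
    for a, b in pairs:
        if a == b:
            raise ValidationError(f"pair ({a}, {b}) duplicates a probe")
    ind_idx = np.array([
        triplet.probe_index(p) if isinstance(p, str) else int(p)
        for p in individuals
    ], dtype=int)
    pair_idx = np.array([
        (triplet.probe_index(a) if isinstance(a, str) else int(a),
         triplet.probe_index(b) if isinstance(b, str) else int(b))
        for a, b in pairs
    ], dtype=int).reshape(-1, 2)
    probe_pool = np.unique(np.concatenate([ind_idx, pair_idx.ravel()])) \
        if (len(ind_idx) or len(pair_idx)) else np.array([], dtype=int)
    if probe_pool.size == 0:
        raise ValidationError("no features given")

    n_ind, n_pair = len(ind_idx), len(pair_idx)
    total_ind = np.zeros(n_ind, dtype=int)
    total_pair = np.zeros(n_pair, dtype=int)
    hist_ind = np.zeros((rounds, n_ind), dtype=int)
    hist_pair = np.zeros((rounds, n_pair), dtype=int)
    last = {}

    for r in range(rounds):
        sub = _subsample(labels, fraction, np.random.default_rng([seed, 7, r]))
        y_sub = labels.y[sub]
        # A1 on the round's sample: combined projection per involved probe.
        tum = triplet.tumor[np.ix_(probe_pool, sub)]
        nor = triplet.normal[np.ix_(probe_pool, sub)]
        W, proj = combined_projection_batch(tum, nor, y_sub)
        row_of = {int(p): i for i, p in enumerate(probe_pool)}
        cv = CvConfig(n_splits=n_splits, train_fraction=train_fraction,
                      seed=[seed, 2000 + r])
        sub_labels = PhenotypeLabels([triplet.patient_ids[i] for i in sub], y_sub)
        splits = split_matrices(sub_labels, cv)

        if n_ind:
            rows = np.array([row_of[int(i)] for i in ind_idx])
            values = proj[rows]
            points = np.stack([tum[rows], nor[rows]], axis=-1)
            # Fixed classifier per probe: the round's combined model itself.
            Wf = W[rows]
            m1 = points[:, y_sub == 0, :].mean(axis=1)
            m2 = points[:, y_sub == 1, :].mean(axis=1)
            mu1 = np.einsum("fj,fj->f", Wf, m1)
            mu2 = np.einsum("fj,fj->f", Wf, m2)
            thr = (mu1 + mu2) / 2.0
            sgn = np.sign(mu1 - thr)
            seeds = [[seed, 1000 + r, int(i)] for i in ind_idx]
            p_i, e_i = _pool_stats(values, y_sub, B, splits, seeds,
                                   models_2d=(Wf, thr, sgn), points_2d=points,
                                   refit=refit_in_cv)
            ids = [triplet.probe_ids[i] for i in ind_idx]
            sc, _, _ = round_scores(p_i, e_i, table, ids=ids)
            total_ind += sc
            hist_ind[r] = sc
            last["ind"] = (p_i, e_i)

        if n_pair:
            ca = proj[[row_of[int(a)] for a, _ in pair_idx]]
            cb = proj[[row_of[int(b)] for _, b in pair_idx]]
            points = np.stack([ca, cb], axis=-1)  # (F, n_sub, 2)
            Wd, _, _, _, _ = fisher_batch(points[:, y_sub == 0, :],
                                          points[:, y_sub == 1, :])
            values = np.einsum("fnj,fj->fn", points, Wd)
            seeds = [[seed, 3000 + r, int(a), int(b)] for a, b in pair_idx]
            p_p, e_p = _pool_stats(values, y_sub, B, splits, seeds,
                                   points_2d=points, refit=True)
            ids = [f"{triplet.probe_ids[a]}|{triplet.probe_ids[b]}"
                   for a, b in pair_idx]
            sc, _, _ = round_scores(p_p, e_p, table, ids=ids)
            total_pair += sc
            hist_pair[r] = sc
            last["pair"] = (p_p, e_p)

    out = {}
    if n_ind:
        p_i, e_i = last["ind"]
        df = pd.DataFrame({
            "feature": [triplet.probe_ids[i] for i in ind_idx],
            "total_score": total_ind,
            "p_perm": p_i, "mean_error": e_i,
        })
        df = df.sort_values(["total_score", "p_perm", "mean_error"],
                            ascending=[False, True, True],
                            kind="stable").reset_index(drop=True)
        if keep_round_scores:
            df.attrs["round_scores"] = hist_ind
        out["individuals"] = df
    if n_pair:
        p_p, e_p = last["pair"]
        df = pd.DataFrame({
            "feature_a": [triplet.probe_ids[a] for a, _ in pair_idx],
            "feature_b": [triplet.probe_ids[b] for _, b in pair_idx],
            "total_score": total_pair,
            "p_perm": p_p, "mean_error": e_p,
        })
        df = df.sort_values(["total_score", "p_perm", "mean_error"],
                            ascending=[False, True, True],
                            kind="stable").reset_index(drop=True)
        if keep_round_scores:
            df.attrs["round_scores"] = hist_pair
        out["pairs"] = df
    return out


def select_candidates(
    records: pd.DataFrame, rounds: int, threshold: int | None = None
) -> pd.DataFrame:
    """Features whose accumulated score strictly exceeds the threshold.

    The canonical threshold is 200 for 100 rounds ("at least two scores on
    average in each round"); by default it scales as 2 x rounds.
    """
    if threshold is None:
        threshold = 2 * rounds
    return records[records["total_score"] > threshold].reset_index(drop=True)


def euclidean_rank_screen(
    records: pd.DataFrame, top_p_fraction: float = 0.1
) -> pd.DataFrame:
    """Legacy screening variant: distance ranking inside the top-p subset.

    Restricts to the top ``top_p_fraction`` of features by p-value, min-max
    normalises p and mean error over that subset, and ranks by Euclidean
    distance of the normalised (p, error) point to the origin.  Kept for
    comparison; superseded by the vote-accumulation scheme.
    """
    if not (0.0 < top_p_fraction <= 1.0):
        raise ValidationError("top_p_fraction must lie in (0, 1]")
    k = max(int(np.ceil(top_p_fraction * len(records))), 1)
    sub = records.nsmallest(k, "p_perm", keep="first").copy()
    if len(sub) < 2:
        raise ScreenError("screen subset has fewer than 2 records")

    def _norm(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        return np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)

    np_ = _norm(sub["p_perm"].to_numpy(dtype=float))
    ne = _norm(sub["mean_error"].to_numpy(dtype=float))
    sub["distance"] = np.hypot(np_, ne)
    sub = sub.sort_values("distance", kind="stable").reset_index(drop=True)
    sub["distance_rank"] = np.arange(1, len(sub) + 1)
    return sub
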