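"""The joint covariate detection model: data in, ranked candidates out.

:class:`JointCovariateDetection` bundles an expression triplet, phenotype
labels and a :class:`~jointcov.config.RunConfig`; :meth:`fit` runs the full
selection cascade —

1. kNN imputation of missing cells (if any);
2. first-stage combined projection of every probe on all patients;
3. individual screen: permutation Welch p and mean balanced CV error per
   probe;
4. broad pair screen on the whole sample over all enumerated pairs, used to
   shortlist pairs;
5. stepwise permutation escalation of the shortlisted pairs;
6. bootstrap vote accumulation over both pools;
7. candidate selection by accumulated score;
8. affirmation: complete-linkage / centred-Pearson clustering of candidate
   probes into cliques, sample-axis separation count and cross-clique
   annotation of candidate pairs —

and returns a :class:`JointCovariateResults` carrying every intermediate
table, with ``summary()`` and ``save()`` for inspection and persistence.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .affirmation import (CliqueAssignment, cross_clique_pairs, hcluster_complete,
                          merge_tree_frame, sample_separation_report, to_newick,
                          zscore_rows)
from .config import RunConfig
from .errors import ValidationError
from .io import (ExpressionTriplet, PhenotypeLabels, knn_impute, read_expression,
                 read_labels)
from .cverror import CvConfig, batched_fisher_errors, split_matrices
from .permstats import count_ge, null_abs_t, stepwise_pair_permutation, welch_t
from .projection import combined_projection_batch, fisher_batch
from .voting import accumulate, round_scores, select_candidates


class JointCovariateDetection:
    """Model object for joint covariate detection on one dataset."""

    def __init__(
        self,
        triplet: ExpressionTriplet,
        labels: PhenotypeLabels,
        config: RunConfig | None = None,
    ) -> None:
        labels.check_matches(triplet)
        self.triplet = triplet
        self.labels = labels
        self.config = config or RunConfig.desk()

    @classmethod
    def from_files(cls, tumor_path, normal_path, labels_path,
                   config: RunConfig | None = None) -> "JointCovariateDetection":
        triplet = read_expression(tumor_path, normal_path)
        labels = read_labels(labels_path, triplet.patient_ids)
        return cls(triplet, labels, config)

    # -- stages --------------------------------------------------------

    def _impute(self) -> ExpressionTriplet:
        t = self.triplet
        return knn_impute(t) if t.has_missing() else t

    def _individual_screen(self, triplet, proj, W, seed) -> pd.DataFrame:
        cfg = self.config
        y = self.labels.y
        g1 = self.labels.g1_indices
        g2 = self.labels.g2_indices
        F = triplet.n_probes
        splits = split_matrices(self.labels, CvConfig(
            n_splits=cfg.screen_splits, train_fraction=cfg.train_fraction,
            seed=[seed, 11]))
        X = np.stack([triplet.tumor, triplet.normal], axis=-1)  # (F, n, 2)
        rows = []
        for f in range(F):
            res = welch_t(proj[f, g1], proj[f, g2])
            rng = np.random.default_rng([seed, 10, f])
            pooled = np.concatenate([proj[f, g1], proj[f, g2]])
            nulls = null_abs_t(pooled, len(g1), cfg.screen_B, rng)
            p = (1 + count_ge(nulls, abs(res.t))) / (cfg.screen_B + 1)
            if cfg.refit_in_cv:
                errors, valid = batched_fisher_errors(X[f], splits)
                err = float(errors[valid].mean()) if valid.any() else 0.5
            else:
                m1 = X[f, g1].mean(axis=0)
                m2 = X[f, g2].mean(axis=0)
                mu1 = float(W[f] @ m1)
                mu2 = float(W[f] @ m2)
                thr = (mu1 + mu2) / 2.0
                sgn = np.sign(mu1 - thr)
                if sgn == 0:
                    err = 0.5
                else:
                    to_g1 = (X[f] @ W[f] - thr) * sgn > 0
                    er1 = 1.0 - to_g1[splits.test_g1].mean(axis=1)
                    er2 = to_g1[splits.test_g2].mean(axis=1)
                    err = float(((er1 + er2) / 2.0).mean())
            rows.append({"feature": triplet.probe_ids[f], "t": res.t,
                         "df": res.df, "p_perm": p, "B": cfg.screen_B,
                         "mean_error": err})
        return pd.DataFrame(rows)

    def _pair_pool(self, ind: pd.DataFrame, triplet) -> list[tuple[int, int]]:
        cfg = self.config
        F = triplet.n_probes
        order = np.arange(F)
        if F * (F - 1) // 2 > cfg.max_pairs:
            m = cfg.probe_shortlist or 50
            best = ind.sort_values(
                ["p_perm", "mean_error", "feature"], kind="stable"
            ).head(m)["feature"]
            order = np.sort([triplet.probe_index(p) for p in best])
        return list(itertools.combinations(order.tolist(), 2))

    def _broad_pair_screen(self, triplet, proj, pairs, seed) -> pd.DataFrame:
        """One whole-sample screening pass over every enumerated pair."""
        cfg = self.config
        y = self.labels.y
        g1 = self.labels.g1_indices
        g2 = self.labels.g2_indices
        splits = split_matrices(self.labels, CvConfig(
            n_splits=cfg.broad_splits, train_fraction=cfg.train_fraction,
            seed=[seed, 21]))
        ia = np.array([a for a, _ in pairs], dtype=int)
        ib = np.array([b for _, b in pairs], dtype=int)
        points = np.stack([proj[ia], proj[ib]], axis=-1)  # (P, n, 2)
        Wd, _, _, _, _ = fisher_batch(points[:, g1, :], points[:, g2, :])
        values = np.einsum("pnj,pj->pn", points, Wd)
        P = len(pairs)
        p_perm = np.empty(P)
        err = np.empty(P)
        for k in range(P):
            res = welch_t(values[k, g1], values[k, g2])
            rng = np.random.default_rng([seed, 20, int(ia[k]), int(ib[k])])
            pooled = np.concatenate([values[k, g1], values[k, g2]])
            nulls = null_abs_t(pooled, len(g1), cfg.broad_B, rng)
            p_perm[k] = (1 + count_ge(nulls, abs(res.t))) / (cfg.broad_B + 1)
            errors, valid = batched_fisher_errors(points[k], splits)
            err[k] = errors[valid].mean() if valid.any() else 0.5
        pair_ids = [f"{triplet.probe_ids[a]}|{triplet.probe_ids[b]}"
                    for a, b in zip(ia, ib)]
        scores, rank_p, rank_e = round_scores(p_perm, err, ids=pair_ids)
        df = pd.DataFrame({
            "feature_a": [triplet.probe_ids[a] for a in ia],
            "feature_b": [triplet.probe_ids[b] for b in ib],
            "idx_a": ia, "idx_b": ib,
            "p_perm": p_perm, "mean_error": err,
            "rank_p": rank_p, "rank_err": rank_e, "broad_score": scores,
        })
        df["pair_values_row"] = np.arange(P)
        df.attrs["pair_values"] = values
        return df

    def fit(self, seed: int | None = None) -> "JointCovariateResults":
        cfg = self.config
        seed = cfg.seed if seed is None else int(seed)
        triplet = self._impute()

        W, proj = combined_projection_batch(triplet.tumor, triplet.normal,
                                            self.labels.y)
        ind = self._individual_screen(triplet, proj, W, seed)

        pairs = self._pair_pool(ind, triplet)
        broad = self._broad_pair_screen(triplet, proj, pairs, seed)
        short = broad.sort_values(
            ["broad_score", "p_perm", "mean_error", "feature_a", "feature_b"],
            ascending=[False, True, True, True, True], kind="stable",
        ).head(cfg.pair_shortlist)

        # Stepwise permutation escalation on the shortlisted pairs' fixed
        # whole-sample dimension-reduction projections.
        values = broad.attrs["pair_values"][short["pair_values_row"].to_numpy()]
        p_esc, b_esc = stepwise_pair_permutation(
            values, self.labels, schedule=cfg.pair_schedule, seed=seed)
        short = short.copy()
        short["p_perm"] = p_esc
        short["B"] = b_esc

        acc = accumulate(
            triplet, self.labels,
            individuals=list(triplet.probe_ids),
            pairs=list(zip(short["feature_a"], short["feature_b"])),
            rounds=cfg.rounds, fraction=cfg.fraction,
            B=cfg.round_B, n_splits=cfg.round_splits, seed=seed,
            refit_in_cv=cfg.refit_in_cv, train_fraction=cfg.train_fraction,
        )
        ind_acc = acc["individuals"]
        pair_acc = acc.get("pairs", pd.DataFrame(
            columns=["feature_a", "feature_b", "total_score", "p_perm",
                     "mean_error"]))
        cand_ind = select_candidates(ind_acc, cfg.rounds, cfg.threshold)
        cand_pair = select_candidates(pair_acc, cfg.rounds, cfg.threshold) \
            if len(pair_acc) else pair_acc

        results = JointCovariateResults(
            model=self, seed=seed, triplet=triplet,
            combined_weights=W, combined_projections=proj,
            individual_screen=ind,
            pair_screen=broad.drop(columns=["pair_values_row"]),
            pair_escalated=short.drop(columns=["pair_values_row"]),
            individual_table=ind_acc, pair_table=pair_acc,
            candidates_individual=cand_ind, candidates_pair=cand_pair,
        )
        results._affirm()
        return results


@dataclass
class JointCovariateResults:
    """Everything :meth:`JointCovariateDetection.fit` computed."""

    model: JointCovariateDetection
    seed: int
    triplet: ExpressionTriplet
    combined_weights: np.ndarray
    combined_projections: np.ndarray
    individual_screen: pd.DataFrame
    pair_screen: pd.DataFrame
    pair_escalated: pd.DataFrame
    individual_table: pd.DataFrame
    pair_table: pd.DataFrame
    candidates_individual: pd.DataFrame
    candidates_pair: pd.DataFrame
    cliques: CliqueAssignment | None = None
    cross_pairs: pd.DataFrame | None = None
    sample_misclassified: int | None = None

    @property
    def config(self) -> RunConfig:
        return self.model.config

    def _affirm(self) -> None:
        cfg = self.config
        members: list[str] = list(self.candidates_individual["feature"])
        for _, row in self.candidates_pair.iterrows():
            members.extend([row["feature_a"], row["feature_b"]])
        union = sorted(set(members))
        if len(union) < 2:
            return
        idx = [self.triplet.probe_index(p) for p in union]
        Z, _ = zscore_rows(self.combined_projections[idx])
        k = min(cfg.k_cliques, len(union))
        self.cliques = hcluster_complete(Z, ids=union, n_clusters=k)
        try:
            self.sample_misclassified = sample_separation_report(
                Z, self.model.labels)
        except ValidationError:
            self.sample_misclassified = None
        if len(self.candidates_pair):
            pairs = list(zip(self.candidates_pair["feature_a"],
                             self.candidates_pair["feature_b"]))
            self.cross_pairs = cross_clique_pairs(
                pairs, self.cliques,
                scores=self.candidates_pair["total_score"].to_numpy())

    def summary(self) -> str:
        cfg = self.config
        t = self.triplet
        lab = self.model.labels
        lines = [
            "Joint covariate detection results",
            "=" * 70,
            f"probes: {t.n_probes}   patients: {t.n_patients} "
            f"(metastasis-free n1={lab.n1}, metastasis n2={lab.n2})",
            f"preset: {cfg.preset}   rounds: {cfg.rounds}   "
            f"subsample: {cfg.fraction:.0%}   "
            f"threshold: >{cfg.effective_threshold}   seed: {self.seed}",
            "",
            f"candidate individuals: {len(self.candidates_individual)}"
            f"   candidate pairs: {len(self.candidates_pair)}",
        ]
        if len(self.individual_table):
            lines += ["", "Top individuals (by accumulated score)",
                      self.individual_table.head(10).to_string(index=False)]
        if len(self.pair_table):
            lines += ["", "Top pairs (by accumulated score)",
                      self.pair_table.head(10).to_string(index=False)]
        if self.cliques is not None:
            sizes = {c: len(m) for c, m in sorted(self.cliques.clusters().items())}
            lines += ["", f"cliques (k={len(sizes)}): sizes {sizes}"]
            if self.sample_misclassified is not None:
                lines += [f"sample-axis clustering misclassified: "
                          f"{self.sample_misclassified}"]
        if self.cross_pairs is not None and len(self.cross_pairs):
            lines += ["", "Cross-clique candidate pairs",
                      self.cross_pairs.to_string(index=False)]
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Persist every stage as TSV/JSON under ``outdir``."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        proj = pd.DataFrame(self.combined_projections,
                            index=self.triplet.probe_ids,
                            columns=self.triplet.patient_ids)
        proj.index.name = "probe_id"
        proj.to_csv(out / "combined_projections.tsv", sep="\t")
        wdf = pd.DataFrame(self.combined_weights, columns=["w_tumor", "w_normal"])
        wdf.insert(0, "probe_id", self.triplet.probe_ids)
        wdf.to_csv(out / "combined_weights.tsv", sep="\t", index=False)
        self.individual_screen.to_csv(out / "individual_screen.tsv",
                                      sep="\t", index=False)
        self.pair_screen.to_csv(out / "pair_screen.tsv", sep="\t", index=False)
        self.pair_escalated.to_csv(out / "pair_escalated.tsv", sep="\t",
                                   index=False)
        self.individual_table.to_csv(out / "accumulation_individuals.tsv",
                                     sep="\t", index=False)
        self.pair_table.to_csv(out / "accumulation_pairs.tsv", sep="\t",
                               index=False)
        self.candidates_individual.to_csv(out / "candidates_individuals.tsv",
                                          sep="\t", index=False)
        self.candidates_pair.to_csv(out / "candidates_pairs.tsv", sep="\t",
                                    index=False)
        if self.cliques is not None:
            pd.DataFrame({
                "probe_id": self.cliques.probe_ids,
                "clique": self.cliques.cluster_of,
            }).to_csv(out / "cliques.tsv", sep="\t", index=False)
            corr = pd.DataFrame(self.cliques.correlations,
                                index=self.cliques.probe_ids,
                                columns=self.cliques.probe_ids)
            corr.index.name = "probe_id"
            corr.to_csv(out / "correlations.tsv", sep="\t")
            merge_tree_frame(self.cliques).to_csv(out / "merge_tree.tsv",
                                                  sep="\t", index=False)
            (out / "merge_tree.nwk").write_text(to_newick(self.cliques) + "\n",
                                                encoding="utf-8")
        if self.cross_pairs is not None:
            self.cross_pairs.to_csv(out / "cross_clique_pairs.tsv", sep="\t",
                                    index=False)
        manifest = {
            "package_version": _pkg_version,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "n_probes": self.triplet.n_probes,
            "n_patients": self.triplet.n_patients,
            "n1": self.model.labels.n1,
            "n2": self.model.labels.n2,
            "sample_misclassified": self.sample_misclassified,
        }
        with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
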