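"""Reading, writing and imputation of paired tumour/normal expression matrices.

Expression data are tab-delimited matrices with probes in rows (first column
= probe identifier) and patients in columns (header row = patient
identifiers), log2 scale.  Tumour and matched adjacent-normal matrices over
the same probes and patients are assembled into an :class:`ExpressionTriplet`
— the probes x patients x {tumour, normal} container the whole pipeline
operates on.  Missing cells (empty field, ``NA`` or ``null``) are imputed by
k-nearest-neighbour row imputation within each tissue matrix.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .errors import AlignmentError, FormatError, ImputationError, ValidationError

MISSING_SENTINELS = ["", "NA", "na", "N/A", "null", "NULL", "NaN", "nan"]


@dataclass
class ExpressionTriplet:
    """Probes x patients x {tumour, normal} expression values.

    Both matrices share probe and patient ordering; ``tumor[i, j]`` and
    ``normal[i, j]`` are the two tissue measurements of probe ``i`` in
    patient ``j`` (log2 scale, unitless).
    """

    probe_ids: list[str]
    patient_ids: list[str]
    tumor: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.tumor = np.asarray(self.tumor, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.patient_ids = [str(p) for p in self.patient_ids]
        if self.tumor.shape != self.normal.shape:
            raise ValidationError(
                f"tumor {self.tumor.shape} and normal {self.normal.shape} differ in shape"
            )
        if self.tumor.shape != (len(self.probe_ids), len(self.patient_ids)):
            raise ValidationError("matrix shape does not match identifier counts")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise FormatError("duplicate probe ids")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise FormatError("duplicate patient ids")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(f"unknown probe id {probe_id!r}") from None

    def has_missing(self) -> bool:
        return bool(np.isnan(self.tumor).any() or np.isnan(self.normal).any())

    def copy(self) -> "ExpressionTriplet":
        return ExpressionTriplet(
            list(self.probe_ids), list(self.patient_ids),
            self.tumor.copy(), self.normal.copy(),
        )

    def subset_probes(self, indices: Sequence[int]) -> "ExpressionTriplet":
        idx = list(indices)
        return ExpressionTriplet(
            [self.probe_ids[i] for i in idx], list(self.patient_ids),
            self.tumor[idx], self.normal[idx],
        )


@dataclass
class PhenotypeLabels:
    """Per-patient binary phenotype: 0 = metastasis-free, 1 = metastasis."""

    patient_ids: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.y = np.asarray(self.y, dtype=int)
        if self.y.shape != (len(self.patient_ids),):
            raise ValidationError("label vector does not match patient count")
        if not np.isin(self.y, (0, 1)).all():
            raise ValidationError("labels must be 0 (metastasis-free) or 1 (metastasis)")
        if self.n1 < 2 or self.n2 < 2:
            raise ValidationError(
                f"each group needs >= 2 patients (got n1={self.n1}, n2={self.n2})"
            )

    @property
    def n1(self) -> int:
        """Number of metastasis-free patients (group 1)."""
        return int((self.y == 0).sum())

    @property
    def n2(self) -> int:
        """Number of metastasis patients (group 2)."""
        return int((self.y == 1).sum())

    @property
    def g1_indices(self) -> np.ndarray:
        return np.flatnonzero(self.y == 0)

    @property
    def g2_indices(self) -> np.ndarray:
        return np.flatnonzero(self.y == 1)

    def check_matches(self, triplet: ExpressionTriplet) -> None:
        if self.patient_ids != triplet.patient_ids:
            diff = set(self.patient_ids) ^ set(triplet.patient_ids)
            raise AlignmentError(
                f"label/expression patient mismatch: {sorted(diff)!r}"
            )


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=MISSING_SENTINELS,
        keep_default_na=False, dtype=str,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"duplicate probe ids in {path}: {dups}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from None
    return df


def read_expression(path_tumor, path_normal) -> ExpressionTriplet:
    """Read paired tumour/normal TSV matrices, aligning rows and columns by id.

    Alignment follows identifiers, not file order: the normal matrix is
    re-indexed onto the tumour matrix's probe and patient ordering.  A
    patient or probe present in one file but not the other raises
    :class:`AlignmentError` naming the symmetric difference.
    """
    t = _read_matrix(path_tumor)
    n = _read_matrix(path_normal)
    pat_diff = set(t.columns) ^ set(n.columns)
    if pat_diff:
        raise AlignmentError(f"patient sets differ between files: {sorted(pat_diff)}")
    probe_diff = set(t.index) ^ set(n.index)
    if probe_diff:
        raise AlignmentError(f"probe sets differ between files: {sorted(probe_diff)}")
    n = n.reindex(index=t.index, columns=t.columns)
    return ExpressionTriplet(
        list(t.index), list(t.columns), t.to_numpy(), n.to_numpy()
    )


def write_expression(triplet: ExpressionTriplet, path_tumor, path_normal) -> None:
    """Write the triplet back to two TSV matrices (UTF-8, ``NA`` for missing)."""
    for mat, path in ((triplet.tumor, path_tumor), (triplet.normal, path_normal)):
        df = pd.DataFrame(mat, index=triplet.probe_ids, columns=triplet.patient_ids)
        df.index.name = "probe_id"
        df.to_csv(path, sep="\t", na_rep="NA")


_LABEL_MAP = {
    "metastasis": 1, "1": 1,
    "non-metastasis": 0, "nonmetastasis": 0, "non metastasis": 0,
    "non_metastasis": 0, "metastasis-free": 0, "0": 0,
}


def read_labels(path, patient_ids: Sequence[str] | None = None) -> PhenotypeLabels:
    """Read a two-column TSV (patient_id, label).

    Labels accept ``metastasis`` / ``non-metastasis`` (case-insensitive,
    hyphen/underscore/space tolerant) or ``1`` / ``0``.  When ``patient_ids``
    is given, rows are re-ordered to that list and mismatches raise.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"label file {path} needs two tab-separated columns")
    # Tolerate a header row that does not parse as a label.
    first = str(df.iloc[0, 1]).strip().lower()
    if first not in _LABEL_MAP:
        df = df.iloc[1:]
    ids = [str(v).strip() for v in df.iloc[:, 0]]
    y = []
    for raw in df.iloc[:, 1]:
        key = str(raw).strip().lower()
        if key not in _LABEL_MAP:
            raise FormatError(f"unrecognised label {raw!r} in {path}")
        y.append(_LABEL_MAP[key])
    labels = PhenotypeLabels(ids, np.array(y))
    if patient_ids is not None:
        wanted = [str(p) for p in patient_ids]
        diff = set(wanted) ^ set(labels.patient_ids)
        if diff:
            raise AlignmentError(f"label/expression patient mismatch: {sorted(diff)}")
        pos = {p: i for i, p in enumerate(labels.patient_ids)}
        order = [pos[p] for p in wanted]
        labels = PhenotypeLabels(wanted, labels.y[order])
    return labels


def write_labels(labels: PhenotypeLabels, path) -> None:
    names = np.where(labels.y == 1, "metastasis", "non-metastasis")
    pd.DataFrame({"patient_id": labels.patient_ids, "label": names}).to_csv(
        path, sep="\t", index=False, header=False
    )


def knn_impute(triplet: ExpressionTriplet, k: int = 10) -> ExpressionTriplet:
    """Impute missing cells by the mean of the k nearest probe rows.

    Imputation is per tissue matrix.  Nearness is Euclidean distance over
    the columns observed in both rows, rescaled by
    ``sqrt(total columns / observed columns)``; for each missing cell the
    donors are the nearest rows that observe that column (mean of their
    values there).  Observed cells are untouched.  If a column has no donor
    at all, the column mean of observed values is used as a fallback.

    Raises :class:`ImputationError` naming any probe row that is entirely
    missing in one tissue.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    out = triplet.copy()
    for name in ("tumor", "normal"):
        mat = getattr(out, name)
        all_missing = np.isnan(mat).all(axis=1)
        if all_missing.any():
            bad = [triplet.probe_ids[i] for i in np.flatnonzero(all_missing)]
            raise ImputationError(f"probe(s) entirely missing in {name}: {bad}")
        if np.isnan(mat).any():
            imputer = KNNImputer(n_neighbors=k, weights="uniform",
                                 metric="nan_euclidean")
            setattr(out, name, imputer.fit_transform(mat))
    return out


def filter_probes(
    triplet: ExpressionTriplet,
    pattern: str | re.Pattern | Callable[[str], bool],
) -> ExpressionTriplet:
    """Keep probes whose id matches a regex/substring pattern or predicate.

    Row order is preserved.  An empty result is legal and only warns (the
    caller may be probing an id namespace that is absent).
    """
    if callable(pattern) and not isinstance(pattern, re.Pattern):
        pred = pattern
    else:
        rx = re.compile(pattern) if isinstance(pattern, str) else pattern
        pred = lambda pid: rx.search(pid) is not None  # noqa: E731
    keep = [i for i, pid in enumerate(triplet.probe_ids) if pred(pid)]
    if not keep:
        warnings.warn("probe filter matched no probes", UserWarning, stacklevel=2)
    return triplet.subset_probes(keep)
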