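"""Core in-memory containers shared across the pipeline.

The analysis joins three sources on a common subject set: a subject-by-SNP
allele-count matrix (``GenotypeMatrix``), a subject-by-vertex matrix of
continuous brain features such as cortical thickness (``FeatureMatrix``),
and a phenotype/covariate table (``PhenotypeTable``).  Pairwise similarity
kernels derived from the first two live in ``RelatednessMatrix``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call in integer allele-count storage
MISSING_GENOTYPE = -1

VALID_KERNEL_KINDS = ("GRM", "BRM", "CORE", "IDENTITY")


class AlignmentError(ValueError):
    """Subject/marker identifiers do not line up across sources."""


def _check_unique(ids, what: str) -> np.ndarray:
    ids = np.asarray(ids)
    if ids.ndim != 1:
        raise ValueError(f"{what} identifiers must be one-dimensional")
    if len(set(ids.tolist())) != ids.size:
        raise AlignmentError(f"duplicate {what} identifiers")
    return ids


@dataclass
class GenotypeMatrix:
    """Subject-by-SNP allele counts in {0, 1, 2}, ``-1`` marking missing calls.

    Counts are stored as the number of copies of the first (A1) allele, the
    convention used by the PLINK 1 binary format.
    """

    subject_ids: np.ndarray
    snp_ids: np.ndarray
    counts: np.ndarray  # int8, subjects x SNPs

    def __post_init__(self):
        self.subject_ids = _check_unique(self.subject_ids, "subject")
        self.snp_ids = _check_unique(self.snp_ids, "SNP")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.subject_ids.size, self.snp_ids.size):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{self.subject_ids.size} subjects x {self.snp_ids.size} SNPs"
            )
        valid = np.isin(self.counts, (0, 1, 2, MISSING_GENOTYPE))
        if not valid.all():
            bad = np.unique(self.counts[~valid])
            raise ValueError(f"allele counts outside {{0,1,2,missing}}: {bad}")
        self.counts = self.counts.astype(np.int8, copy=False)

    @property
    def n_subjects(self) -> int:
        return self.subject_ids.size

    @property
    def n_snps(self) -> int:
        return self.snp_ids.size

    def imputed(self) -> np.ndarray:
        """Counts as float with missing calls replaced by the per-SNP mean."""
        out = self.counts.astype(float)
        out[self.counts == MISSING_GENOTYPE] = np.nan
        col_mean = np.nanmean(out, axis=0)
        # an all-missing SNP has no information; impute to 0 (dropped later
        # as a zero-variance column)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(out))
        out[idx] = col_mean[idx[1]]
        return out

    def subset(self, subject_ids) -> "GenotypeMatrix":
        idx = _index_of(self.subject_ids, subject_ids)
        return GenotypeMatrix(np.asarray(subject_ids), self.snp_ids.copy(),
                              self.counts[idx])


@dataclass
class FeatureMatrix:
    """Subject-by-feature continuous measurements (e.g. vertex-wise cortical
    thickness in mm), with an optional per-subject batch/scanner label."""

    subject_ids: np.ndarray
    feature_ids: np.ndarray
    values: np.ndarray  # float, subjects x features; NaN marks missing
    batch_labels: np.ndarray | None = None

    def __post_init__(self):
        self.subject_ids = _check_unique(self.subject_ids, "subject")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.subject_ids.size, self.feature_ids.size):
            raise ValueError("values shape does not match identifiers")
        if np.isinf(self.values).any():
            raise ValueError("feature values must be finite or NaN")
        if self.batch_labels is not None:
            self.batch_labels = np.asarray(self.batch_labels)
            if self.batch_labels.size != self.subject_ids.size:
                raise ValueError("one batch label per subject required")

    @property
    def n_subjects(self) -> int:
        return self.subject_ids.size

    @property
    def n_features(self) -> int:
        return self.feature_ids.size

    def subset(self, subject_ids) -> "FeatureMatrix":
        idx = _index_of(self.subject_ids, subject_ids)
        batches = None if self.batch_labels is None else self.batch_labels[idx]
        return FeatureMatrix(np.asarray(subject_ids), self.feature_ids.copy(),
                             self.values[idx], batches)


@dataclass
class PhenotypeTable:
    """Outcome and covariate columns, one row per subject.

    Thin wrapper over a :class:`pandas.DataFrame` indexed by subject id in
    file order; missingness is permitted per cell.
    """

    data: pd.DataFrame

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise AlignmentError("duplicate subject identifiers in table")

    @property
    def subject_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def subset(self, subject_ids) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[list(subject_ids)])


@dataclass
class RelatednessMatrix:
    """Symmetric subject-by-subject similarity kernel.

    ``kind`` is one of GRM (genomic), BRM (brain/morphological), CORE
    (symmetrized Cholesky cross-product used to model the covariance of the
    two random effects) or IDENTITY.  ``n_markers`` records how many columns
    went into a cross-product kernel.
    """

    subject_ids: np.ndarray
    values: np.ndarray
    kind: str = "GRM"
    n_markers: int | None = None

    _SYMMETRY_TOL = 1e-10

    def __post_init__(self):
        self.subject_ids = _check_unique(self.subject_ids, "subject")
        self.values = np.asarray(self.values, dtype=float)
        n = self.subject_ids.size
        if self.values.shape != (n, n):
            raise ValueError("kernel dimension does not match subject count")
        if self.kind not in VALID_KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        scale = max(1.0, float(np.abs(self.values).max(initial=0.0)))
        if np.abs(self.values - self.values.T).max(initial=0.0) > self._SYMMETRY_TOL * scale:
            raise ValueError("kernel is not symmetric")

    @property
    def n_subjects(self) -> int:
        return self.subject_ids.size

    def offdiag(self) -> np.ndarray:
        """Strict lower-triangle values as a flat vector (n(n-1)/2 pairs)."""
        i, j = np.tril_indices(self.n_subjects, k=-1)
        return self.values[i, j]

    def subset(self, subject_ids) -> "RelatednessMatrix":
        idx = _index_of(self.subject_ids, subject_ids)
        return RelatednessMatrix(np.asarray(subject_ids),
                                 self.values[np.ix_(idx, idx)],
                                 self.kind, self.n_markers)


def identity_kernel(subject_ids) -> RelatednessMatrix:
    subject_ids = np.asarray(subject_ids)
    return RelatednessMatrix(subject_ids, np.eye(subject_ids.size), "IDENTITY")


def _index_of(haystack: np.ndarray, needles) -> np.ndarray:
    pos = {s: i for i, s in enumerate(haystack.tolist())}
    try:
        return np.array([pos[s] for s in np.asarray(needles).tolist()], dtype=int)
    except KeyError as exc:  # pragma: no cover - message path
        raise AlignmentError(f"unknown subject identifier {exc.args[0]!r}") from exc
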