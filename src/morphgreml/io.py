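"""Readers and writers for the standard file formats the pipeline touches.

Supported formats
-----------------
* PLINK 1 binary genotypes (``.bed``/``.bim``/``.fam``, SNP-major layout).
* GCTA binary relatedness triplet (``.grm.bin`` float32 lower triangle,
  ``.grm.id`` two-column text, optional ``.grm.N.bin``).
* Tab-separated tables with a header row and a leading subject-id column
  for phenotypes, covariates and dense feature matrices.  ``NA`` and the
  empty string are missing.

Every reader/writer pair is a lossless round trip up to the documented
precision (float32 for the GCTA kernel files).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING_GENOTYPE,
    AlignmentError,
    FeatureMatrix,
    GenotypeMatrix,
    PhenotypeTable,
    RelatednessMatrix,
)

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
# two-bit PLINK codes -> A1 allele count (01 is the missing call)
_BED_DECODE = np.array([2, MISSING_GENOTYPE, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0, MISSING_GENOTYPE: 1, 1: 2, 0: 3}

MISSING_STRINGS = ("NA", "")


class FormatError(ValueError):
    """File does not follow the declared binary/text format."""


class CorruptionError(ValueError):
    """File sizes or element counts are internally inconsistent."""


class ParseError(ValueError):
    """A value could not be parsed as the declared column type."""


# ---------------------------------------------------------------------------
# PLINK 1 binary
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 binary fileset into a :class:`GenotypeMatrix`.

    Counts are copies of the A1 allele (the fifth ``.bim`` column):
    the two-bit codes 00/10/11 decode to 2/1/0 and 01 to missing.
    Subject order follows ``.fam``, SNP order follows ``.bim``.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      dtype=str)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      dtype=str)
    subject_ids = fam.iloc[:, 1].to_numpy()
    snp_ids = bim.iloc[:, 1].to_numpy()
    n, m = subject_ids.size, snp_ids.size

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:2] != _BED_MAGIC[:2]:
        raise FormatError(f"{prefix}.bed: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != _BED_MAGIC[2:3]:
        raise FormatError(f"{prefix}.bed: not SNP-major (mode byte {raw[2]:#x})")
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != m * bytes_per_snp:
        raise CorruptionError(
            f"{prefix}.bed: payload of {payload.size} bytes does not match "
            f"{m} SNPs x {bytes_per_snp} bytes ({n} subjects)"
        )
    blocks = payload.reshape(m, bytes_per_snp)
    # unpack the four 2-bit genotypes per byte, subject index ascending with
    # the low bits first
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    counts = _BED_DECODE[codes[:, :n]].T  # -> subjects x SNPs
    return GenotypeMatrix(subject_ids, snp_ids, counts)


def write_plink(prefix: str | Path, geno: GenotypeMatrix) -> None:
    """Write a :class:`GenotypeMatrix` as a PLINK 1 binary fileset.

    Placeholder pedigree (FID = IID, unknown parents/sex) and map columns
    (chromosome 1, base positions 1..m, alleles A/B) are emitted.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fam = pd.DataFrame({
        0: geno.subject_ids, 1: geno.subject_ids,
        2: "0", 3: "0", 4: "0", 5: "-9",
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame({
        0: "1", 1: geno.snp_ids, 2: "0",
        3: np.arange(1, geno.n_snps + 1), 4: "A", 5: "B",
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    n, m = geno.n_subjects, geno.n_snps
    bytes_per_snp = (n + 3) // 4
    codes = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    # counts {0,1,2} -> codes {3,2,0}; missing (-1, remapped to slot 3) -> 1
    lut = np.array([3, 2, 0, 1], dtype=np.uint8)
    idx = geno.counts.T.copy()
    idx[idx == MISSING_GENOTYPE] = 3
    codes[:, :n] = lut[idx]
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# GCTA binary GRM triplet
# ---------------------------------------------------------------------------

def read_grm_bin(prefix: str | Path, kind: str = "GRM") -> RelatednessMatrix:
    """Read a GCTA binary relatedness triplet (``prefix.grm.bin`` + ``.grm.id``).

    The ``.bin`` file stores the lower triangle (diagonal included) row by
    row as 4-byte floats; ``.grm.id`` holds family and individual ids, of
    which the individual id is used.
    """
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None, dtype=str)
    subject_ids = ids.iloc[:, 1].to_numpy()
    n = subject_ids.size
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    expected = n * (n + 1) // 2
    if tri.size != expected:
        raise CorruptionError(
            f"{prefix}.grm.bin holds {tri.size} elements, expected "
            f"n(n+1)/2 = {expected} for {n} ids"
        )
    values = np.zeros((n, n))
    i, j = np.tril_indices(n)
    values[i, j] = tri
    values[j, i] = tri
    n_markers = None
    npath = Path(f"{prefix}.grm.N.bin")
    if npath.exists():
        counts = np.fromfile(npath, dtype="<f4")
        if counts.size:
            n_markers = int(round(float(counts[0])))
    return RelatednessMatrix(subject_ids, values, kind, n_markers)


def write_grm_bin(prefix: str | Path, matrix: RelatednessMatrix) -> None:
    """Write a :class:`RelatednessMatrix` as a GCTA binary triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({0: matrix.subject_ids, 1: matrix.subject_ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False)
    i, j = np.tril_indices(matrix.n_subjects)
    matrix.values[i, j].astype("<f4").tofile(f"{prefix}.grm.bin")
    n_markers = matrix.n_markers if matrix.n_markers is not None else 0
    np.full(i.size, n_markers, dtype="<f4").tofile(f"{prefix}.grm.N.bin")


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path, role: str = "phenotype"):
    """Read a tab-separated table with a header and leading subject-id column.

    ``role`` selects the container: ``"feature"`` gives a strictly numeric
    :class:`FeatureMatrix`; ``"phenotype"`` or ``"covariate"`` give a
    :class:`PhenotypeTable` whose columns keep their parsed dtypes
    (categorical covariates stay as strings).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=list(MISSING_STRINGS),
                     keep_default_na=False)
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise AlignmentError(f"{path}: duplicated subject id {dup!r}")
    df = df.set_index(id_col)
    if role == "feature":
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: non-numeric value in feature matrix: {exc}") from exc
        return FeatureMatrix(df.index.to_numpy(), df.columns.to_numpy(), values)
    if role in ("phenotype", "covariate"):
        return PhenotypeTable(df)
    raise ValueError(f"unknown table role {role!r}")


def write_table(path: str | Path, obj) -> None:
    """Write a :class:`PhenotypeTable` or :class:`FeatureMatrix` as TSV."""
    if isinstance(obj, FeatureMatrix):
        df = pd.DataFrame(obj.values, index=obj.subject_ids, columns=obj.feature_ids)
    elif isinstance(obj, PhenotypeTable):
        df = obj.data
    else:
        df = pd.DataFrame(obj)
    df = df.rename_axis("subject_id")
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Subject alignment
# ---------------------------------------------------------------------------

def align_subjects(*sources):
    """Intersect subject ids across sources, ordered as in the first source.

    Each source must expose ``subject_ids`` and ``subset``.  Ids absent from
    any source are dropped with a logged count.  Returns the aligned copies
    in input order.
    """
    if not sources:
        return ()
    common = set(sources[0].subject_ids.tolist())
    for src in sources[1:]:
        common &= set(src.subject_ids.tolist())
    ordered = [s for s in sources[0].subject_ids.tolist() if s in common]
    for src in sources:
        dropped = src.subject_ids.size - len(ordered)
        if dropped:
            logger.info("align_subjects: dropped %d of %d subjects from %s",
                        dropped, src.subject_ids.size, type(src).__name__)
    return tuple(src.subset(ordered) for src in sources)
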