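"""Shared data model: genotype matrices, sample metadata, locus annotation.

Genotypes are biallelic SNP calls coded as the number of copies of a
per-locus "counted allele" (0, 1 or 2), with :data:`MISSING` (-1) for
uncalled genotypes.  Sample metadata travels as a validated
:class:`pandas.DataFrame` with a fixed column contract (see
:func:`validate_metadata`); locus annotation likewise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for an uncalled genotype.
MISSING: int = -1

#: Allowed genotype codes (copies of the counted allele) plus the missing sentinel.
VALID_CODES = frozenset({0, 1, 2, MISSING})

#: Recognised migratory-strategy classes for the ``group`` metadata column.
GROUPS = ("migratory", "partial", "resident", "unknown")

#: Recognised sex codes.
SEXES = ("F", "M", "unknown")

#: Metadata columns every table carries after validation.
METADATA_COLUMNS = ("sample_id", "site", "latitude", "group", "capture_day", "sex", "year")


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci, coded as copies of the counted allele.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``codes``.
    locus_ids
        Unique locus identifiers, one per column of ``codes``.
    codes
        ``(n_samples, n_loci)`` integer array over {0, 1, 2, MISSING}.
    counted_allele
        Per-locus label of the allele whose copies are counted (e.g. the
        VCF ALT base).  Purely bookkeeping; flipping it maps codes 0<->2.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    codes: np.ndarray
    counted_allele: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(s) for s in self.locus_ids]
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D array (samples x loci)")
        n, m = self.codes.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.locus_ids) != m:
            raise ValueError(f"{len(self.locus_ids)} locus ids for {m} columns")
        if len(self.counted_allele) != m:
            raise ValueError("counted_allele must have one entry per locus")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(set(self.locus_ids)) != m:
            raise ValueError("locus_ids are not unique")
        bad = set(np.unique(self.codes)) - VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None

    def locus_index(self, locus_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.locus_ids)}
        try:
            return np.array([lookup[s] for s in locus_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown locus id {e.args[0]!r}") from None

    # -- subsetting --------------------------------------------------------
    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = self.sample_index(sample_ids)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.locus_ids),
            self.codes[idx, :],
            list(self.counted_allele),
        )

    def subset_loci(self, locus_ids) -> "GenotypeMatrix":
        idx = self.locus_index(locus_ids)
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.locus_ids[i] for i in idx],
            self.codes[:, idx],
            [self.counted_allele[i] for i in idx],
        )

    # -- summaries ---------------------------------------------------------
    def allele_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Counted-allele frequency per locus over called genotypes.

        ``rows`` optionally restricts to a subset of sample row indices.
        Loci with no calls yield NaN.
        """
        codes = self.codes if rows is None else self.codes[np.asarray(rows), :]
        called = codes != MISSING
        n_alleles = 2 * called.sum(axis=0)
        counts = np.where(called, codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, counts / np.maximum(n_alleles, 1), np.nan)

    def call_rate(self) -> np.ndarray:
        """Fraction of called genotypes per sample."""
        return (self.codes != MISSING).mean(axis=1)


@dataclass
class LocusAnnotation:
    """Genomic coordinates and alleles of one biallelic SNP (VCF 1-based)."""

    locus_id: str
    chrom: str
    pos: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.locus_id}: pos must be >= 1")


def annotation_frame(annotations: list[LocusAnnotation]) -> pd.DataFrame:
    """Annotations as a DataFrame indexed by locus_id."""
    df = pd.DataFrame(
        [(a.locus_id, a.chrom, a.pos, a.ref_allele, a.alt_allele, a.gene) for a in annotations],
        columns=["locus_id", "chrom", "pos", "ref_allele", "alt_allele", "gene"],
    )
    return df.set_index("locus_id", drop=False)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce and validate a sample-metadata table.

    Required column: ``sample_id`` (unique).  Optional columns are filled
    with their missing value: site '' , latitude NaN, group/sex 'unknown',
    capture_day/year pandas NA.  Unknown group or sex categories are mapped
    to 'unknown'.  Raises on duplicate sample ids or out-of-range
    capture_day / latitude.
    """
    df = df.copy()
    if "sample_id" not in df.columns:
        raise ValueError("metadata must have a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id values: {dups}")

    if "site" not in df.columns:
        df["site"] = ""
    df["site"] = df["site"].fillna("").astype(str)

    if "latitude" not in df.columns:
        df["latitude"] = np.nan
    df["latitude"] = pd.to_numeric(df["latitude"], errors="coerce")
    lat = df["latitude"].dropna()
    if ((lat < -90) | (lat > 90)).any():
        raise ValueError("latitude outside [-90, 90]")

    for col, allowed in (("group", GROUPS), ("sex", SEXES)):
        if col not in df.columns:
            df[col] = "unknown"
        df[col] = df[col].fillna("unknown").astype(str)
        df.loc[~df[col].isin(allowed), col] = "unknown"

    for col in ("capture_day", "year"):
        if col not in df.columns:
            df[col] = pd.NA
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    day = df["capture_day"].dropna()
    if ((day < 1) | (day > 366)).any():
        raise ValueError("capture_day outside [1, 366]")

    return df.loc[:, list(METADATA_COLUMNS) + [c for c in df.columns if c not in METADATA_COLUMNS]]


@dataclass
class AssayContext:
    """Flanking-sequence context of one candidate SNP for assay design.

    ``target_offset`` is the 0-based index of the variant base within
    ``flank_seq``; ``nearby_variants`` lists (offset, kind) of other known
    variants in the same coordinate system, kind in {"snp", "indel"}.
    """

    locus_id: str
    flank_seq: str
    target_offset: int
    nearby_variants: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.target_offset < len(self.flank_seq)):
            raise ValueError(f"{self.locus_id}: target_offset outside flank_seq")
        for off, kind in self.nearby_variants:
            if not (0 <= off < len(self.flank_seq)):
                raise ValueError(f"{self.locus_id}: variant offset {off} outside flank_seq")
            if kind not in ("snp", "indel"):
                raise ValueError(f"{self.locus_id}: unknown variant kind {kind!r}")
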