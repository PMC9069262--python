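"""Readers and writers for the standard formats the pipeline consumes.

VCF is read through :mod:`cyvcf2` (GT fields only; biallelic SNP records).
Gene intervals come from BED (0-based half-open) or GFF3 (1-based closed)
and are normalised internally to 0-based half-open coordinates, converted
only at this I/O boundary.  A simple wide CSV carries genotype matrices
between stages; the per-locus counted allele is encoded in the column
header as ``locus:allele`` so a single file round-trips exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .datatypes import (
    MISSING,
    GenotypeMatrix,
    LocusAnnotation,
    validate_metadata,
)

log = logging.getLogger(__name__)

_NUCS = frozenset("ACGT")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, counted_allele_rule: str = "alt"):
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        VCF 4.x file (plain text or bgzipped).
    counted_allele_rule
        Which allele the genotype codes count: ``"alt"`` (default) or
        ``"ref"``.  Downstream major-allele re-polarisation is a separate,
        explicit step (:func:`chronoscan.timing.repolarize_major`).

    Returns
    -------
    (GenotypeMatrix, list[LocusAnnotation])
        One annotation row per retained locus.  Multi-allelic records and
        indels are skipped with a log message.

    Raises
    ------
    OSError
        If the file cannot be read.
    ValueError
        If no biallelic SNP records are retained.
    """
    from cyvcf2 import VCF

    if counted_allele_rule not in ("alt", "ref"):
        raise ValueError("counted_allele_rule must be 'alt' or 'ref'")
    path = Path(path)
    if not path.exists():
        raise OSError(f"VCF not found: {path}")

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    locus_ids: list[str] = []
    counted: list[str] = []
    rows: list[np.ndarray] = []
    annotations: list[LocusAnnotation] = []
    n_skipped = 0

    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if ref not in _NUCS or alt not in _NUCS:
            n_skipped += 1
            continue
        codes = np.full(len(sample_ids), MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a is not None]
            if len(alleles) < 2 or any(a < 0 for a in alleles):
                continue
            codes[i] = sum(1 for a in alleles[:2] if a > 0)
        if counted_allele_rule == "ref":
            codes = np.where(codes == MISSING, MISSING, 2 - codes).astype(np.int8)
        locus_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        locus_ids.append(locus_id)
        counted.append(alt if counted_allele_rule == "alt" else ref)
        rows.append(codes)
        annotations.append(LocusAnnotation(locus_id, var.CHROM, var.POS, ref, alt))

    if n_skipped:
        log.warning("skipped %d non-biallelic-SNP records in %s", n_skipped, path.name)
    if not locus_ids:
        raise ValueError(f"no biallelic SNP records retained from {path}")

    codes = np.stack(rows, axis=1)
    return GenotypeMatrix(sample_ids, locus_ids, codes, counted), annotations


def write_vcf(path: str | Path, gm: GenotypeMatrix, annotations: list[LocusAnnotation]) -> None:
    """Write a minimal VCF 4.2 (GT only) for a genotype matrix.

    Assumes the counted allele is the ALT allele of each annotation, the
    convention produced by the synthetic generators and ``read_vcf``.
    """
    ann = {a.locus_id: a for a in annotations}
    order = sorted(gm.locus_ids, key=lambda lid: (ann[lid].chrom, ann[lid].pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        col = {lid: j for j, lid in enumerate(gm.locus_ids)}
        for lid in order:
            a = ann[lid]
            codes = gm.codes[:, col[lid]]
            fields = [a.chrom, str(a.pos), lid, a.ref_allele, a.alt_allele, ".", "PASS", ".", "GT"]
            fields += [gt_str[int(c)] for c in codes]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample-metadata CSV (see :func:`validate_metadata`)."""
    df = pd.read_csv(path)
    n_unknown_before = 0
    for col in ("group", "sex"):
        if col in df.columns:
            n_unknown_before += df[col].isna().sum()
    out = validate_metadata(df)
    n_unknown = int((out["group"] == "unknown").sum() + (out["sex"] == "unknown").sum())
    if n_unknown > n_unknown_before:
        log.warning("%d category values mapped to 'unknown' in %s", n_unknown, path)
    return out


def write_metadata(path: str | Path, meta: pd.DataFrame) -> None:
    meta.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gene intervals
# ---------------------------------------------------------------------------

class GeneIndex:
    """Gene intervals indexed for point queries, 0-based half-open internally."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self.n_genes = 0

    def add(self, chrom: str, start0: int, end0: int, gene: str) -> bool:
        """Add one normalised interval; returns False (skipped) if empty."""
        if end0 <= start0:
            return False
        self._trees.setdefault(chrom, IntervalTree()).addi(start0, end0, gene)
        self.n_genes += 1
        return True

    def query(self, chrom: str, pos_1based: int) -> list[str]:
        """Gene names overlapping a 1-based (VCF) position, sorted."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.at(pos_1based - 1)})

    def __len__(self) -> int:
        return self.n_genes


def read_gene_intervals(path: str | Path, format: str | None = None) -> GeneIndex:
    """Read gene intervals from BED or GFF3 into a :class:`GeneIndex`.

    BED is 0-based half-open; GFF3 is 1-based closed (only ``gene``
    features are indexed, named by ``Name=``/``gene=``/``ID=``).  The
    format is inferred from the file suffix when not given.  Malformed
    intervals (empty after normalisation) are skipped with a warning.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "GFF3" if suffix in (".gff", ".gff3") else "BED"
    format = format.upper()
    if format not in ("BED", "GFF3"):
        raise ValueError(f"unknown interval format {format!r}")

    idx = GeneIndex()
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if format == "BED":
                if len(parts) < 3:
                    n_skipped += 1
                    continue
                chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
                gene = parts[3] if len(parts) > 3 else f"{chrom}:{start0}-{end0}"
            else:
                if len(parts) < 9 or parts[2].lower() != "gene":
                    continue
                chrom = parts[0]
                start0, end0 = int(parts[3]) - 1, int(parts[4])  # 1-based closed -> half-open
                gene = _gff3_name(parts[8])
            if not idx.add(chrom, start0, end0, gene):
                n_skipped += 1
    if n_skipped:
        log.warning("skipped %d malformed intervals in %s", n_skipped, path.name)
    return idx


def _gff3_name(attributes: str) -> str:
    attrs = dict(
        kv.split("=", 1) for kv in attributes.strip().split(";") if "=" in kv
    )
    for key in ("Name", "gene", "gene_name", "ID"):
        if key in attrs:
            return attrs[key]
    return attributes.strip()


# ---------------------------------------------------------------------------
# Wide genotype CSV
# ---------------------------------------------------------------------------

def write_genotype_csv(path: str | Path, gm: GenotypeMatrix) -> None:
    """Write a wide CSV: rows = samples, columns = ``locus:counted_allele``."""
    cols = [f"{lid}:{al}" for lid, al in zip(gm.locus_ids, gm.counted_allele)]
    df = pd.DataFrame(
        np.where(gm.codes == MISSING, np.nan, gm.codes),
        index=pd.Index(gm.sample_ids, name="sample_id"),
        columns=cols,
    )
    df.to_csv(path, float_format="%.0f")


def read_genotype_csv(path: str | Path) -> GenotypeMatrix:
    """Read a wide genotype CSV written by :func:`write_genotype_csv`.

    Column headers without a ``:allele`` suffix get counted allele "A"
    (arbitrary label) so externally prepared 0/1/2 tables also load.
    """
    df = pd.read_csv(path, index_col=0)
    locus_ids, counted = [], []
    for col in df.columns:
        if ":" in col:
            lid, al = col.rsplit(":", 1)
        else:
            lid, al = col, "A"
        locus_ids.append(lid)
        counted.append(al)
    codes = df.to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    return GenotypeMatrix([str(s) for s in df.index], locus_ids, codes, counted)


# ---------------------------------------------------------------------------
# FASTA + nearby-variant TSV (assay-filter inputs)
# ---------------------------------------------------------------------------

def read_flank_contexts(fasta_path: str | Path, variants_path: str | Path | None = None):
    """Read assay contexts from a FASTA of flanks plus an optional variant TSV.

    FASTA headers are ``>locus_id offset=<target_offset>``; the TSV has
    columns locus_id, offset, kind.
    """
    from .datatypes import AssayContext

    seqs: dict[str, tuple[str, int]] = {}
    name, offset, chunks = None, None, []
    with open(fasta_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = ("".join(chunks), offset)
                header = line[1:].split()
                name = header[0]
                offset = 0
                for tok in header[1:]:
                    if tok.startswith("offset="):
                        offset = int(tok.split("=", 1)[1])
                chunks = []
            else:
                chunks.append(line.strip())
        if name is not None:
            seqs[name] = ("".join(chunks), offset)

    nearby: dict[str, list[tuple[int, str]]] = {}
    if variants_path is not None:
        vdf = pd.read_csv(variants_path, sep="\t")
        for _, row in vdf.iterrows():
            nearby.setdefault(str(row["locus_id"]), []).append((int(row["offset"]), str(row["kind"])))

    return [
        AssayContext(lid, seq, off, nearby.get(lid, []))
        for lid, (seq, off) in seqs.items()
    ]


def write_flank_contexts(fasta_path: str | Path, variants_path: str | Path, contexts) -> None:
    with open(fasta_path, "w") as fh:
        for ctx in contexts:
            fh.write(f">{ctx.locus_id} offset={ctx.target_offset}\n")
            seq = ctx.flank_seq
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    rows = [
        (ctx.locus_id, off, kind)
        for ctx in contexts
        for off, kind in ctx.nearby_variants
    ]
    pd.DataFrame(rows, columns=["locus_id", "offset", "kind"]).to_csv(
        variants_path, sep="\t", index=False
    )
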