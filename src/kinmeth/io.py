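"""Readers and writers for the external file dialects.

Supported formats: the Bismark coverage dialect (6-column TSV: chrom, start,
end, percent methylation, methylated count, unmethylated count), BED6 and
GFF3 gene models, VCF 4.x SNP position lists, and a headered CSV sample
sheet.  Internal coordinates are 1-based inclusive; BED is converted at the
boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .matrix import MISSING, MethylationMatrix, SampleMeta


@dataclass(frozen=True)
class CoverageRecord:
    """One CpG observation from a Bismark coverage file (1-based position)."""

    chrom: str
    pos: int
    strand: str  # '+', '-' or '.' when unknown
    n_meth: int
    n_unmeth: int

    @property
    def total(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def percent(self) -> float:
        return 100.0 * self.n_meth / self.total


@dataclass(frozen=True)
class GeneModel:
    """A gene span, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


class ParseError(ValueError):
    pass


def read_bismark_coverage(path, sample_id: str = "") -> list:
    """Parse a Bismark-style coverage file into CoverageRecords.

    The percent-methylation column is ignored on read (it is recomputed from
    the counts) but is cross-checked against the counts to catch corrupted
    files: a discrepancy beyond 0.1 percentage points is a parse error.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 columns, got {len(parts)}")
            chrom, start, _end, pct, n_meth, n_unmeth = parts[:6]
            try:
                pos = int(start)
                nm = int(n_meth)
                nu = int(n_unmeth)
                pct_val = float(pct)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            if nm < 0 or nu < 0:
                raise ParseError(f"{path}:{lineno}: negative count")
            if nm + nu == 0:
                raise ParseError(f"{path}:{lineno}: zero total coverage line")
            if abs(pct_val - 100.0 * nm / (nm + nu)) > 0.1:
                raise ParseError(
                    f"{path}:{lineno}: %meth column disagrees with counts"
                )
            records.append(CoverageRecord(chrom, pos, ".", nm, nu))
    return records


def write_bismark_coverage(path, records) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.pos}\t"
                f"{rec.percent:.6g}\t{rec.n_meth}\t{rec.n_unmeth}\n"
            )


def assemble_matrix(per_sample_records) -> MethylationMatrix:
    """Join per-sample coverage records into one sites x samples matrix.

    Parameters
    ----------
    per_sample_records : list of (SampleMeta, list of CoverageRecord)

    The site set is the union over samples; a site absent from a sample's
    file is marked missing (distinct from zero coverage, which is invalid
    input).  Sites are sorted by (chrom, pos).
    """
    if not per_sample_records:
        raise ValueError("need at least one sample")
    site_index: dict = {}
    for _meta, recs in per_sample_records:
        for rec in recs:
            site_index.setdefault((rec.chrom, rec.pos), None)
    sites = sorted(site_index)
    lut = {key: i for i, key in enumerate(sites)}
    n, m = len(sites), len(per_sample_records)
    meth = np.full((n, m), MISSING, dtype=np.int64)
    total = np.full((n, m), MISSING, dtype=np.int64)
    metas = []
    for j, (meta, recs) in enumerate(per_sample_records):
        metas.append(meta)
        for rec in recs:
            i = lut[(rec.chrom, rec.pos)]
            if total[i, j] != MISSING:
                raise ValueError(
                    f"sample {meta.sample_id}: duplicate site {rec.chrom}:{rec.pos}"
                )
            meth[i, j] = rec.n_meth
            total[i, j] = rec.total
    site_df = pd.DataFrame(
        {
            "chrom": [c for c, _ in sites],
            "pos": [p for _, p in sites],
            "strand": ["."] * n,
        }
    )
    return MethylationMatrix(site_df, metas, meth, total)


def matrix_to_records(matrix: MethylationMatrix, sample_index: int) -> list:
    """Extract one sample's observed cells back into CoverageRecords."""
    out = []
    chroms = matrix.sites["chrom"].to_numpy()
    poss = matrix.sites["pos"].to_numpy()
    strands = matrix.sites["strand"].to_numpy()
    for i in range(matrix.n_sites):
        t = matrix.total[i, sample_index]
        if t == MISSING:
            continue
        m = matrix.meth[i, sample_index]
        out.append(CoverageRecord(chroms[i], int(poss[i]), strands[i], int(m), int(t - m)))
    return out


def read_gene_models(path, dialect: str) -> list:
    """Read gene models from BED6 (0-based half-open) or GFF3 (1-based).

    Coordinates are normalized to 1-based inclusive internally.
    """
    if dialect not in ("bed", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if dialect == "bed":
                if len(parts) < 4:
                    raise ParseError(f"{path}:{lineno}: BED needs >=4 columns")
                chrom, start0, end0, name = parts[:4]
                strand = parts[5] if len(parts) >= 6 else "+"
                start = int(start0) + 1  # 0-based half-open -> 1-based inclusive
                end = int(end0)
                if start > end:
                    raise ParseError(f"{path}:{lineno}: empty or inverted interval")
                genes.append(GeneModel(name, chrom, start, end, strand))
            else:
                if len(parts) < 9:
                    raise ParseError(f"{path}:{lineno}: GFF3 needs 9 columns")
                chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
                if ftype != "gene":
                    continue
                gene_id = ""
                for item in attrs.split(";"):
                    if item.startswith("ID="):
                        gene_id = item[3:]
                        break
                if not gene_id:
                    gene_id = f"{chrom}:{start}-{end}"
                s, e = int(start), int(end)
                if s > e:
                    raise ParseError(f"{path}:{lineno}: start > end")
                genes.append(GeneModel(gene_id, chrom, s, e, strand if strand in "+-" else "+"))
    return genes


def write_gene_models_bed(path, genes) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_snp_sites(path) -> set:
    """Read a VCF 4.x and return the set of unique (chrom, 1-based pos)."""
    out = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            out.add((rec.chrom, rec.pos))
    return out


SAMPLE_SHEET_COLUMNS = ["sample_id", "group", "timepoint", "tissue", "family_id", "path"]


def read_sample_sheet(path):
    """Read the headered CSV sample sheet.

    Returns a list of (SampleMeta, coverage-file path) pairs; the path column
    may be empty when counts are supplied another way.
    """
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in SAMPLE_SHEET_COLUMNS[:-1] if c not in (reader.fieldnames or [])]
        if missing:
            raise ParseError(f"{path}: sample sheet missing columns {missing}")
        for row in reader:
            meta = SampleMeta(
                sample_id=row["sample_id"],
                group=row["group"],
                timepoint=row["timepoint"],
                tissue=row["tissue"],
                family_id=row.get("family_id") or "unknown",
            )
            rows.append((meta, row.get("path", "")))
    ids = [m.sample_id for m, _ in rows]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate sample_id")
    return rows


def write_sample_sheet(path, metas, paths=None) -> None:
    paths = paths or ["" for _ in metas]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SAMPLE_SHEET_COLUMNS)
        for meta, p in zip(metas, paths):
            writer.writerow(
                [meta.sample_id, meta.group, meta.timepoint, meta.tissue, meta.family_id, p]
            )


def load_dataset(sheet_path) -> MethylationMatrix:
    """Load a full dataset from a sample sheet whose path column points at
    per-sample Bismark coverage files (relative paths resolved against the
    sheet's directory)."""
    base = Path(sheet_path).parent
    pairs = []
    for meta, rel in read_sample_sheet(sheet_path):
        if not rel:
            raise ParseError(f"sample {meta.sample_id}: no coverage path in sheet")
        p = Path(rel)
        if not p.is_absolute():
            p = base / p
        pairs.append((meta, read_bismark_coverage(p, meta.sample_id)))
    return assemble_matrix(pairs)
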