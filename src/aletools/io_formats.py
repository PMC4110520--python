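"""Readers and writers for every external representation the pipeline touches.

All coordinates are 1-based and inclusive, matching the convention of the
genome annotation this pipeline targets.  Indels use an empty-allele
convention (``ref_allele == ""`` for a pure insertion, ``alt_allele == ""``
for a pure deletion); the VCF anchor-base representation is produced/consumed
only at the VCF boundary.

Formats handled here:

* OD tables — tab-separated ``strain, time_days, od750, temp_c[, dilution]``.
* High-confidence difference records — a fixed 8-column tab-separated dialect
  (``replicon, start, end, ref, alt, variant_reads, total_reads, note``) with
  ``>``-prefixed comment lines, standing in for the under-documented mapper
  output the original analysis consumed.
* VCF v4.2 (read support in INFO keys ``DP`` and ``VR``).
* FASTA reference genomes, tabular gene models, and gene-category flatfiles.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ODTimeSeries",
    "DiffRecord",
    "GeneModel",
    "CategoryEntry",
    "FormatError",
    "read_od_table",
    "write_od_table",
    "read_hcdiffs",
    "write_hcdiffs",
    "rename_replicons",
    "read_vcf",
    "write_vcf",
    "read_category_flatfile",
    "write_category_flatfile",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
]

VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates its dialect or an invariant."""


@dataclass(frozen=True)
class ODTimeSeries:
    """One culture's OD750 trace with the temperature in force at each reading.

    ``readings`` is an ordered tuple of ``(time_days, od750, temp_c,
    dilution)``.  ``dilution`` is the factor by which the culture was diluted
    immediately *before* that reading (1.0 = none); growth-rate computation
    unwinds it so dilution events do not register as negative growth.
    """

    strain_id: str
    readings: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        times = [r[0] for r in self.readings]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise FormatError(
                f"strain {self.strain_id!r}: times must be strictly increasing"
            )

    def at_temperature(self, temp_c: float, tol: float = 1e-6) -> "ODTimeSeries":
        """Sub-series of the readings held at ``temp_c`` (within ``tol``)."""
        sub = tuple(r for r in self.readings if abs(r[2] - temp_c) <= tol)
        return ODTimeSeries(self.strain_id, sub)

    @property
    def temperatures(self) -> tuple[float, ...]:
        """Distinct held temperatures, in order of first appearance."""
        seen: dict[float, None] = {}
        for _, _, t, _ in self.readings:
            seen.setdefault(t, None)
        return tuple(seen)


@dataclass(frozen=True)
class DiffRecord:
    """One called difference against the reference.

    For a substitution ``start..end`` covers the replaced bases.  For a pure
    insertion ``ref_allele`` is empty and ``start == end`` names the reference
    base *after which* the new bases sit.  For a pure deletion ``alt_allele``
    is empty and ``start..end`` covers the removed bases.
    """

    replicon: str
    start: int
    end: int
    ref_allele: str
    alt_allele: str
    variant_reads: int
    total_reads: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.ref_allele and self.start > self.end:
            raise FormatError(f"{self}: start > end with non-empty ref allele")
        if self.variant_reads > self.total_reads:
            raise FormatError(
                f"{self.replicon}:{self.start}: variant reads "
                f"{self.variant_reads} exceed total {self.total_reads}"
            )
        for allele in (self.ref_allele, self.alt_allele):
            if set(allele) - VALID_BASES:
                raise FormatError(f"{self}: allele {allele!r} not over ACGT")
        if not self.ref_allele and not self.alt_allele:
            raise FormatError(f"{self.replicon}:{self.start}: both alleles empty")


@dataclass(frozen=True)
class GeneModel:
    locus_tag: str
    replicon: str
    start: int
    end: int
    strand: str
    coding: bool
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"gene {self.locus_tag}: start > end")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.locus_tag}: strand must be + or -")
        if self.coding and (self.end - self.start + 1) % 3 != 0:
            raise FormatError(
                f"gene {self.locus_tag}: coding length not divisible by 3"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CategoryEntry:
    locus_tag: str
    function: str
    category: str
    subcategory: str


UNKNOWN_CATEGORY = CategoryEntry("", "unknown", "unknown", "unknown")


# ---------------------------------------------------------------------------
# helpers

def _as_text(source) -> str:
    if isinstance(source, (str, Path)) and "\n" not in str(source) and str(source):
        return Path(source).read_text()
    if hasattr(source, "read"):
        return source.read()
    return str(source)


def _write_text(text: str, dest) -> str:
    if dest is None:
        return text
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)
    return text


# ---------------------------------------------------------------------------
# OD tables

OD_COLUMNS = ["strain", "time_days", "od750", "temp_c", "dilution"]


def read_od_table(source) -> list[ODTimeSeries]:
    """Parse a tab-separated OD table into one series per strain.

    The ``dilution`` column is optional and defaults to 1.0.  Rejects
    non-numeric cells (naming the row) and non-monotone times (naming the
    strain).
    """
    text = _as_text(source)
    try:
        frame = pd.read_csv(io.StringIO(text), sep="\t", dtype={"strain": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError("OD table is empty (no header)") from exc
    required = OD_COLUMNS[:4]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"OD table missing column(s): {', '.join(missing)}")
    if "dilution" not in frame.columns:
        frame["dilution"] = 1.0
    for col in ("time_days", "od750", "temp_c", "dilution"):
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header
            raise FormatError(f"OD table row {row}: non-numeric value in {col!r}")
        frame[col] = converted
    series: list[ODTimeSeries] = []
    for strain, grp in frame.groupby("strain", sort=True):
        grp = grp.sort_values("time_days", kind="stable")
        times = grp["time_days"].to_numpy()
        if len(times) > 1 and (times[1:] <= times[:-1]).any():
            raise FormatError(f"strain {strain!r}: duplicate time points")
        readings = tuple(
            (float(t), float(od), float(temp), float(dil))
            for t, od, temp, dil in zip(
                times, grp["od750"], grp["temp_c"], grp["dilution"]
            )
        )
        series.append(ODTimeSeries(str(strain), readings))
    return series


def write_od_table(series: Iterable[ODTimeSeries], dest=None) -> str:
    rows = []
    for s in series:
        for t, od, temp, dil in s.readings:
            rows.append((s.strain_id, t, od, temp, dil))
    frame = pd.DataFrame(rows, columns=OD_COLUMNS)
    text = frame.to_csv(sep="\t", index=False, float_format="%.10g")
    return _write_text(text, dest)


# ---------------------------------------------------------------------------
# high-confidence difference records

HCDIFFS_COMMENT = ">"


def read_hcdiffs(source) -> list[DiffRecord]:
    """Parse the 8-column tab-separated difference dialect.

    Lines starting with ``>`` are comments/headers and skipped; every other
    non-blank line must yield exactly one record.  ``-`` encodes an empty
    allele.
    """
    records: list[DiffRecord] = []
    for lineno, line in enumerate(_as_text(source).splitlines(), start=1):
        if not line.strip() or line.startswith(HCDIFFS_COMMENT):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 7:
            raise FormatError(f"HCDiffs line {lineno}: expected ≥7 columns")
        replicon, start, end, ref, alt, vr, tr = fields[:7]
        note = fields[7] if len(fields) > 7 else ""
        try:
            rec = DiffRecord(
                replicon=replicon,
                start=int(start),
                end=int(end),
                ref_allele="" if ref == "-" else ref.upper(),
                alt_allele="" if alt == "-" else alt.upper(),
                variant_reads=int(vr),
                total_reads=int(tr),
                note=note,
            )
        except (ValueError, FormatError) as exc:
            raise FormatError(f"HCDiffs line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_hcdiffs(records: Iterable[DiffRecord], dest=None, header: str = "") -> str:
    lines = []
    if header:
        lines.extend(HCDIFFS_COMMENT + h for h in header.splitlines())
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.replicon,
                    str(r.start),
                    str(r.end),
                    r.ref_allele or "-",
                    r.alt_allele or "-",
                    str(r.variant_reads),
                    str(r.total_reads),
                    r.note,
                ]
            )
        )
    return _write_text("\n".join(lines) + "\n", dest)


def rename_replicons(
    records: Sequence[DiffRecord],
    mapping: Mapping[str, str],
    allow_unmapped: bool = False,
) -> list[DiffRecord]:
    """Replace replicon names, leaving every other field untouched.

    Collisions (two old names mapping to one new name) are permitted;
    downstream identity is keyed by (replicon, position, alleles).
    """
    unmapped = sorted({r.replicon for r in records} - set(mapping))
    if unmapped and not allow_unmapped:
        raise FormatError(f"unmapped replicon(s): {', '.join(unmapped)}")
    return [
        replace(r, replicon=mapping.get(r.replicon, r.replicon)) for r in records
    ]


# ---------------------------------------------------------------------------
# VCF

VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    '##INFO=<ID=VR,Number=1,Type=Integer,Description="Reads supporting the variant">',
]


def write_vcf(
    variants,  # Sequence[VariantRecord]; imported lazily to avoid a cycle
    genome: Mapping[str, str],
    dest=None,
) -> str:
    """Emit VCF v4.2 text for normalized variants.

    Pure indels are converted to the anchor-base representation: POS names
    the reference base preceding the event (or the following base when the
    event is left-aligned to the start of the replicon).
    """
    lines = list(VCF_HEADER_LINES)
    for name in sorted(genome):
        lines.append(f"##contig=<ID={name},length={len(genome[name])}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in variants:
        if set(v.ref_allele or "") - VALID_BASES or set(v.alt_allele or "") - VALID_BASES:
            raise FormatError(f"{v}: allele not over ACGT")
        seq = genome[v.replicon]
        pos, ref, alt = _to_anchor(v.position, v.ref_allele, v.alt_allele, seq)
        lines.append(
            f"{v.replicon}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
            f"DP={v.total_reads};VR={v.variant_reads}"
        )
    return _write_text("\n".join(lines) + "\n", dest)


def _to_anchor(position: int, ref: str, alt: str, seq: str):
    """Empty-allele convention → VCF (POS, REF, ALT)."""
    if ref and alt:
        return position, ref, alt
    if not ref:  # insertion after `position` (0 = before first base)
        if position >= 1:
            anchor = seq[position - 1]
            return position, anchor, anchor + alt
        anchor = seq[0]
        return 1, anchor, alt + anchor
    # deletion of `ref` at position..position+len-1
    if position >= 2:
        anchor = seq[position - 2]
        return position - 1, anchor + ref, anchor
    anchor = seq[position - 1 + len(ref)]
    return 1, ref + anchor, anchor


def _from_anchor(pos: int, ref: str, alt: str):
    """VCF (POS, REF, ALT) → empty-allele convention (position, ref, alt)."""
    if len(ref) == len(alt) == 1 or (len(ref) > 1 and len(alt) > 1):
        return pos, ref, alt
    if len(ref) < len(alt):  # insertion
        if alt[: len(ref)] == ref:
            return pos + len(ref) - 1, "", alt[len(ref):]
        if alt[-len(ref):] == ref:  # start-of-replicon form
            return pos - 1, "", alt[: -len(ref)]
        return pos, ref, alt
    # deletion
    if ref[: len(alt)] == alt:
        return pos + len(alt), ref[len(alt):], ""
    if ref[-len(alt):] == alt:  # start-of-replicon form
        return pos, ref[: -len(alt)], ""
    return pos, ref, alt


def read_vcf(path, strain_id: str = ""):
    """Read a VCF file into VariantRecords (multi-allelic lines are split)."""
    from .variants import VariantRecord  # local import: io layer stays first

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            dp = int(rec.info.get("DP", 0))
            vr_field = rec.info.get("VR", 0)
            if isinstance(vr_field, tuple):
                vr_field = vr_field[0]
            for alt in rec.alts or ():
                pos, ref, alt_ = _from_anchor(rec.pos, rec.ref.upper(), alt.upper())
                out.append(
                    VariantRecord(
                        replicon=rec.chrom,
                        position=pos,
                        ref_allele=ref,
                        alt_allele=alt_,
                        variant_reads=int(vr_field),
                        total_reads=dp,
                        strain_id=strain_id,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# category flatfile

def read_category_flatfile(source) -> dict[str, CategoryEntry]:
    """Load the gene-category flatfile (comma- or tab-separated).

    Columns: ``locus_tag, function, category, subcategory``.  Duplicate locus
    tags are rejected; an empty file yields an empty mapping (annotation then
    falls back to "unknown").
    """
    text = _as_text(source)
    if not text.strip():
        return {}
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    frame = pd.read_csv(io.StringIO(text), sep=sep, dtype=str).fillna("")
    required = ["locus_tag", "function", "category", "subcategory"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"category flatfile missing column(s): {missing}")
    mapping: dict[str, CategoryEntry] = {}
    for row in frame.itertuples(index=False):
        if row.locus_tag in mapping:
            raise FormatError(f"duplicate locus_tag {row.locus_tag!r}")
        mapping[row.locus_tag] = CategoryEntry(
            row.locus_tag, row.function, row.category, row.subcategory
        )
    return mapping


def write_category_flatfile(
    entries: Iterable[CategoryEntry], dest=None, sep: str = ","
) -> str:
    frame = pd.DataFrame(
        [(e.locus_tag, e.function, e.category, e.subcategory) for e in entries],
        columns=["locus_tag", "function", "category", "subcategory"],
    )
    return _write_text(frame.to_csv(sep=sep, index=False), dest)


# ---------------------------------------------------------------------------
# FASTA + gene table

def read_fasta(source) -> dict[str, str]:
    """Read a FASTA file into an uppercase replicon → sequence mapping."""
    if hasattr(source, "read") or (isinstance(source, str) and "\n" in source):
        handle = io.StringIO(_as_text(source))
    else:
        handle = open(source)
    genome: dict[str, str] = {}
    with handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in genome:
                raise FormatError(f"duplicate FASTA header {rec.id!r}")
            genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(genome: Mapping[str, str], dest=None, width: int = 70) -> str:
    buf = io.StringIO()
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=width)
    writer.write_file(records)
    return _write_text(buf.getvalue(), dest)


GENE_COLUMNS = ["locus_tag", "replicon", "start", "end", "strand", "coding_flag", "product"]


def read_gene_table(source, genome: Mapping[str, str] | None = None) -> list[GeneModel]:
    """Read the tabular gene model; validates bounds when a genome is given."""
    frame = pd.read_csv(io.StringIO(_as_text(source)), sep="\t", dtype=str).fillna("")
    missing = [c for c in GENE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"gene table missing column(s): {missing}")
    genes = []
    for row in frame.itertuples(index=False):
        gene = GeneModel(
            locus_tag=row.locus_tag,
            replicon=row.replicon,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            coding=row.coding_flag in {"1", "True", "true", "Y", "yes"},
            product=row.product,
        )
        if genome is not None:
            if gene.replicon not in genome:
                raise FormatError(
                    f"gene {gene.locus_tag}: unknown replicon {gene.replicon!r}"
                )
            if gene.end > len(genome[gene.replicon]):
                raise FormatError(
                    f"gene {gene.locus_tag}: extends past end of {gene.replicon}"
                )
        genes.append(gene)
    return genes


def write_gene_table(genes: Iterable[GeneModel], dest=None) -> str:
    frame = pd.DataFrame(
        [
            (g.locus_tag, g.replicon, g.start, g.end, g.strand,
             "1" if g.coding else "0", g.product)
            for g in genes
        ],
        columns=GENE_COLUMNS,
    )
    return _write_text(frame.to_csv(sep="\t", index=False), dest)
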