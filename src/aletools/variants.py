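"""Mutation identification in a polyploid genome from per-strain variant calls.

The chain mirrors a resequencing analysis of adaptively evolved strains of a
polyploid cyanobacterium: raw difference records are normalized
(left-aligned), the parental wild-type variant set is subtracted, indels in
homopolymer runs are flagged as sequencing artifacts, surviving variants are
annotated with their coding effect and gene-category metadata, read-support
fractions quantify how far each mutation has segregated through the genome
copies, and per-strain results are combined into a presence matrix.  A small
primer-design helper produces Sanger-validation primer pairs under fixed
distance and melting-temperature constraints.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp

from .io_formats import (
    CategoryEntry,
    DiffRecord,
    GeneModel,
    UNKNOWN_CATEGORY,
)

__all__ = [
    "VariantRecord",
    "EffectAnnotation",
    "MutationMatrix",
    "PrimerPair",
    "PipelineError",
    "normalize",
    "subtract_baseline",
    "classify_effect",
    "flag_homopolymer_indels",
    "read_fraction",
    "segregation_call",
    "build_matrix",
    "aggregate_gene_support",
    "annotate_categories",
    "design_validation_primers",
    "primer_tm",
    "round_sig",
]

TRANSLATION_TABLE = 11  # bacterial/archaeal code

SEGREGATION_FULL = 97.0  # percent of reads at/above which a call is "fully segregated"
SEGREGATION_TRACE = 2.0  # percent below which a call is "trace"


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    """One difference vs the reference, keyed by left-aligned coordinates.

    The empty-allele convention of :class:`~aletools.io_formats.DiffRecord`
    carries over: an insertion has ``ref_allele == ""`` and ``position`` names
    the base after which the inserted sequence sits; a deletion has
    ``alt_allele == ""`` and ``position`` names its first removed base.
    """

    replicon: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_reads: int
    total_reads: int
    strain_id: str = ""
    homopolymer_flag: bool = False

    def __post_init__(self) -> None:
        if not self.ref_allele and not self.alt_allele:
            raise PipelineError("variant with both alleles empty")
        if self.variant_reads > self.total_reads:
            raise PipelineError(
                f"{self.replicon}:{self.position}: variant reads exceed total"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.replicon, self.position, self.ref_allele, self.alt_allele)

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def net_length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass(frozen=True)
class EffectAnnotation:
    variant: VariantRecord
    effect_class: str  # AA change | Synonymous | Frameshift | In-frame indel |
    #                    Stop gain | Stop loss | Intergenic
    gene: str  # locus tag or "Intergenic"
    codon_change: str = ""  # e.g. "gAg→gGg" for coding substitutions
    aa_change: str = ""  # e.g. "E→G"
    category: CategoryEntry = UNKNOWN_CATEGORY
    homopolymer_flag: bool = False
    boundary_warning: bool = False
    flanking: tuple[str, str] = ("", "")  # locus tags around an intergenic site

    def __post_init__(self) -> None:
        coding_sub = self.effect_class in {
            "AA change", "Synonymous", "Stop gain", "Stop loss"
        }
        if coding_sub != bool(self.codon_change):
            raise PipelineError(
                f"codon_change must be set exactly for coding substitutions "
                f"({self.effect_class!r} at {self.variant.position})"
            )
        if self.homopolymer_flag and not self.variant.is_indel:
            raise PipelineError("homopolymer flag on a non-indel")


# ---------------------------------------------------------------------------
# normalization & subtraction

def normalize(
    records: Sequence[DiffRecord],
    genome: Mapping[str, str],
    strain_id: str = "",
) -> list[VariantRecord]:
    """Left-align indels against the reference and order deterministically.

    Substitutions pass through unchanged (after a reference check).  All
    equivalent placements of an indel inside a repeat collapse to the
    leftmost one, so downstream (replicon, position, ref, alt) keys are
    stable across strains and callers.
    """
    out: list[VariantRecord] = []
    for rec in records:
        if rec.replicon not in genome:
            raise PipelineError(f"unknown replicon {rec.replicon!r} in {rec}")
        seq = genome[rec.replicon]
        if rec.ref_allele:
            actual = seq[rec.start - 1 : rec.start - 1 + len(rec.ref_allele)]
            if actual != rec.ref_allele:
                raise PipelineError(
                    f"{rec.replicon}:{rec.start}: ref allele {rec.ref_allele!r} "
                    f"disagrees with reference {actual!r}"
                )
        if rec.ref_allele and rec.alt_allele:  # substitution
            pos, ref, alt = rec.start, rec.ref_allele, rec.alt_allele
        elif not rec.ref_allele:  # insertion after rec.start
            pos, alt = _left_align_insertion(seq, rec.start, rec.alt_allele)
            ref = ""
        else:  # deletion of rec.start..rec.end
            pos, ref = _left_align_deletion(seq, rec.start, rec.ref_allele)
            alt = ""
        out.append(
            VariantRecord(
                replicon=rec.replicon,
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                variant_reads=rec.variant_reads,
                total_reads=rec.total_reads,
                strain_id=strain_id,
            )
        )
    out.sort(key=lambda v: (v.replicon, v.position, v.alt_allele, v.ref_allele))
    return out


def _left_align_insertion(seq: str, after: int, inserted: str) -> tuple[int, str]:
    pos, ins = after, inserted
    while pos >= 1 and seq[pos - 1] == ins[-1]:
        ins = seq[pos - 1] + ins[:-1]
        pos -= 1
    return pos, ins


def _left_align_deletion(seq: str, start: int, deleted: str) -> tuple[int, str]:
    pos, dele = start, deleted
    while pos >= 2 and seq[pos - 2] == dele[-1]:
        dele = seq[pos - 2] + dele[:-1]
        pos -= 1
    return pos, dele


def subtract_baseline(
    sample: Sequence[VariantRecord], baseline: Sequence[VariantRecord]
) -> list[VariantRecord]:
    """Drop sample variants whose key is already present in the baseline.

    Both inputs must be normalized.  Satisfies the set algebra
    ``subtract(S, B) ∪ (S ∩ B) = S`` and ``subtract(S, B) ∩ B = ∅``.
    """
    baseline_keys = {v.key for v in baseline}
    return [v for v in sample if v.key not in baseline_keys]


# ---------------------------------------------------------------------------
# effect classification

def _gene_at(genes: Sequence[GeneModel], replicon: str, start: int, end: int):
    """Genes overlapping [start, end] on a replicon (assumed non-overlapping)."""
    return [
        g for g in genes
        if g.replicon == replicon and g.start <= end and start <= g.end
    ]


def check_non_overlapping(genes: Sequence[GeneModel]) -> None:
    by_rep: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_rep.setdefault(g.replicon, []).append(g)
    for rep, gg in by_rep.items():
        gg = sorted(gg, key=lambda g: g.start)
        for a, b in zip(gg, gg[1:]):
            if b.start <= a.end:
                raise PipelineError(
                    f"overlapping genes {a.locus_tag}/{b.locus_tag} on {rep}"
                )


def _variant_span(variant: VariantRecord) -> tuple[int, int]:
    """Reference footprint of a variant; an insertion sits between pos, pos+1."""
    if not variant.ref_allele:  # insertion after `position`
        return variant.position, variant.position + 1
    return variant.position, variant.position + len(variant.ref_allele) - 1


def classify_effect(
    variant: VariantRecord,
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
) -> EffectAnnotation:
    """Classify the consequence of one normalized variant.

    Substitutions inside a coding gene are translated codon-wise on the
    coding strand (bacterial code); indels inside a CDS are frameshifts
    unless the net length change is a multiple of 3.  A variant spanning a
    gene boundary is annotated as Frameshift with a boundary warning.
    Codon changes are rendered lowercase with the substituted base uppercase
    (e.g. ``gAg→gGg``).
    """
    seq = genome[variant.replicon]
    span_start, span_end = _variant_span(variant)
    if not variant.ref_allele:
        # an insertion strictly between genes (or right at a gene's outer
        # edge) does not alter any CDS: it is inside a gene only when both
        # flanking reference bases are
        hits = [
            g for g in genes
            if g.replicon == variant.replicon
            and g.start <= variant.position and variant.position < g.end
        ]
    else:
        hits = _gene_at(genes, variant.replicon, span_start, span_end)
    if not hits:
        left = [g for g in genes
                if g.replicon == variant.replicon and g.end < span_start]
        right = [g for g in genes
                 if g.replicon == variant.replicon and g.start > span_end]
        flank = (
            max(left, key=lambda g: g.end).locus_tag if left else "",
            min(right, key=lambda g: g.start).locus_tag if right else "",
        )
        return EffectAnnotation(
            variant=variant, effect_class="Intergenic", gene="Intergenic",
            flanking=flank,
        )
    gene = hits[0]
    fully_inside = gene.start <= span_start and span_end <= gene.end
    if len(hits) > 1 or not fully_inside:
        return EffectAnnotation(
            variant=variant, effect_class="Frameshift",
            gene=gene.locus_tag, boundary_warning=True,
        )
    if not gene.coding:
        # non-coding feature: report by gene, no codon arithmetic applies
        return EffectAnnotation(
            variant=variant, effect_class="Non-coding", gene=gene.locus_tag,
        )
    if variant.is_indel or len(variant.ref_allele) != 1:
        if variant.net_length_change % 3 != 0:
            effect = "Frameshift"
        elif variant.is_indel:
            effect = "In-frame indel"
        else:
            # length-preserving multi-base substitution: translate rebuilt CDS
            effect = _multibase_sub_effect(variant, gene, seq)
        codon = "n/a" if effect in {"Synonymous", "AA change", "Stop gain",
                                    "Stop loss"} else ""
        return EffectAnnotation(
            variant=variant, effect_class=effect, gene=gene.locus_tag,
            codon_change=codon,
        )
    # single-base substitution in a coding gene
    if gene.strand == "+":
        offset = variant.position - gene.start
        ref_base, alt_base = variant.ref_allele, variant.alt_allele
    else:
        offset = gene.end - variant.position
        ref_base = str(Seq(variant.ref_allele).complement())
        alt_base = str(Seq(variant.alt_allele).complement())
    codon_idx, codon_pos = divmod(offset, 3)
    cds = _coding_sequence(gene, seq)
    old_codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    if old_codon[codon_pos] != ref_base:
        raise PipelineError(
            f"{variant.replicon}:{variant.position}: reference codon mismatch"
        )
    new_codon = old_codon[:codon_pos] + alt_base + old_codon[codon_pos + 1 :]
    old_aa = str(Seq(old_codon).translate(table=TRANSLATION_TABLE))
    new_aa = str(Seq(new_codon).translate(table=TRANSLATION_TABLE))
    if new_aa == old_aa:
        effect = "Synonymous"
    elif new_aa == "*":
        effect = "Stop gain"
    elif old_aa == "*":
        effect = "Stop loss"
    else:
        effect = "AA change"
    return EffectAnnotation(
        variant=variant,
        effect_class=effect,
        gene=gene.locus_tag,
        codon_change=f"{_render_codon(old_codon, codon_pos)}"
        f"→{_render_codon(new_codon, codon_pos)}",
        aa_change=f"{old_aa}→{new_aa}",
    )


def _coding_sequence(gene: GeneModel, seq: str) -> str:
    raw = seq[gene.start - 1 : gene.end]
    return str(Seq(raw).reverse_complement()) if gene.strand == "-" else raw


def _render_codon(codon: str, changed_pos: int) -> str:
    return "".join(
        base.upper() if i == changed_pos else base.lower()
        for i, base in enumerate(codon)
    )


def _multibase_sub_effect(variant: VariantRecord, gene: GeneModel, seq: str) -> str:
    """Length-preserving multi-base substitution: translate and compare."""
    start_idx = variant.position - 1
    mutant = (
        seq[: start_idx] + variant.alt_allele
        + seq[start_idx + len(variant.ref_allele) :]
    )
    old = str(Seq(_coding_sequence(gene, seq)).translate(table=TRANSLATION_TABLE))
    new = str(Seq(_coding_sequence(gene, mutant)).translate(table=TRANSLATION_TABLE))
    if new == old:
        return "Synonymous"
    if "*" in new[:-1] and "*" not in old[:-1]:
        return "Stop gain"
    return "AA change"


# ---------------------------------------------------------------------------
# homopolymer artifact flagging

def _run_length(seq: str, pos0: int) -> int:
    """Length of the maximal run of identical bases covering 0-based pos0."""
    base = seq[pos0]
    left = pos0
    while left > 0 and seq[left - 1] == base:
        left -= 1
    right = pos0
    while right + 1 < len(seq) and seq[right + 1] == base:
        right += 1
    return right - left + 1


def flag_homopolymer_indels(
    variants: Sequence[VariantRecord],
    genome: Mapping[str, str],
    min_run: int = 4,
) -> list[VariantRecord]:
    """Flag indels that look like homopolymer sequencing artifacts.

    An indel is flagged iff its inserted/deleted bases are a single repeated
    nucleotide *and* the reference run of that nucleotide containing (or
    adjacent to) the site is at least ``min_run`` long.  Mixed-base indels
    and substitutions are never flagged.  Flagged records are meant to be
    excluded from matrices but kept in a side report.
    """
    out = []
    for v in variants:
        out.append(replace(v, homopolymer_flag=_is_homopolymer_artifact(
            v, genome[v.replicon], min_run)))
    return out


def _is_homopolymer_artifact(v: VariantRecord, seq: str, min_run: int) -> bool:
    if not v.is_indel:
        return False
    changed = v.alt_allele or v.ref_allele
    if len(set(changed)) != 1:
        return False
    base = changed[0]
    if v.ref_allele:  # deletion: run containing the deleted bases
        run = _run_length(seq, v.position - 1)
        return seq[v.position - 1] == base and run >= min_run
    # insertion after v.position: check the runs touching the insertion point
    for pos0 in (v.position - 1, v.position):
        if 0 <= pos0 < len(seq) and seq[pos0] == base:
            if _run_length(seq, pos0) >= min_run:
                return True
    return False


def partition_flagged(
    variants: Sequence[VariantRecord],
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """(kept, flagged) split after :func:`flag_homopolymer_indels`."""
    kept = [v for v in variants if not v.homopolymer_flag]
    flagged = [v for v in variants if v.homopolymer_flag]
    return kept, flagged


# ---------------------------------------------------------------------------
# read fractions & segregation

def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (report convention)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")


def read_fraction(variant: VariantRecord) -> float:
    """Percentage of reads supporting the variant, to 3 significant figures.

    In a polyploid the read fraction proxies the share of genome copies (and,
    in a mixed culture, strains) carrying the mutation.
    """
    if variant.total_reads == 0:
        raise PipelineError(f"{variant.replicon}:{variant.position}: zero coverage")
    return round_sig(100.0 * variant.variant_reads / variant.total_reads)


def segregation_call(fraction: float) -> str:
    """Classify a read-support percentage.

    >= 97%: "fully segregated" (mutation on essentially all genome copies);
    < 2%: "trace"; otherwise "partial".
    """
    if not (0.0 <= fraction <= 100.0):
        raise PipelineError(f"fraction {fraction} outside [0, 100]")
    if fraction >= SEGREGATION_FULL:
        return "fully segregated"
    if fraction < SEGREGATION_TRACE:
        return "trace"
    return "partial"


# ---------------------------------------------------------------------------
# matrices & reports

@dataclass(frozen=True)
class MutationMatrix:
    """Strains × variants presence matrix (the "X" table)."""

    rows: tuple[tuple[str, int, str, str], ...]  # variant keys, ordered
    strains: tuple[str, ...]
    presence: tuple[tuple[bool, ...], ...]  # rows × strains
    annotations: Mapping[tuple[str, int, str, str], EffectAnnotation]

    @property
    def per_strain_totals(self) -> dict[str, int]:
        return {
            s: sum(row[j] for row in self.presence)
            for j, s in enumerate(self.strains)
        }

    def to_frame(self) -> pd.DataFrame:
        records = []
        for key, row in zip(self.rows, self.presence):
            ann = self.annotations[key]
            rec = {
                "replicon": key[0],
                "position": key[1],
                "mutation_type": ann.effect_class,
                "gene": ann.gene,
                "wt": key[2] or "-",
                "mutant": key[3] or "-",
            }
            for j, s in enumerate(self.strains):
                rec[s] = "X" if row[j] else ""
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_tsv(self, dest=None) -> str:
        text = self.to_frame().to_csv(sep="\t", index=False)
        if dest is not None:
            from .io_formats import _write_text
            return _write_text(text, dest)
        return text


def build_matrix(
    per_strain: Mapping[str, Sequence[EffectAnnotation]],
) -> MutationMatrix:
    """Combine per-strain annotated variants into a presence matrix.

    Homopolymer-flagged indels must already be excluded.  The same variant
    key must carry the same annotation (effect class and gene) in every
    strain, since annotation depends only on the reference.
    """
    annotations: dict[tuple, EffectAnnotation] = {}
    presence_sets: dict[str, set] = {}
    for strain, anns in per_strain.items():
        keys = set()
        for ann in anns:
            if ann.homopolymer_flag or ann.variant.homopolymer_flag:
                raise PipelineError(
                    f"flagged indel {ann.variant.key} passed to build_matrix"
                )
            key = ann.variant.key
            prior = annotations.get(key)
            if prior is not None and (
                prior.effect_class != ann.effect_class or prior.gene != ann.gene
            ):
                raise PipelineError(
                    f"conflicting annotations for {key}: "
                    f"{prior.effect_class}/{prior.gene} vs "
                    f"{ann.effect_class}/{ann.gene}"
                )
            annotations.setdefault(key, ann)
            keys.add(key)
        presence_sets[strain] = keys
    strains = tuple(per_strain.keys())
    rows = tuple(sorted(annotations))
    presence = tuple(
        tuple(key in presence_sets[s] for s in strains) for key in rows
    )
    return MutationMatrix(rows, strains, presence, annotations)


def aggregate_gene_support(
    annotated: pd.DataFrame | Iterable,
    gene_col: str = "gene",
    fraction_col: str = "percent_reads",
) -> pd.Series:
    """Per-gene summed read-support percentage for one sample.

    Distinct mutations within one gene are assumed mutually exclusive per
    genome copy (no copy carries two of them), so their read fractions add to
    the total share of copies with *some* mutation in the gene.  Sums above
    100% violate that assumption and are reported with a warning.
    """
    if not isinstance(annotated, pd.DataFrame):
        annotated = pd.DataFrame(
            [(a.gene, read_fraction(a.variant)) for a in annotated],
            columns=[gene_col, fraction_col],
        )
    annotated = annotated[annotated[gene_col] != "Intergenic"]
    sums = annotated.groupby(gene_col)[fraction_col].sum()
    for gene, total in sums.items():
        if total > 100.0 + 1e-9:
            warnings.warn(
                f"gene {gene}: summed read support {total:.1f}% exceeds 100% "
                "(mutual-exclusivity assumption violated)"
            )
    return sums.map(round_sig)


REPORT_COLUMNS = [
    "replicon", "position", "mutation_type", "gene", "wt", "mutant",
    "codon_change", "percent_reads", "segregation",
    "function", "category", "subcategory", "homopolymer_flag",
    "flanking_left", "flanking_right",
]


def annotate_categories(
    effects: Sequence[EffectAnnotation],
    categories: Mapping[str, CategoryEntry],
) -> pd.DataFrame:
    """Join effect annotations with the gene-category flatfile.

    Genes missing from the flatfile annotate as "unknown"; intergenic rows
    carry the flanking locus tags instead of category data.  Output is the
    spreadsheet-style report table.
    """
    rows = []
    for ann in effects:
        v = ann.variant
        cat = categories.get(ann.gene, UNKNOWN_CATEGORY)
        frac = read_fraction(v) if v.total_reads > 0 else float("nan")
        rows.append(
            {
                "replicon": v.replicon,
                "position": v.position,
                "mutation_type": ann.effect_class,
                "gene": ann.gene,
                "wt": v.ref_allele or "-",
                "mutant": v.alt_allele or "-",
                "codon_change": ann.codon_change,
                "percent_reads": frac,
                "segregation": segregation_call(frac) if math.isfinite(frac) else "",
                "function": cat.function,
                "category": cat.category,
                "subcategory": cat.subcategory,
                "homopolymer_flag": ann.homopolymer_flag or v.homopolymer_flag,
                "flanking_left": ann.flanking[0],
                "flanking_right": ann.flanking[1],
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


# ---------------------------------------------------------------------------
# Sanger-validation primer design

@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    fw_offset: int  # bp from the target base to the forward primer 3' end
    rv_offset: int  # bp from the target base to the reverse primer 3' end
    tm_fw: float
    tm_rv: float

    def __post_init__(self) -> None:
        if not (100 <= self.fw_offset <= 150):
            raise PipelineError("forward offset outside 100-150 bp")
        if not (350 <= self.rv_offset <= 400):
            raise PipelineError("reverse offset outside 350-400 bp")
        for tm in (self.tm_fw, self.tm_rv):
            if not (58.0 <= tm <= 62.0):
                raise PipelineError("melting temperature outside 58-62 degC")
        if abs(self.tm_fw - self.tm_rv) > 2.0:
            raise PipelineError("primer Tm difference above 2 degC")


def primer_tm(seq: str, na_mM: float = 50.0, primer_nM: float = 500.0) -> float:
    """Nearest-neighbor melting temperature (unified parameter set)."""
    return float(
        MeltingTemp.Tm_NN(
            Seq(seq), Na=na_mM, dnac1=primer_nM, dnac2=0, selfcomp=False
        )
    )

PRIMER_LENGTHS = range(18, 28)
FW_OFFSETS = range(100, 151)
RV_OFFSETS = range(350, 401)
EDGE_MARGIN = 500


def design_validation_primers(
    genome: Mapping[str, str], replicon: str, target_position: int
) -> PrimerPair:
    """First primer pair satisfying the distance and Tm constraints.

    The forward primer's 3' end lies 100-150 bp upstream of the target base,
    the reverse primer's 3' end (on the reverse complement) 350-400 bp
    downstream; candidate lengths are 18-27 nt, each primer must melt within
    58-62 degC and the pair within 2 degC of each other.  Scan order is
    deterministic: increasing offset, then length, forward candidates
    outermost.
    """
    seq = genome[replicon]
    if target_position < EDGE_MARGIN or len(seq) - target_position < EDGE_MARGIN:
        raise PipelineError(
            f"target {replicon}:{target_position} closer than {EDGE_MARGIN} bp "
            "to a replicon end"
        )

    def fw_candidates():
        for off in FW_OFFSETS:
            three_prime = target_position - off  # 1-based
            for length in PRIMER_LENGTHS:
                start0 = three_prime - length
                if start0 < 0:
                    continue
                p = seq[start0:three_prime]
                tm = primer_tm(p)
                if 58.0 <= tm <= 62.0:
                    yield p, off, tm

    def rv_candidates():
        for off in RV_OFFSETS:
            three_prime0 = target_position + off - 1  # 0-based index of 3' base
            for length in PRIMER_LENGTHS:
                end0 = three_prime0 + length
                if end0 > len(seq):
                    continue
                p = str(Seq(seq[three_prime0:end0]).reverse_complement())
                tm = primer_tm(p)
                if 58.0 <= tm <= 62.0:
                    yield p, off, tm

    rv_list = list(rv_candidates())
    best_gap = math.inf
    best_pair = None
    for fw, fw_off, tm_fw in fw_candidates():
        for rv, rv_off, tm_rv in rv_list:
            gap = abs(tm_fw - tm_rv)
            if gap <= 2.0:
                return PrimerPair(fw, rv, fw_off, rv_off, tm_fw, tm_rv)
            if gap < best_gap:
                best_gap = gap
                best_pair = (fw_off, rv_off, tm_fw, tm_rv)
    detail = (
        f"best near-miss: fw@{best_pair[0]} ({best_pair[2]:.2f} degC) vs "
        f"rv@{best_pair[1]} ({best_pair[3]:.2f} degC)" if best_pair
        else "no candidate primer melted within 58-62 degC"
    )
    raise PipelineError(f"no primer pair satisfies the constraints; {detail}")
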