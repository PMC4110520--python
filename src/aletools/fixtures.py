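"""Machine-readable encodings of the published result tables.

These small static tables describe the confirmed mutations of five
thermo-tolerant isolates (a strains × variants presence matrix with per-strain
confirmed-mutation totals), the read-support percentages observed in the
evolved mixed culture, and the mutations seen only in that mix.  They drive
regression tests and the acceptance checks.

Known source inconsistency, reproduced here as printed rather than resolved:
the two frameshift insertions in *pyrR* are listed at 2717197 and 2717187 in
the mix table, while the running text gives 2717183 and a five-digit
"271787"; the matrix table lists a single *pyrR* row at 2717197.  One
mix-table entry's mutant allele is typographically truncated in the source
("GTGGCTTTAA…"); the truncated prefix is stored.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .variants import EffectAnnotation, VariantRecord

__all__ = ["PublishedTables", "make_published_tables"]

STRAINS = ("C5K", "A1", "A6", "H2", "H12")

# position, mutation_type, gene, wt, mutant, presence per strain (C5K A1 A6 H2 H12)
_MATRIX_ROWS = [
    (96437, "AA change", "pnp", "gAg", "gGg", (1, 0, 0, 0, 0)),
    (98129, "AA change", "pnp", "aTg", "aCg", (1, 1, 0, 0, 1)),
    (195523, "AA change", "slr1098", "gGc", "gTc", (1, 0, 0, 0, 0)),
    (494155, "AA change", "pilJ", "Cgg", "Tgg", (0, 0, 1, 1, 1)),
    (1103495, "AA change", "pyk2", "ttC", "ttA", (0, 0, 0, 1, 0)),
    (1103586, "AA change", "pyk2", "gGa", "gAa", (1, 1, 0, 0, 1)),
    (1133812, "Intergenic", "Intergenic", "G", "T", (0, 1, 0, 0, 0)),
    (1436521, "Frameshift", "cya1", "-", "GCAA", (0, 1, 0, 0, 0)),
    (2260225, "Intergenic", "Intergenic", "-", "A", (1, 1, 0, 0, 1)),
    (2466798, "AA change", "clpC", "gTg", "gCg", (0, 0, 0, 0, 1)),
    (2466808, "AA change", "clpC", "Cgt", "Tgt", (1, 1, 0, 0, 0)),
    (2467723, "AA change", "clpC", "Gac", "Tac", (1, 0, 0, 0, 0)),
    (2468031, "AA change", "clpC", "gTt", "gCt", (1, 0, 0, 0, 0)),
    (2579829, "AA change", "sll0064", "Ttg", "Atg", (1, 0, 0, 0, 1)),
    (2717197, "Frameshift", "pyrR", "-", "TAATTAACTCCAC", (1, 1, 0, 0, 0)),
    (3371838, "AA change", "sigF", "Cgt", "Tgt", (0, 0, 1, 1, 1)),
]

# position, mutation_type, gene, wt, mutant, percent of reads in the evolved mix
_MIX_ROWS = [
    (98129, "AA change", "pnp", "aTg", "aCg", 100.0),
    (194955, "Frameshift", "slr1098", "-", "T", 11.70),
    (195111, "AA change", "slr1098", "Agt", "Cgt", 23.7),
    (1103495, "AA change", "pyk2", "ttC", "ttA", 0.68),
    (1103586, "AA change", "pyk2", "gGa", "gAa", 94.4),
    (1133812, "Intergenic", "Intergenic", "G", "T", 51.4),
    (1435867, "Frameshift", "cya1", "ATGGTCGACG", "-", 41.3),
    (2260225, "Intergenic", "Intergenic", "-", "A", 100.0),
    (2466798, "AA change", "clpC", "gTg", "gCg", 45.5),
    (2466808, "AA change", "clpC", "Cgt", "Tgt", 8.16),
    (2466882, "AA change", "clpC", "gTa", "gCa", 10.0),
    (2467723, "AA change", "clpC", "Gac", "Tac", 4.65),
    (2468031, "AA change", "clpC", "gTt", "gCt", 20.5),
    (2579430, "Frameshift", "sll0064", "-", "CCCTG", 61.0),
    (2717197, "Frameshift", "pyrR", "AAGGTTAA", "GTGGCTTTAA", 10.9),
    (2717187, "Frameshift", "pyrR", "-", "TTAACTCCACTAA", 70.4),
]

# mutations observed only in the evolved mix
_MIX_ONLY_ROWS = [
    (57479, "AA change", "glgA", "gCc", "gTc", 22.0),
    (853615, "AA change", "rpoC2", "gCc", "gTc", 38.0),
    (2499596, "AA change", "recG", "gCc", "gTc", 70.0),
    (2850065, "AA change", "hemH", "Gat", "Tat", 22.0),
    (3169828, "AA change", "cmpA", "Ggt", "Agt", 54.0),
    (3553027, "Intergenic", "Intergenic", "A", "G", 16.0),
]

CONFIRMED_COUNTS = {"C5K": 10, "A1": 7, "A6": 2, "H2": 3, "H12": 7}

MAX_TEMPS_BIOREACTOR = {
    "wt": None,  # below 43 degC; no stable upper value printed
    "C5K": 44.9, "A1": 45.0, "A6": 45.0, "H2": 45.2, "H12": 45.0,
}


def _alleles(wt: str, mut: str) -> tuple[str, str]:
    """Extract DNA alleles from the table's WT/Mutant notation.

    Codon notation carries the substituted base uppercase (``gAg``); pure
    indels use ``-`` for the missing side; intergenic substitutions and
    multi-base entries are written as plain base strings.
    """
    if wt == "-":
        return "", mut
    if mut == "-":
        return wt, ""
    if len(wt) == 3 and len(mut) == 3:
        upper_wt = [c for c in wt if c.isupper()]
        upper_mut = [c for c in mut if c.isupper()]
        if len(upper_wt) == 1 and len(upper_mut) == 1:
            return upper_wt[0], upper_mut[0]
    return wt.upper(), mut.upper()


@dataclass(frozen=True)
class PublishedTables:
    matrix_table: pd.DataFrame  # isolate presence matrix
    mix_table: pd.DataFrame  # mix read-support table (genes shared w/ isolates)
    mix_only_table: pd.DataFrame  # mutations seen only in the mix
    confirmed_counts: dict[str, int]
    strains: tuple[str, ...] = STRAINS

    def per_strain_annotations(self) -> dict[str, list[EffectAnnotation]]:
        """The presence matrix as per-strain annotated variant lists.

        Read counts are not part of the printed matrix, so the records carry
        zero coverage; identity and annotation are what matters here.
        """
        out: dict[str, list[EffectAnnotation]] = {s: [] for s in self.strains}
        for row in self.matrix_table.itertuples(index=False):
            ref, alt = _alleles(row.wt, row.mutant)
            for strain in self.strains:
                if not getattr(row, strain):
                    continue
                variant = VariantRecord(
                    replicon="chromosome",
                    position=int(row.position),
                    ref_allele=ref,
                    alt_allele=alt,
                    variant_reads=0,
                    total_reads=0,
                    strain_id=strain,
                )
                codon = (
                    f"{row.wt}→{row.mutant}"
                    if row.mutation_type == "AA change"
                    else ""
                )
                out[strain].append(
                    EffectAnnotation(
                        variant=variant,
                        effect_class=row.mutation_type,
                        gene=row.gene,
                        codon_change=codon,
                    )
                )
        return out


def make_published_tables() -> PublishedTables:
    """Bundle the published tables as DataFrames (stable across runs)."""
    matrix = pd.DataFrame(
        [
            (pos, mtype, gene, wt, mut, *presence)
            for pos, mtype, gene, wt, mut, presence in _MATRIX_ROWS
        ],
        columns=["position", "mutation_type", "gene", "wt", "mutant", *STRAINS],
    )
    mix = pd.DataFrame(
        _MIX_ROWS,
        columns=["position", "mutation_type", "gene", "wt", "mutant", "percent_reads"],
    )
    mix_only = pd.DataFrame(
        _MIX_ONLY_ROWS,
        columns=["position", "mutation_type", "gene", "wt", "mutant", "percent_reads"],
    )
    return PublishedTables(
        matrix_table=matrix,
        mix_table=mix,
        mix_only_table=mix_only,
        confirmed_counts=dict(CONFIRMED_COUNTS),
    )
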