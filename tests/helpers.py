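"""Shared independent oracles and hand-built genomes for the test suite.

Everything here deliberately avoids the library code paths it is used to
check: effects are derived by rebuilding and translating whole coding
sequences, melting temperatures by a separate nearest-neighbor
implementation with published thermodynamic constants.
"""

from __future__ import annotations

import math

from Bio.Seq import Seq

from aletools.io_formats import GeneModel
from aletools.variants import VariantRecord


def apply_variant(seq: str, v: VariantRecord) -> str:
    """Mutant chromosome sequence with one variant applied."""
    s0 = v.position - 1
    if not v.ref_allele:  # insertion after position
        return seq[: v.position] + v.alt_allele + seq[v.position :]
    return seq[:s0] + v.alt_allele + seq[s0 + len(v.ref_allele) :]


def brute_force_effect(v: VariantRecord, gene: GeneModel, seq: str) -> str:
    """Effect class by full-CDS rebuild and translation (bacterial code)."""
    net = len(v.alt_allele) - len(v.ref_allele)
    if net % 3 != 0:
        return "Frameshift"
    if net != 0:
        return "In-frame indel"

    def protein(s: str) -> str:
        raw = s[gene.start - 1 : gene.end]
        if gene.strand == "-":
            raw = str(Seq(raw).reverse_complement())
        return str(Seq(raw).translate(table=11))

    old, new = protein(seq), protein(apply_variant(seq, v))
    if old == new:
        return "Synonymous"
    if "*" in new[:-1] and "*" not in old[:-1]:
        return "Stop gain"
    if old[-1] == "*" and new[-1] != "*" and old[:-1] == new[:-1]:
        return "Stop loss"
    return "AA change"


# Allawi & SantaLucia (1997) unified nearest-neighbor set:
# dH kcal/mol, dS cal/(mol*K)
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_TERMINAL = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}
_R = 1.987  # cal/(mol*K)


def tm_oracle(seq: str, na_mM: float = 50.0, primer_nM: float = 500.0) -> float:
    """Independent nearest-neighbor Tm (same model class, separate code)."""
    dh = ds = 0.0
    for end in (seq[0], seq[-1]):
        dh += _TERMINAL[end][0]
        ds += _TERMINAL[end][1]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    k = primer_nM * 1e-9
    return 1000.0 * dh / (ds + _R * math.log(k)) - 273.15


def make_exemplar_genome():
    """Tiny genome holding the three published exemplar mutation contexts.

    A plus-strand gene ``pnp`` whose second codon is GAG (so the middle-base
    A→G substitution gives gAg→gGg, Glu→Gly), a gene ``cya1`` for a 4-base
    GCAA insertion (frameshift), and an intergenic G between them for a G→T
    substitution.  Returns (genome, genes, positions) with the 1-based target
    positions of the three events.
    """
    pad = ("ACGT" * 75)[:300]
    pnp_cds = "ATG" + "GAG" + "CTGGAT" * 20 + "TAA"  # 129 bp
    spacer = ("TTGC" * 40)[:160]
    cya1_cds = "ATG" + "GCCAAT" * 25 + "TAA"  # 156 bp
    tail = ("GTCA" * 75)[:300]

    seq = pad + pnp_cds + spacer + cya1_cds + tail
    pnp_start = len(pad) + 1
    cya1_start = len(pad) + len(pnp_cds) + len(spacer) + 1
    genes = [
        GeneModel("pnp", "chromosome", pnp_start, pnp_start + len(pnp_cds) - 1,
                  "+", True, "polyribonucleotide nucleotidyltransferase"),
        GeneModel("cya1", "chromosome", cya1_start,
                  cya1_start + len(cya1_cds) - 1, "+", True,
                  "adenylate cyclase"),
    ]
    intergenic_region = range(pnp_start + len(pnp_cds), cya1_start)
    intergenic_g = next(p for p in intergenic_region if seq[p - 1] == "G")
    positions = {
        "pnp_sub": pnp_start + 4,  # middle base of the GAG codon
        "intergenic_g": intergenic_g,
        "cya1_ins_after": cya1_start + 10,
    }
    return {"chromosome": seq}, genes, positions
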