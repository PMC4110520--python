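"""Synthetic data with the statistical structure the study design assumes.

The generator produces every input the pipeline consumes, together with the
ground truth needed for recovery tests:

* a random reference genome with non-overlapping protein-coding genes and a
  gene-category flatfile;
* point mutations and indels drawn from a mutagen-like spectrum (UV-type
  GC→AT transitions dominating, MMS-type GC↔TA transversions next), each
  assigned to a subset of strains and a true segregation fraction — the share
  of the cell's many genome copies carrying the mutation;
* per-strain difference records observed through finite read coverage
  (Poisson total depth, binomial variant support), with labelled
  homopolymer-indel artifacts injected at a configurable rate;
* OD750 growth traces whose rate follows each strain's modified Ratkowsky
  curve with multiplicative lognormal observation noise, stepwise
  temperature schedules and recorded dilution events.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .growth import RampProtocol, RatkowskyFit, ratkowsky_mu
from .io_formats import (
    CategoryEntry,
    DiffRecord,
    GeneModel,
    ODTimeSeries,
    write_category_flatfile,
    write_fasta,
    write_gene_table,
    write_hcdiffs,
    write_od_table,
)
from .variants import VariantRecord, _is_homopolymer_artifact

__all__ = [
    "MutationSpectrum",
    "TruthVariant",
    "ArtifactRecord",
    "TruthSet",
    "PopulationModel",
    "simulate_reference",
    "inject_mutations",
    "emit_read_evidence",
    "simulate_growth_experiment",
    "make_sim_provider",
    "simulate_all",
]

BASES = np.array(list("ACGT"))
STOP_CODONS = {"TAA", "TAG", "TGA"}

TRANSITION = {"G": "A", "C": "T", "A": "G", "T": "C"}
GC_TA_TRANSVERSION = {"G": "T", "C": "A", "T": "G", "A": "C"}
OTHER_TRANSVERSION = {"G": "C", "C": "G", "A": "T", "T": "A"}


@dataclass(frozen=True)
class MutationSpectrum:
    """Class probabilities for injected mutations.

    Defaults reflect the biases of the UV + MMS mutagenesis the study design
    assumes: UV drives mainly GC→AT transitions, MMS mainly GC↔TA
    transversions; exact proportions are this package's own choices.  Indel
    lengths are geometric with the given mean; ``homopolymer_bias`` is the
    probability that an injected indel is deliberately placed adjacent to a
    base run (0 = placement uniform).
    """

    gc_at_transition: float = 0.60
    at_gc_transition: float = 0.05
    gc_ta_transversion: float = 0.25
    other_transversion: float = 0.05
    insertion: float = 0.025
    deletion: float = 0.025
    indel_length_mean: float = 4.0
    homopolymer_bias: float = 0.0

    def __post_init__(self) -> None:
        total = (
            self.gc_at_transition + self.at_gc_transition
            + self.gc_ta_transversion + self.other_transversion
            + self.insertion + self.deletion
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum probabilities sum to {total}, not 1")
        if self.indel_length_mean < 1:
            raise ValueError("indel lengths must be >= 1")

    @property
    def classes(self) -> list[tuple[str, float]]:
        return [
            ("gc_at_transition", self.gc_at_transition),
            ("at_gc_transition", self.at_gc_transition),
            ("gc_ta_transversion", self.gc_ta_transversion),
            ("other_transversion", self.other_transversion),
            ("insertion", self.insertion),
            ("deletion", self.deletion),
        ]


@dataclass(frozen=True)
class TruthVariant:
    replicon: str
    position: int  # left-aligned, empty-allele convention
    ref_allele: str
    alt_allele: str
    mutation_class: str
    fraction: float  # true segregation fraction in (0, 1]
    strains: tuple[str, ...]

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.replicon, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class ArtifactRecord:
    strain_id: str
    replicon: str
    position: int
    ref_allele: str
    alt_allele: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.replicon, self.position, self.ref_allele, self.alt_allele)


@dataclass
class TruthSet:
    variants: list[TruthVariant]
    strains: tuple[str, ...]
    baseline: list[TruthVariant] = field(default_factory=list)
    artifacts: list[ArtifactRecord] = field(default_factory=list)
    emitted: dict[str, int] = field(default_factory=dict)  # strain → record count
    emitted_support: dict[str, dict[str, tuple[int, int]]] = field(
        default_factory=dict
    )  # strain → "repl:pos:ref:alt" → (variant_reads, total_reads)

    def to_json(self, dest=None) -> str:
        payload = {
            "strains": list(self.strains),
            "variants": [
                {
                    "replicon": v.replicon, "position": v.position,
                    "ref": v.ref_allele, "alt": v.alt_allele,
                    "class": v.mutation_class, "fraction": v.fraction,
                    "strains": list(v.strains),
                }
                for v in self.variants
            ],
            "baseline": [
                {
                    "replicon": v.replicon, "position": v.position,
                    "ref": v.ref_allele, "alt": v.alt_allele,
                }
                for v in self.baseline
            ],
            "artifacts": [
                {
                    "strain": a.strain_id, "replicon": a.replicon,
                    "position": a.position, "ref": a.ref_allele,
                    "alt": a.alt_allele,
                }
                for a in self.artifacts
            ],
            "emitted": self.emitted,
            "emitted_support": self.emitted_support,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if dest is not None:
            Path(dest).write_text(text)
        return text


@dataclass(frozen=True)
class PopulationModel:
    """Strains with true growth parameters, plus mix composition.

    ``ploidy`` is the number of genome copies per cell (the organism's is
    reported between 58 and 218; 100 is used as a round default).  Mix
    proportions weight the strains when a pooled culture is simulated; its
    growth rate is the weighted mean of the member rates.
    """

    strains: tuple[tuple[str, RatkowskyFit], ...]
    mix_proportions: tuple[float, ...] = ()
    ploidy: int = 100

    def __post_init__(self) -> None:
        if not (2 <= self.ploidy <= 1000):
            raise ValueError("ploidy outside plausibility range")
        if self.mix_proportions:
            if len(self.mix_proportions) != len(self.strains):
                raise ValueError("one mix proportion per strain required")
            if any(w < 0 for w in self.mix_proportions):
                raise ValueError("mix proportions must be non-negative")
            if abs(sum(self.mix_proportions) - 1.0) > 1e-9:
                raise ValueError("mix proportions must sum to 1")


# ---------------------------------------------------------------------------
# reference genome

def simulate_reference(
    n_replicons: int = 1,
    lengths: Sequence[int] = (50_000,),
    gc_content: float = 0.5,
    n_genes: int = 20,
    seed: int = 0,
    min_spacing: int = 200,
) -> tuple[dict[str, str], list[GeneModel], dict[str, CategoryEntry]]:
    """Random genome + non-overlapping CDS gene models + category flatfile.

    Gene sequences are built codon-wise (start codon, non-stop interior
    codons at the target GC, one stop codon), so every coding gene validates
    and translates cleanly.  Fully reproducible from the seed.
    """
    if len(lengths) != n_replicons:
        raise ValueError("one length per replicon required")
    if min(lengths) < 10_000:
        raise ValueError("replicons must be at least 10 kb")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    categories: dict[str, CategoryEntry] = {}
    cat_cycle = [
        ("Energy metabolism", "Glycolysis"),
        ("Transcription", "RNA synthesis"),
        ("Cellular processes", "Chaperones"),
        ("Transport", "ABC transporters"),
        ("Hypothetical", "Unknown"),
    ]
    per_replicon = _split_counts(n_genes, lengths)
    gene_no = 0
    for ri in range(n_replicons):
        name = "chromosome" if ri == 0 else f"plasmid{ri}"
        length = lengths[ri]
        seq = rng.choice(BASES, size=length, p=p)
        cursor = min_spacing + 1
        for _ in range(per_replicon[ri]):
            gene_no += 1
            n_codons = int(rng.integers(100, 300))  # 300-900 bp CDS
            glen = 3 * n_codons
            start = cursor + int(rng.integers(0, min_spacing))
            end = start + glen - 1
            if end > length - min_spacing:
                raise ValueError("infeasible gene packing for requested lengths")
            strand = "+" if rng.random() < 0.5 else "-"
            cds = _random_cds(rng, n_codons, p)
            placed = cds if strand == "+" else _revcomp(cds)
            seq[start - 1 : end] = list(placed)
            tag = f"syn{gene_no:04d}"
            genes.append(
                GeneModel(
                    locus_tag=tag, replicon=name, start=start, end=end,
                    strand=strand, coding=True,
                    product=f"simulated protein {gene_no}",
                )
            )
            cat, subcat = cat_cycle[(gene_no - 1) % len(cat_cycle)]
            categories[tag] = CategoryEntry(
                tag, f"simulated protein {gene_no}", cat, subcat
            )
            cursor = end + 1 + min_spacing
        genome[name] = "".join(seq)
    return genome, genes, categories


def _split_counts(n: int, lengths: Sequence[int]) -> list[int]:
    total = sum(lengths)
    counts = [int(round(n * l / total)) for l in lengths]
    counts[0] += n - sum(counts)
    return counts


def _random_cds(rng: np.random.Generator, n_codons: int, p: np.ndarray) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(BASES, size=3, p=p))
        if codon not in STOP_CODONS:
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# mutation injection

def inject_mutations(
    genome: Mapping[str, str],
    spectrum: MutationSpectrum,
    n: int,
    strains: Sequence[str],
    seed: int = 0,
    assignment: str | Sequence[Sequence[str]] = "random",
    point_mass_weight: float = 0.3,
    fraction_range: tuple[float, float] = (0.02, 0.97),
    avoid_homopolymer_runs: int = 4,
) -> TruthSet:
    """Draw ``n`` ground-truth mutations and assign them to strains.

    Fractions come from a mixture: with probability ``point_mass_weight`` the
    mutation is fully segregated (fraction 1.0), otherwise the fraction is
    uniform on ``fraction_range``.  ``assignment`` is either ``"random"``
    (every non-empty strain subset equally reachable) or an explicit list of
    strain subsets, one per mutation, supporting shared-lineage and
    independent-recurrence patterns.  Injected indels are re-drawn if they
    would meet the homopolymer-artifact definition at run length
    ``avoid_homopolymer_runs`` — true mutations and platform artifacts stay
    distinguishable by construction.
    """
    if isinstance(assignment, str):
        if assignment != "random":
            raise ValueError(f"unknown assignment rule {assignment!r}")
        subsets = None
    else:
        if len(assignment) != n:
            raise ValueError("need one strain subset per mutation")
        subsets = [tuple(s) for s in assignment]
    rng = np.random.default_rng(seed)
    names = list(genome)
    weights = np.array([len(genome[r]) for r in names], dtype=float)
    weights /= weights.sum()
    class_names = [c for c, _ in spectrum.classes]
    class_p = np.array([p for _, p in spectrum.classes])
    used: set[tuple[str, int]] = set()
    variants: list[TruthVariant] = []
    for i in range(n):
        for _attempt in range(10_000):
            replicon = names[int(rng.choice(len(names), p=weights))]
            seq = genome[replicon]
            cls = class_names[int(rng.choice(len(class_names), p=class_p))]
            drawn = _draw_variant(rng, seq, cls, spectrum)
            if drawn is None:
                continue
            pos, ref, alt = drawn
            if (replicon, pos) in used:
                continue
            candidate = VariantRecord(
                replicon=replicon, position=pos, ref_allele=ref,
                alt_allele=alt, variant_reads=0, total_reads=0,
            )
            if candidate.is_indel and _is_homopolymer_artifact(
                candidate, seq, avoid_homopolymer_runs
            ):
                continue
            break
        else:
            raise RuntimeError("could not place mutation; genome too constrained")
        used.add((replicon, pos))
        if subsets is not None:
            carriers = subsets[i]
        else:
            mask = rng.random(len(strains)) < 0.5
            if not mask.any():
                mask[int(rng.integers(len(strains)))] = True
            carriers = tuple(s for s, m in zip(strains, mask) if m)
        if rng.random() < point_mass_weight:
            fraction = 1.0
        else:
            fraction = float(rng.uniform(*fraction_range))
        variants.append(
            TruthVariant(
                replicon=replicon, position=pos, ref_allele=ref,
                alt_allele=alt, mutation_class=cls, fraction=fraction,
                strains=carriers,
            )
        )
    return TruthSet(variants=variants, strains=tuple(strains))


def _draw_variant(
    rng: np.random.Generator, seq: str, cls: str, spectrum: MutationSpectrum
):
    L = len(seq)
    pos = int(rng.integers(201, L - 200))  # keep clear of replicon ends
    base = seq[pos - 1]
    if cls == "gc_at_transition":
        if base not in "GC":
            return None
        return pos, base, TRANSITION[base]
    if cls == "at_gc_transition":
        if base not in "AT":
            return None
        return pos, base, TRANSITION[base]
    if cls == "gc_ta_transversion":
        return pos, base, GC_TA_TRANSVERSION[base]
    if cls == "other_transversion":
        return pos, base, OTHER_TRANSVERSION[base]
    length = int(rng.geometric(1.0 / spectrum.indel_length_mean))
    if cls == "insertion":
        ins = "".join(rng.choice(BASES, size=length))
        p_al, ins_al = _left_align(seq, pos, "", ins)
        return p_al, "", ins_al
    # deletion
    if pos + length - 1 > L - 200:
        return None
    ref = seq[pos - 1 : pos - 1 + length]
    p_al, ref_al = _left_align(seq, pos, ref, "")
    return p_al, ref_al, ""


def _left_align(seq: str, pos: int, ref: str, alt: str):
    from .variants import _left_align_deletion, _left_align_insertion

    if ref:  # deletion
        return _left_align_deletion(seq, pos, ref)
    return _left_align_insertion(seq, pos, alt)


# ---------------------------------------------------------------------------
# read evidence

def emit_read_evidence(
    truth: TruthSet,
    genome: Mapping[str, str],
    coverage: float = 120.0,
    seed: int = 0,
    artifact_rate_per_100kb: float = 0.5,
    artifact_run: int = 4,
    artifact_fraction_range: tuple[float, float] = (0.05, 0.4),
) -> dict[str, list[DiffRecord]]:
    """Observe the truth set through finite coverage, per strain.

    For each truth variant carried by a strain, total reads are
    Poisson(coverage) and variant reads Binomial(total, fraction); records
    with zero supporting reads are not emitted (a caller would not call
    them).  Labelled single-base artifact indels are additionally injected
    inside homopolymer runs of length >= ``artifact_run`` at the given rate
    per 100 kb per strain.  Baseline (parental) variants are emitted for
    every strain at their own fractions.  Bookkeeping (emission counts and
    per-variant read support) is written back onto the truth set.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    runs = {rep: _homopolymer_runs(genome[rep], artifact_run)
            for rep in genome}
    truth_keys = {v.key for v in truth.variants} | {v.key for v in truth.baseline}
    out: dict[str, list[DiffRecord]] = {}
    truth.artifacts = []
    truth.emitted = {}
    truth.emitted_support = {}
    for strain in truth.strains:
        records: list[DiffRecord] = []
        support: dict[str, tuple[int, int]] = {}
        for v in truth.baseline + truth.variants:
            if v not in truth.baseline and strain not in v.strains:
                continue
            total = int(rng.poisson(coverage))
            if total == 0:
                continue
            vr = int(rng.binomial(total, v.fraction))
            if vr == 0:
                continue
            records.append(_to_diff(v, vr, total))
            support[":".join(map(str, v.key))] = (vr, total)
        n_art = int(rng.poisson(
            artifact_rate_per_100kb * sum(len(s) for s in genome.values()) / 1e5
        ))
        placed = 0
        guard = 0
        while placed < n_art and guard < 10_000:
            guard += 1
            rep = list(genome)[int(rng.integers(len(genome)))]
            if not runs[rep]:
                break
            start0, length, base = runs[rep][int(rng.integers(len(runs[rep])))]
            kind = "del" if rng.random() < 0.5 else "ins"
            if kind == "del":
                pos, ref, alt = start0 + 1, base, ""
            else:  # insertion left-aligned to just before the run
                pos, ref, alt = start0, "", base
            if (rep, pos, ref, alt) in truth_keys:
                continue
            total = int(rng.poisson(coverage))
            if total == 0:
                continue
            vr = int(rng.binomial(total, rng.uniform(*artifact_fraction_range)))
            if vr == 0:
                continue
            art = ArtifactRecord(strain, rep, pos, ref, alt)
            truth.artifacts.append(art)
            if ref:
                records.append(DiffRecord(rep, pos, pos, ref, "", vr, total,
                                          note="artifact"))
            else:
                records.append(DiffRecord(rep, pos, pos, "", alt, vr, total,
                                          note="artifact"))
            placed += 1
        records.sort(key=lambda r: (r.replicon, r.start, r.alt_allele))
        out[strain] = records
        truth.emitted[strain] = len(records)
        truth.emitted_support[strain] = support
    return out


def _to_diff(v: TruthVariant, vr: int, total: int) -> DiffRecord:
    if not v.ref_allele:  # insertion
        return DiffRecord(v.replicon, v.position, v.position, "", v.alt_allele,
                          vr, total)
    end = v.position + len(v.ref_allele) - 1
    return DiffRecord(v.replicon, v.position, end, v.ref_allele,
                      v.alt_allele, vr, total)


def _homopolymer_runs(seq: str, min_run: int) -> list[tuple[int, int, str]]:
    """(0-based start, length, base) of maximal runs with length >= min_run."""
    runs = []
    i = 0
    L = len(seq)
    while i < L:
        j = i
        while j + 1 < L and seq[j + 1] == seq[i]:
            j += 1
        if j - i + 1 >= min_run and i > 200 and j < L - 200:
            runs.append((i, j - i + 1, seq[i]))
        i = j + 1
    return runs


# ---------------------------------------------------------------------------
# growth experiments

def simulate_growth_experiment(
    model: PopulationModel,
    temperatures: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
    hold_days: int = 3,
    readings_per_day: int = 1,
    start_od: float = 0.5,
    dilution_threshold: float = 2.0,
    dilution_target: float = 1.0,
    include_mix: bool | None = None,
) -> list[ODTimeSeries]:
    """Simulate OD750 traces under a stepwise temperature schedule.

    Each temperature is held for ``hold_days`` days (``hold_days + 1``
    readings at daily cadence, so a 3-day hold yields the minimum of three
    within-plateau intervals the protocol asks for... strictly, four OD
    values).  OD grows exponentially at the strain's model rate; observation
    noise is multiplicative lognormal with sigma ``noise_sigma``; cultures
    exceeding the dilution threshold are diluted back to the target with the
    factor recorded.  A pooled "mix" trace growing at the
    proportion-weighted mean rate is appended when mix proportions are set.
    """
    rng = np.random.default_rng(seed)
    out = []
    members = [(sid, fit) for sid, fit in model.strains]
    if include_mix is None:
        include_mix = bool(model.mix_proportions)
    tasks: list[tuple[str, Callable[[float], float]]] = [
        (sid, (lambda f: lambda t: ratkowsky_mu(f, t))(fit))
        for sid, fit in members
    ]
    if include_mix:
        weights = model.mix_proportions or tuple(
            1.0 / len(members) for _ in members
        )
        tasks.append(
            (
                "mix",
                lambda t: float(
                    sum(w * ratkowsky_mu(f, t) for w, (_, f) in zip(weights, members))
                ),
            )
        )
    dt = 1.0 / readings_per_day
    for sid, rate in tasks:
        readings = []
        time = 0.0
        for temp in temperatures:
            od = start_od  # fresh inoculum per plateau
            mu = rate(temp)
            for k in range(hold_days * readings_per_day + 1):
                if k > 0:
                    time += dt
                    od *= math.exp(mu * dt)
                dil = 1.0
                if od > dilution_threshold:
                    dil = od / dilution_target
                    od = dilution_target
                noise = math.exp(rng.normal(0.0, noise_sigma)) if noise_sigma else 1.0
                readings.append((round(time, 6), od * noise, temp, dil))
            time += dt  # gap between plateaus keeps times strictly increasing
        out.append(ODTimeSeries(sid, tuple(readings)))
    return out


def make_sim_provider(
    fit: RatkowskyFit,
    noise_sigma: float = 0.0,
    seed: int = 0,
    window_days: float = 14.0,
    start_od: float = 0.5,
) -> Callable[[float], ODTimeSeries]:
    """Culture source for the in-silico temperature-ramp protocol.

    Returns a provider that grows a fresh culture at any requested held
    temperature for the stability window, with daily OD readings.  The noise
    stream is derived from (seed, temperature) so results do not depend on
    the order in which temperatures are requested.
    """

    def provider(temp: float) -> ODTimeSeries:
        sub_seed = (int(seed) * 1_000_003 + int(round(temp * 1000))) % (2**31 - 1)
        rng = np.random.default_rng(sub_seed)
        mu = ratkowsky_mu(fit, temp)
        readings = []
        od = start_od
        t = 0.0
        n_days = int(math.ceil(window_days))
        for k in range(n_days + 1):
            if k > 0:
                t += 1.0
                od *= math.exp(mu)
            dil = 1.0
            if od > 2.0:
                dil = od / 1.0
                od = 1.0
            noise = math.exp(rng.normal(0.0, noise_sigma)) if noise_sigma else 1.0
            readings.append((t, od * noise, temp, dil))
        return ODTimeSeries("sim", tuple(readings))

    return provider


# ---------------------------------------------------------------------------
# one-call dataset

def simulate_all(
    out_dir,
    seed: int = 0,
    n_strains: int = 5,
    coverage: float = 120.0,
    n_mutations: int = 250,
    n_baseline: int = 12,
    genome_length: int = 100_000,
    n_genes: int = 30,
    gc_content: float = 0.5,
    spectrum: MutationSpectrum | None = None,
    noise_sigma: float = 0.02,
    artifact_rate_per_100kb: float = 0.5,
) -> dict:
    """Generate a complete synthetic study into ``out_dir``.

    Emits the reference FASTA, gene table, category flatfile, per-strain
    difference files (plus a parental ``wt`` baseline), OD growth tables and
    a ground-truth JSON.  Returns a manifest of paths plus the in-memory
    objects.  Deterministic for a given seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spectrum = spectrum or MutationSpectrum()
    rng = np.random.default_rng(seed)
    genome, genes, categories = simulate_reference(
        n_replicons=1, lengths=(genome_length,), gc_content=gc_content,
        n_genes=n_genes, seed=int(rng.integers(2**31 - 1)),
    )
    strains = [f"S{i + 1}" for i in range(n_strains)]
    truth = inject_mutations(
        genome, spectrum, n_mutations, strains,
        seed=int(rng.integers(2**31 - 1)),
    )
    baseline_set = inject_mutations(
        genome, MutationSpectrum(), n_baseline, strains,
        seed=int(rng.integers(2**31 - 1)),
        assignment=[tuple(strains)] * n_baseline,
        point_mass_weight=1.0,
    )
    # baseline keys must not collide with new-mutation keys
    new_keys = {v.key for v in truth.variants}
    truth.baseline = [v for v in baseline_set.variants if v.key not in new_keys]
    diff_files = emit_read_evidence(
        truth, genome, coverage=coverage,
        seed=int(rng.integers(2**31 - 1)),
        artifact_rate_per_100kb=artifact_rate_per_100kb,
    )
    # parental wild type carries exactly the baseline variants
    wt_truth = TruthSet(
        variants=[dataclasses.replace(v, strains=("wt",)) for v in truth.baseline],
        strains=("wt",),
    )
    wt_records = emit_read_evidence(
        wt_truth, genome, coverage=coverage,
        seed=int(rng.integers(2**31 - 1)),
        artifact_rate_per_100kb=0.0,
    )["wt"]

    fits = tuple(
        (
            sid,
            RatkowskyFit(
                b=float(rng.uniform(0.002, 0.004)),
                c=float(rng.uniform(0.15, 0.35)),
                t_min=float(rng.uniform(2.0, 5.0)),
                t_max=float(rng.uniform(44.0, 46.0)),
                sse=0.0, n_points_linear=0, n_points_supra=0,
            ),
        )
        for sid in strains
    )
    model = PopulationModel(
        strains=fits,
        mix_proportions=tuple(float(w) for w in np.full(n_strains, 1.0 / n_strains)),
    )
    t_lo = max(f.t_min for _, f in fits) + 10.0
    t_hi = min(f.t_max for _, f in fits)
    temperatures = [round(float(t), 2) for t in np.linspace(t_lo, t_hi - 0.2, 10)]
    od_series = simulate_growth_experiment(
        model, temperatures, noise_sigma=noise_sigma,
        seed=int(rng.integers(2**31 - 1)),
    )

    manifest = {
        "genome": out_dir / "reference.fasta",
        "genes": out_dir / "genes.tsv",
        "categories": out_dir / "categories.csv",
        "od_table": out_dir / "od_table.tsv",
        "truth": out_dir / "truth.json",
        "baseline_hcdiffs": out_dir / "wt.hcdiffs.tsv",
        "samples": {s: out_dir / f"{s}.hcdiffs.tsv" for s in strains},
    }
    write_fasta(genome, manifest["genome"])
    write_gene_table(genes, manifest["genes"])
    write_category_flatfile(categories.values(), manifest["categories"])
    write_od_table(od_series, manifest["od_table"])
    write_hcdiffs(wt_records, manifest["baseline_hcdiffs"],
                  header="parental wild-type high-confidence differences")
    for s in strains:
        write_hcdiffs(diff_files[s], manifest["samples"][s],
                      header=f"strain {s} high-confidence differences")
    truth.to_json(manifest["truth"])
    return {
        "paths": manifest,
        "genome": genome,
        "genes": genes,
        "categories": categories,
        "truth": truth,
        "model": model,
        "diff_records": diff_files,
        "wt_records": wt_records,
        "od_series": od_series,
        "strains": strains,
    }
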