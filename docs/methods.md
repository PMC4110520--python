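# Methods

## Scope and data model

The package reconstructs, as testable software, the two analysis arms of a
thermal adaptive-evolution study on a polyploid cyanobacterium: growth
phenotyping from OD750 time series under stepwise temperature schedules, and
identification of newly arisen mutations from per-strain difference calls
against a reference genome. All genomic coordinates are 1-based and
inclusive. Indels are held in an empty-allele form (empty reference allele
for an insertion placed *after* a named base, empty alternate allele for a
deletion) and converted to VCF anchor-base form only at the VCF boundary;
this keeps baseline subtraction a literal set operation on
(replicon, position, ref, alt) keys.

The raw variant input is a fixed 8-column tab-separated dialect
(`replicon, start, end, ref, alt, variant_reads, total_reads, note`, with
`>` comment lines). The mapper output it stands in for is not publicly
specified; the dialect is this package's own definition, and the simulator
and parser are kept in lockstep by construction.

## Growth model

Rates are two-point estimates μ = ln(X_t/X_0)/t over a held-temperature
plateau (first and last reading), after multiplying out recorded dilution
factors. A regression-of-ln(OD) variant would average over intermediate
readings but is deliberately not the default: the two-point form is the
quantity the screening protocol defines. Rates are effective daily rates;
day/night cycling is not modelled.

The temperature response is the modified Ratkowsky model
μ(T) = b(T−T_min)²(1−e^{c(T−T_max)}) on [T_min, T_max], zero outside. For
b, c > 0 it vanishes exactly at both cardinal temperatures and is positive
strictly between them. Parameters, units, defaults:

| parameter | unit | meaning |
|---|---|---|
| b | d⁻¹·°C⁻² | square of the sub-optimal √μ-vs-T slope |
| c | °C⁻¹ | steepness of the collapse approaching T_max |
| T_min, T_max | °C | minimum/maximum temperature allowing growth |

### Estimation

1. **Linear stage.** Points strictly below the temperature of maximum
   observed rate are the "linear range". OLS of √μ on T gives slope β and
   intercept a; b = β², T_min = −a/β. Regressing √μ (not μ) on T is the
   only reading dimensionally consistent with the main model; a μ-scale
   variant is available behind a flag.
2. **Upper stage.** For a candidate T_max, each usable supra-optimal point
   (T_min < T < T_max and μ < b(T−T_min)²) yields
   c = ln(1 − μ/(b(T−T_min)²))/(T − T_max); the estimate is their mean,
   with violating points skipped and counted. T_max is searched on
   [T_opt, T_opt + 15 °C]: a 0.1 °C grid scan first, then golden section to
   1e-6 °C inside the best grid cell. The grid scan matters because the SSE
   profile in T_max is not unimodal while the linear-stage parameters are
   still biased.
3. **Fixed-point iteration.** The linear stage is biased by the
   (1−e^{c(T−T_max)}) factor, which suppresses even sub-optimal rates by up
   to ~40 % when c is small. After each upper stage, sub-optimal rates are
   divided by the current suppression factor and stage 1 repeats (≤ 12
   iterations).
4. **Polish.** The iteration converges only geometrically for small c, so a
   joint `scipy.optimize.least_squares` refinement of (b, c, T_min, T_max)
   finishes the fit; it is kept only if it lowers the SSE. On noise-free
   samples the full procedure returns the generating parameters to machine
   precision.

### Maximum tolerated temperature

The in-silico ramp mirrors the bioreactor rule: from a viable start
temperature, raise in 0.1 °C grid steps; at each step grow a culture for the
stability window (14 d) and call it stable if the mean rate over the window
is at least the stability threshold. The experimental protocol specifies the
two-week window but no rate threshold; 0.05 d⁻¹ is this package's default
(about one doubling per two weeks), configurable. With threshold 0 the rule
degenerates to "any strictly positive growth", returning T_max rounded down
to the grid. The answer is the last stable grid temperature; instability at
the start temperature is an error, and the ramp aborts after 500 steps.

## Variant pipeline

* **Normalization.** Indels are shifted to their leftmost equivalent
  placement against the reference; substitutions are checked against the
  reference base. Records are ordered deterministically by
  (replicon, position, alt, ref).
* **Baseline subtraction.** A sample variant is removed iff its full key is
  present in the parental set. The operation satisfies
  subtract(S,B) ∪ (S∩B) = S and subtract(S,B) ∩ B = ∅, property-tested on
  arbitrary generated sets.
* **Homopolymer filtering.** The dominant error mode of the sequencing
  platforms involved is indel calls inside base runs. An indel is flagged
  iff its inserted/deleted bases are a single repeated nucleotide and the
  reference run containing or adjacent to the site is ≥ `min_run` long.
  `min_run` defaults to 4, the shortest run conventionally treated as an
  error context for these platforms; mixed-base indels (e.g. a GCAA
  insertion) are never flagged. Flagged records are excluded from matrices
  but retained, marked, in the annotated report.
* **Effect classification.** Single-base substitutions in a coding gene are
  translated codon-wise on the coding strand (genetic code table 11);
  classes are Synonymous, AA change, Stop gain, Stop loss. Indels in a CDS
  are Frameshift unless the net length change is a multiple of 3 (In-frame
  indel); length-preserving multi-base substitutions are classified by
  rebuilding and translating the whole CDS. Variants spanning a gene
  boundary are annotated Frameshift with a boundary warning. Gene models
  must be non-overlapping; overlap is rejected at load time. Codon changes
  are rendered lowercase with the substituted base uppercase (`gAg→gGg`).
  The classifier is verified against an independent full-CDS
  rebuild-and-translate oracle on ≥ 1000 random cases.
* **Segregation.** With ~100 genome copies per cell (reported range 58–218),
  the variant-read fraction estimates the fraction of copies carrying the
  mutation. Calls: ≥ 97 % fully segregated, < 2 % trace, otherwise partial.
  The thresholds are this package's operational choices and are
  configurable; fractions are reported to 3 significant figures.
* **Gene-level support.** Distinct mutations in one gene are assumed
  mutually exclusive per genome copy (each copy carries at most one of
  them, consistent with reads that never show two of the mutations
  simultaneously), so their fractions sum to the share of copies
  carrying *some* mutation in the gene. Sums above 100 % violate the
  assumption and produce a warning but are still reported. Intergenic
  records are excluded — a sum across unrelated intergenic loci is not a
  gene-level quantity.
* **Matrix.** Rows are variant keys, columns strains, cells presence; the
  same key must carry the same annotation in every strain (annotation
  depends only on the reference), otherwise the build errors.
* **Primer design.** Candidate 18–27-mers with the forward 3′ end
  100–150 bp upstream and the reverse 3′ end 350–400 bp downstream of the
  target base are scanned in deterministic order (increasing offset, then
  length); the first pair with both Tm in 58–62 °C and ΔTm ≤ 2 °C wins.
  Tm is nearest-neighbor (Biopython `Tm_NN`, unified parameter set) at
  50 mM monovalent salt and 500 nM primer — the original design tool's
  settings are unrecoverable, and the constraint window is what matters.
  Targets closer than 500 bp to a replicon end are rejected.

## Synthetic data

The generator is a pure function of (parameters, seed) and produces every
pipeline input plus ground truth:

* **Reference.** Random sequence at a target GC (default 0.5) with
  non-overlapping coding genes (start codon, stop-free interior codons at
  the target GC, terminal stop; 300–900 bp; ≥ 200 bp spacing) and a
  category flatfile covering every gene.
* **Mutation spectrum.** Defaults: 60 % GC→AT transitions (UV-like), 25 %
  GC↔TA transversions (MMS-like), 5 % AT→GC transitions, 5 % other
  transversions, 5 % indels with geometric lengths of mean 4. The class
  structure follows the mutagens' documented biases; the exact proportions
  are invented defaults, configurable. Truth indels that would meet the
  homopolymer-artifact definition are re-drawn, so truth and artifacts stay
  distinguishable by construction.
* **Segregation fractions.** Mixture of a point mass at 1.0 (weight 0.3)
  and Uniform[0.02, 0.97] — fully segregated mutations exist alongside
  partially segregated ones, as observed. Fractions are continuous
  stand-ins for copy counts; read fractions, not copy numbers, are what is
  measured.
* **Read evidence.** Per carried variant and strain: total reads
  ~ Poisson(coverage) (default 120-fold, typical of a deep resequencing
  run),
  variant reads ~ Binomial(total, fraction); zero-support draws are not
  emitted. Labelled single-base artifact indels are injected inside runs
  ≥ 4 at 0.5 per 100 kb per strain (invented, configurable). A parental
  baseline set is emitted for the wild type and carried by all strains.
* **Growth.** OD grows exponentially at the strain's model rate per
  plateau, observed through multiplicative lognormal noise (default
  σ = 2 %); cultures exceeding OD 2 are diluted back to 1 with the factor
  recorded. A pooled "mix" trace grows at the proportion-weighted mean of
  member rates.
* **Default sizes.** `simulate_all` uses a 100 kb single-replicon genome
  with 30 genes, 5 strains, 250 injected mutations and 12 baseline
  variants. 250 mutations gives the ≥ 200 distinct truth fractions the
  segregation-slope recovery check requires; a small-experiment scale
  (e.g. 16 mutations with a specific sharing pattern across five strains)
  is reproducible by passing that pattern as an explicit assignment to
  `inject_mutations`.

What the simulator does **not** emulate: read-level data (no FASTQ/BAM, no
flowgram physics), mapping ambiguity, coverage waves along the genome,
strand bias, large structural variants and transposon activity, or
day/night growth cycling. Passing recovery tests therefore demonstrates the
correctness of the analysis chain under its stated statistical assumptions,
not robustness to mapping artifacts or structural variation in real data.

## Numerical and degenerate-input choices

* Temperatures compare within 1e-6 °C when readings are grouped into
  plateaus; grid temperatures are rounded to 6 decimals to avoid float
  drift.
* A growth rate needs ≥ 2 readings at the plateau (an advisory flag marks
  plateaus with fewer than the protocol's preferred 3).
* `estimate_linear` requires ≥ 2 distinct sub-optimal temperatures and a
  positive slope; `estimate_c` requires ≥ 1 usable point; `fit_ratkowsky`
  requires ≥ 4 points spanning the observed optimum.
* Report percentages use 3 significant figures; matrix row order is the
  sorted variant key; all pipeline outputs are byte-identical across
  repeated runs with the same config and seed.
* Multi-allelic VCF lines are split into biallelic records on read.

## Known limitations

* The two-point rate estimator inherits the noise of exactly two readings;
  the regression variant is available but changes the estimator the
  protocol defines.
* Effect annotation assumes non-overlapping, single-CDS gene models and
  ignores start-codon special cases except for stop gain/loss.
* Primer design checks no cross-dimer, hairpin or specificity criteria —
  it enforces the distance/Tm window only.
* The stability threshold (0.05 d⁻¹) and segregation thresholds (97 %/2 %)
  are operational defaults, not measured constants; conclusions sensitive
  to them should be re-run across a range.
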