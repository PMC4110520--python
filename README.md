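# aletools

Analysis toolkit for adaptive-laboratory-evolution experiments on polyploid
cyanobacteria (*Synechocystis*-like organisms): thermal-tolerance phenotyping
of cultures from OD750 time series, and identification of the mutations
behind the evolved phenotypes from per-strain variant calls against a
reference genome.

It is aimed at groups running temperature-selection experiments who need to
(1) turn plate/flask/bioreactor OD readings under stepwise temperature ramps
into comparable growth-vs-temperature phenotypes, and (2) reduce noisy
resequencing difference calls — from homopolymer-error-prone bench-top
platforms — to a confident matrix of newly arisen mutations with their
segregation state across the organism's many genome copies.

## The models at the core

**Growth.** For each held temperature the growth rate is the two-point
estimate μ = ln(X_t/X_0)/t on OD750, with recorded dilution events unwound.
The temperature response is fitted with a modified Ratkowsky equation over
the full biokinetic range,

    μ(T) = b (T − T_min)² · (1 − e^{c (T − T_max)}),

where T_min and T_max are the minimum and maximum temperatures allowing
growth, b scales the square-root-law rise (√μ = √b·(T − T_min) below the
optimum) and c shapes the collapse near T_max. Fitting is staged: ordinary
least squares of √μ on T over the sub-optimal points gives (b, T_min);
T_max is located by a grid-assisted golden-section search with c obtained by
algebraic inversion of the model at each candidate; the stages are iterated
and finished with a joint least-squares polish. The maximum tolerated
temperature is defined operationally: raise the temperature in 0.1 °C steps
and return the last temperature at which the mean growth rate over a
two-week window stays above a stability threshold (0.05 d⁻¹ by default).

**Mutations.** Difference records (a fixed tab-separated dialect or VCF) are
left-aligned, the parental wild-type variant set is subtracted by exact
(replicon, position, ref, alt) key, single-base indels inside homopolymer
runs ≥ 4 are flagged as platform artifacts, and surviving variants are
annotated codon-wise against the reference (bacterial genetic code; effect
classes AA change / Synonymous / Stop gain / Stop loss / Frameshift /
In-frame indel / Intergenic, with codon notation like `gAg→gGg`). Because
the organism carries ~100 genome copies per cell, the variant-read fraction
at each site estimates how far the mutation has segregated through the
copies; ≥ 97 % is called fully segregated, < 2 % trace. Per-strain results
combine into a strains × variants presence matrix, and read fractions of
distinct mutations in one gene sum to a per-gene mutant share (mutations are
assumed mutually exclusive per genome copy). A helper designs
Sanger-validation primer pairs (forward 3′ end 100–150 bp upstream, reverse
350–400 bp downstream of the target, Tm 58–62 °C, pair ΔTm ≤ 2 °C,
nearest-neighbor thermodynamics).

A synthetic-data module generates every input with the statistical structure
the analysis assumes (mutagen-biased mutation spectra, Poisson coverage,
binomial read support, labelled homopolymer artifacts, Ratkowsky growth with
lognormal OD noise) plus ground truth for recovery testing.

## Worked example

```bash
aletools simulate all --out sim --seed 3 --strains 3 --coverage 100 --mutations 30
aletools growth fit --od-table sim/od_table.tsv --out fits.tsv
aletools variants run \
    --sample S1=sim/S1.hcdiffs.tsv --sample S2=sim/S2.hcdiffs.tsv \
    --sample S3=sim/S3.hcdiffs.tsv --baseline sim/wt.hcdiffs.tsv \
    --genome sim/reference.fasta --genes sim/genes.tsv \
    --categories sim/categories.csv --out-dir run1
aletools variants primers --genome sim/reference.fasta --pos chromosome:50000
```

`growth fit` prints `fitted 4 strain(s) → fits.tsv`; the table starts

```
strain  b           c         t_min    t_max    sse          n_linear  n_supra
S1      0.00315001  0.167584  3.17616  44.9649  0.000278851  7         3
S2      0.00227631  0.302681  2.17081  44.7735  0.000758976  7         3
```

i.e. strain S1 stops growing just below 45.0 °C and would reach half its
optimal rate around 40 °C; `sse` is the squared-residual sum of the fit and
`n_linear`/`n_supra` count the points used below/above the observed optimum.
The variant run writes `matrix.tsv`, whose first rows look like

```
replicon    position  mutation_type  gene     wt  mutant  S1  S2  S3
chromosome  1589      AA change      syn0002  G   A               X
chromosome  6534      AA change      syn0007  C   T       X       X
```

an X marking which strains carry each confirmed (artifact-filtered,
baseline-subtracted) mutation, alongside `annotated_report.tsv` (effect,
read percentage, segregation call, gene category), `gene_support.tsv`,
`primers.tsv` and filtered per-strain VCFs. The primer command prints the
selected pair with offsets and melting temperatures:

```
forward  GCTGGGTTGAGAATAGAAGATAGTACG  3'@-104bp  Tm=58.87
reverse  TTGGTAAGACGGATATCTATTCAGCTC  3'@+350bp  Tm=58.16
```

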