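"""End-to-end orchestration: one config, one reproducible run directory.

A run ties the two analysis arms together: growth phenotyping (rate curves,
Ratkowsky fits, maximum tolerated temperature per strain) and mutation
identification (normalize → subtract parental baseline → flag homopolymer
artifacts → classify effects → annotate categories → presence matrix →
gene-level read support → validation primers).  Outputs are plain text and
byte-identical across repeat runs with the same config and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .growth import (
    GrowthModelError,
    RampProtocol,
    compute_growth_rate,
    fit_ratkowsky,
    growth_rate_curve,
)
from .io_formats import (
    read_category_flatfile,
    read_fasta,
    read_gene_table,
    read_hcdiffs,
    read_od_table,
    read_vcf,
    write_vcf,
)
from .simulate import simulate_all
from .variants import (
    PipelineError,
    aggregate_gene_support,
    annotate_categories,
    build_matrix,
    check_non_overlapping,
    classify_effect,
    design_validation_primers,
    flag_homopolymer_indels,
    normalize,
    partition_flagged,
    subtract_baseline,
)

__all__ = ["RunConfig", "ConfigError", "run_end_to_end"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Flat-key run configuration.

    Either ``simulate`` is true (a synthetic dataset is generated under the
    output directory) or the input paths must all point at existing files.
    """

    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True
    # simulation knobs (used when simulate=True)
    n_strains: int = 5
    coverage: float = 120.0
    n_mutations: int = 250
    noise_sigma: float = 0.02
    # explicit inputs (used when simulate=False)
    genome: str = ""
    genes: str = ""
    categories: str = ""
    od_table: str = ""
    baseline: str = ""
    samples: dict[str, str] = field(default_factory=dict)  # strain → diff/VCF path
    # thresholds
    min_run: int = 4
    stability_threshold: float = 0.05
    stability_window: float = 14.0
    step_grid: float = 0.1

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def validate(self) -> None:
        if self.min_run < 1 or self.step_grid <= 0 or self.stability_window <= 0:
            raise ConfigError("thresholds outside documented ranges")
        if self.simulate:
            return
        required = {
            "genome": self.genome, "genes": self.genes,
            "categories": self.categories, "baseline": self.baseline,
        }
        for name, p in {**required, **self.samples}.items():
            if not p or not Path(p).exists():
                raise ConfigError(f"missing input path for {name!r}: {p!r}")
        if self.od_table and not Path(self.od_table).exists():
            raise ConfigError(f"od_table not found: {self.od_table!r}")


def _read_variant_input(path, genome, strain_id):
    """Difference records (own dialect) or VCF, normalized either way."""
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        recs = read_vcf(path, strain_id=strain_id)
        return sorted(
            (dataclasses.replace(v, strain_id=strain_id) for v in recs),
            key=lambda v: (v.replicon, v.position, v.alt_allele, v.ref_allele),
        )
    return normalize(read_hcdiffs(path), genome, strain_id=strain_id)


def run_end_to_end(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Any stage failure aborts with the stage name attached.  The run log
    records the package version, seed, parameters and per-stage record
    counts.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"aletools {__version__}",
        f"seed {config.seed}",
        "config "
        + " ".join(
            f"{k}={v}" for k, v in sorted(dataclasses.asdict(config).items())
            if k != "samples"
        ),
    ]
    stage = "setup"
    try:
        if config.simulate:
            stage = "simulate"
            sim = simulate_all(
                out / "sim", seed=config.seed, n_strains=config.n_strains,
                coverage=config.coverage, n_mutations=config.n_mutations,
                noise_sigma=config.noise_sigma,
            )
            genome = sim["genome"]
            genes = sim["genes"]
            categories = sim["categories"]
            od_path = sim["paths"]["od_table"]
            baseline_path = sim["paths"]["baseline_hcdiffs"]
            sample_paths = sim["paths"]["samples"]
            log.append(f"simulate strains={len(sim['strains'])} "
                       f"truth_variants={len(sim['truth'].variants)} "
                       f"artifacts={len(sim['truth'].artifacts)}")
        else:
            stage = "load-inputs"
            genome = read_fasta(config.genome)
            genes = read_gene_table(config.genes, genome)
            categories = read_category_flatfile(config.categories)
            od_path = config.od_table or None
            baseline_path = config.baseline
            sample_paths = dict(config.samples)
        check_non_overlapping(genes)

        # ---- growth arm -------------------------------------------------
        stage = "growth"
        fit_rows, maxtemp_rows = [], []
        if od_path:
            for series in read_od_table(od_path):
                points = growth_rate_curve(series)
                try:
                    fit = fit_ratkowsky(points)
                    fit_rows.append(
                        (series.strain_id, fit.b, fit.c, fit.t_min, fit.t_max,
                         fit.sse, fit.n_points_linear, fit.n_points_supra)
                    )
                except GrowthModelError as exc:
                    log.append(f"growth fit skipped for {series.strain_id}: {exc}")
                maxtemp_rows.append(
                    (series.strain_id,
                     _max_tolerated_from_series(series, config))
                )
            pd.DataFrame(
                fit_rows,
                columns=["strain", "b", "c", "t_min", "t_max", "sse",
                         "n_linear", "n_supra"],
            ).to_csv(out / "fits.tsv", sep="\t", index=False, float_format="%.6g")
            pd.DataFrame(
                maxtemp_rows, columns=["strain", "max_tolerated_temp_c"]
            ).to_csv(out / "maxtemps.tsv", sep="\t", index=False)
            log.append(f"growth fitted={len(fit_rows)} strains")

        # ---- variant arm ------------------------------------------------
        stage = "baseline"
        baseline = _read_variant_input(baseline_path, genome, "wt")
        log.append(f"baseline records={len(baseline)}")
        per_strain_effects = {}
        report_frames = []
        for strain, path in sample_paths.items():
            stage = f"variants:{strain}"
            sample = _read_variant_input(path, genome, strain)
            # subtraction first (baseline keys are left-aligned too)
            new = flag_homopolymer_indels(
                subtract_baseline(sample, baseline), genome,
                min_run=config.min_run,
            )
            kept, flagged = partition_flagged(new)
            effects = [classify_effect(v, genome, genes) for v in kept]
            per_strain_effects[strain] = effects
            write_vcf(kept, genome, out / f"{strain}.filtered.vcf")
            frame = annotate_categories(effects, categories)
            frame.insert(0, "strain", strain)
            report_frames.append(frame)
            if flagged:
                side = annotate_categories(
                    [classify_effect(v, genome, genes) for v in flagged],
                    categories,
                )
                side.insert(0, "strain", strain)
                report_frames.append(side)
            log.append(
                f"{strain}: in={len(sample)} new={len(new)} "
                f"homopolymer_flagged={len(flagged)} kept={len(kept)}"
            )

        stage = "report"
        report = pd.concat(report_frames, ignore_index=True) if report_frames \
            else pd.DataFrame()
        report.to_csv(out / "annotated_report.tsv", sep="\t", index=False,
                      float_format="%.6g")

        stage = "matrix"
        matrix = build_matrix(per_strain_effects)
        matrix.to_tsv(out / "matrix.tsv")
        totals = matrix.per_strain_totals
        log.append("matrix totals " + " ".join(f"{s}={n}" for s, n in totals.items()))

        stage = "gene-support"
        support_rows = []
        import warnings as _warnings

        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            for strain, effects in per_strain_effects.items():
                coding = [e for e in effects if e.gene != "Intergenic"
                          and e.variant.total_reads > 0]
                if not coding:
                    continue
                sums = aggregate_gene_support(coding)
                for gene, pct in sums.items():
                    support_rows.append((strain, gene, pct))
        for w in caught:
            log.append(f"gene-support: {w.message}")
        pd.DataFrame(
            support_rows, columns=["strain", "gene", "summed_percent_reads"]
        ).to_csv(out / "gene_support.tsv", sep="\t", index=False)

        stage = "primers"
        primer_rows = []
        for key in matrix.rows:
            replicon, pos = key[0], key[1]
            try:
                pair = design_validation_primers(genome, replicon, pos)
                primer_rows.append(
                    (replicon, pos, pair.forward, pair.reverse,
                     pair.fw_offset, pair.rv_offset,
                     round(pair.tm_fw, 2), round(pair.tm_rv, 2))
                )
            except PipelineError as exc:
                log.append(f"primers unavailable for {replicon}:{pos}: {exc}")
        pd.DataFrame(
            primer_rows,
            columns=["replicon", "position", "forward", "reverse",
                     "fw_offset", "rv_offset", "tm_fw", "tm_rv"],
        ).to_csv(out / "primers.tsv", sep="\t", index=False)
    except (ConfigError, PipelineError, GrowthModelError, OSError) as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out / "run.log").write_text("\n".join(log) + "\n")
    return out


def _max_tolerated_from_series(series, config: RunConfig):
    """Apply the stable-growth rule to the plateaus recorded in a series."""
    temps = sorted(series.temperatures)
    last_stable = None
    for temp in temps:
        sub = series.at_temperature(temp)
        if len(sub.readings) < 2:
            continue
        mu = compute_growth_rate(series, temp).mu
        if config.stability_threshold > 0:
            ok = mu >= config.stability_threshold
        else:
            ok = mu > 0
        if ok:
            last_stable = temp
        else:
            break
    return last_stable if last_stable is not None else float("nan")
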