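"""Normalization, subtraction, effect calls, filtering, matrices, primers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aletools.fixtures import make_published_tables
from aletools.io_formats import DiffRecord, GeneModel
from aletools.variants import (
    PipelineError,
    VariantRecord,
    aggregate_gene_support,
    annotate_categories,
    build_matrix,
    classify_effect,
    design_validation_primers,
    flag_homopolymer_indels,
    normalize,
    primer_tm,
    read_fraction,
    segregation_call,
    subtract_baseline,
)
from helpers import apply_variant, brute_force_effect, make_exemplar_genome, tm_oracle


class TestNormalize:
    def test_substitution_passes_through(self, reference):
        genome, _, _ = reference
        pos = 5000
        ref = genome["chromosome"][pos - 1]
        rec = DiffRecord("chromosome", pos, pos, ref, "T" if ref != "T" else "A",
                         3, 10)
        (v,) = normalize([rec], genome)
        assert (v.position, v.ref_allele, v.alt_allele) == (
            pos, rec.ref_allele, rec.alt_allele
        )

    def test_in_run_insertion_shifts_left(self):
        genome = {"chromosome": "TTTTCAAAAGTTTT"}
        # insert an extra A at the right end of the AAAA run (positions 6-9)
        rec = DiffRecord("chromosome", 9, 9, "", "A", 3, 10)
        (v,) = normalize([rec], genome)
        assert v.position == 5  # before the run
        assert v.alt_allele == "A"

    def test_reference_mismatch_rejected(self, reference):
        genome, _, _ = reference
        base = genome["chromosome"][99]
        wrong = "A" if base != "A" else "C"
        rec = DiffRecord("chromosome", 100, 100, wrong, base, 3, 10)
        with pytest.raises(PipelineError, match="disagrees"):
            normalize([rec], genome)

    def test_all_equivalent_placements_collapse(self, reference):
        # brute force: every placement producing the same mutant sequence
        # must normalize to one representation
        genome, _, _ = reference
        seq = genome["chromosome"]
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 50:
            pos = int(rng.integers(500, len(seq) - 500))
            base = seq[pos - 1]
            run_end = pos
            while seq[run_end] == base:
                run_end += 1
            # candidate single-base deletions at each offset within the run
            candidates = [
                DiffRecord("chromosome", p, p, seq[p - 1], "", 3, 10)
                for p in range(pos, run_end + 1)
                if seq[p - 1] == base
            ]
            if len(candidates) < 2:
                continue
            results = {
                apply_variant(seq, normalize([c], genome)[0])
                for c in candidates
            }
            keys = {normalize([c], genome)[0].key for c in candidates}
            assert len(results) == 1
            assert len(keys) == 1
            checked += 1


class TestSubtractBaseline:
    def make(self, pos, ref, alt, strain="s"):
        return VariantRecord("chromosome", pos, ref, alt, 3, 10, strain)

    def test_identical_sets_cancel(self):
        s = [self.make(10, "G", "T"), self.make(20, "", "A")]
        assert subtract_baseline(s, s) == []

    def test_empty_baseline_is_identity(self):
        s = [self.make(10, "G", "T")]
        assert subtract_baseline(s, []) == s

    def test_parental_variants_removed_from_every_strain(self):
        baseline = [self.make(p, "G", "T", "wt") for p in (100, 200, 300)]
        for strain in ("a", "b", "c"):
            sample = [self.make(p, "G", "T", strain) for p in (100, 200, 300)]
            sample.append(self.make(400, "C", "A", strain))
            out = subtract_baseline(sample, baseline)
            assert {v.position for v in out} == {400}

    @given(
        st.sets(st.integers(1, 40), max_size=12),
        st.sets(st.integers(1, 40), max_size=12),
    )
    @settings(derandomize=True, max_examples=200)
    def test_subtraction_set_algebra(self, sample_pos, base_pos):
        sample = [self.make(p, "G", "T") for p in sorted(sample_pos)]
        baseline = [self.make(p, "G", "T") for p in sorted(base_pos)]
        out = subtract_baseline(sample, baseline)
        out_keys = {v.key for v in out}
        sample_keys = {v.key for v in sample}
        base_keys = {v.key for v in baseline}
        assert out_keys | (sample_keys & base_keys) == sample_keys
        assert out_keys & base_keys == set()


class TestClassifyEffect:
    def test_exemplar_aa_change_codon_rendering(self):
        genome, genes, pos = make_exemplar_genome()
        v = VariantRecord("chromosome", pos["pnp_sub"], "A", "G", 10, 10)
        ann = classify_effect(v, genome, genes)
        assert ann.effect_class == "AA change"
        assert ann.gene == "pnp"
        assert ann.codon_change == "gAg→gGg"
        assert ann.aa_change == "E→G"

    def test_exemplar_four_base_insertion_is_frameshift(self):
        genome, genes, pos = make_exemplar_genome()
        v = VariantRecord("chromosome", pos["cya1_ins_after"], "", "GCAA", 10, 10)
        ann = classify_effect(v, genome, genes)
        assert ann.effect_class == "Frameshift"
        assert ann.gene == "cya1"

    def test_exemplar_intergenic_substitution(self):
        genome, genes, pos = make_exemplar_genome()
        p = pos["intergenic_g"]
        v = VariantRecord("chromosome", p, "G", "T", 10, 10)
        ann = classify_effect(v, genome, genes)
        assert ann.effect_class == "Intergenic"
        assert ann.gene == "Intergenic"
        assert ann.flanking == ("pnp", "cya1")

    def test_synonymous_codon(self):
        genome, genes, _ = make_exemplar_genome()
        # pnp codon 3 is CTG (Leu); CTG->CTA stays Leu
        gene = genes[0]
        p = gene.start + 8
        assert genome["chromosome"][p - 1] == "G"
        ann = classify_effect(
            VariantRecord("chromosome", p, "G", "A", 10, 10), genome, genes
        )
        assert ann.effect_class == "Synonymous"

    def test_boundary_spanning_deletion_warns_frameshift(self):
        genome, genes, _ = make_exemplar_genome()
        gene = genes[0]
        start = gene.start - 2
        ref = genome["chromosome"][start - 1 : start + 4]
        ann = classify_effect(
            VariantRecord("chromosome", start, ref, "", 10, 10), genome, genes
        )
        assert ann.effect_class == "Frameshift"
        assert ann.boundary_warning

    def test_agrees_with_full_cds_rebuild_oracle(self, reference):
        genome, genes, _ = reference
        seq = genome["chromosome"]
        rng = np.random.default_rng(7)
        for _ in range(300):
            gene = genes[rng.integers(len(genes))]
            kind = rng.choice(["sub", "ins", "del"], p=[0.6, 0.2, 0.2])
            if kind == "sub":
                p = int(rng.integers(gene.start, gene.end + 1))
                ref = seq[p - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                v = VariantRecord("chromosome", p, ref, alt, 1, 1)
            elif kind == "ins":
                p = int(rng.integers(gene.start, gene.end - 1))
                ins = "".join(rng.choice(list("ACGT"),
                                         size=int(rng.integers(1, 6))))
                v = VariantRecord("chromosome", p, "", ins, 1, 1)
            else:
                ln = int(rng.integers(1, 6))
                p = int(rng.integers(gene.start, gene.end - ln + 1))
                v = VariantRecord("chromosome", p, seq[p - 1 : p - 1 + ln],
                                  "", 1, 1)
            ann = classify_effect(v, genome, genes)
            if not ann.boundary_warning:
                assert ann.effect_class == brute_force_effect(v, gene, seq), v


class TestHomopolymerFlagging:
    def test_single_base_deletion_in_run_flagged(self):
        genome = {"chromosome": "CGTACAAAAAGTCG"}
        v = VariantRecord("chromosome", 6, "A", "", 3, 10)
        assert flag_homopolymer_indels([v], genome)[0].homopolymer_flag

    def test_mixed_base_insertion_never_flagged(self):
        genome = {"chromosome": "CGTACAAAAAGTCG"}
        v = VariantRecord("chromosome", 6, "", "GCAA", 3, 10)
        assert not flag_homopolymer_indels([v], genome)[0].homopolymer_flag

    def test_short_run_not_flagged(self):
        genome = {"chromosome": "CGTACAAAGTCGTT"}  # run of 3 A's
        v = VariantRecord("chromosome", 6, "A", "", 3, 10)
        assert not flag_homopolymer_indels([v], genome, min_run=4)[0].homopolymer_flag

    def test_substitutions_never_flagged(self):
        genome = {"chromosome": "CGTACAAAAAGTCG"}
        v = VariantRecord("chromosome", 6, "A", "G", 3, 10)
        assert not flag_homopolymer_indels([v], genome)[0].homopolymer_flag

    def test_generator_labelled_artifacts_all_flagged(self, reference):
        from aletools.simulate import (
            MutationSpectrum, emit_read_evidence, inject_mutations,
        )

        genome, _, _ = reference
        truth = inject_mutations(genome, MutationSpectrum(), 40,
                                 ["s1", "s2", "s3"], seed=9)
        files = emit_read_evidence(truth, genome, coverage=80, seed=10,
                                   artifact_rate_per_100kb=8.0)
        assert truth.artifacts, "expected some injected artifacts"
        art_keys = {a.key for a in truth.artifacts}
        truth_keys = {v.key for v in truth.variants}
        for strain, records in files.items():
            flagged = flag_homopolymer_indels(
                normalize(records, genome, strain), genome, min_run=4
            )
            for v in flagged:
                if v.key in art_keys:
                    assert v.homopolymer_flag  # recall = 1
                if v.key in truth_keys and not v.is_indel:
                    assert not v.homopolymer_flag


class TestFractionsAndSegregation:
    def test_simple_percentage(self):
        v = VariantRecord("c", 1, "G", "T", 45, 100)
        assert read_fraction(v) == 45.0

    def test_full_support_is_100(self):
        v = VariantRecord("c", 1, "G", "T", 123, 123)
        assert read_fraction(v) == 100.0

    def test_three_significant_figures(self):
        v = VariantRecord("c", 1, "G", "T", 1, 3)
        assert read_fraction(v) == 33.3

    def test_zero_coverage_rejected(self):
        v = VariantRecord("c", 1, "G", "T", 0, 0)
        with pytest.raises(PipelineError):
            read_fraction(v)

    @pytest.mark.parametrize(
        "fraction,call",
        [
            (100.0, "fully segregated"),
            (97.0, "fully segregated"),
            (94.4, "partial"),
            (45.5, "partial"),
            (2.0, "partial"),
            (0.68, "trace"),
            (0.0, "trace"),
        ],
    )
    def test_segregation_thresholds(self, fraction, call):
        assert segregation_call(fraction) == call

    def test_binomial_sampling_recovers_fraction(self):
        rng = np.random.default_rng(123)
        f, cov, n = 0.455, 123, 200
        est = []
        for _ in range(n):
            total = rng.poisson(cov)
            est.append(100 * rng.binomial(total, f) / total)
        se = 100 * np.sqrt(f * (1 - f) / cov) / np.sqrt(n)
        assert abs(np.mean(est) - 45.5) < 3 * se


class TestMatrixAndAggregation:
    def test_published_matrix_totals(self):
        fx = make_published_tables()
        matrix = build_matrix(fx.per_strain_annotations())
        assert matrix.per_strain_totals == fx.confirmed_counts

    def test_single_strain_matrix(self):
        anns = make_published_tables().per_strain_annotations()["A6"]
        matrix = build_matrix({"A6": anns})
        assert matrix.per_strain_totals == {"A6": 2}
        assert len(matrix.rows) == 2

    def test_conflicting_annotations_rejected(self):
        fx = make_published_tables()
        anns = fx.per_strain_annotations()
        import dataclasses

        bad = dataclasses.replace(anns["A1"][0], gene="other")
        anns["A1"][0] = bad
        conflict = any(
            a.variant.key == bad.variant.key for a in anns["C5K"]
        ) or any(a.variant.key == bad.variant.key for a in anns["H12"])
        assert conflict
        with pytest.raises(PipelineError, match="conflicting"):
            build_matrix(anns)

    def test_pyrr_gene_support_aggregation(self):
        fx = make_published_tables()
        sums = aggregate_gene_support(fx.mix_table, fraction_col="percent_reads")
        assert sums["pyrR"] == 81.3

    def test_single_variant_gene_aggregate(self):
        fx = make_published_tables()
        sums = aggregate_gene_support(fx.mix_table, fraction_col="percent_reads")
        assert sums["pnp"] == 100.0

    def test_sum_above_100_warns_but_reports(self):
        import pandas as pd

        frame = pd.DataFrame({"gene": ["g", "g"], "percent_reads": [70.0, 60.0]})
        with pytest.warns(UserWarning, match="exceeds 100"):
            sums = aggregate_gene_support(frame)
        assert sums["g"] == 130.0


class TestAnnotateCategories:
    def test_known_and_unknown_genes(self, reference):
        genome, genes, categories = reference
        gene = genes[0]
        p = gene.start + 3
        ref = genome["chromosome"][p - 1]
        alt = "A" if ref != "A" else "G"
        ann = classify_effect(
            VariantRecord("chromosome", p, ref, alt, 5, 10), genome, genes
        )
        table = annotate_categories([ann], categories)
        assert table.loc[0, "category"] != "unknown"
        table2 = annotate_categories([ann], {})
        assert table2.loc[0, "category"] == "unknown"
        assert len(table2) == 1


class TestPrimerDesign:
    def test_constraints_verified_independently(self, reference):
        genome, _, _ = reference
        pair = design_validation_primers(genome, "chromosome", 25_000)
        # independent re-check of every constraint
        assert 100 <= pair.fw_offset <= 150
        assert 350 <= pair.rv_offset <= 400
        for primer, tm in ((pair.forward, pair.tm_fw), (pair.reverse, pair.tm_rv)):
            assert 18 <= len(primer) <= 27
            assert 58.0 <= tm_oracle(primer) <= 62.0
        assert abs(tm_oracle(pair.forward) - tm_oracle(pair.reverse)) <= 2.0
        # placement: forward matches the + strand upstream, reverse the
        # - strand downstream of the target
        seq = genome["chromosome"]
        three = 25_000 - pair.fw_offset
        assert seq[three - len(pair.forward) : three] == pair.forward

    def test_tm_matches_independent_nearest_neighbor(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"),
                                     size=int(rng.integers(18, 28))))
            assert abs(primer_tm(seq) - tm_oracle(seq)) < 0.01

    def test_target_near_replicon_end_rejected(self, reference):
        genome, _, _ = reference
        with pytest.raises(PipelineError, match="closer than"):
            design_validation_primers(genome, "chromosome", 200)
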