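"""The constraint-solving synthetic-genome generator."""

import itertools

import numpy as np
import pytest

from sargmito import (FORMS, GeneratorConfig, build_references,
                      generate_cohort, generate_marker_panel, layout_genes,
                      scan_variants, solve_codon_constraint)
from sargmito.errors import InfeasibleConstraintError, ValidationError
from sargmito.genetics import (COMPLEMENT, STOP_CODONS, expand_chain,
                               revcomp, translate_codon)
from sargmito.model import VariantRecord
from sargmito.simulate import feasible_codons


def brute_force_solutions(alleles, chain, allow_tga=False):
    """Exhaustive oracle: every (strand, offset, codon) whose per-form
    substitutions translate to the chain. 64 codons x 3 offsets x 2 strands."""
    aas = expand_chain(alleles, chain)
    out = []
    for strand in "+-":
        bases = [a if strand == "+" else COMPLEMENT[a] for a in alleles]
        for offset in range(3):
            for combo in itertools.product("ACGT", repeat=3):
                if combo[offset] != bases[0]:
                    continue
                codons = ["".join(combo[:offset] + (b,) + combo[offset + 1:])
                          for b in bases]
                if not allow_tga and "TGA" in codons:
                    continue
                if all(translate_codon(c) == aa
                       for c, aa in zip(codons, aas)):
                    out.append((strand, offset, "".join(combo)))
    return out


class TestCodonSolver:
    def test_rpl5_pro_to_ser_plus_strand(self):
        rec = VariantRecord(10313, "rpl5", ("C", "C", "T"), "Pro > Ser")
        sol = solve_codon_constraint(rec)
        assert (sol.strand, sol.offset, sol.codon) == ("+", 0, "CCA")
        assert translate_codon("CCA") == "Pro"
        assert translate_codon("TCA") == "Ser"

    def test_glu_to_stop_needs_minus_strand(self):
        rec = VariantRecord(10783, "orf129", ("C", "A", "A"), "Glu > Stop")
        sol = solve_codon_constraint(rec)
        assert sol.strand == "-"
        assert sol.codon == "GAA"   # coding GAA -> TAA via plus-strand C -> A
        # the oracle confirms no plus-strand solution exists
        assert not [s for s in brute_force_solutions(rec.alleles, rec.aa_chain)
                    if s[0] == "+"]

    def test_pro_to_met_is_infeasible(self):
        rec = VariantRecord(99, "toy", ("C", "A", "A"), "Pro > Met")
        assert brute_force_solutions(rec.alleles, rec.aa_chain,
                                     allow_tga=True) == []
        with pytest.raises(InfeasibleConstraintError):
            solve_codon_constraint(rec)

    def test_solver_agrees_with_enumeration_on_every_coding_row(
            self, variant_table):
        for rec in variant_table:
            if rec.kind != "CDS":
                continue
            sols = brute_force_solutions(rec.alleles, rec.aa_chain)
            if not sols:
                sols = brute_force_solutions(rec.alleles, rec.aa_chain,
                                             allow_tga=True)
            assert sols, f"row {rec.position} has no solution at all"
            got = solve_codon_constraint(rec)
            assert (got.strand, got.offset, got.codon) == sols[0]

    def test_noncoding_row_rejected(self, variant_table):
        rec = next(v for v in variant_table if v.kind != "CDS")
        with pytest.raises(ValidationError):
            solve_codon_constraint(rec)

    def test_feasible_codons_subset_of_oracle(self, variant_table):
        rec = next(v for v in variant_table if v.position == 14516)
        aas = expand_chain(rec.alleles, rec.aa_chain)
        for strand in "+-":
            for offset in range(3):
                got = {(strand, offset, c)
                       for c in feasible_codons(rec.alleles, aas, strand, offset)}
                oracle = {s for s in brute_force_solutions(rec.alleles, rec.aa_chain)
                          if s[0] == strand and s[1] == offset}
                assert got == oracle


class TestLayout:
    def test_gene_count_and_nonoverlap(self, layout, config):
        feats = sorted(layout, key=lambda f: f.start)
        assert len(feats) == config.gene_count == 65
        for a, b in zip(feats, feats[1:]):
            assert a.end < b.start

    def test_every_listed_locus_present(self, layout, variant_table):
        genic = {v.locus for v in variant_table if v.kind != "intergenic"}
        assert genic <= {f.locus for f in layout}

    def test_cds_cover_their_sites_in_frame(self, layout, variant_table):
        for v in variant_table:
            if v.kind != "CDS":
                continue
            plan = layout.plan(v.locus)
            f = plan.feature
            assert f.contains(v.position)
            sc = plan.site_codons[v.position]
            assert f.start <= sc.span[0] and sc.span[1] <= f.end
            if f.strand == "+":
                assert (v.position - f.start) % 3 == sc.offset
            else:
                assert (f.end - v.position) % 3 == sc.offset

    def test_deterministic(self, variant_table, config, primer_panel):
        a = layout_genes(variant_table, config, primer_panel)
        b = layout_genes(variant_table, config, primer_panel)
        assert a.features == b.features

    def test_conflicting_phases_are_infeasible(self):
        # Ile > Phe with alleles (T, A, A) is solvable only at minus-strand
        # offset 0; two such sites 4 bp apart demand incompatible frames.
        rows = [
            VariantRecord(9, "toygene", ("T", "A", "A"), "Ile > Phe"),
            VariantRecord(13, "toygene", ("T", "A", "A"), "Ile > Phe"),
        ]
        cfg = GeneratorConfig(genome_length=400, gene_count=1)
        with pytest.raises(InfeasibleConstraintError):
            layout_genes(rows, cfg)

    def test_primer_footprints_recorded_and_variant_free(
            self, layout, variant_table):
        positions = {v.position for v in variant_table}
        for assay in ("cox2", "cox3"):
            plan = next(p for p in layout.plans if p.assay == assay)
            for fp in (plan.fwd_footprint, plan.rev_footprint):
                assert fp is not None
                assert not any(fp[0] <= p <= fp[1] for p in positions)


class TestReferences:
    def test_lengths(self, genomes, config):
        assert [len(g) for g in genomes] == [config.genome_length] * 3
        assert config.genome_length == 34727

    def test_planted_alleles_at_14516(self, by_form):
        assert by_form["fluitans_III"].seq[14515] == "G"
        assert by_form["natans_I"].seq[14515] == "A"
        assert by_form["natans_VIII"].seq[14515] == "G"

    def test_self_comparison_is_empty(self, by_form):
        from sargmito import count_differences
        g = by_form["fluitans_III"]
        assert count_differences(g, g) == 0

    def test_scan_round_trip_reproduces_panel(self, genomes, by_form,
                                              variant_table):
        sites = scan_variants(genomes)
        assert len(sites) == len(variant_table)
        for site, rec in zip(sites, variant_table):
            assert site.position == rec.position
            observed = tuple(site.alleles[by_form[f].id] for f in FORMS)
            assert observed == rec.alleles

    def test_same_seed_is_byte_identical(self, layout, variant_table, config):
        a, _ = build_references(layout, variant_table, config)
        b, _ = build_references(layout, variant_table, config)
        assert [g.seq for g in a] == [g.seq for g in b]

    def test_at_fraction_within_band(self, genomes, config):
        from sargmito import at_content
        for g in genomes:
            assert abs(at_content(g) - config.at_fraction) <= 0.01

    def test_no_internal_stop_codons_in_any_form(self, genomes, annotation):
        for f in annotation:
            if f.kind != "CDS":
                continue
            for g in genomes:
                seg = g.seq[f.start - 1:f.end]
                coding = seg if f.strand == "+" else revcomp(seg)
                codons = [coding[i:i + 3] for i in range(0, len(coding), 3)]
                assert not any(c in STOP_CODONS for c in codons[:-1]), \
                    f"internal stop in {f.locus} ({g.form})"

    def test_nonvariant_columns_identical(self, genomes, variant_table):
        arrs = [np.frombuffer(g.seq.encode(), dtype=np.uint8) for g in genomes]
        diff = (arrs[0] != arrs[1]) | (arrs[0] != arrs[2])
        positions = set(np.flatnonzero(diff) + 1)
        assert positions == {v.position for v in variant_table}

    def test_undersized_genome_rejected(self, variant_table, primer_panel):
        cfg = GeneratorConfig(genome_length=30000)
        with pytest.raises(ValidationError):
            layout_genes(variant_table, cfg, primer_panel)


class TestCohort:
    def test_noiseless_default_cohort(self, cohort, genomes, primer_panel,
                                      by_form):
        from sargmito import insilico_pcr
        assert len(cohort) == 71
        products = {
            (pair.name, form): insilico_pcr(by_form[form], pair).seq
            for pair in primer_panel for form in by_form
        }
        for sp in cohort:
            for assay, seq in sp.amplicons.items():
                assert seq == products[(assay, sp.true_form)]

    def test_composition(self, cohort):
        from collections import Counter
        counts = Counter(sp.true_form for sp in cohort)
        assert counts == {"natans_VIII": 53, "natans_I": 13, "fluitans_III": 5}

    def test_same_seed_reproducible(self, genomes, primer_panel):
        cfg = GeneratorConfig(seed=11, noise_rate=0.02)
        a = generate_cohort(genomes, primer_panel, cfg)
        b = generate_cohort(genomes, primer_panel, cfg)
        assert [sp.amplicons for sp in a] == [sp.amplicons for sp in b]

    def test_half_noise_rejected(self, genomes, primer_panel):
        cfg = GeneratorConfig(noise_rate=0.5)
        with pytest.raises(ValidationError):
            generate_cohort(genomes, primer_panel, cfg)

    def test_negative_cohort_size_rejected(self, genomes, primer_panel):
        cfg = GeneratorConfig(cohort_sizes={"natans_I": -1})
        with pytest.raises(ValidationError):
            generate_cohort(genomes, primer_panel, cfg)


class TestMarkerPanel:
    @staticmethod
    def diffs(panel, marker, a, b):
        sa, sb = panel[marker][a], panel[marker][b]
        return sum(x != y for x, y in zip(sa, sb))

    def test_negative_and_positive_marker_results(self, config):
        panel = generate_marker_panel(config)
        for marker in ("18S", "5.8S"):
            for a, b in (("fluitans_III", "natans_I"),
                         ("fluitans_III", "natans_VIII"),
                         ("natans_I", "natans_VIII")):
                assert self.diffs(panel, marker, a, b) == 0
        assert self.diffs(panel, "ITS-2", "natans_VIII", "natans_I") == 1
        assert self.diffs(panel, "ITS-2", "natans_VIII", "fluitans_III") == 1
        assert self.diffs(panel, "ITS-2", "natans_I", "fluitans_III") == 0
        assert self.diffs(panel, "rbcL", "fluitans_III", "natans_I") == 3
        assert self.diffs(panel, "rbcL", "fluitans_III", "natans_VIII") == 3
        assert self.diffs(panel, "rbcL", "natans_I", "natans_VIII") == 0
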