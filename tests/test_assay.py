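"""In-silico PCR and fixed-site typing."""

import numpy as np
import pytest

from sargmito import (FORMS, GeneratorConfig, Genome, find_primer_sites,
                      generate_cohort, insilico_pcr, type_cohort,
                      type_specimen)
from sargmito.errors import AmplificationError, ValidationError
from sargmito.genetics import revcomp


def brute_force_sites(seq, primer, max_mismatch=2, clamp=3):
    """Sliding-window oracle over both strands."""
    hits = []
    k = len(primer)
    for strand, pattern in (("+", primer), ("-", revcomp(primer))):
        for i in range(len(seq) - k + 1):
            window = seq[i:i + k]
            mism = sum(a != b for a, b in zip(window, pattern))
            sl = slice(k - clamp, k) if strand == "+" else slice(0, clamp)
            if mism <= max_mismatch and window[sl] == pattern[sl]:
                hits.append((strand, i + 1, i + k, mism))
    return sorted(hits, key=lambda h: (h[1], h[0]))


class TestFindPrimerSites:
    def test_embedded_footprints_found_exactly_once(self, genomes,
                                                    primer_panel):
        for g in genomes:
            for pair in primer_panel:
                fwd = find_primer_sites(g, pair.fwd_seq)
                rev = find_primer_sites(g, pair.rev_seq)
                assert len(fwd) == 1 and fwd[0].strand == "+"
                assert fwd[0].mismatches == 0
                assert len(rev) == 1 and rev[0].strand == "-"
                assert rev[0].mismatches == 0

    def test_no_site_above_mismatch_budget(self):
        g = Genome("g", "query", "A" * 200)
        assert find_primer_sites(g, "CCCCCCCCCCCCCCCC", max_mismatch=2) == []

    def test_agrees_with_sliding_window_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=400))
            primer = "".join(rng.choice(list("ACGT"), size=18))
            # embed a forward and a reverse-complement copy
            seq = seq[:50] + primer + seq[50:300] + revcomp(primer) + seq[300:]
            g = Genome("g", "query", seq)
            got = [(s.strand, s.start, s.end, s.mismatches)
                   for s in find_primer_sites(g, primer)]
            assert got == brute_force_sites(seq, primer)

    def test_short_primer_rejected(self, genomes):
        with pytest.raises(ValidationError):
            find_primer_sites(genomes[0], "ACGTACGT")


class TestInsilicoPcr:
    def test_cox3_product_contains_diagnostic_sites(self, by_form,
                                                    primer_panel):
        cox3 = next(p for p in primer_panel if p.name == "cox3")
        amp = insilico_pcr(by_form["natans_I"], cox3)
        assert amp.start <= 14466 <= amp.end
        assert amp.start <= 14516 <= amp.end
        lo, hi = amp.inner_interval
        assert lo <= 14466 <= hi and lo <= 14516 <= hi

    def test_product_is_primer_inclusive(self, by_form, primer_panel):
        cox2 = next(p for p in primer_panel if p.name == "cox2")
        amp = insilico_pcr(by_form["fluitans_III"], cox2)
        assert amp.seq.startswith(cox2.fwd_seq)
        assert amp.seq.endswith(revcomp(cox2.rev_seq))
        assert len(amp) == amp.end - amp.start + 1 == len(amp.seq)

    def test_missing_reverse_site_is_no_amplification(self, primer_panel):
        cox2 = next(p for p in primer_panel if p.name == "cox2")
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        seq = seq[:100] + cox2.fwd_seq + seq[100:]
        with pytest.raises(AmplificationError) as err:
            insilico_pcr(Genome("g", "query", seq), cox2)
        assert err.value.n_products == 0

    def test_duplicated_forward_site_is_multiple_products(self, primer_panel):
        cox2 = next(p for p in primer_panel if p.name == "cox2")
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=900))
        seq = (seq[:50] + cox2.fwd_seq + seq[50:200] + cox2.fwd_seq +
               seq[200:700] + revcomp(cox2.rev_seq) + seq[700:])
        with pytest.raises(AmplificationError) as err:
            insilico_pcr(Genome("g", "query", seq), cox2)
        assert err.value.n_products == 2


class TestDiagnosticProfiles:
    def test_cox3_separates_natans_i(self, profiles):
        sites = dict(profiles["cox3"].sites)
        assert 14516 in sites
        assert sites[14516] == {"fluitans_III": "G", "natans_I": "A",
                                "natans_VIII": "G"}

    def test_cox2_sites_separate_fluitans_only(self, profiles):
        sites = profiles["cox2"].sites
        assert len(sites) >= 3
        for _, alleles in sites:
            assert alleles["natans_I"] == alleles["natans_VIII"]
            assert alleles["fluitans_III"] != alleles["natans_I"]

    def test_profiles_jointly_separate_all_three_forms(self, profiles):
        vectors = {}
        for form in FORMS:
            vec = tuple(
                alleles[form]
                for prof in profiles.values() for _, alleles in prof.sites)
            vectors[form] = vec
        assert len(set(vectors.values())) == 3

    def test_sites_exclude_primer_footprints(self, profiles):
        for prof in profiles.values():
            for pos, _ in prof.sites:
                assert not prof.fwd_footprint[0] <= pos <= prof.fwd_footprint[1]
                assert not prof.rev_footprint[0] <= pos <= prof.rev_footprint[1]


class TestTypeSpecimen:
    @staticmethod
    def amplicon_with(profiles, assay, form, overrides):
        prof = profiles[assay]
        seq = list(prof.products[form])
        for pos, base in overrides.items():
            seq[pos - prof.interval[0]] = base
        return "".join(seq)

    def test_natans_viii_haplotype(self, profiles):
        amplicons = {
            "cox2": self.amplicon_with(profiles, "cox2", "natans_VIII", {}),
            "cox3": self.amplicon_with(profiles, "cox3", "natans_VIII",
                                       {14466: "G", 14516: "G"}),
        }
        call = type_specimen(amplicons, profiles)
        assert call.call == "natans_VIII"
        assert call.n_conflicting == 0
        assert call.n_supporting >= 1

    def test_fluitans_haplotype_from_cox3(self, profiles):
        amplicons = {
            "cox3": self.amplicon_with(profiles, "cox3", "fluitans_III",
                                       {14466: "A", 14516: "G"}),
        }
        assert type_specimen(amplicons, profiles).call == "fluitans_III"

    def test_novel_haplotype_is_unknown(self, profiles):
        # cox3 alleles matching no reference form at all
        amplicons = {
            "cox3": self.amplicon_with(profiles, "cox3", "natans_I",
                                       {14466: "C", 14516: "C"}),
        }
        assert type_specimen(amplicons, profiles).call == "unknown"

    def test_disagreeing_assays_conflict(self, profiles):
        amplicons = {
            "cox2": self.amplicon_with(profiles, "cox2", "fluitans_III", {}),
            "cox3": self.amplicon_with(profiles, "cox3", "natans_I", {}),
        }
        assert type_specimen(amplicons, profiles).call == "conflict"

    def test_n_sites_are_ignored(self, profiles):
        prof = profiles["cox3"]
        seq = self.amplicon_with(profiles, "cox3", "natans_VIII",
                                 {14466: "N"})
        call = type_specimen({"cox3": seq}, profiles)
        # with 14466 unreadable only 14516=G remains: fluitans and VIII match
        assert call.call == "unknown"

    def test_truncated_amplicon_rejected(self, profiles):
        with pytest.raises(ValidationError):
            type_specimen({"cox3": "ACGTACGTACGT"}, profiles)

    def test_no_amplicons_rejected(self, profiles):
        with pytest.raises(ValidationError):
            type_specimen({}, profiles)


class TestTypeCohort:
    def test_noiseless_cohort_composition(self, cohort, profiles):
        report = type_cohort(cohort, profiles)
        assert report.summary == {
            "fluitans_III": 5, "natans_I": 13, "natans_VIII": 53,
            "unknown": 0, "conflict": 0}
        assert report.label_mismatches == []

    def test_relabeled_specimen_is_listed_not_recalled(self, cohort,
                                                       profiles):
        from sargmito.simulate import Specimen, SyntheticCohort
        specimens = list(cohort)
        target = specimens[0]
        specimens[0] = Specimen(target.specimen_id, "natans_I",
                                target.amplicons)  # wrong morphology label
        report = type_cohort(SyntheticCohort(specimens, cohort.seed), profiles)
        calls = {c.specimen_id: c.call for c in report.calls}
        assert calls[target.specimen_id] == target.true_form
        assert any(m["specimen"] == target.specimen_id
                   for m in report.label_mismatches)

    def test_order_permutation_permutes_but_preserves_calls(self, cohort,
                                                            profiles):
        from sargmito.simulate import SyntheticCohort
        report = type_cohort(cohort, profiles)
        reversed_cohort = SyntheticCohort(list(cohort)[::-1], cohort.seed)
        report_rev = type_cohort(reversed_cohort, profiles)
        assert {c.specimen_id: c.call for c in report.calls} == \
               {c.specimen_id: c.call for c in report_rev.calls}

    def test_empty_cohort_rejected(self, profiles):
        from sargmito.simulate import SyntheticCohort
        with pytest.raises(ValidationError):
            type_cohort(SyntheticCohort([], 0), profiles)

    def test_noisy_confident_calls_fully_supported(self, genomes,
                                                   primer_panel, profiles):
        # under substitution noise a confident call must still be backed by
        # every observed diagnostic allele (zero conflicting sites); calls
        # that cannot be backed degrade to unknown or conflict
        for seed in range(3):
            cfg = GeneratorConfig(seed=seed, noise_rate=0.01)
            noisy = generate_cohort(genomes, primer_panel, cfg)
            report = type_cohort(noisy, profiles)
            for call in report.calls:
                if call.call in FORMS:
                    assert call.n_conflicting == 0
                    for ev in call.evidence:
                        if ev["observed"] != "N":
                            assert ev["expected"][call.call] == ev["observed"]
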