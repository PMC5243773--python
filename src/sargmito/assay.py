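"""In-silico PCR and fixed-site typing of specimens.

Primer matching is ungapped with a mismatch budget (default 2) and an exact
3-base 3' clamp, a standard in-silico PCR convention. Products are reported
primer-inclusive; diagnostic evidence is read only from the region strictly
between the two primer footprints, so footprint bases never contribute.
A confident call requires *zero* conflicting sites — the premise of the
assay is that the diagnostic sites are fixed within forms, so majority
voting is deliberately rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import AmplificationError, ValidationError
from .genetics import revcomp
from .model import FORMS, Genome, PrimerPair, VariantRecord


@dataclass(frozen=True)
class PrimerSite:
    """An ungapped primer binding site (1-based inclusive footprint)."""

    genome_id: str
    strand: str
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product, primer-inclusive."""

    genome_id: str
    start: int
    end: int
    seq: str
    fwd_site: PrimerSite
    rev_site: PrimerSite

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def inner_interval(self) -> tuple[int, int]:
        """Genomic interval strictly between the two primer footprints."""
        return self.fwd_site.end + 1, self.rev_site.start - 1


@dataclass(frozen=True)
class DiagnosticProfile:
    """Per-assay diagnostic sites with each form's expected allele."""

    assay: str
    interval: tuple[int, int]       # product interval on the references
    sites: tuple[tuple[int, dict], ...]  # (position, {form: allele})
    products: dict                  # form -> reference product sequence
    fwd_footprint: tuple[int, int] = (0, 0)
    rev_footprint: tuple[int, int] = (0, 0)

    def expected(self, form: str) -> dict[int, str]:
        return {pos: alleles[form] for pos, alleles in self.sites}

    @property
    def primer_span(self) -> int:
        """Total bases covered by the two primer footprints."""
        return (self.fwd_footprint[1] - self.fwd_footprint[0] + 1) + \
               (self.rev_footprint[1] - self.rev_footprint[0] + 1)


@dataclass(frozen=True)
class TypingCall:
    specimen_id: str
    call: str        # a form name, 'unknown' or 'conflict'
    evidence: tuple  # per-site dicts: assay, position, observed, expected
    n_supporting: int
    n_conflicting: int


@dataclass
class TypingReport:
    calls: list[TypingCall]
    summary: dict = field(default_factory=dict)
    label_mismatches: list = field(default_factory=list)


def _as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def find_primer_sites(genome: Genome, primer_seq: str, max_mismatch: int = 2,
                      clamp: int = 3) -> list[PrimerSite]:
    """All ungapped binding sites of an oligo on either strand.

    A site needs at most ``max_mismatch`` mismatches overall and none in the
    ``clamp`` bases at the primer's 3' end; N never matches. Sites come back
    ordered by footprint start, plus strand before minus on ties.
    """
    if len(primer_seq) < 15:
        raise ValidationError(f"primer shorter than 15 nt: {primer_seq!r}")
    arr = _as_array(genome.seq)
    k = len(primer_seq)
    if k > len(arr):
        return []
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    sites = []
    for strand, pattern in (("+", primer_seq), ("-", revcomp(primer_seq))):
        mism = (windows != _as_array(pattern)).sum(axis=1)
        # 3' end of the primer: last bases on plus, first on minus
        clamp_slice = slice(k - clamp, k) if strand == "+" else slice(0, clamp)
        clamp_ok = (windows[:, clamp_slice] ==
                    _as_array(pattern)[clamp_slice]).all(axis=1)
        for i in np.flatnonzero((mism <= max_mismatch) & clamp_ok):
            sites.append(PrimerSite(genome.id, strand, int(i) + 1,
                                    int(i) + k, int(mism[i])))
    return sorted(sites, key=lambda s: (s.start, s.strand))


def insilico_pcr(genome: Genome, pair: PrimerPair, max_mismatch: int = 2,
                 max_product: int = 2000) -> Amplicon:
    """Predict the unique product of a primer pair on one genome.

    A product is a plus-strand forward site with a downstream minus-strand
    reverse site within ``max_product``. Zero or multiple products raise
    :class:`AmplificationError`.
    """
    fwd = [s for s in find_primer_sites(genome, pair.fwd_seq, max_mismatch)
           if s.strand == "+"]
    rev = [s for s in find_primer_sites(genome, pair.rev_seq, max_mismatch)
           if s.strand == "-"]
    products = [
        (f, r) for f in fwd for r in rev
        if f.end < r.start and r.end - f.start + 1 <= max_product
    ]
    if not products:
        raise AmplificationError(
            f"{pair.name}: no amplification on {genome.id}", n_products=0)
    if len(products) > 1:
        raise AmplificationError(
            f"{pair.name}: {len(products)} products on {genome.id}",
            n_products=len(products))
    f, r = products[0]
    return Amplicon(genome.id, f.start, r.end,
                    genome.seq[f.start - 1:r.end], f, r)


def derive_diagnostic_profile(references: Sequence[Genome],
                              pairs: Sequence[PrimerPair],
                              variants: Sequence[VariantRecord],
                              max_mismatch: int = 2) -> dict[str, DiagnosticProfile]:
    """Diagnostic sites per assay: variant positions strictly between the
    primer footprints, with each form's allele."""
    by_form = {g.form: g for g in references}
    if set(FORMS) - set(by_form):
        raise ValidationError("profiles need all three reference forms")
    profiles = {}
    for pair in pairs:
        amps = {form: insilico_pcr(by_form[form], pair, max_mismatch)
                for form in FORMS}
        lengths = {len(a) for a in amps.values()}
        if len(lengths) != 1:
            raise ValidationError(
                f"{pair.name}: product lengths differ across forms "
                f"({sorted(lengths)}); cannot align allele coordinates")
        ref = amps[FORMS[0]]
        lo, hi = ref.inner_interval
        sites = tuple(
            (v.position, {form: v.allele_of(form) for form in FORMS})
            for v in variants if lo <= v.position <= hi
        )
        profiles[pair.name] = DiagnosticProfile(
            assay=pair.name, interval=(ref.start, ref.end), sites=sites,
            products={form: a.seq for form, a in amps.items()},
            fwd_footprint=(ref.fwd_site.start, ref.fwd_site.end),
            rev_footprint=(ref.rev_site.start, ref.rev_site.end))
    return profiles


def _anchor_offset(amplicon: str, reference: str) -> int | None:
    """Best ungapped offset of ``amplicon`` within ``reference``.

    Equal lengths anchor at 0; shorter amplicons slide to the offset with
    the fewest mismatches (lowest offset on ties); longer ones do not anchor.
    """
    if len(amplicon) == len(reference):
        return 0
    if len(amplicon) > len(reference):
        return None
    a = _as_array(amplicon)
    r = _as_array(reference)
    windows = np.lib.stride_tricks.sliding_window_view(r, len(a))
    mism = (windows != a).sum(axis=1)
    return int(np.argmin(mism))


def type_specimen(amplicons: Mapping[str, str],
                  profiles: Mapping[str, DiagnosticProfile],
                  specimen_id: str = "specimen") -> TypingCall:
    """Assign a specimen to a form from its amplicon sequences.

    Observed alleles are read at each profile position after anchoring the
    amplicon to the reference product. The call is the unique form matching
    every observed non-N allele across all assays; no such form gives
    'unknown', and assays that individually match but disagree give
    'conflict'.
    """
    if not amplicons:
        raise ValidationError("at least one amplicon is required")
    evidence = []
    per_assay_matches: list[set[str]] = []
    for assay, seq in sorted(amplicons.items()):
        seq = seq.upper()
        if assay not in profiles:
            raise ValidationError(f"no diagnostic profile for assay {assay!r}")
        prof = profiles[assay]
        if len(seq) < prof.primer_span:
            raise ValidationError(
                f"{assay}: amplicon of {len(seq)} nt is shorter than the "
                f"combined primer footprints ({prof.primer_span} nt)")
        offset = _anchor_offset(seq, prof.products[FORMS[0]])
        if offset is None:
            raise ValidationError(
                f"{assay}: amplicon longer than the reference product")
        matches = set(FORMS)
        for pos, alleles in prof.sites:
            idx = pos - prof.interval[0] - offset
            obs = seq[idx] if 0 <= idx < len(seq) else "N"
            evidence.append({"assay": assay, "position": pos,
                            "observed": obs, "expected": dict(alleles)})
            if obs == "N":
                continue
            matches &= {f for f in FORMS if alleles[f] == obs}
        per_assay_matches.append(matches)

    joint = set(FORMS)
    for m in per_assay_matches:
        joint &= m
    if len(joint) == 1:
        call = joint.pop()
    elif joint:
        # amplicons consistent with several forms: not enough evidence
        call = "unknown"
    elif all(m for m in per_assay_matches):
        call = "conflict"
    else:
        call = "unknown"

    n_support = n_conflict = 0
    if call in FORMS:
        for ev in evidence:
            if ev["observed"] == "N":
                continue
            if ev["expected"][call] == ev["observed"]:
                n_support += 1
            else:
                n_conflict += 1
    return TypingCall(specimen_id, call, tuple(evidence), n_support, n_conflict)


def type_cohort(cohort, profiles: Mapping[str, DiagnosticProfile]) -> TypingReport:
    """Type every specimen of a cohort and tally calls and label mismatches."""
    specimens = list(cohort)
    if not specimens:
        raise ValidationError("empty cohort")
    calls = []
    summary: dict[str, int] = {form: 0 for form in FORMS}
    summary.update({"unknown": 0, "conflict": 0})
    mismatches = []
    for sp in specimens:
        call = type_specimen(sp.amplicons, profiles, specimen_id=sp.specimen_id)
        calls.append(call)
        summary[call.call] = summary.get(call.call, 0) + 1
        if call.call in FORMS and call.call != sp.true_form:
            mismatches.append(
                {"specimen": sp.specimen_id, "label": sp.true_form,
                 "molecular": call.call})
    return TypingReport(calls=calls, summary=summary,
                        label_mismatches=mismatches)
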