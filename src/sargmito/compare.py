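"""Columnwise comparison of collinear genomes.

The genomes under study are equal-length and collinear, so no aligner is
involved: unequal lengths are a :class:`CollinearityError`, never silently
aligned. N is treated as missing data and never counts as a difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import CollinearityError, ValidationError
from .model import FORMS, GeneFeature, Genome, VariantRecord

_N = ord("N")


@dataclass(frozen=True)
class SiteVariant:
    """One polymorphic alignment column: position plus per-genome alleles."""

    position: int
    alleles: dict  # genome id -> base (may include 'N')
    locus: str | None = None


@dataclass(frozen=True)
class DifferenceMatrix:
    """Pairwise difference counts over an alignment of collinear genomes."""

    taxa: tuple[str, ...]
    counts: np.ndarray          # symmetric integer matrix
    compared: np.ndarray        # per-pair non-N columns
    length: int                 # alignment length

    def count(self, a: str, b: str) -> int:
        return int(self.counts[self.taxa.index(a), self.taxa.index(b)])

    @property
    def p_distances(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(self.compared > 0, self.counts / self.compared, 0.0)
        return p


@dataclass(frozen=True)
class SyntenyReport:
    shared_genes: int
    breakpoints: int
    order_identical: bool


def _arrays(genomes: Sequence[Genome]) -> np.ndarray:
    lengths = {len(g) for g in genomes}
    if len(lengths) != 1:
        raise CollinearityError(
            f"genomes have unequal lengths {sorted(lengths)}; inputs must be "
            "collinear")
    return np.vstack([np.frombuffer(g.seq.encode(), dtype=np.uint8)
                      for g in genomes])


def count_differences(a: Genome, b: Genome) -> int:
    """Number of columns at which two collinear genomes carry distinct
    non-N nucleotides."""
    arr = _arrays([a, b])
    valid = (arr[0] != _N) & (arr[1] != _N)
    return int(((arr[0] != arr[1]) & valid).sum())


def difference_matrix(genomes: Sequence[Genome]) -> DifferenceMatrix:
    arr = _arrays(genomes)
    n = len(genomes)
    counts = np.zeros((n, n), dtype=int)
    compared = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            valid = (arr[i] != _N) & (arr[j] != _N)
            d = int(((arr[i] != arr[j]) & valid).sum())
            counts[i, j] = counts[j, i] = d
            compared[i, j] = compared[j, i] = int(valid.sum())
        compared[i, i] = arr.shape[1]
    return DifferenceMatrix(tuple(g.id for g in genomes), counts, compared,
                            arr.shape[1])


def scan_variants(genomes: Sequence[Genome],
                  annotation: Sequence[GeneFeature] | None = None) -> list[SiteVariant]:
    """All columns at which at least two genomes carry distinct non-N bases.

    Alleles are reported on the plus strand, positions ascending. With an
    annotation, each variant is labelled with its containing locus.
    """
    if len(genomes) < 2:
        raise ValidationError("variant scanning needs at least two genomes")
    arr = _arrays(genomes)
    valid = arr != _N
    # a column is variant if its non-N residues are not all equal
    lo = np.where(valid, arr, 255).min(axis=0)
    hi = np.where(valid, arr, 0).max(axis=0)
    poly = (valid.sum(axis=0) >= 2) & (lo != hi)
    out = []
    for col in np.flatnonzero(poly):
        alleles = {g.id: chr(arr[i, col]) for i, g in enumerate(genomes)}
        locus = None
        if annotation is not None:
            from .effects import locate

            feature = locate(int(col) + 1, annotation)
            locus = feature.locus if feature is not None else "intergenic"
        out.append(SiteVariant(int(col) + 1, alleles, locus))
    return out


def at_content(genome: Genome) -> float:
    """(A+T) / (A+C+G+T); N excluded from the denominator."""
    arr = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    acgt = int((arr != _N).sum())
    if acgt == 0:
        raise ValidationError(f"genome {genome.id!r} contains only N")
    at = int(((arr == ord("A")) | (arr == ord("T"))).sum())
    return at / acgt


def locus_summary(variants: Sequence[VariantRecord],
                  annotation: Sequence[GeneFeature],
                  pair: tuple[str, str],
                  all_loci: bool = False) -> dict[str, int]:
    """Differences between two forms, broken down by locus.

    Only sites at which the two named forms actually differ are counted;
    with ``all_loci`` every annotated locus appears, zeros included.
    Sites outside any feature are pooled under 'intergenic'.
    """
    from .effects import locate

    for form in pair:
        if form not in FORMS:
            raise ValidationError(f"unknown form {form!r}")
    counts: dict[str, int] = {}
    if all_loci:
        counts = {f.locus: 0 for f in annotation}
        counts["intergenic"] = 0
    for v in variants:
        if not v.differs(*pair):
            continue
        feature = locate(v.position, annotation)
        locus = feature.locus if feature is not None else "intergenic"
        counts[locus] = counts.get(locus, 0) + 1
    return counts


def compare_synteny(annot_a: Sequence[GeneFeature],
                    annot_b: Sequence[GeneFeature]) -> SyntenyReport:
    """Gene content and order comparison of two annotations.

    Breakpoints are orientation-aware adjacencies of A (restricted to shared
    genes) that are absent from B, counting a reversed pair with flipped
    strands as the same adjacency.
    """
    if not annot_a or not annot_b:
        raise ValidationError("annotations must be non-empty")
    names_a = {f.locus for f in annot_a}
    names_b = {f.locus for f in annot_b}
    shared = names_a & names_b
    if not shared:
        return SyntenyReport(0, 0, False)

    def order(annot):
        return [(f.locus, f.strand)
                for f in sorted(annot, key=lambda f: f.start)
                if f.locus in shared]

    def adjacencies(seq):
        out = set()
        for (g1, s1), (g2, s2) in zip(seq, seq[1:]):
            flip = {"+": "-", "-": "+"}
            out.add(((g1, s1), (g2, s2)))
            out.add(((g2, flip[s2]), (g1, flip[s1])))
        return out

    seq_a, seq_b = order(annot_a), order(annot_b)
    adj_b = adjacencies(seq_b)
    breakpoints = sum(
        ((g1, s1), (g2, s2)) not in adj_b
        for (g1, s1), (g2, s2) in zip(seq_a, seq_a[1:])
    )
    return SyntenyReport(len(shared), breakpoints, seq_a == seq_b)


@dataclass(frozen=True)
class FixedSiteReport:
    per_site: dict    # (position, form) -> {'alleles': set, 'fixed': bool}
    passed: bool
    mismatches: tuple  # specimens whose alleles match a different form


def verify_fixed_sites(observed: Mapping[str, Mapping[str, Mapping[int, str]]],
                       expected: Mapping[int, Mapping[str, str]]) -> FixedSiteReport:
    """Check that diagnostic sites are fixed within forms.

    ``observed`` maps form -> specimen -> position -> allele (as read from
    the cohort's amplicons); ``expected`` maps position -> form -> reference
    allele. A site is fixed within a form when a single non-N allele is
    seen. The report passes when every site is fixed and matches the
    reference panel; specimens whose full allele vector matches a different
    form than their label are listed as label/molecular mismatches.
    """
    per_site = {}
    passed = True
    for form, specimens in observed.items():
        if not specimens:
            raise ValidationError(f"form {form!r} has no specimens")
    for pos, by_form in expected.items():
        for form in by_form:
            specimens = observed.get(form, {})
            if not specimens:
                raise ValidationError(f"no specimens observed for {form!r}")
            alleles = {al.get(pos, "N") for al in specimens.values()} - {"N"}
            fixed = len(alleles) == 1
            matches_ref = fixed and next(iter(alleles)) == by_form[form]
            per_site[(pos, form)] = {"alleles": alleles, "fixed": fixed,
                                     "matches_reference": matches_ref}
            passed = passed and matches_ref
    mismatches = []
    for form, specimens in observed.items():
        for spec_id, alleles in specimens.items():
            profile = {p: alleles.get(p, "N") for p in expected}
            candidates = [
                f for f in FORMS
                if all(obs == "N" or expected[p].get(f) == obs
                       for p, obs in profile.items())
            ]
            if len(candidates) == 1 and candidates[0] != form:
                mismatches.append((spec_id, form, candidates[0]))
    return FixedSiteReport(per_site, passed, tuple(mismatches))
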