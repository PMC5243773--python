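"""Codon-level effect annotation of variant sites.

For a coding site the codon containing it is read off each form's genome on
the coding strand and translated; the per-form amino acids are reported as
a chain in fixed form order (fluitans III, natans I, natans VIII), with one
entry per run of equal nucleotide alleles — so a synonymous change still
prints two entries ("Ala > Ala") while a site where the outer forms agree
prints three ("Gly > Asp > Gly"). Non-coding sites report "–".

This annotator is deliberately independent of the synthetic-data
generator's internals: the two meet only at the contract that re-annotation
reproduces the reference panel's amino-acid column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import AmbiguityError, AnnotationError, ValidationError
from .genetics import merge_chain, revcomp, translate_codon
from .model import FORMS, GeneFeature, Genome, VariantRecord

#: chain placeholder for non-coding sites (en dash, as printed)
NO_CHAIN = "–"


@dataclass(frozen=True)
class EffectAnnotation:
    variant: VariantRecord
    feature: GeneFeature | None
    codon_index: int | None
    codon_offset: int | None
    aa_chain: str
    per_form_aa: tuple[str, str, str] | None
    effect_class: str  # synonymous | nonsynonymous | nonsense | rRNA | tRNA | intergenic


def locate(position: int, annotation: Sequence[GeneFeature]) -> GeneFeature | None:
    """The unique feature containing a position, or None for non-genic.

    Overlapping features covering the position raise :class:`AmbiguityError`.
    """
    if position < 1:
        raise ValidationError(f"position {position} is not 1-based")
    hits = [f for f in annotation if f.contains(position)]
    if len(hits) > 1:
        raise AmbiguityError(
            f"position {position} lies in {len(hits)} overlapping features: "
            f"{[f.locus for f in hits]}")
    return hits[0] if hits else None


def _codon_coords(position: int, feature: GeneFeature) -> tuple[int, int, tuple[int, int]]:
    """(codon_index, codon_offset, genomic span) of the codon containing a
    position, on the feature's coding strand."""
    if feature.strand == "+":
        q = position - feature.start          # 0-based coding position
    else:
        q = feature.end - position
    codon_index, offset = divmod(q, 3)
    if feature.strand == "+":
        span = (feature.start + 3 * codon_index,
                feature.start + 3 * codon_index + 2)
    else:
        span = (feature.end - 3 * codon_index - 2,
                feature.end - 3 * codon_index)
    return codon_index, offset, span


def annotate_effect(variant: VariantRecord, genomes: Sequence[Genome],
                    annotation: Sequence[GeneFeature],
                    table: int = 1) -> EffectAnnotation:
    """Annotate one variant with codon context, amino-acid chain and class."""
    by_form = {g.form: g for g in genomes}
    missing = set(FORMS) - set(by_form)
    if missing:
        raise ValidationError(f"missing reference forms {sorted(missing)}")
    feature = locate(variant.position, annotation)

    if feature is None or feature.kind != "CDS":
        cls = "intergenic" if feature is None else feature.kind
        return EffectAnnotation(variant, feature, None, None, NO_CHAIN, None, cls)

    codon_index, offset, span = _codon_coords(variant.position, feature)
    if span[0] < feature.start or span[1] > feature.end:
        raise AnnotationError(
            f"position {variant.position}: codon extends past the "
            f"{feature.locus} CDS boundary")
    aas = []
    for form in FORMS:
        g = by_form[form]
        codon = g.seq[span[0] - 1:span[1]]
        if feature.strand == "-":
            codon = revcomp(codon)
        # sanity: the genome must carry this form's allele at the site
        base = g.seq[variant.position - 1]
        expected = variant.allele_of(form)
        if base != expected:
            raise AnnotationError(
                f"position {variant.position}: genome {g.id} carries {base}, "
                f"panel expects {expected} for {form}")
        aas.append(translate_codon(codon, table))
    aas = tuple(aas)
    chain = merge_chain(variant.alleles, aas)
    if len(set(aas)) == 1:
        cls = "synonymous"
    elif "Stop" in aas:
        cls = "nonsense"
    else:
        cls = "nonsynonymous"
    return EffectAnnotation(variant, feature, codon_index, offset, chain,
                            aas, cls)


def annotate_all(variants: Sequence[VariantRecord], genomes: Sequence[Genome],
                 annotation: Sequence[GeneFeature],
                 table: int = 1) -> list[EffectAnnotation]:
    return [annotate_effect(v, genomes, annotation, table) for v in variants]


@dataclass(frozen=True)
class EffectSummary:
    pair: tuple[str, str]
    genes: frozenset          # CDS loci with an amino-acid difference
    gene_sites: dict          # locus -> number of aa-changing sites
    rrna_sites: dict          # rRNA locus -> number of differing sites


def effect_summary(annotations: Sequence[EffectAnnotation],
                   pair: tuple[str, str]) -> EffectSummary:
    """CDS loci at which two forms' amino acids differ, and rRNA loci with
    nucleotide differences, for one pair of forms."""
    for form in pair:
        if form not in FORMS:
            raise ValidationError(f"unknown form {form!r}")
    ia, ib = FORMS.index(pair[0]), FORMS.index(pair[1])
    gene_sites: dict[str, int] = {}
    rrna_sites: dict[str, int] = {}
    for ann in annotations:
        v = ann.variant
        if v.alleles[ia] == v.alleles[ib]:
            continue
        if ann.per_form_aa is not None:
            if ann.per_form_aa[ia] != ann.per_form_aa[ib]:
                locus = ann.feature.locus
                gene_sites[locus] = gene_sites.get(locus, 0) + 1
        elif ann.effect_class == "rRNA":
            locus = ann.feature.locus
            rrna_sites[locus] = rrna_sites.get(locus, 0) + 1
    return EffectSummary(pair, frozenset(gene_sites), gene_sites, rrna_sites)
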