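"""Domain types: genomes, variant records, gene features, primers, config.

Coordinates are 1-based inclusive throughout (GFF3 convention, matching the
reference panel's "Genomic position" column). Any half-open arithmetic is
internal to the functions that need it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ValidationError

#: The three holopelagic forms, in fixed reporting order. Amino-acid chains
#: and allele tuples always follow this order.
FORMS = ("fluitans_III", "natans_I", "natans_VIII")

#: Additional label for sequences of unknown provenance.
QUERY = "query"

_SEQ_RE = re.compile(r"^[ACGTN]+$")

#: Non-genic locus labels used by the reference panel. Both normalize to a
#: single intergenic category; the original label is kept for report fidelity.
NONGENIC_LOCI = ("Intergenic Region", "Intergenic Spacer")
INTERGENIC = "intergenic"


def locus_kind(locus: str) -> str:
    """Classify a reference-panel locus name: CDS, rRNA, tRNA or intergenic."""
    if locus in NONGENIC_LOCI:
        return INTERGENIC
    if locus.endswith("rRNA"):
        return "rRNA"
    if locus.startswith("trn"):
        return "tRNA"
    return "CDS"


@dataclass(frozen=True)
class Genome:
    """A named nucleotide sequence with a form label."""

    id: str
    form: str
    seq: str

    def __post_init__(self):
        if self.form not in FORMS and self.form != QUERY:
            raise ValidationError(f"unknown form label {self.form!r}")
        if not self.seq:
            raise ValidationError(f"genome {self.id!r} has an empty sequence")
        object.__setattr__(self, "seq", self.seq.upper())
        if not _SEQ_RE.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValidationError(
                f"genome {self.id!r} contains non-nucleotide symbols {bad}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class VariantRecord:
    """One row of the reference panel: a site where the forms differ."""

    position: int
    locus: str
    alleles: tuple[str, str, str]  # fluitans III, natans I, natans VIII
    aa_chain: str

    def __post_init__(self):
        if self.position < 1:
            raise ValidationError(f"position {self.position} is not 1-based")
        for a in self.alleles:
            if a not in "ACGT":
                raise ValidationError(
                    f"position {self.position}: allele {a!r} is not A/C/G/T"
                )
        if len(set(self.alleles)) == 1:
            raise ValidationError(
                f"position {self.position}: monomorphic row (all alleles "
                f"{self.alleles[0]})"
            )

    @property
    def allele_fluitans(self) -> str:
        return self.alleles[0]

    @property
    def allele_natansI(self) -> str:
        return self.alleles[1]

    @property
    def allele_natansVIII(self) -> str:
        return self.alleles[2]

    def allele_of(self, form: str) -> str:
        return self.alleles[FORMS.index(form)]

    def differs(self, form_a: str, form_b: str) -> bool:
        return self.allele_of(form_a) != self.allele_of(form_b)

    @property
    def kind(self) -> str:
        return locus_kind(self.locus)


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene on the mitogenome (1-based inclusive interval)."""

    locus: str
    start: int
    end: int
    strand: str
    kind: str  # CDS | rRNA | tRNA

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"feature {self.locus!r}: invalid interval "
                f"[{self.start}, {self.end}]"
            )
        if self.strand not in "+-":
            raise ValidationError(f"feature {self.locus!r}: bad strand {self.strand!r}")
        if self.kind not in ("CDS", "rRNA", "tRNA"):
            raise ValidationError(f"feature {self.locus!r}: unknown kind {self.kind!r}")
        if self.kind == "CDS" and (self.end - self.start + 1) % 3 != 0:
            raise ValidationError(
                f"CDS {self.locus!r} length {self.end - self.start + 1} is "
                "not divisible by 3"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse oligo pair targeting one marker gene."""

    name: str
    fwd_name: str
    fwd_seq: str
    rev_name: str
    rev_seq: str
    gene: str

    def __post_init__(self):
        for label, seq in ((self.fwd_name, self.fwd_seq), (self.rev_name, self.rev_seq)):
            if len(seq) < 15:
                raise ValidationError(f"primer {label}: length {len(seq)} < 15")
            if not set(seq) <= set("ACGT"):
                bad = sorted(set(seq) - set("ACGT"))
                raise ValidationError(f"primer {label}: non-ACGT characters {bad}")


def _default_cohort_sizes() -> dict[str, int]:
    # Field-survey composition of the 71-specimen validation cohort.
    return {"natans_VIII": 53, "natans_I": 13, "fluitans_III": 5}


@dataclass
class GeneratorConfig:
    """Tunable knobs of the synthetic-data generator.

    Defaults mirror the study system: a 34,727 bp mitogenome with 65 genes,
    63.8% AT, and a 71-specimen amplicon cohort (53 natans VIII / 13
    natans I / 5 fluitans III). ``noise_rate`` is the per-base substitution
    probability applied to cohort amplicons (0 emulates clean Sanger reads).
    """

    seed: int = 7
    genome_length: int = 34727
    at_fraction: float = 0.638
    gene_count: int = 65
    noise_rate: float = 0.0
    cohort_sizes: dict[str, int] = field(default_factory=_default_cohort_sizes)
    bootstrap_replicates: int = 1000
    genetic_code: int = 1

    def validate(self, min_length: int = 0) -> "GeneratorConfig":
        if self.genome_length < min_length:
            raise ValidationError(
                f"genome_length {self.genome_length} is smaller than the "
                f"largest variant position {min_length}"
            )
        if not 0.0 <= self.at_fraction <= 1.0:
            raise ValidationError(f"at_fraction {self.at_fraction} outside [0, 1]")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValidationError(
                f"noise_rate {self.noise_rate} outside [0, 0.5)"
            )
        for form, n in self.cohort_sizes.items():
            if form not in FORMS:
                raise ValidationError(f"cohort_sizes: unknown form {form!r}")
            if n < 0:
                raise ValidationError(f"cohort_sizes[{form}] = {n} is negative")
        if self.bootstrap_replicates < 1:
            raise ValidationError("bootstrap_replicates must be >= 1")
        if self.genetic_code not in (1, 4):
            raise ValidationError("genetic_code must be 1 (standard) or 4")
        return self
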