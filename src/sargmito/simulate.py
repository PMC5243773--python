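"""Constraint-based synthetic reference genomes, amplicon cohorts and marker loci.

The generator builds three collinear mitogenomes that realize the packaged
variant table *exactly*: every listed site carries each form's printed
allele, every other position is identical across forms, and every coding
site sits in a codon whose per-form translations reproduce the printed
amino-acid chain. Gene placement is a small constraint-satisfaction
problem solved deterministically; only the unconstrained sequence background
is random (seeded).

The solver works per gene: a single strand and reading frame must satisfy
all of the gene's sites simultaneously. Stop codons are TAA/TAG wherever a
choice exists; TGA is admitted only where the variant table forces it
(nad7's terminal stop, where the Leu>Leu site at 33828 pins the frame so
the Stop>Stop site at 34589 can only be realized as TGA -> TAA).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import InfeasibleConstraintError, SargmitoError, ValidationError
from .genetics import (COMPLEMENT, STOP_CODONS, expand_chain, revcomp,
                       translate_codon)
from .model import (FORMS, GeneFeature, GeneratorConfig, Genome, PrimerPair,
                    VariantRecord, locus_kind)

# ---------------------------------------------------------------------------
# codon-constraint solving

_LEAD = 15    # bp of coding sequence placed before a gene's first listed site
_TAIL = 15    # likewise after the last site, before the stop codon
_RRNA_PAD = 100
_TRNA_SPAN = (30, 41)   # bases before/after the single site of a tRNA
_MAX_INNER_SPAN = 360   # max span of diagnostic sites inside one amplicon


@dataclass(frozen=True)
class CodonSolution:
    """A (strand, offset, codon) triple satisfying one amino-acid chain.

    ``codon`` is the coding-strand codon carrying the first form's
    (strand-adjusted) allele at ``offset``; substituting each form's allele
    reproduces that form's amino acid.
    """

    strand: str
    offset: int
    codon: str


def feasible_codons(alleles: Sequence[str], aas: Sequence[str], strand: str,
                    offset: int, allow_tga: bool = False) -> list[str]:
    """All codons (lexicographic) realizing the per-form amino acids at
    ``offset`` on ``strand``. TGA is excluded unless ``allow_tga``."""
    bases = [a if strand == "+" else COMPLEMENT[a] for a in alleles]
    out = []
    for combo in itertools.product("ACGT", repeat=3):
        if combo[offset] != bases[0]:
            continue
        ok = True
        for b, aa in zip(bases, aas):
            cod = combo[:offset] + (b,) + combo[offset + 1:]
            codon = "".join(cod)
            if codon == "TGA" and not allow_tga:
                ok = False
                break
            if translate_codon(codon) != aa:
                ok = False
                break
        if ok:
            out.append("".join(combo))
    return out


def solve_codon_constraint(record: VariantRecord) -> CodonSolution:
    """First (strand, offset, codon) satisfying a coding variant's chain.

    Search order is deterministic: plus strand before minus, offsets
    ascending, codons lexicographic; TGA-free solutions are exhausted before
    TGA is admitted as a stop.
    """
    if record.kind != "CDS":
        raise ValidationError(
            f"position {record.position}: locus {record.locus!r} is not coding"
        )
    aas = expand_chain(record.alleles, record.aa_chain)
    for allow_tga in (False, True):
        for strand in "+-":
            for offset in range(3):
                sols = feasible_codons(record.alleles, aas, strand, offset,
                                       allow_tga=allow_tga)
                if sols:
                    return CodonSolution(strand, offset, sols[0])
    raise InfeasibleConstraintError(
        f"position {record.position} ({record.locus}): no codon realizes "
        f"chain {record.aa_chain!r} with alleles {record.alleles}"
    )


def _gene_frame(rows: list[VariantRecord]):
    """Single (strand, phase, {position: (offset, codon)}) satisfying every
    site of one gene, or None.

    ``phase`` is start % 3 for plus-strand genes and end % 3 for minus-strand
    genes; either determines each site's codon offset.
    """
    chains = {r.position: expand_chain(r.alleles, r.aa_chain) for r in rows}
    for allow_tga in (False, True):
        for strand in "+-":
            for phase in range(3):
                assignment = {}
                for r in rows:
                    if strand == "+":
                        offset = (r.position - phase) % 3
                    else:
                        offset = (phase - r.position) % 3
                    sols = feasible_codons(r.alleles, chains[r.position],
                                           strand, offset, allow_tga=allow_tga)
                    if not sols:
                        assignment = None
                        break
                    assignment[r.position] = (offset, sols[0])
                if assignment is not None:
                    return strand, phase, assignment
    return None


# ---------------------------------------------------------------------------
# gene layout

@dataclass(frozen=True)
class SiteCodon:
    """A solved codon for one coding variant, located on the genome."""

    position: int
    offset: int          # 0-based offset of the site within the coding codon
    codon_index: int     # 0-based codon number within the CDS
    span: tuple[int, int]  # genomic interval of the codon, 1-based inclusive
    per_form: tuple[str, str, str]  # coding-strand codon per form


@dataclass
class GenePlan:
    feature: GeneFeature
    site_codons: dict[int, SiteCodon] = field(default_factory=dict)
    primer: PrimerPair | None = None
    fwd_footprint: tuple[int, int] | None = None
    rev_footprint: tuple[int, int] | None = None

    @property
    def assay(self) -> str | None:
        return self.primer.name if self.primer else None


class Layout(Sequence):
    """An ordered, non-overlapping gene annotation plus build instructions.

    Iterating yields :class:`GeneFeature`; the per-gene codon plans and
    primer footprints used by :func:`build_references` live in ``plans``.
    """

    def __init__(self, plans: list[GenePlan], genome_length: int):
        self.plans = sorted(plans, key=lambda p: p.feature.start)
        self.genome_length = genome_length
        prev = None
        for p in self.plans:
            f = p.feature
            if f.end > genome_length:
                raise InfeasibleConstraintError(
                    f"feature {f.locus} extends past genome end")
            if prev is not None and f.start <= prev.end:
                raise InfeasibleConstraintError(
                    f"features {prev.locus} and {f.locus} overlap")
            prev = f

    @property
    def features(self) -> list[GeneFeature]:
        return [p.feature for p in self.plans]

    def __getitem__(self, i):
        return self.features[i]

    def __len__(self) -> int:
        return len(self.plans)

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def plan(self, locus: str) -> GenePlan:
        for p in self.plans:
            if p.feature.locus == locus:
                return p
        raise KeyError(locus)


_TRN_FILLERS = [
    "trnA(ugc)", "trnC(gca)", "trnD(guc)", "trnE(uuc)", "trnF(gaa)",
    "trnG(gcc)", "trnG(ucc)", "trnH(gug)", "trnI(gau)", "trnK(uuu)",
    "trnL(uaa)", "trnL(uag)", "trnM(cau)", "trnMf(cau)", "trnN(guu)",
    "trnP(ugg)", "trnR(acg)", "trnR(ucu)", "trnS(gcu)", "trnS(uga)",
    "trnT(ugu)", "trnT(ggu)", "trnV(uac)", "trnY(gua)",
]
_ORF_FILLERS = ["orf25", "orf31", "orf38", "orf42", "orf47", "orf58", "orf64"]


def _align_up(value: int, phase: int) -> int:
    return value + (phase - value) % 3


def _align_down(value: int, phase: int) -> int:
    return value - (value - phase) % 3


def _codon_span(position: int, offset: int, strand: str) -> tuple[int, int]:
    if strand == "+":
        return position - offset, position - offset + 2
    return position - (2 - offset), position + offset


def _per_form_codons(codon: str, offset: int, strand: str,
                     alleles: Sequence[str]) -> tuple[str, str, str]:
    out = []
    for a in alleles:
        b = a if strand == "+" else COMPLEMENT[a]
        out.append(codon[:offset] + b + codon[offset + 1:])
    return tuple(out)


def _frame_stop_free(footprint_seq: str, fp_start: int, phase: int,
                     strand: str, gene_ref: int) -> bool:
    """True if no in-frame codon falls fully inside the footprint and reads
    as a stop on the coding strand."""
    if strand == "+":
        coding = footprint_seq
        first = fp_start
        # genomic positions of codon starts are = phase (mod 3)
        shift = (phase - first) % 3
    else:
        coding = revcomp(footprint_seq)
        first = gene_ref - (fp_start + len(footprint_seq) - 1)  # coding coord
        shift = (-first) % 3
    for i in range(shift, len(coding) - 2, 3):
        if coding[i:i + 3] in STOP_CODONS:
            return False
    return True


def _place_footprint(seq: str, candidates: Iterator[int], length: int,
                     variant_positions: set[int], phase: int,
                     lo: int, hi: int) -> tuple[int, int]:
    """First candidate start where the footprint avoids variants and
    introduces no in-frame stop codon on the plus strand."""
    for start in candidates:
        end = start + length - 1
        if start < lo or end > hi:
            continue
        if any(start <= v <= end for v in variant_positions):
            continue
        if _frame_stop_free(seq, start, phase, "+", 0):
            return start, end
    raise InfeasibleConstraintError("no admissible primer footprint placement")


def layout_genes(variants: Sequence[VariantRecord], config: GeneratorConfig,
                 primers: Sequence[PrimerPair] = ()) -> Layout:
    """Assign strand, frame and a genomic interval to every listed locus,
    plus filler genes up to ``config.gene_count``.

    Deterministic: identical inputs give an identical layout. Raises
    :class:`InfeasibleConstraintError` if a gene's sites admit no common
    strand/frame or the primer constraints cannot be met.
    """
    config.validate(min_length=max(v.position for v in variants))
    positions = sorted(v.position for v in variants)
    primer_by_gene = {p.gene: p for p in primers}

    loci: dict[str, list[VariantRecord]] = {}
    for v in variants:
        if v.kind != "intergenic":
            loci.setdefault(v.locus, []).append(v)
    ordered = sorted(loci, key=lambda g: min(v.position for v in loci[g]))

    plans: list[GenePlan] = []
    prev_end = 0
    for locus in ordered:
        rows = sorted(loci[locus], key=lambda v: v.position)
        kind = rows[0].kind
        own = {v.position for v in rows}
        lo_site, hi_site = rows[0].position, rows[-1].position
        foreign_lt = max((p for p in positions if p < lo_site and p not in own),
                         default=0)
        foreign_gt = min((p for p in positions if p > hi_site and p not in own),
                         default=config.genome_length + 1)
        lo = max(prev_end + 1, foreign_lt + 1, 1)
        hi = min(foreign_gt - 1, config.genome_length)

        if kind == "tRNA":
            before, after = _TRNA_SPAN
            start = max(lo, lo_site - before)
            end = min(hi, hi_site + after)
            plans.append(GenePlan(GeneFeature(locus, start, end, "+", "tRNA")))
        elif kind == "rRNA":
            start = max(lo, lo_site - _RRNA_PAD)
            end = min(hi, hi_site + _RRNA_PAD)
            plans.append(GenePlan(GeneFeature(locus, start, end, "+", "rRNA")))
        else:
            frame = _gene_frame(rows)
            if frame is None:
                raise InfeasibleConstraintError(
                    f"gene {locus}: no single strand/frame satisfies its "
                    f"{len(rows)} amino-acid chains"
                )
            strand, phase, assignment = frame
            plan = _place_cds(locus, rows, strand, phase, assignment, lo, hi,
                              primer_by_gene.get(locus))
            plans.append(plan)
        prev_end = plans[-1].feature.end

    plans.extend(_fillers(plans, positions, config))
    return Layout(plans, config.genome_length)


def _place_cds(locus, rows, strand, phase, assignment, lo, hi, primer):
    lo_site, hi_site = rows[0].position, rows[-1].position
    chains = {r.position: expand_chain(r.alleles, r.aa_chain) for r in rows}
    stop_rows = [r for r in rows if "Stop" in chains[r.position]]

    fwd_fp = rev_fp = None
    if primer is not None:
        if strand != "+":
            raise InfeasibleConstraintError(
                f"gene {locus}: primer placement implemented for plus-strand "
                "genes only")
        sites = [r.position for r in rows]
        window = [sites[0]]
        for p in sites[1:]:
            if p - window[0] <= _MAX_INNER_SPAN:
                window.append(p)
        natans_sites = [r.position for r in rows
                        if r.alleles[1] != r.alleles[2]]
        if any(p not in window for p in natans_sites):
            raise InfeasibleConstraintError(
                f"gene {locus}: natans-discriminating sites do not fit in "
                "one amplicon window")
        next_own = min((p for p in sites if p > window[-1]), default=hi + 1)
        all_var = set(sites)  # foreign variants already outside (lo, hi)
        fwd_fp = _place_footprint(
            primer.fwd_seq,
            range(window[0] - 8 - len(primer.fwd_seq) + 1,
                  window[0] - 60 - len(primer.fwd_seq), -1),
            len(primer.fwd_seq), all_var, phase, lo + 6, window[0] - 1)
        rev_fp = _place_footprint(
            revcomp(primer.rev_seq),
            iter(range(window[-1] + 8, window[-1] + 80)),
            len(primer.rev_seq), all_var, phase, window[-1] + 1, next_own - 1)

    if strand == "+":
        start = _align_up(max(lo, (fwd_fp[0] if fwd_fp else lo_site) - _LEAD),
                          phase)
        if stop_rows:
            r = stop_rows[-1]
            off = assignment[r.position][0]
            end = r.position + (2 - off)
        else:
            target = hi_site + _TAIL
            n_codons = math.ceil((target - start + 1) / 3)
            end = start + 3 * n_codons - 1
    else:
        end = _align_down(min(hi, hi_site + _LEAD), phase)
        if stop_rows:
            r = stop_rows[0]
            off = assignment[r.position][0]
            start = r.position - (2 - off)
        else:
            target = lo_site - _TAIL
            n_codons = math.ceil((end - target + 1) / 3)
            start = end - 3 * n_codons + 1
    if start < lo or end > hi:
        raise InfeasibleConstraintError(
            f"gene {locus}: interval [{start}, {end}] collides with its "
            f"neighbours (allowed [{lo}, {hi}])")

    feature = GeneFeature(locus, start, end, strand, "CDS")
    site_codons = {}
    for r in rows:
        off, codon = assignment[r.position]
        span = _codon_span(r.position, off, strand)
        if not (start <= span[0] and span[1] <= end):
            raise InfeasibleConstraintError(
                f"gene {locus}: codon for site {r.position} exceeds the CDS")
        if strand == "+":
            codon_index = (span[0] - start) // 3
        else:
            codon_index = (end - span[1]) // 3
        site_codons[r.position] = SiteCodon(
            r.position, off, codon_index, span,
            _per_form_codons(codon, off, strand, r.alleles))
    return GenePlan(feature, site_codons, primer=primer,
                    fwd_footprint=fwd_fp, rev_footprint=rev_fp)


def _fillers(plans, positions, config):
    need = config.gene_count - len(plans)
    if need < 0:
        raise ValidationError(
            f"gene_count {config.gene_count} is below the {len(plans)} loci "
            "of the variant table")
    names = _TRN_FILLERS + _ORF_FILLERS
    if need > len(names):
        raise ValidationError(
            f"gene_count {config.gene_count} exceeds the "
            f"{len(plans) + len(names)} available gene names")
    out = []
    bounds = [(p.feature.start, p.feature.end) for p in plans]
    gaps = []
    prev = 0
    for s, e in bounds:
        if s - prev - 1 >= 120:
            gaps.append((prev + 1, s - 1))
        prev = e
    if config.genome_length - prev >= 120:
        gaps.append((prev + 1, config.genome_length))

    idx = 0
    for gap_start, gap_end in gaps:
        pos = gap_start + 10
        while idx < need:
            name = names[idx]
            length = 72 if name.startswith("trn") else 120
            end = pos + length - 1
            if end > gap_end - 10:
                break
            if any(pos - 4 <= v <= end + 4 for v in positions):
                # slide past the variant run
                nxt = min(v for v in positions if v >= pos - 4)
                pos = nxt + 5
                continue
            kind = "tRNA" if name.startswith("trn") else "CDS"
            out.append(GenePlan(GeneFeature(name, pos, end, "+", kind)))
            idx += 1
            pos = end + 16
        if idx == need:
            break
    if idx < need:
        raise InfeasibleConstraintError(
            f"could not place {need} filler genes in the available gaps")
    return out


# ---------------------------------------------------------------------------
# sequence construction

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _base_weights(at: float) -> np.ndarray:
    return np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])


def _codon_at_fraction(at: float) -> float:
    """Expected AT fraction of a codon drawn i.i.d. then conditioned on not
    being a stop codon."""
    w = dict(zip("ACGT", _base_weights(at)))
    num = den = 0.0
    for combo in itertools.product("ACGT", repeat=3):
        codon = "".join(combo)
        if codon in STOP_CODONS:
            continue
        p = w[combo[0]] * w[combo[1]] * w[combo[2]]
        num += p * sum(c in "AT" for c in combo) / 3
        den += p
    return num / den


def _cds_weights(target_at: float) -> np.ndarray:
    """Per-base weights whose stop-rejected codon distribution hits the
    target AT fraction."""
    lo, hi = 0.05, 0.95
    t = min(max(target_at, _codon_at_fraction(lo)), _codon_at_fraction(hi))
    a = brentq(lambda x: _codon_at_fraction(x) - t, lo, hi, xtol=1e-9)
    return _base_weights(a)


def build_references(layout: Layout, variants: Sequence[VariantRecord],
                     config: GeneratorConfig,
                     max_attempts: int = 25) -> tuple[list[Genome], list[GeneFeature]]:
    """Build the three reference mitogenomes realizing the variant table.

    Returns the genomes (in fixed form order) and the annotation. The three
    sequences are identical except at listed sites, CDS frames are free of
    internal stop codons in every form, and each primer footprint occurs
    exactly once (verified; the random background is redrawn on the rare
    spurious near-match).
    """
    from . import assay as _assay  # local import; assay has no simulate dep

    config.validate(min_length=max(v.position for v in variants))
    for attempt in range(max_attempts):
        rng = np.random.default_rng([config.seed % (2 ** 31), attempt])
        seqs = _build_once(layout, variants, config, rng)
        genomes = [Genome(id=f"{form}", form=form, seq=s)
                   for form, s in zip(FORMS, seqs)]
        _verify(genomes, layout, variants)
        if _footprints_unique(genomes, layout, _assay):
            return genomes, layout.features
    raise SargmitoError(
        f"failed to build spurious-primer-free references in {max_attempts} "
        "attempts")


def _build_once(layout, variants, config, rng):
    L = config.genome_length
    bg = _base_weights(config.at_fraction)
    cds_w = _cds_weights(config.at_fraction)
    backbone = _BASES[rng.choice(4, size=L, p=bg)]
    seqs = [backbone.copy() for _ in FORMS]

    for plan in layout.plans:
        f = plan.feature
        if f.kind != "CDS":
            continue
        n_codons = len(f) // 3
        # fixed base assignments in coding coordinates, per form
        fixed: dict[int, tuple[str, str, str]] = {}

        def coding_pos(g: int) -> int:
            return g - f.start if f.strand == "+" else f.end - g

        for sc in plan.site_codons.values():
            base_idx = sc.codon_index * 3
            for k in range(3):
                fixed[base_idx + k] = tuple(c[k] for c in sc.per_form)
        for fp in (plan.fwd_footprint, plan.rev_footprint):
            if fp is None:
                continue
            fp_seq = _footprint_plus_seq(plan, fp)
            for g, base in zip(range(fp[0], fp[1] + 1), fp_seq):
                q = coding_pos(g)
                b = base if f.strand == "+" else COMPLEMENT[base]
                if q in fixed and any(x != b for x in fixed[q]):
                    raise InfeasibleConstraintError(
                        f"{f.locus}: primer footprint collides with a "
                        "variant codon")
                fixed[q] = (b, b, b)
        last = n_codons - 1
        if not any(q // 3 == last for q in fixed):
            for k, b in enumerate("TAA"):
                fixed[last * 3 + k] = (b, b, b)

        coding = [_fill_codons(n_codons, fixed, i, cds_w, rng)
                  for i in range(len(FORMS))]
        for i, cod in enumerate(coding):
            arr = np.frombuffer(cod.encode(), dtype=np.uint8)
            if f.strand == "+":
                seqs[i][f.start - 1:f.end] = arr
            else:
                seqs[i][f.start - 1:f.end] = np.frombuffer(
                    revcomp(cod).encode(), dtype=np.uint8)

    for v in variants:
        if v.kind != "CDS":
            for i, allele in enumerate(v.alleles):
                seqs[i][v.position - 1] = ord(allele)
    return [s.tobytes().decode() for s in seqs]


def _footprint_plus_seq(plan, fp):
    # fwd footprints carry the oligo verbatim on the plus strand, rev
    # footprints its reverse complement.
    if fp == plan.fwd_footprint:
        return plan.primer.fwd_seq
    return revcomp(plan.primer.rev_seq)


def _fill_codons(n_codons, fixed, form_index, weights, rng):
    # codons are drawn jointly across forms once (shared background); only
    # fully fixed (variant) codons differ between forms. To keep the three
    # sequences identical outside variant sites, free draws are cached on
    # the fixed dict itself keyed by codon index.
    cache = fixed.setdefault("_cache", {})
    out = []
    for k in range(n_codons):
        bases = [fixed.get(3 * k + j, (None,) * len(FORMS))[form_index]
                 for j in range(3)]
        if all(b is not None for b in bases):
            out.append("".join(bases))
            continue
        if k in cache:
            draw = cache[k]
        else:
            while True:
                draw = [bases[j] if bases[j] is not None else
                        "ACGT"[rng.choice(4, p=weights)] for j in range(3)]
                if "".join(draw) not in STOP_CODONS:
                    break
            cache[k] = draw
        out.append("".join(draw))
    return "".join(out)


def _verify(genomes, layout, variants):
    arrs = [np.frombuffer(g.seq.encode(), dtype=np.uint8) for g in genomes]
    expected = {v.position: v.alleles for v in variants}
    diff = (arrs[0] != arrs[1]) | (arrs[0] != arrs[2]) | (arrs[1] != arrs[2])
    found = {int(i) + 1 for i in np.flatnonzero(diff)}
    if found != set(expected):
        raise SargmitoError(
            f"generator bug: variant positions {sorted(found ^ set(expected))} "
            "do not round-trip")
    for pos, alleles in expected.items():
        got = tuple(chr(a[pos - 1]) for a in arrs)
        if got != alleles:
            raise SargmitoError(
                f"generator bug: position {pos} carries {got}, expected "
                f"{alleles}")
    for plan in layout.plans:
        f = plan.feature
        if f.kind != "CDS":
            continue
        for g in genomes:
            seg = g.seq[f.start - 1:f.end]
            coding = seg if f.strand == "+" else revcomp(seg)
            internal = [coding[i:i + 3] for i in range(0, len(coding) - 3, 3)]
            if any(c in STOP_CODONS for c in internal):
                raise SargmitoError(
                    f"generator bug: internal stop codon in {f.locus} "
                    f"({g.form})")


def _footprints_unique(genomes, layout, assay_mod):
    for plan in layout.plans:
        if plan.primer is None:
            continue
        pair = plan.primer
        for g in genomes:
            fwd = assay_mod.find_primer_sites(g, pair.fwd_seq, max_mismatch=2)
            rev = assay_mod.find_primer_sites(g, pair.rev_seq, max_mismatch=2)
            fwd_plus = [s for s in fwd if s.strand == "+"]
            rev_minus = [s for s in rev if s.strand == "-"]
            if len(fwd) != 1 or len(rev) != 1:
                return False
            if (fwd_plus[0].start, fwd_plus[0].end) != plan.fwd_footprint:
                return False
            if (rev_minus[0].start, rev_minus[0].end) != plan.rev_footprint:
                return False
    return True


# ---------------------------------------------------------------------------
# cohorts and marker panel

@dataclass(frozen=True)
class Specimen:
    specimen_id: str
    true_form: str
    amplicons: dict  # assay name -> sequence


@dataclass
class SyntheticCohort:
    specimens: list[Specimen]
    seed: int

    def __len__(self) -> int:
        return len(self.specimens)

    def __iter__(self) -> Iterator[Specimen]:
        return iter(self.specimens)

    def to_fasta_records(self) -> list[tuple[str, str]]:
        recs = []
        for sp in self.specimens:
            for assay, seq in sorted(sp.amplicons.items()):
                recs.append((f"{sp.specimen_id}|{assay}|form={sp.true_form}", seq))
        return recs


def generate_cohort(references: Sequence[Genome], primers: Sequence[PrimerPair],
                    config: GeneratorConfig) -> SyntheticCohort:
    """Labelled per-specimen cox2/cox3 amplicons copied from each specimen's
    true-form reference, with i.i.d. per-base substitution noise."""
    from .assay import insilico_pcr

    config.validate()
    by_form = {g.form: g for g in references}
    products = {
        (pair.name, form): insilico_pcr(by_form[form], pair).seq
        for pair in primers for form in by_form
    }
    rng = np.random.default_rng([config.seed % (2 ** 31), 104729])
    specimens = []
    for form in FORMS:
        for i in range(config.cohort_sizes.get(form, 0)):
            amplicons = {}
            for pair in primers:
                seq = products[(pair.name, form)]
                amplicons[pair.name] = _noisy(seq, config.noise_rate, rng)
            specimens.append(
                Specimen(f"{form}_{i + 1:03d}", form, amplicons))
    return SyntheticCohort(specimens, config.seed)


def _noisy(seq: str, rate: float, rng) -> str:
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        others = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = others[rng.integers(3)]
    return arr.tobytes().decode()


_MARKER_LENGTHS = {"18S": 600, "5.8S": 155, "ITS-2": 300, "rbcL": 750}


def generate_marker_panel(config: GeneratorConfig) -> dict[str, dict[str, str]]:
    """Toy barcoding loci reproducing the negative marker-gene results:
    18S and 5.8S identical across forms, ITS-2 with one site setting
    natans VIII apart, rbcL with three sites setting fluitans apart."""
    rng = np.random.default_rng([config.seed % (2 ** 31), 7919])
    bg = _base_weights(config.at_fraction)
    panel: dict[str, dict[str, str]] = {}
    for marker, length in _MARKER_LENGTHS.items():
        base = _BASES[rng.choice(4, size=length, p=bg)]
        per_form = {form: base.copy() for form in FORMS}
        if marker == "ITS-2":
            _plant(per_form, ["natans_VIII"], 1, length, rng)
        elif marker == "rbcL":
            _plant(per_form, ["fluitans_III"], 3, length, rng)
        panel[marker] = {f: a.tobytes().decode() for f, a in per_form.items()}
    return panel


def _plant(per_form, deviant_forms, n_sites, length, rng):
    sites = sorted(rng.choice(np.arange(20, length - 20), size=n_sites,
                              replace=False))
    for pos in sites:
        current = per_form[deviant_forms[0]][pos]
        alt = [b for b in b"ACGT" if b != current][int(rng.integers(3))]
        for form in deviant_forms:
            per_form[form][pos] = alt
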