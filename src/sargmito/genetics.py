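"""Small genetic-code utilities shared across modules.

Amino acids are handled as three-letter names ("Ala", "Stop") because that
is how variant effect chains are reported; translation itself is delegated
to Biopython's codon tables.
"""

from __future__ import annotations

from Bio.Data import CodonTable

from .errors import ValidationError

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}

AA_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Stop",
}

#: Genomes are modelled over the unambiguous alphabet plus missing data.
NUCLEOTIDES = "ACGT"


def _codon_map(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = {codon: AA_THREE[aa] for codon, aa in table.forward_table.items()}
    for codon in table.stop_codons:
        mapping[codon] = "Stop"
    return mapping


#: codon -> three-letter amino acid, standard code (NCBI table 1) and the
#: mold/protozoan mitochondrial code (table 4, TGA = Trp).
CODON_TO_AA3 = {1: _codon_map(1), 4: _codon_map(4)}

STOP_CODONS = frozenset(c for c, aa in CODON_TO_AA3[1].items() if aa == "Stop")


def translate_codon(codon: str, table: int = 1) -> str:
    """Translate a single codon to its three-letter amino acid ('Stop')."""
    try:
        return CODON_TO_AA3[table][codon.upper()]
    except KeyError:
        raise ValidationError(f"cannot translate codon {codon!r}") from None


def complement(base: str) -> str:
    return COMPLEMENT[base]


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def expand_chain(alleles: tuple[str, ...], chain: str) -> tuple[str, ...]:
    """Expand a merged amino-acid chain into one entry per form.

    Chains list one amino acid per *run of equal alleles* in fixed form
    order, e.g. alleles (C, C, T) with chain "Pro > Ser" expand to
    (Pro, Pro, Ser), while (G, A, G) needs three entries ("Gly > Asp > Gly").
    """
    entries = [e.strip() for e in chain.split(">")]
    runs: list[list[int]] = []
    for i, a in enumerate(alleles):
        if runs and alleles[runs[-1][-1]] == a:
            runs[-1].append(i)
        else:
            runs.append([i])
    if len(runs) != len(entries):
        raise ValidationError(
            f"chain {chain!r} has {len(entries)} entries but alleles "
            f"{alleles} form {len(runs)} runs"
        )
    out = [""] * len(alleles)
    for run, entry in zip(runs, entries):
        for i in run:
            out[i] = entry
    return tuple(out)


def merge_chain(alleles: tuple[str, ...], aas: tuple[str, ...]) -> str:
    """Inverse of :func:`expand_chain`: merge per-form amino acids into the
    reported chain, one entry per run of equal alleles."""
    parts = []
    for i, (a, aa) in enumerate(zip(alleles, aas)):
        if i == 0 or alleles[i - 1] != a:
            parts.append(aa)
        elif parts[-1] != aa:
            raise ValidationError(
                f"forms sharing allele {a} translate differently: {aas}"
            )
    return " > ".join(parts)
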