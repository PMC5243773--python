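"""Reading and writing the formats the pipeline touches.

FASTA goes through Biopython, GFF3 through gffutils; the packaged reference
panel (variant table, primer panel) is plain TSV read with pandas. All
coordinates are 1-based inclusive.
"""

from __future__ import annotations

import io as _io
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError
from .model import GeneFeature, PrimerPair, VariantRecord

# IUPAC ambiguity codes collapse to N: downstream allele logic is exact.
_CLEAN = str.maketrans(
    {"U": "T", "R": "N", "Y": "N", "S": "N", "W": "N", "K": "N", "M": "N",
     "B": "N", "D": "N", "H": "N", "V": "N"}
)


def _clean_seq(raw: str, record_id: str) -> str:
    seq = raw.upper().translate(_CLEAN)
    if not seq:
        raise FormatError(f"FASTA record {record_id!r} has no sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise FormatError(
            f"FASTA record {record_id!r} contains non-nucleotide symbols "
            f"{sorted(bad)}"
        )
    return seq


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA file, in file order.

    Sequences are uppercased, U is mapped to T and IUPAC ambiguity codes to
    N; anything else is a format error, as are empty files and headers
    without sequence.
    """
    path = Path(path)
    records = [(rec.id, _clean_seq(str(rec.seq), rec.id))
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


_GFF_KINDS = ("CDS", "rRNA", "tRNA")


def read_gff3(path) -> list[GeneFeature]:
    """Read gene features from GFF3, sorted by start coordinate."""
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
        if end < start:
            raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
        if cols[2] not in _GFF_KINDS:
            raise FormatError(f"{path}:{lineno}: unknown feature kind {cols[2]!r}")
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, merge_strategy="create_unique",
        keep_order=True,
    )
    features = []
    for f in db.all_features():
        locus = f.attributes.get("Name", f.attributes.get("ID", [f.id]))[0]
        features.append(
            GeneFeature(locus=locus, start=f.start, end=f.end,
                        strand=f.strand, kind=f.featuretype)
        )
    return sorted(features, key=lambda g: g.start)


def write_gff3(path, features: Sequence[GeneFeature], seqid: str = "mitogenome") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(sorted(features, key=lambda g: g.start), 1):
            fh.write(
                f"{seqid}\tsargmito\t{f.kind}\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID=gene{i:03d};Name={f.locus}\n"
            )


_TABLE_COLUMNS = ["position", "locus", "nt_fluitans", "nt_natansI",
                  "nt_natansVIII", "aa_chain"]


def load_variant_table(path=None) -> list[VariantRecord]:
    """Load a variant table (the packaged reference panel by default).

    Records come back sorted by position; duplicate positions, monomorphic
    rows and non-ACGT alleles are validation errors.
    """
    if path is None:
        with resources.files("sargmito.data").joinpath("variant_table.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"variant table missing columns {sorted(missing)}")
    df["position"] = df["position"].astype(int)
    dup = df["position"][df["position"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate variant positions {sorted(set(dup))}")
    df = df.sort_values("position")
    return [
        VariantRecord(
            position=int(r.position),
            locus=r.locus,
            alleles=(r.nt_fluitans, r.nt_natansI, r.nt_natansVIII),
            aa_chain=r.aa_chain,
        )
        for r in df.itertuples()
    ]


def write_variant_table(path, records: Sequence[VariantRecord]) -> None:
    df = pd.DataFrame(
        [
            {"position": r.position, "locus": r.locus,
             "nt_fluitans": r.alleles[0], "nt_natansI": r.alleles[1],
             "nt_natansVIII": r.alleles[2], "aa_chain": r.aa_chain}
            for r in records
        ],
        columns=_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def load_primer_panel(path=None) -> list[PrimerPair]:
    """Load the primer panel (the packaged cox2/cox3 panel by default)."""
    if path is None:
        with resources.files("sargmito.data").joinpath("primer_panel.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"name", "fwd_name", "fwd_seq", "rev_name", "rev_seq", "gene"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"primer panel missing columns {sorted(missing)}")
    return [
        PrimerPair(name=r.name, fwd_name=r.fwd_name, fwd_seq=r.fwd_seq,
                   rev_name=r.rev_name, rev_seq=r.rev_seq, gene=r.gene)
        for r in df.itertuples(index=False)
    ]
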