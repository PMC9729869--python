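"""Sequence I/O: validated nucleotide/protein records, FASTA, GenBank and GFF3.

Internal coordinates are 0-based half-open everywhere in this package;
serialized outputs (GFF3, JSON report) are 1-based inclusive, matching the
conventions of those formats and of published residue numbering.

Only the forward strand is modeled: the cDNA and gene of a co-oriented
eukaryotic locus, which is the use case this package targets.
"""

from __future__ import annotations

import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

NUC_ALPHABET = set("ACGTN")
PROT_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

Alphabet = Literal["nucleotide", "protein"]


class SeqIOError(ValueError):
    """Malformed input: bad characters, duplicate ids, missing blocks."""


@dataclass(frozen=True)
class NucRecord:
    """A named nucleotide sequence (genomic DNA or cDNA).

    ``seq`` is uppercase over {A,C,G,T,N}; lowercase input is folded and
    RNA 'U' is mapped to 'T' at construction time.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        seq = self.seq.upper().replace("U", "T")
        if not seq:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - NUC_ALPHABET
        if bad:
            raise SeqIOError(
                f"record {self.id!r}: illegal nucleotide character(s) "
                f"{sorted(bad)!r}"
            )
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProtRecord:
    """A named amino-acid sequence over the 20 standard residues.

    Ambiguity codes (X, B, Z) and stop characters are rejected: downstream
    physicochemical property computations are undefined for them.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if not seq:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - PROT_ALPHABET
        if bad:
            raise SeqIOError(
                f"record {self.id!r}: non-standard residue(s) {sorted(bad)!r}"
            )
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenBankRecord:
    """A GenBank nucleotide entry plus any CDS feature intervals (0-based half-open)."""

    record: NucRecord
    cds_intervals: tuple[tuple[int, int], ...] = field(default_factory=tuple)


def read_fasta(path: str | Path, alphabet: Alphabet) -> list[NucRecord] | list[ProtRecord]:
    """Read a multi-record FASTA file into validated records.

    Order is preserved, sequences are uppercased, whitespace stripped.
    Duplicate ids, empty sequences and out-of-alphabet characters raise
    :class:`SeqIOError` naming the offending record.
    """
    cls = NucRecord if alphabet == "nucleotide" else ProtRecord
    out: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        out.append(cls(id=rec.id, seq=str(rec.seq), description=desc))
    if not out:
        raise SeqIOError(f"no FASTA records found in {path}")
    return out


def write_fasta(records: Iterable[NucRecord | ProtRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_genbank(path: str | Path) -> GenBankRecord:
    """Read a GenBank flat file; return the sequence and CDS intervals.

    CDS feature coordinates come back in the package's internal 0-based
    half-open convention (a GenBank ``CDS 1..6`` becomes ``(0, 6)``).
    A record without an ORIGIN sequence block is a parse error.
    """
    try:
        rec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise SeqIOError(f"no GenBank record found in {path}") from None
    except ValueError as err:  # truncated record, e.g. missing ORIGIN block
        raise SeqIOError(f"{path}: malformed GenBank record: {err}") from None
    try:
        seq = str(rec.seq)
    except Exception:  # undefined sequence: LOCUS present but no ORIGIN block
        raise SeqIOError(f"{path}: GenBank record has no ORIGIN sequence") from None
    if not seq:
        raise SeqIOError(f"{path}: GenBank record has no ORIGIN sequence")
    cds: list[tuple[int, int]] = []
    for feat in rec.features:
        if feat.type == "CDS":
            for part in feat.location.parts:
                cds.append((int(part.start), int(part.end)))
    return GenBankRecord(
        record=NucRecord(id=rec.id, seq=seq, description=rec.description),
        cds_intervals=tuple(sorted(cds)),
    )


def write_gff3(model, path: str | Path, source: str = "ggpstyper") -> None:
    """Write a gene model as GFF3 (gene + exon features, 1-based inclusive).

    ``model`` is a :class:`ggpstyper.gene_structure.GeneModel`; the strand is
    always "+" (forward-strand-only package scope).
    """
    seqid = model.genomic_id
    gene_id = f"gene:{model.cdna_id}"
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        gstart, gend = model.exons[0][0] + 1, model.exons[-1][1]
        fh.write(
            f"{seqid}\t{source}\tgene\t{gstart}\t{gend}\t.\t+\t.\tID={gene_id}\n"
        )
        for n, (s, e) in enumerate(model.exons, start=1):
            fh.write(
                f"{seqid}\t{source}\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                f"ID={gene_id}.exon{n};Parent={gene_id}\n"
            )


def read_gff3_exons(path: str | Path) -> list[tuple[int, int]]:
    """Read exon intervals back from a GFF3 file, as 0-based half-open tuples."""
    exons: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise SeqIOError(f"{path}: malformed GFF3 line: {line!r}")
            if cols[2] == "exon":
                exons.append((int(cols[3]) - 1, int(cols[4])))
    return sorted(exons)


_EUTILS = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db={db}&id={acc}&rettype={rettype}&retmode=text"
)


def fetch_accession(
    accession: str,
    path: str | Path,
    db: str = "nuccore",
    rettype: str = "gb",
    timeout: float = 60.0,
) -> Path:
    """Download a GenBank/FASTA record from NCBI E-utilities to a local file.

    This is the only network-touching code path in the package; everything
    else operates on local files. Requires internet access.
    """
    url = _EUTILS.format(db=db, acc=accession, rettype=rettype)
    path = Path(path)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    if not data.strip():
        raise SeqIOError(f"empty response fetching {accession}")
    path.write_bytes(data)
    return path
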