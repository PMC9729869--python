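"""ORF finding, translation, and protein physicochemical properties.

Molecular mass is the sum of average (isotope-abundance-weighted) residue
masses plus one water, the convention of standard proteomics property
calculators. The isoelectric point is the pH at which the Henderson-
Hasselbalch net charge over the termini and the ionizable side chains
(D, E, C, Y, H, K, R) is zero, computed with the Bjellqvist pKa set —
including its residue-specific N-terminal pKa values — and located by
bisection. Both the pKa table and the mass table are plain dicts and can
be overridden per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from Bio.Seq import Seq

from .seq_io import NucRecord, ProtRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}


class OrfError(ValueError):
    """No complete ORF, or an ORF violating the reading-frame invariants."""


@dataclass(frozen=True)
class OrfCall:
    """A complete open reading frame on a cDNA.

    ``start``/``end`` are 0-based half-open on the cDNA and include the stop
    codon; ``frame`` is ``start % 3``.
    """

    start: int
    end: int
    complete: bool = True

    @property
    def frame(self) -> int:
        return self.start % 3

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ProteinStats:
    """Derived physicochemical properties of a translated ORF."""

    length: int
    mw_da: float
    pi: float
    composition: dict[str, int]

    @property
    def mw_kda(self) -> float:
        return round(self.mw_da / 1000.0, 2)


def find_orf(cdna: NucRecord) -> OrfCall:
    """Return the longest complete forward-strand ORF (ATG ... stop).

    Ties on length are broken by the smaller start coordinate. Raises
    :class:`OrfError` when no ATG-initiated, stop-terminated frame exists.
    """
    seq = cdna.seq
    if len(seq) < 6:
        raise OrfError(f"{cdna.id}: sequence shorter than one codon pair")
    best: OrfCall | None = None
    for start in _find_all(seq, "ATG"):
        end = _first_inframe_stop(seq, start)
        if end is None:
            continue
        if best is None or end - start > len(best):
            best = OrfCall(start=start, end=end)
    if best is None:
        raise OrfError(f"{cdna.id}: no complete ORF on the forward strand")
    return best


def _find_all(seq: str, sub: str) -> list[int]:
    out, i = [], seq.find(sub)
    while i != -1:
        out.append(i)
        i = seq.find(sub, i + 1)
    return out


def _first_inframe_stop(seq: str, start: int) -> int | None:
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i + 3
    return None


def translate(orf: OrfCall, cdna: NucRecord) -> ProtRecord:
    """Translate an ORF with the standard genetic code; the stop is dropped."""
    nt = cdna.seq[orf.start : orf.end]
    if len(nt) % 3 != 0:
        raise OrfError(f"{cdna.id}: ORF length {len(nt)} not divisible by 3")
    if "N" in nt:
        raise OrfError(f"{cdna.id}: ambiguous base inside ORF")
    aa = str(Seq(nt).translate(table=1))
    if not aa.endswith("*"):
        raise OrfError(f"{cdna.id}: ORF does not end in a stop codon")
    body = aa[:-1]
    if "*" in body:
        raise OrfError(f"{cdna.id}: internal stop codon in ORF")
    return ProtRecord(id=cdna.id, seq=body, description="translated ORF")


# Average residue (= amino acid - water) masses in Da.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524


def molecular_weight(protein: ProtRecord, masses: Mapping[str, float] | None = None) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water."""
    table = AVERAGE_RESIDUE_MASS if masses is None else masses
    total = WATER_MASS
    for pos, aa in enumerate(protein.seq, start=1):
        try:
            total += table[aa]
        except KeyError:
            raise ValueError(
                f"{protein.id}: non-standard residue {aa!r} at position {pos}"
            ) from None
    return total


# Bjellqvist pKa set. Side chains D/E/C/Y deprotonate (negative above pKa);
# H/K/R and the N-terminus protonate (positive below pKa). The N-terminal
# pKa depends on the first residue.
BJELLQVIST_PKA: dict[str, float] = {
    "Cterm": 3.55,
    "Nterm": 7.5,
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0,
    "H": 5.98,
    "K": 10.0,
    "R": 12.0,
}
BJELLQVIST_NTERM_PKA: dict[str, float] = {
    "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
}
BJELLQVIST_CTERM_PKA: dict[str, float] = {"D": 4.55, "E": 4.75}

_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("H", "K", "R")


def net_charge(
    protein: ProtRecord,
    ph: float,
    pka: Mapping[str, float] | None = None,
    nterm_pka: Mapping[str, float] | None = None,
    cterm_pka: Mapping[str, float] | None = None,
) -> float:
    """Henderson–Hasselbalch net charge of the protein at a given pH.

    Terminal pKa values are residue-specific where the Bjellqvist set
    defines them (N-terminal A/M/S/P/T/V/E; C-terminal D/E).
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH {ph} outside [0, 14]")
    table = dict(BJELLQVIST_PKA if pka is None else pka)
    nterm_table = BJELLQVIST_NTERM_PKA if nterm_pka is None else nterm_pka
    cterm_table = BJELLQVIST_CTERM_PKA if cterm_pka is None else cterm_pka
    seq = protein.seq
    counts = {aa: seq.count(aa) for aa in _ACIDIC + _BASIC}

    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pk))

    def neg(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - ph))

    charge = pos(nterm_table.get(seq[0], table["Nterm"]))
    charge += neg(cterm_table.get(seq[-1], table["Cterm"]))
    for aa in _BASIC:
        charge += counts[aa] * pos(table[aa])
    for aa in _ACIDIC:
        charge += counts[aa] * neg(table[aa])
    return charge


def isoelectric_point(
    protein: ProtRecord,
    pka: Mapping[str, float] | None = None,
    nterm_pka: Mapping[str, float] | None = None,
    cterm_pka: Mapping[str, float] | None = None,
    tol: float = 1e-4,
) -> float:
    """pH of zero net charge, by bisection on [0, 14] to |charge| < tol.

    The charge is strictly decreasing in pH, so the zero is unique. Returned
    at full precision; report-level rounding to 2 dp happens downstream.
    """
    lo, hi = 0.0, 14.0
    # charge(0) > 0 > charge(14) always holds: the termini alone guarantee it.
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(protein, mid, pka=pka, nterm_pka=nterm_pka, cterm_pka=cterm_pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def protein_stats(protein: ProtRecord) -> ProteinStats:
    """Bundle length, mass, pI and residue composition for reporting."""
    comp = {aa: protein.seq.count(aa) for aa in sorted(set(protein.seq))}
    return ProteinStats(
        length=len(protein),
        mw_da=molecular_weight(protein),
        pi=isoelectric_point(protein),
        composition=comp,
    )
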