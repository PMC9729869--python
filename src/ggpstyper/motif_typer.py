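"""Aspartate-rich motif detection, CLD extraction and GGPPS type calling.

Trans-prenyltransferases carry two aspartate-rich motifs: the FARM (first
aspartate-rich motif, DDxxD or DDxxxxD) near the N-terminus and the SARM
(second aspartate-rich motif, DDxxD) near the C-terminus; the allylic
substrate diphosphate binds between them via Mg2+. The FARM plus the five
residues immediately upstream form the chain-length determination (CLD)
region, whose bulk/aromaticity pattern separates the three GGPPS classes:

* type I (archaeal): FARM is DDxxD, the fifth residue upstream of the FARM
  is aromatic and the fourth is not;
* type II (plant/bacterial) and type III (animal/fungal): FARM is DDxxxxD
  with non-aromatic fourth and fifth upstream residues. The rule alone
  cannot separate II from III, so the call falls back to CLD homology
  against a typed reference panel.

Residue correspondence between homologs (e.g. transferring annotated
product-blocking residues) uses Needleman-Wunsch global alignment with
BLOSUM62 and affine gaps.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import ProtRecord, read_fasta

AROMATIC = frozenset("FYW")

# Distance window (SARM start - FARM start) accepted between the two motifs.
FARM_SARM_MIN_GAP = 80
FARM_SARM_MAX_GAP = 250

# The FARM is searched in the N-terminal 60% of the protein, the SARM in the
# C-terminal 60%; prevents swapped assignments on aspartate-rich sequences.
TERMINAL_FRACTION = 0.6

_FARM_SHORT = re.compile(r"(?=(DD..D))")
_FARM_LONG = re.compile(r"(?=(DD....D))")
_SARM = re.compile(r"(?=(DD..D))")


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class MotifHit:
    """One FARM or SARM match; interval is 0-based half-open on the protein."""

    kind: Literal["FARM", "SARM"]
    start: int
    end: int
    pattern: str
    farm_form: Literal["DDxxD", "DDxxxxD"] | None = None


@dataclass(frozen=True)
class CLDRegion:
    """The FARM match plus the five residues immediately upstream."""

    sequence: str
    start: int  # 0-based start of the CLD (= FARM start - 5)
    upstream5: str  # residue at FARM-5 (first CLD residue)
    upstream4: str  # residue at FARM-4


@dataclass(frozen=True)
class TypeCall:
    """GGPPS type assignment with the evidence that produced it."""

    type: Literal["I", "II", "III", "unclassified"]
    rule_evidence: str
    nearest_reference: str | None = None
    nearest_identity: float | None = None


@dataclass(frozen=True)
class PanelEntry:
    """A typed reference protein used for the II-vs-III homology call."""

    id: str
    ggpps_type: Literal["I", "II", "III"]
    cld: str


@dataclass(frozen=True)
class MappedResidue:
    ref_pos: int  # 1-based position on the reference
    query_pos: int | None  # 1-based aligned position on the query, None if gap
    ref_aa: str
    query_aa: str | None


@dataclass(frozen=True)
class ResidueMap:
    query_id: str
    reference_id: str
    pairs: tuple[MappedResidue, ...]


def scan_motifs(protein: ProtRecord) -> list[MotifHit]:
    """Locate the FARM and the SARM; empty list when no valid pair exists.

    The FARM is the most N-terminal DDxxD/DDxxxxD match (short form first on
    a shared start) that has a compatible SARM downstream; the SARM is the
    C-terminal-most DDxxD whose distance to that FARM lies in the accepted
    window.
    """
    seq = protein.seq
    if len(seq) < 100:
        raise MotifError(f"{protein.id}: protein shorter than 100 residues")
    n_limit = int(len(seq) * TERMINAL_FRACTION)
    c_start = len(seq) - n_limit

    farm_candidates: list[MotifHit] = []
    for regex, form in ((_FARM_SHORT, "DDxxD"), (_FARM_LONG, "DDxxxxD")):
        for m in regex.finditer(seq):
            if m.start() < n_limit:
                farm_candidates.append(
                    MotifHit("FARM", m.start(), m.start() + len(m.group(1)),
                             m.group(1), form)
                )
    farm_candidates.sort(key=lambda h: (h.start, h.end))

    sarm_candidates = [
        MotifHit("SARM", m.start(), m.start() + 5, m.group(1))
        for m in _SARM.finditer(seq)
        if m.start() >= c_start
    ]

    for farm in farm_candidates:
        compatible = [
            s for s in sarm_candidates
            if FARM_SARM_MIN_GAP <= s.start - farm.start <= FARM_SARM_MAX_GAP
        ]
        if compatible:
            return [farm, max(compatible, key=lambda s: s.start)]
    return []


def extract_cld(protein: ProtRecord, farm: MotifHit) -> CLDRegion:
    """Cut the CLD (FARM plus five upstream residues) out of the protein."""
    if farm.start < 5:
        raise MotifError(
            f"{protein.id}: FARM at position {farm.start + 1} is too close to "
            "the N-terminus for a CLD (needs 5 upstream residues)"
        )
    start = farm.start - 5
    return CLDRegion(
        sequence=protein.seq[start : farm.end],
        start=start,
        upstream5=protein.seq[farm.start - 5],
        upstream4=protein.seq[farm.start - 4],
    )


def cld_identity(a: str, b: str) -> float:
    """Identity fraction between two CLD strings under global alignment."""
    if a == b:
        return 1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    matches = sum(
        1
        for (a0, a1), (b0, b1) in zip(*aln.aligned)
        for i, j in zip(range(a0, a1), range(b0, b1))
        if a[i] == b[j]
    )
    return matches / max(len(a), len(b))


def classify_type(
    farm: MotifHit,
    cld: CLDRegion,
    panel: Sequence[PanelEntry] = (),
) -> TypeCall:
    """Apply the CLD rule, then disambiguate type II vs III by panel homology.

    Rule stage: type I iff the FARM is DDxxD with an aromatic fifth and a
    non-aromatic fourth upstream residue; candidate {II, III} iff the FARM is
    DDxxxxD with both upstream positions non-aromatic; anything else is
    unclassified. The II/III candidate is resolved to the type of the
    highest-CLD-identity type-II/III panel reference.
    """
    u5_arom = cld.upstream5 in AROMATIC
    u4_arom = cld.upstream4 in AROMATIC
    evidence = (
        f"farm_form={farm.farm_form}, upstream5={cld.upstream5}"
        f"({'aromatic' if u5_arom else 'non-aromatic'}), "
        f"upstream4={cld.upstream4}"
        f"({'aromatic' if u4_arom else 'non-aromatic'})"
    )
    if farm.farm_form == "DDxxD" and u5_arom and not u4_arom:
        return TypeCall("I", rule_evidence=evidence + " -> type I rule")
    if farm.farm_form == "DDxxxxD" and not u5_arom and not u4_arom:
        refs = [p for p in panel if p.ggpps_type in ("II", "III")]
        if not refs:
            raise MotifError(
                "panel required: CLD rule yields candidate {II,III}; a typed "
                "reference panel is needed for the homology call"
            )
        best = max(refs, key=lambda p: (cld_identity(cld.sequence, p.cld), p.id))
        ident = cld_identity(cld.sequence, best.cld)
        return TypeCall(
            best.ggpps_type,
            rule_evidence=evidence + " -> candidate {II,III}, resolved by homology",
            nearest_reference=best.id,
            nearest_identity=ident,
        )
    return TypeCall("unclassified", rule_evidence=evidence + " -> no rule matched")


def load_panel(fasta_path: str | Path, types_path: str | Path) -> list[PanelEntry]:
    """Load a reference panel: a protein FASTA plus a TSV of ``id<TAB>type``.

    Each panel protein's CLD is extracted with the package's own motif
    scanner; entries whose motifs cannot be located are rejected (a panel
    member without a detectable FARM cannot anchor a homology call).
    """
    types: dict[str, str] = {}
    with open(types_path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2 or row[1] not in ("I", "II", "III"):
                raise MotifError(f"{types_path}: bad panel type row {row!r}")
            types[row[0]] = row[1]
    entries: list[PanelEntry] = []
    for rec in read_fasta(fasta_path, "protein"):
        if rec.id not in types:
            raise MotifError(f"panel protein {rec.id!r} missing from {types_path}")
        hits = scan_motifs(rec)
        if not hits:
            raise MotifError(f"panel protein {rec.id!r}: no FARM/SARM found")
        cld = extract_cld(rec, hits[0])
        entries.append(PanelEntry(id=rec.id, ggpps_type=types[rec.id], cld=cld.sequence))
    return entries


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def map_residues(
    query: ProtRecord,
    reference: ProtRecord,
    positions: Sequence[int],
) -> ResidueMap:
    """Map 1-based reference positions onto the query via global alignment.

    Uses Needleman-Wunsch with BLOSUM62 and affine gaps (open 10, extend 1).
    A reference position falling in a query gap maps to ``None``.
    """
    for p in positions:
        if not 1 <= p <= len(reference):
            raise MotifError(
                f"position {p} out of range for reference {reference.id!r} "
                f"(length {len(reference)})"
            )
    aln = _global_aligner().align(query.seq, reference.seq)[0]
    q_blocks, r_blocks = aln.aligned
    ref_to_query: dict[int, int] = {}
    for (q0, q1), (r0, r1) in zip(q_blocks, r_blocks):
        for qi, ri in zip(range(q0, q1), range(r0, r1)):
            ref_to_query[ri] = qi
    pairs = []
    for p in positions:
        qi = ref_to_query.get(p - 1)
        pairs.append(
            MappedResidue(
                ref_pos=p,
                query_pos=None if qi is None else qi + 1,
                ref_aa=reference.seq[p - 1],
                query_aa=None if qi is None else query.seq[qi],
            )
        )
    return ResidueMap(query_id=query.id, reference_id=reference.id, pairs=tuple(pairs))
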