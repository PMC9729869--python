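"""Seeded synthetic gene/protein fixtures with serialized ground truth.

The gene generator emulates the structure of a compact fungal
prenyltransferase locus: a multi-exon gene whose introns are GT..AG, whose
concatenated exons carry exactly one complete ATG-initiated ORF, and whose
translation carries planted FARM/SARM motifs of a chosen GGPPS type.
Defaults mirror a ~1.1 kb cDNA in a ~1.7 kb locus: nine exons of 60-200 nt
and introns of 40-110 nt.

Every fixture is deterministic for a fixed seed, and the ground truth
(exon/intron coordinates, ORF interval, motif positions, expected type
call) is emitted beside it so each pipeline stage can be scored.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .seq_io import NucRecord, ProtRecord, write_fasta

NUCS = "ACGT"
BACKGROUND_AA = "ACEFGHIKLMNPQRSTVWY"  # the 20 standard residues minus D
SMALL_NONAROMATIC = "ASGTC"
AROMATIC = "FYW"

MotifPlant = Literal["none", "type_I", "type_II_III"]


class SpecError(ValueError):
    """Infeasible or invalid generator specification."""


@dataclass(frozen=True)
class GeneSpec:
    """Parameters of one synthetic gene fixture."""

    seed: int
    exon_count: int = 9
    exon_len_range: tuple[int, int] = (60, 200)
    intron_len_range: tuple[int, int] = (40, 110)
    mutation_rate: float = 0.0
    indel_rate: float = 0.0  # stress-test mode; excluded from recovery guarantees
    non_canonical_fraction: float = 0.0
    motif_plant: MotifPlant = "type_II_III"

    def __post_init__(self) -> None:
        if self.exon_count < 1:
            raise SpecError("exon_count must be >= 1")
        if self.intron_len_range[0] < 25:
            raise SpecError("minimum intron length must be >= 25")
        if self.exon_len_range[0] < 1 or self.exon_len_range[1] < self.exon_len_range[0]:
            raise SpecError("bad exon length range")
        if self.intron_len_range[1] < self.intron_len_range[0]:
            raise SpecError("bad intron length range")
        if not 0.0 <= self.mutation_rate <= 0.25:
            raise SpecError("mutation_rate must be in [0, 0.25]")
        if not 0.0 <= self.non_canonical_fraction <= 1.0:
            raise SpecError("non_canonical_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth serialized beside every generated fixture."""

    seed: int
    exons: tuple[tuple[int, int], ...] = ()
    introns: tuple[tuple[int, int], ...] = ()
    intron_canonical: tuple[bool, ...] = ()
    orf: tuple[int, int] | None = None  # on the cDNA, includes stop codon
    protein: str | None = None
    farm_start: int | None = None  # 0-based on the protein
    farm_form: str | None = None
    sarm_start: int | None = None
    upstream5: str | None = None
    upstream4: str | None = None
    expected_type: Literal["I", "II_III"] | None = None
    mutated_positions: tuple[int, ...] = ()

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("exons", "introns"):
            raw[key] = tuple(tuple(x) for x in raw[key])
        raw["intron_canonical"] = tuple(raw["intron_canonical"])
        raw["mutated_positions"] = tuple(raw["mutated_positions"])
        if raw.get("orf") is not None:
            raw["orf"] = tuple(raw["orf"])
        return cls(**raw)


def generate_protein_with_cld(
    plant: Literal["type_I", "type_II_III"], length: int, seed: int
) -> tuple[ProtRecord, SyntheticTruth]:
    """A random protein with a planted FARM/SARM pair and typed CLD.

    Background residues never include D, so the planted motifs are the only
    aspartate-rich matches; the FARM sits in the N-terminal 60%, the SARM
    90-200 residues downstream in the C-terminal 60%.
    """
    if length < 150:
        raise SpecError("protein length must be >= 150 to host FARM and SARM")
    if plant not in ("type_I", "type_II_III"):
        raise SpecError(f"unknown motif plant {plant!r}")
    rng = random.Random(seed)

    farm_len = 5 if plant == "type_I" else 7
    farm_hi = min(int(length * 0.6) - farm_len, length - 6 - 90)
    if farm_hi < 10:
        raise SpecError(f"length {length} too small to place motifs")
    farm_start = rng.randint(10, farm_hi)
    dist_lo = max(90, -(-(length * 2) // 5) - farm_start)  # SARM in C-terminal 60%
    dist_hi = min(200, length - 5 - farm_start)
    if dist_hi < dist_lo:
        raise SpecError(f"length {length}: no valid FARM-SARM distance")
    sarm_start = farm_start + rng.randint(dist_lo, dist_hi)

    res = [rng.choice(BACKGROUND_AA) for _ in range(length)]
    xs = lambda k: [rng.choice(BACKGROUND_AA) for _ in range(k)]
    farm = ["D", "D", *xs(farm_len - 3), "D"]
    res[farm_start : farm_start + farm_len] = farm
    res[sarm_start : sarm_start + 5] = ["D", "D", *xs(2), "D"]
    u5 = rng.choice(AROMATIC if plant == "type_I" else SMALL_NONAROMATIC)
    u4 = rng.choice(SMALL_NONAROMATIC)
    res[farm_start - 5] = u5
    res[farm_start - 4] = u4

    seq = "".join(res)
    protein = ProtRecord(id=f"synthetic_{plant}_{seed}", seq=seq,
                         description=f"synthetic protein, planted {plant} CLD")
    truth = SyntheticTruth(
        seed=seed,
        protein=seq,
        farm_start=farm_start,
        farm_form="DDxxD" if plant == "type_I" else "DDxxxxD",
        sarm_start=sarm_start,
        upstream5=u5,
        upstream4=u4,
        expected_type="I" if plant == "type_I" else "II_III",
    )
    return protein, truth


_CODON_TABLE = unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_CODON_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)
_STOPS = sorted(_CODON_TABLE.stop_codons)


def _reverse_translate(protein: str, rng: random.Random) -> str:
    return "".join(rng.choice(_CODONS_FOR[aa]) for aa in protein) + rng.choice(_STOPS)


def _random_utr(rng: random.Random, length: int) -> str:
    while True:
        utr = "".join(rng.choice(NUCS) for _ in range(length))
        if "ATG" not in utr:
            return utr


def _make_intron(rng: random.Random, length: int, canonical: bool) -> str:
    interior = "".join(rng.choice(NUCS) for _ in range(length - 4))
    return ("GT" + interior + "AG") if canonical else ("CT" + interior + "AC")


def _left_shift_ambiguous(g: str, s: int, e: int, max_d: int = 12) -> bool:
    """True when a score-preserving left shift of intron [s, e) is canonical.

    Such a placement would (correctly) win the refiner's leftmost-donor
    tie-break, making exact recovery of the planted coordinates ill-posed.
    """
    for d in range(1, max_d + 1):
        if s - d < 1 or any(g[s - k] != g[e - k] for k in range(1, d + 1)):
            return False
        if g[s - d : s - d + 2] == "GT" and g[e - d - 2 : e - d] == "AG":
            return True
    return False


def generate_gene(spec: GeneSpec) -> tuple[NucRecord, NucRecord, SyntheticTruth]:
    """Generate (genomic, cDNA, truth) for one synthetic multi-exon gene.

    The cDNA is the concatenation of the exons before mutation; point
    substitutions (and, in stress mode, single-base indels) are applied only
    to the exon copies inside the genomic sequence.
    """
    rng = random.Random(spec.seed)
    for _ in range(30):
        result = _try_generate(spec, rng)
        if result is not None:
            return result
    raise SpecError(f"could not generate a consistent fixture for {spec}")


def _try_generate(
    spec: GeneSpec, rng: random.Random
) -> tuple[NucRecord, NucRecord, SyntheticTruth] | None:
    from .protein_props import OrfError, find_orf  # local import: no cycle at module load

    exon_lens = [rng.randint(*spec.exon_len_range) for _ in range(spec.exon_count)]
    total = sum(exon_lens)

    if spec.motif_plant == "none":
        cdna_seq = "".join(rng.choice(NUCS) for _ in range(total))
        orf = None
        ptruth = SyntheticTruth(seed=spec.seed)
    else:
        utr5_len = rng.randint(12, 30)
        utr3_len = rng.randint(12, 30)
        coding = total - utr5_len - utr3_len
        aa_len = coding // 3 - 1
        if aa_len < 150:
            raise SpecError(
                f"exons too short to host a planted ORF (total {total} nt, "
                f"{aa_len} residues)"
            )
        utr3_len += coding - 3 * (aa_len + 1)
        protein, ptruth = generate_protein_with_cld(
            spec.motif_plant, aa_len, seed=rng.randrange(2**31)
        )
        if not protein.seq.startswith("M"):
            # the ORF must be ATG-initiated
            seq = "M" + protein.seq[1:]
            protein = ProtRecord(id=protein.id, seq=seq, description=protein.description)
            ptruth = dataclasses.replace(ptruth, protein=seq)
        cdna_seq = (
            _random_utr(rng, utr5_len)
            + _reverse_translate(protein.seq, rng)
            + _random_utr(rng, utr3_len)
        )
        orf = (utr5_len, utr5_len + 3 * (aa_len + 1))

    # Cut the cDNA into exons and interleave introns.
    exons: list[tuple[int, int]] = []
    introns: list[tuple[int, int]] = []
    canonical_flags: list[bool] = []
    pieces: list[str] = []
    gpos = 0
    cpos = 0
    for k, ln in enumerate(exon_lens):
        pieces.append(cdna_seq[cpos : cpos + ln])
        exons.append((gpos, gpos + ln))
        gpos += ln
        cpos += ln
        if k < spec.exon_count - 1:
            ilen = rng.randint(*spec.intron_len_range)
            canonical = rng.random() >= spec.non_canonical_fraction
            for _ in range(20):
                intron = _make_intron(rng, ilen, canonical)
                g_so_far = "".join(pieces) + intron
                if not _left_shift_ambiguous(g_so_far, gpos, gpos + ilen):
                    break
            pieces.append(intron)
            introns.append((gpos, gpos + ilen))
            canonical_flags.append(canonical)
            gpos += ilen
    genomic_seq = "".join(pieces)

    # Point substitutions restricted to exon copies in the genomic sequence.
    mutated: list[int] = []
    if spec.mutation_rate > 0 or spec.indel_rate > 0:
        gl = list(genomic_seq)
        for s, e in exons:
            for i in range(s, e):
                if rng.random() < spec.mutation_rate:
                    gl[i] = rng.choice([b for b in NUCS if b != gl[i]])
                    mutated.append(i)
        if spec.indel_rate > 0:
            for s, e in reversed(exons):
                for i in range(e - 3, s + 2, -1):
                    if rng.random() < spec.indel_rate:
                        if rng.random() < 0.5:
                            gl.insert(i, rng.choice(NUCS))
                        else:
                            del gl[i]
        genomic_seq = "".join(gl)

    cdna = NucRecord(
        id=f"synthetic_cdna_{spec.seed}", seq=cdna_seq,
        description=f"synthetic cDNA, {spec.exon_count} exons",
    )
    genomic = NucRecord(
        id=f"synthetic_gene_{spec.seed}", seq=genomic_seq,
        description=f"synthetic genomic locus, {len(introns)} introns",
    )

    if orf is not None:
        try:
            call = find_orf(cdna)
        except OrfError:
            return None
        if (call.start, call.end) != orf:
            return None  # a chance competing ORF; resample

    truth = dataclasses.replace(
        ptruth,
        seed=spec.seed,
        exons=tuple(exons),
        introns=tuple(introns),
        intron_canonical=tuple(canonical_flags),
        orf=orf,
        mutated_positions=tuple(mutated),
    )
    return genomic, cdna, truth


def write_fixture(
    genomic: NucRecord, cdna: NucRecord, truth: SyntheticTruth, out_dir: str | Path,
    stem: str = "fixture",
) -> dict[str, Path]:
    """Write genomic FASTA, cDNA FASTA and truth JSON into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomic": out / f"{stem}.genomic.fasta",
        "cdna": out / f"{stem}.cdna.fasta",
        "truth": out / f"{stem}.truth.json",
    }
    write_fasta([genomic], paths["genomic"])
    write_fasta([cdna], paths["cdna"])
    truth.to_json(paths["truth"])
    return paths
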