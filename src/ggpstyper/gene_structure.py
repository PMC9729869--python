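"""Exon/intron inference by spliced alignment of a cDNA against its locus.

The alignment model is substitution-only and collinear: the cDNA is cut into
consecutive segments (exons), each placed contiguously on the genomic
forward strand, separated by genomic-only gaps (introns) of at least
``min_intron`` bases. The objective is

    matches * match_score
    - mismatches * mismatch_penalty
    - introns * intron_open_penalty
    + canonical_bonus per GT..AG intron

maximized over all exon chains covering the cDNA end to end.

Two solvers implement this objective:

* an anchored solver (default): exact k-mer matches between cDNA and genome
  are chained collinearly and each inter-anchor junction is resolved by
  scanning every possible splice placement on the two flanking diagonals;
  ambiguous regions fall back to the exact solver on the sub-problem;
* an exact two-state dynamic program over (genomic position, cDNA position)
  with exon and intron states, used directly for small inputs, as the
  fallback, and as the oracle the anchored solver is tested against.

``refine_boundaries`` then slides each intron through the score-preserving
shifts allowed by junction-flanking repeats, preferring GT..AG placements
and, among equals, the leftmost donor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .seq_io import NucRecord

NEG_INF = float(-1e18)


class SplicedAlignError(RuntimeError):
    """No spliced mapping at the required identity."""


@dataclass(frozen=True)
class AlignParams:
    """Scoring and search parameters for the spliced aligner.

    Defaults strongly prefer fewer, canonical introns; ``min_intron`` = 20 is
    below any plausible fungal intron yet blocks spurious micro-introns.
    """

    match_score: float = 1.0
    mismatch_penalty: float = 2.0
    intron_open_penalty: float = 8.0
    canonical_bonus: float = 4.0
    min_intron: int = 20
    min_identity: float = 0.95
    anchor_k: int = 12
    # Combined length at or below which the exact DP runs directly.
    dp_direct_len: int = 2000
    # Largest (len(genomic) * len(cdna)) for which the exact DP may run.
    dp_max_cells: int = 8_000_000


@dataclass(frozen=True)
class GeneModel:
    """Ordered exon intervals of a cDNA on its genomic sequence.

    Intervals are 0-based half-open; introns are exactly the gaps between
    consecutive exons. ``identity`` is the fraction of cDNA bases matching
    their aligned genomic base; ``score`` is the objective value.
    """

    genomic_id: str
    cdna_id: str
    exons: tuple[tuple[int, int], ...]
    identity: float
    score: float

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("a gene model needs at least one exon")
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError(f"empty exon interval [{s}, {e})")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 <= e0:
                raise ValueError("exons must be strictly increasing and disjoint")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    def spliced_sequence(self, genomic: NucRecord) -> str:
        return "".join(genomic.seq[s:e] for s, e in self.exons)


@dataclass(frozen=True)
class IntronAudit:
    interval: tuple[int, int]
    donor: str
    acceptor: str

    @property
    def canonical(self) -> bool:
        return self.donor == "GT" and self.acceptor == "AG"


@dataclass(frozen=True)
class SpliceAudit:
    introns: tuple[IntronAudit, ...] = field(default_factory=tuple)

    @property
    def all_canonical(self) -> bool:
        return all(i.canonical for i in self.introns)


def _score_model(
    exons: Sequence[tuple[int, int]], g: str, c: str, params: AlignParams
) -> tuple[float, float]:
    """(score, identity) of an exon chain under the objective."""
    matches = 0
    j = 0
    for s, e in exons:
        seg = g[s:e]
        matches += sum(a == b for a, b in zip(seg, c[j : j + len(seg)]))
        j += len(seg)
    mismatches = len(c) - matches
    score = matches * params.match_score - mismatches * params.mismatch_penalty
    for (_, e0), (s1, _) in zip(exons, list(exons)[1:]):
        score -= params.intron_open_penalty
        if g[e0 : e0 + 2] == "GT" and g[s1 - 2 : s1] == "AG":
            score += params.canonical_bonus
    return score, matches / len(c)


# ---------------------------------------------------------------------------
# exact two-state dynamic program
# ---------------------------------------------------------------------------

def spliced_align_dp(
    cdna: NucRecord, genomic: NucRecord, params: AlignParams | None = None
) -> GeneModel:
    """Exact solver: optimal exon chain by dynamic programming.

    O(n*m) time with numpy-vectorized cDNA axis; O(n*m) memory for the
    traceback. Use for small inputs or as the oracle/fallback.
    """
    params = params or AlignParams()
    g, c = genomic.seq, cdna.seq
    n, m = len(g), len(c)
    if m > n:
        raise ValueError("cDNA longer than genomic sequence")
    if n * m > params.dp_max_cells:
        raise SplicedAlignError(
            f"DP problem too large ({n} x {m}); use align_spliced"
        )

    garr = np.frombuffer(g.encode(), dtype=np.uint8)
    carr = np.frombuffer(c.encode(), dtype=np.uint8)
    match = params.match_score
    mis = -params.mismatch_penalty
    open_pen = params.intron_open_penalty
    bonus = params.canonical_bonus
    mi = params.min_intron

    # E[i, j]: best score with cDNA prefix j whose last base sits at genomic
    # row i (rows 1-based). Jumps (introns) land from any row r <= i-1-mi.
    E = np.full((n + 1, m + 1), NEG_INF)
    choice = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 jump, 2 GT jump
    jump_src = np.zeros((n + 1, m + 1), dtype=np.int32)

    amax = np.full(m + 1, NEG_INF)  # best E[r, j] over eligible rows r
    aarg = np.zeros(m + 1, dtype=np.int32)
    gmax = np.full(m + 1, NEG_INF)  # same, restricted to donor-GT rows
    garg = np.zeros(m + 1, dtype=np.int32)

    donor_gt = np.zeros(n + 1, dtype=bool)  # row r: intron starting at 0-based r
    donor_gt[: n - 1] = (garr[:-1] == ord("G")) & (garr[1:] == ord("T"))
    accept_ag = np.zeros(n + 1, dtype=bool)  # acceptor for row i is g[i-3], g[i-2]
    if n >= 3:
        rows = np.arange(3, n + 1)
        accept_ag[rows] = (garr[rows - 3] == ord("A")) & (garr[rows - 2] == ord("G"))

    js = np.arange(1, m + 1)
    for i in range(1, n + 1):
        r = i - 1 - mi
        if r >= 1:
            upd = E[r, :] > amax
            amax[upd] = E[r, upd]
            aarg[upd] = r
            if donor_gt[r]:
                updg = E[r, :] > gmax
                gmax[updg] = E[r, updg]
                garg[updg] = r
        s_row = np.where(garr[i - 1] == carr, match, mis)  # length m, index j-1
        diag = E[i - 1, 0:m]  # E[i-1, j-1] for j=1..m
        best = diag.copy()
        ch = np.zeros(m, dtype=np.int8)
        src = np.zeros(m, dtype=np.int32)
        jump = amax[0:m] - open_pen
        take = jump > best
        best[take] = jump[take]
        ch[take] = 1
        src[take] = aarg[0:m][take]
        if accept_ag[i]:
            jump_g = gmax[0:m] - open_pen + bonus
            takeg = jump_g > best
            best[takeg] = jump_g[takeg]
            ch[takeg] = 2
            src[takeg] = garg[0:m][takeg]
        best[0] = 0.0  # first cDNA base opens the first exon anywhere
        ch[0] = 0
        E[i, js] = s_row + best
        choice[i, js] = ch
        jump_src[i, js] = src

    i_best = int(np.argmax(E[:, m]))
    if E[i_best, m] <= NEG_INF / 2:
        raise SplicedAlignError("no spliced mapping found")

    # Traceback into exon intervals.
    introns: list[tuple[int, int]] = []
    i, j = i_best, m
    while j > 1:
        if choice[i, j] == 0:
            i, j = i - 1, j - 1
        else:
            r = int(jump_src[i, j])
            introns.append((r, i - 1))  # 0-based half-open genomic interval
            i, j = r, j - 1
    first_exon_start = i - 1  # 0-based genomic position of cDNA base 0
    introns.reverse()
    exons: list[tuple[int, int]] = []
    start = first_exon_start
    for (ist, ien) in introns:
        exons.append((start, ist))
        start = ien
    exons.append((start, i_best))

    score, identity = _score_model(exons, g, c, params)
    model = GeneModel(
        genomic_id=genomic.id,
        cdna_id=cdna.id,
        exons=tuple(exons),
        identity=identity,
        score=score,
    )
    if identity < params.min_identity:
        raise SplicedAlignError(
            f"no spliced mapping at identity >= {params.min_identity} "
            f"(best {identity:.3f})"
        )
    return model


# ---------------------------------------------------------------------------
# anchored solver
# ---------------------------------------------------------------------------

def _find_anchors(c: str, g: str, k: int, max_occ: int = 50) -> list[tuple[int, int, int]]:
    """Maximal exact matches >= k as (j_start, i_start, length) tuples."""
    index: dict[str, list[int]] = {}
    for i in range(len(g) - k + 1):
        index.setdefault(g[i : i + k], []).append(i)
    by_diag: dict[int, list[int]] = {}
    for j in range(len(c) - k + 1):
        hits = index.get(c[j : j + k])
        if hits and len(hits) <= max_occ:
            for i in hits:
                by_diag.setdefault(i - j, []).append(j)
    anchors: list[tuple[int, int, int]] = []
    for d, jlist in by_diag.items():
        jlist.sort()
        run_start = prev = jlist[0]
        for j in jlist[1:] + [None]:  # type: ignore[list-item]
            if j is not None and j == prev + 1:
                prev = j
                continue
            anchors.append((run_start, run_start + d, prev - run_start + k))
            if j is not None:
                run_start = prev = j
    anchors.sort()
    return anchors


def _chain_anchors(
    anchors: list[tuple[int, int, int]], params: AlignParams
) -> list[tuple[int, int, int]]:
    """Best collinear chain (same diagonal or intron-sized forward jumps)."""
    A = len(anchors)
    val = [float(a[2]) for a in anchors]
    prev = [-1] * A
    for b in range(A):
        jb, ib, lb = anchors[b]
        db = ib - jb
        for a in range(b):
            ja, ia, la = anchors[a]
            da = ia - ja
            if jb < ja:
                continue
            if db != da and db - da < params.min_intron:
                continue
            if db < da:
                continue
            overlap = max(0, ja + la - jb)
            add = lb - overlap
            if add <= 0:
                continue
            cand = val[a] + add - (params.intron_open_penalty if db != da else 0.0)
            if cand > val[b]:
                val[b] = cand
                prev[b] = a
    if A == 0:
        return []
    best = max(range(A), key=lambda x: val[x])
    chain = []
    while best != -1:
        chain.append(anchors[best])
        best = prev[best]
    chain.reverse()
    return chain


def _merge_segments(chain: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Collapse same-diagonal anchors to (diag, j_start, j_end) segments."""
    segs: list[tuple[int, int, int]] = []
    for j, i, ln in chain:
        d = i - j
        if segs and segs[-1][0] == d:
            segs[-1] = (d, segs[-1][1], max(segs[-1][2], j + ln))
        else:
            segs.append((d, j, j + ln))
    return segs


def _prefix_scores(c: str, g: str, d: int, lo: int, hi: int, params: AlignParams) -> np.ndarray:
    """Prefix sums of per-base score of c[j] vs g[j+d] for j in [lo, hi)."""
    out = np.zeros(hi - lo + 1)
    acc = 0.0
    for idx, j in enumerate(range(lo, hi)):
        gi = j + d
        if 0 <= gi < len(g) and c[j] == g[gi]:
            acc += params.match_score
        else:
            acc -= params.mismatch_penalty
        out[idx + 1] = acc
    return out


def _resolve_junction(
    c: str,
    g: str,
    seg_a: tuple[int, int, int],
    seg_b: tuple[int, int, int],
    params: AlignParams,
    pad: int = 12,
) -> tuple[int, float]:
    """Best cDNA split s between two segments on different diagonals.

    Returns (s, window_score): exon A covers cDNA [.., s) on diag dA, exon B
    covers [s, ..) on diag dB; the intron is [s+dA, s+dB), its length fixed
    at dB-dA. Ties prefer the canonical and then the leftmost donor.
    """
    dA, jA0, jA1 = seg_a
    dB, jB0, jB1 = seg_b
    lo = max(jA0 + 1, jA1 - pad, 1)
    hi = min(jB1 - 1, jB0 + pad, len(c) - 1)
    if hi < lo:
        lo = hi = max(1, min(len(c) - 1, jA1))
    pa = _prefix_scores(c, g, dA, lo, hi, params)
    pb = _prefix_scores(c, g, dB, lo, hi, params)
    best_s, best_val = lo, NEG_INF
    for s in range(lo, hi + 1):
        k = s - lo
        val = pa[k] + (pb[-1] - pb[k])
        if g[s + dA : s + dA + 2] == "GT" and g[s + dB - 2 : s + dB] == "AG":
            val += params.canonical_bonus
        if val > best_val:  # strict: keeps the leftmost donor on ties
            best_val, best_s = val, s
    return best_s, float(best_val)


def _window_mismatches(c: str, g: str, exons: list[tuple[int, int]]) -> int:
    j = 0
    mism = 0
    for s, e in exons:
        for off in range(e - s):
            if c[j + off] != g[s + off]:
                mism += 1
        j += e - s
    return mism


def align_spliced(
    cdna: NucRecord, genomic: NucRecord, params: AlignParams | None = None
) -> GeneModel:
    """Infer the exon chain of ``cdna`` on ``genomic``.

    Anchored chaining with per-junction splice placement; ambiguous or
    unanchored regions are re-solved with the exact DP, and the whole
    problem falls back to the DP when chaining cannot reach
    ``min_identity`` and the problem is small enough.
    """
    params = params or AlignParams()
    g, c = genomic.seq, cdna.seq
    n, m = len(g), len(c)
    if m == 0 or n == 0:
        raise ValueError("empty sequence")
    if m > n:
        raise ValueError("cDNA longer than genomic sequence")
    if n + m <= params.dp_direct_len:
        return spliced_align_dp(cdna, genomic, params)

    def dp_fallback(err: str) -> GeneModel:
        if n * m <= params.dp_max_cells:
            return spliced_align_dp(cdna, genomic, params)
        raise SplicedAlignError(err)

    anchors = _find_anchors(c, g, params.anchor_k)
    if not anchors:
        return dp_fallback("no anchors and problem too large for exact DP")
    segs = _merge_segments(_chain_anchors(anchors, params))

    # Extend the terminal segments to the cDNA ends along their diagonals.
    d0 = segs[0][0]
    if 0 + d0 < 0:
        return dp_fallback("cDNA head extends past genomic start")
    segs[0] = (d0, 0, segs[0][2])
    dl = segs[-1][0]
    if m + dl > n:
        return dp_fallback("cDNA tail extends past genomic end")
    segs[-1] = (dl, segs[-1][1], m)

    # Resolve each junction to a precise splice placement.
    cuts: list[int] = [0]
    for a, b in zip(segs, segs[1:]):
        s, _ = _resolve_junction(c, g, a, b, params)
        cuts.append(s)
    cuts.append(m)
    exons: list[tuple[int, int]] = []
    ok = True
    for (d, _, _), ja, jb in zip(segs, cuts, cuts[1:]):
        if jb <= ja:
            ok = False
            break
        exons.append((ja + d, jb + d))
    if ok:
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 - e0 < params.min_intron:
                ok = False
                break
    if not ok:
        return dp_fallback("inconsistent anchor chain")

    # Re-solve locally where the placed chain leaves a dense mismatch patch
    # (e.g. a short exon with no anchor swallowed into an intron).
    exons = _patch_bad_regions(c, g, exons, params)

    score, identity = _score_model(exons, g, c, params)
    if identity < params.min_identity:
        try:
            return dp_fallback(
                f"no spliced mapping at identity >= {params.min_identity}"
            )
        except SplicedAlignError:
            raise SplicedAlignError(
                f"no spliced mapping at identity >= {params.min_identity} "
                f"(best {identity:.3f})"
            ) from None
    return GeneModel(
        genomic_id=genomic.id,
        cdna_id=cdna.id,
        exons=tuple(exons),
        identity=identity,
        score=score,
    )


def _patch_bad_regions(
    c: str, g: str, exons: list[tuple[int, int]], params: AlignParams
) -> list[tuple[int, int]]:
    """Re-run the exact DP across junctions whose flanks mismatch heavily."""
    out = list(exons)
    changed = True
    guard = 0
    while changed and guard < 10:
        changed = False
        guard += 1
        cum = [0]
        for s, e in out:
            cum.append(cum[-1] + (e - s))
        for idx in range(len(out) - 1):
            (s0, e0), (s1, e1) = out[idx], out[idx + 1]
            wa = min(30, e0 - s0)
            wb = min(30, e1 - s1)
            mism = _window_mismatches(
                c[cum[idx + 1] - wa : cum[idx + 1] + wb],
                g,
                [(e0 - wa, e0), (s1, s1 + wb)],
            )
            if mism <= max(2, int(0.15 * (wa + wb))):
                continue
            # sub-problem: cDNA window against the genomic span it must occupy
            ja = cum[idx + 1] - wa
            jb = cum[idx + 1] + wb
            ga, gb = e0 - wa, s1 + wb
            if (gb - ga) * (jb - ja) > params.dp_max_cells:
                continue
            try:
                sub = spliced_align_dp(
                    NucRecord(id="sub_c", seq=c[ja:jb]),
                    NucRecord(id="sub_g", seq=g[ga:gb]),
                    replace(params, min_identity=0.0),
                )
            except (SplicedAlignError, ValueError):
                continue
            sub_exons = [(s + ga, e + ga) for s, e in sub.exons]
            if sub_exons[0][0] != ga or sub_exons[-1][1] != gb:
                continue  # sub-alignment must tile the window exactly
            new = out[:idx] + _splice_in(out[idx], out[idx + 1], wa, wb, sub_exons) + out[idx + 2 :]
            cand_score, _ = _score_model(new, g, c, params)
            cur_score, _ = _score_model(out, g, c, params)
            if cand_score > cur_score:
                out = new
                changed = True
                break
    return out


def _splice_in(
    exon_a: tuple[int, int],
    exon_b: tuple[int, int],
    wa: int,
    wb: int,
    sub_exons: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Stitch a locally re-solved exon set back between two flank exons."""
    merged: list[tuple[int, int]] = []
    head = (exon_a[0], exon_a[1] - wa)
    tail = (exon_b[0] + wb, exon_b[1])
    pieces = sub_exons[:]
    if head[1] > head[0]:
        if pieces and pieces[0][0] == head[1]:
            pieces[0] = (head[0], pieces[0][1])
        else:
            merged.append(head)
    merged.extend(pieces)
    if tail[1] > tail[0]:
        if merged and merged[-1][1] == tail[0]:
            merged[-1] = (merged[-1][0], tail[1])
        else:
            merged.append(tail)
    return merged


# ---------------------------------------------------------------------------
# boundary refinement and splice auditing
# ---------------------------------------------------------------------------

def refine_boundaries(
    model: GeneModel, genomic: NucRecord, cdna: NucRecord, params: AlignParams | None = None
) -> GeneModel:
    """Slide introns through score-preserving shifts to canonical placements.

    A shift by d is score-preserving when the bases entering one exon equal
    the bases leaving the other (junction-flanking repeat), so the spliced
    sequence — hence matches and mismatches — is unchanged. Among all such
    placements the one scoring highest (canonical bonus) wins; ties go to
    the leftmost donor. The score never decreases.
    """
    params = params or AlignParams()
    g = genomic.seq
    exons = list(model.exons)
    for k in range(len(exons) - 1):
        s, e = exons[k][1], exons[k + 1][0]
        # Maximal valid shift ranges limited by flanking repeats and exon size.
        max_left = 0
        while (
            s - max_left - 1 >= exons[k][0] + 1
            and g[s - max_left - 1] == g[e - max_left - 1]
        ):
            max_left += 1
        max_right = 0
        while (
            e + max_right < exons[k + 1][1] - 1
            and s + max_right < len(g)
            and g[s + max_right] == g[e + max_right]
        ):
            max_right += 1
        canonical_ds = [
            d
            for d in range(-max_left, max_right + 1)
            if g[s + d : s + d + 2] == "GT" and g[e + d - 2 : e + d] == "AG"
        ]
        # Move only toward a canonical placement; among canonical placements
        # the leftmost donor wins. Without any canonical option, stay put.
        best_d = min(canonical_ds) if canonical_ds else 0
        if best_d:
            exons[k] = (exons[k][0], s + best_d)
            exons[k + 1] = (e + best_d, exons[k + 1][1])
    score, identity = _score_model(exons, g, cdna.seq, params)
    return GeneModel(
        genomic_id=model.genomic_id,
        cdna_id=model.cdna_id,
        exons=tuple(exons),
        identity=identity,
        score=score,
    )


def audit_splice_sites(model: GeneModel, genomic: NucRecord) -> SpliceAudit:
    """Report donor/acceptor dinucleotides and GT-AG flags for each intron."""
    audits = []
    for s, e in model.introns:
        if s < 0 or e > len(genomic) or e - s < 4:
            raise ValueError(f"intron [{s}, {e}) out of bounds or shorter than 4 nt")
        audits.append(
            IntronAudit(interval=(s, e), donor=genomic.seq[s : s + 2], acceptor=genomic.seq[e - 2 : e])
        )
    return SpliceAudit(introns=tuple(audits))
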