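"""Independent oracles used by the test suite.

These deliberately re-derive results by brute force (exhaustive enumeration,
dense grid search, quadratic scans) and share no code with the package paths
they check.
"""

from __future__ import annotations

import itertools
import re

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orf(seq: str) -> tuple[int, int] | None:
    """Longest ATG..stop interval by scanning every (start, end) pair."""
    best: tuple[int, int] | None = None
    n = len(seq)
    for start in range(n - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for end in range(start + 6, n + 1, 3):
            codon = seq[end - 3 : end]
            if codon in STOPS:
                if best is None or end - start > best[1] - best[0]:
                    best = (start, end)
                break
    return best


def grid_isoelectric_point(
    seq: str, pka: dict, nterm_pka: dict, cterm_pka: dict | None = None, step: float = 1e-4
) -> float:
    """pH grid point with the smallest |net charge| (vectorized dense grid)."""
    cterm_pka = cterm_pka or {}
    ph = np.arange(0.0, 14.0 + step, step)
    charge = np.zeros_like(ph)
    charge += 1.0 / (1.0 + 10.0 ** (ph - nterm_pka.get(seq[0], pka["Nterm"])))
    charge -= 1.0 / (1.0 + 10.0 ** (cterm_pka.get(seq[-1], pka["Cterm"]) - ph))
    for aa in "HKR":
        charge += seq.count(aa) / (1.0 + 10.0 ** (ph - pka[aa]))
    for aa in "DECY":
        charge -= seq.count(aa) / (1.0 + 10.0 ** (pka[aa] - ph))
    return float(ph[np.argmin(np.abs(charge))])


def brute_force_motifs(seq: str) -> list[tuple[str, int, str]]:
    """Re-derive the FARM/SARM selection rule from regex-everywhere matches.

    Returns [] or [("FARM", start, pattern), ("SARM", start, pattern)].
    """
    n_limit = int(len(seq) * 0.6)
    c_start = len(seq) - n_limit
    farms = []
    for m in re.finditer(r"(?=(DD..D))", seq):
        if m.start() < n_limit:
            farms.append((m.start(), m.start() + 5, m.group(1), "DDxxD"))
    for m in re.finditer(r"(?=(DD....D))", seq):
        if m.start() < n_limit:
            farms.append((m.start(), m.start() + 7, m.group(1), "DDxxxxD"))
    farms.sort(key=lambda f: (f[0], f[1]))
    sarms = [
        (m.start(), m.group(1))
        for m in re.finditer(r"(?=(DD..D))", seq)
        if m.start() >= c_start
    ]
    for fs, fe, fpat, _form in farms:
        ok = [s for s in sarms if 80 <= s[0] - fs <= 250]
        if ok:
            best = max(ok, key=lambda s: s[0])
            return [("FARM", fs, fpat), ("SARM", best[0], best[1])]
    return []


def enumerate_exon_chains(
    c: str,
    g: str,
    min_intron: int,
    max_introns: int = 2,
    match: float = 1.0,
    mismatch: float = 2.0,
    intron_open: float = 8.0,
    bonus: float = 4.0,
) -> float:
    """Optimal spliced-alignment score by exhaustive chain enumeration.

    Every way of cutting the cDNA into up to ``max_introns``+1 segments and
    placing them collinearly on the genome with intron-sized gaps is scored.
    Only feasible for tiny inputs.
    """
    m, n = len(c), len(g)

    def seg_score(j0: int, j1: int, i0: int) -> float:
        sc = 0.0
        for off in range(j1 - j0):
            sc += match if c[j0 + off] == g[i0 + off] else -mismatch
        return sc

    best = -np.inf
    for t in range(0, max_introns + 1):
        for splits in itertools.combinations(range(1, m), t):
            bounds = (0, *splits, m)
            seg_lens = [bounds[k + 1] - bounds[k] for k in range(t + 1)]
            slack = n - m - t * min_intron
            if slack < 0:
                continue
            for extras in _compositions(slack, t + 1):
                i0 = extras[0]
                intron_lens = [min_intron + e for e in extras[1:]]
                sc = 0.0
                gpos = i0
                for k in range(t + 1):
                    sc += seg_score(bounds[k], bounds[k + 1], gpos)
                    gpos += seg_lens[k]
                    if k < t:
                        il = intron_lens[k]
                        sc -= intron_open
                        if g[gpos : gpos + 2] == "GT" and g[gpos + il - 2 : gpos + il] == "AG":
                            sc += bonus
                        gpos += il
                if sc > best:
                    best = sc
    return best


def _compositions(total: int, parts: int):
    """All tuples of ``parts`` non-negative ints summing to <= total.

    First element is the genomic start offset; the rest are intron length
    extras, so trailing genomic slack is implicit.
    """
    if parts == 1:
        for a in range(total + 1):
            yield (a,)
        return
    for a in range(total + 1):
        for rest in _compositions(total - a, parts - 1):
            yield (a, *rest)
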