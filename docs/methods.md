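# Methods

## Scope and coordinate conventions

The package characterizes a single-isoform, forward-strand gene from its
cDNA and (optionally) its genomic locus. Internally all intervals are
0-based half-open; every serialized output (GFF3, the JSON report) is
1-based inclusive, so reported residue numbers line up with published
protein numbering. Reverse-strand mapping, multi-isoform alignment and
polyA handling are out of scope.

## Spliced alignment

### Objective

An alignment is an *exon chain*: the cDNA cut into consecutive segments,
each placed contiguously and collinearly on the genome, separated by
genomic-only gaps (introns). The model is substitution-only — no indels
within exons — which matches the intended regime of a cDNA aligned back
to its own locus at ≥ 95% identity. The score is

    matches · match_score
  − mismatches · mismatch_penalty
  − introns · intron_open_penalty
  + canonical_bonus for each intron beginning GT and ending AG

with defaults `match_score = 1`, `mismatch_penalty = 2`,
`intron_open_penalty = 8`, `canonical_bonus = 4`, `min_intron = 20`,
`min_identity = 0.95`. Rationale: an intron must never be cheaper than a
short run of mismatches (8 − 4 = 4 net, i.e. more than one mismatch, less
than two — enough to forbid gratuitous micro-introns while still allowing
a canonical intron to beat two junction-adjacent mismatches);
`min_intron = 20` is below any plausible spliceosomal intron yet blocks
degenerate 1–2 nt "introns"; `min_identity` guards against accepting an
alignment of the wrong transcript. No biological consensus beyond the
GT/AG dinucleotides is modeled (no branch point, no GC-AG class).

### Solvers

*Exact DP.* A two-state dynamic program over (genomic row, cDNA column):
stay in the exon state diagonally, or enter an intron of length ≥
`min_intron` (a row jump), with the canonical bonus applied when the jump
leaves after a GT and lands after an AG. Running maxima over eligible
source rows (one unrestricted, one restricted to GT donors) make it
O(n·m) time. It is used directly whenever `len(genomic) + len(cdna) ≤
dp_direct_len` (default 2,000 nt), as the fallback for larger inputs, and
as the oracle the anchored solver is tested against.

*Anchored solver.* For larger inputs: exact k-mer matches (default
`anchor_k = 12`) are merged into maximal ungapped anchors, chained by a
collinearity DP (same diagonal, or a forward diagonal jump ≥
`min_intron`), and each junction between chained segments is resolved by
scanning every split of the inter-anchor cDNA window across the two
flanking diagonals, scoring mismatches plus the canonical bonus; ties
prefer the leftmost donor. Junctions whose resolved flanks remain
mismatch-dense (e.g. a short exon with no anchor swallowed by an intron
call) are re-solved by running the exact DP on the local window and
stitching the result back in; if the final chain still falls short of
`min_identity` the whole problem falls back to the exact DP when it fits
within `dp_max_cells`.

### Boundary refinement

When the junction flanks repeat, several intron placements splice to the
same cDNA and tie on score; `refine_boundaries` enumerates the
score-preserving shift range of each intron (bases entering one exon must
equal the bases leaving the other), and moves the intron only if a GT..AG
placement exists, choosing the leftmost donor among canonical ties. The
score therefore never decreases, and an already-canonical intron with no
canonical alternative is a fixed point.

## ORF and protein properties

`find_orf` returns the longest ATG-initiated, stop-terminated
forward-strand ORF (ties to the smallest start); this is the standard
policy for a complete mRNA clone and the only one the package implements.
Translation uses the standard genetic code; ambiguous bases inside the
ORF are an error rather than silently translated.

Molecular mass is the sum of average (isotope-weighted) residue masses
plus one water (18.01524 Da) — the convention of the common web property
calculators, so values are comparable with published predictions.

Net charge at a given pH is the Henderson–Hasselbalch sum over the
N-terminus, the C-terminus and the D, E, C, Y, H, K, R side chains. The
pKa set is Bjellqvist's, including its residue-specific N-terminal values
(A, M, S, P, T, V, E) and C-terminal values (D, E); the tables are plain
dicts and can be overridden per call. Because each term is strictly
decreasing in pH the zero is unique; bisection on [0, 14] to |charge| <
1e-4 finds it, and the suite checks it against an independent 1e-4-step
grid search (agreement within ±0.01 over 100 random proteins) and
against Biopython's implementation of the same model. The report rounds
mass to 2 dp kDa and pI to 2 dp; full precision is kept internally.

## Motif scan, CLD and type call

The FARM is searched as `DD..D` or `DD....D` (regex, overlapping) in the
N-terminal 60% of the protein, the SARM as `DD..D` in the C-terminal 60%;
restricting the windows prevents swapped assignments on aspartate-rich
sequences. A FARM/SARM pair is accepted when the SARM starts 80–250
residues downstream of the FARM; the reported FARM is the most N-terminal
candidate with a compatible SARM (short form first on a shared start) and
the reported SARM the most C-terminal compatible match. The window
[80, 250] is a package decision: it comfortably brackets the motif
spacing of known short-chain prenyltransferases while rejecting adjacent
spurious matches.

The CLD is the FARM plus the five residues immediately upstream. The rule
stage of the type call treats "aromatic" as membership in {F, Y, W}: type
I requires the short FARM with an aromatic fifth and non-aromatic fourth
upstream residue; the long FARM with both positions non-aromatic yields
the joint candidate {II, III} — the rule cannot separate types II and III,
which share the same CLD signature — and the candidate is resolved to the
type of the highest-CLD-identity reference in a typed panel (identity
from a global alignment of the CLD strings). An empty panel with a
{II, III} candidate is an error, not a guess.

The bundled panel is **synthetic** (generated by this package's own
fixture generator, labelled as such in the file names and headers): it
exercises the machinery and the I-vs-{II,III} rule but carries no
biological information about the II/III split. For real classification
the user supplies a curated homolog panel (protein FASTA + id/type TSV).
Conserved domains other than the two motif-bearing ones are reported only
as "not assessed": they have no sequence-level definition to implement.

Residue correspondence between homologs uses Needleman–Wunsch global
alignment with BLOSUM62 and affine gaps (open 10, extend 1; Biopython's
`PairwiseAligner`); a requested reference position maps to its aligned
query position or to a gap.

## Synthetic fixtures

The gene generator emulates a compact fungal prenyltransferase locus:
nine exons of 60–200 nt and GT..AG introns of 40–110 nt by default
(≈ 1.1 kb mRNA in a ≈ 1.7 kb locus), uniform base composition, a single
ATG-initiated ORF covering most of the cDNA (UTRs are kept ATG-free so
the planted ORF is the unique longest), and a planted FARM/SARM pair of a
chosen type in the translation. Protein backgrounds exclude D entirely so
the planted motifs are the only aspartate-rich matches — the
100%-recovery checks need a noise-free truth. Point substitutions
(default 0, up to 2% in the recovery studies) are applied only to the
exon copies in the genomic sequence, so the cDNA remains the pre-mutation
exon concatenation; a single-base indel mode exists for stress testing
but is excluded from recovery guarantees. Two generator details keep
"exact planted recovery" well-posed: an intron is resampled if a
score-preserving left shift of it would also be canonical (the refiner's
leftmost-donor rule would otherwise move it, correctly, off the planted
coordinates), and a fixture is resampled if a chance competing ORF
outranks the planted one.

What passing on these fixtures does *not* show: tolerance to indels or
sequencing error inside exons, non-uniform composition, very short
(< 25 nt) introns, non-GT-AG splice classes, or biologically meaningful
II-vs-III discrimination (see the panel note above). Replicate counts in
the test suite and acceptance script (200 genes, 200 proteins, 100
pI/mass draws) were chosen as the smallest sizes at which the measured
rates are stable across seeds.

## Numerical and degenerate-input choices

- Alignment score ties: fewest introns first (the chain/DP prefers the
  diagonal over a jump on equal score), then leftmost donor.
- A cDNA longer than its genomic sequence is a precondition error; an
  alignment below `min_identity` raises rather than returning a bad model.
- `NucRecord`/`ProtRecord` validate at construction: nucleotides fold to
  uppercase with U→T; ambiguity codes (N in an ORF, X/B/Z/* in a protein)
  are rejected wherever a property computation would be undefined.
- Empty FASTA, duplicate ids, and GenBank records without an ORIGIN block
  are parse errors naming the offender; parsing never drops records.
- Reports are timestamp-free and echo every effective parameter, so
  reruns on identical inputs are byte-identical.

## Known limitations

- The aligner's optimum is the scoring optimum: with mutations clustered
  at a junction an alternative placement can genuinely outscore the
  planted one (observed ≈ 0.5% of 2%-mutation replicates), which bounds
  exact-recovery below 100% by construction, not by implementation error.
- Substitution-only exon model: genomic indels inside exons are not
  represented and will depress identity instead.
- The pI model is the uncorrected Bjellqvist charge sum; tools that add
  charged-neighbor corrections can differ in the second decimal for
  cysteine-rich termini.
- Type II vs III is only as good as the supplied panel; with the bundled
  synthetic panel the resolved label is arbitrary by design.
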