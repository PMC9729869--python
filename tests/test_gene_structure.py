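"""Spliced alignment, splice-site auditing and boundary refinement."""

import random

import pytest

from oracles import enumerate_exon_chains

from ggpstyper.gene_structure import (
    AlignParams,
    GeneModel,
    SplicedAlignError,
    align_spliced,
    audit_splice_sites,
    refine_boundaries,
    spliced_align_dp,
)
from ggpstyper.seq_io import NucRecord
from ggpstyper.synthetic_data import GeneSpec, generate_gene


def _nuc(seq, rid="s"):
    return NucRecord(id=rid, seq=seq)


def _random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestAlignSpliced:
    def test_identical_sequences_single_exon(self, rng):
        seq = _random_dna(rng, 180)
        model = align_spliced(_nuc(seq, "c"), _nuc(seq, "g"))
        assert model.exons == ((0, 180),)
        assert model.introns == ()
        assert model.identity == 1.0

    def test_two_exon_planted_intron(self, rng):
        e1, e2 = _random_dna(rng, 60), _random_dna(rng, 60)
        intron = "GT" + _random_dna(rng, 36) + "AG"
        genomic = _nuc(e1 + intron + e2, "g")
        cdna = _nuc(e1 + e2, "c")
        model = align_spliced(cdna, genomic)
        model = refine_boundaries(model, genomic, cdna)
        assert model.exons == ((0, 60), (100, 160))
        assert model.introns == ((60, 100),)

    def test_cdna_longer_than_genomic_is_precondition_error(self, rng):
        with pytest.raises(ValueError):
            align_spliced(_nuc(_random_dna(rng, 50)), _nuc(_random_dna(rng, 20)))

    def test_unmappable_cdna_raises(self, rng):
        cdna = _nuc(_random_dna(rng, 120), "c")
        genomic = _nuc(_random_dna(rng, 400), "g")
        with pytest.raises(SplicedAlignError, match="identity"):
            align_spliced(cdna, genomic)

    def test_spliced_sequence_reproduces_cdna_at_full_identity(self):
        for seed in range(5):
            g, c, t = generate_gene(GeneSpec(seed=seed, exon_count=4, motif_plant="none"))
            model = align_spliced(c, g)
            assert model.identity == 1.0
            assert model.spliced_sequence(g) == c.seq

    @pytest.mark.parametrize("mutation_rate", [0.0, 0.02])
    def test_planted_recovery_sample(self, mutation_rate):
        """Exact planted exon recovery on a small replicate sample."""
        hits = 0
        n = 25
        for seed in range(n):
            g, c, t = generate_gene(
                GeneSpec(seed=1000 + seed, exon_count=9, mutation_rate=mutation_rate)
            )
            model = refine_boundaries(align_spliced(c, g), g, c)
            hits += model.exons == t.exons
        assert hits == n

    def test_score_invariant_under_refinement(self):
        for seed in range(5):
            g, c, t = generate_gene(GeneSpec(seed=seed, exon_count=5, mutation_rate=0.01, motif_plant="none"))
            model = align_spliced(c, g)
            refined = refine_boundaries(model, g, c)
            assert refined.score == pytest.approx(model.score)


class TestDpOracle:
    """The exact DP against exhaustive enumeration of all exon chains."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_enumeration_on_planted_instances(self, seed):
        rng = random.Random(seed)
        params = AlignParams(min_intron=8, min_identity=0.0, dp_max_cells=10**6)
        e1, e2, e3 = (_random_dna(rng, k) for k in (10, 8, 9))
        i1 = "GT" + _random_dna(rng, 6) + "AG"
        i2 = "CT" + _random_dna(rng, 8) + "AC"
        g = _random_dna(rng, 4) + e1 + i1 + e2 + i2 + e3 + _random_dna(rng, 5)
        c = e1 + e2 + e3
        best = enumerate_exon_chains(c, g, min_intron=8, max_introns=2)
        model = spliced_align_dp(_nuc(c, "c"), _nuc(g, "g"), params)
        assert model.score == pytest.approx(best)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_enumeration_on_random_instances(self, seed):
        rng = random.Random(seed)
        params = AlignParams(min_intron=6, min_identity=0.0, dp_max_cells=10**6)
        c = _random_dna(rng, 12)
        g = _random_dna(rng, 50)
        best = enumerate_exon_chains(c, g, min_intron=6, max_introns=2)
        model = spliced_align_dp(_nuc(c, "c"), _nuc(g, "g"), params)
        assert model.score == pytest.approx(best)

    @pytest.mark.parametrize("seed", [20, 21, 22, 23])
    def test_anchored_solver_matches_dp_score(self, seed):
        g, c, t = generate_gene(
            GeneSpec(
                seed=seed,
                exon_count=3,
                exon_len_range=(40, 70),
                intron_len_range=(25, 45),
                mutation_rate=0.01,
                motif_plant="none",
            )
        )
        # dp_direct_len=0 forces the anchored route even on small inputs
        chained = align_spliced(c, g, AlignParams(dp_direct_len=0))
        exact = spliced_align_dp(c, g)
        assert chained.score == pytest.approx(exact.score)
        assert chained.exons == exact.exons


class TestAuditSpliceSites:
    def test_canonical_and_noncanonical_dinucleotides(self):
        g = _nuc("A" * 10 + "GT" + "C" * 16 + "AG" + "T" * 10, "g")
        model = GeneModel(
            genomic_id="g", cdna_id="c", exons=((0, 10), (30, 40)), identity=1.0, score=0.0
        )
        audit = audit_splice_sites(model, g)
        assert audit.introns[0].donor == "GT"
        assert audit.introns[0].acceptor == "AG"
        assert audit.all_canonical

        g2 = _nuc("A" * 10 + "CT" + "C" * 16 + "AC" + "T" * 10, "g")
        audit2 = audit_splice_sites(model, g2)
        assert not audit2.introns[0].canonical
        assert not audit2.all_canonical

    def test_planted_nine_exon_gene_all_canonical(self):
        g, c, t = generate_gene(GeneSpec(seed=5, exon_count=9))
        model = refine_boundaries(align_spliced(c, g), g, c)
        audit = audit_splice_sites(model, g)
        assert len(audit.introns) == 8
        assert audit.all_canonical

    def test_out_of_bounds_intron_rejected(self):
        g = _nuc("ACGT" * 5, "g")
        model = GeneModel(
            genomic_id="g", cdna_id="c", exons=((0, 4), (30, 34)), identity=1.0, score=0.0
        )
        with pytest.raises(ValueError):
            audit_splice_sites(model, g)


class TestRefineBoundaries:
    def test_shift_to_canonical_donor(self):
        # Junction-flanking repeat: the misplaced cut [0,11)+[35,44) splices
        # to the same cDNA as the canonical [0,10)+[34,44) placement, so a
        # 1 nt left shift restores GT..AG without changing any match.
        e1, e2 = "AAAAAAAAAA", "GAAAATTTTT"
        intron = "GT" + "C" * 20 + "AG"
        g = _nuc(e1 + intron + e2, "g")
        c = _nuc(e1 + e2, "c")
        misplaced = GeneModel(
            genomic_id="g", cdna_id="c", exons=((0, 11), (35, 44)),
            identity=1.0, score=0.0,
        )
        assert misplaced.spliced_sequence(g) == c.seq
        refined = refine_boundaries(misplaced, g, c)
        assert refined.introns == ((10, 34),)
        assert g.seq[10:12] == "GT" and g.seq[32:34] == "AG"

    def test_already_canonical_is_fixed_point(self):
        g, c, t = generate_gene(GeneSpec(seed=3, exon_count=6, motif_plant="none"))
        model = align_spliced(c, g)
        refined = refine_boundaries(model, g, c)
        again = refine_boundaries(refined, g, c)
        assert again.exons == refined.exons

    def test_leftmost_donor_tie_break(self):
        # Exon1 ends GTAG and the intron ends AG+GTAG, so the placements
        # [10,36) and [6,32) are both canonical and splice identically;
        # the leftmost donor (position 6) must win.
        e1 = "ACCCCCGTAG"
        intron = "GT" + "C" * 18 + "AG" + "GTAG"
        e2 = "TTTTTTTTTT"
        g = _nuc(e1 + intron + e2, "g")
        c = _nuc(e1 + e2, "c")
        params = AlignParams(min_intron=20)
        model = refine_boundaries(align_spliced(c, g, params), g, c, params)
        assert model.introns[0][0] == 6
        assert g.seq[6:8] == "GT" and g.seq[30:32] == "AG"
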