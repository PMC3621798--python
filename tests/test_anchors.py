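"""Six-frame translation, translated search, tiers and split-hit merging."""
from __future__ import annotations

import random

import pytest
from Bio.Seq import Seq

from mbnmine import GenomeRecord, SeedProtein
from mbnmine.anchors import (
    merge_split_hits,
    search_anchors,
    six_frame_translate,
    tier_anchor,
    translate_frame,
)
from mbnmine import align as malign
from mbnmine.records import revcomp
from mbnmine.simulate import back_translate

from conftest import random_dna, random_protein
from oracle_dp import local_affine_score


def test_translate_simple_codon_lookup():
    assert translate_frame("ATGAAA") == "MK"
    # reverse strand of TTTCAT read from its 5' end
    assert translate_frame(revcomp("TTTCAT")) == "MK"


def test_six_frames_match_biopython_oracle():
    seq = random_dna(300, 10)
    genome = GenomeRecord("g", seq)
    frames = six_frame_translate(genome)
    rc = revcomp(seq)
    for f in range(3):
        n = (len(seq) - f) // 3
        fwd = str(Seq(seq[f : f + 3 * n]).translate(table=11))
        rev = str(Seq(rc[f : f + 3 * n]).translate(table=11))
        assert frames[("+", f)] == fwd
        assert frames[("-", f)] == rev


def test_n_codons_translate_to_x():
    assert translate_frame("ATGANAAAA") == "MXK"
    assert translate_frame("NNN") == "X"


def test_local_scores_match_bruteforce_dp():
    """Library-backed Smith-Waterman equals a hand-rolled affine DP."""
    rng = random.Random(7)
    for _ in range(25):
        a = random_protein(rng.randint(5, 20), rng.randint(0, 10**6))[1:]
        b = random_protein(rng.randint(5, 20), rng.randint(0, 10**6))[1:]
        assert malign.local_score(a, b) == pytest.approx(local_affine_score(a, b))


def test_exact_planted_seed_is_found():
    seed_aa = random_protein(100, 42)
    dna = back_translate(seed_aa, 1)
    genome = GenomeRecord("g", random_dna(2000, 2) + dna + random_dna(2000, 3))
    seed = SeedProtein("s1", "MbnB", seed_aa)
    hits = search_anchors(genome, [seed])
    assert hits, "exact match must be found"
    h = hits[0]
    assert h.aligned_fraction == pytest.approx(1.0)
    assert h.evalue < 1e-20
    assert h.region.start == 2000 and h.region.end == 2000 + 3 * 100
    assert h.translation == seed_aa


def test_random_genome_has_no_hits_and_oracle_agrees():
    """Unrelated seed vs random DNA: no hit at E<1e-20, confirmed by a full
    brute-force DP over all frames of a smaller genome."""
    seed_aa = random_protein(100, 99)
    seed = SeedProtein("s1", "MbnB", seed_aa)

    big = GenomeRecord("g", random_dna(50000, 4))
    assert search_anchors(big, [seed]) == []

    small = GenomeRecord("g2", random_dna(3000, 5))
    assert search_anchors(small, [seed]) == []
    frames = six_frame_translate(small)
    n_total = sum(len(v) for v in frames.values())
    thresh = malign.evalue_threshold_score(1e-20, len(seed_aa), n_total)
    for prot in frames.values():
        for piece in prot.split("*"):
            if len(piece) >= 5:
                assert local_affine_score(piece, seed_aa) < thresh


@pytest.mark.parametrize(
    "evalue,expected",
    [(1e-60, "core_family"), (1e-30, "distant_relative"), (1e-50, "distant_relative")],
)
def test_tier_thresholds_strict(evalue, expected):
    from mbnmine.anchors import ProteinHit
    from mbnmine.records import Region

    hit = ProteinHit("s", Region("g", 0, 300, "+"), 0, 500.0, 140.0, evalue, 1.0)
    assert tier_anchor(hit) == expected


def test_emax_monotonicity():
    """Every hit at a stricter threshold also appears at a looser one."""
    seed_aa = random_protein(120, 5)
    mutated = list(seed_aa)
    rng = random.Random(6)
    for i in range(1, len(mutated), 4):  # ~25% divergence
        mutated[i] = rng.choice("ACDEFGHIKLMNPQRSTVWY")
    genome = GenomeRecord(
        "g", random_dna(1500, 7) + back_translate("".join(mutated), 8) + random_dna(1500, 9)
    )
    seed = SeedProtein("s", "MbnB", seed_aa)
    strict = search_anchors(genome, [seed], e_max=1e-40)
    loose = search_anchors(genome, [seed], e_max=1e-10)
    strict_keys = {(h.region.start, h.region.end) for h in strict}
    loose_keys = {(h.region.start, h.region.end) for h in loose}
    assert strict_keys <= loose_keys
    assert len(loose) >= len(strict)


def test_strand_invariance():
    seed_aa = random_protein(80, 11)
    genome_seq = random_dna(1000, 12) + back_translate(seed_aa, 13) + random_dna(1000, 14)
    g1 = GenomeRecord("g", genome_seq)
    g2 = GenomeRecord("g", revcomp(genome_seq))
    seed = SeedProtein("s", "MbnB", seed_aa)
    h1 = search_anchors(g1, [seed])[0]
    h2 = search_anchors(g2, [seed])[0]
    assert h1.raw_score == h2.raw_score
    assert h1.evalue == pytest.approx(h2.evalue)
    L = len(genome_seq)
    assert (h2.region.start, h2.region.end) == (L - h1.region.end, L - h1.region.start)
    assert {h1.strand, h2.strand} == {"+", "-"}


def test_short_seed_rejected():
    genome = GenomeRecord("g", random_dna(300, 1))
    with pytest.raises(ValueError, match="shorter than 10"):
        search_anchors(genome, [SeedProtein("s", "MbnB", "MKLVWFACD")])


class TestSplitHitMerging:
    def _split_genome(self, seed_aa, seed=21):
        dna = back_translate(seed_aa, seed)
        mid = (len(seed_aa) // 2) * 3
        dna = dna[:mid] + "TGA" + dna[mid + 3 :]  # replace one codon with a stop
        return GenomeRecord("g", random_dna(1200, seed) + dna + random_dna(1200, seed + 1))

    def test_planted_stop_split_gene_merges_to_one_hit(self, seeds, seeds_by_id):
        seed = [s for s in seeds if s.role == "MbnB"][0]
        genome = self._split_genome(seed.aa_seq)
        hits = search_anchors(genome, [seed])
        assert len(hits) == 2, "stop-split gene must give one hit per fragment"
        merged = merge_split_hits(genome, hits, seeds_by_id)
        assert len(merged) == 1
        m = merged[0]
        assert m.merged
        assert m.region.start == min(h.region.start for h in hits)
        assert m.region.end == max(h.region.end for h in hits)
        # the bridged translation replaces the stop by glycine and re-scores
        assert "*" not in m.translation
        assert m.raw_score >= max(h.raw_score for h in hits)
        assert m.aligned_fraction == pytest.approx(1.0, abs=0.02)
        assert tier_anchor(m) == "core_family"

    def test_hits_to_different_seeds_do_not_merge(self, seeds_by_id):
        a = random_protein(60, 31)
        b = random_protein(60, 32)
        genome = GenomeRecord(
            "g",
            random_dna(900, 33) + back_translate(a, 34) + "TAA"
            + back_translate(b, 35) + random_dna(900, 36),
        )
        sa, sb = SeedProtein("sa", "MbnB", a), SeedProtein("sb", "MbnC", b)
        hits = search_anchors(genome, [sa, sb])
        merged = merge_split_hits(genome, hits, {"sa": sa, "sb": sb})
        assert len(merged) == len(hits)
        assert not any(h.merged for h in merged)

    def test_merge_on_minus_strand(self, seeds, seeds_by_id):
        seed = [s for s in seeds if s.role == "MbnB"][0]
        genome = self._split_genome(seed.aa_seq)
        flipped = GenomeRecord("g", revcomp(genome.seq))
        hits = search_anchors(flipped, [seed])
        merged = merge_split_hits(flipped, hits, seeds_by_id)
        assert len(merged) == 1 and merged[0].merged
        assert merged[0].strand == "-"
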