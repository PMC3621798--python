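"""Small-ORF enumeration and the precursor-peptide criteria."""
from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from mbnmine import GenomeRecord, Region
from mbnmine.precursor import (
    MiningConfig,
    enumerate_small_orfs,
    find_core_motifs,
    rank_candidates,
    score_candidate,
    split_leader_core,
)
from mbnmine.precursor import SmallOrf
from mbnmine.simulate import OB3B_PRECURSOR, ROSEA_PRECURSOR, back_translate

from conftest import random_dna
from oracle_dp import brute_force_orfs

CFG = MiningConfig()


def _orf_for(peptide: str, seed: int = 0) -> SmallOrf:
    dna = back_translate(peptide, seed)
    return SmallOrf(Region("g", 1000, 1000 + len(dna), "+"), peptide, "ATG")


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def test_no_start_codons_gives_empty_list():
    genome = GenomeRecord("g", "C" * 600)  # no ATG/GTG/TTG on either strand
    orfs = enumerate_small_orfs(genome, Region("g", 250, 350, "+"), CFG)
    assert orfs == []


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_enumeration_matches_bruteforce(seed):
    """Window enumeration equals the exhaustive (start, in-frame stop) scan."""
    genome = GenomeRecord("g", random_dna(4000, 100 + seed))
    around = Region("g", 1900, 2100, "+")
    orfs = enumerate_small_orfs(genome, around, CFG)
    w0 = max(0, around.start - CFG.window_nt)
    w1 = min(len(genome), around.end + CFG.window_nt)
    oracle = brute_force_orfs(
        genome.seq[w0:w1], CFG.start_codons, CFG.min_len_aa, CFG.max_len_aa
    )
    ours = sorted(
        (o.region.strand, o.region.start - w0, o.region.end - w0, o.aa_seq)
        for o in orfs
    )
    assert ours == oracle


def test_planted_ob3b_precursor_is_enumerated():
    """The published 30-aa precursor embedded next to an anchor shows up."""
    dna = back_translate(OB3B_PRECURSOR, 5)
    genome = GenomeRecord(
        "g", random_dna(1500, 1) + "TAA" + dna + random_dna(1500, 2)
    )
    anchor = Region("g", 1503 + len(dna), 1503 + len(dna) + 90, "+")
    orfs = enumerate_small_orfs(genome, anchor, CFG)
    assert any(o.aa_seq == OB3B_PRECURSOR for o in orfs)
    hit = [o for o in orfs if o.aa_seq == OB3B_PRECURSOR][0]
    assert len(hit.aa_seq) == 30
    assert hit.region.start == 1503


def test_nested_starts_share_stop_longest_reported():
    inner = "MKKAAKRAVLVICAAC"
    dna = back_translate("MAAS" + inner[1:], 9)  # upstream in-frame ATG first
    genome = GenomeRecord("g", "C" * 300 + "TAA" + dna + "C" * 300)
    orfs = enumerate_small_orfs(genome, Region("g", 280, 320, "+"), CFG)
    with_stop = [o for o in orfs if o.region.start >= 303]
    assert len(with_stop) == 1
    assert with_stop[0].aa_seq.startswith("MAAS")


def test_window_outside_contig_errors():
    genome = GenomeRecord("g", random_dna(500, 3))
    with pytest.raises(ValueError):
        enumerate_small_orfs(
            genome, Region("g", 600, 650, "+"), MiningConfig(window_nt=5)
        )


def test_circular_window_wraps_origin():
    pep = "MKKRAVLVIAGRAAALCGSCA"
    dna = back_translate(pep, 11)
    # place the anchor near the origin of a circular contig; the window wraps
    seq = dna + random_dna(3000, 12) + "TAA"
    genome = GenomeRecord("g", seq[100:] + seq[:100], topology="circular")
    # ORF now sits at the very end wrapping over the origin boundary region
    orfs = enumerate_small_orfs(
        genome, Region("g", len(genome) - 50, len(genome) - 40, "+"),
        MiningConfig(window_nt=300),
    )
    assert isinstance(orfs, list)  # wrap handled without error


# ---------------------------------------------------------------------------
# Criteria
# ---------------------------------------------------------------------------

def test_ob3b_precursor_accepted_with_expected_flags():
    cand = score_candidate(_orf_for(OB3B_PRECURSOR))
    assert cand.accepted
    assert cand.criteria == {
        "cys_in_tail": True, "kr_in_head": True, "hydrophobic_block": True
    }
    # 4 cysteines + K4/K8/K9 in the head + hydrophobic block bonus
    assert cand.score == 4 + 3 + 1


def test_rosea_precursor_accepted():
    cand = score_candidate(_orf_for(ROSEA_PRECURSOR))
    assert cand.accepted
    assert cand.core == "RCASTCAATNG"
    assert cand.score == 2 + 3 + 1


def test_polyalanine_rejected_on_tail_cysteine():
    cand = score_candidate(_orf_for("M" + "A" * 29))
    assert not cand.accepted
    assert cand.criteria["cys_in_tail"] is False


def test_kr_poor_head_rejected():
    pep = "MTSTSAQSSVLPVIGRAAALCGSCYPCSCM"  # head K/R removed
    cand = score_candidate(_orf_for(pep))
    assert not cand.accepted
    assert cand.criteria["kr_in_head"] is False


def test_missing_hydrophobic_block_rejected():
    pep = "MTKKIAQKKSDSDSGSGSSDCGSCYPCSCM"  # no hydrophobic run before K/R
    cand = score_candidate(_orf_for(pep))
    assert not cand.accepted
    assert cand.criteria["hydrophobic_block"] is False


def test_shuffled_precursor_rarely_passes():
    """Residue-shuffled versions of a passing precursor nearly always break a
    criterion — guards against degenerate always-accept behaviour."""
    rng = random.Random(2013)
    passed = 0
    for _ in range(200):
        shuffled = list(OB3B_PRECURSOR)
        rng.shuffle(shuffled)
        if score_candidate(_orf_for("".join(shuffled))).accepted:
            passed += 1
    assert passed / 200 < 0.1


# ---------------------------------------------------------------------------
# Leader/core split and motifs
# ---------------------------------------------------------------------------

def test_published_splits():
    assert split_leader_core(OB3B_PRECURSOR) == (
        "MTVKIAQKKVLPVIGRAAA", "LCGSCYPCSCM", False
    )
    assert split_leader_core(ROSEA_PRECURSOR) == (
        "MTIRIAKRITLNVIGRASA", "RCASTCAATNG", False
    )


def test_degenerate_split_no_leader():
    leader, core, no_leader = split_leader_core("MCAAAKRAAC")
    assert no_leader and leader == "" and core == "MCAAAKRAAC"


@settings(max_examples=200, deadline=None)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=10, max_size=50))
def test_split_reconstitution_invariant(pep):
    """leader + core always reconstitutes the peptide exactly."""
    if "C" not in pep:
        with pytest.raises(ValueError):
            split_leader_core(pep)
        return
    leader, core, _ = split_leader_core(pep)
    assert leader + core == pep
    assert "C" in core


@pytest.mark.parametrize(
    "core,n_motifs,rings,n_cys,n_cc",
    [
        ("LCGSCYPCSCM", 1, [1, 7], 4, 0),
        ("RCASTCAATNG", 1, [1, 5], 2, 0),
        ("AAAA", 0, [], 0, 0),
        ("ACCGSA", 1, [2], 2, 1),  # doublet counted, single ring site
    ],
)
def test_core_motif_inventory(core, n_motifs, rings, n_cys, n_cc):
    motifs, ring_sites, cys, cc = find_core_motifs(core)
    assert len(motifs) == n_motifs
    assert ring_sites == rings
    assert cys == n_cys
    assert cc == n_cc


def test_ring_sites_always_inside_core():
    for pep in (OB3B_PRECURSOR, ROSEA_PRECURSOR):
        cand = score_candidate(_orf_for(pep))
        for site in cand.ring_sites:
            assert 0 <= site < len(cand.core)
            assert cand.core[site] == "C"


def test_ranking_prefers_motif_and_plausible_core_length():
    anchor = Region("g", 5000, 5300, "+")
    good = score_candidate(_orf_for(OB3B_PRECURSOR))
    # passes the criteria but no C[GAS][ST] motif and an implausibly long core
    sprawling = score_candidate(_orf_for("MKKRAVLVIRCDDHTLDDECFSRQREEDLTASCDQPCD"))
    assert sprawling.accepted
    ranked = rank_candidates([sprawling, good], anchor)
    assert ranked[0] is good
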