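"""Neighborhood role assignment, NExT detection and group classification."""
from __future__ import annotations

import pytest

from mbnmine import GenomeRecord
from mbnmine.operon import (
    classify_group,
    collect_neighborhood,
    detect_next_extension,
)
from mbnmine.pipeline import RunConfig, mine_genome
from mbnmine.io import operons_to_json
from mbnmine.profiles import build_profile, scan_profile
from mbnmine.simulate import PlantSpec, generate_genome, role_protein

from conftest import random_dna
from oracle_dp import local_affine_score


@pytest.fixture(scope="module")
def groupI_mined(seeds_module, next_profile_module):
    spec = PlantSpec(template="groupI_OB3b_like", aa_identity=1.0, seed=71)
    genome, entry = generate_genome(spec, "gI")
    ops = mine_genome(genome, seeds_module, next_profile=next_profile_module)
    assert len(ops) == 1
    return genome, entry, ops[0]


@pytest.fixture(scope="module")
def seeds_module():
    from mbnmine.pipeline import load_seed_bundle

    return load_seed_bundle()


@pytest.fixture(scope="module")
def next_profile_module():
    from mbnmine.profiles import load_next_profile

    return load_next_profile()


def test_all_template_roles_recovered(groupI_mined):
    """A Group I style operon yields every planted role assignment."""
    _genome, entry, op = groupI_mined
    expected = {"MbnA", "MbnB", "MbnC", "MbnM", "MbnN", "MbnT", "MbnI", "MbnR",
                "MbnP", "MbnH"}
    assert expected <= op.roles_present()
    # role regions agree with the manifest
    by_role = {f.role: f.region for f in entry["planted"]}
    for g in op.genes:
        if g.role in by_role and g.role != "MbnA":
            assert g.region.overlap_len(by_role[g.role]) > 0.8 * len(by_role[g.role])


def test_random_window_all_unknown(seeds_module):
    from mbnmine.anchors import ProteinHit
    from mbnmine.records import Region

    genome = GenomeRecord("g", random_dna(8000, 55))
    anchor = ProteinHit("MbnB_syn", Region("g", 3900, 4200, "+"), 0, 500.0,
                        140.0, 1e-40, 0.9, 0, 100, 10**6)
    genes = collect_neighborhood(genome, anchor, seeds_module)
    assert all(g.role == "unknown" for g in genes)


def test_best_role_matches_bruteforce_alignment_oracle(groupI_mined, seeds_module):
    """The MbnC call is the seed a brute-force DP alignment ranks first."""
    _genome, entry, op = groupI_mined
    mbnc = [g for g in op.genes if g.role == "MbnC"][0]
    scores = {s.role: local_affine_score(mbnc.aa_seq, s.aa_seq) for s in seeds_module}
    assert max(scores, key=scores.get) == "MbnC"


def test_role_removal_degrades_to_unknown_only(groupI_mined, seeds_module,
                                               next_profile_module):
    """Dropping a role's seed can only move genes to unknown, never to a
    different role."""
    genome, _entry, op = groupI_mined
    reduced = [s for s in seeds_module if s.role != "MbnN"]
    genes = collect_neighborhood(genome, op.anchor, reduced,
                                 next_profile=next_profile_module)
    before = {(g.region.start, g.region.end): g.role
              for g in op.genes if g.role != "MbnA"}
    after = {(g.region.start, g.region.end): g.role for g in genes}
    for key, role in before.items():
        if key not in after:
            continue
        if role == "MbnN":
            assert after[key] == "unknown"
        else:
            assert after[key] == role


def test_determinism_byte_identical_json(seeds_module, next_profile_module):
    spec = PlantSpec(template="groupII_rosea_like", aa_identity=0.9, seed=7)
    g1, _ = generate_genome(spec, "gd")
    g2, _ = generate_genome(spec, "gd")
    ops1 = mine_genome(g1, seeds_module, next_profile=next_profile_module)
    ops2 = mine_genome(g2, seeds_module, next_profile=next_profile_module)
    assert operons_to_json(ops1) == operons_to_json(ops2)


class TestNextExtension:
    def test_planted_extension_detected(self, groupI_mined):
        _genome, _entry, op = groupI_mined
        flags = [g.next_extension for g in op.genes if g.role == "MbnT"]
        assert any(flags), "Group I MbnT carries the N-terminal extension"

    def test_extension_ablation(self, next_profile_module):
        full = role_protein("MbnT_next")
        bare = role_protein("MbnT")
        plug_start_full = len(full) - len(bare)
        assert detect_next_extension(full, plug_start_full, next_profile_module)
        assert not detect_next_extension(bare, 0, next_profile_module)

    def test_missing_plug_match_warns_false(self, next_profile_module):
        with pytest.warns(UserWarning):
            assert not detect_next_extension("M" + "A" * 200, None,
                                             next_profile_module)

    def test_threshold_is_weakest_training_self_score(self):
        """Recompute the acceptance threshold from the training rows."""
        from mbnmine.profiles import _read_packaged_alignment

        aln = _read_packaged_alignment("synthetic_next_alignment.fasta")
        prof = build_profile(aln)
        selfs = [scan_profile(prof, row).score for row in aln.rows]
        assert prof.acceptance_threshold == pytest.approx(min(selfs))


class TestClassification:
    def test_group_I_ob3b_fixture(self, make_operon):
        op = make_operon("MTVKIAQKKVLPVIGRAAALCGSCYPCSCM",
                         roles=("MbnC", "MbnI", "MbnR", "MbnT"), next_mbnt=True)
        assert op.group == "I"

    def test_group_I_via_regulatory_signature(self, make_operon):
        # two-cysteine core, but the MbnI/MbnR/NExT triad still labels I
        op = make_operon("MTVKIAQKKVLPVIGRAAALCGGGGGGGCM",
                         roles=("MbnI", "MbnR", "MbnT"), next_mbnt=True)
        assert op.group == "I"

    def test_group_II_rosea_fixture(self, make_operon):
        op = make_operon("MTIRIAKRITLNVIGRASARCASTCAATNG",
                         roles=("MbnC", "MbnM", "MbnS"))
        assert op.group == "II"
        assert "MbnS" in op.group_rationale or "sulfo" in op.group_rationale

    def test_group_II_trp_subfamily(self, make_operon):
        op = make_operon("MTIRIAKRITLNVIGRASARCASTCWATNG", roles=("MbnC",))
        assert op.group == "II"

    def test_group_III_doublets(self, make_operon):
        op = make_operon("MTIRIAKRITLNVIGRASARCCASTGGCCG", roles=("MbnC",))
        assert op.group == "III"

    def test_group_IV_two_nonadjacent(self, make_operon):
        op = make_operon("MTIRIAKRITLNVIGRASARCAGGGGGCGG", roles=("MbnC",))
        assert op.group == "IV"

    def test_group_V_fixture(self, make_operon):
        op = make_operon("MTAKIAQRKTLPVIGRAAALCGSTAHTEAG",
                         gene_between_a_b=True)
        assert op.group == "V"

    def test_single_cys_with_mbnc_is_not_group_V(self, make_operon):
        op = make_operon("MTAKIAQRKTLPVIGRAAALCGSTAHTEAG", roles=("MbnC",),
                         gene_between_a_b=True)
        assert op.group != "V"

    def test_classification_total_with_rationale(self, make_operon):
        peptides = [
            "MTVKIAQKKVLPVIGRAAALCGSCYPCSCM",
            "MTIRIAKRITLNVIGRASARCASTCAATNG",
            "MTAKIAQRKTLPVIGRAAALCGSTAHTEAG",
            "MKKRAVLVIRCDDHTLDDECFSRQREEDLC",
        ]
        for pep in peptides:
            op = make_operon(pep)
            group, rationale = classify_group(op)
            assert group in ("I", "II", "III", "IV", "V", "unclassified")
            assert rationale
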