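from __future__ import annotations

import random

import pytest

from mbnmine import GenomeRecord, Region
from mbnmine.anchors import ProteinHit
from mbnmine.operon import GeneAssignment, OperonModel
from mbnmine.pipeline import load_seed_bundle
from mbnmine.precursor import SmallOrf, score_candidate
from mbnmine.profiles import load_mbna_profile, load_next_profile
from mbnmine.simulate import back_translate


@pytest.fixture(scope="session")
def seeds():
    return load_seed_bundle()


@pytest.fixture(scope="session")
def seeds_by_id(seeds):
    return {s.id: s for s in seeds}


@pytest.fixture(scope="session")
def next_profile():
    return load_next_profile()


@pytest.fixture(scope="session")
def mbna_profile():
    return load_mbna_profile()


def random_dna(n: int, seed: int, gc: float = 0.5) -> str:
    rng = random.Random(seed)
    g = gc / 2
    at = (1 - gc) / 2
    return "".join(rng.choices("ACGT", weights=[at, g, g, at], k=n))


def random_protein(n: int, seed: int) -> str:
    rng = random.Random(seed)
    return "M" + "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(n - 1))


@pytest.fixture
def make_operon():
    """Factory for hand-built operon models used by the classifier and
    product-predictor tests (gene coordinates laid out left to right)."""

    def _make(peptide: str, roles=(), next_mbnt: bool = False,
              gene_between_a_b: bool = False, genome_id: str = "fixture"):
        dna = back_translate(peptide, 0)
        orf = SmallOrf(Region(genome_id, 1000, 1000 + len(dna), "+"), peptide,
                       "ATG")
        cand = score_candidate(orf)
        assert cand.accepted, "fixture peptide must pass the criteria"
        cursor = 1200
        genes = [GeneAssignment(orf.region, "MbnA", aa_seq=peptide)]
        if gene_between_a_b:
            genes.append(GeneAssignment(Region(genome_id, cursor, cursor + 300, "+"),
                                        "unknown", aa_seq="M" + "A" * 99))
            cursor += 400
        anchor_region = Region(genome_id, cursor, cursor + 810, "+")
        anchor = ProteinHit("MbnB_syn", anchor_region, 0, 900.0, 250.0, 1e-60,
                            1.0, 0, 270, 10**6)
        genes.append(GeneAssignment(anchor_region, "MbnB",
                                    evidence=("MbnB_syn", 250.0, 1e-60)))
        cursor += 900
        for role in roles:
            r = Region(genome_id, cursor, cursor + 300, "+")
            ga = GeneAssignment(r, role, evidence=(f"{role}_syn", 100.0, 1e-30))
            if role == "MbnT":
                ga.next_extension = next_mbnt
            genes.append(ga)
            cursor += 400
        op = OperonModel(genome_id=genome_id, anchor=anchor, genes=genes,
                         precursors=[cand])
        from mbnmine.operon import classify_group

        op.group, op.group_rationale = classify_group(op)
        return op

    return _make
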