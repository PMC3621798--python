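"""Synthetic genomes with planted, mutated Mbn operons and truth manifests.

Templates mirror the three operon architectures the pipeline must recognize:

* ``groupI_OB3b_like`` — regulatory block (MbnT with N-terminal extension,
  MbnP/MbnH, MbnI/MbnR) followed by MbnA-MbnB-MbnC-MbnM-MbnN, with the
  published 30-aa OB3b precursor;
* ``groupII_rosea_like`` — MbnT, MbnP/MbnH, then MbnA-MbnB-MbnC-MbnM-MbnF-
  MbnS with the published rosea precursor;
* ``groupV_like`` — a single-cysteine precursor separated from MbnB by an
  unassigned gene, no MbnC.

Planted proteins are the packaged synthetic role seeds; amino-acid
substitutions are applied uniformly at rate (1 - aa_identity) before
back-translation.  Substitutions on the precursor avoid its defining
residues (start Met, cysteines, head K/R, the pre-core K/R and its
hydrophobic block, core prolines in the Group I template) and never
introduce new cysteines — emulating the purifying selection visible in the
real precursor family, where exactly these positions are conserved.  Decoy
small ORFs exercising each rejection path are planted alongside, and a
truth manifest records every feature.
"""
from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable

from .anchors import translate_frame
from .precursor import MiningConfig
from .records import GenomeRecord, Region

OB3B_PRECURSOR = "MTVKIAQKKVLPVIGRAAALCGSCYPCSCM"
ROSEA_PRECURSOR = "MTIRIAKRITLNVIGRASARCASTCAATNG"
GROUPV_PRECURSOR = "MTAKIAQRKTLPVIGRAAALCGSTAHTEAG"

STOP_CODON = "TAA"
AA20 = "ACDEFGHIKLMNPQRSTVWY"


@lru_cache(maxsize=None)
def _synonymous_codons() -> dict:
    table = CodonTable.unambiguous_dna_by_id[11]
    by_aa: dict = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for aa in by_aa:
        by_aa[aa].sort()
    return by_aa


@lru_cache(maxsize=None)
def _packaged_proteins() -> dict:
    out = {}
    for fname in ("synthetic_role_seeds.fasta", "synthetic_extra_proteins.fasta"):
        ref = resources.files("mbnmine.data") / fname
        with resources.as_file(ref) as p:
            for rec in SeqIO.parse(str(p), "fasta"):
                role = rec.id.rsplit("_syn", 1)[0]
                out[role] = str(rec.seq).upper()
    ref = resources.files("mbnmine.data") / "synthetic_next_alignment.fasta"
    with resources.as_file(ref) as p:
        recs = list(SeqIO.parse(str(p), "fasta"))
    out["NExT"] = str(recs[0].seq).upper()
    return out


def role_protein(role: str) -> str:
    """The packaged synthetic protein for a role; MbnT_next is the TBDT with
    its N-terminal extension prepended."""
    prots = _packaged_proteins()
    if role == "MbnT_next":
        return prots["NExT"] + prots["MbnT"]
    return prots[role]


def packaged_role_seeds_path():
    """Path context for the packaged role seed FASTA (anchor + accessory)."""
    return resources.as_file(resources.files("mbnmine.data") / "synthetic_role_seeds.fasta")


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------
# Each template: ordered layout of (kind, payload) with kind in
# {"gene": (role, protein), "precursor": peptide, "decoy_zone": n}

def _template_layouts() -> dict:
    return {
        "groupI_OB3b_like": {
            "precursor": OB3B_PRECURSOR,
            "expected_group": "I",
            "layout": [
                ("gene", ("MbnT", "MbnT_next")),
                ("gene", ("MbnP", "MbnP")),
                ("gene", ("MbnH", "MbnH")),
                ("gene", ("MbnI", "MbnI")),
                ("gene", ("MbnR", "MbnR")),
                ("decoy_zone", 2),
                ("precursor", None),
                ("gene", ("MbnB", "MbnB")),
                ("gene", ("MbnC", "MbnC")),
                ("decoy_zone", 2),
                ("gene", ("MbnM", "MbnM")),
                ("gene", ("MbnN", "MbnN")),
            ],
        },
        "groupII_rosea_like": {
            "precursor": ROSEA_PRECURSOR,
            "expected_group": "II",
            "layout": [
                ("gene", ("MbnT", "MbnT")),
                ("gene", ("MbnP", "MbnP")),
                ("gene", ("MbnH", "MbnH")),
                ("decoy_zone", 2),
                ("precursor", None),
                ("gene", ("MbnB", "MbnB")),
                ("gene", ("MbnC", "MbnC")),
                ("decoy_zone", 2),
                ("gene", ("MbnM", "MbnM")),
                ("gene", ("MbnF", "MbnF")),
                ("gene", ("MbnS", "MbnS")),
            ],
        },
        "groupV_like": {
            "precursor": GROUPV_PRECURSOR,
            "expected_group": "V",
            "layout": [
                ("decoy_zone", 2),
                ("precursor", None),
                ("gene", ("unknown", "unknown_orf")),
                ("gene", ("MbnB", "MbnB")),
                ("decoy_zone", 2),
                ("gene", ("MbnM", "MbnM")),
            ],
        },
    }


@dataclass
class PlantSpec:
    """Parameters of one synthetic genome."""

    template: str = "groupI_OB3b_like"
    aa_identity: float = 1.0
    include_roles: frozenset | None = None
    split_mbnB: bool = False
    decoy_orf_count: int = 10
    background_gc: float = 0.63  # alphaproteobacterial methanotroph-like GC
    genome_length: int = 20000
    seed: int = 0
    custom_layout: list | None = None
    custom_precursor: str | None = None
    expected_group: str | None = None

    def resolved(self):
        if self.template == "custom":
            if not self.custom_layout or not self.custom_precursor:
                raise ValueError("custom template requires custom_layout and custom_precursor")
            layout, precursor = self.custom_layout, self.custom_precursor
            group = self.expected_group or "unclassified"
        else:
            t = _template_layouts()[self.template]
            layout, precursor, group = t["layout"], t["precursor"], t["expected_group"]
        if self.include_roles is not None:
            keep = set(self.include_roles) | {"MbnB"}
            layout = [
                item
                for item in layout
                if item[0] != "gene" or item[1][0] in keep
            ]
        if not (0.0 < self.aa_identity <= 1.0):
            raise ValueError("aa_identity must lie in (0, 1]")
        return layout, precursor, group


@dataclass
class PlantedFeature:
    role: str
    region: Region
    original_peptide: str
    mutated_peptide: str

    def to_dict(self) -> dict:
        return {
            "role": self.role,
            "region": self.region.to_dict(),
            "original_peptide": self.original_peptide,
            "mutated_peptide": self.mutated_peptide,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(d["role"], Region.from_dict(d["region"]),
                   d["original_peptide"], d["mutated_peptide"])


@dataclass
class DecoyFeature:
    decoy_class: str  # a: Cys-free; b: K/R-poor head; c: valid but off-window
    region: Region
    peptide: str

    def to_dict(self) -> dict:
        return {
            "decoy_class": self.decoy_class,
            "region": self.region.to_dict(),
            "peptide": self.peptide,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(d["decoy_class"], Region.from_dict(d["region"]), d["peptide"])


@dataclass
class TruthManifest:
    """Ground truth for a generated genome set."""

    genomes: dict = field(default_factory=dict)
    # genome_id -> {"planted": [...], "decoys": [...], "expected_group": str,
    #               "anchor": region dict}

    def to_json(self) -> str:
        ser = {}
        for gid, entry in self.genomes.items():
            ser[gid] = {
                "planted": [f.to_dict() for f in entry["planted"]],
                "decoys": [d.to_dict() for d in entry["decoys"]],
                "expected_group": entry["expected_group"],
                "anchor": entry["anchor"].to_dict(),
            }
        return json.dumps(ser, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        raw = json.loads(text)
        genomes = {}
        for gid, entry in raw.items():
            genomes[gid] = {
                "planted": [PlantedFeature.from_dict(f) for f in entry["planted"]],
                "decoys": [DecoyFeature.from_dict(d) for d in entry["decoys"]],
                "expected_group": entry["expected_group"],
                "anchor": Region.from_dict(entry["anchor"]),
            }
        return cls(genomes)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path) -> "TruthManifest":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Sequence-level helpers
# ---------------------------------------------------------------------------

def back_translate(peptide: str, seed: int | random.Random) -> str:
    """Codon-table-11 back-translation with uniform synonymous codon choice
    and a trailing stop codon; translating the output reproduces the input."""
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    by_aa = _synonymous_codons()
    codons = []
    for aa in peptide:
        if aa not in by_aa:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        codons.append(rng.choice(by_aa[aa]))
    codons.append(rng.choice(["TAA", "TAG", "TGA"]))
    return "".join(codons)


def mutate_protein(
    aa_seq: str,
    identity: float,
    rng: random.Random,
    protected: set | None = None,
    hydrophobic_redirect: set | None = None,
    forbid: str = "",
) -> str:
    """Uniform substitutions at rate (1 - identity).

    ``protected`` positions never change; ``hydrophobic_redirect`` positions
    mutate only within the hydrophobic set; residues in ``forbid`` are never
    introduced anywhere.
    """
    protected = protected or set()
    hydrophobic_redirect = hydrophobic_redirect or set()
    rate = 1.0 - identity
    cfg = MiningConfig()
    out = list(aa_seq)
    for i, aa in enumerate(out):
        if rng.random() >= rate:
            continue
        if i in protected:
            continue
        if i in hydrophobic_redirect:
            choices = [a for a in sorted(cfg.hydrophobic_set) if a != aa]
        else:
            choices = [a for a in AA20 if a != aa and a not in forbid]
        if choices:
            out[i] = rng.choice(choices)
    return "".join(out)


def precursor_protected_positions(peptide: str, groupI: bool = False):
    """(protected, hydrophobic_redirect) index sets for criterion-preserving
    precursor mutation."""
    cfg = MiningConfig()
    protected = {0} | {i for i, a in enumerate(peptide) if a == "C"}
    protected |= {i for i, a in enumerate(peptide[: cfg.first_k]) if a in "KR"}
    fc = peptide.find("C")
    # keep the family-defining C(G|A|S)(S|T) motif at the first core cysteine
    protected |= {i for i in (fc + 1, fc + 2) if 0 < i < len(peptide)}
    redirect = set()
    if fc > 0:
        kr_positions = [
            p for p in range(max(0, fc - cfg.pre_cys_window), fc) if peptide[p] in "KR"
        ]
        protected |= set(kr_positions)
        for p in kr_positions:
            for q in range(max(0, p - cfg.hydrophobic_window), p):
                if peptide[q] in cfg.hydrophobic_set:
                    redirect.add(q)
    if groupI:
        protected |= {i for i in range(fc - 1, len(peptide)) if peptide[i] == "P"}
    return protected, redirect - protected


def random_background(n: int, gc: float, rng: random.Random) -> str:
    at = (1.0 - gc) / 2.0
    g = gc / 2.0
    return "".join(rng.choices("ACGT", weights=[at, g, g, at], k=n))


def _decoy_peptide(decoy_class: str, rng: random.Random) -> str:
    """A small-ORF peptide violating (a, b) or satisfying (c) the criteria."""
    if decoy_class == "a":  # cysteine-free, otherwise leader-like
        n = rng.randint(15, 40)
        alphabet = AA20.replace("C", "")
        pep = "M" + "".join(rng.choice(alphabet) for _ in range(n - 1))
        return pep
    if decoy_class == "b":  # cysteines present but K/R-poor head
        head_alphabet = "AGSTNQDELVI"
        tail_alphabet = AA20.replace("K", "").replace("R", "")
        n = rng.randint(15, 40)
        head = "M" + "".join(rng.choice(head_alphabet) for _ in range(9))
        tail = "".join(rng.choice(tail_alphabet) for _ in range(n - 12)) + "CA"
        return head + tail
    if decoy_class == "c":  # passes every criterion; planted far from anchors
        return GROUPV_PRECURSOR
    raise ValueError(f"unknown decoy class {decoy_class!r}")


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

def generate_genome(spec: PlantSpec, genome_id: str = "synthetic1"):
    """Build one genome from a spec; returns (GenomeRecord, manifest entry)."""
    rng = random.Random(spec.seed)
    layout, precursor_peptide, expected_group = spec.resolved()

    planted: list[PlantedFeature] = []
    decoys: list[DecoyFeature] = []
    pieces: list[str] = []
    cursor = 0

    def emit(s: str):
        nonlocal cursor
        pieces.append(s)
        cursor += len(s)

    def spacer(lo=30, hi=80):
        n = rng.randint(lo, hi)
        s = random_background(n, spec.background_gc, rng)
        # in-frame stop guard so planted ORFs never extend upstream
        return s[:-3] + STOP_CODON

    def plant_peptide(role, original, mutated, record_list, extra=None):
        emit(spacer())
        dna = back_translate(mutated, rng)
        region = Region(genome_id, cursor, cursor + len(dna), "+")
        emit(dna)
        if record_list is planted:
            planted.append(PlantedFeature(role, region, original, mutated))
        else:
            decoys.append(DecoyFeature(role, region, mutated))
        return region

    # left flank
    left = rng.randint(3000, 3400)
    emit(random_background(left, spec.background_gc, rng))

    groupI = "I" == expected_group
    anchor_region = None
    n_inwindow_decoys = 0
    for kind, payload in layout:
        if kind == "gene":
            role, prot_key = payload
            prot = role_protein(prot_key)
            mutated = mutate_protein(prot, spec.aa_identity, rng)
            if role == "MbnB" and spec.split_mbnB:
                mid = len(mutated) // 2
                dna = back_translate(mutated, rng)
                stop_at = mid * 3
                dna = dna[:stop_at] + "TGA" + dna[stop_at + 3 :]
                emit(spacer())
                region = Region(genome_id, cursor, cursor + len(dna), "+")
                emit(dna)
                planted.append(PlantedFeature(role, region, prot, mutated))
            else:
                region = plant_peptide(role, prot, mutated, planted)
            if role == "MbnB":
                anchor_region = region
        elif kind == "precursor":
            protected, redirect = precursor_protected_positions(
                precursor_peptide, groupI=groupI
            )
            mutated = mutate_protein(
                precursor_peptide,
                spec.aa_identity,
                rng,
                protected=protected,
                hydrophobic_redirect=redirect,
                forbid="C",
            )
            plant_peptide("MbnA", precursor_peptide, mutated, planted)
        elif kind == "decoy_zone":
            for _ in range(payload):
                if n_inwindow_decoys >= spec.decoy_orf_count:
                    break
                cls_ = rng.choice("ab")
                pep = _decoy_peptide(cls_, rng)
                plant_peptide(cls_, pep, pep, decoys)
                n_inwindow_decoys += 1
        else:
            raise ValueError(f"unknown layout item {kind!r}")

    if anchor_region is None:
        raise ValueError("template must plant an MbnB anchor")

    # gap past the anchor window, then class-c decoys, then right flank
    remaining_decoys = max(0, spec.decoy_orf_count - n_inwindow_decoys)
    tail_needed = 2500 + remaining_decoys * 250 + 500
    if cursor + tail_needed > spec.genome_length:
        raise ValueError(
            f"operon footprint ({cursor}) plus decoys exceeds genome_length "
            f"{spec.genome_length}"
        )
    emit(random_background(2500, spec.background_gc, rng))
    for _ in range(remaining_decoys):
        pep = _decoy_peptide("c", rng)
        emit(spacer(60, 120))
        dna = back_translate(pep, rng)
        region = Region(genome_id, cursor, cursor + len(dna), "+")
        emit(dna)
        decoys.append(DecoyFeature("c", region, pep))
    emit(random_background(spec.genome_length - cursor, spec.background_gc, rng))

    genome = GenomeRecord(id=genome_id, seq="".join(pieces))
    entry = {
        "planted": planted,
        "decoys": decoys,
        "expected_group": expected_group,
        "anchor": anchor_region,
    }
    return genome, entry


def generate_genome_set(specs):
    """Generate genomes for a list of PlantSpecs; returns (genomes, manifest)."""
    genomes = []
    manifest = TruthManifest()
    for i, spec in enumerate(specs, 1):
        gid = f"syn{i:03d}_{spec.template}"
        genome, entry = generate_genome(spec, gid)
        genomes.append(genome)
        manifest.genomes[gid] = entry
    return genomes, manifest


def write_genomes_fasta(genomes, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id} {g.description}".rstrip() + "\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")
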