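"""Neighborhood assembly, accessory-role assignment and Group I-V labels.

Around each MbnB anchor the pipeline gathers candidate genes (annotated CDS
when the input is GenBank, maximal ORFs >= 60 aa otherwise), assigns each a
role by best-seed homology (MbnC, the MATE exporter MbnM, the TBDT importer
MbnT, aminotransferase MbnN, sulfotransferase MbnS, FAD oxidoreductase MbnF,
the FecIRA-like regulators MbnI/MbnR, the MbnP/MbnH pair, and genetic
mobility elements), flags TBDTs carrying the N-terminal signalling extension
(NExT), and classifies the operon into one of five groups.

Classification uses only sequence and operon features — never taxonomy — so
the labels generalize to novel genomes:

I   long 4-cysteine proline-containing cores, or the MbnI/MbnR/NExT-MbnT
    regulatory signature;
II  2-3 core cysteines plus a sulfotransferase/oxidoreductase or a CAST-like
    (conserved-threonine) core, including the Cys-Trp subfamily;
III cores with cysteine doublets;
IV  exactly two non-adjacent core cysteines;
V   single-cysteine cores with no MbnC and an extra gene between MbnA and
    MbnB.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from . import align
from .anchors import ProteinHit, SeedProtein
from .precursor import MiningConfig, PrecursorCandidate, enumerate_small_orfs
from .records import GenomeRecord, Region

ROLE_E_MAX_DEFAULT = 1e-10
NEIGHBORHOOD_WINDOW_DEFAULT = 10000
MIN_GENE_AA = 60
NEXT_MIN_UPSTREAM = 70

ROLES = (
    "MbnA", "MbnB", "MbnC", "MbnM", "MbnT", "MbnN", "MbnS", "MbnF",
    "MbnI", "MbnR", "MbnP", "MbnH", "mobility", "unknown",
)


@dataclass
class GeneAssignment:
    region: Region
    role: str
    evidence: tuple | None = None  # (seed_id, bitscore, evalue)
    next_extension: bool = False
    aa_seq: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role not in ("MbnA", "unknown") and self.evidence is None:
            raise ValueError(f"role {self.role} requires homology evidence")

    def to_dict(self) -> dict:
        return {
            "region": self.region.to_dict(),
            "role": self.role,
            "evidence": list(self.evidence) if self.evidence else None,
            "next_extension": self.next_extension,
            "aa_seq": self.aa_seq,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneAssignment":
        d = dict(d)
        d["region"] = Region.from_dict(d["region"])
        if d["evidence"] is not None:
            d["evidence"] = tuple(d["evidence"])
        return cls(**d)


@dataclass
class OperonModel:
    """An assembled Mbn-like operon: anchor, role-assigned neighborhood genes,
    ranked precursor candidates (the first is the detection call) and the
    group label."""

    genome_id: str
    anchor: ProteinHit
    genes: list
    precursors: list
    group: str = "unclassified"
    group_rationale: str = ""
    truncated: bool = False
    anchor_tier: str = ""
    product: dict | None = None

    @property
    def primary_precursor(self) -> PrecursorCandidate:
        return self.precursors[0]

    def roles_present(self) -> set:
        return {g.role for g in self.genes}

    def has_role(self, role: str) -> bool:
        return any(g.role == role for g in self.genes)

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "anchor": self.anchor.to_dict(),
            "genes": [g.to_dict() for g in self.genes],
            "precursors": [p.to_dict() for p in self.precursors],
            "group": self.group,
            "group_rationale": self.group_rationale,
            "truncated": self.truncated,
            "anchor_tier": self.anchor_tier,
            "product": self.product,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OperonModel":
        d = dict(d)
        d["anchor"] = ProteinHit.from_dict(d["anchor"])
        d["genes"] = [GeneAssignment.from_dict(g) for g in d["genes"]]
        d["precursors"] = [PrecursorCandidate.from_dict(p) for p in d["precursors"]]
        return cls(**d)

    def gff_items(self):
        """(kind, region, attributes) triples for GFF3 export."""
        span = Region(
            self.genome_id,
            min(g.region.start for g in self.genes),
            max(g.region.end for g in self.genes),
            self.anchor.strand,
        )
        yield "operon", span, {"group": self.group}
        yield "anchor", self.anchor.region, {"Name": "MbnB", "tier": self.anchor_tier}
        for p in self.precursors:
            yield "precursor", p.orf.region, {"Name": "MbnA", "core": p.core}
        for g in self.genes:
            if g.role in ("MbnA",):
                continue
            attrs = {"Name": g.role}
            if g.next_extension:
                attrs["next_extension"] = "true"
            yield "gene", g.region, attrs

    def tsv_row(self):
        roles = ",".join(sorted(self.roles_present() - {"unknown"}))
        prod = ""
        if self.product:
            prod = self.product.get("summary", "")
        p = self.primary_precursor
        return [
            self.genome_id,
            self.group,
            self.anchor.region.start,
            self.anchor.region.end,
            self.anchor.strand,
            p.core,
            roles,
            prod,
            self.group_rationale,
        ]


# ---------------------------------------------------------------------------
# Neighborhood collection and role assignment
# ---------------------------------------------------------------------------

def collect_neighborhood(
    genome: GenomeRecord,
    anchor: ProteinHit,
    role_seeds,
    window_nt: int = NEIGHBORHOOD_WINDOW_DEFAULT,
    cds_features=None,
    role_e_max: float = ROLE_E_MAX_DEFAULT,
    next_profile=None,
) -> list[GeneAssignment]:
    """Role-assign every candidate gene within ``window_nt`` of the anchor.

    A gene takes the role of its best-scoring seed when that alignment's
    expectation is below ``role_e_max``; otherwise it is ``unknown``.  TBDT
    (MbnT) genes are additionally checked for the N-terminal extension.
    """
    win = Region(
        genome.id,
        max(0, anchor.region.start - window_nt),
        min(len(genome), anchor.region.end + window_nt),
        "+",
    )
    candidates = []  # (region, aa_seq)
    if cds_features:
        for feat in cds_features:
            if feat.region.genome_id == genome.id and feat.region.overlaps(win):
                candidates.append((feat.region, feat.attributes.get("translation", "")))
    else:
        cfg = MiningConfig(window_nt=window_nt)
        orfs = enumerate_small_orfs(
            genome, anchor.region, cfg, min_len_aa=MIN_GENE_AA, max_len_aa=None
        )
        candidates = [(o.region, o.aa_seq) for o in orfs]

    assignments = []
    for region, aa in candidates:
        if not aa:
            continue
        role, evidence, plug_start = _best_role(aa, role_seeds, role_e_max)
        ga = GeneAssignment(region=region, role=role, evidence=evidence, aa_seq=aa)
        if role == "MbnT" and next_profile is not None:
            ga.next_extension = detect_next_extension(aa, plug_start, next_profile)
        assignments.append(ga)
    assignments.sort(key=lambda g: (g.region.start, g.region.end))
    return assignments


def _best_role(aa: str, role_seeds, role_e_max: float):
    best = None
    aa = "".join(c if c in align.PROTEIN_ALPHABET else "X" for c in aa)
    for seed in role_seeds:
        found = align.best_local_alignment(aa, seed.aa_seq)
        if found is None:
            continue
        raw, (t0, _t1), _q, _cov = found
        ev = align.evalue(raw, len(seed), len(aa))
        if best is None or ev < best[2]:
            best = (seed, raw, ev, t0)
    if best is None or best[2] >= role_e_max:
        return "unknown", None, None
    seed, raw, ev, t0 = best
    return seed.role, (seed.id, align.bitscore(raw), ev), t0


def detect_next_extension(tbdt_aa: str, plug_match_start, next_profile) -> bool:
    """True when >= 70 residues precede the plug-domain match and that
    N-terminal segment scores above the NExT profile's acceptance threshold
    (the self-score of the weakest training sequence)."""
    if plug_match_start is None:
        import warnings

        warnings.warn("MbnT without a plug-domain match; NExT undetectable")
        return False
    if plug_match_start < NEXT_MIN_UPSTREAM:
        return False
    from .profiles import scan_profile

    res = scan_profile(next_profile, tbdt_aa[:plug_match_start])
    return bool(res.is_hit)


# ---------------------------------------------------------------------------
# Operon assembly and classification
# ---------------------------------------------------------------------------

def assemble_operon(
    genome: GenomeRecord,
    anchor: ProteinHit,
    ranked_candidates,
    genes,
    anchor_tier: str = "",
) -> OperonModel:
    """Combine anchor, neighborhood genes and ranked precursor candidates into
    an operon model (the top candidate becomes the MbnA call)."""
    if not ranked_candidates:
        raise ValueError("an operon requires at least one accepted precursor")
    genes = list(genes)
    primary = ranked_candidates[0]
    # make sure MbnA and MbnB appear in the gene list exactly once
    genes = [
        g
        for g in genes
        if not (g.region.overlaps(primary.orf.region) and g.role == "unknown")
    ]
    genes.append(
        GeneAssignment(region=primary.orf.region, role="MbnA", aa_seq=primary.orf.aa_seq)
    )
    if not any(g.role == "MbnB" for g in genes):
        genes.append(
            GeneAssignment(
                region=anchor.region,
                role="MbnB",
                evidence=(anchor.seed_id, anchor.bitscore, anchor.evalue),
                aa_seq=anchor.translation,
            )
        )
    genes.sort(key=lambda g: (g.region.start, g.region.end))
    truncated = _touches_edge(anchor.region, len(genome)) or any(
        _touches_edge(g.region, len(genome)) for g in genes
    )
    op = OperonModel(
        genome_id=genome.id,
        anchor=anchor,
        genes=genes,
        precursors=list(ranked_candidates),
        truncated=truncated,
        anchor_tier=anchor_tier,
    )
    op.group, op.group_rationale = classify_group(op)
    return op


def _touches_edge(region: Region, genome_len: int) -> bool:
    return region.start == 0 or region.end == genome_len


def _gene_between(op: OperonModel, role_a: str, role_b: str) -> bool:
    """Is there a non-anchor gene strictly between the role_a and role_b genes?"""
    ra = [g.region for g in op.genes if g.role == role_a]
    rb = [g.region for g in op.genes if g.role == role_b]
    if not ra or not rb:
        return False
    a, b = ra[0], rb[0]
    lo, hi = min(a.end, b.end), max(a.start, b.start)
    if lo >= hi:
        return False
    between = Region(op.genome_id, lo, hi, "+")
    for g in op.genes:
        if g.role in (role_a, role_b):
            continue
        if g.region.overlap_len(between) >= min(len(g.region), len(between)) * 0.5:
            return True
    return False


def classify_group(op: OperonModel) -> tuple[str, str]:
    """Apply the Group I-V rules in fixed priority order; total function."""
    p = op.primary_precursor
    core = p.core
    n_cys = p.n_core_cys
    n_cc = p.n_cys_doublets
    has = op.has_role

    # V: single-cysteine divergent operons lacking MbnC, with an extra gene
    if n_cys == 1 and not has("MbnC") and _gene_between(op, "MbnA", "MbnB"):
        return "V", (
            "group V: single core cysteine, no MbnC, and an unassigned gene "
            "between MbnA and MbnB"
        )
    # I: long proline-containing four-cysteine cores, or the full
    # MbnI/MbnR/NExT-MbnT regulatory signature
    next_t = any(g.role == "MbnT" and g.next_extension for g in op.genes)
    if (11 <= len(core) <= 15 and n_cys == 4 and "P" in core) or (
        has("MbnI") and has("MbnR") and next_t
    ):
        return "I", (
            "group I: 11-15 aa core with four cysteines and a proline, or "
            "MbnI+MbnR with a NExT-bearing MbnT"
        )
    # II: short 2-3 cysteine cores with sulfo/FAD genes or CAST-like cores
    trp_sub = _cys_trp_subfamily(core)
    if 2 <= n_cys <= 3 and (has("MbnS") or has("MbnF") or "CAST" in core or trp_sub):
        why = []
        if has("MbnS"):
            why.append("sulfotransferase MbnS present")
        if has("MbnF"):
            why.append("FAD oxidoreductase MbnF present")
        if "CAST" in core:
            why.append("CAST-like core")
        if trp_sub:
            why.append("second cysteine followed by tryptophan")
        return "II", "group II: 2-3 core cysteines with " + "; ".join(why)
    # III: cysteine doublets
    if n_cc >= 1:
        return "III", "group III: core contains a cysteine doublet"
    # IV: exactly two non-adjacent cysteines
    if n_cys == 2 and n_cc == 0:
        return "IV", "group IV: exactly two non-adjacent core cysteines"
    return "unclassified", "no group rule matched"


def _cys_trp_subfamily(core: str) -> bool:
    """Group II subfamily whose second core cysteine is followed by Trp."""
    positions = [i for i, a in enumerate(core) if a == "C"]
    if len(positions) < 2:
        return False
    i = positions[1]
    return i + 1 < len(core) and core[i + 1] == "W"
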