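"""Translated homology search for the conserved Mbn biosynthesis anchors.

The pipeline mines unannotated DNA, so anchor genes (MbnB, the DUF692-like
core biosynthesis protein, and MbnC) are found by aligning seed proteins
against all six reading frames of each contig — a reimplementation of the
tBLASTn workflow with full Smith-Waterman dynamics instead of heuristic word
seeding.  Two expectation-value tiers are used downstream: hits below 1e-20
are examined for neighbouring genes and precursors, and hits below 1e-50 are
labelled members of the core MbnB-like family, reflecting the sharp E-value
drop-off that separates that subgroup from other DUF692-like proteins.

MbnB is split into two consecutive ORFs by an in-frame stop in some genomes
(Methylosinus trichosporium OB3b among them); such split hits are merged into
a single conceptual gene with a glycine bridging the stop.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

from . import align
from .records import GenomeRecord, Region, revcomp

E_MAX_DEFAULT = 1e-20
SUBGROUP_E_DEFAULT = 1e-50
MAX_HITS_PER_FRAME = 8
STOP_CHAR = "*"


@lru_cache(maxsize=None)
def _codon_map() -> dict:
    table = CodonTable.unambiguous_dna_by_id[11]
    m = dict(table.forward_table)
    for stop in table.stop_codons:
        m[stop] = STOP_CHAR
    return m


def translate_frame(seq: str) -> str:
    """Translate a DNA string codon-by-codon (table 11).

    Stop codons become ``*``; any codon containing a character outside
    {A,C,G,T} (N in particular) becomes ``X``.  Trailing partial codons are
    dropped.
    """
    cmap = _codon_map()
    out = []
    for i in range(0, len(seq) - 2, 3):
        out.append(cmap.get(seq[i : i + 3], "X"))
    return "".join(out)


def six_frame_translate(genome: GenomeRecord) -> dict:
    """All six conceptual translations of a contig.

    Returns a dict keyed by ``(strand, frame)`` with strand in ``{"+", "-"}``
    and frame in ``{0, 1, 2}`` relative to that strand (frame f skips the
    first f nucleotides of the strand's 5' end).
    """
    fwd = genome.seq
    rev = revcomp(fwd)
    frames = {}
    for f in range(3):
        frames[("+", f)] = translate_frame(fwd[f:])
        frames[("-", f)] = translate_frame(rev[f:])
    return frames


def frame_to_genome_region(
    genome_len: int, strand: str, frame: int, pstart: int, pend: int, genome_id: str
) -> Region:
    """Map a protein interval [pstart, pend) in a frame back to nt coordinates."""
    nt_start = frame + 3 * pstart
    nt_end = frame + 3 * pend
    if strand == "+":
        return Region(genome_id, nt_start, nt_end, "+")
    return Region(genome_id, genome_len - nt_end, genome_len - nt_start, "-")


@dataclass
class SeedProtein:
    """A search seed: an anchor (MbnB/MbnC) or accessory-role protein."""

    id: str
    role: str
    aa_seq: str

    def __post_init__(self) -> None:
        self.aa_seq = self.aa_seq.upper().rstrip("*")
        bad = set(self.aa_seq) - set(align.PROTEIN_ALPHABET)
        if bad:
            raise ValueError(f"seed {self.id!r} has non-standard residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.aa_seq)


@dataclass
class ProteinHit:
    """One translated-search match of a seed inside a genome."""

    seed_id: str
    region: Region
    frame: int
    raw_score: float
    bitscore: float
    evalue: float
    aligned_fraction: float
    seed_start: int = 0
    seed_end: int = 0
    search_space: int = 0  # m*n used for the E-value, kept for re-scoring
    translation: str = ""
    merged: bool = False

    def __post_init__(self) -> None:
        if len(self.region) % 3 != 0:
            raise ValueError("hit region length must be divisible by 3")
        if not (0.0 < self.aligned_fraction <= 1.0):
            raise ValueError("aligned_fraction must lie in (0, 1]")

    @property
    def strand(self) -> str:
        return self.region.strand

    def to_dict(self) -> dict:
        return {
            "seed_id": self.seed_id,
            "region": self.region.to_dict(),
            "frame": self.frame,
            "raw_score": self.raw_score,
            "bitscore": self.bitscore,
            "evalue": self.evalue,
            "aligned_fraction": self.aligned_fraction,
            "seed_start": self.seed_start,
            "seed_end": self.seed_end,
            "search_space": self.search_space,
            "translation": self.translation,
            "merged": self.merged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProteinHit":
        d = dict(d)
        d["region"] = Region.from_dict(d["region"])
        return cls(**d)


def search_anchors(
    genome: GenomeRecord,
    seeds,
    e_max: float = E_MAX_DEFAULT,
) -> list[ProteinHit]:
    """Six-frame Smith-Waterman search of every seed against a contig.

    Hits with ``evalue < e_max`` are returned sorted by E-value ascending.
    Multiple non-overlapping hits per frame are recovered by masking each
    reported alignment with stop sentinels and re-searching, so a stop-split
    gene yields one hit per fragment.  Overlap deduplication falls out of the
    masking: a later hit can never reuse already-reported positions.
    """
    if not seeds:
        raise ValueError("at least one seed protein is required")
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    for s in seeds:
        if len(s) < 10:
            raise ValueError(
                f"seed {s.id!r} is shorter than 10 aa; alignment statistics unreliable"
            )
    frames = six_frame_translate(genome)
    n_total = sum(len(v) for v in frames.values())
    hits: list[ProteinHit] = []
    for seed in seeds:
        m = len(seed)
        space = m * n_total
        for (strand, frame), prot in frames.items():
            target = prot
            for _ in range(MAX_HITS_PER_FRAME):
                found = align.best_local_alignment(target, seed.aa_seq)
                if found is None:
                    break
                raw, (t0, t1), (q0, q1), covered = found
                if align.evalue(raw, m, n_total) >= e_max:
                    break
                # a single alignment may step over an in-frame stop with a
                # gap; report each stop-free fragment as its own hit so the
                # split-gene merge logic sees the fragments explicitly
                for f0, f1, fraw, fq0, fq1, fcov in _stop_free_subhits(
                    target, seed.aa_seq, t0, t1, raw, q0, q1, covered
                ):
                    ev = align.evalue(fraw, m, n_total)
                    if ev >= e_max:
                        continue
                    region = frame_to_genome_region(
                        len(genome), strand, frame, f0, f1, genome.id
                    )
                    hits.append(
                        ProteinHit(
                            seed_id=seed.id,
                            region=region,
                            frame=frame,
                            raw_score=fraw,
                            bitscore=align.bitscore(fraw),
                            evalue=ev,
                            aligned_fraction=fcov / m,
                            seed_start=fq0,
                            seed_end=fq1,
                            search_space=space,
                            translation=prot[f0:f1],
                        )
                    )
                target = target[:t0] + STOP_CHAR * (t1 - t0) + target[t1:]
    hits.sort(key=lambda h: (h.evalue, h.region.start))
    return hits


def _stop_free_subhits(target, seed_aa, t0, t1, raw, q0, q1, covered):
    """Break an alignment whose target span contains stop sentinels into
    per-fragment local alignments; pass through unchanged otherwise."""
    span = target[t0:t1]
    if STOP_CHAR not in span:
        return [(t0, t1, raw, q0, q1, covered)]
    out = []
    pos = 0
    for piece in span.split(STOP_CHAR):
        if len(piece) >= 10:
            sub = align.best_local_alignment(piece, seed_aa)
            if sub is not None:
                sraw, (s0, s1), (sq0, sq1), scov = sub
                out.append((t0 + pos + s0, t0 + pos + s1, sraw, sq0, sq1, scov))
        pos += len(piece) + 1
    return out


def tier_anchor(hit: ProteinHit, subgroup_e: float = SUBGROUP_E_DEFAULT) -> str:
    """Classify a hit as ``core_family`` (E strictly below the subgroup tier)
    or ``distant_relative``."""
    return "core_family" if hit.evalue < subgroup_e else "distant_relative"


def merge_split_hits(
    genome: GenomeRecord,
    hits,
    seeds_by_id: dict | None = None,
    max_gap_nt: int = 30,
) -> list[ProteinHit]:
    """Merge pairs of hits that represent one gene split by a single stop.

    Two hits merge when they match the same seed on the same strand and frame,
    are collinear in the seed, lie within ``max_gap_nt`` of each other, and
    exactly one in-frame stop codon separates them.  The merged hit's
    conceptual translation bridges the stop with a glycine (mirroring the
    glycine-bridged conjugate used to annotate split MbnB genes) and is
    re-scored against the seed.  Non-mergeable hits pass through unchanged.
    """
    seeds_by_id = seeds_by_id or {}
    by_group: dict = {}
    for h in hits:
        by_group.setdefault((h.seed_id, h.strand, h.frame), []).append(h)

    merged_out: list[ProteinHit] = []
    for (seed_id, strand, frame), group in by_group.items():
        # order along the reading direction of the strand
        group.sort(key=lambda h: h.region.start, reverse=(strand == "-"))
        i = 0
        while i < len(group):
            h = group[i]
            if i + 1 < len(group):
                nxt = group[i + 1]
                m = _try_merge(genome, h, nxt, seeds_by_id.get(seed_id), max_gap_nt)
                if m is not None:
                    group[i + 1] = m
                    i += 1
                    continue
            merged_out.append(h)
            i += 1
    merged_out.sort(key=lambda h: (h.evalue, h.region.start))
    return merged_out


def _try_merge(genome, h1, h2, seed, max_gap_nt):
    strand = h1.strand
    if strand == "+":
        gap_start, gap_end = h1.region.end, h2.region.start
    else:
        gap_start, gap_end = h2.region.end, h1.region.start
    gap = gap_end - gap_start
    if gap < 0 or gap > max_gap_nt or gap % 3 != 0:
        return None
    # collinear in the seed, allowing a few residues of slop at the junction
    if not (h1.seed_start < h2.seed_start and h1.seed_end <= h2.seed_start + 5):
        return None
    gap_dna = genome.seq[gap_start:gap_end]
    if strand == "-":
        gap_dna = revcomp(gap_dna)
    if translate_frame(gap_dna).count(STOP_CHAR) != 1:
        return None
    span_start = min(h1.region.start, h2.region.start)
    span_end = max(h1.region.end, h2.region.end)
    span_dna = genome.seq[span_start:span_end]
    if strand == "-":
        span_dna = revcomp(span_dna)
    bridged = translate_frame(span_dna).replace(STOP_CHAR, "G")
    space = h1.search_space
    if seed is not None:
        found = align.best_local_alignment(bridged, seed.aa_seq)
        if found is None:
            return None
        raw, _t, (q0, q1), covered = found
        frac = covered / len(seed)
    else:  # no seed sequence at hand: approximate with the summed fragments
        raw = h1.raw_score + h2.raw_score
        q0, q1 = h1.seed_start, h2.seed_end
        frac = min(1.0, h1.aligned_fraction + h2.aligned_fraction)
    ev = align.evalue(raw, 1, max(1, space))
    return ProteinHit(
        seed_id=h1.seed_id,
        region=Region(genome.id, span_start, span_end, strand),
        frame=h1.frame,
        raw_score=raw,
        bitscore=align.bitscore(raw),
        evalue=ev,
        aligned_fraction=min(1.0, frac),
        seed_start=q0,
        seed_end=q1,
        search_space=space,
        translation=bridged,
        merged=True,
    )
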