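"""Small-ORF enumeration and MbnA precursor-peptide criteria.

Mbn precursor peptides (MbnA) are short (10-50 aa) ribosomal peptides that
standard gene callers routinely miss, so every MbnB anchor's flanking 2 kb is
scanned for candidate small ORFs, which are then filtered on the features the
known precursors share:

* at least one cysteine within the last 10 residues (the core peptide, the
  part that becomes the mature natural product, is C-terminal and its
  cysteines become thioamides/heterocycles);
* multiple (>= 2 by default) lysines/arginines within the first 10 residues
  of the leader;
* a lysine or arginine a few residues before the first cysteine, preceded by
  a hydrophobic block — the conserved leader/core junction.

The leader/core split places the core start one residue before the first
cysteine, which reproduces the two experimentally grounded splits:
MTVKIAQKKVLPVIGRAAA | LCGSCYPCSCM and MTIRIAKRITLNVIGRASA | RCASTCAATNG.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

from .records import GenomeRecord, Region, revcomp
from .anchors import translate_frame

START_CODONS_DEFAULT = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

CORE_MOTIF_RE = re.compile(r"(?=C[GAS][ST])")
RING_SITE_RE = re.compile(r"(?=C[GAS])")


@dataclass
class MiningConfig:
    """Tunable thresholds of the precursor scan (defaults follow the study
    conditions: 2 kb windows, 10-50 aa ORFs, 10-residue head/tail windows)."""

    window_nt: int = 2000
    min_len_aa: int = 10
    max_len_aa: int = 50
    last_k: int = 10
    first_k: int = 10
    min_kr: int = 2
    hydrophobic_set: frozenset = frozenset("AVLIMFWP")
    hydrophobic_window: int = 6
    min_hydrophobic: int = 3
    pre_cys_window: int = 5
    start_codons: tuple = START_CODONS_DEFAULT

    def __post_init__(self) -> None:
        if self.min_len_aa >= self.max_len_aa:
            raise ValueError("min_len_aa must be < max_len_aa")
        if self.window_nt <= 0:
            raise ValueError("window_nt must be positive")
        for v in (self.last_k, self.first_k, self.min_kr, self.hydrophobic_window,
                  self.min_hydrophobic, self.pre_cys_window):
            if v < 1:
                raise ValueError("all thresholds must be >= 1")


@dataclass
class SmallOrf:
    """A small ORF: start codon through the first in-frame stop (region
    includes the stop codon; aa_seq does not)."""

    region: Region
    aa_seq: str
    start_codon: str

    def __post_init__(self) -> None:
        if len(self.region) != 3 * (len(self.aa_seq) + 1):
            raise ValueError("ORF region must cover peptide plus stop codon")

    def to_dict(self) -> dict:
        return {
            "region": self.region.to_dict(),
            "aa_seq": self.aa_seq,
            "start_codon": self.start_codon,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SmallOrf":
        return cls(Region.from_dict(d["region"]), d["aa_seq"], d["start_codon"])


@dataclass
class PrecursorCandidate:
    """A scored small ORF with criterion flags and the leader/core split."""

    orf: SmallOrf
    criteria: dict
    accepted: bool
    score: float
    leader: str = ""
    core: str = ""
    no_leader: bool = False
    core_motifs: list = field(default_factory=list)
    ring_sites: list = field(default_factory=list)
    n_core_cys: int = 0
    n_cys_doublets: int = 0
    fused: bool = False

    def to_dict(self) -> dict:
        d = {
            "orf": self.orf.to_dict(),
            "criteria": dict(self.criteria),
            "accepted": self.accepted,
            "score": self.score,
            "leader": self.leader,
            "core": self.core,
            "no_leader": self.no_leader,
            "core_motifs": [list(m) for m in self.core_motifs],
            "ring_sites": list(self.ring_sites),
            "n_core_cys": self.n_core_cys,
            "n_cys_doublets": self.n_cys_doublets,
            "fused": self.fused,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PrecursorCandidate":
        d = dict(d)
        d["orf"] = SmallOrf.from_dict(d["orf"])
        d["core_motifs"] = [tuple(m) for m in d["core_motifs"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# ORF enumeration
# ---------------------------------------------------------------------------

_UNSET = object()


def enumerate_small_orfs(
    genome: GenomeRecord,
    around: Region,
    cfg: MiningConfig | None = None,
    min_len_aa: int | object = _UNSET,
    max_len_aa: int | None | object = _UNSET,
) -> list[SmallOrf]:
    """All small ORFs on both strands within ``around`` extended by the
    configured window, clipped to the contig (wrapped when circular).

    An ORF runs from a configured start codon to the first in-frame stop;
    nested ORFs sharing a stop are reported only from their longest in-bounds
    start.  ``min_len_aa``/``max_len_aa`` override the config bounds (used by
    the operon builder to call ordinary genes with the same machinery).
    """
    cfg = cfg or MiningConfig()
    lo = cfg.min_len_aa if min_len_aa is _UNSET else min_len_aa
    hi = cfg.max_len_aa if max_len_aa is _UNSET else max_len_aa  # None: unbounded
    L = len(genome)
    win_start = around.start - cfg.window_nt
    win_end = around.end + cfg.window_nt
    if genome.topology == "circular":
        if win_end - win_start >= L:
            win_start, win_end = 0, L
            window_seq = genome.seq
        else:
            window_seq = "".join(
                genome.seq[i % L] for i in range(win_start, win_end)
            )
    else:
        win_start = max(0, win_start)
        win_end = min(L, win_end)
        if win_start >= L or win_end <= 0 or win_start >= win_end:
            raise ValueError("mining window lies entirely outside the contig")
        window_seq = genome.seq[win_start:win_end]

    orfs = _orfs_in_window(window_seq, cfg.start_codons, lo, hi)
    out = []
    for strand, w0, w3, pep, start_codon in orfs:
        if genome.topology == "circular":
            g0 = (win_start + w0) % L
            # regions never wrap in the report; skip the rare origin-spanning ORF
            g3 = g0 + (w3 - w0)
            if g3 > L:
                continue
        else:
            g0 = win_start + w0
            g3 = win_start + w3
        out.append(
            SmallOrf(
                region=Region(genome.id, g0, g3, strand),
                aa_seq=pep,
                start_codon=start_codon,
            )
        )
    out.sort(key=lambda o: (o.region.start, o.region.strand))
    return out


def _orfs_in_window(seq: str, start_codons, lo: int, hi: int | None):
    """Yield (strand, window_start, window_end, peptide, start_codon) tuples;
    window coordinates are forward-strand offsets into ``seq`` including the
    stop codon.  One ORF per (strand, stop): the longest in-bounds start."""
    W = len(seq)
    results = {}
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        stop_index = _first_stop_index(s)
        for i in range(0, W - 2):
            codon = s[i : i + 3]
            if codon not in start_codons:
                continue
            j = stop_index[i]
            if j is None:
                continue
            n_aa = (j - i) // 3
            if not (lo <= n_aa <= (hi if hi is not None else n_aa)):
                continue
            key = (strand, j)
            if key in results and results[key][0] >= n_aa:
                continue
            pep = "M" + translate_frame(s[i + 3 : j])
            if strand == "+":
                w0, w3 = i, j + 3
            else:
                w0, w3 = W - (j + 3), W - i
            results[key] = (n_aa, (strand, w0, w3, pep, codon))
    return [v for _n, v in results.values()]


def _first_stop_index(s: str):
    """For every position i, the offset of the first in-frame stop codon at or
    after i (None if the frame runs off the end)."""
    W = len(s)
    nxt: list = [None] * max(W, 1)
    for f in range(3):
        last = None
        start = W - ((W - f) % 3) - 3
        for i in range(start, f - 1, -3):
            if i < 0:
                break
            if s[i : i + 3] in STOP_CODONS:
                last = i
            nxt[i] = last
    return nxt


# ---------------------------------------------------------------------------
# Criteria, leader/core split, motifs
# ---------------------------------------------------------------------------

def score_candidate(orf: SmallOrf, cfg: MiningConfig | None = None) -> PrecursorCandidate:
    """Apply the precursor criteria; always returns a candidate whose
    ``accepted`` flag and per-criterion diagnostics record the outcome."""
    cfg = cfg or MiningConfig()
    pep = orf.aa_seq
    n_cys = pep.count("C")
    head = pep[: cfg.first_k]
    n_kr_head = sum(1 for a in head if a in "KR")

    cys_in_tail = "C" in pep[-cfg.last_k :]
    kr_in_head = n_kr_head >= cfg.min_kr
    hydrophobic_block = _has_hydrophobic_block(pep, cfg)

    criteria = {
        "cys_in_tail": cys_in_tail,
        "kr_in_head": kr_in_head,
        "hydrophobic_block": hydrophobic_block,
    }
    accepted = all(criteria.values())
    score = n_cys + n_kr_head + (1 if hydrophobic_block else 0)
    cand = PrecursorCandidate(
        orf=orf, criteria=criteria, accepted=accepted, score=float(score)
    )
    if accepted:
        leader, core, no_leader = split_leader_core(pep, cfg)
        motifs, ring_sites, n_core_cys, n_cc = find_core_motifs(core)
        cand.leader, cand.core, cand.no_leader = leader, core, no_leader
        cand.core_motifs = motifs
        cand.ring_sites = ring_sites
        cand.n_core_cys = n_core_cys
        cand.n_cys_doublets = n_cc
    return cand


def _has_hydrophobic_block(pep: str, cfg: MiningConfig) -> bool:
    """A K/R within ``pre_cys_window`` residues upstream of the first Cys,
    itself preceded by >= min_hydrophobic residues from the hydrophobic set
    within ``hydrophobic_window`` positions."""
    fc = pep.find("C")
    if fc < 0:
        return False
    for p in range(max(0, fc - cfg.pre_cys_window), fc):
        if pep[p] not in "KR":
            continue
        block = pep[max(0, p - cfg.hydrophobic_window) : p]
        if sum(1 for a in block if a in cfg.hydrophobic_set) >= cfg.min_hydrophobic:
            return True
    return False


def split_leader_core(
    peptide: str, cfg: MiningConfig | None = None
) -> tuple[str, str, bool]:
    """Split a precursor peptide into (leader, core, no_leader_flag).

    The core starts one residue before the first cysteine.  When the first
    cysteine sits at position <= 2 (1-based) there is no room for a leader;
    the whole peptide is returned as core with the flag set.
    """
    fc = peptide.find("C")
    if fc < 0:
        raise ValueError("peptide contains no cysteine; no core can be defined")
    if fc <= 1:  # 1-based position <= 2
        return "", peptide, True
    split = fc - 1
    return peptide[:split], peptide[split:], False


def find_core_motifs(core: str):
    """Motif inventory of a core peptide.

    Returns ``(core_motifs, ring_sites, n_core_cys, n_cys_doublets)`` where
    ``core_motifs`` lists (offset, 3-mer) matches of C[GAS][ST],
    ``ring_sites`` lists the 0-based offsets of cysteines followed by G/A/S
    (the cyclization/thioamidation signature), and doublets count CC pairs.
    """
    if not core:
        raise ValueError("core peptide is empty")
    motifs = [(m.start(), core[m.start() : m.start() + 3]) for m in CORE_MOTIF_RE.finditer(core)]
    ring_sites = [m.start() for m in RING_SITE_RE.finditer(core)]
    n_core_cys = core.count("C")
    n_cc = len(re.findall(r"(?=CC)", core))
    return motifs, ring_sites, n_core_cys, n_cc


def rank_candidates(candidates, anchor: Region):
    """Order accepted candidates for the per-operon precursor call.

    Two family-level plausibility keys lead the ordering: known precursor
    cores are 7-15 aa and every one carries at least one C(G|A|S)(S|T)
    motif.  Ties then break by score, proximity to the anchor, and leftmost
    coordinate.
    """

    def distance(c):
        r = c.orf.region
        if r.end <= anchor.start:
            return anchor.start - r.end
        if r.start >= anchor.end:
            return r.start - anchor.end
        return 0

    return sorted(
        candidates,
        key=lambda c: (
            0 if 7 <= len(c.core) <= 15 else 1,
            0 if c.core_motifs else 1,
            -c.score,
            distance(c),
            c.orf.region.start,
        ),
    )
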