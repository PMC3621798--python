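"""Position-specific scoring profiles for precursor and NExT detection.

Profiles here are ungapped log-odds matrices built from curated alignments —
sufficient for the fixed-length precursor cores and the TBDT N-terminal
extension, and far simpler than full profile HMMs.  The acceptance threshold
of a profile is the self-score of its weakest training sequence, so every
training sequence scores as a hit by construction.  A minimal HMMER3-ASCII
emitter is provided for interchange (parity with hmmbuild is a non-goal).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .align import PROTEIN_ALPHABET
from .msa import GAP, Alignment

FLOOR_SCORE = -10.0  # nats, for residues unobserved in the training alignment
MAX_GAP_FRACTION = 0.5


@dataclass
class ScanResult:
    score: float
    offset: int | None
    is_hit: bool
    warning: str | None = None


@dataclass
class Profile:
    columns: list            # per-column residue -> probability
    background: dict         # residue -> background frequency
    pseudocount: float
    acceptance_threshold: float
    log_odds: list = field(default_factory=list)  # per-column residue -> nats
    training_ids: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.columns)

    def column_score(self, j: int, residue: str) -> float:
        return self.log_odds[j].get(residue, FLOOR_SCORE)

    def score_window(self, seq: str, offset: int) -> float:
        return sum(
            self.column_score(j, seq[offset + j]) for j in range(self.length)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "columns": self.columns,
                "background": self.background,
                "pseudocount": self.pseudocount,
                "acceptance_threshold": self.acceptance_threshold,
                "log_odds": self.log_odds,
                "training_ids": self.training_ids,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "Profile":
        return cls(**json.loads(text))


def build_profile(
    aln: Alignment, pseudocount: float = 0.5, background: dict | None = None
) -> Profile:
    """Build an ungapped log-odds profile from an alignment.

    Columns with more than 50% gaps are dropped.  Column probabilities are
    ``(count + pseudocount * bg) / (n + pseudocount)`` with n the number of
    residues observed in the column; the default background is uniform over
    the residues observed anywhere in the alignment.  The acceptance
    threshold is the minimum per-row aligned self-score.
    """
    if not aln.rows:
        raise ValueError("empty alignment")
    n_rows = len(aln.rows)
    kept = [
        j
        for j in range(aln.n_cols)
        if sum(1 for r in aln.rows if r[j] == GAP) / n_rows <= MAX_GAP_FRACTION
    ]
    if not kept:
        raise ValueError("alignment has no usable (non-gap-majority) columns")

    observed = sorted({c for r in aln.rows for c in r if c != GAP})
    if background is None:
        background = {a: 1.0 / len(observed) for a in observed}
    total_bg = sum(background.values())
    if abs(total_bg - 1.0) > 1e-6:
        background = {a: p / total_bg for a, p in background.items()}

    columns = []
    log_odds = []
    for j in kept:
        residues = [r[j] for r in aln.rows if r[j] != GAP]
        n = len(residues)
        probs = {}
        lods = {}
        for a, bg in background.items():
            count = residues.count(a)
            p = (count + pseudocount * bg) / (n + pseudocount)
            probs[a] = p
            if p > 0 and bg > 0:
                lods[a] = math.log(p / bg)
        columns.append(probs)
        log_odds.append(lods)

    prof = Profile(
        columns=columns,
        background=background,
        pseudocount=pseudocount,
        acceptance_threshold=0.0,
        log_odds=log_odds,
        training_ids=list(aln.ids),
    )
    # threshold: weakest aligned self-score over the training rows
    selfs = []
    for r in aln.rows:
        s = 0.0
        for jj, j in enumerate(kept):
            if r[j] != GAP:
                s += prof.column_score(jj, r[j])
        selfs.append(s)
    prof.acceptance_threshold = min(selfs)
    return prof


def scan_profile(profile: Profile, seq: str) -> ScanResult:
    """Best ungapped window of the profile along ``seq``; a hit iff the score
    reaches the profile's acceptance threshold."""
    L = profile.length
    if len(seq) < L:
        return ScanResult(
            score=float("-inf"),
            offset=None,
            is_hit=False,
            warning="sequence shorter than profile",
        )
    best, best_off = float("-inf"), 0
    for off in range(len(seq) - L + 1):
        s = profile.score_window(seq, off)
        if s > best:
            best, best_off = s, off
    return ScanResult(
        score=best, offset=best_off, is_hit=best >= profile.acceptance_threshold
    )


def write_hmmer3(profile: Profile, name: str, path) -> None:
    """Emit a minimal HMMER3-ASCII match-state rendering of the profile."""
    alpha = PROTEIN_ALPHABET
    lines = [
        "HMMER3/f [mbnmine ungapped profile export]",
        f"NAME  {name}",
        f"LENG  {profile.length}",
        "ALPH  amino",
        "HMM        " + "  ".join(alpha),
    ]
    for j, probs in enumerate(profile.columns, 1):
        scores = []
        for a in alpha:
            p = probs.get(a, 0.0)
            scores.append(f"{-math.log(p):.5f}" if p > 0 else "*")
        lines.append(f"{j:7d} " + " ".join(scores))
    lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Packaged profiles
# ---------------------------------------------------------------------------

def _read_packaged_alignment(filename: str) -> Alignment:
    from Bio import SeqIO

    ref = resources.files("mbnmine.data") / filename
    with resources.as_file(ref) as p:
        recs = list(SeqIO.parse(str(p), "fasta"))
    return Alignment([r.id for r in recs], [str(r.seq).upper() for r in recs])


def load_mbna_profile(pseudocount: float = 0.5) -> Profile:
    """Profile over the packaged precursor seed alignment (two published
    precursors plus synthetic family reconstructions)."""
    return build_profile(_read_packaged_alignment("mbna_seed_alignment.fasta"), pseudocount)


def load_next_profile(pseudocount: float = 0.5) -> Profile:
    """Profile over the packaged synthetic TBDT N-terminal-extension alignment."""
    return build_profile(
        _read_packaged_alignment("synthetic_next_alignment.fasta"), pseudocount
    )
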