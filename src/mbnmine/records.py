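"""Core coordinate and sequence record types shared by every pipeline stage.

All genomic coordinates are 0-based, half-open, and reported on the forward
strand; the strand of a feature is carried as a separate field.  GFF3 output
converts to 1-based inclusive at serialization time only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """One DNA contig/scaffold/chromosome.

    Parameters
    ----------
    id : unique identifier within a run.
    seq : uppercase DNA over {A, C, G, T, N}.
    topology : ``"linear"`` or ``"circular"``.  Circular topology lets
        mining windows wrap across the origin.
    """

    id: str
    seq: str
    topology: str = "linear"
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"genome record {self.id!r} has an empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"genome record {self.id!r} contains characters outside "
                f"{{A,C,G,T,N}}: {sorted(bad)}; ambiguity codes other than N "
                "are rejected rather than silently mapped"
            )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Region:
    """Half-open genomic interval [start, end) on the forward coordinate axis."""

    genome_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad region [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.genome_id == other.genome_id
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "Region") -> int:
        if self.genome_id != other.genome_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def to_gff3_coords(self) -> tuple[int, int]:
        """Convert to the 1-based inclusive convention used by GFF3."""
        return self.start + 1, self.end

    @classmethod
    def from_gff3_coords(
        cls, genome_id: str, start1: int, end1: int, strand: str = "+"
    ) -> "Region":
        return cls(genome_id, start1 - 1, end1, strand)

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "start": self.start,
            "end": self.end,
            "strand": self.strand,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Region":
        return cls(d["genome_id"], d["start"], d["end"], d["strand"])


@dataclass
class Feature:
    """An annotated interval: a CDS from GenBank input or a pipeline call."""

    region: Region
    kind: str  # CDS | smallORF | anchor | precursor | accessory
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind == "CDS" and len(self.region) % 3 != 0:
            raise ValueError("CDS feature length must be divisible by 3")
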