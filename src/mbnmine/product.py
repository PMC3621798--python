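"""Prediction of the mature, post-translationally modified methanobactin.

Characterized Mbns bind copper through two nitrogen heterocycles (oxazolone,
or pyrazinedione for the first site in the Methylocystis family) each paired
with a thioamide derived from an adjacent cysteine.  Given a classified
precursor and its operon's gene content the predictor applies the observed
modification grammar:

1. the leader peptide is removed;
2. every ring-site cysteine (C followed by G/A/S; Cys-Trp sites in Group II
   operons are included at low confidence) becomes a thioamide with a ring on
   the preceding residue — the first ring is a pyrazinedione in Group II
   operons, all others oxazolones;
3. non-ring cysteines pair sequentially into disulfides;
4. an operon aminotransferase (MbnN) adds N-terminal transamination; a
   sulfotransferase (MbnS) sulfonates the first threonine between the first
   two ring cysteines;
5. Group II cores keep a "variably lost" C-terminal tail annotation past the
   last ring cysteine + 2 residues (reproducing the reported -TNG/-NG losses).

Modification offsets are 0-based positions in the core; ring/thioamide pairs
are both recorded at their cysteine.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .operon import OperonModel
from .precursor import PrecursorCandidate


@dataclass
class Modification:
    kind: str
    offset: int | None = None
    partner: int | None = None  # second cysteine of a disulfide pair
    low_confidence: bool = False

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "offset": self.offset,
            "partner": self.partner,
            "low_confidence": self.low_confidence,
        }


@dataclass
class ProductModel:
    core: str
    modifications: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def by_kind(self, kind: str) -> list:
        return [m for m in self.modifications if m.kind == kind]

    def summary(self) -> str:
        """Human-readable modification string, e.g.
        ``pyz(C2)·thio(C2)·oxa(C6)·thio(C6)·sulfo(T5)``."""
        short = {
            "oxazolone_ring": "oxa",
            "pyrazinedione_ring": "pyz",
            "thioamide": "thio",
            "disulfide_pair": "ss",
            "sulfo_threonine": "sulfo",
            "n_terminal_transamination": "transam",
            "variably_lost_tail": "tail",
        }
        parts = []
        for m in self.modifications:
            tag = short[m.kind]
            if m.kind == "disulfide_pair":
                parts.append(f"{tag}(C{m.offset + 1},C{m.partner + 1})")
            elif m.kind == "n_terminal_transamination":
                parts.append(tag)
            elif m.kind == "variably_lost_tail":
                parts.append(f"{tag}({m.offset + 1}-)")
            else:
                res = self.core[m.offset]
                parts.append(f"{tag}({res}{m.offset + 1})")
        return "·".join(parts)

    def to_dict(self) -> dict:
        return {
            "core": self.core,
            "modifications": [m.to_dict() for m in self.modifications],
            "warnings": list(self.warnings),
            "summary": self.summary(),
        }


def predict_product(candidate: PrecursorCandidate, operon: OperonModel) -> ProductModel:
    """Apply the modification grammar to a classified precursor."""
    core = candidate.core
    model = ProductModel(core=core)

    ring_sites = list(candidate.ring_sites)
    low_conf = set()
    if operon.group == "II":
        for i in _cys_trp_sites(core):
            if i not in ring_sites:
                ring_sites.append(i)
                low_conf.add(i)
                model.warnings.append(
                    f"cysteine {i + 1} followed by Trp: heterocycle identity "
                    "unknown in this subfamily, ring predicted at low confidence"
                )
        ring_sites.sort()

    if not ring_sites:
        model.warnings.append("no ring sites: no Mbn-like product predicted")
        return model

    for k, i in enumerate(ring_sites):
        ring_kind = (
            "pyrazinedione_ring" if (k == 0 and operon.group == "II") else "oxazolone_ring"
        )
        lc = i in low_conf
        model.modifications.append(Modification(ring_kind, i, low_confidence=lc))
        model.modifications.append(Modification("thioamide", i, low_confidence=lc))

    free_cys = [i for i, a in enumerate(core) if a == "C" and i not in ring_sites]
    if len(free_cys) > 2:
        model.warnings.append(
            f"{len(free_cys)} free cysteines: higher-order disulfide pairing untested"
        )
    for a, b in zip(free_cys[0::2], free_cys[1::2]):
        model.modifications.append(Modification("disulfide_pair", a, partner=b))
    if len(free_cys) % 2 == 1:
        model.warnings.append(
            f"odd number of free cysteines ({len(free_cys)}); one left unpaired"
        )

    if operon.has_role("MbnN"):
        model.modifications.append(Modification("n_terminal_transamination", 0))

    if operon.has_role("MbnS"):
        t = _first_thr_between_rings(core, ring_sites)
        if t is None:
            model.warnings.append(
                "MbnS present but no threonine between the first two ring "
                "cysteines; sulfonation site unassigned"
            )
        else:
            model.modifications.append(Modification("sulfo_threonine", t))

    if operon.group == "II":
        tail_start = ring_sites[-1] + 3  # past the last ring cysteine + 2 residues
        if tail_start < len(core):
            model.modifications.append(Modification("variably_lost_tail", tail_start))

    return model


def _cys_trp_sites(core: str) -> list:
    return [i for i in range(len(core) - 1) if core[i] == "C" and core[i + 1] == "W"]


def _first_thr_between_rings(core: str, ring_sites) -> int | None:
    if len(ring_sites) < 2:
        return None
    c1, c2 = ring_sites[0], ring_sites[1]
    for i in range(c1 + 1, c2):
        if core[i] == "T":
            return i
    return None
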