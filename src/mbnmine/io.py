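"""Reading genome/protein sequence files and writing all pipeline reports.

Inputs are plain FASTA (unannotated contigs) or GenBank flat files, in which
case CDS features are carried along so that the operon builder can use the
existing annotation instead of calling ORFs.  Outputs are GFF3 (1-based
inclusive coordinates), a lossless JSON report and a one-row-per-operon TSV.
"""
from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable

from .records import Feature, GenomeRecord, Region

CODON_TABLE_ID = 11

GFF3_HEADER = "##gff-version 3"


def read_sequences(path, fmt: str | None = None):
    """Parse genomes from FASTA or GenBank.

    Returns ``(records, features)``; ``features`` is empty for FASTA and holds
    one ``Feature(kind="CDS")`` per annotated CDS for GenBank, with a
    ``translation`` attribute (annotated translation when present, else the
    conceptual codon-table-11 translation of the region).

    Raises ``ValueError`` naming the offending record on malformed input; an
    empty file yields an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".gbff") else "fasta"
    if fmt not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {fmt!r}")

    records: list[GenomeRecord] = []
    features: list[Feature] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:  # Biopython raises assorted parse errors
        raise ValueError(f"malformed {fmt} file {path}: {exc}") from exc
    for rec in parsed:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        topology = "linear"
        if fmt == "genbank" and rec.annotations.get("topology") == "circular":
            topology = "circular"
        try:
            genome = GenomeRecord(
                id=rec.id,
                seq=str(rec.seq),
                topology=topology,
                description=rec.description,
            )
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r} in {path}: {exc}") from exc
        records.append(genome)
        if fmt == "genbank":
            features.extend(_cds_features(rec, genome))
    if not records:
        warnings.warn(f"no sequence records found in {path}")
    return records, features


def _cds_features(rec, genome: GenomeRecord) -> list[Feature]:
    out = []
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        start = int(feat.location.start)
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        region = Region(genome.id, start, end, strand)
        quals = feat.qualifiers
        if "translation" in quals:
            translation = quals["translation"][0]
        else:
            translation = _translate_region(genome.seq, start, end, strand)
        attrs = {"translation": translation}
        for key in ("locus_tag", "gene", "product"):
            if key in quals:
                attrs[key] = quals[key][0]
        out.append(Feature(region=region, kind="CDS", attributes=attrs))
    return out


def _translate_region(seq: str, start: int, end: int, strand: str) -> str:
    from .anchors import translate_frame
    from .records import revcomp

    sub = seq[start:end]
    if strand == "-":
        sub = revcomp(sub)
    return translate_frame(sub).rstrip("*")


def load_seed_proteins(path):
    """Load seed proteins from a FASTA file or a directory of per-role FASTAs.

    In a single FASTA, the role is read from a ``role=NAME`` token on the
    description line; in a directory, each file's stem names the role.
    """
    from .anchors import SeedProtein

    path = Path(path)
    seeds = []
    if path.is_dir():
        for f in sorted(path.glob("*.fasta")) + sorted(path.glob("*.fa")):
            for rec in SeqIO.parse(str(f), "fasta"):
                seeds.append(SeedProtein(rec.id, f.stem, str(rec.seq).upper()))
    else:
        for rec in SeqIO.parse(str(path), "fasta"):
            role = None
            for token in rec.description.split():
                if token.startswith("role="):
                    role = token[5:]
            if role is None:
                role = rec.id
            seeds.append(SeedProtein(rec.id, role, str(rec.seq).upper()))
    if not seeds:
        raise ValueError(f"no seed proteins found at {path}")
    return seeds


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def operons_to_gff3(operons) -> str:
    """Render operon models as GFF3 (coordinates converted to 1-based inclusive)."""
    lines = [GFF3_HEADER]
    for i, op in enumerate(operons, 1):
        oid = f"operon{i:03d}"
        for kind, region, attrs in op.gff_items():
            start1, end1 = region.to_gff3_coords()
            attr_str = ";".join(
                [f"Parent={oid}" if kind != "operon" else f"ID={oid}"]
                + [f"{k}={v}" for k, v in attrs.items()]
            )
            lines.append(
                "\t".join(
                    [
                        region.genome_id,
                        "mbnmine",
                        kind,
                        str(start1),
                        str(end1),
                        ".",
                        region.strand,
                        ".",
                        attr_str,
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def write_results(operons, out_dir) -> dict:
    """Write GFF3 + JSON + TSV reports; returns the paths written."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    gff_path = out_dir / "operons.gff3"
    json_path = out_dir / "operons.json"
    tsv_path = out_dir / "operons.tsv"

    gff_path.write_text(operons_to_gff3(operons))
    json_path.write_text(operons_to_json(operons))

    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "genome_id",
                "group",
                "anchor_start",
                "anchor_end",
                "strand",
                "core",
                "roles",
                "product",
                "rationale",
            ]
        )
        for op in operons:
            w.writerow(op.tsv_row())
    return {"gff3": gff_path, "json": json_path, "tsv": tsv_path}


def operons_to_json(operons) -> str:
    return json.dumps([op.to_dict() for op in operons], indent=1, sort_keys=True)


def read_operons_json(path):
    from .operon import OperonModel

    data = json.loads(Path(path).read_text())
    return [OperonModel.from_dict(d) for d in data]
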