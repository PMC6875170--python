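"""Readers and writers for FASTA, GFF3 and Newick.

Internal coordinates throughout the package are 0-based half-open; GFF3 is
converted to/from 1-based inclusive at this boundary and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
from Bio import SeqIO

from .errors import FormatError, ValidationError

__all__ = [
    "SequenceRecord",
    "FeatureRecord",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_newick",
    "read_alignment_fasta",
]


@dataclass
class SequenceRecord:
    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record with empty id")
        if not self.seq:
            raise ValidationError(f"sequence record {self.id!r} has empty sequence")


@dataclass
class FeatureRecord:
    """One GFF3 feature; start/end are 1-based inclusive as in the file."""

    contig: str
    start: int
    end: int
    strand: str
    type: str
    attributes: dict[str, str] = field(default_factory=dict)
    source: str = "tescope"
    score: str = "."

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"feature on {self.contig}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in "+-.":
            raise ValidationError(f"invalid strand {self.strand!r}")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Sequences are upper-cased and U is mapped to T.  Raises
    :class:`FormatError` naming the offending record on malformed input.
    """
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: first non-blank line is not a FASTA header"
                    )
                break
        else:
            raise FormatError(f"{path}: empty file")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        records.append(SequenceRecord(id=rec.id, seq=seq, description=rec.description))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_alignment_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read an aligned FASTA block; all rows must be equal length."""
    records = read_fasta(path)
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise FormatError(f"{path}: alignment rows have unequal lengths {sorted(lengths)}")
    return records


_GFF_ESCAPE = {"%": "%25", ";": "%3B", "=": "%3D", "&": "%26", ",": "%2C", "\t": "%09", "\n": "%0A"}


def _escape(value: str) -> str:
    out = value.replace("%", "%25")
    for ch, rep in _GFF_ESCAPE.items():
        if ch != "%":
            out = out.replace(ch, rep)
    return out


def _unescape(value: str) -> str:
    return re.sub("%([0-9A-Fa-f]{2})", lambda m: chr(int(m.group(1), 16)), value)


def write_gff3(
    features: Iterable[FeatureRecord],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write GFF3 (version pragma first, 9 tab-separated columns).

    When ``contig_lengths`` is supplied, coordinates are validated against it.
    """
    feats = list(features)
    if contig_lengths is not None:
        for f in feats:
            if f.contig not in contig_lengths:
                raise ValidationError(f"feature on unknown contig {f.contig!r}")
            if f.end > contig_lengths[f.contig]:
                raise ValidationError(
                    f"feature {f.type} on {f.contig}: end {f.end} exceeds "
                    f"contig length {contig_lengths[f.contig]}"
                )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            attrs = ";".join(f"{_escape(k)}={_escape(v)}" for k, v in f.attributes.items())
            fh.write(
                "\t".join(
                    [
                        f.contig,
                        f.source,
                        f.type,
                        str(f.start),
                        str(f.end),
                        f.score,
                        f.strand,
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[FeatureRecord]:
    path = Path(path)
    features = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##gff-version"):
            raise FormatError(f"{path}: missing ##gff-version pragma")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            attrs = {}
            if cols[8] != ".":
                for pair in cols[8].split(";"):
                    if not pair:
                        continue
                    key, _, value = pair.partition("=")
                    attrs[_unescape(key)] = _unescape(value)
            features.append(
                FeatureRecord(
                    contig=cols[0],
                    source=cols[1],
                    type=cols[2],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    score=cols[5],
                    strand=cols[6],
                    attributes=attrs,
                )
            )
    return features


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single Newick tree.

    Tip labels are exposed via ``leaf.taxon.label``; an absent branch length
    is ``None`` (never coerced to zero).
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"{path}: Newick parse error: {exc}") from exc
    return tree


def tip_branch_lengths(tree: dendropy.Tree) -> dict[str, float | None]:
    """Terminal branch length per tip label; ``None`` when absent in the file."""
    out: dict[str, float | None] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        if label is None:
            continue
        out[label] = leaf.edge.length
    return out
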