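"""Divergence-based activity statistics.

Intra-element LTR identity, Nei's nucleotide diversity (pi) over insertion
cohorts, and terminal-branch-length age classification.  LTR sequences are
identical when a daughter element integrates and accumulate mutations
independently afterwards, so the identity between an element's own LTRs
dates the insertion; pi over a family's LTR cohort summarises within-family
divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

import dendropy

from .catalog import SW_GAP, SW_MATCH, SW_MISMATCH, InsertionRecord
from .errors import UndefinedStatisticError, ValidationError
from .genetics import revcomp
from .seqio import read_newick

__all__ = [
    "AlignedBlock",
    "DiversityResult",
    "TipAgeReport",
    "pairwise_identity",
    "intra_element_ltr_identity",
    "nucleotide_diversity",
    "classify_tip_ages",
    "cohort_builder",
]

GAP_CHARS = frozenset("-N")


@dataclass
class AlignedBlock:
    """Equal-length gapped rows; the unit of diversity computation."""

    sequences: list[str]
    ids: list[str]
    cohort: str = "All"

    def __post_init__(self) -> None:
        if len({len(s) for s in self.sequences}) > 1:
            raise ValidationError("alignment rows have unequal lengths")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


@dataclass
class DiversityResult:
    pi: float
    n_sequences: int
    n_sites_analysed: float
    cohort: str


@dataclass
class TipAgeReport:
    """Per-tip young/ancient classification at a substitutions/site cutoff."""

    tips: list[tuple[str, float | None, str]]  # (label, length, class)
    threshold: float

    @property
    def n_ancient(self) -> int:
        return sum(1 for _, _, c in self.tips if c == "ancient")

    @property
    def n_young(self) -> int:
        return sum(1 for _, _, c in self.tips if c == "young")


def _global_align(a: str, b: str) -> tuple[str, str]:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = SW_MATCH
    aligner.mismatch_score = SW_MISMATCH
    aligner.open_gap_score = SW_GAP
    aligner.extend_gap_score = SW_GAP
    aln = aligner.align(a.upper(), b.upper())[0]
    # reconstruct gapped rows from the coordinate path
    ta, tb = [], []
    ca, cb = aln.coordinates
    pa, pb = ca[0], cb[0]
    for na, nb in zip(ca[1:], cb[1:]):
        if na > pa and nb > pb:
            ta.append(a[pa:na].upper())
            tb.append(b[pb:nb].upper())
        elif na > pa:
            ta.append(a[pa:na].upper())
            tb.append("-" * (na - pa))
        else:
            ta.append("-" * (nb - pb))
            tb.append(b[pb:nb].upper())
        pa, pb = na, nb
    return "".join(ta), "".join(tb)


def pairwise_identity(
    seq_a: str, seq_b: str, exclude_indel_columns: bool = False, aligned: bool = False
) -> float:
    """Percent identity between two sequences.

    Unless ``aligned``, the pair is globally aligned first.  Gap columns
    count as mismatches by default; with ``exclude_indel_columns`` they are
    dropped from the denominator (the dual reporting used for elements whose
    LTRs differ mainly by slippage indels).
    """
    if aligned:
        if len(seq_a) != len(seq_b):
            raise ValidationError("pre-aligned sequences must have equal length")
        ra, rb = seq_a.upper(), seq_b.upper()
    else:
        ra, rb = _global_align(seq_a, seq_b)
    matches = compared = 0
    for x, y in zip(ra, rb):
        if x == "-" and y == "-":
            continue
        if exclude_indel_columns and ("-" in (x, y)):
            continue
        compared += 1
        if x == y and x != "-":
            matches += 1
    if compared == 0:
        raise UndefinedStatisticError("no comparable columns")
    return 100.0 * matches / compared


def intra_element_ltr_identity(
    fle_record: InsertionRecord,
    genome: Mapping[str, str] | str,
    exclude_indel_columns: bool = False,
) -> float:
    """Identity between an element's own 5' and 3' LTR copies."""
    if fle_record.kind != "FLE":
        raise ValidationError("intra-element LTR identity requires an FLE record")
    if len(fle_record.ltr_intervals) != 2:
        raise ValidationError("FLE record is missing its LTR intervals")
    contigs = {"chr1": genome} if isinstance(genome, str) else genome
    seq = contigs[fle_record.contig]
    (s1, e1), (s2, e2) = fle_record.ltr_intervals
    return pairwise_identity(seq[s1:e1], seq[s2:e2], exclude_indel_columns)


def nucleotide_diversity(
    block: AlignedBlock, deletion_mode: str = "complete"
) -> DiversityResult:
    """Nei's pi: average pairwise differences per analysed site.

    pi = 2 / (n(n-1)) * sum_{i<j} d_ij / L.  ``complete`` deletion analyses
    only columns free of gaps (and N) in every row, with one shared L;
    ``pairwise`` uses each pair's own gap-free columns (per-pair L).  Not
    distance-corrected: this is raw pi.
    """
    if block.n < 2:
        raise ValidationError("diversity requires at least two sequences")
    if deletion_mode not in ("complete", "pairwise"):
        raise ValidationError(f"unknown deletion_mode {deletion_mode!r}")
    arr = np.array([list(s.upper()) for s in block.sequences])
    bad = np.isin(arr, list(GAP_CHARS))
    if deletion_mode == "complete":
        keep = ~bad.any(axis=0)
        L = int(keep.sum())
        if L == 0:
            raise UndefinedStatisticError("no gap-free columns under complete deletion")
        sub = arr[:, keep]
        total = 0.0
        for i, j in combinations(range(block.n), 2):
            total += np.count_nonzero(sub[i] != sub[j]) / L
        n_pairs = block.n * (block.n - 1) / 2
        return DiversityResult(
            pi=total / n_pairs, n_sequences=block.n, n_sites_analysed=L, cohort=block.cohort
        )
    totals = []
    Ls = []
    for i, j in combinations(range(block.n), 2):
        keep = ~(bad[i] | bad[j])
        L = int(keep.sum())
        if L == 0:
            raise UndefinedStatisticError(f"rows {i},{j}: no shared gap-free columns")
        totals.append(np.count_nonzero(arr[i, keep] != arr[j, keep]) / L)
        Ls.append(L)
    return DiversityResult(
        pi=float(np.mean(totals)),
        n_sequences=block.n,
        n_sites_analysed=float(np.mean(Ls)),
        cohort=block.cohort,
    )


def classify_tip_ages(
    tree: "dendropy.Tree | str", threshold: float = 0.05
) -> TipAgeReport:
    """Classify tree tips as young or ancient by terminal branch length.

    A tip is ancient when its terminal branch length is >= ``threshold``
    substitutions per site (boundary inclusive).  Tips without a branch
    length are reported ``unclassified``, never assumed zero.
    """
    if isinstance(tree, str):
        tree = read_newick(tree)
    tips = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else "?"
        length = leaf.edge.length
        if length is None:
            cls = "unclassified"
        else:
            cls = "ancient" if length >= threshold else "young"
        tips.append((label, length, cls))
    return TipAgeReport(tips=tips, threshold=threshold)


def _representative_ltr(record: InsertionRecord, seq: str) -> str | None:
    """The LTR that represents an insertion: the 5' LTR of an FLE (by
    strand), falling back to the 3'; a solo LTR is itself."""
    if not record.ltr_intervals:
        return None
    ivs = sorted(record.ltr_intervals)
    if record.kind == "FLE":
        s, e = ivs[0] if record.strand == "+" else ivs[-1]
    else:
        s, e = ivs[0]
    ltr = seq[s:e]
    return revcomp(ltr) if record.strand == "-" else ltr


def cohort_builder(
    insertions: Sequence[InsertionRecord],
    genome: Mapping[str, str] | str,
    family: str | None = None,
) -> dict[str, AlignedBlock]:
    """Build All / FLE / Solo aligned LTR cohorts for one family.

    One LTR enters per FLE (5' when present), every solo LTR enters.
    Cohorts with fewer than two sequences are omitted.  Equal-length
    sequences stack directly; otherwise rows are anchored to the longest
    sequence by pairwise global alignment (insertions relative to the
    anchor are discarded).
    """
    contigs = {"chr1": genome} if isinstance(genome, str) else genome
    fle, solo = [], []
    for rec in insertions:
        if family is not None and rec.family != family:
            continue
        ltr = _representative_ltr(rec, contigs[rec.contig])
        if ltr is None:
            continue
        if rec.kind == "FLE":
            fle.append((f"{rec.contig}:{rec.start}", ltr))
        elif rec.kind == "solo_LTR":
            solo.append((f"{rec.contig}:{rec.start}", ltr))
    cohorts = {"All": fle + solo, "FLE": fle, "Solo": solo}
    out = {}
    for name, members in cohorts.items():
        if len(members) < 2:
            continue
        ids = [m[0] for m in members]
        seqs = [m[1] for m in members]
        out[name] = AlignedBlock(sequences=_stack(seqs), ids=ids, cohort=name)
    return out


def _stack(seqs: list[str]) -> list[str]:
    if len({len(s) for s in seqs}) == 1:
        return [s.upper() for s in seqs]
    anchor = max(seqs, key=len)
    rows = []
    for s in seqs:
        ta, tb = _global_align(anchor, s)
        # project onto anchor columns, dropping insertions relative to it
        row = "".join(y for x, y in zip(ta, tb) if x != "-")
        rows.append(row.ljust(len(anchor), "-"))
    return rows
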