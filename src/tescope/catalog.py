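"""Rediscovery and classification of TE insertions in a genome.

Given family definitions (consensus, terminal-repeat and TSD parameters)
the catalog stage scans the genome with terminal-repeat and internal-region
probes, pairs termini through target-site duplications and spacing, and
classifies each locus as a full-length element (FLE), a solo LTR, or a
truncated copy.  Family delimitation follows the 80-80-80 rule: repeats
belong to different families when they share <80% identity over <80% of an
aligned stretch of at least 80 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio import Align

from .errors import ParameterError, UndefinedStatisticError, ValidationError
from .genetics import revcomp
from .simulate import TEFamily

log = logging.getLogger(__name__)

__all__ = [
    "RepeatHit",
    "InsertionRecord",
    "FamilySummary",
    "scan_terminal_repeats",
    "find_tsd",
    "pair_insertions",
    "delimit_families",
    "count_identical_paralogs",
    "summarize_family",
    "catalog_genome",
]

# Pinned local-alignment scores: match +1, mismatch -1, gap -2.
SW_MATCH, SW_MISMATCH, SW_GAP = 1.0, -1.0, -2.0


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = SW_MATCH
    a.mismatch_score = SW_MISMATCH
    a.open_gap_score = SW_GAP
    a.extend_gap_score = SW_GAP
    return a


def _alignment_stats(alignment) -> tuple[int, int, int, int, int]:
    """(matches, columns, t_start, t_end, q_span) of a pairwise alignment."""
    counts = alignment.counts()
    matches = counts.identities
    columns = counts.identities + counts.mismatches + counts.gaps
    t_start = int(alignment.coordinates[0][0])
    t_end = int(alignment.coordinates[0][-1])
    q_span = int(alignment.coordinates[1][-1]) - int(alignment.coordinates[1][0])
    return matches, columns, t_start, t_end, q_span


@dataclass
class RepeatHit:
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    identity: float
    probe: str  # "<family>:<ltr|itr|internal>"
    edge_truncated: bool = False

    @property
    def family(self) -> str:
        return self.probe.split(":", 1)[0]

    @property
    def kind(self) -> str:
        return self.probe.split(":", 1)[1]


def scan_terminal_repeats(
    genome: Mapping[str, str] | str,
    probe_seq: str,
    probe_name: str = "probe:ltr",
    min_identity: float = 0.8,
    seed_k: int = 12,
    min_coverage: float = 0.8,
) -> list[RepeatHit]:
    """Find genomic copies of ``probe_seq`` on both strands.

    k-mer seeds are clustered by diagonal, each candidate window is aligned
    with exact Smith-Waterman at the pinned scores, and hits reaching
    ``min_identity`` over at least ``min_coverage`` of the probe are
    reported; overlapping same-strand hits are merged keeping the higher
    identity.  Identity counts gap columns as mismatches.
    """
    if len(probe_seq) < seed_k:
        raise ParameterError(f"probe ({len(probe_seq)} bp) shorter than seed_k={seed_k}")
    if not 0.5 <= min_identity <= 1.0:
        raise ParameterError("min_identity must be within [0.5, 1]")
    contigs = {"chr1": genome} if isinstance(genome, str) else dict(genome)
    probe_seq = probe_seq.upper()
    aligner = _aligner()
    hits: list[RepeatHit] = []
    for contig, seq in contigs.items():
        seq = seq.upper()
        for strand, probe in (("+", probe_seq), ("-", revcomp(probe_seq))):
            kmers: dict[str, list[int]] = {}
            for i in range(len(probe) - seed_k + 1):
                kmers.setdefault(probe[i : i + seed_k], []).append(i)
            seeds: list[tuple[int, int]] = []  # (diagonal, genome pos)
            for g in range(len(seq) - seed_k + 1):
                positions = kmers.get(seq[g : g + seed_k])
                if positions:
                    for p in positions:
                        seeds.append((g - p, g))
            hits.extend(
                _extend_clusters(seeds, seq, probe, contig, strand, probe_name,
                                 aligner, min_identity, min_coverage)
            )
    return _merge_hits(hits)


def _extend_clusters(
    seeds, seq, probe, contig, strand, probe_name, aligner, min_identity, min_coverage,
    diag_tol: int = 25,
) -> list[RepeatHit]:
    if not seeds:
        return []
    plen = len(probe)
    seeds.sort()
    clusters: list[list[tuple[int, int]]] = [[seeds[0]]]
    for d, g in seeds[1:]:
        pd, pg = clusters[-1][-1]
        if abs(d - pd) <= diag_tol and abs(g - pg) <= plen + diag_tol:
            clusters[-1].append((d, g))
        else:
            clusters.append([(d, g)])
    # clusters on nearby diagonals may describe the same locus; merge by span
    spans = []
    for cl in clusters:
        lo = max(0, min(d for d, _ in cl) - 30)
        hi = min(len(seq), max(d for d, _ in cl) + plen + 30)
        spans.append((lo, hi))
    spans.sort()
    merged = [spans[0]]
    for lo, hi in spans[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    out = []
    # a window may hold several copies of the probe: realign iteratively,
    # masking each reported segment, until the score drops below the floor
    # of a minimally acceptable hit
    score_floor = max(
        min_coverage * plen * (min_identity - (1.0 - min_identity)), 4 * 2
    )
    for lo, hi in merged:
        window = list(seq[lo:hi])
        for _ in range(32):
            try:
                aln = aligner.align("".join(window), probe)[0]
            except IndexError:
                break
            if aln.score < score_floor:
                break
            matches, columns, t0, t1, q_span = _alignment_stats(aln)
            if t1 <= t0:
                break
            if columns > 0 and q_span >= min_coverage * plen:
                identity = matches / columns
                if identity >= min_identity:
                    start, end = lo + t0, lo + t1
                    out.append(
                        RepeatHit(
                            contig=contig,
                            start=start,
                            end=end,
                            strand=strand,
                            identity=identity,
                            probe=probe_name,
                            edge_truncated=start <= 2 or end >= len(seq) - 2,
                        )
                    )
            window[t0:t1] = "X" * (t1 - t0)
    return out


def _merge_hits(hits: list[RepeatHit]) -> list[RepeatHit]:
    hits.sort(key=lambda h: (h.contig, h.strand, h.start, -h.identity))
    out: list[RepeatHit] = []
    for h in hits:
        if out and out[-1].contig == h.contig and out[-1].strand == h.strand and h.start < out[-1].end:
            if h.identity > out[-1].identity:
                out[-1] = h
            continue
        out.append(h)
    out.sort(key=lambda h: (h.contig, h.start))
    return out


class TsdResult(NamedTuple):
    seq: str | None
    at_edge: bool


def find_tsd(
    genome_seq: str,
    left_bound: int,
    right_bound: int,
    len_range: tuple[int, int] = (2, 9),
) -> str | None:
    """Longest identical direct repeat flanking [left_bound, right_bound).

    Returns the longest k in ``len_range`` with
    ``genome[left-k:left] == genome[right:right+k]``, or ``None``.
    """
    return find_tsd_detailed(genome_seq, left_bound, right_bound, len_range).seq


def find_tsd_detailed(
    genome_seq: str,
    left_bound: int,
    right_bound: int,
    len_range: tuple[int, int] = (2, 9),
) -> TsdResult:
    lo, hi = len_range
    if not (0 <= left_bound <= right_bound <= len(genome_seq)):
        raise ParameterError("bounds outside the contig")
    for k in range(hi, lo - 1, -1):
        if left_bound - k < 0 or right_bound + k > len(genome_seq):
            if k == lo:
                return TsdResult(None, True)
            continue
        left = genome_seq[left_bound - k : left_bound]
        if left == genome_seq[right_bound : right_bound + k] and "N" not in left:
            return TsdResult(left, False)
    return TsdResult(None, False)


def _tsd_with_jitter(
    seq: str, left: int, right: int, len_range: tuple[int, int], jitter: int = 5
) -> tuple[str | None, int, int]:
    """TSD search tolerating a few bp of alignment-endpoint slop.

    Offsets are tried nearest-first; returns (tsd, left, right) at the
    offsets that produced the match.
    """
    offsets = sorted(range(-jitter, jitter + 1), key=abs)
    for dl in offsets:
        for dr in offsets:
            l, r = left + dl, right + dr
            if 0 <= l <= r <= len(seq):
                tsd = find_tsd(seq, l, r, len_range)
                if tsd is not None:
                    return tsd, l, r
    return None, left, right


@dataclass
class InsertionRecord:
    family: str
    kind: str  # FLE | solo_LTR | truncated
    contig: str
    start: int
    end: int
    strand: str
    tsd_seq: str | None = None
    ltr_intervals: tuple[tuple[int, int], ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        if self.kind == "FLE" and len(self.ltr_intervals) not in (0, 2):
            raise ValidationError("FLE must carry two LTR intervals")


def _family_tsd_range(family: TEFamily) -> tuple[int, int] | None:
    t = family.tsd_len
    if t is None:
        return None
    if isinstance(t, tuple):
        return t
    return (t, t)


def pair_insertions(
    hits: Sequence[RepeatHit],
    family: TEFamily,
    genome: Mapping[str, str] | str,
    adjacency: int = 150,
    fle_length_tolerance: int = 50,
) -> tuple[list[InsertionRecord], list[InsertionRecord]]:
    """Assemble per-family hits into classified insertion records.

    Returns ``(records, partials)``; partials are loci touching a contig
    edge, excluded from copy-number counts.  Hits are clustered into loci by
    proximity; a locus with two paired termini at a spacing within
    [0.5x, 1.5x] of the consensus internal length (sharing a TSD when the
    family produces one) is an FLE unless >= ``fle_length_tolerance`` bp of
    internal sequence is missing, in which case it is truncated.  A lone
    terminal repeat with no adjacent internal sequence is a solo LTR.
    """
    contigs = {"chr1": genome} if isinstance(genome, str) else dict(genome)
    records: list[InsertionRecord] = []
    partials: list[InsertionRecord] = []
    fam_hits = [h for h in hits if h.family == family.name]
    tsd_range = _family_tsd_range(family)
    internal_len = family.internal_len if family.terminal_repeat_len else len(family.consensus)
    for contig in sorted({h.contig for h in fam_hits}):
        seq = contigs[contig].upper()
        chits = sorted((h for h in fam_hits if h.contig == contig), key=lambda h: h.start)
        # cluster hits into loci: FLE termini are bridged by internal-probe
        # hits, so a small adjacency gap suffices and neighbouring separate
        # insertions stay apart
        clusters: list[list[RepeatHit]] = []
        for h in chits:
            if clusters and h.start - max(x.end for x in clusters[-1]) <= adjacency:
                clusters[-1].append(h)
            else:
                clusters.append([h])
        for cluster in clusters:
            recs = _classify_cluster(
                cluster, family, seq, contig, internal_len, tsd_range,
                fle_length_tolerance,
            )
            if any(h.edge_truncated for h in cluster):
                for rec in recs:
                    rec.notes = (rec.notes + ";" if rec.notes else "") + "contig_edge"
                partials.extend(recs)
            else:
                records.extend(recs)
    if tsd_range is not None:
        records = _join_split_truncations(records, contigs, tsd_range)
    return records, partials


def _join_split_truncations(
    records: list[InsertionRecord],
    contigs: Mapping[str, str],
    tsd_range: tuple[int, int],
    join_gap: int = 800,
) -> list[InsertionRecord]:
    """Rejoin fragments of one damaged insertion.

    An internal deletion can leave a terminal repeat far enough from the
    surviving internal sequence that the two report as separate loci.  When
    a truncated record and an adjacent lone-terminal or truncated record of
    the same family are flanked, as a combined span, by an identical
    target-site duplication, they derive from a single insertion event and
    are merged into one truncated record.
    """
    records = sorted(records, key=lambda r: (r.contig, r.start))
    out: list[InsertionRecord] = []
    for rec in records:
        prev = out[-1] if out else None
        joinable = (
            prev is not None
            and prev.contig == rec.contig
            and prev.family == rec.family
            and prev.strand == rec.strand
            and rec.start - prev.end <= join_gap
            and "truncated" in (prev.kind, rec.kind)
            and {prev.kind, rec.kind} <= {"truncated", "solo_LTR"}
        )
        if joinable:
            seq = contigs[rec.contig].upper()
            tsd, _, _ = _tsd_with_jitter(seq, prev.start, rec.end, tsd_range)
            if tsd is not None:
                out[-1] = InsertionRecord(
                    family=rec.family, kind="truncated", contig=rec.contig,
                    start=prev.start, end=rec.end, strand=rec.strand,
                    tsd_seq=tsd,
                    ltr_intervals=tuple(prev.ltr_intervals) + tuple(rec.ltr_intervals),
                    notes="joined_fragments",
                )
                continue
        out.append(rec)
    return out


def _classify_cluster(
    cluster, family, seq, contig, internal_len, tsd_range, tol
) -> list[InsertionRecord]:
    terminals = [h for h in cluster if h.kind in ("ltr", "itr")]
    internals = [h for h in cluster if h.kind == "internal"]
    strand = terminals[0].strand if terminals else (internals[0].strand if internals else "+")
    start = min(h.start for h in cluster)
    end = max(h.end for h in cluster)

    def tsd_at(l: int, r: int) -> str | None:
        if tsd_range is None:
            return None
        tsd, _, _ = _tsd_with_jitter(seq, l, r, tsd_range)
        return tsd

    if family.terminal_repeat_len is None:
        # no terminal repeats (helitron-like): classify on internal coverage
        kind = "FLE" if end - start >= len(family.consensus) - tol else "truncated"
        return [
            InsertionRecord(
                family=family.name, kind=kind, contig=contig,
                start=start, end=end, strand=strand,
                tsd_seq=tsd_at(start, end),
            )
        ]

    if len(terminals) >= 2:
        pair = _best_terminal_pair(terminals, family, internal_len, seq, tsd_range)
        if pair is not None:
            left, right = pair
            gap = right.start - left.end
            tsd = tsd_at(left.start, right.end)
            kind = "FLE" if abs(gap - internal_len) < tol else "truncated"
            # spacing says full-length but the expected duplication is
            # absent: keep the FLE call and note it
            note = "no_tsd" if (kind == "FLE" and tsd_range and tsd is None) else ""
            # inverted terminal repeats are strand-symmetric, so transposon
            # orientation comes from the internal hit
            rec_strand = left.strand
            if not family.is_ltr and internals:
                rec_strand = internals[0].strand
            return [
                InsertionRecord(
                    family=family.name, kind=kind, contig=contig,
                    start=left.start, end=right.end,
                    strand=rec_strand, tsd_seq=tsd,
                    ltr_intervals=((left.start, left.end), (right.start, right.end)),
                    notes=note,
                )
            ]
    if terminals and not internals:
        if family.is_ltr:
            # lone LTRs with no adjacent internal sequence are solo LTRs
            return [
                InsertionRecord(
                    family=family.name, kind="solo_LTR", contig=contig,
                    start=h.start, end=h.end, strand=h.strand,
                    tsd_seq=tsd_at(h.start, h.end),
                    ltr_intervals=((h.start, h.end),),
                )
                for h in terminals
            ]
        # lone ITRs without internal sequence: fragments, not solo LTRs
        return [
            InsertionRecord(
                family=family.name, kind="truncated", contig=contig,
                start=h.start, end=h.end, strand=h.strand,
                notes="single_terminal",
            )
            for h in terminals
        ]
    if not terminals and not internals:
        return []
    # remaining combinations cover internal sequence without both termini
    ivs = tuple((h.start, h.end) for h in terminals)
    return [
        InsertionRecord(
            family=family.name, kind="truncated", contig=contig,
            start=start, end=end, strand=strand,
            ltr_intervals=ivs,
        )
    ]


def _best_terminal_pair(terminals, family, internal_len, seq, tsd_range):
    """Choose the terminal pair for a locus: TSD presence first, then
    spacing closest to the consensus internal length."""
    lo, hi = 0.5 * internal_len, 1.5 * internal_len
    candidates = []
    for i, a in enumerate(terminals):
        for b in terminals[i + 1 :]:
            if family.is_ltr and a.strand != b.strand:
                continue
            if not family.is_ltr and (a.strand, b.strand) not in (("+", "-"), ("-", "+")):
                continue
            left, right = (a, b) if a.start <= b.start else (b, a)
            gap = right.start - left.end
            if not lo <= gap <= hi:
                continue
            has_tsd = False
            if tsd_range is not None:
                tsd, _, _ = _tsd_with_jitter(seq, left.start, right.end, tsd_range)
                has_tsd = tsd is not None
            candidates.append((not has_tsd, abs(gap - internal_len), left, right))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1]))
    return candidates[0][2], candidates[0][3]


# ---------------------------------------------------------------------------
# 80-80-80 family delimitation


@dataclass
class FamilyPartition:
    groups: list[list[str]]
    subfamily_pairs: list[tuple[str, str]]
    undecidable_pairs: list[tuple[str, str]]
    verdicts: dict[tuple[str, str], str] = field(default_factory=dict)


def delimit_families(
    candidate_repeats: Mapping[str, str],
    identity_threshold: float = 0.80,
    coverage_threshold: float = 0.80,
    min_aligned: int = 80,
    subfamily_window: int = 160,
    subfamily_identity: float = 0.98,
) -> FamilyPartition:
    """Partition candidate repeat consensuses under the 80-80-80 rule.

    Two repeats are the same family when they align at >=80% identity over
    >=80% of the shorter sequence with >=80 aligned bp.  Pairs failing the
    full-length rule but sharing >= ``subfamily_identity`` over the terminal
    ``subfamily_window`` bp of their 3' ends are the same family flagged as
    subfamilies.  Aligned length under ``min_aligned`` gives an undecidable
    verdict, never a split.
    """
    names = sorted(candidate_repeats)
    if len(names) < 2:
        raise ParameterError("need at least two candidate repeats")
    aligner = _aligner()
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    part = FamilyPartition(groups=[], subfamily_pairs=[], undecidable_pairs=[])
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sa, sb = candidate_repeats[a].upper(), candidate_repeats[b].upper()
            verdict = "different"
            try:
                aln = aligner.align(sa, sb)[0]
            except IndexError:
                aln = None
            if aln is not None:
                matches, columns, t0, t1, q_span = _alignment_stats(aln)
                aligned_len = columns
                if aligned_len < min_aligned:
                    verdict = "undecidable"
                elif (
                    matches / columns >= identity_threshold
                    and aligned_len >= coverage_threshold * min(len(sa), len(sb))
                ):
                    verdict = "same"
            if verdict == "different":
                ta, tb = sa[-subfamily_window:], sb[-subfamily_window:]
                try:
                    sub = aligner.align(ta, tb)[0]
                except IndexError:
                    sub = None
                if sub is not None:
                    m, c, *_ = _alignment_stats(sub)
                    if c >= 0.8 * subfamily_window and m / c >= subfamily_identity:
                        verdict = "subfamily"
            part.verdicts[(a, b)] = verdict
            if verdict == "same":
                parent[find(a)] = find(b)
            elif verdict == "subfamily":
                parent[find(a)] = find(b)
                part.subfamily_pairs.append((a, b))
            elif verdict == "undecidable":
                part.undecidable_pairs.append((a, b))
    groups: dict[str, list[str]] = {}
    for n in names:
        groups.setdefault(find(n), []).append(n)
    part.groups = sorted(groups.values())
    return part


def count_identical_paralogs(insertion_sequences: Sequence[str]) -> int:
    """Number of insertions exactly identical to another insertion elsewhere."""
    from collections import Counter

    counts = Counter(s.upper() for s in insertion_sequences)
    return sum(1 for s in insertion_sequences if counts[s.upper()] > 1)


@dataclass
class FamilySummary:
    family: str
    n_fle: int
    n_solo: int
    n_truncated: int
    n_identical_paralogs: int
    read_count: int | None
    ltr_identity_range: tuple[float, float] | None

    @property
    def copy_number_total(self) -> int:
        return self.n_fle + self.n_solo + self.n_truncated

    @property
    def copy_number_display(self) -> str:
        return f"{self.copy_number_total} ({self.n_fle}/{self.n_solo}/{self.n_truncated})"


def summarize_family(
    family: str,
    insertions: Sequence[InsertionRecord],
    expression_count: int | None = None,
    ltr_identities: Sequence[float] = (),
    insertion_sequences: Sequence[str] = (),
) -> FamilySummary:
    ins = [r for r in insertions if r.family == family]
    rng = (min(ltr_identities), max(ltr_identities)) if ltr_identities else None
    return FamilySummary(
        family=family,
        n_fle=sum(1 for r in ins if r.kind == "FLE"),
        n_solo=sum(1 for r in ins if r.kind == "solo_LTR"),
        n_truncated=sum(1 for r in ins if r.kind == "truncated"),
        n_identical_paralogs=(
            count_identical_paralogs(insertion_sequences) if insertion_sequences else 0
        ),
        read_count=expression_count,
        ltr_identity_range=rng,
    )


def summaries_to_tsv(summaries: Iterable[FamilySummary], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "family\tcopy_number\tn_fle\tn_solo\tn_truncated\t"
            "identical_paralogs\treads\tltr_identity_min\tltr_identity_max\n"
        )
        for s in summaries:
            lo, hi = s.ltr_identity_range or ("-", "-")
            fh.write(
                f"{s.family}\t{s.copy_number_display}\t{s.n_fle}\t{s.n_solo}\t"
                f"{s.n_truncated}\t{s.n_identical_paralogs}\t"
                f"{s.read_count if s.read_count is not None else '-'}\t{lo}\t{hi}\n"
            )


def catalog_genome(
    contigs: Mapping[str, str],
    families: Mapping[str, TEFamily],
    min_identity: float = 0.8,
    seed_k: int = 12,
) -> tuple[list[InsertionRecord], list[InsertionRecord]]:
    """Scan + pair every family; returns (records, edge partials)."""
    records: list[InsertionRecord] = []
    partials: list[InsertionRecord] = []
    for name, fam in families.items():
        hits: list[RepeatHit] = []
        if fam.terminal_repeat_len:
            probe_kind = "ltr" if fam.is_ltr else "itr"
            hits += scan_terminal_repeats(
                contigs, fam.terminal_repeat, f"{name}:{probe_kind}",
                min_identity, seed_k,
            )
        internal = fam.internal_seq if fam.terminal_repeat_len else fam.consensus
        # low coverage floor so truncated copies still report internal hits;
        # spurious seeds cannot extend to a quarter of the internal length
        hits += scan_terminal_repeats(
            contigs, internal, f"{name}:internal", min_identity, seed_k,
            min_coverage=0.25,
        )
        recs, parts = pair_insertions(hits, fam, contigs)
        log.info("family %s: %d records, %d partial", name, len(recs), len(parts))
        records += recs
        partials += parts
    return records, partials
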