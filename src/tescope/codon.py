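"""Codon-usage statistics from first principles.

The battery follows the classical population-genetics toolkit for detecting
selection on synonymous codon usage:

* **Nc** - Wright's effective number of codons, from 20 (one codon per
  amino acid: maximal bias) to 61 (uniform synonymous usage).  Computed via
  per-amino-acid codon homozygosity F and its degeneracy-class means:
  ``Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``.
* **GC3s** - the fraction of G or C at synonymous third positions, i.e.
  over codons of amino acids with degeneracy >= 2 (Met, Trp and stops
  excluded).
* **Fop** - frequency of optimal codons: optimal codons divided by total
  sense codons.  The optimal set is host-specific configuration (the suite
  of translationally optimal codons identified from highly expressed host
  genes); it is never inferred here.
* **RSCU** - observed codon count scaled by expectation under equal
  synonymous usage.
* **non-coding GC** - GC fraction over a family's non-coding compartments
  (LTR/ITR, UTRs, introns), the neutral baseline against which GC3s is
  compared when asking whether mutation pressure explains codon bias.

Codons containing N are excluded (and logged).  Stop codons are never
counted.  A repetitive-region mask reproduces the exclusion of
low-complexity CDS stretches applied before expression counting.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import UndefinedStatisticError, ValidationError
from .genetics import GeneticCode, standard_genetic_code

log = logging.getLogger(__name__)

__all__ = [
    "CodingSequence",
    "CodonUsageStats",
    "PreferredCodonEntry",
    "effective_number_of_codons",
    "gc3s",
    "fop",
    "rscu",
    "noncoding_gc",
    "preferred_codon_table",
    "mask_repetitive_regions",
]


@dataclass
class CodingSequence:
    """A CDS as a list of sense codons with optional per-codon region labels.

    ``from_nucleotides`` drops a terminal stop codon, raises on internal
    stops unless ``allow_internal_stops``, and drops codons containing N
    (logged).  ``region_labels``, when present, aligns 1:1 with ``codons``
    with values in {domain, non_domain, masked}.
    """

    id: str
    codons: list[str]
    family: str | None = None
    region_labels: list[str] | None = None
    code: GeneticCode = field(default_factory=standard_genetic_code)

    def __post_init__(self) -> None:
        if not self.codons:
            raise ValidationError(f"CDS {self.id!r}: no codons after exclusions")
        if self.region_labels is not None and len(self.region_labels) != len(self.codons):
            raise ValidationError(f"CDS {self.id!r}: region label length mismatch")

    @classmethod
    def from_nucleotides(
        cls,
        id: str,
        seq: str,
        family: str | None = None,
        code: GeneticCode | None = None,
        allow_internal_stops: bool = False,
        region_labels: Sequence[str] | None = None,
    ) -> "CodingSequence":
        code = code or standard_genetic_code()
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3:
            seq = seq[: len(seq) - len(seq) % 3]
        raw = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        labels = list(region_labels) if region_labels is not None else None
        if raw and code.codon_to_aa.get(raw[-1]) == "*":
            raw = raw[:-1]
            if labels:
                labels = labels[: len(raw)]
        codons, kept_labels = [], []
        n_dropped = 0
        for i, c in enumerate(raw):
            aa = code.codon_to_aa.get(c)
            if aa is None:  # contains N or other ambiguity
                n_dropped += 1
                continue
            if aa == "*":
                if not allow_internal_stops:
                    raise ValidationError(f"CDS {id!r}: internal stop at codon {i}")
                n_dropped += 1
                continue
            codons.append(c)
            if labels is not None:
                kept_labels.append(labels[i])
        if n_dropped:
            log.info("CDS %s: dropped %d ambiguous/stop codons", id, n_dropped)
        return cls(
            id=id, codons=codons, family=family,
            region_labels=kept_labels if labels is not None else None, code=code,
        )

    def counts(self, include_masked: bool = True) -> Counter:
        if include_masked or self.region_labels is None:
            return Counter(self.codons)
        return Counter(
            c for c, lab in zip(self.codons, self.region_labels) if lab != "masked"
        )


@dataclass
class CodonUsageStats:
    """One family's codon-usage summary row."""

    nc: float
    gc3s: float
    fop: float
    noncoding_gc: float | None
    n_codons: int
    class_homozygosity: dict[int, float] = field(default_factory=dict)  # F2,F3,F4,F6


@dataclass
class PreferredCodonEntry:
    amino_acid: str
    most_abundant_codon: str | None  # None on an exact tie
    classification: str  # tRNA_complementary | optimal_non_tRNA | neither | no_single_favoured


def _aa_counts(cds: CodingSequence, include_masked: bool = True) -> dict[str, Counter]:
    by_aa: dict[str, Counter] = {}
    for codon, n in cds.counts(include_masked).items():
        aa = cds.code.codon_to_aa[codon]
        by_aa.setdefault(aa, Counter())[codon] += n
    return by_aa


def effective_number_of_codons(cds: CodingSequence) -> float:
    """Wright's effective number of codons, capped to [20, 61].

    For each amino acid with n >= 2 observed codons the codon homozygosity
    is ``F = (n * sum(p_i^2) - 1) / (n - 1)``; class means F2/F3/F4/F6
    average F over amino acids of each degeneracy class with F > 0.  When
    the three-fold class (Ile) is unobserved its mean is interpolated as
    (F2 + F4) / 2; any other missing class requires at least 18 observed
    codons and is then dropped from the sum (rule firings logged).
    """
    by_aa = _aa_counts(cds)
    class_F: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    n_total = sum(cds.counts().values())
    informative = 0
    for aa, counts in by_aa.items():
        deg = cds.code.degeneracy_class.get(aa, 0)
        if deg < 2:
            continue
        n = sum(counts.values())
        if n < 2:
            continue
        informative += 1
        s = sum((c / n) ** 2 for c in counts.values())
        F = (n * s - 1) / (n - 1)
        if F > 0:
            class_F[deg].append(F)
    if informative == 0:
        raise UndefinedStatisticError(
            f"CDS {cds.id!r}: no degenerate amino acid observed at least twice"
        )
    means = {k: (sum(v) / len(v) if v else None) for k, v in class_F.items()}
    if means[3] is None and means[2] is not None and means[4] is not None:
        means[3] = (means[2] + means[4]) / 2
        log.info("CDS %s: F3 interpolated from F2 and F4", cds.id)
    terms = {2: 9, 3: 1, 4: 5, 6: 3}
    nc = 2.0
    for deg, count in terms.items():
        if means[deg] is None:
            if n_total < 18:
                raise UndefinedStatisticError(
                    f"CDS {cds.id!r}: degeneracy class {deg} unobserved and "
                    f"too few codons ({n_total}) to drop it"
                )
            log.info("CDS %s: degeneracy class %d dropped (unobserved)", cds.id, deg)
            continue
        nc += count / means[deg]
    return min(max(nc, 20.0), 61.0)


def gc3s(cds: CodingSequence) -> float:
    """Fraction of G/C third bases among codons of degenerate amino acids."""
    num = den = 0
    for codon, n in cds.counts().items():
        aa = cds.code.codon_to_aa[codon]
        if cds.code.degeneracy_class.get(aa, 0) < 2:
            continue
        den += n
        if codon[2] in "GC":
            num += n
    if den == 0:
        raise UndefinedStatisticError(f"CDS {cds.id!r}: no synonymous sites")
    return num / den


def fop(cds: CodingSequence, optimal_set: Iterable[str],
        restrict_to_optimal_aas: bool = False) -> float:
    """Frequency of optimal codons.

    Denominator is all sense codons.  ``restrict_to_optimal_aas`` switches
    to the variant that counts only codons of amino acids possessing an
    optimal codon (use logged).
    """
    optimal = {c.upper() for c in optimal_set}
    if not optimal:
        raise ValidationError("empty optimal codon set")
    counts = cds.counts()
    total = sum(counts.values())
    if total == 0:
        raise UndefinedStatisticError(f"CDS {cds.id!r}: empty")
    if restrict_to_optimal_aas:
        log.info("CDS %s: Fop restricted to amino acids with an optimal codon", cds.id)
        opt_aas = {cds.code.codon_to_aa[c] for c in optimal if c in cds.code.codon_to_aa}
        total = sum(n for c, n in counts.items() if cds.code.codon_to_aa[c] in opt_aas)
        if total == 0:
            raise UndefinedStatisticError(f"CDS {cds.id!r}: no codons of optimal amino acids")
    return sum(n for c, n in counts.items() if c in optimal) / total


def rscu(cds: CodingSequence) -> dict[str, float]:
    """Relative synonymous codon usage; codons of unobserved amino acids
    are absent from the result."""
    out: dict[str, float] = {}
    for aa, counts in _aa_counts(cds).items():
        if aa == "*":
            continue
        k = cds.code.degeneracy_class[aa]
        total = sum(counts.values())
        if total == 0:
            continue
        for codon in cds.code.synonyms[aa]:
            out[codon] = counts.get(codon, 0) * k / total
    return out


def noncoding_gc(
    genome: Mapping[str, str] | str,
    noncoding_intervals: Sequence[tuple[str, int, int]] | Sequence[tuple[int, int]],
) -> float | None:
    """GC fraction over concatenated non-coding regions (0-based half-open
    intervals); N bases leave the denominator.  Returns None for an empty
    region list or zero countable length."""
    contigs = {"chr1": genome} if isinstance(genome, str) else genome
    gc = total = 0
    for iv in noncoding_intervals:
        if len(iv) == 3:
            contig, s, e = iv
        else:
            contig, (s, e) = "chr1", iv
        for base in contigs[contig][s:e].upper():
            if base in "GC":
                gc += 1
                total += 1
            elif base in "AT":
                total += 1
    if total == 0:
        return None
    return gc / total


def preferred_codon_table(
    cds: CodingSequence,
    trna_complement_set: Iterable[str],
    optimal_set: Iterable[str],
) -> list[PreferredCodonEntry]:
    """Most abundant codon per degenerate amino acid, classified against the
    host's major-tRNA-complementary and optimal codon sets.  Exact count
    ties give ``no_single_favoured``."""
    trna = {c.upper() for c in trna_complement_set}
    optimal = {c.upper() for c in optimal_set}
    entries = []
    for aa, counts in sorted(_aa_counts(cds).items()):
        if cds.code.degeneracy_class.get(aa, 0) < 2:
            continue
        ranked = counts.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            entries.append(PreferredCodonEntry(aa, None, "no_single_favoured"))
            continue
        top = ranked[0][0]
        if top in trna:
            cls = "tRNA_complementary"
        elif top in optimal:
            cls = "optimal_non_tRNA"
        else:
            cls = "neither"
        entries.append(PreferredCodonEntry(aa, top, cls))
    return entries


def mask_repetitive_regions(
    seq: str,
    min_run: int = 24,
    max_motif: int = 6,
    min_purity: float = 0.9,
) -> tuple[list[tuple[int, int]], list[int]]:
    """Mask tandem repeats in a CDS before expression counting.

    A run is masked when a motif of length 1..``max_motif`` repeats over at
    least ``min_run`` bp at >= ``min_purity`` (fraction of bases equal to
    the base one motif-length upstream).  Returns (merged masked intervals,
    indices of codons overlapping a mask).
    """
    seq = seq.upper()
    n = len(seq)

    def is_match(k: int, m: int) -> bool:
        return seq[k] == seq[k - m] and seq[k] != "N"

    intervals: list[tuple[int, int]] = []
    for m in range(1, max_motif + 1):
        i = m
        while i < n:
            if not is_match(i, m):
                i += 1
                continue
            start = i - m  # include the seed motif copy
            mismatches = 0
            last_good = i
            j = i
            while j < n:
                if is_match(j, m):
                    last_good = j
                else:
                    mismatches += 1
                    if mismatches > (1.0 - min_purity) * (j - start + 1):
                        break
                j += 1
            end = last_good + 1
            compared = end - start - m
            mism = sum(1 for k in range(start + m, end) if not is_match(k, m))
            if end - start >= min_run and compared > 0 and (
                (compared - mism) / compared >= min_purity
            ):
                intervals.append((start, end))
            i = end + 1
    if not intervals:
        return [], []
    intervals.sort()
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    masked_codons = sorted(
        {
            idx
            for s, e in merged
            for idx in range(s // 3, min((e + 2) // 3, n // 3))
        }
    )
    return merged, masked_codons
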