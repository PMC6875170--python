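"""Synthetic genomes with planted transposable-element insertions.

The generator emulates the repeat structure reported for compact protist
genomes such as *Salpingoeca rosetta*: LTR retrotransposons that insert as
full-length elements flanked by identical LTRs and a short target-site
duplication (TSD), solo LTRs left behind by intra-element recombination,
truncated copies, inverted-terminal-repeat DNA transposons with spliceosomal
introns, TE open reading frames with a tunable frequency of optimal codons
(Fop) and synonymous GC content (GC3s), and negative-binomial expression
counts spanning several orders of magnitude.

Every downstream stage of the pipeline is exercised against the exact
ground truth (:class:`SimTruth`) that planting records.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import FeasibilityError, ParameterError, PlacementError, ValidationError
from .genetics import BASES, GeneticCode, revcomp, standard_genetic_code
from .seqio import FeatureRecord, SequenceRecord, write_fasta, write_gff3

TE_CLASSES = (
    "LTR_copia",
    "LTR_chromovirus",
    "LTR_gypsy_nonchromo",
    "DNA_transposon",
    "helitron",
)
LTR_CLASSES = TE_CLASSES[:3]

# A purely synthetic default optimal-codon set (one codon per degenerate
# amino acid, GC-ending where available).  Real analyses must supply the
# host's empirically determined optimal codons.
SYNTHETIC_OPTIMAL_CODONS = frozenset(
    {
        "TTC", "CTG", "ATC", "GTG", "TCC", "CCC", "ACC", "GCC", "TAC",
        "CAC", "CAG", "AAC", "AAG", "GAC", "GAG", "TGC", "CGC", "GGC",
    }
)


# ---------------------------------------------------------------------------
# Codon model


@dataclass(frozen=True)
class CodonModel:
    """Per-amino-acid codon emission probabilities hitting Fop/GC3s targets.

    Amino acids are drawn uniformly over the 20; conditional on the amino
    acid, codons are drawn from ``per_aa_codon_probs``.  The expected Fop of
    emitted codons equals ``target_fop`` exactly and the expected GC3s is
    within ±0.02 of ``target_gc3s`` (solved numerically).
    """

    optimal_set: frozenset[str]
    target_fop: float
    target_gc3s: float
    per_aa_codon_probs: dict[str, tuple[tuple[str, ...], tuple[float, ...]]]
    code: GeneticCode = field(default_factory=standard_genetic_code)

    def sample_codons(self, n: int, rng: np.random.Generator) -> list[str]:
        aas = rng.choice(self.code.amino_acids(), size=n)
        return [self.sample_codon_for(aa, rng) for aa in aas]

    def sample_codon_for(self, aa: str, rng: np.random.Generator) -> str:
        codons, probs = self.per_aa_codon_probs[aa]
        return codons[rng.choice(len(codons), p=np.asarray(probs))]


def _gc3(codon: str) -> bool:
    return codon[2] in "GC"


def build_codon_model(
    optimal_set: Sequence[str] | frozenset[str],
    target_fop: float,
    target_gc3s: float,
    code: GeneticCode | None = None,
) -> CodonModel:
    """Construct a :class:`CodonModel` meeting joint Fop/GC3s targets.

    Raises :class:`FeasibilityError` (listing the attainable range) when the
    target pair cannot be met with the given optimal set.
    """
    code = code or standard_genetic_code()
    optimal = frozenset(c.upper() for c in optimal_set)
    if not 0.0 <= target_fop <= 1.0:
        raise ParameterError(f"target_fop {target_fop} outside [0, 1]")
    by_aa: dict[str, str] = {}
    for c in optimal:
        aa = code.codon_to_aa.get(c)
        if aa is None or aa == "*":
            raise ParameterError(f"optimal codon {c!r} is not a sense codon")
        if aa in by_aa:
            raise ParameterError(f"two optimal codons for amino acid {aa}")
        by_aa[aa] = c

    aas = code.amino_acids()
    n_aa = len(aas)
    fixed = sum(1 for aa in by_aa if code.degeneracy_class[aa] == 1)
    adjustable = sum(1 for aa in by_aa if code.degeneracy_class[aa] > 1)
    lo, hi = fixed / n_aa, (fixed + adjustable) / n_aa
    if not lo - 1e-12 <= target_fop <= hi + 1e-12:
        raise FeasibilityError(
            f"target_fop {target_fop} unattainable; with this optimal set the "
            f"expected Fop under uniform amino-acid usage lies in [{lo:.3f}, {hi:.3f}]"
        )
    q = 0.0 if adjustable == 0 else (target_fop * n_aa - fixed) / adjustable
    q = min(max(q, 0.0), 1.0)

    deg_aas = code.amino_acids(min_degeneracy=2)

    def probs_for(aa: str, beta: float) -> tuple[tuple[str, ...], np.ndarray]:
        codons = code.synonyms[aa]
        opt = by_aa.get(aa)
        if len(codons) == 1:
            return codons, np.array([1.0])
        others = [c for c in codons if c != opt]
        w = np.exp([beta * _gc3(c) for c in others])
        w = w / w.sum()
        if opt is None:
            return tuple(others), w
        return (opt, *others), np.concatenate([[q], (1.0 - q) * w])

    def expected_gc3s(beta: float) -> float:
        total = 0.0
        for aa in deg_aas:
            codons, p = probs_for(aa, beta)
            total += sum(pi for c, pi in zip(codons, p) if _gc3(c))
        return total / len(deg_aas)

    lo_gc, hi_gc = expected_gc3s(-40.0), expected_gc3s(40.0)
    if not lo_gc - 0.02 <= target_gc3s <= hi_gc + 0.02:
        raise FeasibilityError(
            f"target_gc3s {target_gc3s} unattainable with target_fop {target_fop}; "
            f"attainable range is [{lo_gc:.3f}, {hi_gc:.3f}]"
        )
    if target_gc3s <= lo_gc:
        beta = -40.0
    elif target_gc3s >= hi_gc:
        beta = 40.0
    else:
        beta = brentq(lambda b: expected_gc3s(b) - target_gc3s, -40.0, 40.0, xtol=1e-10)

    table = {}
    for aa in aas:
        codons, p = probs_for(aa, beta)
        table[aa] = (tuple(codons), tuple(float(x) for x in p))
    return CodonModel(
        optimal_set=optimal,
        target_fop=target_fop,
        target_gc3s=target_gc3s,
        per_aa_codon_probs=table,
        code=code,
    )


# ---------------------------------------------------------------------------
# Family construction


@dataclass
class FamilySpec:
    """Blueprint for one TE family consensus.

    Lengths are in bp; ``tsd_len`` may be an int, a ``(lo, hi)`` range or
    ``None`` for families that create no identifiable duplication.
    Domain intervals are in codons relative to the ORF.
    """

    name: str
    te_class: str
    terminal_repeat_len: int | None = 243
    tsd_len: int | tuple[int, int] | None = 5
    orf_len_codons: int = 400
    utr5_len: int = 120
    utr3_len: int = 120
    domain_codon_intervals: tuple[tuple[int, int], ...] = ()
    intron_positions: tuple[tuple[int, int], ...] = ()  # (codon index, intron bp)
    noncoding_gc: float = 0.50
    target_fop: float = 0.60
    target_gc3s: float = 0.70

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise ValidationError(f"unknown te_class {self.te_class!r}")
        if self.te_class == "helitron":
            self.terminal_repeat_len = None
        elif not self.terminal_repeat_len or self.terminal_repeat_len < 20:
            raise ValidationError(f"{self.name}: terminal repeat too short")
        for s, e in self.domain_codon_intervals:
            if not 0 <= s < e <= self.orf_len_codons:
                raise ValidationError(f"{self.name}: domain interval ({s},{e}) outside ORF")


@dataclass
class TEFamily:
    """A realized family: concrete consensus plus annotation intervals.

    All intervals are 0-based half-open on the consensus.  LTR families carry
    two identical terminal-repeat copies; ITR families carry reverse-
    complement terminal repeats.
    """

    name: str
    te_class: str
    consensus: str
    terminal_repeat_len: int | None
    tsd_len: int | tuple[int, int] | None
    orf_intervals: tuple[tuple[int, int, int], ...]  # (start, end, frame) exons
    domain_intervals: tuple[tuple[int, int], ...]
    intron_intervals: tuple[tuple[int, int], ...]
    spec: FamilySpec | None = None

    @property
    def is_ltr(self) -> bool:
        return self.te_class in LTR_CLASSES

    @property
    def internal_len(self) -> int:
        t = self.terminal_repeat_len or 0
        return len(self.consensus) - 2 * t

    @property
    def terminal_repeat(self) -> str:
        if self.terminal_repeat_len is None:
            raise ValidationError(f"{self.name} has no terminal repeat")
        return self.consensus[: self.terminal_repeat_len]

    @property
    def internal_seq(self) -> str:
        t = self.terminal_repeat_len or 0
        return self.consensus[t : len(self.consensus) - t]


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def generate_family(
    spec: FamilySpec, codon_model: CodonModel, seed: int | np.random.Generator
) -> TEFamily:
    """Emit a concrete consensus for ``spec``.

    The ORF starts with ATG, contains no internal stop, ends with a stop
    codon; introns (GT..AG) are inserted between codons so exon frames stay
    trivial to track.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    code = codon_model.code

    codons = ["ATG"] + codon_model.sample_codons(spec.orf_len_codons - 2, rng)
    codons.append(str(rng.choice(list(code.stop_codons))))
    assert len(codons) == spec.orf_len_codons

    # Split ORF at intron positions (codon indices), ascending.
    intron_at = sorted(spec.intron_positions)
    pieces: list[tuple[str, str]] = []  # (kind, seq) kind in {exon, intron}
    prev = 0
    for codon_idx, intron_len in intron_at:
        if not 1 <= codon_idx < spec.orf_len_codons:
            raise ValidationError(f"{spec.name}: intron position {codon_idx} outside ORF")
        pieces.append(("exon", "".join(codons[prev:codon_idx])))
        intron = "GT" + _random_seq(max(intron_len - 4, 0), spec.noncoding_gc, rng) + "AG"
        pieces.append(("intron", intron))
        prev = codon_idx
    pieces.append(("exon", "".join(codons[prev:])))

    term = (
        _random_seq(spec.terminal_repeat_len, spec.noncoding_gc, rng)
        if spec.terminal_repeat_len
        else ""
    )
    utr5 = _random_seq(spec.utr5_len, spec.noncoding_gc, rng)
    utr3 = _random_seq(spec.utr3_len, spec.noncoding_gc, rng)

    left = term
    right = term if spec.te_class in LTR_CLASSES else revcomp(term)

    parts = [left, utr5]
    orf_intervals: list[tuple[int, int, int]] = []
    intron_intervals: list[tuple[int, int]] = []
    pos = len(left) + len(utr5)
    coding_nt = 0
    for kind, seq in pieces:
        if kind == "exon":
            orf_intervals.append((pos, pos + len(seq), coding_nt % 3))
            coding_nt += len(seq)
        else:
            intron_intervals.append((pos, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)
    parts.extend([utr3, right])
    consensus = "".join(parts)

    # Map domain codon intervals (ORF codon space) to consensus nt intervals.
    domain_intervals = []
    for cs, ce in spec.domain_codon_intervals:
        ns, ne = _coding_to_consensus(cs * 3, ce * 3, orf_intervals)
        domain_intervals.extend(zip(ns, ne))

    fam = TEFamily(
        name=spec.name,
        te_class=spec.te_class,
        consensus=consensus,
        terminal_repeat_len=spec.terminal_repeat_len,
        tsd_len=spec.tsd_len,
        orf_intervals=tuple(orf_intervals),
        domain_intervals=tuple(domain_intervals),
        intron_intervals=tuple(intron_intervals),
        spec=spec,
    )
    if spec.te_class in LTR_CLASSES:
        assert fam.consensus[: spec.terminal_repeat_len] == fam.consensus[-spec.terminal_repeat_len :]
    return fam


def _coding_to_consensus(
    nt_start: int, nt_end: int, exons: Sequence[tuple[int, int, int]]
) -> tuple[list[int], list[int]]:
    """Map a half-open coding-space interval through exon coordinates."""
    starts, ends = [], []
    offset = 0
    for es, ee, _ in exons:
        elen = ee - es
        lo = max(nt_start, offset)
        hi = min(nt_end, offset + elen)
        if lo < hi:
            starts.append(es + (lo - offset))
            ends.append(es + (hi - offset))
        offset += elen
    return starts, ends


# ---------------------------------------------------------------------------
# Sequence evolution


def evolve_copy(
    seq: str,
    age: float,
    rng: np.random.Generator,
    gc_bias: float = 0.0,
    indel_rate: float = 0.0,
    mean_indel_len: float = 3.0,
) -> str:
    """Diverge ``seq`` from its source by ``age`` expected substitutions/site.

    Each site is substituted independently with probability ``age`` (uniform
    replacement over the three alternatives; ``gc_bias`` > 0 tilts the choice
    towards G/C to emulate GC-ward mutation pressure).  Indel events occur at
    ``indel_rate * age`` per site with geometric lengths (mean
    ``mean_indel_len``), insertions and deletions equiprobable.
    """
    if age < 0:
        raise ParameterError("age must be non-negative")
    if age == 0 and indel_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n = len(arr)
    hit = np.nonzero(rng.random(n) < age)[0]
    base_idx = {b: i for i, b in enumerate(BASES)}
    bases = np.array(list(BASES), dtype="S1")
    for i in hit:
        cur = arr[i].decode()
        if cur not in base_idx:
            continue
        alts = [b for b in range(4) if b != base_idx[cur]]
        w = np.array([1.0 + (gc_bias if BASES[a] in "GC" else 0.0) for a in alts])
        arr[i] = bases[alts[rng.choice(3, p=w / w.sum())]]
    out = arr.tobytes().decode()
    if indel_rate > 0 and age > 0:
        n_events = rng.binomial(n, indel_rate * age)
        for _ in range(n_events):
            if not out:
                break
            pos = int(rng.integers(0, len(out)))
            length = int(rng.geometric(1.0 / mean_indel_len))
            if rng.random() < 0.5:
                out = out[:pos] + _random_seq(length, 0.5, rng) + out[pos:]
            else:
                out = out[:pos] + out[pos + length :]
    return out


def slippage_mutate(seq: str, rng: np.random.Generator, rate: float = 0.5) -> str:
    """Expand/contract dinucleotide tandem runs (replication slippage).

    Runs of >= 4 copies of a dinucleotide motif each slip with probability
    ``rate``, gaining or losing 1-3 motif units.
    """
    out = []
    i = 0
    while i < len(seq) - 3:
        motif = seq[i : i + 2]
        if motif[0] == motif[1]:
            out.append(seq[i])
            i += 1
            continue
        j = i + 2
        while seq[j : j + 2] == motif:
            j += 2
        n_units = (j - i) // 2
        if n_units >= 4 and rng.random() < rate:
            delta = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
            n_units = max(2, n_units + delta)
        out.append(motif * n_units)
        i = j
    out.append(seq[i:])
    return "".join(out)


# ---------------------------------------------------------------------------
# Insertion planting


@dataclass
class InsertionPlan:
    family: str
    kind: str  # FLE | solo_LTR | truncated
    age: float
    position: int  # target site in the background contig (pre-insertion coords)
    strand: str = "+"
    contig: str = "chr1"
    truncation_interval: tuple[int, int] | None = None  # on the element, 0-based

    def __post_init__(self) -> None:
        if self.kind not in ("FLE", "solo_LTR", "truncated"):
            raise ValidationError(f"unknown insertion kind {self.kind!r}")
        if self.age < 0:
            raise ValidationError("age must be >= 0")


@dataclass
class RealizedInsertion:
    """Ground-truth coordinates of one planted insertion (0-based half-open,
    final genome coordinates, excluding the flanking TSD copies)."""

    family: str
    kind: str
    contig: str
    start: int
    end: int
    strand: str
    age: float
    tsd_seq: str | None
    ltr_intervals: tuple[tuple[int, int], ...] = ()
    truncation_interval: tuple[int, int] | None = None


@dataclass
class SimTruth:
    insertions: list[RealizedInsertion]
    parameters: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "parameters": self.parameters,
            "insertions": [dataclasses.asdict(i) for i in self.insertions],
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))

    def to_gff3(self, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
        kinds = {"FLE": "te_full_length", "solo_LTR": "te_solo_ltr", "truncated": "te_truncated"}
        feats = []
        for ins in self.insertions:
            attrs = {"Family": ins.family, "Kind": ins.kind, "Age": f"{ins.age:.6g}"}
            if ins.tsd_seq:
                attrs["TSD"] = ins.tsd_seq
            for i, (s, e) in enumerate(ins.ltr_intervals):
                attrs[f"LTR{'53'[i]}"] = f"{s + 1}-{e}"
            feats.append(
                FeatureRecord(
                    contig=ins.contig,
                    start=ins.start + 1,
                    end=ins.end,
                    strand=ins.strand,
                    type=kinds[ins.kind],
                    attributes=attrs,
                )
            )
        write_gff3(feats, path, contig_lengths)


def _realize_element(
    family: TEFamily, plan: InsertionPlan, rng: np.random.Generator,
    gc_bias: float, indel_rate: float,
) -> tuple[str, tuple[tuple[int, int], ...]]:
    """Build the diverged element sequence for one plan (plus strand,
    element-local LTR intervals)."""
    t = family.terminal_repeat_len or 0
    if plan.kind == "solo_LTR":
        if not family.is_ltr:
            raise ValidationError(f"solo_LTR planned for non-LTR family {family.name}")
        seq = evolve_copy(family.terminal_repeat, plan.age, rng, gc_bias, indel_rate)
        return seq, ((0, len(seq)),)
    seq = evolve_copy(family.consensus, plan.age, rng, gc_bias, indel_rate)
    if plan.kind == "truncated":
        ts, te = plan.truncation_interval or _default_truncation(family, rng)
        ts = max(0, min(ts, len(seq)))
        te = max(ts, min(te, len(seq)))
        seq = seq[:ts] + seq[te:]
        ivs = []
        for s, e in ((0, t), (len(family.consensus) - t, len(family.consensus))) if t else ():
            # keep an LTR interval only if untouched by the truncation
            if e <= ts:
                ivs.append((s, e))
            elif s >= te:
                ivs.append((s - (te - ts), e - (te - ts)))
        return seq, tuple(ivs)
    ivs = ((0, t), (len(seq) - t, len(seq))) if t else ()
    return seq, ivs


def _default_truncation(family: TEFamily, rng: np.random.Generator) -> tuple[int, int]:
    """Delete either an internal chunk or one terminal repeat plus a margin."""
    t = family.terminal_repeat_len or 0
    n = len(family.consensus)
    if t and rng.random() < 0.5:
        # remove the 3' terminal repeat and some internal sequence
        cut = int(rng.integers(100, max(101, family.internal_len // 2)))
        return (n - t - cut, n)
    # internal deletion of 100..40% of internal length
    max_del = max(101, int(0.4 * (n - 2 * t)))
    length = int(rng.integers(100, max_del))
    start = int(rng.integers(t + 10, max(t + 11, n - t - length - 10)))
    return (start, start + length)


def _draw_tsd_len(tsd_len: int | tuple[int, int] | None, rng: np.random.Generator) -> int:
    if tsd_len is None:
        return 0
    if isinstance(tsd_len, tuple):
        return int(rng.integers(tsd_len[0], tsd_len[1] + 1))
    return int(tsd_len)


def plant_insertions(
    background: str,
    families: dict[str, TEFamily],
    plans: Sequence[InsertionPlan],
    seed: int | np.random.Generator,
    gc_bias: float = 0.0,
    indel_rate: float = 0.0,
    contig: str = "chr1",
    min_separation: int = 300,
) -> tuple[str, SimTruth]:
    """Insert planned TE copies into ``background``, returning the final
    contig and exact truth coordinates.

    Full-length layout at a target site is TSD + element + TSD, with the TSD
    copied from the insertion site and identical on both flanks; the genome
    grows by element length + one TSD length per insertion.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ordered = sorted(plans, key=lambda p: p.position)
    for a, b in zip(ordered, ordered[1:]):
        if b.position - a.position < min_separation:
            raise PlacementError(
                f"plans at {a.position} and {b.position} closer than {min_separation} bp"
            )
    if ordered and not (0 <= ordered[0].position and ordered[-1].position <= len(background)):
        raise PlacementError("plan position outside the background contig")

    pieces: list[str] = []
    truth: list[RealizedInsertion] = []
    cursor = 0
    out_len = 0
    for plan in ordered:
        family = families[plan.family]
        seq, ltr_local = _realize_element(family, plan, rng, gc_bias, indel_rate)
        tlen = _draw_tsd_len(family.tsd_len, rng)
        tsd = background[plan.position : plan.position + tlen] if tlen else ""
        if plan.strand == "-":
            L = len(seq)
            seq = revcomp(seq)
            ltr_local = tuple(sorted((L - e, L - s) for s, e in ltr_local))
        pieces.append(background[cursor : plan.position])
        out_len += plan.position - cursor
        start = out_len + len(tsd)  # left TSD copy is the original site sequence
        pieces.append(tsd + seq)
        out_len += len(tsd) + len(seq)
        pieces.append("")  # right TSD copy comes from the unconsumed background
        truth.append(
            RealizedInsertion(
                family=plan.family,
                kind=plan.kind,
                contig=contig,
                start=start,
                end=start + len(seq),
                strand=plan.strand,
                age=plan.age,
                tsd_seq=tsd or None,
                ltr_intervals=tuple((start + s, start + e) for s, e in ltr_local),
                truncation_interval=plan.truncation_interval,
            )
        )
        cursor = plan.position  # background from the site onward retained -> duplication
    pieces.append(background[cursor:])
    genome = "".join(pieces)
    params = {"n_plans": len(plans), "gc_bias": gc_bias, "indel_rate": indel_rate}
    return genome, SimTruth(insertions=truth, parameters=params)


# ---------------------------------------------------------------------------
# Expression counts


def simulate_expression(
    family_names: Sequence[str],
    mean_counts: Sequence[float],
    dispersion: float | None,
    seed: int | np.random.Generator,
    zero_inflation: float = 0.0,
) -> dict[str, int]:
    """Negative-binomial read counts per family.

    ``dispersion`` is the NB size parameter; ``None`` (or ``inf``) gives the
    Poisson limit.  ``zero_inflation`` is the probability a family is silent.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dispersion is not None and dispersion <= 0 and not np.isinf(dispersion):
        raise ParameterError("dispersion must be positive (or None for Poisson)")
    out: dict[str, int] = {}
    for name, mu in zip(family_names, mean_counts):
        if mu < 0:
            raise ParameterError(f"mean count for {name} is negative")
        if zero_inflation and rng.random() < zero_inflation:
            out[name] = 0
            continue
        if mu == 0:
            out[name] = 0
        elif dispersion is None or np.isinf(dispersion):
            out[name] = int(rng.poisson(mu))
        else:
            p = dispersion / (dispersion + mu)
            out[name] = int(rng.negative_binomial(dispersion, p))
    return out


# ---------------------------------------------------------------------------
# Whole-genome convenience + default study conditions


def default_family_specs() -> list[FamilySpec]:
    """Three-family default emulating the reported repeat landscape:
    a chromoviral LTR family (243 bp LTR, 5 bp TSD), a non-chromoviral
    gypsy-like family (373 bp LTR, 4 bp TSD) and an ITR DNA transposon
    (28 bp ITR, 8 bp TSD, one intron)."""
    return [
        FamilySpec(
            name="simcv1", te_class="LTR_chromovirus", terminal_repeat_len=243,
            tsd_len=5, orf_len_codons=500, utr5_len=150, utr3_len=150,
            domain_codon_intervals=((60, 180), (300, 430)),
            target_fop=0.60, target_gc3s=0.70,
        ),
        FamilySpec(
            name="simgyp1", te_class="LTR_gypsy_nonchromo", terminal_repeat_len=373,
            tsd_len=4, orf_len_codons=450, utr5_len=120, utr3_len=140,
            domain_codon_intervals=((50, 170), (250, 380)),
            target_fop=0.70, target_gc3s=0.80,
        ),
        FamilySpec(
            name="simtnp1", te_class="DNA_transposon", terminal_repeat_len=28,
            tsd_len=8, orf_len_codons=350, utr5_len=260, utr3_len=120,
            domain_codon_intervals=((40, 150),),
            intron_positions=((120, 90),),
            target_fop=0.55, target_gc3s=0.62,
        ),
    ]


DEFAULT_COPY_PLAN = {
    # (n_fle, n_solo, n_truncated) mirroring low-copy families of the survey
    "simcv1": (8, 5, 3),
    "simgyp1": (6, 2, 1),
    "simtnp1": (6, 0, 3),
}

DEFAULT_EXPRESSION_MEANS = {"simcv1": 457, "simgyp1": 197, "simtnp1": 15354}


def simulate_genome(
    seed: int,
    specs: Sequence[FamilySpec] | None = None,
    copy_plan: dict[str, tuple[int, int, int]] | None = None,
    background_len: int = 120_000,
    background_gc: float = 0.50,
    age_range: tuple[float, float] = (0.001, 0.02),
    gc_bias: float = 0.0,
    indel_rate: float = 0.0,
    expression_means: dict[str, float] | None = None,
    expression_dispersion: float = 0.5,
) -> tuple[dict[str, str], dict[str, TEFamily], SimTruth, dict[str, int]]:
    """Generate a complete synthetic genome with planted truth.

    Same seed and configuration give byte-identical output.  Ages are drawn
    uniformly from ``age_range`` (expected substitutions/site per copy), so
    default divergence from consensus stays at or below ~2% and intra-element
    LTR divergence below ~4%.
    """
    rng = np.random.default_rng(seed)
    specs = list(specs) if specs is not None else default_family_specs()
    copy_plan = copy_plan or {
        s.name: DEFAULT_COPY_PLAN.get(s.name, (4, 2, 1)) for s in specs
    }
    families = {}
    for spec in specs:
        model = build_codon_model(
            SYNTHETIC_OPTIMAL_CODONS, spec.target_fop, spec.target_gc3s
        )
        families[spec.name] = generate_family(spec, model, rng)

    background = _random_seq(background_len, background_gc, rng)
    plans: list[InsertionPlan] = []
    total_copies = sum(sum(v) for v in copy_plan.values())
    # leave margins so no insertion abuts a contig edge
    margin = 2000
    positions = np.sort(
        rng.choice(
            np.arange(margin, background_len - margin), size=total_copies, replace=False
        )
    )
    # enforce separation; with this density collisions are rare, fix greedily
    min_sep = 400
    for i in range(1, len(positions)):
        if positions[i] - positions[i - 1] < min_sep:
            positions[i] = positions[i - 1] + min_sep
    if positions[-1] >= background_len - margin:
        raise PlacementError("too many insertions for the background length")

    kinds = []
    for name, (n_fle, n_solo, n_trunc) in copy_plan.items():
        fam = families[name]
        if n_solo and not fam.is_ltr:
            raise ValidationError(f"solo_LTR copies planned for non-LTR family {name}")
        kinds += [(name, "FLE")] * n_fle + [(name, "solo_LTR")] * n_solo + [
            (name, "truncated")
        ] * n_trunc
    order = rng.permutation(len(kinds))
    for pos, idx in zip(positions, order):
        name, kind = kinds[idx]
        plans.append(
            InsertionPlan(
                family=name,
                kind=kind,
                age=float(rng.uniform(*age_range)),
                position=int(pos),
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    genome, truth = plant_insertions(
        background, families, plans, rng, gc_bias=gc_bias, indel_rate=indel_rate,
        min_separation=min_sep,
    )
    truth.parameters.update(
        {
            "seed": seed,
            "background_len": background_len,
            "background_gc": background_gc,
            "age_range": list(age_range),
            "copy_plan": {k: list(v) for k, v in copy_plan.items()},
        }
    )
    means = expression_means or {
        s.name: DEFAULT_EXPRESSION_MEANS.get(s.name, 100) for s in specs
    }
    counts = simulate_expression(
        list(means), [means[k] for k in means], expression_dispersion, rng
    )
    return {"chr1": genome}, families, truth, counts


def families_to_json(families: dict[str, TEFamily], path: str | Path) -> None:
    payload = []
    for fam in families.values():
        payload.append(
            {
                "name": fam.name,
                "te_class": fam.te_class,
                "consensus": fam.consensus,
                "terminal_repeat_len": fam.terminal_repeat_len,
                "tsd_len": list(fam.tsd_len) if isinstance(fam.tsd_len, tuple) else fam.tsd_len,
                "orf_intervals": [list(x) for x in fam.orf_intervals],
                "domain_intervals": [list(x) for x in fam.domain_intervals],
                "intron_intervals": [list(x) for x in fam.intron_intervals],
            }
        )
    Path(path).write_text(json.dumps({"families": payload}, indent=1))


def families_from_json(path: str | Path) -> dict[str, TEFamily]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for entry in payload["families"]:
        tsd = entry["tsd_len"]
        out[entry["name"]] = TEFamily(
            name=entry["name"],
            te_class=entry["te_class"],
            consensus=entry["consensus"],
            terminal_repeat_len=entry["terminal_repeat_len"],
            tsd_len=tuple(tsd) if isinstance(tsd, list) else tsd,
            orf_intervals=tuple(tuple(x) for x in entry["orf_intervals"]),
            domain_intervals=tuple(tuple(x) for x in entry["domain_intervals"]),
            intron_intervals=tuple(tuple(x) for x in entry["intron_intervals"]),
        )
    return out


def write_simulation(
    out_prefix: str | Path,
    contigs: dict[str, str],
    families: dict[str, TEFamily],
    truth: SimTruth,
    counts: dict[str, int],
) -> None:
    """Write genome FASTA, consensus FASTA, family JSON, truth GFF3/JSON and
    counts TSV."""
    prefix = str(out_prefix)
    families_to_json(families, prefix + ".families.json")
    write_fasta(
        [SequenceRecord(id=k, seq=v) for k, v in contigs.items()],
        prefix + ".genome.fasta",
    )
    write_fasta(
        [SequenceRecord(id=f.name, seq=f.consensus) for f in families.values()],
        prefix + ".consensus.fasta",
    )
    truth.to_gff3(prefix + ".truth.gff3", {k: len(v) for k, v in contigs.items()})
    truth.to_json(prefix + ".truth.json")
    with open(prefix + ".expression.tsv", "w") as fh:
        fh.write("family\treads\n")
        for k, v in counts.items():
            fh.write(f"{k}\t{v}\n")
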