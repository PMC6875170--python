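"""The standard genetic code and its degeneracy structure.

All codon statistics in :mod:`tescope.codon` are driven by a
:class:`GeneticCode` object rather than hard-wired tables, so tests can
inject toy codes.  Only the standard nuclear code ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

BASES = "ACGT"
STOP = "*"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Standard code written per amino acid; every codon appears exactly once.
_STANDARD_SYNONYMS: dict[str, tuple[str, ...]] = {
    "F": ("TTT", "TTC"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "I": ("ATT", "ATC", "ATA"),
    "M": ("ATG",),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "Y": ("TAT", "TAC"),
    "H": ("CAT", "CAC"),
    "Q": ("CAA", "CAG"),
    "N": ("AAT", "AAC"),
    "K": ("AAA", "AAG"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "C": ("TGT", "TGC"),
    "W": ("TGG",),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    STOP: ("TAA", "TAG", "TGA"),
}


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code plus the degeneracy bookkeeping downstream statistics need.

    Attributes
    ----------
    codon_to_aa:
        Maps each of the 64 codons to a one-letter amino acid or ``"*"``.
    synonyms:
        Amino acid -> tuple of its codons (stops included under ``"*"``).
    degeneracy_class:
        Amino acid -> size of its synonymous family (1, 2, 3, 4 or 6).
    """

    codon_to_aa: dict[str, str]
    synonyms: dict[str, tuple[str, ...]] = field(default_factory=dict)
    degeneracy_class: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.synonyms:
            syn: dict[str, list[str]] = {}
            for codon, aa in self.codon_to_aa.items():
                syn.setdefault(aa, []).append(codon)
            object.__setattr__(
                self, "synonyms", {aa: tuple(sorted(c)) for aa, c in syn.items()}
            )
        if not self.degeneracy_class:
            object.__setattr__(
                self,
                "degeneracy_class",
                {aa: len(c) for aa, c in self.synonyms.items() if aa != STOP},
            )

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c, aa in sorted(self.codon_to_aa.items()) if aa != STOP)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.synonyms.get(STOP, ())))

    def amino_acids(self, min_degeneracy: int = 1) -> tuple[str, ...]:
        return tuple(
            aa
            for aa in sorted(self.degeneracy_class)
            if self.degeneracy_class[aa] >= min_degeneracy
        )

    def translate(self, seq: str) -> str:
        seq = seq.upper().replace("U", "T")
        return "".join(
            self.codon_to_aa.get(seq[i : i + 3], "X")
            for i in range(0, len(seq) - len(seq) % 3, 3)
        )


@lru_cache(maxsize=1)
def standard_genetic_code() -> GeneticCode:
    """Return the standard nuclear genetic code (61 sense codons, 3 stops)."""
    codon_to_aa = {
        codon: aa for aa, codons in _STANDARD_SYNONYMS.items() for codon in codons
    }
    assert len(codon_to_aa) == 64
    return GeneticCode(codon_to_aa=codon_to_aa)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]
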