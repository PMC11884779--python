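"""Genetic-code-derived amino-acid and pair metrics.

Every mutational covariate used downstream comes from the structure of the
standard genetic code (NCBI translation table 1): the mean GC fraction of an
amino acid's codons, the mean pyrimidine fraction of its codons (a proxy for
how often exchanges between two amino acids require transversions rather than
transitions), and the minimum number of nucleotide changes separating any
codon of one amino acid from any codon of another.

Codons are handled in DNA alphabet internally; ``U`` is accepted on input and
normalized to ``T``. Amino acids follow the PAML canonical order
``A R N D C Q E G H I L K M F P S T W Y V`` everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, product

import pandas as pd

#: PAML canonical amino-acid order used by every matrix and table in the package.
AA_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

_BASES = "TCAG"
# NCBI translation table 1, TCAG nesting (first base outermost).
_TABLE1_AAS = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

STANDARD_CODE: dict[str, str] = {
    b1 + b2 + b3: aa
    for (b1, b2, b3), aa in zip(product(_BASES, repeat=3), _TABLE1_AAS)
}


class InvalidAminoAcidError(ValueError):
    """Raised for a letter outside the 20 canonical one-letter codes."""


class InvalidCodonError(ValueError):
    """Raised for a triplet outside the {A,C,G,T,U} alphabet."""


def normalize_codon(codon: str) -> str:
    """Uppercase a triplet and replace RNA ``U`` with ``T``."""
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(b not in "ACGT" for b in c):
        raise InvalidCodonError(f"not a valid nucleotide triplet: {codon!r}")
    return c


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map with its inverse over the sense codons.

    Only the standard code is supported: alternative (e.g. mitochondrial)
    codes are rejected at construction rather than silently substituted,
    because every pair metric in this package is defined on table 1.
    """

    codon_to_aa: dict[str, str]
    aa_to_codons: dict[str, frozenset[str]] = field(init=False)

    def __post_init__(self) -> None:
        sense = {c: a for c, a in self.codon_to_aa.items() if a != "*"}
        if len(sense) != 61:
            raise ValueError(f"expected 61 sense codons, found {len(sense)}")
        inv: dict[str, set[str]] = {}
        for codon, aa in sense.items():
            inv.setdefault(aa, set()).add(codon)
        if set(inv) != set(AA_ORDER):
            raise ValueError("code does not cover the 20 canonical amino acids")
        for aa, n in (("M", 1), ("W", 1), ("L", 6), ("S", 6), ("R", 6)):
            if len(inv[aa]) != n:
                raise ValueError(f"not the standard code: {aa} has {len(inv[aa])} codons")
        object.__setattr__(
            self, "aa_to_codons", {a: frozenset(cs) for a, cs in inv.items()}
        )

    @classmethod
    def standard(cls) -> "GeneticCode":
        return _standard_code()

    def codons_for(self, aa: str) -> frozenset[str]:
        """Sense codons of one amino acid (one-letter code, case-insensitive)."""
        key = aa.upper()
        if key not in self.aa_to_codons:
            raise InvalidAminoAcidError(f"unknown amino acid: {aa!r}")
        return self.aa_to_codons[key]

    def gc_content(self, aa: str) -> float:
        """Mean over the amino acid's codons of the G+C fraction per codon."""
        codons = self.codons_for(aa)
        return sum(sum(b in "GC" for b in c) / 3 for c in codons) / len(codons)

    def pyrimidine_proportion(self, aa: str) -> float:
        """Mean over the amino acid's codons of the C+T fraction per codon."""
        codons = self.codons_for(aa)
        return sum(sum(b in "CT" for b in c) / 3 for c in codons) / len(codons)

    def min_mutational_steps(self, aa1: str, aa2: str) -> int:
        """Minimum Hamming distance between any codons of the two amino acids.

        Intermediate codons are not required to be sense codons; this is the
        plain minimum over codon pairs, 0 iff the amino acids are identical,
        otherwise 1-3.
        """
        c1, c2 = self.codons_for(aa1), self.codons_for(aa2)
        return min(
            sum(a != b for a, b in zip(x, y)) for x in c1 for y in c2
        )

    def pair_metric_table(self) -> pd.DataFrame:
        """All 190 unordered pair metrics as a DataFrame.

        Columns: ``aa1``, ``aa2`` (aa1 before aa2 in PAML order),
        ``min_steps``, ``gc_diff``, ``pyr_diff``.
        """
        rows = []
        for a1, a2 in combinations(AA_ORDER, 2):
            rows.append(
                {
                    "aa1": a1,
                    "aa2": a2,
                    "min_steps": self.min_mutational_steps(a1, a2),
                    "gc_diff": abs(self.gc_content(a1) - self.gc_content(a2)),
                    "pyr_diff": abs(
                        self.pyrimidine_proportion(a1) - self.pyrimidine_proportion(a2)
                    ),
                }
            )
        return pd.DataFrame(rows)


@lru_cache(maxsize=1)
def _standard_code() -> GeneticCode:
    return GeneticCode(dict(STANDARD_CODE))


# Module-level conveniences bound to the standard code.

def codons_for(aa: str) -> frozenset[str]:
    return GeneticCode.standard().codons_for(aa)


def gc_content(aa: str) -> float:
    return GeneticCode.standard().gc_content(aa)


def pyrimidine_proportion(aa: str) -> float:
    return GeneticCode.standard().pyrimidine_proportion(aa)


def min_mutational_steps(aa1: str, aa2: str) -> int:
    return GeneticCode.standard().min_mutational_steps(aa1, aa2)


def pair_metric_table() -> pd.DataFrame:
    return GeneticCode.standard().pair_metric_table()
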