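"""Genetic codes and codon state spaces.

The substitution models in this package act on an ordered alphabet of codons.
For protein-coding data the alphabet is the sense codons of a genetic code
(61 states under the standard code); for neutral controls such as intronic
trinucleotides a stop-inclusive 64-state variant is available, in which STOP
is treated as a distinct 21st amino-acid symbol so that any change of encoded
symbol — including sense↔stop — counts as nonsynonymous, while stop↔stop
changes are synonymous.

Codons are ordered lexicographically over the DNA alphabet A < C < G < T and
every matrix and vector in the package follows that order.  RNA input (U) is
normalised to T.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}
STOP = "*"

#: transition pairs (purine<->purine, pyrimidine<->pyrimidine)
TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})

ALL_CODONS = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
)


def normalize_codon(codon: str) -> str:
    """Uppercase a trinucleotide and map U to T."""
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(n not in NUC_INDEX for n in c):
        raise ValueError(f"not a DNA trinucleotide: {codon!r}")
    return c


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: a total map from the 64 codons to amino acids or STOP."""

    name: str
    codon_to_aa: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            raise ValueError("genetic code must map exactly the 64 codons")

    @classmethod
    def from_ncbi_id(cls, table_id: int = 1) -> "GeneticCode":
        """Build from an NCBI translation-table number (default 1, standard)."""
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = STOP
        return cls(name=table.names[0], codon_to_aa=mapping)

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls.from_ncbi_id(1)

    def aa(self, codon: str) -> str:
        return self.codon_to_aa[normalize_codon(codon)]

    def is_stop(self, codon: str) -> bool:
        return self.aa(codon) == STOP

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] == STOP)


@dataclass(frozen=True)
class CodonStateSpace:
    """Ordered codon alphabet for a genetic code.

    ``codons`` is lexicographic over A<C<G<T; 61 states for the sense-only
    standard code, 64 when stops are included.
    """

    code: GeneticCode
    include_stops: bool
    codons: tuple[str, ...]
    index: dict[str, int] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.codons)

    def __contains__(self, codon: str) -> bool:
        return codon in self.index

    def aa(self, codon: str) -> str:
        return self.code.aa(codon)


@lru_cache(maxsize=None)
def _space(table_id: int, include_stops: bool) -> CodonStateSpace:
    code = GeneticCode.from_ncbi_id(table_id)
    if include_stops:
        codons = ALL_CODONS
    else:
        codons = tuple(c for c in ALL_CODONS if code.codon_to_aa[c] != STOP)
    return CodonStateSpace(
        code=code,
        include_stops=include_stops,
        codons=codons,
        index={c: i for i, c in enumerate(codons)},
    )


def codon_state_space(table_id: int = 1, include_stops: bool = False) -> CodonStateSpace:
    """The codon state space for an NCBI translation table (cached)."""
    return _space(table_id, include_stops)


def sense_codons(code: GeneticCode | None = None) -> CodonStateSpace:
    """Sense-codon state space (61 states for the standard code)."""
    if code is None:
        return codon_state_space(1, include_stops=False)
    codons = tuple(c for c in ALL_CODONS if code.codon_to_aa[c] != STOP)
    return CodonStateSpace(
        code=code,
        include_stops=False,
        codons=codons,
        index={c: i for i, c in enumerate(codons)},
    )


def nucleotide_change(c1: str, c2: str) -> tuple[int, str, str]:
    """The single differing position (1-based) and nucleotide pair of a codon pair.

    Raises ``ValueError`` unless the codons differ at exactly one position.
    """
    c1, c2 = normalize_codon(c1), normalize_codon(c2)
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if len(diffs) != 1:
        raise ValueError(
            f"codons {c1}/{c2} differ at {len(diffs)} positions, expected 1"
        )
    i = diffs[0]
    return i + 1, c1[i], c2[i]


def substitution_class(space: CodonStateSpace, c1: str, c2: str) -> str:
    """Classify a codon pair: identical / multi / synonymous / nonsynonymous.

    ``multi`` means the codons differ at two or more positions; single-position
    changes are synonymous iff both codons encode the same symbol (STOP counts
    as its own symbol in stop-inclusive spaces).
    """
    c1, c2 = normalize_codon(c1), normalize_codon(c2)
    for c in (c1, c2):
        if c not in space:
            raise ValueError(f"codon {c} not in state space")
    if c1 == c2:
        return "identical"
    ndiff = sum(a != b for a, b in zip(c1, c2))
    if ndiff > 1:
        return "multi"
    return "synonymous" if space.aa(c1) == space.aa(c2) else "nonsynonymous"
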