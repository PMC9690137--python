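"""Codon counting and nucleotide-composition statistics.

The genetic code is taken from NCBI translation tables (via Biopython);
the default is the standard code, under which 61 sense codons encode the
20 amino acids (Met and Trp by a single codon each) and three codons
terminate translation.  STOP codons are kept in every count table — the
downstream ANOVA treats STOP as a 21st "amino acid" family — and are
excluded, where appropriate, at the index level instead.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Data import CodonTable

from .cds_io import CodingSequence

BASES = "ACGT"
#: The 64 codons in lexicographic order.
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(BASES, repeat=3)
)

STOP_SYMBOL = "*"


@dataclass(frozen=True)
class GeneticCode:
    """A total map from the 64 codons to amino acids (one-letter) plus STOP.

    ``families`` groups synonymous codons: ``families[aa]`` is the tuple of
    codons encoding ``aa`` (STOP is the family of the ``*`` symbol).  The
    family size is the degeneracy ``n_i`` of the amino acid.
    """

    code_id: str
    codon_to_aa: Mapping[str, str]
    families: Mapping[str, tuple[str, ...]] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            raise ValueError("codon_to_aa must map exactly the 64 codons")
        fam: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            fam.setdefault(self.codon_to_aa[codon], []).append(codon)
        object.__setattr__(
            self, "families", {aa: tuple(c) for aa, c in fam.items()}
        )

    def family_of(self, codon: str) -> tuple[str, ...]:
        """Synonymous family containing ``codon``."""
        return self.families[self.codon_to_aa[codon]]

    def degeneracy(self, codon: str) -> int:
        return len(self.family_of(codon))

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return self.families[STOP_SYMBOL]

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard nuclear code (NCBI translation table 1)."""
        table = CodonTable.unambiguous_dna_by_id[1]
        mapping = dict(table.forward_table)
        for codon in table.stop_codons:
            mapping[codon] = STOP_SYMBOL
        return cls(code_id="standard", codon_to_aa=mapping)


STANDARD_CODE = GeneticCode.standard()


@dataclass
class CodonCountTable:
    """Counts over all 64 codons for one sequence or a pooled corpus."""

    source_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        full = {codon: 0 for codon in ALL_CODONS}
        for codon, n in self.counts.items():
            if codon not in full:
                raise ValueError(f"not a codon: {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon}")
            full[codon] = int(n)
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def family_total(self, aa: str, code: GeneticCode = STANDARD_CODE) -> int:
        return sum(self.counts[c] for c in code.families[aa])

    def scaled(self, k: int) -> "CodonCountTable":
        """Every count multiplied by a positive integer ``k``."""
        if k <= 0:
            raise ValueError("scale factor must be a positive integer")
        return CodonCountTable(
            source_id=self.source_id,
            counts={c: n * k for c, n in self.counts.items()},
        )


@dataclass
class PositionalBaseFrequencies:
    """Proportion of each base at codon positions 1..3, over counted codons."""

    freq: dict[tuple[int, str], float]

    def __getitem__(self, key: tuple[int, str]) -> float:
        return self.freq[key]


def count_codons(seq: CodingSequence) -> CodonCountTable:
    """Count non-overlapping in-frame triplets of a CDS.

    The sequence must be in frame (length a multiple of 3) and contain only
    A/C/G/T; the resulting total equals length/3.
    """
    s = seq.sequence
    if len(s) == 0 or len(s) % 3 != 0:
        raise ValueError(
            f"{seq.id}: length {len(s)} is not a positive multiple of 3"
        )
    if set(s) - set(BASES):
        raise ValueError(f"{seq.id}: sequence contains non-ACGT symbols")
    tally = Counter(s[i : i + 3] for i in range(0, len(s), 3))
    return CodonCountTable(source_id=seq.id, counts=dict(tally))


def pool_counts(tables: Iterable[CodonCountTable]) -> CodonCountTable:
    """Codon-wise sum of count tables (the corpus-level reference set)."""
    tables = list(tables)
    if not tables:
        raise ValueError("cannot pool an empty list of count tables")
    pooled = Counter()
    for t in tables:
        pooled.update(t.counts)
    label = "pool(" + ",".join(t.source_id for t in tables[:5])
    label += ",..." if len(tables) > 5 else ""
    return CodonCountTable(source_id=label + ")", counts=dict(pooled))


def gc_content(seq: CodingSequence) -> float:
    """GC percentage of the full record, at full precision.

    Report layers round to 2 decimals; computation never does.
    """
    s = seq.sequence
    if not s:
        raise ValueError(f"{seq.id}: empty sequence")
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def positional_base_frequencies(
    counts: CodonCountTable,
) -> PositionalBaseFrequencies:
    """Normalized frequency of each base at each codon position.

    freq(n, m) = (#counted codons with base m at position n) / total codons.
    For each position the four proportions sum to 1.
    """
    total = counts.total
    if total == 0:
        raise ValueError("positional frequencies undefined for all-zero counts")
    freq = {(pos, base): 0.0 for pos in (1, 2, 3) for base in BASES}
    for codon, n in counts.counts.items():
        if n == 0:
            continue
        for pos in (1, 2, 3):
            freq[(pos, codon[pos - 1])] += n
    return PositionalBaseFrequencies(
        freq={k: v / total for k, v in freq.items()}
    )
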