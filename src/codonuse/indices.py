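"""The four codon-usage bias indices: CAI, RSCU, RCBS and MRCBS.

CAI (Sharp & Li) is the geometric mean of relative-adaptiveness weights
w_i = f_i / f_{aa,max} over a gene's codons, taken against a reference
codon-count table.  RSCU measures a codon's usage relative to its
synonymous family; two conventions are provided.  The *fraction* variant
reports the within-family fraction x_ij / sum_j x_ij (neutral point 1/n_i;
for two-fold families 0.5 separates frequent from rare codons).  The
*classical* variant scales by the degeneracy n_i so that equal usage gives
1 for every codon.  RCBS_xyz compares a codon's observed frequency with
the product of its positional base frequencies, f_xyz / (f1(x) f2(y) f3(z)),
equal to 1 under positional independence.  MRCBS_xyz = RCBS_xyz / max RCBS
within the codon's family lies in [0, 1]; its gene-level geometric mean
summarizes predicted expression, with amino acids above a threshold
(default 0.62) classified as highly expressed.

Gene-level scores are geometric means computed in log space: an unrooted
product over hundreds of codons underflows and would not lie in the
(0, 1] range these scores are interpreted on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .codon_core import (
    ALL_CODONS,
    STANDARD_CODE,
    STOP_SYMBOL,
    CodonCountTable,
    GeneticCode,
    PositionalBaseFrequencies,
    positional_base_frequencies,
)

#: Amino acids excluded from CAI by default: the single-codon families
#: (Met, Trp) carry no bias information, and STOP is not translated.
DEFAULT_CAI_EXCLUDE: frozenset[str] = frozenset({"M", "W", STOP_SYMBOL})

#: MRCBS threshold separating predicted high from low expression.
DEFAULT_EXPRESSION_THRESHOLD = 0.62


@dataclass
class ReferenceWeights:
    """Relative adaptiveness w per codon: family max has w = 1.

    Codons of families unused in the reference are absent from ``w``
    (undefined).  Zero-count codons inside a used family receive the
    pseudo-weight 0.5/max-count so that log-space CAI stays defined.
    """

    w: dict[str, float]
    reference_label: str
    pseudo_codons: frozenset[str] = field(default_factory=frozenset)

    def __getitem__(self, codon: str) -> float:
        return self.w[codon]

    def __contains__(self, codon: str) -> bool:
        return codon in self.w


@dataclass
class IndexVector:
    """Per-codon values of one index for one sequence."""

    index_name: str
    source_id: str
    values: dict[str, float]

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]


@dataclass
class GeneScore:
    """A single gene-level summary (CAI, RCBS_gene or MRCBS_gene)."""

    index_name: str
    source_id: str
    value: float


def reference_weights(
    reference_counts: CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    pseudo_factor: float = 0.5,
) -> ReferenceWeights:
    """Compute w(codon) = count / max count within each synonymous family.

    Families with zero usage in the reference get no weight (undefined);
    zero-count codons within a used family get ``pseudo_factor``/max-count.
    """
    if reference_counts.total == 0:
        raise ValueError("reference counts are empty")
    w: dict[str, float] = {}
    pseudo: set[str] = set()
    for aa, family in code.families.items():
        fmax = max(reference_counts.counts[c] for c in family)
        if fmax == 0:
            continue
        for c in family:
            n = reference_counts.counts[c]
            if n == 0:
                w[c] = pseudo_factor / fmax
                pseudo.add(c)
            else:
                w[c] = n / fmax
    return ReferenceWeights(
        w=w,
        reference_label=reference_counts.source_id,
        pseudo_codons=frozenset(pseudo),
    )


def cai(
    gene_counts: CodonCountTable,
    weights: ReferenceWeights,
    code: GeneticCode = STANDARD_CODE,
    exclude: frozenset[str] = DEFAULT_CAI_EXCLUDE,
) -> GeneScore:
    """Codon adaptation index: geometric mean of w over the gene's codons.

    Computed as exp(sum count*ln w / N) over all counted codon occurrences
    whose amino acid is not in ``exclude`` and whose weight is defined.
    """
    log_sum = 0.0
    n_occ = 0
    for codon, count in gene_counts.counts.items():
        if count == 0 or code.codon_to_aa[codon] in exclude:
            continue
        if codon not in weights:
            continue
        log_sum += count * math.log(weights[codon])
        n_occ += count
    if n_occ == 0:
        raise ValueError(
            f"{gene_counts.source_id}: no codon with a defined weight "
            "outside the excluded families"
        )
    return GeneScore(
        index_name="CAI",
        source_id=gene_counts.source_id,
        value=math.exp(log_sum / n_occ),
    )


def rscu_fraction(
    gene_counts: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> IndexVector:
    """Within-family usage fraction: value(codon) = count / family total.

    Values of a used family sum to 1; all members of an unused family get 0.
    The neutral point is 1/n_i, so 0.5 is the frequent/rare threshold for
    two-fold families.
    """
    values: dict[str, float] = {}
    for family in code.families.values():
        fam_total = sum(gene_counts.counts[c] for c in family)
        for c in family:
            values[c] = gene_counts.counts[c] / fam_total if fam_total else 0.0
    return IndexVector("RSCU_fraction", gene_counts.source_id, values)


def rscu_classical(
    gene_counts: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> IndexVector:
    """Classical RSCU: n_i x count / family total; equal usage gives 1."""
    frac = rscu_fraction(gene_counts, code)
    values = {
        c: len(code.family_of(c)) * v for c, v in frac.values.items()
    }
    return IndexVector("RSCU_classical", gene_counts.source_id, values)


def rscu(
    gene_counts: CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    variant: str = "fraction",
) -> IndexVector:
    """RSCU in the requested convention ('fraction' or 'classical')."""
    if variant == "fraction":
        return rscu_fraction(gene_counts, code)
    if variant == "classical":
        return rscu_classical(gene_counts, code)
    raise ValueError(f"unknown RSCU variant: {variant!r}")


def rcbs(
    gene_counts: CodonCountTable,
    positional: PositionalBaseFrequencies | None = None,
) -> tuple[IndexVector, GeneScore]:
    """Relative codon bias strength per codon, plus the gene-level score.

    RCBS_xyz = f_xyz / (f1(x) f2(y) f3(z)), with f_xyz the codon's
    proportion of total codons and f_n(m) the base proportions at the three
    codon positions of the same gene.  Codons with count 0 get value 0.
    The gene score is the geometric mean of RCBS over counted occurrences.
    """
    if positional is None:
        positional = positional_base_frequencies(gene_counts)
    total = gene_counts.total
    values: dict[str, float] = {}
    log_sum = 0.0
    for codon in ALL_CODONS:
        count = gene_counts.counts[codon]
        if count == 0:
            values[codon] = 0.0
            continue
        expected = (
            positional[(1, codon[0])]
            * positional[(2, codon[1])]
            * positional[(3, codon[2])]
        )
        values[codon] = (count / total) / expected
        log_sum += count * math.log(values[codon])
    vec = IndexVector("RCBS", gene_counts.source_id, values)
    score = GeneScore(
        "RCBS_gene", gene_counts.source_id, math.exp(log_sum / total)
    )
    return vec, score


def mrcbs(
    gene_counts: CodonCountTable,
    positional: PositionalBaseFrequencies | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[IndexVector, GeneScore]:
    """RCBS normalized by the family maximum; values in [0, 1].

    MRCBS_xyz = RCBS_xyz / max RCBS over the codon's synonymous family,
    so every used family has at least one codon at exactly 1 (ties all get
    1).  The gene score is the log-space geometric mean over counted
    occurrences and lies in (0, 1].
    """
    rcbs_vec, _ = rcbs(gene_counts, positional)
    values: dict[str, float] = {}
    log_sum = 0.0
    total = gene_counts.total
    for family in code.families.values():
        fam_max = max(rcbs_vec[c] for c in family)
        for c in family:
            if gene_counts.counts[c] == 0:
                values[c] = 0.0
            else:
                values[c] = min(rcbs_vec[c] / fam_max, 1.0)
                log_sum += gene_counts.counts[c] * math.log(values[c])
    vec = IndexVector("MRCBS", gene_counts.source_id, values)
    score = GeneScore(
        "MRCBS_gene", gene_counts.source_id, math.exp(log_sum / total)
    )
    return vec, score


def classify_expression(
    mean_mrcbs_per_aa: Mapping[str, float],
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> dict[str, str]:
    """Label amino acids 'high' when mean MRCBS strictly exceeds the threshold.

    A value exactly at the threshold is 'low' (strict inequality).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return {
        aa: ("high" if value > threshold else "low")
        for aa, value in mean_mrcbs_per_aa.items()
    }
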