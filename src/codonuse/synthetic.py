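"""Synthetic coding sequences with known codon-usage structure.

The generator emulates a small corpus of AT-rich plant transcripts:
~10-20 coding sequences of 800-4000 nt with GC% in the 33-45% band, each
a clean open reading frame (ATG start, in-body sense codons only, one
terminal STOP).  Amino acids are drawn i.i.d. from a composition vector
and codons from per-family preference vectors, so every index computed
downstream has an exact multinomial ground truth.  Each draw is recorded
in a ledger, which serves as an independent oracle for codon counting and
for parameter-recovery checks.

When no codon preferences are given, a corpus-level preference vector is
sampled from a Dirichlet distribution centred on an AT-leaning mean
(codon weight 0.35^#GC, which puts the expected corpus GC near 39%, the
middle of the target band).  GC control is by per-sequence rejection
sampling, never by distorting the preferences, so the recorded ground
truth stays exact.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cds_io import CodingSequence
from .codon_core import STANDARD_CODE, STOP_SYMBOL, GeneticCode

#: Per-GC-base down-weighting of the default codon-preference mean.
DEFAULT_AT_BIAS = 0.35
#: Dirichlet concentration (total pseudo-counts per family) around the mean.
DEFAULT_DIRICHLET_CONCENTRATION = 20.0

AMINO_ACIDS = tuple(sorted(set(STANDARD_CODE.codon_to_aa.values()) - {STOP_SYMBOL}))


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for a synthetic CDS corpus.

    length_range bounds the full nt length (ATG + body + STOP) and is
    snapped to multiples of 3; target_gc_band is an inclusive (low%, high%)
    window enforced by rejection sampling (capped at 1000 attempts per
    sequence).
    """

    n_sequences: int = 19
    length_range: tuple[int, int] = (801, 3999)
    aa_composition: Mapping[str, float] | None = None
    codon_preferences: Mapping[str, Mapping[str, float]] | None = None
    stop_preferences: Mapping[str, float] | None = None
    target_gc_band: tuple[float, float] | None = (33.0, 45.0)
    seed: int = 0
    max_attempts: int = 1000

    def validate(self, code: GeneticCode = STANDARD_CODE) -> None:
        lo, hi = self.length_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"bad length_range {self.length_range}")
        if lo // 3 * 3 < 9:
            raise ValueError("minimum length must allow ATG + body + STOP")
        if self.n_sequences <= 0:
            raise ValueError("n_sequences must be positive")
        if self.aa_composition is not None:
            if set(self.aa_composition) - set(AMINO_ACIDS):
                raise ValueError("aa_composition has unknown amino acids")
            _check_simplex("aa_composition", self.aa_composition.values())
        if self.codon_preferences is not None:
            for aa, prefs in self.codon_preferences.items():
                family = set(code.families[aa])
                if set(prefs) - family:
                    raise ValueError(f"preferences for {aa} outside its family")
                _check_simplex(f"codon_preferences[{aa}]", prefs.values())
        if self.stop_preferences is not None:
            _check_simplex("stop_preferences", self.stop_preferences.values())
        if self.target_gc_band is not None:
            lo_gc, hi_gc = self.target_gc_band
            if not 0 <= lo_gc < hi_gc <= 100:
                raise ValueError(f"bad GC band {self.target_gc_band}")


def _check_simplex(name: str, values) -> None:
    v = np.asarray(list(values), dtype=float)
    if (v < 0).any() or abs(v.sum() - 1.0) > 1e-12:
        raise ValueError(f"{name} must be a probability vector summing to 1")


@dataclass
class GenerationLedger:
    """Exact record of one generated sequence's draws."""

    index: int
    codons_drawn: Counter = field(default_factory=Counter)
    gc_percent: float = 0.0
    attempts: int = 1


def default_preference_mean(
    code: GeneticCode = STANDARD_CODE, at_bias: float = DEFAULT_AT_BIAS
) -> dict[str, dict[str, float]]:
    """AT-leaning codon-preference mean: weight(codon) = at_bias ** #GC."""
    prefs: dict[str, dict[str, float]] = {}
    for aa, family in code.families.items():
        if aa == STOP_SYMBOL:
            continue
        w = np.array(
            [at_bias ** sum(b in "GC" for b in c) for c in family], dtype=float
        )
        w /= w.sum()
        prefs[aa] = dict(zip(family, w))
    return prefs


def sample_preferences(
    rng: np.random.Generator,
    code: GeneticCode = STANDARD_CODE,
    concentration: float = DEFAULT_DIRICHLET_CONCENTRATION,
    at_bias: float = DEFAULT_AT_BIAS,
) -> dict[str, dict[str, float]]:
    """Dirichlet-sample per-family codon preferences around the AT-leaning mean."""
    mean = default_preference_mean(code, at_bias)
    prefs: dict[str, dict[str, float]] = {}
    for aa, fam_mean in mean.items():
        codons = list(fam_mean)
        if len(codons) == 1:
            prefs[aa] = {codons[0]: 1.0}
            continue
        alpha = concentration * np.array([fam_mean[c] for c in codons])
        draw = rng.dirichlet(alpha)
        prefs[aa] = dict(zip(codons, draw / draw.sum()))
    return prefs


def _resolved(spec: SyntheticSpec, code: GeneticCode) -> tuple[dict, dict, dict]:
    """Fill in defaults: aa composition, codon preferences, stop preferences."""
    aa_comp = (
        dict(spec.aa_composition)
        if spec.aa_composition is not None
        else {aa: 1.0 / len(AMINO_ACIDS) for aa in AMINO_ACIDS}
    )
    if spec.codon_preferences is not None:
        prefs = {aa: dict(p) for aa, p in spec.codon_preferences.items()}
        for aa in aa_comp:
            if aa not in prefs:  # unspecified families fall back to the mean
                prefs[aa] = default_preference_mean(code)[aa]
    else:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(0xD1,))
        )
        prefs = sample_preferences(rng, code)
    stops = (
        dict(spec.stop_preferences)
        if spec.stop_preferences is not None
        else {c: 1.0 / len(code.stop_codons) for c in code.stop_codons}
    )
    return aa_comp, prefs, stops


def generate_cds(
    spec: SyntheticSpec,
    index: int,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[CodingSequence, GenerationLedger]:
    """Generate one CDS, deterministic given (spec.seed, index).

    The sequence is ATG + i.i.d. body (amino acid ~ aa_composition, codon
    ~ preferences within the family; STOP codons are excluded from the
    body) + one STOP codon.  The ledger records every codon drawn, the
    realized GC% and the number of rejection attempts.
    """
    spec.validate(code)
    aa_comp, prefs, stop_prefs = _resolved(spec, code)
    band = spec.target_gc_band
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(index,))
    )
    aas = list(aa_comp)
    aa_p = np.array([aa_comp[a] for a in aas])
    fam_codons = {aa: list(prefs[aa]) for aa in aas}
    fam_p = {aa: np.array(list(prefs[aa].values())) for aa in aas}
    stops = list(stop_prefs)
    stop_p = np.array(list(stop_prefs.values()))

    lo = max(spec.length_range[0] // 3, 3)
    hi = spec.length_range[1] // 3
    for attempt in range(1, spec.max_attempts + 1):
        n_codons = int(rng.integers(lo, hi + 1))
        body_aas = rng.choice(aas, size=n_codons - 2, p=aa_p)
        codons = ["ATG"]
        for aa in body_aas:
            codons.append(
                fam_codons[aa][rng.choice(len(fam_codons[aa]), p=fam_p[aa])]
            )
        codons.append(stops[rng.choice(len(stops), p=stop_p)])
        sequence = "".join(codons)
        gc = 100.0 * (sequence.count("G") + sequence.count("C")) / len(sequence)
        if band is None or band[0] <= gc <= band[1]:
            seq = CodingSequence(id=f"synth{index:02d}", sequence=sequence)
            ledger = GenerationLedger(
                index=index,
                codons_drawn=Counter(codons),
                gc_percent=gc,
                attempts=attempt,
            )
            return seq, ledger
    raise RuntimeError(
        f"sequence {index}: GC band {band} not attained in "
        f"{spec.max_attempts} attempts — the codon preferences force a GC% "
        "incompatible with the requested band"
    )


@dataclass
class CorpusGroundTruth:
    """Spec echo plus exact generation record for a whole corpus."""

    spec: SyntheticSpec
    aa_composition: dict[str, float]
    codon_preferences: dict[str, dict[str, float]]
    stop_preferences: dict[str, float]
    ledgers: list[GenerationLedger]

    def pooled_draws(self) -> Counter:
        pooled: Counter = Counter()
        for ledger in self.ledgers:
            pooled.update(ledger.codons_drawn)
        return pooled


def generate_corpus(
    spec: SyntheticSpec, code: GeneticCode = STANDARD_CODE
) -> tuple[list[CodingSequence], CorpusGroundTruth]:
    """Generate the full corpus with its ground truth, byte-reproducible by seed."""
    spec.validate(code)
    aa_comp, prefs, stop_prefs = _resolved(spec, code)
    seqs: list[CodingSequence] = []
    ledgers: list[GenerationLedger] = []
    for i in range(spec.n_sequences):
        seq, ledger = generate_cds(spec, i, code)
        seqs.append(seq)
        ledgers.append(ledger)
    truth = CorpusGroundTruth(
        spec=spec,
        aa_composition=aa_comp,
        codon_preferences=prefs,
        stop_preferences=stop_prefs,
        ledgers=ledgers,
    )
    return seqs, truth


def ground_truth_json(truth: CorpusGroundTruth) -> dict:
    """JSON-serializable echo of spec, preferences and per-sequence ledgers."""
    return {
        "spec": {
            "n_sequences": truth.spec.n_sequences,
            "length_range": list(truth.spec.length_range),
            "target_gc_band": (
                list(truth.spec.target_gc_band)
                if truth.spec.target_gc_band
                else None
            ),
            "seed": truth.spec.seed,
        },
        "aa_composition": truth.aa_composition,
        "codon_preferences": truth.codon_preferences,
        "stop_preferences": truth.stop_preferences,
        "ledgers": [
            {
                "index": ledger.index,
                "gc_percent": ledger.gc_percent,
                "attempts": ledger.attempts,
                "codons": dict(ledger.codons_drawn),
            }
            for ledger in truth.ledgers
        ],
    }
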