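"""End-to-end analysis: validate -> count -> indices -> stats -> report.

Produces data files shaped like the study outputs of a codon-usage
survey: a per-sequence table (id, accession, CAI, GC%, length), a tidy
per-codon index table, per-amino-acid summaries, a three-source ANOVA of
MRCBS, a per-codon z-screen, an expression classification, and a
correlation-matrix PCA of the three per-codon indices.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cds_io, codon_core, indices, stats
from .codon_core import STANDARD_CODE, GeneticCode

log = logging.getLogger("codonuse")


@dataclass
class AnalysisConfig:
    """Pipeline settings; defaults follow the standard choices of the analysis.

    reference_fasta: optional FASTA whose pooled counts define the CAI
    weights; by default the input corpus itself is the reference.
    """

    rscu_variant: str = "fraction"
    reference_fasta: str | None = None
    cai_exclude: frozenset[str] = indices.DEFAULT_CAI_EXCLUDE
    mrcbs_threshold: float = indices.DEFAULT_EXPRESSION_THRESHOLD
    alpha: float = 0.05
    cds_only: bool = False
    require_start: bool = True
    require_stop: bool = True
    summary_exclude: frozenset[str] = frozenset({"M", "W"})


@dataclass
class AnalysisReport:
    per_sequence: pd.DataFrame
    per_codon: pd.DataFrame
    amino_acid_summary: pd.DataFrame
    anova: stats.AnovaTable | None
    pca: stats.PcaResult | None
    z_screen: pd.DataFrame | None
    classification: dict[str, str]
    qc: cds_io.ValidationReport
    config: AnalysisConfig = field(repr=False, default_factory=AnalysisConfig)


def run_analysis(
    fasta: str | Path,
    config: AnalysisConfig | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> AnalysisReport:
    """Run the full analysis on a FASTA of coding sequences.

    Deterministic given inputs and config.  GC% and length are reported on
    the full input record; indices are computed on the analyzed CDS (the
    extracted ORF when ``cds_only`` is set).
    """
    config = config or AnalysisConfig()
    records = cds_io.read_fasta(fasta)
    log.info("read %d records from %s", len(records), fasta)
    full_records = {r.id: r for r in records}
    kept, qc = cds_io.qc_pipeline(
        records,
        require_start=config.require_start,
        require_stop=config.require_stop,
        cds_only=config.cds_only,
    )
    log.info(
        "QC: %d passed, %d rejected, %d duplicates",
        len(qc.passed), len(qc.rejected), len(qc.duplicates_removed),
    )
    for rid, reason in qc.rejected:
        log.info("rejected %s: %s", rid, reason)
    if not kept:
        raise ValueError("no sequences survived QC")

    tables = [codon_core.count_codons(s) for s in kept]

    if config.reference_fasta:
        ref_records = cds_io.read_fasta(config.reference_fasta)
        ref_kept, _ = cds_io.qc_pipeline(
            ref_records,
            require_start=config.require_start,
            require_stop=config.require_stop,
            cds_only=config.cds_only,
        )
        if not ref_kept:
            raise ValueError("reference FASTA yielded no valid CDS")
        reference = codon_core.pool_counts(
            [codon_core.count_codons(s) for s in ref_kept]
        )
        log.info("CAI reference: %s", config.reference_fasta)
    else:
        reference = codon_core.pool_counts(tables)
        log.info("CAI reference: pooled input corpus")
    weights = indices.reference_weights(reference, code)

    per_seq_rows = []
    long_rows = []
    for seq, counts in zip(kept, tables):
        full = full_records[seq.id]
        rscu_vec = indices.rscu(counts, code, config.rscu_variant)
        positional = codon_core.positional_base_frequencies(counts)
        rcbs_vec, rcbs_score = indices.rcbs(counts, positional)
        mrcbs_vec, mrcbs_score = indices.mrcbs(counts, positional, code)
        cai_score = indices.cai(counts, weights, code, config.cai_exclude)
        per_seq_rows.append(
            {
                "sequence_id": seq.id,
                "accession": full.accession,
                "CAI": cai_score.value,
                "GC_percent": codon_core.gc_content(full),
                "length_bp": len(full),
                "RCBS_gene": rcbs_score.value,
                "MRCBS_gene": mrcbs_score.value,
            }
        )
        for codon in codon_core.ALL_CODONS:
            long_rows.append(
                {
                    "sequence_id": seq.id,
                    "amino_acid": code.codon_to_aa[codon],
                    "codon": codon,
                    "count": counts.counts[codon],
                    "RSCU": rscu_vec[codon],
                    "RCBS": rcbs_vec[codon],
                    "MRCBS": mrcbs_vec[codon],
                }
            )

    per_sequence = pd.DataFrame(per_seq_rows)
    per_codon = pd.DataFrame(long_rows)

    aa_summary = _amino_acid_summary(per_codon, config.summary_exclude)

    mrcbs_long = per_codon.rename(columns={"MRCBS": "value"})[
        ["sequence_id", "amino_acid", "codon", "value"]
    ]
    anova = z_screen = pca = None
    if len(per_sequence) >= 2:
        anova = stats.anova_three_source(mrcbs_long)
        mean_mrcbs_per_codon = (
            per_codon.groupby("codon")["MRCBS"].mean().to_dict()
        )
        z_screen = stats.codon_z_screen(mean_mrcbs_per_codon, alpha=config.alpha)
    else:
        log.info("single sequence: ANOVA and z-screen skipped")

    # expression class per amino acid: mean MRCBS over *used* codons, all
    # sequences (an unused codon has no bias value, not a zero one)
    used = per_codon[per_codon["count"] > 0]
    aa_means = used.groupby("amino_acid")["MRCBS"].mean().to_dict()
    classification = indices.classify_expression(
        aa_means, threshold=config.mrcbs_threshold
    )

    try:
        pca = stats.pca_indices(used[["RSCU", "MRCBS", "RCBS"]])
    except ValueError as exc:
        log.info("PCA skipped: %s", exc)

    log.info(
        "analysis done: %d sequences, %d long-table rows",
        len(per_sequence), len(per_codon),
    )
    return AnalysisReport(
        per_sequence=per_sequence,
        per_codon=per_codon,
        amino_acid_summary=aa_summary,
        anova=anova,
        pca=pca,
        z_screen=z_screen,
        classification=classification,
        qc=qc,
        config=config,
    )


def _amino_acid_summary(
    per_codon: pd.DataFrame, exclude: frozenset[str]
) -> pd.DataFrame:
    """Mean +/- sd per amino acid for each index, single-codon families excluded.

    Met and Trp carry no synonymous choice, so their RSCU/MRCBS are
    constant and only clutter the summary.
    """
    sub = per_codon[~per_codon["amino_acid"].isin(exclude)]
    out = sub.groupby("amino_acid")[["RSCU", "RCBS", "MRCBS"]].agg(
        ["mean", "std"]
    )
    out.columns = [f"{idx}_{stat}" for idx, stat in out.columns]
    return out.reset_index()


def write_report(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Write every stage output under ``out_dir`` with a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _save(name: str, text: str) -> None:
        p = out / name
        p.write_text(text)
        written.append(p)

    _save("per_sequence.tsv", report.per_sequence.to_csv(sep="\t", index=False))
    _save("per_codon.tsv", report.per_codon.to_csv(sep="\t", index=False))
    _save(
        "amino_acid_summary.tsv",
        report.amino_acid_summary.to_csv(sep="\t", index=False),
    )
    if report.anova is not None:
        _save(
            "anova.tsv", report.anova.to_frame().to_csv(sep="\t", index=False)
        )
    if report.pca is not None:
        _save(
            "pca.json",
            json.dumps(
                {
                    "eigenvalues": report.pca.eigenvalues.tolist(),
                    "proportions": report.pca.proportions.tolist(),
                    "loadings": report.pca.loadings.to_dict(),
                },
                indent=2,
            ),
        )
    if report.z_screen is not None:
        _save(
            "z_screen.tsv", report.z_screen.to_csv(sep="\t", index=False)
        )
    _save("classification.json", json.dumps(report.classification, indent=2))
    _save("qc_report.json", report.qc.to_json())
    _save("qc_report.tsv", report.qc.to_tsv())
    manifest = {"files": [p.name for p in written]}
    _save("manifest.json", json.dumps(manifest, indent=2))
    return written
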