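"""Downstream summaries of codon-index tables.

Fixed-effects ANOVA with sequential (fit-order) sums of squares, a
per-codon z-score screen, an empirical normality summary, and a
correlation-matrix PCA of the three per-codon indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

LONG_COLUMNS = ("sequence_id", "amino_acid", "codon", "value")

_FACTOR_LABELS = {
    "sequence_id": "Sequences",
    "amino_acid": "Amino acids",
    "codon": "Codons",
}


def check_long_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the tidy (sequence_id, amino_acid, codon, value) table."""
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"long table missing columns: {missing}")
    if table.duplicated(subset=["sequence_id", "codon"]).any():
        raise ValueError("duplicate (sequence_id, codon) pairs in long table")
    aa_per_codon = table.groupby("codon")["amino_acid"].nunique()
    if (aa_per_codon > 1).any():
        bad = aa_per_codon[aa_per_codon > 1].index.tolist()
        raise ValueError(f"codons mapped to several amino acids: {bad}")
    return table


@dataclass
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float
    f_value: float
    p_value: float


@dataclass
class AnovaTable:
    """Sources, residual and total of a fixed-effects ANOVA."""

    rows: list[AnovaRow]
    residual_df: int
    residual_ss: float
    total_ss: float

    @property
    def residual_ms(self) -> float:
        return self.residual_ss / self.residual_df

    def to_frame(self) -> pd.DataFrame:
        records = [
            {
                "Source": r.source,
                "DF": r.df,
                "Anova SS": r.ss,
                "Mean Square": r.ms,
                "F Value": r.f_value,
                "Pr > F": r.p_value,
            }
            for r in self.rows
        ]
        records.append(
            {
                "Source": "Residual",
                "DF": self.residual_df,
                "Anova SS": self.residual_ss,
                "Mean Square": self.residual_ms,
                "F Value": np.nan,
                "Pr > F": np.nan,
            }
        )
        return pd.DataFrame.from_records(records)


def _design_matrix(table: pd.DataFrame, factors: list[str]) -> np.ndarray:
    cols = [np.ones((len(table), 1))]
    for f in factors:
        d = pd.get_dummies(table[f], dtype=float)
        cols.append(d.to_numpy())
    return np.hstack(cols)


def _rss(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of the least-squares fit."""
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def anova_fixed(
    table: pd.DataFrame,
    factors: list[str],
    response: str = "value",
) -> AnovaTable:
    """Sequential (fit-order) sums of squares for an additive fixed-effects model.

    Each factor's SS is the reduction in residual SS when it enters the
    model after the factors listed before it; its DF is the rank gained,
    which for a factor with k levels is k - 1 unless the factor is aliased
    with earlier terms (e.g. codon entered after amino acid).  F-ratios are
    against the residual mean square of the full additive model.
    """
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    y = table[response].to_numpy(dtype=float)
    total_ss = float(((y - y.mean()) ** 2).sum())

    rss_prev, rank_prev = _rss(y, np.ones((len(y), 1)))
    contributions: list[tuple[str, float, int]] = []
    for i in range(1, len(factors) + 1):
        x = _design_matrix(table, factors[:i])
        rss_cur, rank_cur = _rss(y, x)
        contributions.append(
            (factors[i - 1], rss_prev - rss_cur, rank_cur - rank_prev)
        )
        rss_prev, rank_prev = rss_cur, rank_cur

    residual_df = len(y) - rank_prev
    if residual_df <= 0:
        raise ValueError(
            f"saturated design: factors {factors} leave no residual "
            "degrees of freedom"
        )
    residual_ss = rss_prev
    ms_error = residual_ss / residual_df
    rows = []
    for name, ss, df in contributions:
        ms = ss / df
        if ms_error == 0:  # zero-noise data: F undefined
            f_value = np.nan
            p = np.nan
        else:
            f_value = ms / ms_error
            p = float(sps.f.sf(f_value, df, residual_df))
        rows.append(
            AnovaRow(_FACTOR_LABELS.get(name, name), df, ss, ms, f_value, p)
        )
    return AnovaTable(rows, residual_df, residual_ss, total_ss)


def anova_three_source(table: pd.DataFrame) -> AnovaTable:
    """Three-source ANOVA of an index long table: sequences, amino acids, codons.

    Amino acid and codon are aliased factors (a codon determines its amino
    acid), so a single additive fit cannot carry both at full degrees of
    freedom.  This summary therefore merges two two-way fixed-effects fits:
    value ~ sequence + codon supplies the Sequences and Codons rows and the
    residual; value ~ sequence + amino_acid supplies the Amino acids row,
    tested against that same residual.  Each factor appears at its full
    k - 1 degrees of freedom.
    """
    check_long_table(table)
    by_codon = anova_fixed(table, ["sequence_id", "codon"])
    by_aa = anova_fixed(table, ["sequence_id", "amino_acid"])
    ms_error = by_codon.residual_ms
    aa_row = by_aa.rows[1]
    f_value = aa_row.ms / ms_error
    aa_adj = AnovaRow(
        aa_row.source,
        aa_row.df,
        aa_row.ss,
        aa_row.ms,
        f_value,
        float(sps.f.sf(f_value, aa_row.df, by_codon.residual_df)),
    )
    return AnovaTable(
        rows=[by_codon.rows[0], aa_adj, by_codon.rows[1]],
        residual_df=by_codon.residual_df,
        residual_ss=by_codon.residual_ss,
        total_ss=by_codon.total_ss,
    )


def codon_z_screen(
    values: dict[str, float], alpha: float = 0.05
) -> pd.DataFrame:
    """Z-score each codon's value against the across-codon mean and sd.

    z = (value - mean) / sd with the sample sd (n - 1); two-sided normal
    p-value; codons with p < alpha are flagged.  Raises on zero variance.
    """
    if len(values) < 3:
        raise ValueError("z-screen needs at least 3 codon values")
    codons = list(values)
    v = np.array([values[c] for c in codons], dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("z-screen undefined: zero variance across codons")
    z = (v - v.mean()) / sd
    p = 2.0 * sps.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"codon": codons, "z": z, "p": p, "significant": p < alpha}
    )


@dataclass
class NormalitySummary:
    mean: float
    sd: float
    within_1sd: float
    within_2sd: float


def normality_summary(values) -> NormalitySummary:
    """Sample mean/sd plus empirical coverage of mean +/- 1 and 2 sd.

    For normal data the 1-sd coverage is ~68% and the 2-sd coverage ~95%.
    A constant list is degenerate: sd = 0 and coverage 1.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("normality summary needs at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0:
        return NormalitySummary(mean, 0.0, 1.0, 1.0)
    within1 = float(np.mean(np.abs(v - mean) <= sd))
    within2 = float(np.mean(np.abs(v - mean) <= 2 * sd))
    return NormalitySummary(mean, sd, within1, within2)


@dataclass
class PcaResult:
    """Correlation-matrix PCA: eigenvalues sum to the number of columns."""

    eigenvalues: np.ndarray
    proportions: np.ndarray
    loadings: pd.DataFrame  # variables x components

    def to_frame(self) -> pd.DataFrame:
        comps = [f"PC{i + 1}" for i in range(len(self.eigenvalues))]
        return pd.DataFrame(
            {"component": comps,
             "eigenvalue": self.eigenvalues,
             "proportion": self.proportions}
        )


def pca_indices(matrix: pd.DataFrame) -> PcaResult:
    """PCA of standardized index columns via the correlation matrix.

    Rows are (sequence, codon) observations; columns are index values.
    Eigenvalues are returned descending with proportions eigenvalue/k.
    Sign convention: the largest-magnitude loading of each component is
    made positive.  A constant column makes the correlation undefined and
    raises, naming the column.
    """
    if len(matrix) < 3:
        raise ValueError("PCA needs at least 3 rows")
    x = matrix.to_numpy(dtype=float)
    sds = x.std(axis=0, ddof=1)
    constant = [c for c, s in zip(matrix.columns, sds) if s == 0]
    if constant:
        raise ValueError(f"constant column(s) not admissible for PCA: {constant}")
    corr = np.corrcoef(x, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        if eigvecs[np.argmax(np.abs(eigvecs[:, j])), j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    k = corr.shape[0]
    loadings = pd.DataFrame(
        eigvecs,
        index=list(matrix.columns),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(eigvals, eigvals / k, loadings)
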