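"""Tissue-specificity of gene expression.

The tau index summarizes how concentrated a gene's expression is across N
tissues:

    tau = sum_i (1 - x_i) / (N - 1),   x_i = expression_i / max_i expression_i

tau is 0 for flat (housekeeping) profiles and 1 for single-tissue
profiles; genes above 0.8 are conventionally called tissue-specific.
Expression matrices are filtered first: per-entry values below 0.1 TPM are
zeroed and genes whose total across tissues stays below 0.1 x N are
excluded.  Cross-tissue location shifts are tested with the Friedman test
plus a Wilcoxon–Nemenyi–McDonald–Thompson post-hoc and paired rank-
biserial effect sizes.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

TAU_SPECIFIC_CUTOFF = 0.8


def filter_expression(
    matrix: pd.DataFrame, low: float = 0.1
) -> tuple[pd.DataFrame, list]:
    """Zero sub-threshold entries, then drop consistently low genes.

    Entries below ``low`` TPM are set to 0; genes whose row sum over the
    N tissues is below ``low * N`` are removed.  Returns the filtered
    matrix and the excluded gene list.
    """
    if (matrix < 0).any().any():
        raise ValueError("expression values must be nonnegative")
    out = matrix.where(matrix >= low, 0.0)
    n = matrix.shape[1]
    keep = out.sum(axis=1) >= low * n
    return out.loc[keep], list(out.index[~keep])


@dataclass
class TauResult:
    gene_id: str
    tau: float
    tissue_fractions: pd.Series  # x_i / max, per tissue


def compute_tau(profile: pd.Series, gene_id: str | None = None) -> TauResult:
    """Tau tissue-specificity index of one nonnegative expression profile."""
    x = profile.astype(float)
    if len(x) < 2:
        raise ValueError("tau needs >= 2 tissues")
    if (x < 0).any():
        raise ValueError("expression values must be nonnegative")
    m = x.max()
    if m == 0:
        raise ValueError("all-zero profile: tau undefined (filter upstream)")
    xn = x / m
    tau = float((1 - xn).sum() / (len(x) - 1))
    return TauResult(
        gene_id=gene_id if gene_id is not None else str(profile.name),
        tau=tau,
        tissue_fractions=xn,
    )


def tau_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Tau and per-tissue fractions for every gene of a filtered matrix."""
    xn = matrix.div(matrix.max(axis=1), axis=0)
    tau = (1 - xn).sum(axis=1) / (matrix.shape[1] - 1)
    out = xn.copy()
    out.insert(0, "tau", tau)
    return out


def normalize_tissue_expression(
    matrix: pd.DataFrame, method: str = "quantile"
) -> pd.DataFrame:
    """Within- and across-tissue normalization applied before tau.

    ``quantile``: per-tissue rank-quantile scaling to a common [0, 1]
    grid, then per-gene max normalization happens inside tau itself.
    ``log``: log10(x + 1) per entry (a milder alternative).
    """
    if method == "quantile":
        ranked = matrix.rank(axis=0, method="average")
        return ranked.div(ranked.max(axis=0), axis=1) * matrix.max(axis=0).mean()
    if method == "log":
        return np.log10(matrix + 1.0)
    raise ValueError("method must be 'quantile' or 'log'")


def _paired_rank_biserial(a: np.ndarray, b: np.ndarray) -> float:
    """Matched-pairs rank-biserial correlation from signed ranks."""
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    return float((w_pos - w_neg) / (w_pos + w_neg))


def compare_tissue_expression(matrix: pd.DataFrame) -> dict:
    """Friedman test across tissues plus all-pairs post-hoc and effect sizes.

    ``matrix`` is gene x tissue.  With exactly two tissues the Friedman
    test is computed as the exact two-sided sign test (they coincide and
    the chi-square approximation would be poor).  Post-hoc all-pairs
    p-values use the Wilcoxon–Nemenyi–McDonald–Thompson studentized-range
    statistic on rank sums; paired rank-biserial effect sizes are reported
    for pairs significant at 0.05.
    """
    tissues = list(matrix.columns)
    k = len(tissues)
    n = len(matrix)
    if n < 10:
        raise ValueError("need >= 10 genes after filtering")
    X = matrix.to_numpy(float)

    if k == 2:
        d = X[:, 0] - X[:, 1]
        nz = d[d != 0]
        if len(nz) == 0:
            stat_p = (0.0, 1.0)
        else:
            npos = int((nz > 0).sum())
            stat_p = (
                float(npos),
                float(stats.binomtest(npos, len(nz), 0.5).pvalue),
            )
        statistic, pvalue = stat_p
    else:
        with np.errstate(invalid="ignore"):
            statistic, pvalue = stats.friedmanchisquare(
                *(X[:, j] for j in range(k))
            )
        if not np.isfinite(statistic):
            # all within-gene ranks tied (e.g. identical columns)
            statistic, pvalue = 0.0, 1.0

    # within-gene ranks (average ranks on ties) drive the post-hoc
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12 * n))
    posthoc = pd.DataFrame(np.ones((k, k)), index=tissues, columns=tissues)
    effects = {}
    for i, j in combinations(range(k), 2):
        q = abs(mean_ranks[i] - mean_ranks[j]) / se
        p = float(stats.studentized_range.sf(q, k, np.inf))
        posthoc.iloc[i, j] = posthoc.iloc[j, i] = p
        if p < 0.05:
            effects[(tissues[i], tissues[j])] = _paired_rank_biserial(
                X[:, i], X[:, j]
            )
    return {
        "friedman_statistic": float(statistic),
        "friedman_p": float(pvalue),
        "posthoc_p": posthoc,
        "rank_biserial": effects,
        "mean_ranks": pd.Series(mean_ranks, index=tissues),
    }


def tissue_specific_fraction(
    tau_tbl: pd.DataFrame, tissue: str, cutoff: float = TAU_SPECIFIC_CUTOFF
) -> float:
    """Fraction of genes specific to ``tissue`` (tau fraction above cutoff)."""
    return float((tau_tbl[tissue] > cutoff).mean())
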