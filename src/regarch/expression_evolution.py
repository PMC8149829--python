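"""Cross-species differential-expression patterns and their association
with regulatory-architecture complexity.

Pairwise differential-expression Q-values (produced upstream; this module
consumes them) are turned into per-gene pattern labels: not differentially
expressed, species-specific (one species drives every significant pair),
or non-species-specific.  Direction is read off the mean normalized
expression of the driving species against the rest.  A signed-rank test
then asks, per (component, state), whether gaining elements of that kind
tracks expression in the expected direction — up for strong and weak
activities, down for poised ones.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .networks import COMPONENTS
from .states import CORE_LABELS

DE_LABELS = ("not_DE", "species_specific", "non_species_specific")

# expected direction of the expression change per activity class
_DIRECTION = {"s": "greater", "w": "greater", "p": "less"}


@dataclass
class DEPattern:
    gene_id: str
    label: str
    species: str | None  # driving species for species-specific patterns
    direction: str  # up / down / none


def pair_columns(species: list[str]) -> list[tuple[str, str]]:
    """Canonical ordering of the species pairwise comparisons."""
    return list(combinations(sorted(species), 2))


def de_pattern_labels(
    qvalues: pd.DataFrame,
    expression_means: pd.DataFrame,
    fdr: float = 0.1,
) -> list[DEPattern]:
    """Label each gene's cross-species differential-expression pattern.

    ``qvalues`` has one row per gene and one column per species pair named
    "A|B"; ``expression_means`` is gene x species mean normalized
    expression.  A gene is not_DE when no pair passes the FDR;
    species-specific when the significant pairs are exactly the pairs
    involving one particular species; anything else (including
    inconsistent topologies) is non-species-specific.
    """
    species = sorted(expression_means.columns)
    pairs = pair_columns(species)
    expected_cols = [f"{a}|{b}" for a, b in pairs]
    missing = set(expected_cols) - set(qvalues.columns)
    if missing:
        raise ValueError(f"missing pairwise comparisons: {sorted(missing)}")
    if ((qvalues[expected_cols] < 0) | (qvalues[expected_cols] > 1)).any().any():
        raise ValueError("Q-values must lie in [0, 1]")

    out = []
    for gene, row in qvalues.iterrows():
        sig = {
            (a, b)
            for (a, b), col in zip(pairs, expected_cols)
            if row[col] < fdr
        }
        if not sig:
            out.append(DEPattern(gene, "not_DE", None, "none"))
            continue
        driver = None
        for s in species:
            s_pairs = {p for p in pairs if s in p}
            if sig == s_pairs:
                driver = s
                break
        if driver is None:
            # inconsistent / multi-species topology: direction read off the
            # most DE-involved species group against the rest
            involvement = {s: sum(s in p for p in sig) for s in species}
            top = max(involvement.values())
            group = [s for s in species if involvement[s] == top]
            rest = [s for s in species if s not in group] or species
            direction = (
                "up"
                if expression_means.loc[gene, group].mean()
                > expression_means.loc[gene, rest].mean()
                else "down"
            )
            out.append(DEPattern(gene, "non_species_specific", None, direction))
            continue
        mean_s = expression_means.loc[gene, driver]
        mean_rest = expression_means.loc[
            gene, [s for s in species if s != driver]
        ].mean()
        direction = "up" if mean_s > mean_rest else "down"
        out.append(DEPattern(gene, "species_specific", driver, direction))
    return out


def patterns_frame(patterns: list[DEPattern]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.gene_id, p.label, p.species, p.direction) for p in patterns],
        columns=["gene_id", "label", "species", "direction"],
    )


def complexity_association(
    state_counts: pd.DataFrame,
    expression: pd.DataFrame,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Signed-rank association between component-state counts and expression.

    ``state_counts`` has one row per (gene, species) and one column per
    "component/state" combination holding the number of elements of that
    kind in the gene's architecture; ``expression`` is gene x species.
    For each gene and species the deltas against the gene's cross-species
    mean are paired; a one-sided Wilcoxon signed-rank test asks whether
    element gains track higher expression (strong/weak) or lower
    expression (poised).  P-values are BH-corrected across the 30
    (component, state) tests.
    """
    species = sorted(expression.columns)
    counts = state_counts.set_index(["gene_id", "species"]) if "gene_id" in state_counts.columns else state_counts
    expr_mean = expression[species].mean(axis=1)

    rows = []
    for comp in COMPONENTS:
        for state in CORE_LABELS:
            col = f"{comp}/{state}"
            if col not in counts.columns:
                rows.append((comp, state, np.nan, 0, True))
                continue
            wide = counts[col].unstack("species").reindex(columns=species)
            genes = wide.index.intersection(expression.index)
            wide = wide.loc[genes].fillna(0.0)
            count_mean = wide.mean(axis=1)
            d_count = wide.sub(count_mean, axis=0)
            d_expr = expression.loc[genes, species].sub(expr_mean.loc[genes], axis=0)
            dc = d_count.to_numpy().ravel()
            de = d_expr.to_numpy().ravel()
            informative = dc != 0
            n_inf = int(informative.sum())
            if n_inf < min_pairs:
                rows.append((comp, state, np.nan, n_inf, True))
                continue
            aligned = de[informative] * np.sign(dc[informative])
            alternative = _DIRECTION[state[0]]
            if np.all(aligned == 0):
                p = 1.0
            else:
                p = stats.wilcoxon(
                    aligned, alternative=alternative, zero_method="wilcox"
                ).pvalue
            rows.append((comp, state, float(p), n_inf, False))
    out = pd.DataFrame(
        rows, columns=["component", "state", "p", "n_pairs", "underpowered"]
    )
    ok = out["p"].notna()
    out["p_adjusted"] = np.nan
    if ok.any():
        out.loc[ok, "p_adjusted"] = multipletests(
            out.loc[ok, "p"], method="fdr_bh"
        )[1]
    return out
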