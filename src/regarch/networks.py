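"""Signal design matrix, eigencomponents, sparse partial-correlation
networks and the promoter/intragenic-enhancer expression GLM.

The design matrix has one row per (gene, species, replicate) case and 51
columns: expression plus the summed signal of 5 histone marks x 2
regulatory-state classes (P/E) x 5 architecture components.  Each
(state, component) block of 5 mark columns is summarized by its first
principal component ("eigencomponent"), sign-aligned with H3K27ac.
Partial correlations are estimated per species from a shrinkage-
regularized correlation matrix, tested and BH-adjusted, and retained only
when recovered in >= 4 of 5 species and when reciprocal cross-validated
LASSO models of both endpoint variables generalize across species
(held-out R^2 > 0).
"""
from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import LedoitWolf
from sklearn.linear_model import LassoCV, LinearRegression
from statsmodels.stats.multitest import multipletests

from .states import ENHANCER_LABELS, PROMOTER_LABELS

MARKS = ["h3k4me3", "h3k4me1", "h3k27ac", "h3k36me3", "h3k27me3"]
STATE_CLASSES = ["P", "E"]
COMPONENTS = ["gP", "gE", "prE", "PiE", "EiE"]
GLM_MARKS = ["h3k27ac", "h3k27me3", "h3k36me3"]


def design_columns() -> list[str]:
    """Deterministic 51-column ordering: expression, then component-major blocks."""
    cols = ["expression"]
    for comp in COMPONENTS:
        for state in STATE_CLASSES:
            for mark in MARKS:
                cols.append(f"{comp}/{state}/{mark}")
    return cols


def build_design_matrix(
    architectures: pd.DataFrame,
    signals: pd.DataFrame,
    expression: pd.DataFrame,
    require_all_species: bool = False,
) -> pd.DataFrame:
    """Aggregate per-element signals into the gene x 51-variable matrix.

    ``architectures`` needs columns gene_id/species/element/component/state
    (one row per element-gene association); ``signals`` one row per
    (element, species, sample) with the five mark columns; ``expression``
    is gene x (species, sample) with columns named "species:sample".
    Signals of all elements with a given state class in a given component
    are summed per case; components with no element contribute 0.
    """
    unknown = set(architectures["component"]) - set(COMPONENTS)
    if unknown:
        raise ValueError(f"unknown component labels: {sorted(unknown)}")

    arch = architectures.copy()
    arch["state_class"] = arch["state"].map(
        lambda s: "P" if s in PROMOTER_LABELS else ("E" if s in ENHANCER_LABELS else None)
    )
    arch = arch.dropna(subset=["state_class"])

    sig = signals.merge(
        arch[["gene_id", "species", "element", "component", "state_class"]],
        on=["element", "species"],
        how="inner",
    )
    sums = (
        sig.groupby(["gene_id", "species", "sample", "component", "state_class"])[MARKS]
        .sum()
        .reset_index()
    )

    genes = sorted(expression.index)
    if require_all_species:
        per_gene = arch.groupby("gene_id")["species"].nunique()
        n_species = arch["species"].nunique()
        genes = [g for g in genes if per_gene.get(g, 0) == n_species]
    cols = design_columns()
    sample_keys = sorted(expression.columns)
    index = pd.MultiIndex.from_product(
        [genes, sample_keys], names=["gene_id", "case"]
    )
    mat = pd.DataFrame(0.0, index=index, columns=cols)
    mat["expression"] = expression.loc[genes, sample_keys].to_numpy(float).ravel()
    if len(sums):
        sums = sums.assign(case=sums["species"] + ":" + sums["sample"])
        wide = sums.pivot_table(
            index=["gene_id", "case"],
            columns=["component", "state_class"],
            values=MARKS,
            aggfunc="sum",
            fill_value=0.0,
        )
        wide.columns = [
            f"{comp}/{state}/{mark}" for mark, comp, state in wide.columns
        ]
        wide = wide.reindex(index, fill_value=0.0).fillna(0.0)
        for c in wide.columns:
            if c in mat.columns:
                mat[c] = wide[c].to_numpy()
    mat = mat.reset_index()
    mat[["species", "sample"]] = mat["case"].str.split(":", n=1, expand=True)
    mat = mat.drop(columns="case")
    return mat[["gene_id", "species", "sample"] + cols]


@dataclass
class Eigencomponent:
    component: str
    state_class: str
    scores: np.ndarray
    variance_explained: float
    sign_flipped: bool
    degenerate: bool = False

    @property
    def name(self) -> str:
        return f"EC:{self.component}/{self.state_class}"


def compute_eigencomponents(matrix: pd.DataFrame) -> list[Eigencomponent]:
    """First-PC summaries of each (component, state) block of 5 mark columns.

    Scores are sign-aligned so their correlation with the block's H3K27ac
    column is nonnegative.  An all-zero block yields a flagged degenerate
    eigencomponent with zero scores.
    """
    if len(matrix) < 6:
        raise ValueError("need >= 6 cases")
    out = []
    for comp in COMPONENTS:
        for state in STATE_CLASSES:
            cols = [f"{comp}/{state}/{m}" for m in MARKS]
            X = matrix[cols].to_numpy(float)
            if np.allclose(X, 0) or np.allclose(X.std(axis=0), 0):
                out.append(
                    Eigencomponent(comp, state, np.zeros(len(X)), 0.0, False, True)
                )
                continue
            Xc = X - X.mean(axis=0)
            sd = Xc.std(axis=0)
            sd[sd == 0] = 1.0
            Xs = Xc / sd
            u, s, vt = np.linalg.svd(Xs, full_matrices=False)
            scores = Xs @ vt[0]
            var_explained = float(s[0] ** 2 / (s**2).sum())
            k27ac = Xs[:, MARKS.index("h3k27ac")]
            flipped = False
            r = np.corrcoef(scores, k27ac)[0, 1] if k27ac.std() > 0 else 0.0
            if r < 0:
                scores = -scores
                flipped = True
            out.append(Eigencomponent(comp, state, scores, var_explained, flipped))
    return out


# ---------------------------------------------------------------------------
# sparse partial correlations


@dataclass
class NetworkEdge:
    var_a: str
    var_b: str
    partial_correlation: float
    p_adjusted: float
    n_species_recovered: int
    retained: bool


def partial_correlation_matrix(X: np.ndarray) -> np.ndarray:
    """Partial correlations from the shrinkage-regularized precision matrix."""
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    lw = LedoitWolf(assume_centered=True).fit(Xs)
    prec = np.linalg.inv(lw.covariance_)
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def _partial_corr_pvalues(pc: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for partial correlations controlling k-2 variables."""
    k = pc.shape[0]
    dof = n - (k - 2) - 2
    if dof <= 0:
        raise ValueError("not enough cases for partial-correlation inference")
    r = np.clip(pc, -0.999999, 0.999999)
    t = r * np.sqrt(dof / (1 - r**2))
    return 2 * stats.t.sf(np.abs(t), dof)


def _cv_r2_per_variable(
    X: np.ndarray,
    groups: np.ndarray,
    seed: int | None,
) -> np.ndarray:
    """Mean held-out R^2 of a LASSO model per variable across group folds."""
    uniq = np.unique(groups)
    k = X.shape[1]
    r2 = np.zeros((k, len(uniq)))
    for f, g in enumerate(uniq):
        test = groups == g
        train = ~test
        Xtr = X[train]
        Xte = X[test]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Ztr = (Xtr - mu) / sd
        Zte = (Xte - mu) / sd
        for j in range(k):
            others = np.delete(np.arange(k), j)
            model = LassoCV(cv=3, alphas=20, random_state=seed, max_iter=5000)
            model.fit(Ztr[:, others], Ztr[:, j])
            pred = model.predict(Zte[:, others])
            ss_res = np.sum((Zte[:, j] - pred) ** 2)
            ss_tot = np.sum((Zte[:, j] - Zte[:, j].mean()) ** 2)
            r2[j, f] = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return r2.mean(axis=1)


def sparse_partial_correlation(
    data: pd.DataFrame,
    species: np.ndarray | pd.Series,
    alpha: float = 0.05,
    n_folds: int = 5,
    seed: int | None = None,
    min_species: int = 4,
) -> list[NetworkEdge]:
    """Species-replicated sparse partial-correlation network.

    Per species: estimate the partial-correlation matrix, test each edge
    and BH-adjust.  An edge is a candidate when significant in at least
    ``min_species`` species; candidates are kept only when the reciprocal
    LASSO models of both endpoints predict the held-out species with
    positive R^2 (the anti-overfitting filter).
    """
    species = np.asarray(species)
    uniq = np.unique(species)
    if len(uniq) < n_folds:
        raise ValueError(f"need cases from >= {n_folds} species groups")
    varnames = list(data.columns)
    X = data.to_numpy(float)
    k = len(varnames)

    sig_count = np.zeros((k, k), dtype=int)
    pc_all = np.zeros((k, k))
    padj_max = np.zeros((k, k))
    for sp in uniq:
        Xs = X[species == sp]
        if Xs.std(axis=0).min() == 0:
            raise ValueError("constant variable within a species group")
        pc = partial_correlation_matrix(Xs)
        pvals = _partial_corr_pvalues(pc, len(Xs))
        iu = np.triu_indices(k, 1)
        rej, padj, *_ = multipletests(pvals[iu], alpha=alpha, method="fdr_bh")
        sig = np.zeros((k, k), dtype=bool)
        sig[iu] = rej
        adj = np.ones((k, k))
        adj[iu] = padj
        sig_count += sig
        pc_all += pc / len(uniq)
        padj_max = np.maximum(padj_max, adj)

    candidates = [
        (i, j)
        for i, j in zip(*np.triu_indices(k, 1))
        if sig_count[i, j] >= min_species
    ]
    generalizes = np.ones(k, dtype=bool)
    if candidates:
        r2 = _cv_r2_per_variable(X, species, seed)
        generalizes = r2 > 0

    edges = []
    for i, j in zip(*np.triu_indices(k, 1)):
        retained = (
            sig_count[i, j] >= min_species
            and bool(generalizes[i])
            and bool(generalizes[j])
        )
        edges.append(
            NetworkEdge(
                var_a=varnames[i],
                var_b=varnames[j],
                partial_correlation=float(pc_all[i, j]),
                p_adjusted=float(padj_max[i, j]),
                n_species_recovered=int(sig_count[i, j]),
                retained=retained,
            )
        )
    return edges


def residual_network(
    matrix: pd.DataFrame,
    eigencomponents: list[Eigencomponent],
    species: np.ndarray | pd.Series,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[NetworkEdge]]:
    """Partial-correlation network of mark signals residualized on their
    eigencomponents.

    Each mark column is replaced by the residual of a univariate linear
    fit on its block's eigencomponent; degenerate eigencomponents leave
    their block unresidualized.  The network is then estimated on the
    residuals plus the expression column.
    """
    resid = pd.DataFrame(index=matrix.index)
    resid["expression"] = matrix["expression"].to_numpy()
    ec_by_block = {(e.component, e.state_class): e for e in eigencomponents}
    for comp in COMPONENTS:
        for state in STATE_CLASSES:
            ec = ec_by_block[(comp, state)]
            for mark in MARKS:
                col = f"{comp}/{state}/{mark}"
                y = matrix[col].to_numpy(float)
                if ec.degenerate:
                    resid[col] = y
                    continue
                x = ec.scores.reshape(-1, 1)
                fit = LinearRegression().fit(x, y)
                resid[col] = y - fit.predict(x)
    keep = [c for c in resid.columns if resid[c].std() > 0]
    edges = sparse_partial_correlation(
        resid[keep], species, alpha=alpha, seed=seed
    )
    return resid, edges


# ---------------------------------------------------------------------------
# expression GLM


@dataclass
class GlmFit:
    model: str
    coefficients: pd.Series
    variance_explained: float
    predictors: list[str] = field(default_factory=list)


def glm_predictor_names(model: str = "core15") -> list[str]:
    if model == "core15":
        mains = [f"gP/P/{m}" for m in GLM_MARKS] + [f"gE/E/{m}" for m in GLM_MARKS]
        inter = [
            f"gP/P/{mp} x gE/E/{me}" for mp in GLM_MARKS for me in GLM_MARKS
        ]
        return mains + inter
    if model == "naive":
        return [c for c in design_columns() if c != "expression"]
    raise ValueError("model must be 'core15' or 'naive'")


def glm_design(matrix: pd.DataFrame, model: str = "core15") -> pd.DataFrame:
    names = glm_predictor_names(model)
    X = pd.DataFrame(index=matrix.index)
    for name in names:
        if " x " in name:
            a, b = name.split(" x ")
            X[name] = matrix[a].to_numpy() * matrix[b].to_numpy()
        else:
            X[name] = matrix[name].to_numpy()
    return X


def expression_glm(matrix: pd.DataFrame, model: str = "core15") -> GlmFit:
    """Gaussian GLM of expression on gP/gE mark signals.

    ``core15``: H3K27ac/H3K27me3/H3K36me3 at the genic promoter (P state)
    and intragenic enhancers (E state), 6 main effects plus the 9 gP x gE
    cross-products.  ``naive``: all 50 signal columns, no interactions.
    """
    X = glm_design(matrix, model)
    sd = X.std(axis=0)
    if (sd == 0).any():
        # constant columns make an unidentifiable fit only when they
        # collide; drop them from the design like R's glm would alias them
        X = X.loc[:, sd > 0]
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the collinear group for the error message
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"most collinear pair: {X.columns[i]!r} ~ {X.columns[j]!r}"
        )
    y = matrix["expression"].to_numpy(float)
    import statsmodels.api as sm

    fit = sm.OLS(y, sm.add_constant(X)).fit()
    coeffs = fit.params.drop("const")
    return GlmFit(
        model=model,
        coefficients=coeffs,
        variance_explained=float(fit.rsquared),
        predictors=list(X.columns),
    )


def edges_frame(edges: list[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                e.var_a,
                e.var_b,
                e.partial_correlation,
                e.p_adjusted,
                e.n_species_recovered,
                e.retained,
            )
            for e in edges
        ],
        columns=[
            "var_a",
            "var_b",
            "partial_correlation",
            "p_adjusted",
            "n_species_recovered",
            "retained",
        ],
    )
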