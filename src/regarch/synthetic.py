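"""Synthetic comparative-epigenomics datasets with known ground truth.

The generator lays out a toy genome of per-gene cassettes, each carrying
one element per architecture component (genic promoter, intragenic
enhancer, proximal enhancer, a distal element wired to the promoter by an
interaction, one wired to the intragenic enhancer, and an orphan), draws
per-species epigenetic states with state-dependent conservation, emits
200-bp chromatin-state segmentations and replicate-level mark signals
around state-conditional means, generates expression from the
promoter/intragenic-enhancer GLM, and fabricates conservation tracks,
TADs, tissue profiles, pairwise DE Q-values and a multi-species variant
panel with planted decoy sites.

Defaults encode the study conditions the pipeline targets: 5 species, 2
replicates, promoter-high H3K4me3 vs enhancer-high H3K4me1, strong states
rich in H3K27ac and accessibility, poised states rich in H3K27me3, and
conservation falling from strong promoters to weak enhancers.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_core import SIGNAL_COLUMNS, DatasetBundle
from .networks import GLM_MARKS
from .states import CORE_LABELS, ENHANCER_LABELS, NON_RE, PROMOTER_LABELS

SPECIES_POOL = ["human", "chimpanzee", "gorilla", "orangutan", "macaque"]

# mark order: h3k4me3, h3k4me1, h3k27ac, h3k36me3, h3k27me3, accessibility
DEFAULT_STATE_MARK_MEANS: dict[str, tuple[float, ...]] = {
    "sP": (4.0, 1.0, 3.5, 0.5, 0.0, 3.0),
    "pP": (3.0, 1.0, 0.5, 0.0, 3.5, 1.5),
    "wP": (2.5, 0.5, 1.0, 0.5, 0.5, 1.0),
    "sE": (0.5, 3.5, 3.0, 1.0, 0.0, 2.5),
    "pE": (0.5, 3.0, 0.5, 0.5, 3.0, 1.0),
    "wE": (0.5, 2.0, 1.0, 0.5, 0.5, 0.5),
}

# probability that an orthologous element keeps its state in another species
DEFAULT_CONSERVATION_RATES = {
    "sP": 0.90,
    "pP": 0.75,
    "wP": 0.55,
    "sE": 0.70,
    "pE": 0.65,
    "wE": 0.45,
}

# core15 generative coefficients: strong acetylation up, poised methylation down
DEFAULT_GLM_COEFFICIENTS = {
    "intercept": 1.0,
    "gP/P/h3k27ac": 0.8,
    "gP/P/h3k27me3": -0.6,
    "gP/P/h3k36me3": 0.3,
    "gE/E/h3k27ac": 0.5,
    "gE/E/h3k27me3": -0.4,
    "gE/E/h3k36me3": 0.4,
    "gP/P/h3k27ac x gE/E/h3k27ac": 0.10,
    "gP/P/h3k27ac x gE/E/h3k27me3": -0.05,
    "gP/P/h3k27ac x gE/E/h3k36me3": 0.05,
    "gP/P/h3k27me3 x gE/E/h3k27ac": -0.05,
    "gP/P/h3k27me3 x gE/E/h3k27me3": 0.05,
    "gP/P/h3k27me3 x gE/E/h3k36me3": -0.05,
    "gP/P/h3k36me3 x gE/E/h3k27ac": 0.05,
    "gP/P/h3k36me3 x gE/E/h3k27me3": -0.05,
    "gP/P/h3k36me3 x gE/E/h3k36me3": 0.05,
}

# per-gene cassette layout (bp offsets within a 60 kb stride)
STRIDE = 60_000
GENE_BODY = (20_000, 40_000)
ELEMENT_LEN = 600  # three 200-bp bins
_LAYOUT = {
    # component -> element start offset
    "gP": 16_800,   # 2.6 kb upstream of the TSS
    "prE": 12_200,  # 7.2 kb upstream
    "gE": 28_000,   # inside the gene body
    "PiE": 46_000,  # distal, interaction to the gP element
    "EiE": 50_000,  # distal, interaction to the gE element
    "orphan": 54_000,
}
_STATE_BINS = {
    "sP": ("E9", "E8", "E9"),
    "pP": ("E8", "E14", "E8"),
    "wP": ("E8", "E8", "E8"),
    "sE": ("E3", "E5", "E3"),
    "pE": ("E7", "E14", "E7"),
    "wE": ("E7", "E7", "E7"),
}

TAD_LEN = 60_000  # one TAD per cassette
TRACK_STEP = 200


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset; defaults are the study conditions."""

    n_species: int = 5
    n_replicates: int = 2
    n_genes: int = 50
    n_elements: int = 300
    n_tissues: int = 29
    state_mark_means: dict = field(
        default_factory=lambda: dict(DEFAULT_STATE_MARK_MEANS)
    )
    state_mark_sd: float = 0.5
    replicate_sd: float = 0.25
    conservation_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_CONSERVATION_RATES)
    )
    expression_glm_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_GLM_COEFFICIENTS)
    )
    expression_noise_sd: float = 1.0
    tau_profile_mix: float = 0.5  # fraction of housekeeping genes
    hsnc_rate_background: float = 1e-3  # fixed changes per bp
    hsnc_rate_enriched: float = 1e-2
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_species, self.n_replicates, self.n_genes, self.n_tissues) <= 0:
            raise ConfigError("counts must be positive")
        if self.n_species > len(SPECIES_POOL):
            raise ConfigError(f"at most {len(SPECIES_POOL)} species supported")
        if self.n_elements < 6 * self.n_genes:
            raise ConfigError(
                "n_elements too small to place all component types "
                f"(need >= {6 * self.n_genes})"
            )
        if self.state_mark_sd <= 0 and self.state_mark_sd != 0:
            raise ConfigError("state_mark_sd must be >= 0")
        for s, r in self.conservation_rates.items():
            if not 0 <= r <= 1:
                raise ConfigError(f"conservation rate for {s} outside [0,1]")
        if not 0 <= self.tau_profile_mix <= 1:
            raise ConfigError("tau_profile_mix outside [0,1]")
        if self.hsnc_rate_background < 0 or self.hsnc_rate_enriched <= 0:
            raise ConfigError("hSNC rates must be positive")

    @property
    def species(self) -> list[str]:
        return SPECIES_POOL[: self.n_species]


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    elements: pd.DataFrame  # element, chrom, start, end, gene_id, component
    true_states: pd.DataFrame  # element x species state labels
    glm_coefficients: dict
    tau_class: pd.Series  # gene -> housekeeping / tissue_specific
    enriched_enhancers: list[str] = field(default_factory=list)
    variant_sites: pd.DataFrame | None = None


def _draw_states(
    config: SimulationConfig, rng: np.random.Generator, elements: pd.DataFrame
) -> pd.DataFrame:
    """Reference-species states plus independent per-species conservation flips."""
    n = len(elements)
    promoter_like = elements["component"].eq("gP").to_numpy()
    ref = np.where(
        promoter_like,
        rng.choice(["sP", "pP", "wP"], size=n, p=[0.6, 0.2, 0.2]),
        rng.choice(["sE", "pE", "wE"], size=n, p=[0.4, 0.2, 0.4]),
    ).astype(object)
    cols = {config.species[0]: ref}
    labels = list(CORE_LABELS)
    for sp in config.species[1:]:
        keep_p = np.array([config.conservation_rates[s] for s in ref])
        keep = rng.random(n) < keep_p
        out = ref.copy()
        flips = ~keep
        n_flip = int(flips.sum())
        if n_flip:
            to_non = rng.random(n_flip) < 0.5
            alt = np.array(
                [
                    rng.choice([l for l in labels if l != s])
                    for s in ref[flips]
                ],
                dtype=object,
            )
            out_f = np.where(to_non, NON_RE, alt)
            out[flips] = out_f
        cols[sp] = out
    return pd.DataFrame(cols, index=elements["element"].to_numpy())


def simulate_epigenome(
    config: SimulationConfig,
) -> tuple[DatasetBundle, GroundTruth]:
    """Generate a full dataset bundle plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = config.species
    samples = {
        f"{sp}{r}": {"species": sp, "replicate": r}
        for sp in species
        for r in range(1, config.n_replicates + 1)
    }

    # --- genome layout -----------------------------------------------------
    gene_rows, elem_rows, bedpe_rows = [], [], []
    eid = 0
    for g in range(config.n_genes):
        base = g * STRIDE
        gid = f"g{g:05d}"
        gene_rows.append(
            (gid, "chr1", base + GENE_BODY[0], base + GENE_BODY[1], "+",
             "protein_coding")
        )
        offsets = dict(_LAYOUT)
        comp_elem = {}
        for comp, off in offsets.items():
            elem_rows.append(
                (eid, "chr1", base + off, base + off + ELEMENT_LEN,
                 gid if comp != "orphan" else None, comp)
            )
            comp_elem[comp] = (base + off, base + off + ELEMENT_LEN)
            eid += 1
        bedpe_rows.append(
            ("chr1", *comp_elem["PiE"], "chr1", *comp_elem["gP"], "synthetic")
        )
        bedpe_rows.append(
            ("chr1", *comp_elem["EiE"], "chr1", *comp_elem["gE"], "synthetic")
        )
    # extra intergenic orphans beyond the per-gene cassettes
    tail = config.n_genes * STRIDE
    for k in range(config.n_elements - 6 * config.n_genes):
        start = tail + 2_000 + k * 2_000
        elem_rows.append((eid, "chr1", start, start + ELEMENT_LEN, None, "orphan"))
        eid += 1

    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "gene_type"],
    )
    genes["tss"] = genes["start"]
    elements = pd.DataFrame(
        elem_rows,
        columns=["element", "chrom", "start", "end", "gene_id", "component"],
    )
    interactions = pd.DataFrame(
        bedpe_rows,
        columns=["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
                 "source"],
    )

    # --- states, segmentations, signals ------------------------------------
    true_states = _draw_states(config, rng, elements)
    seg_rows = []
    sig_rows = []
    mark_means = {
        s: np.asarray(v, float) for s, v in config.state_mark_means.items()
    }
    elem_effect = rng.normal(0.0, config.state_mark_sd,
                             size=(len(elements), len(species), 6))
    for si, sp in enumerate(species):
        states_sp = true_states[sp].to_numpy()
        for r in range(1, config.n_replicates + 1):
            sample = f"{sp}{r}"
            for i, t in enumerate(elements.itertuples(index=False)):
                s = states_sp[i]
                if s == NON_RE:
                    continue
                for b, bin_state in enumerate(_STATE_BINS[s]):
                    seg_rows.append(
                        (t.chrom, t.start + 200 * b, t.start + 200 * (b + 1),
                         bin_state, sample)
                    )
                sig = (
                    mark_means[s]
                    + elem_effect[i, si]
                    + rng.normal(0.0, config.replicate_sd, 6)
                )
                sig_rows.append(
                    (t.element, sp, sample, t.chrom, t.start, t.end, *sig)
                )
    segmentations = pd.DataFrame(
        seg_rows, columns=["chrom", "start", "end", "state", "sample"]
    )
    signals = pd.DataFrame(
        sig_rows,
        columns=["element", "species", "sample", "chrom", "start", "end"]
        + SIGNAL_COLUMNS,
    )

    # --- expression from the core15 GLM ------------------------------------
    coeffs = config.expression_glm_coefficients
    sig_idx = signals.set_index(["element", "sample"])
    expr_cols = {}
    p_class = PROMOTER_LABELS
    e_class = ENHANCER_LABELS
    gp_of = elements[elements["component"] == "gP"].set_index("gene_id")["element"]
    ge_of = elements[elements["component"] == "gE"].set_index("gene_id")["element"]
    mark_pos = {m: SIGNAL_COLUMNS.index(m) for m in GLM_MARKS}
    for sp in species:
        states_sp = true_states[sp]
        for r in range(1, config.n_replicates + 1):
            sample = f"{sp}{r}"
            vals = []
            for gid in genes["gene_id"]:
                x = {}
                for comp, lookup, cls in (
                    ("gP", gp_of, p_class),
                    ("gE", ge_of, e_class),
                ):
                    e = lookup[gid]
                    state = states_sp.loc[e]
                    if state in cls:
                        row = sig_idx.loc[(e, sample)]
                        for m in GLM_MARKS:
                            x[f"{comp}/{'P' if comp == 'gP' else 'E'}/{m}"] = row[m]
                    else:
                        for m in GLM_MARKS:
                            x[f"{comp}/{'P' if comp == 'gP' else 'E'}/{m}"] = 0.0
                y = coeffs.get("intercept", 0.0)
                for name, c in coeffs.items():
                    if name == "intercept":
                        continue
                    if " x " in name:
                        a, b = name.split(" x ")
                        y += c * x[a] * x[b]
                    else:
                        y += c * x[name]
                vals.append(y)
            noise = rng.normal(0.0, config.expression_noise_sd, len(vals))
            expr_cols[f"{sp}:{sample}"] = np.asarray(vals) + noise
    expression = pd.DataFrame(expr_cols, index=genes["gene_id"])
    expression.index.name = "gene_id"

    # --- orthology (shared toy coordinate frame across species) ------------
    ortho = pd.concat(
        [
            elements.assign(species=sp)[
                ["element", "species", "chrom", "start", "end"]
            ]
            for sp in species
        ],
        ignore_index=True,
    ).rename(columns={"element": "region_id"})

    # --- TADs and conservation track ----------------------------------------
    genome_len = config.n_genes * STRIDE + max(
        0, (config.n_elements - 6 * config.n_genes)
    ) * 2_000 + 4_000
    n_tads = int(np.ceil(genome_len / TAD_LEN))
    tads = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_tads) * TAD_LEN,
            "end": np.minimum((np.arange(n_tads) + 1) * TAD_LEN, genome_len),
        }
    )
    steps = np.arange(0, genome_len, TRACK_STEP)
    scores = np.clip(rng.normal(0.3, 0.1, len(steps)), 0.0, 1.0)
    # sequence conservation rises with epigenetic conservation of the element
    n_cons = (true_states.to_numpy() != NON_RE).sum(axis=1)
    for i, t in enumerate(elements.itertuples(index=False)):
        lo, hi = t.start // TRACK_STEP, -(-t.end // TRACK_STEP)
        scores[lo:hi] = np.clip(
            scores[lo:hi] + 0.08 * n_cons[i], 0.0, 1.0
        )
    track = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": steps,
            "end": np.minimum(steps + TRACK_STEP, genome_len),
            "score": scores,
        }
    )

    # --- tissue expression ---------------------------------------------------
    tissues = [f"tissue{i:02d}" for i in range(config.n_tissues)]
    hk = rng.random(config.n_genes) < config.tau_profile_mix
    tissue_rows = np.empty((config.n_genes, config.n_tissues))
    for i in range(config.n_genes):
        if hk[i]:
            level = rng.uniform(5, 50)
            tissue_rows[i] = level * rng.uniform(0.8, 1.2, config.n_tissues)
        else:
            tissue_rows[i] = rng.uniform(0.0, 0.05, config.n_tissues)
            tissue_rows[i, rng.integers(config.n_tissues)] = rng.uniform(20, 100)
    tissue_expression = pd.DataFrame(
        tissue_rows, index=genes["gene_id"], columns=tissues
    )
    tissue_expression.index.name = "gene_id"
    tau_class = pd.Series(
        np.where(hk, "housekeeping", "tissue_specific"),
        index=genes["gene_id"],
        name="tau_class",
    )

    bundle = DatasetBundle(
        species=species,
        samples=samples,
        tissues=tissues,
        segmentations=segmentations,
        signals=signals,
        genes=genes,
        interactions=interactions,
        orthology=ortho,
        conservation_track=track,
        tads=tads,
        expression=expression,
        tissue_expression=tissue_expression,
    )
    truth = GroundTruth(
        elements=elements,
        true_states=true_states,
        glm_coefficients=dict(coeffs),
        tau_class=tau_class,
    )
    bundle.validate()
    return bundle, truth


# ---------------------------------------------------------------------------
# variant panel

_PANEL_SIZES = {
    "human": 19,
    "chimpanzee": 61,
    "gorilla": 42,
    "orangutan": 27,
    "macaque": 30,
}


def _panel_rows(chrom, pos, species, human_fixed, rng):
    """One fixed-difference (or background-identical) site across species."""
    rows = []
    alleles = ["A", "G"] if rng.random() < 0.5 else ["C", "T"]
    human_allele, other_allele = alleles if rng.random() < 0.5 else alleles[::-1]
    for sp in species:
        n = _PANEL_SIZES[sp]
        allele = human_allele if (sp == "human" and human_fixed) else other_allele
        rows.append((chrom, pos, sp, f"{allele}={n}", n, n))
    return rows, human_allele, other_allele


def simulate_variant_panel(
    config: SimulationConfig,
    enhancers: pd.DataFrame,
    enriched_ids: list[str],
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multi-species allele panel with planted hSNCs and decoy sites.

    ``enhancers`` needs chrom/start/end/name; true fixed differences are
    placed uniformly at ``hsnc_rate_enriched`` per bp inside the enhancers
    named in ``enriched_ids`` and at ``hsnc_rate_background`` elsewhere.
    Planted decoys (low-coverage, polymorphic at 89.5% majority, and
    triallelic) must be rejected by the caller.  Returns (panel table,
    ground-truth site table).
    """
    config.validate()
    ids = set(enhancers["name"])
    if not set(enriched_ids) <= ids:
        raise ConfigError("enriched_ids must be a subset of enhancer names")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    species = config.species
    rows, truth_rows = [], []

    for t in enhancers.itertuples(index=False):
        rate = (
            config.hsnc_rate_enriched
            if t.name in set(enriched_ids)
            else config.hsnc_rate_background
        )
        n_sites = rng.poisson(rate * (t.end - t.start))
        for pos in sorted(rng.integers(t.start, t.end, size=n_sites)):
            site_rows, hu, ot = _panel_rows(t.chrom, int(pos), species, True, rng)
            rows.extend(site_rows)
            truth_rows.append((t.chrom, int(pos), "hSNC", t.name))

    # decoy sites on a spare stretch downstream of the last enhancer
    decoy_base = int(enhancers["end"].max()) + 10_000
    chrom = enhancers["chrom"].iloc[0]
    # low coverage: too few humans with sufficient data
    rows.append((chrom, decoy_base, "human", "A=5", 5, _PANEL_SIZES["human"]))
    for sp in species[1:]:
        n = _PANEL_SIZES[sp]
        rows.append((chrom, decoy_base, sp, f"G={n}", n, n))
    truth_rows.append((chrom, decoy_base, "low_coverage", None))
    # polymorphic: 17/19 = 89.5% majority in humans
    rows.append((chrom, decoy_base + 1, "human", "A=17;G=2", 19, 19))
    for sp in species[1:]:
        n = _PANEL_SIZES[sp]
        rows.append((chrom, decoy_base + 1, sp, f"G={n}", n, n))
    truth_rows.append((chrom, decoy_base + 1, "polymorphic", None))
    # triallelic: three fixed alleles across species
    if len(species) >= 3:
        tri = ["A", "G", "C"]
        for i, sp in enumerate(species):
            n = _PANEL_SIZES[sp]
            allele = tri[min(i, 2)]
            rows.append((chrom, decoy_base + 2, sp, f"{allele}={n}", n, n))
        truth_rows.append((chrom, decoy_base + 2, "triallelic", None))

    panel = pd.DataFrame(
        rows, columns=["chrom", "pos", "species", "allele_counts", "n_pass",
                       "n_total"]
    ).sort_values(["chrom", "pos", "species"]).reset_index(drop=True)
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "pos", "label", "enhancer"]
    )
    return panel, truth


def simulate_de_qvalues(
    config: SimulationConfig,
    frac_not_de: float = 0.5,
    frac_species_specific: float = 0.3,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Pairwise DE Q-value tables with known pattern labels.

    Returns (qvalues, per-species mean expression, true labels); Q-values
    mimic an upstream differential-expression fit at FDR 0.1.
    """
    from itertools import combinations

    rng = np.random.default_rng(config.seed if seed is None else seed)
    species = sorted(config.species)
    pairs = list(combinations(species, 2))
    genes = [f"g{g:05d}" for g in range(config.n_genes)]
    q = pd.DataFrame(index=genes, columns=[f"{a}|{b}" for a, b in pairs],
                     dtype=float)
    means = pd.DataFrame(
        rng.uniform(4, 6, size=(len(genes), len(species))),
        index=genes, columns=species,
    )
    labels = pd.Series("not_DE", index=genes, name="label")
    for gi, gene in enumerate(genes):
        u = rng.random()
        if u < frac_not_de:
            q.loc[gene] = rng.uniform(0.2, 1.0, len(pairs))
        elif u < frac_not_de + frac_species_specific:
            sp = species[rng.integers(len(species))]
            labels[gene] = "species_specific"
            up = rng.random() < 0.5
            means.loc[gene, sp] += 3.0 if up else -3.0
            for col, (a, b) in zip(q.columns, pairs):
                q.loc[gene, col] = (
                    rng.uniform(0.0, 0.05) if sp in (a, b)
                    else rng.uniform(0.2, 1.0)
                )
        else:
            labels[gene] = "non_species_specific"
            grp = list(rng.choice(species, size=2, replace=False))
            means.loc[gene, grp] += 3.0
            for col, (a, b) in zip(q.columns, pairs):
                cross = (a in grp) != (b in grp)
                q.loc[gene, col] = (
                    rng.uniform(0.0, 0.05) if cross else rng.uniform(0.2, 1.0)
                )
    return q, means, labels
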