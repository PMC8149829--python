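"""Human-fixed single-nucleotide changes (hSNCs) and their enrichment in
human-specific weak intragenic enhancers.

A multi-species diversity panel is filtered site by site: a species'
genotype is usable when at least half of its individuals have adequate
coverage, and the species is called monomorphic when at least 90% of the
kept individuals share one allele.  Sites that survive in every species,
are biallelic, and where the human allele differs from the single allele
shared by all other species are hSNCs.  Per-enhancer enrichment is tested
by randomly re-placing the observed number of changes across the enhancer
universe (length-corrected), with Bonferroni adjustment, and the number of
enriched enhancers ("hits") is itself tested against the simulated hit
counts.  Fisher overlap tests and a W->S (A/T -> G/C) composition check
for GC-biased gene conversion complete the module.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalIndex

NUCLEOTIDES = frozenset("ACGT")
WEAK_BASES = frozenset("AT")  # W; S = G/C

MONOMORPHIC_FRACTION = 0.9
MIN_DATA_FRACTION = 0.5


@dataclass
class HsncSite:
    chrom: str
    pos: int
    human_allele: str
    other_allele: str


def _parse_allele_counts(spec: str) -> dict[str, int]:
    """Parse "A=17;G=2" into {"A": 17, "G": 2}."""
    out = {}
    for item in str(spec).split(";"):
        item = item.strip()
        if not item:
            continue
        allele, _, count = item.partition("=")
        out[allele] = out.get(allele, 0) + int(count)
    return out


def call_fixed_differences(
    panel: pd.DataFrame,
    human_species: str = "human",
) -> tuple[list[HsncSite], pd.DataFrame]:
    """Call human-fixed single-nucleotide changes from a variant panel.

    ``panel`` holds one row per (site, species) with columns chrom, pos,
    species, allele_counts ("A=17;G=2", counts among coverage-passing
    individuals), n_pass and n_total.  Returns the hSNC list and a
    per-site audit table with the rejection reason for every non-hSNC.
    """
    if human_species not in set(panel["species"]):
        raise ValueError(f"panel lacks the human population {human_species!r}")
    if (panel.groupby("species")["n_total"].max() == 0).any():
        raise ValueError("species with zero individuals in panel")

    sites = []
    audit = []
    for (chrom, pos), grp in panel.groupby(["chrom", "pos"], sort=True):
        reason = None
        majors: dict[str, str] = {}
        alleles_seen: set[str] = set()
        for row in grp.itertuples(index=False):
            counts = _parse_allele_counts(row.allele_counts)
            alleles_seen |= set(counts)
            kept = sum(counts.values())
            if row.n_pass < MIN_DATA_FRACTION * row.n_total or kept == 0:
                reason = "insufficient_data"
                break
            major, major_n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
            if major_n < MONOMORPHIC_FRACTION * kept:
                reason = "polymorphic"
                break
            majors[row.species] = major
        if reason is None:
            if any(len(a) != 1 or a not in NUCLEOTIDES for a in alleles_seen):
                reason = "indel"
            elif len(set(majors.values())) > 2 or len(alleles_seen) > 2:
                reason = "triallelic"
            elif human_species not in majors:
                reason = "insufficient_data"
            else:
                human = majors[human_species]
                others = {a for s, a in majors.items() if s != human_species}
                if len(others) == 1 and human not in others:
                    sites.append(HsncSite(chrom, int(pos), human, others.pop()))
                    reason = "hSNC"
                else:
                    reason = "not_fixed_difference"
        audit.append((chrom, int(pos), reason))
    audit_df = pd.DataFrame(audit, columns=["chrom", "pos", "call"])
    return sites, audit_df


def assign_regions_to_genes(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    interactions: pd.DataFrame | None = None,
    gbgc_tracts: pd.DataFrame | None = None,
    upstream: int = 5_000,
) -> set[str]:
    """Genes targeted by selection/acceleration regions.

    Regions overlapping a gBGC tract are removed first.  A region maps to
    a gene when it lies within the gene or up to ``upstream`` bp upstream
    of its TSS, and additionally to any gene its interaction partner
    anchor touches (gene body or upstream window).
    """
    regions = regions.reset_index(drop=True)
    if gbgc_tracts is not None and len(gbgc_tracts):
        tract_idx = IntervalIndex(gbgc_tracts)
        keep = [
            not tract_idx.query(t.chrom, t.start, t.end)
            for t in regions.itertuples(index=False)
        ]
        regions = regions.loc[keep].reset_index(drop=True)

    win = genes[["gene_id", "chrom", "start", "end", "strand", "tss"]].copy()
    up_start = np.where(
        win["strand"] == "-", win["start"], (win["start"] - upstream).clip(0)
    )
    up_end = np.where(
        win["strand"] == "-", win["end"] + upstream, win["end"]
    )
    win["start"] = np.minimum(win["start"], up_start)
    win["end"] = np.maximum(win["end"], up_end)
    win_idx = IntervalIndex(win)

    assigned: set[str] = set()
    region_hits: list[set[str]] = []
    for t in regions.itertuples(index=False):
        hits = {
            win.iloc[i]["gene_id"] for i in win_idx.query(t.chrom, t.start, t.end)
        }
        region_hits.append(hits)
        assigned |= hits

    if interactions is not None and len(interactions):
        reg_idx = IntervalIndex(regions)
        for t in interactions.itertuples(index=False):
            for side, other in ((("a", "b")), (("b", "a"))):
                r_hits = reg_idx.query(
                    getattr(t, f"chrom_{side}"),
                    getattr(t, f"start_{side}"),
                    getattr(t, f"end_{side}"),
                )
                if not r_hits:
                    continue
                g_hits = {
                    win.iloc[i]["gene_id"]
                    for i in win_idx.query(
                        getattr(t, f"chrom_{other}"),
                        getattr(t, f"start_{other}"),
                        getattr(t, f"end_{other}"),
                    )
                }
                assigned |= g_hits
    return assigned


@dataclass
class DensityResult:
    enhancer_id: str
    length: int
    count: int

    @property
    def density(self) -> float:
        return self.count / self.length


def hsnc_density(
    enhancers: pd.DataFrame, hsncs: list[HsncSite] | pd.DataFrame
) -> list[DensityResult]:
    """Per-enhancer hSNC count and per-bp density (half-open containment)."""
    if isinstance(hsncs, list):
        hs = pd.DataFrame(
            [(h.chrom, h.pos) for h in hsncs], columns=["chrom", "pos"]
        )
    else:
        hs = hsncs[["chrom", "pos"]]
    if (enhancers["end"] <= enhancers["start"]).any():
        raise ValueError("zero-length enhancer")
    out = []
    for t in enhancers.itertuples(index=False):
        n = int(
            (
                (hs["chrom"] == t.chrom)
                & (hs["pos"] >= t.start)
                & (hs["pos"] < t.end)
            ).sum()
        )
        eid = getattr(t, "name", f"{t.chrom}:{t.start}-{t.end}")
        out.append(DensityResult(str(eid), int(t.end - t.start), n))
    return out


def simulate_universe_densities(
    universe_lengths: np.ndarray,
    m: int,
    n_sim: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulated per-enhancer densities from uniform placement of m changes.

    Placement over the concatenated universe with replacement is exactly a
    multinomial draw with per-enhancer probabilities proportional to
    length; returns an (n_sim, n_enhancers) density array.
    """
    L = np.asarray(universe_lengths, float)
    total = L.sum()
    if total <= 0:
        raise ValueError("empty enhancer universe")
    counts = rng.multinomial(m, L / total, size=n_sim)
    return counts / L


@dataclass
class EnrichmentResult:
    p: np.ndarray
    p_bonferroni: np.ndarray
    critical_density: np.ndarray | None = None
    observed_hits: int | None = None
    global_p: float | None = None
    simulated_densities: np.ndarray | None = None


def enhancer_density_randomization(
    focal: pd.DataFrame,
    universe: pd.DataFrame,
    hsncs: list[HsncSite] | pd.DataFrame,
    n_sim: int = 10_000,
    seed: int | None = None,
) -> tuple[EnrichmentResult, list[DensityResult]]:
    """Length-corrected per-enhancer hSNC enrichment test.

    All hSNCs falling in the ``universe`` enhancers are counted, that many
    changes are re-placed uniformly across the universe ``n_sim`` times,
    and each focal enhancer's p is the fraction of simulations whose
    density matches or exceeds its observed density, Bonferroni-corrected
    over the number of focal enhancers.
    """
    import warnings

    if n_sim < 100:
        warnings.warn("n_sim < 100 gives very coarse empirical p-values")
    uni_dens = hsnc_density(universe, hsncs)
    m = sum(d.count for d in uni_dens)
    if m < 1:
        raise ValueError("no hSNCs in the enhancer universe")
    rng = np.random.default_rng(seed)
    lengths = universe["end"].to_numpy() - universe["start"].to_numpy()
    sims = simulate_universe_densities(lengths, m, n_sim, rng)

    focal_dens = hsnc_density(focal, hsncs)
    # locate each focal enhancer's column in the universe
    uni_key = {
        (t.chrom, t.start, t.end): i
        for i, t in enumerate(universe.itertuples(index=False))
    }
    cols = []
    for t in focal.itertuples(index=False):
        key = (t.chrom, t.start, t.end)
        if key not in uni_key:
            raise ValueError(f"focal enhancer {key} not part of the universe")
        cols.append(uni_key[key])
    cols = np.asarray(cols)
    obs = np.array([d.density for d in focal_dens])
    p = (sims[:, cols] >= obs[None, :]).mean(axis=0)
    result = EnrichmentResult(
        p=p,
        p_bonferroni=np.minimum(1.0, p * len(focal_dens)),
        simulated_densities=sims[:, cols],
    )
    return result, focal_dens


def hits_count_randomization(
    simulated_densities: np.ndarray,
    observed_densities: np.ndarray,
    alpha: float = 0.05,
    n_tests: int | None = None,
    tail: str = "upper",
) -> EnrichmentResult:
    """Global test of the number of enriched enhancers.

    Each enhancer's critical density is the upper-tail quantile of its own
    simulated densities at level alpha / n_tests (at alpha 5%, 100
    enhancers and 10,000 simulations: the 5th largest value).  Observed
    hits are enhancers at or above their critical density; the global p is
    the fraction of simulations whose own hit count matches or exceeds the
    observed one.  ``tail="lower"`` gives the literal smallest-to-largest
    reading instead.
    """
    import warnings

    sims = np.asarray(simulated_densities, float)
    obs = np.asarray(observed_densities, float)
    n_sim, n_enh = sims.shape
    if n_tests is None:
        n_tests = n_enh
    if len(obs) != n_enh:
        raise ValueError("observed densities do not match simulation columns")
    level = alpha / n_tests
    kth = int(np.ceil(level * n_sim))
    if kth < 1:
        warnings.warn(
            "alpha/n_tests below simulation resolution; critical value is the "
            "simulated maximum"
        )
        kth = 1
    sims_sorted = np.sort(sims, axis=0)
    if tail == "upper":
        critical = sims_sorted[n_sim - kth, :]
    elif tail == "lower":
        critical = sims_sorted[kth - 1, :]
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    observed_hits = int((obs >= critical).sum())
    sim_hits = (sims >= critical[None, :]).sum(axis=1)
    global_p = float((sim_hits >= observed_hits).mean())
    per_p = (sims >= obs[None, :]).mean(axis=0)
    return EnrichmentResult(
        p=per_p,
        p_bonferroni=np.minimum(1.0, per_p * n_tests),
        critical_density=critical,
        observed_hits=observed_hits,
        global_p=global_p,
    )


def gene_overlap_fisher(
    set_a: set[str],
    set_b: set[str],
    universe: set[str],
    sided: str = "one",
) -> dict:
    """Fisher's exact test of the overlap of two gene sets in a universe.

    Returns the 2x2 table, the sample odds ratio (inf-flagged on zero
    cells) and the exact hypergeometric p (one-tailed tests enrichment).
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("gene sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    alternative = "greater" if sided == "one" else "two-sided"
    p = stats.fisher_exact(table, alternative=alternative).pvalue
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return {
        "table": table,
        "odds_ratio": float(odds) if np.isfinite(odds) else odds,
        "odds_ratio_unbounded": not np.isfinite(odds),
        "p": float(p),
    }


def classify_ws(ancestral: str, derived: str) -> str:
    """Weak/strong mutation class: W = A/T, S = G/C."""
    for allele in (ancestral, derived):
        if allele not in NUCLEOTIDES:
            raise ValueError(f"allele {allele!r} outside A/C/G/T")
    a = "W" if ancestral in WEAK_BASES else "S"
    d = "W" if derived in WEAK_BASES else "S"
    return f"{a}->{d}"


def gbgc_ws_test(
    focal: list[HsncSite], background: list[HsncSite]
) -> dict:
    """One-tailed Fisher test of W->S excess in focal vs background hSNCs.

    A W->S excess among the human-derived alleles would point at GC-biased
    gene conversion rather than selection.
    """
    def ws_count(sites):
        n_ws = sum(
            classify_ws(s.other_allele, s.human_allele) == "W->S" for s in sites
        )
        return n_ws, len(sites) - n_ws

    a, b = ws_count(focal)
    c, d = ws_count(background)
    table = np.array([[a, b], [c, d]])
    p = stats.fisher_exact(table, alternative="greater").pvalue
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return {
        "table": table,
        "odds_ratio": float(odds) if np.isfinite(odds) else odds,
        "p": float(p),
    }
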