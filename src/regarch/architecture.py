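"""Gene regulatory-architecture construction.

Each regulatory element is classified by its role with respect to genes:
genic promoter (gP, within 5 kb upstream of a TSS), intragenic enhancer
(gE, overlapping a gene body), proximal enhancer (prE, within 10 kb
upstream of a TSS), and — for distal elements rescued through chromatin
interactions — promoter-interacting (PiE) and enhancer-interacting (EiE)
enhancers.  Unrescued distal elements are orphans.  Per-gene architectures
collect the component-labeled elements of each gene.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .intervals import IntervalIndex

GP_WINDOW = 5_000
PRE_WINDOW = 10_000

COMPONENT_LABELS = ("gP", "gE", "prE", "PiE", "EiE", "orphan")
ENHANCER_COMPONENTS = frozenset({"gE", "prE", "PiE"})


def _upstream_distance(e_start: int, e_end: int, tss: int, strand: str) -> int | None:
    """Distance from element edge to TSS, only if the element lies upstream.

    An element overlapping the TSS has distance 0.  Returns None when the
    element is strictly downstream of the TSS.
    """
    if e_start <= tss < e_end:
        return 0
    if strand == "-":
        if e_start > tss:
            return e_start - tss - 1
        return None
    if e_end <= tss:
        return tss - e_end
    return None


def assign_proximity_components(
    elements: pd.DataFrame,
    genes: pd.DataFrame,
    symmetric_pre: bool = False,
) -> pd.DataFrame:
    """Proximity-based component labels, one row per (element, gene) pair.

    Rules per gene, in precedence order: within 5 kb upstream of the TSS
    (strand-aware, edge-to-TSS) -> gP; overlapping the gene body -> gE;
    within 10 kb upstream -> prE.  Elements matching no gene get a single
    row with component "dE" and gene_id NA.  ``symmetric_pre`` widens the
    prE rule to either side of the TSS.
    """
    if "tss" not in genes.columns:
        raise ValueError("genes table must carry a tss column")
    if genes["tss"].isna().any():
        raise ValueError("gene without TSS")
    elements = elements.reset_index(drop=True)
    gene_idx = IntervalIndex(genes)
    # windows around each TSS large enough to cover every rule
    win = genes[["gene_id", "chrom", "tss", "strand"]].copy()
    win["start"] = (win["tss"] - PRE_WINDOW).clip(lower=0)
    win["end"] = win["tss"] + PRE_WINDOW + 1
    win_idx = IntervalIndex(win)

    rows = []
    for ei, e in enumerate(elements.itertuples(index=False)):
        labels: dict[str, str] = {}
        # gene-body overlap -> candidate gE
        for gi in gene_idx.query(e.chrom, e.start, e.end):
            labels[genes.iloc[gi]["gene_id"]] = "gE"
        # TSS-window relations -> gP / prE with precedence over gE
        for wi in win_idx.query(e.chrom, e.start, e.end):
            g = win.iloc[wi]
            d = _upstream_distance(e.start, e.end, int(g["tss"]), g["strand"])
            if d is None and symmetric_pre:
                # downstream side only rescues prE, never gP
                d_down = min(abs(e.start - g["tss"]), abs(e.end - 1 - g["tss"]))
                if d_down <= PRE_WINDOW and labels.get(g["gene_id"]) is None:
                    labels[g["gene_id"]] = "prE"
                continue
            if d is None:
                continue
            if d <= GP_WINDOW:
                labels[g["gene_id"]] = "gP"
            elif d <= PRE_WINDOW and labels.get(g["gene_id"]) != "gE":
                labels.setdefault(g["gene_id"], "prE")
        if labels:
            for gid in sorted(labels):
                rows.append((ei, gid, labels[gid]))
        else:
            rows.append((ei, None, "dE"))
    return pd.DataFrame(rows, columns=["element", "gene_id", "component"])


def rescue_distal(
    elements: pd.DataFrame,
    assignments: pd.DataFrame,
    interactions: pd.DataFrame,
    rescue_all_enhancers: bool = False,
) -> pd.DataFrame:
    """Rescue distal elements through first- and second-order interactions.

    A dE overlapping an interaction anchor whose partner anchor overlaps a
    gP becomes PiE of that gP's gene; one whose partner overlaps an
    enhancer component (gE/prE/PiE) becomes EiE of that enhancer's gene.
    Remaining dE become orphans.  Non-dE assignments are never relabeled;
    with ``rescue_all_enhancers`` an already-assigned enhancer may *gain*
    PiE/EiE associations with additional genes (its existing labels are
    kept untouched).
    """
    elements = elements.reset_index(drop=True)
    idx = IntervalIndex(elements)

    # element -> overlapping anchor partner element lists
    partner_of: dict[int, set[int]] = {}
    if interactions is not None and len(interactions):
        for t in interactions.itertuples(index=False):
            hits_a = idx.query(t.chrom_a, t.start_a, t.end_a)
            hits_b = idx.query(t.chrom_b, t.start_b, t.end_b)
            for ea in hits_a:
                partner_of.setdefault(ea, set()).update(hits_b)
            for eb in hits_b:
                partner_of.setdefault(eb, set()).update(hits_a)

    comp_by_elem: dict[int, list[tuple[str | None, str]]] = {}
    for t in assignments.itertuples(index=False):
        comp_by_elem.setdefault(t.element, []).append((t.gene_id, t.component))

    de_elements = sorted(
        e for e, comps in comp_by_elem.items()
        if all(c == "dE" for _, c in comps)
    )
    eligible = (
        sorted(set(de_elements) | {e for e, c in comp_by_elem.items()
                                   if any(x in ENHANCER_COMPONENTS for _, x in c)})
        if rescue_all_enhancers
        else de_elements
    )

    rescued: dict[int, dict[str, str]] = {e: {} for e in eligible}
    already = {
        e: {gid for gid, _ in comps if gid is not None}
        for e, comps in comp_by_elem.items()
    }
    # first order: eligible element touching a gP partner
    for e in eligible:
        for p in partner_of.get(e, ()):
            for gid, comp in comp_by_elem.get(p, ()):
                if comp == "gP" and gid is not None and gid not in already.get(e, ()):
                    rescued[e][gid] = "PiE"
    # second order: eligible element touching an enhancer-component partner
    # (including freshly rescued PiE)
    for e in eligible:
        for p in partner_of.get(e, ()):
            for gid, comp in comp_by_elem.get(p, ()):
                if (
                    comp in ENHANCER_COMPONENTS
                    and gid is not None
                    and gid not in already.get(e, ())
                ):
                    rescued[e].setdefault(gid, "EiE")
            if p in rescued:
                for gid in rescued[p]:
                    if rescued[p][gid] == "PiE" and gid not in already.get(e, ()):
                        rescued[e].setdefault(gid, "EiE")

    rows = []
    for t in assignments.itertuples(index=False):
        if t.element in de_elements:
            continue
        rows.append((t.element, t.gene_id, t.component))
    for e in eligible:
        if e not in de_elements:
            for gid in sorted(rescued[e]):
                rows.append((e, gid, rescued[e][gid]))
        elif rescued[e]:
            for gid in sorted(rescued[e]):
                rows.append((e, gid, rescued[e][gid]))
        else:
            rows.append((e, None, "orphan"))
    out = pd.DataFrame(rows, columns=["element", "gene_id", "component"])
    return out.sort_values(["element", "gene_id"], na_position="last").reset_index(
        drop=True
    )


@dataclass
class GeneArchitecture:
    """A gene with its component-labeled regulatory elements."""

    gene_id: str
    gene_type: str
    components: list[tuple[int, str, str]] = field(default_factory=list)
    # (element index, component label, state label)

    @property
    def full(self) -> bool:
        present = {c for _, c, _ in self.components}
        return {"gP", "gE", "prE", "PiE", "EiE"} <= present


def build_architectures(
    assignments: pd.DataFrame,
    states: pd.Series | dict,
    genes: pd.DataFrame,
) -> dict[str, GeneArchitecture]:
    """Group component assignments into per-gene architectures.

    ``states`` maps element index -> consensus state label.  Elements
    assigned to genes absent from the annotation raise a consistency
    error; dE/orphan rows are skipped.
    """
    gene_type = dict(zip(genes["gene_id"], genes["gene_type"]))
    archs: dict[str, GeneArchitecture] = {}
    seen: set[tuple[str, int, str]] = set()
    for t in assignments.itertuples(index=False):
        if t.gene_id is None or (isinstance(t.gene_id, float) and pd.isna(t.gene_id)):
            continue
        if t.component in ("dE", "orphan"):
            continue
        if t.gene_id not in gene_type:
            raise ValueError(f"element assigned to unknown gene {t.gene_id!r}")
        key = (t.gene_id, t.element, t.component)
        if key in seen:
            continue
        seen.add(key)
        arch = archs.setdefault(
            t.gene_id, GeneArchitecture(t.gene_id, gene_type[t.gene_id])
        )
        arch.components.append((t.element, t.component, states[t.element]))
    for arch in archs.values():
        arch.components.sort()
    return archs


def architectures_frame(archs: dict[str, GeneArchitecture]) -> pd.DataFrame:
    rows = [
        (a.gene_id, a.gene_type, e, c, s, a.full)
        for a in archs.values()
        for e, c, s in a.components
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "gene_type", "element", "component", "state", "full"],
    ).sort_values(["gene_id", "element", "component"]).reset_index(drop=True)
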