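"""End-to-end convenience wrappers connecting the pipeline stages.

Each function is a thin composition of the stage modules so that a bundle
can be taken from segmentations to a design matrix (and onward to
networks and the expression GLM) in a few calls; the CLI and the worked
examples use these.
"""
from __future__ import annotations

import pandas as pd

from .architecture import assign_proximity_components, rescue_distal
from .io_core import DatasetBundle
from .networks import COMPONENTS, build_design_matrix
from .states import annotate_elements, downstream_filter


def annotate_bundle(bundle: DatasetBundle, refine: bool = True) -> pd.DataFrame:
    """Per-species element annotation with raw, refined and consensus labels."""
    return annotate_elements(
        bundle.segmentations, bundle.signals, bundle.samples, refine=refine
    )


def architecture_table(
    bundle: DatasetBundle, annotated: pd.DataFrame
) -> pd.DataFrame:
    """Component assignments per species for all consensus-core elements.

    Returns one row per (element, gene, species) association with columns
    gene_id / species / element / component / state, where ``element``
    refers to the bundle's signal-table element ids (matched on
    coordinates).
    """
    frames = []
    for sp in bundle.species:
        sub = downstream_filter(
            annotated[annotated["species"] == sp]
        ).reset_index(drop=True)
        if sub.empty:
            continue
        prox = assign_proximity_components(sub, bundle.genes)
        resc = rescue_distal(sub, prox, bundle.interactions)
        resc = resc.assign(
            species=sp,
            state=resc["element"].map(sub["consensus"]),
            chrom=resc["element"].map(sub["chrom"]),
            start=resc["element"].map(sub["start"]),
            end=resc["element"].map(sub["end"]),
        )
        frames.append(resc)
    arch = pd.concat(frames, ignore_index=True)
    if bundle.signals is not None and "element" in bundle.signals.columns:
        key = bundle.signals.drop_duplicates(
            subset=["species", "chrom", "start", "end"]
        )[["species", "chrom", "start", "end", "element"]]
        arch = arch.drop(columns="element").merge(
            key, on=["species", "chrom", "start", "end"], how="left"
        )
    return arch[
        ["gene_id", "species", "element", "component", "state", "chrom",
         "start", "end"]
    ]


def design_matrix_from_bundle(
    bundle: DatasetBundle,
    architectures: pd.DataFrame | None = None,
    annotated: pd.DataFrame | None = None,
    require_all_species: bool = False,
) -> pd.DataFrame:
    """Design matrix straight from a bundle (annotating if needed)."""
    if architectures is None:
        if annotated is None:
            annotated = annotate_bundle(bundle)
        architectures = architecture_table(bundle, annotated)
    arch = architectures[architectures["component"].isin(COMPONENTS)].dropna(
        subset=["gene_id", "element"]
    )
    return build_design_matrix(
        arch, bundle.signals, bundle.expression,
        require_all_species=require_all_species,
    )
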