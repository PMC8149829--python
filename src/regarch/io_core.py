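"""Dataset bundle I/O.

A :class:`DatasetBundle` groups every table the pipeline consumes:
chromatin-state segmentations, per-element signal enrichments, gene
annotations, interaction pairs, orthology maps, conservation tracks, TADs,
expression matrices, variant panels and selection-region sets.  A YAML
manifest declares species/sample/tissue identifiers once and points at one
file per table; each table is stored in its canonical plain-text format
(BED, GTF-like, BEDPE, bedGraph, TSV).

Conventions: tab-separated, header row for TSV tables, "." for missing
values, coordinates 0-based half-open internally (GTF converted on read),
deterministic (chrom, start, end, id) row ordering on write.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .intervals import VALID_STRANDS, validate_interval_frame

logger = logging.getLogger("regarch")

SIGNAL_COLUMNS = [
    "h3k4me3",
    "h3k4me1",
    "h3k27ac",
    "h3k36me3",
    "h3k27me3",
    "accessibility",
]

_TABLE_NAMES = [
    "segmentations",
    "signals",
    "genes",
    "interactions",
    "orthology",
    "conservation_track",
    "tads",
    "expression",
    "tissue_expression",
    "variants",
    "selection_regions",
]


class ManifestError(ValueError):
    """Raised for inconsistent manifest declarations."""


@dataclass
class DatasetBundle:
    """In-memory view of a full comparative-epigenomics dataset."""

    species: list[str]
    samples: dict[str, dict]  # sample id -> {"species":..., "replicate":...}
    tissues: list[str] = field(default_factory=list)
    excluded_singleton_samples: list[str] = field(default_factory=list)

    segmentations: Optional[pd.DataFrame] = None  # chrom,start,end,state,sample
    signals: Optional[pd.DataFrame] = None  # element_id,species,sample,interval,marks
    genes: Optional[pd.DataFrame] = None  # gene_id,chrom,start,end,strand,gene_type
    interactions: Optional[pd.DataFrame] = None  # BEDPE anchors + source
    orthology: Optional[pd.DataFrame] = None  # region_id,species,chrom,start,end
    conservation_track: Optional[pd.DataFrame] = None  # bedGraph
    tads: Optional[pd.DataFrame] = None  # chrom,start,end
    expression: Optional[pd.DataFrame] = None  # gene_id x sample
    tissue_expression: Optional[pd.DataFrame] = None  # gene_id x tissue
    variants: Optional[pd.DataFrame] = None  # site x species allele summary
    selection_regions: Optional[pd.DataFrame] = None  # chrom,start,end[,name]

    def table_names(self) -> list[str]:
        return [n for n in _TABLE_NAMES if getattr(self, n) is not None]

    def validate(self) -> None:
        declared_species = set(self.species)
        for sample, meta in self.samples.items():
            if meta["species"] not in declared_species:
                raise ManifestError(
                    f"sample {sample} references undeclared species "
                    f"{meta['species']!r}"
                )
        for name in ("segmentations", "tads", "selection_regions", "genes",
                     "conservation_track", "orthology"):
            df = getattr(self, name)
            if df is not None:
                validate_interval_frame(df, name)
        if self.interactions is not None and len(self.interactions):
            for side in ("a", "b"):
                tmp = self.interactions.rename(
                    columns={
                        f"chrom_{side}": "chrom",
                        f"start_{side}": "start",
                        f"end_{side}": "end",
                    }
                )
                validate_interval_frame(tmp, f"interactions anchor {side}")
        if self.signals is not None and len(self.signals):
            validate_interval_frame(self.signals, "signals")
            unknown = set(self.signals["species"]) - declared_species
            if unknown:
                raise ManifestError(f"signals reference unknown species {unknown}")
        if self.orthology is not None and len(self.orthology):
            unknown = set(self.orthology["species"]) - declared_species
            if unknown:
                raise ManifestError(f"orthology references unknown species {unknown}")
        if self.genes is not None and len(self.genes):
            bad = ~self.genes["strand"].isin(VALID_STRANDS)
            if bad.any():
                raise ManifestError("genes table contains invalid strand values")


# ---------------------------------------------------------------------------
# readers


def read_bed(path: str | os.PathLike, extra_cols: list[str] | None = None) -> pd.DataFrame:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype={0: str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=cols)
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    _validate_with_lines(df, path)
    return df


def _validate_with_lines(df: pd.DataFrame, path) -> None:
    bad = df.index[(df["end"] <= df["start"]) | (df["start"] < 0)]
    if len(bad):
        raise ValueError(
            f"{path}: line {bad[0] + 1}: interval end <= start or negative start"
        )


def read_bedgraph(path) -> pd.DataFrame:
    df = read_bed(path, ["score"])
    df["score"] = df["score"].astype(float)
    return df


def read_bedpe(path) -> pd.DataFrame:
    cols = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "source"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str},
                     float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=cols)
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BEDPE needs >= 6 columns")
    if df.shape[1] == 6:
        df[6] = "synthetic"
    df = df.iloc[:, :7]
    df.columns = cols
    for c in ("start_a", "end_a", "start_b", "end_b"):
        df[c] = df[c].astype(int)
    return df


def read_gtf_genes(path) -> pd.DataFrame:
    """Read gene records from a GTF-like file into the internal gene table.

    Only `gene` features are kept; 1-based closed coordinates become
    0-based half-open.  TSS is derived from strand.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}: line {ln}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            if feature != "gene":
                continue
            attr = _parse_gtf_attrs(attrs)
            if strand not in ("+", "-"):
                logger.warning("%s line %d: unstranded gene defaulted to '+'", path, ln)
                strand = "+"
            rows.append(
                (
                    attr.get("gene_id", f"gene{ln}"),
                    chrom,
                    int(start) - 1,
                    int(end),
                    strand,
                    attr.get("gene_type", "protein_coding"),
                )
            )
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "gene_type"]
    )
    df["tss"] = df["start"].where(df["strand"] == "+", df["end"] - 1)
    _validate_with_lines(df, path)
    return df


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=True,
                       float_precision="round_trip")


def read_matrix(path, index_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["."], float_precision="round_trip")
    return df.set_index(index_col)


# ---------------------------------------------------------------------------
# bundle load / write


def load_bundle(manifest_path: str | os.PathLike) -> DatasetBundle:
    """Load a DatasetBundle from a YAML manifest.

    The manifest declares species/samples/tissues and one relative file
    path per table; all paths resolve relative to the manifest location.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    files = manifest.get("files", {})

    def path_of(name):
        p = files.get(name)
        if p is None:
            return None
        full = base / p
        if not full.exists():
            raise FileNotFoundError(f"{name} file not found: {full}")
        return full

    bundle = DatasetBundle(
        species=list(manifest["species"]),
        samples={k: dict(v) for k, v in manifest["samples"].items()},
        tissues=list(manifest.get("tissues", [])),
        excluded_singleton_samples=list(
            manifest.get("excluded_singleton_samples", [])
        ),
    )

    seg_spec = files.get("segmentations")
    if seg_spec is not None:
        frames = []
        for sample, rel in sorted(seg_spec.items()):
            full = base / rel
            if not full.exists():
                raise FileNotFoundError(f"segmentations file not found: {full}")
            df = read_bed(full, ["state"])
            df["sample"] = sample
            frames.append(df)
        bundle.segmentations = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["chrom", "start", "end", "state", "sample"])
        )

    p = path_of("signals")
    if p is not None:
        bundle.signals = read_tsv(p)
    p = path_of("genes")
    if p is not None:
        bundle.genes = read_gtf_genes(p)
    p = path_of("interactions")
    if p is not None:
        bundle.interactions = read_bedpe(p)
    p = path_of("orthology")
    if p is not None:
        bundle.orthology = read_tsv(p)
    p = path_of("conservation_track")
    if p is not None:
        bundle.conservation_track = read_bedgraph(p)
    p = path_of("tads")
    if p is not None:
        bundle.tads = read_bed(p)
    p = path_of("expression")
    if p is not None:
        bundle.expression = read_matrix(p, "gene_id")
    p = path_of("tissue_expression")
    if p is not None:
        bundle.tissue_expression = read_matrix(p, "gene_id")
    p = path_of("variants")
    if p is not None:
        bundle.variants = read_tsv(p)
    p = path_of("selection_regions")
    if p is not None:
        bundle.selection_regions = read_bed(p, ["name"])

    bundle.validate()
    for name in bundle.table_names():
        logger.info("loaded %s: %d rows", name, len(getattr(bundle, name)))
    return bundle


def _sort_canonical(df: pd.DataFrame) -> pd.DataFrame:
    keys = [c for c in ("chrom", "start", "end", "region_id", "element_id",
                        "gene_id", "species", "sample", "pos") if c in df.columns]
    if not keys:
        return df.reset_index(drop=True)
    return df.sort_values(keys, kind="mergesort").reset_index(drop=True)


def write_bundle(bundle: DatasetBundle, out_dir: str | os.PathLike) -> Path:
    """Write every table of the bundle in its canonical format.

    Returns the manifest path.  Output ordering is deterministic so that a
    write -> load -> write cycle is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.validate()
    files: dict = {}

    if bundle.segmentations is not None:
        seg_files = {}
        for sample in sorted(bundle.samples):
            sub = bundle.segmentations[bundle.segmentations["sample"] == sample]
            sub = _sort_canonical(sub[["chrom", "start", "end", "state"]])
            fname = f"segmentation_{sample}.bed"
            sub.to_csv(out / fname, sep="\t", header=False, index=False)
            seg_files[sample] = fname
        files["segmentations"] = seg_files

    def write_tsv(df, fname, key):
        _sort_canonical(df).to_csv(out / fname, sep="\t", index=False, na_rep=".")
        files[key] = fname

    if bundle.signals is not None:
        write_tsv(bundle.signals, "signals.tsv", "signals")
    if bundle.genes is not None:
        fname = "genes.gtf"
        with open(out / fname, "w") as fh:
            for row in _sort_canonical(bundle.genes).itertuples(index=False):
                fh.write(
                    f"{row.chrom}\tregarch\tgene\t{row.start + 1}\t{row.end}\t.\t"
                    f'{row.strand}\t.\tgene_id "{row.gene_id}"; '
                    f'gene_type "{row.gene_type}";\n'
                )
        files["genes"] = fname
    if bundle.interactions is not None:
        df = bundle.interactions.sort_values(
            ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"],
            kind="mergesort",
        )
        df.to_csv(out / "interactions.bedpe", sep="\t", header=False, index=False)
        files["interactions"] = "interactions.bedpe"
    if bundle.orthology is not None:
        write_tsv(bundle.orthology, "orthology.tsv", "orthology")
    if bundle.conservation_track is not None:
        _sort_canonical(bundle.conservation_track).to_csv(
            out / "conservation.bedGraph", sep="\t", header=False, index=False
        )
        files["conservation_track"] = "conservation.bedGraph"
    if bundle.tads is not None:
        _sort_canonical(bundle.tads).to_csv(
            out / "tads.bed", sep="\t", header=False, index=False
        )
        files["tads"] = "tads.bed"
    if bundle.expression is not None:
        bundle.expression.sort_index().to_csv(
            out / "expression.tsv", sep="\t", index_label="gene_id", na_rep="."
        )
        files["expression"] = "expression.tsv"
    if bundle.tissue_expression is not None:
        bundle.tissue_expression.sort_index().to_csv(
            out / "tissue_expression.tsv", sep="\t", index_label="gene_id", na_rep="."
        )
        files["tissue_expression"] = "tissue_expression.tsv"
    if bundle.variants is not None:
        write_tsv(bundle.variants, "variants.tsv", "variants")
    if bundle.selection_regions is not None:
        df = bundle.selection_regions
        _sort_canonical(df).to_csv(
            out / "selection_regions.bed", sep="\t", header=False, index=False
        )
        files["selection_regions"] = "selection_regions.bed"

    manifest = {
        "species": list(bundle.species),
        "samples": {k: dict(v) for k, v in sorted(bundle.samples.items())},
        "tissues": list(bundle.tissues),
        "excluded_singleton_samples": list(bundle.excluded_singleton_samples),
        "files": files,
    }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path
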