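"""Regulatory-element definition and epigenetic state assignment.

Elements are maximal runs of contiguous 200-bp chromatin-state bins after
excluding elongating (E1, E2), low-signal (E15) and repressed
heterochromatin (E16) states.  Each element receives a chromatin-state
based label from a fixed hierarchy (promoter states E8/E9/E11; poised via
E14; strong enhancers via E3-E6/E12), which is then refined by linear
discriminant analysis on the quantitative mark/accessibility signals, and
finally reconciled across biological replicates into a consensus label.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .intervals import merge_intervals
from .io_core import SIGNAL_COLUMNS

BIN = 200

EXCLUDED_STATES = frozenset({"E1", "E2", "E15", "E16"})
PROMOTER_STATES = frozenset({"E8", "E9", "E11"})
STRONG_PROMOTER_STATES = frozenset({"E9", "E11"})
STRONG_ENHANCER_STATES = frozenset({"E3", "E4", "E5", "E6", "E12"})
POISED_STATE = "E14"

CORE_LABELS = ("sP", "pP", "wP", "sE", "pE", "wE")
PROMOTER_LABELS = frozenset({"sP", "pP", "wP"})
ENHANCER_LABELS = frozenset({"sE", "pE", "wE"})
AMBIGUOUS_LABELS = ("aP", "aE", "P/E", "P/Non-RE", "E/Non-RE")
NON_RE = "non-RE"
ALL_LABELS = frozenset(CORE_LABELS) | frozenset(AMBIGUOUS_LABELS) | {NON_RE}

# poised > strong > weak, used only to break exact posterior ties
_TIE_ORDER = {"pP": 0, "sP": 1, "wP": 2, "pE": 0, "sE": 1, "wE": 2}

ALL_E_STATES = frozenset(f"E{i}" for i in range(1, 17))


def log_enrichment(ip: np.ndarray, background: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Background-normalized signal: log2((IP + c) / (input + c)), c = 1."""
    return np.log2((np.asarray(ip, float) + pseudocount) / (np.asarray(background, float) + pseudocount))


def define_elements(segments: pd.DataFrame) -> pd.DataFrame:
    """Merge consecutive 200-bp bins into regulatory elements.

    ``segments`` needs columns chrom/start/end/state (one sample).  Bins
    in excluded states break runs.  Returns elements with the set of
    constituent chromatin states.
    """
    req = {"chrom", "start", "end", "state"}
    if not req.issubset(segments.columns):
        raise ValueError(f"segments require columns {sorted(req)}")
    bad = segments.loc[
        ((segments["end"] - segments["start"]) % BIN != 0)
    ]
    if len(bad):
        raise ValueError("segment lengths must be multiples of 200 bp")
    seg = segments.sort_values(["chrom", "start"]).reset_index(drop=True)
    # overlapping segments within one sample are malformed input
    same_chrom = seg["chrom"] == seg["chrom"].shift()
    if (same_chrom & (seg["start"] < seg["end"].shift())).any():
        raise ValueError("overlapping segments within one sample")

    rows = []
    cur = None  # [chrom, start, end, states]
    for t in seg.itertuples(index=False):
        if t.state in EXCLUDED_STATES or t.state not in ALL_E_STATES:
            if t.state not in ALL_E_STATES:
                raise ValueError(f"unknown chromatin state {t.state!r}")
            if cur is not None:
                rows.append(cur)
                cur = None
            continue
        if cur is not None and t.chrom == cur[0] and t.start == cur[2]:
            cur[2] = t.end
            cur[3].add(t.state)
        else:
            if cur is not None:
                rows.append(cur)
            cur = [t.chrom, t.start, t.end, {t.state}]
    if cur is not None:
        rows.append(cur)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "states"])


def union_species_elements(
    rep_elements: dict[str, pd.DataFrame],
    include_single_replicate: bool = True,
    excluded_singleton: str | None = None,
) -> pd.DataFrame:
    """Union of per-replicate elements into species elements.

    Overlapping intervals across replicates are merged.  When
    ``include_single_replicate`` is false, merged elements supported only
    by the replicate named ``excluded_singleton`` are dropped (the
    one-anomalous-replicate rule).
    """
    if not rep_elements:
        raise ValueError("at least one replicate required")
    frames = []
    for rep, df in rep_elements.items():
        d = df[["chrom", "start", "end"]].copy()
        d["replicate"] = rep
        frames.append(d)
    allel = pd.concat(frames, ignore_index=True)
    merged = merge_intervals(allel)
    support = []
    for t in merged.itertuples(index=False):
        reps = set(
            allel.loc[
                (allel["chrom"] == t.chrom)
                & (allel["start"] < t.end)
                & (allel["end"] > t.start),
                "replicate",
            ]
        )
        support.append(reps)
    merged["replicates"] = support
    if not include_single_replicate and excluded_singleton is not None:
        keep = merged["replicates"].map(lambda s: s != {excluded_singleton})
        merged = merged.loc[keep].reset_index(drop=True)
    return merged


def hierarchy_label(element_states: Iterable[str]) -> str:
    """Chromatin-state based label from the fixed promoter/enhancer hierarchy.

    Promoters: any of E8/E9/E11 present.  E14 marks poised; otherwise
    E9/E11 mark strong promoters and E3/E4/E5/E6/E12 strong enhancers;
    what remains is weak.
    """
    states = set(element_states)
    unknown = states - ALL_E_STATES
    if unknown:
        raise ValueError(f"unknown chromatin states {sorted(unknown)}")
    informative = states - EXCLUDED_STATES
    if not informative:
        raise ValueError("element contains only excluded states")
    if states & PROMOTER_STATES:
        if POISED_STATE in states:
            return "pP"
        if states & STRONG_PROMOTER_STATES:
            return "sP"
        return "wP"
    if POISED_STATE in states:
        return "pE"
    if states & STRONG_ENHANCER_STATES:
        return "sE"
    return "wE"


@dataclass
class LdaModel:
    """Fitted discriminant model retained for audit."""

    classes: list[str]
    means: np.ndarray  # class x feature
    scatter: np.ndarray  # shared within-class covariance
    coefficients: np.ndarray
    priors: np.ndarray
    estimator: LinearDiscriminantAnalysis


def lda_refine(
    signals: pd.DataFrame,
    raw_labels: Sequence[str],
    ridge: float = 1e-6,
) -> tuple[LdaModel, np.ndarray]:
    """Refine chromatin-state labels by LDA on the quantitative signals.

    Predictors are the six background-normalized signals; the response is
    the raw hierarchy label.  The refined label is the posterior argmax,
    with exact posterior ties broken poised > strong > weak.  Classes must
    be the six core labels with >= 7 members each (more observations than
    predictors per class).
    """
    X = signals[SIGNAL_COLUMNS].to_numpy(float)
    if not np.isfinite(X).all():
        raise ValueError("signals must be finite")
    y = np.asarray(raw_labels)
    bad = set(y) - set(CORE_LABELS)
    if bad:
        raise ValueError(f"raw labels outside core set: {sorted(bad)}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("LDA needs >= 2 classes")
    if counts.min() < 7:
        small = classes[counts < 7]
        raise ValueError(
            f"classes with < 7 members cannot be refined: {list(small)}"
        )
    # pooled within-class scatter, kept for audit; if it is singular the
    # svd solver is swapped for a lightly regularized eigen solver so a
    # degenerate signal column cannot silently abort the run
    Xc = X - np.vstack([X[y == c].mean(axis=0) for c in classes])[
        np.searchsorted(classes, y)
    ]
    scatter = Xc.T @ Xc / max(len(y) - len(classes), 1)
    if np.linalg.matrix_rank(scatter) < scatter.shape[0]:
        est = LinearDiscriminantAnalysis(solver="eigen", shrinkage=ridge)
    else:
        est = LinearDiscriminantAnalysis(solver="svd")
    est.fit(X, y)
    post = est.predict_proba(X)
    refined = _argmax_with_hierarchy_ties(post, list(est.classes_))
    model = LdaModel(
        classes=list(est.classes_),
        means=est.means_,
        scatter=scatter,
        coefficients=est.coef_,
        priors=est.priors_,
        estimator=est,
    )
    return model, refined


def _argmax_with_hierarchy_ties(post: np.ndarray, classes: list[str]) -> np.ndarray:
    order = np.array([_TIE_ORDER.get(c, 9) for c in classes])
    # lexicographic: max posterior first, then poised > strong > weak
    best = np.empty(len(post), dtype=object)
    for i, row in enumerate(post):
        m = row.max()
        tied = np.flatnonzero(np.isclose(row, m, rtol=0, atol=1e-12))
        best[i] = classes[tied[np.argmin(order[tied])]]
    return best.astype(str)


def posterior_oracle(
    x: np.ndarray,
    means: dict[str, np.ndarray],
    cov: np.ndarray,
    priors: dict[str, float],
) -> dict[str, float]:
    """Independent Gaussian-posterior computation via explicit quadratic forms.

    Used as a cross-check for the LDA refinement; shares no code with it.
    """
    inv = np.linalg.inv(cov)
    logp = {}
    for c, mu in means.items():
        d = x - mu
        logp[c] = -0.5 * d @ inv @ d + np.log(priors[c])
    mx = max(logp.values())
    w = {c: np.exp(v - mx) for c, v in logp.items()}
    z = sum(w.values())
    return {c: v / z for c, v in w.items()}


def consensus_state(rep1: str, rep2: str) -> str:
    """Species-level consensus of two replicate labels.

    Identical labels pass through; same class with different activity is
    ambiguous (aP/aE); opposite classes give P/E; one missing replicate
    gives P/Non-RE or E/Non-RE.
    """
    for lab in (rep1, rep2):
        if lab not in CORE_LABELS and lab != NON_RE:
            raise ValueError(f"invalid replicate label {lab!r}")
    if rep1 == rep2:
        return rep1
    s = {rep1, rep2}
    if NON_RE in s:
        other = (s - {NON_RE}).pop()
        return "P/Non-RE" if other in PROMOTER_LABELS else "E/Non-RE"
    if s <= PROMOTER_LABELS:
        return "aP"
    if s <= ENHANCER_LABELS:
        return "aE"
    return "P/E"


def annotate_elements(
    segmentations: pd.DataFrame,
    signals: pd.DataFrame,
    samples: dict[str, dict],
    refine: bool = True,
    pooled: bool = True,
) -> pd.DataFrame:
    """Full per-species annotation: elements, raw and refined labels, consensus.

    ``signals`` must carry one row per (element interval, sample) with the
    six signal columns.  Returns a per-species element table with
    per-replicate labels and the consensus label.  With ``pooled`` the LDA
    is fitted once across all samples; otherwise per sample.
    """
    by_species: dict[str, dict[str, pd.DataFrame]] = {}
    for sample, meta in samples.items():
        seg = segmentations[segmentations["sample"] == sample]
        if seg.empty:
            continue
        elems = define_elements(seg)
        by_species.setdefault(meta["species"], {})[sample] = elems

    records = []
    for species, reps in sorted(by_species.items()):
        rep_names = sorted(reps)
        union = union_species_elements(reps)
        for t in union.itertuples(index=False):
            rec = {
                "species": species,
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
            }
            for i, rep in enumerate(rep_names[:2], start=1):
                sub = reps[rep]
                hit = sub[
                    (sub["chrom"] == t.chrom)
                    & (sub["start"] < t.end)
                    & (sub["end"] > t.start)
                ]
                if hit.empty:
                    rec[f"raw_{i}"] = NON_RE
                else:
                    states = set().union(*hit["states"])
                    rec[f"raw_{i}"] = hierarchy_label(states)
            if len(rep_names) == 1:
                rec["raw_2"] = rec["raw_1"]
            records.append(rec)
    out = pd.DataFrame.from_records(records)
    if out.empty:
        return out

    for i in (1, 2):
        out[f"refined_{i}"] = out[f"raw_{i}"]
    if refine and signals is not None and len(signals):
        out = out.reset_index(drop=True)
        obs_frames = []
        for species, reps in sorted(by_species.items()):
            rep_names = sorted(reps)
            sub = out[out["species"] == species]
            for i, rep in enumerate(rep_names[:2], start=1):
                m = sub[["species", "chrom", "start", "end", f"raw_{i}"]].copy()
                m = m.rename(columns={f"raw_{i}": "label"})
                m["sample"] = rep
                m["rep_index"] = i
                m["row"] = sub.index
                obs_frames.append(m[m["label"] != NON_RE])
        obs = pd.concat(obs_frames, ignore_index=True)
        obs = obs.merge(
            signals,
            on=["species", "sample", "chrom", "start", "end"],
            how="inner",
        ).dropna(subset=SIGNAL_COLUMNS)
        groups = [obs] if pooled else [g for _, g in obs.groupby("sample")]
        for g in groups:
            try:
                _, refined = lda_refine(g[SIGNAL_COLUMNS], g["label"])
            except ValueError:
                continue  # class too small or single class: keep raw labels
            for row, idx, lab in zip(g["row"], g["rep_index"], refined):
                out.loc[row, f"refined_{idx}"] = lab
    out["consensus"] = [
        consensus_state(a, b) for a, b in zip(out["refined_1"], out["refined_2"])
    ]
    return out


def downstream_filter(annotated: pd.DataFrame) -> pd.DataFrame:
    """Keep only elements whose consensus is one of the six core states."""
    return annotated[annotated["consensus"].isin(CORE_LABELS)].reset_index(drop=True)
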