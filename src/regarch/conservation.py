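"""Cross-species conservation of epigenetic states and underlying sequence.

For each one-to-one orthologous regulatory region we count, per state, the
number of species (1..n) sharing it — either at the class level (promoter
vs enhancer, activities collapsed) or at the activity level (exact strong/
poised/weak labels).  Randomization tests permute each species' state
column independently across regions.  Sequence conservation is summarized
as TAD-background-normalized per-bp Z-scores, averaged in overlapping
200-bp bins, taking the per-region maximum.
"""
from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .states import CORE_LABELS, NON_RE, PROMOTER_LABELS

logger = logging.getLogger("regarch")

EVENT_CLASSES = (
    "fully_conserved",
    "species_specific",
    "repurposed",
    "gained",
    "other",
)


def _class_of(label: str) -> str:
    if label == NON_RE:
        return NON_RE
    if label in PROMOTER_LABELS or label in ("aP", "P/Non-RE"):
        return "P"
    if label == "P/E":
        return "P/E"
    return "E"


@dataclass
class ConservationProfile:
    counts: dict[str, int]
    event: str


def count_state_conservation(
    states: list[str] | tuple[str, ...],
    level: str = "activity",
) -> ConservationProfile:
    """Per-state species counts for one orthologous region.

    ``level="class"`` collapses activities to P/E before counting;
    ``level="activity"`` counts exact labels and refuses ambiguous ones.
    """
    if level not in ("class", "activity"):
        raise ValueError("level must be 'class' or 'activity'")
    states = list(states)
    if all(s == NON_RE for s in states):
        raise ValueError("region without regulatory state in any species")
    if level == "activity":
        bad = [s for s in states if s not in CORE_LABELS and s != NON_RE]
        if bad:
            raise ValueError(
                f"ambiguous labels excluded at activity level: {bad}"
            )
        keys = [s for s in states if s != NON_RE]
    else:
        states = [_class_of(s) for s in states]
        keys = [s for s in states if s != NON_RE]
    counts: dict[str, int] = {}
    for s in keys:
        counts[s] = counts.get(s, 0) + 1
    n = len(states)
    classes = [_class_of(s) for s in states]
    if counts and max(counts.values()) == n:
        event = "fully_conserved"
    elif sum(s != NON_RE for s in states) == 1:
        event = "species_specific"
    else:
        ev = classify_recent_events(classes)
        event = ev if ev in ("repurposed", "gained") else "other"
    return ConservationProfile(counts=counts, event=event)


def classify_recent_events(class_states: list[str]) -> str:
    """Recent-event classification of a class-level (P/E/non-RE) state vector.

    Repurposed: exactly one species shows a promoter state while all the
    others show an enhancer state, or vice versa.  Gained (novel state):
    exactly one species shows a promoter or enhancer state while all the
    others show no regulatory activity.  Anything else is "other".
    """
    v = [_class_of(s) for s in class_states]
    n = len(v)
    n_p = v.count("P")
    n_e = v.count("E")
    n_non = v.count(NON_RE)
    if (n_p == 1 and n_e == n - 1) or (n_e == 1 and n_p == n - 1):
        return "repurposed"
    if (n_p + n_e) == 1 and n_non == n - 1:
        return "gained"
    return "other"


def _mean_conservation(matrix: np.ndarray, state_set: np.ndarray) -> dict[str, float]:
    """Mean per-region species count of each state over regions containing it."""
    out = {}
    for s in state_set:
        if s == NON_RE:
            continue
        hits = matrix == s
        per_region = hits.sum(axis=1)
        mask = per_region > 0
        if mask.any():
            out[s] = float(per_region[mask].mean())
    return out


def conservation_randomization(
    regions: pd.DataFrame,
    n_rand: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation test of state conservation against independent species.

    ``regions`` holds one row per orthologous region, one column per
    species, entries being state labels (or non-RE).  Each randomization
    permutes each species' column independently across regions; p is the
    fraction of randomizations whose mean conservation is >= observed.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if len(regions) < 2:
        raise ValueError("need >= 2 regions")
    rng = np.random.default_rng(seed)
    matrix = regions.to_numpy(dtype=object)
    state_set = np.unique(matrix)
    observed = _mean_conservation(matrix, state_set)
    exceed = {s: 0 for s in observed}
    perm = matrix.copy()
    n_regions = len(matrix)
    for _ in range(n_rand):
        for j in range(matrix.shape[1]):
            perm[:, j] = matrix[rng.permutation(n_regions), j]
        rand_means = _mean_conservation(perm, state_set)
        for s in exceed:
            if rand_means.get(s, 0.0) >= observed[s]:
                exceed[s] += 1
    rows = [
        (s, observed[s], exceed[s] / n_rand, exceed[s] == 0)
        for s in sorted(observed)
    ]
    return pd.DataFrame(
        rows, columns=["state", "observed_mean_conservation", "p", "below_resolution"]
    )


@dataclass
class TadBackground:
    chrom: str
    start: int
    end: int
    mean: float
    sd: float


def tad_backgrounds(track: pd.DataFrame, tads: pd.DataFrame) -> list[TadBackground]:
    """Per-TAD mean and standard deviation of the per-bp conservation score."""
    out = []
    for t in tads.itertuples(index=False):
        scores = _expand_track(track, t.chrom, t.start, t.end)
        if scores.size == 0:
            continue
        out.append(
            TadBackground(t.chrom, t.start, t.end, float(scores.mean()), float(scores.std()))
        )
    return out


def _expand_track(track: pd.DataFrame, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-bp scores over [start, end); uncovered positions score 0."""
    out = np.zeros(end - start, dtype=float)
    sub = track[
        (track["chrom"] == chrom) & (track["start"] < end) & (track["end"] > start)
    ]
    for t in sub.itertuples(index=False):
        s = max(t.start, start) - start
        e = min(t.end, end) - start
        out[s:e] = t.score
    return out


def tad_zscore(
    region: tuple[str, int, int],
    track: pd.DataFrame,
    tads: list[TadBackground],
    bin_len: int = 200,
    bin_overlap: int = 50,
    keep_partial: bool = True,
) -> float:
    """Maximum binned Z-score of a region against its TAD background.

    Per-bp Z = (score - mu_TAD) / sigma_TAD; bins of ``bin_len`` tiled
    from the region start with stride ``bin_len - bin_overlap``; the
    returned score is the maximum bin mean.  Regions spanning two TADs are
    assigned by midpoint.
    """
    chrom, start, end = region
    mid = (start + end) / 2
    containing = [
        t for t in tads if t.chrom == chrom and t.start <= mid < t.end
    ]
    if not containing:
        raise ValueError(f"region {chrom}:{start}-{end} not inside any TAD")
    tad = containing[0]
    if not (tad.start <= start and end <= tad.end):
        logger.info(
            "region %s:%d-%d spans a TAD boundary; assigned by midpoint",
            chrom, start, end,
        )
    if tad.sd <= 0:
        raise ValueError("degenerate TAD background (sigma = 0)")
    scores = _expand_track(track, chrom, start, end)
    z = (scores - tad.mean) / tad.sd
    stride = bin_len - bin_overlap
    if stride <= 0:
        raise ValueError("bin_overlap must be smaller than bin_len")
    means = []
    pos = 0
    n = len(z)
    while pos < n:
        chunk = z[pos : pos + bin_len]
        if len(chunk) < bin_len and not keep_partial and means:
            break
        means.append(chunk.mean())
        if pos + bin_len >= n:
            break
        pos += stride
    return float(max(means))


def epi_seq_correlation(
    zscores: np.ndarray,
    counts: np.ndarray,
    n_rand: int = 1000,
    seed: int | None = None,
) -> dict:
    """Spearman correlation between sequence Z-scores and state conservation.

    Significance by permutation of the Z-scores: p = fraction of
    randomizations with rho >= observed.  Constant inputs give an
    undefined-rho flag rather than a crash.
    """
    z = np.asarray(zscores, float)
    c = np.asarray(counts, float)
    if len(z) != len(c):
        raise ValueError("length mismatch")
    if np.all(z == z[0]) or np.all(c == c[0]):
        return {"rho": np.nan, "p": np.nan, "undefined": True}
    rng = np.random.default_rng(seed)
    rho = stats.spearmanr(z, c).statistic
    exceed = 0
    for _ in range(n_rand):
        r = stats.spearmanr(rng.permutation(z), c).statistic
        if r >= rho:
            exceed += 1
    return {"rho": float(rho), "p": exceed / n_rand, "undefined": False}
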