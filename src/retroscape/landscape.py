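"""Windowed genome statistics and activity-pattern typing.

Genomes are tiled in non-overlapping windows of up to 1 Mb (scaffolds
between 100 kb and 1 Mb form a single window; shorter scaffolds are
discarded).  Windows carry genic fraction, LTR class counts, element ages
and deletion density; the genome-wide median genic fraction locates
pericentromere candidates; and per-species age histograms are typed into
one of three activity models:

* model a — continuous, roughly exponential growth toward the present;
* model b — growth, then a sudden arrest and decline;
* model c — like b but with a final recent burst.

The arrest point sits near 0.06 K2P units in the genomes that motivated
this taxonomy, so 0.06 is the default changepoint and 0.02 bounds the
"recent" segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import chronos

GENE_BIN_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


@dataclass(frozen=True)
class ActivityPattern:
    genome_id: str
    group: str
    model: str  # a | b | c
    changepoint_d: float
    segment_slopes: tuple[float, float, float]  # old, middle, recent
    n_elements: int
    low_confidence: bool

    def __post_init__(self) -> None:
        if self.model not in {"a", "b", "c"}:
            raise ValueError("model must be one of a, b, c")


def make_windows(
    scaffold_lengths: Mapping[str, int],
    window: int = 1_000_000,
    keep_min: int = 100_000,
) -> pd.DataFrame:
    """Tile scaffolds into windows (columns window_id, scaffold, start, end).

    Scaffolds shorter than ``keep_min`` are discarded; scaffolds shorter
    than ``window`` become a single window; a trailing partial window is
    kept.
    """
    rows = []
    for scaffold in sorted(scaffold_lengths):
        length = scaffold_lengths[scaffold]
        if length <= 0:
            raise ValueError(f"scaffold {scaffold} has non-positive length")
        if length < keep_min:
            continue
        if length <= window:
            rows.append({"scaffold": scaffold, "start": 0, "end": length})
            continue
        for start in range(0, length, window):
            rows.append({"scaffold": scaffold, "start": start, "end": min(start + window, length)})
    for i, r in enumerate(rows):
        r["window_id"] = f"W{i + 1:04d}"
    return pd.DataFrame(rows, columns=["window_id", "scaffold", "start", "end"])


def assign_to_windows(
    windows: pd.DataFrame, positions: Iterable[tuple[str, int]]
) -> list[str | None]:
    """Window id containing each (scaffold, start) position, else None."""
    lookup: dict[str, list[tuple[int, int, str]]] = {}
    for row in windows.itertuples(index=False):
        lookup.setdefault(row.scaffold, []).append((int(row.start), int(row.end), row.window_id))
    out: list[str | None] = []
    for scaffold, pos in positions:
        hit = None
        for start, end, wid in lookup.get(scaffold, []):
            if start <= pos < end:
                hit = wid
                break
        out.append(hit)
    return out


def genic_fraction(
    windows: pd.DataFrame, genes: Sequence[tuple[str, int, int]]
) -> pd.Series:
    """Fraction of each window covered by (clipped, unioned) gene intervals."""
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for scaffold, start, end in genes:
        by_scaffold.setdefault(scaffold, []).append((start, end))
    for ivs in by_scaffold.values():
        ivs.sort()
    values = []
    for row in windows.itertuples(index=False):
        w0, w1 = int(row.start), int(row.end)
        covered = 0
        last = w0
        for s, e in by_scaffold.get(row.scaffold, []):
            s, e = max(s, w0, last), min(e, w1)
            if e > s:
                covered += e - s
                last = e
        values.append(covered / (w1 - w0))
    return pd.Series(values, index=windows["window_id"], name="genic_fraction")


def call_pericentromeres(
    windows: pd.DataFrame,
    genic: pd.Series,
    threshold: float | None = None,
) -> tuple[list[str], dict[str, list[str]]]:
    """Flag windows with genic fraction strictly below the threshold.

    The threshold defaults to the genome-wide median genic fraction.
    Returns (flagged window ids, per-scaffold maximal run of consecutive
    flagged windows — the pericentromere candidate).
    """
    if threshold is None:
        threshold = float(genic.median())
    flagged = [wid for wid in windows["window_id"] if genic[wid] < threshold]
    flagged_set = set(flagged)
    candidates: dict[str, list[str]] = {}
    for scaffold, sub in windows.groupby("scaffold", sort=True):
        best: list[str] = []
        run: list[str] = []
        for wid in sub.sort_values("start")["window_id"]:
            if wid in flagged_set:
                run.append(wid)
                if len(run) > len(best):
                    best = list(run)
            else:
                run = []
        if best:
            candidates[scaffold] = best
    return flagged, candidates


def correlate(frame: pd.DataFrame, x_field: str, y_field: str) -> tuple[float, float]:
    """Spearman rank correlation between two window statistics."""
    if len(frame) < 3:
        raise ValueError("need at least 3 windows")
    x = frame[x_field].to_numpy(dtype=float)
    y = frame[y_field].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant field")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def gene_content_bin(fraction: float) -> int | None:
    """Six left-closed 10% bins over [0, 60%); >= 60% is excluded (None)."""
    if fraction < 0:
        raise ValueError("genic fraction must be >= 0")
    if fraction >= GENE_BIN_EDGES[-1]:
        return None
    return min(int(fraction / 0.1), 5)


def ages_by_gene_bin(
    windows: pd.DataFrame,
    genic: pd.Series,
    element_windows: Sequence[str | None],
    element_ages: Sequence[float],
    bin_width: float = 0.01,
) -> pd.DataFrame:
    """Normalised element-age distribution per gene-content bin.

    Elements are pooled by the gene-content bin of their window; the output
    is tidy (gene_bin, bin_left, count, proportion, low_confidence) and
    proportions sum to 1 within each gene bin.
    """
    window_bin = {
        wid: gene_content_bin(float(genic[wid])) for wid in windows["window_id"]
    }
    ds, groups = [], []
    for wid, age in zip(element_windows, element_ages):
        if wid is None:
            continue
        b = window_bin.get(wid)
        if b is None:
            continue
        ds.append(age)
        groups.append(f"bin{b}")
    if not ds:
        return pd.DataFrame(
            columns=["group", "bin_left", "count", "proportion", "low_confidence"]
        )
    return chronos.age_histogram(ds, groups, bin_width=bin_width)


def ltr_count_metrics(paired: int, solo: int, nonsolo: int) -> tuple[int, int]:
    """(stack total, insertion-equivalent total) for one window or genome.

    The stack total is the plain sum of the three classes; the insertion
    equivalent counts each unpaired LTR twice, since a complete insertion
    contributes two LTRs but an excision product only one.
    """
    stack = paired + solo + nonsolo
    insertion_equivalent = paired + 2 * (solo + nonsolo)
    return stack, insertion_equivalent


def window_ltr_metrics(window_counts: pd.DataFrame) -> pd.DataFrame:
    """Add both LTR count metrics to a per-window class-count frame."""
    out = window_counts.copy()
    out["total_ltr"] = out["paired"] + out["solo"] + out["nonsolo"]
    out["insertion_equivalent"] = out["paired"] + 2 * (out["solo"] + out["nonsolo"])
    return out


def classify_activity_pattern(
    histogram: pd.DataFrame,
    genome_id: str = "",
    group: str = "species",
    changepoint_d: float = 0.06,
    recent_d: float = 0.02,
    d_max: float = 0.20,
    low_conf_min: int = 100,
    slope_tol: float = 1e-9,
) -> ActivityPattern:
    """Type an age histogram into activity model a, b, or c.

    ``histogram`` needs columns ``bin_left`` and ``count``.  Counts are
    regressed on time-toward-the-present within three segments of the age
    axis — old (d in (changepoint, d_max]), middle (d in (recent,
    changepoint]), recent (d in [0, recent]) — and the model follows from
    the middle/recent slope signs: both non-negative is sustained growth
    (a); a recent rebound after a middle decline is a final burst (c);
    anything else is arrest/decline (b).
    """
    if histogram.empty or histogram["count"].sum() == 0:
        raise ValueError("empty histogram")
    d = histogram["bin_left"].to_numpy(dtype=float)
    c = histogram["count"].to_numpy(dtype=float)
    n = int(c.sum())

    def slope(mask: np.ndarray) -> float:
        if mask.sum() < 2:
            return 0.0
        # regress counts on -d so positive slope = growth toward the present
        return float(np.polyfit(-d[mask], c[mask], 1)[0])

    s_old = slope((d > changepoint_d) & (d <= d_max))
    s_mid = slope((d > recent_d) & (d <= changepoint_d))
    s_rec = slope(d <= recent_d)

    if s_mid >= -slope_tol and s_rec >= -slope_tol:
        model = "a"
    elif s_rec > slope_tol:
        model = "c"
    else:
        model = "b"
    return ActivityPattern(
        genome_id=genome_id,
        group=group,
        model=model,
        changepoint_d=changepoint_d,
        segment_slopes=(s_old, s_mid, s_rec),
        n_elements=n,
        low_confidence=n < low_conf_min,
    )
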