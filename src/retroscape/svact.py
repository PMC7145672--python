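"""Deletion-call evidence of retrotransposon activity.

Deletion calls from resequenced samples (VCF, SVTYPE=DEL) become activity
evidence when they reciprocally cover >= 80% of a complete LTR element
(at least 80% of the deletion lies on the element and vice versa) and are
shorter than 100 kb.  The per-sample read-support fraction calls zygosity:
>= 80% homozygous, >= 20% hemizygous, below that unsupported (excluded).
Insertion-versus-deletion polarity is deliberately not resolved — a call
can reflect either an excision in the sample or an insertion in the
reference lineage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


@dataclass(frozen=True)
class DeletionCall:
    sample_id: str
    scaffold: str
    start: int  # 0-based half-open
    end: int
    supporting_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.supporting_fraction <= 1:
            raise ValueError("supporting fraction must be in [0,1]")
        if self.end <= self.start:
            raise ValueError("deletion must have positive length")


@dataclass(frozen=True)
class ElementDeletion:
    sample_id: str
    element_id: str
    scaffold: str
    start: int
    end: int
    zygosity: str  # hemizygous | homozygous | unsupported
    overlap_on_deletion: float
    overlap_on_element: float


def read_deletion_vcf(path: str | Path) -> list[DeletionCall]:
    """Read SVTYPE=DEL records with per-sample AO/RO read support.

    One :class:`DeletionCall` is emitted per (record, sample) with alt
    support; samples without informative reads are skipped.  Records whose
    genotyping carries no allele-support fields (AO/RO) are refused rather
    than inferred from genotype likelihoods.  Malformed records raise a
    ValueError naming the record number.
    """
    import pysam

    calls: list[DeletionCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for idx, rec in enumerate(vcf, start=1):
            try:
                if rec.info.get("SVTYPE") != "DEL":
                    continue
                end = rec.stop  # pysam resolves INFO/END
                start = rec.start
                for sample in samples:
                    fmt = rec.samples[sample]
                    if "AO" not in fmt or "RO" not in fmt:
                        raise ValueError(
                            "no AO/RO allele-support fields; refusing to infer "
                            "support from genotype likelihoods"
                        )
                    ao = _scalar(fmt["AO"])
                    ro = _scalar(fmt["RO"])
                    if ao is None or ro is None or ao + ro == 0 or ao == 0:
                        continue
                    calls.append(
                        DeletionCall(
                            sample_id=sample,
                            scaffold=rec.chrom,
                            start=start,
                            end=end,
                            supporting_fraction=ao / (ao + ro),
                        )
                    )
            except ValueError as exc:
                raise ValueError(f"VCF record {idx}: {exc}") from exc
    return calls


def _scalar(value):
    if isinstance(value, tuple):
        value = value[0] if value else None
    return value


def reciprocal_overlap(
    a: tuple[int, int], b: tuple[int, int]
) -> tuple[float, float]:
    """(overlap/len(a), overlap/len(b)); symmetric under swapping."""
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return ov / (a[1] - a[0]), ov / (b[1] - b[0])


def call_zygosity(
    supporting_fraction: float, hemi_min: float = 0.20, homo_min: float = 0.80
) -> str:
    """Closed lower bounds: >= 0.80 homozygous, >= 0.20 hemizygous."""
    if supporting_fraction >= homo_min:
        return "homozygous"
    if supporting_fraction >= hemi_min:
        return "hemizygous"
    return "unsupported"


def assign_deletions(
    calls: Sequence[DeletionCall],
    elements: Mapping[str, tuple[str, int, int]],
    max_len: int = 100_000,
    reciprocal_min: float = 0.80,
    hemi_min: float = 0.20,
    homo_min: float = 0.80,
    include_unsupported: bool = False,
) -> list[ElementDeletion]:
    """Assign deletion calls to complete elements by reciprocal overlap.

    ``elements`` maps element_id -> (scaffold, start, end).  A call shorter
    than ``max_len`` is assigned to an element when each covers >=
    ``reciprocal_min`` of the other; when several elements qualify (only
    possible if elements overlap) the one with the highest minimum
    reciprocal fraction wins.  Unsupported-zygosity assignments are
    excluded unless requested.
    """
    trees: dict[str, IntervalTree] = {}
    for eid, (scaffold, start, end) in elements.items():
        trees.setdefault(scaffold, IntervalTree()).addi(start, end, eid)

    out: list[ElementDeletion] = []
    for call in calls:
        if call.end - call.start >= max_len:
            continue
        tree = trees.get(call.scaffold)
        if tree is None:
            continue
        best = None
        for iv in tree.overlap(call.start, call.end):
            on_del, on_elem = reciprocal_overlap(
                (call.start, call.end), (iv.begin, iv.end)
            )
            if on_del >= reciprocal_min and on_elem >= reciprocal_min:
                key = (min(on_del, on_elem), iv.data)
                if best is None or key > best[0]:
                    best = (key, iv.data, on_del, on_elem)
        if best is None:
            continue
        _, element_id, on_del, on_elem = best
        zyg = call_zygosity(call.supporting_fraction, hemi_min, homo_min)
        if zyg == "unsupported" and not include_unsupported:
            continue
        out.append(
            ElementDeletion(
                sample_id=call.sample_id,
                element_id=element_id,
                scaffold=call.scaffold,
                start=call.start,
                end=call.end,
                zygosity=zyg,
                overlap_on_deletion=on_del,
                overlap_on_element=on_elem,
            )
        )
    return out


def deletion_density(
    assignments: Sequence[ElementDeletion],
    windows: pd.DataFrame,
    samples: Sequence[str] | None = None,
    hotspot_quantile: float = 0.95,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Per-window per-sample assignment counts, cross-sample mean, hotspots.

    ``windows`` needs columns ``window_id, scaffold, start, end``; an
    assignment falls in the window containing its start position.  Hotspots
    are windows whose mean density exceeds the given quantile of the means.
    """
    if samples is None:
        samples = sorted({a.sample_id for a in assignments})
    counts = pd.DataFrame(
        0, index=list(windows["window_id"]), columns=list(samples), dtype=int
    )
    lookup: dict[str, list[tuple[int, int, str]]] = {}
    for row in windows.itertuples(index=False):
        lookup.setdefault(row.scaffold, []).append((int(row.start), int(row.end), row.window_id))
    for a in assignments:
        for start, end, wid in lookup.get(a.scaffold, []):
            if start <= a.start < end:
                if a.sample_id in counts.columns:
                    counts.loc[wid, a.sample_id] += 1
                break
    mean = counts.mean(axis=1) if len(counts.columns) else pd.Series(0.0, index=counts.index)
    if len(mean) and mean.max() > 0:
        threshold = mean.quantile(hotspot_quantile)
        hotspots = [wid for wid, v in mean.items() if v > threshold]
    else:
        hotspots = []
    return counts, mean, hotspots


def write_density_tsv(path, counts: pd.DataFrame, mean: pd.Series) -> None:
    out = counts.copy()
    out["mean"] = mean
    out.index.name = "window_id"
    out.to_csv(path, sep="\t")
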