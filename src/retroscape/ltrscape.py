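"""Resolution of LTRs into paired, solo, nonsolo, and discarded classes.

The workflow mirrors the standard homology route: LTR sequences from
paired (complete) elements are searched against the genome (identity >= 80%
over >= 90% of the query; hits closer than 100 bp are merged); each
resulting LTR locus is tested for a similar self-copy within 30 kb of
flanking sequence (paired if found); unpaired loci are searched for a
4-7 bp target-site duplication in the 20 bp flanking each side (solo if
found, nonsolo otherwise); loci with no self-homology are discarded.

The class ratio 1 : solo/paired : nonsolo/paired summarises the excision
regime of a genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

_ENC = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


@dataclass(frozen=True)
class LTRRecord:
    ltr_id: str
    genome_id: str
    scaffold: str
    start: int
    end: int
    status: str  # paired | solo | nonsolo | discarded
    partner_ltr_id: str | None = None
    tsd: str | None = None
    element_id: str | None = None

    def __post_init__(self) -> None:
        if self.status == "paired" and self.partner_ltr_id is None:
            raise ValueError("paired LTR requires a partner")
        if self.status != "paired" and self.partner_ltr_id is not None:
            raise ValueError("only paired LTRs carry a partner")
        if self.status == "solo" and not (self.tsd and 4 <= len(self.tsd) <= 7):
            raise ValueError("solo LTR requires a 4-7 bp TSD")
        if self.status == "nonsolo" and self.tsd is not None:
            raise ValueError("nonsolo LTR must not carry a TSD")


@dataclass(frozen=True)
class LTRClassCounts:
    paired: int
    solo: int
    nonsolo: int
    discarded: int = 0

    def __post_init__(self) -> None:
        if min(self.paired, self.solo, self.nonsolo, self.discarded) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.paired + self.solo + self.nonsolo + self.discarded

    def ratios(self) -> tuple[float, float, float]:
        return class_ratios(self)


def class_ratios(counts: LTRClassCounts | tuple[int, int, int]) -> tuple[float, float, float]:
    """Normalised class ratio (1 : solo/paired : nonsolo/paired).

    Exact rational division, then round-half-even to two decimals.  The
    discarded class is excluded.  Raises ValueError when paired is zero.
    """
    if isinstance(counts, LTRClassCounts):
        paired, solo, nonsolo = counts.paired, counts.solo, counts.nonsolo
    else:
        paired, solo, nonsolo = counts
    if paired <= 0:
        raise ValueError("ratio undefined: paired LTR count is zero")

    def component(num: int) -> float:
        frac = Fraction(num, paired)
        dec = Decimal(frac.numerator) / Decimal(frac.denominator)
        return float(dec.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))

    return (1.0, component(solo), component(nonsolo))


# -- sequence search --------------------------------------------------------


class KmerIndex:
    """Sorted 2-bit k-mer index of one scaffold (numpy searchsorted lookup)."""

    def __init__(self, sequence: str, k: int = 13):
        if k > 31:
            raise ValueError("k must be <= 31")
        self.k = k
        self.length = len(sequence)
        arr = _ENC[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
        n = len(arr) - k + 1
        if n <= 0:
            self.codes = np.empty(0, dtype=np.int64)
            self.order = np.empty(0, dtype=np.int64)
            return
        codes = np.zeros(n, dtype=np.int64)
        for j in range(k):
            codes = codes * 4 + arr[j : n + j]
        self.order = np.argsort(codes, kind="stable")
        self.codes = codes[self.order]

    def positions(self, kmer_code: int) -> np.ndarray:
        lo = np.searchsorted(self.codes, kmer_code, side="left")
        hi = np.searchsorted(self.codes, kmer_code, side="right")
        return self.order[lo:hi]


def _query_codes(query: str, k: int) -> np.ndarray:
    arr = _ENC[np.frombuffer(query.encode("ascii"), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + arr[j : n + j]
    return codes


def _alignment_stats(query: str, target: str) -> tuple[float, float, tuple[int, int]] | None:
    """(identity, query_coverage, target_location) of the best infix hit."""
    if not target or not query:
        return None
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    matches = cols = q_aligned = 0
    for count, op in _iter_cigar(res["cigar"]):
        cols += count
        if op == "=":
            matches += count
            q_aligned += count
        elif op == "X":
            q_aligned += count
        # 'I' consumes query only (opposite a target gap), 'D' target only
    identity = matches / cols if cols else 0.0
    coverage = q_aligned / len(query)
    loc = res["locations"][0]
    return identity, coverage, (loc[0], loc[1] + 1)


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def find_copies_in_scaffold(
    query: str,
    scaffold_seq: str,
    index: KmerIndex,
    identity_min: float = 0.80,
    coverage_min: float = 0.90,
    seed_stride: int = 8,
) -> list[tuple[int, int, float]]:
    """Locate copies of ``query`` in one scaffold by seed-and-verify.

    Seed k-mers sampled every ``seed_stride`` positions vote for approximate
    start diagonals; diagonal clusters are verified with an infix alignment
    and kept when identity >= ``identity_min`` and query coverage >=
    ``coverage_min``.  Returns (start, end, identity) tuples.
    """
    k = index.k
    qcodes = _query_codes(query, k)
    if qcodes.size == 0:
        return []
    qlen = len(query)
    starts: list[int] = []
    for q_off in range(0, qcodes.size, seed_stride):
        for pos in index.positions(int(qcodes[q_off])):
            starts.append(int(pos) - q_off)
    if not starts:
        return []
    starts.sort()
    radius = max(50, int(0.4 * qlen))
    clusters: list[list[int]] = [[starts[0]]]
    for s in starts[1:]:
        if s - clusters[-1][-1] <= radius:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    margin = max(32, int(0.2 * qlen))
    hits: list[tuple[int, int, float]] = []
    for cl in clusters:
        centre = cl[len(cl) // 2]
        lo = max(0, centre - margin)
        hi = min(index.length, centre + qlen + margin)
        stats = _alignment_stats(query, scaffold_seq[lo:hi])
        if stats is None:
            continue
        identity, coverage, (t0, t1) = stats
        if identity >= identity_min and coverage >= coverage_min:
            hits.append((lo + t0, lo + t1, identity))
    return hits


def merge_close_hits(
    hits: Sequence[tuple[int, int, float]], merge_gap: int = 100
) -> list[tuple[int, int, float]]:
    """Merge hits whose gap is strictly smaller than ``merge_gap`` bp."""
    merged: list[list] = []
    for start, end, ident in sorted(hits):
        if merged and start - merged[-1][1] < merge_gap:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2] = max(merged[-1][2], ident)
        else:
            merged.append([start, end, ident])
    return [tuple(m) for m in merged]


def find_ltr_copies(
    ltr_queries: Mapping[str, str],
    genome: Mapping[str, str],
    identity_min: float = 0.80,
    coverage_min: float = 0.90,
    merge_gap: int = 100,
    indexes: Mapping[str, KmerIndex] | None = None,
) -> pd.DataFrame:
    """Genome-wide LTR copy search for a set of query LTR sequences.

    Returns a frame with columns ``query_id, scaffold, start, end,
    identity``; per-query hits on a scaffold closer than ``merge_gap`` bp
    are merged.  An empty query set yields an empty frame.
    """
    if indexes is None:
        indexes = {name: KmerIndex(seq) for name, seq in genome.items()}
    rows = []
    for qid in sorted(ltr_queries):
        query = ltr_queries[qid]
        for scaffold in sorted(genome):
            raw = find_copies_in_scaffold(
                query, genome[scaffold], indexes[scaffold], identity_min, coverage_min
            )
            for start, end, ident in merge_close_hits(raw, merge_gap):
                rows.append(
                    {
                        "query_id": qid,
                        "scaffold": scaffold,
                        "start": start,
                        "end": end,
                        "identity": ident,
                    }
                )
    return pd.DataFrame(rows, columns=["query_id", "scaffold", "start", "end", "identity"])


def collapse_loci(hits: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-query hits into distinct genomic LTR loci.

    Hits from different queries overlapping by >= 1 bp describe the same
    locus and are unioned.  Returns ``locus_id, scaffold, start, end``
    sorted by position.
    """
    rows = []
    for scaffold, sub in hits.groupby("scaffold", sort=True):
        merged: list[list[int]] = []
        for start, end in sorted(zip(sub["start"], sub["end"])):
            if merged and start < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        rows.extend({"scaffold": scaffold, "start": s, "end": e} for s, e in merged)
    rows.sort(key=lambda r: (r["scaffold"], r["start"]))
    for i, r in enumerate(rows):
        r["locus_id"] = f"L{i + 1:05d}"
    return pd.DataFrame(rows, columns=["locus_id", "scaffold", "start", "end"])


# -- classification ---------------------------------------------------------


def classify_paired(
    genome: Mapping[str, str],
    scaffold: str,
    start: int,
    end: int,
    flank_bp: int = 30_000,
    self_coverage_min: float = 0.90,
    identity_min: float = 0.80,
) -> tuple[str, tuple[int, int] | None]:
    """Test whether an LTR has a similar self-copy within its flanks.

    Returns ("paired", partner_interval) when a copy with identity >=
    ``identity_min`` covering >= ``self_coverage_min`` of the LTR lies
    within ``flank_bp`` on either side, else ("unpaired", None).  Flanks are
    silently clipped at scaffold edges.
    """
    seq = genome[scaffold]
    ltr = seq[start:end]
    left = seq[max(0, start - flank_bp) : start]
    right = seq[end : end + flank_bp]
    for flank, offset in ((left, max(0, start - flank_bp)), (right, end)):
        stats = _alignment_stats(ltr, flank)
        if stats is None:
            continue
        identity, coverage, (t0, t1) = stats
        if identity >= identity_min and coverage >= self_coverage_min:
            return "paired", (offset + t0, offset + t1)
    return "unpaired", None


def detect_tsd_in_flanks(
    left_flank: str, right_flank: str, k_min: int = 4, k_max: int = 7
) -> str | None:
    """Longest k-mer (k_max..k_min) present in both flanks; ties resolved by
    the leftmost occurrence in the 5' flank."""
    left_flank, right_flank = left_flank.upper(), right_flank.upper()
    for k in range(k_max, k_min - 1, -1):
        if len(left_flank) < k or len(right_flank) < k:
            continue
        right_kmers = {right_flank[i : i + k] for i in range(len(right_flank) - k + 1)}
        for i in range(len(left_flank) - k + 1):
            kmer = left_flank[i : i + k]
            if kmer in right_kmers:
                return kmer
    return None


def detect_tsd(
    genome: Mapping[str, str],
    scaffold: str,
    start: int,
    end: int,
    flank: int = 20,
    k_min: int = 4,
    k_max: int = 7,
) -> str | None:
    """TSD search in the ``flank`` bp on each side of an LTR interval."""
    seq = genome[scaffold]
    if start < 0 or end > len(seq) or end <= start:
        raise ValueError(f"interval {scaffold}:{start}-{end} outside scaffold")
    left = seq[max(0, start - flank) : start]
    right = seq[end : end + flank]
    return detect_tsd_in_flanks(left, right, k_min, k_max)


def has_self_homology(seq: str, min_length: int = 50, max_base_fraction: float = 0.8) -> bool:
    """Crude self-homology screen: very short or near-homopolymeric LTR
    candidates align to nothing meaningful and are discarded."""
    if len(seq) < min_length:
        return False
    seq = seq.upper()
    top = max(seq.count(b) for b in "ACGT")
    return top / len(seq) < max_base_fraction


def classify_unpaired(has_homology: bool, tsd: str | None) -> str:
    """solo (TSD found), nonsolo (no TSD), or discarded (no self-homology)."""
    if not has_homology:
        return "discarded"
    return "solo" if tsd else "nonsolo"


def classify_loci(
    genome: Mapping[str, str],
    loci: pd.DataFrame,
    genome_id: str = "",
    flank_bp: int = 30_000,
    self_coverage_min: float = 0.90,
    identity_min: float = 0.80,
    tsd_flank: int = 20,
) -> list[LTRRecord]:
    """Assign every locus (``locus_id, scaffold, start, end``) one status."""
    interim = []
    for row in loci.itertuples(index=False):
        status, partner_iv = classify_paired(
            genome, row.scaffold, int(row.start), int(row.end),
            flank_bp, self_coverage_min, identity_min,
        )
        interim.append((row, status, partner_iv))

    # resolve partner intervals to locus ids by overlap
    by_scaffold: dict[str, list[tuple[int, int, str]]] = {}
    for row in loci.itertuples(index=False):
        by_scaffold.setdefault(row.scaffold, []).append(
            (int(row.start), int(row.end), row.locus_id)
        )

    def locate(scaffold: str, iv: tuple[int, int]) -> str | None:
        best, best_ov = None, 0
        for s, e, lid in by_scaffold.get(scaffold, []):
            ov = min(e, iv[1]) - max(s, iv[0])
            if ov > best_ov:
                best, best_ov = lid, ov
        return best

    records: list[LTRRecord] = []
    for row, status, partner_iv in interim:
        start, end = int(row.start), int(row.end)
        seq = genome[row.scaffold][start:end]
        if status == "paired":
            partner = locate(row.scaffold, partner_iv) or (
                f"{row.scaffold}:{partner_iv[0]}-{partner_iv[1]}"
            )
            records.append(
                LTRRecord(row.locus_id, genome_id, row.scaffold, start, end,
                          "paired", partner_ltr_id=partner)
            )
            continue
        homology = has_self_homology(seq)
        tsd = detect_tsd(genome, row.scaffold, start, end, tsd_flank) if homology else None
        cls = classify_unpaired(homology, tsd)
        records.append(
            LTRRecord(
                row.locus_id, genome_id, row.scaffold, start, end, cls,
                tsd=tsd if cls == "solo" else None,
            )
        )
    return records


def count_classes(records: Iterable[LTRRecord]) -> LTRClassCounts:
    tally = {"paired": 0, "solo": 0, "nonsolo": 0, "discarded": 0}
    for r in records:
        tally[r.status] += 1
    return LTRClassCounts(**tally)


def write_class_beds(outdir: str | Path, records: Iterable[LTRRecord]) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_status: dict[str, list[LTRRecord]] = {}
    for r in records:
        by_status.setdefault(r.status, []).append(r)
    paths = {}
    for status, recs in sorted(by_status.items()):
        path = outdir / f"ltr_{status}.bed"
        lines = [
            f"{r.scaffold}\t{r.start}\t{r.end}\t{r.ltr_id}"
            for r in sorted(recs, key=lambda r: (r.scaffold, r.start))
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        paths[status] = path
    return paths
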