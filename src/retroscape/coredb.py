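"""Validation and propagation of LTR-retrotransposon cores.

A candidate core is accepted when, after an e-value filter, it carries
exactly one copy of each of the three retroelement domains (integrase IN,
reverse transcriptase RT, RNase H RH).  The strand-normalised left-to-right
domain order assigns the superfamily: IN-RT-RH is Copia, RT-RH-IN is Gypsy.
Validated cores are then propagated to other genomes through tabular
homology hits filtered on query coverage and e-value, with overlapping hits
merged per scaffold and strand.

Coordinates are 0-based half-open internally; the 12-column tabular hit
dialect (1-based inclusive) is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .simgenome import HIT_COLUMNS

DOMAINS = ("IN", "RT", "RH")
COPIA_ORDER = ("IN", "RT", "RH")
GYPSY_ORDER = ("RT", "RH", "IN")

LINEAGES = (
    "Tork", "SIRE", "Oryco", "Retrofit",
    "Tat", "Athila", "Galadriel", "Del", "CRM", "Reina",
)


@dataclass(frozen=True)
class DomainHit:
    query_id: str
    domain: str  # IN | RT | RH
    start: int  # on query, 0-based half-open
    end: int
    strand: str  # '+' | '-'
    evalue: float
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.end <= self.start:
            raise ValueError("empty domain interval")


@dataclass(frozen=True)
class RetroCore:
    core_id: str
    genome_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    superfamily: str  # Copia | Gypsy | unclassified
    lineage: str = "unassigned"
    family_id: str | None = None
    reason: str | None = None  # set when superfamily is unclassified


@dataclass(frozen=True)
class Rejection:
    candidate_id: str
    reason: str


def read_hits_tsv(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tabular homology-hit file (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)
    return df


def domain_hits_from_table(df: pd.DataFrame) -> dict[str, list[DomainHit]]:
    """Group a tabular hit file into per-candidate :class:`DomainHit` lists.

    The domain is parsed from the subject id, which must contain one of
    IN/RT/RH as an underscore-separated token (e.g. ``GyDB_RT_Tork``).
    """
    out: dict[str, list[DomainHit]] = {}
    for row in df.itertuples(index=False):
        tokens = str(row.subject).split("_")
        domain = next((t for t in tokens if t in DOMAINS), None)
        if domain is None:
            raise ValueError(f"cannot parse domain from subject {row.subject!r}")
        qstart, qend = int(row.qstart), int(row.qend)
        strand = "+" if qstart <= qend else "-"
        lo, hi = (qstart, qend) if strand == "+" else (qend, qstart)
        out.setdefault(str(row.query), []).append(
            DomainHit(
                query_id=str(row.query),
                domain=domain,
                start=lo - 1,
                end=hi,
                strand=strand,
                evalue=float(row.evalue),
                identity=float(row.pident) / 100.0,
            )
        )
    return out


def validate_core(
    candidate_id: str,
    hits: Sequence[DomainHit],
    evalue_max: float = 1e-20,
    require_domains: Sequence[str] = DOMAINS,
    genome_id: str = "",
    scaffold: str = "",
) -> RetroCore | Rejection:
    """Accept a candidate iff it has exactly one good hit per required domain.

    Hits at or above ``evalue_max`` are discarded first.  Candidates with a
    missing domain or a duplicated domain are rejected with a reason code;
    mixed-strand domain sets and unknown orders yield an accepted core with
    superfamily ``unclassified`` and a reason code.
    """
    if any(h.query_id != candidate_id for h in hits):
        raise ValueError("hits must all belong to the candidate")
    kept = [h for h in hits if h.evalue < evalue_max]
    if not kept:
        return Rejection(candidate_id, "no_domains")
    by_domain: dict[str, list[DomainHit]] = {}
    for h in kept:
        by_domain.setdefault(h.domain, []).append(h)
    for dom in require_domains:
        if dom not in by_domain:
            return Rejection(candidate_id, f"missing_domain:{dom}")
        if len(by_domain[dom]) > 1:
            return Rejection(candidate_id, f"duplicated_domain:{dom}")
    chosen = sorted((by_domain[dom][0] for dom in require_domains), key=lambda h: h.start)
    strands = {h.strand for h in chosen}
    span = (min(h.start for h in chosen), max(h.end for h in chosen))
    if len(strands) > 1:
        return RetroCore(
            candidate_id, genome_id, scaffold, span[0], span[1], ".",
            "unclassified", reason="mixed_strand",
        )
    strand = strands.pop()
    order = tuple(h.domain for h in chosen)
    if strand == "-":  # read right-to-left on the minus strand
        order = tuple(reversed(order))
    if order == COPIA_ORDER:
        superfamily = "Copia"
        reason = None
    elif order == GYPSY_ORDER:
        superfamily = "Gypsy"
        reason = None
    else:
        superfamily = "unclassified"
        reason = "ambiguous_order"
    return RetroCore(
        candidate_id, genome_id, scaffold, span[0], span[1], strand,
        superfamily, reason=reason,
    )


def validate_cores(
    candidates: Mapping[str, Sequence[DomainHit]],
    evalue_max: float = 1e-20,
    genome_id: str = "",
) -> tuple[list[RetroCore], list[Rejection]]:
    accepted: list[RetroCore] = []
    rejected: list[Rejection] = []
    for cid in sorted(candidates):
        res = validate_core(cid, candidates[cid], evalue_max, genome_id=genome_id)
        (accepted if isinstance(res, RetroCore) else rejected).append(res)
    return accepted, rejected


def _merge_intervals(
    intervals: list[tuple[int, int, str]]
) -> list[tuple[int, int, set[str]]]:
    """Merge intervals overlapping by >=1 bp; carries the query-id sets."""
    merged: list[tuple[int, int, set[str]]] = []
    for start, end, query in sorted(intervals):
        if merged and start < merged[-1][1]:
            last = merged[-1]
            merged[-1] = (last[0], max(last[1], end), last[2] | {query})
        else:
            merged.append((start, end, {query}))
    return merged


def propagate_cores(
    core_queries: Mapping[str, tuple[int, str]],
    genome_hits: pd.DataFrame,
    coverage_min: float = 0.80,
    evalue_max: float = 1e-25,
    genome_id: str = "",
    scaffold_lengths: Mapping[str, int] | None = None,
) -> list[RetroCore]:
    """Propagate validated cores to a genome through tabular homology hits.

    ``core_queries`` maps query id -> (query length, superfamily).  Hits
    with query coverage >= ``coverage_min`` and e-value < ``evalue_max``
    survive; surviving hits overlapping on the same scaffold and strand are
    merged into one core, which inherits the superfamily of its queries
    (``unclassified`` if merged queries disagree).
    """
    buckets: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for row in genome_hits.itertuples(index=False):
        query = str(row.query)
        if query not in core_queries:
            raise KeyError(f"hit references unknown query {query!r}")
        qlen, _ = core_queries[query]
        coverage = (abs(int(row.qend) - int(row.qstart)) + 1) / qlen
        if coverage < coverage_min or float(row.evalue) >= evalue_max:
            continue
        sstart, send = int(row.sstart), int(row.send)
        strand = "+" if sstart <= send else "-"
        lo, hi = (sstart, send) if strand == "+" else (send, sstart)
        start, end = lo - 1, hi
        scaffold = str(row.subject)
        if scaffold_lengths is not None:
            limit = scaffold_lengths.get(scaffold)
            if limit is None or start < 0 or end > limit:
                raise ValueError(
                    f"hit {query} -> {scaffold}:{start}-{end} outside scaffold bounds"
                )
        buckets.setdefault((scaffold, strand), []).append((start, end, query))

    cores: list[RetroCore] = []
    for (scaffold, strand) in sorted(buckets):
        for start, end, queries in _merge_intervals(buckets[(scaffold, strand)]):
            superfamilies = {core_queries[q][1] for q in queries}
            superfamily = superfamilies.pop() if len(superfamilies) == 1 else "unclassified"
            cores.append(
                RetroCore(
                    core_id=f"{genome_id or 'genome'}:{scaffold}:{start}-{end}:{strand}",
                    genome_id=genome_id,
                    scaffold=scaffold,
                    start=start,
                    end=end,
                    strand=strand,
                    superfamily=superfamily,
                    reason=None if superfamily != "unclassified" else "mixed_query_superfamily",
                )
            )
    return cores


def write_cores_gff3(path: str | Path, cores: Iterable[RetroCore]) -> None:
    lines = ["##gff-version 3"]
    for c in sorted(cores, key=lambda c: (c.scaffold, c.start)):
        attrs = f"ID={c.core_id};superfamily={c.superfamily};lineage={c.lineage}"
        if c.family_id:
            attrs += f";family={c.family_id}"
        lines.append(
            f"{c.scaffold}\tretroscape\tretrotransposon_core\t{c.start + 1}\t{c.end}"
            f"\t.\t{c.strand}\t.\t{attrs}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
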