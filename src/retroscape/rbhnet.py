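"""Reciprocal-best-hit relatedness network of unpaired LTRs.

Each unpaired LTR is queried against the full LTR collection (paired and
unpaired, self excluded).  A hit qualifies at >= 90% identity over >= 90%
of the query; the top-scoring qualifying hit is the best hit.  Only mutual
pairs (A's best is B and B's best is A) become edges, and edges are
aggregated into a symmetric genome-pair weight matrix whose diagonal counts
within-genome ("self-loop") edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import edlib
import pandas as pd


@dataclass(frozen=True)
class RBHEdge:
    ltr_a: str
    ltr_b: str
    genome_a: str
    genome_b: str
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        if self.ltr_a == self.ltr_b:
            raise ValueError("self edges are not allowed")


def _pair_stats(query: str, subject: str) -> tuple[float, float, int]:
    """(identity, query_coverage, score) of a global alignment."""
    res = edlib.align(query, subject, mode="NW", task="path")
    matches = cols = q_aligned = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        count = int(num)
        num = ""
        cols += count
        if ch == "=":
            matches += count
            q_aligned += count
        elif ch == "X":
            q_aligned += count
    identity = matches / cols if cols else 0.0
    coverage = q_aligned / len(query) if query else 0.0
    return identity, coverage, matches


def best_hits(
    queries: Mapping[str, str],
    database: Mapping[str, str],
    identity_min: float = 0.90,
    coverage_min: float = 0.90,
) -> dict[str, tuple[str, float, float, int]]:
    """Best qualifying database hit per query.

    Returns ``query_id -> (subject_id, identity, coverage, score)``; the
    score is the number of matching columns.  Ties break to the higher
    identity, then the lexicographically smaller subject id.  Queries with
    no qualifying hit are absent from the map.
    """
    out: dict[str, tuple[str, float, float, int]] = {}
    for qid in sorted(queries):
        best: tuple[int, float, str] | None = None  # (score, identity, subject)
        best_stats: tuple[str, float, float, int] | None = None
        for sid in sorted(database):
            if sid == qid:
                continue
            identity, coverage, score = _pair_stats(queries[qid], database[sid])
            if identity < identity_min or coverage < coverage_min:
                continue
            key = (score, identity, _NegStr(sid))
            if best is None or key > best:
                best = key
                best_stats = (sid, identity, coverage, score)
        if best_stats is not None:
            out[qid] = best_stats
    return out


class _NegStr(str):
    """Orders strings descending inside a max-compared tuple."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def reciprocal_network(
    best_map: Mapping[str, tuple[str, float, float, int]],
    genome_of: Mapping[str, str],
    genomes: list[str] | None = None,
) -> tuple[list[RBHEdge], pd.DataFrame]:
    """Mutual-pair edges and the genome-pair weight matrix.

    The matrix is symmetric; within-genome edges sit on the diagonal.
    """
    edges: list[RBHEdge] = []
    for a in sorted(best_map):
        b, identity, coverage, _ = best_map[a]
        if a < b and b in best_map and best_map[b][0] == a:
            edges.append(
                RBHEdge(a, b, genome_of[a], genome_of[b], identity, coverage)
            )
    if genomes is None:
        genomes = sorted(set(genome_of.values()))
    matrix = pd.DataFrame(0, index=genomes, columns=genomes, dtype=int)
    for e in edges:
        ga, gb = sorted((e.genome_a, e.genome_b))
        matrix.loc[ga, gb] += 1
        if ga != gb:
            matrix.loc[gb, ga] += 1
    return edges, matrix


def self_loop_fraction(matrix: pd.DataFrame, genome: str) -> float:
    """Fraction of a genome's edges whose partner is the same genome."""
    total = int(matrix.loc[genome].sum())
    if total == 0:
        raise ValueError(f"genome {genome!r} has no edges")
    return int(matrix.loc[genome, genome]) / total


def write_edges_tsv(path, edges: list[RBHEdge]) -> None:
    pd.DataFrame(
        [
            {
                "ltr_a": e.ltr_a,
                "ltr_b": e.ltr_b,
                "genome_a": e.genome_a,
                "genome_b": e.genome_b,
                "identity": e.identity,
                "coverage": e.coverage,
            }
            for e in edges
        ]
    ).to_csv(path, sep="\t", index=False)
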