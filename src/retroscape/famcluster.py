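"""Family clustering of retrotransposon cores and clade presence analysis.

Two cores belong to the same family when they share at least 80% identity
over at least 80% of the shorter sequence with a minimum of 80 aligned bp
(the 80/80/80 criterion).  Families are the connected components of the
qualifying-pair graph (deterministic single linkage), clustered per genome,
and named Wicker-style by superfamily plus an ordinal assigned from the
genomic position of the family representative (its longest member; ties go
to the lexicographically smallest core id).

Family gains and losses across genomes are read off a supplied phylogeny of
family representatives: every internal clade with more than ``min_size``
family tips is checked for genomes with no representative inside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .coredb import RetroCore


@dataclass(frozen=True)
class Family:
    family_id: str
    genome_id: str
    member_ids: tuple[str, ...]
    representative_id: str

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member")


@dataclass(frozen=True)
class CladeReport:
    clade_id: str
    families: tuple[str, ...]
    present: frozenset[str]
    missing: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.families)


def pair_qualifies(
    identity: float,
    aligned_length: int,
    len_a: int,
    len_b: int,
    identity_min: float = 0.80,
    length_frac_min: float = 0.80,
    overlap_min_bp: int = 80,
) -> bool:
    """The 80/80/80 linkage predicate, measured on the shorter sequence."""
    shorter = min(len_a, len_b)
    return (
        identity >= identity_min
        and aligned_length >= length_frac_min * shorter
        and aligned_length >= overlap_min_bp
    )


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def pairwise_identities(sequences: Mapping[str, str]) -> pd.DataFrame:
    """All-vs-all global identities via edlib (small synthetic core sets).

    Returns columns ``core_a, core_b, identity, aligned_length`` where the
    identity is matches over alignment columns.
    """
    import edlib

    ids = sorted(sequences)
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            res = edlib.align(sequences[a], sequences[b], task="path", mode="NW")
            cols = matches = 0
            for count, op in _cigar_ops(res["cigar"]):
                cols += count
                if op == "=":
                    matches += count
            rows.append(
                {
                    "core_a": a,
                    "core_b": b,
                    "identity": matches / cols if cols else 0.0,
                    "aligned_length": matches + sum(
                        c for c, op in _cigar_ops(res["cigar"]) if op == "X"
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["core_a", "core_b", "identity", "aligned_length"])


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops


def cluster_families(
    cores: Sequence[RetroCore],
    pairwise: pd.DataFrame,
    core_lengths: Mapping[str, int] | None = None,
    identity_min: float = 0.80,
    length_frac_min: float = 0.80,
    overlap_min_bp: int = 80,
) -> list[Family]:
    """Single-linkage 80/80/80 clustering, independently per genome.

    ``pairwise`` needs columns ``core_a, core_b, identity, aligned_length``.
    Core lengths default to the genomic interval length of each core.
    """
    by_id = {c.core_id: c for c in cores}
    if core_lengths is None:
        core_lengths = {c.core_id: c.end - c.start for c in cores}
    uf = _UnionFind(by_id)
    for row in pairwise.itertuples(index=False):
        a, b = str(row.core_a), str(row.core_b)
        if a not in by_id or b not in by_id:
            raise KeyError(f"identity record references unknown core: {a!r}/{b!r}")
        if by_id[a].genome_id != by_id[b].genome_id:
            continue  # clustering is per genome
        if pair_qualifies(
            float(row.identity), int(row.aligned_length),
            core_lengths[a], core_lengths[b],
            identity_min, length_frac_min, overlap_min_bp,
        ):
            uf.union(a, b)

    components: dict[str, list[str]] = {}
    for cid in by_id:
        components.setdefault(uf.find(cid), []).append(cid)

    def representative(members: list[str]) -> str:
        return min(members, key=lambda m: (-core_lengths[m], m))

    # deterministic numbering by (genome, superfamily, representative position)
    pre = []
    for members in components.values():
        rep = representative(members)
        core = by_id[rep]
        pre.append((core.genome_id, core.superfamily, core.scaffold, core.start, rep, members))
    pre.sort(key=lambda t: t[:5])

    counters: dict[tuple[str, str], int] = {}
    families = []
    for genome_id, superfamily, _, _, rep, members in pre:
        key = (genome_id, superfamily)
        counters[key] = counters.get(key, 0) + 1
        families.append(
            Family(
                family_id=f"{superfamily}_{counters[key]}",
                genome_id=genome_id,
                member_ids=tuple(sorted(members)),
                representative_id=rep,
            )
        )
    return families


def write_family_table(path: str | Path, families: Iterable[Family]) -> None:
    pd.DataFrame(
        [
            {
                "family_id": f.family_id,
                "genome": f.genome_id,
                "members": ",".join(f.member_ids),
                "representative": f.representative_id,
            }
            for f in families
        ]
    ).to_csv(path, sep="\t", index=False)


def find_missing_genome_clades(
    tree: str | dendropy.Tree,
    family_to_genome: Mapping[str, str],
    genomes: Sequence[str] | None = None,
    min_size: int = 20,
    reference_tips: Iterable[str] = (),
) -> list[CladeReport]:
    """Report internal clades (> ``min_size`` family tips) missing genomes.

    ``tree`` is a Newick string, a path, or a dendropy Tree whose tips are
    family representatives; ``family_to_genome`` maps tip label -> genome.
    Tips listed in ``reference_tips`` (curated database sequences) are
    ignored.  Unmapped tips raise a ValueError listing the names.
    """
    if isinstance(tree, dendropy.Tree):
        t = tree
    elif str(tree).lstrip().startswith("("):
        t = dendropy.Tree.get(data=str(tree), schema="newick", preserve_underscores=True)
    else:
        t = dendropy.Tree.get(path=str(tree), schema="newick", preserve_underscores=True)
    refs = set(reference_tips)
    universe = set(genomes) if genomes is not None else set(family_to_genome.values())

    labels = [leaf.taxon.label for leaf in t.leaf_node_iter()]
    unmapped = sorted(l for l in labels if l not in family_to_genome and l not in refs)
    if unmapped:
        raise ValueError(f"tree tips not mapped to a genome: {', '.join(unmapped)}")

    reports: list[CladeReport] = []
    counter = 0
    for node in t.preorder_internal_node_iter():
        tips = [leaf.taxon.label for leaf in node.leaf_iter()]
        fam_tips = [l for l in tips if l not in refs]
        if len(fam_tips) <= min_size:
            continue
        present = frozenset(family_to_genome[l] for l in fam_tips)
        missing = frozenset(universe - present)
        counter += 1
        if missing:
            reports.append(
                CladeReport(
                    clade_id=f"clade_{counter}",
                    families=tuple(sorted(fam_tips)),
                    present=present,
                    missing=missing,
                )
            )
    return reports
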