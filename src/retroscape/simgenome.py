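"""Ground-truth genome simulator for the LTR-retrotransposon pipeline.

Emulates the input universe of a genus-wide retrotransposon survey: genomes
with genes and LTR elements inserted at known K2P ages, flanked by target
site duplications (TSDs); solo-LTR excision products (one LTR, TSDs kept);
illegitimate-recombination truncations (one LTR, no TSDs); and deletion
calls over complete elements with specified read-support fractions.

Every stochastic draw flows from a single :class:`numpy.random.Generator`
seeded from ``SimulationConfig.seed``, so a fixed seed gives byte-identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: transition partner per base index (A<->G, C<->T)
TRANSITION = np.array([2, 3, 0, 1], dtype=np.int8)
#: the two transversion partners per base index
TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.int8)

COPIA_LINEAGES = ("Tork", "SIRE", "Oryco", "Retrofit")
GYPSY_LINEAGES = ("Tat", "Athila", "Galadriel", "Del", "CRM", "Reina")

HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatches", "gaps",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class PlacementError(RuntimeError):
    """Could not place an interval after bounded retries."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic genome.

    Defaults emulate a compact plant genome carrying a realistic mix of
    complete, solo-excised, and truncated LTR retrotransposons: element
    cores average ~2.6 kb, LTRs span 0.2-2 kb, TSDs are 4-7 bp, and
    insertion ages cover the recent-to-old K2P range seen in citrus-sized
    surveys.
    """

    seed: int = 0
    scaffold_lengths: tuple[int, ...] = (2_000_000, 1_500_000, 1_000_000, 500_000)
    gc_content: float = 0.38
    n_genes: int = 400
    gene_length_range: tuple[int, int] = (1_000, 6_000)
    n_elements: int = 300
    ltr_length_range: tuple[int, int] = (200, 2_000)
    core_length_mean: int = 2_590
    core_length_sd: int = 300
    element_ages: tuple[float, ...] = (0.0, 0.02, 0.06, 0.12)
    transition_fraction: float = 0.5
    solo_fraction: float = 0.45
    nonsolo_fraction: float = 0.20
    tsd_length_choices: tuple[int, ...] = (4, 5, 6, 7)
    deletion_samples: int = 10
    deletion_support_fractions: tuple[float, ...] = (0.1, 0.25, 0.5, 0.9, 1.0)
    n_families: int = 12
    intra_family_divergence: float = 0.02
    # same-family elements are kept farther apart than the pairing flank so
    # that planted paired/solo/nonsolo labels remain well defined
    family_min_gap: int = 32_000
    edge_margin: int = 100
    allow_nesting: bool = False
    spatial_structure: bool = False
    deletion_element_fraction: float = 0.5
    deletion_presence_prob: float = 0.5
    placement_retries: int = 500

    @property
    def n_scaffolds(self) -> int:
        return len(self.scaffold_lengths)

    def validate(self) -> None:
        if self.solo_fraction < 0 or self.nonsolo_fraction < 0:
            raise ValueError("class fractions must be non-negative")
        if self.solo_fraction + self.nonsolo_fraction > 1:
            raise ValueError("solo_fraction + nonsolo_fraction must be <= 1")
        if not self.scaffold_lengths or min(self.scaffold_lengths) <= 0:
            raise ValueError("scaffold lengths must be positive")
        for lo, hi in (self.gene_length_range, self.ltr_length_range):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")
        if any(a < 0 or a > 0.3 for a in self.element_ages):
            raise ValueError("element ages must lie in [0, 0.3]")
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must be a fraction")
        if not all(4 <= k <= 7 for k in self.tsd_length_choices):
            raise ValueError("TSD lengths must be in 4..7")
        if not 0 < self.transition_fraction < 1:
            raise ValueError("transition_fraction must be in (0,1)")
        if any(not 0 <= f <= 1 for f in self.deletion_support_fractions):
            raise ValueError("support fractions must be fractions")


@dataclass(frozen=True)
class GroundTruthRecord:
    """One planted element; intervals are 0-based half-open, TSDs excluded."""

    element_id: str
    scaffold: str
    start: int
    end: int
    true_age: float
    status: str  # complete | solo | nonsolo
    tsd_sequence: str  # empty for nonsolo
    superfamily: str
    lineage: str
    family_id: str

    def __post_init__(self) -> None:
        if self.status == "solo" and not self.tsd_sequence:
            raise ValueError("solo record requires a TSD sequence")
        if self.status == "nonsolo" and self.tsd_sequence:
            raise ValueError("nonsolo record must not carry a TSD")


@dataclass(frozen=True)
class ElementDetail:
    """Genomic layout of one planted element (internal bookkeeping)."""

    element_id: str
    scaffold: str
    ltr_a: tuple[int, int]
    ltr_b: tuple[int, int] | None  # None for solo / nonsolo
    core: tuple[int, int] | None


def k2p_site_probabilities(distance: float, transition_fraction: float) -> tuple[float, float]:
    """Per-site transition (P) and transversion (Q) probabilities after
    evolving a branch of the given K2P length.

    The instantaneous rates are normalised so one unit of distance equals
    one expected substitution per site, split so that ``transition_fraction``
    of substitutions are transitions.
    """
    alpha = transition_fraction
    beta = (1.0 - transition_fraction) / 2.0
    e1 = math.exp(-4.0 * beta * distance)
    e2 = math.exp(-2.0 * (alpha + beta) * distance)
    P = 0.25 + 0.25 * e1 - 0.5 * e2
    Q = 0.5 - 0.5 * e1
    return P, Q


def _evolve_codes(
    codes: np.ndarray, distance: float, transition_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    if distance == 0:
        return codes.copy()
    P, Q = k2p_site_probabilities(distance, transition_fraction)
    u = rng.random(codes.size)
    out = codes.copy()
    ts = u < P
    tv = (u >= P) & (u < P + Q)
    out[ts] = TRANSITION[codes[ts]]
    which = rng.integers(0, 2, size=int(tv.sum()))
    out[tv] = TRANSVERSIONS[codes[tv], which]
    return out


def evolve_k2p(
    sequence: str,
    distance: float,
    transition_fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> str:
    """Evolve a sequence along one branch of K2P length ``distance``.

    Sites mutate independently with the exact K2P substitution matrix, so
    the process composes correctly across branches: the two LTRs of an
    element aged ``d`` are each evolved ``d/2`` from their ancestor and the
    measured pairwise distance is ``d`` in expectation.  No indels are
    introduced.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = encode(sequence)
    if np.any(codes < 0):
        raise ValueError("sequence must be over {A,C,G,T}")
    return decode(_evolve_codes(codes, distance, transition_fraction, rng))


def encode(sequence: str) -> np.ndarray:
    table = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode("ascii")


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.int8)


@dataclass
class SimulatedGenome:
    """In-memory result of :func:`simulate_genome` plus file writers."""

    config: SimulationConfig
    scaffolds: dict[str, str]
    genes: list[tuple[str, int, int, str]]  # (scaffold, start, end, gene_id)
    truth: list[GroundTruthRecord]
    details: dict[str, ElementDetail]
    domain_hits: pd.DataFrame
    core_hits: pd.DataFrame
    deletion_truth: pd.DataFrame  # element_id, sample, support_fraction
    vcf_text: str

    # -- convenience accessors -------------------------------------------
    def sequence(self, scaffold: str, start: int, end: int) -> str:
        return self.scaffolds[scaffold][start:end]

    def ltr_loci(self) -> list[dict]:
        """All planted LTR loci (two per complete element, one otherwise)."""
        loci = []
        for rec in self.truth:
            det = self.details[rec.element_id]
            loci.append(
                {
                    "locus_id": f"{rec.element_id}_L1",
                    "element_id": rec.element_id,
                    "scaffold": rec.scaffold,
                    "start": det.ltr_a[0],
                    "end": det.ltr_a[1],
                    "status": "paired" if rec.status == "complete" else rec.status,
                }
            )
            if det.ltr_b is not None:
                loci.append(
                    {
                        "locus_id": f"{rec.element_id}_L2",
                        "element_id": rec.element_id,
                        "scaffold": rec.scaffold,
                        "start": det.ltr_b[0],
                        "end": det.ltr_b[1],
                        "status": "paired",
                    }
                )
        return loci

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "element_id": r.element_id,
                    "scaffold": r.scaffold,
                    "start": r.start,
                    "end": r.end,
                    "true_age": r.true_age,
                    "status": r.status,
                    "tsd_sequence": r.tsd_sequence,
                    "superfamily": r.superfamily,
                    "lineage": r.lineage,
                    "family_id": r.family_id,
                }
                for r in self.truth
            ],
            columns=[
                "element_id", "scaffold", "start", "end", "true_age", "status",
                "tsd_sequence", "superfamily", "lineage", "family_id",
            ],
        )

    # -- writers ---------------------------------------------------------
    def write_all(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "genes": outdir / "genes.gff3",
            "truth": outdir / "truth.tsv",
            "truth_gff": outdir / "truth.gff3",
            "domain_hits": outdir / "domain_hits.tsv",
            "core_hits": outdir / "core_hits.tsv",
            "deletions": outdir / "deletions.vcf",
        }
        self.write_fasta(paths["fasta"])
        self.write_genes_gff3(paths["genes"])
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        self.write_truth_gff3(paths["truth_gff"])
        self.domain_hits.to_csv(paths["domain_hits"], sep="\t", index=False, header=False)
        self.core_hits.to_csv(paths["core_hits"], sep="\t", index=False, header=False)
        paths["deletions"].write_text(self.vcf_text)
        return paths

    def write_fasta(self, path: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.scaffolds.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_genes_gff3(self, path: str | Path) -> None:
        lines = ["##gff-version 3"]
        for scaffold, start, end, gene_id in self.genes:
            lines.append(
                f"{scaffold}\tretroscape\tgene\t{start + 1}\t{end}\t.\t+\t.\tID={gene_id}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def write_truth_gff3(self, path: str | Path) -> None:
        lines = ["##gff-version 3"]
        for r in self.truth:
            attrs = (
                f"ID={r.element_id};status={r.status};superfamily={r.superfamily};"
                f"lineage={r.lineage};family={r.family_id};age={r.true_age:g}"
            )
            lines.append(
                f"{r.scaffold}\tretroscape\tLTR_retrotransposon\t{r.start + 1}\t{r.end}"
                f"\t.\t+\t.\t{attrs}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------


def _weight(pos: int, length: int, kind: str) -> float:
    """Spatial acceptance weight: a gene-poor, element-rich middle third."""
    in_valley = length / 3 <= pos < 2 * length / 3
    if kind == "gene":
        return 0.05 if in_valley else 1.0
    if kind == "element":
        return 1.0 if in_valley else 0.35
    return 1.0


class _Placer:
    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.names = [f"scf{i + 1}" for i in range(config.n_scaffolds)]
        self.trees = {n: IntervalTree() for n in self.names}
        self.family_sites: dict[tuple[str, str], list[int]] = {}
        lengths = np.asarray(config.scaffold_lengths, dtype=float)
        self.p = lengths / lengths.sum()

    def place(self, size: int, kind: str, family_id: str | None = None) -> tuple[str, int]:
        cfg = self.config
        last_scaffold = self.names[0]
        for _ in range(cfg.placement_retries):
            idx = int(self.rng.choice(len(self.names), p=self.p))
            name = self.names[idx]
            last_scaffold = name
            length = cfg.scaffold_lengths[idx]
            lo = cfg.edge_margin
            hi = length - cfg.edge_margin - size
            if hi <= lo:
                continue
            start = int(self.rng.integers(lo, hi))
            if cfg.spatial_structure:
                if self.rng.random() > _weight(start, length, kind):
                    continue
            if not (kind == "element" and cfg.allow_nesting):
                # 30 bp pad keeps neighbouring constructs out of TSD flanks
                if self.trees[name].overlap(start - 30, start + size + 30):
                    continue
            if family_id is not None:
                sites = self.family_sites.setdefault((name, family_id), [])
                if any(abs(start - s) < cfg.family_min_gap for s in sites):
                    continue
                sites.append(start)
            self.trees[name].addi(start, start + size)
            return name, start
        raise PlacementError(
            f"could not place a {size} bp {kind} on scaffold {last_scaffold} "
            f"after {cfg.placement_retries} retries; genome too crowded"
        )


@dataclass(frozen=True)
class _FamilyModel:
    family_id: str
    superfamily: str
    lineage: str
    ltr: np.ndarray
    core: np.ndarray


def _make_families(config: SimulationConfig, rng: np.random.Generator) -> list[_FamilyModel]:
    fams = []
    for i in range(config.n_families):
        superfamily = "Copia" if i % 2 == 0 else "Gypsy"
        lineages = COPIA_LINEAGES if superfamily == "Copia" else GYPSY_LINEAGES
        lineage = lineages[(i // 2) % len(lineages)]
        ltr_len = int(rng.integers(config.ltr_length_range[0], config.ltr_length_range[1] + 1))
        core_len = max(600, int(rng.normal(config.core_length_mean, config.core_length_sd)))
        fams.append(
            _FamilyModel(
                family_id=f"{superfamily}_{i + 1}",
                superfamily=superfamily,
                lineage=lineage,
                ltr=random_sequence(ltr_len, config.gc_content, rng),
                core=random_sequence(core_len, config.gc_content, rng),
            )
        )
    return fams


def _domain_layout(core_len: int, superfamily: str) -> list[tuple[str, int, int]]:
    """Ordered (domain, start, end) inside the core, 0-based half-open."""
    order = ("IN", "RT", "RH") if superfamily == "Copia" else ("RT", "RH", "IN")
    seg = core_len // 3
    pad = max(1, seg // 10)
    return [
        (dom, i * seg + pad, (i + 1) * seg - pad) for i, dom in enumerate(order)
    ]


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Build a synthetic genome with full ground truth.

    Deterministic for a fixed ``config.seed``.  Raises
    :class:`PlacementError` (naming a scaffold) if element placement keeps
    colliding after bounded retries.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    placer = _Placer(config, rng)
    scaffolds = {
        name: random_sequence(length, config.gc_content, rng)
        for name, length in zip(placer.names, config.scaffold_lengths)
    }
    families = _make_families(config, rng)

    # element statuses in planted proportions, shuffled reproducibly
    n = config.n_elements
    n_solo = int(round(config.solo_fraction * n))
    n_nonsolo = int(round(config.nonsolo_fraction * n))
    n_solo = min(n_solo, n)
    n_nonsolo = min(n_nonsolo, n - n_solo)
    statuses = ["solo"] * n_solo + ["nonsolo"] * n_nonsolo + ["complete"] * (n - n_solo - n_nonsolo)
    statuses = [statuses[i] for i in rng.permutation(n)]
    _ensure_family_anchors(statuses, [i % len(families) for i in range(n)])

    truth: list[GroundTruthRecord] = []
    details: dict[str, ElementDetail] = {}
    domain_rows: list[list] = []
    core_rows: list[list] = []

    for i in range(n):
        fam = families[i % len(families)]
        age = float(config.element_ages[int(rng.integers(0, len(config.element_ages)))])
        status = statuses[i]
        eid = f"E{i + 1:05d}"
        tf = config.transition_fraction

        elem_ltr = _evolve_codes(fam.ltr, config.intra_family_divergence, tf, rng)
        ltr_a = _evolve_codes(elem_ltr, age / 2.0, tf, rng)
        tsd_len = int(config.tsd_length_choices[int(rng.integers(0, len(config.tsd_length_choices)))])
        tsd = random_sequence(tsd_len, config.gc_content, rng)

        if status == "complete":
            core = _evolve_codes(
                fam.core, config.intra_family_divergence + age / 2.0, tf, rng
            )
            ltr_b = _evolve_codes(elem_ltr, age / 2.0, tf, rng)
            construct = np.concatenate([tsd, ltr_a, core, ltr_b, tsd])
            inner = (tsd_len, construct.size - tsd_len)
        elif status == "solo":
            construct = np.concatenate([tsd, ltr_a, tsd])
            inner = (tsd_len, construct.size - tsd_len)
        else:  # nonsolo
            construct = ltr_a
            inner = (0, construct.size)

        scaffold, start = placer.place(construct.size, "element", fam.family_id)
        scaffolds[scaffold][start : start + construct.size] = construct
        e_start, e_end = start + inner[0], start + inner[1]
        if status == "nonsolo":
            _scrub_chance_tsd(scaffolds[scaffold], e_start, e_end, config.gc_content, rng)
        truth.append(
            GroundTruthRecord(
                element_id=eid,
                scaffold=scaffold,
                start=e_start,
                end=e_end,
                true_age=age,
                status=status,
                tsd_sequence="" if status == "nonsolo" else decode(tsd),
                superfamily=fam.superfamily,
                lineage=fam.lineage,
                family_id=fam.family_id,
            )
        )
        if status == "complete":
            la = (e_start, e_start + ltr_a.size)
            core_iv = (la[1], la[1] + core.size)
            lb = (core_iv[1], core_iv[1] + ltr_b.size)
            details[eid] = ElementDetail(eid, scaffold, la, lb, core_iv)
            core_id = f"{eid}_core"
            for dom, ds, de in _domain_layout(core.size, fam.superfamily):
                length = de - ds
                domain_rows.append(
                    [core_id, f"GyDB_{dom}_{fam.lineage}", 97.0, length, 0, 0,
                     ds + 1, de, 1, length, 1e-40, 2 * length]
                )
            core_rows.append(
                [core_id, scaffold, round(100.0 * (1 - age / 2), 2), core.size, 0, 0,
                 1, core.size, core_iv[0] + 1, core_iv[1], 1e-60, 2 * core.size]
            )
        else:
            details[eid] = ElementDetail(eid, scaffold, (e_start, e_end), None, None)

    genes: list[tuple[str, int, int, str]] = []
    for g in range(config.n_genes):
        size = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
        scaffold, start = placer.place(size, "gene")
        genes.append((scaffold, start, start + size, f"G{g + 1:05d}"))
    genes.sort()

    deletion_truth, vcf_text = _simulate_deletions(config, rng, truth, details, placer.names)

    return SimulatedGenome(
        config=config,
        scaffolds={name: decode(arr) for name, arr in scaffolds.items()},
        genes=genes,
        truth=truth,
        details=details,
        domain_hits=pd.DataFrame(domain_rows, columns=HIT_COLUMNS),
        core_hits=pd.DataFrame(core_rows, columns=HIT_COLUMNS),
        deletion_truth=deletion_truth,
        vcf_text=vcf_text,
    )


def _ensure_family_anchors(statuses: list[str], family_of: list[int]) -> None:
    """Give every family at least one complete element when any exist.

    Solo and truncated LTRs are only discoverable through homology with a
    paired element of their family, so a family with no complete member
    would leave undiscoverable ground truth.  Swaps statuses in place,
    preserving the global class proportions exactly; does nothing when the
    configuration plants no complete elements at all.
    """
    by_family: dict[int, list[int]] = {}
    for idx, fam in enumerate(family_of):
        by_family.setdefault(fam, []).append(idx)
    complete_by_family = {
        fam: [i for i in idxs if statuses[i] == "complete"]
        for fam, idxs in by_family.items()
    }
    donors = [fam for fam, c in complete_by_family.items() if len(c) >= 2]
    for fam, idxs in sorted(by_family.items()):
        if complete_by_family[fam] or not donors:
            continue
        donor = donors[-1]
        give = complete_by_family[donor].pop()
        take = idxs[0]
        statuses[give], statuses[take] = statuses[take], "complete"
        complete_by_family[fam] = [take]
        if len(complete_by_family[donor]) < 2:
            donors.pop()


def _scrub_chance_tsd(
    scaffold_arr: np.ndarray,
    ltr_start: int,
    ltr_end: int,
    gc: float,
    rng: np.random.Generator,
    flank: int = 20,
    tries: int = 50,
) -> None:
    """Resample the right flank of a truncated LTR until no shared 4-7-mer
    remains, so the planted no-TSD label is unambiguous."""
    from .ltrscape import detect_tsd_in_flanks

    lo = max(0, ltr_start - flank)
    hi = min(scaffold_arr.size, ltr_end + flank)
    for _ in range(tries):
        left = decode(scaffold_arr[lo:ltr_start])
        right = decode(scaffold_arr[ltr_end:hi])
        if detect_tsd_in_flanks(left, right) is None:
            return
        scaffold_arr[ltr_end:hi] = random_sequence(hi - ltr_end, gc, rng)


def _simulate_deletions(
    config: SimulationConfig,
    rng: np.random.Generator,
    truth: list[GroundTruthRecord],
    details: dict[str, ElementDetail],
    scaffold_names: list[str],
) -> tuple[pd.DataFrame, str]:
    """Deletion calls reciprocally covering >=80% of chosen complete elements."""
    complete = [r for r in truth if r.status == "complete"]
    n_pick = int(round(config.deletion_element_fraction * len(complete)))
    if complete and config.spatial_structure:
        # recent activity (deletions) concentrates in gene-rich arms
        w = np.array(
            [
                _weight((r.start + r.end) // 2,
                        config.scaffold_lengths[scaffold_names.index(r.scaffold)],
                        "gene")
                for r in complete
            ]
        )
        w = w / w.sum()
        idx = rng.choice(len(complete), size=min(n_pick, len(complete)), replace=False, p=w)
    elif complete:
        idx = rng.choice(len(complete), size=min(n_pick, len(complete)), replace=False)
    else:
        idx = np.array([], dtype=int)
    chosen = sorted((complete[i] for i in idx), key=lambda r: (r.scaffold, r.start))

    samples = [f"S{i + 1:02d}" for i in range(config.deletion_samples)]
    fracs = list(config.deletion_support_fractions)
    total_reads = 20
    rows = []
    records = []
    for r in chosen:
        length = r.end - r.start
        jitter = int(rng.integers(0, max(1, length // 20)))
        d_start = r.start + jitter
        d_end = r.end - int(rng.integers(0, max(1, length // 20)))
        sample_fields = []
        for s in samples:
            if rng.random() < config.deletion_presence_prob:
                frac = float(fracs[int(rng.integers(0, len(fracs)))])
                ao = int(round(frac * total_reads))
                ro = total_reads - ao
                gt = "1/1" if frac >= 0.8 else "0/1"
                rows.append({"element_id": r.element_id, "sample": s, "support_fraction": ao / total_reads})
            else:
                ao, ro, gt = 0, total_reads, "0/0"
            sample_fields.append(f"{gt}:{ao}:{ro}")
        records.append(
            f"{r.scaffold}\t{d_start + 1}\t{r.element_id}_del\tN\t<DEL>\t.\tPASS\t"
            f"SVTYPE=DEL;END={d_end};SVLEN={-(d_end - d_start)}\tGT:AO:RO\t"
            + "\t".join(sample_fields)
        )

    header = ["##fileformat=VCFv4.2"]
    for name, length in zip(scaffold_names, config.scaffold_lengths):
        header.append(f"##contig=<ID={name},length={length}>")
    header += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AO,Number=1,Type=Integer,Description="Reads supporting ALT">',
        '##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Reads supporting REF">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    vcf_text = "\n".join(header + records) + "\n"
    frame = pd.DataFrame(rows, columns=["element_id", "sample", "support_fraction"])
    return frame, vcf_text
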