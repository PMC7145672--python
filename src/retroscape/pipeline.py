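"""End-to-end orchestration of the synthetic-genome analysis.

``run_full`` drives the whole chain — simulate, validate cores, resolve
LTR classes, date elements, build the relatedness network, assign deletion
calls, and compute the windowed landscape — and reports how well the
pipeline recovered the planted ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import chronos, coredb, landscape, ltrscape, rbhnet, svact
from .simgenome import SimulationConfig, SimulatedGenome, simulate_genome


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline thresholds, at their standard defaults."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    core_evalue_max: float = 1e-20
    propagate_evalue_max: float = 1e-25
    propagate_coverage_min: float = 0.80
    family_identity_min: float = 0.80
    family_length_frac_min: float = 0.80
    family_overlap_min_bp: int = 80
    ltr_identity_min: float = 0.80
    ltr_coverage_min: float = 0.90
    ltr_merge_gap: int = 100
    pair_flank_bp: int = 30_000
    pair_self_coverage_min: float = 0.90
    tsd_flank: int = 20
    tsd_k_min: int = 4
    tsd_k_max: int = 7
    rbh_identity_min: float = 0.90
    rbh_coverage_min: float = 0.90
    sv_max_len: int = 100_000
    sv_reciprocal_min: float = 0.80
    sv_hemi_min: float = 0.20
    sv_homo_min: float = 0.80
    window_size: int = 1_000_000
    window_keep_min: int = 100_000
    age_bin_width: float = 0.01
    rate_low: float = 4e-9
    rate_high: float = 5e-9
    ltr_factor: float = 2.0
    pattern_changepoint_d: float = 0.06
    pattern_recent_d: float = 0.02

    # -- flat key=value serialisation ------------------------------------
    def to_text(self) -> str:
        lines = []
        for f in fields(SimulationConfig):
            v = getattr(self.sim, f.name)
            lines.append(f"sim.{f.name}={_fmt(v)}")
        for f in fields(PipelineConfig):
            if f.name == "sim":
                continue
            lines.append(f"{f.name}={_fmt(getattr(self, f.name))}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        sim_kwargs: dict[str, Any] = {}
        kwargs: dict[str, Any] = {}
        sim_fields = {f.name: f for f in fields(SimulationConfig)}
        own_fields = {f.name: f for f in fields(cls) if f.name != "sim"}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key.startswith("sim."):
                name = key[4:]
                if name not in sim_fields:
                    raise KeyError(f"unknown config key {key!r}")
                sim_kwargs[name] = _parse(value, getattr(SimulationConfig(), name))
            else:
                if key not in own_fields:
                    raise KeyError(f"unknown config key {key!r}")
                kwargs[key] = _parse(value, getattr(cls(), key))
        return cls(sim=SimulationConfig(**sim_kwargs), **kwargs)


def _fmt(value: Any) -> str:
    if isinstance(value, tuple):
        return ",".join(_fmt(v) for v in value)
    if isinstance(value, bool):
        return "true" if value else "false"
    return repr(value) if isinstance(value, float) else str(value)


def _parse(value: str, template: Any) -> Any:
    if isinstance(template, bool):
        return value.lower() in {"1", "true", "yes"}
    if isinstance(template, tuple):
        if not value:
            return ()
        elem = template[0] if template else 0.0
        return tuple(type(elem)(float(v)) if isinstance(elem, int) else type(elem)(v)
                     for v in value.split(","))
    if isinstance(template, int):
        return int(float(value))
    if isinstance(template, float):
        return float(value)
    return value


@dataclass
class PipelineResult:
    sim: SimulatedGenome
    cores: list
    core_rejections: list
    ltr_records: list
    counts: ltrscape.LTRClassCounts
    ratios: tuple[float, float, float]
    dated: list
    dating_excluded: list
    rbh_edges: list
    rbh_matrix: pd.DataFrame
    sv_assignments: list
    windows: pd.DataFrame
    window_stats: pd.DataFrame
    status_recovery: pd.DataFrame
    recovery_accuracy: float
    recall: float
    pattern: landscape.ActivityPattern | None


def _match_truth(
    records: list[ltrscape.LTRRecord], sim: SimulatedGenome
) -> tuple[pd.DataFrame, float, float]:
    """Match classified loci to planted LTR loci by >=50% overlap."""
    truth = sim.ltr_loci()
    by_scaffold: dict[str, list[dict]] = {}
    for t in truth:
        by_scaffold.setdefault(t["scaffold"], []).append(t)
    rows = []
    matched_truth = set()
    for r in records:
        best, best_ov = None, 0
        for t in by_scaffold.get(r.scaffold, []):
            ov = min(r.end, t["end"]) - max(r.start, t["start"])
            if ov > best_ov:
                best, best_ov = t, ov
        if best is not None and best_ov >= 0.5 * (best["end"] - best["start"]):
            matched_truth.add(best["locus_id"])
            rows.append(
                {
                    "ltr_id": r.ltr_id,
                    "truth_locus": best["locus_id"],
                    "predicted": r.status,
                    "truth": best["status"],
                    "correct": r.status == best["status"],
                }
            )
        else:
            rows.append(
                {
                    "ltr_id": r.ltr_id,
                    "truth_locus": None,
                    "predicted": r.status,
                    "truth": None,
                    "correct": False,
                }
            )
    frame = pd.DataFrame(
        rows, columns=["ltr_id", "truth_locus", "predicted", "truth", "correct"]
    )
    matched = frame[frame["truth_locus"].notna()]
    accuracy = float(matched["correct"].mean()) if len(matched) else 0.0
    recall = len(matched_truth) / len(truth) if truth else 1.0
    return frame, accuracy, recall


def paired_elements(records: list[ltrscape.LTRRecord]) -> dict[str, tuple[str, int, int, str, str]]:
    """Reconstruct complete elements from mutually paired LTR records.

    Returns element_id -> (scaffold, start, end, ltr_id_a, ltr_id_b).
    """
    by_id = {r.ltr_id: r for r in records}
    out = {}
    for r in records:
        if r.status != "paired" or r.partner_ltr_id not in by_id:
            continue
        p = by_id[r.partner_ltr_id]
        if p.partner_ltr_id != r.ltr_id or r.ltr_id > p.ltr_id:
            continue
        eid = f"elem_{r.ltr_id}_{p.ltr_id}"
        start = min(r.start, p.start)
        end = max(r.end, p.end)
        out[eid] = (r.scaffold, start, end, r.ltr_id, p.ltr_id)
    return out


def run_full(config: PipelineConfig | None = None) -> PipelineResult:
    """Simulate a genome and run every downstream stage against the truth."""
    cfg = config or PipelineConfig()
    sim = simulate_genome(cfg.sim)
    genome = sim.scaffolds
    genome_id = "sim"

    # core validation from the simulated domain-hit table
    candidates = coredb.domain_hits_from_table(sim.domain_hits)
    cores, rejections = coredb.validate_cores(
        candidates, cfg.core_evalue_max, genome_id=genome_id
    )

    # LTR copy discovery seeded from the paired elements' LTR sequences
    queries = {}
    for rec in sim.truth:
        if rec.status != "complete":
            continue
        det = sim.details[rec.element_id]
        queries[f"{rec.element_id}_q"] = sim.sequence(rec.scaffold, *det.ltr_a)
    hits = ltrscape.find_ltr_copies(
        queries, genome, cfg.ltr_identity_min, cfg.ltr_coverage_min, cfg.ltr_merge_gap
    )
    loci = ltrscape.collapse_loci(hits)
    records = ltrscape.classify_loci(
        genome, loci, genome_id, cfg.pair_flank_bp, cfg.pair_self_coverage_min,
        cfg.ltr_identity_min, cfg.tsd_flank,
    )
    counts = ltrscape.count_classes(records)
    ratios = ltrscape.class_ratios(counts) if counts.paired else (1.0, 0.0, 0.0)
    status_recovery, accuracy, recall = _match_truth(records, sim)

    # dating of reconstructed complete elements
    model = chronos.RateModel(cfg.rate_low, cfg.rate_high, cfg.ltr_factor)
    elements = paired_elements(records)
    triples = []
    by_id = {r.ltr_id: r for r in records}
    for eid, (scaffold, _, _, a, b) in sorted(elements.items()):
        ra, rb = by_id[a], by_id[b]
        triples.append(
            (eid, genome[scaffold][ra.start : ra.end], genome[scaffold][rb.start : rb.end])
        )
    dated, excluded = chronos.date_elements(triples, model)

    # relatedness network over unpaired LTRs
    unpaired = {
        r.ltr_id: genome[r.scaffold][r.start : r.end]
        for r in records
        if r.status in {"solo", "nonsolo"}
    }
    database = {
        r.ltr_id: genome[r.scaffold][r.start : r.end]
        for r in records
        if r.status != "discarded"
    }
    best = rbhnet.best_hits(unpaired, database, cfg.rbh_identity_min, cfg.rbh_coverage_min)
    genome_of = {r.ltr_id: genome_id for r in records}
    edges, matrix = rbhnet.reciprocal_network(best, genome_of)

    # deletion-call assignment against reconstructed elements
    element_intervals = {
        eid: (scaffold, start, end)
        for eid, (scaffold, start, end, _, _) in elements.items()
    }
    import io
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False) as fh:
        fh.write(sim.vcf_text)
        vcf_path = fh.name
    calls = svact.read_deletion_vcf(vcf_path)
    Path(vcf_path).unlink()
    assignments = svact.assign_deletions(
        calls, element_intervals, cfg.sv_max_len, cfg.sv_reciprocal_min,
        cfg.sv_hemi_min, cfg.sv_homo_min,
    )

    # windowed landscape
    scaffold_lengths = {name: len(seq) for name, seq in genome.items()}
    windows = landscape.make_windows(scaffold_lengths, cfg.window_size, cfg.window_keep_min)
    genic = landscape.genic_fraction(windows, [(s, a, b) for s, a, b, _ in sim.genes])
    class_positions = {
        status: [(r.scaffold, r.start) for r in records if r.status == status]
        for status in ("paired", "solo", "nonsolo")
    }
    window_stats = windows.copy()
    window_stats["genic_fraction"] = genic.to_numpy()
    for status, positions in class_positions.items():
        assigned = landscape.assign_to_windows(windows, positions)
        tally = pd.Series(assigned).value_counts()
        window_stats[status] = [int(tally.get(w, 0)) for w in windows["window_id"]]
    window_stats = landscape.window_ltr_metrics(window_stats)
    del_counts, del_mean, _ = svact.deletion_density(assignments, windows)
    window_stats["deletion_mean"] = del_mean.to_numpy()

    pattern = None
    if dated:
        hist = chronos.age_histogram([e.d for e in dated], bin_width=cfg.age_bin_width)
        pattern = landscape.classify_activity_pattern(
            hist, genome_id, "species", cfg.pattern_changepoint_d, cfg.pattern_recent_d
        )

    return PipelineResult(
        sim=sim,
        cores=cores,
        core_rejections=rejections,
        ltr_records=records,
        counts=counts,
        ratios=ratios,
        dated=dated,
        dating_excluded=excluded,
        rbh_edges=edges,
        rbh_matrix=matrix,
        sv_assignments=assignments,
        windows=windows,
        window_stats=window_stats,
        status_recovery=status_recovery,
        recovery_accuracy=accuracy,
        recall=recall,
        pattern=pattern,
    )


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(config.to_text().encode()).hexdigest()


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, config: PipelineConfig, inputs: dict[str, Path]) -> None:
    from . import __version__

    manifest = {
        "package_version": __version__,
        "config_sha256": config_hash(config),
        "inputs": {name: file_checksum(p) for name, p in sorted(inputs.items())},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
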