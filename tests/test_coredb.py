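"""Core validation by domain order and homology propagation with merging."""

import numpy as np
import pandas as pd
import pytest

from retroscape import coredb
from retroscape.coredb import DomainHit, Rejection, RetroCore
from retroscape.simgenome import HIT_COLUMNS


def _hit(domain, start, end, strand="+", evalue=1e-30, q="cand"):
    return DomainHit(q, domain, start, end, strand, evalue)


class TestValidateCore:
    def test_in_rt_rh_order_is_copia(self):
        hits = [_hit("IN", 100, 500), _hit("RT", 600, 1400), _hit("RH", 1500, 1900)]
        core = coredb.validate_core("cand", hits)
        assert isinstance(core, RetroCore)
        assert core.superfamily == "Copia"
        assert (core.start, core.end) == (100, 1900)

    def test_rt_rh_in_order_is_gypsy(self):
        hits = [_hit("RT", 100, 900), _hit("RH", 1000, 1400), _hit("IN", 1500, 2100)]
        assert coredb.validate_core("cand", hits).superfamily == "Gypsy"

    def test_minus_strand_call_matches_plus_strand(self):
        # the same Copia architecture seen on the minus strand reads
        # RH-RT-IN left to right and must normalise to the same call
        hits = [
            _hit("RH", 100, 500, "-"),
            _hit("RT", 600, 1400, "-"),
            _hit("IN", 1500, 1900, "-"),
        ]
        assert coredb.validate_core("cand", hits).superfamily == "Copia"

    def test_rejection_reasons(self):
        assert coredb.validate_core("cand", []).reason == "no_domains"
        weak = [_hit("IN", 0, 10, evalue=1e-10)]
        assert coredb.validate_core("cand", weak).reason == "no_domains"
        missing = [_hit("IN", 0, 10), _hit("RT", 20, 40)]
        assert coredb.validate_core("cand", missing).reason.startswith("missing_domain")
        dup = [
            _hit("IN", 0, 10), _hit("RT", 20, 40), _hit("RT", 50, 80),
            _hit("RH", 90, 120),
        ]
        assert coredb.validate_core("cand", dup).reason.startswith("duplicated_domain")

    def test_mixed_strand_set_is_unclassified(self):
        hits = [
            _hit("IN", 100, 500, "+"), _hit("RT", 600, 1400, "-"),
            _hit("RH", 1500, 1900, "+"),
        ]
        core = coredb.validate_core("cand", hits)
        assert core.superfamily == "unclassified" and core.reason == "mixed_strand"

    def test_foreign_hits_rejected(self):
        with pytest.raises(ValueError):
            coredb.validate_core("cand", [_hit("IN", 0, 10, q="other")])

    def test_acceptance_count_matches_brute_force_refilter(self):
        """Candidate set with planted defects: the accepted count equals an
        independent per-candidate re-filter, in proportions echoing a
        genome-scale survey (most candidates valid, a minority defective)."""
        rng = np.random.default_rng(5)
        candidates = {}
        planted_pass = 0
        for i in range(200):
            cid = f"c{i:03d}"
            kind = rng.random()
            hits = [
                _hit("IN", 0, 300, q=cid), _hit("RT", 400, 1100, q=cid),
                _hit("RH", 1200, 1500, q=cid),
            ]
            if kind < 0.05:
                hits.append(_hit("RT", 1600, 1900, q=cid))  # duplicated domain
            elif kind < 0.10:
                hits = hits[:2]  # missing domain
            elif kind < 0.13:
                hits = [DomainHit(cid, h.domain, h.start, h.end, h.strand, 1e-5)
                        for h in hits]  # all hits too weak
            else:
                planted_pass += 1
            candidates[cid] = hits
        accepted, rejected = coredb.validate_cores(candidates)
        assert len(accepted) == planted_pass
        # independent oracle: re-filter each candidate from scratch
        oracle = 0
        for cid, hits in candidates.items():
            strong = [h for h in hits if h.evalue < 1e-20]
            per_domain = {d: [h for h in strong if h.domain == d] for d in ("IN", "RT", "RH")}
            if all(len(v) == 1 for v in per_domain.values()):
                oracle += 1
        assert len(accepted) == oracle


def _hit_row(query, subject, qstart, qend, sstart, send, evalue=1e-30, pident=95.0):
    length = abs(qend - qstart) + 1
    return [query, subject, pident, length, 0, 0, qstart, qend, sstart, send, evalue, length * 2]


class TestPropagateCores:
    QUERIES = {"q1": (1000, "Copia"), "q2": (1000, "Gypsy")}

    def test_single_good_hit_becomes_core(self):
        hits = pd.DataFrame([_hit_row("q1", "scf1", 1, 850, 5001, 5850)], columns=HIT_COLUMNS)
        cores = coredb.propagate_cores(self.QUERIES, hits)
        assert len(cores) == 1
        assert cores[0].superfamily == "Copia"
        assert (cores[0].start, cores[0].end) == (5000, 5850)

    def test_low_coverage_or_weak_evalue_filtered(self):
        hits = pd.DataFrame(
            [
                _hit_row("q1", "scf1", 1, 700, 5001, 5700),          # 70% coverage
                _hit_row("q1", "scf1", 1, 900, 8001, 8900, evalue=1e-20),  # weak
            ],
            columns=HIT_COLUMNS,
        )
        assert coredb.propagate_cores(self.QUERIES, hits) == []

    def test_one_bp_overlap_merges_to_union(self):
        hits = pd.DataFrame(
            [
                _hit_row("q1", "scf1", 1, 900, 1001, 1900),
                _hit_row("q1", "scf1", 1, 900, 1900, 2800),
            ],
            columns=HIT_COLUMNS,
        )
        cores = coredb.propagate_cores(self.QUERIES, hits)
        assert len(cores) == 1
        assert (cores[0].start, cores[0].end) == (1000, 2800)

    def test_unknown_query_raises(self):
        hits = pd.DataFrame([_hit_row("ghost", "scf1", 1, 900, 1, 900)], columns=HIT_COLUMNS)
        with pytest.raises(KeyError):
            coredb.propagate_cores(self.QUERIES, hits)

    def test_out_of_bounds_hit_names_record(self):
        hits = pd.DataFrame([_hit_row("q1", "scf1", 1, 900, 99_500, 100_400)], columns=HIT_COLUMNS)
        with pytest.raises(ValueError, match="q1"):
            coredb.propagate_cores(self.QUERIES, hits, scaffold_lengths={"scf1": 100_000})

    def test_random_table_matches_quadratic_oracle_and_is_order_invariant(self):
        rng = np.random.default_rng(11)
        rows = []
        for _ in range(500):
            q = rng.choice(["q1", "q2"])
            cov = rng.uniform(0.5, 1.0)
            length = int(cov * 1000)
            s = int(rng.integers(0, 50_000))
            ev = 10.0 ** rng.uniform(-60, -10)
            rows.append(_hit_row(q, "scf1", 1, length, s + 1, s + length, evalue=ev))
        hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
        cores = coredb.propagate_cores(self.QUERIES, hits)

        # quadratic oracle: filter, then repeatedly merge any overlapping pair
        surv = []
        for r in rows:
            if (abs(r[7] - r[6]) + 1) / 1000 >= 0.80 and r[10] < 1e-25:
                surv.append([r[8] - 1, r[9]])
        changed = True
        while changed:
            changed = False
            for i in range(len(surv)):
                for j in range(i + 1, len(surv)):
                    a, b = surv[i], surv[j]
                    if a[0] < b[1] and b[0] < a[1]:
                        surv[i] = [min(a[0], b[0]), max(a[1], b[1])]
                        surv.pop(j)
                        changed = True
                        break
                if changed:
                    break
        expected = sorted(tuple(x) for x in surv)
        assert sorted((c.start, c.end) for c in cores) == expected

        # order invariance and idempotence of the merge
        shuffled = hits.sample(frac=1.0, random_state=3).reset_index(drop=True)
        cores2 = coredb.propagate_cores(self.QUERIES, shuffled)
        assert sorted((c.start, c.end) for c in cores2) == expected
        # no two surviving cores overlap on the same strand
        for i in range(len(expected)):
            for j in range(i + 1, len(expected)):
                a, b = expected[i], expected[j]
                assert a[1] <= b[0] or b[1] <= a[0]

    def test_simulated_core_hits_round_trip(self, small_sim):
        queries = {}
        for r in small_sim.truth:
            if r.status == "complete":
                det = small_sim.details[r.element_id]
                queries[f"{r.element_id}_core"] = (
                    det.core[1] - det.core[0], r.superfamily
                )
        cores = coredb.propagate_cores(queries, small_sim.core_hits, genome_id="sim")
        assert len(cores) == len(queries)
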