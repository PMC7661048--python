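import math
from collections import Counter

import numpy as np
import pytest

from trnaflux import synthetic_data as sd
from trnaflux.yamat_quant import (
    AlignmentPolicy,
    Reference,
    ReferenceSet,
    SampleIndexTable,
    align_read,
    demultiplex,
    exclude_low_types,
    length_filter,
    quantify,
    run_sample,
    strain_pools,
)


@pytest.fixture(scope="module")
def refs():
    return sd.gen_reference_set(n_refs=8, n_types=6, seed=5,
                                near_duplicate_pairs=1)


class TestDemultiplex:
    TABLE = SampleIndexTable({"AAAAAA": "s1", "CCCCCC": "s2"})

    def test_exact_assignment(self):
        reads = ["AAAAAA" + "G" * 80, "CCCCCC" + "G" * 80, "AAAAAA" + "T" * 80]
        by_sample, unassigned = demultiplex(reads, self.TABLE)
        assert len(by_sample["s1"]) == 2
        assert len(by_sample["s2"]) == 1
        assert unassigned == 0

    def test_one_mismatch_index_is_unassigned(self):
        reads = ["AAAAAT" + "G" * 80]
        by_sample, unassigned = demultiplex(reads, self.TABLE)
        assert unassigned == 1
        assert not any(by_sample.values())

    def test_non_6bp_index_rejected(self):
        with pytest.raises(ValueError, match="6 bp"):
            SampleIndexTable({"AAAA": "s1"})

    def test_generator_bookkeeping_recovered(self, refs):
        """Multi-sample read pools demultiplex back to exact per-sample
        counts recorded by the generator."""
        pool = sd.gen_pool(refs, seed=6)
        indices = {"AAAAAA": "s1", "CCCCCC": "s2", "GGGGGG": "s3"}
        sizes = {"AAAAAA": 400, "CCCCCC": 300, "GGGGGG": 300}
        all_reads = []
        for i, (idx, n) in enumerate(sizes.items()):
            reads, _ = sd.gen_yamat_reads(refs, pool, n, index=idx, seed=10 + i)
            all_reads.extend(reads)
        by_sample, unassigned = demultiplex(all_reads, SampleIndexTable(indices))
        assert unassigned == 0
        assert {s: len(r) for s, r in by_sample.items()} == {
            "s1": 400, "s2": 300, "s3": 300
        }


class TestLengthFilter:
    def test_window_boundaries_inclusive(self):
        reads = ["A" * 79, "A" * 80, "A" * 151, "A" * 152]
        kept, retention = length_filter(reads)
        assert kept == ["A" * 80, "A" * 151]
        assert retention == 0.5

    def test_empty_input(self):
        kept, retention = length_filter([])
        assert kept == [] and retention == 1.0

    def test_generator_out_of_range_fraction(self, refs):
        pool = sd.gen_pool(refs, seed=6)
        reads, _ = sd.gen_yamat_reads(refs, pool, 3000,
                                      out_of_range_fraction=0.01, seed=9)
        _, retention = length_filter(reads)
        se = math.sqrt(0.01 * 0.99 / 3000)
        assert abs((1 - retention) - 0.01) < 4 * se


class TestAlignRead:
    def test_exact_body_with_flanks_assigned(self, refs):
        r = refs.records[3]
        read = "AAAAAA" + "TT" + r.sequence + "GG" * 6
        out = align_read(read, refs)
        assert out.status == "assigned"
        assert out.ref_id == r.ref_id

    def test_near_duplicate_pair_tie_is_ambiguous(self, refs):
        """A read carrying the sequence midway between two references that
        differ by one substitution aligns equally well to both."""
        a = next(r for r in refs.records if r.ref_id == "ref_00")
        b = next(r for r in refs.records if r.ref_id == "ref_nd00")
        (pos,) = [i for i, (x, y) in enumerate(zip(a.sequence, b.sequence))
                  if x != y]
        third = next(c for c in "ACGT"
                     if c not in (a.sequence[pos], b.sequence[pos]))
        mid = a.sequence[:pos] + third + a.sequence[pos + 1 :]
        read = "AAAAAA" + "CT" + mid + "ACGT"
        out = align_read(read, refs)
        assert out.status == "ambiguous"

    def test_excess_mismatches_unaligned(self, refs):
        r = refs.records[2]
        rng = np.random.default_rng(0)
        seq = list(r.sequence)
        n_mut = int(0.15 * len(seq)) + 1  # 12%+ mismatches to nearest ref
        for p in rng.choice(len(seq), size=n_mut, replace=False):
            seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
        read = "AAAAAA" + "".join(seq) + "ACGTACGT"
        assert align_read(read, refs).status == "unaligned"

    def test_few_mismatches_still_assigned(self, refs):
        r = refs.records[4]
        seq = list(r.sequence)
        seq[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[10]]
        read = "AAAAAA" + "".join(seq) + "ACGTACGT"
        out = align_read(read, refs)
        assert out.status == "assigned" and out.ref_id == r.ref_id

    def test_ambiguous_bases_tolerated_up_to_five(self, refs):
        r = refs.records[5]
        seq = list(r.sequence)
        for p in (3, 9, 15, 21, 27):
            seq[p] = "N"
        read = "AAAAAA" + "".join(seq) + "ACGT"
        assert align_read(read, refs).status == "assigned"
        for p in (33, 39, 45):
            seq[p] = "N"
        read = "AAAAAA" + "".join(seq) + "ACGT"
        assert align_read(read, refs).status != "assigned"

    def test_reference_order_never_changes_assignment(self, refs):
        pool = sd.gen_pool(refs, seed=6)
        reads, _ = sd.gen_yamat_reads(refs, pool, 150, error_rate=0.02, seed=3)
        reversed_refs = ReferenceSet(records=list(reversed(refs.records)))
        for read in reads:
            a = align_read(read, refs)
            b = align_read(read, reversed_refs)
            assert (a.status, a.ref_id) == (b.status, b.ref_id)


class TestQuantify:
    REFS = ReferenceSet(records=[
        Reference("refA1", "A", "ACGTACGTAC" * 6),
        Reference("refA2", "A", "TGCATGCATG" * 6),
        Reference("refB", "B", "GGATCCGGAT" * 6),
    ])

    def test_refs_aggregate_to_types(self):
        assignments = {"s1": ["refA1"] * 30 + ["refA2"] * 10 + ["refB"] * 60}
        table = quantify(assignments, self.REFS)
        assert table.type_counts["s1"] == Counter({"A": 40, "B": 60})
        assert table.proportions["s1"] == {"A": 0.4, "B": 0.6}

    def test_single_ref_all_reads(self):
        table = quantify({"s1": ["refB"] * 5}, self.REFS)
        assert table.proportions["s1"] == {"B": 1.0}

    def test_zero_read_sample_excluded_from_strain_mean(self):
        table = quantify({"s1": ["refB"] * 4, "s2": []}, self.REFS)
        pools = strain_pools(table, {"strain": ["s1", "s2"]})
        assert pools["strain"] == {"B": 1.0}

    def test_strain_pool_is_mean_of_replicate_proportions(self):
        table = quantify(
            {"r1": ["refA1"] * 2 + ["refB"] * 2, "r2": ["refB"] * 4}, self.REFS
        )
        pools = strain_pools(table, {"strain": ["r1", "r2"]})
        assert pools["strain"]["A"] == pytest.approx(0.25)
        assert pools["strain"]["B"] == pytest.approx(0.75)


class TestExcludeLowTypes:
    def _table(self, props_by_sample):
        # build a CountTable via quantify on synthetic assignments
        refs = ReferenceSet(records=[
            Reference(t, t, ("ACGT" * 20)[: 40 + 2 * i])
            for i, t in enumerate(sorted({t for p in props_by_sample.values()
                                          for t in p}))
        ])
        assignments = {
            s: [t for t, n in counts.items() for _ in range(n)]
            for s, counts in props_by_sample.items()
        }
        return quantify(assignments, refs)

    def test_type_low_everywhere_excluded(self):
        table = self._table({
            "s1": {"X": 1, "Y": 20000}, "s2": {"X": 1, "Y": 30000}
        })
        reduced, excluded = exclude_low_types(table, threshold=1e-4)
        assert excluded == ["X"]
        assert reduced.proportions["s1"] == {"Y": 1.0}

    def test_all_above_threshold_identity(self):
        table = self._table({"s1": {"X": 50, "Y": 50}})
        reduced, excluded = exclude_low_types(table)
        assert excluded == []
        assert reduced.type_counts == table.type_counts

    def test_high_in_one_sample_retained(self):
        table = self._table({
            "s1": {"X": 1, "Y": 20000}, "s2": {"X": 500, "Y": 500}
        })
        _, excluded = exclude_low_types(table)
        assert excluded == []


class TestPipelineRecovery:
    def test_noiseless_round_trip(self, refs):
        """With zero error rate every read re-assigns to its source ref."""
        pool = sd.gen_pool(refs, seed=6)
        reads, truth = sd.gen_yamat_reads(refs, pool, 500, error_rate=0.0,
                                          seed=4)
        assigned, stats = run_sample(reads, refs)
        assert stats["assigned"] == 500
        assert Counter(assigned) == Counter(truth["ref_id"])

    def test_read_accounting_conserved(self, refs):
        pool = sd.gen_pool(refs, seed=6)
        reads, _ = sd.gen_yamat_reads(refs, pool, 800, error_rate=0.05,
                                      out_of_range_fraction=0.02, seed=8)
        _, stats = run_sample(reads, refs)
        assert sum(stats.values()) == 800

    def test_proportions_converge_with_depth(self):
        """Estimated proportions approach truth as read depth grows."""
        refs = sd.gen_reference_set(n_refs=12, n_types=12, seed=21)
        pool = sd.gen_pool(refs, seed=22, span=(1e-3, 0.1))
        errs = {}
        for n in (2000, 20000):
            reads, _ = sd.gen_yamat_reads(refs, pool, n, error_rate=0.003,
                                          seed=23)
            assigned, _ = run_sample(reads, refs)
            table = quantify({"s": assigned}, refs)
            props = table.proportions["s"]
            errs[n] = sum(abs(props.get(t, 0) - p) for t, p in pool.items())
        assert errs[20000] < errs[2000]

    def test_triplicate_strain_recovery_within_binomial_error(self, refs):
        pool = sd.gen_pool(refs, seed=30, overrides={"T00": 0.006, "T01": 0.015})
        per_rep = 6000
        assignments = {}
        for rep in range(3):
            reads, _ = sd.gen_yamat_reads(refs, pool, per_rep, seed=40 + rep)
            assigned, _ = run_sample(reads, refs)
            assignments[f"r{rep}"] = assigned
        table = quantify(assignments, refs)
        pools = strain_pools(table, {"strain": ["r0", "r1", "r2"]})
        n_total = 3 * per_rep
        for t, p in pool.items():
            se = math.sqrt(p * (1 - p) / n_total)
            assert abs(pools["strain"].get(t, 0) - p) < 3 * se + 1e-4, t
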