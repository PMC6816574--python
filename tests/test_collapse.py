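"""UMI grouping and consensus: oracles, partition properties, noise reduction."""

import itertools
from collections import Counter

import numpy as np
import pytest

from _util import (make_read, make_reference, snv_at, insertion_at, deletion_at,
                   TRANSVERSION, oracle_consensus_bases, exact_consensus_error_oracle)

from mrdseq.panel_io import GenomicInterval
from mrdseq.sequence import GAP, N_CODE, decode, encode
from mrdseq.simulate import SimConfig, simulate_sample
from mrdseq.collapse import (CollapseParams, ConsensusSet, FamilyKey, ReadFamily,
                             build_consensus, collapse_sample, error_rate_profile,
                             group_reads)
from mrdseq.pileup import build_pileup

REGION = GenomicInterval("chr1", 0, 3000)


class TestGrouping:
    def test_same_key_one_family(self, reference):
        reads = [make_read(reference, 100, 200, "AAAAAA", read_id="a"),
                 make_read(reference, 100, 200, "AAAAAA", read_id="b")]
        fams = group_reads(reads)
        assert len(fams) == 1 and fams[0].size == 2

    def test_different_umi_two_families(self, reference):
        reads = [make_read(reference, 100, 200, "AAAAAA"),
                 make_read(reference, 100, 200, "CCCCCC")]
        assert len(group_reads(reads)) == 2

    def test_missing_umi_goes_to_side_channel(self, reference):
        reads = [make_read(reference, 100, 200, ""),
                 make_read(reference, 100, 200, "AAAAAA")]
        fams = group_reads(reads)
        assert len(fams) == 1
        assert fams.rejected == 1

    def test_tolerance_one_merges_near_umi(self, reference):
        reads = [make_read(reference, 100, 200, "AAAAAA", read_id="a"),
                 make_read(reference, 100, 200, "AAAAAA", read_id="b"),
                 make_read(reference, 100, 200, "AAAAAC", read_id="c"),
                 make_read(reference, 100, 200, "GGGGGG", read_id="d")]
        fams = group_reads(reads, umi_mismatch_tolerance=1)
        sizes = sorted(f.size for f in fams)
        assert sizes == [1, 3]
        big = next(f for f in fams if f.size == 3)
        assert big.key.umi == "AAAAAA"  # larger family absorbs the smaller

    def test_simulated_families_reproduce_molecule_assignment(self, reference):
        cfg = SimConfig(n_molecules=2500, region=REGION, seed=31,
                        fragment_length_mean=200, fragment_length_sd=30,
                        family_size_dist=("constant", 4),
                        pcr_error_rate=0.0, seq_error_rate=0.0)
        _, readset, truth = simulate_sample(cfg, reference)
        assert len(readset) == 10_000
        fams = group_reads(readset.to_reads(reference))
        # with error-free UMIs the partition is exactly the molecule partition
        assert len(fams) == 2500
        for fam in fams:
            mols = {r.molecule_id for r in fam.members}
            assert len(mols) == 1
            assert fam.size == truth.family_sizes[mols.pop()]

    def test_partition_property(self, reference, rng):
        reads = [make_read(reference, 100 * (i % 3), 100 * (i % 3) + 150,
                           "".join(rng.choice(list("ACGT"), 6)), read_id=f"r{i}")
                 for i in range(60)]
        fams = group_reads(reads)
        ids = [r.id for f in fams for r in f.members]
        assert sorted(ids) == sorted(r.id for r in reads)  # no read lost or duplicated


class TestBuildConsensus:
    def make_family(self, reference, column_bases, pos=150, start=100, end=200, umi="AAAAAA"):
        members = [make_read(reference, start, end, umi, subs=[(pos, b)] if b else [],
                             read_id=f"m{i}")
                   for i, b in enumerate(column_bases)]
        return ReadFamily(key=FamilyKey("chr1", start, end, umi), members=members)

    def test_family_below_min_size_gives_none(self, reference):
        fam = self.make_family(reference, [None, None])
        assert build_consensus(fam) is None

    def test_majority_and_no_majority_columns(self, reference):
        ref_base = reference.base("chr1", 150)
        others = [b for b in "ACGT" if b != ref_base]
        # two reads agree on an alt, one holds another alt -> majority alt call
        fam = self.make_family(reference, [others[0], others[0], others[1]])
        cons = build_consensus(fam)
        assert decode(cons.bases[50:51]) == others[0]
        # three-way disagreement -> N
        fam = self.make_family(reference, [others[0], others[1], others[2]])
        cons = build_consensus(fam)
        assert cons.bases[50] == N_CODE
        assert cons.n_fraction == pytest.approx(1 / 100)

    def test_matches_vote_oracle_on_random_families(self, reference, rng):
        for _ in range(1000):
            size = int(rng.integers(3, 9))
            start = int(rng.integers(0, 2900))
            end = start + int(rng.integers(20, 60))
            members = []
            for i in range(size):
                n_err = int(rng.integers(0, 6))
                subs = [(int(p), rng.choice(list("ACGT")))
                        for p in rng.integers(start, end, n_err)]
                members.append(make_read(reference, start, end, "ACGTAC", subs=subs,
                                         read_id=f"m{i}"))
            fam = ReadFamily(key=FamilyKey("chr1", start, end, "ACGTAC"), members=members)
            cons = build_consensus(fam)
            expected = oracle_consensus_bases([m.bases for m in members])
            np.testing.assert_array_equal(cons.bases, expected)

    def test_indel_strict_majority(self, reference):
        start, end = 100, 200
        members = [make_read(reference, start, end, "AAAAAA", read_id=f"m{i}",
                             insertions=[(150, "GT")] if i < 2 else [])
                   for i in range(3)]
        fam = ReadFamily(key=FamilyKey("chr1", start, end, "AAAAAA"), members=members)
        cons = build_consensus(fam)
        assert cons.insertions == [(150, "GT", 2)]  # 2/3 > 0.5
        members = [make_read(reference, start, end, "AAAAAA", read_id=f"m{i}",
                             deletions=[(150, 152)] if i == 0 else [])
                   for i in range(4)]
        fam = ReadFamily(key=FamilyKey("chr1", start, end, "AAAAAA"), members=members)
        cons = build_consensus(fam)
        assert cons.deletions == []  # 1/4 is a minority


class TestCollapseSample:
    def sim(self, reference, **kw):
        defaults = dict(n_molecules=400, region=REGION, seed=41, fragment_length_mean=150,
                        fragment_length_sd=20, family_size_dist=("ztnb", 6, 2),
                        pcr_error_rate=1e-4, seq_error_rate=0.01)
        defaults.update(kw)
        cfg = SimConfig(**defaults)
        return simulate_sample(cfg, reference)

    def test_sparse_and_dense_paths_agree(self, reference):
        spikes = [(snv_at(reference, 1500), 0.3), (insertion_at(reference, 1000), 0.2),
                  (deletion_at(reference, 2000), 0.2)]
        _, readset, _ = self.sim(reference, spikes=spikes, seed=43)
        sparse, m1 = collapse_sample(readset)
        dense, m2 = collapse_sample(readset.to_reads(reference), reference=reference)
        a = sparse.to_consensus_reads(reference)
        b = dense.to_consensus_reads(reference)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert x.key == y.key and x.family_size == y.family_size
            np.testing.assert_array_equal(x.bases, y.bases)
            assert x.insertions == y.insertions
            assert [d[0] for d in x.deletions] == [d[0] for d in y.deletions]
        assert m1.families_passing == m2.families_passing
        assert m1.collapsed_median_depth == m2.collapsed_median_depth

    def test_error_free_consensus_equals_molecule_sequences(self, reference):
        mols, readset, truth = self.sim(reference, pcr_error_rate=0.0, seq_error_rate=0.0,
                                        family_size_dist=("constant", 4), seed=47)
        cset, metrics = collapse_sample(readset)
        assert metrics.consensus_count == 400
        assert len(cset.sub_pos) == 0 and len(cset.n_pos) == 0  # bit-exact reference copies
        assert np.all(cset.n_fraction == 0.0)

    def test_consensus_count_monotone_in_min_family_size(self, reference):
        _, readset, _ = self.sim(reference, seed=53)
        counts = [collapse_sample(readset, params=CollapseParams(min_family_size=k))[1]
                  .consensus_count for k in (1, 2, 3, 5, 8)]
        assert counts == sorted(counts, reverse=True)

    def test_order_independence(self, reference, rng):
        _, readset, _ = self.sim(reference, seed=59)
        reads = readset.to_reads(reference)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        a, _ = collapse_sample(reads, reference=reference)
        b, _ = collapse_sample(shuffled, reference=reference)
        for x, y in zip(a.to_consensus_reads(reference), b.to_consensus_reads(reference)):
            assert x.key == y.key
            np.testing.assert_array_equal(x.bases, y.bases)

    def test_all_small_families_give_zero_consensus(self, reference):
        _, readset, _ = self.sim(reference, family_size_dist=("constant", 2), seed=61)
        cset, metrics = collapse_sample(readset)
        assert metrics.families_passing == 0 and len(cset) == 0
        assert metrics.family_count == 400

    def test_on_target_rate(self, reference):
        _, readset, _ = self.sim(reference, seed=67)
        _, metrics = collapse_sample(readset, panel_intervals=[REGION])
        assert metrics.on_target_rate == 1.0
        _, metrics = collapse_sample(readset,
                                     panel_intervals=[GenomicInterval("chr2", 0, 100)])
        assert metrics.on_target_rate == 0.0

    def test_empty_input_zeroed_metrics(self, caplog):
        with caplog.at_level("WARNING"):
            cset, metrics = collapse_sample([])
        assert len(cset) == 0 and metrics.raw_read_count == 0


class TestNoiseReduction:
    @pytest.mark.parametrize("e", [0.002, 0.005, 0.01])
    def test_consensus_error_rate_matches_enumeration_oracle(self, reference, e):
        n_mol = 4000 if e >= 0.005 else 8000
        cfg = SimConfig(n_molecules=n_mol, region=REGION, seed=71, fragment_length_mean=200,
                        fragment_length_sd=1, family_size_dist=("constant", 3),
                        pcr_error_rate=0.0, seq_error_rate=e)
        _, readset, _ = simulate_sample(cfg, reference)
        cset, _ = collapse_sample(readset)
        calls = int((cset.end - cset.start).sum()) - len(cset.n_pos)
        errors = len(cset.sub_pos)
        expected, _ = exact_consensus_error_oracle(e, size=3)
        se = np.sqrt(expected * (1 - expected) / calls)
        assert abs(errors / calls - expected) < 3 * se

    def test_consensus_cleaner_than_raw(self, reference):
        cfg = SimConfig(n_molecules=1500, region=REGION, seed=73, fragment_length_mean=200,
                        fragment_length_sd=20, family_size_dist=("ztnb", 6, 2),
                        pcr_error_rate=0.0, seq_error_rate=0.005)
        _, readset, _ = simulate_sample(cfg, reference)
        cset, _ = collapse_sample(readset)
        interval = [GenomicInterval("chr1", 1000, 1400)]
        raw_profile = error_rate_profile(
            build_pileup(readset, interval, reference), reference)
        cons_profile = error_rate_profile(
            build_pileup(cset, interval, reference), reference)
        assert cons_profile.mean() < raw_profile.mean()
        assert raw_profile.mean() == pytest.approx(0.005, rel=0.25)

    def test_error_free_background_is_zero_and_uncovered_missing(self, reference):
        cfg = SimConfig(n_molecules=100, region=GenomicInterval("chr1", 500, 900), seed=79,
                        fragment_length_mean=100, fragment_length_sd=5,
                        family_size_dist=("constant", 3),
                        pcr_error_rate=0.0, seq_error_rate=0.0)
        _, readset, _ = simulate_sample(cfg, reference)
        cset, _ = collapse_sample(readset)
        cols = build_pileup(cset, [GenomicInterval("chr1", 400, 900)], reference)
        profile = error_rate_profile(cols, reference)
        assert (profile == 0.0).all()
        assert profile.index.min() >= 500  # uncovered positions are missing, not zero
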