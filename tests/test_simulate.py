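"""Simulator: reproducibility, conservation, error-rate calibration, SAM I/O."""

import numpy as np
import pytest

from _util import deletion_at, insertion_at, make_read, make_reference, snv_at

from mrdseq.panel_io import GenomicInterval
from mrdseq.sequence import GAP, C, G, A, T, decode, encode
from mrdseq.simulate import (ConfigError, SimConfig, amplify_and_sequence, simulate_molecules,
                             simulate_sample)
from mrdseq import samio

REGION = GenomicInterval("chr1", 0, 3000)


def base_config(**kw):
    defaults = dict(n_molecules=500, region=REGION, seed=1, fragment_length_mean=200,
                    fragment_length_sd=30, family_size_dist=("constant", 1),
                    pcr_error_rate=0.0, seq_error_rate=0.0)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestMolecules:
    def test_reproducible_bit_identical(self, reference):
        cfg = base_config(seed=9, spikes=[(snv_at(make_reference(), 1500), 0.01)],
                          seq_error_rate=0.003)
        a = simulate_sample(cfg, reference)[1]
        b = simulate_sample(cfg, reference)[1]
        np.testing.assert_array_equal(a.start, b.start)
        np.testing.assert_array_equal(a.umi_codes, b.umi_codes)
        np.testing.assert_array_equal(a.sub_pos, b.sub_pos)
        np.testing.assert_array_equal(a.sub_alt, b.sub_alt)

    @pytest.mark.parametrize("vaf,expected", [(0.0, 0), (1.0, 1000)])
    def test_degenerate_spike_rates(self, reference, vaf, expected):
        cfg = base_config(n_molecules=1000, spikes=[(snv_at(reference, 1500), vaf)])
        mols = simulate_molecules(cfg, reference)
        assert mols.n_carriers(0) == expected

    def test_spike_outside_region_rejected(self, reference):
        cfg = base_config(region=GenomicInterval("chr1", 0, 1000),
                          spikes=[(snv_at(reference, 2500), 0.1)])
        with pytest.raises(ConfigError, match="outside region"):
            simulate_molecules(cfg, reference)

    def test_carrier_fraction_matches_binomial_oracle(self, reference):
        # mean carrier fraction over many seeds within 3 SE of the target VAF
        vaf, n, seeds = 0.001, 50_000, 200
        spike = snv_at(reference, 1500)
        fractions = []
        for seed in range(seeds):
            cfg = base_config(n_molecules=n, seed=seed, spikes=[(spike, vaf)])
            mols = simulate_molecules(cfg, reference)
            fractions.append(mols.n_carriers(0) / n)
        se = np.sqrt(vaf * (1 - vaf) / (n * seeds))
        assert abs(np.mean(fractions) - vaf) < 3 * se

    def test_molecule_objects_carry_variant_and_umi(self, reference):
        cfg = base_config(n_molecules=50, spikes=[(snv_at(reference, 1500), 1.0)],
                          umi_length=6)
        mols = simulate_molecules(cfg, reference)
        m = mols[0]
        assert len(m.umi) == 6 and set(m.umi) <= set("ACGT")
        assert m.carries_variant is not None


class TestAmplify:
    def test_constant_one_read_per_molecule_error_free(self, reference):
        cfg = base_config(n_molecules=200, seed=3)
        mols, reads, truth = simulate_sample(cfg, reference)
        assert len(reads) == 200
        assert truth.total_reads == int(truth.family_sizes.sum()) == 200
        assert len(reads.sub_pos) == 0  # error-free: reads match reference exactly
        r = reads.get_read(0, reference)
        mol = mols[int(reads.mol_id[0])]
        assert decode(r.bases) == mol.sequence(reference)
        assert r.umi == mol.umi

    def test_truth_conservation(self, reference):
        cfg = base_config(n_molecules=300, seed=5, family_size_dist=("ztnb", 6, 2),
                          spikes=[(snv_at(reference, 1500), 0.1)])
        _, reads, truth = simulate_sample(cfg, reference)
        assert len(reads) == truth.total_reads
        np.testing.assert_array_equal(np.bincount(reads.mol_id, minlength=300),
                                      truth.family_sizes)
        s = truth.spikes[0]
        assert s.true_vaf == s.n_carrier_molecules / truth.n_molecules

    def test_sequencing_error_rate_calibrated(self, reference):
        # per-read mismatch fraction within 3 SE of the configured rate
        e = 0.005
        cfg = base_config(n_molecules=2500, seed=7, fragment_length_mean=400,
                          fragment_length_sd=1, seq_error_rate=e)
        _, reads, _ = simulate_sample(cfg, reference)
        total = int((reads.end - reads.start).sum())
        observed = len(reads.sub_pos) / total
        se = np.sqrt(e * (1 - e) / total)
        assert total > 900_000
        assert abs(observed - e) < 3 * se

    def test_oxidation_bias_forces_c_to_a_g_to_t(self, reference):
        cfg = base_config(n_molecules=500, seed=11, pcr_error_rate=0.01,
                          oxidation_bias=1.0)
        _, reads, _ = simulate_sample(cfg, reference)
        assert len(reads.sub_pos) > 100
        ref_bases = reference["chr1"][reads.sub_pos]
        ok_ca = (ref_bases == C) & (reads.sub_alt == A)
        ok_gt = (ref_bases == G) & (reads.sub_alt == T)
        assert np.all(ok_ca | ok_gt)

    def test_spiked_reads_all_carry_allele(self, reference):
        spike = snv_at(reference, 1500)
        cfg = base_config(n_molecules=100, seed=13, family_size_dist=("constant", 4),
                          spikes=[(spike, 1.0)], fragment_length_mean=2900,
                          fragment_length_sd=1)
        _, reads, truth = simulate_sample(cfg, reference)
        # every fragment covers the locus; every read shows the alt allele
        at_locus = reads.sub_pos == spike.pos
        assert int(at_locus.sum()) == len(reads)
        assert truth.spikes[0].n_expressed == 100

    def test_indel_spike_events_on_reads(self, reference):
        ins = insertion_at(reference, 1200)
        dele = deletion_at(reference, 1800)
        cfg = base_config(n_molecules=200, seed=17, fragment_length_mean=2900,
                          fragment_length_sd=1, spikes=[(ins, 0.4), (dele, 0.4)])
        mols, reads, truth = simulate_sample(cfg, reference)
        assert len(reads.ins_read) == truth.spikes[0].n_expressed
        assert len(reads.del_read) == truth.spikes[1].n_expressed
        assert set(reads.ins_seq) == {"GT"}

    def test_degenerate_family_dist_warns_and_uses_size_one(self, reference, caplog):
        cfg = base_config(n_molecules=10, family_size_dist=("ztnb", 0, 2))
        with caplog.at_level("WARNING"):
            _, reads, _ = simulate_sample(cfg, reference)
        assert len(reads) == 10

    def test_empty_molecule_list_rejected(self, reference):
        with pytest.raises(ConfigError):
            amplify_and_sequence([], base_config(), reference)


class TestSamRoundTrip:
    def test_cigar_deletion(self, reference, tmp_path):
        r = make_read(reference, 100, 200, deletions=[(110, 112)])
        samio.write_sam([r], tmp_path / "a.sam", reference)
        text = (tmp_path / "a.sam").read_text()
        assert "10M2D88M" in text

    def test_cigar_insertion(self, reference, tmp_path):
        r = make_read(reference, 100, 200, insertions=[(105, "GT")])
        samio.write_sam([r], tmp_path / "b.sam", reference)
        assert "6M2I94M" in (tmp_path / "b.sam").read_text()

    def test_unsorted_input_rejected(self, reference, tmp_path):
        reads = [make_read(reference, 500, 600, read_id="x"),
                 make_read(reference, 100, 200, read_id="y")]
        with pytest.raises(ValueError, match="sorted"):
            samio.write_sam(reads, tmp_path / "c.sam", reference)

    def test_roundtrip_identity_100_reads(self, reference, tmp_path):
        spike = insertion_at(reference, 1200)
        cfg = base_config(n_molecules=100, seed=23, seq_error_rate=0.01,
                          spikes=[(spike, 0.3)])
        _, reads, _ = simulate_sample(cfg, reference)
        path = tmp_path / "d.sam"
        samio.write_sam(reads, path, reference)
        back = samio.read_sam(path)
        assert len(back) == len(reads)
        original = {r.id: r for r in reads.to_reads(reference)}
        for r in back:
            o = original[r.id]
            assert (r.chrom, r.start, r.end, r.umi) == (o.chrom, o.start, o.end, o.umi)
            np.testing.assert_array_equal(r.bases, o.bases)
            assert r.insertions == o.insertions
            assert r.deletions == o.deletions
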