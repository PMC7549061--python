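"""The generator's outputs must match their declared sampling distributions
and carry internally consistent truth annotations."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import musaqc as mq
from musaqc.exceptions import InvalidParameterError
from musaqc.pileup import read_pileup_tsv, write_pileup_tsv
from musaqc.synthdata import read_truth_sites, write_truth_sites


class TestGenerateSubgenomes:
    def test_zero_divergence_identity(self):
        pair = mq.generate_subgenomes(seed=1, n_chrom=2, chrom_length=500, divergence_rate=0.0)
        assert pair.truth_sites == ()
        assert pair.a_seqs == pair.b_seqs

    def test_same_seed_is_byte_identical(self):
        kwargs = dict(n_chrom=2, chrom_length=2000, divergence_rate=0.01, indel_rate=1e-3)
        assert mq.generate_subgenomes(7, **kwargs) == mq.generate_subgenomes(7, **kwargs)

    def test_divergent_site_count_is_binomial(self):
        # Binomial(1e5, 0.005): mean 500, sd = sqrt(1e5 * 0.005 * 0.995) = 22.3
        pair = mq.generate_subgenomes(seed=3, n_chrom=1, chrom_length=100_000, divergence_rate=0.005)
        sd = math.sqrt(100_000 * 0.005 * 0.995)
        assert abs(len(pair.truth_sites) - 500) < 4 * sd

    def test_truth_sites_are_where_sequences_differ(self, small_pair):
        for chrom in small_pair.chrom_names:
            a, b = small_pair.a_seqs[chrom], small_pair.b_seqs[chrom]
            diff = {i + 1 for i in range(len(a)) if a[i] != b[i]}
            listed = {s.pos for s in small_pair.truth_sites if s.chrom == chrom}
            assert diff == listed

    def test_truth_positions_strictly_increasing_per_chrom(self, small_pair):
        for chrom in small_pair.chrom_names:
            pos = [s.pos for s in small_pair.truth_sites if s.chrom == chrom]
            assert pos == sorted(set(pos))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_chrom=0),
            dict(chrom_length=0),
            dict(divergence_rate=0.2),
            dict(divergence_rate=-0.1),
            dict(indel_rate=0.5),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(n_chrom=1, chrom_length=100, divergence_rate=0.01, indel_rate=0.0)
        base.update(kwargs)
        with pytest.raises(InvalidParameterError):
            mq.generate_subgenomes(seed=0, **base)


class TestComposeGenotype:
    def test_pure_a_has_zero_dosage(self, small_pair):
        acc = mq.compose_genotype(small_pair, mq.GenotypeSpec("AA"))
        assert set(acc.truth_b_dosage) == {0.0}

    def test_pure_b_has_unit_dosage(self, small_pair):
        acc = mq.compose_genotype(small_pair, mq.GenotypeSpec("BB"))
        assert set(acc.truth_b_dosage) == {1.0}

    def test_hx_segment_zeroes_dosage_inside_interval(self, small_pair):
        chrom = small_pair.chrom_names[0]
        seg = mq.HxSegment(chrom, 5_000, 15_000, "A", 2)  # convert the B copy to A
        acc = mq.compose_genotype(small_pair, mq.GenotypeSpec("AAB", (seg,)))
        for site, dosage in zip(small_pair.truth_sites, acc.truth_b_dosage):
            if site.chrom == chrom and 5_000 <= site.pos < 15_000:
                assert dosage == 0.0
            else:
                assert dosage == pytest.approx(1 / 3)

    def test_haplotypes_match_dosage_by_direct_inspection(self, small_pair):
        acc = mq.compose_genotype(small_pair, mq.GenotypeSpec("ABB"))
        for site, dosage in zip(small_pair.truth_sites, acc.truth_b_dosage):
            haps = acc.haplotypes[site.chrom]
            k = sum(h[site.pos - 1] == site.b_allele for h in haps)
            assert dosage == k / 3

    def test_bad_composition_rejected(self, small_pair):
        for comp in ("AAX", "", "A", "AABBA"):
            with pytest.raises(InvalidParameterError):
                mq.compose_genotype(small_pair, mq.GenotypeSpec(comp))

    def test_overlapping_hx_segments_rejected(self, small_pair):
        chrom = small_pair.chrom_names[0]
        segs = (
            mq.HxSegment(chrom, 100, 1000, "A", 2),
            mq.HxSegment(chrom, 500, 2000, "A", 2),
        )
        with pytest.raises(InvalidParameterError):
            mq.compose_genotype(small_pair, mq.GenotypeSpec("AAB", segs))

    @given(
        comp=st.text(alphabet="AB", min_size=2, max_size=4).filter(
            lambda s: len(s) in (2, 3, 4)
        )
    )
    def test_composition_complement_symmetry(self, comp):
        """Swapping A<->B in the composition maps dosage d to 1-d."""
        pair = mq.generate_subgenomes(seed=5, n_chrom=1, chrom_length=3000, divergence_rate=0.01)
        flipped = comp.translate(str.maketrans("AB", "BA"))
        d1 = mq.compose_genotype(pair, mq.GenotypeSpec(comp)).truth_b_dosage
        d2 = mq.compose_genotype(pair, mq.GenotypeSpec(flipped)).truth_b_dosage
        assert np.allclose(np.asarray(d1) + np.asarray(d2), 1.0)


class TestSimulatePileup:
    def test_error_free_pure_a_supports_only_reference(self, small_pair):
        acc = mq.compose_genotype(small_pair, mq.GenotypeSpec("AA"))
        pu = mq.simulate_pileup(acc, mean_depth=20, error_rate=0.0, seed=2)
        for col in pu:
            assert col.alt_count == 0
            assert col.ref_count == col.depth

    def test_depth_is_poisson_with_requested_mean(self, small_pair):
        acc = mq.compose_genotype(small_pair, mq.GenotypeSpec("AA"))
        pu = mq.simulate_pileup(acc, mean_depth=30, error_rate=0.0, seed=3)
        depths = np.array([c.depth for c in pu])
        assert depths.size >= 10_000
        assert abs(depths.mean() - 30) < 0.01 * 30
        # Poisson: variance tracks the mean
        assert abs(depths.var() - 30) < 0.05 * 30

    def test_b_fraction_converges_to_dosage_at_high_depth(self, small_pair):
        """Uniform copy choice makes the aggregate B fraction -> k/ploidy."""
        acc = mq.compose_genotype(small_pair, mq.GenotypeSpec("AAB"))
        positions = {
            c: [s.pos for s in small_pair.truth_sites if s.chrom == c]
            for c in small_pair.chrom_names
        }
        pu = mq.simulate_pileup(acc, mean_depth=100, error_rate=0.0, seed=4, positions=positions)
        site_allele = {(s.chrom, s.pos): s.b_allele for s in small_pair.truth_sites}
        b_reads = sum(c.count(site_allele[(c.chrom, c.pos)]) for c in pu)
        total = sum(c.depth for c in pu)
        se = math.sqrt((1 / 3) * (2 / 3) / total)
        assert abs(b_reads / total - 1 / 3) < 3 * se

    def test_error_model_dosage_conservation(self):
        """Expected B-base fraction is d*(1-e) + (1-d)*e/3 under the miscall model."""
        pair = mq.generate_subgenomes(seed=13, n_chrom=1, chrom_length=200_000, divergence_rate=0.05)
        acc = mq.compose_genotype(pair, mq.GenotypeSpec("AAB"))
        positions = {"chr01": [s.pos for s in pair.truth_sites]}
        error = 0.01
        pu = mq.simulate_pileup(acc, mean_depth=30, error_rate=error, seed=6, positions=positions)
        assert len(pu) >= 10_000
        site_allele = {(s.chrom, s.pos): s.b_allele for s in pair.truth_sites}
        b_reads = sum(c.count(site_allele[(c.chrom, c.pos)]) for c in pu)
        total = sum(c.depth for c in pu)
        d = 1 / 3
        expected = d * (1 - error) + (1 - d) * error / 3
        se = math.sqrt(expected * (1 - expected) / total)
        assert abs(b_reads / total - expected) < 3 * se

    def test_same_seed_reproduces_pileup(self, small_pair):
        acc = mq.compose_genotype(small_pair, mq.GenotypeSpec("ABB"))
        pu1 = mq.simulate_pileup(acc, 15, 0.01, seed=9)
        pu2 = mq.simulate_pileup(acc, 15, 0.01, seed=9)
        assert pu1 == pu2

    def test_indel_support_appears_at_b_private_indels(self, small_pair):
        assert small_pair.indel_sites  # fixture includes indels
        acc = mq.compose_genotype(small_pair, mq.GenotypeSpec("BB"))
        pu = mq.simulate_pileup(acc, mean_depth=30, error_rate=0.0, seed=10)
        by_site = {(c.chrom, c.pos): c for c in pu}
        for site in small_pair.indel_sites:
            col = by_site[(site.chrom, site.pos)]
            assert col.indel_support == col.depth  # every read is from a B copy

    def test_invalid_read_parameters_rejected(self, small_pair):
        acc = mq.compose_genotype(small_pair, mq.GenotypeSpec("AA"))
        with pytest.raises(InvalidParameterError):
            mq.simulate_pileup(acc, mean_depth=0)
        with pytest.raises(InvalidParameterError):
            mq.simulate_pileup(acc, mean_depth=10, error_rate=0.3)


class TestSimulateHeterozygousSites:
    def test_dosage_classes_span_one_to_ploidy_minus_one(self):
        for p in (2, 3, 4):
            _, dosage = mq.simulate_heterozygous_sites(p, 2000, seed=1)
            assert set(np.round(dosage * p).astype(int)) == set(range(1, p))

    def test_alt_counts_are_binomial_at_dosage(self):
        cols, dosage = mq.simulate_heterozygous_sites(2, 5000, depth=40, error_rate=0.0, seed=2)
        fracs = np.array([1 - c.ref_count / c.depth for c in cols])
        assert abs(fracs.mean() - 0.5) < 3 * math.sqrt(0.25 / 40 / 5000) + 0.01


class TestSerialization:
    def test_truth_sites_round_trip(self, small_pair, tmp_path):
        path = tmp_path / "truth.tsv"
        write_truth_sites(small_pair, path)
        assert read_truth_sites(path) == list(small_pair.truth_sites)

    def test_pileup_tsv_round_trip(self, bb_pileup, tmp_path):
        path = tmp_path / "pileup.tsv"
        subset = bb_pileup[:500]
        write_pileup_tsv(subset, path)
        assert read_pileup_tsv(path) == subset

    def test_reference_fastas_round_trip(self, small_pair, tmp_path):
        from Bio import SeqIO

        a_path, b_path = tmp_path / "a.fasta", tmp_path / "b.fasta"
        mq.synthdata.write_reference_fastas(small_pair, a_path, b_path)
        a_back = {r.id: str(r.seq) for r in SeqIO.parse(str(a_path), "fasta")}
        assert a_back == dict(small_pair.a_seqs)
        b_back = {r.id: str(r.seq) for r in SeqIO.parse(str(b_path), "fasta")}
        assert b_back == dict(small_pair.b_seqs)
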