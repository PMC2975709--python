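"""Meiosis, selection, pooling and read-sampling behaviour."""

import numpy as np
import pandas as pd
import pytest

import hawmap as hm
from hawmap.pool_simulator import BRISTOL, HAWAIIAN, Gamete


def _one_chrom_model(length=1_000_000, cm=50.0):
    return hm.build_genome_model([hm.ChromosomeSpec("c", length, cm)])


def _manual_gamete(model, per_chrom):
    """Build a gamete from {chrom: [(end_bp, origin), ...]}."""
    segments = {}
    for chrom, segs in per_chrom.items():
        ends = np.array([e for e, _ in segs], dtype=np.int64)
        origins = np.array([o for _, o in segs], dtype=np.int8)
        segments[chrom] = (ends, origins)
    return Gamete(segments=segments)


class TestGamete:
    def test_segments_tile_chromosome(self, small_model, rng):
        """Segment ends reach the chromosome end; origins alternate."""
        for _ in range(2000):
            g = hm.simulate_gamete(small_model, rng)
            for chrom in small_model.names:
                ends, origins = g.segments[chrom]
                assert ends[-1] == small_model.physical_length(chrom)
                assert np.all(np.diff(ends) > 0)
                assert np.all(ends >= 1)
                assert np.all(np.abs(np.diff(origins)) == 1)  # origins alternate

    def test_full_length_recombination_fraction_is_half(self, rng):
        model = _one_chrom_model()
        ends = np.array([1, 1_000_000])
        n = 10_000
        rec = 0
        for _ in range(n):
            g = hm.simulate_gamete(model, rng)
            o = g.origin_at("c", ends)
            rec += int(o[0] != o[1])
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(rec / n - 0.5) < 3 * se

    def test_ten_cm_recombination_fraction(self, rng):
        """Loci 10 cM apart recombine in ~10% of gametes: r(d) = d/100."""
        model = _one_chrom_model()
        gmap = model.genetic_map("c")
        p1 = gmap.cm_to_phys(-5.0)
        p2 = gmap.cm_to_phys(5.0)
        n = 10_000
        rec = 0
        for _ in range(n):
            o = hm.simulate_gamete(model, rng).origin_at("c", np.array([p1, p2]))
            rec += int(o[0] != o[1])
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(rec / n - 0.1) < 3 * se

    def test_zero_distance_never_recombines(self, rng):
        model = _one_chrom_model()
        for _ in range(200):
            g = hm.simulate_gamete(model, rng)
            o = g.origin_at("c", np.array([123_456, 123_456]))
            assert o[0] == o[1]


class TestSelection:
    def test_selected_f2s_are_bristol_homozygous_at_causal(self, small_model):
        cfg = hm.SimulationConfig(
            causal=hm.CausalLocus("chr2", 1_000_000), n_recombinants=30, seed=5
        )
        f2s = hm.simulate_selected_f2(small_model, cfg)
        assert len(f2s) == 30
        for f2 in f2s:
            assert f2.hawaiian_dosage("chr2", np.array([1_000_000]))[0] == 0

    def test_unlinked_loci_average_half_hawaiian(self, small_model):
        """Selection leaves unlinked chromosomes at 50% Hawaiian."""
        cfg = hm.SimulationConfig(
            causal=hm.CausalLocus("chr1", 1_000_000), n_recombinants=50, seed=9
        )
        rng = np.random.default_rng(9)
        probe = np.array([250_000, 750_000, 1_250_000, 1_750_000])
        n_reps = 100
        dosages = []
        for _ in range(n_reps):
            f2s = hm.simulate_selected_f2(small_model, cfg, rng=rng)
            for f2 in f2s:
                dosages.append(f2.hawaiian_dosage("chr3", probe) / 2.0)
        mean = np.mean(dosages)
        # each allele is a fair coin; alleles at different loci are correlated,
        # so take the conservative SE of one locus per animal
        se = np.sqrt(0.25 / (2 * 50 * n_reps))
        assert abs(mean - 0.5) < 4 * se

    def test_causal_position_validation(self, small_model):
        cfg = hm.SimulationConfig(causal=hm.CausalLocus("nope", 5), n_recombinants=1)
        with pytest.raises(ValueError, match="not in model"):
            hm.simulate_selected_f2(small_model, cfg)


class TestExpectedFrequency:
    @pytest.mark.parametrize(
        "d, linked, expected",
        [(0.0, True, 0.0), (10.0, True, 0.10), (50.0, True, 0.5),
         (80.0, True, 0.5), (10.0, False, 0.5)],
    )
    def test_closed_form(self, d, linked, expected):
        assert hm.expected_hawaiian_frequency(d, linked=linked) == expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            hm.expected_hawaiian_frequency(-1.0)

    def test_matches_selected_pool_simulation(self):
        """Pooled frequency at 10 cM from the lesion ~ r(10) = 0.10."""
        model = _one_chrom_model()
        causal_bp = model.cm_to_phys("c", 0.0)
        probe = np.array([model.cm_to_phys("c", 10.0)])
        cfg = hm.SimulationConfig(
            causal=hm.CausalLocus("c", causal_bp), n_recombinants=2000, seed=21
        )
        f2s = hm.simulate_selected_f2(model, cfg)
        freq = np.mean([f2.hawaiian_dosage("c", probe)[0] / 2.0 for f2 in f2s])
        se = np.sqrt(0.1 * 0.9 / (2 * 2000))
        assert abs(freq - hm.expected_hawaiian_frequency(10.0)) < 3 * se


class TestParameterRecovery:
    def test_frequency_slope_recovers_map_relation(self):
        """Pool frequency vs distance regression recovers slope 1/100.

        Over a large selected pool the Hawaiian frequency at distance d from
        the lesion is r(d) = d/100; the fitted slope must land within 10%.
        """
        model = _one_chrom_model(length=10_000_000)
        cat = hm.generate_snp_catalog(model, density=1e-4,
                                      blacklist_fraction=0.0, seed=3)
        causal_bp = model.cm_to_phys("c", 0.0)
        cfg = hm.SimulationConfig(causal=hm.CausalLocus("c", causal_bp),
                                  n_recombinants=5000, seed=8)
        f2s = hm.simulate_selected_f2(model, cfg)
        freqs = hm.pool_allele_frequencies(f2s, cat)
        dist = np.abs(model.phys_to_cm("c", cat.df["position"].to_numpy()))
        sel = dist <= 25
        slope = np.polyfit(dist[sel], freqs[sel], 1)[0]
        assert abs(slope - 0.01) < 0.001


class TestPooling:
    def test_all_hawaiian_gives_one(self, small_model, small_catalog):
        g = _manual_gamete(
            small_model,
            {c: [(small_model.physical_length(c), HAWAIIAN)]
             for c in small_model.names},
        )
        f2 = hm.F2Genotype(maternal=g, paternal=g)
        freqs = hm.pool_allele_frequencies([f2] * 5, small_catalog)
        assert np.all(freqs == 1.0)

    def test_single_heterozygote_among_fifty(self, small_model, small_catalog):
        bristol = _manual_gamete(
            small_model,
            {c: [(small_model.physical_length(c), BRISTOL)]
             for c in small_model.names},
        )
        hawaiian = _manual_gamete(
            small_model,
            {c: [(small_model.physical_length(c), HAWAIIAN)]
             for c in small_model.names},
        )
        hom = hm.F2Genotype(maternal=bristol, paternal=bristol)
        het = hm.F2Genotype(maternal=bristol, paternal=hawaiian)
        freqs = hm.pool_allele_frequencies([het] + [hom] * 49, small_catalog)
        assert np.allclose(freqs, 0.01)

    def test_matches_bruteforce_dosage_count(self, small_model, small_catalog, rng):
        f2s = [
            hm.F2Genotype(
                maternal=hm.simulate_gamete(small_model, rng),
                paternal=hm.simulate_gamete(small_model, rng),
            )
            for _ in range(10)
        ]
        freqs = hm.pool_allele_frequencies(f2s, small_catalog)
        # brute force: per locus, count Hawaiian alleles over all gametes
        for i, locus in enumerate(small_catalog.df.itertuples(index=False)):
            count = 0
            for f2 in f2s:
                pos = np.array([locus.position])
                count += int(f2.maternal.origin_at(locus.chromosome, pos)[0])
                count += int(f2.paternal.origin_at(locus.chromosome, pos)[0])
            assert freqs[i] == pytest.approx(count / 20.0)

    def test_weight_length_mismatch(self, small_model, small_catalog):
        g = _manual_gamete(
            small_model,
            {c: [(small_model.physical_length(c), BRISTOL)]
             for c in small_model.names},
        )
        f2 = hm.F2Genotype(maternal=g, paternal=g)
        with pytest.raises(ValueError, match="weights"):
            hm.pool_allele_frequencies([f2, f2], small_catalog, weights=[1.0])


class TestPileupSampling:
    def _config(self, **kw):
        base = dict(causal=hm.CausalLocus("chr1", 100), n_recombinants=5,
                    mean_depth=20.0, error_rate=0.0, seed=2)
        base.update(kw)
        return hm.SimulationConfig(**base)

    def test_no_hawaiian_signal_without_error(self, small_catalog):
        freqs = np.zeros(len(small_catalog))
        pileup = hm.sample_pileup(freqs, small_catalog, self._config())
        assert (pileup["hawaiian_reads"] == 0).all()

    def test_mean_depth_is_poisson_mean(self, small_catalog):
        freqs = np.full(len(small_catalog), 0.5)
        pileup = hm.sample_pileup(freqs, small_catalog, self._config())
        n = len(pileup)
        se = np.sqrt(20.0 / n)
        assert abs(pileup["total_reads"].mean() - 20.0) < 3 * se

    def test_miscalls_land_on_specific_base(self, small_catalog):
        """With f=0 and error e, Hawaiian-base reads appear at rate e/3."""
        e = 0.01
        freqs = np.zeros(len(small_catalog))
        cfg = self._config(error_rate=e, mean_depth=30.0)
        pileup = hm.sample_pileup(freqs, small_catalog, cfg)
        total = pileup["total_reads"].sum()
        frac = pileup["hawaiian_reads"].sum() / total
        se = np.sqrt((e / 3) * (1 - e / 3) / total)
        assert abs(frac - e / 3) < 3 * se

    def test_blacklisted_loci_read_pure_hawaiian(self, small_model):
        cat = hm.generate_snp_catalog(small_model, density=1e-3,
                                      blacklist_fraction=0.2, seed=13)
        freqs = np.zeros(len(cat))
        pileup = hm.sample_pileup(freqs, cat, self._config())
        black = cat.df["blacklisted"].to_numpy()
        assert (pileup.loc[black, "hawaiian_reads"]
                == pileup.loc[black, "total_reads"]).all()
        assert (pileup.loc[~black, "hawaiian_reads"] == 0).all()

    def test_counts_never_exceed_total(self, small_catalog, rng):
        freqs = rng.uniform(0, 1, len(small_catalog))
        pileup = hm.sample_pileup(freqs, small_catalog, self._config(error_rate=0.01))
        assert (pileup["hawaiian_reads"] + pileup["bristol_reads"]
                <= pileup["total_reads"]).all()


class TestBackgroundVariants:
    def test_causal_stop_always_injected(self, small_model):
        for seed in range(20):
            cfg = hm.SimulationConfig(
                causal=hm.CausalLocus("chr2", 777_777), n_recombinants=5, seed=seed
            )
            variants = hm.simulate_background_variants(small_model, cfg)
            at_causal = variants.loc[
                (variants["chromosome"] == "chr2") & (variants["position"] == 777_777)
            ]
            assert (at_causal["class"] == "stop").any()

    def test_noise_records_fail_caller_thresholds(self, small_model):
        cfg = hm.SimulationConfig(causal=hm.CausalLocus("chr1", 5), seed=4)
        variants = hm.simulate_background_variants(small_model, cfg)
        called = hm.call_variants(variants)
        # noise records carry multiplicity > 1; none may survive
        assert (called["multiplicity"] == 1).all()
        assert len(called) < len(variants)


class TestDeterminism:
    def test_identical_config_reproduces_pileup_bitwise(self, small_model):
        cfg = hm.SimulationConfig(causal=hm.CausalLocus("chr1", 900_000),
                                  n_recombinants=10, seed=99)
        a = hm.simulate_experiment(small_model, cfg)
        b = hm.simulate_experiment(small_model, cfg)
        pd.testing.assert_frame_equal(a.pileup, b.pileup)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_prebuilt_catalog_preserves_downstream_streams(self, small_model):
        cfg = hm.SimulationConfig(causal=hm.CausalLocus("chr1", 900_000),
                                  n_recombinants=10, seed=99)
        a = hm.simulate_experiment(small_model, cfg)
        b = hm.simulate_experiment(small_model, cfg, catalog=a.catalog)
        pd.testing.assert_frame_equal(a.pileup, b.pileup)
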