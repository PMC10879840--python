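"""Synthetic allele pools, genotypes, amplicon spectra and nest records."""

import numpy as np
import pandas as pd
import pytest

from owlmhc import simdata
from owlmhc.genotyper import translate
from owlmhc.simdata import (
    DEFAULT_LOCI,
    EffectConfig,
    LocusSpec,
    NoiseConfig,
    generate_allele_pool,
    simulate_amplicon_reads,
    simulate_breeding,
    simulate_population,
)


class TestLocusSpec:
    def test_off_frame_length_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            LocusSpec("L", 100, 5, (1,))

    def test_selected_site_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="selected_sites"):
            LocusSpec("L", 30, 5, (11,))


class TestAllelePool:
    def test_single_allele_pool_all_distances_zero(self):
        spec = LocusSpec("L", 30, 1, (2, 5), n_motifs=1)
        pool = generate_allele_pool(spec, seed=0)
        assert len(pool) == 1

    def test_same_seed_identical_pools(self):
        spec = DEFAULT_LOCI["DAB1"]
        assert generate_allele_pool(spec, 42) == generate_allele_pool(spec, 42)

    def test_dab2_like_pool_has_22_distinct_translations(self, dab2_pool):
        _, pool = dab2_pool
        translations = {translate(s) for s in pool.values()}
        assert len(pool) == 22 and len(translations) == 22

    def test_pool_sequences_in_frame_and_stop_free(self, dab2_pool):
        spec, pool = dab2_pool
        for seq in pool.values():
            assert len(seq) == spec.exon_length_nt
            assert "*" not in translate(seq)

    def test_impossible_spec_rejected(self):
        with pytest.raises(ValueError, match="sequence space"):
            LocusSpec("L", 3, 100, (1,))


class TestPopulation:
    def test_one_allele_pool_everyone_homozygous(self):
        pool = {"L": {"L*1": "ATGGCT"}}
        loci = {"L": LocusSpec("L", 6, 1, (1,), n_motifs=1)}
        g = simulate_population(pool, 20, seed=0, loci=loci)
        assert (g["alleles"] == "L*1").all()

    def test_two_equifrequent_alleles_heterozygosity(self):
        pool = {"L": {"L*1": "ATGGCT", "L*2": "ATGTCT"}}
        loci = {"L": LocusSpec("L", 6, 2, (1,), n_motifs=2)}
        n = 4000
        g = simulate_population(pool, n, seed=1, loci=loci)
        het = (g["alleles"].str.contains(";")).mean()
        se = np.sqrt(0.25 / n)
        assert abs(het - 0.5) < 3 * se

    def test_coamplified_locus_at_most_four_distinct(self):
        spec = DEFAULT_LOCI["MHC-Ia"]
        pool = {"MHC-Ia": generate_allele_pool(spec, 0)}
        g = simulate_population(pool, 100, seed=2)
        n_distinct = g["alleles"].str.split(";").apply(len)
        assert n_distinct.max() <= 4
        n_copies = g["copies"].str.split(";").apply(len)
        assert (n_copies == 4).all()

    def test_bad_frequencies_rejected(self):
        pool = {"L": {"L*1": "ATGGCT", "L*2": "ATGTCT"}}
        loci = {"L": LocusSpec("L", 6, 2, (1,), n_motifs=2)}
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_population(pool, 5, seed=0, loci=loci,
                                allele_freqs={"L": np.array([0.7, 0.7])})


@pytest.fixture(scope="module")
def setup(dab2_pool):
    spec, pool = dab2_pool
    g = simulate_population({"DAB2": pool}, 30, seed=4)
    return pool, g


class TestAmpliconReads:
    def test_noiseless_variants_equal_true_alleles(self, setup):
        pool, g = setup
        tables = simulate_amplicon_reads(g, {"DAB2": pool}, NoiseConfig.noiseless(), seed=0)
        truth = {r.sample_id: {pool[c] for c in r.copies.split(";")}
                 for r in g.itertuples(index=False)}
        for t in tables:
            assert set(t.sequences) == truth[t.sample_id]

    def test_chimeras_are_crossovers_of_deeper_variants(self, setup):
        pool, g = setup
        noise = NoiseConfig(substitution_rate=0.0, chimera_rate=1.0)
        tables = simulate_amplicon_reads(g, {"DAB2": pool}, noise, seed=1)
        true_seqs = set(pool.values())
        n_chim = 0
        for t in tables:
            for seq, depth in zip(t.sequences, t.depths):
                if seq in true_seqs:
                    continue
                n_chim += 1
                deeper = [s for s, d in zip(t.sequences, t.depths)
                          if d > depth and s in true_seqs]
                ok = any(
                    seq[:k] == a[:k] and seq[k:] == b[k:]
                    for k in range(1, len(seq))
                    for a in deeper for b in deeper if a != b
                )
                assert ok, "chimeric variant not reconstructable"
        assert n_chim > 0

    def test_full_replication_two_independent_tables(self, setup):
        pool, g = setup
        noise = NoiseConfig(replicate_fraction=1.0)
        tables = simulate_amplicon_reads(g, {"DAB2": pool}, noise, seed=2)
        by_sample = {}
        for t in tables:
            by_sample.setdefault(t.sample_id, []).append(t)
        assert all(len(v) == 2 for v in by_sample.values())
        # independent noise: depth spectra differ between replicates
        diffs = sum(v[0].depths != v[1].depths for v in by_sample.values())
        assert diffs > 0

    def test_zero_depth_warns_and_empties(self, setup):
        pool, g = setup
        with pytest.warns(UserWarning, match="zero requested depth"):
            tables = simulate_amplicon_reads(
                g, {"DAB2": pool}, NoiseConfig(mean_depth=0.0), seed=0
            )
        assert all(not t.sequences for t in tables)


@pytest.fixture(scope="module")
def divergence_series():
    rng = np.random.default_rng(9)
    return pd.Series(rng.gamma(4, 1.3, 600),
                     index=[f"ind{i:04d}" for i in range(600)])


class TestBreeding:
    def test_null_effects_match_configured_means(self, divergence_series):
        eff = EffectConfig(
            fledging_intercept=0.405, clutch_log_mean=float(np.log(6.0)),
            sigma_year=0.0, sigma_individual=0.0,
            covariate_effects={},
        )
        nests = simulate_breeding(divergence_series, eff, 5000, seed=3,
                                  crossfoster_plan="none", n_years=5)
        # clutch mean: Poisson(6) clamped at >= 1 barely shifts the mean
        assert abs(nests["clutch"].mean() - 6.0) < 3 * np.sqrt(6.0 / 5000) + 0.02
        p = 1 / (1 + np.exp(-0.405))
        rate = nests["fledged"].sum() / nests["clutch"].sum()
        se = np.sqrt(p * (1 - p) / nests["clutch"].sum())
        assert abs(rate - p) < 3 * se

    def test_no_crossfostering_social_equals_genetic(self, divergence_series):
        nests = simulate_breeding(divergence_series, EffectConfig(), 50, seed=0,
                                  crossfoster_plan="none")
        assert (nests["genetic_mother"] == nests["social_mother"]).all()
        assert (nests["genetic_father"] == nests["social_father"]).all()

    def test_full_swaps_exchange_parents_pairwise(self, divergence_series):
        nests = simulate_breeding(divergence_series, EffectConfig(), 60, seed=1,
                                  crossfoster_plan="full")
        full = nests[nests["crossfoster"] == "full"]
        assert len(full) % 2 == 0 and len(full) > 0
        assert (full["genetic_mother"] != full["social_mother"]).all()
        # swaps are reciprocal: the social couple's own nest points back
        by_couple = {(r.genetic_mother, r.genetic_father): r for r in full.itertuples()}
        for r in full.itertuples():
            partner = by_couple[(r.social_mother, r.social_father)]
            assert (partner.social_mother, partner.social_father) == (
                r.genetic_mother, r.genetic_father)

    def test_fledged_never_exceeds_clutch(self, divergence_series):
        nests = simulate_breeding(divergence_series, EffectConfig(), 300, seed=2)
        assert (nests["fledged"] <= nests["clutch"]).all()
        assert (nests["clutch"] >= 1).all()

    def test_determinism_same_seed(self, divergence_series):
        a = simulate_breeding(divergence_series, EffectConfig(), 40, seed=7)
        b = simulate_breeding(divergence_series, EffectConfig(), 40, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="SDs"):
            EffectConfig(sigma_year=-1.0)
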