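"""Transmission HMM: oracle equivalence, EM counting, MCS, two-run filter."""

from itertools import product

import numpy as np
import pytest

from halfsibmap import popsim
from halfsibmap.inference import (
    build_meiosis_batch,
    crossover_counts,
    decode_paths,
    decode_transmission,
    em_estimate_rates,
    forward_backward,
    infer_genetic_map,
    locate_crossovers,
    marker_confidence,
    near_double_crossover_stats,
    split_families,
)
from halfsibmap.qc_io import allele_frequencies


def _batch(ds, min_progeny=2):
    geno = ds.observed_genotypes()
    fams = split_families(geno, ds.ids, ds.pedigree, "sire", min_progeny)
    freqs = allele_frequencies(geno)
    return build_meiosis_batch(fams, ds.markers, freqs)


def _enumerate_oracle(batch, rates, j):
    """Exhaustive-path posteriors and switch probabilities for meiosis j."""
    E = batch.emissions
    q = E.shape[1]
    probs = np.zeros(q)
    sw = np.zeros(q - 1)
    tot = 0.0
    for path in product((0, 1), repeat=q):
        p = 0.5
        for m in range(q):
            p *= E[j, m, path[m]]
            if m:
                p *= rates[m - 1] if path[m] != path[m - 1] else 1 - rates[m - 1]
        tot += p
        probs += p * np.array(path)
        sw += p * (np.diff(path) != 0)
    return probs / tot, sw / tot


class TestForwardBackwardOracle:
    def test_posteriors_match_exhaustive_enumeration(self):
        """q = 10 forward-backward equals brute force over 2^10 origin paths."""
        scen = popsim.SimScenario(n_families=1, n_progeny=25, n_markers=10, seed=3)
        ds = popsim.build_half_sib_population(scen, length_morgan=0.5)
        batch = _batch(ds)
        rng = np.random.default_rng(0)
        rates = rng.uniform(0.01, 0.3, 9)
        post, xi, flagged, _ = forward_backward(batch, rates)
        assert not flagged.any()
        for j in range(min(batch.n_meioses, 8)):
            probs, sw = _enumerate_oracle(batch, rates, j)
            np.testing.assert_allclose(post[j], probs, atol=1e-10)
            np.testing.assert_allclose(xi[j], sw, atol=1e-10)

    def test_posteriors_are_probabilities(self):
        scen = popsim.SimScenario(n_families=2, n_progeny=30, n_markers=50, seed=8)
        ds = popsim.build_half_sib_population(scen, length_morgan=0.6)
        batch = _batch(ds)
        post, xi, _, _ = forward_backward(batch, np.full(49, 1e-2))
        assert np.all((post >= 0) & (post <= 1))
        assert np.all((xi >= 0) & (xi <= 1))


class TestDecoding:
    def test_zero_rates_constant_path(self, discriminating_dataset):
        ds = discriminating_dataset
        sire = ds.pedigree[ds.pedigree["sire"] != "0"]["sire"].iloc[0]
        haps = ds.parent_haplotypes[sire]
        q = ds.markers.n_markers
        # a recombination-free gamete from homolog 1, dam contributes zeros
        progeny = haps[0].copy()
        post, xi = decode_transmission(
            haps, progeny, np.zeros(q, dtype=np.int8), np.zeros(q - 1),
            ds.markers, freqs=np.full(q, 0.5),
        )
        # absorbing chain: no switches, a constant origin path
        assert xi.max() < 1e-12
        assert np.all(post < 1e-9)

    def test_discriminating_marker_posterior_one(self, discriminating_dataset):
        ds = discriminating_dataset
        batch = _batch(ds)
        rates = np.minimum(ds.male_map.rates(), 0.5)
        paths = decode_paths(batch, rates)
        assert paths.informative.all()
        assert np.all(paths.posterior.astype(np.float64) >= 1.0 - 1e-6)

    def test_decoded_counts_match_simulation_exactly(self, discriminating_dataset):
        """Fully heterozygous sire, all markers discriminating: the decoded
        crossover count equals the simulated count for every meiosis."""
        ds = discriminating_dataset
        batch = _batch(ds)
        rates, post, it = em_estimate_rates(batch)
        paths = decode_paths(batch, rates)
        records = locate_crossovers(paths)
        decoded = crossover_counts(records, paths.progeny_ids)
        truth = ds.true_crossover_counts("male").reindex(decoded.index)
        np.testing.assert_array_equal(decoded.to_numpy(), truth.to_numpy())

    def test_crossover_flanks_exact_when_all_markers_informative(
        self, discriminating_dataset
    ):
        ds = discriminating_dataset
        batch = _batch(ds)
        rates, _, _ = em_estimate_rates(batch)
        records = locate_crossovers(decode_paths(batch, rates))
        truth = ds.crossovers[ds.crossovers["parent_sex"] == "male"]
        merged = records.merge(
            truth, left_on=["progeny", "left_bp"], right_on=["progeny", "left_bp"]
        )
        assert len(merged) == len(records) == len(truth)
        np.testing.assert_array_equal(
            merged["right_bp_x"].to_numpy(), merged["right_bp_y"].to_numpy()
        )

    def test_em_rates_are_switch_fractions(self, discriminating_dataset):
        ds = discriminating_dataset
        batch = _batch(ds)
        rates, _, _ = em_estimate_rates(batch)
        truth = ds.crossovers[ds.crossovers["parent_sex"] == "male"]
        counts = np.bincount(truth["interval"], minlength=ds.markers.n_markers - 1)
        np.testing.assert_allclose(rates, counts / batch.n_meioses, atol=1e-5)


class TestMapRecovery:
    def test_total_length_within_5pct(self):
        scen = popsim.SimScenario(n_families=10, n_progeny=100, n_markers=300, seed=31)
        ds = popsim.build_half_sib_population(scen)
        res = infer_genetic_map(
            ds.observed_genotypes(), ds.ids, ds.pedigree, ds.markers, method="hmm"
        )
        realized = ds.true_crossover_counts("male").mean()
        assert res.genetic_map.total_length() == pytest.approx(realized, rel=0.05)


class TestMarkerConfidence:
    def test_noiseless_data_scores_one(self, discriminating_dataset):
        ds = discriminating_dataset
        batch = _batch(ds)
        rates, _, _ = em_estimate_rates(batch)
        mcs = marker_confidence(decode_paths(batch, rates))
        assert np.nanmin(mcs) == pytest.approx(1.0)

    def test_planted_misplacement_scores_low(self):
        scen = popsim.SimScenario(n_families=4, n_progeny=60, n_markers=150, seed=13)
        ds = popsim.build_half_sib_population(scen, length_morgan=0.8)
        geno = ds.genotypes.copy()
        rng = np.random.default_rng(5)
        planted = 75
        prog = ds.progeny_index
        geno[prog, planted] = geno[rng.permutation(prog), planted]
        fams = split_families(geno, ds.ids, ds.pedigree, "sire", 2)
        batch = build_meiosis_batch(fams, ds.markers, allele_frequencies(geno))
        rates, _, _ = em_estimate_rates(batch)
        mcs = marker_confidence(decode_paths(batch, rates))
        assert mcs[planted] < 0.986
        intact = np.delete(mcs, planted)
        assert mcs[planted] < np.nanmin(intact)


class TestTwoRunFilter:
    def test_clean_confident_data_no_removals(self, discriminating_dataset):
        ds = discriminating_dataset
        res = infer_genetic_map(
            ds.observed_genotypes(), ds.ids, ds.pedigree, ds.markers,
            method="hmm", two_run=True,
        )
        assert res.removed_markers == 0
        assert res.removed_individuals == 0

    def test_high_crossover_individual_removed(self, discriminating_dataset):
        ds = discriminating_dataset
        counts = ds.true_crossover_counts("male")
        threshold = int(counts.max()) - 1
        assert threshold >= 1
        res = infer_genetic_map(
            ds.observed_genotypes(), ds.ids, ds.pedigree, ds.markers,
            method="hmm", two_run=True, max_crossovers=threshold,
        )
        assert res.removed_individuals == int((counts > threshold).sum())

    def test_planted_misplacement_absent_from_final_map(self):
        scen = popsim.SimScenario(n_families=4, n_progeny=60, n_markers=150, seed=13)
        ds = popsim.build_half_sib_population(scen, length_morgan=0.8)
        geno = ds.genotypes.copy()
        rng = np.random.default_rng(5)
        planted = 75
        prog = ds.progeny_index
        geno[prog, planted] = geno[rng.permutation(prog), planted]
        res = infer_genetic_map(geno, ds.ids, ds.pedigree, ds.markers,
                                method="hmm", two_run=True)
        assert ds.markers.marker_id[planted] not in set(res.markers.marker_id)


class TestNearDoubleCrossovers:
    def test_pair_within_threshold_counted(self):
        import pandas as pd

        rec = pd.DataFrame(
            {
                "progeny": ["p1", "p1", "p2"],
                "parent_sex": ["male"] * 3,
                "chrom": [1, 1, 1],
                "midpoint_bp": [10_000_000, 11_500_000, 40_000_000],
            }
        )
        prop = near_double_crossover_stats(rec)
        assert prop[1] == pytest.approx(2 / 3)

    def test_single_crossover_contributes_zero(self):
        import pandas as pd

        rec = pd.DataFrame(
            {"progeny": ["p1"], "parent_sex": ["male"], "chrom": [2],
             "midpoint_bp": [5_000_000]}
        )
        assert near_double_crossover_stats(rec)[2] == 0.0

    def test_zero_threshold_gives_zero(self):
        import pandas as pd

        rec = pd.DataFrame(
            {
                "progeny": ["p1", "p1"],
                "parent_sex": ["male", "male"],
                "chrom": [1, 1],
                "midpoint_bp": [10_000_000, 10_100_000],
            }
        )
        assert near_double_crossover_stats(rec, threshold_bp=0).max() == 0.0

    def test_midpoint_arithmetic(self):
        assert (10_000_000 + 10_845_000) // 2 == 10_422_500
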