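"""Interaction matrices, degrees, densities, success rates, correlations."""
import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

import rearingnet as rn
from rearingnet.network import (build_matrix, degree_stats, export_network,
                                host_density, mass_correlations, read_edge_list,
                                spearman_mass_correlation, success_rates)
from rearingnet.records import summarize

P1, P2 = "2007-2008", "2018-2019"


class TestBuildMatrix:
    def test_single_sample_cell(self, tiny_dataset):
        m = build_matrix(tiny_dataset, P1)
        assert m.counts.loc["X", "T1"] == 30
        assert m.binary.loc["X", "T1"] == 1
        assert m.counts.loc["Y", "T3"] == 0  # other period

    def test_pooled_matrix_conserves_total_count(self, synthetic):
        ds, _ = synthetic
        m = build_matrix(ds)
        assert m.total == sum(e.count for e in ds.emergences)

    def test_period_matrices_partition_the_pooled_one(self, synthetic):
        ds, _ = synthetic
        pooled = build_matrix(ds).counts
        parts = sum(build_matrix(ds, p).counts for p in ds.periods)
        assert pooled.equals(parts)

    def test_binary_occupancy_matches_pair_scan(self, small_synthetic):
        ds, _ = small_synthetic
        b = build_matrix(ds).binary
        sample_taxon = {u.sample_id: u.taxon_code for u in ds.samples}
        pairs = {(e.fly_code, sample_taxon[e.sample_id]) for e in ds.emergences}
        for f, h in itertools.product(b.index, b.columns):
            assert b.loc[f, h] == int((f, h) in pairs)

    def test_empty_emergences_give_zero_matrix(self, tiny_dataset):
        tiny_dataset.emergences = []
        m = build_matrix(tiny_dataset)
        assert m.total == 0

    def test_unknown_period_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="unknown period"):
            build_matrix(tiny_dataset, "1999")


class TestDegreeStats:
    def test_families_counted_across_hosts(self, tiny_dataset):
        m = build_matrix(tiny_dataset)
        d = degree_stats(m, tiny_dataset.taxa)
        # X bred in pineapple (Bromeliaceae) and banana (Musaceae)
        assert d.per_fly.loc["X"].tolist() == [2, 2]
        # Y bred in banana and carrot (Musaceae, Apiaceae)
        assert d.per_fly.loc["Y"].tolist() == [2, 2]
        assert d.per_fly.loc["Z"].tolist() == [0, 0]
        assert d.per_host["T2"] == 2

    def test_pooled_host_range_dominates_period_ranges(self, synthetic):
        ds, _ = synthetic
        pooled = degree_stats(build_matrix(ds), ds.taxa).per_fly["n_hosts"]
        for p in ds.periods:
            per = degree_stats(build_matrix(ds, p), ds.taxa).per_fly["n_hosts"]
            assert (pooled >= per).all()


class TestHostDensity:
    def test_empty_samples_excluded_from_denominator(self, tiny_dataset):
        d = host_density(tiny_dataset)
        assert d["T1"] == pytest.approx(0.30)

    def test_two_productive_samples(self):
        import rearingnet.records as r
        ds = r.RearingDataset(
            taxa=[r.PlantTaxon("T", "x", "F", r.Origin.EXOTIC,
                               r.ResourceType.FLESHY_FRUIT)],
            species=[r.FlySpecies("A", "a", r.Origin.EXOTIC)],
            samples=[r.SampleUnit("s1", P1, "T", 10.0),
                     r.SampleUnit("s2", P1, "T", 10.0)],
            emergences=[r.EmergenceRecord("s1", "A", 5),
                        r.EmergenceRecord("s2", "A", 15)])
        assert host_density(ds)["T"] == pytest.approx(1.0)
        assert host_density(ds, productive_only=False)["T"] == pytest.approx(1.0)

    def test_unproductive_taxa_omitted(self, tiny_dataset):
        d = host_density(tiny_dataset)
        assert "T3" in d.index  # carrot produced Y
        tiny_dataset.emergences = [e for e in tiny_dataset.emergences
                                   if e.sample_id != "S4"]
        assert "T3" not in host_density(tiny_dataset).index

    def test_density_times_productive_mass_recovers_totals(self, synthetic):
        ds, _ = synthetic
        d = host_density(ds)
        productive = {u.sample_id: 0 for u in ds.samples}
        for e in ds.emergences:
            productive[e.sample_id] += e.count
        mass = {}
        flies = {}
        for u in ds.samples:
            if productive[u.sample_id] > 0:
                mass[u.taxon_code] = mass.get(u.taxon_code, 0.0) + u.mass_g
            flies[u.taxon_code] = flies.get(u.taxon_code, 0) + productive[u.sample_id]
        for code, val in d.items():
            assert val * mass[code] == pytest.approx(flies[code], abs=1e-9)
            assert val > 0


class TestSuccessRates:
    def test_study_rates(self, paper):
        sr = success_rates(paper.plant_rows)
        assert (sr.overall.emerged, sr.overall.total) == (35, 50)
        assert sr.overall.pct_1dp == 70.0
        assert (sr.fleshy_fruit.emerged, sr.fleshy_fruit.total) == (30, 39)
        assert sr.fleshy_fruit.pct_1dp == 76.9
        assert (sr.other_pooled.emerged, sr.other_pooled.total) == (5, 11)
        assert sr.other_pooled.pct_1dp == 45.5

    def test_no_root_tuber_ever_produced_flies(self, paper):
        sr = success_rates(paper.plant_rows)
        assert sr.per_type["RT"].emerged == 0

    def test_empty_registry_rejected(self, paper):
        with pytest.raises(ValueError, match="empty"):
            success_rates(paper.plant_rows.iloc[:0])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_mass_correlation([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)
        assert spearman_mass_correlation([1, 2, 3], [30, 20, 10]).rho == pytest.approx(-1.0)

    def test_tied_case_against_enumeration_oracle(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        res = spearman_mass_correlation(x, y)
        # rho = Pearson correlation of midranks
        xr, yr = sps.rankdata(x), sps.rankdata(y)
        assert res.rho == pytest.approx(sps.pearsonr(xr, yr)[0])
        assert res.rho == pytest.approx(sps.spearmanr(x, y)[0])
        # exhaustive two-sided permutation p-value, computed independently
        obs = abs(sps.pearsonr(xr, yr)[0])
        hits = sum(abs(sps.pearsonr(xr, np.array(p))[0]) >= obs - 1e-9
                   for p in itertools.permutations(yr))
        assert res.p_value == pytest.approx(hits / math.factorial(4))
        assert res.method == "exact-permutation"

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(5)
        x = rng.random(30)
        y = x + 0.3 * rng.random(30)
        res = spearman_mass_correlation(x, y)
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)
        assert res.method == "t-approximation"

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_mass_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="at least 3"):
            spearman_mass_correlation([1, 2], [1, 2])

    def test_mass_drives_abundance_in_fully_compatible_surveys(self):
        cfg = rn.SimulationConfig(n_host_taxa=50,
                                  compat=rn.CompatProbs(1.0, 1.0, 1.0, 1.0))
        rhos = []
        for seed in range(20):
            ds, _ = rn.generate_dataset(cfg, seed)
            rhos.append(mass_correlations(ds)["abundance"].rho)
        assert all(r > 0 for r in rhos)
        assert np.mean(rhos) > 0.5


class TestExport:
    def test_edge_list_round_trip(self, tmp_path, small_synthetic):
        ds, _ = small_synthetic
        m = build_matrix(ds)
        path = tmp_path / "edges.tsv"
        export_network(m, ds.taxa, ds.species, path)
        edges = read_edge_list(path)
        rebuilt = np.zeros_like(m.binary.to_numpy())
        fly_pos = {c: i for i, c in enumerate(m.counts.index)}
        host_pos = {c: j for j, c in enumerate(m.counts.columns)}
        for row in edges.to_dict("records"):
            rebuilt[fly_pos[row["fly_code"]], host_pos[row["taxon_code"]]] = 1
            assert row["count"] == m.counts.loc[row["fly_code"], row["taxon_code"]]
        assert (rebuilt == m.binary.to_numpy()).all()

    def test_export_is_bit_reproducible(self, tmp_path, small_synthetic):
        ds, _ = small_synthetic
        m = build_matrix(ds)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        export_network(m, ds.taxa, ds.species, a)
        export_network(m, ds.taxa, ds.species, b)
        assert a.read_bytes() == b.read_bytes()

    def test_all_zero_matrix_exports_header_only(self, tmp_path, tiny_dataset):
        tiny_dataset.emergences = []
        m = build_matrix(tiny_dataset)
        path = tmp_path / "edges.tsv"
        export_network(m, tiny_dataset.taxa, tiny_dataset.species, path)
        assert path.read_text().strip().splitlines() == [
            "fly_code\ttaxon_code\tcount\tfly_origin\thost_origin"]

    def test_matrix_csv_round_trips_counts(self, tmp_path, small_synthetic):
        ds, _ = small_synthetic
        m = build_matrix(ds)
        path = tmp_path / "m.csv"
        export_network(m, ds.taxa, ds.species, path, fmt="matrix_csv")
        import pandas as pd
        back = pd.read_csv(path, index_col=0)
        assert (back.to_numpy() == m.counts.to_numpy()).all()
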