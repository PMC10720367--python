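"""Meiosis, inbreeding and trial-generator behaviour against closed forms."""

import numpy as np
import pandas as pd
import pytest

from namqtl import ammi, simdata


def _one_chrom_map(positions):
    return simdata.GeneticMap(pd.DataFrame({
        "chromosome": "1A",
        "marker_id": [f"m{i}" for i in range(len(positions))],
        "position_cM": positions,
    }))


class TestGamete:
    def test_single_marker_equal_parental_odds(self, rng):
        gmap = _one_chrom_map([0.0])
        a, b = np.array([1]), np.array([0])
        draws = np.array([simdata.simulate_gamete(a, b, gmap, rng)[0]
                          for _ in range(2000)])
        assert abs(draws.mean() - 0.5) < 3 * 0.5 / np.sqrt(2000)

    def test_zero_distance_never_recombines(self, rng):
        gmap = _one_chrom_map([5.0, 5.0])
        a, b = np.array([1, 1]), np.array([0, 0])
        for _ in range(300):
            g = simdata.simulate_gamete(a, b, gmap, rng)
            assert g[0] == g[1]

    def test_haldane_recombinant_fraction_at_one_morgan(self, rng):
        gmap = _one_chrom_map([0.0, 100.0])
        a, b = np.array([1, 1]), np.array([0, 0])
        n = 10_000
        rec = np.array([simdata.simulate_gamete(a, b, gmap, rng)
                        for _ in range(n)])
        frac = (rec[:, 0] != rec[:, 1]).mean()
        expected = 0.5 * (1 - np.exp(-2.0))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_adjacent_gaps_invert_to_cM(self, rng):
        """Inverse-Haldane of estimated recombination fractions recovers the map."""
        gmap = _one_chrom_map([0.0, 8.0, 20.0, 45.0])
        a = np.ones(4, dtype=int)
        b = np.zeros(4, dtype=int)
        n = 10_000
        g = np.array([simdata.simulate_gamete(a, b, gmap, rng) for _ in range(n)])
        for j, gap in enumerate(np.diff([0.0, 8.0, 20.0, 45.0])):
            rf = (g[:, j] != g[:, j + 1]).mean()
            d_hat = -50.0 * np.log(1 - 2 * rf)
            r_true = 0.5 * (1 - np.exp(-2 * gap / 100))
            se_rf = np.sqrt(r_true * (1 - r_true) / n)
            se_d = se_rf * 100.0 / (1 - 2 * r_true)
            assert abs(d_hat - gap) < 3 * se_d

    def test_length_mismatch_rejected(self, rng):
        gmap = _one_chrom_map([0.0, 10.0])
        with pytest.raises(ValueError):
            simdata.simulate_gamete(np.array([1]), np.array([0, 0]), gmap, rng)


class TestRil:
    @pytest.mark.parametrize("g", [1, 2, 4, 6])
    def test_heterozygosity_decay(self, g, rng):
        gmap = _one_chrom_map(list(np.linspace(0, 50, 20)))
        a, b = np.ones(20, dtype=int), np.zeros(20, dtype=int)
        n = 400
        het = np.array([
            (simdata.derive_ril(a, b, gmap, g, rng) == 1).mean()
            for _ in range(n)])
        expected = 0.5**g
        se = het.std(ddof=1) / np.sqrt(n)
        assert abs(het.mean() - expected) < 3 * max(se, 1e-4)

    def test_f1_heterozygous_everywhere(self, rng):
        gmap = _one_chrom_map([0.0, 30.0, 60.0])
        g = simdata.derive_ril(np.array([1, 1, 1]), np.array([0, 0, 0]),
                               gmap, 0, rng)
        assert (g == 1).all()

    def test_monomorphic_marker_fixed(self, rng):
        gmap = _one_chrom_map([0.0, 30.0])
        for _ in range(50):
            g = simdata.derive_ril(np.array([1, 1]), np.array([1, 0]),
                                   gmap, 4, rng)
            assert g[0] == 2


class TestNam:
    def test_default_design_counts(self, small_study):
        sim = small_study.sim
        assert sim.genotypes.n_lines == 426 + 4
        counts = sim.pedigree[~sim.pedigree["is_parent"]][
            "subfamily"].value_counts()
        assert sorted(counts.to_numpy()) == [138, 142, 146]

    def test_missing_rate_zero_leaves_no_gaps(self, small_map, rng):
        parents = simdata.make_parents(small_map, rng, donor_ids=("D1", "D2"))
        sim = simdata.simulate_nam(parents, small_map, simdata.SimConfig(
            n_rils_per_cross=(10, 10), missing_rate=0.0,
            genotyping_error_rate=0.0, seed=3))
        assert not np.isnan(sim.genotypes.calls).any()

    def test_seed_reproducible(self, small_map):
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        p1 = simdata.make_parents(small_map, rng1, donor_ids=("D1",))
        p2 = simdata.make_parents(small_map, rng2, donor_ids=("D1",))
        cfg = simdata.SimConfig(n_rils_per_cross=(25,), seed=9)
        s1 = simdata.simulate_nam(p1, small_map, cfg)
        s2 = simdata.simulate_nam(p2, small_map, cfg)
        assert np.array_equal(s1.genotypes.calls, s2.genotypes.calls,
                              equal_nan=True)

    def test_subfamily_allele_frequency_near_half(self, biparental):
        gmap, parents, prog = biparental
        freq = prog.calls.mean(axis=0) / 2.0
        se = np.sqrt(0.25 / prog.n_lines)
        assert (np.abs(freq - 0.5) < 4 * se).mean() > 0.95

    def test_no_near_duplicate_lines(self, small_study):
        prog = small_study.sim.true_genotypes
        sub = prog.calls[:100]
        same = (sub[:, None, :] == sub[None, :, :]).mean(axis=2)
        np.fill_diagonal(same, 0.0)
        assert same.max() <= 0.99


class TestGeneticValues:
    def test_empty_qtl_list_zero_variance(self, biparental):
        gmap, _, prog = biparental
        gv = simdata.genetic_values(prog, [], gmap)
        assert float(gv.to_numpy().var()) == 0.0

    def test_homozygous_class_gap_is_twice_effect(self, biparental):
        gmap, _, prog = biparental
        q = simdata.PlantedQtl("T", "1A", 50.0, 1.7)
        gv = simdata.genetic_values(prog, [q], gmap)["T"]
        dose = prog.calls[:, prog.marker_index("m5")]
        gap = gv[dose == 2].mean() - gv[dose == 0].mean()
        assert gap == pytest.approx(2 * 1.7)

    def test_three_qtl_enumeration(self, biparental):
        """Class means over the 8 homozygous haplotypes match hand enumeration."""
        gmap, _, prog = biparental
        effects = [2.0, 1.0, 1.0]
        markers = ["m1", "m5", "m9"]
        qtls = [simdata.PlantedQtl("T", "1A", p, a)
                for p, a in zip([10.0, 50.0, 90.0], effects)]
        gv = simdata.genetic_values(prog, qtls, gmap)["T"].to_numpy()
        doses = prog.calls[:, [prog.marker_index(m) for m in markers]]
        expected = doses @ np.array(effects)
        assert np.allclose(gv, expected)
        # hand enumeration of the 8 all-homozygous patterns
        for pattern in range(8):
            bits = [(pattern >> k) & 1 for k in range(3)]
            sel = np.all(doses == 2 * np.array(bits), axis=1)
            if sel.any():
                hand = 2 * (2.0 * bits[0] + 1.0 * bits[1] + 1.0 * bits[2])
                assert gv[sel].mean() == pytest.approx(hand)

    def test_unknown_chromosome_rejected(self, biparental):
        gmap, _, prog = biparental
        with pytest.raises(KeyError):
            simdata.genetic_values(
                prog, [simdata.PlantedQtl("T", "9Z", 5.0, 1.0)], gmap)


class TestTrials:
    def _specs(self, checks, residual_sd, trend, loading):
        return [simdata.EnvSpec(
            env_id=f"E{j}", moisture_class="stressed" if j < 1 else "non_stressed",
            main_effect={"TKW": 40.0 + j, "GY": 3000.0, "DtH": 100.0,
                         "DtM": 140.0, "PLH": 80.0, "Spk.m2": 300.0},
            ipca_loading=np.array(loading[j]),
            blocks=4, block_size=16, check_ids=tuple(checks),
            spatial_trend={"TKW": trend},
            residual_sd={k: residual_sd for k in
                         ("TKW", "GY", "DtH", "DtM", "PLH", "Spk.m2")},
        ) for j in range(len(loading))]

    def test_noiseless_plots_are_exactly_additive(self, rng):
        gv = pd.DataFrame({t: rng.normal(size=40) for t in
                           ("TKW", "GY", "DtH", "DtM", "PLH", "Spk.m2")},
                          index=[f"L{i}" for i in range(40)])
        gv["TKW"] = np.abs(gv["TKW"])
        specs = self._specs(["L0", "L1"], 1e-12, (0.0, 0.0), [[0.0], [0.0]])
        plots, _, _ = simdata.simulate_trials(
            gv, specs, rng, interaction_sd={t: 0.0 for t in gv.columns})
        tkw = plots["kernel_sample_weight"] * 5
        expect = (plots["entry_id"].map(gv["TKW"]).to_numpy()
                  + plots["env_id"].map({s.env_id: s.main_effect["TKW"]
                                         for s in specs}).to_numpy())
        assert np.allclose(tkw, expect, atol=1e-8)

    def test_checks_replicated_once_per_block(self, small_study):
        plots = small_study.plots
        checks = small_study.parents.parent_ids
        for env, sub in plots.groupby("env_id"):
            counts = sub[sub["entry_id"].isin(checks)]["entry_id"].value_counts()
            assert (counts >= 10).all()

    def test_rank_one_interaction_recovered_by_ammi(self, rng):
        gv = pd.DataFrame({t: rng.normal(size=40) for t in
                           ("TKW", "GY", "DtH", "DtM", "PLH", "Spk.m2")},
                          index=[f"L{i}" for i in range(40)])
        loadings = [[1.0], [-0.5], [0.25], [-0.75]]
        specs = self._specs(["L0", "L1"], 1e-9, (0.0, 0.0), loadings)
        plots, _, _ = simdata.simulate_trials(
            gv, specs, rng, interaction_sd={"TKW": 2.0})
        tkw = plots.assign(TKW=plots["kernel_sample_weight"] * 5)
        ge = tkw.pivot_table(index="entry_id", columns="env_id", values="TKW")
        dec = ammi.fit_ammi(ge)
        assert dec.variance_share[0] > 0.95

    def test_capacity_guard(self, rng):
        gv = pd.DataFrame({t: rng.normal(size=200) for t in
                           ("TKW", "GY", "DtH", "DtM", "PLH", "Spk.m2")},
                          index=[f"L{i}" for i in range(200)])
        specs = self._specs(["L0"], 1.0, (0.0, 0.0), [[0.0]])
        with pytest.raises(ValueError, match="capacity"):
            simdata.simulate_trials(gv, specs, rng)

    def test_stressed_sites_get_less_grainfill_rain(self, small_study):
        from namqtl import envclim
        cm = envclim.build_climate_matrix(small_study.climate,
                                          small_study.stage_dates)
        stressed = [s.env_id for s in small_study.env_specs
                    if s.moisture_class == "stressed"]
        other = [s.env_id for s in small_study.env_specs
                 if s.moisture_class != "stressed"]
        assert (cm.loc[stressed, "grain_fill_rain_total"].max()
                <= 20.0 < cm.loc[other, "grain_fill_rain_total"].min())
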