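"""GLM/interval scans, LD-protected thresholds, MTA merging and stability."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from namqtl import assoc, simdata
from namqtl.simdata import GeneticMap, GenotypeMatrix


def _random_panel(rng, n=300, m=120):
    calls = rng.choice([0.0, 2.0], size=(n, m))
    return GenotypeMatrix([f"L{i}" for i in range(n)],
                          [f"M{j}" for j in range(m)], calls)


class TestGlmScan:
    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(21)
        geno = _random_panel(rng)
        q = pd.DataFrame(rng.normal(size=(300, 2)), index=geno.line_ids)
        dth = pd.Series(rng.normal(size=300), index=geno.line_ids)
        ps = []
        for _ in range(30):
            y = pd.Series(rng.normal(size=300), index=geno.line_ids)
            ps.append(assoc.glm_scan(geno, y, q, dth)["p_value"].to_numpy())
        stat = stats.kstest(np.concatenate(ps), "uniform")
        assert stat.pvalue > 0.01

    def test_planted_qtl_peak_localised(self, biparental):
        """Peak within 5 cM of a planted effect of 1.5 residual SD."""
        gmap, _, prog = biparental
        rng = np.random.default_rng(3)
        hits = 0
        for rep in range(10):
            dose = prog.calls[:, prog.marker_index("m5")]
            y = pd.Series(0.75 * dose + rng.normal(0, 1.0, prog.n_lines),
                          index=prog.line_ids)
            scan = assoc.glm_scan(prog, y)
            peak = scan.loc[scan["lod"].idxmax(), "marker_id"]
            pos = gmap.table.set_index("marker_id")["position_cM"]
            hits += abs(pos[peak] - 50.0) <= 5.0
        assert hits >= 9

    def test_monomorphic_marker_skipped_with_warning(self, rng):
        geno = _random_panel(rng, n=60, m=5)
        geno.calls[:, 2] = 2.0
        y = pd.Series(rng.normal(size=60), index=geno.line_ids)
        with pytest.warns(UserWarning, match="skipped"):
            scan = assoc.glm_scan(geno, y)
        assert scan.loc[2, "skip_reason"] == "monomorphic"
        assert np.isnan(scan.loc[2, "p_value"])

    def test_effect_recovers_allele_substitution(self, rng):
        geno = _random_panel(rng, n=4000, m=3)
        dose = geno.calls[:, 0]
        y = pd.Series(1.3 * dose + rng.normal(0, 0.2, 4000),
                      index=geno.line_ids)
        scan = assoc.glm_scan(geno, y)
        assert scan.loc[0, "effect"] == pytest.approx(1.3, abs=0.02)


@pytest.fixture(scope="module")
def planted_mid_interval():
    """Trait generated at a pseudo-marker (45 cM) hidden from the scan."""
    pos = list(np.arange(0.0, 101.0, 10.0)) + [45.0]
    ids = [f"m{i}" for i in range(11)] + ["q"]
    gmap_full = GeneticMap(pd.DataFrame(
        {"chromosome": "1A", "marker_id": ids, "position_cM": pos}))
    rng = np.random.default_rng(2)
    parents = simdata.make_parents(gmap_full, rng, donor_ids=("D1",),
                                   donor_poly_rate=1.0)
    sim = simdata.simulate_nam(parents, gmap_full, simdata.SimConfig(
        n_rils_per_cross=(300,), missing_rate=0.0,
        genotyping_error_rate=0.0, seed=5))
    prog = sim.true_genotypes.subset_lines(
        ~sim.pedigree["is_parent"].to_numpy())
    keep = [m for m in prog.marker_ids if m != "q"]
    obs = GenotypeMatrix(prog.line_ids, keep,
                         prog.calls[:, [prog.marker_index(m) for m in keep]])
    gmap = GeneticMap(gmap_full.table[gmap_full.table.marker_id != "q"])
    return prog, obs, gmap, rng


class TestIntervalScan:
    def test_peak_between_flanks_and_above_them(self, planted_mid_interval):
        prog, obs, gmap, rng = planted_mid_interval
        y = pd.Series(prog.calls[:, prog.marker_index("q")]
                      + rng.normal(0, 1.0, prog.n_lines), index=prog.line_ids)
        prof, _ = assoc.interval_scan(obs, gmap, y, walk_cM=1.0)
        seg = prof[(prof.position_cM > 40) & (prof.position_cM < 50)]
        flank = prof[prof.position_cM.isin([40.0, 50.0])]["lod"].max()
        assert seg["lod"].max() > flank
        peak_pos = seg.loc[seg["lod"].idxmax(), "position_cM"]
        assert 40.0 < peak_pos < 50.0

    def test_two_linked_qtl_resolved_with_cofactors(self, planted_mid_interval):
        prog, obs, gmap, _ = planted_mid_interval
        rng = np.random.default_rng(9)
        y = pd.Series(prog.calls[:, prog.marker_index("m2")]
                      + prog.calls[:, prog.marker_index("m6")]
                      + rng.normal(0, 1.0, prog.n_lines), index=prog.line_ids)
        prof, cof = assoc.interval_scan(obs, gmap, y, walk_cM=2.0)
        peaks = assoc.profile_peaks(prof, 3.0)
        assert len(peaks) >= 2
        assert (abs(peaks["position_cM"] - 20.0) <= 6.0).any()
        assert (abs(peaks["position_cM"] - 60.0) <= 6.0).any()
        # without cofactor control the two signals blur into one excursion
        prof0, _ = assoc.interval_scan(obs, gmap, y, walk_cM=2.0,
                                       max_cofactors=0)
        peaks0 = assoc.profile_peaks(prof0, 3.0)
        assert len(peaks0) <= len(peaks)

    def test_null_exceedance_modest(self, planted_mid_interval):
        prog, obs, gmap, _ = planted_mid_interval
        rng = np.random.default_rng(11)
        thr = assoc.significance_thresholds(25, 0.05)["lod_threshold"]
        exceed = 0
        n_reps = 40
        for _ in range(n_reps):
            y = pd.Series(rng.normal(size=prog.n_lines), index=prog.line_ids)
            prof, _ = assoc.interval_scan(obs, gmap, y, walk_cM=4.0)
            exceed += prof["lod"].max() >= thr
        # nominal ~5%: allow a generous binomial envelope
        assert exceed <= 8

    def test_profile_continuous_across_marker_boundaries(self,
                                                         planted_mid_interval):
        prog, obs, gmap, _ = planted_mid_interval
        rng = np.random.default_rng(13)
        y = pd.Series(prog.calls[:, prog.marker_index("m5")]
                      + rng.normal(0, 1.0, prog.n_lines), index=prog.line_ids)
        prof, cof = assoc.interval_scan(obs, gmap, y, walk_cM=0.5,
                                        max_cofactors=0)  # no cofactors
        lod = prof.sort_values("position_cM")["lod"].to_numpy()
        assert np.abs(np.diff(lod)).max() < 3.0  # no grid-construction jumps


class TestThresholds:
    def test_effective_tests_paper_inputs(self):
        assert assoc.effective_tests(1879.0, 7.06) == 266

    def test_effective_tests_guards(self):
        assert assoc.effective_tests(10.0, 10.0) == 1
        assert assoc.effective_tests(5.0, 10.0) == 1
        with pytest.raises(ValueError):
            assoc.effective_tests(-1.0, 5.0)

    def test_effective_tests_monotone(self):
        assert assoc.effective_tests(2000, 7.0) >= assoc.effective_tests(1800, 7.0)
        assert assoc.effective_tests(1800, 5.0) >= assoc.effective_tests(1800, 7.0)

    def test_lod_thresholds_closed_form(self):
        t1 = assoc.significance_thresholds(1, 0.01)
        assert t1["lod_threshold"] == pytest.approx(2.0)
        t2 = assoc.significance_thresholds(100, 0.05)
        assert t2["lod_threshold"] == pytest.approx(-np.log10(5e-4), abs=1e-9)

    def test_r2_threshold_matches_t_inversion_oracle(self):
        thr = assoc.significance_thresholds(10, 0.01, n_lines=102)
        df = 100

        def pval(r):
            t = r * np.sqrt(df / (1 - r**2))
            return 2 * stats.t.sf(t, df)

        r_crit = optimize.brentq(lambda r: pval(r) - 0.05, 1e-9, 1 - 1e-9,
                                 xtol=1e-12)
        assert thr["r2_threshold"] == pytest.approx(r_crit**2, abs=1e-6)

    def test_small_panels_rejected(self):
        with pytest.raises(ValueError):
            assoc.significance_thresholds(10, 0.01, n_lines=3)


def _mta(chrom, pos, lod=5.0, trait="TKW", env=("E1",), method="glm",
         ctx=None):
    return {"trait": trait, "env_context": ctx or f"env:{env[0]}" if env else "c",
            "environments": tuple(env), "marker_id": f"mk_{chrom}_{pos}",
            "chromosome": chrom, "position_cM": float(pos), "lod": lod,
            "p_value": 10.0**-lod, "effect": 1.0, "r2": 0.1, "method": method}


class TestMergeMtas:
    def test_single_mta_single_qtl(self):
        q = assoc.merge_mtas(pd.DataFrame([_mta("1A", 10.0)]), 7.06)
        assert len(q) == 1
        assert q.iloc[0]["start_cM"] == q.iloc[0]["end_cM"] == 10.0

    def test_transitive_chaining(self):
        rows = [_mta("1A", 0.0), _mta("1A", 10.0), _mta("1A", 20.0)]
        q = assoc.merge_mtas(pd.DataFrame(rows), 7.06)  # 2xLD = 14.12
        assert len(q) == 1
        assert q.iloc[0]["n_mtas"] == 3

    def test_chromosomes_never_merge(self):
        rows = [_mta("1A", 10.0), _mta("2B", 10.0)]
        q = assoc.merge_mtas(pd.DataFrame(rows), 50.0)
        assert len(q) == 2

    def test_order_invariant_and_idempotent(self, rng):
        rows = [_mta("1A", p, lod=rng.uniform(4, 9)) for p in
                (0.0, 5.0, 30.0, 33.0, 80.0)]
        df = pd.DataFrame(rows)
        q1 = assoc.merge_mtas(df, 5.0)
        q2 = assoc.merge_mtas(df.sample(frac=1.0, random_state=2), 5.0)
        pd.testing.assert_frame_equal(q1, q2)
        assert len(q1) == 3  # gaps of 25 and 47 exceed 2x5 cM

    def test_peak_is_max_lod_member(self):
        rows = [_mta("1A", 0.0, lod=4.0), _mta("1A", 6.0, lod=9.0)]
        q = assoc.merge_mtas(pd.DataFrame(rows), 7.06)
        assert q.iloc[0]["peak_marker"] == "mk_1A_6.0"

    def test_union_of_annotations(self):
        rows = [_mta("1A", 0.0, env=("E1",), method="glm"),
                _mta("1A", 5.0, env=("E2",), method="interval", trait="GY")]
        q = assoc.merge_mtas(pd.DataFrame(rows), 7.06)
        assert q.iloc[0]["environments"] == ("E1", "E2")
        assert q.iloc[0]["methods"] == ("glm", "interval")
        assert q.iloc[0]["traits"] == ("GY", "TKW")


class TestClassifyStable:
    def _qtl(self, envs, methods):
        return pd.DataFrame([{"qtl_id": "q", "chromosome": "1A",
                              "start_cM": 0.0, "end_cM": 1.0,
                              "peak_marker": "m", "peak_lod": 5.0,
                              "traits": ("TKW",), "environments": tuple(envs),
                              "env_contexts": (), "methods": tuple(methods),
                              "n_mtas": 1}])

    def test_rules(self):
        assert not assoc.classify_stable(
            self._qtl(["E1"], ["glm", "interval"]))["stable"].iloc[0]
        assert not assoc.classify_stable(
            self._qtl(["E1", "E2", "E3"], ["glm"]))["stable"].iloc[0]
        assert assoc.classify_stable(
            self._qtl(["E1", "E2"], ["glm", "interval"]))["stable"].iloc[0]
        assert assoc.classify_stable(
            self._qtl(["E1", "E2"], ["glm"]),
            require_both_methods=False)["stable"].iloc[0]
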