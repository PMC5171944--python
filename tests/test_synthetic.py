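from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from fluxconverge.data_model import parse_dataframe
from fluxconverge.budget import assemble_bm_budget
from fluxconverge.pipeline import run_convergence_analysis
from fluxconverge.synthetic import SimConfig, generate_dataset, recovery_report


class TestGenerateDataset:
    def test_same_seed_identical_output(self):
        s1, t1 = generate_dataset(SimConfig(seed=11))
        s2, t2 = generate_dataset(SimConfig(seed=11))
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self):
        s1, _ = generate_dataset(SimConfig(seed=11))
        s2, _ = generate_dataset(SimConfig(seed=12))
        assert not s1["nep_ec"].equals(s2["nep_ec"])

    def test_zone_counts_and_schema(self, synthetic_dataset):
        sites, truth = synthetic_dataset
        assert sites["climate_zone"].value_counts().to_dict() == {
            "temperate": 22, "boreal": 6, "tropical": 3}
        records = parse_dataframe(sites)  # parses cleanly under the reader schema
        assert len(records) == 31

    def test_truth_satisfies_budget_identities(self, synthetic_dataset):
        _, truth = synthetic_dataset
        assert np.allclose(truth["nep"], truth["gpp"] - truth["reco"])
        assert np.allclose(truth["reco"], truth["ra"] + truth["rh"])
        assert np.allclose(truth["rsoil"], truth["rroot"] + truth["rh_soil"])

    def test_generated_bm_satisfies_rsoil_partition(self, synthetic_dataset):
        sites, _ = synthetic_dataset
        assert np.allclose(sites["rsoil"], sites["rroot"] + sites["rh_soil"])

    def test_zone_flux_magnitudes_in_observed_ranges(self, synthetic_dataset):
        sites, truth = synthetic_dataset
        by_zone = truth.groupby("climate_zone")["gpp"].mean()
        assert 600 < by_zone["boreal"] < 1600
        assert 1200 < by_zone["temperate"] < 2600
        assert 2500 < by_zone["tropical"] < 3600
        assert sites["reco_ec"].between(300, 4000).all()

    def test_zero_noise_zero_bias_is_exact(self):
        cfg = SimConfig(seed=5).zero_bias()
        sites, truth = generate_dataset(cfg)
        records = parse_dataframe(sites)
        for rec, (_, t) in zip(records, truth.iterrows()):
            bud = assemble_bm_budget(rec.bm)
            assert bud.nep_bm == pytest.approx(rec.ec.nep, abs=1e-9)
            assert bud.nep_bm == pytest.approx(t["nep"], abs=1e-9)
            assert bud.reco_bm == pytest.approx(rec.ec.reco, abs=1e-9)
            assert bud.gpp_bm == pytest.approx(rec.ec.gpp, abs=1e-9)
        bundle = run_convergence_analysis(sites)
        for reg in bundle.fig2_stats.values():
            assert reg.slope == pytest.approx(1.0, abs=1e-9)
        t2 = bundle.table2
        glob = t2[t2["stratum"] == "global"]
        assert np.allclose(glob["abs_diff_mean"], 0.0, atol=1e-9)

    def test_nep_offset_moves_bm_down(self):
        base = SimConfig(seed=3).zero_bias()
        shifted = replace(base, nep_bm_offset=-150.0)
        sites, _ = generate_dataset(shifted)
        records = parse_dataframe(sites)
        diffs = [rec.ec.nep - assemble_bm_budget(rec.bm).nep_bm for rec in records]
        assert np.mean(diffs) == pytest.approx(150.0, abs=1e-6)

    def test_impossible_shares_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(npp_shares=(0.5, 0.5, 0.3, 0.1))


class TestBiasMonotonicity:
    def test_rleaf_overestimate_raises_reco_relative_difference(self):
        rels = []
        for over in (0.0, 0.2, 0.4):
            cfg = replace(SimConfig(seed=9).zero_bias(),
                          rleaf_overestimate_no_light_inhibition=over,
                          p_light_inhibition=0.0)  # nobody accounts for it
            sites, _ = generate_dataset(cfg)
            bundle = run_convergence_analysis(sites)
            t2 = bundle.table2
            rels.append(float(t2[(t2["flux"] == "reco") & (t2["stratum"] == "global")]
                              ["rel_diff_mean_pct"].iloc[0]))
        assert rels[0] == pytest.approx(0.0, abs=1e-9)
        assert rels[0] < rels[1] < rels[2]

    def test_nsnf_underestimate_can_offset_rleaf_overestimate(self):
        # error compensation: Rsoil deficit cancels the Rleaf excess for NSNF sites
        cfg = replace(SimConfig(seed=21).zero_bias(),
                      rleaf_overestimate_no_light_inhibition=0.20,
                      p_light_inhibition=0.0, p_nsf=0.0)
        sites, truth = generate_dataset(cfg)
        rec0 = parse_dataframe(sites)[0]
        t0 = truth.iloc[0]
        excess = 0.20 * t0["ra_leaf"]
        u = excess / t0["rsoil"]  # underestimate fraction that exactly cancels
        cfg2 = replace(cfg, nsnf_rsoil_underestimate=float(u))
        sites2, _ = generate_dataset(cfg2)
        rec2 = parse_dataframe(sites2)[0]
        reco_bm = assemble_bm_budget(rec2.bm).reco_bm
        assert reco_bm == pytest.approx(rec2.ec.reco, rel=1e-9)


class TestRecoveryReport:
    def test_zero_bias_unbiased(self):
        cfg = replace(SimConfig(seed=2).zero_bias(), cv_ec=0.03, cv_bm=0.03,
                      nep_bm_offset=0.0)
        rep = recovery_report(cfg, n_replicates=20, base_seed=100)
        assert abs(rep.loc["nep_diff_ec_minus_bm", "bias"]) < 15.0
        for k in ("ma_slope_nep", "ma_slope_reco", "ma_slope_gpp"):
            assert abs(rep.loc[k, "bias"]) < 0.1
            # MA slope CIs undercover slightly when EC and BM error variances
            # differ (NEP: additive EC noise vs smaller aggregated BM noise)
            assert rep.loc[k, "coverage"] > 0.7
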