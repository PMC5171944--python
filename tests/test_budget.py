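import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from fluxconverge.budget import (
    InconsistencyError, InsufficientDataError, UnsupportedStatisticError,
    assemble_bm_budget, composition_summary, nep_from_stocks, partition_rsoil,
    relative_difference,
)
from fluxconverge.data_model import BmComponents, StockInventory

flux = hst.floats(min_value=0.0, max_value=3000.0, allow_nan=False)


class TestPartitionRsoil:
    @pytest.mark.parametrize("triple, expected", [
        ((650.0, 300.0, None), (650.0, 300.0, 350.0)),
        ((650.0, None, 350.0), (650.0, 300.0, 350.0)),
        ((None, 300.0, 350.0), (650.0, 300.0, 350.0)),
        ((500.0, 0.0, None), (500.0, 0.0, 500.0)),  # zero autotrophic case
    ])
    def test_completes_missing_member(self, triple, expected):
        assert partition_rsoil(*triple) == pytest.approx(expected)

    def test_negative_member_is_inconsistent(self):
        with pytest.raises(InconsistencyError):
            partition_rsoil(200.0, 300.0, None)

    def test_single_member_insufficient(self):
        with pytest.raises(InsufficientDataError):
            partition_rsoil(650.0, None, None)

    def test_all_three_checked_within_tolerance(self):
        partition_rsoil(650.0, 300.0, 350.5)  # 0.5 g slack allowed
        with pytest.raises(InconsistencyError):
            partition_rsoil(650.0, 300.0, 300.0)


class TestAssembleBudget:
    def test_worked_example(self):
        c = BmComponents(npp_wood_aboveground=300, npp_foliage=150, npp_fineroot=50,
                         ra_leaf=250, ra_wood=150, rroot=300, rh_soil=350, rh_cwd=50)
        b = assemble_bm_budget(c)
        assert b.npp_total == 500
        assert b.nep_bm == 100
        assert b.reco_bm == 1100
        assert b.gpp_bm == 1200
        assert b.gpp_bm - b.reco_bm == b.nep_bm

    def test_all_zero_components_give_zero_fluxes(self):
        c = BmComponents(npp_wood_aboveground=0, npp_foliage=0, npp_fineroot=0,
                         ra_leaf=0, ra_wood=0, rroot=0, rh_soil=0, rh_cwd=0)
        b = assemble_bm_budget(c)
        assert (b.nep_bm, b.reco_bm, b.gpp_bm) == (0, 0, 0)

    def test_missing_rh_cwd_flagged_and_treated_as_zero(self):
        c = BmComponents(npp_wood_aboveground=300, npp_foliage=150, npp_fineroot=50,
                         ra_leaf=250, ra_wood=150, rroot=300, rh_soil=350)
        b = assemble_bm_budget(c)
        assert b.nep_bm == 500 - 350
        assert b.completeness_flags["rh_cwd"] == "omitted"
        assert b.gpp_bm - b.reco_bm == pytest.approx(b.nep_bm)

    def test_missing_npp_part_blocks_nep_not_reco(self):
        c = BmComponents(ra_leaf=250, ra_wood=150, rsoil=650)
        b = assemble_bm_budget(c)
        assert b.nep_bm is None and b.gpp_bm is None
        assert b.reco_bm == 250 + 150 + 650

    @given(wood=flux, fol=flux, fine=flux, ra_leaf=flux, ra_wood=flux,
           rroot=flux, rh_soil=flux, rh_cwd=flux)
    @settings(max_examples=150, derandomize=True)
    def test_closure_identity(self, wood, fol, fine, ra_leaf, ra_wood,
                              rroot, rh_soil, rh_cwd):
        c = BmComponents(npp_wood_aboveground=wood, npp_foliage=fol,
                         npp_fineroot=fine, ra_leaf=ra_leaf, ra_wood=ra_wood,
                         rroot=rroot, rh_soil=rh_soil, rh_cwd=rh_cwd)
        b = assemble_bm_budget(c)
        assert b.gpp_bm - b.reco_bm - b.nep_bm == pytest.approx(0.0, abs=1e-9)

    def test_additivity_under_scaling(self):
        c = BmComponents(npp_wood_aboveground=300, npp_foliage=150, npp_fineroot=50,
                         ra_leaf=250, ra_wood=150, rroot=300, rh_soil=350, rh_cwd=50)
        b1 = assemble_bm_budget(c)
        c2 = BmComponents(**{k: (v * 2 if v is not None else None)
                             for k, v in vars(c).items()})
        b2 = assemble_bm_budget(c2)
        for name in ("nep_bm", "reco_bm", "gpp_bm"):
            assert getattr(b2, name) == pytest.approx(2 * getattr(b1, name))


class TestNepFromStocks:
    def test_worked_example(self):
        inv = StockInventory(2000, 2002, 10000, 10300, 5000, 5050, lateral_losses=25)
        assert nep_from_stocks(inv) == pytest.approx(200.0)

    def test_no_change_is_zero(self):
        inv = StockInventory(2000, 2001, 1000, 1000, 500, 500)
        assert nep_from_stocks(inv) == 0.0

    def test_declining_stocks_are_a_source(self):
        inv = StockInventory(2000, 2001, 1000, 950, 500, 450)
        assert nep_from_stocks(inv) == -100.0


class TestRelativeDifference:
    def test_worked_example(self):
        assert relative_difference(115.0, 100.0) == pytest.approx(15 / 107.5)

    def test_identity_is_zero(self):
        assert relative_difference(840.0, 840.0, "gpp") == 0.0

    def test_nep_unsupported(self):
        with pytest.raises(UnsupportedStatisticError):
            relative_difference(100.0, 120.0, "nep")

    @given(a=hst.floats(1.0, 4000.0), b=hst.floats(1.0, 4000.0))
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetric_and_bounded(self, a, b):
        rd = relative_difference(a, b)
        assert rd == pytest.approx(-relative_difference(b, a))
        assert -2.0 < rd < 2.0


class TestCompositionSummary:
    def test_two_identical_sites(self):
        c = BmComponents(rsoil=550, ra_leaf=280, ra_wood=150, rh_cwd=20,
                         rroot=250, rh_soil=300)
        df = composition_summary([c, c])
        assert df.loc["reco_share_rsoil", "mean"] == pytest.approx(0.55)
        assert df.loc["reco_share_rleaf", "mean"] == pytest.approx(0.28)
        assert df.loc["reco_share_rwood", "mean"] == pytest.approx(0.15)
        assert df.loc["reco_share_rh_cwd", "mean"] == pytest.approx(0.02)
        assert df.loc["reco_share_rsoil", "sem"] == 0.0

    def test_shares_sum_to_one_within_partitions(self, synthetic_dataset, rng):
        from fluxconverge.data_model import parse_dataframe
        sites, _ = synthetic_dataset
        comps = [r.bm for r in parse_dataframe(sites)]
        df = composition_summary(comps)
        reco = df.loc[[s for s in df.index if s.startswith("reco_share_")
                       and s not in ("reco_share_ra", "reco_share_rh")], "mean"]
        assert reco.sum() == pytest.approx(1.0, abs=1e-9)
        npp = df.loc[[s for s in df.index if s.startswith("npp_share_")], "mean"]
        assert npp.sum() == pytest.approx(1.0, abs=1e-9)
        assert df.loc["reco_share_ra", "mean"] + df.loc["reco_share_rh", "mean"] \
            == pytest.approx(1.0, abs=1e-9)

    def test_single_site_insufficient(self):
        with pytest.raises(InsufficientDataError):
            composition_summary([BmComponents(rsoil=550, ra_leaf=280, ra_wood=150)])
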