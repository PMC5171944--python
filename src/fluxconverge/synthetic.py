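"""Generator of study-shaped EC/BM flux datasets with known ground truth.

Emulates the structure of a multi-site forest carbon-flux compilation:
three climate zones with zone-dependent flux magnitudes, biometric
component fluxes derived from a latent true GPP through configurable
partition fractions, method-variant categories sampled per site, and
configurable method-specific measurement biases.  The latent truth
satisfies the budget identities exactly, so every systematic EC-BM
discrepancy in a generated dataset is traceable to an injected bias
parameter — which is what makes parameter-recovery testing possible.

The generated site table uses the same column schema as the reader in
:mod:`fluxconverge.data_model`; a companion truth table carries the latent
fluxes.  Generation is fully reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "generate_dataset", "recovery_report"]


@dataclass
class SimConfig:
    """Simulation parameters; defaults mirror the study conditions.

    Flux units gC m-2 y-1.  `n_sites` defaults to 6 boreal / 22 temperate /
    3 tropical sites; true GPP is drawn per zone from a normal distribution
    whose means sit inside the observed per-zone flux ranges.  Partition
    fractions set NPP:GPP ~ 0.45, NPP shares ~ 30/34/30(+6 other)% for
    foliage/wood/roots, Ra shares ~ 39/22/38%, Rh:Reco ~ 0.32 and fine
    roots ~ 70% of root NPP.

    Bias parameters (all zero-able):

    * ``nep_bm_offset`` — additive offset injected into BM aboveground wood
      NPP, shifting NEP_BM and GPP_BM by the same amount;
    * ``rleaf_overestimate_no_light_inhibition`` — fractional Rleaf
      inflation at sites neglecting light inhibition of leaf respiration;
    * ``nsnf_rsoil_underestimate`` — fractional Rsoil deficit for closed
      static (NSNF) chamber sites;
    * ``npp_missing_fraction`` — fractional NPP shrink at sites not
      measuring branch turnover;
    * ``p_rh_cwd_considered`` — probability a site reports Rh-cwd at all
      (unreported Rh-cwd biases NEP_BM upward).
    """

    # design
    n_sites: dict = field(default_factory=lambda: {"boreal": 6, "temperate": 22, "tropical": 3})
    gpp_mean_sd: dict = field(default_factory=lambda: {
        "boreal": (1000.0, 200.0), "temperate": (1800.0, 400.0), "tropical": (3200.0, 300.0),
    })
    n_stock_sites: int = 7

    # partition fractions (latent truth)
    npp_gpp_ratio: float = 0.45
    npp_gpp_sd: float = 0.03
    npp_shares: tuple = (0.30, 0.34, 0.30, 0.06)   # foliage, abovegr. wood, root, other
    ra_shares: tuple = (0.39, 0.22, 0.38, 0.01)    # leaf, wood, root, understory
    fineroot_frac_of_root: float = 0.70
    rh_reco_ratio: float = 0.32
    rh_cwd_frac_of_reco: float = 0.05
    share_jitter_cv: float = 0.06

    # observation noise (coefficients of variation)
    cv_ec: float = 0.05
    cv_bm: float = 0.08

    # measurement biases
    nep_bm_offset: float = -100.0
    npp_missing_fraction: float = 0.0
    rleaf_overestimate_no_light_inhibition: float = 0.20
    nsnf_rsoil_underestimate: float = 0.15
    daytime_reco_offset: float = 0.04   # daytime-partitioned Reco_EC vs nighttime

    # method-variant category probabilities
    p_light_inhibition: float = 0.28
    p_nsf: float = 0.60
    p_scrubbing_given_nsf: float = 0.30
    p_high_quality: float = 0.60
    p_rh_cwd_considered: float = 0.65
    p_branch_measured: float = 0.20
    p_mycorrhiza_measured: float = 0.10
    p_daytime_partitioning: float = 0.30
    rh_soil_method_probs: tuple = (0.60, 0.20, 0.10, 0.10)
    fine_root_method_probs: tuple = (0.26, 0.19, 0.23, 0.32)

    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.npp_shares) > 1.0 + 1e-9 or sum(self.ra_shares) > 1.0 + 1e-9:
            raise ValueError("partition shares must sum to <= 1")
        for name in ("npp_gpp_ratio", "rh_reco_ratio", "rh_cwd_frac_of_reco",
                     "fineroot_frac_of_root", "npp_missing_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if any(n < 1 for n in self.n_sites.values()):
            raise ValueError("each included zone needs n_sites >= 1")

    def zero_bias(self) -> "SimConfig":
        """Copy with all noise and bias parameters switched off."""
        return replace(
            self, cv_ec=0.0, cv_bm=0.0, nep_bm_offset=0.0,
            npp_missing_fraction=0.0, rleaf_overestimate_no_light_inhibition=0.0,
            nsnf_rsoil_underestimate=0.0, daytime_reco_offset=0.0,
            share_jitter_cv=0.0, npp_gpp_sd=0.0, p_rh_cwd_considered=1.0,
        )


_LAT_RANGES = {"boreal": (55.0, 66.0), "temperate": (35.0, 55.0), "tropical": (0.0, 20.0)}
_MAT = {"boreal": (-1.0, 3.0), "temperate": (9.0, 4.0), "tropical": (26.0, 1.0)}
_MAP = {"boreal": (550.0, 150.0), "temperate": (900.0, 300.0), "tropical": (2500.0, 500.0)}


def _shares(rng, base, jitter_cv):
    base = np.asarray(base, dtype=float)
    if jitter_cv <= 0:
        return base / base.sum()
    j = base * (1 + rng.normal(0.0, jitter_cv, size=len(base)))
    j = np.clip(j, 1e-3, None)
    return j / j.sum()


def _mult_noise(rng, cv):
    return 1.0 + rng.normal(0.0, cv) if cv > 0 else 1.0


def generate_dataset(cfg: Optional[SimConfig] = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (site table, ground-truth table) as DataFrames.

    The site table matches the reader schema; truth carries the latent
    per-site fluxes (gpp, reco, nep, npp, ra, rh_soil, rh_cwd, ...).
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    rows, truth_rows = [], []
    site_no = 0
    for zone, n in cfg.n_sites.items():
        mu, sd = cfg.gpp_mean_sd[zone]
        for _ in range(n):
            site_no += 1
            sid = f"SYN-{zone[:3].upper()}-{site_no:02d}"
            gpp = max(float(rng.normal(mu, sd)) if sd > 0 else mu, 400.0)

            npp_ratio = cfg.npp_gpp_ratio
            if cfg.npp_gpp_sd > 0:
                npp_ratio = float(np.clip(rng.normal(npp_ratio, cfg.npp_gpp_sd), 0.30, 0.60))
            npp = npp_ratio * gpp
            ra = gpp - npp
            reco = ra / (1.0 - cfg.rh_reco_ratio)
            rh = reco - ra
            rh_cwd = cfg.rh_cwd_frac_of_reco * reco
            rh_soil = rh - rh_cwd
            nep = gpp - reco

            f_fol, f_wood, f_root, f_other = _shares(rng, cfg.npp_shares, cfg.share_jitter_cv)
            npp_fol, npp_wood = f_fol * npp, f_wood * npp
            npp_root, npp_under = f_root * npp, f_other * npp
            npp_fine = cfg.fineroot_frac_of_root * npp_root
            npp_coarse = npp_root - npp_fine

            s_leaf, s_wood, s_root, s_under = _shares(rng, cfg.ra_shares, cfg.share_jitter_cv)
            ra_leaf, ra_wood = s_leaf * ra, s_wood * ra
            rroot, ra_under = s_root * ra, s_under * ra
            rsoil = rroot + rh_soil

            # --- method profile ----------------------------------------
            light_inh = bool(rng.random() < cfg.p_light_inhibition)
            nsf = bool(rng.random() < cfg.p_nsf)
            chamber = "nsf" if nsf else "nsnf"
            scrubbing = bool(rng.random() < cfg.p_scrubbing_given_nsf) if nsf else None
            quality = "high" if rng.random() < cfg.p_high_quality else "fair"
            cwd_considered = bool(rng.random() < cfg.p_rh_cwd_considered)
            branch_meas = bool(rng.random() < cfg.p_branch_measured)
            myco_meas = bool(rng.random() < cfg.p_mycorrhiza_measured)
            partitioning = (
                "daytime" if rng.random() < cfg.p_daytime_partitioning else "nighttime"
            )
            rh_method = ["root_exclusion", "root_respiration",
                         "component_integration", "other"][
                int(rng.choice(4, p=cfg.rh_soil_method_probs))]
            fr_method = ["sequential_coring", "ingrowth_cores", "minirhizotron", "other"][
                int(rng.choice(4, p=cfg.fine_root_method_probs))]

            # --- EC observations ----------------------------------------
            nep_noise_sd = cfg.cv_ec * gpp
            nep_ec = nep + (float(rng.normal(0.0, nep_noise_sd)) if cfg.cv_ec > 0 else 0.0)
            reco_ec = reco * _mult_noise(rng, cfg.cv_ec)
            gpp_ec = nep_ec + reco_ec
            reco_ec_day = reco * (1 + cfg.daytime_reco_offset) * _mult_noise(rng, cfg.cv_ec)
            gpp_ec_day = nep_ec + reco_ec_day

            # --- BM observations (noise then biases) --------------------
            shrink = 1.0 - (cfg.npp_missing_fraction if not branch_meas else 0.0)
            bm_fol = npp_fol * _mult_noise(rng, cfg.cv_bm) * shrink
            bm_wood = npp_wood * _mult_noise(rng, cfg.cv_bm) * shrink
            bm_fine = npp_fine * _mult_noise(rng, cfg.cv_bm) * shrink
            bm_coarse = npp_coarse * _mult_noise(rng, cfg.cv_bm) * shrink
            bm_under = npp_under * _mult_noise(rng, cfg.cv_bm)
            if cfg.nep_bm_offset != 0.0:
                # shift total BM NPP by exactly the offset, spread proportionally
                total = bm_fol + bm_wood + bm_fine + bm_coarse + bm_under
                factor = max(total + cfg.nep_bm_offset, 1.0) / total
                bm_fol, bm_wood, bm_fine, bm_coarse, bm_under = (
                    v * factor for v in (bm_fol, bm_wood, bm_fine, bm_coarse, bm_under)
                )

            rleaf_bias = (
                1.0 + cfg.rleaf_overestimate_no_light_inhibition if not light_inh else 1.0
            )
            bm_ra_leaf = ra_leaf * _mult_noise(rng, cfg.cv_bm) * rleaf_bias
            bm_ra_wood = ra_wood * _mult_noise(rng, cfg.cv_bm)
            bm_ra_under = ra_under * _mult_noise(rng, cfg.cv_bm)

            soil_bias = 1.0 - (cfg.nsnf_rsoil_underestimate if chamber == "nsnf" else 0.0)
            bm_rroot = rroot * _mult_noise(rng, cfg.cv_bm) * soil_bias
            bm_rh_soil = rh_soil * _mult_noise(rng, cfg.cv_bm) * soil_bias
            bm_rsoil = bm_rroot + bm_rh_soil   # partition identity holds exactly
            bm_rh_cwd = rh_cwd * _mult_noise(rng, cfg.cv_bm) if cwd_considered else None

            # --- site metadata ------------------------------------------
            lat_lo, lat_hi = _LAT_RANGES[zone]
            lat = float(rng.uniform(lat_lo, lat_hi))
            mat = float(rng.normal(*_MAT[zone]))
            map_ = max(float(rng.normal(*_MAP[zone])), 100.0)
            years = int(rng.integers(1, 9))

            row = {
                "site_id": sid, "latitude": lat,
                "longitude": float(rng.uniform(-180.0, 180.0)),
                "climate_zone": zone, "years_measured": years,
                "data_quality": quality,
                "nep_ec": nep_ec, "reco_ec": reco_ec, "gpp_ec": gpp_ec,
                "reco_ec_daytime": reco_ec_day, "gpp_ec_daytime": gpp_ec_day,
                "ec_partitioning": partitioning,
                "mean_annual_temperature": mat, "mean_annual_precipitation": map_,
                "fertility": str(rng.choice(["low", "medium", "high"])),
                "leaf_type": str(rng.choice(["needleleaved", "broadleaved", "mixed"])),
                "leaf_habit": str(rng.choice(["evergreen", "deciduous", "mixed"])),
                "lai": float(rng.uniform(1.5, 8.0)),
                "elevation_variability": float(rng.uniform(1.0, 120.0)),
                "topographical_slope": float(rng.uniform(0.5, 30.0)),
                "npp_wood_aboveground": bm_wood, "npp_foliage": bm_fol,
                "npp_fineroot": bm_fine, "npp_coarseroot": bm_coarse,
                "npp_understory": bm_under,
                "ra_leaf": bm_ra_leaf, "ra_wood": bm_ra_wood,
                "ra_understory": bm_ra_under,
                "rsoil": bm_rsoil, "rroot": bm_rroot, "rh_soil": bm_rh_soil,
                "rh_cwd": bm_rh_cwd,
                "fine_root_npp_method": fr_method,
                "allometry_quality": str(rng.choice(["low", "moderate", "high"])),
                "leaf_npp_method": str(rng.choice(["litter_trap", "allometry"], p=[0.7, 0.3])),
                "soil_chamber": chamber, "co2_scrubbing": scrubbing,
                "rh_soil_method": rh_method,
                "rh_cwd_considered": cwd_considered,
                "rsoil_model_drivers": str(rng.choice(
                    ["temperature", "temperature_and_water"])),
                "rleaf_model_drivers": str(rng.choice(
                    ["temperature", "temperature_plus_other"])),
                "rleaf_parameterization": str(rng.choice(
                    ["site_specific", "generic"], p=[0.6, 0.4])),
                "rleaf_variable_q10": bool(rng.random() < 0.5),
                "light_inhibition_considered": light_inh,
                "leaf_growth_respiration": bool(rng.random() < 0.5),
                "wood_growth_respiration": bool(rng.random() < 0.5),
                "rwood_model_drivers": str(rng.choice(
                    ["temperature", "temperature_plus_other"])),
                "rwood_scaling": str(rng.choice(["wood_volume", "wood_area"])),
                "branch_stem_separated": bool(rng.random() < 0.5),
                "npp_branch_turnover_measured": branch_meas,
                "npp_mycorrhiza_measured": myco_meas,
            }
            rows.append(row)
            truth_rows.append({
                "site_id": sid, "climate_zone": zone,
                "gpp": gpp, "reco": reco, "nep": nep,
                "npp": npp, "ra": ra, "rh": rh,
                "rh_soil": rh_soil, "rh_cwd": rh_cwd, "rsoil": rsoil,
                "rroot": rroot, "ra_leaf": ra_leaf, "ra_wood": ra_wood,
                "npp_foliage": npp_fol, "npp_wood_aboveground": npp_wood,
                "npp_fineroot": npp_fine, "npp_coarseroot": npp_coarse,
            })

    sites = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)

    # stock inventories for the first n_stock_sites sites (exact under zero noise)
    n_stock = min(cfg.n_stock_sites, len(sites))
    stock_idx = rng.choice(len(sites), size=n_stock, replace=False)
    for col in ("time_start", "time_end", "wood_stock_start", "wood_stock_end",
                "soil_stock_start", "soil_stock_end", "lateral_losses"):
        sites[col] = np.nan
    for i in stock_idx:
        nep_true = float(truth.loc[i, "nep"])
        dt = float(rng.integers(2, 9))
        lateral = float(rng.uniform(0.0, 40.0))
        noise = float(rng.normal(0.0, cfg.cv_bm * truth.loc[i, "gpp"])) if cfg.cv_bm > 0 else 0.0
        d_total = (nep_true + noise - lateral) * dt
        wood0 = float(rng.uniform(8000.0, 16000.0))
        soil0 = float(rng.uniform(4000.0, 9000.0))
        w_frac = float(rng.uniform(0.5, 0.9))
        sites.loc[i, ["time_start", "time_end"]] = (2000.0, 2000.0 + dt)
        sites.loc[i, "wood_stock_start"] = wood0
        sites.loc[i, "wood_stock_end"] = max(wood0 + w_frac * d_total, 0.0)
        sites.loc[i, "soil_stock_start"] = soil0
        sites.loc[i, "soil_stock_end"] = max(soil0 + (1 - w_frac) * d_total, 0.0)
        sites.loc[i, "lateral_losses"] = lateral
    return sites, truth


def recovery_report(
    cfg: Optional[SimConfig] = None,
    n_replicates: int = 50,
    base_seed: Optional[int] = None,
) -> pd.DataFrame:
    """Bias/coverage of key pipeline statistics over seeded replicates.

    For each replicate a fresh dataset is generated and pushed through the
    budget + comparison pipeline; the report gives, per statistic, the mean
    estimate across replicates, the injected target, the bias, and the
    fraction of replicates whose nominal 95% interval covers the target.
    """
    from . import pipeline as _pipeline  # deferred: pipeline imports this module's sibling

    cfg = cfg or SimConfig()
    if n_replicates < 2:
        raise ValueError("need n_replicates >= 2")
    if base_seed is None:
        base_seed = cfg.seed
    est: dict[str, list[float]] = {k: [] for k in (
        "nep_diff_ec_minus_bm", "reco_rel_diff_pct", "ma_slope_nep",
        "ma_slope_reco", "ma_slope_gpp")}
    cover: dict[str, list[bool]] = {"nep_diff_ec_minus_bm": [],
                                    "ma_slope_nep": [], "ma_slope_reco": [], "ma_slope_gpp": []}
    for r in range(n_replicates):
        sites, _ = generate_dataset(replace(cfg, seed=(base_seed + r) % (2**31)))
        bundle = _pipeline.run_convergence_analysis(sites)
        t2 = bundle.table2
        row = t2[(t2["flux"] == "nep") & (t2["stratum"] == "global")].iloc[0]
        est["nep_diff_ec_minus_bm"].append(-row["abs_diff_mean"])  # BM-EC stored; flip
        cover["nep_diff_ec_minus_bm"].append(
            abs(-row["abs_diff_mean"] - (-cfg.nep_bm_offset)) <= 1.96 * row["abs_diff_sem"]
        )
        reco_row = t2[(t2["flux"] == "reco") & (t2["stratum"] == "global")]
        est["reco_rel_diff_pct"].append(
            float(reco_row["rel_diff_mean_pct"].iloc[0]) if len(reco_row) else float("nan")
        )
        for kind in ("nep", "reco", "gpp"):
            reg = bundle.fig2_stats.get(kind)
            if reg is None:
                est[f"ma_slope_{kind}"].append(float("nan"))
                continue
            est[f"ma_slope_{kind}"].append(reg.slope)
            lo, hi = reg.slope_ci95
            cover[f"ma_slope_{kind}"].append(lo <= 1.0 <= hi)
    targets = {
        "nep_diff_ec_minus_bm": -cfg.nep_bm_offset,
        "reco_rel_diff_pct": float("nan"),
        "ma_slope_nep": 1.0, "ma_slope_reco": 1.0, "ma_slope_gpp": 1.0,
    }
    rows = []
    for name, vals in est.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        mean = float(arr.mean()) if len(arr) else float("nan")
        target = targets[name]
        rows.append({
            "statistic": name,
            "injected": target,
            "mean_estimate": mean,
            "bias": mean - target if math.isfinite(target) else float("nan"),
            "coverage": float(np.mean(cover[name])) if name in cover and cover[name]
            else float("nan"),
            "n_replicates": n_replicates,
        })
    return pd.DataFrame(rows).set_index("statistic")
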