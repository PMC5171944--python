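"""Orchestration of the full EC-BM convergence analysis.

Given a site table, the pipeline

1. assembles biometric budgets and matches them with the EC fluxes;
2. fits major-axis regressions of BM on EC per flux (scatter-level agreement);
3. runs normality-gated paired comparisons per flux and climate-zone
   stratum (absolute differences for NEP, relative for Reco/GPP);
4. screens the flux differences against environmental covariates and the
   applicable methodological variants with inverse-uncertainty-weighted
   least squares, including leave-one-out outlier sensitivity;
5. runs the NSF-subset two-way ANOVA (light inhibition x Rleaf
   parameterization) on the Reco relative difference;
6. summarizes flux composition across sites;
7. compares stock-change NEP against EC NEP where inventories exist;
8. reports the NPP gap-fill sensitivity.

Outlying sites are intentionally retained throughout: large discrepancies
are the object of study, not nuisances.  Differences are stored as
D = BM - EC; the EC - BM orientation is its negation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import stats as st
from .budget import (
    BmBudget, assemble_bm_budget, composition_summary, nep_from_stocks,
    relative_difference,
)
from .data_model import (
    ClimateZone, FluxKind, ParsedSite, parse_dataframe, read_site_table,
    validate_dataset,
)
from .gapfill import GapfillConfig, gapfill_npp
from .uncertainty import UncertaintyConfig, build_flux_pairs

__all__ = ["RunConfig", "ReportBundle", "run_convergence_analysis",
           "compare_partitioning_variants", "write_report"]


@dataclass
class RunConfig:
    """Run-level configuration; loadable from YAML with dotted sections."""

    uncertainty: UncertaintyConfig = dc_field(default_factory=UncertaintyConfig)
    gapfill: GapfillConfig = dc_field(default_factory=GapfillConfig)
    alpha_gate: float = 0.05        # Shapiro-Wilk and Breusch-Pagan gates
    weight_power: float = 1.0       # 1 -> weights 1/s, 2 -> 1/s^2
    include_rh_cwd: bool = True
    outlier_p_threshold: float = 0.10  # run leave-one-out only for screens below this

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "uncertainty" in raw:
            cfg.uncertainty = UncertaintyConfig(**raw["uncertainty"])
        if "gapfill" in raw:
            cfg.gapfill = GapfillConfig(**raw["gapfill"])
        for key in ("alpha_gate", "weight_power", "include_rh_cwd", "outlier_p_threshold"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg


@dataclass
class ReportBundle:
    table2: pd.DataFrame                      # per-flux, per-stratum paired comparisons
    table3: pd.DataFrame                      # weighted covariate/variant screens
    fig2_stats: dict[str, st.RegressionResult]  # MA regressions keyed by flux
    composition: Optional[pd.DataFrame]
    anova_nsf: Optional[st.AnovaResult]
    stock_comparison: Optional[st.PairedTestResult]
    gapfill_report: pd.DataFrame
    partitioning_comparison: Optional[dict]
    validation: object
    log: list[str] = dc_field(default_factory=list)


TableLike = Union[str, Path, pd.DataFrame, Sequence[ParsedSite]]


def _as_records(table: TableLike) -> list[ParsedSite]:
    if isinstance(table, (str, Path)):
        return read_site_table(table)
    if isinstance(table, pd.DataFrame):
        return parse_dataframe(table)
    return list(table)


_STRATA = ("global", "boreal", "temperate", "tropical")

# Environmental/stand covariates screened for every flux
_ENV_VARIABLES = (
    ("elevation_variability", "site"), ("topographical_slope", "site"),
    ("lai", "site"), ("leaf_type", "site"), ("leaf_habit", "site"),
    ("fertility", "site"), ("climate_zone", "site"),
    ("mean_annual_precipitation", "site"), ("mean_annual_temperature", "site"),
)

# Methodological variants and the fluxes they apply to (mirrors the screen design)
_METHOD_VARIABLES = (
    ("fine_root_npp_method", ("nep", "gpp")),
    ("allometry_quality", ("nep", "gpp")),
    ("leaf_npp_method", ("nep", "gpp")),
    ("soil_chamber", ("reco",)),
    ("co2_scrubbing", ("reco",)),        # NSF subset only
    ("rh_soil_method", ("nep",)),
    ("rh_cwd_considered", ("nep", "reco")),
    ("rsoil_model_drivers", ("reco",)),
    ("rleaf_model_drivers", ("reco", "gpp")),
    ("rleaf_parameterization", ("reco", "gpp")),
    ("rleaf_variable_q10", ("reco", "gpp")),
    ("light_inhibition_considered", ("reco", "gpp")),
    ("leaf_growth_respiration", ("reco", "gpp")),
    ("wood_growth_respiration", ("reco", "gpp")),
    ("rwood_model_drivers", ("reco", "gpp")),
    ("rwood_scaling", ("reco", "gpp")),
    ("branch_stem_separated", ("reco", "gpp")),
    ("ec_partitioning", ("nep", "reco", "gpp")),
)


def _pair_weight(pair) -> float:
    """Combined EC+BM half-range uncertainty (root-sum-square) -> weight 1/s."""
    s = math.hypot(pair.ec_uncertainty, pair.bm_uncertainty)
    return 1.0 / s if s > 0 else 1.0


def _difference_frame(records, budgets, pairs_by_site) -> pd.DataFrame:
    """One row per (site, flux) with D = BM - EC, relative D and weight."""
    rows = []
    for rec in records:
        sid = rec.site.site_id
        for kind, pair in pairs_by_site.get(sid, {}).items():
            d = pair.bm_value - pair.ec_value
            rel = None
            if kind in (FluxKind.RECO, FluxKind.GPP):
                rel = relative_difference(pair.bm_value, pair.ec_value, kind)
            rows.append({
                "site_id": sid,
                "flux": kind.value,
                "zone": rec.site.climate_zone.value,
                "ec": pair.ec_value, "bm": pair.bm_value,
                "diff_bm_minus_ec": d,
                "rel_diff": rel,
                "weight": _pair_weight(pair),
            })
    return pd.DataFrame(rows)


def _table2(diffs: pd.DataFrame, alpha_gate: float, log: list[str]) -> pd.DataFrame:
    rows = []
    for kind in ("nep", "reco", "gpp"):
        sub_all = diffs[diffs["flux"] == kind]
        for stratum in _STRATA:
            sub = sub_all if stratum == "global" else sub_all[sub_all["zone"] == stratum]
            n = len(sub)
            if n < 3:
                if n:
                    log.append(f"table2 {kind}/{stratum}: n={n} < 3, marked NA")
                rows.append({"flux": kind, "stratum": stratum, "n": n,
                             "abs_diff_mean": sub["diff_bm_minus_ec"].mean() if n else np.nan,
                             "abs_diff_sem": np.nan, "p_value": np.nan, "test_used": "NA",
                             "rel_diff_mean_pct": np.nan, "rel_diff_sem_pct": np.nan,
                             "marker": ""})
                continue
            res = st.paired_compare(sub["bm"].to_numpy(), sub["ec"].to_numpy(), alpha_gate)
            rel_mean = rel_sem = np.nan
            if kind in ("reco", "gpp"):
                rel = sub["rel_diff"].to_numpy(dtype=float) * 100.0
                rel_mean = float(rel.mean())
                rel_sem = float(np.std(rel, ddof=1) / math.sqrt(n))
            rows.append({
                "flux": kind, "stratum": stratum, "n": n,
                "abs_diff_mean": res.mean_difference, "abs_diff_sem": res.sem,
                "p_value": res.p_value, "test_used": res.test_used,
                "rel_diff_mean_pct": rel_mean, "rel_diff_sem_pct": rel_sem,
                "marker": st.significance_marker(res.p_value),
            })
    return pd.DataFrame(rows)


def _screen_response(sub: pd.DataFrame, kind: str) -> np.ndarray:
    if kind == "nep":
        return sub["diff_bm_minus_ec"].to_numpy(dtype=float)
    return sub["rel_diff"].to_numpy(dtype=float)


def _site_attr(rec: ParsedSite, name: str):
    for owner in (rec.site, rec.methods):
        if hasattr(owner, name):
            v = getattr(owner, name)
            if isinstance(v, bool) or hasattr(v, "value"):
                return str(v)  # booleans and enums screen as categories
            return v
    return None


def _table3(records, diffs, cfg: RunConfig, log: list[str]) -> pd.DataFrame:
    by_id = {rec.site.site_id: rec for rec in records}
    rows = []
    all_vars = [(name, ("nep", "reco", "gpp")) for name, _ in _ENV_VARIABLES]
    all_vars += [(name, fluxes) for name, fluxes in _METHOD_VARIABLES]
    for kind in ("nep", "reco", "gpp"):
        sub = diffs[diffs["flux"] == kind].reset_index(drop=True)
        if len(sub) < 4:
            continue
        y_all = _screen_response(sub, kind)
        for var, fluxes in all_vars:
            if kind not in fluxes:
                continue
            values = [_site_attr(by_id[sid], var) for sid in sub["site_id"]]
            mask = np.array([v is not None and v == v for v in values])
            if var == "co2_scrubbing":
                # only defined within the NSF-chamber subset
                chamber = [_site_attr(by_id[sid], "soil_chamber") for sid in sub["site_id"]]
                mask &= np.array([c == "nsf" for c in chamber])
            n = int(mask.sum())
            if n < 5:
                log.append(f"table3 {kind}/{var}: n={n} < 5, skipped")
                continue
            y = y_all[mask]
            pred = pd.Series([values[i] for i in np.flatnonzero(mask)])
            w = sub.loc[mask, "weight"].to_numpy(dtype=float)
            try:
                res = st.weighted_screen(y, pred, w, cfg.alpha_gate, cfg.weight_power)
            except (st.SingularDesignError, ValueError) as e:
                log.append(f"table3 {kind}/{var}: {e}")
                continue
            outlier_flag = ""
            numeric = pd.api.types.is_numeric_dtype(pred)
            if numeric and res.p_value < cfg.outlier_p_threshold and n >= 5:
                sens = st.outlier_sensitivity(y, pred, w, cfg.alpha_gate)
                n_infl = int(sens["influential"].sum())
                if n_infl:
                    outlier_flag = f"{n_infl} influential point(s)"
            rows.append({
                "flux": kind, "variable": var, "n": n,
                "p_value": res.p_value, "r_squared": res.r_squared,
                "heteroskedastic": res.heteroskedastic,
                "inference_method": res.inference_method,
                "marker": st.significance_marker(res.p_value),
                "outlier_sensitivity": outlier_flag,
            })
    return pd.DataFrame(rows)


def _nsf_anova(records, diffs, log: list[str]) -> Optional[st.AnovaResult]:
    by_id = {rec.site.site_id: rec for rec in records}
    sub = diffs[diffs["flux"] == "reco"].reset_index(drop=True)
    keep, li, par = [], [], []
    for i, sid in enumerate(sub["site_id"]):
        rec = by_id[sid]
        if _site_attr(rec, "soil_chamber") != "nsf":
            continue
        a = _site_attr(rec, "light_inhibition_considered")
        b = _site_attr(rec, "rleaf_parameterization")
        if a is None or b is None:
            continue
        keep.append(i)
        li.append(str(a))
        par.append(str(b))
    if len(keep) < 6:
        log.append(f"NSF-subset ANOVA skipped: only {len(keep)} usable sites")
        return None
    y = sub.loc[keep, "rel_diff"].to_numpy(dtype=float)
    try:
        return st.two_way_anova(y, li, par)
    except ValueError as e:
        log.append(f"NSF-subset ANOVA not estimable: {e}")
        return None


def _gapfill_report(records, budgets, cfg: GapfillConfig) -> pd.DataFrame:
    rows = []
    for rec, bud in zip(records, budgets):
        if bud.npp_total is None or bud.npp_total <= 0:
            continue
        filled, added = gapfill_npp(
            bud.npp_total, rec.bm.npp_wood_aboveground,
            bool(rec.methods.npp_branch_turnover_measured),
            bool(rec.methods.npp_mycorrhiza_measured),
            cfg,
        )
        rows.append({
            "site_id": rec.site.site_id,
            "npp_original": bud.npp_total,
            "npp_gapfilled": filled,
            "increase_pct": 100.0 * (filled / bud.npp_total - 1.0),
            **{f"added_{k}": v for k, v in added.items()},
        })
    return pd.DataFrame(rows)


def compare_partitioning_variants(
    table: TableLike, alpha_gate: float = 0.05
) -> Optional[dict]:
    """Paired comparison of daytime- vs nighttime-partitioned EC fluxes.

    Uses sites reporting both variants of Reco_EC (and GPP_EC when present).
    Returns per-flux paired-test results and relative-difference summaries,
    or None when no dual-variant sites exist.
    """
    records = _as_records(table)
    out = {}
    for kind, get_night, get_day in (
        ("reco", lambda r: r.ec.reco, lambda r: r.ec.reco_daytime),
        ("gpp", lambda r: r.ec.gpp, lambda r: r.ec.gpp_daytime),
    ):
        night, day = [], []
        for rec in records:
            n_val, d_val = get_night(rec), get_day(rec)
            if n_val is not None and d_val is not None:
                night.append(n_val)
                day.append(d_val)
        if len(night) < 3:
            continue
        res = st.paired_compare(np.array(day), np.array(night), alpha_gate)
        rel = np.array([
            relative_difference(d, n_, kind) for d, n_ in zip(day, night)
        ]) * 100.0
        out[kind] = {
            "paired": res,
            "rel_diff_mean_pct": float(rel.mean()),
            "rel_diff_sem_pct": float(np.std(rel, ddof=1) / math.sqrt(len(rel))),
            "n": len(night),
        }
    return out or None


def run_convergence_analysis(
    table: TableLike, config: Optional[RunConfig] = None
) -> ReportBundle:
    """Run the full convergence analysis; see the module docstring for the steps."""
    cfg = config or RunConfig()
    records = _as_records(table)
    if not records:
        raise ValueError("empty site table")
    log: list[str] = []
    validation = validate_dataset(records)
    for issue in validation.issues:
        log.append(f"validation {issue.severity}: {issue.site_id}/{issue.field}: {issue.message}")

    budgets: list[BmBudget] = []
    pairs_by_site = {}
    for rec in records:
        bud = assemble_bm_budget(rec.bm, include_rh_cwd=cfg.include_rh_cwd)
        budgets.append(bud)
        for fl, reason in bud.completeness_flags.items():
            if "not computable" in reason:
                log.append(f"{rec.site.site_id}: {fl} {reason}")
        pairs_by_site[rec.site.site_id] = build_flux_pairs(rec, bud, cfg.uncertainty)

    diffs = _difference_frame(records, budgets, pairs_by_site)
    if diffs.empty:
        raise ValueError("no site has both EC and BM values for any flux")

    fig2: dict[str, st.RegressionResult] = {}
    for kind in ("nep", "reco", "gpp"):
        sub = diffs[diffs["flux"] == kind]
        if len(sub) >= 3:
            fig2[kind] = st.ma_regression(sub["ec"].to_numpy(), sub["bm"].to_numpy())
        else:
            log.append(f"MA regression {kind}: n={len(sub)} < 3, skipped")

    table2 = _table2(diffs, cfg.alpha_gate, log)
    table3 = _table3(records, diffs, cfg, log)
    anova = _nsf_anova(records, diffs, log)

    try:
        composition = composition_summary([rec.bm for rec in records])
    except Exception as e:  # insufficient shared components
        composition = None
        log.append(f"composition summary skipped: {e}")

    stock_cmp = None
    stock_nep, stock_ec = [], []
    for rec in records:
        if rec.stocks is not None:
            stock_nep.append(nep_from_stocks(rec.stocks))
            stock_ec.append(rec.ec.nep)
    if len(stock_nep) >= 3:
        stock_cmp = st.paired_compare(np.array(stock_nep), np.array(stock_ec), cfg.alpha_gate)
    elif stock_nep:
        log.append(f"stock-change NEP comparison skipped: only {len(stock_nep)} sites")

    gap_df = _gapfill_report(records, budgets, cfg.gapfill)
    part = compare_partitioning_variants(records, cfg.alpha_gate)

    return ReportBundle(
        table2=table2, table3=table3, fig2_stats=fig2, composition=composition,
        anova_nsf=anova, stock_comparison=stock_cmp, gapfill_report=gap_df,
        partitioning_comparison=part, validation=validation, log=log,
    )


def write_report(bundle: ReportBundle, outdir: str | Path) -> None:
    """Write the report bundle to CSV/JSON files under `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.table2.to_csv(outdir / "table2.csv", index=False)
    bundle.table3.to_csv(outdir / "table3.csv", index=False)
    fig2 = {k: v.to_dict() for k, v in bundle.fig2_stats.items()}
    (outdir / "fig2_stats.json").write_text(json.dumps(fig2, indent=2))
    if bundle.composition is not None:
        bundle.composition.to_csv(outdir / "composition.csv")
    if not bundle.gapfill_report.empty:
        bundle.gapfill_report.to_csv(outdir / "gapfill.csv", index=False)
    extras = {}
    if bundle.anova_nsf is not None:
        extras["nsf_anova"] = vars(bundle.anova_nsf)
    if bundle.stock_comparison is not None:
        extras["stock_vs_ec_nep"] = bundle.stock_comparison.to_dict()
    if bundle.partitioning_comparison:
        extras["partitioning"] = {
            k: {"rel_diff_mean_pct": v["rel_diff_mean_pct"],
                "rel_diff_sem_pct": v["rel_diff_sem_pct"],
                "p_value": v["paired"].p_value, "n": v["n"]}
            for k, v in bundle.partitioning_comparison.items()
        }
    (outdir / "extras.json").write_text(json.dumps(extras, indent=2, default=float))
    (outdir / "log.txt").write_text("\n".join(bundle.log) + "\n")
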