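"""Carbon-budget accounting from biometric components.

Assembles site-level NEP, Reco and GPP from measured biometric components
using the budget identities

    Reco = Ra + Rh
    GPP  = NPP + Ra
    NEP  = GPP - Reco = NPP - Rh
    Rsoil = Rroot + Rh-soil

and provides the stock-change NEP estimate, the symmetric relative-difference
statistic and cross-site composition summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import BmComponents, FluxKind, StockInventory, RSOIL_PARTITION_TOL

__all__ = [
    "BmBudget", "InsufficientDataError", "InconsistencyError",
    "UnsupportedStatisticError", "partition_rsoil", "assemble_bm_budget",
    "nep_from_stocks", "relative_difference", "composition_summary",
]


class InsufficientDataError(ValueError):
    """Too few components present to evaluate an identity."""


class InconsistencyError(ValueError):
    """The stated components contradict a budget identity."""


class UnsupportedStatisticError(ValueError):
    """The requested statistic is not defined for this flux."""


@dataclass
class BmBudget:
    """Assembled biometric budget for one site (gC m-2 y-1; None = not computable)."""

    npp_total: Optional[float] = None
    ra_aboveground: Optional[float] = None
    nep_bm: Optional[float] = None
    reco_bm: Optional[float] = None
    gpp_bm: Optional[float] = None
    completeness_flags: dict[str, str] = field(default_factory=dict)


def partition_rsoil(
    rsoil: Optional[float],
    rroot: Optional[float],
    rh_soil: Optional[float],
    tol: float = RSOIL_PARTITION_TOL,
) -> tuple[float, float, float]:
    """Complete the soil-respiration partition Rsoil = Rroot + Rh-soil.

    At least two of the three members must be present; the missing one is
    computed from the identity.  When all three are present their consistency
    is asserted within `tol` gC m-2 y-1.
    """
    present = sum(v is not None for v in (rsoil, rroot, rh_soil))
    if present < 2:
        raise InsufficientDataError(
            "at least two of (rsoil, rroot, rh_soil) are needed to complete the partition"
        )
    if rsoil is None:
        rsoil = rroot + rh_soil
    elif rroot is None:
        rroot = rsoil - rh_soil
    elif rh_soil is None:
        rh_soil = rsoil - rroot
    else:
        gap = rsoil - (rroot + rh_soil)
        if abs(gap) > tol:
            raise InconsistencyError(
                f"Rsoil partition inconsistent by {gap:+.1f} gC m-2 y-1"
            )
    if rroot < 0 or rh_soil < 0 or rsoil < 0:
        raise InconsistencyError(
            f"Rsoil partition yields a negative flux "
            f"(rsoil={rsoil:.1f}, rroot={rroot:.1f}, rh_soil={rh_soil:.1f})"
        )
    return rsoil, rroot, rh_soil


_NPP_PARTS = (
    "npp_wood_aboveground", "npp_foliage", "npp_fineroot", "npp_coarseroot",
    "npp_understory", "npp_branch_turnover", "npp_reproductive", "npp_other",
)
_NPP_REQUIRED = ("npp_wood_aboveground", "npp_foliage", "npp_fineroot")


def assemble_bm_budget(components: BmComponents, include_rh_cwd: bool = True) -> BmBudget:
    """Assemble NEP/Reco/GPP from biometric components.

    NPP requires at least the three major parts (aboveground wood, foliage,
    fine roots); all further parts present are summed in.  Aboveground Ra is
    Rleaf + Rwood, plus understory respiration when it was reported
    separately.  Rh-cwd is treated as zero when absent or excluded — in both
    NEP and Reco, so the closure identity GPP - Reco = NEP holds exactly
    whenever all three fluxes are computable.

    Fluxes whose preconditions fail are returned as None with the blocking
    component recorded in ``completeness_flags``; the other fluxes are still
    assembled.
    """
    c = components
    flags: dict[str, str] = {}

    npp_total: Optional[float] = None
    missing_req = [n for n in _NPP_REQUIRED if getattr(c, n) is None]
    if missing_req:
        flags["npp_total"] = f"not computable: missing {', '.join(missing_req)}"
    else:
        npp_total = 0.0
        for name in _NPP_PARTS:
            v = getattr(c, name)
            if v is not None:
                npp_total += v
            elif name not in _NPP_REQUIRED:
                flags[name] = "omitted"

    ra_above: Optional[float] = None
    if c.ra_leaf is not None and c.ra_wood is not None:
        ra_above = c.ra_leaf + c.ra_wood
        if c.ra_understory is not None:
            ra_above += c.ra_understory
        else:
            flags["ra_understory"] = "omitted (assumed folded into Rleaf/Rwood)"
    else:
        missing = [n for n in ("ra_leaf", "ra_wood") if getattr(c, n) is None]
        flags["ra_aboveground"] = f"not computable: missing {', '.join(missing)}"

    # Soil partition: complete it when possible; keep a bare Rsoil for Reco.
    rsoil = rroot = rh_soil = None
    n_soil = sum(v is not None for v in (c.rsoil, c.rroot, c.rh_soil))
    if n_soil >= 2:
        rsoil, rroot, rh_soil = partition_rsoil(c.rsoil, c.rroot, c.rh_soil)
    else:
        rsoil, rroot, rh_soil = c.rsoil, c.rroot, c.rh_soil

    if c.rh_cwd is None:
        rh_cwd_eff = 0.0
        flags["rh_cwd"] = "omitted"
    elif not include_rh_cwd:
        rh_cwd_eff = 0.0
        flags["rh_cwd"] = "excluded"
    else:
        rh_cwd_eff = c.rh_cwd

    nep = reco = gpp = None
    if npp_total is not None and rh_soil is not None:
        nep = npp_total - rh_soil - rh_cwd_eff
    else:
        flags.setdefault("nep_bm", "not computable: needs NPP total and Rh-soil")
    if ra_above is not None and rsoil is not None:
        reco = ra_above + rsoil + rh_cwd_eff
    else:
        flags.setdefault("reco_bm", "not computable: needs Rleaf+Rwood and Rsoil")
    if npp_total is not None and ra_above is not None and rroot is not None:
        gpp = npp_total + ra_above + rroot
    else:
        flags.setdefault("gpp_bm", "not computable: needs NPP total, Rleaf+Rwood and Rroot")

    return BmBudget(
        npp_total=npp_total, ra_aboveground=ra_above,
        nep_bm=nep, reco_bm=reco, gpp_bm=gpp,
        completeness_flags=flags,
    )


def nep_from_stocks(inv: StockInventory) -> float:
    """NEP from repeated stock inventories: annualized stock change plus exports."""
    dt = inv.time_end - inv.time_start
    if dt <= 0:
        raise ValueError("stock inventory interval must be positive")
    d_stock = (inv.wood_stock_end + inv.soil_stock_end) - (
        inv.wood_stock_start + inv.soil_stock_start
    )
    return d_stock / dt + inv.lateral_losses


def relative_difference(bm: float, ec: float, flux_kind: FluxKind | str = FluxKind.RECO) -> float:
    """Symmetric relative difference (BM - EC) / ((BM + EC) / 2).

    Defined for Reco and GPP only: NEP takes both signs, which breaks the
    normalization (the denominator can vanish or flip sign).
    """
    kind = FluxKind.parse(flux_kind) if not isinstance(flux_kind, FluxKind) else flux_kind
    if kind == FluxKind.NEP:
        raise UnsupportedStatisticError(
            "relative difference is undefined for NEP (values of both signs)"
        )
    denom = (bm + ec) / 2.0
    if denom == 0:
        raise ZeroDivisionError("relative difference undefined: BM + EC = 0")
    return (bm - ec) / denom


def _share_rows(c: BmComponents) -> dict[str, float]:
    """Per-site composition shares; only partitions whose parts are all present."""
    out: dict[str, float] = {}

    npp_parts = {
        "foliage": c.npp_foliage,
        "wood_aboveground": c.npp_wood_aboveground,
    }
    root = None
    if c.npp_fineroot is not None:
        root = c.npp_fineroot + (c.npp_coarseroot or 0.0)
    npp_parts["root"] = root
    if all(v is not None for v in npp_parts.values()):
        other = sum(
            getattr(c, n) or 0.0
            for n in ("npp_understory", "npp_branch_turnover", "npp_reproductive", "npp_other")
        )
        total = sum(npp_parts.values()) + other
        if total > 0:
            for name, v in npp_parts.items():
                out[f"npp_share_{name}"] = v / total
            out["npp_share_other"] = other / total

    if c.npp_fineroot is not None and c.npp_coarseroot is not None:
        root_total = c.npp_fineroot + c.npp_coarseroot
        if root_total > 0:
            out["fineroot_share_of_root_npp"] = c.npp_fineroot / root_total

    ra_parts = {"leaf": c.ra_leaf, "wood": c.ra_wood, "root": c.rroot}
    if all(v is not None for v in ra_parts.values()):
        ra_total = sum(ra_parts.values()) + (c.ra_understory or 0.0)
        if ra_total > 0:
            for name, v in ra_parts.items():
                out[f"ra_share_{name}"] = v / ra_total
            out["ra_share_understory"] = (c.ra_understory or 0.0) / ra_total

    # Reco partition: Rsoil / Rleaf / Rwood / Rh-cwd (+ understory if split out)
    if c.rsoil is not None and c.ra_leaf is not None and c.ra_wood is not None:
        reco = c.rsoil + c.ra_leaf + c.ra_wood + (c.ra_understory or 0.0) + (c.rh_cwd or 0.0)
        if reco > 0:
            out["reco_share_rsoil"] = c.rsoil / reco
            out["reco_share_rleaf"] = c.ra_leaf / reco
            out["reco_share_rwood"] = c.ra_wood / reco
            out["reco_share_rh_cwd"] = (c.rh_cwd or 0.0) / reco
            out["reco_share_understory"] = (c.ra_understory or 0.0) / reco
            if c.rroot is not None and c.rh_soil is not None:
                ra = c.ra_leaf + c.ra_wood + (c.ra_understory or 0.0) + c.rroot
                rh = c.rh_soil + (c.rh_cwd or 0.0)
                out["reco_share_ra"] = ra / reco
                out["reco_share_rh"] = rh / reco
    return out


def composition_summary(datasets: Sequence[BmComponents]) -> pd.DataFrame:
    """Cross-site mean and s.e.m. of flux-composition shares.

    Returns a DataFrame indexed by share name with columns ``mean``, ``sem``
    and ``n``; shares within each partition sum to 1 at every site.
    Requires at least two sites contributing to some partition.
    """
    per_site = [_share_rows(c) for c in datasets]
    all_names: list[str] = []
    for row in per_site:
        for k in row:
            if k not in all_names:
                all_names.append(k)
    rows = []
    for name in all_names:
        vals = np.array([row[name] for row in per_site if name in row], dtype=float)
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append({"share": name, "mean": float(vals.mean()), "sem": sem, "n": n})
    df = pd.DataFrame(rows).set_index("share") if rows else pd.DataFrame()
    if df.empty or int(df["n"].max()) < 2:
        raise InsufficientDataError("composition summary needs >= 2 sites with shared components")
    return df
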