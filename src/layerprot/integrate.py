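"""Cross-platform integration of differential-expression results.

The two platforms (isobaric TMT and label-free) measure aliquots of the
same physical samples, so their per-protein test statistics are positively
correlated and naive independent p-value combination would be
anti-conservative.  Results are joined by accession, p-values merged with a
correlation-adjusted Stouffer combination, effect sizes combined into the
weighted estimate (WE, inverse-variance weighted average of the platform
contrasts), combined-level DE called, and DE proteins scored and ranked
directionally for the "top" lists and percentile selections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixed_de import bh_adjust

_TINY_P = np.finfo(float).tiny


@dataclass
class IntegrationConfig:
    fdr_alpha: float = 0.05
    we_min: float = 0.3
    merge_method: str = "dependent_stouffer"
    rho_estimate_mode: str = "empirical"  # or "fixed"
    rho_fixed: float = 0.5
    top_k: int = 30
    percentile_sm: float = 0.25
    percentile_mp: float = 0.33

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.we_min < 0:
            raise ValueError("we_min must be >= 0")
        for p in (self.percentile_sm, self.percentile_mp):
            if not 0.0 < p <= 1.0:
                raise ValueError("percentiles must lie in (0, 1]")
        if self.merge_method not in ("dependent_stouffer", "fisher", "max_p"):
            raise ValueError(f"unknown merge method {self.merge_method!r}")


def join_platforms(de_a: pd.DataFrame, de_b: pd.DataFrame) -> pd.DataFrame:
    """Full outer join of two per-platform DE tables by accession.

    Produces one row per (protein, comparison) with suffixed per-platform
    columns; single-platform proteins keep the other side absent.
    """
    keys = ["protein_id", "comparison"]
    for name, t in (("first", de_a), ("second", de_b)):
        if t.duplicated(subset=keys).any():
            dups = t.loc[t.duplicated(subset=keys), "protein_id"].unique()[:5]
            raise ValueError(f"duplicate accessions in {name} table, e.g. {list(dups)}")
    cols = keys + ["delta_emm", "se", "p", "fdr", "de_flag", "fit_status"]
    a = de_a.loc[:, [c for c in cols if c in de_a.columns]].copy()
    b = de_b.loc[:, [c for c in cols if c in de_b.columns]].copy()
    return a.merge(b, on=keys, how="outer", suffixes=("_a", "_b"))


def merge_pvalues(
    p_a, p_b, rho: float = 0.0, method: str = "dependent_stouffer"
) -> np.ndarray:
    """Merge two (possibly dependent) p-values; vectorized.

    Default is the correlation-adjusted Stouffer combination
    z = (z_a + z_b) / sqrt(2 + 2 rho) with z_i the upper-tail normal
    quantile of p_i; rho = 0 recovers independent Stouffer and rho = 1
    collapses to a single test (pass-through).  Where one input is missing,
    the other passes through unchanged.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    for p in (p_a, p_b):
        ok = np.isnan(p) | ((p >= 0) & (p <= 1))
        if not ok.all():
            raise ValueError("p-values must lie in [0, 1]")
    pa = np.clip(p_a, _TINY_P, 1.0)
    pb = np.clip(p_b, _TINY_P, 1.0)
    if method == "dependent_stouffer":
        z = (stats.norm.isf(pa) + stats.norm.isf(pb)) / np.sqrt(2.0 + 2.0 * rho)
        merged = stats.norm.sf(z)
    elif method == "fisher":
        chi2 = -2.0 * (np.log(pa) + np.log(pb))
        merged = stats.chi2.sf(chi2, df=4)
    elif method == "max_p":
        merged = np.maximum(pa, pb)
    else:
        raise ValueError(f"unknown merge method {method!r}")
    merged = np.clip(merged, _TINY_P, 1.0)
    out = np.where(np.isnan(p_a), p_b, np.where(np.isnan(p_b), p_a, merged))
    return out if out.ndim else float(out)


def estimate_rho(joined: pd.DataFrame) -> float:
    """Across-protein correlation of signed platform z-scores.

    Signed z = sign(delta) * Phi^-1(1 - p/2) over dual-platform records;
    clipped to [0, 1] (the merge assumes non-negative dependence).
    """
    both = joined.dropna(subset=["p_a", "p_b", "delta_emm_a", "delta_emm_b"])
    if len(both) < 10:
        return 0.0
    za = np.sign(both["delta_emm_a"]) * stats.norm.isf(np.clip(both["p_a"], _TINY_P, 1) / 2)
    zb = np.sign(both["delta_emm_b"]) * stats.norm.isf(np.clip(both["p_b"], _TINY_P, 1) / 2)
    r = float(np.corrcoef(za, zb)[0, 1])
    return float(np.clip(r, 0.0, 1.0))


def weighted_estimate(est_a, se_a, est_b, se_b) -> np.ndarray:
    """Inverse-variance weighted average of the platform contrasts (WE).

    w_i = 1 / se_i^2;  WE = (w_a est_a + w_b est_b) / (w_a + w_b).
    Single-platform records pass the available estimate through.
    """
    est_a, se_a = np.asarray(est_a, float), np.asarray(se_a, float)
    est_b, se_b = np.asarray(est_b, float), np.asarray(se_b, float)
    have_a = np.isfinite(est_a) & np.isfinite(se_a) & (se_a > 0)
    have_b = np.isfinite(est_b) & np.isfinite(se_b) & (se_b > 0)
    wa = np.where(have_a, 1.0 / np.where(have_a, se_a, 1.0) ** 2, 0.0)
    wb = np.where(have_b, 1.0 / np.where(have_b, se_b, 1.0) ** 2, 0.0)
    tot = wa + wb
    num = np.where(have_a, wa * np.nan_to_num(est_a), 0.0) + \
        np.where(have_b, wb * np.nan_to_num(est_b), 0.0)
    out = np.where(tot > 0, num / np.where(tot > 0, tot, 1.0), np.nan)
    return out if out.ndim else float(out)


def call_combined(joined: pd.DataFrame, config: IntegrationConfig | None = None) -> pd.DataFrame:
    """Merged p, BH FDR, WE and the combined-level DE call.

    The combined rule is merged_fdr < alpha AND |WE| >= we_min; note the
    non-strict effect-size bound at the combined level versus the strict
    per-platform bound.
    """
    config = config or IntegrationConfig()
    out = joined.copy()
    if config.rho_estimate_mode == "empirical":
        rho = estimate_rho(out)
    else:
        rho = config.rho_fixed
    out["rho_used"] = rho
    out["merged_p"] = merge_pvalues(
        out["p_a"].to_numpy(), out["p_b"].to_numpy(), rho=rho,
        method=config.merge_method,
    )
    out["we"] = weighted_estimate(
        out["delta_emm_a"].to_numpy(), out["se_a"].to_numpy(),
        out["delta_emm_b"].to_numpy(), out["se_b"].to_numpy(),
    )
    out = out[~out["we"].isna() | ~out["merged_p"].isna()].reset_index(drop=True)
    out["merged_fdr"] = np.nan
    for cmp_name, idx in out.groupby("comparison").groups.items():
        out.loc[idx, "merged_fdr"] = bh_adjust(out.loc[idx, "merged_p"].to_numpy())
    out["combined_de"] = (
        (out["merged_fdr"] < config.fdr_alpha) & (out["we"].abs() >= config.we_min)
    ).fillna(False)
    return out


def rank_proteins(combined: pd.DataFrame, config: IntegrationConfig | None = None) -> pd.DataFrame:
    """Directional ranking of combined-level DE proteins.

    Per comparison, each DE protein gets
    rank_score = sign(WE) * mean(percentile of |WE|, percentile of
    -log10(merged FDR)) among the comparison's DE proteins, so stronger and
    more significant changes in the positive direction score more
    positively.  Ranks are assigned per direction by descending |score|
    (ties broken by |WE|, then accession) and the top-k flag marks the
    paper-style "top" list per comparison and direction.
    """
    config = config or IntegrationConfig()
    de = combined[combined["combined_de"]].copy()
    if de.empty:
        de["rank_score"] = pd.Series(dtype=float)
        de["rank"] = pd.Series(dtype="Int64")
        de["top_k"] = pd.Series(dtype=bool)
        return de
    pieces = []
    for cmp_name, grp in de.groupby("comparison"):
        g = grp.copy()
        abs_we = g["we"].abs()
        neglog_fdr = -np.log10(np.clip(g["merged_fdr"], _TINY_P, 1.0))
        pct_we = abs_we.rank(method="average", pct=True)
        pct_sig = neglog_fdr.rank(method="average", pct=True)
        g["rank_score"] = np.sign(g["we"]) * (pct_we + pct_sig) / 2.0
        g["direction"] = np.where(g["we"] >= 0, "up", "down")
        g["rank"] = pd.NA
        for _, didx in g.groupby("direction").groups.items():
            sub = g.loc[didx].sort_values(
                by=["rank_score", "we", "protein_id"],
                key=lambda s: s.abs() if s.name in ("rank_score", "we") else s,
                ascending=[False, False, True],
            )
            g.loc[sub.index, "rank"] = np.arange(1, len(sub) + 1)
        g["rank"] = g["rank"].astype("Int64")
        g["top_k"] = g["rank"] <= config.top_k
        pieces.append(g)
    return pd.concat(pieces, ignore_index=True)


def top_k_union(ranked: pd.DataFrame, config: IntegrationConfig | None = None) -> pd.DataFrame:
    """Union of per-comparison top-k proteins (may exceed k per direction)."""
    config = config or IntegrationConfig()
    top = ranked[ranked["top_k"]]
    return top.sort_values(["direction", "comparison", "rank"]).reset_index(drop=True)


def select_top_percentile(
    combined: pd.DataFrame, percentile: float,
    comparisons: tuple[str, ...] = ("STRvCTRL", "STRvNSTR"),
) -> pd.DataFrame:
    """DE proteins in the top |WE| percentile of either comparison.

    Within each comparison and direction, the nearest-rank (1 - percentile)
    quantile of |WE| among DE proteins is the threshold; proteins strictly
    above it are selected, and the union over the comparisons is returned.
    """
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must lie in (0, 1]")
    de = combined[combined["combined_de"] & combined["comparison"].isin(comparisons)]
    if de.empty:
        return de.copy()
    selected_ids: set = set()
    for (_, _), grp in de.groupby(
        ["comparison", np.where(de["we"] >= 0, "up", "down")]
    ):
        vals = np.sort(grp["we"].abs().to_numpy())
        n = len(vals)
        if percentile >= 1.0:
            selected_ids.update(grp["protein_id"])
            continue
        k = int(np.ceil((1.0 - percentile) * n))  # nearest-rank quantile index
        thr = vals[k - 1] if k >= 1 else -np.inf
        sel = grp[grp["we"].abs() > thr]
        selected_ids.update(sel["protein_id"])
    return de[de["protein_id"].isin(selected_ids)].reset_index(drop=True)
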