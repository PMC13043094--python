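"""Multivariate structure and proximity-gradient trend analyses.

Covers: PCA of the batch-corrected complete-observation matrix with a
deterministic component orientation, marker-to-component Pearson
correlation, classification of DE proteins by interlayer concordance,
scaling of refined-group contrasts onto the CTRL=0 / STR=1 axis with a
4x4 reference grid, trend-pattern classification and sequential-DE
counting along the CTRL -> Dist -> Adj -> STR chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

INTERLAYER_CATEGORIES = (
    "concordant_up", "concordant_down", "discordant", "sm_predominant", "mp_predominant",
)
TREND_PATTERNS = ("progressive", "adjacent_saturating", "early_shift", "non_monotone")
SEQUENTIAL_CHAIN = ("DistvCTRL", "AdjvDist", "STRvAdj", "AdjvCTRL")
DEFAULT_PATTERN_TOL = 0.25  # one grid cell


@dataclass
class PCAResult:
    scores: pd.DataFrame = field(repr=False)       # samples x components
    loadings: pd.DataFrame = field(repr=False)     # proteins x components
    var_explained: np.ndarray = field(repr=False)  # fraction per component


def run_pca(
    matrix: pd.DataFrame,
    groups: pd.Series | None = None,
    n_components: int | None = None,
) -> PCAResult:
    """Protein-centered PCA of a complete proteins-x-samples matrix.

    Principal-component signs are arbitrary; each component is oriented so
    the mean STR sample score is >= the mean CTRL score (when group labels
    are supplied), making score plots reproducible across runs.
    """
    if matrix.isna().any().any():
        raise ValueError("PCA input must have no missing cells; batch-correct first")
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 proteins and 2 samples")
    X = matrix.T.to_numpy(dtype=float)  # samples x proteins
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T

    if groups is not None:
        g = groups.reindex(matrix.columns)
        str_m = (g == "STR").to_numpy()
        ctrl_m = (g == "CTRL").to_numpy()
        if str_m.any() and ctrl_m.any():
            flip = scores[str_m].mean(axis=0) < scores[ctrl_m].mean(axis=0)
            scores[:, flip] *= -1.0
            loadings[:, flip] *= -1.0

    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.index, columns=comp_names),
        var_explained=pca.explained_variance_ratio_,
    )


def correlate_markers(
    matrix: pd.DataFrame,
    pca: PCAResult,
    markers: Mapping[str, str],
    components: tuple[str, str] = ("PC1", "PC3"),
    de_flags: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Pearson correlation between marker abundances and PC sample scores.

    Markers absent from the matrix are reported with status 'absent';
    zero-variance markers with status 'undefined'.  DE status is attached
    for plotting when provided.
    """
    records = []
    for pid, category in markers.items():
        rec = {"protein_id": pid, "category": category, "status": "ok"}
        for comp in components:
            rec[f"r_{comp}"] = np.nan
        if pid not in matrix.index:
            rec["status"] = "absent"
        else:
            v = matrix.loc[pid].to_numpy(dtype=float)
            if np.std(v) == 0:
                rec["status"] = "undefined"
            else:
                for comp in components:
                    rec[f"r_{comp}"] = float(stats.pearsonr(v, pca.scores[comp].to_numpy())[0])
        if de_flags is not None:
            rec["de_flag"] = bool(de_flags.get(pid, False))
        records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Interlayer concordance
# ---------------------------------------------------------------------------

def _layer_summary(combined: pd.DataFrame, comparisons: tuple[str, str]) -> pd.DataFrame:
    """Per-protein average WE (proxy for the layer's change) and DE state."""
    if combined.empty or "comparison" not in combined.columns:
        return pd.DataFrame(columns=["avg_we", "de", "direction"])
    sub = combined[combined["comparison"].isin(comparisons)]
    if sub.empty:
        return pd.DataFrame(columns=["avg_we", "de", "direction"])
    g = sub.groupby("protein_id")
    out = pd.DataFrame({
        "avg_we": g["we"].mean(),
        "de": g["combined_de"].any(),
    })
    out["direction"] = np.sign(out["avg_we"])
    return out


def classify_interlayer(
    combined_sm: pd.DataFrame,
    combined_mp: pd.DataFrame,
    comparisons: tuple[str, str] = ("STRvCTRL", "STRvNSTR"),
) -> pd.DataFrame:
    """Cross-tabulate each DE protein's direction of change across layers.

    DE in both layers with the same direction -> concordant_up/down;
    opposite directions -> discordant; DE in one layer only -> that layer
    predominant.  The average WE over the two stricture comparisons proxies
    each layer's change; for a protein not quantified in a layer the
    average WE is set to zero.
    """
    sm = _layer_summary(combined_sm, comparisons)
    mp = _layer_summary(combined_mp, comparisons)
    union = sm.index[sm["de"]].union(mp.index[mp["de"]])
    records = []
    for pid in union:
        in_sm, in_mp = pid in sm.index, pid in mp.index
        we_sm = float(sm.loc[pid, "avg_we"]) if in_sm else 0.0  # zero rule
        we_mp = float(mp.loc[pid, "avg_we"]) if in_mp else 0.0
        de_sm = bool(sm.loc[pid, "de"]) if in_sm else False
        de_mp = bool(mp.loc[pid, "de"]) if in_mp else False
        if de_sm and de_mp:
            if np.sign(we_sm) == np.sign(we_mp):
                cat = "concordant_up" if we_sm > 0 else "concordant_down"
            else:
                cat = "discordant"
        elif de_sm:
            cat = "sm_predominant"
        else:
            cat = "mp_predominant"
        records.append({
            "protein_id": pid, "avg_we_sm": we_sm, "avg_we_mp": we_mp, "category": cat,
        })
    return pd.DataFrame.from_records(
        records, columns=["protein_id", "avg_we_sm", "avg_we_mp", "category"]
    )


# ---------------------------------------------------------------------------
# CTRL -> STR trend scaling and the 16-box grid
# ---------------------------------------------------------------------------

def scale_trend(emm_by_group: Mapping[str, float]) -> tuple[float, float]:
    """Scale Adj/Dist marginal means onto the CTRL=0, STR=1 axis.

    x_adj = (EMM_Adj - EMM_CTRL) / (EMM_STR - EMM_CTRL), likewise y_dist.
    The division makes the scaling direction-agnostic: a decreased protein
    whose Dist/Adj means lie between CTRL and STR also lands in [0, 1].
    Raises for a zero CTRL-STR span (no axis to scale on).
    """
    span = emm_by_group["STR"] - emm_by_group["CTRL"]
    if span == 0 or not np.isfinite(span):
        raise ValueError("EMM_STR equals EMM_CTRL; trend coordinates undefined")
    x_adj = (emm_by_group["Adj"] - emm_by_group["CTRL"]) / span
    y_dist = (emm_by_group["Dist"] - emm_by_group["CTRL"]) / span
    return float(x_adj), float(y_dist)


def assign_box(x_adj: float, y_dist: float) -> int:
    """Box index 1..16 on the 4x4 grid over the unit square.

    Boxes are numbered row-major from the top-left (y descending, x
    ascending); coordinates outside [0, 1] clamp to the boundary cells and
    the right/top edges belong to the last cell.
    """
    if not (np.isfinite(x_adj) and np.isfinite(y_dist)):
        raise ValueError("trend coordinates must be finite")
    col = int(np.clip(np.floor(x_adj / 0.25), 0, 3))
    row_from_bottom = int(np.clip(np.floor(y_dist / 0.25), 0, 3))
    row_from_top = 3 - row_from_bottom
    return row_from_top * 4 + col + 1


def classify_pattern(
    x_adj: float,
    y_dist: float,
    refined_de: Mapping[str, bool] | None = None,
    tol: float = DEFAULT_PATTERN_TOL,
) -> tuple[str, int]:
    """Trend pattern from scaled coordinates, plus the sequential-DE count.

    early_shift: already near the STR level in Dist (y >= 1 - tol);
    adjacent_saturating: near the STR level in Adj but not yet in Dist
    (x >= 1 - tol, y < x); progressive: monotone CTRL <= Dist <= Adj <= STR
    within tol; anything else non_monotone.  The sequential-DE count tallies
    DE flags along DistvCTRL, AdjvDist, STRvAdj plus the composite AdjvCTRL
    (comparisons missing from ``refined_de`` are simply not counted).
    """
    if y_dist >= 1.0 - tol:
        pattern = "early_shift"
    elif x_adj >= 1.0 - tol and y_dist < x_adj:
        pattern = "adjacent_saturating"
    elif -tol <= y_dist <= x_adj + tol and x_adj <= 1.0 + tol:
        pattern = "progressive"
    else:
        pattern = "non_monotone"
    n_seq = 0
    if refined_de:
        n_seq = sum(bool(refined_de.get(cmp, False)) for cmp in SEQUENTIAL_CHAIN)
    return pattern, n_seq


def trend_profiles(
    de_refined: pd.DataFrame,
    combined_std: pd.DataFrame | None = None,
    tol: float = DEFAULT_PATTERN_TOL,
) -> pd.DataFrame:
    """Per-protein trend coordinates, box index, pattern and sequential-DE count.

    ``de_refined`` holds refined-comparison contrast records (one layer,
    one platform) including DistvCTRL / AdjvCTRL / STRvCTRL so the group
    EMMs relative to CTRL can be reconstructed; the direction comes from
    the STRvCTRL contrast.  When ``combined_std`` is given, only proteins
    that are combined-level DE in STRvCTRL are profiled (the refinement
    gate); otherwise all estimable proteins are.
    """
    need = {"DistvCTRL", "AdjvCTRL", "STRvCTRL"}
    have = set(de_refined["comparison"].unique())
    if not need <= have:
        raise ValueError(f"refined DE table lacks comparisons: {sorted(need - have)}")
    wide = de_refined.pivot_table(
        index="protein_id", columns="comparison", values="delta_emm", aggfunc="first"
    )
    flags = de_refined.pivot_table(
        index="protein_id", columns="comparison", values="de_flag", aggfunc="first"
    ).astype(bool)

    gate = None
    if combined_std is not None:
        gate = set(
            combined_std.loc[
                (combined_std["comparison"] == "STRvCTRL") & combined_std["combined_de"],
                "protein_id",
            ]
        )

    records = []
    for pid, row in wide.iterrows():
        if gate is not None and pid not in gate:
            continue
        emm = {
            "CTRL": 0.0,
            "Dist": row.get("DistvCTRL", np.nan),
            "Adj": row.get("AdjvCTRL", np.nan),
            "STR": row.get("STRvCTRL", np.nan),
        }
        if any(not np.isfinite(v) for v in emm.values()):
            records.append({"protein_id": pid, "x_adj": np.nan, "y_dist": np.nan,
                            "box_index": pd.NA, "pattern": "not_estimable",
                            "n_sequential_de": 0})
            continue
        try:
            x, y = scale_trend(emm)
        except ValueError:
            records.append({"protein_id": pid, "x_adj": np.nan, "y_dist": np.nan,
                            "box_index": pd.NA, "pattern": "undefined_span",
                            "n_sequential_de": 0})
            continue
        refined_flags = flags.loc[pid].to_dict() if pid in flags.index else {}
        pattern, n_seq = classify_pattern(x, y, refined_flags, tol=tol)
        records.append({
            "protein_id": pid, "x_adj": x, "y_dist": y,
            "box_index": assign_box(x, y), "pattern": pattern,
            "n_sequential_de": n_seq,
        })
    out = pd.DataFrame.from_records(records)
    if not out.empty:
        out["box_index"] = out["box_index"].astype("Int64")
    return out
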