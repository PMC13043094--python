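"""Per-protein linear mixed-model differential expression.

Model
-----
For each protein, log2 abundance is modeled as

    abundance ~ group + multiplex_set + (1 | individual)

with the tissue group (STR/NSTR/CTRL, or the refined STR/Adj/Dist/CTRL) and
the multiplex set as fixed effects and a per-individual random intercept
that absorbs the pairing of strictured and non-strictured samples from the
same patient.  For proteins quantified in exactly one set the set term is
omitted.  Estimation is REML, computed here by profiling the likelihood on
the variance ratio lambda = sigma_b^2 / sigma_e^2, which for a single
random intercept reduces the fit to a smooth one-dimensional optimization
that is solved to near machine precision (important: the paired-design
special case must reproduce the closed-form paired t-test exactly).

Group contrasts are differences of estimated marginal means.  Because the
model is additive, the marginal means averaged over set levels with equal
weights differ exactly by the difference of the group coefficients, so a
contrast is a linear function of the fixed effects.  Degrees of freedom use
the Satterthwaite approximation,

    df = 2 f(theta)^2 / Var(f(theta)),   f(theta) = c' (X' V^-1 X)^-1 c,

with the gradient of f taken analytically in (sigma_b^2, sigma_e^2) and
Var(f) from the inverse expected REML information.  In balanced designs
(including the paired two-group case) this recovers the exact
between-within degrees of freedom.  Kenward-Roger, used by some mixed-model
front ends, agrees closely for near-balanced designs like this one; the
df method is recorded in the output so the choice is transparent.

Proteins with a zero random-intercept variance (boundary REML solutions)
fall back to the ordinary fixed-effects model with residual degrees of
freedom.  Contrasts involving a group with no observations are reported as
not estimable rather than zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .design import StudyDesign
from .preprocess import NormTable

DEFAULT_FDR_ALPHA = 0.05
DEFAULT_EMM_MIN = 0.3

STANDARD_COMPARISONS = ("STRvCTRL", "STRvNSTR")
REFINED_COMPARISONS = (
    "STRvAdj", "STRvDist", "AdjvCTRL", "DistvCTRL", "AdjvDist", "STRvCTRL",
)
_REFINED_LEVELS = {"Adj", "Dist"}

_SINGULAR_LAMBDA = 1e-8


def parse_comparison(comparison: str) -> tuple[str, str]:
    a, _, b = comparison.partition("v")
    if not a or not b:
        raise ValueError(f"comparison {comparison!r} is not of the form 'AvB'")
    return a, b


def comparison_is_refined(comparison: str) -> bool:
    return bool(set(parse_comparison(comparison)) & _REFINED_LEVELS)


# ---------------------------------------------------------------------------
# REML machinery for the random-intercept model
# ---------------------------------------------------------------------------

@dataclass
class ProteinFit:
    """A fitted per-protein model (REML variance components + GLS fixed effects)."""

    beta: np.ndarray
    cov_beta: np.ndarray
    coef_names: list[str]
    sigma2_e: float
    sigma2_b: float
    X: np.ndarray = field(repr=False)
    group_codes: np.ndarray = field(repr=False)
    n_obs: int = 0
    rank: int = 0
    groups_present: tuple[str, ...] = ()
    singular: bool = False
    degenerate: bool = False  # zero residual variation

    @property
    def df_resid(self) -> float:
        return float(self.n_obs - self.rank)


def _profile_stats(lam: float, y, X, starts, counts):
    """Sufficient statistics for W(lam) = I + lam * Z Z' via per-group sums."""
    # shrinkage weight per group: lam / (1 + k_i lam)
    w = lam / (1.0 + counts * lam)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    Sx = np.add.reduceat(X, starts, axis=0)      # per-group column sums
    Sy = np.add.reduceat(y, starts)
    XtWX = XtX - (Sx.T * w) @ Sx
    XtWy = Xty - (Sx.T * w) @ Sy
    ytWy = yty - float((w * Sy) @ Sy)
    logdetW = float(np.log1p(counts * lam).sum())
    return XtWX, XtWy, ytWy, logdetW


def _reml_grad(lam, y, X, starts, counts, n, p):
    """d(-2 l_R)/d lambda via the envelope theorem (per-group sums only)."""
    XtWX, XtWy, ytWy, _ = _profile_stats(lam, y, X, starts, counts)
    C = np.linalg.inv(XtWX)
    beta = C @ XtWy
    rss = ytWy - float(XtWy @ beta)
    denom = 1.0 + counts * lam
    r = y - X @ beta
    Sr = np.add.reduceat(r, starts) / denom          # Z' W^-1 r
    SX = np.add.reduceat(X, starts, axis=0) / denom[:, None]  # Z' W^-1 X
    d_logdetW = float((counts / denom).sum())
    d_logdetXtWX = -float(np.einsum("ij,ji->", C, SX.T @ SX))
    d_rss = -float(Sr @ Sr)
    if rss <= 1e-300:  # perfect fit: treat as boundary
        return np.inf
    return d_logdetW + d_logdetXtWX + (n - p) * d_rss / rss


def _fit_reml(y: np.ndarray, X: np.ndarray, ind_codes: np.ndarray):
    """Profiled REML for abundance ~ X beta + (1 | individual).

    The variance ratio lambda = sigma_b^2 / sigma_e^2 solves the stationarity
    equation of the profiled criterion; the root is bracketed and solved by
    Brent to near machine precision (a boundary solution lambda = 0 is kept
    when the criterion increases on all of lambda > 0).

    Returns (lam, sigma2_e, beta, cov_beta, degenerate).
    """
    order = np.argsort(ind_codes, kind="stable")
    y, X, ind = y[order], X[order], ind_codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(ind) != 0])
    counts = np.diff(np.r_[starts, len(ind)]).astype(float)
    n, p = X.shape

    lam = 0.0
    try:
        g0 = _reml_grad(0.0, y, X, starts, counts, n, p)
    except np.linalg.LinAlgError:
        g0 = np.inf
    if np.isfinite(g0) and g0 < 0:
        # criterion decreasing at 0: bracket the interior optimum
        lo, hi = 0.0, 1.0
        ghi = _reml_grad(hi, y, X, starts, counts, n, p)
        while ghi < 0 and hi < 1e8:
            lo, hi = hi, hi * 8.0
            ghi = _reml_grad(hi, y, X, starts, counts, n, p)
        if ghi >= 0:
            lam = float(optimize.brentq(
                _reml_grad, lo, hi, args=(y, X, starts, counts, n, p),
                xtol=1e-14, rtol=8.9e-16, maxiter=200,
            ))
        else:
            lam = hi
    if lam < _SINGULAR_LAMBDA:
        lam = 0.0

    XtWX, XtWy, ytWy, _ = _profile_stats(lam, y, X, starts, counts)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = ytWy - float(XtWy @ beta)
    sigma2_e = max(rss, 0.0) / (n - p) if n > p else 0.0
    cov_beta = sigma2_e * np.linalg.inv(XtWX)
    degenerate = sigma2_e < 1e-14
    return lam, sigma2_e, beta, cov_beta, degenerate


def _satterthwaite_df(fit: ProteinFit, c: np.ndarray) -> float:
    """Satterthwaite df for the contrast c' beta, expected-information version."""
    if fit.singular or fit.sigma2_b <= 0:
        return fit.df_resid
    X = fit.X
    n = X.shape[0]
    Z = (fit.group_codes[:, None] == np.unique(fit.group_codes)[None, :]).astype(float)
    V = fit.sigma2_e * np.eye(n) + fit.sigma2_b * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    C = np.linalg.inv(XtViX)
    f = float(c @ C @ c)

    ViX = Vi @ X
    P = Vi - ViX @ C @ ViX.T
    Vb = Z @ Z.T          # dV / d sigma_b^2
    # gradient of f wrt (sigma_b^2, sigma_e^2)
    a = ViX @ (C @ c)     # V^-1 X C c
    g = np.array([float(a @ Vb @ a), float(a @ a)])
    # expected REML information I_jk = 0.5 tr(P V_j P V_k)
    PVb = P @ Vb
    info = 0.5 * np.array([
        [np.trace(PVb @ PVb), np.trace(PVb @ P)],
        [np.trace(PVb @ P), np.trace(P @ P)],
    ])
    try:
        var_f = float(g @ np.linalg.solve(info, g))
    except np.linalg.LinAlgError:
        return fit.df_resid
    if var_f <= 0:
        return fit.df_resid
    df = 2.0 * f * f / var_f
    return float(np.clip(df, 1.0, fit.df_resid * 10 + n))


# ---------------------------------------------------------------------------
# Public fitting / contrast API
# ---------------------------------------------------------------------------

def fit_protein_model(
    values: pd.Series,
    design: StudyDesign,
    refined: bool = False,
) -> ProteinFit:
    """Fit the mixed model for one protein.

    ``values`` is a log2-abundance series indexed by sample_id (missing
    values are dropped).  ``refined`` selects the 4-level proximity
    grouping (STR/Adj/Dist/CTRL) instead of STR/NSTR/CTRL.  The multiplex
    set term is included only when the protein is quantified in more than
    one set.
    """
    meta = design.table.set_index("sample_id")
    obs = values.dropna()
    obs = obs[obs.index.isin(meta.index)]
    if len(obs) < 3:
        raise ValueError("need at least 3 observations")
    group_col = "refined_group" if refined else "group"
    groups = meta.loc[obs.index, group_col].astype(str)
    sets = meta.loc[obs.index, "tmt_set"]
    individuals = meta.loc[obs.index, "individual_id"].astype(str)

    glevels = sorted(pd.unique(groups), key=_group_order)
    if len(glevels) < 2:
        raise ValueError("need at least 2 groups represented")
    slevels = sorted(pd.unique(sets.dropna().astype(str)))
    use_set = len(slevels) > 1  # omit set term for single-set proteins

    y = obs.to_numpy(dtype=float)
    n = len(y)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["(Intercept)"]
    for g in glevels[1:]:
        cols.append((groups == g).to_numpy(dtype=float))
        names.append(f"group[{g}]")
    if use_set:
        s = sets.astype(str)
        for lv in slevels[1:]:
            cols.append((s == lv).to_numpy(dtype=float))
            names.append(f"set[{lv}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    ind_codes = pd.Categorical(individuals).codes.astype(np.int64)

    lam, sigma2_e, beta, cov_beta, degenerate = _fit_reml(y, X, ind_codes)
    singular = lam == 0.0
    if singular and not degenerate:
        # boundary fit: fall back to the fixed-effects model (identical beta
        # at lam=0, residual df downstream)
        pass
    return ProteinFit(
        beta=beta,
        cov_beta=cov_beta,
        coef_names=names,
        sigma2_e=sigma2_e,
        sigma2_b=lam * sigma2_e,
        X=X,
        group_codes=ind_codes,
        n_obs=n,
        rank=rank,
        groups_present=tuple(glevels),
        singular=singular,
        degenerate=degenerate,
    )


def _group_order(g: str) -> int:
    order = {"CTRL": 0, "Dist": 1, "Adj": 2, "NSTR": 2, "STR": 3}
    return order.get(g, 9)


def contrast_emm(fit: ProteinFit, comparison: str) -> dict:
    """Marginal-mean contrast for 'AvB': delta = EMM_A - EMM_B.

    Averaging marginal means over set levels with equal weights, the set
    coefficients cancel in the difference, leaving the group-coefficient
    contrast.  Two-sided p from a t reference with Satterthwaite df.
    """
    a, b = parse_comparison(comparison)
    rec = {
        "comparison": comparison, "delta_emm": np.nan, "se": np.nan,
        "df": np.nan, "p": np.nan, "fit_status": "ok",
    }
    if a not in fit.groups_present or b not in fit.groups_present:
        rec["fit_status"] = "not_estimable"
        return rec
    c = np.zeros(len(fit.coef_names))
    for gname, sign in ((a, 1.0), (b, -1.0)):
        key = f"group[{gname}]"
        if key in fit.coef_names:
            c[fit.coef_names.index(key)] = sign
        # reference level contributes 0
    delta = float(c @ fit.beta)
    if fit.degenerate:
        rec.update(delta_emm=delta, se=0.0, df=fit.df_resid,
                   p=1.0 if delta == 0.0 else 0.0, fit_status="degenerate")
        return rec
    se = float(np.sqrt(max(c @ fit.cov_beta @ c, 0.0)))
    df = _satterthwaite_df(fit, c)
    if se == 0.0 or df <= 0:
        rec.update(delta_emm=delta, se=se, df=df, p=np.nan, fit_status="not_estimable")
        return rec
    tval = delta / se
    p = float(2.0 * stats.t.sf(abs(tval), df))
    status = "singular" if fit.singular else "ok"
    rec.update(delta_emm=delta, se=se, df=df, p=p, fit_status=status)
    return rec


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def run_de(
    norm: NormTable,
    design: StudyDesign | None = None,
    comparisons: tuple[str, ...] = STANDARD_COMPARISONS,
    fdr_alpha: float = DEFAULT_FDR_ALPHA,
    emm_min: float = DEFAULT_EMM_MIN,
) -> pd.DataFrame:
    """Differential expression over all proteins of one (layer, platform).

    One contrast record per protein per comparison.  FDR is adjusted within
    each comparison family; a protein is flagged DE when fdr < ``fdr_alpha``
    and |delta_emm| > ``emm_min`` (both strict, the per-platform rule).
    Comparisons naming Adj or Dist use the refined proximity grouping.
    """
    design = design or norm.design
    if design is None:
        raise ValueError("run_de needs a study design")
    needs_refined = any(comparison_is_refined(cmp) for cmp in comparisons)
    needs_standard = any(not comparison_is_refined(cmp) for cmp in comparisons)

    records = []
    for pid, row in norm.values.iterrows():
        fits: dict[bool, ProteinFit | None] = {}
        for refined, needed in ((False, needs_standard), (True, needs_refined)):
            if not needed:
                continue
            try:
                fits[refined] = fit_protein_model(row, design, refined=refined)
            except (ValueError, np.linalg.LinAlgError):
                fits[refined] = None
        for cmp_name in comparisons:
            refined = comparison_is_refined(cmp_name)
            fit = fits.get(refined)
            if fit is None:
                rec = {"comparison": cmp_name, "delta_emm": np.nan, "se": np.nan,
                       "df": np.nan, "p": np.nan, "fit_status": "unfit"}
            else:
                rec = contrast_emm(fit, cmp_name)
            rec["protein_id"] = pid
            records.append(rec)

    de = pd.DataFrame.from_records(records)
    if de.empty:
        warnings.warn("empty comparison family: no proteins to test")
        return de
    de["platform"] = norm.platform
    de["fdr"] = np.nan
    for cmp_name, idx in de.groupby("comparison").groups.items():
        de.loc[idx, "fdr"] = bh_adjust(de.loc[idx, "p"].to_numpy())
    de["de_flag"] = (de["fdr"] < fdr_alpha) & (de["delta_emm"].abs() > emm_min)
    de["de_flag"] = de["de_flag"].fillna(False)
    cols = ["protein_id", "platform", "comparison", "delta_emm", "se", "df",
            "p", "fdr", "de_flag", "fit_status"]
    return de.loc[:, cols]
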