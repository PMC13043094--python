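"""Synthetic two-platform quantification data with planted ground truth.

The generator emulates the measurement structure the downstream analysis
assumes: a log-normal protein intensity model with per-individual random
intercepts, additive multiplex-set batch effects for the isobaric (TMT)
platform, a pooled per-layer reference channel, an optional high-input
booster channel, and a parallel label-free measurement of one-tenth
aliquots of the same samples.  Because both platforms measure the same
physical aliquots, their measurement errors are correlated; the dial for
that correlation (``rho_platforms``) is what makes dependence-aware
p-value merging testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import StudyDesign

DE_CLASSES = ("null", "up", "down")
TREND_CLASSES = ("flat", "progressive", "adjacent_saturating", "early_shift")
SET_MEMBERSHIPS = ("both_sets", "set1_only", "set2_only")

QUANT_COLUMNS = (
    "protein_id", "sample_id", "platform", "layer", "tmt_set",
    "channel_role", "intensity",
)

#: Canonical scaled (Adj, Dist) coordinate windows for each planted trend
#: shape, on the CTRL=0 / STR=1 axis.  Jitter is drawn uniformly inside the
#: window so that planted classes sit well inside their classification cell.
_TREND_WINDOWS: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "progressive": ((0.45, 0.65), (0.40, 0.60)),        # x_adj, y_dist/x_adj ratio
    "adjacent_saturating": ((0.95, 1.05), (0.30, 0.50)),  # x_adj, y_dist absolute
    "early_shift": ((0.95, 1.05), (0.95, 1.05)),
}


@dataclass
class NoiseConfig:
    """Variance components and missingness settings, all on the log2 scale.

    Defaults reflect protein-level summaries of isobaric reporter data:
    between-individual biological SD of ~0.35, multiplex-set batch SD of
    0.2, measurement SDs of 0.15 (TMT) and 0.25 (label-free), and a
    moderate shared-aliquot error correlation of 0.5.  Label-free
    missingness is intensity-dependent (logistic in log2 intensity).
    """

    sigma_individual: float = 0.35
    sigma_set: float = 0.2
    sigma_meas_tmt: float = 0.15
    sigma_meas_lf: float = 0.25
    rho_platforms: float = 0.5
    lf_dropout_midpoint: float = 8.0
    lf_dropout_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_individual", "sigma_set", "sigma_meas_tmt", "sigma_meas_lf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.rho_platforms <= 1.0:
            raise ValueError("rho_platforms must lie in [0, 1]")


@dataclass
class TruthTable:
    """Planted per-(protein, layer) ground truth.

    ``table`` columns: protein_id, layer, baseline_log2, eff_STR, eff_Adj,
    eff_Dist (all log2 offsets relative to CTRL = 0), de_class,
    trend_class, detect_tmt, detect_lf, set_membership.
    """

    table: pd.DataFrame = field(repr=False)
    config: dict = field(default_factory=dict)

    def effects(self, layer: str) -> pd.DataFrame:
        t = self.table[self.table["layer"] == layer].set_index("protein_id")
        out = pd.DataFrame(index=t.index)
        out["CTRL"] = 0.0
        out["Dist"] = t["eff_Dist"]
        out["Adj"] = t["eff_Adj"]
        out["STR"] = t["eff_STR"]
        # NSTR samples inherit their refined-group effect; kept for lookups
        return out

    def subset(self, layer: str) -> pd.DataFrame:
        return self.table[self.table["layer"] == layer].reset_index(drop=True)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = out < lo
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo, None)


def generate_truth(
    n_proteins: int,
    fractions: Mapping[str, float] | None = None,
    trend_fractions: Mapping[str, float] | None = None,
    effect_params: Mapping[str, float] | None = None,
    seed: int = 0,
    layers: tuple[str, ...] = ("SM", "MP"),
    frac_single_set: float = 0.1,
    baseline_mean: float = 11.0,
    baseline_sd: float = 1.5,
) -> TruthTable:
    """Draw planted protein effects.

    ``fractions`` maps de classes (``up``/``down``) to proportions; the
    remainder is null.  ``trend_fractions`` partitions DE proteins into
    proximity-trend shapes (progressive / adjacent_saturating /
    early_shift).  ``effect_params`` gives the |log2 effect| distribution
    (truncated normal; keys mean, sd, min).  Classes are drawn
    independently per layer.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    fractions = dict(fractions) if fractions is not None else {"up": 0.05, "down": 0.05}
    for k, v in fractions.items():
        if k not in ("up", "down"):
            raise ValueError(f"unknown de class {k!r}")
        if v < 0:
            raise ValueError("fractions must be non-negative")
    if sum(fractions.values()) > 1.0 + 1e-12:
        raise ValueError("de fractions must sum to <= 1")
    trend_fractions = dict(
        trend_fractions
        or {"progressive": 0.6, "adjacent_saturating": 0.2, "early_shift": 0.2}
    )
    if any(v < 0 for v in trend_fractions.values()):
        raise ValueError("trend fractions must be non-negative")
    tot = sum(trend_fractions.values())
    if tot <= 0:
        raise ValueError("trend fractions must sum to > 0")
    trend_fractions = {k: v / tot for k, v in trend_fractions.items()}
    effect_params = dict(effect_params or {"mean": 1.5, "sd": 0.4, "min": 0.8})

    rng = _rng(seed, 10)
    proteins = np.array([f"P{i + 1:05d}" for i in range(n_proteins)])

    # platform detection and set membership are protein properties
    memb = rng.choice(
        SET_MEMBERSHIPS, size=n_proteins,
        p=[1 - frac_single_set, frac_single_set / 2, frac_single_set / 2],
    )

    rows = []
    for layer in layers:
        baseline = rng.normal(baseline_mean, baseline_sd, size=n_proteins)
        p_null = 1.0 - sum(fractions.values())
        de = rng.choice(
            ["null", *fractions.keys()], size=n_proteins,
            p=[p_null, *fractions.values()],
        )
        trend = np.where(
            de == "null", "flat",
            rng.choice(list(trend_fractions), size=n_proteins, p=list(trend_fractions.values())),
        )
        mag = _truncnorm(
            rng, effect_params["mean"], effect_params["sd"],
            effect_params.get("min", 0.0), n_proteins,
        )
        sign = np.where(de == "up", 1.0, np.where(de == "down", -1.0, 0.0))
        eff_str = sign * mag

        x_adj = np.zeros(n_proteins)
        y_dist = np.zeros(n_proteins)
        for cls, ((xa, xb), (ya, yb)) in _TREND_WINDOWS.items():
            m = (trend == cls) & (de != "null")
            n = int(m.sum())
            if n == 0:
                continue
            x = rng.uniform(xa, xb, size=n)
            if cls == "progressive":
                y = x * rng.uniform(ya, yb, size=n)
            else:
                y = rng.uniform(ya, yb, size=n)
            x_adj[m], y_dist[m] = x, y

        rows.append(pd.DataFrame({
            "protein_id": proteins,
            "layer": layer,
            "baseline_log2": baseline,
            "eff_STR": eff_str,
            "eff_Adj": x_adj * eff_str,
            "eff_Dist": y_dist * eff_str,
            "de_class": de,
            "trend_class": trend,
            "detect_tmt": True,
            "detect_lf": True,
            "set_membership": memb,
        }))

    config = {
        "n_proteins": n_proteins, "fractions": fractions,
        "trend_fractions": trend_fractions, "effect_params": effect_params,
        "frac_single_set": frac_single_set, "seed": seed,
        "baseline_mean": baseline_mean, "baseline_sd": baseline_sd,
    }
    return TruthTable(pd.concat(rows, ignore_index=True), config=config)


def _latent_layer(
    design: StudyDesign, truth: TruthTable, noise: NoiseConfig, layer: str
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Latent log2 sample signals plus the shared measurement-error draw.

    Returns (samples, latent_log2[protein, sample], u_shared[protein, sample]).
    The latent signal (baseline + refined-group effect + individual
    intercept) and the shared error component are identical for both
    platforms because they measure aliquots of the same sample.
    """
    t = truth.subset(layer)
    samples = design.samples(layer=layer)
    n_p, n_s = len(t), len(samples)

    eff = np.zeros((n_p, n_s))
    refined = samples["refined_group"].to_numpy()
    for gi, gname in enumerate(refined):
        if gname == "STR":
            eff[:, gi] = t["eff_STR"]
        elif gname == "Adj":
            eff[:, gi] = t["eff_Adj"]
        elif gname == "Dist":
            eff[:, gi] = t["eff_Dist"]

    rng = _rng(noise.seed, 20 + hash_layer(layer))
    individuals = pd.unique(samples["individual_id"])
    b = rng.normal(0.0, noise.sigma_individual, size=(n_p, len(individuals)))
    ind_idx = pd.Index(individuals).get_indexer(samples["individual_id"])
    latent = t["baseline_log2"].to_numpy()[:, None] + eff + b[:, ind_idx]
    u_shared = rng.standard_normal((n_p, n_s))
    return samples, latent, u_shared


def hash_layer(layer: str) -> int:
    # stable small stream offset per layer name
    return sum(ord(c) for c in layer) % 97


def simulate_tmt(
    design: StudyDesign,
    truth: TruthTable,
    noise: NoiseConfig,
    booster_factor: float = 10.0,
) -> pd.DataFrame:
    """Simulate isobaric reporter intensities (long format).

    Sample intensity = 2^(baseline + group effect + individual intercept +
    set effect + measurement error).  The reference channel carries the
    per-layer pooled mean of all sample aliquot amounts (pooling happens
    before labeling, so a single pool serves every set of the layer); the
    booster channel carries ``booster_factor`` times the mean STR amount.
    Proteins with single-set membership are absent from the other set.
    """
    layers = design.layers
    if set(layers) - set(truth.table["layer"]):
        raise ValueError("truth does not cover all design layers")
    rho = noise.rho_platforms
    rows = []
    for layer in layers:
        samples, latent, u_shared = _latent_layer(design, truth, noise, layer)
        t = truth.subset(layer)
        keep = t["detect_tmt"].to_numpy()
        rng = _rng(noise.seed, 40 + hash_layer(layer))
        sets = design.sets(layer)
        set_eff = rng.normal(0.0, noise.sigma_set, size=(len(t), len(sets)))
        u_priv = rng.standard_normal(latent.shape)
        eps = noise.sigma_meas_tmt * (np.sqrt(rho) * u_shared + np.sqrt(1 - rho) * u_priv)

        amounts = np.power(2.0, latent)              # linear-scale aliquot amounts
        pool = amounts.mean(axis=1)                  # per-layer pooled reference
        str_mask = (samples["group"] == "STR").to_numpy()
        boost = booster_factor * (amounts[:, str_mask].mean(axis=1) if str_mask.any() else pool)

        set_of_sample = samples["tmt_set"].to_numpy()
        for si, tset in enumerate(sets):
            in_set = np.ones(len(t), dtype=bool)
            if len(sets) > 1:
                memb = t["set_membership"].to_numpy()
                in_set = np.where(memb == "set1_only", si == 0,
                                  np.where(memb == "set2_only", si == 1, True))
            pmask = keep & in_set
            cols = np.flatnonzero(set_of_sample == tset)
            inten = amounts[np.ix_(pmask, cols)] * np.power(
                2.0, set_eff[pmask, si][:, None] + eps[np.ix_(pmask, cols)]
            )
            pid = t.loc[pmask, "protein_id"].to_numpy()
            for j, ci in enumerate(cols):
                rows.append(pd.DataFrame({
                    "protein_id": pid,
                    "sample_id": samples.loc[ci, "sample_id"],
                    "platform": "tmt",
                    "layer": layer,
                    "tmt_set": tset,
                    "channel_role": "sample",
                    "intensity": inten[:, j],
                }))
            # reference and booster channels, with their own measurement error
            nonsample = design.table[
                (design.table["tmt_set"] == tset)
                & (design.table["channel_role"] != "sample")
            ]
            for _, ch in nonsample.iterrows():
                base = pool[pmask] if ch["channel_role"] == "reference" else boost[pmask]
                e = noise.sigma_meas_tmt * rng.standard_normal(int(pmask.sum()))
                rows.append(pd.DataFrame({
                    "protein_id": pid,
                    "sample_id": ch["sample_id"],
                    "platform": "tmt",
                    "layer": layer,
                    "tmt_set": tset,
                    "channel_role": ch["channel_role"],
                    "intensity": base * np.power(2.0, set_eff[pmask, si] + e),
                }))
    return pd.concat(rows, ignore_index=True)


def simulate_labelfree(
    design: StudyDesign,
    truth: TruthTable,
    noise: NoiseConfig,
    dropout: bool = True,
) -> pd.DataFrame:
    """Simulate the parallel label-free platform (long format).

    Uses the same latent sample signals as :func:`simulate_tmt` (shared via
    the aliquot split), platform-specific measurement error correlated with
    the TMT error by ``rho_platforms``, logistic intensity-dependent
    dropout, and no reference/booster channels.
    """
    if set(design.layers) - set(truth.table["layer"]):
        raise ValueError("truth does not cover all design layers")
    rho = noise.rho_platforms
    rows = []
    for layer in design.layers:
        samples, latent, u_shared = _latent_layer(design, truth, noise, layer)
        t = truth.subset(layer)
        keep = t["detect_lf"].to_numpy()
        rng = _rng(noise.seed, 60 + hash_layer(layer))
        u_priv = rng.standard_normal(latent.shape)
        eps = noise.sigma_meas_lf * (np.sqrt(rho) * u_shared + np.sqrt(1 - rho) * u_priv)
        log2_obs = latent + eps
        present = np.ones(latent.shape, dtype=bool)
        if dropout:
            p_miss = expit(-noise.lf_dropout_slope * (log2_obs - noise.lf_dropout_midpoint))
            present = rng.random(latent.shape) >= p_miss
        present &= keep[:, None]

        pid = t["protein_id"].to_numpy()
        for j in range(len(samples)):
            m = present[:, j]
            rows.append(pd.DataFrame({
                "protein_id": pid[m],
                "sample_id": samples.loc[j, "sample_id"],
                "platform": "labelfree",
                "layer": layer,
                "tmt_set": None,
                "channel_role": "sample",
                "intensity": np.power(2.0, log2_obs[m, j]),
            }))
    return pd.concat(rows, ignore_index=True)


def generate_tissue_mask(
    width_px: int,
    height_px: int,
    um_per_px: float,
    density_profile: float | tuple | None = 1.0,
    seed: int = 0,
):
    """Generate a binary tissue mask with a prescribed foreground density.

    ``density_profile`` is either a uniform density in [0, 1], a tuple
    ``("gradient", d0, d1)`` ramping column-wise densities from d0 to d1,
    or ``("blobs", density, scale_px)`` for a smoothed-noise texture whose
    overall foreground fraction equals ``density``.
    """
    from .tissue import TissueMask  # local import to avoid a cycle

    if width_px < 1 or height_px < 1 or um_per_px <= 0:
        raise ValueError("mask dimensions and scale must be positive")
    rng = _rng(seed, 80)
    if density_profile is None:
        density_profile = 1.0
    if np.isscalar(density_profile):
        d = float(density_profile)
        if not 0.0 <= d <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        if d == 1.0:
            pixels = np.ones((height_px, width_px), dtype=bool)
        elif d == 0.0:
            pixels = np.zeros((height_px, width_px), dtype=bool)
        else:
            pixels = rng.random((height_px, width_px)) < d
    else:
        kind = density_profile[0]
        if kind == "gradient":
            _, d0, d1 = density_profile
            col_d = np.linspace(d0, d1, width_px)
            pixels = rng.random((height_px, width_px)) < col_d[None, :]
        elif kind == "blobs":
            from scipy.ndimage import gaussian_filter
            _, d, scale = density_profile
            noise_field = gaussian_filter(rng.standard_normal((height_px, width_px)), sigma=scale)
            thr = np.quantile(noise_field, 1.0 - d)
            pixels = noise_field > thr
        else:
            raise ValueError(f"unknown density profile {kind!r}")
    return TissueMask(pixels=pixels, um_per_px=float(um_per_px))


def noise_config_dict(noise: NoiseConfig) -> dict:
    return asdict(noise)
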