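"""End-to-end orchestration: simulate -> normalize -> DE -> integrate -> trends.

A single YAML-configurable entry point that runs the whole layer-resolved
analysis on synthetic data with planted truth, writes every intermediate
table as TSV with a provenance header, and reports recovery metrics
against the planted truth.  All randomness flows from one root seed via
named substreams, so a fixed seed reproduces every output byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import StudyDesign, generate_design
from .integrate import (
    IntegrationConfig, call_combined, join_platforms, rank_proteins,
)
from .mixed_de import REFINED_COMPARISONS, STANDARD_COMPARISONS, run_de
from .preprocess import (
    NormTable, batch_correct_complete, filter_proteins, normalize_labelfree,
    normalize_tmt,
)
from .simulate import (
    NoiseConfig, TruthTable, generate_truth, simulate_labelfree, simulate_tmt,
)
from .trends import classify_interlayer, run_pca, trend_profiles


@dataclass
class PipelineConfig:
    """Validated configuration for a full synthetic run."""

    n_cases: int = 12
    n_controls: int = 8
    sets_per_layer: int = 2
    samples_per_set: int = 16
    n_proteins: int = 1000
    fractions: dict = field(default_factory=lambda: {"up": 0.05, "down": 0.05})
    trend_fractions: dict | None = None
    effect_params: dict | None = None
    noise: dict = field(default_factory=dict)
    integration: dict = field(default_factory=dict)
    comparisons: list = field(default_factory=lambda: list(STANDARD_COMPARISONS))
    refined_comparisons: list = field(
        default_factory=lambda: sorted(set(REFINED_COMPARISONS))
    )
    min_frac_per_group: float = 0.5
    seed: int = 0
    layers: list = field(default_factory=lambda: ["SM", "MP"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def noise_config(self, seed: int) -> NoiseConfig:
        return NoiseConfig(**{**self.noise, "seed": seed})

    def integration_config(self) -> IntegrationConfig:
        return IntegrationConfig(**self.integration)


def _substream(seed: int, idx: int) -> int:
    """A derived 31-bit child seed for stage ``idx``."""
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(idx,)).generate_state(1)[0] % (2 ** 31))


def _write_tsv(df: pd.DataFrame, path: Path, provenance: dict) -> None:
    with open(path, "w") as fh:
        for k, v in provenance.items():
            fh.write(f"# {k}={json.dumps(v, sort_keys=True, default=str)}\n")
        df.to_csv(fh, sep="\t", index=False)


def recovery_summary(combined: pd.DataFrame, truth: TruthTable, layer: str) -> dict:
    """Sensitivity / FDR / WE bias of combined STRvCTRL calls vs planted truth."""
    t = truth.subset(layer).set_index("protein_id")
    sub = combined[combined["comparison"] == "STRvCTRL"].set_index("protein_id")
    joined = sub.join(t[["de_class", "eff_STR"]], how="left")
    is_de_true = joined["de_class"].isin(["up", "down"])
    called = joined["combined_de"].fillna(False)
    tp = int((called & is_de_true).sum())
    fp = int((called & ~is_de_true).sum())
    fn = int((~called & is_de_true).sum())
    de_true = joined[is_de_true]
    bias = float((de_true["we"] - de_true["eff_STR"]).mean()) if len(de_true) else np.nan
    return {
        "layer": layer,
        "n_tested": int(len(joined)),
        "true_de": int(is_de_true.sum()),
        "called_de": int(called.sum()),
        "sensitivity": tp / max(tp + fn, 1),
        "empirical_fdr": fp / max(tp + fp, 1),
        "we_mean_bias": bias,
    }


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full pipeline; returns a dict of result tables + summary."""
    out: dict = {}
    provenance = {"config": config.to_dict()}

    design = generate_design(
        config.n_cases, config.n_controls, config.sets_per_layer,
        config.samples_per_set, layers=tuple(config.layers),
    )
    truth = generate_truth(
        config.n_proteins, fractions=config.fractions,
        trend_fractions=config.trend_fractions, effect_params=config.effect_params,
        seed=_substream(config.seed, 1), layers=tuple(config.layers),
    )
    noise = config.noise_config(seed=_substream(config.seed, 2))
    raw_tmt = simulate_tmt(design, truth, noise)
    raw_lf = simulate_labelfree(design, truth, noise)
    out.update(design=design, truth=truth, raw_tmt=raw_tmt, raw_lf=raw_lf)

    icfg = config.integration_config()
    all_comparisons = tuple(dict.fromkeys([*config.comparisons, *config.refined_comparisons]))
    summary: dict = {"layers": {}, "config_seed": config.seed}
    combined_by_layer: dict[str, pd.DataFrame] = {}
    for layer in config.layers:
        ldesign = design.subset(layer)
        norm_tmt = filter_proteins(
            normalize_tmt(raw_tmt[raw_tmt["layer"] == layer], ldesign),
            config.min_frac_per_group,
        )
        norm_lf = filter_proteins(
            normalize_labelfree(raw_lf[raw_lf["layer"] == layer], ldesign),
            config.min_frac_per_group,
        )
        de_tmt = run_de(norm_tmt, ldesign, comparisons=all_comparisons)
        de_lf = run_de(norm_lf, ldesign, comparisons=all_comparisons)
        combined = call_combined(join_platforms(de_tmt, de_lf), icfg)
        ranked = rank_proteins(combined, icfg)

        corrected = batch_correct_complete(norm_tmt)
        groups = ldesign.table.set_index("sample_id")["group"]
        pca = run_pca(corrected, groups=groups)

        profiles = trend_profiles(
            de_tmt[de_tmt["comparison"].isin(config.refined_comparisons)],
            combined_std=combined,
        )

        combined_by_layer[layer] = combined
        out[f"norm_tmt_{layer}"] = norm_tmt
        out[f"norm_lf_{layer}"] = norm_lf
        out[f"de_tmt_{layer}"] = de_tmt
        out[f"de_lf_{layer}"] = de_lf
        out[f"combined_{layer}"] = combined
        out[f"ranked_{layer}"] = ranked
        out[f"pca_{layer}"] = pca
        out[f"trends_{layer}"] = profiles

        # unique proteins DE in either stricture comparison, by direction
        stricture = combined[combined["comparison"].isin(["STRvCTRL", "STRvNSTR"])]
        per_protein = stricture.groupby("protein_id").agg(
            de=("combined_de", "any"), we=("we", "mean"))
        de_calls = per_protein[per_protein["de"]]
        summary["layers"][layer] = {
            "n_proteins_tmt": int(norm_tmt.n_proteins),
            "n_proteins_lf": int(norm_lf.n_proteins),
            "combined_de_up": int((de_calls["we"] > 0).sum()),
            "combined_de_down": int((de_calls["we"] < 0).sum()),
            "recovery": recovery_summary(combined, truth, layer),
            "pca_var_explained_pc1": float(pca.var_explained[0]),
            "trend_pattern_counts": profiles["pattern"].value_counts().to_dict()
            if len(profiles) else {},
        }

    if len(config.layers) == 2:
        sm, mp = config.layers
        interlayer = classify_interlayer(combined_by_layer[sm], combined_by_layer[mp])
        out["interlayer"] = interlayer
        summary["interlayer_counts"] = interlayer["category"].value_counts().to_dict()
    summary_df = pd.json_normalize(summary, sep=".")
    out["summary"] = summary

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        design.to_tsv(outdir / "design.tsv")
        _write_tsv(truth.table, outdir / "truth.tsv", provenance)
        for layer in config.layers:
            out[f"norm_tmt_{layer}"].to_tsv(outdir / f"norm_tmt_{layer}.tsv")
            out[f"norm_lf_{layer}"].to_tsv(outdir / f"norm_lf_{layer}.tsv")
            _write_tsv(out[f"de_tmt_{layer}"], outdir / f"de_tmt_{layer}.tsv", provenance)
            _write_tsv(out[f"de_lf_{layer}"], outdir / f"de_lf_{layer}.tsv", provenance)
            _write_tsv(out[f"combined_{layer}"], outdir / f"combined_{layer}.tsv", provenance)
            _write_tsv(out[f"ranked_{layer}"], outdir / f"ranked_{layer}.tsv", provenance)
            _write_tsv(out[f"trends_{layer}"], outdir / f"trends_{layer}.tsv", provenance)
            out[f"pca_{layer}"].scores.to_csv(outdir / f"pca_scores_{layer}.tsv", sep="\t")
        if "interlayer" in out:
            _write_tsv(out["interlayer"], outdir / "interlayer.tsv", provenance)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        summary_df.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    return out
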