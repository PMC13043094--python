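"""Normalization and filtering of raw quantification tables.

The isobaric platform is normalized against its pooled reference channel
(log2 sample/reference ratio, then per-sample median centering within each
multiplex set); the label-free platform is log2-transformed and
median-centered per sample.  Zero intensities are treated as not
quantified.  Batch handling for PCA removes additive multiplex-set offsets
on the complete-observation submatrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StudyDesign


class PreprocessError(ValueError):
    pass


@dataclass
class NormTable:
    """Analysis-ready log2 abundance matrix (proteins x samples).

    Sample columns exclude reference and booster channels.  ``provenance``
    records the normalization applied; ``filter_log`` accumulates protein
    counts before/after filtering steps.
    """

    values: pd.DataFrame = field(repr=False)
    platform: str = "tmt"
    design: StudyDesign | None = field(default=None, repr=False)
    provenance: dict = field(default_factory=dict)
    filter_log: list = field(default_factory=list)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    def sample_sets(self) -> pd.Series:
        """sample_id -> tmt_set for the columns (NaN for label-free)."""
        if self.design is None:
            return pd.Series(index=self.values.columns, dtype=object)
        t = self.design.table.set_index("sample_id")["tmt_set"]
        return t.reindex(self.values.columns)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.provenance.items():
                fh.write(f"# {k}={v}\n")
            self.values.to_csv(fh, sep="\t")


def _pivot(raw: pd.DataFrame, role: str = "sample") -> pd.DataFrame:
    sub = raw[raw["channel_role"] == role]
    wide = sub.pivot_table(
        index="protein_id", columns="sample_id", values="intensity", aggfunc="first"
    )
    return wide.replace(0.0, np.nan)  # zero reporter intensity = not quantified


def normalize_tmt(raw: pd.DataFrame, design: StudyDesign) -> NormTable:
    """Reference-ratio normalization for the isobaric platform.

    value = log2(sample intensity / same-set reference intensity), followed
    by per-sample median centering within each multiplex set.  Proteins
    with a zero/absent reference in a set are missing for that whole set.
    """
    wide = _pivot(raw, "sample")
    refs = raw[raw["channel_role"] == "reference"]
    if refs.empty:
        raise PreprocessError("no reference channels in input")
    ref_wide = refs.pivot_table(
        index="protein_id", columns="tmt_set", values="intensity", aggfunc="first"
    ).replace(0.0, np.nan)

    meta = design.table.set_index("sample_id")
    out = {}
    for col in wide.columns:
        tset = meta.loc[col, "tmt_set"]
        if tset not in ref_wide.columns:
            raise PreprocessError(f"missing reference channel for set {tset}")
        ref = ref_wide[tset].reindex(wide.index)
        out[col] = np.log2(wide[col] / ref)
    values = pd.DataFrame(out, index=wide.index)

    # per-sample median centering (within set == per sample column)
    values = values - values.median(axis=0, skipna=True)

    sub_design = StudyDesign(meta.loc[list(values.columns)].reset_index())
    return NormTable(
        values=values,
        platform="tmt",
        design=sub_design,
        provenance={
            "platform": "tmt",
            "normalization": "log2 sample/reference ratio + per-sample median centering",
        },
    )


def normalize_labelfree(raw: pd.DataFrame, design: StudyDesign | None = None) -> NormTable:
    """log2 transform + median-polish-style per-sample centering.

    Per-sample offsets are medians of deviations from each protein's own
    cross-sample median, taken over proteins observed in every sample
    (fallback: all observed).  Deviations concentrate the centering basis
    far more tightly than raw abundances, which keeps the offsets robust
    both to differentially expressed proteins and to the compositional
    imbalance that intensity-dependent dropout induces in the basis.
    The protein medians are also subtracted (a per-protein constant, so
    group contrasts are untouched).  Missing cells stay missing.
    """
    wide = _pivot(raw, "sample")
    n_obs = wide.notna().sum(axis=0)
    if (n_obs == 0).any():
        empty = list(n_obs.index[n_obs == 0])
        raise PreprocessError(f"samples with no observed proteins: {empty}")
    values = np.log2(wide)
    complete = values.dropna(axis=0)
    basis = "complete-observation proteins"
    if complete.empty:
        complete = values
        basis = "all observed proteins (no complete rows)"
    # pass 1: raw per-sample medians (absorbs sample scaling exactly)
    values = values - complete.median(axis=0, skipna=True)
    # pass 2: refine on deviations from each protein's cross-sample median;
    # the concentrated basis keeps offsets robust to DE proteins and to the
    # compositional imbalance that intensity-dependent dropout induces
    row_med = values.median(axis=1, skipna=True)
    deviations = values.sub(row_med, axis=0)
    basis_dev = deviations.loc[deviations.index.intersection(complete.index)]
    values = deviations - basis_dev.median(axis=0, skipna=True)

    sub_design = None
    if design is not None:
        meta = design.table.set_index("sample_id")
        sub_design = StudyDesign(meta.loc[list(values.columns)].reset_index())
    return NormTable(
        values=values,
        platform="labelfree",
        design=sub_design,
        provenance={
            "platform": "labelfree",
            "normalization": (
                "log2, per-protein median subtraction, per-sample "
                f"median-of-deviations centering over {basis}"
            ),
        },
    )


def filter_proteins(norm: NormTable, min_frac_per_group: float) -> NormTable:
    """Keep proteins observed in >= min_frac of samples in at least one group."""
    if not 0.0 <= min_frac_per_group <= 1.0:
        raise PreprocessError("min_frac_per_group must lie in [0, 1]")
    if norm.design is None:
        raise PreprocessError("filtering needs a design with group labels")
    groups = norm.design.table.set_index("sample_id")["group"].reindex(norm.values.columns)
    observed = norm.values.notna()
    frac_by_group = observed.T.groupby(groups.values).mean().T
    keep = (frac_by_group >= min_frac_per_group).any(axis=1)
    out = NormTable(
        values=norm.values.loc[keep].copy(),
        platform=norm.platform,
        design=norm.design,
        provenance=dict(norm.provenance),
        filter_log=list(norm.filter_log),
    )
    out.filter_log.append({
        "step": "filter_proteins",
        "min_frac_per_group": min_frac_per_group,
        "before": int(norm.values.shape[0]),
        "after": int(keep.sum()),
    })
    return out


def batch_correct_complete(norm: NormTable) -> pd.DataFrame:
    """Complete-observation matrix with additive set offsets removed.

    Restricts to proteins observed in every sample, subtracts per-protein
    within-set means and adds back the per-protein grand mean, so an
    additive multiplex-set batch effect is removed exactly while within-set
    sample contrasts are untouched.  Label-free input (no sets) passes
    through with only the completeness restriction.
    """
    complete = norm.values.dropna(axis=0)
    if complete.shape[0] < 2:
        raise PreprocessError("need at least 2 complete-observation proteins")
    sets = norm.sample_sets()
    if sets.isna().all():
        return complete.copy()
    grand = complete.mean(axis=1)
    corrected = complete.copy()
    for tset, cols in complete.columns.to_series().groupby(sets.values):
        cs = list(cols)
        corrected[cs] = complete[cs].sub(complete[cs].mean(axis=1), axis=0).add(grand, axis=0)
    return corrected
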