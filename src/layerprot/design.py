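"""Study design: sample-to-cohort bookkeeping for the layer-resolved workflow.

The design maps every multiplex channel to an individual, a tissue group
(strictured STR, paired non-strictured NSTR, independent control CTRL), a
refined proximity group (NSTR subdivided into adjacent Adj / distal Dist),
an intestinal wall layer (submucosa SM, muscularis propria MP), a multiplex
set and a channel role (sample, pooled reference, booster).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

GROUPS = ("STR", "NSTR", "CTRL")
REFINED_GROUPS = ("STR", "Adj", "Dist", "CTRL")
LAYERS = ("SM", "MP")
CHANNEL_ROLES = ("sample", "reference", "booster")

#: TMTpro 18-plex reporter labels, in elution/channel order.
TMTPRO_18 = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C",
    "131N", "131C", "132N", "132C", "133N", "133C", "134N", "134C", "135N",
)

DESIGN_COLUMNS = (
    "sample_id", "individual_id", "group", "refined_group",
    "layer", "tmt_set", "channel", "channel_role",
)


class DesignError(ValueError):
    """Raised when a study design is internally inconsistent."""


@dataclass
class StudyDesign:
    """A sample sheet for one cohort across one or more tissue layers.

    ``table`` has one row per multiplex channel (including non-sample
    reference/booster channels) with the columns in :data:`DESIGN_COLUMNS`.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(DESIGN_COLUMNS) - set(self.table.columns)
        if missing:
            raise DesignError(f"design table missing columns: {sorted(missing)}")
        self.table = self.table.loc[:, list(DESIGN_COLUMNS)].reset_index(drop=True)

    # -- accessors ---------------------------------------------------------

    def samples(self, layer: str | None = None, tmt_set: str | None = None) -> pd.DataFrame:
        """Rows with channel_role == 'sample', optionally restricted."""
        t = self.table
        m = t["channel_role"] == "sample"
        if layer is not None:
            m &= t["layer"] == layer
        if tmt_set is not None:
            m &= t["tmt_set"] == tmt_set
        return t.loc[m].reset_index(drop=True)

    @property
    def layers(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.table["layer"]))

    def sets(self, layer: str | None = None) -> tuple[str, ...]:
        t = self.table if layer is None else self.table[self.table["layer"] == layer]
        return tuple(pd.unique(t["tmt_set"].dropna()))

    def subset(self, layer: str) -> "StudyDesign":
        return StudyDesign(self.table[self.table["layer"] == layer].copy())

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        t = self.table
        bad = set(t["group"]) - set(GROUPS)
        if bad:
            raise DesignError(f"unknown groups: {sorted(bad)}")
        bad = set(t["refined_group"]) - set(REFINED_GROUPS)
        if bad:
            raise DesignError(f"unknown refined groups: {sorted(bad)}")
        bad = set(t["channel_role"]) - set(CHANNEL_ROLES)
        if bad:
            raise DesignError(f"unknown channel roles: {sorted(bad)}")
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise DesignError(f"duplicate sample ids: {dups}")

        s = t[t["channel_role"] == "sample"]
        # refined group is Adj/Dist exactly for NSTR
        nstr = s["group"] == "NSTR"
        if not s.loc[nstr, "refined_group"].isin(["Adj", "Dist"]).all():
            raise DesignError("NSTR samples must be refined to Adj or Dist")
        if not (s.loc[~nstr, "refined_group"] == s.loc[~nstr, "group"]).all():
            raise DesignError("non-NSTR samples must keep their group as refined group")

        # every STR sample has a same-individual, same-layer NSTR partner
        for layer in self.layers:
            sl = s[s["layer"] == layer]
            str_ids = set(sl.loc[sl["group"] == "STR", "individual_id"])
            nstr_ids = set(sl.loc[sl["group"] == "NSTR", "individual_id"])
            if str_ids != nstr_ids:
                raise DesignError(
                    f"layer {layer}: STR/NSTR pairing broken "
                    f"(unpaired: {sorted(str_ids ^ nstr_ids)})"
                )
            ctrl = sl[sl["group"] == "CTRL"]
            counts = ctrl.groupby("individual_id").size()
            if (counts != 1).any():
                raise DesignError(f"layer {layer}: CTRL individuals must contribute one sample")

        # per (layer, set): exactly one reference, at most one booster
        for (layer, tset), grp in t.groupby(["layer", "tmt_set"], dropna=True):
            n_ref = int((grp["channel_role"] == "reference").sum())
            n_boost = int((grp["channel_role"] == "booster").sum())
            if n_ref != 1:
                raise DesignError(f"set {tset} ({layer}): expected 1 reference, got {n_ref}")
            if n_boost > 1:
                raise DesignError(f"set {tset} ({layer}): more than one booster")

    # -- IO ----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StudyDesign":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


def _channel_label(i: int) -> str:
    return TMTPRO_18[i] if i < len(TMTPRO_18) else f"ch{i + 1:02d}"


def generate_design(
    n_cases: int = 12,
    n_controls: int = 8,
    sets_per_layer: int = 2,
    samples_per_set: int = 16,
    layers: tuple[str, ...] = LAYERS,
    booster: bool = True,
) -> StudyDesign:
    """Build a paired stricture cohort design.

    Each case individual contributes a paired STR + NSTR sample per layer;
    each control individual contributes one CTRL sample per layer.  Samples
    are dealt to multiplex sets so that groups stay balanced across sets,
    keeping each STR/NSTR pair within one set.  Every set receives a pooled
    reference channel and (optionally) a booster channel.

    The default arguments reproduce the study cohort: 12 cases and 8
    controls give 32 sample channels per layer, split into 2 sets of 16,
    i.e. 64 microdissected samples and 4 multiplex sets over both layers.
    """
    if n_cases < 1 or n_controls < 0:
        raise DesignError("need at least one case and a non-negative control count")
    per_layer = 2 * n_cases + n_controls
    if sets_per_layer * samples_per_set != per_layer:
        raise DesignError(
            f"cohort size mismatch: {n_cases} cases + {n_controls} controls give "
            f"{per_layer} sample channels per layer, but {sets_per_layer} sets x "
            f"{samples_per_set} channels hold {sets_per_layer * samples_per_set}"
        )

    cases = [f"CD{i + 1:02d}" for i in range(n_cases)]
    controls = [f"CTRL{i + 1:02d}" for i in range(n_controls)]
    # NSTR proximity refinement: alternate adjacent / distal across cases.
    refined_nstr = {cid: ("Adj" if i % 2 == 0 else "Dist") for i, cid in enumerate(cases)}

    rows: list[dict] = []
    for layer in layers:
        # deal STR/NSTR pairs round-robin, then fill with controls
        set_members: list[list[tuple[str, str]]] = [[] for _ in range(sets_per_layer)]
        capacity = [samples_per_set] * sets_per_layer
        si = 0
        for cid in cases:
            tries = 0
            while capacity[si] < 2:
                si = (si + 1) % sets_per_layer
                tries += 1
                if tries > sets_per_layer:
                    raise DesignError("cannot place an STR/NSTR pair without splitting it")
            set_members[si].append((cid, "STR"))
            set_members[si].append((cid, "NSTR"))
            capacity[si] -= 2
            si = (si + 1) % sets_per_layer
        ctrl_iter = iter(controls)
        for si in range(sets_per_layer):
            while capacity[si] > 0:
                set_members[si].append((next(ctrl_iter), "CTRL"))
                capacity[si] -= 1

        for si, members in enumerate(set_members):
            tset = f"{layer}{si + 1}"
            for ci, (ind, group) in enumerate(members):
                refined = refined_nstr[ind] if group == "NSTR" else group
                rows.append({
                    "sample_id": f"{ind}-{layer}-{group}",
                    "individual_id": ind,
                    "group": group,
                    "refined_group": refined,
                    "layer": layer,
                    "tmt_set": tset,
                    "channel": _channel_label(ci),
                    "channel_role": "sample",
                })
            ci = len(members)
            rows.append({
                "sample_id": f"REF-{tset}",
                "individual_id": "POOL",
                "group": "CTRL",  # placeholder; non-sample rows carry no group meaning
                "refined_group": "CTRL",
                "layer": layer,
                "tmt_set": tset,
                "channel": _channel_label(ci),
                "channel_role": "reference",
            })
            if booster:
                rows.append({
                    "sample_id": f"BOOST-{tset}",
                    "individual_id": "BOOST",
                    "group": "STR",
                    "refined_group": "STR",
                    "layer": layer,
                    "tmt_set": tset,
                    "channel": _channel_label(ci + 1),
                    "channel_role": "booster",
                })

    design = StudyDesign(pd.DataFrame(rows))
    design.validate()
    return design
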