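"""Healthy-lifestyle (HL) composite score and participant exclusion filters.

The HL score sums eight lifestyle components — healthy weight, physical
activity, plant food, fast/processed food, red and processed meat,
sugar-sweetened beverages, alcohol, and smoking — each scored 1 for high
adherence, 0.5 for intermediate, 0 for low, giving a total on [0, 8] in 0.5
steps. Participants are dichotomized at 4 points (high: total >= 4).

Component cut-offs are configuration, not code: the packaged default YAML
implements a 2018 WCRF/AICR-style operationalization and every rule can be
overridden by the user. Numeric rules are evaluated high-first with interval
endpoints inclusive toward the healthier level.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from ._containers import MetaboliteMatrix, ValidationError

COMPONENTS = (
    "healthy_weight",
    "physical_activity",
    "plant_food",
    "fast_processed_food",
    "red_processed_meat",
    "sugar_sweetened_beverages",
    "alcohol",
    "smoking",
)

#: Sex-specific daily energy-intake plausibility bounds (kcal/day); values
#: strictly outside the open interval are excluded.
ENERGY_BOUNDS = {"female": (500.0, 3500.0), "male": (800.0, 4000.0)}

#: Participants with at least this fraction of missing metabolite values are
#: excluded (the cut-off is inclusive for participants).
PARTICIPANT_MISSING_CUTOFF = 0.20


@dataclass(frozen=True)
class Interval:
    """A numeric interval with explicit endpoint inclusivity."""

    min: float = -np.inf
    max: float = np.inf
    min_inclusive: bool = True
    max_inclusive: bool = True

    def contains(self, x: float) -> bool:
        lo = x >= self.min if self.min_inclusive else x > self.min
        hi = x <= self.max if self.max_inclusive else x < self.max
        return bool(lo and hi)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Interval":
        return cls(
            min=float(d.get("min", -np.inf)),
            max=float(d.get("max", np.inf)),
            min_inclusive=bool(d.get("min_inclusive", True)),
            max_inclusive=bool(d.get("max_inclusive", True)),
        )


@dataclass(frozen=True)
class ComponentDefinition:
    """Scoring rule for one HL component.

    ``kind`` is one of ``numeric`` (one high/intermediate interval pair),
    ``numeric_by_sex`` (separate pairs per sex), or ``categorical`` (an
    explicit value -> points mapping). ``domain`` bounds plausible raw
    values and is used by the synthetic generator.
    """

    name: str
    kind: str
    unit: str = ""
    high: Interval | None = None
    intermediate: Interval | None = None
    by_sex: Mapping[str, tuple[Interval, Interval, tuple[float, float]]] | None = None
    mapping: Mapping[str, float] | None = None
    domain: tuple[float, float] = (0.0, 1.0)

    @classmethod
    def from_dict(cls, name: str, d: Mapping[str, Any]) -> "ComponentDefinition":
        kind = d["kind"]
        if kind == "categorical":
            return cls(name=name, kind=kind, unit=d.get("unit", ""),
                       mapping=dict(d["mapping"]))
        if kind == "numeric_by_sex":
            by_sex = {}
            for sex in ("female", "male"):
                sub = d[sex]
                by_sex[sex] = (
                    Interval.from_dict(sub["high"]),
                    Interval.from_dict(sub["intermediate"]),
                    tuple(sub.get("domain", (0.0, 1.0))),
                )
            return cls(name=name, kind=kind, unit=d.get("unit", ""), by_sex=by_sex)
        if kind == "numeric":
            return cls(
                name=name,
                kind=kind,
                unit=d.get("unit", ""),
                high=Interval.from_dict(d["high"]),
                intermediate=Interval.from_dict(d["intermediate"]),
                domain=tuple(d.get("domain", (0.0, 1.0))),
            )
        raise ValidationError(f"component {name}: unknown rule kind {kind!r}")


def load_component_rules(path: str | None = None) -> dict[str, ComponentDefinition]:
    """Load component scoring rules from YAML (packaged defaults if no path)."""
    if path is None:
        ref = importlib.resources.files("hlmetsig").joinpath("data/hl_components.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    rules = raw["hl_components"]
    out = {name: ComponentDefinition.from_dict(name, d) for name, d in rules.items()}
    missing = set(COMPONENTS) - set(out)
    if missing:
        raise ValidationError(f"component rules missing for: {sorted(missing)}")
    return out


def score_component(
    raw_value: Any,
    definition: ComponentDefinition,
    sex: str | None = None,
    participant: Any = None,
) -> float:
    """Map one raw component measurement to 0, 0.5 or 1 adherence points."""
    who = f" (participant {participant})" if participant is not None else ""
    if raw_value is None or (isinstance(raw_value, float) and np.isnan(raw_value)):
        raise ValidationError(f"missing value for component {definition.name}{who}")
    if definition.kind == "categorical":
        try:
            return float(definition.mapping[raw_value])
        except KeyError:
            raise ValidationError(
                f"unknown category {raw_value!r} for component {definition.name}{who}"
            ) from None
    if definition.kind == "numeric_by_sex":
        if sex not in definition.by_sex:
            raise ValidationError(
                f"component {definition.name} needs sex in "
                f"{sorted(definition.by_sex)}, got {sex!r}{who}"
            )
        high, intermediate, _ = definition.by_sex[sex]
    else:
        high, intermediate = definition.high, definition.intermediate
    x = float(raw_value)
    if high.contains(x):
        return 1.0
    if intermediate.contains(x):
        return 0.5
    return 0.0


def compute_hl_score(
    cohort: pd.DataFrame,
    rules: Mapping[str, ComponentDefinition] | None = None,
) -> pd.DataFrame:
    """Score every participant on all 8 components and total them.

    ``cohort`` must carry one raw column per component (named as in
    :data:`COMPONENTS`) and a ``sex`` column ('female'/'male'). Returns a
    DataFrame indexed like ``cohort`` with per-component point columns
    (``pts_<component>``), ``hl_total`` and ``hl_category``.

    Raises :class:`ValidationError` naming the first participant/component
    with a missing or out-of-domain value.
    """
    rules = rules or load_component_rules()
    missing_cols = [c for c in COMPONENTS if c not in cohort.columns]
    if missing_cols:
        raise ValidationError(f"cohort lacks component columns: {missing_cols}")
    out = pd.DataFrame(index=cohort.index)
    for comp in COMPONENTS:
        definition = rules[comp]
        vals = cohort[comp]
        sexes = cohort["sex"] if definition.kind == "numeric_by_sex" else None
        pts = np.empty(len(cohort))
        for i, (idx, v) in enumerate(vals.items()):
            sex = sexes.loc[idx] if sexes is not None else None
            pts[i] = score_component(v, definition, sex=sex, participant=idx)
        out[f"pts_{comp}"] = pts
    out["hl_total"] = out.sum(axis=1)
    out["hl_category"] = np.where(out["hl_total"] >= 4.0, "high", "low")
    return out


def classify_hl(total: float | np.ndarray | pd.Series):
    """Dichotomize an HL total: 'high' iff total >= 4 points, else 'low'."""
    arr = np.asarray(total, dtype=float)
    out = np.where(arr >= 4.0, "high", "low")
    if np.ndim(total) == 0:
        return out.item()
    if isinstance(total, pd.Series):
        return pd.Series(out, index=total.index)
    return out


def apply_exclusions(
    cohort: pd.DataFrame,
    metabolome: MetaboliteMatrix | None = None,
    energy_col: str = "energy_kcal",
) -> tuple[pd.Index, dict[str, int]]:
    """Apply the participant exclusion filters, in order, with first-rule
    attribution.

    1. Missing FFQ/lifestyle data (``ffq_missing`` flag, or any missing
       component raw value).
    2. Implausible energy intake: women < 500 or > 3500 kcal/day, men < 800
       or > 4000 (strict inequalities — boundary values are retained).
    3. >= 20% missing metabolite values for the participant.

    Returns the retained index and a log of counts per rule
    ``{"ffq": ..., "energy": ..., "met_missing": ...}``. Each excluded
    participant is counted once, under the first rule it triggers.
    """
    log = {"ffq": 0, "energy": 0, "met_missing": 0}
    excluded = pd.Series(False, index=cohort.index)

    comp_cols = [c for c in COMPONENTS if c in cohort.columns]
    ffq_bad = cohort.get("ffq_missing", pd.Series(False, index=cohort.index)).astype(bool)
    if comp_cols:
        ffq_bad = ffq_bad | cohort[comp_cols].isna().any(axis=1)
    log["ffq"] = int(ffq_bad.sum())
    excluded |= ffq_bad

    energy = cohort[energy_col].astype(float)
    lo = cohort["sex"].map(lambda s: ENERGY_BOUNDS[s][0])
    hi = cohort["sex"].map(lambda s: ENERGY_BOUNDS[s][1])
    energy_bad = ((energy < lo) | (energy > hi)) & ~excluded
    log["energy"] = int(energy_bad.sum())
    excluded |= energy_bad

    if metabolome is not None:
        pv = metabolome.participant_values()
        frac = pv.isna().mean(axis=1)
        frac = frac.reindex(cohort.index).fillna(0.0)
        met_bad = (frac >= PARTICIPANT_MISSING_CUTOFF) & ~excluded
        log["met_missing"] = int(met_bad.sum())
        excluded |= met_bad

    return cohort.index[~excluded], log
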