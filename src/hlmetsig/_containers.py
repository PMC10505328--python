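"""Shared containers and error types used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """A configuration field is missing, out of range, or inconsistent."""


class ValidationError(ValueError):
    """Input data violate a declared precondition."""


class DimensionError(ValueError):
    """Two inputs that must be aligned have inconsistent shapes."""


@dataclass
class MetaboliteMatrix:
    """Participants-by-metabolites abundance matrix with injection metadata.

    Attributes
    ----------
    values
        Abundances, one row per injected record (participant samples and
        pooled-reference pseudo-samples), one column per metabolite.
        Missing measurements are ``NaN``.
    meta
        Per-metabolite metadata indexed by metabolite name; at minimum a
        boolean column ``is_internal_standard``.
    run_order
        Strictly increasing injection positions, one per row of ``values``.
    is_reference
        Boolean per row; ``True`` marks pooled-reference pseudo-samples.
    unusable
        Metabolites flagged unusable (e.g. no valid pooled reference).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    run_order: np.ndarray
    is_reference: np.ndarray
    unusable: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.run_order = np.asarray(self.run_order)
        self.is_reference = np.asarray(self.is_reference, dtype=bool)
        n = len(self.values)
        if len(self.run_order) != n or len(self.is_reference) != n:
            raise DimensionError(
                "run_order / is_reference must have one entry per record"
            )
        if n > 1 and not np.all(np.diff(self.run_order) > 0):
            raise ValidationError("run_order must be strictly increasing")
        missing_meta = set(self.values.columns) - set(self.meta.index)
        if missing_meta:
            raise DimensionError(
                f"metabolites without metadata: {sorted(missing_meta)[:5]}"
            )

    @property
    def n_participants(self) -> int:
        return int((~self.is_reference).sum())

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    def participant_values(self) -> pd.DataFrame:
        """Rows of ``values`` belonging to participant samples."""
        return self.values.loc[~self.is_reference]

    def missing_fraction(self) -> pd.Series:
        """Per-metabolite missing fraction among participant samples."""
        pv = self.participant_values()
        return pv.isna().mean()

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            values=self.values.copy(),
            meta=self.meta.copy(),
            run_order=self.run_order.copy(),
            is_reference=self.is_reference.copy(),
            unusable=list(self.unusable),
        )


@dataclass
class CaseCohortDesign:
    """A case-cohort sample: all cases plus a random subcohort.

    ``table`` has one row per unique sampled participant with columns
    ``id``, ``in_subcohort``, ``is_case``, ``entry_time``, ``event_time``
    (observed time: event or censoring). ``sampling_fraction`` is the
    subcohort sampling fraction f used for Barlow weighting.
    """

    table: pd.DataFrame
    sampling_fraction: float
    n_full_cohort: int

    @property
    def n_cases(self) -> int:
        return int(self.table["is_case"].sum())

    @property
    def n_subcohort(self) -> int:
        return int(self.table["in_subcohort"].sum())

    @property
    def n_overlap(self) -> int:
        return int((self.table["is_case"] & self.table["in_subcohort"]).sum())

    @property
    def n_unique(self) -> int:
        return len(self.table)
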