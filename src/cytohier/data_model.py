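"""Observation/dataset containers for long-format assay tables.

A dataset holds one assay's measurements: ELISA cytokine concentrations
(pg/ml) or qPCR cycle-threshold (Ct) values, indexed by age group
(adult/foal), incubation condition (Control / LPS / PCSK / LPS+PCSK),
subject and replicate.  Detection-limit handling supports two regimes:

``substitute``
    every value below the limit of detection (LOD) is replaced by the LOD
    itself (a conservative convention when essentially all values in a cell
    sit below the limit);
``censor``
    sub-LOD values are flagged as left-censored; they keep the LOD as a
    placeholder so tables stay rectangular, and the flag — not the value —
    drives the likelihood downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import DataValidationError, DomainError, SchemaError, StateError

AGE_GROUPS: tuple[str, ...] = ("adult", "foal")
CONDITIONS: tuple[str, ...] = ("Control", "LPS", "PCSK", "LPS_PCSK")

#: Value scales a dataset can be on. ELISA tables start on ``concentration``
#: (pg/ml) and move to ``log_concentration`` via :func:`transform_to_model_scale`;
#: qPCR tables are born on ``ct`` and never transformed.
SCALES: tuple[str, ...] = ("concentration", "log_concentration", "ct")

LOD_RULES: tuple[str, ...] = ("none", "substitute", "censor")

#: Default column-name map for :func:`read_long_table` / :func:`write_long_table`.
DEFAULT_SCHEMA: Mapping[str, str] = {
    "assay": "assay",
    "group": "group",
    "condition": "condition",
    "subject": "horse",
    "replicate": "rep",
    "value": "value",
    "censored": "censored",
    "detection_limit": "lod",
}

#: Spellings accepted for condition labels on input.
CONDITION_ALIASES: Mapping[str, str] = {
    "Control": "Control",
    "control": "Control",
    "LPS": "LPS",
    "PCSK": "PCSK",
    "LPS_PCSK": "LPS_PCSK",
    "LPS+PCSK": "LPS_PCSK",
    "LPSPCSK": "LPS_PCSK",
}

GROUP_ALIASES: Mapping[str, str] = {
    "adult": "adult",
    "Adult": "adult",
    "mare": "adult",
    "foal": "foal",
    "Foal": "foal",
}


@dataclass(frozen=True)
class Observation:
    """One assay measurement.

    ``value`` is a concentration in pg/ml (ELISA, before transform), a natural
    log-concentration (after transform), or a Ct in cycles (qPCR).  When
    ``censored`` is true the value is a placeholder equal to the detection
    limit on the current scale.
    """

    assay_id: str
    age_group: str
    condition: str
    subject_id: str
    replicate: int
    value: float
    censored: bool = False
    detection_limit: float | None = None

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise DataValidationError(f"unknown age group {self.age_group!r}")
        if self.condition not in CONDITIONS:
            raise DataValidationError(f"unknown condition {self.condition!r}")
        if self.replicate < 1:
            raise DataValidationError("replicate index must be >= 1")
        if self.censored and self.detection_limit is None:
            raise DataValidationError("censored observation needs a detection limit")
        if not math.isfinite(self.value):
            raise DataValidationError("observation value must be finite")


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of observations from one assay on one scale."""

    observations: tuple[Observation, ...]
    scale: str
    lod_rule_applied: str = "none"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise DataValidationError(f"unknown scale {self.scale!r}")
        if self.lod_rule_applied not in LOD_RULES:
            raise DataValidationError(f"unknown LOD rule {self.lod_rule_applied!r}")
        assays = {o.assay_id for o in self.observations}
        if len(assays) > 1:
            raise DataValidationError(f"dataset mixes assays: {sorted(assays)}")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def assay_id(self) -> str | None:
        return self.observations[0].assay_id if self.observations else None

    def subjects(self) -> list[tuple[str, str]]:
        """(age_group, subject_id) pairs in first-appearance order."""
        seen: dict[tuple[str, str], None] = {}
        for o in self.observations:
            seen.setdefault((o.age_group, o.subject_id), None)
        return list(seen)

    def cells(self) -> list[tuple[str, str]]:
        """(age_group, condition) cells observed, in design order."""
        present = {(o.age_group, o.condition) for o in self.observations}
        return [(g, c) for g in AGE_GROUPS for c in CONDITIONS if (g, c) in present]

    def to_frame(self, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
        cols = dict(DEFAULT_SCHEMA, **(schema or {}))
        return pd.DataFrame(
            {
                cols["assay"]: [o.assay_id for o in self.observations],
                cols["group"]: [o.age_group for o in self.observations],
                cols["condition"]: [o.condition for o in self.observations],
                cols["subject"]: [o.subject_id for o in self.observations],
                cols["replicate"]: [o.replicate for o in self.observations],
                cols["value"]: [o.value for o in self.observations],
                cols["censored"]: [o.censored for o in self.observations],
                cols["detection_limit"]: [o.detection_limit for o in self.observations],
            }
        )


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_long_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    scale: str = "concentration",
) -> Dataset:
    """Read a long-format CSV/TSV of assay measurements.

    ``schema`` maps the logical column names (``assay``, ``group``,
    ``condition``, ``subject``, ``replicate``, ``value`` and optionally
    ``censored``, ``detection_limit``) onto the file's actual header names.
    Raw ELISA values are *not* log-transformed here; see
    :func:`transform_to_model_scale`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, sep=_delimiter_for(path))

    required = ["assay", "group", "condition", "subject", "replicate", "value"]
    for key in required:
        if cols[key] not in df.columns:
            raise SchemaError(f"missing required column {cols[key]!r} (for {key})")

    has_cens = cols["censored"] in df.columns
    has_lod = cols["detection_limit"] in df.columns

    observations: list[Observation] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        raw_cond = str(rec[cols["condition"]]).strip()
        if raw_cond not in CONDITION_ALIASES:
            raise DataValidationError(f"row {i}: unknown condition {raw_cond!r}")
        raw_group = str(rec[cols["group"]]).strip()
        if raw_group not in GROUP_ALIASES:
            raise DataValidationError(f"row {i}: unknown age group {raw_group!r}")
        try:
            value = float(rec[cols["value"]])
        except (TypeError, ValueError) as exc:
            raise DataValidationError(
                f"row {i}: non-numeric value {rec[cols['value']]!r}"
            ) from exc
        if not math.isfinite(value):
            raise DataValidationError(f"row {i}: non-finite value")
        lod = None
        if has_lod:
            lod_raw = rec[cols["detection_limit"]]
            if lod_raw is not None and not pd.isna(lod_raw):
                lod = float(lod_raw)
        censored = bool(rec[cols["censored"]]) if has_cens else False
        observations.append(
            Observation(
                assay_id=str(rec[cols["assay"]]),
                age_group=GROUP_ALIASES[raw_group],
                condition=CONDITION_ALIASES[raw_cond],
                subject_id=str(rec[cols["subject"]]),
                replicate=int(rec[cols["replicate"]]),
                value=value,
                censored=censored,
                detection_limit=lod,
            )
        )
    return Dataset(tuple(observations), scale=scale)


def write_long_table(
    dataset: Dataset, path: str | Path, schema: Mapping[str, str] | None = None
) -> None:
    """Write the dataset as a long-format CSV/TSV (delimiter from suffix)."""
    path = Path(path)
    dataset.to_frame(schema).to_csv(path, sep=_delimiter_for(path), index=False)


def apply_detection_limit(dataset: Dataset, lod: float, rule: str) -> Dataset:
    """Apply a limit-of-detection rule to a raw-concentration dataset.

    ``substitute`` replaces sub-LOD values by the LOD (censored flags stay
    false); ``censor`` flags sub-LOD values as left-censored with the LOD as
    placeholder value.  Either rule may be applied at most once per dataset.
    """
    if lod <= 0:
        raise DomainError(f"detection limit must be positive, got {lod}")
    if rule not in ("substitute", "censor"):
        raise DomainError(f"unknown LOD rule {rule!r}")
    if dataset.lod_rule_applied != "none":
        raise StateError(
            f"LOD rule {dataset.lod_rule_applied!r} already applied to this dataset"
        )
    if dataset.scale != "concentration":
        raise StateError("LOD rules apply to raw concentrations, before the log transform")

    out: list[Observation] = []
    for o in dataset.observations:
        if o.value < lod:
            if rule == "substitute":
                out.append(replace(o, value=lod, detection_limit=lod))
            else:
                out.append(replace(o, value=lod, censored=True, detection_limit=lod))
        else:
            out.append(replace(o, detection_limit=lod))
    return Dataset(tuple(out), scale=dataset.scale, lod_rule_applied=rule)


def transform_to_model_scale(dataset: Dataset) -> Dataset:
    """Natural-log transform concentrations; Ct datasets pass through.

    Detection limits are transformed alongside values so the censoring bound
    stays consistent on the model scale.
    """
    if dataset.scale == "ct":
        return dataset
    if dataset.scale == "log_concentration":
        raise StateError("dataset already on the log scale")
    out: list[Observation] = []
    for o in dataset.observations:
        if o.value <= 0:
            raise DomainError(f"cannot log-transform nonpositive concentration {o.value}")
        lod = math.log(o.detection_limit) if o.detection_limit is not None else None
        out.append(replace(o, value=math.log(o.value), detection_limit=lod))
    return Dataset(tuple(out), scale="log_concentration", lod_rule_applied=dataset.lod_rule_applied)


def inverse_transform_from_model_scale(dataset: Dataset) -> Dataset:
    """Invert :func:`transform_to_model_scale` (log-concentration -> pg/ml)."""
    if dataset.scale == "ct":
        return dataset
    if dataset.scale == "concentration":
        raise StateError("dataset already on the raw concentration scale")
    out: list[Observation] = []
    for o in dataset.observations:
        lod = math.exp(o.detection_limit) if o.detection_limit is not None else None
        out.append(replace(o, value=math.exp(o.value), detection_limit=lod))
    return Dataset(tuple(out), scale="concentration", lod_rule_applied=dataset.lod_rule_applied)
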