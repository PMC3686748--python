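"""Synthetic assay panels with the study's design and error structure.

The generator draws data exactly as the hierarchical model assumes them to
arise: for each of 2 age groups x 4 incubation conditions x 6 subjects per
group x 3 replicates,

    y = mu[group, condition] + u_subject + v_subject_condition + eps

on the model scale (natural-log pg/ml for ELISA, Ct cycles for qPCR).
ELISA panels are exponentiated back to pg/ml and passed through the
detection-limit rule (substitute at 15.6 pg/ml for TNF-alpha, left-censor
at 156.3 pg/ml for IL-10), so the raw tables look like what the assay
produces.  Ground truth travels with the dataset in a sidecar record so
recovery experiments never have to re-derive it.

``default_study_config`` bakes in the study-level values that are known
(group sizes, triplicates, LODs, and the printed basal TLR-2/TLR-4 control
Ct means); all other cell means are documented placeholders chosen to be
realistic for stimulated PBMC panels, not study estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .data_model import (
    AGE_GROUPS,
    CONDITIONS,
    Dataset,
    Observation,
    apply_detection_limit,
)
from .exceptions import ConfigError

#: Default error-structure scales (model-scale units: log pg/ml or Ct
#: cycles): between-horse, incubation-within-horse, and replicate noise.
DEFAULT_SIGMA_SUBJECT = 0.5
DEFAULT_SIGMA_SUBJECT_CONDITION = 0.3
DEFAULT_SIGMA_RESID = 0.4

LOD_TNFA = 15.6    # pg/ml
LOD_IL10 = 156.3   # pg/ml


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters and design dimensions for one assay panel."""

    assay_id: str = "synthetic"
    n_subjects_per_group: int = 6
    n_replicates: int = 3
    conditions: tuple[str, ...] = CONDITIONS
    true_cell_means: Mapping[tuple[str, str], float] = field(default_factory=dict)
    sigma_subject: float = DEFAULT_SIGMA_SUBJECT
    sigma_subject_condition: float = DEFAULT_SIGMA_SUBJECT_CONDITION
    sigma_resid: float = DEFAULT_SIGMA_RESID
    scale: str = "log_concentration"
    lod: float | None = None
    lod_rule: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1 or self.n_replicates < 1:
            raise ConfigError("design dimensions must be positive")
        for s in (self.sigma_subject, self.sigma_subject_condition, self.sigma_resid):
            if s < 0:
                raise ConfigError("error-term sds cannot be negative")
        if self.scale not in ("log_concentration", "ct"):
            raise ConfigError(f"unknown scale {self.scale!r}")
        if self.lod_rule not in ("none", "substitute", "censor"):
            raise ConfigError(f"unknown LOD rule {self.lod_rule!r}")
        if self.lod_rule != "none":
            if self.scale != "log_concentration":
                raise ConfigError("LOD rules only apply to concentration panels")
            if self.lod is None or self.lod <= 0:
                raise ConfigError("LOD rule requires a positive detection limit")
        for g in AGE_GROUPS:
            for c in self.conditions:
                if (g, c) not in self.true_cell_means:
                    raise ConfigError(f"no true cell mean for cell ({g}, {c})")
                if not np.isfinite(self.true_cell_means[(g, c)]):
                    raise ConfigError("cell means must be finite")

    def ground_truth(self) -> dict:
        return {
            "assay_id": self.assay_id,
            "scale": self.scale,
            "true_cell_means": {f"{g}:{c}": m for (g, c), m in self.true_cell_means.items()},
            "sigma_subject": self.sigma_subject,
            "sigma_subject_condition": self.sigma_subject_condition,
            "sigma_resid": self.sigma_resid,
            "n_subjects_per_group": self.n_subjects_per_group,
            "n_replicates": self.n_replicates,
            "conditions": list(self.conditions),
            "lod": self.lod,
            "lod_rule": self.lod_rule,
            "seed": self.seed,
        }


def _subject_label(group: str, i: int) -> str:
    return f"{'A' if group == 'adult' else 'F'}{i + 1}"


def generate_dataset(config: SimulationConfig) -> tuple[Dataset, dict]:
    """Simulate one assay panel; returns (dataset, ground-truth record).

    On the ``log_concentration`` scale the returned dataset is in pg/ml with
    the configured LOD rule already applied (or raw if the rule is
    ``none``); Ct panels come back directly on the Ct scale.  Identical
    configs (including seed) give identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    S, R = config.n_subjects_per_group, config.n_replicates
    conds = config.conditions

    observations: list[Observation] = []
    for g in AGE_GROUPS:
        u = rng.normal(0.0, config.sigma_subject, size=S)
        v = rng.normal(0.0, config.sigma_subject_condition, size=(S, len(conds)))
        eps = rng.normal(0.0, config.sigma_resid, size=(S, len(conds), R))
        for i in range(S):
            for ci, c in enumerate(conds):
                base = config.true_cell_means[(g, c)] + u[i] + v[i, ci]
                for r in range(R):
                    val = base + eps[i, ci, r]
                    if config.scale == "log_concentration":
                        val = float(np.exp(val))
                    observations.append(
                        Observation(
                            assay_id=config.assay_id,
                            age_group=g,
                            condition=c,
                            subject_id=_subject_label(g, i),
                            replicate=r + 1,
                            value=float(val),
                        )
                    )

    raw_scale = "concentration" if config.scale == "log_concentration" else "ct"
    dataset = Dataset(tuple(observations), scale=raw_scale)
    if config.lod_rule != "none":
        dataset = apply_detection_limit(dataset, config.lod, config.lod_rule)
    return dataset, config.ground_truth()


def write_truth_json(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2))


def _grid(adult: Mapping[str, float], foal: Mapping[str, float]) -> dict:
    means = {}
    for c in CONDITIONS:
        means[("adult", c)] = adult[c]
        means[("foal", c)] = foal[c]
    return means


# True cell means for the built-in study assays.  Values marked [printed]
# are study-level control Ct means quoted in the source report; everything
# else is a placeholder chosen to be a realistic stimulated-PBMC response
# with the reported direction of effect, NOT a study estimate.
_STUDY_ASSAYS: dict[str, dict] = {
    "TNFa_ELISA": dict(
        scale="log_concentration", lod=LOD_TNFA, lod_rule="substitute",
        means=_grid(
            adult={"Control": 2.75, "LPS": 8.00, "PCSK": 4.60, "LPS_PCSK": 7.90},
            foal={"Control": 2.75, "LPS": 5.96, "PCSK": 4.30, "LPS_PCSK": 6.13},
        ),
    ),
    "IL10_ELISA": dict(
        scale="log_concentration", lod=LOD_IL10, lod_rule="censor",
        means=_grid(
            adult={"Control": 6.20, "LPS": 6.80, "PCSK": 6.60, "LPS_PCSK": 7.27},
            foal={"Control": 6.20, "LPS": 6.50, "PCSK": 6.40, "LPS_PCSK": 6.43},
        ),
    ),
    "TLR2_qPCR": dict(
        scale="ct",
        means=_grid(
            # control means [printed]; treated cells are placeholders
            adult={"Control": 22.98, "LPS": 21.50, "PCSK": 21.70, "LPS_PCSK": 20.82},
            foal={"Control": 21.92, "LPS": 21.90, "PCSK": 21.90, "LPS_PCSK": 21.90},
        ),
    ),
    "TLR4_qPCR": dict(
        scale="ct",
        means=_grid(
            # control means [printed]; treated cells are placeholders
            adult={"Control": 23.62, "LPS": 23.60, "PCSK": 23.60, "LPS_PCSK": 22.75},
            foal={"Control": 22.24, "LPS": 22.20, "PCSK": 22.20, "LPS_PCSK": 22.20},
        ),
    ),
    "TLR9_qPCR": dict(
        scale="ct",
        means=_grid(
            adult={"Control": 26.00, "LPS": 27.20, "PCSK": 27.20, "LPS_PCSK": 27.20},
            foal={"Control": 26.00, "LPS": 26.00, "PCSK": 26.00, "LPS_PCSK": 26.00},
        ),
    ),
    "TNFa_qPCR": dict(
        scale="ct",
        means=_grid(
            adult={"Control": 28.00, "LPS": 23.00, "PCSK": 25.50, "LPS_PCSK": 23.20},
            foal={"Control": 28.00, "LPS": 25.84, "PCSK": 27.90, "LPS_PCSK": 26.52},
        ),
    ),
    "IL6_qPCR": dict(
        scale="ct",
        means=_grid(
            adult={"Control": 27.00, "LPS": 22.50, "PCSK": 24.50, "LPS_PCSK": 22.70},
            foal={"Control": 27.00, "LPS": 23.00, "PCSK": 25.93, "LPS_PCSK": 24.59},
        ),
    ),
    "IL10_qPCR": dict(
        scale="ct",
        means=_grid(
            adult={"Control": 25.00, "LPS": 23.50, "PCSK": 24.00, "LPS_PCSK": 22.36},
            foal={"Control": 25.00, "LPS": 23.80, "PCSK": 24.30, "LPS_PCSK": 23.58},
        ),
    ),
    # housekeeping genes: stable across all cells by construction
    "ACTB_qPCR": dict(
        scale="ct",
        means=_grid(
            adult={c: 18.0 for c in CONDITIONS}, foal={c: 18.0 for c in CONDITIONS}
        ),
    ),
    "GAPDH_qPCR": dict(
        scale="ct",
        means=_grid(
            adult={c: 20.0 for c in CONDITIONS}, foal={c: 20.0 for c in CONDITIONS}
        ),
    ),
}

STUDY_ASSAYS: tuple[str, ...] = tuple(_STUDY_ASSAYS)


def default_study_config(assay: str, seed: int = 0) -> SimulationConfig:
    """Study-design simulation config for one of the built-in assays.

    Six subjects per age group, triplicates, the four incubation
    conditions, and the assay's scale/LOD regime.  Raises ``KeyError`` for
    assays outside :data:`STUDY_ASSAYS`.
    """
    if assay not in _STUDY_ASSAYS:
        raise KeyError(f"unknown assay {assay!r}; choose from {STUDY_ASSAYS}")
    entry = _STUDY_ASSAYS[assay]
    return SimulationConfig(
        assay_id=assay,
        true_cell_means=dict(entry["means"]),
        scale=entry["scale"],
        lod=entry.get("lod"),
        lod_rule=entry.get("lod_rule", "none"),
        seed=seed,
    )
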