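"""Posterior contrasts, fold changes, percent differences and Livak ddCt.

A contrast between two design cells is computed draw-wise on the model
scale (log pg/ml or Ct cycles), preserving posterior correlation; it is
called significant when its central 95% credible interval excludes zero.
Back-transformation to a fold change depends on the scale:

* log-concentration: concentration ratio a/b = exp(delta);
* Ct: expression ratio a/b = 2^(-delta), since each extra cycle halves
  the starting template (lower Ct = higher expression).

Two headline conventions are reported side by side: the back-transform of
the posterior mean difference (the headline value) and the posterior mean
of the back-transformed draws.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AGE_GROUPS, CONDITIONS
from .diagnostics import credible_interval
from .exceptions import DomainError, OrientationError
from .sampler import PosteriorDraws


@dataclass
class ContrastResult:
    """Posterior difference mu_a - mu_b between two (group, condition) cells."""

    cell_a: tuple[str, str]
    cell_b: tuple[str, str]
    delta_mean: float
    lower: float
    upper: float
    significant: bool
    fold: float                 # a relative to b, from the mean difference
    fold_draws_mean: float      # posterior mean of draw-wise folds
    percent_lower: float | None  # 100*(1 - fold), defined when fold < 1
    scale: str
    delta_draws: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "cell_a": "/".join(self.cell_a),
            "cell_b": "/".join(self.cell_b),
            "delta_mean": self.delta_mean,
            "lower": self.lower,
            "upper": self.upper,
            "significant": self.significant,
            "fold": self.fold,
            "fold_draws_mean": self.fold_draws_mean,
            "percent_lower": self.percent_lower,
        }


def _backtransform(delta: np.ndarray | float, scale: str):
    if scale == "log_concentration":
        return np.exp(delta)
    if scale == "ct":
        return 2.0 ** (-np.asarray(delta, dtype=float))
    raise DomainError(f"no fold-change back-transform for scale {scale!r}")


def contrast(
    draws: PosteriorDraws,
    cell_a: tuple[str, str],
    cell_b: tuple[str, str],
    level: float = 0.95,
    keep_draws: bool = False,
) -> ContrastResult:
    """Draw-wise posterior contrast mu_a - mu_b with BCI significance call.

    Raises ``KeyError`` when either cell is absent from the fitted model.
    """
    cell_a, cell_b = tuple(cell_a), tuple(cell_b)
    a = draws.retained_pooled(draws.mu_name(cell_a))
    b = draws.retained_pooled(draws.mu_name(cell_b))
    delta = a - b
    lo, hi = credible_interval(delta, level)
    dmean = float(np.mean(delta))
    fold = float(_backtransform(dmean, draws.scale))
    fold_draws = float(np.mean(_backtransform(delta, draws.scale)))
    return ContrastResult(
        cell_a=cell_a,
        cell_b=cell_b,
        delta_mean=dmean,
        lower=lo,
        upper=hi,
        significant=bool(lo > 0.0 or hi < 0.0),
        fold=fold,
        fold_draws_mean=fold_draws,
        percent_lower=(100.0 * (1.0 - fold)) if fold < 1.0 else None,
        scale=draws.scale,
        delta_draws=delta if keep_draws else None,
    )


def fold_change_from_ct(ct_mean_ref: float, ct_mean_other: float) -> float:
    """Expression fold of "other" relative to "ref" from mean Ct values.

    Returns 2^(ct_ref - ct_other): a lower Ct in "other" means more starting
    template, one cycle per factor of two.  E.g. adult/foal basal Ct means of
    23.62 and 22.24 give 2^1.38 = 2.6.
    """
    if not (math.isfinite(ct_mean_ref) and math.isfinite(ct_mean_other)):
        raise DomainError("Ct means must be finite")
    return 2.0 ** (ct_mean_ref - ct_mean_other)


def percent_lower_from_fold(fold: float) -> float:
    """Express a fold < 1 as 'percent lower': 0.13 -> 87.0.

    Raises :class:`OrientationError` for fold >= 1 — invert the ratio first
    so the reference cell is the larger one.
    """
    if fold <= 0:
        raise DomainError("fold must be positive")
    if fold >= 1.0:
        raise OrientationError(
            f"fold {fold} is not a reduction; invert the contrast orientation"
        )
    return 100.0 * (1.0 - fold)


def livak_ddct(
    ct_target_treated: float,
    ct_hk_treated: float,
    ct_target_control: float,
    ct_hk_control: float,
) -> float:
    """Relative expression 2^(-ddCt) normalised to a housekeeping gene.

    ddCt = (Ct_target - Ct_housekeeping)_treated - (Ct_target -
    Ct_housekeeping)_control; the result is the treated/control expression
    ratio of the target after correcting for total mRNA input.
    """
    for x in (ct_target_treated, ct_hk_treated, ct_target_control, ct_hk_control):
        if not math.isfinite(x):
            raise DomainError("Ct values must be finite")
    ddct = (ct_target_treated - ct_hk_treated) - (ct_target_control - ct_hk_control)
    return 2.0 ** (-ddct)


def all_condition_pairs() -> list[tuple[str, str]]:
    return list(itertools.combinations(CONDITIONS, 2))


def housekeeping_stability_check(
    draws_by_assay: dict[str, PosteriorDraws], level: float = 0.95
) -> pd.DataFrame:
    """Within-group condition contrasts for housekeeping-gene fits.

    For each fitted housekeeping assay, contrasts every condition pair
    within each age group and reports the significance calls; stable
    housekeeping expression should produce (close to) zero significant
    contrasts.  Returns an empty frame when fewer than two conditions were
    fitted.
    """
    rows = []
    for assay, draws in draws_by_assay.items():
        cells = set(map(tuple, draws.cells))
        for g in AGE_GROUPS:
            conds = [c for c in CONDITIONS if (g, c) in cells]
            for ca, cb in itertools.combinations(conds, 2):
                res = contrast(draws, (g, ca), (g, cb), level=level)
                rows.append(
                    {
                        "assay": assay,
                        "age_group": g,
                        "condition_a": ca,
                        "condition_b": cb,
                        "delta_mean": res.delta_mean,
                        "lower": res.lower,
                        "upper": res.upper,
                        "significant": res.significant,
                    }
                )
    cols = [
        "assay", "age_group", "condition_a", "condition_b",
        "delta_mean", "lower", "upper", "significant",
    ]
    return pd.DataFrame(rows, columns=cols)


def relative_expression_table(
    draws: PosteriorDraws,
    reference_cell: tuple[str, str],
    level: float = 0.95,
) -> pd.DataFrame:
    """Fold change of every cell relative to one reference cell.

    Reproduces the 'relative expression compared with a reference' figure
    convention using the same draw-wise contrast machinery.
    """
    rows = []
    for cell in draws.cells:
        res = contrast(draws, tuple(cell), tuple(reference_cell), level=level)
        rows.append(
            {
                "age_group": cell[0],
                "condition": cell[1],
                "fold_vs_reference": res.fold,
                "lower_delta": res.lower,
                "upper_delta": res.upper,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)
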