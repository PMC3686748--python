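"""Convergence diagnostics and posterior summaries.

Implements the classic Gelman-Rubin potential scale reduction factor
(PSRF) on whole chains — the between/within-chain variance ratio — and the
"mean + 95% Bayesian credible interval" summary used to report every
parameter: posterior mean, sd, and the 2.5%/97.5% percentiles of the
pooled retained draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, StateError
from .sampler import PosteriorDraws

logger = logging.getLogger(__name__)

#: Conventional convergence threshold; parameters above it are flagged.
DEFAULT_PSRF_THRESHOLD = 1.1


def psrf(per_chain_draws: np.ndarray, split: bool = False) -> float:
    """Gelman-Rubin potential scale reduction factor for one scalar parameter.

    ``per_chain_draws`` is an (m, n) array of m >= 2 chains of n retained
    draws.  With W the mean within-chain variance and B/n the variance of the
    chain means, returns sqrt(var+ / W) where var+ = (n-1)/n W + B/n.
    All-equal constant input returns 1.0 by convention.  ``split=True``
    halves each chain first (the split-chain variant).
    """
    x = np.asarray(per_chain_draws, dtype=float)
    if x.ndim != 2:
        raise DomainError("expected a 2-D (chains x draws) array")
    if x.shape[0] < 2:
        raise DomainError("PSRF needs multiple chains")
    if x.shape[1] < 2:
        raise DomainError("PSRF needs at least 2 draws per chain")
    if split:
        half = x.shape[1] // 2
        x = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    m, n = x.shape
    if np.ptp(x) == 0.0:
        return 1.0
    chain_means = x.mean(axis=1)
    w = float(np.mean(x.var(axis=1, ddof=1)))
    b_over_n = float(np.var(chain_means, ddof=1))
    if w == 0.0:
        return np.inf
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Central credible interval from percentiles (linear interpolation)."""
    if not (0 < level < 1):
        raise DomainError("credible level must be in (0, 1)")
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(draws, [tail, 100.0 - tail])
    return float(lo), float(hi)


@dataclass
class PosteriorSummary:
    """Per-parameter posterior summary table plus convergence flags."""

    table: pd.DataFrame
    level: float
    psrf_threshold: float

    @property
    def unconverged(self) -> list[str]:
        bad = self.table.index[~self.table["converged"]]
        return list(bad)

    def __getitem__(self, parameter: str) -> pd.Series:
        return self.table.loc[parameter]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="parameter")

    def report(self) -> str:
        lines = [
            f"Posterior summary ({self.level:.0%} credible intervals, "
            f"PSRF threshold {self.psrf_threshold})",
            "",
        ]
        for name, row in self.table.iterrows():
            flag = "" if row["converged"] else "  [PSRF ABOVE THRESHOLD]"
            lines.append(
                f"  {name:34s} {row['mean']:9.3f}  "
                f"({row['lower']:9.3f}, {row['upper']:9.3f})  "
                f"PSRF {row['psrf']:.3f}{flag}"
            )
        return "\n".join(lines)


def summarize(
    draws: PosteriorDraws,
    level: float = 0.95,
    psrf_threshold: float = DEFAULT_PSRF_THRESHOLD,
    split: bool = False,
) -> PosteriorSummary:
    """Pool retained draws across chains and summarise every parameter.

    Means, sds and percentile credible bounds come from the pooled
    post-burn-in draws; the PSRF is computed per parameter across chains
    (NaN for single-chain runs).  Parameters with PSRF above the threshold
    are flagged ``converged=False`` and logged as warnings, never errors.
    """
    n_retained = draws.config.n_iter - draws.config.burn_in
    if n_retained <= 0:
        raise StateError("no retained draws after burn-in")
    rows = []
    for name in draws.parameter_names:
        per_chain = draws.retained(name)
        pooled = per_chain.ravel()
        lo, hi = credible_interval(pooled, level)
        if per_chain.shape[0] >= 2:
            r = psrf(per_chain, split=split)
        else:
            r = float("nan")
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(pooled)),
                "sd": float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0,
                "lower": lo,
                "upper": hi,
                "psrf": r,
                "n_draws": int(pooled.size),
                "converged": bool(np.isnan(r) or r <= psrf_threshold),
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    bad = table.index[~table["converged"]]
    for name in bad:
        logger.warning(
            "PSRF %.3f above threshold %.3f for %s",
            table.loc[name, "psrf"], psrf_threshold, name,
        )
    return PosteriorSummary(table=table, level=level, psrf_threshold=psrf_threshold)
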