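"""The Bayesian hierarchical linear model with left-censoring.

For one assay, each measurement y on the model scale (log pg/ml or Ct
cycles) is

    y_{g,c,i,r} = mu_{g,c} + u_i + v_{i,c} + eps_{g,c,i,r}

with one free cell mean mu_{g,c} per (age group, condition) cell (8 in the
full design), a subject-level random effect u_i ~ N(0, sigma2_subject), a
condition-within-subject effect v_{i,c} ~ N(0, sigma2_subject_condition)
and residual noise eps ~ N(0, sigma2_resid).  Priors are weakly
informative: mu_{g,c} ~ N(0, 100^2) and independent inverse-gamma priors
with mean 1 and variance 10,000 on all three variance components.

Left-censored observations (ELISA signal below the detection limit) enter
the likelihood through a latent value constrained below the log-LOD;
:func:`censored_marginal_loglik` integrates the latent structure out
numerically on tiny instances and serves as an independent oracle for the
sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, stats
from scipy.special import log_ndtr

from .data_model import AGE_GROUPS, CONDITIONS, Dataset
from .exceptions import DomainError, OracleSizeError, StateError

FULL_GRID: tuple[tuple[str, str], ...] = tuple(
    (g, c) for g in AGE_GROUPS for c in CONDITIONS
)


def ig_hyperparams(target_mean: float, target_variance: float) -> tuple[float, float]:
    """Shape/scale of the inverse-gamma with a given mean and variance.

    Solves  mean = beta/(alpha-1),  variance = mean^2/(alpha-2)  for
    (alpha, beta); alpha > 2 whenever both targets are positive.  The default
    variance-component prior uses ``ig_hyperparams(1, 10_000)`` =
    (2.0001, 1.0001).
    """
    if target_mean <= 0 or target_variance <= 0:
        raise DomainError("inverse-gamma moment targets must be positive")
    alpha = 2.0 + target_mean**2 / target_variance
    beta = target_mean * (alpha - 1.0)
    return alpha, beta


_DEFAULT_IG = ig_hyperparams(1.0, 10_000.0)


@dataclass
class ModelSpec:
    """Cell means, variance components and priors for one assay's model.

    ``cell_means`` and the three variances may be ``None`` while the spec
    only carries priors (the sampler's input); they must be set for density
    evaluation.  A variance fixed to a number is *not* sampled by
    :func:`cytohier.sampler.run_chains`; fixing it to ``0.0`` removes the
    corresponding random effect entirely.
    """

    cells: tuple[tuple[str, str], ...] = FULL_GRID
    cell_means: Mapping[tuple[str, str], float] | None = None
    sigma2_subject: float | None = None
    sigma2_subject_condition: float | None = None
    sigma2_resid: float | None = None
    prior_mean_mu: float = 0.0
    prior_sd_mu: float = 100.0
    prior_ig_shape: float = _DEFAULT_IG[0]
    prior_ig_scale: float = _DEFAULT_IG[1]

    def __post_init__(self) -> None:
        if self.prior_sd_mu <= 0:
            raise DomainError("prior sd for cell means must be positive")
        if self.prior_ig_shape <= 1 or self.prior_ig_scale <= 0:
            raise DomainError("inverse-gamma prior needs shape > 1 and scale > 0")
        for s2 in (self.sigma2_subject, self.sigma2_subject_condition, self.sigma2_resid):
            if s2 is not None and s2 < 0:
                raise DomainError("variance components cannot be negative")

    def require_full(self) -> None:
        if self.cell_means is None:
            raise StateError("ModelSpec has no cell means set")
        missing = [c for c in self.cells if c not in self.cell_means]
        if missing:
            raise StateError(f"cell means missing for {missing}")
        if self.sigma2_resid is None or self.sigma2_resid <= 0:
            raise DomainError("sigma2_resid must be a positive number")
        for name in ("sigma2_subject", "sigma2_subject_condition"):
            if getattr(self, name) is None:
                raise StateError(f"{name} must be set for density evaluation")

    def to_json_dict(self) -> dict:
        return {
            "cells": [list(c) for c in self.cells],
            "cell_means": (
                None
                if self.cell_means is None
                else {f"{g}:{c}": m for (g, c), m in self.cell_means.items()}
            ),
            "variances": {
                "sigma2_subject": self.sigma2_subject,
                "sigma2_subject_condition": self.sigma2_subject_condition,
                "sigma2_resid": self.sigma2_resid,
            },
            "priors": {
                "mean_mu": self.prior_mean_mu,
                "sd_mu": self.prior_sd_mu,
                "ig_shape": self.prior_ig_shape,
                "ig_scale": self.prior_ig_scale,
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ModelSpec":
        cm = d.get("cell_means")
        if cm is not None:
            cm = {tuple(k.split(":")): v for k, v in cm.items()}
        var = d.get("variances", {})
        pri = d.get("priors", {})
        return cls(
            cells=tuple(tuple(c) for c in d["cells"]),
            cell_means=cm,
            sigma2_subject=var.get("sigma2_subject"),
            sigma2_subject_condition=var.get("sigma2_subject_condition"),
            sigma2_resid=var.get("sigma2_resid"),
            prior_mean_mu=pri.get("mean_mu", 0.0),
            prior_sd_mu=pri.get("sd_mu", 100.0),
            prior_ig_shape=pri.get("ig_shape", _DEFAULT_IG[0]),
            prior_ig_scale=pri.get("ig_scale", _DEFAULT_IG[1]),
        )


@dataclass
class DesignIndex:
    """Integer index arrays linking observations to model parameters.

    Built once per dataset and shared by the density evaluator and the
    sampler so both agree on parameter ordering.
    """

    y: np.ndarray                 # observed/placeholder values, model scale
    cell_idx: np.ndarray          # -> position in spec.cells
    subject_idx: np.ndarray       # -> position in subjects
    sc_idx: np.ndarray            # -> position in subject_conditions
    censored: np.ndarray          # boolean mask
    upper: np.ndarray             # censoring bound (log-LOD); NaN if uncensored
    cells: tuple[tuple[str, str], ...]
    subjects: tuple[tuple[str, str], ...]
    subject_conditions: tuple[tuple[str, str, str], ...]

    @property
    def n_obs(self) -> int:
        return self.y.size


def build_design_index(dataset: Dataset, cells: Sequence[tuple[str, str]] = FULL_GRID) -> DesignIndex:
    if dataset.scale == "concentration":
        raise StateError("dataset must be on the model scale (log or Ct)")
    cells = tuple(tuple(c) for c in cells)
    cell_pos = {c: k for k, c in enumerate(cells)}
    subjects = tuple(dataset.subjects())
    subj_pos = {s: k for k, s in enumerate(subjects)}
    sc_seen: dict[tuple[str, str, str], int] = {}
    rows_cell, rows_subj, rows_sc = [], [], []
    for o in dataset.observations:
        key = (o.age_group, o.condition)
        if key not in cell_pos:
            raise StateError(f"observation cell {key} not in model cells")
        rows_cell.append(cell_pos[key])
        rows_subj.append(subj_pos[(o.age_group, o.subject_id)])
        sc_key = (o.age_group, o.subject_id, o.condition)
        rows_sc.append(sc_seen.setdefault(sc_key, len(sc_seen)))
    y = np.array([o.value for o in dataset.observations], dtype=float)
    cens = np.array([o.censored for o in dataset.observations], dtype=bool)
    upper = np.array(
        [o.detection_limit if o.censored else np.nan for o in dataset.observations],
        dtype=float,
    )
    return DesignIndex(
        y=y,
        cell_idx=np.array(rows_cell, dtype=np.intp),
        subject_idx=np.array(rows_subj, dtype=np.intp),
        sc_idx=np.array(rows_sc, dtype=np.intp),
        censored=cens,
        upper=upper,
        cells=cells,
        subjects=subjects,
        subject_conditions=tuple(sc_seen),
    )


@dataclass
class LatentState:
    """Subject effects, subject-condition effects and imputed censored values.

    ``u`` is indexed like ``DesignIndex.subjects``, ``v`` like
    ``DesignIndex.subject_conditions`` and ``y_latent`` like the censored
    observations in dataset order.
    """

    u: np.ndarray
    v: np.ndarray
    y_latent: np.ndarray = field(default_factory=lambda: np.empty(0))


def _normal_logpdf(x: np.ndarray, mean: np.ndarray, var: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def log_joint(spec: ModelSpec, state: LatentState, dataset: Dataset) -> float:
    """Log of likelihood x random-effect densities x priors.

    Censored observations contribute through their imputed latent values in
    ``state.y_latent`` (each must lie below its log-LOD bound).  This is the
    (unnormalised) target density the MCMC sampler explores.
    """
    spec.require_full()
    idx = build_design_index(dataset, spec.cells)
    if state.u.shape != (len(idx.subjects),):
        raise StateError("latent u has wrong length for this dataset")
    if state.v.shape != (len(idx.subject_conditions),):
        raise StateError("latent v has wrong length for this dataset")
    n_cens = int(idx.censored.sum())
    if state.y_latent.shape != (n_cens,):
        raise StateError(f"expected {n_cens} latent censored values")
    if n_cens and np.any(state.y_latent >= idx.upper[idx.censored]):
        return -np.inf

    mu = np.array([spec.cell_means[c] for c in idx.cells])
    y = idx.y.copy()
    y[idx.censored] = state.y_latent
    mean = mu[idx.cell_idx] + state.u[idx.subject_idx] + state.v[idx.sc_idx]

    total = float(np.sum(_normal_logpdf(y, mean, spec.sigma2_resid)))
    if state.u.size:
        if spec.sigma2_subject <= 0:
            if np.any(state.u != 0):
                return -np.inf
        else:
            total += float(np.sum(_normal_logpdf(state.u, 0.0, spec.sigma2_subject)))
    if state.v.size:
        if spec.sigma2_subject_condition <= 0:
            if np.any(state.v != 0):
                return -np.inf
        else:
            total += float(
                np.sum(_normal_logpdf(state.v, 0.0, spec.sigma2_subject_condition))
            )

    # priors
    mu_all = np.array([spec.cell_means[c] for c in spec.cells])
    total += float(
        np.sum(_normal_logpdf(mu_all, spec.prior_mean_mu, spec.prior_sd_mu**2))
    )
    for s2 in (spec.sigma2_subject, spec.sigma2_subject_condition, spec.sigma2_resid):
        if s2 is not None and s2 > 0:
            total += float(
                stats.invgamma.logpdf(s2, spec.prior_ig_shape, scale=spec.prior_ig_scale)
            )
    return total


_ORACLE_MAX_OBS = 3


def censored_marginal_loglik(spec: ModelSpec, dataset: Dataset) -> float:
    """Marginal log-likelihood with u, v and censored values integrated out.

    Numeric-quadrature oracle for tiny instances (<= 3 observations, one
    subject): the subject effect and each condition-within-subject effect
    are integrated by adaptive quadrature, and each censored observation
    contributes the normal left-tail probability Phi((bound - mean)/sd)
    analytically.  Excludes the priors, so this is a pure likelihood.
    """
    spec.require_full()
    idx = build_design_index(dataset, spec.cells)
    if idx.n_obs == 0:
        return 0.0
    if idx.n_obs > _ORACLE_MAX_OBS or len(idx.subjects) > 1:
        raise OracleSizeError(
            "quadrature oracle is restricted to <= 3 observations from one subject"
        )

    mu = np.array([spec.cell_means[c] for c in idx.cells])
    sd_e = math.sqrt(spec.sigma2_resid)
    s_u = math.sqrt(spec.sigma2_subject)
    s_v = math.sqrt(spec.sigma2_subject_condition)

    # group observations by subject-condition pair
    by_sc: dict[int, list[int]] = {}
    for j in range(idx.n_obs):
        by_sc.setdefault(int(idx.sc_idx[j]), []).append(j)

    def obs_lik(j: int, mean: float) -> float:
        if idx.censored[j]:
            return math.exp(log_ndtr((idx.upper[j] - mean) / sd_e))
        return math.exp(_normal_logpdf(idx.y[j], mean, spec.sigma2_resid))

    def cond_lik_given_u(sc: int, u: float) -> float:
        base = [(j, mu[idx.cell_idx[j]] + u) for j in by_sc[sc]]
        if s_v == 0.0:
            prod = 1.0
            for j, m in base:
                prod *= obs_lik(j, m)
            return prod

        def integrand(v: float) -> float:
            prod = math.exp(-0.5 * (v / s_v) ** 2) / (s_v * math.sqrt(2 * math.pi))
            for j, m in base:
                prod *= obs_lik(j, m + v)
            return prod

        val, _ = integrate.quad(integrand, -8 * s_v, 8 * s_v, limit=200)
        return val

    def lik_given_u(u: float) -> float:
        prod = 1.0
        for sc in by_sc:
            prod *= cond_lik_given_u(sc, u)
        return prod

    if s_u == 0.0:
        lik = lik_given_u(0.0)
    else:

        def outer(u: float) -> float:
            return (
                math.exp(-0.5 * (u / s_u) ** 2)
                / (s_u * math.sqrt(2 * math.pi))
                * lik_given_u(u)
            )

        lik, _ = integrate.quad(outer, -8 * s_u, 8 * s_u, limit=200)

    if lik <= 0.0:
        return -np.inf
    return math.log(lik)
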