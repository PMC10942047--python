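"""λ-scaling calibration: match scaled classifier logits to posterior logit laws.

Raw classifier logits ``u`` are mapped to ``u* = -λ u`` (and probabilities
``p* = σ(u*)``).  For each diagnosis group D, the empirical distribution of
``u*`` among subjects annotated as D should match the posterior logit density
``p_u(u | D)``.  λ is fitted by minimizing the mean (over available groups)
of an L2 distance on a fixed grid between a Gaussian-kernel density estimate
of the scaled sample and the analytic posterior density; a CDF-based
Cramér-von-Mises-style distance is available as an alternative.

The distance discretization and the choice to average the per-subject logits
across CV models before scaling are package design decisions (the grouping
statistic itself does not prescribe them); both are recorded in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import gaussian_kde

from .posterior import DiagnosisGroup, GROUP_ORDER, posterior_logit_density
from .synthetic import AnnotationRecord

__all__ = ["DistanceConfig", "CalibrationResult", "scale_outputs",
           "distribution_distance", "fit_lambda"]


@dataclass(frozen=True)
class DistanceConfig:
    """Grid, KDE and distance settings for the distribution match."""

    grid_min: float = -10.0
    grid_max: float = 10.0
    grid_points: int = 512
    bandwidth: str = "silverman"
    distance: str = "l2"  # "l2" (densities) or "cvm" (CDFs)
    min_group_size: int = 10
    lambda_bounds: tuple = (1e-3, 10.0)
    tolerance: float = 1e-4
    sign: int = -1  # u* = sign·λ·u; -1 per the scaled-output convention,
    # +1 for backends whose positive-class logit increases with probability

    def __post_init__(self):
        if self.grid_points < 64:
            raise ValueError("grid must have at least 64 points")
        if self.grid_max <= self.grid_min:
            raise ValueError("grid bounds must be increasing")
        if self.distance not in ("l2", "cvm"):
            raise ValueError("distance must be 'l2' or 'cvm'")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")

    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_min, self.grid_max, self.grid_points)


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted scale with per-group diagnostics."""

    finding: str
    lambda_hat: float
    group_distances: Dict[DiagnosisGroup, float]
    groups_used: tuple
    group_sizes: Dict[DiagnosisGroup, int]
    objective: float
    config: DistanceConfig


def scale_outputs(logits: Sequence[float], lam: float, sign: int = -1) -> pd.DataFrame:
    """u* = -λu (or +λu with sign=+1) and p* = σ(u*) for each raw logit."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if sign not in (-1, 1):
        raise ValueError("sign must be -1 or +1")
    u = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("logits must be finite")
    u_star = sign * lam * u
    return pd.DataFrame({"u": u, "u_star": u_star, "p_star": 1.0 / (1.0 + np.exp(-u_star))})


def _grid_density(sample: np.ndarray, grid: np.ndarray, bandwidth: str) -> np.ndarray:
    if len(sample) < 2 or np.ptp(sample) == 0:
        # degenerate sample: nearest-grid-point histogram density
        d = np.zeros_like(grid)
        idx = np.abs(grid - sample.mean()).argmin()
        d[idx] = 1.0 / (grid[1] - grid[0])
        return d
    return gaussian_kde(sample, bw_method=bandwidth)(grid)


def distribution_distance(logit_sample: Sequence[float], group: DiagnosisGroup,
                          lam: float, config: DistanceConfig) -> float:
    """Distance between the scaled-sample KDE and the posterior logit density.

    ``l2``: sqrt ∫ (f̂ - p_u)² du on the grid.  ``cvm``: sqrt ∫ (F̂ - P_u)² du
    with both CDFs accumulated on the same grid.
    """
    sample = np.asarray(logit_sample, dtype=float)
    if sample.size == 0:
        raise ValueError("empty logit sample")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    grid = config.grid()
    f_hat = _grid_density(config.sign * lam * sample, grid, config.bandwidth)
    f_ref = np.asarray(posterior_logit_density(group, grid))
    if config.distance == "l2":
        return float(np.sqrt(np.trapezoid((f_hat - f_ref) ** 2, grid)))
    du = grid[1] - grid[0]
    F_hat = np.cumsum(f_hat) * du
    F_ref = np.cumsum(f_ref) * du
    return float(np.sqrt(np.trapezoid((F_hat - F_ref) ** 2, grid)))


def _group_samples(predictions: pd.DataFrame, annotations: Sequence[AnnotationRecord],
                   finding: str, per_model: bool) -> Dict[DiagnosisGroup, np.ndarray]:
    sub = predictions[predictions["finding"] == finding]
    if sub.empty:
        raise ValueError(f"no predictions for finding {finding!r}")
    if per_model:
        pooled = sub.set_index("subject_id")["logit"]
        by_subject = pooled.groupby(level=0).apply(lambda s: s.to_numpy())
    else:
        by_subject = sub.groupby("subject_id")["logit"].mean()
    groups: Dict[DiagnosisGroup, List[float]] = {g: [] for g in GROUP_ORDER}
    for rec in annotations:
        if rec.subject_id not in by_subject.index:
            continue
        val = by_subject.loc[rec.subject_id]
        g = rec.group(finding)
        if per_model:
            groups[g].extend(np.atleast_1d(val).tolist())
        else:
            groups[g].append(float(val))
    return {g: np.asarray(v) for g, v in groups.items()}


def fit_lambda(predictions: pd.DataFrame, annotations: Sequence[AnnotationRecord],
               finding: str, config: Optional[DistanceConfig] = None,
               per_model: bool = False) -> CalibrationResult:
    """Fit λ by bounded scalar minimization of the mean per-group distance.

    Per-subject logits are averaged across the CV models before scaling
    unless ``per_model`` pools every model's output.  Groups with fewer than
    ``config.min_group_size`` subjects are dropped (all six groups weighted
    equally among those retained); fewer than two usable groups triggers a
    warning, none is an error.
    """
    config = config or DistanceConfig()
    samples = _group_samples(predictions, annotations, finding, per_model)
    sizes = {g: int(len(s)) for g, s in samples.items()}
    used = tuple(g for g in GROUP_ORDER if sizes[g] >= config.min_group_size)
    if not used:
        nonempty = tuple(g for g in GROUP_ORDER if sizes[g] > 0)
        if not nonempty:
            raise ValueError("no diagnosis group has any members")
        used = nonempty
    if len(used) < 2:
        warnings.warn(
            f"only {len(used)} diagnosis group(s) with >= {config.min_group_size} "
            "members; λ fit may be poorly constrained"
        )

    def objective(lam: float) -> float:
        return float(np.mean([
            distribution_distance(samples[g], g, lam, config) for g in used
        ]))

    res = minimize_scalar(objective, bounds=config.lambda_bounds, method="bounded",
                          options={"xatol": config.tolerance})
    lam_hat = float(res.x)
    dists = {g: distribution_distance(samples[g], g, lam_hat, config) for g in used}
    return CalibrationResult(
        finding=finding,
        lambda_hat=lam_hat,
        group_distances=dists,
        groups_used=used,
        group_sizes=sizes,
        objective=float(res.fun),
        config=config,
    )
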