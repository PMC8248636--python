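"""Monte-Carlo quasi-extinction projection.

The fitted state-space model supplies a posterior for current abundance and
for process variation in growth.  To turn those into extinction risk as a
function of the (unknown) mean growth rate, abundance is projected forward as
a lognormal random walk for each candidate mean growth rate ``rs`` on a grid:

    log N[t+1] = log N[t] + r',     r' ~ Normal(rs, sigma_r)

A replicate is quasi-extinct if N drops below the threshold (250 breeding
birds by default) at any point within the horizon (50 years).  Each replicate
draws its initial abundance and sigma_r from the posterior — jointly from the
same posterior iteration by default, preserving their correlation — and the
estimated probability at each grid point is the fraction of quasi-extinct
replicates.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .ssm import PosteriorDraws

__all__ = ["ProjectionConfig", "ExtinctionCurve", "project_once", "extinction_curve"]


def _default_rs_grid() -> tuple[float, ...]:
    # 81 points, step 0.01, spanning the support of the growth-rate posteriors
    return tuple(np.round(np.linspace(-0.4, 0.4, 81), 10))


@dataclasses.dataclass(frozen=True)
class ProjectionConfig:
    """Projection settings: 50-year horizon, quasi-extinction threshold of
    250 breeding birds, 10,000 replicates per grid point, and a mean-growth
    grid spanning [-0.4, 0.4]."""

    horizon: int = 50
    qe_threshold: float = 250.0
    n_reps: int = 10_000
    rs_grid: tuple[float, ...] = dataclasses.field(default_factory=_default_rs_grid)
    seed: int = 0
    joint_draws: bool = True  # draw (N_final, sigma_r) from the same posterior iteration

    def __post_init__(self) -> None:
        if self.horizon < 1 or self.n_reps < 1 or not (self.qe_threshold > 0):
            raise ValueError("horizon, n_reps must be >= 1 and qe_threshold > 0")
        grid = np.asarray(self.rs_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("rs_grid must be a strictly increasing 1-d grid")


@dataclasses.dataclass(frozen=True)
class ExtinctionCurve:
    """Estimated 50-year quasi-extinction probability per candidate mean
    growth rate."""

    rs_values: tuple[float, ...]
    probabilities: tuple[float, ...]
    n_reps: int

    def __post_init__(self) -> None:
        if len(self.rs_values) != len(self.probabilities):
            raise ValueError("rs_values and probabilities must have equal length")
        if any(not (0.0 <= q <= 1.0) for q in self.probabilities):
            raise ValueError("probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rs": self.rs_values, "probability": self.probabilities,
             "n_reps": self.n_reps}
        )

    def write_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def project_once(n0: float, rs: float, sigma_r: float,
                 config: ProjectionConfig, rng: np.random.Generator) -> bool:
    """Project one trajectory; True iff abundance falls below the threshold
    in any projected year (the starting state itself is not checked)."""
    if not n0 > 0:
        raise ValueError("n0 must be positive")
    if sigma_r < 0:
        raise ValueError("sigma_r must be non-negative")
    logn = math.log(n0)
    log_thresh = math.log(config.qe_threshold)
    increments = rs + sigma_r * rng.standard_normal(config.horizon)
    path = logn + np.cumsum(increments)
    return bool(path.min() < log_thresh)


def extinction_curve(posterior: PosteriorDraws, config: ProjectionConfig | None = None,
                     final_year: int | None = None) -> ExtinctionCurve:
    """Quasi-extinction probability across the mean-growth grid.

    For every grid value ``rs``, ``n_reps`` replicates each draw an initial
    abundance (the final observed year's ``N`` unless ``final_year`` is
    given) and a process SD from the posterior, then run the 50-year
    projection.  With ``config.joint_draws`` (the default) the two come from
    the same posterior iteration; otherwise they are resampled independently.
    """
    if config is None:
        config = ProjectionConfig()
    year = posterior.years[-1] if final_year is None else final_year
    n_final = posterior.pooled(f"N_{year}")
    sigma_r = posterior.pooled("sigma_r")
    if n_final.size == 0:
        raise ValueError("posterior contains no draws")
    rng = np.random.default_rng(config.seed)
    log_thresh = math.log(config.qe_threshold)

    probs = []
    for rs in config.rs_grid:
        idx_n = rng.integers(0, n_final.size, size=config.n_reps)
        idx_s = idx_n if config.joint_draws else rng.integers(0, n_final.size,
                                                              size=config.n_reps)
        logn0 = np.log(n_final[idx_n])
        sig = sigma_r[idx_s]
        shocks = rs + sig[:, None] * rng.standard_normal((config.n_reps, config.horizon))
        lowest = (logn0[:, None] + np.cumsum(shocks, axis=1)).min(axis=1)
        probs.append(float(np.mean(lowest < log_thresh)))

    return ExtinctionCurve(rs_values=tuple(float(r) for r in config.rs_grid),
                           probabilities=tuple(probs), n_reps=config.n_reps)
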