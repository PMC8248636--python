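"""Shared fixtures.

The study-settings fits (3 chains, 100,000 iterations, 70,000 burn-in,
thin 2) are session-scoped so that abundance, convergence and decision tests
reuse one sampler run per model instead of refitting.
"""

from __future__ import annotations

import pytest

from eiderpva import (
    Action,
    MCMCSettings,
    ProjectionConfig,
    build_loss_curves,
    default_model_spec,
    expected_loss,
    extinction_curve,
    sample_posterior,
)

#: Fixed seeds for the study-settings reruns and the projection stage.
FIT_SEED = 42
PROJ_SEED = 1042

#: Short sampler settings for unit tests that only need a valid posterior.
SMOKE = MCMCSettings(n_chains=2, n_iterations=3_000, n_burnin=1_000, thin=2,
                     n_adapt=500, seed=7)


def paper_settings(seed: int = FIT_SEED) -> MCMCSettings:
    return MCMCSettings(seed=seed)


@pytest.fixture(scope="session")
def paper_fits():
    """Study-settings posterior draws for the constant-detection models."""
    fits = {}
    for name in ("ACP1", "YKD1", "YKD2", "YKD3"):
        spec, series = default_model_spec(name)
        fits[name] = sample_posterior(spec, series, paper_settings())
    return fits


@pytest.fixture(scope="session")
def paper_risks(paper_fits):
    """Full-config decision risks (under, over) per constant-detection model."""
    risks = {}
    for name, draws in paper_fits.items():
        ext = extinction_curve(draws, ProjectionConfig(seed=PROJ_SEED))
        loss = build_loss_curves(ext)
        risks[name] = (
            expected_loss(loss, draws.pooled("rbar"), Action.DELIST),
            expected_loss(loss, draws.pooled("rbar"), Action.MAINTAIN_THREATENED),
        )
    return risks
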