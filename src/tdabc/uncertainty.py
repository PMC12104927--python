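"""Monte Carlo uncertainty propagation for activity costs.

Each elicited quantity (an activity duration in minutes, or a capacity cost
rate in A$/minute) is mapped to a normal distribution whose mean is the
elicited point estimate and whose standard deviation is read off the
elicited (low, high) pair interpreted as a symmetric 95% interval:

    sigma = (high - low) / (2 * 1.959964)

An activity's cost is then simulated as the product of an independent time
draw and rate draw.  Because a product of independent normals is not
normal, the summary statistics use empirical percentiles for the 95% CI
(the product distribution is right-skewed when the coefficients of
variation are large) and the exact product moments

    E[TR]  = mu_t * mu_r
    SD[TR] = sqrt(mu_t^2 s_r^2 + mu_r^2 s_t^2 + s_t^2 s_r^2)

serve as a closed-form oracle against which the simulation is checked.

Draws are *not* truncated at zero: for very wide elicitation intervals the
fitted normal admits negative values, and these are retained (with a
logged warning when they exceed 1% of draws) so that the simulated spread
reflects the stated elicitation uncertainty.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

import pandas as pd

from .model import Activity, ClinicModel, ElicitedQuantity, StaffResource

logger = logging.getLogger(__name__)

#: Two-sided 95% normal quantile (scipy.stats.norm.ppf(0.975) to 6 dp).
Z95 = 1.959964

#: Default number of Monte Carlo iterations.
DEFAULT_ITERATIONS = 1000

#: Default base seed for all simulation entry points (the costing year).
DEFAULT_SEED = 2023


def child_seed(base: int, *keys: object) -> int:
    """Derive a reproducible sub-stream seed (< 2^31) from a base seed.

    String keys are hashed stably so the same (base, keys) always yields
    the same seed across processes and sessions.
    """
    parts = [int(base)]
    for k in keys:
        if isinstance(k, (int, np.integer)):
            parts.append(int(k))
        else:
            digest = hashlib.blake2s(str(k).encode(), digest_size=4).digest()
            parts.append(int.from_bytes(digest, "big"))
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class NormalParams:
    """Parameters of a fitted normal distribution (native units)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")


class CostEstimate(BaseModel):
    """Monte Carlo summary of a cost in A$."""

    model_config = ConfigDict(frozen=True)

    mean: float
    sd: float = Field(ge=0)
    ci_low: float
    ci_high: float
    n_iterations: int = Field(ge=1)
    seed: int


def normal_from_interval(q: ElicitedQuantity) -> NormalParams:
    """Fit a normal to an elicited (mean, low, high) triple.

    (low, high) is read as a central 95% interval, so
    ``sigma = (high - low) / (2 * 1.959964)``.  A degenerate interval
    (low == high) yields sigma 0.
    """
    if q.high < q.low:
        raise ValueError(f"high ({q.high}) must not be below low ({q.low})")
    return NormalParams(mu=q.mean, sigma=q.width / (2.0 * Z95))


def product_moment_oracle(t: NormalParams, r: NormalParams) -> tuple[float, float]:
    """Exact mean and SD of the product of two independent normals."""
    mean = t.mu * r.mu
    var = t.mu**2 * r.sigma**2 + r.mu**2 * t.sigma**2 + t.sigma**2 * r.sigma**2
    return mean, float(np.sqrt(var))


def draw_product(
    t: NormalParams, r: NormalParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` independent (time x rate) products from fitted normals."""
    times = rng.normal(t.mu, t.sigma, size=n)
    rates = rng.normal(r.mu, r.sigma, size=n)
    return times * rates


def sample_activity_cost(
    activity: Activity,
    resource: StaffResource,
    n: int = DEFAULT_ITERATIONS,
    seed: int = DEFAULT_SEED,
) -> np.ndarray:
    """Simulate ``n`` cost draws (A$) for one activity.

    Time and rate are drawn independently from the normals fitted to the
    activity duration and the performer's capacity cost rate.  The same
    (activity, resource, n, seed) always returns the identical vector.
    """
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    if activity.performer != resource.id:
        raise ValueError(
            f"activity {activity.id} is performed by {activity.performer!r}, "
            f"not {resource.id!r}"
        )
    rng = np.random.default_rng(seed)
    samples = draw_product(
        normal_from_interval(activity.duration),
        normal_from_interval(resource.ccr),
        n,
        rng,
    )
    neg = np.count_nonzero(samples < 0)
    if neg > 0.01 * n:
        logger.warning(
            "activity %s: %.1f%% of cost draws are negative (wide elicitation interval)",
            activity.id,
            100.0 * neg / n,
        )
    return samples


def summarize_samples(samples: np.ndarray, seed: int) -> CostEstimate:
    """Summarise cost draws into mean, sample SD, and empirical 95% CI.

    The CI bounds are the 2.5th and 97.5th percentiles (linear
    interpolation between order statistics), not a normal approximation:
    product-of-normals costs are skewed and their percentile intervals
    asymmetric around the mean.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError(f"need at least 2 samples to summarise, got {samples.size}")
    ci_low, ci_high = np.percentile(samples, [2.5, 97.5])
    return CostEstimate(
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=1)),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_iterations=int(samples.size),
        seed=int(seed),
    )


def activity_cost_estimate(
    activity: Activity,
    resource: StaffResource,
    n: int = DEFAULT_ITERATIONS,
    seed: int = DEFAULT_SEED,
) -> CostEstimate:
    """Monte Carlo cost estimate for one activity (simulate + summarise)."""
    return summarize_samples(sample_activity_cost(activity, resource, n, seed), seed)


def activity_cost_table(
    model: ClinicModel,
    n: int = DEFAULT_ITERATIONS,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Monte Carlo cost estimates for every activity of a clinic model.

    Each activity gets its own seed sub-stream derived from ``seed`` and
    its id, so estimates are stable under reordering of the table.
    """
    rows = []
    for a in model.process_map.activities:
        est = activity_cost_estimate(
            a, model.resource_for(a), n=n, seed=child_seed(seed, "activity", a.id)
        )
        rows.append(
            {
                "activity_id": a.id,
                "label": a.label,
                "process": a.process,
                "performer": a.performer,
                "duration_mean": a.duration.mean,
                "mean": est.mean,
                "sd": est.sd,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_iterations": est.n_iterations,
            }
        )
    return pd.DataFrame(rows)
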