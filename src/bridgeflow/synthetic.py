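"""Synthetic bridging-vein cohorts from truncated-normal moment matching.

The cadaveric raw data behind the anatomical table are not deposited; only
per-group summaries are printed: mean ± SD with a hard observed range for the
vein diameter and the entry angle. This module generates stand-in cohorts
whose per-group distributions reproduce those printed statistics.

The generative family is the normal distribution truncated to the printed
range. Naively truncating a normal with the printed mean/SD biases both
moments, so the underlying (mu, sigma) are solved such that the *truncated*
distribution has the requested mean and SD (moment matching). Sampling is by
inverse CDF on the truncated distribution: deterministic under a fixed seed
and incapable of producing out-of-range values.

Not every (mean, SD) pair is attainable: truncated normals are log-concave,
so on a finite interval their SD is bounded (the supremum sits on the
truncated-exponential boundary of the family). The posterior entry-angle
moments printed in the source table exceed that bound; see
``GeneratorConfig.on_infeasible``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

import numpy as np
from scipy import optimize, stats

from .cohort import BVRecord, Group
from .errors import InputError, MomentMatchError

__all__ = [
    "GroupSpec",
    "GeneratorConfig",
    "anterior_spec",
    "posterior_spec",
    "default_config",
    "solve_truncnorm_params",
    "closest_truncnorm_params",
    "generate_cohort",
]


@dataclass(frozen=True)
class GroupSpec:
    """Target moments and hard bounds for one cohort group."""

    group: Group
    n: int
    diameter_mean: float
    diameter_sd: float
    diameter_bounds: tuple[float, float]
    angle_mean: float
    angle_sd: float
    angle_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        if self.n < 0:
            raise InputError("group size must be >= 0")
        for mean, sd, (lo, hi), what in [
            (self.diameter_mean, self.diameter_sd, self.diameter_bounds, "diameter"),
            (self.angle_mean, self.angle_sd, self.angle_bounds, "angle"),
        ]:
            if not lo < mean < hi:
                raise InputError(f"{what}: bounds must bracket the mean ({lo}, {mean}, {hi})")
            if not sd > 0:
                raise InputError(f"{what}: sd must be positive")


def anterior_spec(n: int = 62) -> GroupSpec:
    """Anterior group defaults: printed moments of the anatomical table."""
    return GroupSpec(Group.anterior, n, 2.0, 0.9, (0.6, 5.2), 93.0, 34.0, (40.0, 170.0))


def posterior_spec(n: int = 75) -> GroupSpec:
    """Posterior group defaults: printed moments of the anatomical table."""
    return GroupSpec(Group.posterior, n, 3.0, 1.1, (0.8, 5.8), 43.0, 25.0, (10.0, 90.0))


@dataclass(frozen=True)
class GeneratorConfig:
    """Reproducible cohort generation.

    ``correlation`` is a Gaussian-copula correlation between diameter and
    entry angle within a group (default 0: independent margins — the source
    reports no joint distribution). ``on_infeasible`` controls what happens
    when the printed moments are not attainable by any truncated normal:
    ``"closest"`` matches the mean exactly and takes the closest attainable
    SD; ``"error"`` propagates :class:`MomentMatchError`.
    """

    specs: tuple[GroupSpec, ...] = field(
        default_factory=lambda: (anterior_spec(), posterior_spec())
    )
    seed: int = 0
    correlation: float = 0.0
    on_infeasible: Literal["closest", "error"] = "closest"

    def __post_init__(self) -> None:
        if not -1.0 < self.correlation < 1.0:
            raise InputError("correlation must lie in (-1, 1)")


def default_config(seed: int = 0) -> GeneratorConfig:
    return GeneratorConfig(seed=seed)


def _truncnorm_moments(mu: float, sigma: float, lo: float, hi: float) -> tuple[float, float]:
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(math.sqrt(v))


def solve_truncnorm_params(
    target_mean: float,
    target_sd: float,
    lo: float,
    hi: float,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Underlying normal (mu, sigma) whose [lo, hi]-truncation has the target moments.

    Both moments are matched to within ``tol``; if no truncated normal attains
    them (SD too large for the interval at that mean), :class:`MomentMatchError`
    is raised.
    """
    if not target_sd > 0:
        raise InputError("target_sd must be positive")
    if math.isinf(lo) and math.isinf(hi):
        return target_mean, target_sd
    if not lo < target_mean < hi:
        raise InputError("target_mean must lie strictly inside (lo, hi)")

    def residuals(x):
        mu, log_sigma = x
        m, s = _truncnorm_moments(mu, math.exp(log_sigma), lo, hi)
        return [m - target_mean, s - target_sd]

    sol = optimize.least_squares(
        residuals, [target_mean, math.log(target_sd)], xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    mu, sigma = float(sol.x[0]), float(math.exp(sol.x[1]))
    m, s = _truncnorm_moments(mu, sigma, lo, hi)
    if abs(m - target_mean) > tol or abs(s - target_sd) > tol:
        raise MomentMatchError(
            f"moments (mean={target_mean}, sd={target_sd}) not attainable on "
            f"[{lo}, {hi}]: best truncated-normal fit gives (mean={m:.6g}, sd={s:.6g})"
        )
    return mu, sigma


def _mu_for_mean(target_mean: float, sigma: float, lo: float, hi: float) -> float:
    # Truncated mean is strictly increasing in mu; bracket and bisect.
    span = hi - lo
    lo_mu, hi_mu = lo - 60 * sigma - span, hi + 60 * sigma + span

    def f(mu):
        return _truncnorm_moments(mu, sigma, lo, hi)[0] - target_mean

    return float(optimize.brentq(f, lo_mu, hi_mu, xtol=1e-12 * max(1.0, abs(span))))


def closest_truncnorm_params(
    target_mean: float, target_sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Mean-exact fallback: match the mean, minimise |SD - target| over sigma."""
    span = hi - lo

    def sd_gap(log_sigma):
        sigma = math.exp(log_sigma)
        mu = _mu_for_mean(target_mean, sigma, lo, hi)
        return abs(_truncnorm_moments(mu, sigma, lo, hi)[1] - target_sd)

    # The attainable SD saturates well before sigma ~ 3 * span (the family
    # approaches its truncated-exponential boundary); keeping sigma bounded
    # keeps (mu, sigma) numerically tame.
    res = optimize.minimize_scalar(
        sd_gap,
        bounds=(math.log(span * 1e-3), math.log(span * 3.0)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    sigma = float(math.exp(res.x))
    return _mu_for_mean(target_mean, sigma, lo, hi), sigma


@lru_cache(maxsize=256)
def _solve_cached(mean: float, sd: float, lo: float, hi: float, on_infeasible: str):
    try:
        return solve_truncnorm_params(mean, sd, lo, hi)
    except MomentMatchError:
        if on_infeasible == "error":
            raise
        return closest_truncnorm_params(mean, sd, lo, hi)


def _group_params(spec: GroupSpec, on_infeasible: str) -> dict[str, tuple[float, float]]:
    out = {}
    for key, mean, sd, (lo, hi) in [
        ("diameter", spec.diameter_mean, spec.diameter_sd, spec.diameter_bounds),
        ("angle", spec.angle_mean, spec.angle_sd, spec.angle_bounds),
    ]:
        out[key] = _solve_cached(mean, sd, lo, hi, on_infeasible)
    return out


def generate_cohort(config: GeneratorConfig) -> list[BVRecord]:
    """Sample one synthetic cohort.

    Exactly ``spec.n`` records per group, ids ``{group}_{index}``; every value
    strictly inside its bounds; bit-for-bit reproducible for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    records: list[BVRecord] = []
    rho = config.correlation
    for spec in config.specs:
        params = _group_params(spec, config.on_infeasible)
        z = rng.standard_normal(size=(spec.n, 2))
        z[:, 1] = rho * z[:, 0] + math.sqrt(1.0 - rho * rho) * z[:, 1]
        u = stats.norm.cdf(z)
        values = {}
        for col, key, (lo, hi) in [
            (0, "diameter", spec.diameter_bounds),
            (1, "angle", spec.angle_bounds),
        ]:
            mu, sigma = params[key]
            a, b = (lo - mu) / sigma, (hi - mu) / sigma
            x = stats.truncnorm.ppf(u[:, col], a, b, loc=mu, scale=sigma)
            # ppf is exact-support by construction; clip only guards the
            # u -> {0,1} floating endpoints.
            values[key] = np.clip(x, np.nextafter(lo, hi), np.nextafter(hi, lo))
        for i in range(spec.n):
            records.append(
                BVRecord(
                    id=f"{spec.group.value}_{i:03d}",
                    group=spec.group,
                    diameter_mm=float(values["diameter"][i]),
                    entry_angle_deg=float(values["angle"][i]),
                )
            )
    return records
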