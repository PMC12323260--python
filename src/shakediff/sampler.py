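"""Reverse-SDE sampling with interleaved constraint enforcement.

The sampler integrates the reverse-time dynamics of a score-based
diffusion model with an Euler-Maruyama scheme and, per step, interleaves

1. the deterministic schedule update (bound tightening),
2. optional tangent-space projection of the noise increment,
3. the stochastic trial step,
4. position projection (SHAKE), harmonic guidance, or nothing.

Two stepping modes are supported, keyed by the score model:

``reverse_sde``
    For scores that are exact noised scores of the forward process
    (the built-in Gaussian-mixture score), the reverse SDE

        dx = [f(x,t) - g(t)^2 grad log p_t(x)] dt + g(t) dW~

    is integrated from t = 1 down to 0 under a variance-exploding or
    variance-preserving noise schedule.

``langevin``
    For the annealed Boltzmann surrogate score -grad U / k_B T(tau), an
    overdamped Langevin step

        x <- x + D s(x, tau) dt + sqrt(2 D dt) eta

    whose stationary law for a frozen score is exp(-U / k_B T).  This is
    the appropriate dynamics for a score that is not the exact noised
    score; the reverse-SDE g^2 drift factor would square the density.

Reduced units: k_B = 1, so temperatures are in energy units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .constraints import ConstraintSet
from .guidance import GuidanceParams, guidance_step
from .projection import (
    ANGULAR_WEIGHT,
    DEFAULT_TOL,
    project,
    project_noise,
)
from .schedules import resolve_active

__all__ = [
    "VESchedule",
    "VPSchedule",
    "GaussianMixtureScore",
    "BoltzmannScore",
    "gaussian_mixture_score",
    "toy_boltzmann_score",
    "SamplerConfig",
    "TrajectoryRecord",
    "SampleResult",
    "sample",
    "demo_particle_1d",
    "demo_density_2d",
]


# ---------------------------------------------------------------------------
# noise schedules
# ---------------------------------------------------------------------------

@dataclass
class VESchedule:
    """Variance-exploding schedule: sigma(t) = sigma_min (sigma_max/sigma_min)^t,
    f = 0, g(t)^2 = d sigma^2/dt."""

    sigma_min: float = 0.01
    sigma_max: float = 5.0

    def sigma(self, t):
        return self.sigma_min * (self.sigma_max / self.sigma_min) ** t

    def marginal(self, t):
        """(scale, added variance) of x_t = scale * x_0 + sqrt(var) eta."""
        return 1.0, self.sigma(t) ** 2

    def f(self, x, t):
        return np.zeros_like(x)

    def g2(self, t):
        return self.sigma(t) ** 2 * 2.0 * math.log(self.sigma_max / self.sigma_min)


@dataclass
class VPSchedule:
    """Variance-preserving schedule with linear beta(t) = b0 + (b1 - b0) t."""

    beta_min: float = 0.1
    beta_max: float = 20.0

    def _B(self, t):
        return self.beta_min * t + 0.5 * (self.beta_max - self.beta_min) * t * t

    def alpha(self, t):
        return math.exp(-0.5 * self._B(t))

    def marginal(self, t):
        a = self.alpha(t)
        return a, 1.0 - a * a

    def f(self, x, t):
        beta = self.beta_min + (self.beta_max - self.beta_min) * t
        return -0.5 * beta * x

    def g2(self, t):
        return self.beta_min + (self.beta_max - self.beta_min) * t


# ---------------------------------------------------------------------------
# score models
# ---------------------------------------------------------------------------

@dataclass
class GaussianMixtureScore:
    """Exact time-dependent score of an isotropic Gaussian mixture under a
    diffusion noise schedule.

    The data law is sum_k w_k N(mu_k, v0 I); convolved with the forward
    process at time t each component stays Gaussian, so the score is the
    responsibility-weighted sum of per-component Gaussian scores — a
    closed-form stand-in for a trained score network.
    """

    means: np.ndarray          # (K, d)
    weights: np.ndarray        # (K,)
    base_variance: float
    noise_schedule: object = field(default_factory=VESchedule)
    mode: str = "reverse_sde"

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        if self.means.shape[0] == 0:
            raise ValueError("mixture must have at least one component")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("mixture weights must be positive")
        self.weights = w / w.sum()
        if self.base_variance <= 0:
            raise ValueError("base_variance must be positive")

    @property
    def dim(self):
        return self.means.shape[1]

    def _component_params(self, t):
        scale, var = self.noise_schedule.marginal(t)
        return scale * self.means, self.base_variance * scale * scale + var

    def _log_resp(self, x, t):
        means_t, v = self._component_params(t)
        # (B, K) squared distances
        d2 = ((x[:, None, :] - means_t[None, :, :]) ** 2).sum(-1)
        logp = np.log(self.weights)[None, :] - 0.5 * d2 / v \
            - 0.5 * self.dim * np.log(2 * np.pi * v)
        return logp, means_t, v

    def log_density(self, x, t):
        x = np.atleast_2d(x)
        logp, _, _ = self._log_resp(x, t)
        m = logp.max(axis=1, keepdims=True)
        return (m[:, 0] + np.log(np.exp(logp - m).sum(axis=1)))

    def score(self, x, t):
        x2 = np.atleast_2d(x)
        logp, means_t, v = self._log_resp(x2, t)
        m = logp.max(axis=1, keepdims=True)
        resp = np.exp(logp - m)
        resp /= resp.sum(axis=1, keepdims=True)
        s = (resp[:, :, None] * (means_t[None, :, :] - x2[:, None, :])).sum(1) / v
        return s if np.ndim(x) == 2 else s[0]

    def prior_sample(self, rng, batch):
        """Exact draw from the noised mixture at t = 1."""
        means_t, v = self._component_params(1.0)
        comp = rng.choice(len(self.weights), size=batch, p=self.weights)
        return means_t[comp] + math.sqrt(v) * rng.standard_normal((batch, self.dim))


@dataclass
class BoltzmannScore:
    """Annealed Boltzmann surrogate score s(x, tau) = -grad U(x) / k_B T(tau).

    An approximation, not an exact noised score: it enables energy-driven
    sampling (butane-like chains) without a trained network, and the sampler
    integrates it as overdamped Langevin dynamics.  ``energy_fn`` and
    optional ``gradient_fn`` act on flat coordinate vectors; a central
    finite difference fills in when the gradient is not supplied.
    """

    energy_fn: Callable[[np.ndarray], float]
    gradient_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None
    temperature_schedule: Callable[[float], float] = None
    reference: Optional[np.ndarray] = None
    init_spread: float = 2.0
    mode: str = "langevin"
    fd_step: float = 1e-5
    #: set when ``energy_fn``/``gradient_fn`` accept (B, d) batches directly
    batched: bool = False

    def __post_init__(self):
        if self.temperature_schedule is None:
            # geometric anneal from a hot start to T = 1 (reduced units)
            self.temperature_schedule = lambda tau: 5.0 ** (1.0 - tau)
        elif np.isscalar(self.temperature_schedule):
            t_const = float(self.temperature_schedule)
            self.temperature_schedule = lambda tau: t_const
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float).ravel()

    def _grad(self, x):
        if self.gradient_fn is not None:
            return np.asarray(self.gradient_fn(x), dtype=float).ravel()
        g = np.empty_like(x)
        h = self.fd_step
        for k in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            g[k] = (self.energy_fn(xp) - self.energy_fn(xm)) / (2 * h)
        return g

    def score(self, x, tau):
        temp = self.temperature_schedule(tau)
        x2 = np.atleast_2d(x)
        if self.batched and self.gradient_fn is not None:
            out = -np.asarray(self.gradient_fn(x2), dtype=float) / temp
        else:
            out = np.empty_like(x2)
            for b in range(x2.shape[0]):
                e = self.energy_fn(x2[b])
                if not np.isfinite(e):
                    raise FloatingPointError(
                        "energy function returned a non-finite value"
                    )
                out[b] = -self._grad(x2[b]) / temp
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("score is non-finite")
        return out if np.ndim(x) == 2 else out[0]

    def prior_sample(self, rng, batch):
        if self.reference is None:
            raise ValueError("BoltzmannScore needs a reference point to initialize")
        d = self.reference.size
        return self.reference[None, :] + self.init_spread * rng.standard_normal((batch, d))


def gaussian_mixture_score(means, weights=None, base_variance=1.0,
                           noise_schedule=None) -> GaussianMixtureScore:
    """Build the exact noised score of a Gaussian mixture (see
    :class:`GaussianMixtureScore`)."""
    means = np.atleast_2d(np.asarray(means, dtype=float))
    if means.shape[0] == 0:
        raise ValueError("mixture must have at least one component")
    if weights is None:
        weights = np.full(means.shape[0], 1.0 / means.shape[0])
    if noise_schedule is None:
        noise_schedule = VESchedule()
    return GaussianMixtureScore(means, weights, base_variance, noise_schedule)


def toy_boltzmann_score(energy_fn, temperature_schedule=None, gradient_fn=None,
                        reference=None, init_spread=2.0,
                        batched=False) -> BoltzmannScore:
    """Build the annealed -grad U / k_B T surrogate score (see
    :class:`BoltzmannScore`)."""
    return BoltzmannScore(energy_fn, gradient_fn, temperature_schedule,
                          reference, init_spread, batched=batched)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    """Configuration of one sampling run.

    ``shape`` gives (n_atoms, dim) for constraint evaluation; leave ``None``
    for unconstrained runs in flat coordinates.  ``project_noise`` defaults
    to on for the projection method and off otherwise.
    """

    n_steps: int = 1000
    batch_size: int = 1
    method: str = "shake"            # shake | guidance | none
    project_noise: Optional[bool] = None
    tol: float = DEFAULT_TOL
    seed: int = 0
    shape: Optional[tuple] = None
    max_iter: int = 100
    on_failure: str = "raise"
    guidance: GuidanceParams = field(default_factory=GuidanceParams)
    langevin_diffusion: float = 1.0
    langevin_dt: float = 0.01
    record_positions_every: int = 0

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.method not in ("shake", "guidance", "none"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.project_noise is None:
            self.project_noise = self.method == "shake"


@dataclass
class TrajectoryRecord:
    """Per-step diagnostics of a sampling run (aggregated over the batch)."""

    tau: np.ndarray
    t: np.ndarray
    max_residual: np.ndarray
    mean_residual: np.ndarray
    shake_norm: np.ndarray
    guidance_norm: np.ndarray
    iterations: np.ndarray
    n_active: np.ndarray
    positions: list = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": np.arange(len(self.tau)),
                "tau": self.tau,
                "t": self.t,
                "max_residual": self.max_residual,
                "mean_residual": self.mean_residual,
                "shake_norm": self.shake_norm,
                "guidance_norm": self.guidance_norm,
                "iterations": self.iterations,
                "n_active": self.n_active,
            }
        )

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class SampleResult:
    samples: np.ndarray            # (B, N, D) when shape known else (B, d)
    trajectory: TrajectoryRecord


def _bound_violation(c, coords, lo, up, weight):
    v = c.value(coords)
    if getattr(c, "angular", False):
        from .constraints import wrap_degrees

        mid = 0.5 * (lo + up) if np.isfinite(lo) and np.isfinite(up) else c.target
        v = mid + wrap_degrees(v - mid)
    viol = max(v - up, lo - v, 0.0)
    return viol * weight


def _all_strict_equalities(cset):
    return all(
        getattr(c, "schedule", None) is None and c.lower_final == c.upper_final
        for c in cset
    )


def sample(score, cset: Optional[ConstraintSet] = None,
           config: Optional[SamplerConfig] = None) -> SampleResult:
    """Run the constrained reverse-diffusion sampler.

    Identical seeds give bit-identical output.  With the projection method,
    every logged post-step ``max_residual`` (the weighted violation of the
    currently active bounds) is at most ``config.tol``.
    """
    config = config or SamplerConfig()
    cset = cset if cset is not None else ConstraintSet()
    rng = np.random.default_rng(config.seed)
    B = config.batch_size
    x = np.atleast_2d(score.prior_sample(rng, B)).astype(float)
    d = x.shape[1]
    shape = config.shape
    if shape is None and len(cset) > 0:
        raise ValueError("config.shape=(n_atoms, dim) is required with constraints")
    langevin = getattr(score, "mode", "reverse_sde") == "langevin"
    n = config.n_steps
    dt = 1.0 / n

    weights = np.array(
        [ANGULAR_WEIGHT if getattr(c, "angular", False) else 1.0 for c in cset]
    )
    strict = _all_strict_equalities(cset)

    # the constrained formulation assumes a feasible initial condition:
    # project the prior draw onto the initially-active manifold before
    # stepping (consumes no randomness; scheduled constraints are typically
    # still unbounded at tau = 0 and contribute nothing here)
    if len(cset) > 0 and config.method == "shake":
        for b in range(B):
            coords = x[b].reshape(shape)
            if strict:
                active_idx, targets = list(range(len(cset))), None
            else:
                view = resolve_active(cset, coords, 0.0)
                active_idx, targets = view.active_indices, view.effective_targets
            if active_idx:
                sub = ConstraintSet([cset[a] for a in active_idx])
                res = project(
                    coords, sub, targets, tol=config.tol,
                    max_iter=config.max_iter, on_failure=config.on_failure,
                )
                x[b] = res.coordinates.ravel()

    rec = TrajectoryRecord(*[np.zeros(n) for _ in range(8)])

    for step in range(n):
        tau0 = step / n
        tau1 = (step + 1) / n
        t_now = 1.0 - tau0
        eta = rng.standard_normal((B, d))

        # active sets at the incoming bounds (used for noise projection)
        if len(cset) > 0 and config.method == "shake" and config.project_noise:
            for b in range(B):
                coords = x[b].reshape(shape)
                if strict:
                    active_idx = range(len(cset))
                    targets = None
                else:
                    view = resolve_active(cset, coords, tau1)
                    active_idx = view.active_indices
                    targets = view.effective_targets
                if len(list(active_idx)) > 0:
                    sub = ConstraintSet([cset[a] for a in active_idx])
                    try:
                        eta[b] = project_noise(eta[b], sub, coords, targets)
                    except Exception:
                        pass  # fall back to unprojected noise at degenerate frames

        # stochastic trial step
        if langevin:
            dtl = config.langevin_dt
            drift = config.langevin_diffusion * score.score(x, tau0)
            x = x + drift * dtl + math.sqrt(2.0 * config.langevin_diffusion * dtl) * eta
        else:
            g2 = score.noise_schedule.g2(t_now)
            drift = g2 * score.score(x, t_now) - score.noise_schedule.f(x, t_now)
            x = x + drift * dt + math.sqrt(g2 * dt) * eta
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite coordinates at step {step}")

        # constraint handling at the advanced bounds
        max_res = 0.0
        res_sum = 0.0
        res_count = 0
        shake_norms = []
        guid_norms = []
        iters = 0
        n_active = 0
        if len(cset) > 0 and config.method != "none":
            for b in range(B):
                coords = x[b].reshape(shape)
                if strict:
                    active_idx = list(range(len(cset)))
                    targets = None
                    bounds = [(c.lower_final, c.upper_final) for c in cset]
                else:
                    view = resolve_active(cset, coords, tau1)
                    active_idx = view.active_indices
                    targets = view.effective_targets
                    bounds = view.bounds
                n_active += len(active_idx)
                if active_idx:
                    sub = ConstraintSet([cset[a] for a in active_idx])
                    if config.method == "shake":
                        result = project(
                            coords, sub, targets, tol=config.tol,
                            max_iter=config.max_iter, on_failure=config.on_failure,
                        )
                        coords = result.coordinates
                        shake_norms.append(result.correction_norm)
                        iters = max(iters, result.iterations_used)
                    else:
                        coords, gnorm = guidance_step(
                            coords, sub, config.guidance, targets
                        )
                        guid_norms.append(gnorm)
                    x[b] = coords.ravel()
                # post-step violation over all constraints
                if strict:
                    bounds = [(c.lower_final, c.upper_final) for c in cset]
                for a, c in enumerate(cset):
                    viol = _bound_violation(c, coords, *bounds[a], weights[a])
                    max_res = max(max_res, viol)
                    res_sum += viol
                    res_count += 1

        rec.tau[step] = tau1
        rec.t[step] = 1.0 - tau1
        rec.max_residual[step] = max_res
        rec.mean_residual[step] = res_sum / res_count if res_count else 0.0
        rec.shake_norm[step] = float(np.mean(shake_norms)) if shake_norms else 0.0
        rec.guidance_norm[step] = float(np.mean(guid_norms)) if guid_norms else 0.0
        rec.iterations[step] = iters
        rec.n_active[step] = n_active / B if B else 0.0
        if config.record_positions_every and step % config.record_positions_every == 0:
            rec.positions.append(x.copy())

    samples = x.reshape((B,) + tuple(shape)) if shape is not None else x
    return SampleResult(samples, rec)


# ---------------------------------------------------------------------------
# pedagogical demonstrations
# ---------------------------------------------------------------------------

def demo_particle_1d(n_steps: int = 1000, seed: int = 0, step_sd: float = 0.1,
                     target: Optional[Callable[[float], float]] = None,
                     bounds: Optional[Callable[[float], tuple]] = None,
                     tol: float = DEFAULT_TOL):
    """Random walk of a 1D particle under a time-dependent constraint.

    ``target(tau)`` imposes a moving equality (projection onto a point is
    exact); ``bounds(tau)`` imposes a moving interval (clamping).  Returns a
    dict with positions, unconstrained positions (same noise) and residuals.
    """
    rng = np.random.default_rng(seed)
    xs = np.zeros(n_steps + 1)
    free = np.zeros(n_steps + 1)
    residuals = np.zeros(n_steps + 1)
    x = xf = 0.0
    for step in range(1, n_steps + 1):
        tau = step / n_steps
        eta = rng.standard_normal()
        x += step_sd * eta
        xf += step_sd * eta
        if target is not None:
            goal = target(tau)
            residuals[step] = abs(x - goal)
            x = goal
        elif bounds is not None:
            lo, up = bounds(tau)
            residuals[step] = max(x - up, lo - x, 0.0)
            x = min(max(x, lo), up)
        xs[step] = x
        free[step] = xf
    return {"positions": xs, "unconstrained": free, "residuals": residuals}


def demo_density_2d(n_steps: int = 400, batch: int = 512, seed: int = 0,
                    radius: float = 1.0, method: str = "shake",
                    beta: float = 10.0, t0: float = 0.5, tol: float = DEFAULT_TOL):
    """2D Gaussian samples herded into a disc by a scheduled radial bound.

    The disc radius acts as an upper bound on the distance from the origin
    that tightens from unbounded to ``radius``; the final cloud satisfies
    the bound to ``tol`` under the projection method, while the guidance
    variant typically leaves a nonzero violation fraction.

    Returns a dict with the final (batch, 2) cloud and the feasible
    fraction at tolerance.
    """
    from .constraints import RadialConstraint
    from .schedules import BoundSchedule

    sched = BoundSchedule(beta=beta, t0=t0, lower_initial=0.0, upper_initial=None,
                          lower_final=0.0, upper_final=radius)
    con = RadialConstraint(0, np.zeros(2), radius, lower_final=0.0,
                           upper_final=radius, schedule=sched)
    score = gaussian_mixture_score(np.zeros((1, 2)), base_variance=1.0)
    config = SamplerConfig(n_steps=n_steps, batch_size=batch, method=method,
                           seed=seed, shape=(1, 2), tol=tol, on_failure="warn")
    result = sample(score, ConstraintSet([con]), config)
    cloud = result.samples.reshape(batch, 2)
    radii = np.linalg.norm(cloud, axis=1)
    feasible = float(np.mean(radii <= radius + tol))
    return {"cloud": cloud, "feasible_fraction": feasible,
            "trajectory": result.trajectory}
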