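"""Overdamped Langevin sampling of biased windows on a 1D free-energy surface.

This is the desk-scale surrogate for the MD engine: instead of explicit
solvent, each window's reaction coordinate diffuses on the analytic surface
G(z) plus its harmonic restraint under the Leimkuhler-Matthews variant of
Euler-Maruyama dynamics

    z <- z - (D / RT) * (G'(z) + k (z - z0)) * dt
           + sqrt(2 D dt) * (xi_prev + xi) / 2,

with xi ~ N(0, 1) and xi_prev the previous step's noise.  Averaging
consecutive noises costs nothing but removes the leading O(dt) error of the
sampled configurational distribution (for a purely harmonic potential the
stationary variance is exact), so the stiff restraints do not bias the
reconstructed profiles.  Time is in reduced units (only the stationary
distribution matters for WHAM, so no mapping to ns is claimed); the long-run
histogram of each window converges to the Boltzmann density of the biased
potential at the configured temperature.

Windows are seeded independently as ``seed + window_index`` so a window's
trajectory is identical whether it is sampled alone or in a batch, and
replicates are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .constants import kT
from .potential import PotentialModel
from .windows import UmbrellaWindow

__all__ = ["SamplerConfig", "SamplerInstabilityError", "sample_window", "sample_windows"]

# noise is drawn per window in blocks of this many steps to bound memory
_BLOCK = 8192


class SamplerInstabilityError(RuntimeError):
    """A trajectory left the allowed domain (divergent integration)."""


@dataclass(frozen=True)
class SamplerConfig:
    """Integration settings for the Langevin surrogate.

    dt and diffusion are in reduced units (nm^2 per unit time for the
    diffusion coefficient); ``n_steps`` is the number of integration steps
    per window and one sample is recorded every ``stride`` steps.  With
    ``boundary="reflect"`` trajectories reflect at ±z_max of the potential,
    which is required for unbiased (k = 0) runs.

    The defaults are tuned to the canonical 2000 kJ mol^-1 nm^-2 restraint
    at 300 K: the per-step damping a = D k dt / RT is 0.2, so the window
    relaxation time is ~5 steps and samples taken every 10 steps are close
    to independent; 300k steps then yield 30k samples per window (20k after
    discarding the first third as equilibration).
    """

    dt: float = 2.5e-4
    diffusion: float = 1.0
    temperature: float = 300.0
    n_steps: int = 300_000
    stride: int = 10
    seed: int = 0
    boundary: str = "none"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.diffusion <= 0:
            raise ValueError("dt and diffusion must be positive")
        if self.n_steps < 0 or self.stride <= 0:
            raise ValueError("n_steps must be >= 0 and stride positive")
        if self.boundary not in ("none", "reflect"):
            raise ValueError(f"unknown boundary condition: {self.boundary!r}")

    def step_scale(self) -> float:
        """Single-step noise displacement scale sqrt(2 D dt) in nm."""
        return float(np.sqrt(2.0 * self.diffusion * self.dt))

    def validate_for(self, model: PotentialModel) -> None:
        """Stability guard: the noise step must resolve the interface well."""
        if self.step_scale() >= model.w_interface / 5.0:
            raise ValueError(
                "dt too large for this surface: sqrt(2 D dt) = "
                f"{self.step_scale():.4g} nm must be < w_interface/5 = "
                f"{model.w_interface / 5.0:.4g} nm"
            )


def sample_windows(
    model: PotentialModel,
    windows: Sequence[UmbrellaWindow],
    cfg: SamplerConfig,
    window_indices: Sequence[int] | None = None,
) -> list[UmbrellaWindow]:
    """Sample all ``windows`` on ``model`` simultaneously (vectorised).

    Window i uses its own RNG stream seeded ``cfg.seed + window_indices[i]``
    (indices default to 0..n-1), so results are independent of batch
    composition.  Returns new windows carrying the recorded samples.
    """
    cfg.validate_for(model)
    n_w = len(windows)
    if n_w == 0:
        return []
    for w in windows:
        if w.n_samples:
            raise ValueError("windows must have empty samples before sampling")
    if window_indices is None:
        window_indices = range(n_w)
    gens = [np.random.default_rng(cfg.seed + int(i)) for i in window_indices]

    centers = np.array([w.center for w in windows], dtype=float)
    ks = np.array([w.force_constant for w in windows], dtype=float)
    rt = kT(cfg.temperature)
    mob = cfg.diffusion * cfg.dt / rt
    sig = cfg.step_scale()
    z_lim = model.z_max + 1.0

    n_samples = cfg.n_steps // cfg.stride
    out = np.empty((n_w, n_samples))
    z = centers.copy()
    xi_prev = np.array([g.standard_normal() for g in gens])
    step = 0
    rec = 0
    while step < cfg.n_steps:
        block = min(_BLOCK, cfg.n_steps - step)
        noise = np.empty((n_w, block))
        for i, g in enumerate(gens):
            noise[i] = g.standard_normal(block)
        for t in range(block):
            xi = noise[:, t]
            force = model.gradient(z) + ks * (z - centers)
            z = z - mob * force + sig * 0.5 * (xi_prev + xi)
            xi_prev = xi
            if cfg.boundary == "reflect":
                z = np.where(z > model.z_max, 2.0 * model.z_max - z, z)
                z = np.where(z < -model.z_max, -2.0 * model.z_max - z, z)
            step += 1
            if step % cfg.stride == 0:
                out[:, rec] = z
                rec += 1
        bad = np.abs(z) > z_lim
        if np.any(bad):
            i = int(np.argmax(bad))
            raise SamplerInstabilityError(
                f"window {window_indices[i] if window_indices is not None else i} "
                f"(center {centers[i]:+.3f} nm) diverged: |z| > {z_lim:.2f} nm"
            )
    return [replace(w, samples=out[i]) for i, w in enumerate(windows)]


def sample_window(
    model: PotentialModel,
    window: UmbrellaWindow,
    cfg: SamplerConfig,
    window_index: int = 0,
) -> UmbrellaWindow:
    """Sample a single umbrella window (see :func:`sample_windows`)."""
    return sample_windows(model, [window], cfg, window_indices=[window_index])[0]
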