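"""Parametric 1D free-energy surface of a solute crossing a vacuum-water slab.

The surface mimics the generic shape of a small-molecule potential of mean
force across a thin water slab centred at z = 0 with vacuum on both sides:
a vacuum plateau at ``g_vacuum`` for large |z|, a bulk-water plateau at
``g_bulk`` around z = 0, and an adsorption well at the two equivalent
interfaces (±``z_interface``) whose depth is set so the global minimum is
exactly ``g_surface_min``.  By construction the generator therefore has
known ground-truth landmarks:

* gas → surface free energy  ΔG_gs  = ``g_surface_min`` − ``g_vacuum``
* hydration free energy      ΔG_hydr = ``g_bulk`` − ``g_vacuum``

so recovery of these quantities by the umbrella-sampling/WHAM machinery can
be checked against exact values.

The plateau-to-plateau transition uses a compact-support quintic smoothstep
(C² smooth, exactly 1 inside the slab and exactly 0 in vacuum); the wells are
Gaussians of half-width ``w_interface`` mirrored at ±``z_interface``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = ["PotentialModel", "pmf_value", "pmf_gradient"]


def _smoothstep(t: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: 0 for t<=0, 1 for t>=1, C^2 in between."""
    t = np.clip(t, 0.0, 1.0)
    return t * t * t * (t * (6.0 * t - 15.0) + 10.0)


def _smoothstep_deriv(t: np.ndarray) -> np.ndarray:
    inside = (t > 0.0) & (t < 1.0)
    tc = np.clip(t, 0.0, 1.0)
    d = 30.0 * tc * tc * (tc - 1.0) * (tc - 1.0)
    return np.where(inside, d, 0.0)


@dataclass(frozen=True)
class PotentialModel:
    """Even 1D free-energy surface G(z) with vacuum, interface and bulk levels.

    Parameters
    ----------
    g_bulk : float
        Bulk-water plateau level in kJ/mol; stands for the hydration free
        energy of the emulated species.
    g_surface_min : float
        Level of the interfacial adsorption minimum in kJ/mol; stands for the
        gas-to-surface free energy change.
    g_vacuum : float
        Vacuum reference level in kJ/mol (0 by convention).
    z_interface : float
        Position of the interface well centre in nm (> 0; mirrored at −z).
        Also the midpoint of the slab-edge switching region.
    w_interface : float
        Gaussian half-width of the adsorption well in nm.
    w_switch : float
        Half-width in nm of the smoothstep transition between the bulk level
        (inside the slab) and the vacuum level.
    z_max : float
        Half-extent of the coordinate domain in nm; G is only defined on
        [−z_max, z_max].
    """

    g_bulk: float = 0.0
    g_surface_min: float = 0.0
    g_vacuum: float = 0.0
    z_interface: float = 1.6
    w_interface: float = 0.25
    w_switch: float = 0.2
    z_max: float = 4.0
    _well_amplitude: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        if self.z_interface <= 0:
            raise ValueError("z_interface must be positive")
        if self.w_interface <= 0 or self.w_switch <= 0:
            raise ValueError("well and switch widths must be positive")
        if self.z_max <= self.z_interface:
            raise ValueError("z_max must exceed z_interface")
        object.__setattr__(self, "_well_amplitude", self._calibrate_well())

    # -- construction helpers -------------------------------------------------

    def _baseline(self, z: np.ndarray) -> np.ndarray:
        """Plateau part: g_vacuum outside the slab, g_bulk inside."""
        t = (np.abs(z) - (self.z_interface - self.w_switch)) / (2.0 * self.w_switch)
        s = 1.0 - _smoothstep(t)  # 1 inside the slab, 0 in vacuum
        return self.g_vacuum + (self.g_bulk - self.g_vacuum) * s

    def _wells(self, z: np.ndarray, amplitude: float) -> np.ndarray:
        w2 = 2.0 * self.w_interface**2
        return -amplitude * (
            np.exp(-((z - self.z_interface) ** 2) / w2)
            + np.exp(-((z + self.z_interface) ** 2) / w2)
        )

    def _value_with_amplitude(self, z: np.ndarray, amplitude: float) -> np.ndarray:
        return self._baseline(z) + self._wells(z, amplitude)

    def _min_with_amplitude(self, amplitude: float) -> float:
        # even surface: minimise on [0, z_max] (coarse grid + local refinement)
        grid = np.linspace(0.0, self.z_max, 2001)
        vals = self._value_with_amplitude(grid, amplitude)
        i = int(np.argmin(vals))
        lo = grid[max(i - 2, 0)]
        hi = grid[min(i + 2, grid.size - 1)]
        res = minimize_scalar(
            lambda x: float(self._value_with_amplitude(np.asarray(x), amplitude)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return min(float(res.fun), float(vals[i]))

    def _calibrate_well(self) -> float:
        """Solve for the Gaussian amplitude giving min G = g_surface_min."""
        plateau_min = min(self.g_vacuum, self.g_bulk)
        if self.g_surface_min >= plateau_min:
            return 0.0  # no well deeper than the plateaus: flat/plain slab
        hi = 2.0 * (plateau_min - self.g_surface_min) + 1.0
        while self._min_with_amplitude(hi) > self.g_surface_min:
            hi *= 2.0
            if hi > 1e6:  # pragma: no cover - unreachable for sane inputs
                raise RuntimeError("well calibration failed to bracket")
        return float(
            brentq(
                lambda a: self._min_with_amplitude(a) - self.g_surface_min,
                0.0,
                hi,
                xtol=1e-12,
                rtol=1e-14,
            )
        )

    # -- public surface -------------------------------------------------------

    def value(self, z):
        """G(z) in kJ/mol; ``z`` may be a scalar or array, |z| <= z_max."""
        z = np.asarray(z, dtype=float)
        if np.any(np.abs(z) > self.z_max + 1e-12):
            raise ValueError(
                f"z out of domain: |z| must be <= z_max = {self.z_max} nm"
            )
        out = self._value_with_amplitude(z, self._well_amplitude)
        return float(out) if out.ndim == 0 else out

    def gradient(self, z):
        """dG/dz in kJ mol^-1 nm^-1 (no domain check: used in tight loops)."""
        z = np.asarray(z, dtype=float)
        if self._well_amplitude == 0.0 and self.g_bulk == self.g_vacuum:
            out = np.zeros_like(z)
            return float(out) if out.ndim == 0 else out
        t = (np.abs(z) - (self.z_interface - self.w_switch)) / (2.0 * self.w_switch)
        ds = -_smoothstep_deriv(t) / (2.0 * self.w_switch) * np.sign(z)
        grad = (self.g_bulk - self.g_vacuum) * ds
        a = self._well_amplitude
        if a != 0.0:
            w2 = self.w_interface**2
            zm = z - self.z_interface
            zp = z + self.z_interface
            grad = grad + a * (
                zm / w2 * np.exp(-(zm**2) / (2.0 * w2))
                + zp / w2 * np.exp(-(zp**2) / (2.0 * w2))
            )
        return float(grad) if grad.ndim == 0 else grad

    @property
    def well_amplitude(self) -> float:
        """Calibrated Gaussian well amplitude in kJ/mol (0 for no well)."""
        return self._well_amplitude

    def is_flat(self) -> bool:
        return (
            self.g_bulk == self.g_vacuum == self.g_surface_min
        ) and self._well_amplitude == 0.0


def pmf_value(model: PotentialModel, z):
    """Free energy G(z) of ``model`` at reaction coordinate ``z`` (nm)."""
    return model.value(z)


def pmf_gradient(model: PotentialModel, z):
    """Derivative dG/dz of ``model`` at ``z`` (nm)."""
    return model.gradient(z)
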