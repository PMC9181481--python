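"""Umbrella-sampling window placement and per-window sample containers.

The placement scheme reproduces the multi-solute design used for slab
free-energy calculations: each replicate restrains ``n_positions`` solutes
simultaneously, spaced ``position_spacing`` apart along z, and successive
replicates shift the whole comb by ``position_spacing / n_replicates`` so
that the union of all replicates tiles the coordinate uniformly.  Seven
positions spaced 1 nm over [-3.5, 3.5] nm with 12 replicates give the
canonical 84 windows spaced 1/12 nm; 20 replicates give a 0.05 nm spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "UmbrellaWindow",
    "WindowScheme",
    "make_window_scheme",
    "discard_equilibration",
]


@dataclass(frozen=True)
class UmbrellaWindow:
    """One biased simulation: harmonic restraint plus its z time series.

    The bias is U(z) = k/2 (z - center)^2 with ``force_constant`` k in
    kJ mol^-1 nm^-2 and ``center`` in nm.  ``samples`` holds the ordered
    reaction-coordinate values (nm); ``n_equilibration`` records how many
    leading samples were discarded before analysis.
    """

    center: float
    force_constant: float
    samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_equilibration: int = 0

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float).ravel()
        )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    def bias_energy(self, z):
        """Restraint energy k/2 (z - z0)^2 in kJ/mol."""
        z = np.asarray(z, dtype=float)
        return 0.5 * self.force_constant * (z - self.center) ** 2


@dataclass(frozen=True)
class WindowScheme:
    """Grid of restraint centres from offset replicates of a solute comb."""

    n_positions: int
    position_spacing: float
    n_replicates: int
    z_min: float
    z_max: float

    def __post_init__(self) -> None:
        if self.n_positions <= 0 or self.n_replicates <= 0:
            raise ValueError("n_positions and n_replicates must be positive")
        if self.position_spacing <= 0:
            raise ValueError("position_spacing must be positive")
        span = self.z_max - self.z_min
        if self.n_positions * self.position_spacing > span + self.position_spacing + 1e-9:
            raise ValueError(
                "scheme does not fit: n_positions * position_spacing exceeds "
                f"[{self.z_min}, {self.z_max}]"
            )

    @property
    def offset_step(self) -> float:
        """Per-replicate shift delta = position_spacing / n_replicates (nm)."""
        return self.position_spacing / self.n_replicates

    @property
    def offsets(self) -> np.ndarray:
        """Per-replicate shifts r * delta, r = 0 .. n_replicates-1 (nm)."""
        return np.arange(self.n_replicates) * self.offset_step

    @property
    def n_windows(self) -> int:
        return self.n_positions * self.n_replicates

    def centers(self) -> np.ndarray:
        """All window centres, ordered replicate-major then position."""
        j = np.arange(self.n_positions) * self.position_spacing
        r = self.offsets
        return (self.z_min + j[None, :] + r[:, None]).ravel()

    def replicate_ids(self) -> np.ndarray:
        """Replicate index of each centre, aligned with :meth:`centers`."""
        return np.repeat(np.arange(self.n_replicates), self.n_positions)


def make_window_scheme(
    n_positions: int,
    position_spacing: float,
    n_replicates: int,
    z_min: float,
    z_max: float,
) -> WindowScheme:
    """Build the offset-replicate window grid.

    Centres are ``z_min + j*position_spacing + r*delta`` for position j and
    replicate r, with ``delta = position_spacing / n_replicates``; the sorted
    centres are uniformly spaced by delta and number
    ``n_positions * n_replicates`` in total.
    """
    return WindowScheme(n_positions, position_spacing, n_replicates, z_min, z_max)


def discard_equilibration(window: UmbrellaWindow, fraction: float = 1.0 / 3.0) -> UmbrellaWindow:
    """Drop the leading ``fraction`` of a window's samples as equilibration.

    The default 1/3 matches the convention of analysing the last two thirds
    of each biased run (e.g. the last 4 ns of a 6 ns window).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    n_drop = math.floor(fraction * window.n_samples)
    return replace(
        window,
        samples=window.samples[n_drop:],
        n_equilibration=window.n_equilibration + n_drop,
    )
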