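"""Free-energy profile container plus referencing and symmetrization.

Profiles live on a uniform bin-centre grid; bins never visited by any window
carry NaN rather than an interpolated value, and downstream consumers
(referencing, landmark extraction) are required to tolerate these gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["FreeEnergyProfile", "ReferencingError", "set_reference", "symmetrize"]


class ReferencingError(ValueError):
    """The requested reference region contains no defined bins."""


@dataclass(frozen=True)
class FreeEnergyProfile:
    """1D free energy profile G(z).

    Attributes
    ----------
    z : ndarray
        Bin centres in nm (uniform, ascending).
    g : ndarray
        Free energy per bin in kJ/mol; NaN marks unvisited bins.
    temperature : float
        Temperature (K) at which the profile was constructed.
    reference : str or None
        Label of the zero convention (e.g. ``"vacuum-plateau"``); None while
        the profile still carries the arbitrary WHAM gauge.
    se : ndarray or None
        Optional per-bin bootstrap standard error in kJ/mol.
    meta : dict
        Provenance (bin width, tolerance, iterations, seed, ...).
    """

    z: np.ndarray
    g: np.ndarray
    temperature: float = 300.0
    reference: str | None = None
    se: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if z.shape != g.shape or z.ndim != 1:
            raise ValueError("z and g must be 1D arrays of equal length")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "g", g)
        if self.se is not None:
            se = np.asarray(self.se, dtype=float)
            if se.shape != z.shape:
                raise ValueError("se must match the grid")
            object.__setattr__(self, "se", se)

    @property
    def occupied(self) -> np.ndarray:
        """Boolean mask of bins with a defined free energy."""
        return np.isfinite(self.g)

    @property
    def bin_width(self) -> float:
        return float(self.z[1] - self.z[0]) if self.z.size > 1 else np.nan

    def region_mask(self, region: tuple[float, float]) -> np.ndarray:
        """Mask of bins with |z| inside the closed interval ``region``.

        Regions are specified on |z| because the slab has two equivalent
        interfaces; (3.0, 3.5) selects both vacuum plateaus.
        """
        lo, hi = region
        if hi < lo:
            raise ValueError(f"invalid region ({lo}, {hi})")
        a = np.abs(self.z)
        return (a >= lo - 1e-12) & (a <= hi + 1e-12)

    def to_dataframe(self):
        import pandas as pd

        d = {"z": self.z, "g": self.g}
        if self.se is not None:
            d["se"] = self.se
        return pd.DataFrame(d)


def set_reference(
    profile: FreeEnergyProfile,
    region: tuple[float, float] = (3.0, 3.5),
    label: str = "vacuum-plateau",
) -> FreeEnergyProfile:
    """Shift the profile so the mean over ``region`` (on |z|) is zero.

    The gas phase is the conventional zero of interfacial free energy
    changes, so the default region is the vacuum plateau |z| >= 3 nm.  The
    unweighted mean of the defined bins in the region is subtracted.
    """
    mask = profile.region_mask(region) & profile.occupied
    if not np.any(mask):
        raise ReferencingError(
            f"reference region |z| in [{region[0]}, {region[1]}] nm contains "
            "no occupied bins"
        )
    shift = float(np.mean(profile.g[mask]))
    meta = dict(profile.meta, reference_region=tuple(region))
    return replace(profile, g=profile.g - shift, reference=label, meta=meta)


def symmetrize(profile: FreeEnergyProfile) -> FreeEnergyProfile:
    """Average G(z) and G(-z); the two slab interfaces are equivalent.

    The grid must be symmetric about z = 0.  Where only one of the mirrored
    bins is defined its value is used unchanged; the operation is idempotent
    and reduces statistical noise on symmetric surfaces.
    """
    z = profile.z
    if not np.allclose(z + z[::-1], 0.0, atol=1e-9):
        raise ValueError("grid is not symmetric about z = 0; cannot mirror")
    import warnings as _warnings

    g_rev = profile.g[::-1]
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN mirror pairs
        g_sym = np.nanmean(np.vstack([profile.g, g_rev]), axis=0)
        se = profile.se
        if se is not None:
            # conservative: mirror-average the se, no independence reduction
            se = np.nanmean(np.vstack([se, se[::-1]]), axis=0)
    return replace(profile, g=g_sym, se=se, meta=dict(profile.meta, symmetrized=True))
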