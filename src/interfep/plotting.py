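"""Minimal profile plotting (free energy vs z with an error band)."""

from __future__ import annotations

import numpy as np

from .profiles import FreeEnergyProfile

__all__ = ["plot_profile"]


def plot_profile(profile: FreeEnergyProfile, ax=None, label=None, color=None):
    """Plot G(z); shades ±se if bootstrap errors are attached."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    m = profile.occupied
    (line,) = ax.plot(profile.z[m], profile.g[m], label=label, color=color)
    if profile.se is not None:
        se = np.where(np.isfinite(profile.se), profile.se, 0.0)
        ax.fill_between(
            profile.z[m],
            profile.g[m] - se[m],
            profile.g[m] + se[m],
            alpha=0.3,
            color=line.get_color(),
        )
    ax.axhline(0.0, lw=0.5, color="grey")
    ax.set_xlabel("z (nm)")
    ax.set_ylabel(r"$\Delta G$ (kJ/mol)")
    if label:
        ax.legend()
    return ax
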