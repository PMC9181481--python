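"""Plain-text umbrella-sampling file formats.

Two conventions are supported, matching what standard WHAM tools consume:

* per-window time-series files — '#'-prefixed header lines followed by two
  whitespace-separated columns (time/index, z in nm); a single-column file
  of z values is also accepted;
* a metadata file — one line per window: ``path  center  force_constant``
  (path relative to the metadata file), '#' comments allowed.

Profiles are written as tab-separated (z, G[, se]) tables whose '#' header
records temperature, bin width, tolerance and seed, i.e. enough provenance
to re-run the stage that produced them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .profiles import FreeEnergyProfile
from .windows import UmbrellaWindow

__all__ = [
    "write_window",
    "read_timeseries",
    "write_windows",
    "read_windows",
    "write_profile",
    "read_profile",
]


def write_window(path, window: UmbrellaWindow, dt_per_sample: float = 1.0,
                 header_extra: dict | None = None) -> None:
    """Write one window's time series as (time, z) text columns."""
    path = Path(path)
    lines = [
        f"# umbrella window: center = {window.center:.10g} nm, "
        f"force_constant = {window.force_constant:.10g} kJ/mol/nm^2",
        f"# n_equilibration = {window.n_equilibration}",
    ]
    for k, v in (header_extra or {}).items():
        lines.append(f"# {k} = {v}")
    t = np.arange(window.n_samples) * dt_per_sample
    body = "\n".join(
        f"{ti:.10g}\t{zi:.10g}" for ti, zi in zip(t, window.samples)
    )
    path.write_text("\n".join(lines) + "\n" + body + ("\n" if body else ""))


def read_timeseries(path) -> np.ndarray:
    """Read reaction-coordinate samples; last column if two, else the only one."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size == 0:
        return np.empty(0)
    return data[:, -1] if data.shape[1] >= 2 else data[:, 0]


def write_windows(
    out_dir,
    windows: Sequence[UmbrellaWindow],
    metadata_name: str = "metadata.txt",
    dt_per_sample: float = 1.0,
    header_extra: dict | None = None,
) -> Path:
    """Write per-window files plus the metadata index; returns metadata path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_lines = ["# file  center(nm)  force_constant(kJ/mol/nm^2)"]
    for k, v in (header_extra or {}).items():
        meta_lines.append(f"# {k} = {v}")
    for i, w in enumerate(windows):
        fname = f"window_{i:03d}.dat"
        write_window(out_dir / fname, w, dt_per_sample, header_extra)
        meta_lines.append(f"{fname}\t{w.center:.10g}\t{w.force_constant:.10g}")
    meta_path = out_dir / metadata_name
    meta_path.write_text("\n".join(meta_lines) + "\n")
    return meta_path


def read_windows(metadata_path) -> list[UmbrellaWindow]:
    """Load windows listed in a metadata file (paths relative to it)."""
    metadata_path = Path(metadata_path)
    base = metadata_path.parent
    windows: list[UmbrellaWindow] = []
    for raw in metadata_path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"bad metadata line (need path center k): {raw!r}")
        rel, center, k = parts[0], float(parts[1]), float(parts[2])
        ts_path = Path(rel)
        if not ts_path.is_absolute():
            ts_path = base / ts_path
        if not ts_path.exists():
            raise FileNotFoundError(f"time-series file not found: {ts_path}")
        samples = read_timeseries(ts_path)
        windows.append(UmbrellaWindow(center=center, force_constant=k, samples=samples))
    if not windows:
        raise ValueError(f"no windows listed in {metadata_path}")
    return windows


def write_profile(path, profile: FreeEnergyProfile, seed=None) -> None:
    """Write a (z, G[, se]) tab-separated profile with a provenance header."""
    path = Path(path)
    meta = profile.meta
    lines = [
        "# free energy profile",
        f"# temperature = {profile.temperature:.10g} K",
        f"# bin_width = {meta.get('bin_width', float('nan')):.10g} nm",
        f"# tol = {meta.get('tol', float('nan')):.10g} kJ/mol",
        f"# n_iter = {meta.get('n_iter', 'NA')}",
        f"# residual = {meta.get('residual', float('nan')):.10g}",
        f"# reference = {profile.reference}",
        f"# symmetrized = {meta.get('symmetrized', False)}",
    ]
    if seed is not None:
        lines.append(f"# seed = {seed}")
    if "n_boot" in meta:
        lines.append(f"# n_boot = {meta['n_boot']} (seed {meta.get('bootstrap_seed')})")
    cols = "z(nm)\tG(kJ/mol)" + ("\tse(kJ/mol)" if profile.se is not None else "")
    lines.append("# " + cols)
    for i in range(profile.z.size):
        row = f"{profile.z[i]:.10g}\t{profile.g[i]:.10g}"
        if profile.se is not None:
            row += f"\t{profile.se[i]:.10g}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def read_profile(path) -> FreeEnergyProfile:
    """Read a profile written by :func:`write_profile`."""
    path = Path(path)
    meta: dict = {}
    reference = None
    temperature = 300.0
    rows = []
    for raw in path.read_text().splitlines():
        s = raw.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s.lstrip("# ").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key, val = key.strip(), val.strip()
                if key == "temperature":
                    temperature = float(val.split()[0])
                elif key == "reference":
                    reference = None if val == "None" else val
                elif key in ("bin_width", "tol", "residual"):
                    meta[key] = float(val.split()[0])
                elif key == "symmetrized":
                    meta[key] = val == "True"
            continue
        rows.append([float(x) for x in s.split()])
    arr = np.asarray(rows)
    se = arr[:, 2] if arr.shape[1] >= 3 else None
    return FreeEnergyProfile(
        z=arr[:, 0], g=arr[:, 1], temperature=temperature,
        reference=reference, se=se, meta=meta,
    )
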