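"""Weighted histogram analysis method (WHAM) for 1D umbrella sampling.

Given windows i with bias U_i(z) = k_i/2 (z - z0_i)^2, bin counts h_i(b) and
totals N_i, the self-consistent WHAM equations are iterated to a fixed point:

    P(z_b) = sum_i h_i(b) / sum_i N_i exp((f_i - U_i(z_b)) / RT)
    f_i    = -RT ln sum_b P(z_b) exp(-U_i(z_b) / RT)

with P normalised over occupied bins each sweep; the unbiased profile is
G(z_b) = -RT ln P(z_b).  Iteration stops when max_i |Δf_i| < tol.  The
estimator is deterministic (f initialised to 0, no randomness).

Two numerical choices matter with stiff restraints (a 2000 kJ mol^-1 nm^-2
bias at 300 K confines a window to sd 0.035 nm): bins must be comfortably
narrower than that sd (default 0.01 nm) and the bias factor exp(-U_i/RT) is
averaged analytically over each bin (an erf expression) rather than being
evaluated at the bin centre — at coarse resolution the centre-value variant
distorts well depths by ~0.5 kJ/mol or more.  The self-consistent iteration
is warm-started at the maximum of the equivalent concave WHAM
log-likelihood (L-BFGS), after which only a short polishing iteration is
needed to reach the fixed-point tolerance.

The module also provides the modelling-object surface: ``UmbrellaSampling``
holds the windows and binning and ``fit()`` returns ``WHAMResults`` with the
referenced, optionally symmetrized profile, the window free energies,
convergence diagnostics, bootstrap errors and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import kT
from .profiles import FreeEnergyProfile, set_reference, symmetrize
from .windows import UmbrellaWindow, discard_equilibration

__all__ = [
    "HistogramSet",
    "WhamError",
    "ConvergenceError",
    "build_histograms",
    "wham_solve",
    "bootstrap_profile",
    "UmbrellaSampling",
    "WHAMResults",
]


class WhamError(RuntimeError):
    """Invalid WHAM input (empty windows, disconnected overlap, ...)."""


class ConvergenceError(WhamError):
    """The self-consistent iteration did not reach the tolerance."""

    def __init__(self, msg: str, residual: float, n_iter: int):
        super().__init__(msg)
        self.residual = residual
        self.n_iter = n_iter


@dataclass(frozen=True)
class HistogramSet:
    """Per-window bin counts on a shared uniform grid."""

    bin_edges: np.ndarray          # (B+1,) ascending, uniform
    counts: np.ndarray             # (W, B) integer counts
    n_samples: np.ndarray          # (W,) in-range totals per window
    out_of_range: np.ndarray       # (W,) samples outside the grid

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_windows(self) -> int:
        return int(self.counts.shape[0])

    def out_of_range_fraction(self) -> float:
        total = self.n_samples.sum() + self.out_of_range.sum()
        return float(self.out_of_range.sum() / total) if total else 0.0

    def subset(self, idx: Sequence[int]) -> "HistogramSet":
        idx = np.asarray(idx, dtype=int)
        return HistogramSet(
            self.bin_edges, self.counts[idx], self.n_samples[idx], self.out_of_range[idx]
        )


def build_histograms(
    windows: Sequence[UmbrellaWindow],
    bin_width: float,
    z_range: tuple[float, float],
) -> HistogramSet:
    """Histogram every window's samples on a common uniform grid.

    The grid covers ``z_range`` with bins of exactly ``bin_width`` (the upper
    edge is extended to a whole number of bins if needed).  Samples outside
    the grid are counted per window and reported, not silently dropped.
    A window with zero in-range samples is an error, naming the window.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = z_range
    if hi <= lo:
        raise ValueError("empty z_range")
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-9))
    edges = lo + bin_width * np.arange(n_bins + 1)

    counts = np.zeros((len(windows), n_bins), dtype=np.int64)
    totals = np.zeros(len(windows), dtype=np.int64)
    out = np.zeros(len(windows), dtype=np.int64)
    for i, w in enumerate(windows):
        s = w.samples
        if s.size == 0:
            raise WhamError(
                f"window {i} (center {w.center:+.3f} nm) has no samples"
            )
        c, _ = np.histogram(s, bins=edges)
        counts[i] = c
        totals[i] = c.sum()
        out[i] = s.size - c.sum()
        if totals[i] == 0:
            raise WhamError(
                f"window {i} (center {w.center:+.3f} nm) has no samples inside "
                f"[{edges[0]:.3f}, {edges[-1]:.3f}] nm"
            )
    return HistogramSet(edges, counts, totals, out)


def _check_overlap(hist: HistogramSet, centers: np.ndarray) -> None:
    """Warn on weak neighbour overlap; error on a disconnected overlap graph."""
    occ = hist.counts > 0
    n = hist.n_windows
    order = np.argsort(centers)
    # union-find over windows sharing at least one occupied bin
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n):
        for b in range(a + 1, n):
            if np.any(occ[a] & occ[b]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    roots = {find(i) for i in range(n)}
    if len(roots) > 1:
        srt = centers[order]
        gaps = []
        for j in range(n - 1):
            a, b = order[j], order[j + 1]
            if find(a) != find(b):
                gaps.append(f"[{srt[j]:+.3f}, {srt[j+1]:+.3f}] nm")
        raise WhamError(
            "window overlap graph is disconnected; no mutually occupied bins "
            "across " + ", ".join(gaps)
        )
    for j in range(n - 1):
        a, b = order[j], order[j + 1]
        if not np.any(occ[a] & occ[b]):
            warnings.warn(
                f"adjacent windows at {centers[a]:+.3f} and {centers[b]:+.3f} nm "
                "share no occupied bin; profile relies on indirect overlap",
                stacklevel=3,
            )


def _bias_factors(
    edges: np.ndarray, centers: np.ndarray, ks: np.ndarray, rt: float
) -> np.ndarray:
    """Bin-averaged bias Boltzmann factors c[i, b] = <exp(-U_i/RT)>_bin.

    For harmonic biases the average over a bin is an erf expression; for a
    zero force constant it is exactly 1.  Averaging (rather than sampling
    the bin centre) keeps WHAM unbiased when the bins are not much narrower
    than the biased distributions.
    """
    from scipy.special import erf

    width = edges[1] - edges[0]
    c = np.ones((centers.size, edges.size - 1))
    biased = ks > 0
    if np.any(biased):
        a = np.sqrt(0.5 * ks[biased, None] / rt)          # (Wb, 1)
        lo = a * (edges[None, :-1] - centers[biased, None])
        hi = a * (edges[None, 1:] - centers[biased, None])
        with np.errstate(under="ignore"):
            c[biased] = np.sqrt(np.pi) / 2.0 * (erf(hi) - erf(lo)) / (a * width)
    return c


def _likelihood_warm_start(
    c: np.ndarray, n_i: np.ndarray, pooled: np.ndarray, rt: float, f0: np.ndarray
) -> np.ndarray:
    """Maximise the concave WHAM log-likelihood in the window free energies.

    Solves max_x sum_i N_i x_i - sum_b H_b ln(sum_i N_i e^{x_i} c_ib) with
    x_i = f_i / RT (deterministic; the fixed point of the self-consistent
    iteration is the stationary point of this objective).  Used purely as a
    warm start: the caller still polishes with the fixed-point iteration
    until the max |Δf_i| tolerance is met.
    """
    from scipy.optimize import minimize

    occ = pooled > 0
    h = pooled[occ]
    cb = c[:, occ]

    def neg_like(x):
        with np.errstate(under="ignore", divide="ignore"):
            w = n_i * np.exp(x)
            denom = w @ cb
            good = denom > 0
            val = -(n_i @ x) + h[good] @ np.log(denom[good])
            # d/dx_j: -N_j + sum_b h_b w_j c_jb / denom_b
            grad = -n_i + w * (cb[:, good] @ (h[good] / denom[good]))
        return val, grad

    res = minimize(
        neg_like, f0 / rt, jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    x = res.x - res.x[0]
    return x * rt


def wham_solve(
    hist: HistogramSet,
    centers: Sequence[float],
    force_constants: Sequence[float],
    temperature: float = 300.0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    f_init: np.ndarray | None = None,
    check_overlap: bool = True,
    warm_start: bool = True,
) -> FreeEnergyProfile:
    """Iterate the WHAM equations to self-consistency.

    Returns the profile in the solver's own gauge (un-referenced); iteration
    count and final residual are recorded in ``profile.meta``.  ``f_init``
    may pre-set the window free energies (used by the bootstrap);
    ``warm_start=False`` skips the likelihood maximisation and runs the
    plain fixed-point iteration from ``f_init``/zero.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    centers = np.asarray(centers, dtype=float)
    ks = np.asarray(force_constants, dtype=float)
    if centers.size != hist.n_windows or ks.size != hist.n_windows:
        raise ValueError("centers/force_constants must match histogram windows")
    if check_overlap:
        _check_overlap(hist, centers)

    rt = kT(temperature)
    zb = hist.bin_centers
    c = _bias_factors(hist.bin_edges, centers, ks, rt)

    pooled = hist.counts.sum(axis=0).astype(float)
    occ = pooled > 0
    n_i = hist.n_samples.astype(float)
    f = np.zeros(hist.n_windows) if f_init is None else np.asarray(f_init, float).copy()
    if warm_start:
        f = _likelihood_warm_start(c, n_i, pooled, rt, f)

    residual = np.inf
    n_iter = 0
    with np.errstate(under="ignore", divide="ignore"):
        for n_iter in range(1, max_iter + 1):
            efrt = np.exp(f / rt)
            denom = (n_i * efrt) @ c            # (B,)
            p = np.where(occ, pooled / np.where(denom > 0, denom, 1.0), 0.0)
            p /= p.sum()
            f_new = -rt * np.log(c @ p)
            residual = float(np.max(np.abs(f_new - f)))
            f = f_new
            if residual < tol:
                break
        else:
            raise ConvergenceError(
                f"WHAM did not converge in {max_iter} iterations "
                f"(residual {residual:.3g} kJ/mol > tol {tol:g})",
                residual,
                max_iter,
            )
        g = np.where(occ, -rt * np.log(np.where(occ, p, 1.0)), np.nan)

    meta = {
        "temperature": temperature,
        "bin_width": float(zb[1] - zb[0]) if zb.size > 1 else np.nan,
        "tol": tol,
        "n_iter": n_iter,
        "residual": residual,
        "window_free_energies": f,
        "out_of_range_fraction": hist.out_of_range_fraction(),
    }
    return FreeEnergyProfile(z=zb, g=g, temperature=temperature, meta=meta)


def bootstrap_profile(
    windows: Sequence[UmbrellaWindow],
    bin_width: float,
    z_range: tuple[float, float],
    temperature: float = 300.0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    n_boot: int = 50,
    seed: int = 0,
    reference_region: tuple[float, float] = (3.0, 3.5),
    do_symmetrize: bool = True,
    boot_tol: float | None = None,
) -> FreeEnergyProfile:
    """Window-level bootstrap of the whole WHAM pipeline.

    Whole windows are resampled with replacement (mirroring the independently
    repeated biased runs), WHAM is re-solved, referenced and optionally
    symmetrized per resample, and the per-bin standard deviation across
    resamples becomes the profile ``se``.  Requires ``n_boot >= 20``.

    The resample solves run at ``boot_tol`` (default ``max(tol, 1e-5)``
    kJ/mol): the se is a statistical quantity of order 0.01-1 kJ/mol, so
    resolving each resample to the main solve's 1e-7 gauge is wasted effort,
    and resamples with thinned coverage converge slowly.
    """
    if n_boot < 20:
        raise ValueError(f"n_boot must be >= 20, got {n_boot}")
    if boot_tol is None:
        boot_tol = max(tol, 1e-5)
    centers = np.array([w.center for w in windows])
    ks = np.array([w.force_constant for w in windows])
    hist = build_histograms(windows, bin_width, z_range)
    main = wham_solve(hist, centers, ks, temperature, tol, max_iter)
    f_warm = main.meta["window_free_energies"]
    main = set_reference(main, reference_region)
    if do_symmetrize:
        main = symmetrize(main)

    rng = np.random.default_rng(seed)
    n = len(windows)
    boots = np.full((n_boot, main.z.size), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            prof = wham_solve(
                hist.subset(idx),
                centers[idx],
                ks[idx],
                temperature,
                boot_tol,
                max_iter,
                f_init=f_warm[idx],
                check_overlap=False,
            )
            prof = set_reference(prof, reference_region)
            if do_symmetrize:
                prof = symmetrize(prof)
        except WhamError as exc:
            raise WhamError(f"bootstrap resample {b}: {exc}") from exc
        boots[b] = prof.g
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        se = np.nanstd(boots, axis=0, ddof=1)
    se = np.where(np.isfinite(main.g), se, np.nan)
    meta = dict(main.meta, n_boot=n_boot, bootstrap_seed=seed)
    return replace(main, se=se, meta=meta)


# --------------------------------------------------------------------------
# modelling-object surface
# --------------------------------------------------------------------------


class UmbrellaSampling:
    """Umbrella-sampling free-energy model over a set of biased windows.

    Parameters
    ----------
    windows : sequence of UmbrellaWindow
        Biased reaction-coordinate time series (already equilibrated or use
        ``equilibration_fraction`` in :meth:`fit`).
    temperature : float
        Temperature in K (default 300, the thermostat setting).
    bin_width : float
        Histogram bin width in nm (default 0.01; must be comfortably
        narrower than the biased-window sd, 0.035 nm for k = 2000 at 300 K).
    z_range : tuple
        Coordinate range covered by the histogram grid.
    replicate_ids : array-like, optional
        Replicate/group label per window, used by ``combine="mean"``.

    Examples
    --------
    >>> model = UmbrellaSampling(windows, temperature=300.0)
    >>> res = model.fit()
    >>> res.profile.g  # referenced, symmetrized free energies
    """

    def __init__(
        self,
        windows: Sequence[UmbrellaWindow],
        temperature: float = 300.0,
        bin_width: float = 0.01,
        z_range: tuple[float, float] = (-3.6, 3.6),
        replicate_ids: Sequence[int] | None = None,
    ):
        if not windows:
            raise ValueError("need at least one window")
        self.windows = list(windows)
        self.temperature = float(temperature)
        self.bin_width = float(bin_width)
        self.z_range = (float(z_range[0]), float(z_range[1]))
        self.replicate_ids = (
            None if replicate_ids is None else np.asarray(replicate_ids, dtype=int)
        )

    @classmethod
    def from_metadata(
        cls,
        metadata_path,
        temperature: float = 300.0,
        bin_width: float = 0.01,
        z_range: tuple[float, float] = (-3.6, 3.6),
        equilibration_fraction: float = 0.0,
    ) -> "UmbrellaSampling":
        """Build the model from a WHAM-style metadata file on disk."""
        from .io import read_windows

        windows = read_windows(metadata_path)
        if equilibration_fraction:
            windows = [discard_equilibration(w, equilibration_fraction) for w in windows]
        return cls(windows, temperature, bin_width, z_range)

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.center for w in self.windows])

    @property
    def force_constants(self) -> np.ndarray:
        return np.array([w.force_constant for w in self.windows])

    def fit(
        self,
        tol: float = 1e-7,
        max_iter: int = 100_000,
        reference_region: tuple[float, float] = (3.0, 3.5),
        do_symmetrize: bool = True,
        combine: str = "pooled",
        n_groups: int = 2,
    ) -> "WHAMResults":
        """Solve WHAM and return referenced (and symmetrized) results.

        ``combine="pooled"`` (default) solves one WHAM over all windows.
        ``combine="mean"`` partitions the windows into interleaved offset
        groups that each still span the full coordinate range, solves and
        references each group separately and averages the per-group profiles
        (the per-replicate-averaging reading of multi-replicate setups).
        """
        if combine == "pooled":
            hist = build_histograms(self.windows, self.bin_width, self.z_range)
            raw = wham_solve(
                hist, self.centers, self.force_constants, self.temperature, tol, max_iter
            )
            profile = set_reference(raw, reference_region)
            if do_symmetrize:
                profile = symmetrize(profile)
        elif combine == "mean":
            profile, raw = self._fit_mean(
                tol, max_iter, reference_region, do_symmetrize, n_groups
            )
        else:
            raise ValueError(f"unknown combine mode: {combine!r}")
        return WHAMResults(
            self, profile, raw, reference_region=reference_region,
            symmetrized=do_symmetrize, tol=tol, max_iter=max_iter,
        )

    def _groups(self, n_groups: int) -> list[np.ndarray]:
        """Interleaved window groups, each spanning the full z range."""
        if self.replicate_ids is not None:
            rep = self.replicate_ids
            labels = np.unique(rep)
            return [
                np.flatnonzero(np.isin(rep, labels[labels % n_groups == m]))
                for m in range(n_groups)
            ]
        order = np.argsort(self.centers)
        return [order[m::n_groups] for m in range(n_groups)]

    def _fit_mean(self, tol, max_iter, reference_region, do_symmetrize, n_groups):
        profiles = []
        raw = None
        for idx in self._groups(n_groups):
            sub = [self.windows[i] for i in idx]
            hist = build_histograms(sub, self.bin_width, self.z_range)
            r = wham_solve(
                hist,
                self.centers[idx],
                self.force_constants[idx],
                self.temperature,
                tol,
                max_iter,
            )
            raw = r
            p = set_reference(r, reference_region)
            if do_symmetrize:
                p = symmetrize(p)
            profiles.append(p.g)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            g = np.nanmean(np.vstack(profiles), axis=0)
        meta = dict(raw.meta, combine="mean", n_groups=len(profiles))
        prof = FreeEnergyProfile(
            z=raw.z, g=g, temperature=self.temperature,
            reference="vacuum-plateau", meta=meta,
        )
        return prof, raw

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"UmbrellaSampling(n_windows={len(self.windows)}, "
            f"T={self.temperature} K, bin_width={self.bin_width} nm)"
        )


class WHAMResults:
    """Fitted free-energy profile plus diagnostics.

    Attributes
    ----------
    profile : FreeEnergyProfile
        Referenced (and, by default, symmetrized) free-energy profile.
    raw_profile : FreeEnergyProfile
        Profile in the solver gauge before referencing.
    window_free_energies : ndarray
        Converged per-window free energies f_i (kJ/mol).
    n_iter, residual : int, float
        Iteration count and final max |Δf| (kJ/mol).
    """

    def __init__(self, model, profile, raw_profile, reference_region, symmetrized,
                 tol, max_iter):
        self.model = model
        self.profile = profile
        self.raw_profile = raw_profile
        self.reference_region = reference_region
        self.symmetrized = symmetrized
        self.tol = tol
        self.max_iter = max_iter

    @property
    def window_free_energies(self) -> np.ndarray:
        return self.raw_profile.meta["window_free_energies"]

    @property
    def n_iter(self) -> int:
        return self.raw_profile.meta["n_iter"]

    @property
    def residual(self) -> float:
        return self.raw_profile.meta["residual"]

    def bootstrap(self, n_boot: int = 50, seed: int = 0) -> "WHAMResults":
        """Attach window-bootstrap standard errors to the profile."""
        self.profile = bootstrap_profile(
            self.model.windows,
            self.model.bin_width,
            self.model.z_range,
            self.model.temperature,
            self.tol,
            self.max_iter,
            n_boot=n_boot,
            seed=seed,
            reference_region=self.reference_region,
            do_symmetrize=self.symmetrized,
        )
        return self

    def landmarks(self, regions=None):
        """Extract ΔG_gs / ΔG_sl / ΔG_hydr landmarks from the profile."""
        from .landmarks import Regions, extract_landmarks

        return extract_landmarks(self.profile, regions or Regions())

    def summary(self) -> str:
        """Plain-text summary of the fit, statsmodels-style."""
        p = self.profile
        occ = int(p.occupied.sum())
        lines = [
            "Umbrella Sampling / WHAM Results",
            "=" * 40,
            f"windows:            {len(self.model.windows)}",
            f"temperature:        {self.model.temperature:.2f} K",
            f"bin width:          {self.model.bin_width:.3f} nm",
            f"occupied bins:      {occ} / {p.z.size}",
            f"iterations:         {self.n_iter}",
            f"final residual:     {self.residual:.3e} kJ/mol",
            f"reference:          {p.reference} (|z| in "
            f"[{self.reference_region[0]}, {self.reference_region[1]}] nm)",
            f"symmetrized:        {self.symmetrized}",
        ]
        try:
            lm = self.landmarks()
            lines += [
                "-" * 40,
                f"dG_gs   (gas->surface): {lm.dg_gs:+8.2f} kJ/mol at |z| = {lm.z_min:.2f} nm",
                f"dG_sl   (surface->liq): {lm.dg_sl:+8.2f} kJ/mol",
                f"dG_hydr (gas->bulk):    {lm.dg_hydr:+8.2f} kJ/mol",
            ]
        except Exception:
            lines += ["-" * 40, "landmarks: not available for this profile"]
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        """Plot the profile (with its error band if bootstrapped)."""
        from .plotting import plot_profile

        return plot_profile(self.profile, ax=ax, **kwargs)
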