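"""End-to-end orchestration: config, per-species runs, report and validation.

A run configuration describes, per species, either a synthetic generator
(the parametric interface surface with target landmark levels) or a path to
external window data, plus the global analysis settings (temperature,
binning, landmark regions, bootstrap count, base seed).  ``run_pipeline``
takes each species through generate/read → equilibration discard → WHAM →
reference → symmetrize → bootstrap → landmarks and merges the per-species
summaries into one tab-separated report; failures are isolated per species.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .io import write_profile, write_windows
from .landmarks import HenryConstant, Regions, SpeciesSummary, summarize_species
from .potential import PotentialModel
from .sampler import SamplerConfig, sample_windows
from .wham import UmbrellaSampling, WhamError
from .windows import UmbrellaWindow, discard_equilibration, make_window_scheme

__all__ = [
    "SpeciesConfig",
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "generate_species_windows",
    "validate_against_table",
    "summaries_to_report",
]

REPORT_COLUMNS = [
    "species",
    "dg_gs",
    "dg_sl",
    "dg_hydr",
    "dg_hydr_expt",
    "enhancement_surface",
    "enhancement_bulk",
    "hydro_class",
]


@dataclass(frozen=True)
class SpeciesConfig:
    """One species: either generator parameters or an external metadata path."""

    name: str
    generator: dict | None = None        # PotentialModel keyword overrides
    metadata: str | None = None          # path to external window metadata
    henry: dict | None = None            # HenryConstant fields

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.metadata is None):
            raise ValueError(
                f"species {self.name!r}: exactly one of generator/metadata required"
            )


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    species: tuple[SpeciesConfig, ...]
    temperature: float = 300.0
    bin_width: float = 0.01
    z_range: tuple[float, float] = (-3.6, 3.6)
    regions: Regions = field(default_factory=Regions)
    equilibration_fraction: float = 1.0 / 3.0
    n_boot: int = 50
    seed: int = 2022
    tol: float = 1e-7
    max_iter: int = 100_000
    combine: str = "pooled"
    scheme: dict = field(
        default_factory=lambda: {
            "n_positions": 7,
            "position_spacing": 1.0,
            "n_replicates": 12,
            "z_min": -3.5,
            "z_max": 3.5,
        }
    )
    sampler: dict = field(
        default_factory=lambda: {
            "dt": 2.5e-4,
            "diffusion": 1.0,
            "n_steps": 300_000,
            "stride": 10,
        }
    )

    # -- (de)serialisation ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["species"] = [
            {k: v for k, v in sp.items() if v is not None} for sp in d["species"]
        ]
        d["z_range"] = list(self.z_range)
        d["regions"] = {
            "vacuum": list(self.regions.vacuum),
            "interface": list(self.regions.interface),
            "bulk": list(self.regions.bulk),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        species = tuple(SpeciesConfig(**sp) for sp in d.pop("species"))
        if "regions" in d:
            d["regions"] = Regions(
                **{k: tuple(v) for k, v in d["regions"].items()}
            )
        if "z_range" in d:
            d["z_range"] = tuple(d["z_range"])
        return cls(species=species, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    summaries: list[SpeciesSummary]
    report: "object"                       # pandas DataFrame
    failures: dict[str, str]
    provenance: dict

    @property
    def ok(self) -> bool:
        return not self.failures


def generate_species_windows(
    cfg: RunConfig, sp: SpeciesConfig, species_index: int
) -> tuple[list[UmbrellaWindow], np.ndarray]:
    """Generate this species' biased windows on its parametric surface."""
    model = PotentialModel(**(sp.generator or {}))
    scheme = make_window_scheme(**cfg.scheme)
    # distinct seed block per species; window i adds its own index
    base = cfg.seed + 100_000 * species_index
    sampler = SamplerConfig(temperature=cfg.temperature, seed=base, **cfg.sampler)
    windows = [
        UmbrellaWindow(center=c, force_constant=2000.0) for c in scheme.centers()
    ]
    windows = sample_windows(model, windows, sampler)
    windows = [
        discard_equilibration(w, cfg.equilibration_fraction) for w in windows
    ]
    return windows, scheme.replicate_ids()


def _run_species(cfg: RunConfig, sp: SpeciesConfig, idx: int, out_dir: Path | None,
                 dump_windows: bool = False):
    if sp.generator is not None:
        windows, rep_ids = generate_species_windows(cfg, sp, idx)
    else:
        from .io import read_windows

        windows = read_windows(sp.metadata)
        windows = [discard_equilibration(w, cfg.equilibration_fraction) for w in windows]
        rep_ids = None
    model = UmbrellaSampling(
        windows,
        temperature=cfg.temperature,
        bin_width=cfg.bin_width,
        z_range=cfg.z_range,
        replicate_ids=rep_ids,
    )
    res = model.fit(
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        reference_region=cfg.regions.vacuum,
        combine=cfg.combine,
    )
    if cfg.n_boot:
        res = res.bootstrap(n_boot=cfg.n_boot, seed=cfg.seed + 7 * idx + 1)
    henry = HenryConstant(**sp.henry) if sp.henry else None
    summary = summarize_species(
        sp.name, res.profile, cfg.regions, cfg.temperature, henry
    )
    if out_dir is not None:
        write_profile(out_dir / f"profile_{sp.name}.tsv", res.profile, seed=cfg.seed)
        if dump_windows and sp.generator is not None:
            write_windows(
                out_dir / f"windows_{sp.name}",
                windows,
                header_extra={"seed": cfg.seed, "species": sp.name},
            )
    prov = {
        "n_windows": len(windows),
        "n_iter": res.n_iter,
        "residual": res.residual,
        "out_of_range_fraction": res.raw_profile.meta["out_of_range_fraction"],
    }
    return summary, prov


def summaries_to_report(summaries: list[SpeciesSummary]):
    """Merge species summaries into a report table (Table-1 column order)."""
    import pandas as pd

    rows = []
    for s in summaries:
        lm = s.landmarks
        rows.append(
            {
                "species": s.name,
                "dg_gs": lm.dg_gs,
                "dg_sl": lm.dg_sl,
                "dg_hydr": lm.dg_hydr,
                "dg_hydr_expt": s.dg_hydr_expt,
                "enhancement_surface": s.enhancement_surface,
                "enhancement_bulk": s.enhancement_bulk,
                "hydro_class": s.hydro_class,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def run_pipeline(cfg: RunConfig, out_dir=None, write_windows_files: bool = False):
    """Run every species through the full analysis; failures are isolated.

    Returns a :class:`PipelineResult`; when ``out_dir`` is given, writes
    per-species profiles, the merged report (``report.tsv``) and a
    machine-readable provenance log (``provenance.json``).
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    summaries: list[SpeciesSummary] = []
    failures: dict[str, str] = {}
    prov: dict = {
        "package": "interfep",
        "version": __version__,
        "seed": cfg.seed,
        "temperature": cfg.temperature,
        "bin_width": cfg.bin_width,
        "tol": cfg.tol,
        "combine": cfg.combine,
        "species": {},
    }
    for idx, sp in enumerate(cfg.species):
        try:
            summary, sp_prov = _run_species(
                cfg, sp, idx, out_path, dump_windows=write_windows_files
            )
            summaries.append(summary)
            prov["species"][sp.name] = sp_prov
        except (WhamError, ValueError, OSError) as exc:
            failures[sp.name] = str(exc)
            prov["species"][sp.name] = {"error": str(exc)}
    report = summaries_to_report(summaries)
    if out_path is not None:
        header = (
            f"# interfep report  seed={cfg.seed} T={cfg.temperature} "
            f"bin={cfg.bin_width} tol={cfg.tol} combine={cfg.combine}\n"
        )
        body = report.to_csv(sep="\t", index=False, float_format="%.10g")
        (out_path / "report.tsv").write_text(header + body)
        (out_path / "provenance.json").write_text(json.dumps(prov, indent=2))
    return PipelineResult(summaries, report, failures, prov)


# --------------------------------------------------------------------------
# validation against printed reference values
# --------------------------------------------------------------------------

TOL_IDENTITY = 0.01       # kJ/mol on dg_gs + dg_sl - dg_hydr
TOL_ENHANCEMENT = 0.01    # relative, from +/-0.005 kJ/mol print rounding


def validate_against_table(report, reference) -> "object":
    """Cell-wise comparison of a report against reference rows.

    ``report`` and ``reference`` are DataFrames with the report columns.
    Checks, per species: the additive identity |dg_gs + dg_sl − dg_hydr|
    (absolute, 0.01 kJ/mol); surface and bulk enhancements (1% relative);
    the hydrophilicity class (exact).  Returns a diff table with one row per
    (species, cell) and a boolean ``passed``.
    """
    import pandas as pd

    for df, tag in ((report, "report"), (reference, "reference")):
        missing = {"species", "dg_gs", "dg_sl", "dg_hydr"} - set(df.columns)
        if missing:
            raise ValueError(f"{tag} is missing columns: {sorted(missing)}")
    ref = reference.set_index("species")
    rows = []
    for _, r in report.iterrows():
        name = r["species"]
        if name not in ref.index:
            raise ValueError(f"species {name!r} not present in reference rows")
        t = ref.loc[name]
        ident = r["dg_gs"] + r["dg_sl"] - r["dg_hydr"]
        rows.append(
            {
                "species": name,
                "cell": "identity",
                "value": ident,
                "expected": 0.0,
                "passed": abs(ident) <= TOL_IDENTITY,
            }
        )
        for cell in ("enhancement_surface", "enhancement_bulk"):
            if cell in report.columns and cell in reference.columns:
                v, e = float(r[cell]), float(t[cell])
                rows.append(
                    {
                        "species": name,
                        "cell": cell,
                        "value": v,
                        "expected": e,
                        "passed": abs(v - e) <= TOL_ENHANCEMENT * abs(e),
                    }
                )
        if "hydro_class" in report.columns and "hydro_class" in reference.columns:
            rows.append(
                {
                    "species": name,
                    "cell": "hydro_class",
                    "value": r["hydro_class"],
                    "expected": t["hydro_class"],
                    "passed": r["hydro_class"] == t["hydro_class"],
                }
            )
    return pd.DataFrame(rows)


def reference_report():
    """The printed reference rows as a report-shaped DataFrame."""
    import pandas as pd

    from .reference_table import TABLE1

    rows = []
    for t in TABLE1:
        rows.append(
            {
                "species": t.name,
                "dg_gs": t.dg_gs,
                "dg_sl": t.dg_sl,
                "dg_hydr": t.dg_hydr,
                "dg_hydr_expt": t.dg_hydr_expt,
                "enhancement_surface": t.enhancement_surface,
                "enhancement_bulk": t.enhancement_bulk,
                "hydro_class": "hydrophilic" if t.dg_hydr < 0 else "hydrophobic",
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
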