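"""Published landmark free energies and enhancements for twelve RONS.

These are the printed reference values for plasma-generated reactive oxygen
and nitrogen species crossing a vacuum-water slab: gas-to-surface free
energy ΔG_gs, surface-to-liquid change ΔG_sl and hydration free energy
ΔG_hydr (kJ/mol, from explicit-solvent umbrella sampling at 300 K), the
Henry's-law-derived experimental hydration free energy where available, and
the surface/bulk concentration enhancements relative to the gas phase.

They serve as inputs for consistency suites (the additive identity
ΔG_hydr = ΔG_gs + ΔG_sl, Boltzmann enhancements, hydrophilicity grouping)
and as generator targets for synthetic end-to-end runs.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReferenceRow", "TABLE1", "get_row"]


@dataclass(frozen=True)
class ReferenceRow:
    name: str
    dg_gs: float
    dg_sl: float
    dg_hydr: float
    dg_hydr_expt: float | None
    enhancement_surface: float
    enhancement_bulk: float


TABLE1: tuple[ReferenceRow, ...] = (
    ReferenceRow("O3", -3.94, 7.92, 3.98, 3.46, 4.8, 0.20),
    ReferenceRow("NO", -1.21, 8.68, 7.47, 7.61, 1.6, 0.05),
    ReferenceRow("NO2", -4.66, 7.27, 2.61, 3.01, 6.4, 0.35),
    ReferenceRow("OH", -22.04, 5.53, -16.51, -17.09, 6880.9, 749.5),
    ReferenceRow("HO2", -28.97, 5.76, -23.21, -24.29, 110740.7, 10999.3),
    ReferenceRow("H2O2", -36.21, 0.45, -35.76, -36.50, 2018128.0, 1684976.9),
    ReferenceRow("N2O4", -12.70, 6.70, -6.00, -8.86, 162.7, 11.1),
    ReferenceRow("trans-HNO2", -23.06, 7.09, -15.97, -18.0, 10357.3, 603.6),
    ReferenceRow("cis-HNO2", -18.93, 7.24, -11.69, -11.2, 1977.5, 108.5),
    ReferenceRow("HNO3", -32.16, 5.29, -26.87, -36.42, 397883.2, 47714.6),
    ReferenceRow("tp-ONOOH", -26.55, 8.05, -18.50, None, 41969.4, 1664.4),
    ReferenceRow("cp-ONOOH", -25.47, 7.45, -18.02, None, 27219.6, 1373.0),
)


def get_row(name: str) -> ReferenceRow:
    for row in TABLE1:
        if row.name == name:
            return row
    raise KeyError(f"no reference row for species {name!r}")
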