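"""Material definitions for applicator components and pelvic tissues.

Electrical properties are tabulated at the 27 MHz operating frequency of the
capacitive applicators; thermal properties feed the Pennes bioheat solver.
The table ships as a packaged CSV so custom material sets can be supplied in
the same format.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

#: vacuum permittivity (F/m)
EPS0 = 8.8541878128e-12

#: operating frequency of the applicators (Hz)
DEFAULT_FREQUENCY = 27e6


@dataclass(frozen=True)
class Material:
    """Electric and thermal properties of one tissue or applicator material.

    Parameters
    ----------
    name : str
        Material name.
    sigma : float
        Electric conductivity at 27 MHz (S/m).
    eps_r : float
        Relative permittivity at 27 MHz (dimensionless).
    rho : float
        Mass density (kg/m^3).
    c : float
        Specific heat capacity (J/kg/K).
    k : float
        Thermal conductivity (W/m/K).
    perfusion : float or None
        Blood perfusion rate (mL/kg/min); ``None`` for non-tissue materials.
    """

    name: str
    sigma: float
    eps_r: float
    rho: float
    c: float
    k: float
    perfusion: float | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"{self.name}: conductivity must be >= 0")
        if self.eps_r < 1:
            raise ValueError(f"{self.name}: relative permittivity must be >= 1")
        if self.rho <= 0:
            raise ValueError(f"{self.name}: density must be > 0")
        if self.perfusion is not None and self.perfusion < 0:
            raise ValueError(f"{self.name}: perfusion must be >= 0")

    @property
    def eps(self) -> float:
        """Absolute permittivity (F/m)."""
        return self.eps_r * EPS0

    def admittivity(self, omega: float) -> complex:
        """Complex admittivity sigma + j*omega*eps (S/m) at angular frequency omega."""
        return self.sigma + 1j * omega * self.eps

    @property
    def is_tissue(self) -> bool:
        return self.perfusion is not None


def load_material_table(path=None) -> dict[str, Material]:
    """Load a material table from CSV (columns: name, rho, sigma, eps_r, c, k, perfusion).

    With no argument, the packaged default table is returned.
    """
    if path is None:
        with resources.files("thermoplan.data").joinpath("materials.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    table: dict[str, Material] = {}
    for row in df.itertuples(index=False):
        perf = None if pd.isna(row.perfusion) else float(row.perfusion)
        table[row.name] = Material(
            name=row.name,
            sigma=float(row.sigma),
            eps_r=float(row.eps_r),
            rho=float(row.rho),
            c=float(row.c),
            k=float(row.k),
            perfusion=perf,
        )
    return table


def tissue_table() -> dict[str, Material]:
    """Return the default material table (applicator materials + pelvic tissues)."""
    return load_material_table()
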