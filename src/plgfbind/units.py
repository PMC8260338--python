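"""Mass <-> molar concentration conversion for immunoassay analytes.

Automated immunoassays report sFlt-1 and PlGF in pg/mL; the equilibrium
binding equations require molar units (pmol/L).  With a molecular weight
``MW`` in Daltons (g/mol),

    pmol/L = pg/mL * 1000 / MW

since 1 pg/mL = 1 ng/L and (ng/L) / (g/mol) = nmol/L * 1e-9 -> pmol/L * 1e-3.

All internal binding math in this package is done in pmol/L; pg/mL appears
only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._exceptions import DomainError, InvalidAnalyteError

__all__ = [
    "AnalyteSpec",
    "PLGF",
    "SFLT1",
    "ANALYTES",
    "mass_to_molar",
    "molar_to_mass",
]


@dataclass(frozen=True)
class AnalyteSpec:
    """An analyte and its molecular weight in Daltons (g/mol)."""

    name: str
    molecular_weight: float

    def __post_init__(self) -> None:
        if not self.molecular_weight > 0:
            raise InvalidAnalyteError(
                f"molecular weight of {self.name!r} must be positive, "
                f"got {self.molecular_weight}"
            )


#: PlGF as detected by the free-PlGF immunoassay, taken as 34 kDa.
PLGF = AnalyteSpec("PlGF", 34_000.0)

#: Soluble Fms-like tyrosine kinase-1, taken as 100 kDa.
SFLT1 = AnalyteSpec("sFlt-1", 100_000.0)

#: Built-in analyte registry. Extensible by callers; the two defaults are fixed.
ANALYTES: dict[str, AnalyteSpec] = {"PlGF": PLGF, "sFlt-1": SFLT1}


def mass_to_molar(value_pg_ml: float, analyte: AnalyteSpec) -> float:
    """Convert a mass concentration (pg/mL) to molar concentration (pmol/L).

    Parameters
    ----------
    value_pg_ml
        Non-negative concentration in pg/mL.
    analyte
        Analyte whose molecular weight sets the conversion factor.

    Returns
    -------
    float
        Concentration in pmol/L.
    """
    if not analyte.molecular_weight > 0:
        raise InvalidAnalyteError(f"invalid molecular weight: {analyte.molecular_weight}")
    if value_pg_ml < 0:
        raise DomainError(f"mass concentration must be non-negative, got {value_pg_ml}")
    return value_pg_ml * 1000.0 / analyte.molecular_weight


def molar_to_mass(value_pmol_l: float, analyte: AnalyteSpec) -> float:
    """Convert a molar concentration (pmol/L) to mass concentration (pg/mL).

    Exact inverse of :func:`mass_to_molar`.
    """
    if not analyte.molecular_weight > 0:
        raise InvalidAnalyteError(f"invalid molecular weight: {analyte.molecular_weight}")
    if value_pmol_l < 0:
        raise DomainError(f"molar concentration must be non-negative, got {value_pmol_l}")
    return value_pmol_l * analyte.molecular_weight / 1000.0
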