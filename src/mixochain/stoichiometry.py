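"""Compound registry and electron/carbon equivalent conversions.

Every balance in this package is expressed in one of two "equivalent"
currencies:

* **carbon equivalents** (C-mmol): molar amount times the number of carbon
  atoms per molecule, and
* **electron equivalents** (e⁻-mmol): molar amount times the degree of
  reduction γ, the number of electrons a molecule releases on complete
  oxidation to CO₂ and H₂O.  For a CHO compound γ = 4·n_C + n_H − 2·n_O.

Carboxylates are booked as the undissociated acids (CnH2nO2); the molar
masses of the acids are what match reported g/L values at fermentation pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "CompoundSpec",
    "CompoundRegistry",
    "default_registry",
    "degree_of_reduction",
    "convert_concentration",
    "c_rate_to_gCO2",
    "ATOMIC_MASS",
    "CO2_MOLAR_MASS",
    "CONCENTRATION_UNITS",
]

#: Standard atomic masses (g/mol) used to derive molar masses from formulas.
ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}

#: Molar mass of CO₂ used for g-CO₂-equivalent reporting.
CO2_MOLAR_MASS = 44.01

CONCENTRATION_UNITS = ("mM", "g/L", "C-mmol/L", "e-mmol/L")

PHASES = ("dissolved", "gas")
COMPOUND_CLASSES = (
    "carboxylate",
    "alcohol",
    "gas_substrate",
    "organic_substrate",
    "other",
)


class InvalidCompoundError(ValueError):
    """Raised when a compound definition is internally inconsistent."""


@dataclass(frozen=True)
class CompoundSpec:
    """Elemental composition and bookkeeping metadata for one compound.

    Parameters
    ----------
    name:
        Registry identifier, e.g. ``"n-caproate"``.
    n_c, n_h, n_o:
        CHO atom counts of the neutral molecule (acid form for
        carboxylates).
    molar_mass:
        g/mol.  If omitted it is computed from the atom counts (plus
        ``extra_mass`` for non-CHO atoms such as the N in biomass or N₂).
    phase:
        ``"dissolved"`` or ``"gas"``.
    compound_class:
        One of ``carboxylate, alcohol, gas_substrate, organic_substrate,
        other``.
    chain_length:
        Carbon chain length used for product pooling (0 for gases and
        non-chain compounds).
    iso_flag:
        True for branched (iso-) isomers.
    extra_mass:
        Mass contribution of atoms outside C/H/O (g/mol).
    gamma_override:
        Explicit degree of reduction for compounds whose γ is not given by
        the CHO formula (e.g. N₂ at its own reference state, or biomass
        with an NH₃-referenced nitrogen correction).
    """

    name: str
    n_c: int
    n_h: int
    n_o: int
    molar_mass: float | None = None
    phase: str = "dissolved"
    compound_class: str = "other"
    chain_length: int = 0
    iso_flag: bool = False
    extra_mass: float = 0.0
    gamma_override: float | None = None

    def __post_init__(self) -> None:
        if min(self.n_c, self.n_h, self.n_o) < 0:
            raise InvalidCompoundError(f"{self.name}: negative atom count")
        if self.phase not in PHASES:
            raise InvalidCompoundError(f"{self.name}: unknown phase {self.phase!r}")
        if self.compound_class not in COMPOUND_CLASSES:
            raise InvalidCompoundError(
                f"{self.name}: unknown class {self.compound_class!r}"
            )
        if self.chain_length < 0:
            raise InvalidCompoundError(f"{self.name}: negative chain length")
        formula_mass = (
            self.n_c * ATOMIC_MASS["C"]
            + self.n_h * ATOMIC_MASS["H"]
            + self.n_o * ATOMIC_MASS["O"]
            + self.extra_mass
        )
        if self.molar_mass is None:
            object.__setattr__(self, "molar_mass", formula_mass)
        if self.molar_mass <= 0:
            raise InvalidCompoundError(f"{self.name}: molar mass must be positive")
        if abs(self.molar_mass - formula_mass) > 0.1:
            raise InvalidCompoundError(
                f"{self.name}: molar mass {self.molar_mass:.3f} differs from "
                f"formula mass {formula_mass:.3f} by more than 0.1 g/mol"
            )
        if self.gamma < 0:
            raise InvalidCompoundError(
                f"{self.name}: negative degree of reduction ({self.gamma})"
            )

    @property
    def gamma(self) -> float:
        """Degree of reduction (electrons per molecule)."""
        if self.gamma_override is not None:
            return self.gamma_override
        return 4 * self.n_c + self.n_h - 2 * self.n_o


def degree_of_reduction(spec: CompoundSpec) -> float:
    """Electrons released per molecule on full oxidation to CO₂/H₂O.

    γ = 4·n_C + n_H − 2·n_O for CHO compounds; e.g. lactate C₃H₆O₃ → 12,
    CO → 2, H₂ → 2, CO₂ → 0 (the reference state).
    """
    return spec.gamma


class CompoundRegistry:
    """Name → :class:`CompoundSpec` mapping with tabular (de)serialization."""

    def __init__(self, specs: Iterable[CompoundSpec] = ()) -> None:
        self._specs: dict[str, CompoundSpec] = {}
        for spec in specs:
            self.add(spec)

    def add(self, spec: CompoundSpec) -> None:
        if spec.name in self._specs:
            raise InvalidCompoundError(f"duplicate compound name {spec.name!r}")
        self._specs[spec.name] = spec

    def __getitem__(self, name: str) -> CompoundSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise KeyError(
                f"unknown compound {name!r}; registered: {sorted(self._specs)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def names(self) -> list[str]:
        return list(self._specs)

    def gamma(self, name: str) -> float:
        return self[name].gamma

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": s.name,
                "n_c": s.n_c,
                "n_h": s.n_h,
                "n_o": s.n_o,
                "molar_mass": s.molar_mass,
                "phase": s.phase,
                "compound_class": s.compound_class,
                "chain_length": s.chain_length,
                "iso_flag": s.iso_flag,
                "extra_mass": s.extra_mass,
                "gamma": s.gamma,
            }
            for s in self._specs.values()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CompoundRegistry":
        reg = cls()
        for row in frame.itertuples(index=False):
            gamma_formula = 4 * int(row.n_c) + int(row.n_h) - 2 * int(row.n_o)
            override = None
            if hasattr(row, "gamma") and not math.isclose(
                float(row.gamma), gamma_formula, abs_tol=1e-9
            ):
                override = float(row.gamma)
            reg.add(
                CompoundSpec(
                    name=str(row.name),
                    n_c=int(row.n_c),
                    n_h=int(row.n_h),
                    n_o=int(row.n_o),
                    molar_mass=float(row.molar_mass),
                    phase=str(row.phase),
                    compound_class=str(row.compound_class),
                    chain_length=int(row.chain_length),
                    iso_flag=bool(row.iso_flag),
                    extra_mass=float(getattr(row, "extra_mass", 0.0)),
                    gamma_override=override,
                )
            )
        return reg


def _acid(name: str, n: int, iso: bool = False) -> CompoundSpec:
    # saturated monocarboxylic acid CnH2nO2
    cls = "carboxylate"
    return CompoundSpec(name, n, 2 * n, 2, compound_class=cls, chain_length=n, iso_flag=iso)


def _alcohol(name: str, n: int) -> CompoundSpec:
    # saturated primary alcohol CnH(2n+2)O
    return CompoundSpec(name, n, 2 * n + 2, 1, compound_class="alcohol", chain_length=n)


def default_registry() -> CompoundRegistry:
    """Registry covering the full chain-elongation product spectrum.

    Includes the organic substrates (lactate, acetate), C2–C8 carboxylates
    and alcohols, the recirculated gases (H₂, CO, CO₂, N₂, CH₄), formate
    and a generic biomass pseudo-compound (per C-mol, CH₁.₈O₀.₅N₀.₂ with
    γ = 4.2).
    """
    specs = [
        CompoundSpec("lactate", 3, 6, 3, compound_class="organic_substrate", chain_length=3),
        _acid("acetate", 2),
        _acid("propionate", 3),
        _acid("n-butyrate", 4),
        _acid("i-butyrate", 4, iso=True),
        _acid("n-valerate", 5),
        _acid("i-valerate", 5, iso=True),
        _acid("n-caproate", 6),
        _acid("i-caproate", 6, iso=True),
        _acid("n-heptanoate", 7),
        _acid("n-caprylate", 8),
        CompoundSpec("formate", 1, 2, 2, compound_class="other", chain_length=1),
        _alcohol("ethanol", 2),
        _alcohol("n-propanol", 3),
        _alcohol("n-butanol", 4),
        _alcohol("n-pentanol", 5),
        _alcohol("n-hexanol", 6),
        CompoundSpec("H2", 0, 2, 0, phase="gas", compound_class="gas_substrate"),
        CompoundSpec("CO", 1, 0, 1, phase="gas", compound_class="gas_substrate"),
        CompoundSpec("CO2", 1, 0, 2, phase="gas", compound_class="gas_substrate"),
        CompoundSpec("CH4", 1, 4, 0, phase="gas", compound_class="other"),
        CompoundSpec(
            "N2", 0, 0, 0,
            phase="gas", compound_class="other",
            extra_mass=2 * ATOMIC_MASS["N"], gamma_override=0.0,
        ),
        # per C-mol biomass; γ = 4 + 1.8 − 2·0.5 − 3·0.2 with NH3-referenced N
        CompoundSpec(
            "biomass", 1, 0, 0,
            molar_mass=1 * ATOMIC_MASS["C"]
            + 1.8 * ATOMIC_MASS["H"]
            + 0.5 * ATOMIC_MASS["O"]
            + 0.2 * ATOMIC_MASS["N"],
            compound_class="other",
            extra_mass=1.8 * ATOMIC_MASS["H"] + 0.5 * ATOMIC_MASS["O"] + 0.2 * ATOMIC_MASS["N"],
            gamma_override=4.2,
        ),
    ]
    return CompoundRegistry(specs)


def _to_mM(value: float, unit: str, spec: CompoundSpec) -> float:
    if unit == "mM":
        return value
    if unit == "g/L":
        return value / spec.molar_mass * 1000.0
    if unit == "C-mmol/L":
        if spec.n_c == 0:
            raise ValueError(f"{spec.name} has no carbon; C-equivalents undefined")
        return value / spec.n_c
    if unit == "e-mmol/L":
        if spec.gamma == 0:
            raise ValueError(f"{spec.name} has γ = 0; electron equivalents undefined")
        return value / spec.gamma
    raise ValueError(f"unknown unit {unit!r}; expected one of {CONCENTRATION_UNITS}")


def _from_mM(value_mM: float, unit: str, spec: CompoundSpec) -> float:
    if unit == "mM":
        return value_mM
    if unit == "g/L":
        return value_mM * spec.molar_mass / 1000.0
    if unit == "C-mmol/L":
        if spec.n_c == 0:
            raise ValueError(f"{spec.name} has no carbon; C-equivalents undefined")
        return value_mM * spec.n_c
    if unit == "e-mmol/L":
        if spec.gamma == 0:
            raise ValueError(f"{spec.name} has γ = 0; electron equivalents undefined")
        return value_mM * spec.gamma
    raise ValueError(f"unknown unit {unit!r}; expected one of {CONCENTRATION_UNITS}")


def convert_concentration(
    value: float, from_unit: str, to_unit: str, spec: CompoundSpec
) -> float:
    """Convert a concentration (or volumetric rate) between unit systems.

    Supported units: ``mM``, ``g/L``, ``C-mmol/L`` and ``e-mmol/L``; rates
    in any of these per day convert identically.  The conversion is exact
    and linear via molar mass, carbon number and degree of reduction;
    nothing is rounded.

    >>> reg = default_registry()
    >>> round(convert_concentration(133, "mM", "g/L", reg["lactate"]), 2)
    11.98
    """
    if value < 0:
        raise ValueError("concentration must be non-negative")
    return _from_mM(_to_mM(value, from_unit, spec), to_unit, spec)


def c_rate_to_gCO2(rate_c_mmol: float) -> float:
    """Express a carbon rate (C-mmol L⁻¹ d⁻¹) as g CO₂-equivalents L⁻¹ d⁻¹.

    One C-mmol corresponds to one mmol of CO₂, i.e. 44.01 mg.
    """
    return rate_c_mmol * CO2_MOLAR_MASS / 1000.0
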