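"""Registry of flux-met variable bases: units, hard physical limits, kind.

The registry covers the variables most commonly submitted to a flux-data
repository (fluxes, radiation, meteorology, soil, concentrations).  Hard
limits are *physical* bounds used to reject impossible values; they are
deliberately generous and are not plausibility bounds (those are derived
per site and season by the data checks).  The registry is user-extensible
via :meth:`VariableRegistry.add` or :meth:`VariableRegistry.extend`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

KINDS = ("flux", "meteorology", "radiation", "soil", "concentration", "quality_flag")


@dataclass(frozen=True)
class RegistryEntry:
    base: str
    units: str
    hard_min: float
    hard_max: float
    kind: str

    def __post_init__(self) -> None:
        if self.hard_min >= self.hard_max:
            raise ValueError(f"{self.base}: hard_min must be < hard_max")
        if self.kind not in KINDS:
            raise ValueError(f"{self.base}: unknown kind {self.kind!r}")

    @property
    def is_percent(self) -> bool:
        """True for variables expressed in percent (targets of the ratio check)."""
        return self.units == "%"


# base, units, hard_min, hard_max, kind
_DEFAULT_ENTRIES = [
    # carbon / trace-gas fluxes
    ("FC", "umolCO2 m-2 s-1", -100.0, 100.0, "flux"),
    ("FCH4", "nmolCH4 m-2 s-1", -500.0, 2000.0, "flux"),
    ("NEE", "umolCO2 m-2 s-1", -100.0, 100.0, "flux"),
    ("GPP", "umolCO2 m-2 s-1", -50.0, 100.0, "flux"),
    ("RECO", "umolCO2 m-2 s-1", -10.0, 100.0, "flux"),
    ("SC", "umolCO2 m-2 s-1", -100.0, 100.0, "flux"),
    ("SCH4", "nmolCH4 m-2 s-1", -500.0, 2000.0, "flux"),
    # energy fluxes
    ("LE", "W m-2", -500.0, 1500.0, "flux"),
    ("H", "W m-2", -500.0, 1500.0, "flux"),
    ("G", "W m-2", -500.0, 800.0, "flux"),
    ("SLE", "W m-2", -500.0, 1500.0, "flux"),
    ("SH", "W m-2", -500.0, 1500.0, "flux"),
    ("TAU", "kg m-1 s-2", -20.0, 20.0, "flux"),
    # radiation
    ("SW_IN", "W m-2", -50.0, 1500.0, "radiation"),
    ("SW_OUT", "W m-2", -50.0, 1300.0, "radiation"),
    ("SW_DIF", "W m-2", -50.0, 1200.0, "radiation"),
    ("LW_IN", "W m-2", 50.0, 750.0, "radiation"),
    ("LW_OUT", "W m-2", 50.0, 900.0, "radiation"),
    ("NETRAD", "W m-2", -500.0, 1300.0, "radiation"),
    ("PPFD_IN", "umolPhoton m-2 s-1", -100.0, 3000.0, "radiation"),
    ("PPFD_OUT", "umolPhoton m-2 s-1", -100.0, 2500.0, "radiation"),
    ("PPFD_DIF", "umolPhoton m-2 s-1", -100.0, 2500.0, "radiation"),
    ("PPFD_BC_IN", "umolPhoton m-2 s-1", -100.0, 3000.0, "radiation"),
    ("APAR", "umolPhoton m-2 s-1", -100.0, 3000.0, "radiation"),
    # meteorology
    ("TA", "deg C", -60.0, 60.0, "meteorology"),
    ("T_SONIC", "deg C", -60.0, 60.0, "meteorology"),
    ("T_CANOPY", "deg C", -60.0, 70.0, "meteorology"),
    ("RH", "%", 0.0, 100.0, "meteorology"),
    ("VPD", "hPa", 0.0, 120.0, "meteorology"),
    ("PA", "kPa", 30.0, 115.0, "meteorology"),
    ("WS", "m s-1", 0.0, 60.0, "meteorology"),
    ("WS_MAX", "m s-1", 0.0, 100.0, "meteorology"),
    ("WD", "Decimal degrees", 0.0, 360.0, "meteorology"),
    ("USTAR", "m s-1", 0.0, 6.0, "meteorology"),
    ("ZL", "nondimensional", -1e5, 1e5, "meteorology"),
    ("MO_LENGTH", "m", -1e6, 1e6, "meteorology"),
    ("P", "mm", 0.0, 300.0, "meteorology"),
    ("P_RAIN", "mm", 0.0, 300.0, "meteorology"),
    ("P_SNOW", "mm", 0.0, 300.0, "meteorology"),
    ("D_SNOW", "cm", 0.0, 1000.0, "meteorology"),
    ("PBLH", "m", 0.0, 6000.0, "meteorology"),
    # soil
    ("TS", "deg C", -50.0, 70.0, "soil"),
    ("SWC", "%", 0.0, 100.0, "soil"),
    ("WTD", "m", -20.0, 20.0, "soil"),
    ("T_BOLE", "deg C", -50.0, 70.0, "soil"),
    # concentrations
    ("CO2", "umolCO2 mol-1", 100.0, 1500.0, "concentration"),
    ("CO2_SIGMA", "umolCO2 mol-1", 0.0, 500.0, "concentration"),
    ("H2O", "mmolH2O mol-1", 0.0, 100.0, "concentration"),
    ("H2O_SIGMA", "mmolH2O mol-1", 0.0, 50.0, "concentration"),
    ("CH4", "nmolCH4 mol-1", 0.0, 100000.0, "concentration"),
    # quality flags / turbulence diagnostics
    ("FC_SSITC_TEST", "nondimensional", 0.0, 10.0, "quality_flag"),
    ("LE_SSITC_TEST", "nondimensional", 0.0, 10.0, "quality_flag"),
    ("H_SSITC_TEST", "nondimensional", 0.0, 10.0, "quality_flag"),
    ("TAU_SSITC_TEST", "nondimensional", 0.0, 10.0, "quality_flag"),
    # footprint
    ("FETCH_MAX", "m", 0.0, 1e6, "quality_flag"),
    ("FETCH_70", "m", 0.0, 1e6, "quality_flag"),
    ("FETCH_90", "m", 0.0, 1e6, "quality_flag"),
    ("LEAF_WET", "%", 0.0, 100.0, "meteorology"),
]


class VariableRegistry:
    """Mapping from variable base name to its :class:`RegistryEntry`.

    Lookups never guess: an unknown base returns ``None``.
    """

    def __init__(self, entries: Optional[Iterable[RegistryEntry]] = None) -> None:
        self._entries: dict[str, RegistryEntry] = {}
        if entries is not None:
            self.extend(entries)

    @classmethod
    def default(cls) -> "VariableRegistry":
        return cls(
            RegistryEntry(base, units, lo, hi, kind)
            for base, units, lo, hi, kind in _DEFAULT_ENTRIES
        )

    def add(self, entry: RegistryEntry) -> None:
        self._entries[entry.base] = entry

    def extend(self, entries: Iterable[RegistryEntry]) -> None:
        for e in entries:
            self.add(e)

    def lookup(self, base: str) -> Optional[RegistryEntry]:
        return self._entries.get(base)

    def __contains__(self, base: str) -> bool:
        return base in self._entries

    def __iter__(self) -> Iterator[RegistryEntry]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def bases(self) -> list[str]:
        return list(self._entries)
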