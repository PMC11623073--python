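"""Operational energy and carbon accounting for pipeline phases.

Emissions follow the standard product rule:

    emissions (gCO2eq) = energy (kWh) x regional carbon intensity (gCO2eq/kWh)

with energy integrated from phase durations under a constant power model
(CPU watts plus RAM watts at 3 W per 8 GB, the convention of common ML
emissions trackers).  Defaults mirror a hosted-notebook CPU allocation of
42.5 W and 12.678 GB RAM with 15 s sampling.  Emissions are reported in
grams; at desk-scale energies (hundredths of a kWh) gram-scale numbers are
the physically plausible magnitude.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

from .errors import ContractError

#: gCO2eq per kWh by grid region (emissions-tracker convention values).
CARBON_INTENSITY = {
    "US": 367.8,
    "EU": 230.0,
    "IN": 708.0,
    "CN": 555.0,
    "GLOBAL": 475.0,
}

RAM_WATTS_PER_GB = 3.0 / 8.0  # 3 W per 8 GB module


@dataclass(frozen=True)
class PowerModel:
    cpu_watts: float = 42.5
    ram_gigabytes: float = 12.678
    ram_watts_per_gb: float = RAM_WATTS_PER_GB
    sample_interval_s: float = 15.0

    def __post_init__(self) -> None:
        if min(
            self.cpu_watts, self.ram_gigabytes,
            self.ram_watts_per_gb, self.sample_interval_s,
        ) <= 0:
            raise ContractError("power model parameters must be positive")

    @property
    def ram_watts(self) -> float:
        return self.ram_gigabytes * self.ram_watts_per_gb


def estimate_energy(duration_s: float, power: PowerModel) -> tuple[float, float]:
    """(RAM kWh, CPU kWh) for a phase of the given duration.

    With a constant power model the sampled integral collapses to
    ``power x duration``; the sampling interval only matters for
    variable-power models, and is kept on :class:`PowerModel` for API
    compatibility with them.
    """
    if duration_s < 0:
        raise ContractError("negative phase duration")
    ram_kwh = power.ram_watts * duration_s / 3.6e6
    cpu_kwh = power.cpu_watts * duration_s / 3.6e6
    return ram_kwh, cpu_kwh


def estimate_emissions(energy_kwh: float, intensity_g_per_kwh: float) -> float:
    """gCO2eq = kWh x gCO2eq/kWh, exactly."""
    if energy_kwh < 0 or intensity_g_per_kwh < 0:
        raise ContractError("energy and intensity must be non-negative")
    return energy_kwh * intensity_g_per_kwh


@dataclass
class LedgerRow:
    name: str
    duration_s: float
    ram_kwh: float
    cpu_kwh: float
    emissions_g: float


@dataclass
class EnergyLedger:
    rows: list[LedgerRow]
    intensity_g_per_kwh: float
    region: str
    power: PowerModel

    @property
    def total_energy_kwh(self) -> float:
        return sum(r.ram_kwh + r.cpu_kwh for r in self.rows)

    @property
    def total_emissions_g(self) -> float:
        return sum(r.emissions_g for r in self.rows)

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "intensity_g_per_kwh": self.intensity_g_per_kwh,
            "power": {
                "cpu_watts": self.power.cpu_watts,
                "ram_gigabytes": self.power.ram_gigabytes,
                "ram_watts_per_gb": self.power.ram_watts_per_gb,
                "sample_interval_s": self.power.sample_interval_s,
            },
            "phases": [
                {
                    "name": r.name,
                    "duration_s": r.duration_s,
                    "ram_kwh": r.ram_kwh,
                    "cpu_kwh": r.cpu_kwh,
                    "emissions_g": r.emissions_g,
                }
                for r in self.rows
            ],
            "total_energy_kwh": self.total_energy_kwh,
            "total_emissions_g": self.total_emissions_g,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EnergyLedger":
        obj = json.loads(text)
        power = PowerModel(**obj["power"])
        return cls(
            rows=[
                LedgerRow(
                    name=p["name"], duration_s=p["duration_s"],
                    ram_kwh=p["ram_kwh"], cpu_kwh=p["cpu_kwh"],
                    emissions_g=p["emissions_g"],
                )
                for p in obj["phases"]
            ],
            intensity_g_per_kwh=obj["intensity_g_per_kwh"],
            region=obj["region"],
            power=power,
        )

    def render(self) -> str:
        header = (
            f"{'Phase':<16}{'RAM (kWh)':>12}{'CPU (kWh)':>12}"
            f"{'gCO2eq':>10}"
        )
        lines = [
            f"region {self.region} @ {self.intensity_g_per_kwh} gCO2eq/kWh",
            header,
            "-" * len(header),
        ]
        for r in self.rows:
            lines.append(
                f"{r.name:<16}{r.ram_kwh:>12.6f}{r.cpu_kwh:>12.6f}"
                f"{r.emissions_g:>10.4f}"
            )
        lines.append("-" * len(header))
        lines.append(
            f"{'total':<16}{'':>12}{self.total_energy_kwh:>12.6f}"
            f"{self.total_emissions_g:>10.4f}"
        )
        return "\n".join(lines)


def ledger_report(
    phases: dict[str, float] | list[tuple[str, float]],
    power: PowerModel = PowerModel(),
    intensity: float | None = None,
    region: str = "US",
) -> EnergyLedger:
    """One ledger row per (phase name, duration seconds).

    ``intensity`` overrides the bundled region table (gCO2eq/kWh).
    """
    items = list(phases.items()) if isinstance(phases, dict) else list(phases)
    if not items:
        raise ContractError("ledger needs at least one phase")
    if intensity is None:
        if region not in CARBON_INTENSITY:
            raise ContractError(
                f"unknown region {region!r}; bundled: {sorted(CARBON_INTENSITY)}"
            )
        intensity = CARBON_INTENSITY[region]
    rows = []
    for name, duration in items:
        ram_kwh, cpu_kwh = estimate_energy(duration, power)
        rows.append(
            LedgerRow(
                name=name,
                duration_s=duration,
                ram_kwh=ram_kwh,
                cpu_kwh=cpu_kwh,
                emissions_g=estimate_emissions(ram_kwh + cpu_kwh, intensity),
            )
        )
    return EnergyLedger(
        rows=rows, intensity_g_per_kwh=intensity, region=region, power=power
    )


class PhaseTimer:
    """Context-manager accumulator of named phase durations (monotonic clock)."""

    def __init__(self) -> None:
        self.durations: dict[str, float] = {}

    class _Phase:
        def __init__(self, timer: "PhaseTimer", name: str) -> None:
            self.timer, self.name = timer, name

        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            self.timer.durations[self.name] = (
                self.timer.durations.get(self.name, 0.0)
                + time.perf_counter() - self.t0
            )
            return False

    def phase(self, name: str) -> "_Phase":
        return self._Phase(self, name)
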