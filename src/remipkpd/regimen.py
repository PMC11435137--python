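"""Intravenous dosing regimens: ordered bolus and zero-order infusion events."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DoseEvent", "Regimen"]


@dataclass(frozen=True)
class DoseEvent:
    """One dose: ``duration == 0`` is an instantaneous bolus into the parent
    central compartment; ``duration > 0`` is a zero-order infusion of
    ``amount`` mg spread over ``duration`` min."""

    time: float      # min
    amount: float    # mg
    duration: float = 0.0  # min

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if not self.amount > 0:
            raise ValueError("dose amount must be > 0")
        if self.duration < 0:
            raise ValueError("dose duration must be >= 0")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/min (0 for a bolus)."""
        return 0.0 if self.duration == 0 else self.amount / self.duration


@dataclass(frozen=True)
class Regimen:
    """Ordered sequence of dose events; overlapping infusion rates add."""

    events: tuple[DoseEvent, ...]

    def __post_init__(self):
        events = tuple(self.events)
        times = [e.time for e in events]
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("dose events must be ordered by start time")
        object.__setattr__(self, "events", events)

    @classmethod
    def bolus(cls, amount: float, time: float = 0.0) -> "Regimen":
        return cls(events=(DoseEvent(time, amount),))

    @classmethod
    def bolus_per_kg(cls, dose_mg_per_kg: float, weight_kg: float,
                     time: float = 0.0) -> "Regimen":
        return cls.bolus(dose_mg_per_kg * weight_kg, time)

    @classmethod
    def loading_plus_maintenance(cls, weight_kg: float,
                                 bolus_mg_per_kg: float,
                                 rate_mg_per_kg_h: float,
                                 duration_min: float,
                                 bolus_duration_min: float = 0.0) -> "Regimen":
        """Induction bolus (optionally a short zero-order loading infusion)
        followed immediately by a maintenance infusion."""
        events = []
        if bolus_mg_per_kg > 0:
            events.append(DoseEvent(0.0, bolus_mg_per_kg * weight_kg,
                                    bolus_duration_min))
        if rate_mg_per_kg_h > 0 and duration_min > 0:
            amount = rate_mg_per_kg_h * weight_kg * duration_min / 60.0
            events.append(DoseEvent(0.0, amount, duration_min))
        if not events:
            raise ValueError("regimen must contain at least one dose")
        return cls(events=tuple(events))

    @property
    def total_dose(self) -> float:
        """Total administered amount, mg."""
        return sum(e.amount for e in self.events)

    @property
    def end_time(self) -> float:
        """Time the last dose finishes, min."""
        return max(e.time + e.duration for e in self.events)
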