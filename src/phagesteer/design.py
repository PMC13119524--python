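"""Experimental-design enumeration for two-phage serial-passage experiments.

A treatment arm fixes the delivery strategy (monophage, simultaneous cocktail,
sequential, or untreated control), which phage starts the treatment, when the
second dose arrives (24 / 48 / 72 h after the first), and how many replicate
populations are propagated.  The helpers here validate arms, enumerate them
into a flat design table (one row per replicate population), and expand an arm
into its concrete dosing schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Strategy",
    "PhageMix",
    "DoseTiming",
    "TreatmentSpec",
    "DoseEvent",
    "DesignError",
    "TIMING_DAY",
    "dose_schedule",
    "enumerate_design",
    "initial_experiment_arms",
    "followup_arms",
    "arms_from_config",
]


class DesignError(ValueError):
    """A treatment specification or design config violates its invariants."""


class Strategy(str, Enum):
    MONOPHAGE = "monophage"
    COCKTAIL = "cocktail"
    SEQUENTIAL = "sequential"
    CONTROL = "control"


class PhageMix(str, Enum):
    """Composition of a dose: a single phage, both in equal parts, or none."""

    T2 = "T2"
    LAMBDA = "LAMBDA"
    BOTH = "BOTH"
    NONE = "NONE"


class DoseTiming(str, Enum):
    EARLY = "early"  # 24 h after the first dose
    MID = "mid"      # 48 h
    LATE = "late"    # 72 h
    NONE = "none"

#: Second doses are added immediately after the daily transfer, so a 24/48/72 h
#: delay lands at the start of day 1/2/3 (day 0 = inoculation).
TIMING_DAY: Mapping[DoseTiming, int] = {
    DoseTiming.EARLY: 1,
    DoseTiming.MID: 2,
    DoseTiming.LATE: 3,
}

_SINGLE = (PhageMix.T2, PhageMix.LAMBDA)


@dataclass(frozen=True)
class TreatmentSpec:
    """One arm of the experiment.

    Parameters
    ----------
    strategy:
        Delivery strategy.
    first_phage:
        Composition of the day-0 dose.
    second_dose_timing, second_dose_phage:
        When the second dose arrives and what it contains.  ``none``/``NONE``
        together mean a single-dose arm.
    n_replicates:
        Number of replicate populations propagated under this arm.
    duration_days:
        Length of the serial-passage experiment (daily transfers).
    """

    strategy: Strategy
    first_phage: PhageMix = PhageMix.NONE
    second_dose_timing: DoseTiming = DoseTiming.NONE
    second_dose_phage: PhageMix = PhageMix.NONE
    n_replicates: int = 3
    duration_days: int = 14

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategy", Strategy(self.strategy))
        object.__setattr__(self, "first_phage", PhageMix(self.first_phage))
        object.__setattr__(
            self, "second_dose_timing", DoseTiming(self.second_dose_timing)
        )
        object.__setattr__(
            self, "second_dose_phage", PhageMix(self.second_dose_phage)
        )
        if not (isinstance(self.n_replicates, int) and self.n_replicates > 0):
            raise DesignError(f"{self._name()}: n_replicates must be a positive integer")
        if not (isinstance(self.duration_days, int) and self.duration_days > 0):
            raise DesignError(f"{self._name()}: duration_days must be a positive integer")

        s, f, t, g = (
            self.strategy,
            self.first_phage,
            self.second_dose_timing,
            self.second_dose_phage,
        )
        if (t is DoseTiming.NONE) != (g is PhageMix.NONE):
            raise DesignError(
                f"{self._name()}: second_dose_timing is 'none' iff second_dose_phage is NONE"
            )
        if s is Strategy.CONTROL:
            if f is not PhageMix.NONE or g is not PhageMix.NONE:
                raise DesignError(f"{self._name()}: control arms must have no phage")
        elif s is Strategy.SEQUENTIAL:
            if f not in _SINGLE or g not in _SINGLE or f is g:
                raise DesignError(
                    f"{self._name()}: sequential arms need two distinct single phages"
                )
        elif s is Strategy.COCKTAIL:
            if f is not PhageMix.BOTH:
                raise DesignError(f"{self._name()}: cocktail arms start with BOTH phages")
            if g not in (PhageMix.BOTH, PhageMix.NONE):
                raise DesignError(
                    f"{self._name()}: cocktail second dose must be BOTH or NONE"
                )
        elif s is Strategy.MONOPHAGE:
            if f not in _SINGLE:
                raise DesignError(f"{self._name()}: monophage arms start with one phage")
            if g not in (f, PhageMix.NONE):
                raise DesignError(
                    f"{self._name()}: monophage second dose must repeat the same phage"
                )

    def _name(self) -> str:
        return f"arm {self.strategy!s}/{self.first_phage!s}/{self.second_dose_timing!s}"

    @property
    def label(self) -> str:
        """Stable arm label used to build population ids."""
        s = self.strategy
        if s is Strategy.CONTROL:
            return "control"
        if s is Strategy.COCKTAIL:
            base = "cocktail"
        elif s is Strategy.SEQUENTIAL:
            base = f"seq-{self.first_phage.value}first"
        else:
            base = f"mono-{self.first_phage.value}"
        if self.second_dose_timing is DoseTiming.NONE:
            return f"{base}-single"
        return f"{base}-{self.second_dose_timing.value}"


@dataclass(frozen=True)
class DoseEvent:
    """A dosing event: PFU added per phage at the start of a given day."""

    day: int
    pfu_by_phage: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.day < 0:
            raise DesignError("dose day must be >= 0")
        for phage, pfu in self.pfu_by_phage.items():
            if pfu < 0:
                raise DesignError(f"negative PFU for {phage}")

    @property
    def total_pfu(self) -> float:
        return float(sum(self.pfu_by_phage.values()))


def _composition(mix: PhageMix, total_pfu: float) -> dict[str, float]:
    if mix is PhageMix.BOTH:
        # Cocktail doses split the total equally between the two phages.
        return {"T2": total_pfu / 2.0, "LAMBDA": total_pfu / 2.0}
    return {mix.value: float(total_pfu)}


def dose_schedule(spec: TreatmentSpec, total_pfu_per_dose: float = 1e6) -> list[DoseEvent]:
    """Expand an arm into its ordered list of dosing events.

    Each event carries ``total_pfu_per_dose`` particles in total; BOTH doses
    are split into equal halves.  Control arms receive no phage and return an
    empty list.
    """
    if spec.strategy is Strategy.CONTROL:
        return []
    if total_pfu_per_dose <= 0:
        raise DesignError("total_pfu_per_dose must be > 0 for phage-treated arms")
    events = [DoseEvent(0, _composition(spec.first_phage, total_pfu_per_dose))]
    if spec.second_dose_phage is not PhageMix.NONE:
        day = TIMING_DAY[spec.second_dose_timing]
        events.append(DoseEvent(day, _composition(spec.second_dose_phage, total_pfu_per_dose)))
    return events


def enumerate_design(arms: Iterable[TreatmentSpec]) -> pd.DataFrame:
    """Enumerate treatment arms into a flat design table.

    One row per replicate population, in config order with replicates
    ``1..n``; population ids are ``<arm-label>_r<k>``.  Deterministic: the
    same arm list always yields a byte-identical table.
    """
    rows = []
    seen: set[str] = set()
    for spec in arms:
        if not isinstance(spec, TreatmentSpec):
            raise DesignError(f"expected TreatmentSpec, got {type(spec).__name__}")
        if spec.label in seen:
            raise DesignError(f"duplicate arm label {spec.label!r}")
        seen.add(spec.label)
        for k in range(1, spec.n_replicates + 1):
            rows.append(
                {
                    "population_id": f"{spec.label}_r{k}",
                    "strategy": spec.strategy.value,
                    "first_phage": spec.first_phage.value,
                    "timing": spec.second_dose_timing.value,
                    "second_dose_phage": spec.second_dose_phage.value,
                    "replicate": k,
                }
            )
    columns = [
        "population_id",
        "strategy",
        "first_phage",
        "timing",
        "second_dose_phage",
        "replicate",
    ]
    return pd.DataFrame(rows, columns=columns)


def initial_experiment_arms(duration_days: int = 14) -> list[TreatmentSpec]:
    """Default 72-population survey.

    Sequential: 2 dose orders x 3 timings x 6 replicates.  Cocktail: 3 timings
    x 3 replicates.  Monophage: 2 phages x 4 schedules (single dose, or a
    second dose early/mid/late) x 3 replicates.  Plus 3 untreated controls.
    The monophage arm structure is a reconstruction (the published appendix is
    not reproduced here) chosen so the documented total of 72 is met.
    """
    timings = (DoseTiming.EARLY, DoseTiming.MID, DoseTiming.LATE)
    arms: list[TreatmentSpec] = []
    for first, second in ((PhageMix.T2, PhageMix.LAMBDA), (PhageMix.LAMBDA, PhageMix.T2)):
        for t in timings:
            arms.append(
                TreatmentSpec(Strategy.SEQUENTIAL, first, t, second, 6, duration_days)
            )
    for t in timings:
        arms.append(
            TreatmentSpec(Strategy.COCKTAIL, PhageMix.BOTH, t, PhageMix.BOTH, 3, duration_days)
        )
    for phage in _SINGLE:
        arms.append(
            TreatmentSpec(Strategy.MONOPHAGE, phage, DoseTiming.NONE, PhageMix.NONE, 3, duration_days)
        )
        for t in timings:
            arms.append(TreatmentSpec(Strategy.MONOPHAGE, phage, t, phage, 3, duration_days))
    arms.append(TreatmentSpec(Strategy.CONTROL, n_replicates=3, duration_days=duration_days))
    return arms


def followup_arms(duration_days: int = 14) -> list[TreatmentSpec]:
    """Follow-up design: T2-first sequential vs. cocktail at mid/late dosing,
    12 replicates per treatment, plus 3 untreated controls (51 populations)."""
    arms: list[TreatmentSpec] = []
    for t in (DoseTiming.MID, DoseTiming.LATE):
        arms.append(
            TreatmentSpec(Strategy.SEQUENTIAL, PhageMix.T2, t, PhageMix.LAMBDA, 12, duration_days)
        )
    for t in (DoseTiming.MID, DoseTiming.LATE):
        arms.append(
            TreatmentSpec(Strategy.COCKTAIL, PhageMix.BOTH, t, PhageMix.BOTH, 12, duration_days)
        )
    arms.append(TreatmentSpec(Strategy.CONTROL, n_replicates=3, duration_days=duration_days))
    return arms


def arms_from_config(config: Sequence[Mapping] | Mapping) -> list[TreatmentSpec]:
    """Build treatment arms from a structured config (parsed YAML/JSON).

    ``config`` is either a list of arm mappings or a mapping with an ``arms``
    key.  Each arm mapping uses the TreatmentSpec field names.
    """
    if isinstance(config, Mapping):
        config = config.get("arms", [])
    arms = []
    for i, entry in enumerate(config):
        try:
            arms.append(TreatmentSpec(**dict(entry)))
        except (TypeError, DesignError) as exc:
            raise DesignError(f"arm #{i + 1}: {exc}") from exc
    return arms
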