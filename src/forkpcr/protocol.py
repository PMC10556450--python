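"""Bench protocol emitter: thermal programs and reaction recipes per round.

Amounts are kept as exact decimal strings (no floats), so a program or
recipe survives JSON round-trips byte-identically.  Template amounts that
are specified as ranges (e.g. 10-100 ng of a microbial genome) are stored
and emitted verbatim as ranges; no single default is invented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = [
    "ProgramStep",
    "CycleBlock",
    "ThermalProgram",
    "ReagentEntry",
    "ReactionRecipe",
    "thermal_program",
    "reaction_recipe",
    "ConfigError",
]


class ConfigError(ValueError):
    """Unknown round, component, or override."""


@dataclass(frozen=True)
class ProgramStep:
    temperature_c: float
    duration_s: int

    def __post_init__(self) -> None:
        if not 4 <= self.temperature_c <= 99:
            raise ValueError(f"temperature {self.temperature_c} outside [4, 99] degC")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class CycleBlock:
    steps: tuple[ProgramStep, ...]
    cycles: int = 1

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycle count must be >= 1")


@dataclass(frozen=True)
class ThermalProgram:
    round_label: str
    blocks: tuple[CycleBlock, ...]

    def min_annealing_temp(self) -> float:
        return min(s.temperature_c for b in self.blocks for s in b.steps)

    def to_dict(self) -> dict:
        return {
            "round": self.round_label,
            "blocks": [
                {
                    "cycles": b.cycles,
                    "steps": [
                        {"temperature_c": s.temperature_c, "duration_s": s.duration_s}
                        for s in b.steps
                    ],
                }
                for b in self.blocks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThermalProgram":
        return cls(
            d["round"],
            tuple(
                CycleBlock(
                    tuple(
                        ProgramStep(s["temperature_c"], s["duration_s"])
                        for s in b["steps"]
                    ),
                    b["cycles"],
                )
                for b in d["blocks"]
            ),
        )

    def to_markdown(self) -> str:
        lines = [f"### {self.round_label} thermal program", ""]
        for b in self.blocks:
            steps = "; ".join(
                f"{s.temperature_c:g} degC, {s.duration_s} s" for s in b.steps
            )
            lines.append(f"- {steps}  (x{b.cycles})")
        return "\n".join(lines)


_ROUND_LABELS = {1: "primary", 2: "secondary", 3: "tertiary"}


def thermal_program(round_no: int) -> ThermalProgram:
    """Thermal cycling program for one walking round.

    Round 1 runs one low-stringency (25 degC) annealing cycle before thirty
    high-stringency (65 degC) cycles; rounds 2 and 3 are identical to each
    other and all-high-stringency.
    """
    if round_no not in _ROUND_LABELS:
        raise ConfigError(f"round must be 1, 2, or 3 (got {round_no})")
    denat = CycleBlock((ProgramStep(95, 120),), 1)
    low = CycleBlock(
        (ProgramStep(95, 10), ProgramStep(25, 30), ProgramStep(72, 120)), 1
    )
    high = CycleBlock(
        (ProgramStep(95, 10), ProgramStep(65, 30), ProgramStep(72, 120)), 30
    )
    final = CycleBlock((ProgramStep(72, 300),), 1)
    if round_no == 1:
        blocks = (denat, low, high, final)
    else:
        blocks = (denat, high, final)
    return ThermalProgram(_ROUND_LABELS[round_no], blocks)


@dataclass(frozen=True)
class ReagentEntry:
    component: str
    amount: str  # exact decimal string, or a verbatim range
    unit: str
    note: str = ""

    def to_dict(self) -> dict:
        d = {"component": self.component, "amount": self.amount, "unit": self.unit}
        if self.note:
            d["note"] = self.note
        return d


@dataclass(frozen=True)
class ReactionRecipe:
    round_label: str
    entries: tuple[ReagentEntry, ...]
    total_volume_uL: int = 50
    deviations: tuple[str, ...] = ()

    def __getitem__(self, component: str) -> ReagentEntry:
        for e in self.entries:
            if e.component == component:
                return e
        raise KeyError(component)

    def to_dict(self) -> dict:
        return {
            "round": self.round_label,
            "total_volume_uL": self.total_volume_uL,
            "entries": [e.to_dict() for e in self.entries],
            "deviations": list(self.deviations),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionRecipe":
        return cls(
            d["round"],
            tuple(
                ReagentEntry(e["component"], e["amount"], e["unit"], e.get("note", ""))
                for e in d["entries"]
            ),
            d["total_volume_uL"],
            tuple(d.get("deviations", [])),
        )

    def to_markdown(self) -> str:
        lines = [
            f"### {self.round_label} reaction ({self.total_volume_uL} uL total)",
            "",
            "| component | amount | unit |",
            "|---|---|---|",
        ]
        for e in self.entries:
            note = f" ({e.note})" if e.note else ""
            lines.append(f"| {e.component}{note} | {e.amount} | {e.unit} |")
        for dev in self.deviations:
            lines.append(f"\n*deviation: {dev}*")
        return "\n".join(lines)


_COMMON = [
    ReagentEntry("dNTP (each)", "0.4", "mM"),
    ReagentEntry("LA Taq buffer II", "1", "x", "plus 2.5 mM Mg2+"),
    ReagentEntry("LA Taq polymerase", "2.5", "U"),
    ReagentEntry("water", "to 50", "uL"),
]

_ROUND_PRIMERS: dict[int, list[ReagentEntry]] = {
    1: [ReagentEntry("PFP", "0.2", "uM"), ReagentEntry("oNSP", "0.2", "uM")],
    2: [
        ReagentEntry("SFP", "0.02", "uM", "1/10 of BP; bridge only"),
        ReagentEntry("BP", "0.2", "uM"),
        ReagentEntry("mNSP", "0.2", "uM"),
    ],
    3: [ReagentEntry("BP", "0.2", "uM"), ReagentEntry("iNSP", "0.2", "uM")],
}

_TEMPLATES: dict[int, ReagentEntry] = {
    1: ReagentEntry(
        "template", "10-100 (microbial) / 100-1000 (rice)", "ng", "genomic DNA"
    ),
    2: ReagentEntry(
        "template", "1", "uL", "primary PCR product; dilute 10-1000 fold if necessary"
    ),
    3: ReagentEntry(
        "template", "1", "uL", "secondary PCR product; dilute 10-1000 fold if necessary"
    ),
}


def reaction_recipe(round_no: int, overrides: dict[str, str] | None = None) -> ReactionRecipe:
    """Reaction assembly for one round, with optional logged overrides.

    Overrides change the amount of a named component (e.g. ``{"SFP": "0.2"}``)
    and are recorded in the recipe's deviation log; overriding a component
    that is not in the round's recipe raises ``ConfigError``.
    """
    if round_no not in _ROUND_PRIMERS:
        raise ConfigError(f"round must be 1, 2, or 3 (got {round_no})")
    entries = [_TEMPLATES[round_no], *_ROUND_PRIMERS[round_no], *_COMMON]
    deviations: list[str] = []
    for comp, amount in (overrides or {}).items():
        matches = [i for i, e in enumerate(entries) if e.component == comp]
        if not matches:
            raise ConfigError(f"unknown component {comp!r} for round {round_no}")
        i = matches[0]
        old = entries[i]
        entries[i] = ReagentEntry(old.component, str(amount), old.unit, old.note)
        deviations.append(f"{comp}: {old.amount} {old.unit} -> {amount} {old.unit}")
    return ReactionRecipe(
        _ROUND_LABELS[round_no], tuple(entries), 50, tuple(deviations)
    )
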