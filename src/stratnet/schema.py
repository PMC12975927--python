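"""Variable schema for the 17-node clinical network.

The analysis operates on a fixed catalog of participant-level variables
spanning three dimensions: sociodemographic profile (sex, age, marital
status, social position index), psychopathology (impulsivity, emotion
dysregulation, global psychological distress, comorbid mental disorder,
suicidal behavior, duration of the behavioral-addiction problem) and the
seven temperament/character personality dimensions of the TCI-R.

Binary variables declare which level is coded 1, because the sign of a
network edge refers to that level (e.g. the sex node is "male = 1", so a
positive edge weight means the association holds for men).
"""

from __future__ import annotations

from dataclasses import dataclass, field

SOCIODEMOGRAPHIC = "sociodemographic"
PSYCHOPATHOLOGY = "psychopathology"
PERSONALITY = "personality"

_DIMENSIONS = (SOCIODEMOGRAPHIC, PSYCHOPATHOLOGY, PERSONALITY)


@dataclass(frozen=True)
class VariableDef:
    """One analysis variable: identifier, display label, dimension and coding."""

    name: str
    label: str
    dimension: str
    mtype: str  # "binary" or "continuous"
    positive_level: str | None = None

    def __post_init__(self) -> None:
        if self.dimension not in _DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if self.mtype not in ("binary", "continuous"):
            raise ValueError(f"unknown measurement type {self.mtype!r}")
        if self.mtype == "binary" and not self.positive_level:
            raise ValueError(f"binary variable {self.name!r} must declare positive_level")


@dataclass(frozen=True)
class VariableSchema:
    """Ordered catalog of analysis variables.

    The default schema (:func:`default_schema`) has exactly 17 entries:
    4 sociodemographic, 6 psychopathology, 7 personality.
    """

    entries: tuple[VariableDef, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, key: int | str) -> VariableDef:
        if isinstance(key, str):
            return self.entries[self.index(key)]
        return self.entries[key]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def index(self, name: str) -> int:
        for i, e in enumerate(self.entries):
            if e.name == name:
                return i
        raise KeyError(name)

    def binary_names(self) -> list[str]:
        return [e.name for e in self.entries if e.mtype == "binary"]

    def continuous_names(self) -> list[str]:
        return [e.name for e in self.entries if e.mtype == "continuous"]

    def dimension_counts(self) -> dict[str, int]:
        counts = {d: 0 for d in _DIMENSIONS}
        for e in self.entries:
            counts[e.dimension] += 1
        return counts

    def as_continuous(self) -> "VariableSchema":
        """Copy of the schema with every variable treated as continuous.

        Used by simulation designs that observe the latent Gaussian scale
        directly (e.g. null-calibration and recovery designs).
        """
        return VariableSchema(
            tuple(
                VariableDef(e.name, e.label, e.dimension, "continuous", None)
                for e in self.entries
            )
        )


def default_schema() -> VariableSchema:
    """The standard 17-variable clinical schema.

    Node labels follow the convention used in published network figures
    (e.g. ``Sex. Male``, ``Marit. NotMarr``, ``TCI.directed``); for binary
    nodes the label names the level coded 1.
    """
    s = SOCIODEMOGRAPHIC
    p = PSYCHOPATHOLOGY
    t = PERSONALITY
    return VariableSchema(
        (
            VariableDef("sex_male", "Sex. Male", s, "binary", positive_level="male"),
            VariableDef("age", "Age", s, "continuous"),
            VariableDef(
                "marital_not_married", "Marit. NotMarr", s, "binary",
                positive_level="not married",
            ),
            VariableDef("ses", "SES", s, "continuous"),
            VariableDef("impulsivity", "Impulsivity", p, "continuous"),
            VariableDef("emotion_reg", "Emotion", p, "continuous"),
            VariableDef("distress", "Psy. Distress", p, "continuous"),
            VariableDef(
                "mental_dis", "MentalDis", p, "binary", positive_level="present",
            ),
            VariableDef("suicidal", "Suicidal", p, "binary", positive_level="present"),
            VariableDef("duration_ba", "DurationBA", p, "continuous"),
            VariableDef("tci_novelty", "TCI.novelty", t, "continuous"),
            VariableDef("tci_harm", "TCI.harm", t, "continuous"),
            VariableDef("tci_reward", "TCI.reward", t, "continuous"),
            VariableDef("tci_persistence", "TCI.persis", t, "continuous"),
            VariableDef("tci_directedness", "TCI.directed", t, "continuous"),
            VariableDef("tci_cooperativeness", "TCI.coopera", t, "continuous"),
            VariableDef("tci_transcendence", "TCI.transcen", t, "continuous"),
        )
    )
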