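"""Wheelchair Skills Test (WST) capacity scoring.

Fifteen power-wheelchair skills are each scored on the standard 0/1/2 scale
(2 = pass, 1 = pass with difficulty, 0 = fail), and the total capacity is

    capacity% = 100 * sum(scores) / (2 * n_skills)

For the 15-skill sheet the denominator is 30.  Printed capacities follow the
one-decimal *truncation* convention (26/30 -> 86.6, not 86.7); the exact
real value is retained alongside the display string.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: the 15 evaluated skills, in sheet order
SKILLS: tuple[str, ...] = (
    "Rolls forward 10 m",
    "Rolls backward 5 m",
    "Turns 90 deg by moving forward",
    "Turns 90 deg by moving backward",
    "Turns 180 deg in place",
    "Maneuvers sideways",
    "Gets through gate",
    "Rolls 100 m",
    "Avoids moving obstacles",
    "Ascends small ramp",
    "Descends small ramp",
    "Ascends long curved ramp",
    "Descends long curved ramp",
    "Rolls 2 m across side-slope",
    "Rolls 2 m on uneven surface",
)

VALID_SCORES = (0, 1, 2)


class SheetValidationError(ValueError):
    """Raised for a malformed score sheet, naming the offending entry."""


@dataclass(frozen=True)
class SkillSheet:
    """One completed WST sheet: a 0/1/2 score per skill."""

    scores: tuple[int, ...]
    interface_label: str = ""
    subject_label: str = ""
    skill_names: tuple[str, ...] = SKILLS

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", tuple(int(s) for s in self.scores))
        if len(self.scores) != len(self.skill_names):
            raise SheetValidationError(
                f"expected {len(self.skill_names)} scores, got {len(self.scores)}"
            )
        for i, s in enumerate(self.scores, start=1):
            if s not in VALID_SCORES:
                raise SheetValidationError(
                    f"skill {i} ({self.skill_names[i - 1]}): score {s} not in 0/1/2"
                )

    @property
    def entries(self) -> list[tuple[int, str, int]]:
        """(skill_id, skill_name, score) triples, 1-based ids."""
        return [
            (i + 1, name, score)
            for i, (name, score) in enumerate(zip(self.skill_names, self.scores))
        ]


@dataclass(frozen=True)
class CapacityResult:
    """Total capacity as an exact percentage plus its one-decimal display."""

    percent: float
    display: str


def validate_sheet(
    raw_scores, interface_label: str = "", subject_label: str = ""
) -> SkillSheet:
    """Validate a raw score list into a sheet, attaching skill names by position."""
    return SkillSheet(tuple(raw_scores), interface_label, subject_label)


def total_capacity(sheet: SkillSheet) -> CapacityResult:
    """Total capacity percentage: 100 * sum / (2 * n_skills).

    The display string truncates toward zero at one decimal, matching how
    capacities are conventionally printed (exact tenths via integer
    arithmetic, so no floating-point rounding sneaks in).
    """
    total = sum(sheet.scores)
    denom = 2 * len(sheet.scores)
    tenths = (1000 * total) // denom
    return CapacityResult(percent=100.0 * total / denom, display=f"{tenths / 10:.1f}")


def compare_interfaces(sheets: list[SkillSheet]) -> pd.DataFrame:
    """Side-by-side per-skill score table with a total-capacity row.

    Columns are labelled "<subject> <interface>"; rows are ordered by
    skill id, with a final ``Total capacity [%]`` row holding the truncated
    one-decimal displays.
    """
    if not sheets:
        return pd.DataFrame()
    names = sheets[0].skill_names
    for sh in sheets:
        if sh.skill_names != names:
            raise SheetValidationError("sheets do not share the same skill list")
    columns = {}
    for sh in sheets:
        label = " ".join(p for p in (sh.subject_label, sh.interface_label) if p) or "sheet"
        base = label
        k = 2
        while label in columns:
            label = f"{base} ({k})"
            k += 1
        columns[label] = list(sh.scores) + [total_capacity(sh).display]
    index = [f"{i + 1}. {name}" for i, name in enumerate(names)] + ["Total capacity [%]"]
    return pd.DataFrame(columns, index=index)


def demo_sheets() -> list[SkillSheet]:
    """The four score sheets from the platform's two-volunteer evaluation.

    Volunteers A and B each completed the 15 skills twice, once steering by
    head tilts and once by voice commands.
    """
    return [
        SkillSheet((2, 2, 2, 1, 2, 1, 2, 2, 2, 2, 2, 2, 2, 2, 2), "head", "volunteer A"),
        SkillSheet((0, 0, 2, 0, 2, 1, 2, 1, 1, 2, 2, 2, 2, 0, 2), "voice", "volunteer A"),
        SkillSheet((2, 2, 1, 2, 2, 1, 2, 2, 2, 2, 2, 2, 2, 0, 2), "head", "volunteer B"),
        SkillSheet((0, 0, 2, 0, 2, 1, 2, 1, 2, 2, 2, 2, 2, 0, 2), "voice", "volunteer B"),
    ]


# -- CSV dialect: skill_id,skill_name,score ---------------------------------

def read_sheet_csv(path, interface_label: str = "", subject_label: str = "") -> SkillSheet:
    df = pd.read_csv(path)
    for col in ("skill_id", "skill_name", "score"):
        if col not in df.columns:
            raise SheetValidationError(f"sheet CSV missing column {col!r}")
    df = df.sort_values("skill_id")
    return SkillSheet(
        tuple(int(s) for s in df["score"]),
        interface_label=interface_label,
        subject_label=subject_label,
        skill_names=tuple(str(n) for n in df["skill_name"]),
    )


def write_sheet_csv(sheet: SkillSheet, path) -> None:
    pd.DataFrame(
        sheet.entries, columns=["skill_id", "skill_name", "score"]
    ).to_csv(path, index=False)
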