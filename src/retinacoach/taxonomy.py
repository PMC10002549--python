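"""Condition taxonomy for the retina study module.

The taxonomy covers 39 fine-grained retinal condition classes (``C0``–``C38``)
assembled from three public fundus-photograph datasets, of which 22 survived
the small-class retention filter.  Because one source dataset does not
distinguish diabetic-retinopathy stages, the four DR stage classes
(``C2``–``C5``) collapse into the single allocation-level class ``DR``,
leaving 19 retinal conditions (RCs) at the level where cases are allocated to
residents.  The 19 RCs are partitioned into six educational topics
(``T1``–``T6``) by the anatomical structure involved.

The taxonomy ships as a versioned CSV data file so the mapping and topic
membership can be audited and extended without touching code.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import FrozenSet, Iterable, Mapping

__all__ = [
    "ConditionClass",
    "ConditionTaxonomy",
    "TaxonomyError",
    "DR_STAGES",
    "DIFFICULTY_SCORES",
    "GOAL_GRADE",
    "load_taxonomy",
    "difficulty_score",
]

#: Fine DR stage classes grouped into the single allocation-level class "DR".
DR_STAGES = frozenset({"C2", "C3", "C4", "C5"})

#: Case difficulty bands map to odd scores so a difficult case outweighs
#: performance differences in the final grade.
DIFFICULTY_SCORES = {"easy": 1, "medium": 3, "difficult": 5}

#: A resident meets the per-condition educational goal with a grade >= 7
#: (performance score plus case difficulty score).
GOAL_GRADE = 7


class TaxonomyError(KeyError):
    """Raised for unknown, non-retained, or non-allocation-level codes."""


@dataclass(frozen=True)
class ConditionClass:
    """One row of the condition taxonomy.

    Attributes
    ----------
    code:
        Canonical class code (``C0``..``C38`` or ``DR``).
    display_name:
        Clinical label.
    topic:
        Educational topic code (``T1``..``T6``), empty for classes that are
        not allocation-level.
    retained:
        Whether the fine class survived the >= 50 image retention filter.
    allocation_level:
        Whether the class is one of the 19 RCs used for case allocation.
    supplementary_rare:
        Whether the class was removed for scarcity; such classes are still
        shown once as virtual cases to residents who met all goals.
    """

    code: str
    display_name: str
    topic: str
    retained: bool
    allocation_level: bool
    supplementary_rare: bool


@dataclass(frozen=True)
class ConditionTaxonomy:
    """Immutable lookup structure over the condition classes."""

    classes: Mapping[str, ConditionClass]
    _topic_members: Mapping[str, FrozenSet[str]] = field(repr=False, default=None)

    def __post_init__(self):
        members: dict[str, set[str]] = {}
        for c in self.classes.values():
            if c.allocation_level:
                members.setdefault(c.topic, set()).add(c.code)
        object.__setattr__(
            self,
            "_topic_members",
            {t: frozenset(m) for t, m in sorted(members.items())},
        )

    # -- code sets ---------------------------------------------------------

    @property
    def retained(self) -> list[str]:
        """The 22 fine classes kept by the retention filter, in code order."""
        return [c.code for c in self._ordered() if c.retained]

    @property
    def allocation_level(self) -> list[str]:
        """The 19 RCs (DR grouped), in code order with DR in place of C2-C5."""
        return [c.code for c in self._ordered() if c.allocation_level]

    @property
    def supplementary_rare(self) -> list[str]:
        return [c.code for c in self._ordered() if c.supplementary_rare]

    @property
    def topics(self) -> Mapping[str, FrozenSet[str]]:
        """Educational topic -> member RC codes (a partition of the 19 RCs)."""
        return self._topic_members

    def _ordered(self) -> list[ConditionClass]:
        def key(c: ConditionClass):
            return (0, int(c.code[1:])) if c.code.startswith("C") else (1, 0)

        return sorted(self.classes.values(), key=key)

    # -- operations --------------------------------------------------------

    def topic_of(self, condition: str) -> str:
        """Return the educational topic containing an allocation-level RC."""
        c = self.classes.get(condition)
        if c is None or not c.allocation_level:
            raise TaxonomyError(
                f"{condition!r} is not an allocation-level retinal condition"
            )
        return c.topic

    def collapse_dr(self, labels: Iterable[str]) -> frozenset[str]:
        """Map a set of retained fine classes to allocation-level codes.

        Every DR stage (C2-C5) is replaced by ``DR``; other codes pass
        through.  Idempotent: ``DR`` itself maps to ``DR``.
        """
        out = set()
        for code in labels:
            c = self.classes.get(code)
            if c is None or not (c.retained or c.allocation_level):
                raise TaxonomyError(f"{code!r} is not a retained class")
            out.add("DR" if code in DR_STAGES else code)
        return frozenset(out)

    def is_allocation_level(self, code: str) -> bool:
        c = self.classes.get(code)
        return c is not None and c.allocation_level


def difficulty_score(band: str) -> int:
    """Map a difficulty band to its score: easy=1, medium=3, difficult=5."""
    try:
        return DIFFICULTY_SCORES[band]
    except KeyError:
        raise ValueError(f"unknown difficulty band {band!r}") from None


def load_taxonomy(path=None) -> ConditionTaxonomy:
    """Load the condition taxonomy from CSV (default: the packaged file)."""
    if path is None:
        source = resources.files("retinacoach.data").joinpath("taxonomy.csv")
        text = source.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    classes = {}
    for row in csv.DictReader(text.splitlines()):
        cc = ConditionClass(
            code=row["code"],
            display_name=row["display_name"],
            topic=row["topic"],
            retained=row["retained"] == "1",
            allocation_level=row["allocation_level"] == "1",
            supplementary_rare=row["supplementary_rare"] == "1",
        )
        if cc.code in classes:
            raise ValueError(f"duplicate taxonomy code {cc.code}")
        classes[cc.code] = cc
    return ConditionTaxonomy(classes=classes)


_DEFAULT: ConditionTaxonomy | None = None


def default_taxonomy() -> ConditionTaxonomy:
    """The packaged taxonomy, loaded once per process."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_taxonomy()
    return _DEFAULT
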