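"""Structure of the simulated symptom rating scale.

The simulated instrument mirrors the Revised Clinical Interview Schedule
(CIS-R): 14 items covering negative symptoms, each assessed through four
binary (0/1) questions — five for depressive ideas — with every endorsed
question contributing one point, so the total score runs from 0 to 57.
Each binary question corresponds to exactly one threshold on the latent
severity scale, which is why threshold counts and maximum total scores
coincide for binary instruments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

__all__ = [
    "ItemSpec",
    "InstrumentSpec",
    "make_cisr_like_instrument",
    "count_thresholds",
    "max_total_score",
]

# Item names and order follow the CIS-R negative-symptom inventory.
_CISR_ITEM_NAMES = (
    "somatic symptoms",
    "fatigue",
    "concentration",
    "sleep",
    "irritability",
    "worry about physical health",
    "depression",
    "depressive ideas",
    "worry",
    "anxiety",
    "phobias",
    "panic",
    "compulsions",
    "obsessions",
)


@dataclass(frozen=True)
class ItemSpec:
    """One scale item: a named group of binary questions.

    Parameters
    ----------
    name : str
        Human-readable item label.
    n_questions : int
        Number of binary questions; each contributes one point.
    """

    name: str
    n_questions: int

    def __post_init__(self) -> None:
        if self.n_questions < 1:
            raise ValueError(f"n_questions must be >= 1, got {self.n_questions}")


@dataclass(frozen=True)
class InstrumentSpec:
    """An ordered collection of items forming a rating scale."""

    items: tuple[ItemSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))

    @property
    def n_questions(self) -> int:
        """Total number of binary questions across all items."""
        return sum(item.n_questions for item in self.items)

    def question_labels(self) -> list[tuple[str, int]]:
        """(item name, 1-based question number) for every question, in order."""
        return [
            (item.name, q + 1)
            for item in self.items
            for q in range(item.n_questions)
        ]

    def to_json(self) -> str:
        """Serialize as a JSON list of ``{"name", "n_questions"}`` objects."""
        return json.dumps(
            [{"name": it.name, "n_questions": it.n_questions} for it in self.items]
        )

    @classmethod
    def from_json(cls, text: str) -> "InstrumentSpec":
        data = json.loads(text)
        return cls(tuple(ItemSpec(d["name"], int(d["n_questions"])) for d in data))


def make_cisr_like_instrument() -> InstrumentSpec:
    """Build the CIS-R-like instrument: 14 items, 57 binary questions.

    Every item has four questions except "depressive ideas", which has five,
    giving per-item scores of 0-4 (0-5 for depressive ideas) and a total
    score range of 0-57.
    """
    items = tuple(
        ItemSpec(name, 5 if name == "depressive ideas" else 4)
        for name in _CISR_ITEM_NAMES
    )
    return InstrumentSpec(items)


def count_thresholds(instrument: InstrumentSpec, thresholds_per_question: int = 1) -> int:
    """Number of latent-scale thresholds implied by the instrument.

    A binary question has one threshold; a k-point Likert question has
    k - 1, passed as ``thresholds_per_question``.  For the CIS-R-like
    instrument this gives 57; a 16-item scale with one four-point question
    per item gives 48.
    """
    if thresholds_per_question < 1:
        raise ValueError(
            f"thresholds_per_question must be >= 1, got {thresholds_per_question}"
        )
    return instrument.n_questions * thresholds_per_question


def max_total_score(instrument: InstrumentSpec) -> int:
    """Maximum attainable total score (every question endorsed)."""
    return instrument.n_questions
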