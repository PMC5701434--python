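"""Per-question symptom prevalence tables.

Threshold calibration needs one general-population endorsement probability
per binary question.  The survey rates the model was built around (APMS
2007) are not publicly tabulated, so this module provides (a) a seeded
generator of plausible synthetic prevalence tables and (b) a frozen
57-row fixture table whose first row carries the one published value,
5.49% for "somatic symptom 1".  Everything downstream is testable against
the fixture without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .instrument import InstrumentSpec, make_cisr_like_instrument

__all__ = [
    "PrevalenceTable",
    "generate_prevalence_table",
    "fixture_prevalence_table",
]

_COLUMNS = ["item", "question", "prevalence"]
_FIXTURE_FILE = "prevalence_fixture_synthetic.csv"


@dataclass(frozen=True)
class PrevalenceTable:
    """Ordered per-question endorsement probabilities.

    ``table`` has columns ``item`` (item name), ``question`` (1-based
    question number within the item) and ``prevalence`` (proportion in the
    open interval (0, 1); the boundary values would make the calibrating
    quantile degenerate).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"prevalence table missing columns {missing}")
        p = df["prevalence"].to_numpy(dtype=float)
        if not np.all((p > 0.0) & (p < 1.0)):
            raise ValueError("all prevalence values must lie strictly in (0, 1)")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def p(self) -> np.ndarray:
        """Prevalence values as a float array, in question order."""
        return self.table["prevalence"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    def matches(self, instrument: InstrumentSpec) -> bool:
        """True if the row count equals the instrument's question count."""
        return len(self) == instrument.n_questions

    def to_csv(self, path: str | Path) -> None:
        """Write as UTF-8 CSV with six-decimal prevalence formatting.

        Six decimals make the write/read round trip bit-exact because
        generated tables are rounded to six decimals at creation.
        """
        self.table.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PrevalenceTable":
        return cls(pd.read_csv(path))


def generate_prevalence_table(
    instrument: InstrumentSpec,
    seed: int,
    p_min: float = 0.01,
    p_max: float = 0.35,
) -> PrevalenceTable:
    """Draw a synthetic prevalence table, one row per question.

    Values are drawn log-uniformly on [p_min, p_max] — symptom endorsement
    rates in population surveys are right-skewed, and a log-uniform spread
    over roughly 1-35% reproduces that skew — then rounded to six decimals
    so CSV round trips are exact.  Deterministic given ``seed``.
    """
    if not (0.0 < p_min < p_max < 1.0):
        raise ValueError(f"require 0 < p_min < p_max < 1, got ({p_min}, {p_max})")
    rng = np.random.default_rng(seed)
    n = instrument.n_questions
    p = np.exp(rng.uniform(np.log(p_min), np.log(p_max), size=n))
    p = np.round(p, 6)
    labels = instrument.question_labels()
    df = pd.DataFrame(
        {
            "item": [item for item, _ in labels],
            "question": [q for _, q in labels],
            "prevalence": p,
        }
    )
    return PrevalenceTable(df)


def fixture_prevalence_table(
    instrument: InstrumentSpec | None = None,
) -> PrevalenceTable:
    """Load the frozen 57-row synthetic prevalence fixture.

    The fixture was generated once by ``generate_prevalence_table`` with
    seed 2007 on the CIS-R-like instrument, after which the first row
    ("somatic symptoms", question 1) was pinned to 0.0549 — the published
    5.49% rate for "somatic symptom 1".  The other 56 values are synthetic
    stand-ins and claim no resemblance to the real survey rates.
    """
    if instrument is None:
        instrument = make_cisr_like_instrument()
    with resources.files("exptrait.data").joinpath(_FIXTURE_FILE).open("r") as fh:
        tab = PrevalenceTable(pd.read_csv(fh))
    if not tab.matches(instrument):
        raise ValueError(
            f"fixture has {len(tab)} rows but instrument has "
            f"{instrument.n_questions} questions"
        )
    return tab
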