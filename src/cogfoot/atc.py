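"""Anatomical Therapeutic Chemical (ATC) code handling.

The WHO ATC system codes medications hierarchically: level 5 identifies a
chemical substance with a 7-character code (e.g. ``M01AE01``, ibuprofen)
and level 4 a pharmacological subgroup with the first 5 characters
(e.g. ``M01AE``, propionic-acid NSAIDs).  Exposure analyses are run
separately at both levels, with level-4 exposure defined as use of *any*
child substance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ATCCode",
    "ATCError",
    "atc_parent",
    "aggregate_level4",
    "prevalence_filter",
]

# Prefixes of a full level-5 code: L1 letter, L2 two digits, L3 letter,
# L4 letter, L5 two digits.  Shorter official codes (e.g. "A10A") stop at
# an intermediate level and are accepted as-is.
_ATC_RE = re.compile(r"^[A-Z]([0-9]{2}([A-Z]([A-Z]([0-9]{2})?)?)?)?$")


class ATCError(ValueError):
    """Raised for strings that do not parse as ATC codes."""


@dataclass(frozen=True)
class ATCCode:
    """A validated ATC code.

    Attributes
    ----------
    code:
        The uppercase code string.
    level:
        5 for 7-character substance codes, 4 for 5-character subgroup
        codes; shorter codes carry their nominal depth (1-3).
    """

    code: str
    level: int

    @classmethod
    def parse(cls, text: str) -> "ATCCode":
        code = str(text).strip().upper()
        if not code or not _ATC_RE.match(code):
            raise ATCError(f"malformed ATC code: {text!r}")
        level = {1: 1, 3: 2, 4: 3, 5: 4, 7: 5}[len(code)]
        return cls(code=code, level=level)

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.code


def atc_parent(code: str | ATCCode) -> ATCCode:
    """Return the level-4 parent of a level-5 code.

    7-character codes are truncated to their first 5 characters; codes of
    length 5 or shorter (already at level 4 or above, e.g. ``A10A``) pass
    through unchanged.
    """
    parsed = code if isinstance(code, ATCCode) else ATCCode.parse(code)
    if len(parsed.code) == 7:
        return ATCCode.parse(parsed.code[:5])
    return parsed


def aggregate_level4(exposures: pd.DataFrame) -> pd.DataFrame:
    """Collapse level-5 exposure indicators to their level-4 parents.

    The level-4 indicator for a participant is the logical OR of all child
    level-5 indicators.  Columns already at level 4 or shallower map to
    themselves, so the operation is idempotent.  Output columns are sorted
    lexicographically.
    """
    if exposures.shape[1] == 0:
        return exposures.iloc[:, :0].copy()
    parents: dict[str, list[str]] = {}
    for col in exposures.columns:
        parents.setdefault(atc_parent(col).code, []).append(col)
    out = {}
    for parent in sorted(parents):
        block = exposures[parents[parent]].to_numpy()
        out[parent] = np.any(block.astype(bool), axis=1).astype(np.int8)
    return pd.DataFrame(out, index=exposures.index)


def prevalence_filter(
    exposures: pd.DataFrame, threshold: float = 0.01
) -> list[str]:
    """Codes whose observed prevalence strictly exceeds ``threshold``.

    "Over 1% prevalence of regular use" is read strictly: a code at
    exactly the threshold is dropped.  Applied independently at whichever
    ATC level the columns represent.
    """
    prev = exposures.mean(axis=0)
    return [c for c in exposures.columns if prev[c] > threshold]
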