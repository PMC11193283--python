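"""The canonical abridged-age schedule: 0, 1-4, then 5-year groups to 95+.

All tables in this package (coefficients, YLD series, life tables) are keyed
by these 21 labels, in this order.  Loaders reject any other spelling rather
than coerce it, so that rows can never be silently misaligned.
"""

from __future__ import annotations

import math
from typing import Sequence

AGE_LABELS: tuple[str, ...] = (
    "0", "1-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34",
    "35-39", "40-44", "45-49", "50-54", "55-59", "60-64", "65-69",
    "70-74", "75-79", "80-84", "85-89", "90-94", "95+",
)

N_AGES = len(AGE_LABELS)  # 21

#: start of each group in exact years
AGE_STARTS: tuple[float, ...] = (0.0, 1.0) + tuple(float(x) for x in range(5, 100, 5))

#: width of each group in years; the last group is open-ended
AGE_WIDTHS: tuple[float, ...] = (1.0, 4.0) + (5.0,) * 18 + (math.inf,)

_LABEL_INDEX = {label: i for i, label in enumerate(AGE_LABELS)}


def age_index(label: str) -> int:
    """Position of an age-group label in the canonical schedule."""
    try:
        return _LABEL_INDEX[label]
    except KeyError:
        raise ValueError(
            f"unknown age-group label {label!r}; expected one of "
            f"{', '.join(AGE_LABELS)}"
        ) from None


def validate_age_labels(labels: Sequence[str]) -> None:
    """Require *labels* to be exactly the canonical 21 labels in order."""
    got = tuple(labels)
    if got != AGE_LABELS:
        missing = [l for l in AGE_LABELS if l not in got]
        extra = [l for l in got if l not in _LABEL_INDEX]
        raise ValueError(
            "age-group labels must be the canonical 21-group schedule in order"
            + (f"; missing {missing}" if missing else "")
            + (f"; unrecognised {extra}" if extra else "")
        )
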