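"""The fixed adult age grid.

Onset is analysed between the 21st and 85th birthdays: diagnoses at ages 20
and below are excluded (developmental rather than ageing-related processes),
as are diagnoses from age 85 on (survival bias in the very old). Every curve
in the package therefore lives on the 64-point integer grid 21..84.
"""

from __future__ import annotations

import numpy as np

AGE_MIN: int = 21
AGE_MAX: int = 84
AGES: np.ndarray = np.arange(AGE_MIN, AGE_MAX + 1)
N_AGES: int = AGES.size  # 64


def check_age_grid(ages) -> np.ndarray:
    """Validate that *ages* is exactly the grid 21..84 and return it as ints.

    Raises
    ------
    AgeGridError
        If any age is missing, duplicated, out of range or unsorted.
    """
    from .exceptions import AgeGridError

    arr = np.asarray(ages)
    if arr.shape != AGES.shape or not np.array_equal(arr, AGES):
        raise AgeGridError(
            f"expected the integer age grid {AGE_MIN}..{AGE_MAX} "
            f"({N_AGES} points, sorted, no gaps); got {arr.size} ages"
        )
    return AGES.copy()
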