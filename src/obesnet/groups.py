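"""Demographic groupings shared across the package.

Agents are stratified into six age groups (16-20, 21-30, 31-45, 46-60,
61-75, 76+) and two genders.  Several calibratable gains (the norms flow
gain and the external-factor gain) are split along exactly this
2 x 6 grid, so the ordering here is load-bearing: male = 0, female = 1,
and age groups are indexed youngest to oldest.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

__all__ = [
    "AGE_GROUP_LABELS",
    "AGE_GROUP_LOWER",
    "AGE_GROUP_UPPER",
    "AgeGroup",
    "Gender",
    "MAX_AGE",
    "age_group_index",
    "age_group_label",
]

#: Upper bound used when sampling/capping ages; agents older than this are
#: still valid but the synthetic age pyramid does not generate them.
MAX_AGE = 90.0

AGE_GROUP_LABELS: tuple[str, ...] = ("16-20", "21-30", "31-45", "46-60", "61-75", "76+")
AGE_GROUP_LOWER = np.array([16.0, 21.0, 31.0, 46.0, 61.0, 76.0])
AGE_GROUP_UPPER = np.array([21.0, 31.0, 46.0, 61.0, 76.0, np.inf])


class Gender(IntEnum):
    MALE = 0
    FEMALE = 1

    @classmethod
    def parse(cls, value) -> "Gender":
        if isinstance(value, Gender):
            return value
        if isinstance(value, (int, np.integer)):
            return cls(int(value))
        text = str(value).strip().lower()
        if text in ("m", "male", "0"):
            return cls.MALE
        if text in ("f", "female", "1"):
            return cls.FEMALE
        raise ValueError(f"unrecognised gender: {value!r}")

    def __str__(self) -> str:  # CSV-friendly
        return "male" if self is Gender.MALE else "female"


class AgeGroup(IntEnum):
    """Index into :data:`AGE_GROUP_LABELS`."""

    G16_20 = 0
    G21_30 = 1
    G31_45 = 2
    G46_60 = 3
    G61_75 = 4
    G76_PLUS = 5

    @property
    def label(self) -> str:
        return AGE_GROUP_LABELS[int(self)]


def age_group_index(age) -> np.ndarray | int:
    """Map age (years; scalar or array) to its age-group index.

    Ages below 16 are clamped into the first group; the partition of
    [16, inf) means every agent belongs to exactly one group.
    """
    arr = np.asarray(age, dtype=float)
    idx = np.searchsorted(AGE_GROUP_LOWER, arr, side="right") - 1
    idx = np.clip(idx, 0, len(AGE_GROUP_LABELS) - 1)
    if np.isscalar(age) or arr.ndim == 0:
        return int(idx)
    return idx.astype(np.int64)


def age_group_label(age: float) -> str:
    return AGE_GROUP_LABELS[int(age_group_index(age))]
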