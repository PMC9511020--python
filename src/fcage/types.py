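"""Core domain containers: ROI time series, connectivity matrices, subjects.

Reference parcellations are 100-region (Schaefer-style, 17-network naming)
and 64-region (BASC-style); any positive region count is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Closed integer age ranges for the four cohort bins (years).
AGE_GROUPS: dict[str, tuple[int, int]] = {
    "young": (20, 40),
    "adult": (41, 55),
    "middle_old": (56, 69),
    "old": (70, 88),
}

GROUP_ORDER: tuple[str, ...] = ("young", "adult", "middle_old", "old")

AGE_MIN, AGE_MAX = 20, 88


def assign_age_group(age: float) -> str:
    """Map an age in years to its cohort bin.

    Ages outside [20, 88] are excluded from the study population and
    raise ``ValueError``.
    """
    if not np.isfinite(age):
        raise ValueError(f"age must be finite, got {age!r}")
    if age < AGE_MIN or age > AGE_MAX:
        raise ValueError(
            f"age {age} outside the study range [{AGE_MIN}, {AGE_MAX}]; "
            "subjects below 20 or above 88 years are excluded"
        )
    for label, (lo, hi) in AGE_GROUPS.items():
        if lo <= age <= hi:
            return label
    # non-integer ages between bin edges (e.g. 40.5) fall to the lower bin
    for label, (lo, hi) in AGE_GROUPS.items():
        if lo <= age <= hi + 1:
            return label
    raise AssertionError("unreachable")


@dataclass
class RoiTimeSeries:
    """One subject's parcellated BOLD signal, timepoints x regions."""

    subject_id: str
    values: np.ndarray  # (T, p)
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D array (T x p)")
        if self.values.shape[1] != len(self.roi_labels):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.roi_labels)} ROI labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in time series of {self.subject_id!r}")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix over regions (unit diagonal)."""

    values: np.ndarray  # (p, p)
    roi_labels: list[str]
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValueError("connectivity matrix must be square")
        if len(self.roi_labels) != p:
            raise ValueError("ROI label count does not match matrix size")

    def validate(self, atol: float = 1e-12) -> None:
        v = self.values
        asym = np.abs(v - v.T).max() if v.size else 0.0
        if asym > atol:
            i, j = np.unravel_index(np.abs(v - v.T).argmax(), v.shape)
            raise ValueError(f"matrix asymmetric: |[{i},{j}] - [{j},{i}]| = {asym:.3g}")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValueError("diagonal must be exactly 1")
        if v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("entries must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureVector:
    """Strictly-lower-triangle vectorization of a connectivity matrix.

    ``index_map`` enumerates (row, col) with row > col in row-major order
    over rows 1..p-1; this order is frozen for reproducibility.
    """

    values: np.ndarray  # (p*(p-1)/2,)
    index_map: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.index_map),):
            raise ValueError("values length does not match index map")


@dataclass
class Subject:
    """A study participant with a group label consistent with their age."""

    subject_id: str
    age: float
    sex: str = "NA"
    group: str = field(default="")

    def __post_init__(self) -> None:
        expected = assign_age_group(self.age)
        if not self.group:
            self.group = expected
        elif self.group != expected:
            raise ValueError(
                f"subject {self.subject_id!r}: group {self.group!r} inconsistent "
                f"with age {self.age} (expected {expected!r})"
            )
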