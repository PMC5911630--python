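"""Median-split dichotomization and subgroup cohort selection.

A marker is dichotomized at the cohort's sample median: samples strictly
above the median are labelled high, everything else (including exact
ties at the median) low.  The tie rule is fixed and stated because the
convention matters for reproducibility with heavily tied expression
values.  Subgroup analyses recompute the split inside each subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["SubgroupSpec", "MedianBinarizer", "median_split", "select_subgroup"]

#: clinical label columns a cohort table may be filtered on
SUBGROUP_LABELS = ("stage", "histology", "her2", "treatment", "all")


@dataclass(frozen=True)
class SubgroupSpec:
    """A clinical subgroup: a label column and the category to keep.

    ``SubgroupSpec("all")`` selects the whole cohort.  Examples:
    ``SubgroupSpec("stage", "3")``, ``SubgroupSpec("histology",
    "intestinal")``, ``SubgroupSpec("her2", "neg")``.
    """

    label: str
    value: str | None = None

    def __post_init__(self):
        if self.label not in SUBGROUP_LABELS:
            raise ValueError(
                f"unknown subgroup label {self.label!r}; expected one of {SUBGROUP_LABELS}"
            )
        if self.label == "all":
            if self.value is not None:
                raise ValueError("'all' takes no value")
        elif self.value is None:
            raise ValueError(f"subgroup label {self.label!r} requires a value")

    def __str__(self) -> str:
        return "all" if self.label == "all" else f"{self.label}={self.value}"

    @classmethod
    def parse(cls, text: str) -> "SubgroupSpec":
        """Parse ``"stage=3"`` / ``"all"`` CLI-style specs."""
        if text == "all":
            return cls("all")
        if "=" not in text:
            raise ValueError(f"subgroup spec {text!r} must look like label=value or 'all'")
        label, value = text.split("=", 1)
        return cls(label, value)


class MedianBinarizer(BaseEstimator, TransformerMixin):
    """Dichotomize a marker at its median (high iff value > median).

    ``fit`` learns ``median_`` from the provided values; ``transform``
    returns 0/1 labels (1 = high).  A constant marker is degenerate and
    rejected at fit time, as is any split that leaves a group empty.
    """

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float).ravel()
        if values.size < 2:
            raise ValueError("median split needs at least 2 values")
        if not np.all(np.isfinite(values)):
            raise ValueError("median split requires finite expression values")
        if np.all(values == values[0]):
            raise ValueError("degenerate marker: all expression values are equal")
        self.median_ = float(np.median(values))
        labels = values > self.median_
        if labels.all() or not labels.any():
            raise ValueError(
                "degenerate marker: median split leaves one group empty "
                "(ties at the median are assigned low)"
            )
        self.n_high_ = int(labels.sum())
        self.n_low_ = int(values.size - self.n_high_)
        return self

    def transform(self, X):
        values = np.asarray(X, dtype=float).ravel()
        return (values > self.median_).astype(int)


def median_split(values) -> np.ndarray:
    """Boolean high/low labels for one marker (True = high).

    High iff strictly above the sample median; exact ties at the median
    go low.  Raises on constant markers or empty groups.
    """
    binarizer = MedianBinarizer().fit(values)
    return binarizer.transform(values).astype(bool)


def select_subgroup(cohort: pd.DataFrame, spec: SubgroupSpec) -> pd.DataFrame:
    """Rows of the cohort matching a subgroup spec, order preserved.

    ``all`` returns the cohort unchanged; an empty selection is an
    error naming the spec.
    """
    if spec.label == "all":
        return cohort
    if spec.label not in cohort.columns:
        raise ValueError(f"cohort has no column {spec.label!r}")
    subset = cohort[cohort[spec.label].astype(str) == str(spec.value)]
    if subset.empty:
        raise ValueError(f"subgroup {spec} selects no samples")
    return subset
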