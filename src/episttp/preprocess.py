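"""Probe filtering and log transformation applied before statistics.

Two filters remove unreliable probes, both defined on linear-scale
processed intensities:

* a low-intensity filter: a probe is kept only if, in at least one
  qualifying replicate group (by default LPS-treated wild-type or
  LPS-treated *Dusp1* knockout samples), at least ``min_passing_replicates``
  of the replicates strictly exceed the intensity threshold (default 100);
* a dispersion filter: a probe is dropped if in any replicate group the
  sample SD (n-1 denominator) exceeds the group mean, a signature of an
  aberrant outlying replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterParams",
    "filter_low_intensity",
    "filter_outlier_dispersion",
    "log2_transform",
]


@dataclass(frozen=True)
class FilterParams:
    intensity_threshold: float = 100.0
    min_passing_replicates: int = 2
    # (genotype, treatment) groups in which expression must be detectable
    qualifying_groups: tuple[tuple[str, str], ...] = field(
        default=(("WT", "LPS"), ("Dusp1KO", "LPS"))
    )

    def validate(self) -> None:
        if self.intensity_threshold <= 0:
            raise ValueError("intensity_threshold must be > 0")
        if self.min_passing_replicates < 1:
            raise ValueError("min_passing_replicates must be >= 1")
        if not self.qualifying_groups:
            raise ValueError("at least one qualifying group is required")


def _group_columns(design: pd.DataFrame, genotype: str, treatment: str) -> list[str]:
    sel = (design["genotype"] == genotype) & (design["treatment"] == treatment)
    return design.loc[sel, "sample_id"].tolist()


def filter_low_intensity(
    matrix: pd.DataFrame, design: pd.DataFrame, params: FilterParams | None = None
) -> pd.Series:
    """Keep-mask: True where the probe is detectably expressed.

    A probe passes if in at least one qualifying group at least
    ``min_passing_replicates`` replicates strictly exceed the threshold.
    Missing values count as failures.
    """
    params = params or FilterParams()
    params.validate()
    keep = np.zeros(len(matrix), dtype=bool)
    for genotype, treatment in params.qualifying_groups:
        cols = _group_columns(design, genotype, treatment)
        if not cols:
            raise ValueError(
                f"qualifying group ({genotype}, {treatment}) absent from design"
            )
        above = (matrix[cols] > params.intensity_threshold).sum(axis=1)
        keep |= (above >= params.min_passing_replicates).to_numpy()
    return pd.Series(keep, index=matrix.index, name="kept")


def filter_outlier_dispersion(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    """Keep-mask: False where any replicate group has SD > mean.

    Evaluated over every (genotype, treatment, timepoint) replicate group in
    the design; groups of size 1 are skipped with a warning.
    """
    drop = np.zeros(len(matrix), dtype=bool)
    for key, sub in design.groupby(["genotype", "treatment", "timepoint"], sort=True):
        cols = sub["sample_id"].tolist()
        if len(cols) < 2:
            warnings.warn(f"replicate group {key} has size 1; dispersion filter skipped")
            continue
        vals = matrix[cols]
        sd = vals.std(axis=1, ddof=1)
        mean = vals.mean(axis=1)
        drop |= (sd > mean).to_numpy()
    return pd.Series(~drop, index=matrix.index, name="kept")


def log2_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(intensity + pseudocount); input must be non-negative."""
    if (matrix < 0).to_numpy().any():
        raise ValueError("negative intensities cannot be log-transformed")
    return np.log2(matrix + pseudocount)
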