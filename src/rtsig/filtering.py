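"""Pre-clustering gene selection: background, fold-change and RIQR filters.

Genes are kept when they are expressed (maximum log2 intensity above a
background floor), vary between samples (linear fold change above a
minimum ratio) and are not invariant, where invariance is measured by the
relative interquartile spread

    RIQR(x) = max(Q3 - Q2, Q2 - Q1) / Q2

with quartiles computed by linear interpolation.  The background floor is
interpreted on the log2 scale, the fold change and (by default) the RIQR
on the linear scale; both RIQR scales are supported and the choice is
recorded in the filter report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix


@dataclass
class GeneFilterParams:
    """Thresholds of the three per-gene filters.

    background_threshold: log2-intensity floor a gene's maximum must reach.
    fold_change_threshold: minimum linear max/min ratio, i.e. 2**(max-min).
    riqr_threshold: minimum relative interquartile spread.
    riqr_scale: scale on which RIQR is evaluated ("linear" or "log2").
    riqr_mode: "absolute" applies riqr_threshold as a cutoff value;
        "quantile" keeps genes above that quantile of the RIQR distribution.
    """

    background_threshold: float = 3.5
    fold_change_threshold: float = 1.2
    riqr_threshold: float = 0.9
    riqr_scale: str = "linear"
    riqr_mode: str = "absolute"

    def __post_init__(self) -> None:
        if min(self.background_threshold, self.fold_change_threshold,
               self.riqr_threshold) <= 0:
            raise ValidationError("filter thresholds must be positive")
        if self.riqr_scale not in ("linear", "log2"):
            raise ValidationError(f"unknown riqr_scale {self.riqr_scale!r}")
        if self.riqr_mode not in ("absolute", "quantile"):
            raise ValidationError(f"unknown riqr_mode {self.riqr_mode!r}")


def riqr(values: Sequence[float]) -> float:
    """Relative interquartile spread max(Q3-Q2, Q2-Q1)/Q2 of a vector.

    Requires at least four strictly positive values (on the scale the
    caller chose); quartiles use linear interpolation.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValidationError(f"RIQR needs >= 4 values, got {x.size}")
    if (x <= 0).any():
        raise ValidationError("RIQR requires strictly positive values")
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    if q2 == 0:
        raise ZeroDivisionError("RIQR undefined: median is zero")
    return float(max(q3 - q2, q2 - q1) / q2)


def filter_genes(matrix: ExpressionMatrix,
                 params: GeneFilterParams | None = None,
                 ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Apply the background / fold-change / RIQR cascade gene by gene.

    Returns the filtered matrix and a per-gene report with each gene's
    statistics, whether it was kept, and the first rule that removed it.
    Filtering is strictly per-gene, so row order never changes the outcome.
    """
    params = params or GeneFilterParams()
    values = matrix.values
    max_log2 = values.max(axis=1)
    fold_change = 2.0 ** np.ptp(values, axis=1)
    riqr_input = 2.0 ** values if params.riqr_scale == "linear" else values
    q1, q2, q3 = np.percentile(riqr_input, [25, 50, 75], axis=1)
    riqr_values = np.maximum(q3 - q2, q2 - q1) / q2

    riqr_cutoff = params.riqr_threshold
    if params.riqr_mode == "quantile":
        riqr_cutoff = float(np.quantile(riqr_values, params.riqr_threshold))

    pass_bg = max_log2 >= params.background_threshold
    pass_fc = fold_change >= params.fold_change_threshold
    pass_riqr = riqr_values >= riqr_cutoff
    kept = pass_bg & pass_fc & pass_riqr

    removed_by = np.where(~pass_bg, "background",
                          np.where(~pass_fc, "fold_change",
                                   np.where(~pass_riqr, "riqr", "")))
    removed_by = np.where(kept, "", removed_by)

    report = pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "max_log2": max_log2,
        "fold_change": fold_change,
        "riqr": riqr_values,
        "kept": kept,
        "removed_by": removed_by,
    }).set_index("gene_id")
    report.attrs["riqr_scale"] = params.riqr_scale
    report.attrs["riqr_cutoff"] = riqr_cutoff

    if not kept.any():
        raise ValidationError("all genes removed by filtering: empty matrix")
    filtered = ExpressionMatrix(matrix.data.loc[kept], log2=matrix.log2)
    return filtered, report
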