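"""Relative qPCR quantification by the 2^-ddCt method.

Expression of a target gene is reported as the N-fold difference relative
to an endogenous reference gene (TBP by default) and a calibrator
condition.  Technical replicates are averaged on the Ct (cycle) scale
before any delta is taken; the calibrator delta-Ct is the mean delta-Ct
of a designated reference sample group.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_REFERENCE_GENE = "TBP"


def fold_change_ddct(ct_target_sample: float, ct_ref_sample: float,
                     ct_target_calibrator: float,
                     ct_ref_calibrator: float) -> float:
    """2^-(ddCt) fold change of a target gene in a sample vs a calibrator.

    dCt_sample = Ct(target, sample) - Ct(reference, sample);
    dCt_calibrator likewise; returns 2^-(dCt_sample - dCt_calibrator).
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator,
           ct_ref_calibrator)
    if not all(math.isfinite(c) for c in cts):
        raise ValidationError("all Ct values must be finite")
    d_sample = ct_target_sample - ct_ref_sample
    d_cal = ct_target_calibrator - ct_ref_calibrator
    return float(2.0 ** -(d_sample - d_cal))


def relative_expression(ct_table: pd.DataFrame, target_gene: str,
                        calibrator_samples: list[str],
                        reference_gene: str = DEFAULT_REFERENCE_GENE,
                        ) -> pd.Series:
    """Per-sample 2^-ddCt fold changes for one target gene.

    ``ct_table`` holds columns sample_id, gene, ct (replicate rows
    allowed; they are averaged on the Ct scale).  The calibrator delta-Ct
    is the mean delta-Ct over ``calibrator_samples``.
    """
    needed = {"sample_id", "gene", "ct"}
    if not needed.issubset(ct_table.columns):
        raise ValidationError(f"Ct table misses {sorted(needed - set(ct_table.columns))}")
    mean_ct = (ct_table.groupby(["sample_id", "gene"])["ct"]
               .mean().unstack("gene"))
    for g in (target_gene, reference_gene):
        if g not in mean_ct.columns:
            raise ValidationError(f"gene {g!r} absent from Ct table")
    missing = [s for s in calibrator_samples if s not in mean_ct.index]
    if missing:
        raise ValidationError(f"calibrator samples absent: {missing}")
    dct = mean_ct[target_gene] - mean_ct[reference_gene]
    if dct.isna().any():
        bad = list(dct.index[dct.isna()])[:5]
        raise ValidationError(f"samples missing target or reference Ct: {bad}")
    dct_cal = float(dct.loc[calibrator_samples].mean())
    folds = 2.0 ** -(dct - dct_cal)
    folds.name = f"fold_{target_gene}_vs_{reference_gene}"
    return folds
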