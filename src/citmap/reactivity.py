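"""T-cell reactivity arithmetic: stimulation index, response calls, readouts.

Proliferation of peptide-stimulated T cells is measured as 3H-thymidine
counts per minute (cpm) over replicate wells; the stimulation index (SI)
is the mean stimulated cpm over the mean background (no-peptide) cpm, with
SI > 2 called a positive proliferative response.  IFN-gamma secretion
above 100 pg/ml is called a strong positive cytokine response.  Both
thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReactivityRecord",
    "ReactivityError",
    "SI_POSITIVE_THRESHOLD",
    "IFNG_STRONG_PG_ML",
    "stimulation_index",
    "classify_response",
    "readout_correlation",
    "reactivity_report",
]

SI_POSITIVE_THRESHOLD = 2.0
IFNG_STRONG_PG_ML = 100.0


class ReactivityError(ValueError):
    """Invalid reactivity computation request."""


@dataclass(frozen=True)
class ReactivityRecord:
    """One patient x condition assay readout (quadruplicate wells)."""

    patient_id: str
    condition: str
    cpm_replicates: tuple[float, ...]
    cpm_background_replicates: tuple[float, ...]
    ifng_pg_ml: float = float("nan")

    def __post_init__(self) -> None:
        if not self.cpm_replicates or not self.cpm_background_replicates:
            raise ReactivityError("replicate lists must be non-empty")
        if min(self.cpm_replicates) < 0 or min(self.cpm_background_replicates) < 0:
            raise ReactivityError("cpm values must be non-negative")


def stimulation_index(record: ReactivityRecord) -> float:
    """SI = mean(stimulated cpm) / mean(background cpm)."""
    background = float(np.mean(record.cpm_background_replicates))
    if background <= 0:
        raise ReactivityError(
            f"{record.patient_id}/{record.condition}: background mean is "
            f"{background}; SI undefined"
        )
    return float(np.mean(record.cpm_replicates)) / background


def classify_response(si: float, ifng_pg_ml: float) -> dict[str, bool]:
    """Strict-threshold response calls from the two readouts."""
    return {
        "proliferation_positive": si > SI_POSITIVE_THRESHOLD,
        "ifng_strong_positive": ifng_pg_ml > IFNG_STRONG_PG_ML,
    }


def readout_correlation(
    si_values: Sequence[float], ifng_values: Sequence[float]
) -> tuple[float, float]:
    """Pearson r and two-sided p between the two readouts."""
    x = np.asarray(si_values, dtype=float)
    y = np.asarray(ifng_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ReactivityError("inputs must be 1-D and of equal length")
    if len(x) < 3:
        raise ReactivityError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ReactivityError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def reactivity_report(
    records: Sequence[ReactivityRecord], path: str | Path | None = None
) -> pd.DataFrame:
    """Per-record SI and response flags, wells reported individually too."""
    rows = []
    for rec in records:
        si = stimulation_index(rec)
        flags = classify_response(si, rec.ifng_pg_ml)
        background = float(np.mean(rec.cpm_background_replicates))
        for well, cpm in enumerate(rec.cpm_replicates, start=1):
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "condition": rec.condition,
                    "well": well,
                    "cpm": cpm,
                    "si_well": cpm / background,
                    "si_mean": si,
                    "ifng_pg_ml": rec.ifng_pg_ml,
                    **flags,
                }
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
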