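"""Class-stratified target-decoy FDR estimation.

Citrullination and deamidation share the same +0.984 Da precursor shift,
and spectra of such 1-Da-modified peptides are harder to tell from chance
matches: their target/decoy score separation is poorer, so a single global
score cutoff under-controls the FDR within that class.  The remedy is to
stratify: estimate a separate target-decoy FDR curve for the
1-Da-modified peptide class and for everything else, and apply each
class's own cutoff at the nominal level.  The modified class then ends up
with a more demanding cutoff whenever its separation is poorer.

Estimator: fdr(t) = #decoys(score >= t) / max(1, #targets(score >= t)),
monotonized into q-values by a cumulative minimum running from the most
permissive threshold upward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import PSM, PeptideKey, parse_modifications

__all__ = [
    "MODIFIED_1DA",
    "OTHER",
    "FDRCurve",
    "FDRError",
    "StratifiedResult",
    "assign_class",
    "fdr_curve",
    "cutoff_at_fdr",
    "stratified_filter",
    "write_fdr_curve",
]

MODIFIED_1DA = "modified_1Da"
OTHER = "other"

_CLASS_1DA_KINDS = frozenset({"citrullination", "deamidation"})


class FDRError(ValueError):
    """Invalid FDR estimation request."""


def assign_class(key: PeptideKey | str) -> str:
    """Classify a peptide key by its modification string.

    ``modified_1Da`` iff any citrullination or deamidation is present;
    oxidation/carbamidomethyl alone (or no modifications) give ``other``.
    """
    modstring = key.modifications if isinstance(key, PeptideKey) else key
    kinds = {kind for kind, _ in parse_modifications(modstring)}
    return MODIFIED_1DA if kinds & _CLASS_1DA_KINDS else OTHER


@dataclass(frozen=True)
class FDRCurve:
    """Target-decoy FDR along the descending grid of observed scores."""

    thresholds: np.ndarray  # descending unique scores
    n_targets_ge: np.ndarray
    n_decoys_ge: np.ndarray
    fdr: np.ndarray
    qvalue: np.ndarray

    def __len__(self) -> int:
        return len(self.thresholds)


def fdr_curve(
    scores: Sequence[float] | np.ndarray,
    is_decoy: Sequence[bool] | np.ndarray,
) -> FDRCurve:
    """Estimate the FDR curve from internal (higher-is-better) scores."""
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    if scores.shape != is_decoy.shape or scores.ndim != 1:
        raise FDRError("scores and is_decoy must be 1-D arrays of equal length")
    if not np.any(~is_decoy):
        raise FDRError("no target PSMs: cannot estimate FDR")
    thresholds = np.unique(scores)[::-1]
    # counts with score >= t for each threshold t (thresholds descending)
    tgt_sorted = np.sort(scores[~is_decoy])
    dec_sorted = np.sort(scores[is_decoy])
    n_targets_ge = len(tgt_sorted) - np.searchsorted(tgt_sorted, thresholds, side="left")
    n_decoys_ge = len(dec_sorted) - np.searchsorted(dec_sorted, thresholds, side="left")
    fdr = n_decoys_ge / np.maximum(1, n_targets_ge)
    # most permissive threshold is the last entry: cumulative min upward
    qvalue = np.minimum.accumulate(fdr[::-1])[::-1]
    return FDRCurve(
        thresholds=thresholds,
        n_targets_ge=n_targets_ge,
        n_decoys_ge=n_decoys_ge,
        fdr=fdr,
        qvalue=qvalue,
    )


def cutoff_at_fdr(curve: FDRCurve, alpha: float) -> float | None:
    """Most permissive observed score threshold with q-value <= alpha.

    Returns None when no threshold attains the level.
    """
    if not 0 < alpha < 1:
        raise FDRError(f"alpha must be in (0, 1), got {alpha}")
    ok = np.flatnonzero(curve.qvalue <= alpha)
    if ok.size == 0:
        return None
    return float(curve.thresholds[ok[-1]])


@dataclass
class StratifiedResult:
    """Per-class curves, cutoffs, and accepted target peptide keys."""

    curves: dict[str, FDRCurve]
    cutoffs: dict[str, float | None]
    accepted: dict[str, set[PeptideKey]]

    @property
    def accepted_keys(self) -> set[PeptideKey]:
        return set().union(*self.accepted.values()) if self.accepted else set()


def stratified_filter(
    best_psms: Mapping[PeptideKey, PSM] | Iterable[PSM],
    alpha: float,
) -> StratifiedResult:
    """Filter best PSMs at level ``alpha`` separately within each class.

    Input is the merged best-PSM set (one PSM per peptide key, targets and
    decoys).  Each class gets its own FDR curve and cutoff; accepted keys
    are the targets at or above their class cutoff.  A class without
    target PSMs is reported empty with a warning.
    """
    if isinstance(best_psms, Mapping):
        items = list(best_psms.items())
    else:
        items = [(p.key, p) for p in best_psms]
    by_class: dict[str, list[tuple[PeptideKey, PSM]]] = {MODIFIED_1DA: [], OTHER: []}
    for key, psm in items:
        by_class[assign_class(key)].append((key, psm))

    curves: dict[str, FDRCurve] = {}
    cutoffs: dict[str, float | None] = {}
    accepted: dict[str, set[PeptideKey]] = {}
    for cls, members in by_class.items():
        targets = [(k, p) for k, p in members if not p.is_decoy]
        if not targets:
            warnings.warn(
                f"class {cls!r} has no target PSMs; reported empty", stacklevel=2
            )
            curves[cls] = None  # type: ignore[assignment]
            cutoffs[cls] = None
            accepted[cls] = set()
            continue
        scores = np.array([p.internal_score for _, p in members])
        decoy = np.array([p.is_decoy for _, p in members])
        curve = fdr_curve(scores, decoy)
        cut = cutoff_at_fdr(curve, alpha)
        curves[cls] = curve
        cutoffs[cls] = cut
        if cut is None:
            accepted[cls] = set()
        else:
            accepted[cls] = {k for k, p in targets if p.internal_score >= cut}
    return StratifiedResult(curves=curves, cutoffs=cutoffs, accepted=accepted)


def write_fdr_curve(curve: FDRCurve, path: str | Path) -> None:
    """Write a curve as TSV (threshold, targets, decoys, fdr, qvalue)."""
    pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "n_targets_ge": curve.n_targets_ge,
            "n_decoys_ge": curve.n_decoys_ge,
            "fdr": curve.fdr,
            "qvalue": curve.qvalue,
        }
    ).to_csv(path, sep="\t", index=False)
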