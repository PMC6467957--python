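"""Target-decoy FDR curves, q-values, and class-stratified filtering."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from citmap.consensus import PeptideKey
from citmap.fdr import (
    FDRCurve,
    FDRError,
    MODIFIED_1DA,
    OTHER,
    assign_class,
    cutoff_at_fdr,
    fdr_curve,
    stratified_filter,
)
from citmap.synthetic import simulate_scored_psms

from conftest import make_psm


# ------------------------------------------------------------ class labels

@pytest.mark.parametrize(
    "mods,expected",
    [
        ("citrullination@5", MODIFIED_1DA),
        ("", OTHER),
        ("oxidation@2;deamidation@7", MODIFIED_1DA),
        ("oxidation@2", OTHER),
        ("carbamidomethyl@1;oxidation@3", OTHER),
        ("deamidation@1", MODIFIED_1DA),
    ],
)
def test_assign_class(mods, expected):
    assert assign_class(mods) == expected
    assert assign_class(PeptideKey("PEPTIDE", mods)) == expected


def test_assign_class_unknown_kind_errors():
    with pytest.raises(Exception):
        assign_class("glycosylation@2")


# ---------------------------------------------------------------- FDR curve

def test_fdr_curve_hand_count():
    """Targets {10,9,8,7}, decoys {8.5,6}: 1 decoy and 3 targets >= 8."""
    curve = fdr_curve([10, 9, 8, 7, 8.5, 6], [False] * 4 + [True] * 2)
    i = int(np.flatnonzero(curve.thresholds == 8.0)[0])
    assert curve.n_decoys_ge[i] == 1 and curve.n_targets_ge[i] == 3
    assert curve.fdr[i] == pytest.approx(1 / 3)


def test_fdr_curve_zero_decoys_is_zero():
    curve = fdr_curve([5.0, 4.0, 3.0], [False, False, False])
    assert np.all(curve.fdr == 0) and np.all(curve.qvalue == 0)


def test_fdr_curve_all_decoys_errors():
    with pytest.raises(FDRError):
        fdr_curve([1.0, 2.0], [True, True])


def _brute_force_curve(scores, is_decoy):
    thresholds = sorted(set(scores), reverse=True)
    fdr = []
    for t in thresholds:
        d = sum(1 for s, dec in zip(scores, is_decoy) if dec and s >= t)
        n = sum(1 for s, dec in zip(scores, is_decoy) if not dec and s >= t)
        fdr.append(d / max(1, n))
    q = [min(fdr[i:]) for i in range(len(fdr))]
    return thresholds, fdr, q


def test_fdr_curve_matches_brute_force(rng):
    for _ in range(50):
        n = int(rng.integers(2, 21))
        scores = np.round(rng.normal(10, 3, size=n), 1)  # force score ties
        decoy = rng.random(n) < 0.4
        if not np.any(~decoy):
            decoy[0] = False
        curve = fdr_curve(scores, decoy)
        thr, fdr, q = _brute_force_curve(scores.tolist(), decoy.tolist())
        assert curve.thresholds.tolist() == thr
        assert curve.fdr.tolist() == pytest.approx(fdr)
        assert curve.qvalue.tolist() == pytest.approx(q)


def test_qvalue_monotone_and_below_fdr(rng):
    for _ in range(20):
        n = int(rng.integers(5, 200))
        scores = rng.normal(size=n)
        decoy = rng.random(n) < 0.5
        if not np.any(~decoy):
            decoy[0] = False
        curve = fdr_curve(scores, decoy)
        assert np.all(curve.qvalue <= curve.fdr)
        assert np.all(np.diff(curve.qvalue) >= 0)  # thresholds descend


# ------------------------------------------------------------------ cutoffs

def _curve(thresholds, qvalues):
    n = len(thresholds)
    return FDRCurve(
        thresholds=np.array(thresholds, dtype=float),
        n_targets_ge=np.arange(1, n + 1),
        n_decoys_ge=np.zeros(n, dtype=int),
        fdr=np.array(qvalues, dtype=float),
        qvalue=np.array(qvalues, dtype=float),
    )


def test_cutoff_takes_most_permissive_qualifying_threshold():
    curve = _curve([30.0, 20.0, 10.0], [0.0005, 0.002, 0.01])
    assert cutoff_at_fdr(curve, 0.001) == 30.0


def test_cutoff_zero_decoys_accepts_everything():
    curve = fdr_curve([5.0, 4.0, 3.0], [False] * 3)
    assert cutoff_at_fdr(curve, 0.001) == 3.0


def test_cutoff_none_attainable():
    curve = _curve([30.0, 20.0], [0.3, 0.5])
    assert cutoff_at_fdr(curve, 0.001) is None


@pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 2.0])
def test_cutoff_alpha_out_of_range(alpha):
    curve = _curve([1.0], [0.0])
    with pytest.raises(FDRError):
        cutoff_at_fdr(curve, alpha)


# ------------------------------------------------------- stratified filter

_ALPHABET = "ACDEFGHILMNPQSTV"  # base-16 residue encoding for unique peptides


def _uniq_seq(i: int) -> str:
    digits = []
    while True:
        digits.append(_ALPHABET[i % 16])
        i //= 16
        if i == 0:
            return "".join(digits)


def _scored_psms(rng, n_target, n_decoy, mean_t, mean_d, sd, cls):
    """Best-PSM-like input with one unique peptide key per PSM."""
    mods = "citrullination@1" if cls == MODIFIED_1DA else ""
    head = "R" if cls == MODIFIED_1DA else "L"
    psms = []
    for i, s in enumerate(rng.normal(mean_t, sd, size=n_target)):
        psms.append(
            make_psm(spectrum_id=f"T{cls}{i}", peptide=head + _uniq_seq(i) + "WK",
                     modifications=mods, score=float(s))
        )
    for i, s in enumerate(rng.normal(mean_d, sd, size=n_decoy)):
        psms.append(
            make_psm(spectrum_id=f"D{cls}{i}", peptide=head + _uniq_seq(i) + "YK",
                     modifications=mods, score=float(s), is_decoy=True)
        )
    return psms


def test_single_class_reduces_to_unstratified(rng):
    psms = _scored_psms(rng, 200, 50, 20, 10, 4, OTHER)
    # keys must be unique per psm for a best-PSM-like input
    by_key = {p.key: p for p in psms}
    with pytest.warns(UserWarning):  # the absent modified class warns
        result = stratified_filter(by_key, alpha=0.05)
    curve = fdr_curve(
        [p.internal_score for p in by_key.values()],
        [p.is_decoy for p in by_key.values()],
    )
    cut = cutoff_at_fdr(curve, 0.05)
    expected = {k for k, p in by_key.items() if not p.is_decoy and p.internal_score >= cut}
    assert result.accepted[OTHER] == expected
    assert result.accepted[MODIFIED_1DA] == set()
    assert result.cutoffs[OTHER] == cut


def test_empty_class_warns_not_fails(rng):
    psms = _scored_psms(rng, 20, 5, 20, 10, 4, OTHER)
    with pytest.warns(UserWarning, match="no target"):
        result = stratified_filter({p.key: p for p in psms}, alpha=0.05)
    assert result.accepted[MODIFIED_1DA] == set()


def test_modified_cutoff_more_demanding_under_poorer_separation():
    """Poorer target/decoy separation in the 1-Da class forces a higher
    class cutoff in >= 95% of seeded replicates (matched decoy sets)."""
    wins = 0
    n_rep = 100
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        psms = _scored_psms(rng, 1000, 300, 14, 10, 5, MODIFIED_1DA)
        psms += _scored_psms(rng, 1000, 300, 28, 10, 5, OTHER)
        result = stratified_filter({p.key: p for p in psms}, alpha=0.01)
        cm, co = result.cutoffs[MODIFIED_1DA], result.cutoffs[OTHER]
        # an unattainable cutoff (None) accepts nothing: maximally demanding
        if co is not None and (cm is None or cm > co):
            wins += 1
    assert wins >= 0.95 * n_rep


def test_equal_classes_give_symmetric_cutoffs():
    """With identical score distributions and sizes, neither class's
    cutoff is systematically higher (paired sign test over seeds)."""
    diffs = []
    for seed in range(60):
        rng = np.random.default_rng(1000 + seed)
        psms = _scored_psms(rng, 500, 150, 20, 10, 5, MODIFIED_1DA)
        psms += _scored_psms(rng, 500, 150, 20, 10, 5, OTHER)
        result = stratified_filter({p.key: p for p in psms}, alpha=0.01)
        cm, co = result.cutoffs[MODIFIED_1DA], result.cutoffs[OTHER]
        if cm is not None and co is not None and cm != co:
            diffs.append(cm > co)
    p = stats.binomtest(sum(diffs), len(diffs), 0.5).pvalue
    assert p > 0.05


def test_stratified_never_more_permissive_than_global_for_clean_class():
    """When the other class is noisier, stratifying cannot accept more of
    it than an unstratified filter would (directional property)."""
    for seed in range(10):
        rng = np.random.default_rng(2000 + seed)
        noisy = _scored_psms(rng, 400, 200, 13, 10, 5, MODIFIED_1DA)
        clean = _scored_psms(rng, 400, 100, 25, 10, 4, OTHER)
        all_psms = {p.key: p for p in noisy + clean}
        strat = stratified_filter(all_psms, alpha=0.05)
        curve = fdr_curve(
            [p.internal_score for p in all_psms.values()],
            [p.is_decoy for p in all_psms.values()],
        )
        cut = cutoff_at_fdr(curve, 0.05)
        global_mod = {
            k
            for k, p in all_psms.items()
            if not p.is_decoy
            and p.internal_score >= cut
            and assign_class(k) == MODIFIED_1DA
        }
        assert strat.accepted[MODIFIED_1DA] <= global_mod


def test_fdp_calibration_quick():
    """Accepted-set false discovery proportion tracks the nominal level
    (small smoke version of the full calibration suite)."""
    fdps = []
    for seed in range(10):
        scores, is_decoy, is_false = simulate_scored_psms(
            seed, 2000, 400, 400, (20.0, 5.0), (8.0, 4.0)
        )
        curve = fdr_curve(scores, is_decoy)
        cut = cutoff_at_fdr(curve, 0.05)
        acc = (~is_decoy) & (scores >= cut)
        fdps.append(is_false[acc].sum() / max(1, acc.sum()))
    assert abs(float(np.mean(fdps)) - 0.05) < 0.02
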