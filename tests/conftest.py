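"""Shared fixtures and tiny factories for the citmap test suite."""

from __future__ import annotations

import numpy as np
import pytest

from citmap.consensus import PSM
from citmap.digest import ProteinRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_psm(
    spectrum_id="S1",
    engine="e1",
    peptide="PEPTIDEK",
    modifications="",
    score=10.0,
    is_decoy=False,
    group="WMC",
    score_convention="higher_better",
    neutral_loss=None,
    protein_ids=(),
) -> PSM:
    return PSM(
        spectrum_id=spectrum_id,
        engine=engine,
        peptide_sequence=peptide,
        modifications=modifications,
        score=score,
        is_decoy=is_decoy,
        group=group,
        score_convention=score_convention,
        neutral_loss=neutral_loss,
        protein_ids=tuple(protein_ids),
    )


def random_protein(rng: np.random.Generator, pid: str, length: int) -> ProteinRecord:
    seq = "".join(rng.choice(list(AA20), size=length))
    return ProteinRecord(id=pid, sequence=seq)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260917)
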