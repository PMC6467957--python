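"""Digestion, decoy, FASTA, and monoisotopic mass behaviour."""

from __future__ import annotations

import numpy as np
import pytest

from citmap.digest import (
    DigestError,
    FastaError,
    Modification,
    ProteinRecord,
    WATER_MONO,
    MOD_DELTAS,
    cleavage_sites,
    digest,
    make_decoy,
    peptide_mass,
    read_fasta,
    write_fasta,
)
from citmap.refdata import synthetic_mbp_like_reference

from conftest import random_protein


# ---------------------------------------------------------------- FASTA I/O

def test_read_fasta_single_record(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">P1\nACDK\n")
    (rec,) = read_fasta(p)
    assert rec.id == "P1" and rec.sequence == "ACDK" and not rec.is_decoy


def test_fasta_roundtrip_preserves_records(tmp_path, rng):
    records = [random_protein(rng, f"P{i}", 150) for i in range(5)]
    p = tmp_path / "r.fasta"
    write_fasta(records, p)
    assert read_fasta(p) == records


def test_read_fasta_lowercase_and_stop_stripped(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">P1\nacdk*\n")
    (rec,) = read_fasta(p)
    assert rec.sequence == "ACDK"


def test_read_fasta_duplicate_id_names_offender(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">P1\nACDK\n>P1\nGGG\n")
    with pytest.raises(FastaError, match="P1"):
        read_fasta(p)


def test_read_fasta_illegal_residue_names_record(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">P9\nACXK\n")
    with pytest.raises(FastaError, match="P9"):
        read_fasta(p)


def test_read_fasta_empty_file_errors(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text("")
    with pytest.raises(FastaError):
        read_fasta(p)


# ------------------------------------------------------------------- decoys

def test_make_decoy_reverses_and_prefixes():
    rec = make_decoy(ProteinRecord(id="P1", sequence="ACDK"))
    assert rec.sequence == "KDCA" and rec.id == "DECOY_P1" and rec.is_decoy


def test_make_decoy_palindrome_fixed_point():
    rec = make_decoy(ProteinRecord(id="P1", sequence="ACA"))
    assert rec.sequence == "ACA" and rec.is_decoy


def test_make_decoy_twice_errors():
    rec = make_decoy(ProteinRecord(id="P1", sequence="ACDK"))
    with pytest.raises(DigestError):
        make_decoy(rec)


# ---------------------------------------------------------------- digestion

def test_trypsin_zero_missed_example():
    rec = ProteinRecord(id="P", sequence="AAKCCRDD")
    peps = digest(rec, ("trypsin",), max_missed=0)
    assert [(p.sequence, p.start, p.end, p.missed_cleavages) for p in peps] == [
        ("AAK", 1, 3, 0),
        ("CCR", 4, 6, 0),
        ("DD", 7, 8, 0),
    ]


def test_trypsin_no_cleavage_before_proline():
    rec = ProteinRecord(id="P", sequence="AAKPCCR")
    peps = digest(rec, ("trypsin",), max_missed=0)
    assert [p.sequence for p in peps] == ["AAKPCCR"]


def test_lysc_cleaves_after_k_only():
    rec = ProteinRecord(id="P", sequence="AAKCCRDD")
    peps = digest(rec, ("lys-c",), max_missed=0)
    assert [p.sequence for p in peps] == ["AAK", "CCRDD"]


def test_lysc_plus_trypsin_equals_trypsin():
    rec = ProteinRecord(id="P", sequence="AAKCCRDDKGGRMM")
    assert digest(rec, ("lys-c", "trypsin"), 2) == digest(rec, ("trypsin",), 2)


def test_reference_peptide_has_internal_missed_cleavage():
    """The multiply-modified reference peptide spans one uncleaved R."""
    rec = synthetic_mbp_like_reference()
    peps = {p.sequence: p for p in digest(rec, ("trypsin",), max_missed=2)}
    pep = peps["SHGRTQDENPVVHFFK"]
    assert (pep.start, pep.end, pep.missed_cleavages) == (77, 92, 1)


def test_blocked_citrulline_site_suppresses_cleavage():
    rec = synthetic_mbp_like_reference()
    peps = {
        p.sequence: p
        for p in digest(rec, ("trypsin",), max_missed=0, blocked_positions={80})
    }
    assert peps["SHGRTQDENPVVHFFK"].missed_cleavages == 0


def test_negative_max_missed_errors():
    with pytest.raises(DigestError):
        digest(ProteinRecord(id="P", sequence="AAK"), max_missed=-1)


def _brute_force_digest(seq, max_missed, blocked):
    """Independent oracle: every substring with cleavage-compatible ends."""
    sites = set()
    for i in range(1, len(seq)):
        if i in blocked:
            continue
        if seq[i - 1] in "KR" and seq[i] != "P":
            sites.add(i)
    ends = sites | {0, len(seq)}
    out = set()
    for a in range(len(seq)):
        for b in range(a + 1, len(seq) + 1):
            if a not in ends or b not in ends:
                continue
            internal = sum(1 for s in sites if a < s < b)
            if internal <= max_missed:
                out.add((a + 1, b, internal))
    return out


def test_digest_matches_brute_force_oracle(rng):
    for _ in range(100):
        length = int(rng.integers(5, 201))
        rec = random_protein(rng, "P", length)
        max_missed = int(rng.integers(0, 3))
        blocked = {
            int(i) + 1
            for i in rng.choice(length, size=min(3, length), replace=False)
        }
        got = {
            (p.start, p.end, p.missed_cleavages)
            for p in digest(rec, ("trypsin",), max_missed, blocked)
        }
        assert got == _brute_force_digest(rec.sequence, max_missed, blocked)


def test_zero_missed_peptides_tile_protein(rng):
    for _ in range(20):
        rec = random_protein(rng, "P", int(rng.integers(10, 120)))
        peps = digest(rec, ("trypsin",), 0)
        assert "".join(p.sequence for p in peps) == rec.sequence
        assert all(p.sequence == rec.sequence[p.start - 1 : p.end] for p in peps)


# -------------------------------------------------------------------- mass

def test_glycine_mass():
    assert peptide_mass("G") == pytest.approx(75.032028, abs=1e-6)


def test_citrullination_adds_one_dalton_nominal():
    base = peptide_mass("SHGRTQDENPVVHFFK")
    mod = peptide_mass(
        "SHGRTQDENPVVHFFK", [Modification(position=4, residue="R", kind="citrullination")]
    )
    assert mod - base == pytest.approx(0.984016, abs=1e-6)
    assert round(mod - base) == 1


def test_citrullination_and_deamidation_deltas_identical():
    assert MOD_DELTAS["citrullination"] == MOD_DELTAS["deamidation"]


def test_empty_modification_list_is_identity():
    assert peptide_mass("ACDK", []) == peptide_mass("ACDK")


def test_mass_additivity_over_random_splits(rng):
    for _ in range(50):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(2, 40))))
        cut = int(rng.integers(1, len(seq)))
        lhs = peptide_mass(seq)
        rhs = peptide_mass(seq[:cut]) + peptide_mass(seq[cut:]) - WATER_MONO
        assert lhs == pytest.approx(rhs, abs=1e-9)


@pytest.mark.parametrize(
    "residue,kind",
    [("A", "citrullination"), ("K", "deamidation"), ("R", "oxidation")],
)
def test_modification_on_wrong_residue_errors(residue, kind):
    with pytest.raises(DigestError):
        Modification(position=1, residue=residue, kind=kind)


def test_unknown_modification_kind_errors():
    with pytest.raises(DigestError):
        Modification(position=1, residue="R", kind="methylation")


def test_modification_position_outside_peptide_errors():
    mod = Modification(position=9, residue="R", kind="citrullination")
    with pytest.raises(DigestError):
        peptide_mass("AR", [mod])


def test_modification_residue_mismatch_errors():
    mod = Modification(position=1, residue="R", kind="citrullination")
    with pytest.raises(DigestError):
        peptide_mass("AR", [mod])


def test_cleavage_sites_unknown_enzyme_errors():
    with pytest.raises(DigestError):
        cleavage_sites("AAKR", enzymes=("pepsin",))
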