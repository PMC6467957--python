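"""SYNTHETIC stand-in for the MBP isoform used as site-numbering reference.

The real 171-residue myelin basic protein isoform (UniProt P02686-5, the
classic 18.5 kDa form with 19 arginines) cannot be bundled here, so this
module constructs a deterministic SYNTHETIC sequence that reproduces its
published shape constraints without being the database sequence:

* 171 residues, exactly 19 arginines;
* the tryptic peptide ``SHGRTQDENPVVHFFK`` at positions 77-92, preceded by
  K76 and followed by N93, with R-80, Q-82 and N-85 at their reported
  coordinates;
* ``GVDAQGTLSK`` at 144-153 (Q-148), preceded by K143;
* arginines at the named site coordinates R6, R10, R26, R32, R34, R44,
  R50, R55, R66, R80, R98 and R171.

Any analysis that needs the genuine isoform sequence must supply its own
FASTA; this stand-in only guarantees the counts and coordinates above.
"""

from __future__ import annotations

from .digest import ProteinRecord

__all__ = ["ARGININE_POSITIONS", "synthetic_mbp_like_reference"]

# 12 published coordinates + 7 synthetic filler positions = 19 arginines.
ARGININE_POSITIONS = (
    6, 10, 14, 20, 26, 32, 34, 44, 50, 55, 66, 80, 98, 105, 112, 120, 130,
    160, 171,
)

_LENGTH = 171
_FILLER = "GSAHTQVLENDFYMPW"  # no K/R: arginine count is fully controlled


def synthetic_mbp_like_reference(record_id: str = "SYN_MBP_REF") -> ProteinRecord:
    """Build the synthetic 19-arginine reference protein (deterministic)."""
    seq = [_FILLER[i % len(_FILLER)] for i in range(_LENGTH)]

    def place(start: int, fragment: str) -> None:
        seq[start - 1 : start - 1 + len(fragment)] = fragment

    place(77, "SHGRTQDENPVVHFFK")  # reported multiply-modified tryptic peptide
    seq[75] = "K"   # K76: tryptic N-terminal context
    seq[92] = "N"   # N93: reported following residue
    place(144, "GVDAQGTLSK")       # reported deamidated peptide, Q-148
    seq[142] = "K"  # K143
    for pos in ARGININE_POSITIONS:
        seq[pos - 1] = "R"
    record = ProteinRecord(
        id=record_id,
        sequence="".join(seq),
        description="synthetic stand-in for the 19-arginine MBP reference isoform",
    )
    assert record.sequence.count("R") == 19
    return record
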