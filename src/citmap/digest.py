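"""FASTA handling, decoy construction, and citrulline-aware in-silico digestion.

Citrullination (deimination of arginine by PADI enzymes) replaces the
guanidinium =NH by =O, adding +0.984016 Da and removing a positive charge.
Deamidation of N/Q carries the identical nominal mass shift, which is why
the two are indistinguishable by precursor mass alone.  Search-engine
settings that list "deamidation (R)" are chemically citrullination; this
package treats the two labels as synonyms on arginine.

Trypsin does not cleave after a citrullinated arginine: the lost positive
charge abolishes substrate recognition.  Digestion therefore accepts a set
of *blocked* cleavage positions so that citrullinated peptides can be
generated with their characteristic missed cleavage.

All masses are monoisotopic, computed from atomic masses; coordinates are
1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "Peptide",
    "Modification",
    "DigestError",
    "FastaError",
    "DECOY_PREFIX",
    "WATER_MONO",
    "RESIDUE_MONO",
    "MOD_DELTAS",
    "MOD_ALLOWED_RESIDUES",
    "read_fasta",
    "write_fasta",
    "make_decoy",
    "digest",
    "cleavage_sites",
    "peptide_mass",
]


class FastaError(ValueError):
    """Malformed or inconsistent FASTA input."""


class DigestError(ValueError):
    """Invalid digestion or mass-computation request."""


DECOY_PREFIX = "DECOY_"

# Monoisotopic atomic masses (u), CODATA/IUPAC values.
_H = 1.0078250319
_C = 12.0
_N = 14.0030740052
_O = 15.9949146221
_S = 31.97207069

WATER_MONO = 2 * _H + _O

# Residue (i.e. amino acid minus water) elemental compositions.
_RESIDUE_FORMULA: dict[str, tuple[int, int, int, int, int]] = {
    # aa: (C, H, N, O, S)
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}

RESIDUE_MONO: dict[str, float] = {
    aa: c * _C + h * _H + n * _N + o * _O + s * _S
    for aa, (c, h, n, o, s) in _RESIDUE_FORMULA.items()
}

STANDARD_RESIDUES = frozenset(RESIDUE_MONO)

# Deimination: guanidinium =NH -> =O, i.e. -NH +O.
CITRULLINATION_DELTA = _O - (_N + _H)

MOD_DELTAS: dict[str, float] = {
    "citrullination": CITRULLINATION_DELTA,
    "deamidation": CITRULLINATION_DELTA,  # identical 1-Da-class shift on N/Q
    "oxidation": _O,
    "carbamidomethyl": 2 * _C + 3 * _H + _N + _O,
}

MOD_ALLOWED_RESIDUES: dict[str, frozenset[str]] = {
    "citrullination": frozenset("R"),
    "deamidation": frozenset("NQ"),
    "oxidation": frozenset("M"),
    "carbamidomethyl": frozenset("C"),
}


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence with target/decoy status."""

    id: str
    sequence: str
    description: str = ""
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise FastaError(
                f"protein {self.id!r}: illegal residue(s) {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class Peptide:
    """A digestion product with 1-based inclusive protein coordinates."""

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Modification:
    """One localized modification within a peptide.

    ``position`` is 1-based within the peptide; ``mass_delta`` defaults to
    the canonical monoisotopic delta for ``kind``.
    """

    position: int
    residue: str
    kind: str
    mass_delta: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.kind not in MOD_DELTAS:
            raise DigestError(f"unknown modification kind {self.kind!r}")
        if self.residue not in MOD_ALLOWED_RESIDUES[self.kind]:
            raise DigestError(
                f"{self.kind} not allowed on residue {self.residue!r} "
                f"(allowed: {sorted(MOD_ALLOWED_RESIDUES[self.kind])})"
            )
        if self.position < 1:
            raise DigestError(f"modification position {self.position} < 1")
        if self.mass_delta != self.mass_delta:  # NaN sentinel
            object.__setattr__(self, "mass_delta", MOD_DELTAS[self.kind])


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records, preserving order.

    Sequences are uppercased and a trailing ``*`` stop codon marker is
    stripped.  Records whose id starts with ``DECOY_`` are flagged as
    decoys.  Duplicate ids and non-standard residues raise
    :class:`FastaError` naming the offending record.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        if rec.id in seen:
            raise FastaError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        try:
            records.append(
                ProteinRecord(
                    id=rec.id,
                    sequence=seq,
                    description=desc,
                    is_decoy=rec.id.startswith(DECOY_PREFIX),
                )
            )
        except FastaError as exc:
            raise FastaError(f"{path}: {exc}") from exc
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as standard 60-column FASTA."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(seqrecords)


def make_decoy(record: ProteinRecord) -> ProteinRecord:
    """Reverse a target protein into its decoy counterpart."""
    if record.is_decoy:
        raise DigestError(f"record {record.id!r} is already a decoy")
    return replace(
        record,
        id=DECOY_PREFIX + record.id,
        sequence=record.sequence[::-1],
        is_decoy=True,
    )


_ENZYME_RULES = ("trypsin", "lys-c")


def cleavage_sites(
    sequence: str,
    enzymes: Sequence[str] = ("trypsin",),
    blocked_positions: Iterable[int] = (),
) -> list[int]:
    """1-based residue indices after which the enzyme mix cleaves.

    Trypsin cuts after K or R except before proline; Lys-C cuts after K.
    Under these rules a combined Lys-C + trypsin digest has the same sites
    as trypsin alone (the K sites are shared).  ``blocked_positions``
    suppress cleavage after the given residue — used for citrullinated
    arginines, which resist trypsin.
    """
    for enzyme in enzymes:
        if enzyme not in _ENZYME_RULES:
            raise DigestError(f"unknown enzyme {enzyme!r}")
    blocked = set(blocked_positions)
    n = len(sequence)
    sites: list[int] = []
    for i in range(1, n):  # cleavage between residue i and i+1 (1-based)
        if i in blocked:
            continue
        aa, nxt = sequence[i - 1], sequence[i]
        cut = False
        if "trypsin" in enzymes and aa in "KR" and nxt != "P":
            cut = True
        if "lys-c" in enzymes and aa == "K":
            cut = True
        if cut:
            sites.append(i)
    return sites


def digest(
    record: ProteinRecord,
    enzymes: Sequence[str] = ("trypsin",),
    max_missed: int = 0,
    blocked_positions: Iterable[int] = (),
) -> list[Peptide]:
    """Enumerate fully- and partially-cleaved peptides.

    Returns every peptide whose both ends are protein termini or cleavage
    sites and which spans at most ``max_missed`` internal cleavage sites,
    ordered by start then end.
    """
    if max_missed < 0:
        raise DigestError(f"max_missed must be >= 0, got {max_missed}")
    seq = record.sequence
    boundaries = [0, *cleavage_sites(seq, enzymes, blocked_positions), len(seq)]
    peptides: list[Peptide] = []
    for i, left in enumerate(boundaries[:-1]):
        for j in range(i + 1, min(i + max_missed + 2, len(boundaries))):
            right = boundaries[j]
            peptides.append(
                Peptide(
                    protein_id=record.id,
                    start=left + 1,
                    end=right,
                    sequence=seq[left:right],
                    missed_cleavages=j - i - 1,
                )
            )
    return peptides


def peptide_mass(
    sequence: str, modifications: Sequence[Modification] = ()
) -> float:
    """Monoisotopic peptide mass in Da, including modification deltas."""
    try:
        mass = sum(RESIDUE_MONO[aa] for aa in sequence) + WATER_MONO
    except KeyError as exc:
        raise DigestError(f"non-standard residue {exc.args[0]!r}") from exc
    for mod in modifications:
        if not 1 <= mod.position <= len(sequence):
            raise DigestError(
                f"modification position {mod.position} outside peptide "
                f"of length {len(sequence)}"
            )
        if sequence[mod.position - 1] != mod.residue:
            raise DigestError(
                f"modification residue {mod.residue!r} does not match "
                f"sequence residue {sequence[mod.position - 1]!r} at "
                f"position {mod.position}"
            )
        mass += mod.mass_delta
    return mass
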