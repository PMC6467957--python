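"""PSM table I/O, best-PSM selection, and multi-engine consensus.

A peptide identification is keyed by its stripped sequence plus the full,
canonicalized modification string — a citrullinated and an unmodified
peptide are distinct identifications, and I/L are not collapsed.  Scores
from engines that report posterior error probabilities (lower is better)
are mapped onto a single internal higher-is-better scale by negation, so
"best" always means the internal maximum.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .digest import MOD_DELTAS

__all__ = [
    "PSM",
    "PeptideKey",
    "EngineResultSet",
    "PSMTableError",
    "SCORE_CONVENTIONS",
    "canonical_modifications",
    "parse_modifications",
    "read_psm_table",
    "write_psm_table",
    "best_psm_per_peptide",
    "engine_consensus",
    "venn_counts",
    "venn3_counts",
]


class PSMTableError(ValueError):
    """Malformed PSM table or inconsistent PSM collection."""


SCORE_CONVENTIONS = ("higher_better", "lower_better")

_MOD_TOKEN = re.compile(r"^([a-z_]+)@(\d+)$")


def parse_modifications(modstring: str) -> list[tuple[str, int]]:
    """Parse ``kind@pos;...`` into (kind, position) pairs."""
    if not modstring:
        return []
    mods = []
    for token in modstring.split(";"):
        m = _MOD_TOKEN.match(token.strip())
        if not m:
            raise PSMTableError(f"unparseable modification token {token!r}")
        kind, pos = m.group(1), int(m.group(2))
        if kind not in MOD_DELTAS:
            raise PSMTableError(f"unknown modification kind {kind!r}")
        mods.append((kind, pos))
    return mods


def canonical_modifications(modstring: str) -> str:
    """Canonical form: tokens sorted by position, then by kind."""
    mods = parse_modifications(modstring)
    return ";".join(f"{kind}@{pos}" for kind, pos in sorted(mods, key=lambda m: (m[1], m[0])))


class PeptideKey(NamedTuple):
    """Modification-resolved peptide identity."""

    sequence: str
    modifications: str  # canonical string, "" if unmodified


@dataclass(frozen=True)
class PSM:
    """One spectrum-to-peptide assignment from one search engine."""

    spectrum_id: str
    engine: str
    peptide_sequence: str
    modifications: str
    score: float
    is_decoy: bool
    group: str
    score_convention: str = "higher_better"
    neutral_loss: bool | None = None
    protein_ids: tuple[str, ...] = ()
    extra: Mapping[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.score_convention not in SCORE_CONVENTIONS:
            raise PSMTableError(
                f"score_convention must be one of {SCORE_CONVENTIONS}, "
                f"got {self.score_convention!r}"
            )
        if not math.isfinite(self.score):
            raise PSMTableError(f"non-finite score for spectrum {self.spectrum_id!r}")
        object.__setattr__(
            self, "modifications", canonical_modifications(self.modifications)
        )

    @property
    def key(self) -> PeptideKey:
        return PeptideKey(self.peptide_sequence, self.modifications)

    @property
    def internal_score(self) -> float:
        """Score on the shared higher-is-better scale."""
        if self.score_convention == "lower_better":
            return -self.score
        return self.score


REQUIRED_COLUMNS = (
    "spectrum_id",
    "engine",
    "peptide",
    "modifications",
    "score",
    "is_decoy",
    "group",
)

_OPTIONAL_DEFAULTS = {
    "score_convention": "higher_better",
    "neutral_loss": "",
    "proteins": "",
}


def _parse_bool(value: str) -> bool:
    return str(value).strip().lower() in ("1", "true", "yes")


def read_psm_table(path: str | Path) -> list[PSM]:
    """Read the tab-separated PSM dialect into PSM objects.

    Required columns: spectrum_id, engine, peptide, modifications, score,
    is_decoy, group.  Optional: score_convention, neutral_loss, proteins
    (comma-separated).  Unknown columns are preserved in ``PSM.extra``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PSMTableError(f"{path}: missing required column(s) {missing}")
    known = set(REQUIRED_COLUMNS) | set(_OPTIONAL_DEFAULTS)
    extra_cols = [c for c in df.columns if c not in known]
    psms: list[PSM] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        rec = dict(zip(df.columns, row))
        try:
            score = float(rec["score"])
        except ValueError:
            raise PSMTableError(
                f"{path}: unparseable score {rec['score']!r} on line {idx}"
            ) from None
        nl_raw = rec.get("neutral_loss", "")
        neutral_loss = None if nl_raw == "" else _parse_bool(nl_raw)
        proteins = tuple(p for p in rec.get("proteins", "").split(",") if p)
        psms.append(
            PSM(
                spectrum_id=rec["spectrum_id"],
                engine=rec["engine"],
                peptide_sequence=rec["peptide"],
                modifications=rec["modifications"],
                score=score,
                is_decoy=_parse_bool(rec["is_decoy"]),
                group=rec["group"],
                score_convention=rec.get("score_convention") or "higher_better",
                neutral_loss=neutral_loss,
                protein_ids=proteins,
                extra={c: rec[c] for c in extra_cols},
            )
        )
    return psms


def write_psm_table(psms: Iterable[PSM], path: str | Path) -> None:
    """Write PSMs in the tab-separated dialect read by :func:`read_psm_table`."""
    rows = []
    for p in psms:
        rows.append(
            {
                "spectrum_id": p.spectrum_id,
                "engine": p.engine,
                "peptide": p.peptide_sequence,
                "modifications": p.modifications,
                "score": repr(p.score),
                "is_decoy": str(p.is_decoy).lower(),
                "group": p.group,
                "score_convention": p.score_convention,
                "neutral_loss": "" if p.neutral_loss is None else str(p.neutral_loss).lower(),
                "proteins": ",".join(p.protein_ids),
                **dict(p.extra),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class EngineResultSet:
    """Best PSM per peptide key for one engine."""

    engine: str
    best: dict[PeptideKey, PSM]

    @property
    def keys(self) -> set[PeptideKey]:
        return set(self.best)


def best_psm_per_peptide(psms: Sequence[PSM]) -> EngineResultSet:
    """Select, per peptide key, the best PSM of a single engine.

    "Best" is the maximum internal score (highest ion-type score, or lowest
    PEP for lower-is-better engines).  Ties break deterministically on the
    lowest spectrum_id, then the lexicographically smallest modification
    string.
    """
    if not psms:
        raise PSMTableError("no PSMs given")
    engines = {p.engine for p in psms}
    if len(engines) > 1:
        raise PSMTableError(
            f"best_psm_per_peptide expects one engine, got {sorted(engines)}"
        )
    best: dict[PeptideKey, PSM] = {}
    for psm in psms:
        cur = best.get(psm.key)
        if cur is None:
            best[psm.key] = psm
            continue
        cand = (psm.internal_score, _tie_rank(psm))
        incumbent = (cur.internal_score, _tie_rank(cur))
        # higher score wins; on exact score tie the smaller rank tuple wins
        if cand[0] > incumbent[0] or (cand[0] == incumbent[0] and cand[1] < incumbent[1]):
            best[psm.key] = psm
    return EngineResultSet(engine=engines.pop(), best=best)


def _tie_rank(psm: PSM) -> tuple[str, str]:
    return (psm.spectrum_id, psm.modifications)


def engine_consensus(
    result_sets: Sequence[EngineResultSet], min_engines: int = 2
) -> set[PeptideKey]:
    """Peptide keys identified by at least ``min_engines`` engines."""
    if min_engines > len(result_sets):
        raise PSMTableError(
            f"min_engines={min_engines} exceeds number of result sets "
            f"({len(result_sets)})"
        )
    counts: dict[PeptideKey, int] = {}
    for rs in result_sets:
        for key in rs.best:
            counts[key] = counts.get(key, 0) + 1
    return {key for key, n in counts.items() if n >= min_engines}


def venn_counts(set_a: set, set_b: set) -> tuple[int, int, int]:
    """(unique to A, shared, unique to B)."""
    shared = len(set_a & set_b)
    return (len(set_a) - shared, shared, len(set_b) - shared)


def venn3_counts(set_a: set, set_b: set, set_c: set) -> dict[str, int]:
    """The 7 disjoint region sizes of a three-set Venn diagram.

    Keys: 'a', 'b', 'c' (unique), 'ab', 'ac', 'bc' (pairwise only),
    'abc' (all three).
    """
    abc = set_a & set_b & set_c
    ab = (set_a & set_b) - abc
    ac = (set_a & set_c) - abc
    bc = (set_b & set_c) - abc
    return {
        "a": len(set_a - set_b - set_c),
        "b": len(set_b - set_a - set_c),
        "c": len(set_c - set_a - set_b),
        "ab": len(ab),
        "ac": len(ac),
        "bc": len(bc),
        "abc": len(abc),
    }
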