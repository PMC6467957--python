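"""Protein-coordinate site mapping, citrulline evidence, and count matrices.

Because citrullination and deamidation are isobaric, a citrulline call is
corroborated by two orthogonal features: the modified residue must be an
arginine whose tryptic cleavage failed (citrulline resists trypsin, so a
genuinely citrullinated R sits *internal* to its peptide), and the
precursor may show the diagnostic 43-Da neutral loss of isocyanic acid
(HNCO) in the instrument.  Evidence flags annotate each call; an optional
strict mode turns them into a filter.

Counting unit is PSMs (spectral counts) per modified site per tissue
group, with a distinct-peptide alternative where the unit is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .consensus import PSM, PeptideKey, parse_modifications
from .digest import Peptide

__all__ = [
    "ModificationSite",
    "EvidenceFlags",
    "SiteMapError",
    "HNCO_MONO",
    "locate_sites",
    "citrulline_evidence",
    "site_count_matrix",
    "protein_filter_min_peptides",
    "bland_altman",
]


class SiteMapError(ValueError):
    """Inconsistent site-mapping request."""


# Isocyanic acid HNCO, the diagnostic neutral loss of citrulline.
_H, _C, _N, _O = 1.0078250319, 12.0, 14.0030740052, 15.9949146221
HNCO_MONO = _H + _N + _C + _O  # 43.005814 Da, prints as "43 Da"


@dataclass(frozen=True)
class ModificationSite:
    """One modified residue in protein coordinates (1-based)."""

    protein_id: str
    position: int
    residue: str
    kind: str

    @property
    def label(self) -> str:
        """Field-standard site label, e.g. ``R80``."""
        return f"{self.residue}{self.position}"


@dataclass(frozen=True)
class EvidenceFlags:
    """Orthogonal evidence that a 1-Da call is citrulline, not deamidation."""

    residue_is_R: bool
    missed_cleavage_at_site: bool
    neutral_loss_43: bool | None  # None = not recorded by the engine


def locate_sites(
    peptide: Peptide, modifications: str | Sequence[tuple[str, int]]
) -> list[ModificationSite]:
    """Map within-peptide modification positions onto protein coordinates.

    Site position = peptide start + within-peptide position - 1.
    """
    mods = (
        parse_modifications(modifications)
        if isinstance(modifications, str)
        else list(modifications)
    )
    sites = []
    for kind, pos in mods:
        if not 1 <= pos <= len(peptide.sequence):
            raise SiteMapError(
                f"modification position {pos} outside peptide "
                f"{peptide.sequence!r} (length {len(peptide.sequence)})"
            )
        sites.append(
            ModificationSite(
                protein_id=peptide.protein_id,
                position=peptide.start + pos - 1,
                residue=peptide.sequence[pos - 1],
                kind=kind,
            )
        )
    return sites


def citrulline_evidence(
    psm: PSM, peptide: Peptide, site: ModificationSite
) -> EvidenceFlags:
    """Evidence flags for one modified site of one PSM.

    ``missed_cleavage_at_site`` is true iff the modified arginine is
    internal to the peptide (an uncleaved tryptic site); a citrulline call
    on a peptide's C-terminal R is suspicious, since trypsin should not
    have cut there.
    """
    if site.protein_id != peptide.protein_id:
        raise SiteMapError(
            f"site protein {site.protein_id!r} does not match peptide "
            f"protein {peptide.protein_id!r}"
        )
    if not peptide.start <= site.position <= peptide.end:
        raise SiteMapError(
            f"site position {site.position} outside peptide span "
            f"[{peptide.start}, {peptide.end}]"
        )
    within = site.position - peptide.start + 1
    residue = peptide.sequence[within - 1]
    return EvidenceFlags(
        residue_is_R=residue == "R",
        missed_cleavage_at_site=residue == "R" and site.position < peptide.end,
        neutral_loss_43=psm.neutral_loss,
    )


def site_count_matrix(
    psms: Sequence[PSM],
    sites_per_psm: Sequence[Sequence[ModificationSite]],
    groups: Sequence[str],
    kind: str = "citrullination",
) -> pd.DataFrame:
    """PSM counts per modified site (rows) per tissue group (columns).

    Rows are indexed by (protein_id, position, residue); only sites of the
    requested modification ``kind`` are counted.  Decoy PSMs must be
    excluded upstream.
    """
    if len(psms) != len(sites_per_psm):
        raise SiteMapError("psms and sites_per_psm must be parallel")
    counts: dict[tuple[str, int, str], dict[str, int]] = {}
    for psm, sites in zip(psms, sites_per_psm):
        if psm.group not in groups:
            raise SiteMapError(
                f"PSM group {psm.group!r} not among configured groups {list(groups)}"
            )
        for site in sites:
            if site.kind != kind:
                continue
            row = counts.setdefault(
                (site.protein_id, site.position, site.residue),
                {g: 0 for g in groups},
            )
            row[psm.group] += 1
    index = pd.MultiIndex.from_tuples(
        sorted(counts), names=["protein_id", "position", "residue"]
    )
    df = pd.DataFrame(
        [[counts[key][g] for g in groups] for key in sorted(counts)],
        index=index,
        columns=list(groups),
        dtype=int,
    )
    return df


def protein_filter_min_peptides(
    peptide_proteins: Mapping[PeptideKey, Iterable[str]],
    min_distinct_citr_peptides: int = 2,
) -> list[str]:
    """Proteins with at least N distinct citrullinated peptide keys.

    Distinct *peptides* are counted, not distinct sites: two citrullinated
    peptides sharing one site still qualify a protein.  Peptides mapping
    to multiple proteins count once per protein.
    """
    per_protein: dict[str, set[PeptideKey]] = {}
    for key, proteins in peptide_proteins.items():
        kinds = {kind for kind, _ in parse_modifications(key.modifications)}
        if "citrullination" not in kinds:
            continue
        for prot in proteins:
            per_protein.setdefault(prot, set()).add(key)
    return sorted(
        p for p, keys in per_protein.items()
        if len(keys) >= min_distinct_citr_peptides
    )


def bland_altman(
    counts_group_a: pd.Series, counts_group_b: pd.Series
) -> pd.DataFrame:
    """Bland–Altman pairs: mean (a+b)/2 vs difference b - a, per protein.

    Convention: ``a`` is the control group and ``b`` the comparison group,
    so positive differences mean more spectral counts in ``b``.
    """
    idx_a, idx_b = set(counts_group_a.index), set(counts_group_b.index)
    if idx_a != idx_b:
        raise SiteMapError(
            f"mismatched protein sets; only in a: {sorted(idx_a - idx_b)}, "
            f"only in b: {sorted(idx_b - idx_a)}"
        )
    b = counts_group_b.reindex(counts_group_a.index)
    return pd.DataFrame(
        {
            "mean": (counts_group_a + b) / 2.0,
            "difference": b - counts_group_a,
        },
        index=counts_group_a.index,
    )
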