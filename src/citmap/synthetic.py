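"""Synthetic proteome and three-engine PSM tables with known ground truth.

The generator emulates the structure of a brain-tissue citrullination
search at desk scale: a toy proteome containing one designated reference
protein with exactly 19 arginines (mirroring the shape of the classic MBP
isoform site map), citrullination planted on arginines with
tissue-group-dependent Poisson PSM abundance, deamidation on N/Q as the
isobaric confounder, engine-dependent peptide detection across three
pseudo-engines (two higher-is-better, one PEP-like lower-is-better), and
target/decoy score distributions whose separation is poorer for the
1-Da-modified class.  Every planted quantity is recorded so downstream
stages can be checked against truth exactly.

All randomness flows from ``SimulationConfig.seed``; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .consensus import PSM, PeptideKey, write_psm_table
from .digest import Peptide, ProteinRecord, digest, make_decoy, write_fasta
from .fdr import MODIFIED_1DA, OTHER, assign_class

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticError",
    "DEFAULT_ENGINES",
    "generate_proteome",
    "generate_psm_tables",
    "simulate_scored_psms",
    "write_outputs",
]


class SyntheticError(ValueError):
    """Invalid simulation configuration."""


# Two ion-score-style engines and one percolator-style (PEP, lower better),
# mirroring a Mascot-without-NL / Mascot-with-NL / multi-engine+percolator
# three-way comparison.
DEFAULT_ENGINES: tuple[tuple[str, str], ...] = (
    ("mascot_noNL", "higher_better"),
    ("mascot_NL", "higher_better"),
    ("percolator", "lower_better"),
)

# Average amino-acid frequencies (UniProtKB statistics, %); composition
# realism is irrelevant downstream, but R at its natural ~5.5% keeps
# plantable arginines plentiful.
_AA_FREQ = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37, "Q": 3.93,
    "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96, "L": 9.66, "K": 5.84,
    "M": 2.42, "F": 3.86, "P": 4.70, "S": 6.56, "T": 5.34, "W": 1.08,
    "Y": 2.92, "V": 6.87,
}
_AA = np.array(sorted(_AA_FREQ))
_AA_P = np.array([_AA_FREQ[a] for a in _AA])
_AA_P = _AA_P / _AA_P.sum()
_AA_NO_R = np.array([a for a in _AA if a != "R"])
_AA_NO_R_P = np.array([_AA_FREQ[a] for a in _AA_NO_R])
_AA_NO_R_P = _AA_NO_R_P / _AA_NO_R_P.sum()

REFERENCE_PROTEIN_ID = "SYNPROT_REF19R"
_REFERENCE_N_ARG = 19


@dataclass
class SimulationConfig:
    """Stated world of the simulation; every free parameter lives here.

    Group PSM means mirror the qualitative tissue pattern of the study
    system: citrullination strongly enriched in diseased white matter,
    slightly depleted in diseased gray matter.  Score distributions are
    free parameters (none are published); defaults give the modified
    class visibly poorer target/decoy separation than the other class.
    """

    seed: int = 0
    n_proteins: int = 12
    protein_length_range: tuple[int, int] = (120, 400)
    n_planted_sites: int = 25
    groups: tuple[str, ...] = ("GMC", "GMMS", "WMC", "WMMS")
    psm_per_site_by_group: dict[str, float] = field(
        default_factory=lambda: {"GMC": 3.0, "GMMS": 2.8, "WMC": 4.0, "WMMS": 6.4}
    )
    target_score_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {MODIFIED_1DA: (18.0, 6.0), OTHER: (28.0, 5.0)}
    )
    decoy_score_params: tuple[float, float] = (10.0, 4.0)
    frac_deamidation_confounders: float = 0.3
    frac_neutral_loss_on_true_citr: float = 0.5
    engine_detection_prob: float = 0.9
    # plumbing beyond the headline knobs
    n_background_peptides: int = 150
    background_psm_mean: float = 1.0
    # matched across classes so that cutoff differences reflect score
    # separation rather than decoy-set size
    n_decoy_psms_per_class: dict[str, int] = field(
        default_factory=lambda: {MODIFIED_1DA: 250, OTHER: 250}
    )
    engines: tuple[tuple[str, str], ...] = DEFAULT_ENGINES

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise SyntheticError("group labels must be unique")
        for name, value in (
            ("frac_deamidation_confounders", self.frac_deamidation_confounders),
            ("frac_neutral_loss_on_true_citr", self.frac_neutral_loss_on_true_citr),
            ("engine_detection_prob", self.engine_detection_prob),
        ):
            if not 0.0 <= value <= 1.0:
                raise SyntheticError(f"{name} must be in [0, 1], got {value}")
        missing = set(self.groups) - set(self.psm_per_site_by_group)
        if missing:
            raise SyntheticError(
                f"psm_per_site_by_group missing group(s) {sorted(missing)}"
            )
        if self.n_proteins < 1:
            raise SyntheticError("n_proteins must be >= 1")
        lo, hi = self.protein_length_range
        if lo < 40 or hi < lo:
            raise SyntheticError("protein_length_range must satisfy 40 <= lo <= hi")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load from a plain-text key-value (YAML) file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("protein_length_range", "groups"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "engines" in raw:
            raw["engines"] = tuple(tuple(e) for e in raw["engines"])
        if "target_score_params" in raw:
            raw["target_score_params"] = {
                k: tuple(v) for k, v in raw["target_score_params"].items()
            }
        if "decoy_score_params" in raw:
            raw["decoy_score_params"] = tuple(raw["decoy_score_params"])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery checks."""

    planted_sites: list[tuple[str, int, str]]
    # (protein_id, position) -> group -> emitted PSM (spectrum) count
    site_counts: dict[tuple[str, int], dict[str, int]] = field(default_factory=dict)
    peptide_class: dict[PeptideKey, str] = field(default_factory=dict)
    confounder_sites: list[tuple[str, int, str]] = field(default_factory=list)


def _random_protein(rng: np.random.Generator, pid: str, length: int) -> ProteinRecord:
    seq = "".join(rng.choice(_AA, size=length, p=_AA_P))
    return ProteinRecord(id=pid, sequence=seq, description="synthetic protein")


def _reference_protein(rng: np.random.Generator, length: int) -> ProteinRecord:
    """A protein with exactly 19 arginines, like the MBP reference isoform."""
    seq = rng.choice(_AA_NO_R, size=length, p=_AA_NO_R_P)
    pos = rng.choice(length, size=_REFERENCE_N_ARG, replace=False)
    seq[pos] = "R"
    return ProteinRecord(
        id=REFERENCE_PROTEIN_ID,
        sequence="".join(seq),
        description=f"synthetic reference protein with exactly {_REFERENCE_N_ARG} R",
    )


def generate_proteome(
    config: SimulationConfig,
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Generate target proteins and plant citrullination sites on arginines.

    The first protein is the designated reference with exactly 19 R.
    Decoys are not generated here (see :func:`citmap.digest.make_decoy`).
    """
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.protein_length_range
    records = [_reference_protein(rng, int(rng.integers(max(lo, 100), hi + 1)))]
    for i in range(1, config.n_proteins):
        records.append(
            _random_protein(rng, f"SYNPROT_{i:04d}", int(rng.integers(lo, hi + 1)))
        )

    # candidate sites: every arginine in the emitted proteome, reference first
    candidates: list[tuple[str, int]] = []
    for rec in records:
        candidates.extend(
            (rec.id, i + 1) for i, aa in enumerate(rec.sequence) if aa == "R"
        )
    if not candidates:
        raise SyntheticError("proteome contains no plantable arginines")
    if config.n_planted_sites > len(candidates):
        raise SyntheticError(
            f"cannot plant {config.n_planted_sites} sites on "
            f"{len(candidates)} available arginines"
        )
    chosen = rng.choice(len(candidates), size=config.n_planted_sites, replace=False)
    planted = sorted(candidates[int(i)] for i in chosen)
    truth = GroundTruth(planted_sites=[(pid, pos, "R") for pid, pos in planted])
    return records, truth


def _covering_peptide(
    record: ProteinRecord, position: int, max_missed: int = 2
) -> Peptide:
    """The tryptic peptide carrying a citrullinated (cleavage-blocked) R.

    Deterministic choice: fewest missed cleavages, then shortest, then
    earliest start.
    """
    peptides = [
        p
        for p in digest(record, ("trypsin",), max_missed, blocked_positions={position})
        if p.start <= position <= p.end
    ]
    if not peptides:  # cannot happen: the whole chain always covers
        raise SyntheticError(f"no peptide covers {record.id}:{position}")
    return min(peptides, key=lambda p: (p.missed_cleavages, len(p), p.start))


def generate_psm_tables(
    proteome: Sequence[ProteinRecord],
    truth: GroundTruth,
    config: SimulationConfig,
) -> dict[str, list[PSM]]:
    """Emit one PSM table per pseudo-engine; fills truth counts/classes.

    Spectra are generated once; each engine independently reports a given
    peptide key with ``engine_detection_prob`` and, when it does, scores
    every spectrum of that key with its own draw from the class's score
    distribution (transformed for lower-is-better engines).
    """
    rng = np.random.default_rng([config.seed, 1])
    by_id = {rec.id: rec for rec in proteome}
    engines = list(config.engines)
    tables: dict[str, list[PSM]] = {name: [] for name, _ in engines}
    spectrum_counter = 0

    def emit(
        key: PeptideKey,
        protein_ids: tuple[str, ...],
        group: str,
        cls: str,
        is_decoy: bool,
        neutral_loss: bool | None,
        detected: dict[str, bool],
    ) -> None:
        nonlocal spectrum_counter
        spectrum_counter += 1
        sid = f"S{spectrum_counter:07d}"
        if is_decoy:
            mean, sd = config.decoy_score_params
        else:
            mean, sd = config.target_score_params[cls]
        for name, convention in engines:
            if not detected[name]:
                continue
            internal = rng.normal(mean, sd)
            score = -internal if convention == "lower_better" else internal
            tables[name].append(
                PSM(
                    spectrum_id=sid,
                    engine=name,
                    peptide_sequence=key.sequence,
                    modifications=key.modifications,
                    score=float(score),
                    is_decoy=is_decoy,
                    group=group,
                    score_convention=convention,
                    neutral_loss=neutral_loss,
                    protein_ids=protein_ids,
                )
            )

    def detection(rng: np.random.Generator) -> dict[str, bool]:
        return {
            name: bool(rng.random() < config.engine_detection_prob)
            for name, _ in engines
        }

    # --- planted citrullination sites -------------------------------------
    for pid, pos, _ in truth.planted_sites:
        record = by_id[pid]
        pep = _covering_peptide(record, pos)
        within = pos - pep.start + 1
        key = PeptideKey(pep.sequence, f"citrullination@{within}")
        truth.peptide_class[key] = assign_class(key)
        detected = detection(rng)
        counts: dict[str, int] = {}
        for group in config.groups:
            n = int(rng.poisson(config.psm_per_site_by_group[group]))
            counts[group] = n
            for _ in range(n):
                nl = bool(rng.random() < config.frac_neutral_loss_on_true_citr)
                emit(key, (pid,), group, MODIFIED_1DA, False, nl, detected)
        truth.site_counts[(pid, pos)] = counts

    # --- background peptides (unmodified + deamidation confounders) ------
    background: list[Peptide] = []
    for rec in proteome:
        background.extend(
            p for p in digest(rec, ("trypsin",), 0) if 6 <= len(p.sequence) <= 30
        )
    if background:
        take = min(config.n_background_peptides, len(background))
        idx = rng.choice(len(background), size=take, replace=False)
        for i in sorted(int(j) for j in idx):
            pep = background[i]
            nq = [k + 1 for k, aa in enumerate(pep.sequence) if aa in "NQ"]
            mods = ""
            cls = OTHER
            if nq and rng.random() < config.frac_deamidation_confounders:
                within = int(rng.choice(nq))
                mods = f"deamidation@{within}"
                cls = MODIFIED_1DA
                truth.confounder_sites.append(
                    (pep.protein_id, pep.start + within - 1, pep.sequence[within - 1])
                )
            key = PeptideKey(pep.sequence, mods)
            truth.peptide_class[key] = assign_class(key)
            detected = detection(rng)
            for group in config.groups:
                n = int(rng.poisson(config.background_psm_mean))
                for _ in range(n):
                    emit(key, (pep.protein_id,), group, cls, False, False, detected)

    # --- decoy PSMs -------------------------------------------------------
    decoy_peps: list[Peptide] = []
    for rec in proteome:
        decoy_peps.extend(
            p
            for p in digest(make_decoy(rec), ("trypsin",), 0)
            if 6 <= len(p.sequence) <= 30
        )
    decoy_mod = [p for p in decoy_peps if any(aa in "RNQ" for aa in p.sequence)]
    for cls, n_decoys in sorted(config.n_decoy_psms_per_class.items()):
        pool = decoy_mod if cls == MODIFIED_1DA else decoy_peps
        if not pool or n_decoys == 0:
            continue
        for _ in range(n_decoys):
            pep = pool[int(rng.integers(len(pool)))]
            mods = ""
            if cls == MODIFIED_1DA:
                rs = [k + 1 for k, aa in enumerate(pep.sequence) if aa == "R"]
                nqs = [k + 1 for k, aa in enumerate(pep.sequence) if aa in "NQ"]
                if rs:
                    mods = f"citrullination@{int(rng.choice(rs))}"
                else:
                    mods = f"deamidation@{int(rng.choice(nqs))}"
            key = PeptideKey(pep.sequence, mods)
            group = str(rng.choice(np.array(config.groups)))
            detected = detection(rng)
            emit(key, (pep.protein_id,), group, cls, True, False, detected)

    return tables


def simulate_scored_psms(
    seed: int,
    n_true: int,
    n_false: int,
    n_decoy: int,
    true_params: tuple[float, float],
    null_params: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scores with known correct/incorrect labels for FDR calibration.

    Targets are a mixture of ``n_true`` correct matches (scores from
    ``true_params``) and ``n_false`` incorrect matches; incorrect targets
    and the ``n_decoy`` decoys are i.i.d. from the same null
    (``null_params``), the exchangeability assumption underlying
    target-decoy estimation.

    Returns ``(scores, is_decoy, is_false_target)``; decoys are False in
    the third array.
    """
    rng = np.random.default_rng(seed)
    scores = np.concatenate(
        [
            rng.normal(*true_params, size=n_true),
            rng.normal(*null_params, size=n_false),
            rng.normal(*null_params, size=n_decoy),
        ]
    )
    is_decoy = np.concatenate(
        [np.zeros(n_true + n_false, dtype=bool), np.ones(n_decoy, dtype=bool)]
    )
    is_false = np.concatenate(
        [
            np.zeros(n_true, dtype=bool),
            np.ones(n_false, dtype=bool),
            np.zeros(n_decoy, dtype=bool),
        ]
    )
    return scores, is_decoy, is_false


def write_outputs(
    proteome: Sequence[ProteinRecord],
    truth: GroundTruth,
    tables: dict[str, list[PSM]],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write FASTA, per-engine PSM TSVs, and ground-truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = outdir / "proteome.fasta"
    write_fasta(proteome, fasta)
    paths["proteome"] = fasta

    for engine, psms in tables.items():
        p = outdir / f"psms_{engine}.tsv"
        write_psm_table(psms, p)
        paths[f"psms_{engine}"] = p

    site_rows = [
        {
            "protein_id": pid,
            "position": pos,
            "residue": res,
            **{g: truth.site_counts.get((pid, pos), {}).get(g, 0) for g in
               sorted({g for c in truth.site_counts.values() for g in c})},
        }
        for pid, pos, res in truth.planted_sites
    ]
    p = outdir / "truth_sites.tsv"
    pd.DataFrame(site_rows).to_csv(p, sep="\t", index=False)
    paths["truth_sites"] = p

    class_rows = [
        {"peptide": k.sequence, "modifications": k.modifications, "class": cls}
        for k, cls in sorted(truth.peptide_class.items())
    ]
    p = outdir / "truth_peptide_classes.tsv"
    pd.DataFrame(class_rows).to_csv(p, sep="\t", index=False)
    paths["truth_peptide_classes"] = p
    return paths
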