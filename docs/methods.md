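# Methods

## Problem

Citrullination — enzymatic deimination of arginine by peptidylarginine
deiminases (PADI) — shifts a peptide's monoisotopic mass by +0.984016 Da
and removes a positive charge. Deamidation of asparagine or glutamine
produces the *same* nominal +1 Da shift, so a shotgun-proteomics search
cannot separate the two by precursor mass. Compounding this, spectra of
1-Da-modified peptides are harder to distinguish from chance matches
than unmodified spectra: their target/decoy score separation is poorer,
and a single global score cutoff silently under-controls the false
discovery rate (FDR) within that class. `citmap` implements the
interpretation protocol for this situation: multi-engine consensus,
class-stratified target-decoy FDR, orthogonal citrulline evidence
(tryptic resistance and the 43-Da neutral loss), and site-resolved
spectral counting across tissue groups.

## Pipeline model

1. **Digestion** (`citmap.digest`). Trypsin cleaves after K/R except
   before proline; Lys-C after K (under these rules a combined Lys-C +
   trypsin digest equals trypsin alone). Citrullinated arginines resist
   trypsin; this is modelled as an explicit set of *blocked* cleavage
   positions rather than a modified alphabet, keeping sequences
   FASTA-round-trippable. Peptides are enumerated with up to
   `max_missed` (default 2) internal cleavage sites; coordinates are
   1-based inclusive. Masses are monoisotopic, computed from atomic
   masses; citrullination and deamidation deltas are equal to machine
   precision by construction. Decoys are whole reversed proteins with a
   `DECOY_` id prefix.

2. **Best PSM and consensus** (`citmap.consensus`). All scores are
   mapped to one internal higher-is-better scale; engines reporting
   posterior error probabilities (lower is better) are ingested negated.
   Per engine, the best PSM per peptide key is kept; ties break on the
   lowest spectrum id, then the lexicographically smallest modification
   string, so selection is deterministic. A peptide key is the stripped
   sequence plus the full canonical modification string (sorted by
   position) — a citrullinated and an unmodified peptide are distinct
   identifications, and I/L are not collapsed. Consensus keeps keys seen
   by at least `min_engines` (default 2) of the engines, treating the
   with- and without-neutral-loss searches of the same engine as
   separate voters.

3. **Stratified FDR** (`citmap.fdr`). Peptide keys are split into two
   classes: `modified_1Da` (any citrullination or deamidation) and
   `other` (everything else; oxidation/carbamidomethyl alone do not
   qualify). Within each class, over the merged best-PSM set,
   `fdr(t) = #decoys(>= t) / max(1, #targets(>= t))`, monotonized into
   q-values by a cumulative minimum from the most permissive threshold
   upward. The class cutoff is the most permissive observed score with
   q <= alpha (default alpha = 0.001, i.e. 0.1%); when no threshold
   attains the level the class accepts nothing ("none attainable",
   which we treat as the maximally demanding cutoff). Decoy PSMs are
   excluded from all downstream counting.

   *Estimator choice.* The simple D/T ratio is used, not (D+1)/T and not
   the Elias–Gygi (2D)/(T+D). D/T carries the well-known anti-conservative
   stopping bias of target-decoy thresholding (selecting the most
   permissive threshold with q <= alpha conditions on a downward
   fluctuation of D); at alpha = 0.01 with ~25 decoys above the cutoff
   this inflates the realized false discovery proportion by roughly
   +0.0005 absolute. The calibration suite measures this and it stays
   within three binomial standard errors of nominal at the tested
   scale, but users filtering small PSM sets at very strict levels
   should be aware the estimator is not the conservative variant.

   *Naming.* Although protocols of this kind sometimes say "local FDR",
   what is computed here (and tested) is threshold FDR with q-values.

4. **Site mapping and evidence** (`citmap.sitemap`). Within-peptide
   modification positions map to protein coordinates as
   `site = peptide_start + position - 1`; labels like `R80` are 1-based
   residue numbers on the supplied isoform sequence. Two orthogonal
   evidence flags annotate every citrulline call: the modified residue
   must be an arginine *internal* to its tryptic peptide (a genuinely
   citrullinated R cannot be a tryptic C-terminus except at the protein
   end), and the engine-reported 43.005814 Da neutral loss of isocyanic
   acid (HNCO) may corroborate it. Flags are annotations by default; in
   `strict_evidence_mode` a PSM is dropped unless the residue is R and
   at least one of the two features holds. The flag is consumed from
   the PSM table, never computed from raw spectra. Counting unit is
   PSMs (spectral counts) per site per tissue group, deduplicated by
   spectrum id across engines; peptides shared by several proteins
   count once per protein (no razor/parsimony). Proteins are reported
   when they carry at least `min_citr_peptides_per_protein` (default 2)
   *distinct* citrullinated peptide keys — peptides, not sites, are
   counted, so two peptides sharing one site still qualify. Group
   agreement is summarized Bland–Altman style: per protein,
   mean (a+b)/2 against difference b−a, with `a` the control group.

5. **Reactivity** (`citmap.reactivity`). Stimulation index
   SI = mean(stimulated cpm) / mean(background cpm) over replicate
   wells; SI > 2 (strict) is a positive proliferative response and
   IFN-γ > 100 pg/ml (strict) a strong cytokine response. Wells are
   reported individually and as means. Readout agreement uses the
   product-moment correlation with the t-transform p-value.

## Synthetic data: what it emulates and what it does not

`citmap.synthetic` generates the stated world every stage is tested
against: target proteins with i.i.d. residues at average amino-acid
frequencies (composition realism is irrelevant to pipeline
correctness); a designated reference protein with exactly 19 arginines
so site maps have the shape of the classic myelin basic protein
reference; citrullination planted on arginines with per-(site, group)
Poisson PSM counts; deamidation confounders on N/Q among background
peptides; three pseudo-engines (two ion-score-like, one PEP-like
emitting negated internal scores) that each detect a given peptide
independently with `engine_detection_prob`; and matched-size decoy PSM
sets per class so that class-cutoff differences reflect score
separation, not decoy-set size.

Defaults (all overridable in `SimulationConfig`, none hard-coded
downstream): four tissue groups GMC/GMMS/WMC/WMMS with per-site PSM
means 3.0/2.8/4.0/6.4 — mirroring the qualitative published pattern of
strong citrullination enrichment in diseased white matter (~1.6x
control) and slight depletion in diseased gray matter; target scores
N(18, 6) for the 1-Da class vs N(28, 5) otherwise against decoys
N(10, 4), i.e. visibly poorer separation for the modified class (no
score distributions are published; these are free parameters);
neutral-loss flag on half the true citrulline PSMs; detection
probability 0.9.

Not emulated: raw spectra (mzML), retention time or HILIC
fractionation, isotope envelopes, score correlations between engines
beyond shared spectra, and protein inference ambiguity. A green test
therefore establishes that the *interpretation chain* — digestion
coordinates, key algebra, FDR arithmetic, site counting — is correct
under the stated world; it says nothing about search-engine behaviour
on real spectra.

For FDR calibration specifically, `simulate_scored_psms` generates
targets with known correct/incorrect labels where incorrect targets
and decoys are i.i.d. from the same null — the exchangeability
assumption under which D/T estimates the false discovery proportion.

## Numerical and design choices

- Monoisotopic masses from atomic masses (H 1.0078250319, C 12,
  N 14.0030740052, O 15.9949146221, S 31.97207069); water 18.010565;
  HNCO 43.005814. Precursor tolerances at Orbitrap level imply
  monoisotopic, never average, masses.
- "Deamidation (R)" in search-engine settings is chemically
  citrullination; the two labels are synonyms on arginine here.
- Best-PSM "lowest PEP / highest ion score" convention: the internal
  scale is higher-is-better and PEPs enter negated; each engine's
  convention travels with its PSMs in the `score_convention` column.
- Degenerate inputs: an all-decoy input refuses FDR estimation; a class
  with no targets is reported empty with a warning, not a failure; an
  empty accepted set produces an all-zero site matrix.
- At very small scale and very strict alpha, both class cutoffs sit
  just above each class's decoy maximum (zero decoys above cutoff), so
  the "modified class cutoff is more demanding" effect is only visible
  once enough targets accumulate for the D/T curve to cross alpha in
  its interior — the regime the stratification tests use (1,000 targets
  and 300 decoys per class at alpha = 0.01).
- The consensus rule compares modification-resolved keys by default;
  `engine_consensus` operates on whatever key sets it is given, so a
  stripped-sequence comparison is a one-line pre-projection if wanted.

## Known limitations

- The bundled 19-arginine reference sequence is a labelled synthetic
  stand-in satisfying the published shape constraints (length 171,
  19 R, anchor peptides at their reported coordinates); it is not the
  database isoform, which offline runs cannot fetch.
- No spectrum-level site localization (no Ascore/ptmRS): a PSM's
  modification position is taken at face value from the table.
- Peptides are located in proteins by first occurrence; repeated exact
  peptides within one protein would map to the first copy.
- No protein parsimony; shared peptides count once per listed protein.
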