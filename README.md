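# citmap

Citrullination site mapping from multi-engine peptide-spectrum matches,
with class-stratified target-decoy FDR.

## The problem

Citrullination (deimination of arginine by PADI enzymes) adds
+0.984016 Da to a peptide and removes a positive charge. Deamidation of
N/Q adds the *same* nominal +1 Da, so the two are indistinguishable by
precursor mass — and spectra of such 1-Da-modified peptides separate
worse from decoys than unmodified ones, so a single global score cutoff
under-controls the FDR exactly where it matters. `citmap` implements
the interpretation chain used to map in-vivo citrullination across
tissue groups from search-engine output:

- citrulline-aware in-silico Lys-C/trypsin digestion (citrullinated R
  resists cleavage) and monoisotopic peptide masses;
- best-PSM-per-peptide selection and ≥2-of-3 engine consensus over
  modification-resolved peptide keys;
- target-decoy FDR estimated *separately* for the 1-Da-modified class
  and everything else, with per-class cutoffs at a nominal level
  (default 0.1%): `fdr(t) = #decoys(≥t) / max(1, #targets(≥t))`,
  q-values by cumulative minimum;
- citrulline-vs-deamidation evidence flags (residue is R; uncleaved
  tryptic site at the modified R; engine-reported 43.005814 Da HNCO
  neutral loss);
- per-site, per-tissue-group spectral count matrices, a
  ≥2-citrullinated-peptides protein filter, and Bland–Altman
  group-agreement tables;
- T-cell reactivity arithmetic (stimulation index SI =
  mean cpm stimulated / mean cpm background, SI > 2 positive;
  IFN-γ > 100 pg/ml strong positive; Pearson readout correlation).

A fully seeded synthetic generator (`citmap.synthetic`) produces a toy
proteome — including a designated reference protein with exactly 19
arginines — and ground-truthed three-engine PSM tables, so every stage
is testable without any raw data. It is first-class, tested code, not a
fixture. See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
from citmap.pipeline import PipelineConfig, run_pipeline

manifest = run_pipeline(
    PipelineConfig(output_dir="demo_out", synthetic=True, seed=7)
)
print(manifest["stages"])
```

prints (numbers produced by this exact run):

```
{'best_psm': {'mascot_NL': 401, 'mascot_noNL': 400, 'percolator': 405},
 'union_peptides': 435,
 'consensus_peptides': 425,
 'accepted_peptides': 156,
 'cutoffs': {'modified_1Da': 24.836654545640855, 'other': 27.626487161790887},
 'accepted_citr_psms': 419,
 'citr_sites': 24,
 'proteins_min_citr_peptides': 7}
```

Reading: the three pseudo-engines each identified ~400 peptides
(best PSM per peptide), 425 survived the 2-of-3 consensus, and 156
passed the class-stratified 0.1% FDR filter — the per-class score
cutoffs are reported so the stratification is observable. The 419
accepted citrullinated PSMs map to 24 arginine sites, and 7 proteins
carry at least two distinct citrullinated peptides. `demo_out/`
contains the per-stage TSVs (`site_counts.tsv` has one row per modified
arginine with one spectral-count column per tissue group, e.g.)

```
  protein_id  position residue  GMC  GMMS  WMC  WMMS
SYNPROT_0001        19       R    2     3    5     7
SYNPROT_0001        26       R    3     4    3    10
```

plus FDR curves, evidence flags, the Bland–Altman table, and a
`manifest.json` recording input checksums, seed, and stage counts;
re-running with the same config is byte-identical.

The same chain is available from the shell:

```sh
citmap run-all --synthetic --seed 7 --out demo_out
citmap simulate --seed 3 --out sim_out
citmap fdr sim_out/psms_percolator.tsv --alpha 0.001 --out fdr_out
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end result from scratch: it generates
the seeded synthetic inputs, runs digestion, consensus, stratified FDR,
and site mapping, verifies the stage-count containments, and writes the
results JSON to `--out`.
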