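# perturbtrace

Analysis stack for image-based pooled CRISPR screens of 3D genome
organization — the "Perturb-tracing" experimental design in which every
cell carries one sgRNA paired with a ternary RNA barcode read out by
sequential FISH, while chromatin tracing maps the 3D positions of the 27
TADs of chromosome 22 in the same cell. The package is written for
computational biologists who have spot-level imaging output (per-round
barcode intensities, traced 3D positions, nuclear masks) and sequencing
read tables, and want decoded perturbation identities and multi-scale
chromatin/nuclear phenotypes with hit statistics.

It implements, end to end:

- **Barcode codec** — the 10-trit code space (3¹⁰ = 59,049 codes), 41-nt
  digit sequence assembly (419-nt barcode body), intensity→trit calling,
  and error-correcting decoding against a good/bad codebook, with
  wildcard handling of low-confidence digits.
- **Codebook construction** — UMI join of sgRNA–UMI and barcode–UMI read
  tables, end-anchored partial-code assembly, good/bad code
  classification, library dropout QC.
- **Trace phenotypes** — pairwise/adjacent TAD distances, the 500-nm
  contact rule, A–A/A–B/B–B compartmental contact frequencies, radius of
  gyration, and the convex-hull A/B polarization index
  PI = √((1 − Vs/Va)(1 − Vs/Vb)) with scrambled-label controls.
- **Screen statistics** — per-sgRNA log₂ fold-change distance matrices
  vs pooled non-targeting controls, Wilcoxon signed-rank (paired by TAD
  pair) and rank-sum tests, Benjamini–Hochberg FDR per phenotype,
  hit calling (FDR < 0.1, |log₂fc| ≥ 0.05), effect-matrix correlations
  with the average compartment-score matrix, <3 Mb short-range vs
  long-range splits, and hierarchical clustering of hit matrices.
- **Nuclear morphometrics** — intensity unevenness (COV of in-mask
  voxel intensities) and 3D sphericity Ψ = π^⅓(6V)^⅔/A from
  marching-cubes meshes on isotropically resampled masks.
- **Polymer simulation** — a bead-spring Metropolis Monte-Carlo chain
  with square-well self-interaction of depth K, whose union-of-spheres
  bounding envelope is scored with the same sphericity code; weaker
  interaction yields multi-lobed, lower-sphericity envelopes.
- **Synthetic screen generator** — ground-truth libraries, read tables,
  noisy barcode readouts, perturbation-scaled traces and nuclear
  phantoms, so the whole pipeline is testable without any downloads.

See `docs/methods.md` for the models, statistics, parameter defaults and
known limitations.

## Worked example

Run a small synthetic screen end to end — generate fixtures, decode every
cell's barcode readout, and call hits:

```python
from perturbtrace.workflows import run_synthetic_screen, score_recovery

result = run_synthetic_screen(seed=1234)   # 60 sgRNAs x 120 cells
print(result.decode_stats)
rec = score_recovery(result)
print(rec["n_recovered"], "of", rec["n_planted"], "planted hits;",
      rec["n_false_positives"], "false positives")
print(result.hits[result.hits.phenotype == "overall_distance"]
      [["sgrna", "log2fc", "fdr", "direction"]].head(4).to_string(index=False))
```

prints

```
{'n_cells': 7200, 'assigned_fraction': 0.9876388888888888, 'correct_fraction': 0.9870833333333333, 'status_counts': {'assigned': 7111, 'rejected_no_match': 62, 'rejected_ambiguous': 27}}
6 of 6 planted hits; 0 false positives
      sgrna    log2fc          fdr direction
sgGENE002_1 -0.304089 4.174273e-58      down
sgGENE001_1 -0.296950 4.174273e-58      down
sgGENE004_1  0.333156 4.174273e-58        up
sgGENE003_1  0.319052 4.174273e-58        up
```

Reading this: 98.8% of the 7,200 cells decoded to an sgRNA (the rest were
rejected as unmatchable or ambiguous rather than misassigned); all six
planted perturbations — two chromatin compactors (distances ×0.8), two
decompactors (×1.25), one sphericity-down and one intensity-unevenness-
down — were recovered with the correct direction, with no spurious hit
among the 54 null sgRNAs. On the overall-distance phenotype the
decompactors surface with log₂fc ≈ +0.32 ≈ log₂(1.25) and the compactors
with ≈ −0.30 ≈ log₂(0.8), as planted.

The same pipeline is exposed as a CLI:

```bash
perturbtrace simulate --seed 3 --n-sgrnas 8 --cells-per-sgrna 12 --out fix/
perturbtrace decode --readout fix/readouts.csv --codebook fix/codebook.json --out assign.tsv
perturbtrace screen --traces fix/traces.tsv --assignments assign.tsv \
    --profile fix/compartments.tsv --out results/
perturbtrace polymer --K 1,0.4,0.1 --n 100 --seed 7 --out polymer/
```

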