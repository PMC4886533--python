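# dystroquant

Quantification pipeline for studies of protease activity and impaired
myogenesis in dystrophic skeletal muscle. The package re-implements, as
tested and reusable Python, the three bespoke quantitative procedures such
studies rely on:

1. **Fluorescence-image quantification** — segment nuclei (DAPI) and a
   marker channel (MyHC, laminin, elastase or Ly6G), split touching nuclei
   by watershed, discard inseparable nuclear clumps above a 900-px size
   cutoff, and compute per-image myogenesis indices by mask logic:

   - *differentiation index* `DI = (nuclei in marker⁺ cells) / (total nuclei)`
   - *fusion index* `FI = (nuclei in myotubes) / (nuclei in marker⁺ cells)`,
     where a myotube is a marker-positive connected component containing
     ≥ 2 nuclei
   - marker⁺ area per image and marker⁺ cell counts.

   Thresholding uses the Li (minimum cross-entropy) or Triangle histogram
   method, implemented as exhaustive 256-bin scans with exactly specified
   tie-breaking.

2. **Fluorogenic protease kinetics** — for plate-reader time courses of
   product accumulation (e.g. AMC release from Suc-Ala-Ala-Ala-AMC read
   every 15 min over 3 h), subtract buffer-only blanks, average technical
   replicates, and extract the inhibitor-sensitive activity fraction
   `S(t) = uninhibited(t) − inhibited(t)` together with OLS activity rates
   and percent inhibition `100·(1 − b_inh/b_uninh)`.

3. **Label-free proteomics differential abundance** — from a peptide
   feature table: retain charges 2+..7+, normalise runs by median
   log-ratio to a reference run, roll up protein abundance as the sum of
   unique-peptide abundances, QC replicates by pairwise R² of log
   abundances, then test Dys vs WT within each age group by one-way ANOVA
   on log abundances with Bonferroni correction
   (`q = min(1, p·m)`; p < 0.05 moderate, q < 0.05 strong evidence).

A synthetic-data module generates ground-truthed micrographs, kinetic
plates and peptide tables with the statistical structure the analyses
assume (including a Serpinb1a-like protein planted at ~6-fold and ~7-fold
enrichment in the two age groups), so every stage is verifiable end to end
with no external data.

## Worked example

```python
import dystroquant as dq
from dystroquant import kinetics as kin, proteomics as prot

# image quantification against known ground truth
rgb, gt = dq.simulate_image(dq.ImageSimParams(seed=3))
idx = dq.quantify_image(rgb)
print(f"true  DI={gt.true_indices.differentiation_index:.3f} "
      f"FI={gt.true_indices.fusion_index:.3f}")
print(f"found DI={idx.differentiation_index:.3f} FI={idx.fusion_index:.3f} "
      f"nuclei={idx.total_nuclei} myotubes={idx.myotube_count}")

# inhibitor-sensitive kinetics
plate = dq.simulate_kinetics(dq.KineticSimParams(seed=1))
row = kin.analyze_plate(plate)["rates"].query("inhibitor == 'cocktail'").iloc[0]
print(f"percent inhibition = {row['percent_inhibition']:.1f}%")

# differential abundance with a planted 6-fold protein
peps, design, _ = dq.simulate_peptide_table(
    dq.ProteomeSimParams(differential_spec=dq.SERPIN_LIKE_SPEC, seed=2))
norm, _ = prot.normalize_runs(prot.filter_peptides(peps), design)
mat = prot.rollup_proteins(norm).matrix
top = prot.differential_test(mat, design, "3").iloc[0]
print(f"top protein {top['protein']}: fold={top['fold_change']:.2f} "
      f"q={top['q_value']:.2e} tier={top['tier']}")
```

prints

```
true  DI=0.275 FI=0.727
found DI=0.275 FI=0.727 nuclei=40 myotubes=2
percent inhibition = 50.0%
top protein P0001: fold=5.76 q=9.08e-05 tier=strong
```

The simulated scene contains 40 nuclei, of which 11 sit in marker-positive
cells (two 4-nucleus myotubes and three mononucleated MyHC⁺ cells), so
DI = 11/40 = 0.275 and FI = 8/11 ≈ 0.727; the end-to-end measurement
recovers both exactly here. The kinetic plate was generated with a true
inhibited fraction of 0.5, and the planted protein is recovered as the
top-ranked hit at strong significance.

## Command line

```sh
dystroquant simulate --kind image --seed 5 --out-dir sim/
dystroquant quantify-image --input sim/scene.png --out indices.csv
dystroquant kinetics --plate plate.csv --out kin/
dystroquant proteomics-diff --peptides peptides.csv --design design.csv --out diff/
dystroquant run-all --seed 7 --out-dir study/   # full synthetic study + manifest
```

`run-all` writes every table as CSV plus a `manifest.json` with SHA-256
hashes; identical config and seed reproduce the outputs byte for byte.

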