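# cctopo

Analysis pipeline for midsagittal corpus-callosum (CC) connection topography
from probabilistic-tractography streamline counts, with a synthetic
longitudinal cohort generator for validation.

The pipeline starts from per-scan, per-hemisphere matrices of streamline
counts between CC voxels and cortical target areas and computes:

1. **Population maps** (`popmap`) — per-voxel normalized connection
   probabilities, binarized at a multi-threshold scheme (0.100–0.200 in
   steps of 0.025) and averaged over thresholds and sample units; plus
   ROI mean profiles and detectability classification of areas
   (passage-field / widespread-weak / undetectable).
2. **Parcellation** (`parcellation`) — bilateral passage fields from the
   voxelwise product of left and right maps thresholded at 0.05², outer
   boundary tracing with hole suppression, and per-scan field sizes.
3. **Symmetry** (`symmetry`) — per-area OLS regression of right-side on
   left-side voxel values; areas with slope within 1 ± 0.5 and adjusted
   R² > 0.7 are flagged symmetric.
4. **Statistics** (`stats`) — linear mixed-effects models
   (`outcome ~ sex + age + (1 | subject)`, maximum likelihood, male
   reference level, age in months) of field size and voxelwise density,
   Benjamini–Hochberg FDR per family, and a male→female group-swap
   confound check.
5. **Synthetic cohorts** (`synthetic`) — unbalanced multi-cohort
   longitudinal designs with anterior–posterior-ordered area templates,
   log-linear age/sex effects, subject random intercepts, monotone
   dropout, controllable left–right asymmetry and negative-binomial count
   noise. Fully seed-deterministic.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the nine acceptance criteria
(normalization conservation, exceedance-oracle equivalence, threshold
monotonicity, parcellation/boundary oracles, symmetry recovery, LME
calibration and recovery, FDR correctness, group-swap dilution, end-to-end
determinism); the remaining files are per-module unit and property tests
with independent brute-force oracles.

## CLI

```sh
# generate a synthetic dataset (TSV counts + metadata + grid JSON)
cctopo simulate --out data/ --seed 1 --preset default   # or --preset small

# full pipeline: population maps, fields, symmetry, statistics
cctopo run --data data/ --out results/ --seed 1

# individual stages
cctopo aggregate  --data data/ --out results/
cctopo parcellate --data data/ --out results/
cctopo symmetry   --data data/ --out results/
cctopo stats      --data data/ --out results/

# human-readable summary of a finished run
cctopo report --out results/
```

Common flags: `--config cfg.yaml`, `--seed`, `--sample-unit {scan,subject}`,
`--threshold-scheme 0.1,0.125,0.15,0.175,0.2`, `--alpha`. Every run writes
`manifest.json` with the fully resolved configuration and a
content-derived run id; outputs are byte-deterministic given the same
inputs and configuration.

Output files: `pmap_{left,right}.tsv`, `detectability.tsv`, `fields.tsv`,
`field_<area>.nii`, `boundaries.json`, `field_sizes.tsv`, `symmetry.tsv`,
`symmetry_pairs.tsv`, `field_size_lme.tsv`, `voxelwise_lme.tsv`,
`manifest.json`. Grid coordinates are reported both as 0-based voxel
indices and in millimetres relative to the anterior-commissure origin.

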