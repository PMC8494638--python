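# patchpipe

A tested, reusable pipeline for multimodal single-neuron analysis: intrinsic
electrophysiology feature extraction from current-clamp sweeps, neuronal
morphometry with laminar alignment, transcriptomic type assignment with
cluster-structure statistics, laminar histology profiling, and cross-modal
group/gradient statistics. Every stage ships with a synthetic-data generator
that produces inputs with known ground truth, so the whole pipeline runs and
is testable end-to-end with no external data.

## Modules

| Module | What it does |
| --- | --- |
| `patchpipe.synthetic` | Generators for all four input kinds: LIF-based current-clamp sweeps (known RMP, R_input, tau, sag, rheobase), SWC morphologies (known apical/basal extents), negative-binomial count matrices (discrete clusters + optional depth gradient), and histology tables (designed density nadir). |
| `patchpipe.sweeps` | Current-clamp sweep container + HDF5 I/O. |
| `patchpipe.ephys_features` | Sweep QC (bridge/bias/RMS criteria), dV/dt spike detection with refinement, per-spike waveform features, and the 18 per-cell intrinsic features. |
| `patchpipe.morph_features` | SWC I/O, shrinkage/tilt corrections, laminar branch-length histograms (length-conserving), apical-histogram PC scores, scalar morphometrics. |
| `patchpipe.transcriptomics` | CPM normalization, beta marker score, binary-gene selection, technical gene filters, NMS quality score, correlation-based cluster mapping, permutation heterogeneity statistic, pairwise discreteness counts, 3-cluster marker selection. |
| `patchpipe.histology_profiles` | Scaled L2/3 depth, 20-bin density and soma-area profiles, nadir detection. |
| `patchpipe.group_stats` | kNN imputation + robust scaling, depth regressions with HC3-robust p and BH-FDR, type-wise ANOVA (eta-squared) with Mann-Whitney post hocs, covariate-adjusted pathology comparisons, sparse PCA projections, and type classifiers with shuffled-label baselines. |

## CLI

A single `patchpipe` entry point with one subcommand per stage:

```sh
# synthetic inputs (one kind each; YAML config optional)
patchpipe simulate ephys --seed 1 --out data/ephys/cell_000
patchpipe simulate expr  --seed 1 --out data/ref
patchpipe simulate hist  --seed 1 --out data/hist

# analysis stages
patchpipe ephys-features --in data/ephys --out features.tsv
patchpipe morph-features --swc swcs/ --layers layers.tsv --out morph/
patchpipe map --ref data/ref --query data/query --out mapped/
patchpipe cluster-stats --matrix data/ref --out stats/
patchpipe profile --table data/hist/histology.tsv --out profiles/
patchpipe stats depth --in cells.tsv --out stats/

# full synthetic pipeline: simulate -> features -> map -> merge -> stats
patchpipe run-all --seed 1 --out runall/
```

## Notes on conventions

- Voltages are reported uncorrected for the liquid junction potential; the
  -14 mV offset is carried as metadata.
- Morphologies are pia-aligned with `y` increasing toward the pia; cortical
  depth is `pia_y - y`. SWC type codes: 1 soma, 2 axon, 3 basal, 4 apical.
- Scaled L2/3 depth is 0 at the L1/2 boundary and -1 at the L3/4 boundary;
  histology bin edges assign boundary cells to the deeper bin.
- "Expressed" means log2(CPM+1) > 1; all sampling is seeded and all
  tie-breaks are lexicographic, so results are reproducible bit-for-bit.
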