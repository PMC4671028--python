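# restnet

Graph-theoretic analysis of resting-state functional brain networks:
from parcellated ROI time series (or precomputed correlation matrices)
through thresholded binary graphs to small-world and cost-efficiency
metrics, degree-distribution model selection, hub/module detection, and
attack-resilience simulation. A synthetic cohort generator with planted
modular, small-world correlation structure makes the whole pipeline
testable without any external data.

## Layout

| module | contents |
| --- | --- |
| `restnet.synthetic` | cohort / motion / reference-graph / degree-sequence generators |
| `restnet.preprocess` | framewise displacement, frame censoring, simultaneous nuisance regression + band-pass (0.01–0.1 Hz) by projection, Pearson connectivity matrices |
| `restnet.graphs` | R / cost / mean-degree thresholding, connected components, threshold grids |
| `restnet.nulls` | degree-preserving rewiring (Maslov–Sneppen), matched ring lattices, preferential-attachment graphs |
| `restnet.metrics` | clustering, path length, global/local efficiency, Brandes betweenness, small-world summary — all from scratch |
| `restnet.degree_dist` | power-law / exponential / truncated power-law fits to the log cumulative degree distribution, AIC selection |
| `restnet.community` | Louvain with restarts + fine-tuning, mean+1SD hub identification |
| `restnet.resilience` | targeted attacks, averaged random failure, isolated-removal sweeps, hub-class comparison |
| `restnet.stats` | paired t-tests vs null ensembles with Bonferroni correction, small-world-index confidence intervals |
| `restnet.pipeline` / `restnet.cli` | orchestration, delimited-text/JSON I/O, `restnet` command |

## CLI

```sh
restnet simulate  --seed 0 --out cohort/ --n-subjects 60
restnet preprocess --timeseries cohort/sub000_timeseries.csv \
                   --motion cohort/sub000_motion.csv --out sub000_matrix.csv
restnet graph     --matrix sub000_matrix.csv --scheme cost --value 0.22 --out g.edges
restnet metrics   --edges g.edges
restnet fitdist   --edges g.edges
restnet community --edges g.edges --seed 0
restnet attack    --edges g.edges --strategy betweenness
restnet report    --seed 0 --out report_dir/        # full pipeline
```

`restnet report` accepts `--config config.yaml` with overrides for the
threshold grids, null-ensemble sizes, censoring thresholds (FD > 0.3 mm,
>10% outlier voxels), band limits, Louvain restarts, and the synthetic
cohort spec.

## File formats

Delimited text throughout: time series as CSV with an ROI-label header
row, motion as 7 columns (3 translations mm, 3 rotations rad, outlier
fraction), correlation matrices as labeled square CSV, graphs as
0-based two-column edge lists, and structured results as JSON with
6-significant-digit floats.
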