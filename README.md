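# motifnet

Multi-region functional-network analysis for delayed-response tasks, built
around a synthetic multi-region session generator with known ground truth.
The pipeline covers:

- **Session model** — trial-structured deconvolved activity (neurons x
  frames at ~9.35 Hz) with region labels, an event table, epoch
  arithmetic, an activity-based neuron-inclusion filter and HDF5/CSV I/O.
- **Synthetic data** — log-link point-process sessions with planted
  directed lag-1/2 coupling (controllable density and same-tuning
  enrichment), stimulus/choice/action tuning, learning-stage series with
  retained/eliminated edge structure, and 60-Hz movement traces with
  confidence dropouts and outliers.
- **Behavior** — tracking-trace cleaning (likelihood interpolation, MAD
  outlier replacement, smoothing) and movement-stereotypy statistics.
- **Population modes** — stimulus/choice coding directions (unit-norm
  right-minus-left difference axes), Gram-Schmidt orthogonalization,
  trial projections with ITI baseline subtraction, choice selectivity
  and trial-by-trial inter-areal coordination (with 40-trial balancing).
- **Decoding statistics** — ROC/AUC with midrank ties, shuffle nulls,
  learning-trend tests, bootstrap, Benjamini-Hochberg FDR, Wilcoxon
  tuning classification.
- **Coupling GLM** — per-neuron Poisson elastic-net encoding model
  (raised-cosine task bases, lagged cell-coupling predictors, 70/30
  split, 5-fold CV over a lambda path, pseudo explained variance,
  2-s-block shuffle significance with FDR, partial-model
  reconstruction). The path solver (IRLS + coordinate descent with
  strong-rule screening; FISTA as an independent second route) is
  implemented in `motifnet.glm.solver` and verified against KKT
  conditions and statsmodels.
- **Network motifs** — convergence and enrichment indices, random-
  coupling nulls, retained/eliminated coupling partitions with
  equal-size subsampled reconstructions, selective in-silico coupling
  ablation with a choice-axis readout, and correlation-based
  connectivity controls.
- **Reduced-rank regression** — rank-constrained inter-areal prediction
  with ITI-correlation matching and 20-neuron subsampling.
- **FORCE RNN** — rate network (tau = 10 ms, dt = 1 ms, sigmoidal
  transfer) trained by per-timestep recursive least squares on
  two-condition target currents, with distractor-perturbation and
  external-connection-ablation assays of the choice attractor.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the ground-truth-recovery acceptance
suite (one test per criterion); the remaining files are fast unit and
property tests.

## CLI

```sh
motifnet simulate --config sim.yaml --seed 3 --out out/   # synthetic session
motifnet validate out/session.h5                          # schema report
motifnet behavior clean out/movement.csv --out clean.csv
motifnet modes --session out/session.h5 --region ALM --mode choice --out axis.csv
motifnet fit-glm --session out/session.h5 --targets ALM --out edges.tsv
motifnet rrr --session out/session.h5 --source PPC --target ALM --ranks 1:5 --out rrr.csv
motifnet run --seed 7 --out report.json                   # end-to-end pipeline
```

## Layout

```
src/motifnet/
  session.py    simulate.py   behavior.py   modes.py   stats.py
  glm/          (basis, design, solver, fit)
  motifs.py     rrr.py        rnn.py        acceptance.py
  config.py     cli.py
tests/          unit + property + acceptance suites
scripts/acceptance.py
```
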