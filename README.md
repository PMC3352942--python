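# slnet — synchronization-likelihood networks from multichannel EEG

`slnet` implements a complete functional-connectivity analysis chain for
band-limited multichannel signals, of the kind used to track how the brain's
resting-state network organization changes across the life span:

1. **Connectivity.** Synchronization likelihood (SL) between every channel
   pair. Each signal's instantaneous state is a time-delay embedding vector
   **X**ᵢ = {xᵢ, xᵢ₊ₗ, …, xᵢ₊₍ₘ₋₁₎ₗ}; within a signal, recurrences of state
   **X**ᵢ are the candidate times j (inside a Theiler window w₁ < |i−j| < w₂)
   whose distance falls below a critical distance ε chosen so that a fixed
   proportion p_ref = 0.02 of comparisons count as recurrent. SL is the
   proportion of those recurrences at which the second signal recurs too —
   a number in [0, 1] that equals p_ref for independent signals and 1 for
   identical ones, and detects linear as well as nonlinear coupling.
2. **Graphs.** SL matrices are thresholded to a fixed average degree K
   (floor(N·K/2) strongest pairs become edges; N = 16 channels at K = 4.0
   gives exactly 32 edges). Clustering coefficient C (per-vertex fraction of
   interconnected neighbour pairs) and harmonic path length L are normalized
   by the mean over 1000 fixed-edge-count Erdős–Rényi graphs of identical
   size, so C_norm = L_norm = 1 means "as random".
3. **Topology.** Sorted degree distributions, rank-wise relative to the
   random ensemble, are matched against prototype families — ring-lattice
   small world, clustered (hub-core) small world, scale-free — to classify
   network quality beyond C and L.
4. **Statistics.** Group contrasts (adjacent and two-step pairs) with
   family-level bootstrap resampling and BCa confidence intervals at
   α = .01; sex-corrected partial correlations between network metrics and
   tissue-volume covariates, with log(SL) and −1/L transforms to tame skew;
   paired-bias correction for substituted leads; a |z| > 4 outlier policy.

Because no public recording set accompanies this kind of analysis, the
package ships a first-class synthetic-data module: band-limited Gaussian
sources, linear mixing with a planted coupling graph, twin-family cohort
structure with an intraclass correlation of ~0.5 on coupling strength, and
optional volume covariates — so every stage is testable end to end against
known ground truth.

## Worked example

The `analysis/` scripts run the whole chain on a simulated cohort (two
groups × 6 twin families × 2 members, planted clustered small-world coupling
at strength 0.25 vs 0.45, 14 channels, 36 s at 250 Hz):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_connectivity.py
python analysis/03_graph_metrics.py
python analysis/04_topology.py
python analysis/05_statistics.py
```

which prints (abridged):

```
SL computed for 24 recordings; mean SL 0.0285 (embedding m=7, lag=6, p_ref=0.02)

normalized metrics by K (means over recordings):
     c_norm  l_norm
3.5   2.163   1.003
4.0   2.075   0.989
4.5   1.882   1.000
5.0   1.625   1.010

cohort degree-ratio curve classified as: clustered_sw

group contrasts (adult - child), alpha = .01:
metric   comparison  difference  ci_low  ci_high  significant
    sl child->adult      0.2888  0.1845   0.3870         True

partial correlations with volumes (sex-corrected), 95% BCa CI:
    sl    wmv  0.583   0.143    0.795
```

Reading it: mean SL sits just above the independence baseline of 0.02 and
rises with planted coupling; C_norm ≫ 1 with L_norm ≈ 1 is the small-world
signature, with C_norm declining toward the random value as the threshold
admits more edges; the degree-ratio curve (low-degree periphery below 1,
hub core above 1) recovers the planted clustered topology; and the
family-bootstrap contrast detects the planted group difference in SL while
the sex-corrected partial correlation links SL to the white-matter covariate
the generator tied it to.

The same stages are available as CLI subcommands
(`slnet simulate | sl | graph | stats | report`) and as a YAML-configured
pipeline (`slnet report --config pipeline.yaml`). Recordings are read from
EDF or delimited text; all outputs are tab-delimited tables with a commented
provenance header (config hash, seeds, version).

## Layout

```
src/slnet/        library: synthetic, preprocess, sl, graphs, stats, io,
                  pipeline, cli
analysis/         numbered narrative drivers writing results/ tables
tests/            pytest suite incl. brute-force oracles
docs/methods.md   model, parameter and design documentation
```
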