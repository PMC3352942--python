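# Methods

## Synchronization likelihood

The state of a signal at time i is the m-dimensional delay vector
**X**ᵢ = {xᵢ, xᵢ₊ₗ, …, xᵢ₊₍ₘ₋₁₎ₗ} with lag l. For each reference time i,
candidate comparison times are j with w₁ < |i − j| < w₂ (two-sided, strict;
truncated at the epoch edges). The critical distance εᵢ is the k-th smallest
Euclidean candidate distance with k = ⌈p_ref · n_candidates⌉ (at least 1):
with a finite candidate set the achieved recurrence fraction cannot equal
p_ref exactly, so the smallest realizable fraction at or above p_ref is
used and reported; ties can push it higher, and an achieved fraction of 1.0
marks a degenerate (all-equidistant) reference. Recurrences of signal x at i
are the candidates within εᵢ(x); hits are those that are simultaneously
recurrences of y under εᵢ(y). SL(x→y) averages hits/recurrences over i, and
the reported pairwise value is the mean of both directions, making the
matrix symmetric by construction. Internally the recurrence threshold is
applied to squared distances (monotone-equivalent) and only the candidate
band of the distance matrix is ever computed, diagonal by diagonal; all-pairs matrices reuse the
per-channel recurrence structure and count hits as popcounts of bit-packed
rows. Both shortcuts are bit-exact re-expressions of the definitions — a
brute-force double-loop reference in the test suite pins the semantics.

Signals are z-scored per channel before embedding, so gain differences
between channels or cohorts cannot drive ε — SL is meant to measure state
recurrence, not amplitude. ε is chosen per reference time (adaptive), the
standard formulation for nonstationary signals; a pooled per-signal ε is
available behind a flag (`global_eps`) for sensitivity analysis, in which
case references left without recurrences drop out of the average.

### Frequency-adapted settings

`montez_params` derives the embedding from the band edges, following the
published recommendation for band-limited SL:

| parameter | formula | alpha (6–13 Hz, 250 Hz) |
|---|---|---|
| lag l | round(fs / (3·f_high)), ≥ 1 | 6 samples |
| dimension m | ⌈3·f_high / f_low⌉ | 7 |
| inner window w₁ | 2·l·(m−1) | 72 samples |
| outer window w₂ | w₁ + ⌊10 / p_ref⌋ | 572 samples |

The lag samples the fastest in-band cycle about three times; the vector
spans roughly one cycle of the slowest component; w₁ excludes
autocorrelation-driven recurrences (twice the vector span); w₂ bounds the
search so p_ref yields on the order of ten recurrences per side. All four
values are emitted in output metadata. These settings are deliberately
uncritical: SL changes smoothly under all of them.

Whether SL should be averaged over multiple 12-s epochs per recording is
left configurable; the default (`sl_recording`) averages epoch-level
matrices, which is also what the analysis drivers do on 36-s recordings.

## Graph metrics

Thresholding keeps the floor(N·K/2) strongest off-diagonal entries; ties are
broken by value, then lexicographic channel-pair order, so results are
deterministic. N is taken from the input matrix — both 14- and 16-channel
layouts are supported (16 channels at K = 4.0 gives the canonical 32 edges).

C is the mean over vertices of closed/(closed+open) neighbour triples;
vertices of degree < 2 contribute Cᵢ = 0 and stay in the mean (exclusion is
available behind the per-vertex output). L aggregates harmonically at the
pair level: 1/Lᵢ is the mean inverse distance from i (unreachable pairs
contribute zero), and L is the harmonic mean of the Lᵢ. Taking the stated
per-vertex +∞ convention literally at the vertex level would make any graph
with an unreachable pair infinite; harmonic aggregation at both levels —
which collapses algebraically to the pair-level form — keeps L finite
whenever any vertex reaches any other while still discounting disconnected
structure, and the unscaled 1/Σ(1/Lᵢ) variant is emitted alongside
(`l_paper`). Both metrics are computed on stacked boolean adjacency matrices
(triangle counting via matrix products; BFS via boolean powers), so a
1000-graph ensemble costs milliseconds; networkx implementations serve as
independent oracles in the tests.

Normalization divides each empirical score by the *ensemble mean* of C and L
over fixed-edge-count Erdős–Rényi graphs G(N, M) — same vertex count, same
edge count, honouring "same average degree" exactly. Disconnected ensemble
members are kept (harmonic L absorbs them), and dividing by the ensemble
mean rather than averaging per-graph ratios sidesteps zero-clustering
members. The normalization constant in L cancels in L_norm.

## Prototype networks and topology classification

Three ordered families at matched N and K, each trimmed/padded to exactly
floor(N·K/2) edges and finished with n_rewire random reconnections (an edge
endpoint moved to a random non-adjacent vertex; edge count preserved):

* **lattice_sw** — ring lattice, K nearest neighbours;
* **clustered_sw** — ⌈N/4⌉ fully interconnected hubs, periphery vertices
  attached to two hubs each (padding prefers high-degree pairs);
* **scale_free** — Barabási–Albert preferential attachment seed, padded with
  degree-weighted edges.

The hub-core and preferential-attachment constructions are this package's
interpretation of the pictured prototype families; they are not unique.

Sorted degree sequences are averaged rank-wise across graphs and divided
rank-wise by the same average over a matched G(N, M) ensemble. Lattice
curves slope downward (uniform degree against the random spread), clustered
curves are rotated-S-shaped (periphery below 1, hub core above), scale-free
curves rise smoothly into the hub tail.

Classification was originally specified as thresholds on the fitted slope
and an S-statistic, but calibration at N = 14, K = 4 showed clustered and
scale-free curves are not separable that way — both are hub-skewed and their
slope/S/tail statistics overlap heavily. The shipped classifier instead
matches the observed curve against cached reference mean curves of the three
families (plus the flat random baseline) by RMS distance
(`TopologyThresholds`; references are configurable and regenerated per curve
length). Self-consistency on prototypes: 100/100 for lattice and clustered
single graphs, ≥ 97/100 for scale-free on 5–10-graph collections, 98–99%
specificity on random inputs. The slope, S-statistic, flatness and
per-reference distances are still reported with every label.

## Synthetic data

Sources are FIR-band-passed Gaussian noise, unit variance — the simplest
model with the band-power structure the pipeline assumes (no 1/f background,
no transients, no artifacts; conclusions about artifact robustness cannot be
drawn from these tests). Channel i observes
sᵢ + Σⱼ c(i,j)·sⱼ + noise·nᵢ. Linear mixing makes SL respond monotonically
to the planted coupling, which is the property the recovery tests lean on.

Its known limitation: channels that share a coupled neighbour acquire
two-hop covariance ≈ c²·(shared neighbours) against a direct-edge covariance
≈ 2c, so beyond c ≈ 0.5 the effective correlation network departs from the
planted graph (at c = 0.9 topology recovery fails completely — the
*measured* network genuinely is not the planted one). Topology-recovery
studies therefore run at coupling 0.4, noise 0.1, 36-s recordings (three
averaged 12-s epochs — a scaled-down stand-in for multi-minute resting
recordings), where thresholded graphs reproduce ~93–100% of planted edges,
and classify the degree-ratio curve averaged over a small cohort sharing the
planted graph, mirroring how degree distributions are averaged over subjects
in practice. Roughly 1% of rewired clustered prototypes are intrinsically
borderline (their own degree curve sits closer to the scale-free reference);
that, not recovery error, bounds the attainable recovery rate.
Group-difference and monotonicity studies use the full 0–1 coupling range,
where monotonicity, not graph identity, is what matters.

Cohorts: groups of twin families (default two members), each family sharing
a Gaussian offset on coupling strength with equal family and subject
variances (intraclass correlation 0.5), so family-level resampling is
genuinely different from subject-level resampling. Repeated measures reuse
the subject's coupling. Optional gray/white-matter volumes are linear in the
subject's coupling plus a sex effect and noise, giving the
partial-correlation path a planted signal. `gen_metric_cohort` draws metric
values directly (family effect + noise, no signal stage) for power and
type-I studies where signal simulation would only add unrelated noise.

Defaults mirror the emulated acquisition: 250 Hz, 12-s epochs (3000
samples), 14 channels, alpha 6.0–13.0 Hz, beta 15.0–25.0 Hz, theta
3.0–5.6 Hz, broadband 1–37 Hz. The theta edges follow the figure-caption
definition of the emulated study rather than its in-text "~4 Hz" shorthand.

## Preprocessing

Band-pass filters are windowed-sinc FIR (Hamming), applied forward-backward
for zero phase; the −6 dB points sit at the nominal edges, and the
transition width is 0.25·f_low clamped to [0.5, 2] Hz (the filter order this
implies is recorded in output metadata). Band power uses Welch's method on
50%-overlapping 4096-sample stretches, integrated over the band, so a
100 µV calibration sine yields 5000 µV² — kept as a unit test of the power
path. Power is meant for full-length recordings; SL for 12-s epochs; both
lengths are configurable. Lead substitution only relabels and flags
channels; the systematic score bias it introduces is removed downstream by
`paired_bias` (additive mean correction on complete pairs).

## Statistics

The bootstrap resamples *families* with replacement up to the original
family count and retrieves every observation of each drawn family, keeping
within-family covariance and repeated measures intact on average. Group
contrasts are restricted to adjacent and two-step group pairs at a
conservative α = .01. Intervals are BCa: bias correction from the proportion
of replicates below the observed value, acceleration from a
leave-one-family-out jackknife (matching the resampling unit); with zero
bias and zero acceleration the interval reduces to the percentile interval.
Degenerate distributions yield zero-width intervals with a warning;
replicates that fail (e.g. empty a group) are flagged, never silently
dropped, and a run with > 1% flagged replicates errors out.

n_boot defaults to 2000: at α = .01 the interval endpoints are 0.5%
quantiles, and with only a few hundred replicates quantile granularity alone
inflates the empirical type-I rate (measured: ~2% at 500 replicates even for
plain percentile intervals). Independently of that, the cluster bootstrap is
mildly anti-conservative when few clusters exist — ~1.7% type-I at 15
families per group for percentile and BCa alike — and approaches the nominal
1% as families grow (1.35% measured at the study-like 50 families × 2
members per group, 2000 null runs), which is the scale the calibration test
uses. Group means under family resampling are computed via a
vectorized multinomial identity (drawing F families with replacement ≡
multinomial counts), which is what makes 1000-run calibration studies cheap;
the generic callable-statistic path follows the identical law and the tests
cross-check the two.

Partial correlations regress the covariates (sex as a binary indicator) out
of both variables by least squares and correlate the residuals; confidence
intervals come from the family bootstrap. SL and L are transformed by log
and −1/x respectively before correlation/contrast analyses (both strictly
increasing, so directions are preserved); C is used untransformed. The
outlier policy flags observations deviating > 4 SD on any metric and is
meant for reporting analyses both with and without the flagged cases.

## Problem sizes and numerical choices

Test and driver scales are chosen to keep full runs in the minutes range
while leaving Monte-Carlo error well below the asserted tolerances: 1000
random graphs per normalization ensemble, 200 input graphs for the
ensemble-consistency benchmark, 50 epochs for the independence baseline,
100 seeded runs for recovery rates, 1000 runs × 2000 replicates for the
type-I calibration. Stochastic assertions use three Monte-Carlo standard
errors. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical inputs and seeds reproduce outputs
bit for bit. Degenerate inputs have defined behaviour throughout: edgeless
graphs give L = +∞ (flagged), constant channels z-score to zero, tied
threshold values resolve lexicographically, and an all-equidistant
candidate set reports achieved fraction 1.0.
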