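# Methods

`readnet` implements a complete graph-theoretical analysis chain for
block-design task fMRI at ROI resolution, of the kind used to compare the
whole-brain functional networks of two reading-ability groups across a
phonological and a visual-orthographic task session. Because no subject
data ship with the package, a synthetic-cohort generator is a first-class
component: it produces data with exactly the statistical structure the
downstream stages assume, so every stage is testable end to end.

## The analysis model

**Network construction.** For each subject and session, edges are Pearson
correlations between the 90 AAL parcel time series over the analyzed run,
variance-stabilized by the Fisher transform z = atanh(r) (r is clipped to
|r| ≤ 1 − 10⁻¹² first so z stays finite for duplicated signals). The
matrix is binarized over a sparsity ladder s ∈ {0.05, 0.10, …, 0.50}:
at each s the strongest positive-z edges are kept until the graph holds
⌊s·N(N−1)/2⌋ edges (200 edges at 5%, 2002 at 50% for N = 90). Negative
correlations never become edges — their physiological interpretation is
ambiguous — so a matrix with too few positive entries yields a sparser
graph than requested, which is recorded (achieved sparsity) and warned
about, never silently ignored. Ties at the cutoff break lexicographically
by (row, column) index, which makes the ladder deterministic and its edge
sets exactly nested.

**Graph metrics.** On each binary undirected graph: clustering coefficient
Cp (mean over all N nodes of C_i = 2T_i/k_i(k_i−1), with C_i = 0 for
k_i < 2), characteristic path length Lp, global efficiency E_glob (mean of
1/d over pairs, 1/∞ = 0), local efficiency E_loc (mean over nodes of the
efficiency of each neighborhood subgraph), nodal degree, and unnormalized
Brandes betweenness (each unordered pair counted once). Sparse graphs can
be disconnected, and the package's declared convention is: Lp averages
over *reachable* pairs only, and every metric record carries
`reachable_fraction` so the convention is visible in the output; a graph
with no edges reports Lp as missing. The alternative (harmonic-mean /
efficiency-style Lp) is deliberately not silently substituted — E_glob is
reported alongside and is the principled summary when connectivity
fragments.

**Small-world normalization.** γ = Cp/⟨Cp_null⟩ and λ = Lp/⟨Lp_null⟩ are
computed against degree-preserving Maslov–Sneppen rewired graphs
(double-edge swaps a–b, c–d → a–d, c–b, rejecting self-loops and
multi-edges; the degree sequence is preserved exactly), with σ = γ/λ.
Defaults: 100 null graphs, 10·|E| swap attempts each, seeded through
numpy `SeedSequence` so every null ensemble is reproducible. Null Lp uses
the same reachable-pairs convention as the data. A complete graph admits
no legal swap and is returned unchanged with a warning, which correctly
yields γ = λ = σ = 1.

**Group inference.** All group comparisons use the pooled-variance
two-sample Student t (df = n₁ + n₂ − 2; with 16 subjects per group,
df = 30), sign convention mean(first group) − mean(second group) with the
group order recorded in every table header. The same routine accepts raw
samples or printed summary statistics (mean, SD, n), and the two forms
agree to 10⁻¹⁰ by construction. Bonferroni families: for global metrics,
the number of sparsity levels actually tested per metric and session
(levels dropped because a subject's Lp is missing shrink the family, with
a warning); for nodal tests, the 90 nodes per measure. Both uncorrected
and corrected significance flags are always emitted, because nodal effects
in this literature are typically reported uncorrected. Nodal comparisons
run at a single sparsity (default 5%); since isolation is most likely
there, the pipeline also writes per-subject isolated-node counts next to
the nodal table rather than guessing whether "most nodes connected" holds.

**ROI-level GLM.** The activation stage builds a design matrix of
canonical-HRF-convolved task and instruction boxcars (double-gamma HRF:
response delay 6 s, undershoot delay 16 s, unit dispersions,
response:undershoot ratio 6, 32-s kernel, peak-normalized; boxcars built
at 16× oversampling then decimated at volume onsets), a discrete-cosine
high-pass set with K = ⌊2D/128 s⌋ columns (K = 2 for the 158-s analyzed
run), optional nuisance columns, and an intercept. Estimation is ordinary
least squares per ROI without autocorrelation modeling — at 79 volumes an
AR fit is poorly conditioned, and the network stage never consumes GLM
variances. The instruction period gets its own regressor so the 2-s cue
does not bias the task boxcar. A centered mean-across-ROIs global-signal
regressor is ON for the activation analysis and OFF for network
construction, each logged. Zero-residual-variance ROIs (exact
interpolation) are flagged rather than propagated as spurious t-values.

## The synthetic cohort

The generator emulates a two-group (16 + 16), two-session block-design
study: runs of four experimental blocks (2-s instruction + eight 3-s
trials = 26 s) interleaved with 12-s fixation, fixation opening and
closing the run (F E F E F E F E F, 164 s, 82 volumes at TR = 2 s). The
first 3 dummy volumes are generated and then removed by the generator
itself, so downstream stages never see them. Fixation flanking every
block is a design choice the run description leaves open; it is standard
practice and places the dummy scans inside the first fixation.

Each subject-session is: unit-amplitude HRF-convolved task signal on six
"active" ROIs (the first ROI of each module — activation must exist for
the GLM stage to detect, but its identity is immaterial to the network
claims) + multivariate normal noise with a module-structured correlation
matrix + white noise. Defaults, chosen once as a realistic regime for
ROI-averaged BOLD: 6 contiguous modules of 15 ROIs; within-module
r = 0.30; between-module r = 0.10; white-noise SD 0.5 relative to the
unit-variance correlated process (ROI averaging suppresses thermal noise,
so the physiological component dominates). With these values the
*observed* correlations are attenuated by 1/(1 + 0.5²) = 0.8, i.e.
within-module r ≈ 0.24 empirically. The group effect is a
+0.15 within-module correlation offset applied to the poor group's
orthographic session only — large enough that a 16-per-group cohort
detects the clustering difference reliably (the stated power property),
while leaving the phonological session exactly null. Perturbed
correlation matrices that lose positive semidefiniteness are repaired by
eigenvalue clipping at 10⁻⁸ and rescaling to unit diagonal, with a
warning.

Behavioral scores are per-group normal draws; defaults are the screening
profile the pipeline is designed around (reading 115.75 ± 13.57 vs
35.63 ± 13.59 — an enormous separation; Raven 68.44 ± 15.78 vs 75 ± 16.73
— matched groups).

Seeding: subject-session seeds derive from
`SeedSequence([cohort_seed, group_index, session_index, subject_index])`,
so the whole cohort is a pure function of one integer while subjects stay
statistically independent.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no between-subject variability in the underlying
correlation structure (all subjects of a group share one target matrix);
no head motion, physiological confounds, scanner drift beyond what the
DCT columns are tested against, or spatially correlated noise; no
hemodynamic variability across regions or subjects; stationary
correlations within a run (no task-block modulation of connectivity). The
calibration results (type-I error, power) therefore characterize the
analysis chain under its own assumptions, not the field reliability of
small-world comparisons.

## Numerical and design choices

- Edge budgets use ⌊s·N(N−1)/2 + 10⁻⁹⌋; the epsilon guards against
  floating-point representations of exact multiples landing a hair below
  the integer.
- Constant ROI series (possible in degenerate synthetic inputs) get zero
  correlation with a warning instead of aborting a cohort run.
- Shortest paths use an all-sources level-synchronous BFS via boolean
  matrix products for graphs up to 128 nodes (faster than sparse-graph
  machinery at this size and exercised against a Floyd–Warshall oracle),
  scipy's Dijkstra above that.
- Correlations are computed over the full analyzed run (task + fixation);
  a `task_blocks_only` flag restricts them to task-block volumes. Whether
  to residualize motion first is exposed the same way (nuisance columns),
  default off.
- The calibration experiments (`readnet.experiments`) run the full chain
  at 16 subjects per group, 90 ROIs, 79 volumes: the null (type-I)
  experiment uses 200 cohorts at a single sparsity (0.10, where subject
  graphs stay mostly connected) and pools the t-values of the four
  non-normalized global metrics for the distributional check — a single
  metric's 200 values cannot distinguish Student(30) at the precision the
  check demands; the detection experiment uses 100 replicates over the
  full 10-level ladder and counts a session as "flagged" when any Cp row
  is Bonferroni-significant (family = 10).

## Known limitations

- σ has no external numerical anchor here; it is validated only through
  its defining identity σ = γ/λ and the canonical-graph limits.
- The high-pass DCT set transitions smoothly around the 128-s cutoff; the
  stop/pass-band bounds quoted in the tests hold for probes clearly inside
  each band, not arbitrarily close to the edge.
- Betweenness delegates to networkx's Brandes implementation (validated
  against exhaustive path enumeration); it is the slowest nodal metric on
  dense ladders.
- The NIfTI import utility (`readnet.io.extract_roi_timeseries`) is
  exercised only on synthetic volumes; real-scanner orientation and
  resampling quirks are out of scope.
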