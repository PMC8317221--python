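# Methods

## Model and assumptions

Each EEG epoch is modelled as a stationary, zero-mean, linear vector
autoregression of order p over N channels,

    x(n) = Σ_{r=1..p} A_r x(n−r) + w(n),

with white Gaussian innovations w of covariance Σ_w. All connectivity
quantities follow deterministically from (A_1..A_p, Σ_w). One
time-invariant model is fitted per epoch; slow nonstationarity across a
recording is therefore represented as variation *between* epochs, not
within one. The frequency-domain coefficient matrix is

    Ā(f) = I − Σ_r A_r e^{−i 2π r f / fs},     H(f) = Ā(f)^{−1}.

Partial directed coherence is the column-normalized magnitude
π_ij(f) = |Ā_ij(f)| / √(a_j^H a_j) (a_j = column j of Ā); the directed
transfer function is the row-normalized magnitude
v_ij(f) = |H_ij(f)| / √(h_i h_i^H) (h_i = row i of H). Two printed
variants of these formulas circulate — one omits the modulus in the
numerator, another mixes rows i and j in the DTF denominator — but only
the forms above are real-valued, lie in [0, 1], and satisfy the unit
sum-of-squares identities (PDC over columns, DTF over rows) that the
package asserts to 1e−9 at every frequency bin; they are the forms used
throughout the PDC/DTF literature and are the ones implemented.

### Estimation

Coefficients are estimated by ordinary least squares on the lagged design
matrix after per-channel demeaning (the approach of stepwise
least-squares ARFIT-style fitting), with residual covariance divided by
n_eff − N·p. A multivariate Yule–Walker solver is available via
`fit_mvar(..., method="yw")`; least squares is the default for its lower
small-sample bias. Model order is chosen by minimizing Schwarz's BIC
(AIC optional) over a candidate range, default 1–20; all candidates are
fitted on a common effective sample (conditioning on the first p_max
samples) so criterion values are comparable, and ties break to the
smallest order. Degenerate range p_min = p_max returns that order
without fitting.

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| low-pass cutoff | 50 | Hz | removes line noise and content above the γ band; 4th-order Butterworth applied forward–backward (zero phase, so no phase distortion biases directed estimates) |
| target rate | 128 | Hz | Nyquist 64 Hz comfortably covers the 0–50 Hz analysis range |
| channels | FP1, FP2, F7, F8, F3, F4, O1, O2 | — | prefrontal/frontal/occipital electrodes covering the visual and executive functions engaged by visuomotor control tasks |
| epoch length | 1,280 | samples | 10 s at 128 Hz; non-overlapping, contiguous from sample 0, remainder dropped |
| frequency grid | 0–64 in 0.5 | Hz | 129 bins; 0.5 Hz resolves the 0.5–4 Hz δ band |
| bands | δ 0.5–4, θ 4–8, α 8–14, β 15–30, γ 30.5–50, All 0–50 | Hz | closed intervals at both edges; a bin on a shared edge (4.0, 8.0 Hz) counts in both adjacent bands; the 14–15 and 30–30.5 Hz gaps belong to no named band |
| edge threshold τ | 0.3 | — | band-averaged PDC/DTF below 0.3 is treated as spurious; edges kept iff strictly greater than τ; diagonal always excluded |
| CV folds | 10 | — | stratified at the epoch level, shuffled with a fixed seed |

Epoch length is configurable because descriptions of this design are
internally inconsistent about epoch duration and count; 1,280 samples is
the explicit sample count honored by default.

## Graph metrics

Graphs keep their weights (no binarization); the graph edge j → i gets
the adjacency value (i, j) so that node strength is outgoing influence.

* **D** — mean over nodes of out-strength k_i = Σ_j w_ij.
* **C** — mean over nodes of C_i = 2 t_i / (κ_i (κ_i − 1)), where
  t_i = ½ Σ_{j≠h} (w_ij w_ih w_jh)^{1/3} and κ_i counts distinct
  neighbors of i over retained edges in either direction; C_i = 0 when
  κ_i < 2. The binary neighbor count is used in the denominator because
  a weighted strength there is not computable in general (a triangle of
  0.5-weight edges would divide by zero); the weighted-numerator /
  binary-denominator form is the standard weighted clustering
  coefficient. Computed as ½·diag(W^∘1/3 · W^∘1/3 · (W^∘1/3)ᵀ), verified
  against brute-force triple enumeration to 1e−12.
* **L** — mean directed shortest-path distance with edge distance
  1/w (Dijkstra on the sparse distance graph, verified against
  brute-force simple-path enumeration to 1e−12), averaged over reachable
  ordered pairs; the unreachable-pair count is reported alongside. For a
  graph with *no* reachable pair, L is NaN. A harmonic-mean
  ("efficiency") variant is available via
  `char_path_length(..., "efficiency")`.

### Disconnected networks

Thresholding at τ = 0.3 routinely empties sparse networks, which makes L
undefined for exactly the epochs whose networks are weakest — the
missingness is itself the group signal, so dropping those rows would
censor one tail of the distribution (and, for a weakly coupled group,
can delete the group outright). The analysis stage therefore imputes
undefined L with the *disconnection ceiling* (N − 1)/τ by default: every
retained edge has distance < 1/τ and a shortest path uses at most N − 1
edges, so any finite L is strictly below this value, and the imputed
value ranks disconnected networks as "worse than any connected one"
without distorting the order statistics. `policy="drop"` restores
row-wise deletion with a logged count.

## Synthetic cohort

The generator emulates a two-group training study: 10 subjects per
group, 5-minute recordings at 1,000 Hz on the eight electrodes above.
Each subject is a fresh stable VAR(3): lag-1 self-regression drawn
uniformly from (0.2, 0.4) and decaying by 0.3 per extra lag (genuine
order-3 memory), directed coupling placed at lag 1 on random ordered
pairs — Hp: density 0.40, |a| ∈ (0.25, 0.45); Lp: density 0.15,
|a| ∈ (0.10, 0.25) — with random signs (influence magnitudes are
sign-blind, and mixed signs keep dense regimes stable). Innovations are
Gaussian with identity covariance, the minimal white-noise assumption.
Coupling strictly stronger and denser in Hp encodes the hypothesis that
training improves cortical connectivity; the effect size is a free,
configurable choice, not an empirical estimate. Coupling is confined to
lag 1 because replicating dense strong coupling across all lags leaves
the stationarity region for essentially every draw.

Models are redrawn (up to 100 retries) until the companion spectral
radius is below 0.98 (margin 0.02), guaranteeing usable spectra;
simulation discards a 1,000-sample burn-in. Per-subject seeds come from
a splitmix64 mix of (master seed, subject index), giving reproducible,
decorrelated streams.

What the generator deliberately does **not** emulate: volume conduction
and reference effects (which induce spurious zero-lag correlation in
real EEG), ocular/muscle artifacts, 1/f spectral shape, nonstationary or
state-dependent coupling, and inter-subject variability structure beyond
independent model draws. Passing tests therefore demonstrate that the
pipeline recovers directed linear coupling under its own model class —
not that real recordings satisfy that model.

## Classification

Presets mirror the common "classifier battery" toolboxes: k-NN (fine = 1
neighbor, medium = 10, coarse = 100, cosine/cubic metrics, distance
weighting), SVM (linear, quadratic, cubic, RBF at three kernel scales),
decision trees (max 100/20/4 leaves), logistic regression, linear and
quadratic discriminants, AdaBoost and random-forest tree ensembles —
hyperparameters are explicit in `classifier_registry`. Folds are
stratified on the label and deterministic given a seed; standardization
is fitted on training folds only (tested by refitting a fold manually
with an injected outlier); held-out predictions and scores are pooled
across folds before computing accuracy, precision, recall, F1 and AUC
with Hp as the positive class. k-NN neighbor counts are clamped to the
training-fold size so fixed-k presets remain runnable on small tables,
and the fold count is clamped to the minority-class size.

Epoch-level folds replicate the emulated study design but let epochs of
one subject span folds, so a classifier can recognize the *subject*
rather than the *group*; accuracies under this scheme are optimistic.
`cv="subject"` provides grouped folds for honest generalization
estimates. Features are standardized within folds by default; t-tests
use pooled-variance Student by default (Welch via `equal_var=False`);
no multiple-testing correction is applied by default
(Benjamini–Hochberg available).

## Problem sizes and determinism

The validation suite runs the full study design (20 subjects, 5 min at
1 kHz → 600 epochs) once, plus 100-model normalization sweeps,
100-epoch direction-recovery scoring, and 100-seed order-selection
replications; every stochastic quantity is a pure function of an integer
seed. The reproduction script (`scripts/acceptance.py`) recomputes all
of these from a single `--seed`.

## Known limitations

* PDC/DTF are linear measures; nonlinear coupling is outside the model
  class, as are time-varying/adaptive MVAR schemes.
* No surrogate-data significance testing of connectivity values; the
  fixed τ = 0.3 plays that role crudely.
* The EDF writer emits standard 16-bit EDF with one-second records and
  therefore requires an integer sampling rate and truncates a trailing
  partial second; amplitude resolution is the per-channel range / 2¹⁶.
* Group statistics at the epoch level inherit the subject-leakage caveat
  above; per-subject aggregation is provided but reduces power.
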