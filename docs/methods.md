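# Methods

## Model and assumptions

The decoder assumes two-class motor-imagery EEG in which class information
is carried by *band power* differences that are localized in frequency,
time within the trial, and space. Each stage operationalizes one of those
axes:

- **Filter bank × time windows.** The trial is decomposed into a grid of
  cells (bandpass filter × time window). Cells are overlapping on both
  axes; the grid is fully determined by four numbers per axis
  (lo, hi, width/length, step) and is only valid when the range minus the
  width is an integer number of steps, so the last cell ends exactly at
  the range edge. Cell order is row-major over (band, window).
- **CSP per cell.** Per-trial covariances are trace-normalized
  (`C = XXᵀ/tr XXᵀ`), removing trial-to-trial broadband power so that CSP
  contrasts *relative* spatial variance structure. Means are not removed:
  band-passed EEG is zero-mean by construction. The projection is obtained
  by whitening the composite covariance and eigendecomposing the whitened
  first-class covariance; eigenvalue complementarity (λ₁ + λ₂ = 1) and the
  whitening identity are enforced as tested invariants. CSP assumes
  stationary class-conditional covariances within a cell — which is exactly
  why small time windows help when the effect is transient.
- **Log-variance features.** `f_p = log(var Z_p / Σ_q var Z_q)` over the
  2m retained components, with variance the *population mean square* (no
  mean subtraction) and the normalizing sum running over the retained
  components only. Consequences, both tested: features are ≤ 0 and their
  exponentials sum to 1; features are invariant to global trial scaling.
- **Backward selection.** Wrapper selection with the classifier in the
  loop. The discarded cell is the one whose *removal leaves the highest
  accuracy* (equivalently, the least useful cell). Greedy elimination is
  not globally optimal in general; for additive evaluators it is, which is
  what the enumeration oracle in the tests exploits.
- **Exact-design RBF network.** One Gaussian unit per training sample;
  weights and bias solved jointly by least squares on the interpolation
  system in ±1 coding. For distinct training points and a well-conditioned
  design this reproduces training labels exactly.

## Parameters

| parameter | default | meaning |
|---|---|---|
| band grid | 4–40 Hz, 4 Hz wide, 2 Hz step | 17 overlapping bands |
| window grid | 500–4500 ms, 2 s long, 500 ms step | 5 overlapping windows |
| broadband | 4–40 Hz, order 5 | preprocessing bandpass (applied before the per-band filters, as a separate stage) |
| `m` | 2 | CSP components kept per tail; 2m features per cell |
| `spread` | 16 | Gaussian width of the RBF units on z-scored features |
| `sigma_mode` | `literal` | σ = spread read off the kernel formula; `matlab` reproduces newrbe's half-response-at-spread convention (σ = spread / (√(2 ln 2))) |
| `folds` / `inner_folds` | 5 / 5 | outer evaluation folds / inner selection folds |
| `protocol` | `nested` | leak-free; `paper_flat` scores selection on the reported folds |
| `seed` | required | drives fold shuffling; echoed in all outputs |

When 2m exceeds the channel count (3-channel montages with m ≥ 2) the
"first and last m rows" are kept literally, duplicating middle rows;
distinct results for m = 2 and m = 3 on 3 channels are only possible if
duplicates are kept, so that is the default (`selected_rows` makes the
duplication explicit).

Eigenvalue ties are broken by ascending original index; each spatial
filter is sign-normalized so its largest-magnitude coefficient is
positive (the features are sign-invariant; this only stabilizes output).
A composite covariance with condition number above 1e10 receives a ridge
of 1e-8 · tr(C)/N · I with a warning.

## Synthetic generator

`synthgen` draws per-channel 1/f-amplitude background noise plus white
sensor noise, and adds planted sources: band-limited Gaussian noise
(fifth-order Butterworth, forward-backward) gated to a time window with
50 ms raised-cosine ramps, mixed into channels by a fixed spatial pattern,
with class-dependent amplitude realizing a stated log band-power ratio.
Defaults state a 22-channel, 250 Hz, 72-trials-per-class, 7 s-epoch world;
unstated levels were fixed once at background RMS 1.0, sensor noise sd
0.5, and source RMS 1.0 (class 1), chosen so a 2.0 log-unit effect is
strong but not trivially separable per trial.

The generator emulates band-power modulation only. It does **not** model
volume-conducted source geometry, non-stationary rhythms, artifacts
(ocular/muscular), or between-session drift. A green end-to-end test
therefore establishes that the pipeline recovers planted band/window/space
effects from realistic noise at realistic trial counts — not that it
attains any particular accuracy on real recordings.

## Numerical choices

- **Zero-phase filtering.** Offline epoched analysis permits
  forward-backward application (no group delay); the stated design order
  refers to the prototype before the double pass. Edge transients are
  absorbed by odd-reflection padding spanning ~10 cycles of the low band
  edge (capped at the epoch length); with this padding, filtering commutes
  with time reversal to ~1e-6, which is the sense in which the
  implementation is zero-phase on finite epochs.
- **Filter-then-crop.** Per-band filters are applied to the full
  preprocessed epoch *before* window cropping, so all windows of a band
  share one filter transient at the epoch edge rather than each window
  acquiring its own; `filter_order_mode="window_first"` exposes the other
  order for comparison.
- **Half-open windows.** Sample windows are 0-based, half-open
  [start, end): adjacent windows partition samples without double
  counting; cropping is idempotent.
- **Least-squares solve.** The RBF interpolation system is solved by SVD
  least squares, never an explicit inverse; duplicate training rows
  degrade gracefully to the minimum-norm solution with a warning.
- **Tie rules.** SBS ties are resolved by discarding the smallest cell id;
  a classifier score of exactly 0 maps to the positive class (first class
  in sort order).

## Known limitations

- **Large spread is numerically singular.** With spread ≫ the z-scored
  feature scatter, the RBF design matrix approaches the all-ones matrix
  (condition ~1e17 at spread 16 on low-dimensional data), and float64
  least squares can no longer interpolate — the exact-design guarantee is
  conditional on a numerically nonsingular design. The property tests
  therefore validate exact interpolation at kernel widths comparable to
  the data scatter; the pipeline keeps the conventional default of 16,
  whose *classification* behavior does not depend on exact interpolation.
- **Exhaustive SBS cost is quadratic in cells.** A full run from F cells
  costs F(F+1)/2 evaluator calls, each an inner-CV classifier fit; the
  85-cell grid with 5 inner folds is minutes-to-hours depending on trial
  count. Tests and examples use reduced grids; the full grid is available
  unchanged.
- **Two classes only.** The CSP construction, the ±1 coding and the
  metrics all assume a binary problem; multi-class extensions are out of
  scope.
- **`paper_flat` is optimistically biased** by construction (selection
  sees the evaluation folds); it exists to reproduce the common flat
  protocol, not as a recommendation. The nested default reports honest
  held-out accuracy, which will typically be lower.
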