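# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `brainfingerprint`, and what the synthetic experiments
do and do not demonstrate.

## Data model and event conventions

A *recording* is one run: a 64 × T matrix of voltages (µV) at 160
samples/s plus an event table of (code, latency, duration) rows, with codes
1 (rest), 2 (left/both-fists onset) and 3 (right/both-feet onset). All
public latencies are 1-based inclusive: an event starting at sample s with
duration d occupies samples s..s+d−1, and the *intermission* between
consecutive events is `next.latency − previous.end`. Under this convention
the reference run's first rest event (latency 1, duration 672) ends at
sample 672 and the following task event at 1313 sits 641 samples away.
Note that the reference event table is not perfectly uniform: twelve of its
fourteen gaps are 641 samples but two (after the 7th and 13th events) are
801; the synthetic protocol reproduces the printed rows verbatim rather
than a uniform template.

Tasks are indexed 1..15: the 14 experimental runs plus a pooled rest
signal (all code-1 spans concatenated) as task 15. Within a run, repeated
events of the same code are concatenated in time order before analysis, so
each (participant, task, event) triple yields one segment (about 5 376
samples of rest, 1 968–2 624 samples of task events).

Besides EDF+ (read through `mne` when installed), a neutral text container
is supported — a tab-delimited signal matrix, a `code latency duration`
TSV and a YAML sidecar — so synthetic cohorts and fixtures never require a
binary writer.

## Preprocessing

The chain is fixed: filter the whole run → artifact hook → cut segments →
first difference.

* **Filtering.** Zero-phase (forward–backward) Hamming windowed-sinc FIR,
  band-pass 1–70 Hz plus a 2 Hz-wide FIR band-stop at 60 Hz. The "auto"
  order follows the common EEG rule — 3.3 divided by the normalized
  transition width, transition = min(max(0.25·low, 2), low) Hz — which
  gives order 528 for the 1 Hz edge at 160 samples/s. Reflect padding of
  one filter length absorbs edge transients; attenuation of the 60 Hz tone
  measured mid-segment is below 10⁻⁵.
* **Artifact removal** is a delegated hook: any callable mapping the
  channels × time array to an equal-shaped array (e.g. an ICA-based
  cleaner). The default is the identity; automatic artifact classification
  is deliberately out of scope, and synthetic data is generated
  artifact-free so the identity hook is exact there.
* **First differencing** (out[n] = in[n+1] − in[n]) whitens slow trends so
  the tercile symbolization reflects sample-to-sample dynamics.

## Symbolic transfer entropy

Per segment, the differenced values of *all 64 channels pooled* are sorted
ascending and split at the ranks ⌊L/3⌋ and ⌊2L/3⌋; each channel's values
map to symbols 1/2/3 by band, values exactly at a threshold joining the
upper band. Pooling (rather than per-channel terciles) preserves
between-channel amplitude relations in the symbol alphabet.

Directed coupling is the plug-in transfer entropy with Markov orders
k = l = 1, computed from empirical joint frequencies of
(x_{n+1}, x_n, y_n) in bits, with 0·log(·) = 0. The estimator is a KL
divergence of empirical distributions and therefore non-negative up to
round-off; negatives below 10⁻⁹ in magnitude are clamped to zero and
anything larger is treated as a bug.

**Symbols vs. embedded words.** A phase-space embedding into overlapping
m-symbol words (delay τ) is provided (`m`, `tau` in the API and config)
and turns each channel into a 3^m-state process. The package default is
m = 1 — TE directly on the tercile symbols — because at the event-segment
lengths of the reference protocol (≈2 000–5 400 differenced samples) the
m = 3 word process implies a 19 683-cell joint histogram whose plug-in
estimate is dominated by a small-sample bias floor. That floor is shared
by all channels and scales with segment length, so it swamps the
participant-specific coupling structure: measured on independent white
noise at n = 2 620, the off-diagonal mean is ≈0.47 bits for m = 3 words
versus ≈0.003 bits for symbols, and synthetic-cohort identification
collapses to near chance under m = 3 while being strong under m = 1. The
27-cell symbol-level joint is well sampled at every event length the
protocol produces.

The full 64×64 matrix is computed with one flat bin-count per target
channel over all sources, touching only occupied histogram cells; a
2 600-sample segment takes ≈0.5 s on one core.

## Directed minimum spanning tree

The STE matrix is read as a complete weighted digraph (diagonal absent).
Two weight orientations are kept one flag apart: `literal` minimizes the
summed TE of the spanning arborescence, `negate` (weights −TE) maximizes
total information flow; which one a fingerprinting study *should* use is a
modelling choice the data cannot settle, so the mode is recorded in every
artifact. The solver is full Chu–Liu/Edmonds: pick each node's cheapest
entering edge, contract any cycle with the reduced cost w − in[u], recurse,
and expand each cycle by dropping the one cycle edge superseded by the
chosen entering edge. Ties between equally cheap entering edges break
toward the lowest source index, making results deterministic given a root.
Root policy is seeded-random by default, with electrode-label override and
a max-out-strength heuristic. The solver is verified against exhaustive
enumeration of all spanning arborescences on hundreds of random digraphs
with n ≤ 5 and against networkx's Edmonds implementation.

## Eigen-spectrum fingerprints

The 64 complex eigenvalues of each STE matrix are sorted canonically
(descending modulus, then descending real part, then descending imaginary
part) so the derived 128-vector (real parts then imaginary parts) is
reproducible across eigensolver orderings. For real input the spectrum is
checked to be conjugate-closed, and the eigenvalue sum is checked against
the (zero) trace.

Real and imaginary parts are z-scored independently *per matrix* (sample
SD, ddof 1): per-matrix scoping keeps fingerprints self-contained rather
than leaking cohort statistics into each one. A component with zero
variance (e.g. an exactly real spectrum) is left centred at 0 with a
warning; an error mode is available.

Coarse-graining bins eigenvalues into square cells of side θ with the
lower edge of the first cell closed and each subsequent cell half-open
upward; counts are conserved exactly. Grids built on explicit shared
ranges reject outside points unless clipping into boundary cells is
requested (clips are counted, never silent).

**Grid resolution.** On the z-scored scale the package default is
θ = 0.5 — one cell per half standard deviation, ≈15×15 cells over a
typical cohort range. θ = 1 (one cell per SD) leaves only ≈6–9 cells per
axis and measurably discards fingerprint information (synthetic recovery
0.73–0.90 across seeds, versus 0.82–0.93 at θ = 0.5). θ = 1 remains the
natural setting for grids on *raw* (un-normalized) eigenvalues, which are
also supported (`--raw`); whether a fingerprint study should grid raw or
normalized spectra is genuinely open, and both paths are first-class.

## SDSS identification

Reference fingerprints are built from task 1 only: per participant the
grids of events 1–3 are summed cell-wise (192 counts) on ranges pooled
over the whole reference cohort, so all grids are cell-aligned. The
"overlapping part" between a test grid and a reference is formalized as
histogram intersection — Σ over cells of min(test, reference) — the
standard overlap for count histograms; it is symmetric, bounded by the
smaller total mass, and equals the total mass only for identical grids.
Note intersection is mass-sensitive: scores are comparable because every
reference carries the same 192-count mass and every test the same 64.
Ties are broken toward the lowest participant id and flagged.

The cross test partitions the cohort into three equal groups per draw
(33/33/33 at the reference cohort size of 99; cohort/3 in general, and the
accuracy denominator generalizes from 99 to the cohort size), tests each
group against its own held-out task, and averages accuracy over draws
(default 1 000). Identification is deterministic per (participant, task),
so winners are precomputed and only the partition is re-drawn.

## Statistics

* Matrix distances are plain Frobenius norms over all 64×64 entries,
  with no per-pair normalization constant (any fixed constant cancels in
  the between/within comparison and in the z-test). The
  between-participant group compares unordered participant pairs at
  matched (task, event) conditions; the within-participant group compares
  unordered condition pairs inside each participant. Group sizes follow
  the unordered-pair convention n(n−1)/2, giving 4 851 and 990 at the
  reference cohort sizes (99 participants; 15 tasks × 3 events).
* The two-sample z-test uses the unpooled standard error
  √(s₁²/n₁ + s₂²/n₂) with normal critical values (2.326 one-tailed /
  2.576 two-tailed at α = 0.01).
* The "repeated measures" ANOVA is implemented as two-way fixed-effects
  ANOVA with replication — the model whose degrees of freedom match
  the reference 99-participant layout exactly (columns 98, rows 44, interaction 4 312, error
  565 785, total 570 239 for 99 participants × 45 conditions × 128
  spectrum entries). SS additivity holds to machine precision and the
  implementation is cross-checked against statsmodels' `anova_lm`.

## Synthetic cohort generator

Each participant's fingerprint is a sparse random coupling matrix A:
off-diagonal entries present with density 0.03, magnitudes U(0.5, 1.5)
with random sign, rescaled to spectral radius 0.95; A[i, j] couples
channel i onto channel j and dynamics follow x_{t+1} = Aᵀx_t + ηε_t with
unit-variance Gaussian noise (η = 1; the symbolization is scale-free, so
only the coupling-to-noise structure matters). Sparse near-critical
coupling was chosen so that directed influences are strong enough for
symbol-level TE to detect within single ≈2 000-sample task events; denser
or weaker coupling (e.g. 5% density at radius 0.85) produces fingerprints
that the coarse-grained spectrum overlap can no longer separate reliably
at these segment lengths. A `separability` floor enforces a minimum
pairwise Frobenius distance between cohort couplings (redrawn up to a
bounded number of times).

During task events a gain of 1.5 multiplies an event-specific half of A's
support (halves fixed per participant), so events 2 and 3 are
distinguishable while the fingerprint support never changes — the
constancy property the pipeline is meant to recover. If modulation pushes
the spectral radius above 0.98 the modulated matrix is rescaled to 0.95.
Runs follow the printed reference protocol verbatim; a 200-step burn-in
precedes each run and divergence aborts with an error.

What the generator does *not* emulate: 1/f spectra, volume conduction,
nonstationarity, artifacts, or any biophysics. Passing the recovery
experiments therefore shows the pipeline's statistical machinery is sound
and the method can recover known directed-coupling fingerprints at the
reference protocol's data lengths — not that real EEG fingerprints are
this separable.

## Reference experiment sizes and observed behaviour

The documented desk-scale recovery experiment uses 10 participants ×
3 runs (run 1 → references; runs 2–3 → 60 held-out test items, all three
events) at the defaults above with seed 42; it completes in about a minute
on one core. Between-participant mean STE distance exceeds the
within-participant mean by ≈3.5× and held-out identification accuracy is
0.88 at the documented seed (0.80–0.88 across other seeds tried during
development; single-item identification is noisy at this cohort size).
The cross test uses a 12-participant cohort (three groups of 4, 1 000
draws) and lands near 0.87. These numbers are recomputed, not stored, by
`scripts/acceptance.py` and the acceptance tests.

## Known limitations

* Transfer entropy is estimated at lag 1 on symbols; couplings acting over
  longer lags, or smeared by the zero-phase filter, are only partially
  captured.
* Histogram intersection on coarse grids discards within-cell geometry;
  identification accuracy is sensitive to θ, and the package makes no
  attempt to select θ automatically.
* The EDF+ path depends on the optional `mne` extra and assumes the
  channel count and annotation alphabet of the reference dataset (a
  relaxed flag admits non-standard files).
* No significance testing of individual TE links, no undirected MST, no
  alternative classifiers (k-NN, SVM) — all deliberately out of scope.
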