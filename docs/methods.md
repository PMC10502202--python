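# Methods

`hbsl` simulates auditory statistical learning as Bayesian sequence
learning: a listener builds an internal Markov model of a melody, chunked
units emerge from jointly probable and reliable transitions, new melodies
are generated from the learned model, and the rhythm of the generated music
is characterized by its amplitude-modulation (AM) spectrum. This note
records the model, its parameters, the numerical choices, and the known
limitations — including two places where the published orderings the
simulation is patterned on cannot all be reproduced simultaneously, and
what the package does about it.

## 1. The learner

**Model.** Token streams are drawn from a melody's notes (pitch, or
(pitch, quantized duration) pairs) over an alphabet of size K. For each
context (the preceding `order` tokens, default order 1) the learner keeps a
Dirichlet distribution over the K continuations. The prior is symmetric,
Dirichlet(a, ..., a); observing symbol i after a context adds 1 to that
component (conjugate update). Derived quantities, all in closed form:

- transition probability: posterior mean `alpha_i / alpha_0`
  (a `count_ratio` estimator — raw observed fraction, 1/K when the context
  is unseen — is available for the maximum-likelihood reading);
- reliability: inverse of the marginal Beta variance
  `alpha_i (alpha_0 - alpha_i) / (alpha_0^2 (alpha_0 + 1))`. Reliability
  grows with evidence: 90-of-100 observations beat 9-of-10 at the same
  0.9 ratio;
- Bayesian surprise of an event: KL divergence (nats) between the
  predictive row of its context before and after the update;
- conditional entropy (bits): `-sum_c w(c) sum_i p(i|c) log2 p(i|c)` under
  caller-supplied context weights (usually empirical frequencies).

**Sensitivity regimes.** Sensory sensitivity is modeled by scaling the
Dirichlet concentrations by a factor f: hypo-sensitive f = 0.25, normal
f = 1, hyper-sensitive f = 4. Two readings are implemented:

- `sensitivity_mode="prior"` (default): f scales the prior concentrations
  at initialization; observations always add +1. A hyper learner starts
  with a concentrated prior, so its predictive distribution moves little
  per observation (small surprise, high reliability); a hypo learner
  starts nearly flat and swings with every input.
- `sensitivity_mode="increment"`: the prior is unscaled and each
  observation adds +f instead.

The two modes are exact mirrors (prior scaling by f is equivalent, up to a
global rescale, to increment scaling by 1/f), which matters for §5.

Contexts are allocated lazily; a model trained on an n-token melody stores
at most n rows regardless of K^order. Model state serializes to JSON
(alphabet size, order, regime, per-context count vectors).

## 2. Chunking and hierarchy

A transition is *chunkable* when it is an outlier in both probability and
reliability: z-scores are computed separately over the posterior-mean
probabilities and the reliabilities of all observed (context, symbol)
pairs, and a pair qualifies when `z_prob > 0`, `z_rel > 0` and
`z_prob * z_rel > c` (default c = 5). A zero-variance dimension yields
all-zero z-scores, so a uniformly trained model never chunks. Maximal runs
of consecutive chunkable transitions in the training stream are merged
into chunks (contiguous sub-phrases, length >= 2); duplicate patterns
collapse into one chunk with its occurrence list.

The second hierarchy level re-encodes the training stream by greedy
longest-then-leftmost replacement of chunk occurrences with unit symbols
(ids K..K+n_chunks-1) and trains a fresh model with the same regime on the
re-encoded stream. Expanding all unit symbols reproduces the original
stream exactly. Exactly two levels are maintained: local chunks, and the
arrangement of chunked units.

**Caveat (measured, not assumed).** With reliability defined as the inverse
Beta variance, the threshold c = 5 is effectively unreachable at small
trial counts: Beta variance is symmetric in `alpha_i <-> alpha_0 - alpha_i`,
so the *rarest observed* continuation of a frequently visited context is
always at least as reliable as the dominant one, and the context at a
motif's end — which necessarily fans out into varied continuations —
supplies such competitors. On planted-motif fixtures the largest z-product
stays near 0.3 after 3 trials across geometries (40–200 notes, 5–20 motif
repeats); because the dominant transition's reliability grows ~t^2 in
trials against competitors' ~t, a first 2-token chunk fires only after
~20 repetitions of the training melody. The chunker is verified against an
independent brute-force recount (counts → variances → z-scores → threshold
→ run merging) over thresholds where chunks both do and do not fire; the
*expectation* that a 5-times-repeated motif chunks at c = 5 within 5
trials is not met by this scoring rule, and the acceptance suite records
that check as failing rather than adjusting c or the fixture.

## 3. Generation and corpus comparison

Composition samples at the chunk level: from the current level-1 context,
the next unit is drawn from the posterior-mean transition distribution,
chunk units are expanded to their token patterns, and the piece is
truncated to the requested length (default: the training piece's length,
starting from the training piece's first token; a stationary start is
available). Sampling uses posterior means directly — no per-step Dirichlet
resampling, no temperature. Pieces are deterministic given (model, length,
seed); corpora derive per-piece seeds from one root seed.

Corpora are compared to the training piece through bigram statistics: each
piece's empirical adjacent-pair frequencies are averaged (unweighted, then
renormalized) and compared with the training piece's bigram distribution
by Jensen-Shannon divergence on the union support with epsilon = 1e-9
smoothing (symmetric, bounded by log 2 nats). A seeded t-SNE embedding of
distribution sets is provided for visualization only; JS distance is the
quantitative criterion because 2-D embedding distances are not
metric-faithful.

## 4. Audio rendering and the AM cascade

**Rendering.** Notes are synthesized additively (3 harmonics at relative
amplitudes 1, 0.5, 0.25, or a pure sine), 10 ms linear attack, exponential
decay to ~5 % at note end, 5 ms declick fade, harmonics above Nyquist
dropped, peak normalization. Tempo default 120 bpm; the module's default
sample rate is 16 kHz. Waveforms are z-scored (mean 0, SD 1) before rhythm
analysis so absolute level cannot influence the modulation measures.

**Probabilistic amplitude demodulation.** A z-scored waveform is modeled
as `y_t = m_t * c_t` with positive slow modulator `m = exp(x)` and white
Gaussian carrier. The log-modulator x has a stationary Gaussian-process
prior with squared-exponential spectrum; its lengthscale is set from a
target cutoff rate r by `l = sqrt(ln 2 / 2) / (pi r)`, which puts the
prior's half-power point at r (so r = 10 Hz isolates the sub-10 Hz
envelope from the faster carrier). The MAP log-modulator minimizes

    sum_t [ x_t + y_t^2 exp(-2 x_t) / (2 s_c^2) ]  +  (1/2) x' K^-1 x

with the prior applied spectrally (circulant FFT parameterization; the DC
bin is left unpenalized so the modulator's operating level is set by the
data). Optimization is L-BFGS with analytic gradients (validated against
finite differences to ~1e-7 relative error), initialized from the log of a
Gaussian-smoothed local envelope, capped at 100 iterations with relative
objective tolerance 1e-7; hitting the cap sets a non-convergence flag on
the result rather than raising. The m/c scale ambiguity is resolved by
fixing mean(m) to the signal's RMS; the carrier is y/m, so modulator x
carrier reconstructs the input identically. An all-zero input short-cuts
to a zero modulator (the data term is otherwise unbounded below).

On synthetic 2 Hz amplitude-modulated noise (8 s), the estimated modulator
correlates with the true envelope at 0.99 for sample rates from 2 to
16 kHz at these settings.

**Cascade and band power.** The first (nonlinear MAP) demodulation
extracts the sub-cutoff modulator. Its mean-removed log is resampled to
the cascade rate (16x the fastest band) and smoothed through the band
rates (default 8, 4, 2, 1, 0.5 Hz, strictly decreasing). Levels after the
first use the closed-form MAP smoother of the Gaussian-observation
analogue in the log domain — an FFT filter with Gaussian amplitude gain —
and each level's *incremental* bandwidth is chosen so the cumulative
response at level i has half amplitude exactly at r_i. Scalogram rows are
the per-level envelopes `exp(x_i + mean)`.

Band power at rate r_i is the mean squared *difference* between the levels
at r_i and r_{i+1} (the last band keeps its full mean-removed power): the
fluctuation content removed when smoothing from one rate to the next. A
pure r-Hz modulation is removed almost entirely between the levels at
r and r/2, so it lands in the band labeled r; closed-form gain analysis
gives a ~1.6x power margin over the neighboring bands, and seeded
replicates localize 1, 2 and 4 Hz modulations correctly 20/20 times. A
naive per-level power (each level's own mean-removed envelope energy)
would instead be maximal at the *fastest* band for any modulation rate,
because every level is a low-pass of the signal — this is why the
difference form is used.

## 5. The simulation grid and what it does (and does not) reproduce

`run_experiment` crosses the three regimes with five cumulative learning
trials (trial k's snapshot has seen the melody exactly k times) — 15
models. Per snapshot it records total surprise, chunk count, the JS
distance of the 100-piece corpus to the training bigrams, and optionally
the corpus-averaged AM band powers. All randomness flows from one root
seed through named substreams; two runs with the same config are
bit-identical.

**Training input.** The default is a synthesized 40-note children's-song-
like fixture: 8 diatonic pitches, durations from {0.5, 1, 2} beats, one
4-note motif planted exactly 5 times among uniform filler (accidental
extra copies are rejected and redrawn), deterministic per seed. Any
monophonic MIDI file may be supplied instead. The experiment tokenizes
with the (pitch, duration) scheme: with pitch-only tokens every generated
piece would share one rhythm and the AM comparison across regimes would be
vacuous.

**Measured outcomes under the default (prior) mode.**

- Surprise: hypo > normal > hyper at every trial, and decreasing over
  trials for normal/hyper — a weak prior swings most per observation.
- Chunks: zero for all regimes and trials on the default fixture (§2), so
  the cross-regime chunk comparison is a tie.
- JS distance at trial 5: hypo 0.096 < normal 0.227 < hyper 0.404 nats.
  The hyper model's strong prior smooths its transition probabilities
  toward uniform, so its corpus is *least* similar to the training piece.

That last ordering is the opposite of the narrative the simulation is
patterned on (the most sensitive learner producing the most faithful
output). The inversion is structural, not a tuning accident: under prior
scaling, faithfulness to training statistics decreases monotonically with
prior mass; under increment scaling the JS ordering comes out
hyper < normal < hypo as narrated, but the surprise ordering flips,
because the two modes are mirrors of each other (§1). No single
parameterization of the concentration-scaling family yields both the
perception ordering (hypo most surprised) and the production ordering
(hyper most faithful): a learner whose predictive distribution moves least
per observation cannot also converge fastest to the data distribution.
The package therefore ships both modes, keeps `prior` as the default, and
the acceptance suite asserts the full published ordering set — with the
JS clause failing honestly under the default rather than being reweighted.
The corpus AM band powers inherit the same limit: the hypo corpus's
relative 1–3 Hz power declines across trials (consistent with the
narrative for hypo), while hyper/normal stay flat rather than rising.

**Desk-scale defaults.** Audio analysis renders at 4 kHz and measures the
first 10 s of each piece (5 full cycles of the slowest 0.5 Hz band); a
full grid with 20 pieces per model and audio takes ~3 minutes on one CPU,
and the symbolic grid with 100 pieces per model takes ~1 s.

## 6. What the fixture does not emulate

The fixture generator plants exact motif repetitions among uniform filler.
Real children's songs have phrase-level form (AABA), scale-degree and
rhythmic dependencies in the filler, and anacrusis/cadence structure; the
fixture has none of these, so passing orderings on the fixture show the
regime mechanics, not coverage of real musical corpora. Audio rendering
is a fixed deterministic timbre — absolute band-power values depend on the
note envelope and are only comparable within an experiment, never across
renderers.

## 7. Other limitations

- Order-1 contexts by default; variable-order/context-tree learning and
  forgetting are out of scope.
- Exactly two hierarchy levels; no soft/probabilistic segmentation.
- PAD returns the MAP pair only, not a posterior; demodulation parameters
  are set manually, not learned.
- MIDI I/O covers format 0/1 note on/off and tempo — sufficient for
  monophonic melodies; polyphony is collapsed to the highest sounding
  pitch at each onset.
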