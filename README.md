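# hbsl — hierarchical Bayesian statistical learning of melodies

`hbsl` is a desk-scale simulator of auditory statistical learning for
computational cognitive science. It models a listener who learns the
transition structure of a melody as an incremental Dirichlet–Markov
model, asking how *sensory sensitivity* shapes what is learned (perception)
and what is produced (composition):

- **Learning.** For each context token the model keeps a Dirichlet
  posterior over the K continuations. The transition probability is the
  posterior mean `α_i/α_0`; its **reliability** is the inverse marginal
  Beta variance `α_i(α_0−α_i)/(α_0²(α_0+1))`, which grows with evidence
  (90-of-100 observations are more reliable than 9-of-10 at the same 90 %
  ratio). Each event's **Bayesian surprise** is the KL divergence between
  the predictive distribution before and after the update, and sequence
  uncertainty is the conditional entropy −Σ P(x_i) Σ P(x_{i+1}|x_i) log₂
  P(x_{i+1}|x_i).
- **Sensitivity regimes.** Scaling the Dirichlet concentrations by
  f ∈ {0.25, 1, 4} yields hypo-, normal- and hyper-sensitive learners
  whose reliability responds differently to the same input stream.
- **Chunking & hierarchy.** Transitions whose z-scored probability and
  reliability are jointly outlying (product > c, default c = 5) are merged
  into chunks; a second-level model is trained on the stream re-encoded
  with chunk units.
- **Production.** New pieces are sampled from the learned hierarchy;
  generated corpora are compared to the training piece by the
  Jensen–Shannon divergence between average bigram distributions (with a
  seeded t-SNE embedding for visualization).
- **Rhythm.** Generated pieces are rendered to audio and decomposed by
  probabilistic amplitude demodulation (PAD): the MAP estimate of
  y_t = m_t·c_t with a log-Gaussian-process modulator and white Gaussian
  carrier, applied recursively to form an AM cascade whose band powers
  summarize rhythm energy (e.g. the 1–3 Hz phrase band).

See `docs/methods.md` for the full model account, numerical choices, and
the limits of what the simulation reproduces.

## Worked example

Run the full perception→production grid (3 regimes × 5 learning trials of
a 40-note planted-motif melody, 100 generated pieces per model):

```python
from hbsl import ExperimentConfig, run_experiment

table = run_experiment(ExperimentConfig(pieces_per_model=100, seed=0))
print(table.frame[["regime", "trial", "total_surprise", "n_chunks",
                   "js_distance"]].to_string(index=False))
```

prints (excerpt):

```
regime  trial  total_surprise  n_chunks  js_distance
 hyper      1        0.050269         0     0.498368
 hyper      5        0.017678         0     0.404296
  hypo      1        3.035435         0     0.265483
  hypo      5        0.111278         0     0.095036
normal      1        0.491551         0     0.428304
normal      5        0.065165         0     0.227250
```

Reading the numbers: `total_surprise` is the summed per-event KL (nats)
for that learning pass — the hypo-sensitive learner, whose flat prior
swings with every note, is the most surprised at every trial
(3.04 ≫ 0.49 ≫ 0.05 at trial 1), and surprise declines with repetition
for all regimes. `js_distance` is the divergence (nats, ≤ log 2 ≈ 0.693)
between each model's generated corpus and the training melody's bigram
distribution: under the default prior-scaling regime semantics the hypo
corpus is the *closest* to the training data (0.095 at trial 5) because
weak priors track the observed statistics most tightly — see
`docs/methods.md` §5 for why this ordering is the mirror of the
increment-scaling reading (`sensitivity_mode="increment"`), and why no
single setting produces both orderings reported for perception and
production. `n_chunks` stays 0 here: at c = 5 with 5 motif repetitions,
no transition is a joint probability/reliability outlier (methods §2).

The same grid is available from the shell:

```bash
hbsl experiment --out results/grid --seed 0 --pieces 100
hbsl fixture melody.mid --motif-repeats 5 && hbsl tokenize melody.mid
```

Adding `--audio` renders each generated piece and appends per-band AM
powers (8/4/2/1/0.5 Hz) to the results table.

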