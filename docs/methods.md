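# Methods

## The benchmark idea

A generative SMILES model trained on a subset of a *finite, exhaustively
enumerated* chemical space can be scored absolutely: sample it `k` times,
count the unique molecules that fall inside the space, and compare that
coverage with what an *ideal model* — a uniform sampler over the space that
emits nothing else — achieves at the same `k`.  Uniform sampling with
replacement is the coupon-collector problem, so the ideal model is fully
closed-form, and by Jensen's inequality the uniform distribution maximizes
expected coverage among all distributions on the space.  The trained model's
gap to the bound therefore mixes exactly the two failure modes of interest:
non-uniformity and incompleteness.

## Ideal-model mathematics (`idealmodel`)

For a space of `n` molecules (per-molecule probability `p = 1/n`):

- `E[T_u] = n·H_n` — expected draws to see everything at least once.  The
  harmonic sum is evaluated exactly up to `n = 10⁶` and by the asymptotic
  `n(ln n + γ) + ½` above (the two agree to well under one part in 10⁶ at
  the crossover; `γ` is the Euler–Mascheroni constant).
- Expected covered fraction of `k` draws: `1 − (1 − 1/n)^k`, computed as
  `-expm1(k·log1p(-1/n))` — literal exponentiation of `1 − 10⁻⁹` at
  billion-scale `n` would be pure rounding noise.
- The uniform sampler's NLL distribution is the point mass at `ln n`
  (mean `ln n`, variance 0) — the reference the monitor compares against.
- Across `M` independent ideal samplers, the number of models generating a
  fixed molecule is `Binomial(M, p_cov)`; the mode is
  `floor((M+1)·p_cov)`, reported as two adjacent modes when `(M+1)·p_cov`
  is an integer.
- For a non-uniform distribution `p_i`, the expected covered fraction is
  `Σᵢ(1 − (1 − p_i)^k)/n`, always at or below the uniform value (checked to
  a relative tolerance of 10⁻⁹); any `p_i = 0` makes full collection
  impossible, which is reported as unbounded rather than computed.

Monte-Carlo simulators (`simulate_coupon_collection`, `simulate_coverage`)
provide independent checks of both closed forms at small `n`; the test
suite requires agreement within 3 standard errors.

## Reference spaces and the toy enumerator (`chemspace`)

All membership decisions compare RDKit canonical SMILES and nothing else —
one pinned canonicalizer (RDKit 2024.09, see `pyproject.toml`), one
dialect.  A space stores its molecules and their *carbon skeletons* (every
heavy atom → carbon, every bond → single), used later to decide whether an
outside molecule's graph topology exists in the space at all.

Because the real enumerated databases are ~10⁹ molecules, the package ships
an exhaustive **toy enumerator**: connected molecular graphs over
{C, N, O} are grown atom-by-atom (bond orders 1–3, implicit hydrogens,
neutral molecules only, at most one ring closure) with canonical-SMILES
dedup at every step, then passed through a GDB-style filter set.  The
default filters are deliberately small and documented rather than
authoritative: a heavy-atom cap (5), allowed elements {C, N, O}, a 1:1
heteroatom/carbon ratio ceiling, disallowed substructures (peroxide O–O,
allenes, N–N single bonds) and a bond rule forbidding in-ring triple
bonds.  With these defaults the space has **n = 1085** molecules — large
enough for meaningful coverage statistics, small enough that every
experiment below runs in seconds.  Enumeration is refused above 7 heavy
atoms, where exhaustiveness stops being checkable.  Completeness is tested
against an independent brute-force construction at ≤3 atoms, and every
member of an enumerated space must pass its own filters.

What the toy space does *not* emulate about a real enumerated database:
molecules are far shorter (≤5 atoms vs. 13), the filter list is a small
illustrative subset, there is no aromaticity at this size, and the space is
three orders of magnitude denser relative to its SMILES alphabet.  Passing
toy-scale tests therefore demonstrates that the *pipeline and mathematics*
are correct, not that any particular architecture will reach a particular
coverage on a real database.

## Tokenization (`tokenizer`)

Atom-level lexical tokenization: bracket expressions (`[N+]`), two-letter
halogens (`Cl`, `Br`) and `%nn` ring closures are single tokens; everything
else is one character.  Sequences are framed by `^` (begin) and `$` (end).
The vocabulary orders the two specials first, then all other tokens
lexicographically, so checkpoints are reproducible regardless of corpus
order.  The model consumes integer ids directly through an embedding layer
— mathematically identical to one-hot × embedding matrix, without
materializing one-hot vectors.

## The language model (`lm`)

Embedding → stacked gated recurrent layers → linear → softmax.  Training is
teacher-forced: the step-`k` loss conditions on the true previous tokens,
and the loss is the per-sequence NLL (natural logs, summed over steps
including the terminal `$`), averaged over a batch.  Optimization is ADAM
(β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) with a geometric learning-rate decay
`lr_e = lr_start · c^(e−1)`, `c = (lr_end/lr_start)^(1/(epochs−1))` — the
schedule spans the configured endpoints exactly for any epoch count.
Sampling is multinomial from the softmax, stopping at `$` or at
`max_sequence_length` (truncated sequences are flagged and counted as
invalid downstream).  Batches are padded with the `$` id and padded
positions are masked out of the loss.

The network and backpropagation-through-time are written directly on NumPy
arrays (both GRU and LSTM cells).  Gradients are verified against central
finite differences in the test suite (agreement to ~10⁻¹⁰ absolute), and
scoring/sampling consistency is tested by comparing empirical sample
frequencies with `exp(−NLL)` on a converged tiny model.  Everything —
initialization, shuffling, sampling — derives from the configured seed, so
runs are bit-reproducible.

Two hyperparameter profiles ship:

| profile | embedding | hidden | layers | batch | LR | epochs | max len |
|---|---|---|---|---|---|---|---|
| toy (default) | 32 | 64 | 1 | 16 | 10⁻² → 10⁻⁴ | 60 | 50 |
| reference (`PAPER_PROFILE`) | 256 | 512 | 3 | 128 | 10⁻³ → 10⁻⁵ | 200 | 140 |

The toy profile was chosen so that one run (300 training molecules) takes a
few seconds on one CPU while still reproducing the qualitative training
phenomenology: validity climbing above 90%, coverage rising then
plateauing, and eventual overfitting.  The toy learning rate is hotter than
the reference profile's because a 300-molecule epoch provides ~19 ADAM
steps rather than ~7800.

## Training-state diagnosis (`monitor`)

After each epoch, NLL distributions of the training, validation and
freshly-sampled sets are histogrammed on one shared binning — fixed
0.5-nat bins spanning `[0, ln n + 20]`.  The binning is a documented choice
(the JSD of continuous samples needs a common discretization); a tiny
10⁻¹² mass is added per bin to keep KL terms finite, and sensitivity to
widths {0.25, 0.5, 1.0} is covered by a test.  The Jensen–Shannon
divergence (natural logs, range `[0, ln 2]`) is computed for all three
pairs via `scipy.spatial.distance.jensenshannon`.

Epochs are staged by rules mirroring the NLL-plot reading of a training
run:

- **converged** — the three pairwise JSDs sit within 3×0.05 nats of their
  joint minimum over the run *and* all are below 0.2 nats (the
  distributions genuinely match, not merely stagnate);
- **overtrained** — not converged, and either JSD(valid, sampled) trends up
  while JSD(train, sampled) does not, or the validation−training mean gap
  is positive (>0.1 nat) and still growing while the training mean still
  falls; once entered the label is absorbing unless the distributions come
  back into agreement;
- **undertrained** — everything earlier (including the initial phase where
  the model reproduces only a sliver of the training distribution).

The recommended epoch window intersects the converged window with the
validation-mean plateau (rolling slope below 0.05 nat/epoch over ≥3
epochs, nearest `ln n`) and the low-variance window; an empty intersection
falls back to the converged window, and a run with no converged epoch
reports `None`.  The thresholds were fixed from the two reference behaviors
the rules must separate: a 300-molecule run whose three JSDs settle around
0.05 nats (converged throughout), and a 12-molecule overfit run whose
train/valid gap grows past 0.6 nats while JSDs stay above 0.2.

## Sample evaluation (`evaluate`)

Every sampled string is classified exactly once: invalid (unparseable, or
truncated at sampling time), or valid and then in/out of the space by
canonical-form intersection; `canonical_as_generated` counts strings that
were emitted already in canonical form (raw string equality).  Totals count
repeats; unique counts are by canonical molecule.  The report carries
`coverage_fraction = unique_in_space / n` next to the ideal fraction at the
same `k`.  Processing is streaming — any iterable works, and the unique set
can be kept on disk (SQLite) for samples larger than memory.

The multi-model **frequency spectrum** counts, for every molecule of the
space, how many of `M` independently trained models generated it, and pairs
the histogram with the `Binomial(M, p_cov)` null.  A chi-square test at
α = 0.01 (sparse tails pooled) verifies that ideal uniform simulators pushed
through the whole pipeline reproduce the null.  `frequency_vs_nll`
stratifies per-molecule mean NLL by frequency and reports Spearman's rank
correlation (strongly negative for trained models).  N-gram tables (orders
1–2, tokenizer rules) connect rare grams to poorly-sampled molecules;
boundary grams (`^C`, `C$`) are excluded by default and available behind a
flag, since either convention is defensible.

## Violation labelling (`labeller`)

Every valid molecule outside the space gets all applicable labels (no
priority): heavy-atom count, element set, heteroatom ratio, functional
groups (by SMARTS, labelled per pattern), heteroatom-neighbour and bond
rules, and `graph_topology` when its carbon skeleton is absent from the
space's skeleton set.  Tautomer detection requires a tautomer enumerator,
which is out of this package's scope, so it is a pluggable hook: supply a
callable returning tautomer SMILES and matches in the space yield
`tautomer_of_member`; without a hook the category is simply not evaluated.
A molecule breaking nothing is `miscellaneous` — for the toy space, which
is exhaustive by construction and uses a single canonicalizer, this
category should be nearly empty (it is an expectation, not an assertion).

## Chemical-space maps (`mqnmap`)

42-dimensional MQN fingerprints (RDKit implementation) are projected by PCA
*without scaling or standardization* — the raw integer counts are the
intended geometry.  Component signs are fixed by orienting each component's
largest-magnitude loading positive, making maps input-order invariant.  The
first two components are min–max normalized onto a `w × h` pixel grid;
each occupied pixel gets HSV colour: hue from the bucket's normalized mean
descriptor (swept blue → cyan → green → yellow → orange → red → magenta),
saturation 1, and value from the max-normalized count through
`value = clip(max(0.25, 1 + log₁₀(count_norm)), 0, 1)` — low-count pixels
fade toward the black background, the top decade of counts reaches full
value, and the rule is pluggable.  (A published variant of this value rule,
`min(0.25, log₁₀(count_norm))`, is degenerate — the log of a [0,1]-normalized
count is ≤ 0, so the `min` always returns it; the rule used here realizes
the stated fade-in intent instead.)

## Problem sizes and numerical choices

All stochastic tests are seeded.  The sizes used by the test and benchmark
suite — toy space n = 1085, training/validation 300/80, k = 2000 samples
per evaluation, 40–60 epochs, M = 3–5 models, 10⁵ Monte-Carlo trials at
n = 10 — were chosen as the smallest sizes at which the statistical
assertions (3-standard-error bands, chi-square at α = 0.01) have
comfortable power; a full run of the suite takes on the order of a minute.
Degenerate inputs fail loudly and early: empty files and corpora, >50%
unparseable lines, vocabulary mismatches, non-finite losses, unnormalized
probability vectors, identical-fingerprint PCA.

## Known limitations

- The toy space's filter list is illustrative; reproducing a real
  database's out-of-space label percentages requires that database's full
  filter definition.
- The NumPy model is meant for desk-scale experiments; the reference
  profile (3×512 GRU, 10⁶-molecule training sets, 10⁹-scale samples) is
  preserved in configuration but is not practical without a GPU framework.
- The monitor's staging thresholds are calibrated at toy scale; on much
  larger validation sets the JSD noise floor drops and `match_threshold`
  could be tightened.
- No stereochemistry, charges, or 3-D structure anywhere in the toy
  enumeration.
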