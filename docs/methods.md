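# Methods

`avsin` analyzes word-identification experiments in which listeners type the
word they heard in noise while watching (or not watching) a talking face.
The pipeline has five analytic stages — scoring, cohort statistics,
per-phoneme rates, a counterfactual phoneme-presence model, and power
analysis — plus a generative simulator that produces complete experiments so
every stage can be tested without human data. This note records the models,
the defaults and why they were chosen, and the places where a design
decision was genuinely open.

## Scoring model

**Word level.** A response is correct iff, after normalization (lowercase;
characters outside `[a-z' -]` dropped; hyphens treated as spaces), it equals
the stimulus word, is a homophone of it (any stress-stripped pronunciation
variant identical), or appears in a curated misspelling-equivalence table.
The table ships seeded with *echos/echoes* and is meant to be extended per
dataset; keeping it as a frozen data file keeps scoring deterministic where
a human rater once exercised judgment.

**Phoneme level.** Stimulus and response are phonemized with a CMU-format
pronouncing lexicon (lexical stress digits stripped; the 39-symbol ARPAbet
set) and compared with the multiset Jaccard index

    J = |S ∩ R| / (|S| + |R| − |S ∩ R|),

where the intersection counts each repeated symbol up to its minimum
multiplicity in the two sequences. Multi-word responses concatenate the
phonemes of all tokens in order. When either word has several pronunciation
variants, the maximum J over variant pairs is used: deterministic, and
lenient in the same direction as accepting misspellings. Word-correct trials
are assigned J = 1 so homophone credit propagates; the alternative
(recomputing J from the literal response text) would score a credited
homophone below 1, which would make the two measures disagree about trials
the word-level rule calls perfect.

**Out-of-vocabulary responses** (typos not in the lexicon) fall back to a
deterministic letter-to-phoneme rule (common digraphs first, then single
letters, final silent *e* dropped). The rule is crude by design — it exists
so that scoring is total and reproducible, not to model English orthography
— and every use is flagged on the trial and counted in the run log. Users
with many OOV responses should extend the lexicon or equivalence table.

## Cohort statistics

Condition means are computed per participant and then averaged without
weights across participants, so participants with (hypothetically) unequal
trial counts contribute equally.

The main effect of format on accuracy is a likelihood-ratio chi-square
(df = number of formats − 1) between a full and a no-format model that both
control for the grouping structure (participant, word, batch):

* *phoneme measure* (Jaccard fraction): Gaussian linear mixed model with
  crossed random intercepts for participant, word and batch, fitted by ML
  (statsmodels `MixedLM` with variance components). Treating a bounded
  fraction as Gaussian is an approximation accepted for this measure.
* *word measure* (binary): there is no frequentist crossed-random-effects
  binomial GLMM in the scientific Python stack, so the default is a
  conditional logistic fit with fixed participant and word intercepts
  (batch is absorbed by participant). With the counterbalanced design the
  two approaches target the same contrast; the fixed-intercept LRT is
  well calibrated once there are roughly ten or more trials per nuisance
  intercept (measured type-I error 3–6% at nominal 5% in the seeded
  calibration tests), and anticonservative below that, which is why the
  calibration tests use ≥32 participants per replicate.

If a mixed fit fails to converge or produces a non-finite likelihood, the
fixed-intercept fit is used and the fallback is recorded in the result.
Pairwise contrasts among the four formats come from the fitted coefficients
with Tukey-family adjustment via the studentized-range distribution (k = 4).

## Per-phoneme identification rates

A stimulus phoneme occurrence is *identified* when it is matched in the
response under the same minimum-multiplicity rule as the Jaccard
intersection; presented and identified counts accumulate per phoneme ×
face type × participant. Comparisons between face types pool counts across
participants and use two-proportion z tests with Bonferroni correction
across the phonemes tested (the same library gap as above rules out a
per-phoneme binomial GLMM; pooled proportions are the documented fallback).
The synthetic-face rate of a phoneme is the unweighted mean of its DNN and
FACS rates, while the pooled counts back the significance test. Auditory-only
rates are computed but excluded from the real-vs-synthetic tests. The
four-phoneme group analysis (/th/, /dh/, /f/, /v/ — the dental and
labiodental fricatives whose visual cues synthetic faces render poorly)
pairs participants: each contributes a group mean and a rest mean, compared
with a paired-samples t test, separately for Real, Synthetic, and their
per-participant difference.

## Counterfactual phoneme-presence model

A logistic model predicts word-level correctness of each audiovisual trial
from 0/1 presence indicators of every phoneme in the stimulus word, with a
separate coefficient vector for real-face and synthetic-face (DNN and FACS
pooled) trials. Defaults and numerical choices:

* **Intercepts**: one per face class by default; a shared-intercept variant
  (`separate_intercepts=False`) exists because the full-substitution
  identity (replace *all* synthetic coefficients → synthetic predictions
  equal real ones) only holds with a shared intercept.
* **Estimation**: Newton–Raphson on the penalized likelihood with a small
  ridge penalty (default strength 1.0, intercepts unpenalized). Presence
  indicators are near-collinear across a 64-word set and quasi-separation is
  routine, so unpenalized ML frequently diverges; the penalty bounds the
  coefficients without materially changing predictions. Convergence is
  declared at a maximum Newton step below 1e-8; after 500 iterations a
  near-stationary point (step < 1e-2) is accepted, since saturated cells
  approach their optimum geometrically slowly.
* **Goodness of fit** is reported as the squared Pearson correlation between
  observed and mean predicted accuracy per word × face class — r² for a
  logistic fit is not otherwise defined, and this is the definition the
  reported number uses.
* **Counterfactual**: replacing the synthetic coefficients of a chosen
  phoneme set with their real-face values and re-averaging predicted
  probabilities over synthetic trials estimates the accuracy synthetic faces
  would support if they rendered those phonemes as well as real video does.

Prevalence extrapolation re-weights pooled per-phoneme rates by an external
phoneme-frequency table (renormalized over the phonemes present in both),
predicting per-condition accuracy for a corpus with a different phoneme
profile. The packaged `prevalence_synthetic.tsv` is a clearly-labeled
synthetic placeholder for testing the machinery; corpus-level conclusions
require a published English frequency table.

## Power analysis

Paired two-dependent-means design, two-tailed: achieved power is
P(|T′| > t_crit) with T′ noncentral t, df = n − 1, noncentrality d·√n.
`required_n` increments n until the target power is reached. Two tails
reproduce both canonical calculations (d = 1.68, α = 0.05 → n = 6;
d = 0.5, α = 0.0167 → n = 57), and the analytic power is cross-checked in
the tests against a 100,000-rep Monte-Carlo paired-t oracle to within 0.01.

## The synthetic-data generator

The generator emulates the study design: 61 participants × 64 noisy words,
formats cycled so participant *i* sees word *j* in format (i + j) mod 4
(16 words per format within participant; every word in every format across
participants), plus 9 clear audiovisual catch trials on disjoint words,
trial order shuffled within participant, participants grouped into batches
of 16.

Each stimulus phoneme survives into the perceived sequence independently
with probability set by its viseme class and the format. The packaged
viseme map groups the 39 phonemes into nine classes (bilabial, labiodental
{F,V}, dental {TH,DH}, alveolar, postalveolar, velar, rounded, spread,
open); no universally agreed English viseme inventory exists, so the map is
a data file and replaceable. Default transmission probabilities are the
observed per-condition phoneme accuracies of the study being modeled:
auditory-only 0.37 everywhere, real faces 0.79 everywhere, synthetic faces
0.61 except the dental and labiodental classes at 0.28, catch trials 0.99.
Untransmitted phonemes are deleted or replaced by their voicing partner
(p/b, f/v, s/z, …), a deliberately simple stand-in for acoustic confusion,
not a fitted confusion model.

Two response modes:

* **Lexical reconstruction on (default)**: the simulated participant types
  the lexicon word with maximal Jaccard to the perceived sequence (ties:
  exact ordered match first, then alphabetical). This mimics whole-word
  typed responses and produces word-level accuracy as an emergent quantity.
* **Reconstruction off (identifiable mode)**: the perceived sequence is
  emitted verbatim, encoded as a pseudo-word (`qq` + symbols joined with
  `q`, unambiguous because no ARPAbet symbol contains *q*) registered in the
  returned lexicon. In this mode per-phoneme identification rates are
  unbiased estimates of the generating transmission probabilities, which is
  what the parameter-recovery tests use.

**What the generator does not emulate.** Real typed responses draw on the
full English vocabulary, not a ~190-word lexicon, so simulated word accuracy
under reconstruction runs higher than human accuracy at matched phoneme
rates (the mini-lexicon offers fewer confusable neighbors). Reconstruction
also couples phonemes that co-occur within words: a word that fails because
its /th/ was lost drags down the measured rates of its other phonemes in the
same condition, inflating real-synthetic differences for phonemes that
co-occur with degraded ones. Passing tests therefore show that the pipeline
recovers what the generator planted — cohort-level ordering, the degraded
phoneme classes at the top of the difference table, counterfactual gains —
not that human data would yield the same numbers. There is no model of
lapses, fatigue, guessing strategies, or perceptual learning.

## Problem sizes used in the seeded test suite

Simulation-based tests choose their own scales: the null-calibration test
uses 200 replicates of 32 participants × 16 words (enough trials per
nuisance intercept for the LRT's nominal behavior, see above); the
planted-effect recovery test uses 20 runs of 120 participants in the
identifiable mode, because a 64-word sample can contain a single word with a
rare phoneme (~15 presentations per face type at n = 60), too few for stable
rank recovery of that phoneme; parameter recovery uses one 60-participant
run and checks 95% binomial-CI coverage of the generating probabilities
across phoneme × face cells.

## Known limitations

* The conditional-logistic word-measure test conditions out, rather than
  models, the participant and word variance; variance-component estimates
  for the word measure are not reported.
* Per-phoneme tests use pooled proportions, which ignore participant-level
  overdispersion; with the counterbalanced design this mainly affects the
  standard errors of rarely-presented phonemes.
* The OOV letter-to-phoneme fallback is intentionally naive; heavy reliance
  on it (visible in the run log) degrades phoneme-level scores.
* The equivalence table must be curated per dataset; only *echos/echoes*
  ships by default. An optional edit-distance rule was considered and
  rejected to keep word scoring free of hidden thresholds.
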