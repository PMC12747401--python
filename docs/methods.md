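# Methods

## The indices

The package analyses daily workplace reports — each report carries an
individual well-being score and a team-atmosphere score, both on the
11-point 0–10 grid, plus a short free-text diary — and summarises each
team's *sharedness* per week: how far members converge in their assessment
of the team's psychological state. The analysis unit is the team-week,
with weeks defined as consecutive seven-day windows anchored at the study
start date; a 61-day study therefore yields nine windows, the last
covering five days. The trailing partial window is retained as a valid
(shorter) window by default and can be dropped by configuration.

**Score-based sharedness index (SSI).** For team *t* and week *w*,

    SSI_{t,w} = −mean(σ_1, …, σ_n)

where σ_i is the standard deviation of the team-atmosphere scores reported
by members of *t* on day *i*, and the mean runs over *eligible* days —
days with at least two reporting members. SSI is 0 under perfect
agreement, bounded below by −5 on the 0–10 grid, and missing when a
team-week has no eligible day. The SD is the population SD (ddof = 0) by
default: a day's reporters are the complete enumeration of that day's
raters, not a sample from a larger pool. The sample SD (ddof = 1) is
available behind a flag for sensitivity analyses; switching flavors can
reorder team-weeks slightly, so all correlation analyses accept either.

**Text-based sharedness index (TSI).** Each member's diary entries within
a week are concatenated into one document; the documents are compared
pairwise by Word Mover's Distance (WMD) over a word-embedding table, and

    TSI_{t,w} = (1/C) Σ_{i≠j} sim(v_{i,w}, v_{j,w})

with C the number of unique member pairs and sim a strictly decreasing
transform of the distance. Documents are normalized bags-of-words (nBOW):
out-of-vocabulary tokens are dropped and the remaining term frequencies
renormalized; a document with no in-vocabulary token is excluded and C
shrinks accordingly. TSI is missing when fewer than two usable documents
exist. Member contribution is decided at the week level (any diary that
week); day-level filtering is available as a configuration alternative.

### Numerical choices

- **WMD is solved exactly** as a transportation linear program (HiGHS dual
  simplex, one redundant marginal constraint dropped, constraint matrices
  cached per support shape). Weekly diary vocabularies are small, so an
  exact solve costs ~2 ms; relaxation-based approximations would break the
  brute-force oracle tests. The ground metric is the Euclidean distance
  between word vectors; cosine is available by flag.
- **Similarity transform: negation (default).** Any strictly decreasing
  affine transform leaves the magnitude of every downstream Pearson
  correlation unchanged, so the choice is immaterial for the association
  analyses; `inv` (1/(1+d)) and `exp` (e^−d) are retained for sensitivity
  work since non-affine transforms can reweight pairs.
- **Tokenization** defaults to lowercasing and splitting on whitespace and
  punctuation. Morphological analyzers (for Japanese text, for instance)
  plug in behind the same text → token-list contract.
- Pearson p-values come from the exact t-distribution of
  r·sqrt((n−2)/(1−r²)) with n−2 degrees of freedom, two-sided.
- Same-day submissions are merged before any analysis: scores averaged,
  diaries newline-concatenated in timestamp order (file order when
  timestamps are absent). The merge is idempotent. Merged fractional
  scores enter σ as-is.

## Association analyses

The team-week table enumerates every candidate unit (teams × windows; 23
teams over 9 windows give 207 candidates) and flags SSI/TSI eligibility
independently. Mean well-being is computed from member-day records on the
same observation window as the index being correlated: the eligible-day
set for SSI, all of the week's member-days for week-level TSI.
A unit's eligibility never depends on the index value itself.

- Overall: two-sided Pearson at α = 0.05 across eligible team-weeks.
- Per-team strata: teams with ≥ 4 eligible weekly units; per-week strata:
  weeks with ≥ 3 eligible teams. Both are exploratory — α = 0.10,
  unadjusted p-values; a Benjamini–Hochberg option exists but is off by
  default. Zero-variance strata are reported as undefined, never r = 0.
- Convergent validity: the nine-item interdependent-happiness responses
  are averaged per respondent and then within team; per-team index means
  (teams with ≥ 3 weekly values) are correlated with the team scale means,
  and the index passes the surrogate criterion iff r ≥ 0.4. The response
  scale of the nine items is whatever the survey declares — nothing is
  hard-coded to a 5-point format.
- A documented hazard: duplicating team-week rows leaves r unchanged but
  shrinks p (pseudo-replication); the tests pin this behaviour.

## Lexical and emotion summaries

High/low report classes are defined by quartiles of the target value
(well-being, or the report's team-week SSI): high ≥ Q3, low ≤ Q1, with
linear-interpolation quantiles and inclusive boundaries so atoms at a
quartile enter the class; realized thresholds are always reported. Word
association uses document-frequency 2×2 tables (presence/absence — robust
to diary length; token-count mode behind a flag) with the
Haldane–Anscombe 0.5 correction so odds ratios stay finite at zero
counts, and a default min_df of 5 across both classes to suppress hapax
artifacts. Swapping the class labels maps every odds ratio to its
reciprocal.

Emotion labels come from a pluggable classifier restricted to seven
emotions (sadness, anxiety, anger, disgust, trust, surprise, fun). The
built-in stand-in is a deterministic lexicon vote: each mapped token casts
one vote, majority wins, ties abstain. It is a transparent fixture for
pipeline testing, not a model of natural language. Per-emotion summaries
report n, mean and SD of well-being and the delta against the pooled
labeled mean; the n-weighted deltas sum to zero by construction.

## Synthetic studies

The generator emulates the structure the analysis assumes, with defaults
chosen to mirror a two-month, 23-team field deployment:

| parameter | default | meaning |
|---|---|---|
| n_teams / members_per_team | 23 / 4–7 | team roster |
| anchor/end date | 2022-09-01 / 2022-10-31 | 61-day window, 9 weeks |
| member_active_prob | 0.75 | members who ever report (~94 of ~126) |
| participation_prob | 0.25 | mean daily submission rate of active members |
| participation_concentration | 1.5 | Beta heterogeneity across members |
| weekend_factor | 0.25 | weekend submission-rate multiplier |
| resubmit_prob | 0.05 | same-day duplicate submissions |
| agreement_spread | Gamma(2.5, 0.55) | latent weekly spread s_{t,w} (mean ≈ 1.4) |
| atmosphere_mean / between-SD | 6.4 / 1.0 | latent weekly level μ_{t,w} |
| coupling_beta | 0.65 | effect of −s on member well-being |
| wellbeing_atmosphere_gamma | 0.3 | effect of μ on member well-being |
| base_wellbeing / noise_sd | 5.65 / 1.8 | intercept and member-day noise |
| λ(s) | exp(−s) | shared-topic token probability |
| embedding_dim / topic_jitter | 16 / 0.5 | synthetic embedding geometry |
| ihs_coupling | 0.8 | team harmony trait ↔ mean agreement |

Atmosphere scores are Normal(μ, s) clipped to [0, 10] and rounded to the
11-point grid by default (clipping slightly attenuates extreme spreads;
this is documented, not corrected). Well-being is
base + β·(−s) + γ·μ + noise, likewise gridded. Diary tokens come from the
team's shared topic with probability λ(s) and otherwise from the member's
own topic; topics live in a synthetic embedding space where topic
centroids are separated by at least 4× the token jitter. Every team keeps
at least one reporter. One integer seed determines everything.

**Calibration.** β = 0.65 with the defaults above was set so that the
model-implied overall SSI–well-being correlation — the large-replicate
mean of the observed statistic, which already includes the attenuation
from estimating daily SDs with 2–5 raters — is ≈ 0.33 with ≈ 120 eligible
units out of 207, matching the regime of interest. Calibrating the *latent*
corr(−s, mean well-being) to 0.33 instead would center the observed r near
0.22 because of that attenuation; the observed-statistic convention is the
one the recovery checks use. Mean well-being lands at ≈ 6.6 and mean
atmosphere at ≈ 6.4 on the 0–10 grid.

**What the generator does not emulate.** Natural language (diaries are
controlled token sequences); declining participation over the study and
other non-stationarities; correlated member-day residuals; the volume of
a fully engaged cohort (with eligibility around 118/207 units, daily
submissions average ~20, below a field deployment's early-period peak —
matching both at once is impossible under time-homogeneous Bernoulli
participation). Passing recovery tests therefore demonstrates that the
pipeline measures what it claims under the assumed structure, not that
the indices are valid on any particular real corpus.

## Problem sizes in the test suite

Replicate-based checks use 500 score-only replicates for null calibration
of the overall test (rejection rate within 2 SE of 0.05) and 200 full
replicates (including exact-WMD TSI) for coupling recovery; WMD exactness
is verified against transportation-polytope vertex enumeration on 200
random small-support pairs, and SSI fixtures are checked to 1e-12.

## Known limitations

- The emotion stand-in cannot generalize beyond its lexicon; real
  deployments should plug in a trained classifier behind the same
  interface.
- Exact WMD scales quadratically in members per team and linearly in
  team-weeks; it is sized for diary-scale vocabularies, not long
  documents.
- The association analyses are correlational; no causal or longitudinal
  dynamics modeling is provided.
- Embedding files are read in the word2vec text dialect only.
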