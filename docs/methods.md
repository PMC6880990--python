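# Methods

## Model and procedure

For an index disease with cases y=1 and controls y=0, each phecode k gets an
aggregate measure m_k per subject — binary presence, occurrence count, or the
first-to-last duration in years of its coded visits within the study window —
and the logistic mean model

    logit P(y = 1) = b0 + bm * m_k + ba * age + bs * sex

is fit by maximum likelihood. The coefficient of interest is theta = bm, the
log odds ratio per unit of the aggregate measure, with a Wald interval
I = theta_hat ± z * se at level gamma (default 0.95). The interpretation of
theta — and hence a sensible indifference zone — differs by measure type:
under the binary measure it is the log-OR of ever carrying the phecode;
under count/duration it is per extra occurrence / per extra year.

**Second-generation p-value.** Against the interval null
N = [log(OR_lo), log(OR_hi)],

    p_delta = (|I ∩ N| / |I|) * max{|I| / (2|N|), 1},

clamped to [0, 1]. The correction factor only matters when the estimate's
interval is more than twice as wide as the null; it never changes which
findings get p_delta = 0, so the significant set is identical with or
without it. All overlap arithmetic is done on the log-odds scale: overlap
proportions are not scale-invariant, so one canonical scale must be fixed,
and the regression coefficient lives there. Config accepts OR-scale nulls
(e.g. [0.3, 1.5]) and records both scales in the run log.

**Power and PPV.** With theta_hat ~ N(theta, se^2),

    P(p_delta = 0 | theta) = Phi((N_lo - theta)/se - z) + Phi((theta - N_hi)/se - z).

The empirical-Bayes positive predictive value of a p_delta = 0 call averages
this power under f0 ~ Uniform(N) (giving alpha) and f1 ~ Uniform(I_observed)
(giving 1 - beta); f1 is deliberately data-dependent — its form is fixed a
priori, its support is the realized interval, recomputed per phecode. Then

    PPV = 1 - [1 + ((1-beta)/alpha) * ((1-pi0)/pi0)]^-1.

Both integrals use fixed-order Gauss–Legendre quadrature (64 nodes). The
integrands are smooth mixtures of normal CDFs, so 64 nodes are far inside
1e-8 absolute error; tests verify agreement with seeded 10^6-draw
Monte-Carlo integration to well under 0.01. Degenerate guard: if alpha
underflows to zero the ratio is treated as infinite and PPV is clamped to 1.
Prior limits pi0 = 0 and 1 return exactly 1 and 0 by construction.

**Novelty.** The PubMed proportion x_k is (papers co-mentioning phecode k's
strings and the disease's strings in title/abstract/keywords) / (papers
mentioning the disease). The novelty score is n_s = 1 - Fhat(x_k) with Fhat
the right-continuous, self-inclusive ECDF (#{x_j <= x} / M): the
most-studied pairing scores exactly 0 and ties share a value. By default the
ECDF is estimated over *all* screened phecodes — the larger reference set
stabilizes it — with a switch to restrict it to p_delta = 0 findings.
NFI = (PPV * n_s) * 10 is reported only where PPV is defined (p_delta = 0).

## Tunable parameters

| parameter | default | units / scale | why |
|---|---|---|---|
| `null_interval_or` | [0.3, 1.5] | odds ratio | indifference zone used in the worked examples; always study-specific and set by clinical input |
| `ci_level` | 0.95 | probability | conventional Wald interval level |
| `pi0` | 0.5 | probability | non-informative prior on the null |
| `min_carriers` | 5 | subjects per class | avoids meaningless fits and separation storms on rare phecodes |
| `measure` | binary | — | presence/count/duration semantics above |
| matching `ratio` | 1 | controls per case | raise for power when the pool allows |

## Censoring and matching conventions

Three windows: `age_interval` keeps visits with lo <= age < hi (closed
below — "at least seven years old" means age 7.0 is in); `left_censor`
keeps dx−hi < age <= dx−lo; `right_censor` keeps dx+lo <= age < dx+hi.
Windows are closed on the bound nearest the diagnosis (a "0–5 years after"
window includes the diagnosis visit itself) and open at the far bound.
Controls have no diagnosis, so each matched control inherits its case's
diagnosis age as a reference age — standard risk-set alignment.

Matching is greedy: cases in descending age order (equal ages shuffled by
the seed), exact on sex, nearest reference age, ties broken by subject-id
sort, sampling without replacement; pool members carrying any exclusion
phecode of the index disease are removed first, and exclusion sets always
contain the index phecode itself even when a map provides no ranges.
Exhausted strata yield fewer controls plus a warning, never reuse.

Covariates: a_k is the subject's mean age over their censored visits
(falling back to the reference age when they have none — such subjects are
kept with m_k = 0 rather than dropped); s_k codes female = 1, male = 0,
and unknown-sex subjects are excluded with a warning.

Separation handling: complete/quasi-complete separation is flagged
(converged = False) and the phecode is excluded from SGPV/PPV, reported as
`not_evaluated`; no penalized fallback, keeping the estimator semantics of
the plain logistic model. Numerically, a fit is also marked separated when
|theta| > 15 or se > 50 on the log-odds scale.

ICD-9 normalization stores the dotted canonical form and accepts the dotless
dialect (dot inserted after the third character, fourth for E-codes). No
phecode hierarchy roll-up is applied: a child code counts only toward its
own phecode.

## What the synthetic generator emulates — and what it does not

`SimConfig` defaults: 1,000 subjects per arm, eight toy-catalog phecodes at
5% background prevalence, ages ~ Normal(55, 15) truncated to [0, 100],
balanced sexes, 1 + Poisson(2) coded visits per carried phecode scattered
within the configured censoring window, phecodes exploded into ICD-9 child
codes through the bundled toy map so the mapping path is exercised. Carriage
is drawn from a logistic model: controls at prevalence p0, cases at
expit(logit(p0) + b) for planted log-OR b, so the population carriage OR
equals the plant exactly.

It does **not** model disease progression, coding noise, visit-frequency
differences between arms, age- or sex-dependent prevalence, or correlation
between phecodes beyond case status. Passing tests therefore demonstrate
that the statistical machinery recovers planted effects under clean
covariate structure — not robustness to confounding or informative-visit
processes in real records.

Test/validation problem sizes are the package's own desk-scale choices:
type-I behaviour is checked on all-null cohorts of 500/2,000/8,000 subjects
per arm (20 phecodes × 3 seeds each), and detection rates on 100 replicates
at 2,000 per arm with planted OR = 4 (detected, target ≥ 95/100) and
OR = 1.2 inside the null (ignored, target ≤ 2/100).

## Literature providers

The fixture provider reads a pinned counts file, keeping results
reproducible while PubMed grows; it is the default everywhere. The live
provider queries NCBI E-utilities (esearch over `[tiab]`-fielded OR-blocks
of strings, ≤ 3 requests/s, 3 retries then a hard error naming the query)
and caches every count on disk keyed by the hash of the normalized query —
a warm cache issues zero requests. Queries normalize strings by lowercasing,
deduplication and sorting so logically equal string sets share a cache entry.

## Known limitations

- Wald intervals misbehave at tiny carrier counts; the carrier filter
  mitigates but does not remove this, and no profile-likelihood or Firth
  alternative is provided.
- The PPV approximation treats theta_hat as exactly normal and uses a
  uniform f1 over the observed interval; both are approximations whose
  quality degrades for extreme estimates.
- Negative-direction findings (interval entirely below the null) are only
  flagged, not removed — their clinical interest is study-specific.
- ICD-10/SNOMED vocabularies, propensity matching, mixed models and NLP of
  abstracts are out of scope.
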