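# playseq

Behavioral-sequence analysis of structured play observation in autistic
(ASD) and typically developing (TD) children: lag-sequential transition
matrices, sequence-complexity metrics, Bernoulli-mixture latent class
analysis, HRV–behavior coupling, and latent-class-stratified
intervention-response analysis — together with a fully seeded synthetic
cohort generator so every stage can be exercised and validated without any
recorded data.

## Who it is for

Researchers working with coded behavior streams from standardized play
sessions (event logs of onset/offset-stamped behavior categories such as
*nonverbal initiation*, *joint attention*, *avoidance*), who want to move
beyond frequency counts to the **dynamics** of social interaction: which
behavior follows which, how diverse and organized the stream is, whether
unobserved subgroups of children share distinct behavioral profiles, and
whether those subgroups respond differently to intervention.

## The models

**Lag-1 sequential analysis.** For behaviors *i, j* in a fixed alphabet,
the transition probability is estimated as

    P(j | i) = N(i -> j) / N(i)

with counts never crossing session boundaries. Multi-step structure uses
the Chapman–Kolmogorov power λᵀ·Pᵀ with an optional decay weight λ.
Sequence complexity is summarized by the Shannon entropy (bits) of the
lag-1 bigram distribution, H = −Σ p(x) log₂ p(x); the average sequence
length (mean events per gap-delimited episode); and cyclicity
Σᵢ wᵢ P(i|i) with transitivity = 1 − cyclicity.

**Latent class analysis.** Children's binary behavior indicators **x** are
modelled as a K-component Bernoulli mixture,

    P(x) = Σₖ πₖ Πᵢ θᵢₖ^xᵢ (1 − θᵢₖ)^(1−xᵢ),

fitted by EM with random restarts; the class count is chosen by minimum
BIC over k = 2…5, cross-checked by the Lo–Mendell–Rubin adjusted LRT (a
parametric-bootstrap LRT is available as the robust alternative).

**Physiological coupling.** A normalized cross-correlation
CC(τ) = corr(HRVₜ, B₍ₜ₊τ₎) between the heart-rate-variability series and a
0/1 behavior indicator, recomputed per lag on the overlapping region, plus
an event-locked pre/post contrast around behavior onsets.

**Clinical association.** Responders are children with a ≥ 20 % reduction
in ADOS-2 total score; per-class response rates, class→response logistic
odds ratios (Eq. log(p/(1−p)) = β₀ + β₁·Class + β₂·Age), ANCOVA-style
adjusted group differences, and entropy-mediation (product of coefficients
with a bootstrap interval) connect the latent classes to outcomes.

## Worked example

```python
import numpy as np
import playseq as ps
from playseq.behavior import default_alphabet
from playseq.cohort import asd_group_kernel, simulate_event_log

alphabet = default_alphabet(6)
log = simulate_event_log(asd_group_kernel(6), alphabet, 5000,
                         np.random.default_rng(0))
tm = ps.transition_probabilities(ps.transition_counts(log))
i, j = alphabet.index("nonverbal_initiation"), alphabet.index("avoidance")
print(f"P(avoidance | nonverbal initiation) = {tm.probs[i, j]:.3f}")
```

prints

```
P(avoidance | nonverbal initiation) = 0.620
```

the probability that a nonverbal social bid is immediately followed by
avoidance in the simulated ASD stream — recovering the 0.62 entry of the
generating kernel. The `examples/` directory has one short script per
capability (transition matrices, entropy and chain mining, latent-class
selection and recovery, HRV coupling, stratified response analysis, and
the end-to-end pipeline); each prints the numbers it computes and a line
on what they mean. A thin `playseq` command-line interface wraps the same
functions (`playseq simulate | preprocess | transitions | metrics |
couple | lca | respond | run`).

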