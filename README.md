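# vpidet

Automatic detection of **velopharyngeal insufficiency (VPI)** from
dual-channel (nasal/oral) speech recordings.

VPI is an incomplete closure between the soft palate and the pharyngeal
walls. During speech it lets airflow and sound leak into the nasal cavity,
producing *nasal air emission* on pressure consonants and *hypernasality* on
vowels. A nasalance-style recording device — two microphones separated by a
baffle, one in front of the nose and one in front of the mouth, sampled at
11,025 Hz — captures both radiation paths simultaneously. `vpidet` turns such
paired recordings into a subject-level VPI / non-VPI call, and ships a
synthetic cohort generator so the whole system is testable without clinical
data.

## Method

**Consonants (spectral-ratio features + SVM).** Each microphone picks up a
crosstalk-attenuated copy of the opposite cavity, `x_o = o + α·n`,
`x_n = α·o + n`. Because the two cavities' frication sources are
uncorrelated and `α² ≈ 0`, the per-frame power spectral densities of the
*recorded* channels approximate those of the *radiated* signals, giving the
per-frame, per-frequency ratio

```
R(ω, i) = S_nn(ω, i) / (S_oo(ω, i) + S_nn(ω, i)) ∈ [0, 1]
```

estimated on 20 ms frames with a 6 ms shift (FFT length 256). A robust
per-frequency average R̄(ω) keeps only each bin's interquartile frames.
Two feature families summarize R̄:

* **RPFD** `[MR, locMR, MDR, locMDR]` — the maximum of R̄ and of its first
  forward difference, with their frequencies;
* **RFD** — the fraction of the area under R̄ in each of 4 equal linear
  subbands (the top band starts at `3·fs/8 ≈ 4134 Hz`, where oral frication
  concentrates).

An SVM with standardized features classifies each consonant.

**Vowels (CARS-Net).** Both channels become 64×64 log-magnitude
spectrograms, jointly min–max normalized so the inter-channel level
difference survives. A weight-shared residual Siamese network processes the
pair; each residual block carries a *cross-attention* coupling — a channel
weight vector computed from the concatenated, globally-pooled pair and
applied to both branches' conv paths:

```
F_{i+1} = skip(F_i) + W_i ⊙ conv(F_i)
```

A softmax head reads the flattened difference of the final maps; training
minimizes cross-entropy plus a contrastive term `y·d² + (1−y)·max(2−d, 0)²`
on the Euclidean distance `d` between the flattened branch outputs
(`y = 1` for VPI). The network is implemented in pure numpy with
hand-derived gradients and Adam; a finite-difference check in the test suite
validates the backward pass.

**Subject fusion.** A subject is called VPI when *strictly more than half*
of their phoneme-level predictions (9 unvoiced consonants
/p t k q c h x sh f/ + 4 vowels /a e i u/) are VPI; ties go to control.

## Worked example

```python
import numpy as np
from vpidet import (ConsonantNoiseModel, extract_consonant_features,
                    gen_unvoiced_consonant)

# a synthetic VPI consonant: 50% of source energy leaks nasally
sig = gen_unvoiced_consonant(ConsonantNoiseModel(leakage=0.5), alpha=0.1, seed=7)
fv = extract_consonant_features(sig)
print("MR   =", round(fv.rpfd.MR, 3))        # MR   = 0.979
print("RFD  =", np.round(fv.rfd.rfd, 3))     # RFD  = [0.965 0.012 0.011 0.011]

# the matching control (no leakage): only crosstalk reaches the nasal mic
ctl = extract_consonant_features(
    gen_unvoiced_consonant(ConsonantNoiseModel(leakage=0.0), alpha=0.1, seed=7))
print("MR   =", round(ctl.rpfd.MR, 3))       # MR   = 0.01
print("RFD  =", np.round(ctl.rfd.rfd, 3))    # RFD  = [0.25 0.25 0.25 0.25]
```

With leakage, the ratio curve saturates in the low band where the nasal
source lives (`MR ≈ 0.98`, 96% of the area in the lowest subband); without
it, the ratio collapses to the crosstalk floor `α²/(1+α²) ≈ 0.01` and the
area spreads uniformly.

The same pipeline from the shell:

```bash
vpi synth --out cohort --n-vpi 15 --n-control 15 --seed 0
vpi crossval --manifest cohort/manifest.csv --folds 5 --out results
```

`results/metrics.json` then holds subject- and phoneme-level accuracy,
precision, recall, F1, TNR and FPR, with `results/predictions.csv` listing
each subject's vote tally.

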