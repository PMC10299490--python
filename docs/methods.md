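# Methods

This note documents the models, numerical choices and limitations of
`glomnet`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external
data.

## Signal model of the synthetic generator

The generator emulates multi-trial Fura-2 recordings from M antennal-lobe
glomeruli under a 1 s ON / 9 s OFF odor protocol sampled at 100 Hz
(defaults: 15 subjects × 6 odorants × 30 trials × 10 glomeruli). Each
trial trace is

    F(t) = F0 · (1 − s(t) − x(t)) + ε(t),

with `F0` the baseline fluorescence, `s(t)` the odor-evoked slow
transient, `x(t)` a coupled fast-fluctuation process, and `ε` white
observation noise. Because Fura-2 dims as calcium rises, both signal
terms are *subtracted*; downstream −ΔF/F normalization maps excitation
back to positive values.

**Slow transient.** A double-exponential kernel (τ_rise = 10 ms,
τ_decay = 0.5 s, peak-normalized) starting at stimulus onset plus a
per-subject latency offset (sd 50 ms, drawn once per subject and shared
by all its trials — emulating animal-specific response latencies). Only
the odor's responsive set (2–4 glomeruli, odor-specific, conserved
across subjects) receives the transient, with peak −ΔF/F amplitude 0.15.
Trial-to-trial variability is essential — a bit-identical repeated
transient would dominate the concatenated ON series and create
arbitrarily strong spurious cross-predictions among responsive channels
— so each trial jitters the latency (sd 10 ms) and scales the amplitude
lognormally (σ = 0.2). These magnitudes were chosen once as typical of
projection-neuron calcium imaging; no quantitative amplitudes or noise
levels were available to copy.

**Fast process and planted network.** `x(t)` is a stable VAR(2): own-lag
coefficients decay geometrically over lags (total 0.5), and a planted
directed network contributes off-diagonal coefficients at lag 1 with
magnitude `coupling_strength` (default 0.2) and random sign, at density
0.12 (11 of 90 ordered pairs for M = 10). During the stimulus second the
background coupling is amplified by `on_coupling_gain` (default 1.5), so
ON-phase networks are denser than OFF-phase ones. Optional *odor-specific*
networks are superimposed only while the stimulus is on: connectivity
then carries odor identity in the ON window and loses it after offset.
Innovation sd is 0.02 fractional fluorescence units; observation noise sd
is 0.005·F0. The defaults (0.2, gain 1.5) keep the companion spectral
radius below ~0.91 for every tested network draw while giving per-link
effects far above the detection threshold at 3000 samples.

**Stability.** Generation refuses any planted VAR whose companion
spectral radius reaches 1 *at the strongest applied coupling* (the ON
gain, plus the odor-specific part where present) — the operative
worst-case condition, since the ON-modulated process is the one actually
simulated.

**Missingness.** Each subject × glomerulus slot is unobservable with
probability 0.05 (NaN traces, mask False), emulating glomeruli that
cannot be identified in every animal. Masked channels are excluded from
every downstream statistic; cross-subject averages use
availability-aware denominators.

What the generator does *not* emulate: photon/shot noise, bleaching,
motion artifacts, spiking or biophysical circuit dynamics, and any
nonlinearity of the indicator. Passing tests therefore show that the
inference chain is correct and calibrated for linear-Gaussian dynamics
with planted causal structure — not that real antennal-lobe data satisfy
those assumptions.

## Preprocessing

−ΔF/F is computed per trial and glomerulus against the mean of the 1 s
immediately preceding stimulus onset; channels with a non-positive
baseline are flagged and masked. Analysis windows are the seven 1 s
intervals 0–7 s after onset (ON, earlyOFF, OFF2…OFF6); within a window
the trials are concatenated naively in acquisition order (30 trials ×
100 samples = 3000 points).

The slow/fast decomposition uses 4th-order Butterworth filters applied
forward–backward (`sosfiltfilt`, reflective padding), i.e. zero-phase
IIR filtering: low-pass at 1.5 Hz for the slow component; high-pass at
2.5 Hz for the fast component *after* subtracting each channel's mean
response across trials (removing the stereotyped transient). Filtering
is done per trial, before concatenation, so nothing smears across
concatenation seams. The filter family and order are implementation
choices (only "zero-phase IIR" is fixed by the design); both are
recorded in the analysis configuration.

## VAR identification and conditional GC

Series are demeaned per column; the VAR(p) is fitted by OLS on the
lagged design matrix. Model order defaults to BIC over 1…20, scored on
the common sample that drops the first `max_order` rows; AIC is
available. Naive trial concatenation leaves p regression rows per trial
whose lags reach across a seam; `mask_seams=True` drops those rows
(default off, matching the plain-concatenation convention; at 30 trials
and p ≤ 2 the difference is < 2% of rows).

The conditional GC value uses the state-space route: the fitted VAR in
innovations form (companion transition matrix, observation matrix
`[A_1 … A_p]`, unit-block Kalman gain), with the restricted model
obtained as the submodel observing all channels except the driver. Its
innovation covariance solves the discrete algebraic Riccati equation
(`scipy.linalg.solve_discrete_are` with the cross-term form), and
GC_{i→j|rest} = ln(λ'_j/λ_j). On exact population parameters this
reproduces closed forms to machine precision (e.g. ln(1+a²) for the
bivariate one-lag system, exact zero for the conditioned-out link of a
chain). Values below 1e−12 are reported as zero; the estimator is
non-negative by construction up to that floor. Fitted models must be
stable (companion spectral radius < 1) and have positive-definite
residual covariance, else the computation aborts with diagnostics.

Significance per directed pair uses the classical asymptotic route: the
restricted model is an explicit OLS refit of the target with the
driver's p lag columns removed, and

    F = ((RSS_r − RSS_f)/p) / (RSS_f / (N_eff − M·p − 1))

is referred to F(p, N_eff − M·p − 1). The state-space value and the
F-test's RSS ratio are two views of the same quantity; tests confirm
they agree for M = 2. The diagonal (self-causality) is never tested.
The 90 off-diagonal p-values are validated by Benjamini–Hochberg at
α = 0.05, and non-significant GC entries are zeroed to give the weighted
connectivity matrix.

Calibration: on null data (independent stationary channels) the per-pair
p-values are uniform and the mean false-discovery proportion after FDR
stays at the nominal level (test suite: 200 datasets of 10 channels ×
3000 samples; `scripts/acceptance.py` recomputes this number).

**Order selection caveat.** At 3000 samples BIC often prefers p = 1 to
the generating p = 2 (the lag-2 own coefficients are worth less log-
likelihood than the 100-parameter penalty). The underfit leaves all
planted links detected and top-ranked by GC value, but admits some
spurious (including reverse-direction) detections beyond the FDR level.
Directional recovery is therefore validated at the generating order,
where reverse-direction false alarms return to the nominal rate, and
separately shown to be ranking-faithful under BIC selection.

## Network summaries

Density is the number of validated links over m(m−1) for the m available
glomeruli. Edge-probability maps binarize each subject's validated mask
before averaging, and each edge's denominator counts only subjects with
both endpoint glomeruli available (the probability times the denominator
is always an integer). The Kruskal–Wallis comparison of density across
the seven windows uses one observation per subject × odor, tie-corrected,
df = windows − 1 = 6; fully tied inputs degenerate to H = 0, p = 1 with
a warning.

The glomerulus-shuffling control reassigns each glomerulus's complete
series (all odors and trials) to a different donor subject using a
Latin-style assignment: every glomerulus column of the donor matrix is a
permutation of subjects (each series is moved, never duplicated, so
per-glomerulus marginals are preserved exactly), and each artificial
subject's donors are pairwise distinct whenever subjects ≥ glomeruli
(with-reuse fallback, warned, otherwise). Stereotyped response maps
survive the shuffle; within-subject coupling does not, and the measured
density collapses toward the false-positive floor.

## Template matching

Maps are vectorized (edge-centered: the weighted GC matrix flattened
off-diagonal in a global glomerulus order, NaN where a subject lacks a
glomerulus; node-centered: per-glomerulus mean −ΔF/F over the window).
Similarity is Pearson correlation over pairwise-complete entries
(undefined below 3 shared entries or at zero variance). The best-match
rule awards score 1 to the most correlated odor template, split equally
among exact ties (correlations compared after rounding to 12 decimals);
templates with undefined correlation are excluded, and if none is
defined — e.g. an empty OFF-window connectivity map — the score is split
uniformly, which is the correct chance-level behavior for an
uninformative test map.

Within subjects, the 30 trials split into 6 contiguous groups of 5; each
group's connectivity map (or each single-trial node map) is tested
against templates that average all remaining maps — the tested map never
contributes to its own template. Across subjects, each subject × odor
all-trial map is tested against leave-that-subject-out averages. Scores
for one test always sum to 1, and under odor-exchangeable maps the
correct-match probability converges to 1/n_odors (1/6 ≈ 0.167 for the
default six odorants).

Per-odor significance against chance uses the one-sample Wilcoxon
signed-rank test on the per-subject probabilities (two-sided, zeros
dropped), BH-FDR corrected across odors. A signed-rank test is the only
well-defined form for comparing one sample against a constant; note its
exact two-sided p-value cannot fall below 2^{1−n}, so fewer than ~6
subjects cannot reach α = 0.05 regardless of effect size.

## Pipeline and reproducibility

The file-based pipeline (simulate → preprocess → gc → density → maps →
template → shuffle → report) derives per-stage seeds from the global
seed via `SeedSequence`, embeds the configuration hash and seed in every
artifact, and is byte-deterministic for JSON/CSV outputs given a fixed
configuration. The test suite and the examples run on scaled-down study
designs (3–6 subjects, 2–3 odors, 6–12 trials, 4–6 glomeruli) chosen so
that every contract is still exercised end to end; the full default
design (15 × 6 × 30 × 10) runs through exactly the same code paths.

## Known limitations

- The F-test is asymptotic; at short windows (e.g. 5-trial groups,
  500 samples) its finite-sample level is approximate.
- GC on the unfiltered ON window mixes planted coupling with
  stimulus-locked cross-predictions among co-responsive glomeruli;
  links among strongly responsive channels are over-represented there.
  The fast component (trial-mean subtracted, high-passed) isolates the
  planted coupling.
- No frequency-domain or time-varying GC; no graph metrics beyond
  density; no alternative classifiers beyond the nearest-template rule.
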