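# Methods

## Scope and model family

`raytox` analyses quantal bioassay data — counts of immobilized animals per
replicate well — for a single chemical and for binary mixtures laid out on
fixed-ratio ("ray") designs. The motivating system is the 48-h acute
immobilization of *Daphnia magna* exposed to silver nitrate (AgNO3, μg/L)
and ZnO nanoparticles (mg/L), but nothing in the code is specific to those
chemicals beyond defaults.

### Single-chemical curve

The response is the percentage of mobile animals,

    y(c) = u_max / (1 + (c / EC50)^β),

a three-parameter log-logistic with the lower asymptote fixed at zero (full
immobilization is achievable at high dose). `u_max` is the fitted control
response on the percent scale (elsewhere written C_max), `β` the
dimensionless slope and `EC50` the median-effect concentration in the
chemical's native unit. The curve satisfies `y(0) = u_max`,
`y(EC50) = u_max/2`, and is strictly decreasing; its inverse is
`ECx = EC50 · (x/(100−x))^{1/β}`.

Fitting minimizes the sum of squared residuals (SS) on replicate-level
percent-mobile values. Counts are kept alongside so the binomial simulator
and the bootstrap can resample at the well level. The optimizer is a
bounded trust-region least-squares (scipy `least_squares`, TRF) restarted
from ≥16 Latin-hypercube points over β ∈ [0.1, 20],
EC50 ∈ [min conc/10, max conc·10], u_max starts in [80, 100]; β and EC50
are optimized in log space for conditioning. EC50 confidence intervals are
nonparametric percentile bootstrap (default 999 draws), resampling
replicate wells with replacement within each treatment and refitting from
the point estimate. The bootstrap is distribution-free and mirrors the
experimental unit; a parametric (binomial) bootstrap would be the natural
alternative but assumes the noise model exactly.

### Mixture reference surfaces

Toxic units normalize potency: `TU_i = c_i / EC50_i`, with fractions
`z_i = TU_i / ΣTU`. Two reference models predict the mixture response from
the single-chemical curves:

* **Concentration addition** (CA, Loewe additivity). The mixture sits at
  the mobility fraction Y solving `Σ c_i / EC_{Y,i} = 1` with
  `EC_{Y,i} = EC50_i ((1−Y)/Y)^{1/β_i}`. Any combination with EC50-based
  ΣTU = 1 gives exactly 50 % effect, regardless of slopes, and iso-effect
  contours (isoboles) are straight lines.
* **Independent action** (IA, Bliss independence). Non-response
  probabilities multiply: `y = u_max · q1 · q2`,
  `q_i = 1/(1 + (c_i/EC50_i)^{β_i})`.

### Deviation functions

Departures from a reference are carried by a scalar G built from the TU
fractions:

| kind | G |
|------|---|
| S/A  | `a · z1 z2` |
| DR   | `(a + b_DR · z_lead) · z1 z2` |
| DL (CA) | `a · (1 − b_DL · ΣTU) · z1 z2` |
| DL (IA) | `a · (1 − b_DL · E_ref) · z1 z2` |

with `E_ref = 1 − q1 q2` the reference IA effect fraction. G enters CA as
`Σ c_i/EC_{Y,i} = exp(G)` and IA as `y = u_max (q1 q2)^{exp(−G)}`. Both
entries recover the reference exactly at G = 0, keep y within (0, u_max],
and give the standard sign convention: G < 0 means lower mobility than the
reference (synergism), G > 0 higher (antagonism).

These algebraic forms are this package's reconstruction of the MIXTOX-style
deviation family from its published behaviour, chosen as the unique affine
forms reproducing every stated switch rule: a and b_DR of opposite sign
flip the interaction at `z_lead = −a/b_DR`; CA-DL flips at `ΣTU = 1/b_DL`
(b_DL = 1 ⇒ the mixture-EC50 level, b_DL ≤ 0 ⇒ no switch); IA-DL flips at
reference effect `1/b_DL` (reachable only for b_DL > 1). The IA deviation
entry (exponent `exp(−G)` on the survival product) was a genuinely open
design choice; it was selected because it preserves range, reduces exactly
at G = 0, and honours the sign convention. All tests are written against
this sign/reduction/switch contract rather than any particular algebra, so
substituting a different published parameterization only requires the same
contract to hold.

The CA dose-level deviation uses **EC50-based** toxic units in its
ΣTU term, so G is a constant during the implicit solve and the left side of
the CA equation remains strictly increasing in Y; the root is then unique
and found by bracketed root-finding (Brent) to |residual| < 1e−10, with the
two float-representable bracket endpoints handled as saturation to 0 or
u_max.

**A note on monotonicity.** The reference surfaces are non-increasing in
each concentration, and every deviation surface is non-increasing along any
fixed-ratio ray (G is constant on a ray). Per-concentration monotonicity
off-ray, however, genuinely fails for strong deviations: at the c1 axis the
effective total toxic unit has derivative `1 − a` in TU1, so antagonism
with a > 1 locally *raises* mobility when a little of the second chemical
is added, and the IA entry shows an analogous effect even for synergism at
extreme ratios (the deviation fades with `z1 z2` faster than the reference
declines). This is a property of ratio-dependent deviation models, not a
solver artifact; the property tests assert exactly the monotonicities that
hold.

Isobole extraction evaluates the chosen surface on a rectilinear grid
(default 101×101 over [0, 2·EC50] per axis) and traces iso-mobility
polylines by marching squares (`skimage.measure.find_contours`), mapping
fractional grid indices back to concentrations.

## Joint inference and model selection

All eight models {CA, IA} × {reference, S/A, DR, DL} are fitted to the
pooled dataset (single-chemical series + mixture rays) by least squares on
**treatment means** — replicates averaged per treatment, the default
aggregation — jointly re-estimating `u_max, β1, β2, EC50_1, EC50_2` plus
the deviation parameters (5, 6 or 7 free parameters). Starts combine the
single-chemical marginal fits with Latin-hypercube perturbations; deviation
parameters start at 0 and ±1.

Nested models are compared by the Gaussian likelihood-ratio statistic
`χ² = n · ln(SS_reduced / SS_extended)` with df equal to the number of
added parameters, each extension tested against its base reference
(df = 1 for S/A, 2 for DR and DL). With the default reconstructed design
(21 mixture + 13 single + 1 control = 35 treatment means) this convention
reproduces, from the published SS values alone, the entire published
p(χ²) row of the motivating study (0.68, 0.03, 0.43 / 0.59, 0.01, 0.81) —
that reconstruction is what fixed both n = 35 and the comparison target,
and is frozen as a test.

**Winner selection** is gated on the better-fitting base: the base (CA or
IA) whose *reference* has the lower SS supplies the candidates, and among
its extensions the significant (p < α, default α = 0.05) one with the
lowest SS wins, falling back to that reference. The gate exists because an
LRT is only meaningful within a base: a 7-parameter deviation of the
misspecified reference routinely earns formal significance merely by
bending its surface toward the other reference (simulations from a pure CA
reference select an "interacting" IA model ~30–40 % of the time without
the gate, versus the expected ~α-level with it). Ties between significant
DR and DL break by lower SS. The S/A→DR and S/A→DL stepwise comparisons
are reported alongside for completeness.

Shared parameters are re-fitted per model rather than frozen at the
single-chemical estimates, matching the practice of reporting per-column
parameter sets. Replicate-level (non-aggregated) fitting is available via
configuration but is not the default.

## Synthetic bioassay generator

The generator emulates the study layout: single-chemical series (6
log-spaced AgNO3 levels over 0.5–2.5 μg/L; 7 log-spaced ZnO levels over
0.04–20 mg/L), three binary rays at TU ratios 5:5 / 3:7 / 7:3, seven ΣTU
levels log-spaced over 0.0625–2.0 (factor 2^(5/6) — a strict factor-2
serial dilution spanning that range would give only six levels, so the
seven-level span is honoured with a slightly denser geometric series), one
shared control, 8 replicate wells × 5 neonates per treatment: 35 treatments,
280 wells, 1400 animals. Mixture TU coordinates convert to native units via
`c_i = z_i · ΣTU · EC50_i` using the generating EC50s.

Noise is binomial at the well level:
`n_immobile ~ Binomial(5, 1 − y_pred/100)` — the natural sampling model for
a quantal endpoint — with no overdispersion term (none is inferable from
the published summaries). Real bioassays can add between-well and
between-day variance components, dose-metering error, and solubility or
aggregation artifacts (particularly relevant to nanoparticle suspensions);
passing recovery tests here therefore demonstrates correctness of the
estimation machinery under the stated sampling model, not robustness to
those field effects. Notably, pure binomial noise at this design yields
SS values around 1400 — larger than the study's printed 534.7 — so the
simulated conditions are, if anything, conservative for power.

Seeding uses numpy `SeedSequence` throughout; a recovery study spawns one
child stream per simulation, making every figure reproducible from one
integer and independent of execution order.

## Problem sizes and runtime choices

Recovery studies default to 200 simulations (medians stabilize well before
that; the 2.5/97.5 percentile band is reported alongside). The bundled
acceptance script runs 200 mixture and 2×200 single-chemical
simulate-and-refit cycles, each mixture fit using 9 deviation-grid starts
and each single fit 8–16 Latin-hypercube starts. Power/specificity checks
in the test suite use smaller fixed-seed batches (8–10 selections), since a
full model selection fits eight models.

## Known limitations

* Strictly binary mixtures; no ≥3-component designs.
* Gaussian-likelihood LRT on treatment means; a binomial GLM likelihood
  would weight extreme-response treatments differently and is out of scope.
* Detection power for the dose-ratio deviation at the reconstructed design
  is modest (~25–40 % at α = 0.05 in simulations from the fitted CA-DR
  model) — consistent with the motivating analysis itself sitting at
  p = 0.03. Median-recovery results are unaffected.
* The deviation algebra is a behavioural reconstruction (see above), not a
  transcription of the original MIXTOX source.
* Hormesis, time-to-event endpoints, and nonzero lower asymptotes are not
  modelled.
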