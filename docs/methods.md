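# Methods

This note documents the models behind `amdtox`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions the implementation commits to.

## Pollution and ecological-risk indices

All per-metal indices are ratios of a measured concentration C (mg l⁻¹)
to a background concentration B (mg l⁻¹) from an uncontaminated reference
site, optionally weighted by an element-specific toxic-response factor Tr:

- CF = C/B; I_geo = log₂(CF/1.5), where the 1.5 is the conventional
  lithogenic-variability factor of the Müller index and the logarithm base
  is 2 (so I_geo − log₂ CF = −log₂ 1.5 identically);
- EF double-normalises CF by a conservative reference element. No default
  reference element is set: effluent in which even Fe is enriched admits
  no credible conservative normaliser, so EF degenerates to CF unless the
  user names one, and the report stamps which variant was used;
- Er = Tr·CF and RI = Σ Er (Hakanson); the "modified" family substitutes
  EF for CF (MEr = Tr·EF, MRI = Σ MEr) and is likewise stamped;
- RQ = MEC/PNEC, reported missing (never silently zero) when no PNEC is
  configured;
- aggregates: PLI is the geometric mean of CFs, PI and MPI the Nemerow
  composite √((max² + mean²)/2) over CFs and EFs respectively, C_d = Σ CF
  and MC_d = C_d/n.

Default Tr weights are Hakanson's (Cd 30, As 10, Pb/Ni/Co/Cu 5, Cr 2,
Zn 1, Hg 40) with Fe given unit weight, since Fe carries no canonical
factor; all are overridable per run because published studies frequently
use bespoke weights.

**Replicate handling.** Indices are evaluated within each replicate and
then summarised as mean ± SEM (ddof = 1; SEM omitted for n = 1).
Aggregate indices are similarly computed per replicate and then averaged.
For nonlinear indices this is not the same as evaluating the index at the
mean concentrations (log₂ of a mean CF exceeds the mean of log₂ CF by
Jensen's inequality); per-replicate-then-average is what triplicate field
protocols report and is what the package commits to. The two coincide
exactly when replicates are identical, which the tests assert.

**Classification.** Interpretation bins are interval→label maps with
explicit open/closed bounds, covering all attainable values so that
classification never silently fails. Families with full published
gradings use them (Hakanson CF/Er/C_d bins at 1/3/6, 40/80/160/320 and
8/16/32; Müller's seven I_geo classes; Nemerow 0.7/1/2/3;
Sutherland-style EF bins, with the "very high" class carrying a closed
lower bound at 25 and "exceptionally high" starting at 50). Where a
grading is a single threshold (PLI > 100 "progressively deteriorating";
RI/MRI > 320 "very high"), the complementary interval is labelled
"below … threshold". Thresholds on the risk side follow the convention
that the top class is entered strictly above the boundary (Er = 320 is
"high", 320.001 "very high"), while EF's 25 bound is inclusive; the
boundary tests enumerate every edge.

**Missing data.** A missing (below-detection) concentration propagates as
missing through every index of that replicate and is excluded from that
replicate's aggregates; no LOD substitution is applied unless the caller
performs it upstream.

## Alpha-diversity estimators

Estimators consume a single sample's integer counts or the frequency
summary F_k (number of OTUs seen exactly k times), S_obs and N.

- **Chao1** (bias-corrected): S_obs + F₁(F₁−1)/(2(F₂+1)), defined even at
  F₂ = 0. Its variance uses Chao's case-specific forms and the 95% bounds
  apply the log-normal transformation to the unseen-richness component
  T = Ŝ − S_obs, so the lower bound cannot undershoot S_obs; with F₁ = 0
  the interval degenerates to S_obs.
- **ACE** with rare/abundant threshold 10 reads (the standard choice,
  configurable): S_abund + S_rare/C + (F₁/C)·γ², C = 1 − F₁/N_rare,
  γ² the coincidence-based rare-class CV estimate clamped at 0. When
  every rare read is a singleton C = 0 and the estimator falls back to
  Chao1, recording the fallback. Optional 95% bounds come from a seeded
  multinomial bootstrap (ACE's analytic variance is unwieldy and rarely
  reported).
- **Jackknife** is the first-order abundance-based form
  S_obs + F₁(N−1)/N; no interval is attached (resampling intervals for
  jackknife at these depths are degenerate).
- **Shannon** is the plug-in entropy in nats; its interval is a seeded
  1000-resample multinomial bootstrap (percentiles 2.5/97.5). Natural log
  is used throughout, consistent with values near ln S for communities of
  ~2000 OTUs.
- **NPShannon** is the Chao–Shen coverage-adjusted entropy: abundances
  shrunk by Good's coverage Ĉ = 1 − F₁/N and each term inflated by its
  Horvitz–Thompson inclusion probability 1 − (1 − p̃)^N. It is undefined
  (NaN) for an all-singleton sample. With F₁ = 0 it converges to — but
  does not exactly equal — the plug-in entropy at finite N; the residual
  Horvitz–Thompson correction decays geometrically with depth, and the
  tests assert agreement to 1e-6 at depths of a few hundred reads.
- **Simpson** is reported as both dominance λ = Σ p² and inverse 1/λ,
  because published tables are frequently ambiguous about which scale a
  "Simpson" column is on.
- **Good's coverage** is (1 − F₁/N)·100, in percent.
- **Rarefaction** is the exact hypergeometric expectation
  E[S_m] = Σ (1 − C(N−N_i, m)/C(N, m)), evaluated with log-gamma
  differences so that depths in the tens of thousands do not overflow;
  terms with N − N_i < m contribute exactly 1.
- **Faith's PD** sums branch lengths over the union of root-to-tip paths
  of the observed OTUs on a user-supplied newick tree (parsed by
  scikit-bio). The in-package implementation is cross-checked against
  scikit-bio's `faith_pd` in the tests, as are the Chao1 and ACE point
  estimates.

## Bioremediation kinetics

- **Urease assay.** The ammonium standard curve is an OLS line through
  (NH₄Cl µM, absorbance); 50–1000 µM is the expected span and points
  outside it warn. A sample's ammonium (µM, = 10⁻³ µmol ml⁻¹) is divided
  by 2 — complete urea hydrolysis releases two ammonia equivalents — then
  by the incubation time in minutes and scaled by dilution, giving
  U ml⁻¹ with 1 U = 1 µmol urea min⁻¹. The stoichiometric divisor is a
  parameter for assays quenched after the first hydrolysis step. Endpoint
  readings with a user-supplied incubation time are assumed.
- **Growth.** K (h⁻¹) is the OLS slope of ln OD600 vs time over either a
  user-specified window (e.g. 6–18 h for a culture with a 6 h lag) or,
  by default, the maximum-slope contiguous run of ≥ 3 points; the fitted
  window is echoed so reports are auditable. Td = ln 2/K; K ≤ 0 is a
  no-growth signal with Td reported missing. OD is taken directly as the
  growth proxy; no OD-to-count calibration is modelled.
- **Sequestration.** SE = (MQM − SQ)/MQM·100, clamped to [0, 100] with a
  warning when assay noise pushes SQ marginally above MQM (a hard error
  would reject routine AAS jitter). Precipitate yield is dry mass per
  culture volume; the mineral identity of the precipitate is not modelled.

## Synthetic generators

The generators produce data with the statistical structure the analysis
stages assume, at the scales typical of a coal-drainage study; all are
deterministic given their seed.

- **Geochemistry:** triplicate samples with lognormal replicate noise
  (concentrations stay positive; CV = 0 degenerates to the mean). Default
  per-metal means (Pb 326, Cd 95.0, As 56.7, Fe 39.7, Ni 28.8, Co 27.3,
  Cr 3.87 mg l⁻¹) and CVs derived from SEM·√3/mean match severely
  polluted coal-mine effluent. Backgrounds for Fe and Cd are pinned by
  inverting study-scale contamination factors (397 and 2.97×10⁶); the
  remaining backgrounds were chosen once so the CF ordering
  Cd > Co > Pb > As > Ni > Cr > Fe holds and Σ CF lands near 3.4×10⁶.
  With those means the geometric-mean PLI is ~2.5×10⁴; a single CF vector
  cannot simultaneously realise that sum and a PLI of ~3×10³, and the sum
  (degree of contamination) was preferred because the Nemerow composite
  is built from it.
- **Community:** S lognormal relative abundances (default S = 2500,
  σ = 2.0 on the log scale, chosen via H ≈ ln S − σ²/2 to put plug-in
  Shannon near 5.9 nats) sampled multinomially to an amplicon-like depth
  (default 26,160 reads). Zero-count rows are retained so true richness
  is recoverable.
- **Culture:** lagged exponential growth (default lag 6 h, K = 0.3 h⁻¹,
  OD₀ = 0.05) saturating at a carrying OD of 1.2, sampled every 3 h to
  48 h. Growth inside the exponential stretch is exactly exponential, so
  a noiseless run returns K to machine precision — a deliberate property
  used by the recovery tests. Urease activity scales with biomass up to
  255 U ml⁻¹; pH rises from 3.5 toward 8.3 as a bounded function of
  cumulative urea hydrolysed (a phenomenological stand-in, not a
  carbonate-speciation model); each metal's precipitated fraction is
  1 − exp(−rate·hydrolysis) with per-metal rate multipliers making Cd/Pb
  complete by 24 h and As/Ni partial, mirroring the relative removal
  order observed experimentally. MQM = SQ(t) + precipitated(t) holds to
  machine precision before observation noise is applied; the noisy
  observations and the exact truth are returned side by side.

What passing tests do **not** show: real effluent has correlated metals,
non-lognormal outliers and censored (below-LOD) values; real amplicon
data carry PCR/chimera artefacts and compositional biases upstream of the
OTU table; real cultures exhibit death phases, pH-dependent urease
kinetics and co-precipitation chemistry none of which are generated. The
suite validates the estimators' mathematics and the pipeline's plumbing,
not instrument- or pipeline-specific biases.

## Numerical conventions and scale choices

- Geometric means are computed as exp(mean log) for stability; the tests
  require agreement with the product form to 1e-9 relative.
- Classification bands are checked for unique membership on every call;
  a value falling in zero or two bands raises rather than guessing.
- Bootstrap and simulation seeds always flow from an explicit
  `random_state`/`seed` argument (numpy `default_rng`); CLI randomness is
  routed through `--seed`, and reports are byte-identical across reruns.
- Test problem sizes: Chao1 interval coverage uses 200 simulations at
  S = 100, σ = 1.0, 20,000 reads (deep coverage, the regime in which
  Chao1 is a consistent estimator rather than a lower bound); rarefaction
  is checked against 50,000 Monte-Carlo draws on toy tables; growth-rate
  bias uses 200 replicates at OD noise σ = 0.005. These sizes make the
  suite exact enough to catch formula errors while completing in seconds.

## Known limitations

- The EF reference-element machinery is exercised but no default
  normaliser is supplied; EF = CF unless configured.
- MC_d is defined as Σ CF/n; other "modified degree of contamination"
  conventions exist and can be added as variants.
- Confidence bounds for ACE are bootstrap-only and off by default; the
  jackknife carries no bounds.
- Faith's PD depends entirely on the supplied tree; no tree inference is
  performed.
- The pH and precipitation sub-models in the culture generator are
  phenomenological and should not be used to predict real carbonate
  chemistry.
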