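# Methods

This note records the models implemented, the defaults and why, the
numerical conventions, and what the synthetic-data experiments do and do
not demonstrate.

## Thermodynamic–kinetic rate law

The rate of a microbial terminal electron-accepting process is
`v = k[X] · F_T · F_K`. We evaluate the two limitation factors, not the
absolute rate: `k[X]` is unknowable from geochemistry alone and is exposed
as a dimensionless `rate_scale` (default 1), so `relative_rate` is
comparable only within a run.

**Thermodynamic factor.** `F_T = 1 − exp((ΔG_A + ΔG_C)/(χRT))` with
R = 8.314 J/(K·mol) and T defaulting to 298 K. ΔG_A is computed from
ΔG° + RT ln Q on activities γ_i[i]. The implementation reports the raw
F_T (which is negative when the environment cannot pay the conserved
energy ΔG_C) alongside a value clamped to [0, 1]; rates always use the
clamp, and a `thermodynamically-infeasible` flag marks clamped rows.
ΔG° is treated as temperature-independent: no enthalpy data are carried,
and the intended use is near-surface sediments close to 25 °C.

**Defaults for acetotrophic sulfate reduction** (the shipped `Reaction`):
ΔG° = −47.6 kJ/mol, χ = 6, ΔG_C = 45 kJ/mol (a literature mid-value in
the 33–47 kJ/mol range for sulfate reducers), K_acetate = 5.0×10⁻⁶ M,
K_sulfate = 9.17×10⁻⁴ M. A ferrihydrite-reduction `Reaction` factory is
provided, but its ΔG°, χ and ΔG_C must be supplied by the user: standard
energetics of iron reduction depend strongly on the mineral phase, and no
defensible default exists.

**Activities.** Two modes. `davies`: log₁₀γ = −Az²(√I/(1+√I) − 0.3 I)
with A = 0.509 (25 °C), clipped at γ = 1 so the contract γ ∈ (0, 1] holds
(the raw expression only exceeds 1 above I ≈ 5.9 mol/L, far beyond
estuarine pore water). `fixed` (the default): per-species constants,
defaulting to midpoints of coefficient ranges computed for this kind of
brackish pore water (SO₄²⁻ 0.16059, acetate and HCO₃⁻ 0.68335, HS⁻
0.64105). Per-row coefficients supplied in the input table always
override either mode. Both modes exist because published profiles rarely
state which convention produced their γ values.

**Detection limits and zeros.** Sulfide in these sediments is typically
below detection (it is scavenged into iron sulfides); profile evaluation
substitutes a configurable ceiling (default 2 μM) when the species is
absent from a row, and similarly 1.6 mM for bicarbonate. A true zero
concentration (acetate can be depleted) would make ln Q undefined, so a
detection-limit floor (default 1 μM) is substituted instead. Every
substitution is recorded as a per-row flag; nothing is silent. Outside
profile evaluation, `gibbs_energy` raises on zero activities unless a
floor is passed explicitly.

## Diversity estimators

All conventions follow the mothur lineage of 16S analysis:

- Good's coverage `1 − n₁/N`.
- Chao1 in the bias-corrected form `S_obs + n₁(n₁−1)/(2(n₂+1))`, which is
  defined even when doubletons are absent.
- Shannon with natural logarithms.
- Inverse Simpson from the unbiased without-replacement estimator
  `N(N−1)/Σnᵢ(nᵢ−1)`; an all-singleton sample makes it undefined and is
  returned as NaN rather than a fabricated number.
- Simpson evenness `(1/Σpᵢ²)/S_obs` with plug-in proportions, which keeps
  E ≤ 1 identically (mixing the unbiased diversity with observed richness
  would not).

Rarefaction draws without replacement to an exact depth (default 1498
reads); samples below depth are dropped with a logged warning. Point
estimates and 95% CIs come from repeated independent rarefactions
(percentile CIs, default 1000 iterations; drivers use 100–200, which is
ample for these CI widths). Whether to report a single rarefaction or the
mean over draws is a genuine convention fork; we report means, which are
stabler and make the CI interpretation coherent.

## Beta diversity, zoning, ordination

Jaccard is incidence-based (`1 − shared/either`), the "jclass" dialect;
Yue–Clayton is `1 − θ` on relative abundances. UPGMA is implemented
directly (rather than through a linkage library) because the zoning
contract requires deterministic lexicographic tie-breaking and ultrametric
node heights at exactly half the merge distance; it is cross-checked
against scipy's average linkage in the tests. Cutting the tree at k
clusters splits the highest nodes first; zone labels are assigned in
order of mean sample depth so "Zone 1" is stable across runs. PCoA uses
Gower double-centering and a symmetric eigendecomposition; negative
eigenvalues (non-Euclidean dissimilarities) are reported, never dropped,
and percent-explained is taken over the positive spectrum only. Axis
signs are fixed by making each axis's first nonzero loading positive.
One-way ANOVA (scipy) on the inverse Simpson index grouped by site is the
default across-site test; other indices are reported descriptively.

## Guilds

Guild assignment is lexical: a guild is a taxonomic rank plus a name
list, matched case-insensitively against RDP-style lineages with "(NN)"
bootstrap confidences; calls below the cutoff (default 50%, the usual
classifier threshold) go to `unassigned`. The IRB definition is a
15-genus list of organisms with demonstrated dissimilatory iron
reduction. For SRB no printed roster exists at genus level, so two modes
ship: an order-level list (Desulfobacterales, Desulfovibrionales,
Desulfuromonadales, Syntrophobacterales — the default) and a class-level
Deltaproteobacteria fallback. Some taxa legitimately belong to both
guilds (e.g. Desulfuromonadales genera reduce both iron and sulfur);
multi-membership is counted in every matching guild, deliberately without
deduplication. Co-abundance is ordinary least squares of one guild's
per-sample reads on another's, with r² the squared Pearson correlation
and a t-test on the slope (n−2 df), run on rarefied counts so library
size does not masquerade as association.

## Synthetic data

The generator emulates the study design it is meant to exercise: 3 sites
× 10 two-centimetre intervals (0–20 cm), three community zones whose
default membership follows the field zonation (Zone 1: all of site A1
plus A2 2–10 cm; Zone 2: A3 0–4 cm plus A2 0–2 cm; Zone 3: the rest).
Samples draw compositions from zone-specific base vectors under
Dirichlet-multinomial noise (precision 80 by default) and library sizes
from a negative binomial (mean 5000, dispersion 10 — the dispersion keeps
the probability of falling under the 1498-read rarefaction depth near
10⁻³, so default runs rarely drop samples). Base compositions allocate
per-zone guild fractions (IRB 3/5/6%, SRB 6/10/8% across zones 1–3) to
ten IRB and six SRB OTU lineages, 60% of the remaining mass to a shared
power-law core and 40% to a zone-specific block; the core's rank-abundance
steepness differs by zone (1.2/0.55/0.8) so zone 2 is most diverse and
zone 1 least, mirroring the down-transect diversity pattern of acidic
versus tidally disturbed sediments. Synthetic IRB lineages use only
iron-reducer genera whose true orders fall outside the default SRB order
list, keeping the two default guilds disjoint in generated data (the real
overlap case is exercised separately in tests).

Guild read *pairs* with a target correlation come from a dedicated
generator: a bivariate latent normal sets two per-sample guild fractions
(mean 6%, sd 2 percentage points), thinned binomially from the library
size. Binomial thinning attenuates correlation, so the latent correlation
is inflated by the analytic attenuation factor
`σ_lat/√(σ_lat² + Npq)` per variable; the default target is √0.59, and
the ground-truth record reports both correlations. Within the OTU-table
generator, guild fractions are constant within a zone — cross-guild
co-variation is this paired generator's job.

Geochemical profiles follow configurable (min, max, shape) triples per
species, defaulting to sulfate 3→45 mM and acetate 0.2→95 mM monotone
with depth, sulfide constant at 2 μM and bicarbonate at 1.6 mM; pH and Eh
columns carry plausible monotone trends for I/O realism only.

**What passing the synthetic experiments shows — and does not.** Zone
recovery (adjusted Rand ≥ 0.9 over 20 seeds) and regression recovery
(mean r² within 0.1 of the 0.6 population value over 200 seeds at n = 13)
demonstrate that the estimators and the clustering pipeline are correct
and well-conditioned at the study's scale. They do not demonstrate that
real CASS communities are this separable: the generator has no
compositional gradients within zones, no taxonomic misclassification, no
chimeras or sequencing error, and its zone separation is a knob. Small-n
regression r² has a wide sampling distribution (roughly [0.2, 0.9] at
n = 13), which is itself a finding worth remembering when interpreting
single-zone regressions on real data.

## Determinism and output conventions

Every stochastic step takes a seed; the pipeline derives all randomness
from the single run seed, writes floats with a fixed `%.10g` format, and
publishes outputs atomically (a temp directory moved into place only on
full success), so reruns with the same configuration are byte-identical
and failed runs leave nothing behind. The manifest records a hash of the
analytic configuration (the output directory is excluded from the hash),
the seed, package version, artifact list, and per-sample drop accounting.

## Problem sizes

Default experiment sizes — 30 samples × 150 OTUs, 100–1000 rarefaction
iterations, 20-seed zoning and 200-seed regression recoveries — were
chosen so every result is stable to reruns at different seeds while the
whole suite and the acceptance script each complete in well under a
minute on a laptop-class single core.

## Known limitations

- No speciation or equilibrium chemistry: activities come from measured
  concentrations and an activity-coefficient model, not a solver.
- ΔG° is not temperature-corrected; profiles far from 25 °C need
  user-supplied energetics.
- Guild assignment is lexical by rank name; it cannot see function that
  taxonomy does not encode, and it inherits classifier errors.
- The biomass term `k[X]` is out of scope, so rates are relative;
  dormancy and biomass dynamics are not modelled.
- UPGMA is O(n³) as implemented — fine for tens to a few hundred samples,
  not for thousands.
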