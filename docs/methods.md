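# Methods

## The quantities

The analysis unit is the *stratum*: one (marker gene, taxon, context) cell,
where a context is the cross of a station class (OMZ, NAtl, SAtl, or the
pooled average ocean) with a depth layer.  Layers follow the conventional
pelagic stratification — epipelagic [0, 200] m, mesopelagic (200, 1000] m,
bathypelagic (1000, 4000] m.  The boundary convention (upper bound
inclusive) is arbitrary but fixed; no sampled depth in practice sits on a
boundary, so any consistent convention yields the same three-way split.

Abundance is expressed in **FPM** (features per million): each ORF's mapped
read count divided by the grand total over the *whole dataset* (all
samples) times 10⁶, so the dataset always sums to one million FPM.  No
gene-length correction is applied; `normalize_fpm` operates on counts as
given, and a length-corrected table can be supplied in their place if
desired.  Normalization is run *after* paralog filtering, which keeps the
10⁶ invariant over retained features; renormalizing after any lossless
regrouping changes all FPM by one global factor and nothing else.

A stratum's observed richness `d_obs` is its number of distinct ORF ids —
each predicted ORF counts as one unique sequence; no identity-threshold
clustering is attempted.

## Paralog purging

Homology search recruits paralogous sequences (e.g. nifH cluster IV, the
hzsA-III clade found in fully oxygenated waters and assigned to organisms
with no known anammox capacity).  Each query's placement on a curated,
clade-labelled reference tree is resolved to the **smallest labelled clade**
containing its best placement edge; the clade's verdict (retain/discard,
defaulting to its functional / non_functional label) decides the query.
Three numerical choices: the best placement is the one with maximal
like-weight ratio; ties between placements with conflicting verdicts break
toward discard (a purge errs conservatively); and placements whose best
weight falls below a threshold (default 0.5, configurable — no principled
value exists because placement software reports weights on slightly
different scales) are discarded as low-confidence.  Counts are conserved
exactly: retained + discarded = input per gene, and filtering is
order-independent.

## The richness–abundance power law and δ, k

Expected richness is `d_exp = c · A^γ`, fitted **per gene**, pooling the
gene's strata across taxa and environments, by ordinary least squares of
log d_obs on log A (natural logs).  Per-gene pooling is the only granularity
at which the regression is well posed (one point per stratum otherwise);
per-gene×taxon and per-layer fits are available behind flags.  Least
squares in log space, rather than a nonlinear fit on raw axes, is the
standard power-law estimator and is exactly homoscedastic under
multiplicative lognormal richness noise.  The fit refuses fewer than three
usable strata or zero variance in log A; strata with A = 0 never reach it
(they are dropped at aggregation).

δ = d_obs/d_exp and k = δ·A follow per stratum; log δ and log k use the
natural log (the displayed scale is log-symmetric around 0, and the base is
a pure display constant).  Note that because the per-gene fit passes
through the data's centroid, δ is self-normalized: a global rescaling of
all abundances is absorbed into ĉ and leaves every δ unchanged.

For radial gene × taxon displays, taxa within one (station class, layer)
cell are ranked by summed k; ranks beyond the top n (default 25) are pooled
into an "Others" entry per gene whose k and A are sums over its members
(so pooled k is conserved); ties in summed k break lexicographically.

## Density comparison

Log δ values per (context, guild class) are smoothed with a Gaussian-kernel
density.  Bandwidth defaults to Silverman's rule of thumb
(0.9·min(sd, IQR/1.34)·n^(−1/5)); kernel and bandwidth are both
overridable since neither is dictated by the method itself.  The evaluation
grid is 512 evenly spaced points spanning the data range padded by **four**
bandwidths: with a three-bandwidth pad an edge kernel loses ≈ 2.7·10⁻³ of
its mass beyond the grid, violating the unit-integral contract at the 10⁻³
tolerance, whereas four bandwidths keep the trapezoidal loss below 10⁻⁴.
Displacement between two curves on a shared grid is summarized by the mode
difference and the difference of the underlying sample means; the
qualitative label uses a ±0.1 natural-log dead-band on the mode shift
("centered" within it), a presentation choice only.  The mode of a KDE is
grid-resolution-limited and, for samples of a few dozen points, noisier
than the sample mean — comparisons that need the ≈ log m displacement of an
injected multiplier should read the mean shift.

## GLM contrasts

Context effects on diversification are estimated with a Gaussian-family,
identity-link GLM fitted by iteratively reweighted least squares
(statsmodels); for this family/link IRLS converges to the ordinary
least-squares solution, which the test suite verifies against an
independent normal-equations oracle to 10⁻⁸.  Effects are *marginal
one-vs-rest contrasts*: for each focal category on an axis (station class,
ignoring layer; or layer, ignoring station), the model `response ~ 1 +
focal indicator` is refit and the indicator's coefficient, standard error
and normal-approximation (z) p-value extracted.  No joint interaction model
is fitted, and no multiple-testing correction is applied to the rotation's
p-values.  The default response is log δ — the scale on which the residual
structure is symmetric and roughly Gaussian, matching the identity link's
assumption — with raw δ behind a flag; the observation unit is the
per-stratum score, unweighted.  Guild classes (uptake vs redox) are
modelled separately.  Fit metrics reported per fit: log-likelihood,
deviance, Pearson χ², and the Cragg–Uhler (Nagelkerke) pseudo-R² —
the likelihood-ratio R² rescaled by its maximum, clipped to [0, 1] (the
unclipped form can exit the unit interval for continuous likelihoods).
Significance stars in summaries use the conventional thresholds * < 0.05,
** < 0.01, *** < 0.001, **** < 10⁻⁴.

Categories with fewer than two observations on either side of the split
have no defined contrast and are skipped; the remaining contrasts are still
emitted.

## N:P context

N:P is the NOx:PO4 molar ratio (undefined, not infinite, at PO4 = 0); 16:1
(Redfield) reads as neither N- nor P-limited.  The mesopelagic maximum of a
station's profile is the maximum over depths ≤ 1000 m, ties toward the
shallower depth.  A station is flagged a low-N:P anomaly when, at every one
of its sampled depths below a threshold (default 600 m — the deeper of the
two pivot depths at which the archetypal anomalous columns separate from
the rest), its ratio is strictly below the minimum of all other stations at
comparable depths; high-N:P is symmetric against the maximum.  "Comparable"
means the nearest sampled depth within ±50 m — profiles are not
interpolated, and no oxygen-based OMZ detection is attempted (oxygen is
carried as metadata only).

## The synthetic cruise

The generator emulates the statistical structure the analysis assumes, with
every quantity's truth recorded:

* **Survey geometry** — 11 stations × 7 depths (3–4000 m, ≈ 77 samples):
  one OMZ-like column, one high-N:P column, one otherwise-anomalous column
  (SAtl, average N:P shape), eight average columns.
* **N:P profiles** — piecewise shapes (linear surface rise to a mesopelagic
  peak, exponential relaxation to a deep value): average peaks 16.3 at
  430 m converging to 15.5 (marginally under Redfield); OMZ-like peaks 12.4
  at 210 m and stays lowest at depth; high-N:P peaks 18.96 and stays
  highest.  Average stations carry Gaussian jitter (sd 0.15) so profiles
  differ without crossing the anomalies.
* **Taxa** — a per-layer pool (default 25) with a configurable shared
  fraction (default 0.5) between adjacent layers.
* **Abundance** — per-stratum FPM is lognormal (default median 50, σ_ln
  1.5, i.e. spanning orders of magnitude — the heavy-tailed spread typical
  of functional profiles; the real-data FPM law is unknown and this choice
  is a stand-in), then globally rescaled so strata sum to exactly 10⁶ FPM.
* **Richness** — d_obs = round(c·A^γ · m · ε), rounded half away from zero
  and floored at one distinct ORF when A > 0, where m is the product of the
  matching injected δ multipliers (keyed by station class, layer, or cell,
  optionally restricted to one guild class) and ε is lognormal with unit
  median (default σ_ln 0.2).  Multiplicative effects match δ's ratio
  definition exactly: an injected m shifts the context's mean log δ by
  log m.
* **Feature rows** — each stratum expands into d_obs distinct ORF ids whose
  (fractional) raw counts Dirichlet-split the stratum's reads across the
  context's samples, so re-aggregation reproduces (A, d_obs) exactly.
* **Placements** — small labelled trees built per clade spec; each query is
  placed on a leaf of its true clade with a configurable like-weight ratio
  (remainder on a random other clade), with a truth table of labels.

One integer seed fixes the full output; sub-generators are split
deterministically per product (profiles / strata / feature rows /
placements), so e.g. the stratum table is invariant to whether feature rows
are also generated.

**What the generator does not emulate:** read-level sequencing error,
assembly and binning artifacts, chimeras and contamination, gene-length
bias, taxon co-occurrence structure, spatial autocorrelation between
stations, and any real covariance between N:P chemistry and gene content —
injected δ effects are the only coupling between context and richness.
Passing tests therefore demonstrate that the estimators recover the model's
own generative truth and that the pipeline's algebra (conservation,
invariances, error control) is correct; they do not validate the power-law
model or the guild interpretation against real ocean data.

## Problem sizes used in validation

Deterministic identities run on noiseless strata generated exactly on the
curve (inverting d = c·A^γ at integer richness, so no rounding intervenes).
Stochastic checks use: 500 strata for single-fit parameter recovery; 20
replicate cruises at the default survey geometry for injected-shift
detection (multiplier 0.8 ⇒ shift log 0.8 ≈ −0.22, detected with ≥ 18/20
significant negative contrasts); and 500 replicate lean cruises (6
stations × 3 depths, 2 genes, 12 taxa/layer — stratum-level generation,
skipping the exact ORF-row expansion) for the type-I error of the focal
contrast, chosen to give a tight binomial check of the 0.05 rejection rate
at sub-minute runtime.

## Known limitations

* The power-law exponent is fitted per gene; genuinely taxon-specific
  diversification laws would be absorbed into residual spread (a per-taxon
  fit exists but needs many strata per taxon).
* δ inherits the fit's leverage: strata of a gene with very few points can
  move their own expectation.
* The KDE mode is a noisy location statistic at small n; the dead-band
  label should be read qualitatively.
* One-vs-rest contrasts on overlapping axes (station, layer) are marginal,
  not adjusted for one another; with unbalanced designs a station effect
  can leak into layer contrasts and vice versa.
* Flagging requires ≥ 3 stations and strict envelope separation; two
  equally extreme stations mask each other by construction.
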