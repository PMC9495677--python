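# Methods

## Model

The package scores equimolar mixtures of antioxidants against an
expected-additivity null. For a k-component equimolar mixture at total
concentration C, the additive expectation is T = Σᵢ Aᵢ / k, where Aᵢ is the
mean activity of component i measured **alone at the full concentration C**.
This is exactly equivalent to "each component contributes its activity at
C/k" only when the individual dose–response is linear through the origin;
the linearity assumption is checked empirically (`linearity_check`; every
compound in the packaged FRAP panel has Pearson r ≥ 0.99 across
100/500/1000 µM) but curvature at low dose is a real limitation of the
index — a deviation from additivity can in principle reflect individual
nonlinearity rather than a molecular interaction.

The interaction index is the percent difference D = 100·E/T − 100 between
the observed mixture mean E and T. Classification uses an inclusive additive
band: |D| ≤ b → additive, D > b → synergistic, D < −b → antagonistic, with
b = 5 percentage points by default. The inclusive-band resolution was chosen
because the band statement ("≅ 0 ± 5% means no interaction") is more
specific than the bare sign rule; the boundary value ±5.0 therefore counts
as additive. The band is configurable (`InteractionConfig.additive_band_pct`
/ the `--band` flag).

No hypothesis test is attached to the classification; the index is
descriptive, as in the source study. The null-calibration property test
quantifies what the ±5 band does under realistic noise: with triplicates at
3% CV and no true interaction, the false-non-additive rate equals the
two-sided Gaussian tail mass beyond 5 points of the delta-method SD
(≈2.4 points under those conditions), and simulation and the analytic tail
agree within 2 percentage points.

## Uncertainty propagation

Published tables carry ± on activities but not on differences. The package
attaches a first-order (delta-method) SD treating E and the Aᵢ as
independent means of n replicates:

Var(D) ≈ (100/T)² · [ sd_E²/n_E + (E/T)² · Σᵢ (sdᵢ²/nᵢ) / k² ].

The implementation uses the algebraically equivalent form
(100/T)·sqrt(Var(E) + (E/T)²·Var(T)), which is well-defined at E = 0. It is
scale-invariant (D is a ratio) and agrees with a 10⁵-draw Gaussian
Monte-Carlo resampling within 5% relative at the noise levels of the data.
Replicate counts default to 3 (the assays are run in triplicate);
summary-only fixtures therefore assume n = 3.

## Reporting and rounding conventions

Differences are rounded half away from zero, displayed with one decimal when
|D| < 10 and as integers otherwise, matching the mixed precision of the
published tables; underlying values are kept at full precision. Printed
table cells are stored verbatim as strings at printed precision (including
"23.9 ± 2" and "1201 ± 0"); comparison against a recomputed value is made
in units of the printed value's final digit after rounding the recomputed
value to that precision, with a ±1-unit pipeline tolerance because the
published tables were rounded from unrounded raw data.

## The published-table comparison report

`reproduce_tables` grades all 416 printed theoretical/difference cells.
Three statuses arise on the packaged data: 365 cells pass at ±1 final-digit
unit; 31 cells are curated transcription errors (`known_typo`), dominated by
the 500 µM theoretical column of the hydroxycinnamic FRAP table where all
15 ferulic-containing rows reproduce exactly if ferulic's 500 µM mean is
taken as 8885 instead of 885 — a single propagated transcription slip —
plus one decimal slip (C+Si at 100 µM, 3560 vs ≈356); 20 cells deviate by
2–28 final-digit units in a way consistent with the authors computing from
unrounded raw replicate means (`raw_mean_gap`); these are reported, not
asserted equal. The report also surfaces two narrative-level
inconsistencies: the text attributes the −24% ORAC antagonism to gentisic +
syringic where the table prints Ge+Sy at +236% and G+Sy at −24% (the table
is taken as authoritative), and one experimental cell ("1440 ± 23") appears
verbatim in two different rows.

One consequence of raw-mean rounding is worth noting: P+Sy under ORAC
recomputes to +5.15% from the printed individual means (printed: 4.1%), so
it crosses the +5 band edge and classifies synergistic from printed inputs
while the published classification is additive. Classification counts
quoted in tests against published tables therefore classify the *printed*
difference cells.

## Assay reduction

Calibration lines are ordinary least squares with a free intercept
(`StandardCurve`, a scikit-learn regressor); forcing through the origin is a
flag. A flat response is rejected at inversion time (zero slope), not at fit
time. ORAC kinetic traces are normalized to their initial fluorescence
before trapezoidal integration — chosen for plate-to-plate comparability and
exposed as `curve_auc(..., normalize=False)` — and the net area is the
sample minus the mean blank area over the same window. Traces must start at
t = 0 with strictly increasing times; a zero initial fluorescence cannot be
normalized and is an error.

## Synthetic data

The generator emulates the study conditions: linear individual
dose–response (activity = slope·C) with multiplicative Gaussian replicate
noise, triplicates, and CV 0.03 — multiplicative because the published SDs
grow with the mean, and 0.03 because that is the relative-error scale of the
published activities (e.g. 2341 ± 32). Default slopes are on the scale of
the published panel (FRAP activity at 1000 µM divided by 1000; ORAC at 5 µM
divided by 5). Interaction effects δ (in percent) are injected on the
mixture mean, E = T·(1 + δ/100), not per replicate, so δ is exactly
identifiable in the noiseless limit. Seeding: one master seed; each
generator uses `default_rng([seed, stream])` with fixed stream ids
(0 individuals, 1 mixtures, 2 ORAC plate), so identical specs yield
identical tables and the three generators are independently reproducible.

Synthetic ORAC plates use exponential decays f(t) = exp(−λt) sampled at
1-min steps over 80 min. Rather than deriving λ from a kinetic model and
accepting an approximately linear ladder, each well's λ is solved
numerically (Brent's method on the trapezoidal area, which is strictly
decreasing in λ) so that its net AUC is *exactly* `ladder_slope` × the
programmed Trolox-equivalent value. The Trolox ladder is therefore exactly
linear (r² = 1) and reduction inverts programmed TE values to 1e−6,
making end-to-end recovery failures attributable to the pipeline, never to
discretization of the simulated chemistry. The cost is that λ(dose) is an
implicit function rather than a mechanistic rate law — the simulator makes
no kinetic claims.

What passing simulator-based tests does and does not show: recovery of an
injected δ under multiplicative noise demonstrates the pipeline's
correctness and the band's behaviour under the stated noise model; it says
nothing about matrix effects, non-Gaussian or heteroscedastic instrument
noise beyond the CV model, plate spatial effects, or chemistry-level
interactions, none of which are modelled.

## Problem sizes

Default test and acceptance runs use the full published dataset (10
compounds, 2 × 26 mixtures, 208 mixture measurements), 200-seed Monte-Carlo
recovery for the δ = 30 experiment, 1000 simulated binary mixtures for the
null-band calibration, 10⁵ draws for the delta-method oracle, and 1000
random instances for the equation-equivalence oracle.

## Degenerate inputs and tie-breaks

* Mixture identity is order-independent; joins use the sorted component-id
  label, display labels preserve source order. Duplicate individual
  measurements for one (compound, assay, concentration) are averaged with a
  warning.
* Zero-variance activity in the linearity check returns r = 0 with a
  `degenerate` flag instead of raising, so panel sweeps never abort;
  zero-variance features in the rank-correlation table likewise report 0.
* Enumeration of k-subsets is ordered k ascending, then lexicographically
  within k.
* `mean ± 0` published rows are stored as printed (one such SD is likely a
  typo in the source, which is recorded, not corrected).

## Known limitations

* The additive expectation inherits the linearity assumption; no
  C/k-measurement alternative is implemented.
* Only counts/indicator structural features are encoded; positional
  electronic effects, hydrogen bonding and dissociation are outside what the
  tabulated substituent data can support.
* The Loewe/Bliss/Chou–Talalay family of combination indices is out of
  scope; only the expected-additivity percent difference is implemented.
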