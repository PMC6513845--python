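# Methods

## Scope and model structure

`pahrisk` implements a chain of four estimators for inhalation exposure to
PM2.5-bound PAHs, each consuming the previous one's output:

1. **TEQ** — a deterministic, linear congener-weighted sum. TEF schemes are
   data, not code: the shipped default is the Nisbet–LaGoy relative-potency
   set, and the dibenz(a,h)anthracene factor — which the literature gives as
   either 1 or 5 — is an explicit constructor argument (`dba_tef`, default
   1.0) rather than a hard-coded constant.
2. **Daily intake** — `DI = TEQ·IR·ET/24` per Monte-Carlo iteration, in
   ng/day when TEQ is in ng/m³.
3. **ILCR** — the product formula
   `TEQ_pg·IR·CF·ED·ET·EF·CSF/(BW·AT)`. Concentrations are carried in
   ng/m³ end-to-end; the pg-based formula is honoured by a single ×1000
   conversion paired with the CF default of 10⁻⁹ mg/pg, both living in one
   constants block (`risk.py`). AT is in hours; a `with_at_years`
   constructor converts explicitly so year/hour confusion fails loudly
   rather than silently scaling risk by 24.
4. **Sensitivity / uncertainty** — partial correlations of the retained
   per-iteration input draws with ILCR, and a nested (two-dimensional)
   Monte-Carlo analysis of the CSF truncation bound.

### Statistical assumptions

* TEQ is lognormal across sampling days. When a raw TEQ series is available
  the spec is fitted by log-scale MLE (mean and n−1 SD of the logs); when
  only a published arithmetic mean ± SD exists, by moment matching
  (σ² = ln(1 + sd²/mean²), μ = ln mean − σ²/2). Both paths are exposed
  (`fit_lognormal`, `lognormal_from_moments`); the pipeline fits seasonal
  specs seasonally and annual specs on the pooled year.
* ET is normal, truncated to the physical support [0, 24] h/day.
* CSF is lognormal with GM 3.14 (mg/kg·day)⁻¹ and GSD 1.80.
* BW is stochastic (truncated normal) only for children; adult body weight
  enters as a point value.
* Inputs are mutually independent — no copulas or rank correlations. This
  mirrors standard practice for screening-level inhalation assessments and
  keeps the product-of-lognormals closed form available as a test oracle.

### Numerical choices

* **Truncation by rejection resampling**, never clipping: clipping creates
  probability atoms at the bounds and biases tail percentiles, which are the
  headline statistics here. Degenerate specs whose point mass lies outside
  the bounds are rejected at construction; resampling aborts after 1000
  rounds rather than hanging on near-empty acceptance regions.
* **Percentiles** use the type-7 (linear-interpolation) rule everywhere —
  `numpy`'s default — fixed and documented because the 95th-percentile ILCR
  is the decision quantity.
* **Seeding**: one master integer seed expands into named substreams via
  `numpy` `SeedSequence(seed, spawn_key=(stream_id,))` with a fixed
  variable→id registry (TEQ=0, ET=1, CSF=2, BW=3, …). Adding a stochastic
  variable to a model therefore never perturbs another variable's draws, and
  identical (spec, n, seed) triples give identical bytes across runs and
  platforms. The pipeline derives one integer sub-seed (< 2³¹) per stratum
  from the master seed and a CRC of the stratum labels.
* **Risk-band boundaries** 10⁻⁶ and 10⁻⁴ are assigned to the middle
  ("potential") band, i.e. acceptable is strictly below 10⁻⁶ and concern
  strictly above 10⁻⁴.

### Sensitivity analysis

Partial correlation is computed by residual regression: each input and the
ILCR output are regressed (with intercept) on the remaining inputs and the
Pearson correlation of the residuals is reported. Constant columns yield
NaN with a warning and are excluded from the control set. The default input
set is TEQ/ET/CSF, plus BW when the group draws it (children), matching how
the assessment is stratified. A `transform` switch offers raw (default),
rank, and log variants: the literature rarely states which scale was used,
so the choice is auditable rather than buried. On the log scale the product
structure makes ILCR exactly linear in the inputs, which the test suite uses
as an internal consistency oracle (coefficients ±1 up to truncation).

### Two-dimensional Monte-Carlo analysis

The CSF source distribution is reported without its upper truncation point.
The 2-D MCA draws 100 truncation multipliers k by Latin hypercube sampling
from U(2, 4) (one draw per equal-width stratum, order randomized), truncates
the CSF lognormal at exp(ln GM + k·ln GSD), and runs the 10,000-iteration
variability loop for each k. All outer iterations share the same inner
substreams (common random numbers), so the spread of the hundred
95th-percentile ILCR values — summarized as their 2.5th–97.5th percentile
interval — reflects truncation uncertainty alone, not inner-loop noise. A
collapsed k-range consequently yields an exactly zero-width interval, which
is asserted in the tests.

## Synthetic data generator

The generator emulates one year of urban monitoring: `n` sampling days per
season (dated within the 10th–16th monitoring window of each month),
16 congeners per day, independent lognormal day-to-day variability with a
common GSD (default 1.8), seasonal multiplicative factors
(winter 2.2 > spring = autumn 1.0 > summer 0.7), and a winter-only
multiplicative enrichment (1.3) of 4–6-ring congeners. Five city profiles
(HZ, JH, LS, NB, ZS) scale a common baseline so annual totals span roughly
7–18 ng/m³ with the JH ≈ HZ ≈ LS > NB ≫ ZS ordering. With these defaults the
expected winter/summer total ratio is ≈3.9 (inside the observed 1.7–5.0
band) and the expected winter 4–6-ring share ≈0.87 (inside 84–92%).

The exposure-survey generator draws truncated-normal outdoor exposure times
per respondent, with per-city means inside the observed adult
(2.1 ± 1.7 … 5.9 ± 2.6 h/day) and child (2.9 ± 0.7 … 7.0 ± 4.1 h/day)
ranges, and body weights from handbook-like values.

What the generator does **not** emulate: day-to-day meteorological
autocorrelation, gas-phase partitioning, below-detection censoring patterns,
inter-congener correlation beyond the shared seasonal factor, and city-level
differences in congener composition. A green calibration test therefore
establishes that the pipeline reproduces the assumed seasonal/compositional
structure — not that the defaults describe any particular city. Likewise the
default exposure factors (IR, ED, EF, AT, BW) are documented placeholders:
the pipeline refuses to run without an explicit population config (a YAML
path or the literal `defaults`), so placeholder numbers can never enter an
analysis silently.

## Below-detection handling

The measurement layer carries a `below_detection` flag and optional
detection limit per row. Substitution is a named policy — `half_lod`
(default), `zero`, or `lod_over_sqrt2` — applied explicitly
(`apply_detection_policy`), never inside the readers, so the raw reported
values round-trip losslessly through CSV.

## Design decisions that were genuinely open

* Diagnostic ratios are computed on group-mean concentrations, not as means
  of per-sample ratios (ratio-of-means is the convention when one ratio per
  city is reported, and it is robust to near-zero per-sample denominators).
* Source consensus is a majority vote over the classified ratios with
  "mixed" on ties; undefined (zero-denominator) and unclassified values
  abstain.
* Season aggregation is unweighted over sampling days.
* The exposure-time point value 24 h/day is admitted (full-day comparison
  scenarios) even though survey means must lie strictly inside (0, 24).

## Known limitations

* Inhalation route only — no dermal or ingestion pathways, no indoor
  exposure, no gas-phase PAHs; estimates are therefore biased low for total
  exposure.
* Independence of inputs is assumed, not tested.
* The default TEFs, ratio thresholds and exposure factors are literature
  stand-ins; published city-level DI/ILCR magnitudes are reproducible only
  with the original survey factors, so the package's tests verify structure
  (orderings, signs, bands, closed-form oracles) rather than those
  magnitudes.
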