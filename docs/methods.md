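# Methods

This note documents the models, conventions, numerical choices and
limitations behind each analysis stage of `dcstoich`.

## SEC-MALS slice model

Each elution slice carries three detector channels: differential
refractive index (dRI), absorbance at 280 nm (A₂₈₀) and a
light-scattering signal (LS).  The inversion chain is

1. **Concentration.**  c = dRI / (dn/dc), with the protein refractive-
   index increment dn/dc = 0.185 mL/g.  Units: dRI is dimensionless, c
   in g/mL internally; molar outputs convert via g/mL → g/L → mol/L with
   the slice molar mass.
2. **Molar mass.**  The zero-angle, zero-virial scattering relation
   LS = K·c·M is used instead of a full angular (Zimm) fit: the
   complexes are treated as point scatterers, so only the product
   K·c·M is observable.  K is a single instrument constant shared
   between the synthetic generator and the analyzer; it carries no
   physical calibration here and cancels in every round trip.
3. **Molar extinction coefficient.**  Beer–Lambert gives
   ε (L g⁻¹cm⁻¹) = A₂₈₀ / (l·c); multiplying by the slice molar mass
   converts to M⁻¹cm⁻¹.

**Peak summaries.**  Over the peak window,
Mw = Σ cᵢMᵢ/Σ cᵢ, Mn = Σ cᵢ/Σ(cᵢ/Mᵢ), Đ = Mw/Mn (≥ 1 by Cauchy–
Schwarz, with equality iff the peak is monodisperse; both averages are
invariant under uniform rescaling of the concentrations).  ε is
summarized as mean ± 1 SD across valid slices; confidence multipliers
(1.96 for a 95% window) are applied downstream by the enumerator.  The
SD is the population SD across slices — vendor software reports a
proprietary uncertainty for Mw/Mn that cannot be reproduced, so the
slice SD stands in for it and only enters through the ε window.

**Degenerate slices.**  Slices with c below a floor (default 10⁻⁹ g/mL)
are excluded from all averages: at peak edges the division by c in the
mass and ε formulas is numerically unstable.  Excluded slices are
logged, never silently dropped from the input table.

**Input concentrations.**  c = A₂₈₀ / (ε̄·l) converts an input-sample
absorbance into a molar concentration using the peak-mean molar ε.
Because complex composition is concentration dependent, ε̄ itself drifts
with concentration; the estimate inherits that systematic uncertainty.

## Stoichiometry enumeration

A candidate complex is an integer vector
(n_APC, n_AXIN1, n_CK1α, n_GSK3β, n_βcat), each ≥ 1.  Its mass and ε
are count-weighted sums over the component table.  Feasibility requires
mass and ε inside mean ± ci·SD windows (ci = 1.96 default) plus the
binding-site rules:

- **AXIN1 minimum**: ≥ 2 for wild type (AXIN1 polymerizes via its DIX
  domain and polymerization dominates complex size), ≥ 1 for the
  polymerization-deficient M3 mutant.
- **AXIN1 per APC**: n_AXIN1 ≥ n_APC (every APC engages at least one
  AXIN1 through its three SAMP repeats).  The 3-per-APC cap is enforced
  **only for M3**: wild-type AXIN1 can chain beyond direct SAMP
  attachment, whereas M3 AXIN1 can only be scaffold-attached.
- **Kinase occupancy**: ceil(n_AXIN1/2) ≤ n_kinase ≤ n_AXIN1 for each
  kinase species (at least 50% occupancy, integer molecules round up;
  at most one site per AXIN1 per kinase).
- **β-catenin lower bound**: at least one per AXIN1 and per APC.  A
  single β-catenin can simultaneously engage an AXIN1 site and an APC
  repeat, so the default bound is max(n_AXIN1, n_APC); the stricter
  additive reading (n_AXIN1 + n_APC) is available via
  `bcat_lower_rule="sum"`.
- **β-catenin upper bound**: n_AXIN1·1 + n_APC·10 (ten usable 15R/20R
  repeats; one repeat does not bind) **plus one per vacant kinase site**
  — Σ(n_AXIN1 − n_kinase) — since an unoccupied kinase site on AXIN1
  can hold an extra β-catenin instead.

**Algorithm.**  Depth-first loops in the order (APC, AXIN1, kinases,
β-catenin), bounded per component by floor(mass upper bound / component
mass) and pruned on the partial mass plus the minimal mass of the
remaining components; every surviving leaf is re-checked by
`check_conditions`, which remains the single source of truth (the
pruning is an optimization, not a second rule set).  The traversal emits
entries in lexicographic order, so results are deterministic and
independent of internal loop organisation.  The test suite proves
equivalence with an independently coded brute-force quintuple loop on
randomized component tables and checks that widening the confidence
multiplier never shrinks the set.

**Cross-variant pairing.**  At each (n_APC, n_AXIN1) pair present in
both the wild-type and M3 feasible sets, M3 entries with
n_βcat > max(wild-type n_βcat) − 1 are dropped (the wild-type complex
carries at least one more β-catenin, and M3 may not exceed it).  The
pair is matched on exact counts; matching on the AXIN1:APC *ratio* is a
defensible alternative but is not implemented.  Pairs without a
counterpart in the other set are retained unchanged.

**Component table.**  Default masses: APC 312 kDa, AXIN1 92 kDa, CK1α
39 kDa, GSK3β 47 kDa, β-catenin 85 kDa.  The default ε values are
synthetic placeholders at typical protein absorptivity (A₂₈₀ of a 1 g/L
solution between 0.8 and 1.1 per protein); for real work compute ε from
sequence with the Gill–von Hippel calculator
(`extinction_coefficient_280nm`: 5500·W + 1490·Y (+125 per cystine))
and supply your own table.

## Kinase kinetics

- **Standard curve**: least squares through the origin (zero radiolabel
  gives zero signal after background correction; a free-intercept fit is
  available via `through_origin=False`).  The spot amounts default to
  the two-fold dilution series 12.5 … 0.195 pmol.
- **Initial rates**: OLS slope of product (pmol) vs time, free
  intercept, time points {0.5, 1, 2, 5} min; t = 0 is not a fit point.
  The design assumes the initial-rate regime (product linear in time).
- **Michaelis–Menten fit**: `scipy.optimize.curve_fit` on
  v₀ = Vmax·[S]/(K_M+[S]) with non-negative bounds, p₀ = (1.2·max rate,
  median [S]); parameter SEs from the fit covariance.  kcat = Vmax/[E_T]
  with [E_T] an *amount* in pmol (convention: the full 6 μL × 150 nM
  kinase-complex load, 0.9 pmol, stands in for the unknown active-kinase
  amount, so kcat values are lower bounds tied to that convention).
- **Saturation heuristic**: the titration is declared non-saturating
  when v(S_max) / v(S_max/2) ≥ 1.8 (2.0 is exactly linear; 1.8
  corresponds to S_max ≈ K_M/4; the half-point rate is linearly
  interpolated from the measured rates).  In that case Vmax, K_M and
  kcat are reported as undetermined and kcat/K_M comes from a linear
  regression of rate on [S] (free intercept), with its SE from the
  regression.  This is a repository convention — the heuristic threshold
  is not a measured quantity.
- **Error propagation**: δ(x/y) = (x/y)·sqrt((δx/x)² + (δy/y)²),
  first-order and adequate for small relative errors; the tests verify
  agreement with Monte-Carlo sampling to two significant figures at
  2–4% relative error.

Under the default study conditions (eight-point ATP titration
0.78–200 μM, K_M = 50 μM, four time points, 2% multiplicative signal
noise, single replicate per point), 200 seeded simulations give a median
relative error of ≈2.7% for kcat and ≈5% for K_M — K_M is the weakly
determined parameter of this design, since only three concentrations
flank it.  Replicates or a denser mid-range grid would tighten it; the
defaults deliberately mirror the sparse experimental design rather than
an idealized one.

## Mass photometry

- **Calibration**: least-squares line mapping contrast to mass on the
  66/146/480/1048 kDa standards, free intercept by default (the vendor
  convention is unknown; `through_origin=True` switches).
- **KDE**: Gaussian kernel with a *fixed* 25 kDa bandwidth — no
  rule-of-thumb selection — evaluated on a 1 kDa grid spanning
  [0, max mass + 4 bandwidths], covering the ≈3 MDa range relevant for
  polymerized complexes.  The kernel sum is formed directly because
  scipy's `gaussian_kde` parameterizes bandwidth relative to the sample
  SD rather than absolutely.  The density is not renormalized after
  truncation at 0 kDa; for events more than ~3 bandwidths above zero the
  trapezoid integral deviates from 1 by far less than 10⁻³.
  Mode detection uses `scipy.signal.find_peaks` with a prominence floor
  of 5% of the global maximum.

## Synthetic data generators

The generators emulate the statistical structure the analyzers assume,
with ground truth stored beside the observations:

- **Chromatograms**: Gaussian elution profiles in volume (the simplest
  shape reproducing single-peak traces), channels formed by the forward
  physical relations, and multiplicative Gaussian noise per channel,
  independent across slices (detector noise scales with signal, and the
  multiplicative form keeps zero-noise round trips exact).  Not
  emulated: band broadening, inter-detector volume delay, second virial
  coefficient, baseline drift.
- **Photometry events**: categorical species mixture + Gaussian mass
  noise, converted to contrasts by inverting a known calibration line.
  No shot-noise physics, particle-detection thresholds or movie
  processing.
- **Kinase assays**: product(t) = v₀·t exactly (no substrate depletion
  or product inhibition), reported as spot signals through a known
  signal-per-pmol slope with multiplicative noise; the matching
  standard-curve table is emitted with the same noise level.

No instrument noise magnitudes are published for the real experiments,
so the default 2% relative noise is a free parameter chosen as a
realistic detector-class figure — passing recovery tests demonstrates
correctness of the inversion chain and reasonable robustness, not
calibrated performance on any particular instrument.

## Reproducibility

Every stochastic routine takes an explicit integer seed
(`numpy.random.default_rng`); the pipeline derives per-stage seeds from
the run seed by fixed offsets (mod 2³¹−1).  Pipeline outputs contain no
timestamps, so a fixed (config, seed) pair reproduces byte-identical
files; `provenance.json` records package and library versions, the seed
and a SHA-256 of the canonicalized config.

Problem sizes used by the test suite and the acceptance script — 150-
slice chromatograms, 200-seed recovery ensembles, 100 randomized
enumeration tables, 5,000 photometry events, 10⁶ Monte-Carlo draws —
were chosen as the smallest sizes at which the statistical checks are
stable.

## Known limitations

- The zero-angle scattering model ignores angular dependence; for
  multi-MDa complexes a real Zimm fit would differ at large radii.
- ε-window feasibility inherits the synthetic placeholder ε values in
  the default table; conclusions about real complexes require
  sequence-derived ε.
- The enumerator treats binding sites as saturable and independent; no
  geometry, cooperativity or affinity modeling.
- Kinetics assumes a single homogeneous enzyme species and no competing
  substrates; kcat is conditional on the [E_T] amount convention.
- `polyubiquitylated_fraction` consumes already linearized,
  background-corrected lane signals; gel image processing is out of
  scope.
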