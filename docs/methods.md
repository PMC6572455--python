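# Methods

## Data model and record filters

The pipeline consumes two point tables per study: cases (service users)
and providers, each carrying an administrative-area code and coordinates —
planar metres (`projected_m`, Euclidean distances) or lon/lat degrees
(`lonlat`, haversine on a 6 371 000 m sphere). Two filters precede any
spatial work:

* institutional residents are excluded (only community dwellers travel to
  community providers);
* providers are deduplicated to one record per exact coordinate pair, the
  first record in input order surviving. Equality is exact float equality,
  with no tolerance: the duplication this removes is several services
  registered at one address, which geocode to bit-identical coordinates.

Every filter emits a report with `n_input = n_excluded + n_retained`
enforced at construction.

## Needs stratification

WHODAS 2.0 (36-item) domain scores are accepted directly or computed from
the 32 retained item responses (the four work/study items dropped) by
simple sum-and-rescale scoring: each domain and the summary mapped to
0–100, higher = more disabled. The high-level-of-need group is defined by
strict conjunctive cutoffs — cognition > 77.5, mobility > 78.5, self-care
> 55 and summary > 66.5. All four must be exceeded; the conjunctive rule
is the only reading that makes the two groups exhaustive and disjoint, and
it is configurable (`combine="any"`) for sensitivity analysis. The
mobility cutoff is 78.5 by default; 78 (a variant that appears in some
tabulations of the same screen) can be set through `NeedsCutoffs`.

## Distance curves

Each case is matched to the nearest provider in its own area (ties broken
by smallest provider id; a KD-tree accelerates large areas and is
exhaustive-scan equivalent up to the identity of exactly tied providers).
Cross-area matching is off by default and available as a sensitivity
switch. Nearest distances are binned into half-open intervals
[k·w, (k+1)·w) anchored at 0, with w = 50 m by default; a distance exactly
on an edge falls in the upper bin. Cases in provider-less areas are
reported separately and their areas classify as "neither".

Straight-line distance is a deliberate simplification; travel time would
be preferable in dense urban areas. The distance column is abstract, so
externally computed travel times can be substituted without code changes.

## Joinpoint model

The binned frequency y over bin-midpoint distances x is fitted by

y(x) = β₀ + β₁x + Σᵢ γᵢ (x − τᵢ)₊

which is continuous by construction. The *frequency* (not the cumulative
count) is the modelled response: the indicator definitions require slopes
that change sign, which a cumulative curve cannot do.

Numerical choices:

* **Candidate grid.** Breakpoints are restricted to the half-bin grid —
  bin midpoints plus interior bin edges. Including the edges lets a peak
  that sits exactly on a bin boundary (e.g. 300 m with 50 m bins) be
  recovered with zero residual; with midpoints only, every such fit would
  carry an irreducible bias of half a bin. Grid search is exhaustive, so
  the fit is the global least-squares optimum on the grid and fully
  deterministic.
* **Minimum segment length** 3 data points per segment (standard joinpoint
  practice; prevents two-point segments with undefined error).
* **Model selection.** Default: sequential permutation testing in the NCI
  style — to test k vs k−1 joinpoints, residuals of the k−1 fit are
  permuted, re-added to its fitted values, both models refitted per
  permuted series, and the observed statistic (RSS_{k−1} − RSS_k)/RSS_k
  compared with its permutation distribution; p = (1+#{T* ≥ T})/(B+1).
  Testing walks k = 1, 2, … up to `k_max` (default 4) and stops at the
  first non-rejection at α = 0.05. The BIC alternative minimises
  n·log(RSS/n) + p·log(n) with p = 2 + 2k (intercept, base slope, and one
  slope change plus one location per joinpoint). RSS values below 1e−10
  are floored to keep ratios finite on numerically exact fits.
* **Per-joinpoint significance** is a two-sided test of the slope change:
  by residual permutation with the joinpoint under test removed (other
  joinpoints held fixed), or a t-test on its coefficient under the BIC
  path. These p-values are computed after model selection on the same
  data, so they are selection-conditioned screening values, not
  family-wise-exact — acceptable here because they only gate indicator
  extraction.
* An all-constant curve short-circuits to k = 0 with a note; empty or
  too-short curves (fewer than 6 bins by default) yield no indicators.

## Indicators, zones, ranking

PWD = first significant joinpoint with slope + → −. TLD = first
significant joinpoint with slope − → + *after the PWD* when a PWD exists;
a trough preceding the supply peak is not a tolerance bound, and this
ordering guarantees TLD > PWD whenever both exist. Reported values are
rounded to the nearest multiple of the bin width (ties upward), matching
the 50 m resolution the curve was measured at.

Zones for individual user locations use inclusive upper bounds: d ≤ PWD is
profitable, PWD < d ≤ TLD tolerable, d > TLD beyond tolerance. In an
only-PWD area a distance beyond the PWD has no defined zone and is flagged
(`None`) rather than guessed.

Service density is cases per provider, rounded to 2 decimals for
reporting; undefined (None) when an area has no providers.

Priority ranking: only-TLD areas first (descending TLD), then both
(descending TLD), then only-PWD, then neither; ties broken by higher
density ratio, then area code. The tie-breaks beyond the tier/TLD rule are
this package's choice, made so the ordering is total and reproducible.

## Synthetic data

The generators stand in for a non-public national registry and are pure
functions of (spec, seed):

* `gen_frequency_curve` evaluates a piecewise-linear specification at bin
  midpoints, adds Gaussian noise, floors at zero and rounds to integers.
* `gen_area_points` places each case at a distance sampled from the binned
  target density (uniform within the bin) and a uniform bearing around a
  randomly chosen provider. Providers are kept at least twice the curve
  extent (n_bins × bin width) apart — slightly stronger than twice the
  largest breakpoint, because sampled distances can exceed that breakpoint
  — which guarantees the anchor provider is the true nearest neighbour, so
  the empirical nearest-distance curve reproduces the target up to
  multinomial sampling error. The price is unrealistically sparse,
  well-separated supply; clustered or overlapping provider neighbourhoods
  (normal in real cities) are *not* emulated, so passing recovery tests
  demonstrates correctness of the detection machinery, not robustness to
  interacting catchments.
* `gen_whodas_cohort` draws domain scores from a two-component
  truncated-normal mixture. The high-need component is truncated strictly
  above every cutoff and the general component strictly below the
  cognition cutoff, so generated labels are recovered exactly by
  stratification and the observed high-need fraction is binomial(n,
  p_high). Component moments echo a community dementia cohort (high-need
  domain means in the 90s, general demand in the 40s–70s); real score
  distributions are skewed and item-correlated in ways the mixture does
  not model.

Default study sizes used by the tests and the acceptance script — 2 000 to
4 000 cases per area, 40-bin curves, 199 permutations, 200 Monte-Carlo
replicates for recovery and type-I studies — were chosen as the smallest
sizes at which the breakpoint estimates concentrate within one bin and a
rate estimate has a usefully narrow binomial band.

## Known limitations

* Within-area matching ignores providers just across a boundary; the
  cross-area switch exists but reassigning supply between areas is out of
  scope.
* Straight-line distance, not travel time.
* Sparse curves (small areas or thin high-need strata) legitimately yield
  "neither"; that is an absence of evidence for the indicators, not
  evidence that services are adequate.
* Per-joinpoint p-values are selection-conditioned (see above).
* The published 22-area table bundled in `careaccess.published` is
  area-level only; case-level indicator values cannot be recomputed from
  it, and the reporting half of the pipeline is validated against it while
  the detection half is validated on synthetic ground truth.
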