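# careaccess

Joinpoint-based spatial accessibility indicators for planning health and
social care resources — built around dementia care, where the question is
not only *how many* providers an administrative area has, but *how far*
its service users must travel and how far providers are willing to reach.

The package is aimed at health-services researchers and planners who have
point locations of service users and providers per administrative area
(plus, optionally, WHODAS 2.0 functioning scores to stratify users by
acuteness of need) and want a defensible priority ordering of areas for
setting up new services.

## The method

For each administrative area, every service user is matched to the nearest
provider **within the same area** and the nearest distances are binned at
50 m into a frequency curve. The curve's typical shape is rise–fall–rise:
counts climb while supply is dense, fall past the range providers willingly
serve, and climb again where users must resort to remote providers. The
curve is modelled by continuous piecewise-linear (joinpoint) regression

```
y(x) = β₀ + β₁·x + Σᵢ γᵢ·max(0, x − τᵢ),   τ₁ < … < τ_k
```

with the number of joinpoints *k* chosen by a sequential Monte-Carlo
permutation test (or BIC) and each slope change γᵢ tested for
significance. Two indicators are read off the selected fit:

* **PWD** (profit willing distance) — the first significant joinpoint
  where the slope turns from positive to negative (the supply peak):
  within this distance providers willingly deliver services.
* **TLD** (tolerance limited distance) — the first significant joinpoint
  after the peak where the slope turns from negative to positive: beyond
  it, services are effectively out of users' tolerable reach.

Areas are classified by indicator presence (both / only-PWD / only-TLD /
neither) and ranked for allocation priority: only-TLD areas first (demand
exists but no willing-supply band), larger TLD first; then areas with both
indicators by descending TLD; then only-PWD; then neither. Cohorts are
analysed in three strata — all users, general demand, and high level of
need (WHODAS 2.0 cognition > 77.5, mobility > 78.5, self-care > 55 and
summary > 66.5, all strict).

## Worked example

Case-level registry data of this kind are not public, so the package ships
seeded generators with known ground truth. The snippet builds one area
whose nearest-distance curve has breakpoints at 300 m and 1500 m, then runs
the full pipeline:

```python
from careaccess import AreaSpec, gen_registry, PipelineConfig, run_pipeline

providers, cases = gen_registry([AreaSpec("A01", n_providers=5, n_cases=4000)], seed=1)
cfg = PipelineConfig(method="permutation", n_perm=199, k_max=3, seed=1)
res = run_pipeline(cfg, cases=cases, providers=providers)

r = res.results["all"][0]
print(r.area_code, r.pwd, r.tld, r.category.value)   # A01 300.0 1550.0 both
print(res.group_counts)  # {'all': 4000, 'general_demand': 2694, 'high_level_of_need': 1306}
fit = res.fits[("A01", "all")]
print(fit.k, fit.breakpoints, fit.p_values)  # 2 (300.0, 1525.0) (0.005, 0.005)
```

The fitter finds two significant joinpoints: the supply peak exactly at
300 m (the PWD) and the trough at 1525 m, reported as TLD = 1550 m after
rounding to the 50 m bin grid — one bin from the generator's 1500 m truth,
which is the expected resolution at this sample size. The area therefore
classifies as "both", i.e. it has a willing-supply band and a measurable
tolerance limit.

The same workflow is available from the shell
(`careaccess simulate | join | curve | fit | indicators | rank | all`), and
the numbered scripts under `analysis/` walk through the full study: a
four-area synthetic registry (one area provider-less), needs
stratification, distance curves, joinpoint fits, and the priority ranking,
plus a re-analysis of the bundled published 22-area table for Taiwan
(`careaccess.published`) reproducing its service densities, category
counts and priority ordering.

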