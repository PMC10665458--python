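# Methods

## Model structure and assumptions

`pulseflow` is a linearized ("impulse-response") climate model of the kind
used to define GHG emission metrics.  It assumes the perturbations of
interest are small enough that atmospheric decay, radiative forcing and the
temperature response are all linear and time-invariant, so any emission
path can be built by superposing pulses.  There is no coupled ocean or
carbon-cycle nonlinearity, no aerosols, and no scenario database; results
for sector-scale aggregates (hundreds of Mt per year) should be read as
order-of-magnitude statements, which is all the offset-feasibility question
requires.

Three gases are modelled:

| gas | decay | effective radiative efficiency |
|-----|-------|-------------------------------|
| CO₂ | `a₀ + Σ aᵢ e^(−t/τᵢ)` with a₀ = 0.2173, (aᵢ, τᵢ) = (0.2240, 394.4 yr), (0.2824, 36.54 yr), (0.2763, 4.304 yr) — the Joos-type fit used for AR6 metrics | 1.709·10⁻¹⁵ W m⁻² kg⁻¹ |
| CH₄ | e-folding lifetime 11.8 yr | 1.364·10⁻¹³ × 1.503 (tropospheric O₃ + stratospheric H₂O) W m⁻² kg⁻¹ |
| N₂O | e-folding lifetime 109 yr | 4.09·10⁻¹³ × 0.88 (net of the induced CH₄-lifetime reduction) W m⁻² kg⁻¹ |

Temperature follows a two-box kernel `Σⱼ (cⱼ/dⱼ) e^(−t/dⱼ)` with
c = (0.454, 0.309) K (W m⁻²)⁻¹ and d = (8.4, 409) yr: a fast mixed-layer
response and a slow deep-ocean response, summing to 0.763 K (W m⁻²)⁻¹
(equilibrium climate sensitivity ≈ 3.0 K at 2×CO₂, the AR6 central value).
The slow timescale makes temperature lag forcing, which is why the warming
from a CH₄ pulse stays above that of an equal CO₂ pulse for several
centuries (crossover around year 800 with the default parameters) even
though the forcing curves cross within decades.

**Carbon-cycle feedback.** Warming releases carbon from land and ocean.
For CH₄ and N₂O this is represented as an additional forcing proportional
to the gas's direct-forcing-induced warming, `F_cc(t) = β·T_direct(t)` with
β = 0.15 W m⁻² K⁻¹ — equivalent to a quasi-equilibrium release of roughly
24 GtC per kelvin converted at the CO₂ efficiency, within the range of
published climate–carbon feedback estimates.  The formulation makes the
feedback track the warming (release while warm, reuptake as the
perturbation fades), giving CH₄ a realistic slow forcing tail: ~2.8·10⁻⁴
nW m⁻² per tonne at year 100, two decades' worth of direct forcing after
the gas itself is gone.  CO₂ carries β = 0 because the airborne-fraction
fit above already embeds the feedback.  The term can be switched off per
call (`include_feedback=False`), which is also how the single-lifetime
plateau identities are tested, since they hold for the direct term only.

**Biogenic CH₄.** Ruminant methane is biogenic: the CO₂ produced by its
oxidation was recently fixed from the atmosphere, so no oxidation term is
added.  The flag is carried per gas in the config for users modelling
fossil CH₄.

## Calibration of the bundled defaults

The exact coefficient set of this model family is not standardized, so the
bundled YAML makes a documented choice: lifetimes, the CO₂ response and the
direct efficiencies are AR6 central values; the indirect multipliers and β
are set within published uncertainty so that the implied GWP-style
integrals stay AR6-consistent (biogenic CH₄ GWP₁₀₀ ≈ 29, N₂O ≈ 282, both
well inside the assessed uncertainty ranges) and
the per-tonne forcing anchors of the three gases (≈0.0017, ≈0.2 and
≈0.36 nW m⁻² in year one) are met.  The two-box timescales follow the
classical AR5-era fit, rescaled to ECS 3.0 K; the TC-based conversion
ratios are sensitive to the slow timescale (a much shorter deep-ocean
memory would inflate them), which this choice keeps consistent with the RF
ratios.  Every number is read from `pulseflow/data/climate_params.yaml` at
run time and can be edited; output files embed a hash of the parameter set.

## Discretization and numerics

- Annual grid by default, values at year-ends (`t = 1` is "year one");
  horizons up to 1000 years.  A finer `step_years` is supported and used in
  tests to bound the quadrature error (the annual rectangle integral of the
  CO₂ pulse forcing agrees with a 0.1-yr trapezoid integration within 1%).
- Emissions are placed at **mid-year**.  This makes a continuous flow —
  the exact superposition of one annual pulse per year, implemented as a
  cumulative sum — reproduce the analytic plateau
  `rate × efficiency × lifetime` of a single-lifetime gas to within 0.05%,
  while start-of-year pulses would bias it by ~4% for CH₄.
- The temperature convolution uses the exact integral of the kernel over
  each step, so a sustained forcing `F` converges to exactly
  `F·Σcⱼ(1 − e^(−t/dⱼ))` with no discretization drift.
- Degenerate inputs are defined: zero mass/rate gives identically zero
  series; horizon 0 gives zero cumulative impact; negative masses, unknown
  gases, off-grid horizons and mismatched inventories raise typed errors.

## The pulse–flow equivalence

The conversion ratio compares the impact of a continuous 1 t/yr flow of
CH₄ or N₂O with the impact of a 1 t CO₂ pulse **evaluated at the same
horizon H** (default `basis="endpoint"`).  The end-point reading asks "is
the warming pressure at year H the same?", which is the natural criterion
for offsetting a stabilized flow with a permanent removal, and it is the
reading under which the ratio grows steeply with H for the long-lived N₂O
(≈36 kt at H=100 vs ≈89 kt at H=500 per t/yr) and gently for CH₄ (less
time-varying).  A `basis="cumulative"` variant integrates impact over
[0, H] instead; it weights the pulse's strong early benefit and therefore
returns smaller ratios (≈2.4 kt for CH₄/RF at H=100).  Both are computed;
end-point is the default and is what all downstream accounting uses.
Continuous CO₂ is excluded by contract: its impact accumulates without
bound and no finite one-off removal is equivalent to it.

A 100-year horizon is the accounting default: soils typically reach their
new SOC equilibrium within a century, CH₄ forcing plateaus well within it,
and it matches the most common metric horizon.  The choice flatters
sequestration — ratios only grow beyond H=100.

**Sequestration timing.** Accounting treats the removal as a year-one
pulse.  Three profile shapes quantify the error of that convention for
equal total carbon: a year-one pulse, a constant-rate ramp, and an
exponential approach to equilibrium (e-folding time = duration/4).  A
20-year ramp changes the century-scale cumulative forcing benefit by under
10%, supporting the convention.

**Ordering under a capacity cap.** When a region's sequestration capacity
cannot cover everything, capacity is allocated to CH₄ first and N₂O gets
the residual: CH₄ dominates ruminant emissions and its flow stabilizes
fastest, making its pulse-flow equivalence the most robust.  The
allocation conserves capacity exactly.

## Synthetic inventories

The regional livestock-emission and grassland-SOC databases the analysis
would ideally use are access-restricted, so `generate_inventories` builds a
**synthetic emulation**: 11 world regions whose global sums are pinned
exactly to the published sector totals (110 Mt CH₄ yr⁻¹, 2.4 Mt N₂O yr⁻¹,
78 Gt SOC in managed grasslands), split regionally by a documented base
table (a South-Asia-like region dominating requirements with little
grassland, a stock-rich East-Europe-like region with few ruminants, cattle
carrying 75% of CH₄) and jittered by a seeded Dirichlet/lognormal draw
(concentration 3000, σ = 0.05 — tight enough that the regional structure is
stable across seeds; identical seeds give byte-identical output).  What
passing tests show: the accounting pipeline is exact (additive,
homogeneous, conserving) on inputs with realistic structure and exact
global totals.  What they do not show: agreement with the real regional
distribution, which the emulation does not claim to reproduce.

The Tier-1 constants are bundled as editable CSVs.  Enteric CH₄ emission
factors span the documented native range 41–138 kg head⁻¹ yr⁻¹ (display
lattice rounded to 40–160).  Grassland sequestration potential is computed
as `SOC_ref × F_grassland − SOC_ref × F_LU,crop × F_MG,full-till ×
F_I,low` — the stock difference between well-managed grassland and poorly
managed cropland — over six climate zones × three soil types; reference
stocks and factors are representative of the IPCC Tier-1 menus (2006
Guidelines / 2019 Refinement) and chosen so the table spans the documented
5–50 t C ha⁻¹ range, with the minimum at (tropical dry, sandy) and the
maximum at (cool temperate moist, high-activity clay).  They are inputs,
not outputs: users with the exact national tables should edit the CSVs.

## Known limitations

- Linearity: sector-scale aggregates stretch the small-perturbation
  assumption; use results as orders of magnitude.
- Constant emissions: herds are projected to grow, which would raise all
  requirements; no demographic module is included.
- Sequestration is treated as permanent once booked; reversal risk
  (disturbance, land-use change) is out of scope.
- Manure-management N₂O enters only through the generic per-region N₂O
  totals, not via a per-head factor derivation.
- No spatial mapping, economics, or mitigation-option modelling.
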