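# pulseflow

Can soil carbon sequestration in grasslands truly offset the greenhouse-gas
emissions of ruminant livestock?  Answering that requires comparing two very
different things: a **one-off, finite** removal of CO₂ into soil organic
carbon (SOC), and a **continuous stream** of short-lived CH₄ (enteric
fermentation) and long-lived N₂O emissions.  Conventional GWP accounting
masks the time profiles that make this comparison meaningful; `pulseflow`
makes them explicit.

The package is aimed at researchers in livestock systems and GHG accounting
who need transparent, auditable numbers for offset-feasibility analyses:
how much carbon a grassland must sequester to neutralize a herd's warming,
how many animals a hectare can "carry", and how regional requirements
compare with current SOC stocks.

## The model

A linearized climate model propagates an emission `E` of gas `x` through
three linear stages:

- **Atmospheric decay.** A pulse of CO₂ follows the multi-exponential
  impulse response `f(t) = a₀ + Σᵢ aᵢ e^(−t/τᵢ)` (Joos-type fit; a fraction
  `a₀` stays airborne practically indefinitely).  CH₄ and N₂O decay with
  single perturbation lifetimes (11.8 and 109 years).
- **Radiative forcing.** `F(t) = A_x · burden(t)`, with effective
  efficiencies `A_x` (W m⁻² kg⁻¹) including indirect chemistry effects,
  plus a temperature-driven carbon-cycle feedback term `β·T(t)` for CH₄ and
  N₂O (CO₂'s impulse response already embeds it).
- **Temperature.** `T(t) = ∫ F(s) Σⱼ (cⱼ/dⱼ) e^(−(t−s)/dⱼ) ds`, a two-box
  (mixed-layer + deep-ocean) kernel with equilibrium sensitivity 3.0 K.

A continuous flow is the superposition of one annual pulse per year: CH₄
and N₂O forcing plateaus (removal balances emission), while CO₂ forcing
grows without bound.  That asymmetry is the heart of the method: the impact
of a continuous CH₄/N₂O flow *at a horizon H* can be matched by a single
CO₂ removal in year one, giving the conversion ratio

```
R(x, H, metric) = impact(continuous 1 t/yr of x, at year H)
                  ----------------------------------------- ,
                  impact(pulse of 1 t CO₂, at year H)
```

in t CO₂ per (t gas yr⁻¹).  One tonne of soil C is 44/12 t CO₂, so a tonne
of sequestered carbon offsets `44/12·1000 / R` kg of gas per year over H.
All parameters (AR6-consistent defaults) live in an editable YAML file.

## Worked example

```
$ pulseflow convert --gas CH4 --metric rf --horizon 100
gas metric  horizon  co2_tonnes_per_tonne_yr  kg_gas_per_yr_per_tonne_c
CH4     RF      100               3718.06918                   0.986175
```

Offsetting the radiative forcing of a continuous 1 t/yr CH₄ stream over 100
years takes a one-off removal of ≈3.7 kt CO₂ — equivalently, one tonne of
soil carbon pays for ≈0.99 kg CH₄ per year.  For the more potent,
longer-lived N₂O the same query gives ≈36 kt CO₂ and ≈0.10 kg N₂O per year.

```
$ pulseflow density --potential 50 --ef 40
allowed density: 1.233 head per ha
```

In the most optimistic case (50 t C/ha sequestration potential, a frugal
40 kg CH₄/head/yr animal), one hectare of grassland carries about 1.25 head
of cattle — about 40 t of soil carbon per animal.  Realistic densities are
usually higher, which is the method's central warning.

```
$ pulseflow make-fixtures --seed 42 --out-dir fx
$ pulseflow offset --emissions fx/emissions.csv --grasslands fx/grasslands.csv \
      --horizon 100 --metric rf --out gaps.csv
wrote 12 rows to gaps.csv
```

`gaps.csv` lists, per region and globally, the required one-off
sequestration against current SOC stocks (`percent_increase` column).  On
the bundled 11-region emulation the needed stock increases span ≈26% (an
East-Europe-like region, large stocks and few ruminants) to ≈1900% (a
South-Asia-like region, ~34 Gt required over 60 Mha).  Globally, offsetting
110 Mt CH₄/yr plus 2.4 Mt N₂O/yr over a century requires ≈135 Gt C —
roughly 1.7× the 78 Gt held in managed grasslands today.  The fixtures are
a seeded synthetic emulation pinned to these global totals; the underlying
regional livestock/soil databases are access-restricted.

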