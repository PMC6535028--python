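# fluvial14c

Radiocarbon-based source apportionment of riverine organic carbon for the
large Siberian Arctic rivers (Ob, Yenisey, Lena, Kolyma).

Arctic rivers export both freshly fixed plant carbon and "preaged" organic
carbon released by thawing permafrost and degrading peat (PP-C). Because the
PP-C pools are old, their Δ¹⁴C signatures are strongly depleted relative to
recent primary production, and the ¹⁴C content of dissolved (DOC) and
particulate (POC) organic carbon becomes a fingerprint of permafrost carbon
remobilization. `fluvial14c` is aimed at isotope biogeochemists who want to
turn monitoring records of Δ¹⁴C and carbon flux into quantitative PP-C
export estimates and to ask how sensitive the fluvial ¹⁴C signal is to
future changes in PP-C release.

## The model

Each observation is a two-endmember mixture on the Δ¹⁴C scale,

    Δ_obs ~ Normal( f·Δ_pp + (1 − f)·Δ_rec , σ_obs ),    f ~ Uniform(0, 1)

where `f` is the PP-C mass fraction, Δ_rec the recent-production endmember
(+97.0 ± 124.8 ‰) and Δ_pp a *composite* PP-C endmember built per river and
scenario from up to three source pools — active layer (−197.5 ± 148.4 ‰),
Holocene deposits (−567.5 ± 156.7 ‰) and Pleistocene Ice Complex deposits
(−954.8 ± 65.8 ‰) — with all fractional pool combinations equally likely
(flat Dirichlet weights). Endmember variability is marginalised inside a
Metropolis–Hastings sampler by redrawing both endmember values every
iteration (defaults: 10⁶ iterations, 10⁴ burn-in, thinning 10).

Downstream, posterior fractions are combined with regression-based seasonal
DOC/POC load estimates (consumed as inputs, mean ± SD) by Monte Carlo to
give PP-C export fluxes, carrier-phase (DOC vs POC) shares and seasonal
shares; a sensitivity module converts a scaling `s` of the PP-C flux at
constant recent-carbon flux into the induced shift in bulk Δ¹⁴C via
`f′ = s·f / (s·f + 1 − f)` and finds the minimum resolvable change in PP-C
release with a flux-weighted t test.

Conventional radiocarbon ages use the standard convention: fraction modern
`F = (Δ/1000 + 1)·exp((y − 1950)/8267)` and age `= −8033·ln F`.

## Worked example

```python
import fluvial14c as f14

# endmember context for the Kolyma under the Best Estimate scenario
recent = f14.recent_pool()
ppc = f14.scenario_endmember("Kolyma", "best_estimate", n_draws=100_000, seed=1)
print(f"PP-C endmember: {ppc.summary_mean:.1f} ± {ppc.summary_sd:.1f} ‰ from {ppc.pools}")

# apportion a winter POC observation of -610 ‰
cfg = f14.MCMCConfig(iterations=100_000, burn_in=10_000, thinning=10, seed=2)
post = f14.apportion(-610.0, recent, ppc, cfg, obs_sd=10.0)
lo, hi = post.credible_interval()
print(f"PP-C fraction: {post.mean:.2f} ± {post.sd:.2f} (95% CI {lo:.2f}-{hi:.2f})")

# conventional age of the observation
age = f14.delta14c_to_conventional_age(-610.0, collection_year=2010)
print(f"conventional age: {age:.0f} y BP")

# sensitivity: doubling PP-C release, western endmembers
west = [p for p in f14.default_pools() if p.name in ("active_layer", "holocene_deposits")]
mean_pp, _ = f14.composite_moments(west)
ms = f14.max_shift(2.0, recent.delta14c_mean, mean_pp)
print(f"doubling PP-C shifts fluvial Δ14C by at most {ms.shift:.0f} ‰ "
      f"(baseline {ms.baseline_delta:.0f} ‰, f* = {ms.f_star:.2f})")
```

Output:

```
PP-C endmember: -575.2 ± 180.0 ‰ from ('active_layer', 'holocene_deposits', 'pleistocene_deposits')
PP-C fraction: 0.94 ± 0.05 (95% CI 0.82-1.00)
conventional age: 7500 y BP
doubling PP-C shifts fluvial Δ14C by at most -82 ‰ (baseline -102 ‰, f* = 0.41)
```

The composite Kolyma endmember averages the three pool means (≈ −573 ‰)
with a spread inflated by the unknown pool proportions; a −610 ‰ POC sample
is therefore almost entirely PP-C (f ≈ 0.94). Doubling PP-C release would
depress fluvial Δ¹⁴C by at most 82 ‰, with the largest response at baseline
values near −100 ‰.

A full synthetic end-to-end run (record simulation → apportionment → flux
partition → sensitivity) is available from the CLI:

```bash
fluvial14c simulate --seed 1 --outdir demo
fluvial14c apportion --samples demo/samples.csv --outdir demo/out --scaled-down
fluvial14c fluxes --samples demo/samples.csv --flux-table demo/flux_table.csv \
    --outdir demo/out --scaled-down
fluvial14c sensitivity --samples demo/samples.csv --outdir demo/out --scaled-down
fluvial14c report --outdir demo/out
```

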