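# cottonfir

Boll-by-boll mapping of cotton fiber **maturity** and **cellulose
crystallinity** from ATR FT-IR absorbance spectra, across a plant's
node/position fruiting architecture.

Conventional fiber-maturity instruments (Fibronaire micronaire, AFIS maturity
ratio) need several grams of fiber — more than a single boll yields — so they
cannot resolve where on the plant a fiber sample came from. Mid-infrared ATR
spectroscopy needs only milligrams, and two band-ratio algorithms turn a raw
absorbance trace into a maturity index and a crystallinity index:

```
R1    = (I956 − I1500) / (I1032 − I1500)        M_IR      = (R1 − 0.14) / 0.45
R2    = (I708 − I800)  / (I730 − I800)          CI_IR (%) = ((R2 − 1.4) / 2.0) × 100
```

where each `I` is a three-point intensity average at the named wavenumber
(cm⁻¹). Both ratios are affine-invariant in the absorbance trace, so
contact-pressure and path-length variation in ATR sampling cancel without any
baseline correction. `cottonfir` implements these algorithms plus everything
around them: spectrum I/O, replicate aggregation with SEM, the node/position
plant map, a growing-degree-day (GDD) phenology model that flags bolls whose
development collides with defoliant sprays, the reporting statistics (Pearson
r with significance stars, linear/quadratic/exponential fits), and a synthetic
generator that renders cellulose-like spectra with *known* M_IR/CI_IR so the
whole pipeline is testable end to end.

## Worked example

Render a virtual boll with designed indices (M_IR = 0.80, CI_IR = 80 %), take
five noisy replicate measurements, and run them through the full pipeline:

```python
from cottonfir.synthetic import target_to_band_amplitudes, render_spectrum
from cottonfir.band_indices import indices_for_sample

model = target_to_band_amplitudes(m_ir=0.80, ci_ir=80.0)
reps = [render_spectrum(model, noise_sigma=0.001, seed=[42, i],
                        sample_id="A:10-1", replicate_id=f"rep{i+1}")
        for i in range(5)]
agg = indices_for_sample(reps)
print(f"M_IR  = {agg.mean_m_ir:.4f} +/- {agg.sem_m_ir:.4f} (SEM, n={agg.n_replicates})")
print(f"CI_IR = {agg.mean_ci_ir:.2f}% +/- {agg.sem_ci_ir:.2f}%")
print(f"classes: {agg.maturity_class.value}, {agg.crystallinity_class.value}")
```

prints

```
M_IR  = 0.7997 +/- 0.0013 (SEM, n=5)
CI_IR = 78.51% +/- 1.24%
classes: intermediate, middle
```

The recovered maturity sits within ~0.003 of the design value despite the
measurement noise; the classes follow the published thresholds (mature > 0.80,
intermediate 0.59–0.80, immature < 0.59; high > 80 %, middle 59–80 %,
low < 59 %) — here both means land just inside the middle band.

## Command line

The `cfir` tool wires the modules into a workflow:

```sh
cfir simulate --out run/ --seed 1 --plants 3      # spectra + boll + truth tables
cfir compute  --spectra-dir run/spectra --boll-csv run/bolls.csv --out run/idx
cfir map      --index-csv run/idx/indices.csv --out run/map
cfir gdd      --temperature-csv temps.csv --out run/gdd
```

`compute` writes a per-boll index CSV (mean, SEM and class per boll); `map`
aggregates locations across plants, fits quadratic node profiles, and — when a
conventional table (`location,mic,m_afis`) is supplied — reports Pearson
correlations between the IR indices and the instrument values; `gdd`
accumulates degree days, locates emergence/squaring events, and tabulates
flowering, maturation and defoliation-impact flags over the node × position
lattice.

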