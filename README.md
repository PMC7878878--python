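# paleospd

Chronometric analysis of sparse, time-averaged faunal records.

Regional change in animal communities — a predator disappearing, a
scavenger spreading — often leaves no stratified record, only a scatter of
radiocarbon-dated bones from mixed cave deposits.  Under a "dates as data"
reading, the dated specimens are a time-random, sparse sample of the death
assemblage, and the *distribution of their ages* carries the signal.
`paleospd` implements that reading end to end for paleoecologists and
zooarchaeologists:

* **Radiocarbon calibration** against any tabulated curve (`.14c` format):
  for a measurement m ± σ_m, the calendar-age density
  p(θ) ∝ exp(−(m − μ(θ))²/2s(θ)²)/s(θ) with s(θ)² = σ_m² + σ_c(θ)², on a
  1-year grid, with highest-posterior-density (HPD) intervals (2σ ≙
  0.954) and modern / beyond-range flagging.
* **Occurrence summaries**: MNI by single-linkage clustering of same-site
  specimens with overlapping 2σ intervals; first/last appearance dates
  (FAD/LAD); post-threshold date fractions; per-cave composition.
* **Summed probability distributions (SPDs)** per taxon, with same-site
  ¹⁴C-age *bins* (cutoff h, default 100 ¹⁴C yr) averaging out
  pseudo-replicated same-event dates.
* **Mark-permutation test**: taxon labels are reshuffled over bins
  (N = 1,000 by default); the observed SPD is compared with the simulated
  95% envelope, yielding signed local deviation intervals and a global
  Monte Carlo p-value from the z-scaled exceedance beyond the envelope.
* **Settlement intensity**: convex-hull areas (ha) of per-period site
  geometries, classified low (< 0.5), medium (0.5–1.0), high (> 1.0 ha).
* **Synthetic-data generation**: piecewise-constant deposition intensities
  with change points, inverse calibration with realistic lab errors, and
  ground-truth tables, so the whole pipeline is testable without any data
  download.

See `docs/methods.md` for the models, defaults, and limitations.

## Worked example

Simulate a three-taxon community-restructuring record (a hyena-like
scavenger whose deposition rate steps up tenfold at 3,400 cal BP, a
leopard-like predator that disappears at 3,400 cal BP, a uniform fox-like
control; 40 dates per taxon across 20 caves), then analyse it:

```python
from paleospd import (calibrate_specimens, carnivore_study_config, fad_lad,
                      fraction_after, load_specimens, make_bins,
                      make_synthetic_curve, mark_permutation_test,
                      assign_mni_clusters, simulate_assemblage)

curve = make_synthetic_curve("wiggly", 0, 12000, sigma=10.0, seed=1)
cfg = carnivore_study_config(curve, seed=42, n_per_taxon=40)
specimens, truth = simulate_assemblage(cfg)
specimens.to_csv("specimens.csv", index=False)

records = calibrate_specimens(load_specimens("specimens.csv"), curve)
hyena, leopard = fad_lad(records, "hyena"), fad_lad(records, "leopard")
print("hyena FAD/LAD:", hyena.fad, hyena.lad,
      "| leopard FAD/LAD:", leopard.fad, leopard.lad)
frac, k, n = fraction_after(records, "hyena", 3400)
print(f"hyena dates post-3400 cal BP: {k}/{n} = {frac:.0%}")
mni = assign_mni_clusters(records, "hyena")
print("hyena MNI:", mni.mni, "of NISP", mni.nisp)

calibrated = [r for r in records if r.is_calibrated]
bins = make_bins(calibrated, h=100)
res = mark_permutation_test(calibrated, "hyena", bins, n_sim=999, seed=7)
print("bins:", res.bins_used, "global p:", res.global_p)
print("deviation intervals:", res.deviation_intervals[:3])
```

prints

```
hyena FAD/LAD: 6555 25 | leopard FAD/LAD: 11341 3602
hyena dates post-3400 cal BP: 37/40 = 92%
hyena MNI: 38 of NISP 40
bins: 117 global p: 0.002
deviation intervals: ((2844, 2807, 'positive'), (2680, 2611, 'positive'), (2397, 2208, 'positive'))
```

The leopard-like taxon's last appearance (~3,600 cal BP) precedes the
change point it was generated with; the hyena-like taxon's dates
concentrate after it (37/40), and the permutation test rejects a random
spread of hyena dates over the pooled record (p = 0.002), with positive
deviations — more hyena probability mass than the permuted envelope
allows — in the last three millennia.  Intervals are (older bound,
younger bound, sign) in cal BP.

The same analysis is available from the shell:

```sh
paleospd simulate --config sim.yaml
paleospd run --curve curve.14c --specimens specimens.csv --out results/
paleospd permtest --curve curve.14c --specimens specimens.csv \
    --taxon hyena --nsim 1000 --seed 1
```

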