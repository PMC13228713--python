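# cartiq

Quantitative MRI analysis of knee articular cartilage around an acute
loading stimulus: voxel-wise T2 relaxation mapping, superficial/deep
laminar splitting of cartilage regions, distance-based thickness
morphometry, and pre/post group-comparison statistics — exercised
end-to-end on synthetic multi-echo phantoms and simulated cohorts with
known ground truth.

## Who this is for

Cartilage T2 relaxation time is a compositional MRI marker: it rises with
collagen disorganisation and free-water content, and it drops acutely
when cartilage is loaded and water is pressed out of the matrix.  Studies
of acute loading compare T2 (and cartilage thickness) before and after a
walking stimulus between healthy controls and people at risk of knee
osteoarthritis.  `cartiq` packages the full measurement chain of such a
study so every stage can be validated against analytic truth, without
any scanner data:

1. **Synthetic data** (`cartiq.phantom`, `cartiq.cohort`) — multi-echo
   knee-like phantoms (bone disc + two-layer cartilage shell, a
   stimulated-echo inflation on the first echo, Rician noise) and
   long-format pre/post cohort tables drawn from the random-intercept
   model the statistics assume.
2. **Relaxometry** (`cartiq.relaxometry`) — voxel-wise Levenberg–
   Marquardt fits of the mono-exponential decay
   `S(TE) = PD · exp(−TE/T2)`, first echo excluded by default, with
   validity flags and NaN sentinels.
3. **Cartilage geometry** (`cartiq.geometry`) — articular and
   bone-interface boundary sets, equidistant laminar splitting
   (superficial iff `d_articular ≤ d_bone`), load-bearing slice
   selection, nearest-neighbour label resampling between grids, and
   local thickness `t(v) = d_articular + d_bone + s` averaged per region.
4. **Statistics** (`cartiq.stats`) — region×layer means, the six-region
   composite, and a statsmodels-backed `GroupTimeModel` whose `fit()`
   returns adjusted cell means, within-group changes and between-group
   differences of changes with 95% CIs and Šidák-adjusted p-values.
5. **Pipeline + CLI** (`cartiq.pipeline`, `cartiq` command) — a
   config-driven run of the whole chain with a hashed output manifest.

## Worked example

Fit the group×time mixed model to a balanced table whose cell means are
set to published pre/post values for the superficial medial tibia:

```python
from cartiq import fit_group_time_model
from cartiq.cohort import REFERENCE_T2_MEANS, balanced_table

table = balanced_table(REFERENCE_T2_MEANS, n_per_group=16)
print(fit_group_time_model(table, "medial_tibia", "superficial").summary())
```

```
Group x time mixed model — region 'medial_tibia', layer 'superficial'
  observations: 64  participants: 32  groups: healthy, at-risk
  REML variance components: sigma_b^2 = 9.807, sigma_e^2 = 0.5333

  Adjusted cell means (95% CI):
         healthy   pre:   50.940 (49.364; 52.516)
         healthy  post:   45.910 (44.334; 47.486)
         at-risk   pre:   52.470 (50.894; 54.046)
         at-risk  post:   47.320 (45.744; 48.896)

  Contrasts (Sidak family m = 3):
                  within:healthy:   -5.030 (-5.536; -4.524)  p = 1.595e-84  p_sidak = 1.595e-84
                  within:at-risk:   -5.150 (-5.656; -4.644)  p = 1.636e-88  p_sidak = 1.636e-88
         between:at-risk-healthy:   -0.120 (-0.836; 0.596)  p = 0.7424  p_sidak = 0.9829
```

T2 in the superficial medial tibia shortens by about 5 ms in both groups
after loading (the acute water-exudation effect), with essentially no
between-group difference in the change (−0.12 ms).  The same machinery
runs from the shell:

```sh
cartiq simulate-cohort --out cohort.csv --seed 7
cartiq analyze cohort.csv --out contrasts.csv --report report.json
cartiq run-all config.yaml        # phantoms → T2 maps → laminae → models
```

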