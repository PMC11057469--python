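# dsfbind

Analysis of protein–ligand binding by **differential scanning fluorimetry
(DSF / thermal shift)**: from raw 96-well melt-curve exports to dissociation
constants, cooperativity analysis, and cross-species affinity comparison.

The package was built around a concrete use case — quantifying how serum
albumins from different species (human, bovine, porcine, rat) bind per- and
polyfluoroalkyl substances (PFAS) — but every stage is generic DSF
machinery: it is for anyone who runs thermal-shift assays on a plate reader
and wants a scripted, testable route from fluorescence traces to affinities.

## What it computes

A DSF experiment heats a protein–dye mixture and records fluorescence
*F*(*T*); the melting temperature *T*<sub>m</sub> is the temperature of the
maximal rate of fluorescence change (the global maximum of d*F*/d*T*).
Stabilizing ligands raise *T*<sub>m</sub>, and the shift
ΔTm(*c*) = *T*<sub>m</sub>(*c*) − *T*<sub>m</sub>(vehicle) grows with
occupancy.  Two binding models are fitted:

* **single-site isotherm** — ΔTm(*c*) = ΔTm<sub>max</sub> · *c* / (*K*<sub>d</sub> + *c*),
  fitted per replicate series; *K*<sub>d</sub> is reported as mean ± SEM
  over replicate estimates;
* **Hill equation** for biphasic melts — when ligand-free and ligand-bound
  transitions coexist, the bound fraction φ(*c*) = *c*<sup>h</sup> /
  (*K*<sub>½</sub><sup>h</sup> + *c*<sup>h</sup>) is estimated from the
  area split of the melt-curve derivative and fitted; *h* > 1 signals
  positive cooperativity.

Ligands producing no shift above a threshold (1.0 °C default) are
classified nonbinding and reported with N/A affinity fields.  On top of
fitted (or published) *K*<sub>d</sub> tables, the `compare` module computes
symmetric percent differences (200·|a−b|/(a+b)), Cohen's d effect sizes,
and affinity rank matrices across species and congeners; `docking`
aggregates docking free energies (per-site mode means, then a geometric
mean of site-mean magnitudes) and correlates them with measured
*K*<sub>d</sub>.  The `synthetic` module generates ground-truthed plates
from a two-state van 't Hoff unfolding model, so the whole chain is
testable without instrument data.

## Worked example

```python
import numpy as np, warnings
from dsfbind import build_delta_tm_series, fit_single_site, join_plate
from dsfbind.synthetic import ALBUMIN_PRESETS, SimBindingParams, simulate_plate

protein = ALBUMIN_PRESETS["HSA"]                       # Tm0 = 71.3 °C
binding = SimBindingParams(ligand="PFOA-like", kd_true_mM=0.79, dtm_max_true_C=13.0)
conc = [0.0] + list(0.79 * np.logspace(-1, 1, 8))      # vehicle + 0.1–10 × Kd

plate, plate_map, truth = simulate_plate(protein, binding, conc, n_replicates=6, seed=1)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    curves = [c for c in join_plate(plate, plate_map) if c.role in ("sample", "vehicle")]
fit = fit_single_site(build_delta_tm_series(curves))
print(f"Kd = {fit.kd_mM:.3f} ± {fit.kd_se_mM:.3f} mM, "
      f"ΔTm_max = {fit.dtm_max_C:.2f} °C, r² = {fit.r2:.4f}")
```

prints

```
Kd = 0.809 ± 0.022 mM, ΔTm_max = 12.82 °C, r² = 0.9952
```

i.e. with realistic replicate Tm scatter (~0.3 °C) the estimator recovers
the generating *K*<sub>d</sub> = 0.79 mM to within a few percent, and the
SEM honestly reflects the replicate spread.  The `examples/` directory has
one narrative script per capability (simulate-and-fit, species contrasts,
biphasic/Hill analysis, docking correlation), and the same workflow is
available from the shell:

```sh
dsfbind simulate --seed 1 --out sim/
dsfbind fit --plate sim/plate.csv --map sim/plate_map.csv --out fit/
dsfbind compare --kd-table fit/results.csv --out cmp/
```

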