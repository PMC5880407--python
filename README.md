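# spindlequant

Simulation and quantification of mitotic spindle dynamics from live-cell
fluorescence microscopy of budding yeast.

When Securin (Pds1) regulation of Separase is perturbed, yeast cells stop
holding a short metaphase spindle and instead begin elongating it the moment
the spindle pole bodies (SPBs) separate. `spindlequant` is a reusable,
tested implementation of the measurements used to quantify that biology from
z-stack time series:

* a **synthetic-data generator** producing spindle-length trajectories,
  sister-chromatid (lacO/lacI-GFP) tracks and rendered fluorescence z-stacks
  with known ground truth;
* **image quantification** — sub-voxel focus localization, 3D spindle length
  (inter-SPB distance), cell-cycle staging (pre-mitotic / short < 2 μm /
  long > 2 μm spindle), 5×5/6×6-pixel integrated-fluorescence measurement
  with local background subtraction, and the pericentric Cohesin
  barrel/nuclear fluorescence ratio (1 = no enrichment);
* a **trajectory classifier** applying three rules anchored at SPB
  separation (t = 0) — spindles that exceed 2 μm within 10 min *and* 2.5 μm
  within 15 min show "immediate spindle elongation"; spindles that never
  reach 6 μm within 60 min show "failed anaphase"; the rest are "normal" —
  with auditable curation of conflicting (immediate/normal,
  normal/immediate) cases via anaphase-onset inflection detection;
* **population statistics** — sister-separation timing with the 0-floor rule
  (separation before spindle formation counts as 0), segregation-fate
  fractions, metaphase duration (formation → anaphase-onset inflection),
  mean ± SD/SEM summaries and Student/Welch t-tests.

See `docs/methods.md` for the models, defaults and numerical conventions.

## Worked example

Simulate a 40-cell population with the default (Securin-depleted) phenotype
mixture, classify every trajectory and summarize:

```sh
spindlequant run --n-cells 40 --seed 7 --out demo/
```

which prints (abridged):

```json
{
  "classes": {
    "n": 40,
    "counts": {"normal": 19, "immediate": 16, "failed": 5},
    "fractions": {"normal": 0.475, "immediate": 0.4, "failed": 0.125},
    "n_conflict": 0,
    "conflict_fraction": 0.0
  },
  "separation_timing_min": {
    "n": 32, "mean": 7.407, "sem": 0.536, "n_failed": 8, "n_censored": 0
  },
  "segregation_fate": {"n": 40, "accurate": 0.8, "failed": 0.2},
  "metaphase_duration_min": {"n": 19, "mean": 23.21, "sem": 0.786}
}
```

Reading the output: 16/40 simulated cells elongated their spindle
immediately upon formation and 5 never reached 6 μm ("failed anaphase"),
close to the generating mixture (0.40/0.10). The 8 cells whose sisters
segregated to one pole are excluded from the timing mean and reported as the
0.2 failed-fate fraction; the remaining 32 separated their sisters
7.4 ± 0.5 min (mean ± SEM) after spindle formation, consistent with the
generator's floored-normal offset (mean 6.71 min before flooring). Normal
cells spent 23.2 ± 0.8 min in metaphase, recovering the configured 22.4-min
average. `demo/` also contains per-cell tables (`trajectories.csv`,
`classification.csv` with rule flags and curation provenance), a
`report.json` with the seed, thresholds and config hash, and
`plots/traces.png` with traces colored black (normal), green (immediate)
and red (failed).

The other subcommands expose the stages separately: `simulate` (optionally
rendering TIFF z-stacks + JSON sidecars), `measure` (foci, lengths, stages
from stacks), `classify`, `stats` and `plot`. Exit codes: 0 ok,
1 validation error, 2 runtime error.

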