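# crowdscore

Aggregation, calibration and evaluation of crowdsourced immunohistochemistry
(IHC) scores on tissue-microarray (TMA) cores.

Citizen scientists classify small image segments of stained tissue cores
(cancer present? proportion of stained cancer cells, in one of three
bin schemes? staining intensity 0–3?). `crowdscore` turns those noisy
categorical responses into per-core and per-patient H-scores and evaluates
them end to end:

- **domain** — data types, the three proportion-bin schemes, conditional
  questioning validation, CSV interchange (`crowdscore.domain`)
- **image_prep** — 6×6 tiling of core images, central-16 segment
  selection, colour inversion (`crowdscore.image_prep`)
- **synthetic** — ground-truthed synthetic crowds: cores with known
  staining truth, rater error models, expert scores, survival outcomes
  with log-hazard linear in the true H-score (`crowdscore.synthetic`)
- **aggregation** — pooled per-core means ignoring "no cancer" responses,
  patient-level means (`crowdscore.aggregation`)
- **correction** — linear bias correction against expert gold standard
  with clipping and leakage-free 10-fold cross-validated prediction for
  expert-scored cores; H-score = proportion × intensity (0–300)
  (`crowdscore.correction`)
- **agreement** — Spearman rho, quadratic-weighted kappa, percentile
  bootstrap CIs, per-marker agreement tables (`crowdscore.agreement`)
- **rater_curves** — accuracy as a function of classifications per core
  (`crowdscore.rater_curves`)
- **survival** — Kaplan–Meier, log-rank, Cox proportional hazards (Efron
  ties via lifelines), quartile/median splits, subgroup analysis
  (`crowdscore.survival`)
- **pipeline / cli** — one deterministic end-to-end run with a manifest
  (`crowdscore.pipeline`, `crowdscore.cli`)

## CLI

All stages operate on a run directory and a flat `key = value` config
(see `crowdscore.config.PipelineConfig` for keys and defaults):

```sh
# full pipeline: synth -> aggregate -> correct -> agree -> survival
crowdscore run --config run.cfg --seed 1 --out runs/demo

# or stage by stage
crowdscore synth     --seed 1 --out runs/demo
crowdscore aggregate --seed 1 --out runs/demo
crowdscore correct   --seed 1 --out runs/demo
crowdscore agree     --seed 1 --out runs/demo
crowdscore curves    --seed 1 --out runs/demo
crowdscore survival  --seed 1 --out runs/demo
```

Outputs are plain CSVs (`classifications.csv`, `core_scores.csv`,
`corrected_scores.csv`, `agreement.csv`, `curve.csv`, `cox_results.csv`,
`km_curves.csv`, …) plus `manifest.json` with the config hash, seed and
per-stage row counts. Same config + seed ⇒ byte-identical outputs.

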