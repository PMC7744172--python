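# lightcore

Simulation and analysis pipeline for rapid 3D open-top light-sheet (OTLS)
pathology of prostate needle-core biopsies: synthetic ground-truthed biopsy
phantoms, a 45°-oblique stage-scanning acquisition simulator, shear-based
volume reconstruction with Sobel edge enhancement, multiresolution XML/HDF5
output, a pipelined 12-biopsy workflow timing model, and the multi-rater
diagnostic-accuracy statistics of a 44-case, 3-pathologist validation study.

## Modules

| Module | Purpose |
| --- | --- |
| `lightcore.phantom` | Seeded synthetic biopsy phantoms (benign / pattern-3 / fused pattern-4 glands, nuclear channel only) and the oblique acquisition forward model with depth attenuation and shot/read noise. |
| `lightcore.reconstruct` | Sampling-geometry derivations (binned pitch, matched frame interval, ROI row choice), lossless integer-shift 45° deskew (with interpolating fallback), Sobel-based en-face edge enhancement. |
| `lightcore.bdvio` | Block-mean image pyramids and a BigDataViewer-style XML + HDF5 container (write/read, level-of-detail access). |
| `lightcore.workflow` | Deterministic pipelined batch schedule (simultaneous staining, sequential imaging, concurrent processing, rolling single-reader diagnosis) and turnaround summaries. |
| `lightcore.raterstats` | Confusion counts, sensitivity/specificity/accuracy/PPV/NPV, majority vote, free-marginal multirater agreement and kappa, percentile-bootstrap CI, and the canonical 44-case rating fixture. |
| `lightcore.cli` | `lightcore` command with `simulate`, `deskew`, `enhance`, `convert`, `schedule`, `evaluate`, `run-all` subcommands. |

## CLI examples

```bash
# full pipeline for one small simulated biopsy
lightcore run-all --n 1 --seed 0 --out runs/demo

# batch timing model
lightcore schedule --n 12 --out schedule.csv

# score a rating table (CSV columns: case_id, truth, one per rater)
lightcore evaluate ratings.csv --out report
```

A rating CSV for the canonical fixture can be produced with:

```python
from lightcore.raterstats import fixture_table, write_rating_csv
table, truth = fixture_table()
write_rating_csv(table, truth, "ratings.csv")
```

## Conventions

- Volumes are indexed `(z, y, x)`: `x` is the stage-scan axis, `y` lateral,
  `z` depth into tissue; physical units are micrometres; voxel `i` sits at
  `i * pitch` (node-centred grids).
- All randomness flows through explicit integer seeds; there is no global
  random state.
- Raw stacks and volumes serialize as multi-page TIFF with a YAML sidecar;
  multiresolution datasets as an `.h5`/`.xml` sibling pair.
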