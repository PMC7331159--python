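# cartstrain

Kinematics-driven articular-cartilage contact-strain mapping and voxelwise
T2* relaxometry, exercised end to end on synthetic joint data with known
ground truth.

The package reimplements an in vivo cartilage measurement chain as a
reusable pipeline:

- **`cartstrain.synthetic`** — generators for every input: an idealised
  conforming ball-and-socket joint (sphere-cap bone / subchondral /
  cartilage surfaces with a smooth thickness field, mean ~0.82 mm),
  periodic 6-DOF gait with cycle-to-cycle variability and marker noise at
  120 frames/s, multi-echo MR volumes with tissue-dependent T2*
  (cartilage vs synovial-fluid contrast), a two-block accuracy phantom
  (0°/30°/60°), and linearly coupled regional Δstrain/ΔT2* scenarios.
- **`cartstrain.kinematics`** — least-squares rigid pose estimation from
  marker triads (Kabsch), surface registration, point-to-surface ICP
  alignment of subchondral profiles, 6-DOF decomposition of the
  humerus-in-glenoid motion (intrinsic Z–Y′–X″ Euler), gait-cycle
  segmentation (mean-crossing boundaries on a periodic grid, 101 samples
  per cycle) and the mean ± 1 SD outlier-rejection rule.
- **`cartstrain.contact`** — cartilage thickness along subchondral
  normals, overlap depth of the rigidly posed cartilage layers by ray
  casting against a watertight solid, contact strain
  (overlap / undeformed thickness, 0.25 mm contact threshold), and
  cumulative maps over a representative cycle.
- **`cartstrain.relaxometry`** — voxelwise mono-exponential T2* fitting
  (Gauss–Newton from a log-linear start), the 50 ms fluid cutoff with
  reason-coded masks, through-thickness surface projection, and
  thickness-sensitivity analysis.
- **`cartstrain.regional`** — 20° posterior-to-anterior regional binning,
  area-weighted regional means and pre/post deltas, Pearson correlation,
  ICC(2,1)/ICC(3,1) with F-based 95% CIs, and RMS differences.
- **`cartstrain.phantom`** — phantom bias/precision measurement and
  propagation of pose errors to strain/contact-area errors.
- **`cartstrain.pipeline`** — the full study:
  simulate → track → strain → t2star → regions → correlate → phantom,
  with deterministic outputs under a fixed seed.

## Command line

```bash
cartstrain simulate shoulder --seed 1 --out-dir model/
cartstrain simulate gait     --seed 1 --out-dir gait/
cartstrain track  --markers gait/markers.csv --model model/ --out-dir track/
cartstrain strain --poses track/representative_cycle.csv --model model/ \
                  --threshold-mm 0.25 --cumulative max --out-dir strain/
cartstrain simulate volume --seed 1 --out-dir vol/
cartstrain t2star --volume vol/multiecho --cutoff-ms 50 --model model/ --out-dir t2/
cartstrain phantom --angle 30 --frames 2000 --noise-mm 0.1 --out-dir audit/
cartstrain run-study --seed 1 --out-dir study/
```

All verbs accept `--config <yaml>` (see `cartstrain.config.RunConfig` for
every key and its default) and `--seed`. `run-study` writes meshes (PLY),
marker tracks (CSV), DOF traces and representative cycles (CSV), multi-echo
volumes (NIfTI + JSON sidecar), cumulative strain maps (PLY/CSV), a
regional pre/post delta table, a correlation report, a phantom audit, and a
manifest with file checksums; two runs with the same seed are
byte-identical.

## Acceptance

Acceptance is property-based (closed-form sphere oracles, Monte-Carlo and
grid-search oracles, reliability simulations); each criterion is one test
in `tests/test_acceptance.py`. The report script runs the full synthetic
study from scratch and prints the recomputed headline quantities:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

No named numeric targets are defined for this package, so the JSON report
is an empty object; the printed summary and the acceptance test suite
carry the verification.
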