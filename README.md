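# penumbra

Mapping the "penumbra" of white-matter lesions: given co-registered
per-participant volumes — tract posterior-probability maps, a binary white
matter hyperintensity (WMH) mask, a normal-appearing white matter (NAWM)
mask, and FA/MD parametric maps on a common (nominally 2 mm isotropic)
grid — this package

1. binarizes each tract at the 1% posterior-probability threshold and
   partitions it into its WMH-intersecting part (tract-WMH) and its NAWM
   part, with the %WMH volume per tract;
2. grows concentric 3D shells around the tract-WMH by repeated one-voxel
   (2 mm) binary dilation up to 10 mm, keeping only voxels in the
   tract-NAWM;
3. identifies *nearby* WMH — connected lesion components that do not touch
   a tract but whose 2–10 mm shells reach its NAWM — and shells them too,
   excluding any voxel already claimed by a tract-WMH contour;
4. samples mean FA and MD per shell into a long-format table, flagging
   CSF-contaminated contours (mean MD > 1e-3 mm²/s) for exclusion;
5. fits log-distance linear mixed models: a gradient family
   (`outcome ~ log(distance+1)` over 0–10 mm with crossed random
   intercepts/slopes for participant and tract) and a type-comparison
   family (`outcome ~ log(distance) + type [+ interaction]` over 2–10 mm,
   interaction kept only if it lowers the BIC), reporting estimates, SEs,
   Type III Wald F statistics with Satterthwaite (or residual) denominator
   df, and p-values.

Because suitable clinical data are not publicly deposited, the package
includes a fully synthetic phantom cohort generator with planted
log-distance FA/MD gradients, participant- and tract-level random effects,
intersecting and nearby ellipsoidal lesions, CSF-like high-MD voxels, and a
ground-truth ledger — every pipeline stage is testable end to end against
known parameters.

## Command line

```bash
# synthetic cohort (NIfTI bundle + ground-truth JSON)
penumbra generate --config phantom.json --out cohort/ --seed 7

# geometry QC: per-tract partition summary, optional shell volumes
penumbra geometry --cohort cohort/ --out partitions.csv --save-shells shells/

# shells + FA/MD sampling -> long table
penumbra sample --cohort cohort/ --out table.csv --md-threshold 1e-3

# mixed models on the table
penumbra fit --table table.csv --outcome fa --family gradient --scope all --out fits/
penumbra fit --table table.csv --outcome md --family comparison --scope per_tract --out fits/

# everything from one JSON config, or check a cohort layout
penumbra run --config run.json --out results/ --seed 3
penumbra validate --cohort cohort/
```

`run.json` minimal example:

```json
{
  "mode": "synthetic",
  "phantom": {"n_participants": 2, "seed": 3,
               "tract_specs": [{"name": "tractA",
                                "control_points": [[3, 16, 12], [44, 16, 12]],
                                "radius_mm": 5.0}],
               "grid_shape": [48, 32, 24],
               "lesion_plan": {"n_intersecting_per_tract": 1,
                                "n_nearby_per_tract": 1}},
  "models": {"families": ["gradient"], "outcomes": ["fa", "md"]}
}
```

## Layout

| module | contents |
| --- | --- |
| `penumbra.volume_io` | NIfTI I/O, typed volumes, common-grid contract, record table CSV |
| `penumbra.synthetic` | phantom cohort generator + ground-truth ledger |
| `penumbra.geometry` | tract partition, dilation shells, nearby-lesion rules |
| `penumbra.sampling` | shell means, long table assembly, CSF exclusion |
| `penumbra.models` | REML/ML variance-components engine, Satterthwaite Wald F, BIC gate, reports |
| `penumbra.pipeline` / `penumbra.cli` | stage orchestration, validation, CLI |

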