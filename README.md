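# emtracer

Template-matching model building for high-resolution (≲3.5 Å) cryo-EM
density maps: automatic secondary-structure detection, global voxel-size
(magnification) calibration, Guinier-based reference-map scaling, and
likelihood-driven Cα chain tracing with optional sequence assignment.

At 3.5 Å and better, a cryo-EM map contains enough information to trace the
protein main chain directly, but two practical obstacles stand in the way of
doing it automatically: the map's voxel size can be wrong by several percent
(microscope magnification error), which makes every distance in the map lie;
and likelihood-based Cα finding needs a reference map on the same amplitude
scale as the working map. `emtracer` addresses both and then builds the
model, in two stages:

1. **Secondary-structure stage.** Pre-computed helix/strand templates —
   each a standard segment with a *mean density map* `S_mean[k] = (1/n) Σ_n S[n,k]`
   and a *correlation (reliability) map* built from per-distance-group
   correlations `CC_i = (1/n) Σ_n ρ(S[n,k], S_mean[k]), k ∈ G_i` — are
   located by a fast pre-screen, scored with a correlation-weighted Pearson
   CC, and refined by simplex. The voxel size is then scanned over 201
   factors m ∈ {0.900, …, 1.100}, each placement re-refined at the trial
   scale, and the corrected size taken as
   `v_new = v_ori · argmax_m Σ_n CC[m,n]`, combining helix- and
   strand-derived estimates by a count-weighted average.
2. **Cα stage.** The reference map is rescaled so its Guinier curve
   (lnF vs d⁻²) matches the working map's beyond 10 Å, then a Cα
   log-likelihood target (per-offset density mean/variance in an oriented
   local frame) is trained on the reference model. Chains grow from both
   ends of each placed secondary structure, one Cα at a time, while the
   target's log-likelihood stays above an adaptive threshold; residue-type
   targets optionally dock the sequence onto the traced fragments.

Everything is exercised end-to-end on packaged synthetic fixtures
(ideal-geometry toy proteins rendered as Gaussian-atom density), so the full
pipeline runs and is tested without any external data. See
`docs/methods.md` for the model details, parameter defaults and the test
bed's scope.

## Worked example

Build templates from a training map/model pair, correct a map whose header
voxel size is 3% too small, and trace the chain:

```python
import numpy as np
from emtracer import fixtures, template_builder, tracer
from emtracer.cli import PipelineConfig, run_pipeline
from emtracer.volio import write_map, write_model

# synthetic stand-ins for real maps (any MRC/PDB paths work the same way)
train = fixtures.template_training_structure()
train_map = fixtures.simulate_map(fixtures.SimulationSpec(model=train))
for kind in ("helix", "strand"):
    tpl = template_builder.build_template(train_map, train, kind)
    template_builder.save_template(tpl, f"{kind}.npz")

toy = fixtures.toy_protein()
toy_map = fixtures.simulate_map(fixtures.SimulationSpec(model=toy))
write_map(fixtures.perturb_voxel_size(toy_map, 0.97), "working.mrc")

ref = fixtures.training_protein()
write_map(fixtures.simulate_map(fixtures.SimulationSpec(model=ref)), "reference.mrc")
write_model(ref, "reference.pdb")

config = PipelineConfig(
    map="working.mrc", resolution=2.5,
    ref_map="reference.mrc", ref_model="reference.pdb",
    helix_template="helix.npz", strand_template="strand.npz",
    out_dir="out", seed=1, n_residues=90,
)
result = run_pipeline(config)
print(f"v_ori={result['v_ori']:.4f}  v_new={result['v_new']:.4f}")
w1, w2, rmsd = tracer.evaluate_model(result["model"], toy)
print(f"within 1A: {w1:.1f}%  within 2A: {w2:.1f}%  rmsd: {rmsd:.2f} A")
```

Output from this exact run:

```
v_ori=0.9700  v_new=1.0049
within 1A: 61.2%  within 2A: 77.6%  rmsd: 1.97 A
```

The header claimed 0.97 Å voxels; the scan recovered the true 1.0 Å scale to
0.5%. Of the Cαs built into the corrected map, 78% lie within 2 Å of the
ground-truth structure (`out/built_model.pdb` holds the traced model,
`out/voxel_scan.tsv` the accumulated-CC profile per factor).

The same pipeline is available from the shell:

```bash
emtracer mktemplate --map train.mrc --model train.pdb --kind helix --out helix.npz
emtracer voxelrefine --map working.mrc --helix-template helix.npz \
    --strand-template strand.npz --out corrected.mrc
emtracer run --map working.mrc --resolution 2.5 --ref-map reference.mrc \
    --ref-model reference.pdb --helix-template helix.npz \
    --strand-template strand.npz --out outdir --seed 1
emtracer evaluate --model outdir/built_model.pdb --truth truth.pdb
```

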