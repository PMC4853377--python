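# serialrecon

3D reconstruction of serially sectioned brain image stacks and registration
of a labeled atlas template onto them — with a fully ground-truthed
synthetic phantom to validate every stage.

Sectioning a brain for histology, receptor autoradiography or polarized
light imaging (PLI) destroys the 3D coherence of the data: every mounted
section carries an unknown rigid motion and smooth deformation.  This
package implements the complete recovery workflow for people building
multimodal 3D brain models:

1. **Blockface reconstruction** — photographs of the frozen block taken
   before each cut are aligned on circular chuck fiducials (translation
   chain), refined against a running z-median to remove camera perspective
   offsets, and the brain is separated from the surround with a 3D
   watershed.
2. **Section-to-blockface alignment**, one strategy per modality:
   histology by centre-of-gravity superposition plus an exhaustive SSD
   rotation search; autoradiographs (which contain zero-signal "empty
   regions" wherever the probed receptor is absent) by a feature-based
   intra-stack chain anchored with landmark rigid transforms every K-th
   section and interpolated in between; PLI by rigid mutual-information
   registration plus a slice-wise cubic B-spline refinement on a fixed
   5×6 control grid.
3. **Atlas integration** — the template (e.g. an MRI atlas), masked to its
   labeled voxels, is registered onto the blockface volume with a
   three-step rigid → affine → cubic-B-spline strategy, each stage
   initialized by the previous one and run over a six-level Gaussian
   pyramid with a mutual-information metric; labels are propagated with
   nearest-neighbour interpolation.  Structures whose position is known to
   be unreliable (the olfactory-bulb situation) can be excluded from the
   metric.
4. **Evaluation** — Dice coefficient (DC), Hausdorff distance (HD) and
   average surface distance (ASD):

   ```
   DC(A,B)  = 2|A∩B| / (|A|+|B|)
   ASD(A,B) = (Σ_{a∈S_A} min_b d(a,b) + Σ_{b∈S_B} min_a d(b,a)) / (|S_A|+|S_B|)
   HD(A,B)  = max( max_a min_b d(a,b), max_b min_a d(b,a) )
   ```

   with `S_A`, `S_B` the surface voxel point sets in mm and `d` the
   Euclidean distance.

A `phantom` module generates all inputs synthetically — blockface stacks
with markers, jitter and perspective offsets; deformed multi-modal section
stacks; a template/label pair related to the truth by a known affine plus
smooth warp — with every applied distortion recorded, so reconstruction
error is measurable exactly.  See `docs/methods.md` for the models,
parameters and limitations.

## Worked example

```python
import serialrecon as sr

# a ground-truthed scene: ellipsoidal brain, internal hippocampus-like
# structure, bulb-like appendage; default 96 x 96 x 64 voxels
scene = sr.make_scene(seed=1)

# blockface stack with fiducials, jitter and perspective offsets
stack = sr.render_blockface(scene, seed=2)
blockface, slice_transforms = sr.reconstruct_blockface(stack)
mask = sr.segment_brain(blockface)
print(f"blockface brain mask Dice vs truth: {sr.dice(mask, scene.brain_mask()):.3f}")

# template differing from the truth by a known affine + smooth warp
template, labels = sr.make_template(scene, seed=9)
masked = sr.mask_template(template, labels)
chain = sr.register(masked, blockface, config=sr.RegistrationConfig(seed=1))
for stage in chain.stage_names():
    propagated = sr.propagate_labels(labels, chain.at_stage(stage), blockface)
    d = sr.dice(propagated.mask(None), scene.brain_mask())
    print(f"whole-brain Dice after {stage:8s}: {d:.3f}")
```

prints (exact numbers from this configuration):

```
blockface brain mask Dice vs truth: 0.991
whole-brain Dice after rigid   : 0.834
whole-brain Dice after affine  : 0.928
whole-brain Dice after bspline : 0.979
```

The blockface mask agrees with the true brain to Dice 0.991, and the
overlap of the propagated template brain improves with every added degree
of freedom of the transform — the registration recovers most of the known
affine at the affine stage and the smooth warp at the B-spline stage.

The same workflow is scriptable from the shell:

```
serialrecon phantom   --config phantom.yaml --out data/
serialrecon blockface --in data/blockface --out recon.nii.gz --markers 4 --median-radius 5
serialrecon sections  --strategy autoradiograph --blockface recon.nii.gz \
                      --in data/autoradiograph --landmarks landmarks.json --out m2.nii.gz
serialrecon atlas     --template t.nii.gz --labels l.nii.gz --fixed recon.nii.gz \
                      --out-chain chain.json --out-labels labels_in_bcs.nii.gz
serialrecon evaluate  --truth data/truth_labels.nii.gz --test labels_in_bcs.nii.gz \
                      --structures whole_brain,inner=2 --out report.csv
serialrecon run       --config pipeline.yaml --out RUNDIR   # everything at once
```

`serialrecon run` consumes a YAML config (seed, phantom shape, modalities,
blockface/section/registration settings, evaluated structures — see
`serialrecon.pipeline.DEFAULT_CONFIG`), writes every intermediate volume,
a stage-wise `report.csv` (DC/HD/ASD per structure and registration
stage), and a `manifest.json` with the config hash, seed, per-stage
timings, output paths and registration metric logs.  Runs are
deterministic: the same config reproduces byte-identical reports.

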