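# tmplkit

Groupwise diffeomorphic brain-template construction and deformation-based
validation, with a synthetic head-phantom population generator standing in
for cohort MRI data.

## The problem

Spatial normalization — warping individual brain images onto a population
template — is the workhorse of group neuroimaging, and its accuracy depends
on how well the template matches the population being studied: templates
built from larger samples, and from the subjects' own population, require
smaller deformations. `tmplkit` implements the full computational pipeline
of a template-construction-and-validation study for people who want to
build population-average templates, quantify the deformation their
normalization imposes, and compare templates statistically:

* **Deformation model** — stationary velocity fields `v`, exponentiated to
  diffeomorphisms `φ = exp(v)` by scaling and squaring, so `exp(−v)` is the
  inverse and the Jacobian determinant stays positive.
* **Registration** — multiresolution diffeomorphic demons on
  channel-weighted SSD (T1 plus tissue probability maps), with a
  monotone-similarity guarantee per pyramid level.
* **Groupwise template** — iterative mean-and-register with an
  `(outer, inner)` schedule (default 6 × 6) and recentring by `exp(−v̄)`
  (v̄ = mean subject velocity), driving the mean subject deformation to
  zero ("unbiased" template).
* **Validation metrics** — per-voxel displacement magnitude
  `‖u(x)·s‖₂` (mm) and log-Jacobian `log det(I + ∇u)`; regions are
  summarised as means of displacement and `|log J|` over an integer-label
  atlas, excluding regions smaller than 500 mm³.
* **Template comparison** — per-region paired t-tests across held-out
  subjects with Bonferroni control (α divided by the number of retained
  regions), after transporting all metric maps to one common reference
  space.
* **Phantoms** — deterministic populations of T1-like head volumes with
  five age strata, balanced sexes, known ground-truth warps, tissue maps
  and a matching atlas, so every stage has an oracle.

See `docs/methods.md` for the models, parameter defaults and their
rationale, and known limitations.

## Worked example

Simulate a small population, build a template, and inspect its convergence:

```python
from tmplkit import (PhantomSpec, generate_population, initial_import,
                     build_template)
import numpy as np

spec = PhantomSpec(strata=[("60-64", 5, 5)])        # 64^3 grid, 3 mm voxels
pop = generate_population(spec, seed=0)             # 10 subjects
imported, _ = initial_import(pop)
tpl = build_template(imported, schedule=(6, 6))

print(tpl.history[["outer_iteration", "mean_displacement_mm",
                   "mean_similarity"]].round(4).to_string(index=False))
mean_u = np.mean([d.displacement for d in tpl.subject_deformations], axis=0)
mask = tpl.brain_mask()
print("unbiasedness:", round(float(np.sqrt((mean_u**2).sum(0))[mask].mean()), 3),
      "voxels")
```

Output:

```
 outer_iteration  mean_displacement_mm  mean_similarity
               0                0.2914           0.0002
               1                0.2138           0.0002
               2                0.1995           0.0002
               3                0.1895           0.0002
               4                0.1916           0.0002
               5                0.1883           0.0002
unbiasedness: 0.063 voxels
```

`mean_displacement_mm` is the template drift — the mean magnitude of the
*average* subject deformation, the quantity the recentring step drives
toward zero: it falls from 0.29 mm to its estimation-noise floor
(~0.19 mm here) as the template converges to the population centre. The
final `unbiasedness` of 0.063 voxels says the ten subject deformations
cancel almost exactly at the converged template.

The same pipeline is scriptable from a shell:

```sh
tmplkit simulate --seed 0 --out pop/           # subjects + atlas + manifest
tmplkit build-template --manifest pop/manifest.tsv --outer 6 --inner 6 --out tpl/
tmplkit normalize --moving pop/s000_60-64_M0/t1.nii.gz \
                  --fixed tpl/template_t1.nii.gz --out norm/
tmplkit metrics --deformation norm/deformation.nii.gz --atlas pop/atlas.nii.gz \
                --regions pop/atlas_regions.tsv --min-volume 500 --out met/
tmplkit experiment --design matched-population --seed 1 --out exp/
```

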