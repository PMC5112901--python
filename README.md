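# lcfp — local connectome fingerprinting for diffusion MRI

White-matter microstructure is unique enough to identify a person.  `lcfp`
implements **local connectome fingerprinting**: diffusion MRI signals are
reconstructed into spin distribution functions (SDFs) in a common template
space, sampled along a shared atlas of fiber directions, and serialized into
a high-dimensional feature vector — the local connectome fingerprint.  The
package then provides the full statistical layer for *subject
identification* (pairwise distances, d′, leave-one-out LDA, extreme-value
error modeling) and *similarity quantification* (similarity index,
longitudinal trends, kinship group comparisons), plus a synthetic
multi-subject phantom generator so every analysis runs end-to-end without
any scanner data.

It is aimed at researchers studying individual variability, plasticity, and
heritability of white-matter architecture, and at anyone who needs a
reference implementation of the q-space diffeomorphic SDF reconstruction
and its downstream identification statistics.

## The model

For a standard-space coordinate **r** mapped into subject space by a
diffeomorphism φ with Jacobian J_φ, the SDF value along unit direction û is

```
ψ(û) = |J_φ(r)| · Z₀⁻¹ · Σᵢ Wᵢ(φ(r)) · sinc( σ √(6 D bᵢ) ⟨ĝᵢ, J_φ(r)û / ‖J_φ(r)û‖⟩ )
```

where Wᵢ is the i-th diffusion-weighted signal (b-value bᵢ, gradient
direction ĝᵢ), σ is the diffusion sampling ratio (default 1.25), D the
free-water diffusivity, and Z₀ a normalization constant estimated from free
water in the ventricle.  With the identity warp this reduces to generalized
q-sampling imaging on the native grid.

The fingerprint samples ψ at each atlas fiber direction in every cerebral
white-matter voxel, orders entries canonically by voxel position (fiber
rank innermost), and scales the vector to unit sample variance.  Pairs of
fingerprints are compared by root-mean-squared error; within- and
between-subject distance distributions yield d′, LOOCV-LDA classification
error, and a generalized-extreme-value estimate of the overlap probability
P(within > between).  The similarity index of a pair is
`100% × (1 − d₁/d₀)`, its distance relative to the mean unrelated-subject
distance.

## Worked example

```python
from lcfp import PopulationSpec, simulate_signals, partition_differences
from lcfp.identify import distance_matrix, identification_report
from lcfp.pipeline import fingerprints_from_scans
from lcfp.similarity import expected_unrelated_distance

spec = PopulationSpec(seed=42, n_subjects=6, sessions_per_subject=2)
scans, truth = simulate_signals(spec)                 # synthetic dMRI cohort
fps = fingerprints_from_scans(scans, truth.template.atlas)
dm = distance_matrix(fps)
rep = identification_report(dm)
d = partition_differences(dm)
d0 = expected_unrelated_distance(dm)
sims = 100 * (1 - d.within / d0)
print(len(fps[0]), rep.dprime, rep.loocv_errors, sims.mean())
```

prints

```
entries per fingerprint: 1336
within pairs: 6, between pairs: 60
d-prime: 63.87
LOOCV errors: 0/66
GEV-modeled error: 0
mean repeat-scan similarity: 77.1%
```

Every fingerprint has one entry per (voxel, fiber) site of the shared
atlas.  The repeat scans of each subject sit ~77% of the way from the
unrelated-pair distance toward identity — noise keeps them well short of
100% — yet the within/between distance distributions are so separated
(d′ ≈ 64, no LOOCV misclassification, vanishing modeled overlap) that every
scan is attributed to the right subject.  That gap between imperfect
repeat-scan similarity and perfect identification is the central behavior
the phantom is calibrated to reproduce.

The same pipeline is available from the shell:

```sh
lcfp simulate --out data/ --seed 31 --n-subjects 4 --sessions 2
lcfp fingerprint --dwi data/sub000_ses00_dwi.nii --btable data/btable.txt \
     --mask data/wm_mask.nii --vent-mask data/ventricle_mask.nii \
     --atlas data/atlas.nii --atlas-mask data/atlas_mask.nii --out sub000_ses00.h5
lcfp compare --manifest fingerprints.csv --out distances.csv
lcfp identify --distances distances.csv --out report.json
```

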