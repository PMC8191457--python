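# locrad — local CT radiomics for radioresistant tumor sub-volumes

`locrad` asks whether the part of a head-and-neck tumor that later recurs
after radiochemotherapy already looks different on the *pretreatment*
planning CT.  It computes a fixed vocabulary of 161 radiomic features (25
intensity + 136 texture: GLCM, GLRLM, GLSZM, GLDZM, NGTDM and NGLDM
families) on tumor regions and sub-regions, and classifies sub-volumes as
recurrence-prone — a candidate target for radiation dose intensification
("dose painting").

Three study designs are implemented end to end:

* **bi-regional** — GTVrec (tumor ∩ recurrence) vs GTVcontrol (tumor minus
  recurrence), one labelled region pair per patient;
* **local, fixed count** — the tumor is split into 8 octants about its
  center of mass and recurrent octants are *detected* without location
  information;
* **local, fixed size** — a 5×5×5-voxel grid (cells with ≥ 25 ROI voxels,
  placement optimised to cover the tumor) evaluated by leave-one-patient-out
  cross-validation.

The statistical core is the selection cascade: a voxel-count correlation
filter (|r| ≤ 0.5), PCA with Horn's parallel analysis, Spearman grouping of
features to retained components, per-group best-AUC representatives
(p < 0.05), multivariable logistic regression with backward AIC
elimination, a 75th-percentile classification cut-off, and 2000-replicate
stratified bootstrap CIs.  Sub-region labels follow the strict
more-than-50%-overlap rule.  Images are resampled to 3.3 mm cubic voxels,
windowed to [-20, 180] HU, and regions under 27 voxels are excluded.
`docs/methods.md` documents every convention and the design choices.

Patient imaging of the original study is not openly available, so the
package ships a synthetic phantom generator (`locrad.synthetic_phantom`)
that produces ground-truth cohorts — ellipsoidal tumors with a focal
recurrent blob whose texture heterogeneity exceeds the remainder by a
controlled *effect size* — against which every stage is tested.

## Worked example

Simulate a cohort (28 training + 12 validation phantoms, twofold planted
heterogeneity) and run the bi-regional and local analyses:

```sh
locrad simulate-cohort cohort/ --n-train 28 --n-val 12 --effect-size 2.0 --seed 1
locrad biregional cohort/ report_biregional.json --seed 1
locrad local-fixed-count cohort/ report_local.json --seed 1
```

or equivalently in Python:

```python
from locrad import RunConfig, generate_cohort, run_biregional
from locrad.synthetic_phantom import CohortSpec
from locrad.pipeline import cohort_from_manifest, run_local_fixed_count

patients = cohort_from_manifest(generate_cohort(CohortSpec(effect_size=2.0, master_seed=1)))
rep = run_biregional(patients, RunConfig(seed=1))
loc = run_local_fixed_count(patients, RunConfig(seed=1))
print(rep["train"]["auc"], rep["validation"]["auc"], loc["validation"]["auc"])
```

With seed 1 this prints training AUC **0.978** and validation AUC
**0.953** for the bi-regional model and validation AUC **0.794** for the
8-octant detection model.  The numbers mean: feature vectors of recurrent
regions differ strongly from controlled ones when the generator plants a
2× heterogeneity contrast (the differentiation task), and even without
knowing where the recurrence is, sub-volume texture ranks recurrent
octants above controlled ones about 8 times out of 10 (the detection
task).  In the same run, every validation patient with a truly recurrent
octant had at least one of them detected at the 75th-percentile cut-off,
and the detected octants covered a median 64% of each recurrence volume.
The run log records every exclusion (regions under the voxel minimum,
patients without both sub-region classes).

Each patient is a NIfTI triplet (`*_ct.nii.gz`, `*_gtv.nii.gz`,
`*_rec.nii.gz`) on a shared grid plus a `manifest.csv`; real cohorts in
the same layout run through the identical commands.  Per-sub-region
parametric maps can be exported with `locrad partition`.

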