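# osteomap

Voxel-based compartmental classification of skull-involving meningiomas
(osteomeningiomas) from binary tumor and skull masks in a common atlas grid.

Meningiomas with an osseous component span a spectrum from purely
intraosseous tumors to large intradural masses with secondary bone
involvement. `osteomap` implements a deterministic, reproducible radiological
classification of that spectrum. Given a tumor mask and a skull mask already
resampled into a shared 1-mm isotropic reference space (e.g. MNI152), it:

1. partitions the head into three mutually exclusive compartments —
   **osseous** (the skull mask), **juxta-osseous/dural** (the band of
   intracranial voxels within a fixed Euclidean distance, default 5 mm, of
   the inner table), and **intradural** (the remaining intracranial space);
2. labels every tumor voxel with the compartment it intersects and tallies
   the counts N_bone, N_dura, N_intra;
3. assigns the subtype as a pure function of those counts:

   | subtype | rule |
   |---|---|
   | POM | N_bone > 0, N_dura = 0, N_intra = 0 |
   | SOM-I | N_bone > 0, N_dura > 0, N_intra = 0 |
   | SOM-IIA | all three > 0 and N_bone ≥ N_intra |
   | SOM-IIB | all three > 0 and N_intra > N_bone |

   Count patterns outside these rules are flagged
   (`not_osteomeningioma`, `skipped_layer`) rather than forced into a class.

The package also provides the study-style statistical layer (Woolf odds-ratio
intervals, Fisher exact and Kruskal–Wallis tests, exploratory logistic
regression with separation flags), cohort aggregation (voxel frequency maps,
index-tumor selection, Dice/Jaccard rater agreement), a layer-thickness
sensitivity analysis over {2, 3, 5} mm, and a seeded phantom generator that
produces skull/lesion masks with exactly known compartment composition so the
whole pipeline is testable without patient data.

It is intended for neuro-imaging researchers working with segmented masks;
it does not segment images, estimate registrations, or read DICOM.

## Worked example

```python
import osteomap as om
from osteomap.phantoms import PhantomCohortSpec, Subtype, make_phantom_case

spec = PhantomCohortSpec()                       # 32^3 grid, shell skull, 5-mm layer
tumor, skull, truth = make_phantom_case(spec, Subtype.SOM_IIB, seed=3)
case = om.CaseInputs(case_id="demo", tumor=tumor, skull=skull)
call = om.classify_case(case, om.LayerSpec(thickness_mm=5.0))
print(call.counts.n_bone, call.counts.n_dura, call.counts.n_intra, call.subtype)
```

prints

```
11 29 117 Subtype.SOM_IIB
```

— 11 tumor voxels in bone, 29 in the 5-mm juxta-osseous band, 117 intradural;
the intradural component exceeds the osseous one, so the call is SOM-IIB,
matching the generator's ground truth.

The statistical layer reproduces published subtype–symptom associations from
per-class counts. For brain edema (SOM-IIB vs the other classes combined,
cells a=49, b=19, c=16, d=84):

```python
from osteomap.stats import ContingencyTable2x2, odds_ratio_woolf
r = odds_ratio_woolf(ContingencyTable2x2(49, 19, 16, 84))
print(round(r.or_point, 2), round(r.ci_low, 2), round(r.ci_high, 2))
# 13.54 6.38 28.74
```

## Command line

```bash
osteomap phantom  --output-root cohort --n-per-subtype 2 --seed 3
osteomap classify --input-root cohort --output-root out
osteomap sensitivity --input-root cohort --output-root out
osteomap stats --cohort-tsv cohort.tsv --output-root out
```

Outputs land under `<out>/derivatives/` as TSV/JSON plus a manifest; reruns
with the same config are byte-identical.

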