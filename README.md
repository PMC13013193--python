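# nigraseg

Fully automated segmentation of the substantia nigra (SN) from
neuromelanin-sensitive MRI (NM-MRI), with uncertainty estimation and
hyperintensity-based Parkinson's-disease (PD) identification.

The SN is a small midbrain nucleus whose dopaminergic neurons — and with
them its neuromelanin signal — degenerate in PD. On NM-MRI the SN appears
as a pair of faintly hyperintense crescents a few hundred mm³ in size, with
vague boundaries and large pose variability, which makes manual annotation
expensive and naive automated segmentation unreliable. `nigraseg`
implements a single-stage pipeline for this problem:

1. **SN-prior probability map (SPPM).** A template volume is chosen from a
   training subset by pairwise affine registration (the subject whose
   propagated SN label maximizes mean Dice against the rest); the SPPM is
   the voxelwise frequency of SN membership across subjects registered to
   the template, normalized to [0, 1].
2. **Prior-guided ROI.** At inference the template (and the SPPM with it)
   is registered to the input scan; a cubic region of interest is centred
   on the registered prior's peak voxel.
3. **Priority-gated attention 3D U-Net.** The ROI and the SPPM crop enter
   a U-Net whose skip connections are filtered by additive attention
   gates; the gating signal is derived from the SPPM by a learned strided
   convolution per scale, embedding the prior's spatial information.
4. **Test-time dropout (TTD).** Dropout stays active at inference; N
   stochastic passes yield the mean probability map
   `s = (1/N) Σ_l s^(l)` and the uncertainty map
   `u = sqrt((1/N) Σ_l (s^(l) − s)²)`.
5. **Hyperintensity and identification.** A 2D U-Net segments the midbrain
   from the paired T1-weighted volume; the hyperintensity cut-off is
   `t = μ + 1.5 σ` over midbrain-minus-SN intensities, and a case whose SN
   hyperintense area (axial slice with the largest SN cross-section) or
   volume falls strictly below a criterion is identified as PD. Sweeping
   the criterion yields ROC curves and AUCs.

Because no public SN-annotated NM-MRI dataset exists, the package ships a
first-class synthetic phantom generator (midbrain ellipsoid, mirrored SN
crescents, nigrosome-like hyperintense cores, cohort-level HC/PD effect
sizes, random affine pose, noise) against which every stage is developed
and tested. See `docs/methods.md` for the models, defaults and the
phantoms' fidelity limits.

## Worked example

```python
import numpy as np
from nigraseg.phantom import PhantomParams, generate_cohort
from nigraseg.hyperintense import estimate_hyperintense, identify_case, roc_auc

records, _ = generate_cohort(n_hc=12, n_pd=12, params=PhantomParams(), seed=11)
scores, labels = [], []
for rec in records:
    hyper = estimate_hyperintense(rec.nm, rec.midbrain, rec.sn, alpha=1.5)
    ident = identify_case(hyper.region, rec.sn, rec.nm.spacing, mode="volume")
    scores.append(ident.score)
    labels.append(rec.label == "PD")
points, auc = roc_auc(scores, labels)
print(f"volume-mode AUC over {len(records)} phantoms: {auc:.3f}")
```

prints

```
volume-mode AUC over 24 phantoms: 0.972
```

i.e. on ground-truth masks, the hyperintense-volume statistic separates
the synthetic PD cohort (smaller SN, smaller and dimmer hyperintense
cores) from controls almost perfectly; the end-to-end pipeline (trained
segmentation instead of ground truth) is exercised by
`examples/03_train_and_segment.py` and the evaluation workflows.

The `examples/` directory contains one narrative script per capability:
cohort simulation, prior-map construction + ROI localization, desk-scale
training + TTD segmentation, and hyperintensity-based identification. A
thin CLI mirrors the pipeline stages:

```sh
nigraseg simulate --n-hc 30 --n-pd 30 --seed 1 --out data/
nigraseg estimate-sppm --manifest data/manifest.csv --subset-size 20 --out bundle/
nigraseg train --manifest data/manifest.csv --bundle bundle/ --out run/
nigraseg run --nm case_nm.nii.gz --t1 case_t1.nii.gz --bundle bundle/ \
             --model run/sn_model.npz --model2d run2d/midbrain_model.npz --out out/
```

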