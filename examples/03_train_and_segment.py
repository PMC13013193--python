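"""Train a small priority-gated attention U-Net and segment a held-out case.

Desk-scale configuration: 32-voxel ROI, depth 3, base 8 channels, a few
dozen epochs. The SN prior crop gates every skip connection, and test-time
dropout turns the trained network into a mean-probability + uncertainty
predictor.
"""

import numpy as np

from nigraseg.phantom import PhantomParams, generate_cohort
from nigraseg.nn.unet import NetConfig, build_unet3d
from nigraseg.registration import estimate_sppm, locate_roi, select_template
from nigraseg.training import TrainConfig, normalize_intensity, train
from nigraseg.ttd import binarize, stitch_roi, ttd_predict
from nigraseg.metrics import precision_sensitivity
from nigraseg.volume import ImageVolume

params = PhantomParams()
records, _ = generate_cohort(n_hc=5, n_pd=5, params=params, seed=3)
atlas, train_recs, test_rec = records[:4], records[4:9], records[9]

subjects = [(r.nm, r.sn) for r in atlas]
bundle = select_template(subjects, subset_size=4, seed=0)
chosen = bundle.selection_report["selected"]
estimate_sppm(bundle, [s for i, s in enumerate(subjects) if i != chosen])


def roi_case(rec):
    box, roi_img, roi_sppm = locate_roi(rec.nm, bundle, edge=32)
    img = normalize_intensity(ImageVolume(roi_img, rec.nm.affine)).data
    return box, (img.astype(np.float32), roi_sppm.astype(np.float32),
                 rec.sn.data[box.slices])


cases = [roi_case(r)[1] for r in train_recs]
model = build_unet3d(NetConfig(depth=3, base_channels=8, in_shape=32,
                               attention="priority", init_seed=1))
model, hist = train(model, cases[:4], cases[4:],
                    TrainConfig(epochs=30, lr=0.01, seed=0))
print(f"trained 30 epochs (best at {hist.best_epoch}), validation Dice "
      f"{max(hist.val_dice):.3f}")

box, (img, sppm, truth) = roi_case(test_rec)
ttd = ttd_predict(model, img, sppm, n=10, seed=0)
mask = stitch_roi(binarize(ttd.prob), box, test_rec.nm.shape,
                  affine=test_rec.nm.affine)
report = precision_sensitivity(mask, test_rec.sn)
print(f"held-out {test_rec.label}: Dice {report.dice:.3f}, "
      f"precision {report.precision:.3f}, sensitivity {report.sensitivity:.3f}")
print(f"mean TTD uncertainty inside ROI: {ttd.uncertainty.mean():.4f}")

# With this miniature training set (4 subjects) the held-out Dice lands
# around 0.7, recall-heavy as the asymmetric loss intends; the full
# desk-scale protocol (14 training subjects, 45 epochs — see the test
# suite) reaches ~0.83. The uncertainty is non-zero only where the
# stochastic passes disagree, i.e. on the vague SN boundary.
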