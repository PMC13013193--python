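"""Affine registration, template selection, SN-prior map and ROI localization.

This is the front half of the segmentation pipeline: pick a template volume
from a training subset by pairwise registration (the volume whose propagated
SN label best matches everyone else), build the SN-prior probability map
(SPPM) as the normalized voxelwise frequency of SN membership over subjects
registered to the template, and at inference time register the template to a
new scan and crop a fixed-size cubic ROI around the registered prior's peak.

Registration itself is multi-resolution affine optimization of normalized
correlation (SimpleITK), with full sampling so results are deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .volume import AffineTransform, BinaryMask, ImageVolume, resample_affine

log = logging.getLogger(__name__)


@dataclass
class RegistrationOptions:
    """Knobs for the two-stage affine registration.

    Stage one fits a similarity transform (rotation + isotropic scale +
    translation) from a moments initialization; stage two polishes it as a
    full affine. The metric (normalized correlation by default) is
    restricted to a dilated bright-foreground mask of the fixed image so
    that the large uniform background does not flatten the rotation basin.
    Full metric sampling keeps results deterministic.
    """

    metric: str = "correlation"  # or "mattes" for cross-modality
    similarity_shrink: tuple[int, ...] = (4, 2)
    similarity_sigmas: tuple[float, ...] = (2.0, 1.0)
    similarity_iterations: int = 300
    affine_shrink: tuple[int, ...] = (2,)
    affine_sigmas: tuple[float, ...] = (0.5,)
    affine_iterations: int = 40
    learning_rate: float = 2.0
    min_step: float = 1e-7
    relaxation: float = 0.7
    gradient_tolerance: float = 1e-8
    use_foreground_mask: bool = True
    mask_dilation: int = 4
    mattes_bins: int = 32


@dataclass
class PriorMap:
    """Voxelwise SN prior probability on the template grid.

    Values are normalized label frequencies, so every voxel is a multiple of
    ``1/n_subjects``.
    """

    data: np.ndarray
    affine: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("prior probabilities must lie in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    def as_image(self) -> ImageVolume:
        return ImageVolume(self.data, self.affine)


@dataclass
class TemplateBundle:
    """Template volume, its SN label, the SPPM, and the selection score table."""

    template: ImageVolume
    template_label: BinaryMask
    sppm: PriorMap | None = None
    selection_report: dict = field(default_factory=dict)


@dataclass
class ROIBox:
    """Axis-aligned half-open cubic voxel box ``[lo, lo+edge)``."""

    lo: tuple[int, int, int]
    edge: int

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError("edge must be positive")
        self.lo = tuple(int(v) for v in self.lo)

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, l + self.edge) for l in self.lo)

    def contains_index(self, idx) -> bool:
        return all(l <= i < l + self.edge for l, i in zip(self.lo, idx))


def save_bundle(bundle: TemplateBundle, out_dir) -> None:
    """Persist a template bundle as three NIfTI files + a JSON report."""
    import json
    from pathlib import Path

    from .volume import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(bundle.template, out / "template.nii.gz")
    write_volume(bundle.template_label, out / "template_label.nii.gz")
    meta = {"selection_report": bundle.selection_report}
    if bundle.sppm is not None:
        write_volume(bundle.sppm.as_image(), out / "sppm.nii.gz")
        meta["n_subjects"] = bundle.sppm.n_subjects
    (out / "bundle.json").write_text(json.dumps(meta, default=str))


def load_bundle(bundle_dir) -> TemplateBundle:
    """Load a template bundle persisted by :func:`save_bundle`."""
    import json
    from pathlib import Path

    from .volume import read_volume

    d = Path(bundle_dir)
    if not (d / "template.nii.gz").exists():
        raise FileNotFoundError(f"no template bundle at {d}")
    meta = json.loads((d / "bundle.json").read_text())
    bundle = TemplateBundle(
        template=read_volume(d / "template.nii.gz"),
        template_label=read_volume(d / "template_label.nii.gz", mask=True),
        selection_report=meta.get("selection_report", {}))
    if (d / "sppm.nii.gz").exists():
        sppm_img = read_volume(d / "sppm.nii.gz")
        bundle.sppm = PriorMap(sppm_img.data, sppm_img.affine,
                               int(meta["n_subjects"]))
    return bundle


def _to_sitk(v: ImageVolume) -> sitk.Image:
    spacing = v.spacing
    direction = v.affine[:3, :3] / spacing
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(v.data.astype(np.float32), (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in v.affine[:3, 3]))
    img.SetDirection(tuple(direction.flatten()))
    return img


def _from_sitk_transform(tx: sitk.Transform) -> AffineTransform:
    # Works for plain and composite transforms alike: an affine map is fully
    # determined by the images of the origin and the three basis points.
    origin = np.asarray(tx.TransformPoint((0.0, 0.0, 0.0)))
    M = np.eye(4)
    for j in range(3):
        e = [0.0, 0.0, 0.0]
        e[j] = 1.0
        M[:3, j] = np.asarray(tx.TransformPoint(tuple(e))) - origin
    M[:3, 3] = origin
    return AffineTransform(M)


def _foreground_mask(fixed: ImageVolume, opts: RegistrationOptions):
    from scipy import ndimage
    data = fixed.data
    lo = np.percentile(data, 50)
    fg = data > lo + 0.25 * (data.max() - lo)
    if not fg.any():
        return None
    if opts.mask_dilation:
        fg = ndimage.binary_dilation(fg, iterations=opts.mask_dilation)
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(fg.astype(np.uint8), (2, 1, 0))))
    return img


def _run_stage(f, m, fmask, init_tx, shrink, sigmas, iterations,
               opts: RegistrationOptions):
    reg = sitk.ImageRegistrationMethod()
    if opts.metric == "correlation":
        reg.SetMetricAsCorrelation()
    elif opts.metric == "mattes":
        reg.SetMetricAsMattesMutualInformation(opts.mattes_bins)
    else:
        raise ValueError(f"unknown metric {opts.metric!r}")
    reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling: deterministic
    if fmask is not None:
        reg.SetMetricFixedMask(fmask)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=opts.learning_rate, minStep=opts.min_step,
        numberOfIterations=iterations, relaxationFactor=opts.relaxation,
        gradientMagnitudeTolerance=opts.gradient_tolerance)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(shrink))
    reg.SetSmoothingSigmasPerLevel(list(sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(init_tx, inPlace=False)
    return reg.Execute(f, m)


def register_affine(moving: ImageVolume, fixed: ImageVolume,
                    opts: RegistrationOptions | None = None) -> AffineTransform:
    """Affine registration of ``moving`` onto ``fixed``.

    Returns the transform mapping fixed-space physical points into
    moving-space physical points (the resampling convention). The
    optimization is deterministic for given inputs and options (full metric
    sampling, fixed iteration budgets). If the optimizer fails, an identity
    transform with ``success=False`` is returned and a warning is emitted.
    """
    opts = opts or RegistrationOptions()
    f = _to_sitk(fixed)
    m = _to_sitk(moving)
    try:
        fmask = _foreground_mask(fixed, opts) if opts.use_foreground_mask \
            else None
        if fmask is not None:
            fmask.CopyInformation(f)
        init = sitk.CenteredTransformInitializer(
            f, m, sitk.Similarity3DTransform(),
            sitk.CenteredTransformInitializerFilter.MOMENTS)
        out = _run_stage(f, m, fmask, init, opts.similarity_shrink,
                         opts.similarity_sigmas, opts.similarity_iterations,
                         opts)
        T = _from_sitk_transform(out)
        if opts.affine_iterations > 0:
            aff = sitk.AffineTransform(3)
            aff.SetMatrix(tuple(T.matrix[:3, :3].flatten()))
            aff.SetTranslation(tuple(T.matrix[:3, 3]))
            out = _run_stage(f, m, fmask, aff, opts.affine_shrink,
                             opts.affine_sigmas, opts.affine_iterations, opts)
            T = _from_sitk_transform(out)
        return T
    except RuntimeError as exc:
        warnings.warn(f"registration failed ({exc}); falling back to identity")
        return AffineTransform.identity(success=False)


def select_template(subjects, opts: RegistrationOptions | None = None,
                    subset_size: int = 20,
                    seed: int | None = None) -> TemplateBundle:
    """Choose the template whose propagated SN label best matches the cohort.

    Each candidate is registered to every other subject in the subset, its
    SN label propagated (nearest interpolation) and scored by Dice against
    that subject's own annotation; the candidate with the highest mean Dice
    wins (ties -> lowest index). ``subjects`` is a sequence of
    ``(ImageVolume, BinaryMask)`` pairs; a subset of ``subset_size`` is drawn
    without replacement when the cohort is larger.
    """
    from .metrics import dice

    subjects = list(subjects)
    if len(subjects) < 2:
        raise ValueError("template selection needs at least two subjects")
    indices = np.arange(len(subjects))
    if len(subjects) > subset_size:
        rng = np.random.default_rng(seed)
        indices = np.sort(rng.choice(indices, size=subset_size, replace=False))
    subset = [subjects[i] for i in indices]

    scores: dict[int, float] = {}
    for ci, (cand_img, cand_lab) in enumerate(subset):
        per_subject = []
        for oi, (other_img, other_lab) in enumerate(subset):
            if oi == ci:
                continue
            T = register_affine(cand_img, other_img, opts)
            if not T.success:
                log.warning("template candidate %d: registration to subject "
                            "%d failed", ci, oi)
                continue
            propagated = resample_affine(cand_lab, T, other_img, "nearest")
            per_subject.append(dice(propagated, other_lab))
        scores[int(indices[ci])] = float(np.mean(per_subject)) \
            if per_subject else float("-inf")

    best = max(scores, key=lambda i: (scores[i], -i))
    if scores[best] == float("-inf"):
        raise RuntimeError("all template candidates failed every registration")
    img, lab = subjects[best]
    return TemplateBundle(template=img, template_label=lab,
                          selection_report={"mean_dice": scores,
                                            "selected": int(best),
                                            "subset": indices.tolist()})


def estimate_sppm(bundle: TemplateBundle, others,
                  opts: RegistrationOptions | None = None) -> PriorMap:
    """Estimate the SN-prior probability map on the template grid.

    Every other subject is registered to the template and its binary SN
    label propagated with nearest interpolation; the SPPM voxel value is the
    label frequency normalized by the number of contributing subjects
    (template's own label included). Subjects whose registration fails are
    excluded with a warning.
    """
    others = list(others)
    if not others:
        raise ValueError("SPPM estimation needs at least one other subject")
    template = bundle.template
    counts = bundle.template_label.data.astype(np.float64)
    n = 1
    for i, (img, lab) in enumerate(others):
        T = register_affine(img, template, opts)
        if not T.success:
            warnings.warn(f"subject {i} excluded from SPPM (registration "
                          "failed)")
            continue
        propagated = resample_affine(lab, T, template, "nearest")
        counts += propagated.data
        n += 1
    sppm = PriorMap(data=(counts / n).astype(np.float32),
                    affine=template.affine, n_subjects=n)
    bundle.sppm = sppm
    return sppm


def locate_roi(input_volume: ImageVolume, bundle: TemplateBundle,
               edge: int = 64, opts: RegistrationOptions | None = None,
               transform: AffineTransform | None = None):
    """Register the SPPM onto an input scan and crop the ROI at its peak.

    The cube is centred on the argmax voxel of the registered prior
    (lexicographically smallest index on ties) and shifted — never shrunk —
    to fit inside the grid. Returns ``(ROIBox, cropped input array,
    cropped registered-SPPM array)``. Pass ``transform`` to reuse an
    already-computed template->input registration.
    """
    if bundle.sppm is None:
        raise ValueError("bundle has no SPPM; run estimate_sppm first")
    shape = np.asarray(input_volume.shape)
    if np.any(shape < edge):
        raise ValueError(f"input grid {tuple(shape)} smaller than ROI edge "
                         f"{edge}")
    T = transform if transform is not None \
        else register_affine(bundle.template, input_volume, opts)
    sppm_reg = resample_affine(bundle.sppm.as_image(), T, input_volume,
                               "linear")
    center = np.unravel_index(int(np.argmax(sppm_reg.data)),
                              sppm_reg.data.shape)
    lo = np.clip(np.asarray(center) - edge // 2, 0, shape - edge)
    box = ROIBox(lo=tuple(lo), edge=edge)
    return box, input_volume.data[box.slices], sppm_reg.data[box.slices]
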