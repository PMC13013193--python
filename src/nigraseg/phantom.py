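"""Synthetic midbrain/substantia-nigra phantoms.

Each phantom emulates the anatomy the segmentation pipeline targets: a
bright midbrain-like ellipsoid on a darker background, two mirrored
crescent-shaped substantia-nigra (SN) regions inside it (each built as the
difference of two offset ellipsoids, giving the concave "vague" boundary),
and a small hyperintense core inside each crescent standing in for
nigrosome-1. The neuromelanin-like (NM) channel shows all four tissue
levels; the T1-like channel shows only midbrain-vs-background contrast.

Cohort structure: PD phantoms draw smaller SN crescents and smaller, dimmer
hyperintense cores than HC phantoms, mirroring the reduced nigral volume and
hyperintense-signal loss seen in Parkinson's disease. Every subject also
gets a random rigid+scale pose (rotation, isotropic scale, translation) and
additive Gaussian noise after light smoothing, so registration, ROI
localization and segmentation are all exercised under realistic variability.

All shapes are evaluated analytically under the subject's pose, so ground
truth masks are exact (no resampling artifacts) and the generating affine is
known for use as a registration oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import AffineTransform, BinaryMask, ImageVolume, write_volume


@dataclass
class PhantomParams:
    """Geometry, intensity and variability settings for phantom generation.

    Lengths are mm; intensities arbitrary units (the pipeline normalizes).
    """

    shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    # midbrain ellipsoid
    midbrain_semiaxes: tuple[float, float, float] = (16.0, 13.0, 11.0)
    background_intensity: float = 90.0
    midbrain_intensity: float = 140.0

    # SN crescents: ellipsoid minus an offset "bite" ellipsoid, mirrored
    # about the midsagittal plane; offsets are relative to the midbrain
    # centre (lateral, anterior, axial), the bite offset relative to the SN
    # centre with the lateral component pointing medially.
    sn_offset: tuple[float, float, float] = (4.8, 2.0, 0.0)
    sn_semiaxes: tuple[float, float, float] = (2.9, 5.0, 3.9)
    bite_offset: tuple[float, float, float] = (-2.1, 1.2, 0.0)
    bite_semiaxes: tuple[float, float, float] = (2.6, 4.6, 3.9)
    sn_intensity: float = 152.0

    # hyperintense cores (nigrosome-1 proxy), one per crescent
    core_offset: tuple[float, float, float] = (1.6, -1.2, 0.0)
    core_radius_mean: dict = field(
        default_factory=lambda: {"HC": 1.5, "PD": 1.1})
    core_radius_sd: float = 0.10
    core_intensity: dict = field(
        default_factory=lambda: {"HC": 200.0, "PD": 185.0})

    # cohort-level SN size gap (isotropic scale on the crescent geometry)
    sn_scale_mean: dict = field(default_factory=lambda: {"HC": 1.0, "PD": 0.89})
    sn_scale_sd: float = 0.04

    # T1-like channel
    t1_background: float = 80.0
    t1_midbrain: float = 160.0

    # per-subject pose variability and noise
    rotation_deg: float = 10.0
    scale_range: float = 0.05
    translation_mm: float = 5.0
    noise_sd: float = 5.0
    smooth_sigma_mm: float = 0.7

    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[0, 0], A[1, 1], A[2, 2] = self.spacing
        return A

    def validate(self) -> None:
        off = np.asarray(self.sn_offset)
        semi = np.asarray(self.sn_semiaxes)
        if np.any(np.abs(off) + semi >= np.asarray(self.midbrain_semiaxes)):
            raise ValueError("SN crescent geometry is not contained in the "
                             "midbrain ellipsoid")
        for label in ("HC", "PD"):
            if self.core_radius_mean[label] <= 0:
                raise ValueError("core radius must be positive")


@dataclass
class CohortRecord:
    """One phantom subject: image pair, ground-truth masks and provenance."""

    id: str
    label: str  # "HC" or "PD"
    nm: ImageVolume
    t1: ImageVolume
    sn: BinaryMask
    midbrain: BinaryMask
    core: BinaryMask
    true_affine: AffineTransform  # canonical -> subject pose (physical mm)
    true_core_volume: float  # mm^3, from the exact core mask


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _pose_affine(params: PhantomParams, center: np.ndarray,
                 rng: np.random.Generator) -> AffineTransform:
    """Random canonical->subject pose, centred on the grid centre."""
    R = _rotation_matrix(rng.uniform(-params.rotation_deg,
                                     params.rotation_deg, size=3))
    s = rng.uniform(1 - params.scale_range, 1 + params.scale_range)
    t = rng.uniform(-params.translation_mm, params.translation_mm, size=3)
    A = np.eye(4)
    A[:3, :3] = R * s
    A[:3, 3] = center - (R * s) @ center + t
    return AffineTransform(A)


def _ellipsoid(q: np.ndarray, center: np.ndarray, semiaxes) -> np.ndarray:
    d = (q - center) / np.asarray(semiaxes, dtype=float)
    return (d * d).sum(axis=-1) <= 1.0


def _grid_physical(params: PhantomParams) -> np.ndarray:
    idx = np.indices(params.shape).astype(np.float64)
    pts = np.stack(
        [idx[i] * params.spacing[i] for i in range(3)], axis=-1)
    return pts  # (H,W,D,3)


def generate_subject(params: PhantomParams, label: str,
                     rng: np.random.Generator,
                     subject_id: str = "subject",
                     pose: AffineTransform | None = None) -> CohortRecord:
    """Render one phantom subject with exact ground-truth masks.

    ``pose`` overrides the random per-subject affine (pass
    ``AffineTransform.identity()`` for the canonical pose).
    """
    if label not in ("HC", "PD"):
        raise ValueError("label must be 'HC' or 'PD'")
    params.validate()
    affine = params.affine()
    center = (np.asarray(params.shape) - 1) / 2.0 * np.asarray(params.spacing)
    if pose is None:
        pose = _pose_affine(params, center, rng)

    sn_scale = rng.normal(params.sn_scale_mean[label], params.sn_scale_sd)
    core_r = max(rng.normal(params.core_radius_mean[label],
                            params.core_radius_sd), 0.3)

    pts = _grid_physical(params)
    inv = np.linalg.inv(pose.matrix)
    q = pts @ inv[:3, :3].T + inv[:3, 3]  # canonical-frame coordinates

    midbrain = _ellipsoid(q, center, params.midbrain_semiaxes)
    sn = np.zeros(params.shape, dtype=bool)
    core = np.zeros(params.shape, dtype=bool)
    for side in (1.0, -1.0):
        mirror = np.array([side, 1.0, 1.0])
        c_sn = center + mirror * np.asarray(params.sn_offset)
        body = _ellipsoid(q, c_sn, np.asarray(params.sn_semiaxes) * sn_scale)
        bite = _ellipsoid(q, c_sn + mirror * np.asarray(params.bite_offset),
                          np.asarray(params.bite_semiaxes) * sn_scale)
        crescent = body & ~bite
        sn |= crescent
        c_core = c_sn + mirror * np.asarray(params.core_offset) * sn_scale
        core |= _ellipsoid(q, c_core, (core_r,) * 3) & crescent
    sn &= midbrain
    core &= sn

    nm = np.full(params.shape, params.background_intensity, dtype=np.float32)
    nm[midbrain] = params.midbrain_intensity
    nm[sn] = params.sn_intensity
    nm[core] = params.core_intensity[label]
    t1 = np.full(params.shape, params.t1_background, dtype=np.float32)
    t1[midbrain] = params.t1_midbrain

    sigma_vox = params.smooth_sigma_mm / np.asarray(params.spacing)
    if params.smooth_sigma_mm > 0:
        nm = ndimage.gaussian_filter(nm, sigma_vox)
        t1 = ndimage.gaussian_filter(t1, sigma_vox)
    if params.noise_sd > 0:
        nm = nm + rng.normal(0, params.noise_sd, params.shape).astype(np.float32)
        t1 = t1 + rng.normal(0, params.noise_sd, params.shape).astype(np.float32)

    voxel_volume = float(np.prod(params.spacing))
    return CohortRecord(
        id=subject_id,
        label=label,
        nm=ImageVolume(nm, affine),
        t1=ImageVolume(t1, affine),
        sn=BinaryMask(sn.astype(np.uint8), affine),
        midbrain=BinaryMask(midbrain.astype(np.uint8), affine),
        core=BinaryMask(core.astype(np.uint8), affine),
        true_affine=pose,
        true_core_volume=float(core.sum()) * voxel_volume,
    )


def canonical_subject(params: PhantomParams, label: str = "HC") -> CohortRecord:
    """The noiseless, identity-pose phantom (registration/template oracle)."""
    quiet = replace(params, noise_sd=0.0, rotation_deg=0.0,
                    scale_range=0.0, translation_mm=0.0,
                    sn_scale_sd=0.0, core_radius_sd=0.0)
    rng = np.random.default_rng(0)
    return generate_subject(quiet, label, rng, subject_id="canonical",
                            pose=AffineTransform.identity())


def generate_cohort(n_hc: int, n_pd: int, params: PhantomParams, seed: int,
                    out_dir=None) -> tuple[list[CohortRecord], pd.DataFrame]:
    """Generate a labelled cohort; optionally persist it as NIfTI + manifest.

    Deterministic per seed: each subject's random stream is an independent
    child of one seed sequence, so records are reproducible bit-for-bit.
    """
    if n_hc < 0 or n_pd < 0:
        raise ValueError("cohort counts must be nonnegative")
    labels = ["HC"] * n_hc + ["PD"] * n_pd
    streams = np.random.SeedSequence(seed).spawn(len(labels))
    records = []
    for i, (label, ss) in enumerate(zip(labels, streams)):
        sid = f"{label.lower()}{i:03d}"
        records.append(generate_subject(params, label,
                                        np.random.default_rng(ss), sid))

    rows = []
    for rec in records:
        row = {"id": rec.id, "label": rec.label,
               "true_core_volume_mm3": rec.true_core_volume}
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            for key in ("nm", "t1", "sn", "midbrain", "core"):
                path = out / f"{rec.id}_{key}.nii.gz"
                write_volume(getattr(rec, key), path)
                row[f"{key}_path"] = str(path)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return records, manifest
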