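"""Synthetic body phantom and dynamic PET generator with known ground
truth.

Emulates a dynamic PET-CT study of the kind used to commission this
pipeline: a soft-tissue body with air-filled lungs, kidneys, a bladder and
a tumor painted as ellipsoids of distinct HU; each organ carries a
mono-exponential time-activity curve A(t) = A0 exp(-(lambda_phy +
lambda_bio) t) in activity concentration (Bq/mL, decay-uncorrected frame
averages); frames follow a nine-frame 90-minute schedule.  Counting noise
is Poisson at a configurable scanner sensitivity and an isotropic Gaussian
PSF (4 mm FWHM by default) emulates reconstruction resolution.

Everything is seed-controlled; the ground-truth tables are sufficient to
compute cumulated activities, local alpha doses and low-dose EQDX limits
in closed form for noise-free settings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .kinetics import FrameSchedule
from .volumes import CTVolume

__all__ = ["OrganSpec", "PhantomSpec", "make_phantom", "make_dynamic_pet"]

#: nine frames over 90 minutes (minutes post-injection)
DEFAULT_FRAME_EDGES_MIN = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 20.0, 30.0, 60.0, 90.0)


@dataclass(frozen=True)
class OrganSpec:
    """One ellipsoidal organ: center/semi-axes in mm (grid coordinates),
    CT number, activity concentration at injection time and biological
    clearance constant."""

    name: str
    center_mm: tuple[float, float, float]
    axes_mm: tuple[float, float, float]
    hu: float
    a0_bq_ml: float
    lambda_bio: float  # 1/h

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.axes_mm):
            raise ValueError(f"degenerate ellipsoid for organ {self.name!r}")
        if self.a0_bq_ml < 0:
            raise ValueError("activity concentration must be nonnegative")


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_hu: float = -1000.0
    organs: tuple[OrganSpec, ...] = ()
    frame_edges_min: tuple[float, ...] = DEFAULT_FRAME_EDGES_MIN
    #: expected detected counts per decay (scanner sensitivity); 0 disables noise
    sensitivity: float = 0.02
    psf_fwhm_mm: float = 4.0
    seed: int = 0

    @property
    def schedule(self) -> FrameSchedule:
        e = self.frame_edges_min
        return FrameSchedule(start_min=e[:-1], end_min=e[1:])


def default_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Default body phantom: soft-tissue body, two lungs, two kidneys,
    bladder and a tumor, on a 64x64x48 grid of 4 mm voxels.

    Activity concentrations and clearance constants are of the order seen
    in F-18 amino-acid-tracer studies (kidney-dominated uptake, slow
    parenchymal clearance, accumulating bladder).
    """
    organs = (
        OrganSpec("body", (128, 128, 96), (100, 70, 95), 40, 50.0, 0.05),
        OrganSpec("lung_l", (80, 128, 120), (30, 35, 45), -700, 200.0, 0.1),
        OrganSpec("lung_r", (176, 128, 120), (30, 35, 45), -700, 200.0, 0.1),
        OrganSpec("kidney_l", (88, 128, 60), (24, 16, 40), 40, 4000.0, 0.15),
        OrganSpec("kidney_r", (168, 128, 60), (24, 16, 40), 40, 4000.0, 0.15),
        OrganSpec("bladder", (128, 128, 26), (22, 22, 22), 20, 6000.0, 0.02),
        OrganSpec("tumor", (128, 80, 100), (16, 16, 16), 45, 2500.0, 0.08),
    )
    return replace(PhantomSpec(organs=organs, seed=seed), **overrides)


def _paint(spec: PhantomSpec):
    """Voxelize ellipsoids in listed order (later organs overwrite)."""
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing_mm
    x = (np.arange(nx) + 0.5) * sx
    y = (np.arange(ny) + 0.5) * sy
    z = (np.arange(nz) + 0.5) * sz
    gx, gy, gz = np.meshgrid(x, y, z, indexing="ij")
    hu = np.full(spec.shape, spec.background_hu)
    label = np.full(spec.shape, -1, dtype=int)
    for i, org in enumerate(spec.organs):
        cx, cy, cz = org.center_mm
        ax, ay, az = org.axes_mm
        inside = ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2 <= 1.0
        hu[inside] = org.hu
        label[inside] = i
    return hu, label


def make_phantom(spec: PhantomSpec) -> dict:
    """Build the synthetic CT, organ masks and ground-truth table.

    Returns dict with 'ct' (CTVolume), 'masks' ({organ: bool array},
    disjoint after overwrite), 'label' (int array, -1 = background) and
    'truth' (per-organ DataFrame: A0, lambda_bio, voxel count, volume)."""
    hu, label = _paint(spec)
    ct = CTVolume(hu=hu, spacing_mm=spec.spacing_mm)
    masks = {org.name: label == i for i, org in enumerate(spec.organs)}
    vox_ml = ct.voxel_volume_cm3
    truth = pd.DataFrame(
        [
            {
                "organ": org.name,
                "hu": org.hu,
                "a0_bq_ml": org.a0_bq_ml,
                "lambda_bio": org.lambda_bio,
                "n_voxels": int(masks[org.name].sum()),
                "volume_ml": float(masks[org.name].sum() * vox_ml),
                "analytic_volume_ml": 4.0 / 3.0 * np.pi * np.prod(org.axes_mm) / 1000.0,
            }
            for org in spec.organs
        ]
    )
    return {"ct": ct, "masks": masks, "label": label, "truth": truth}


def frame_average_concentration(
    a0: float, lam: float, t1_h: float, t2_h: float
) -> float:
    """Analytic frame-averaged concentration of A0*exp(-lam t) over
    [t1, t2] (decay-uncorrected)."""
    if lam == 0:
        return a0
    return a0 * (np.exp(-lam * t1_h) - np.exp(-lam * t2_h)) / (lam * (t2_h - t1_h))


def make_dynamic_pet(
    phantom: dict,
    spec: PhantomSpec,
    lambda_phy: float,
    decay_corrected: bool = False,
) -> np.ndarray:
    """Dynamic PET frames, shape (*grid, n_frames), Bq/mL frame averages.

    Frame values are the analytic frame-averaged exponential; Poisson
    counting noise is applied at the configured sensitivity (expected
    counts = conc x voxel volume x frame duration x sensitivity), then the
    optional Gaussian PSF blur.  decay_corrected=True multiplies the noisy
    frames by exp(+lambda_phy t_mid) (vendor-style correction) for testing
    that input path.
    """
    label = phantom["label"]
    sched = spec.schedule
    starts = np.asarray(sched.start_min) / 60.0
    ends = np.asarray(sched.end_min) / 60.0
    rng = np.random.default_rng(spec.seed)
    vox_ml = phantom["ct"].voxel_volume_cm3

    frames = np.zeros(spec.shape + (sched.n_frames,))
    for i, org in enumerate(spec.organs):
        lam = lambda_phy + org.lambda_bio
        sel = label == i
        for f, (t1, t2) in enumerate(zip(starts, ends)):
            frames[sel, f] = frame_average_concentration(org.a0_bq_ml, lam, t1, t2)

    if spec.sensitivity > 0:
        dur_s = sched.durations_h * 3600.0
        expected_counts = frames * vox_ml * dur_s * spec.sensitivity
        counts = rng.poisson(expected_counts)
        with np.errstate(invalid="ignore", divide="ignore"):
            frames = np.where(
                expected_counts > 0, counts / (vox_ml * dur_s * spec.sensitivity), 0.0
            )

    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm / 2.35482 / np.asarray(spec.spacing_mm)
        for f in range(sched.n_frames):
            frames[..., f] = gaussian_filter(frames[..., f], sigma=sigma_vox)

    if decay_corrected:
        frames = frames * np.exp(lambda_phy * sched.midpoints_h)[None, None, None, :]
    return frames
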