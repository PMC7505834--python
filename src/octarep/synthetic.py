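"""Synthetic OCTA phantom generation.

Real angiograms of the kind analyzed here (repeat 3 x 3 mm en-face
scans of healthy eyes) are not publicly deposited, so every downstream
stage is exercised on phantoms that emulate the relevant structure:

* retinal-plexus phantoms: a bright branching vessel tree grown inward
  from the image border with decaying caliber, a capillary mesh built
  from band-pass-filtered noise, a central dark foveal avascular zone
  (FAZ), and speckle;
* choriocapillaris phantoms: stationary granular flow texture with
  Poisson-placed dark elliptical flow deficits;
* within-subject acquisition variation: local elastic perturbation of
  vessel appearance, sub-pixel rigid misalignment, per-acquisition gain
  and offset, and fresh additive noise;
* between-subject variation: subject-level parameter draws (vessel
  density, FAZ size, deficit density, brightness).

The point is a controllable variance hierarchy (subject / acquisition),
with ground-truth masks, not biophysical realism.  By default phantom
intensities are stretched to the full 0-255 range so that pointwise
contrast gains > 1 clip at both ends, matching the regime in which
retinal quantification repeats poorly across contrast changes; the
``NO_CLIP_RANGE`` switch restricts intensities to [65, 191], where a
gain of up to 2.0 is a strictly monotone injective map, for
contrast-invariance analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy import ndimage
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse

from .images import (
    BinaryImage,
    CohortDataset,
    CohortEntry,
    DeviceProfile,
    GrayImage,
    round_half_away,
)
from .ops import apply_rigid

__all__ = [
    "FULL_RANGE",
    "NO_CLIP_RANGE",
    "SubjectParams",
    "AcquisitionJitter",
    "PhantomTruth",
    "PopulationSpec",
    "JitterSpec",
    "make_retinal_template",
    "make_cc_template",
    "simulate_acquisition",
    "make_cohort",
]

FULL_RANGE = (0, 255)
NO_CLIP_RANGE = (65, 191)


@dataclass
class SubjectParams:
    """Subject-level phantom parameters (the between-subject variation)."""

    vessel_density_level: float = 0.5
    faz_radius_um: float = 300.0
    cc_deficit_density: float = 45.0  # expected deficits per mm^2
    cc_deficit_radius_um: float = 13.0
    base_gain: float = 1.0
    # appearance of the retinal slab: how bright vessels render, the
    # background (non-perfused) level, and the capillary-mesh contrast.
    # These differ between eyes and are what makes each eye's histogram
    # respond differently to contrast changes.
    vessel_brightness: float = 170.0
    background_level: float = 95.0
    mesh_contrast: float = 55.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.vessel_density_level < 1):
            raise ValueError("vessel_density_level must lie in (0, 1)")
        if self.faz_radius_um < 0:
            raise ValueError("faz_radius_um must be >= 0")
        if self.cc_deficit_density < 0 or self.cc_deficit_radius_um <= 0:
            raise ValueError("deficit density must be >= 0 and radius > 0")
        if self.base_gain <= 0:
            raise ValueError("base_gain must be positive")


@dataclass
class AcquisitionJitter:
    """Acquisition-level perturbation (the within-subject variation).

    All scales of zero (and zero shift/rotation) reproduce the subject
    template bit-exactly.
    """

    shift_px: tuple[float, float] = (0.0, 0.0)
    rotation_deg: float = 0.0
    gain_sd: float = 0.0
    offset_sd: float = 0.0
    noise_sd: float = 0.0
    vessel_perturbation_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gain_sd", "offset_sd", "noise_sd", "vessel_perturbation_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PhantomTruth:
    """Ground-truth masks (and planted counts) recorded at generation time."""

    faz_mask: BinaryImage | None = None
    vessel_mask: BinaryImage | None = None
    deficit_mask: BinaryImage | None = None
    n_deficits_planted: int | None = None


def _stretch(img: np.ndarray, out_range: tuple[float, float],
             base_gain: float,
             percentiles: tuple[float, float] = (0.2, 99.8)) -> np.ndarray:
    """Stretch to out_range on percentile anchors, apply brightness gain, clip.

    Anchoring at the 0.5th/99.5th percentiles (rather than min/max, which
    would hang the range on isolated outliers) puts real histogram mass
    at both bounds, so a pointwise contrast gain > 1 genuinely clips —
    the full-range operating regime of exported angiograms.  The
    subject-level ``base_gain`` emulates exposure/brightness differences
    between eyes and is applied about the range midpoint, so brighter
    subjects saturate more.
    """
    lo, hi = out_range
    p_lo, p_hi = np.percentile(img, percentiles)
    if p_hi <= p_lo:
        return np.full_like(img, (lo + hi) / 2.0)
    out = lo + (img - p_lo) * (hi - lo) / (p_hi - p_lo)
    mid = (lo + hi) / 2.0
    out = mid + base_gain * (out - mid)
    return np.clip(out, lo, hi)


def make_retinal_template(
    params: SubjectParams,
    size_px: int,
    scan_size_mm: float = 3.0,
    out_range: tuple[float, float] = FULL_RANGE,
) -> tuple[GrayImage, PhantomTruth]:
    """Retinal-plexus phantom: branching vessels, capillary mesh, dark FAZ.

    The vessel tree is a stochastic branching random walk started at the
    image border with caliber decaying along each branch.  Intensities
    are suppressed toward background inside the central FAZ disc (a
    residual noise floor is kept: a real FAZ is dark but not flat).
    """
    if size_px < 64:
        raise ValueError("size_px must be >= 64")
    pitch = scan_size_mm * 1000.0 / size_px
    faz_r_px = params.faz_radius_um / pitch
    if faz_r_px > size_px / 2:
        raise ValueError("faz_radius_um exceeds half the field")
    rng = default_rng(params.rng_seed)
    scale = size_px / 256.0
    shape = (size_px, size_px)

    vessel = np.zeros(shape, dtype=float)  # caliber-weighted deposit
    vmask = np.zeros(shape, dtype=bool)
    # the tree is grown until it covers a density-controlled fraction of
    # the field, so vessel coverage tracks vessel_density_level tightly
    # rather than inheriting the (large) realization variance of a fixed
    # number of random walks
    target_coverage = 0.08 + 0.22 * params.vessel_density_level
    branch_p = 0.012 + 0.02 * params.vessel_density_level
    max_steps = 5 * size_px

    def new_trunk() -> tuple[float, float, float, float]:
        side = rng.integers(4)
        u = rng.uniform(0, size_px)
        if side == 0:
            y, x, theta = 0.0, u, np.pi / 2
        elif side == 1:
            y, x, theta = size_px - 1.0, u, -np.pi / 2
        elif side == 2:
            y, x, theta = u, 0.0, 0.0
        else:
            y, x, theta = u, size_px - 1.0, np.pi
        theta += rng.uniform(-0.5, 0.5)
        return y, x, theta, rng.uniform(2.2, 4.0) * scale

    walkers = [new_trunk() for _ in range(4)]
    n_trunks = 4
    covered = 0
    target_px = target_coverage * size_px * size_px
    while walkers or (covered < target_px and n_trunks < 400):
        if not walkers:
            walkers.append(new_trunk())
            n_trunks += 1
        y, x, theta, cal = walkers.pop()
        for _ in range(max_steps):
            if cal < 0.5 or not (0 <= y < size_px and 0 <= x < size_px):
                break
            rr, cc = draw_disk((y, x), max(cal, 0.7), shape=shape)
            covered += int((~vmask[rr, cc]).sum())
            vmask[rr, cc] = True
            vessel[rr, cc] = np.maximum(vessel[rr, cc], cal)
            theta += rng.normal(0.0, 0.18)
            y += np.sin(theta)
            x += np.cos(theta)
            cal *= 0.997
            if rng.random() < branch_p and cal > 0.8:
                walkers.append(
                    (y, x, theta + rng.choice((-1, 1)) * rng.uniform(0.5, 1.1),
                     cal * 0.7)
                )
                cal *= 0.85
            if covered >= target_px:
                walkers.clear()
                break

    # capillary mesh: band-pass-filtered white noise
    noise = rng.standard_normal(shape)
    mesh = (
        ndimage.gaussian_filter(noise, 0.8 * scale)
        - ndimage.gaussian_filter(noise, 2.0 * scale)
    )
    mesh = mesh / mesh.std()

    # dark-skewed continuum typical of angiograms: a long bright tail of
    # perfused mesh over a heavy dark mass, with no clean histogram valley.
    # The lower third of the range collapses under a contrast gain, which
    # is what breaks rank-threshold invariance on retinal slabs
    skewed = np.exp(0.7 * mesh)
    skewed /= skewed.mean()
    img = params.background_level * 0.4 + params.mesh_contrast * skewed
    cal_ref = vessel.max() if vessel.max() > 0 else 1.0
    img[vmask] = params.vessel_brightness + 60.0 * (vessel[vmask] / cal_ref)

    # FAZ: soft-edged suppression toward background plus a noise floor
    c = (size_px - 1) / 2.0
    yy, xx = np.indices(shape)
    dist = np.hypot(yy - c, xx - c)
    if faz_r_px > 0:
        supp = 0.12 + 0.88 / (1.0 + np.exp(-(dist - faz_r_px) / (1.5 * scale)))
        faz = dist <= faz_r_px
    else:
        supp = np.ones(shape)
        faz = np.zeros(shape, dtype=bool)
    img = img * supp
    img *= 1.0 + 0.08 * rng.standard_normal(shape)  # speckle
    img += 3.0 * rng.standard_normal(shape)
    vmask &= ~faz

    img = _stretch(img, out_range, params.base_gain)
    gray = GrayImage.from_float(img, pitch)
    truth = PhantomTruth(
        faz_mask=BinaryImage(faz, pitch),
        vessel_mask=BinaryImage(vmask, pitch),
    )
    return gray, truth


def make_cc_template(
    params: SubjectParams,
    size_px: int,
    scan_size_mm: float = 3.0,
    out_range: tuple[float, float] = FULL_RANGE,
) -> tuple[GrayImage, PhantomTruth]:
    """Choriocapillaris phantom: homogeneous granular texture, dark deficits.

    Deficit centers follow a Poisson process with the subject's expected
    density per mm^2; each deficit is a darkened ellipse recorded in the
    truth mask.  There is no FAZ in a CC slab.
    """
    if size_px < 64:
        raise ValueError("size_px must be >= 64")
    pitch = scan_size_mm * 1000.0 / size_px
    rng = default_rng(params.rng_seed)
    scale = size_px / 256.0
    shape = (size_px, size_px)

    tex = ndimage.gaussian_filter(rng.standard_normal(shape), 1.0 * scale)
    img = 128.0 + 48.0 * tex / tex.std()

    dmask = np.zeros(shape, dtype=bool)
    lam = params.cc_deficit_density * scan_size_mm * scan_size_mm
    n_deficits = rng.poisson(lam)
    r_px = max(0.8, params.cc_deficit_radius_um / pitch)
    for _ in range(n_deficits):
        cy, cx = rng.uniform(0, size_px, size=2)
        a = max(0.8, rng.lognormal(np.log(r_px), 0.25))
        b = a * rng.uniform(0.55, 1.0)
        ang = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cy, cx, a, b, shape=shape, rotation=ang)
        dmask[rr, cc] = True

    soft = ndimage.gaussian_filter(dmask.astype(float), 0.8 * scale)
    img *= 1.0 - 0.8 * np.clip(soft, 0, 1)
    img *= 1.0 + 0.06 * rng.standard_normal(shape)

    # a homogeneous CC slab is flat mid-gray: no saturated vessel mass, and
    # its display contrast occupies the middle of the range, so pointwise
    # contrast gains up to 2.0 barely clip it (unlike the retinal slabs)
    lo, hi = out_range
    inset = (lo + 0.28 * (hi - lo), lo + 0.72 * (hi - lo))
    img = _stretch(img, inset, params.base_gain, percentiles=(0.02, 99.98))
    gray = GrayImage.from_float(img, pitch)
    return gray, PhantomTruth(deficit_mask=BinaryImage(dmask, pitch),
                              n_deficits_planted=int(n_deficits))


def simulate_acquisition(
    template: GrayImage,
    jitter: AcquisitionJitter,
    out_range: tuple[float, float] = FULL_RANGE,
) -> GrayImage:
    """One repeat acquisition of a subject template.

    Applies, in order: local elastic perturbation of vessel appearance,
    rigid shift + rotation with interpolation, a per-acquisition
    multiplicative gain and additive offset, and additive noise; the
    result is clipped to ``out_range`` (the cohort's intensity contract,
    full 8-bit by default) and rounded back to 8 bits.  Random draws are
    consumed in a fixed order so the output depends only on the jitter
    seed and scales.
    """
    rng = default_rng(jitter.rng_seed)
    img = template.pixels.astype(float)
    shape = img.shape

    field_y = rng.standard_normal(shape)
    field_x = rng.standard_normal(shape)
    if jitter.vessel_perturbation_sd > 0:
        sigma = max(2.0, 6.0 * shape[0] / 256.0)
        dy = ndimage.gaussian_filter(field_y, sigma)
        dx = ndimage.gaussian_filter(field_x, sigma)
        dy *= jitter.vessel_perturbation_sd / max(dy.std(), 1e-12)
        dx *= jitter.vessel_perturbation_sd / max(dx.std(), 1e-12)
        yy, xx = np.indices(shape, dtype=float)
        img = ndimage.map_coordinates(img, [yy + dy, xx + dx], order=1,
                                      mode="nearest")

    img = apply_rigid(img, jitter.shift_px, jitter.rotation_deg)

    gain = 1.0 + jitter.gain_sd * rng.standard_normal()
    offset = jitter.offset_sd * rng.standard_normal()
    img = gain * img + offset

    noise = rng.standard_normal(shape)
    if jitter.noise_sd > 0:
        img = img + jitter.noise_sd * noise

    img = np.clip(img, out_range[0], out_range[1])
    return GrayImage.from_float(img, template.pitch_um)


@dataclass
class PopulationSpec:
    """Between-subject distribution of phantom parameters.

    Defaults describe a healthy-eye cohort: vascular structure varies
    only modestly between normal subjects (which is precisely what keeps
    between-subject variance, and hence ICC, low in such cohorts), while
    image brightness/exposure differs more noticeably between eyes.
    Subject draws are truncated to the valid ranges of
    :class:`SubjectParams`.
    """

    vessel_density_mean: float = 0.5
    vessel_density_sd: float = 0.015
    faz_radius_um_mean: float = 300.0
    faz_radius_um_sd: float = 25.0
    cc_deficit_density_mean: float = 45.0
    cc_deficit_density_sd: float = 13.0
    cc_deficit_radius_um_mean: float = 13.0
    cc_deficit_radius_um_sd: float = 2.5
    base_gain_sd: float = 0.03
    vessel_brightness_sd: float = 3.0
    background_level_sd: float = 2.0
    mesh_contrast_sd: float = 2.0

    def draw(self, rng: np.random.Generator, rng_seed: int) -> SubjectParams:
        return SubjectParams(
            vessel_density_level=float(np.clip(
                rng.normal(self.vessel_density_mean, self.vessel_density_sd),
                0.05, 0.95)),
            faz_radius_um=float(max(0.0, rng.normal(
                self.faz_radius_um_mean, self.faz_radius_um_sd))),
            cc_deficit_density=float(max(5.0, rng.normal(
                self.cc_deficit_density_mean, self.cc_deficit_density_sd))),
            cc_deficit_radius_um=float(max(6.0, rng.normal(
                self.cc_deficit_radius_um_mean, self.cc_deficit_radius_um_sd))),
            base_gain=float(max(0.5, rng.normal(1.0, self.base_gain_sd))),
            vessel_brightness=float(np.clip(
                rng.normal(170.0, self.vessel_brightness_sd), 120.0, 220.0)),
            background_level=float(np.clip(
                rng.normal(95.0, self.background_level_sd), 60.0, 130.0)),
            mesh_contrast=float(np.clip(
                rng.normal(55.0, self.mesh_contrast_sd), 25.0, 90.0)),
            rng_seed=rng_seed,
        )


@dataclass
class JitterSpec:
    """Within-subject (acquisition-to-acquisition) perturbation scales.

    Defaults: rigid misalignment up to 3 px and 1 degree (so that
    registration has something to correct), mild gain/offset drift,
    additive noise, and a sub-pixel elastic perturbation of vessel
    appearance.
    """

    max_shift_px: float = 3.0
    max_rotation_deg: float = 1.0
    gain_sd: float = 0.10
    offset_sd: float = 6.0
    noise_sd: float = 6.0
    vessel_perturbation_sd: float = 0.6

    @classmethod
    def zero(cls) -> "JitterSpec":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def draw(self, rng: np.random.Generator, rng_seed: int) -> AcquisitionJitter:
        return AcquisitionJitter(
            shift_px=(
                float(rng.uniform(-self.max_shift_px, self.max_shift_px)),
                float(rng.uniform(-self.max_shift_px, self.max_shift_px)),
            ),
            rotation_deg=float(
                rng.uniform(-self.max_rotation_deg, self.max_rotation_deg)),
            gain_sd=self.gain_sd,
            offset_sd=self.offset_sd,
            noise_sd=self.noise_sd,
            vessel_perturbation_sd=self.vessel_perturbation_sd,
            rng_seed=rng_seed,
        )


def _seq_seed(seq: SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2 ** 31))


def make_cohort(
    n_subjects: int = 13,
    n_repeats: int = 3,
    plexus: str = "SCP",
    profile: DeviceProfile | None = None,
    population: PopulationSpec | None = None,
    jitter: JitterSpec | None = None,
    master_seed: int = 0,
    out_range: tuple[float, float] = FULL_RANGE,
) -> CohortDataset:
    """Simulate a subjects x repeats cohort for one plexus and device.

    Seeding is hierarchical (master -> subject -> acquisition): each
    subject's repeats derive from a single template, and the whole
    cohort is a deterministic function of ``master_seed``.  Defaults
    mirror the study layout of 13 eyes with 3 successive acquisitions.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects (ICC undefined otherwise)")
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    profile = profile or DeviceProfile("plex", 1024)
    population = population or PopulationSpec()
    jitter = jitter or JitterSpec()
    size_px = profile.image_size_px
    template_fn = make_cc_template if plexus == "CC" else make_retinal_template

    entries: list[CohortEntry] = []
    master = SeedSequence(master_seed)
    for i, subject_seq in enumerate(master.spawn(n_subjects)):
        draw_seq, template_seq, *acq_seqs = subject_seq.spawn(n_repeats + 2)
        params = population.draw(default_rng(draw_seq), _seq_seed(template_seq))
        template, truth = template_fn(
            params, size_px, scan_size_mm=profile.scan_size_mm,
            out_range=out_range,
        )
        subject_id = f"S{i:03d}"
        for r, acq_seq in enumerate(acq_seqs):
            magnitude_seq, noise_seq = acq_seq.spawn(2)
            acq_jitter = jitter.draw(default_rng(magnitude_seq),
                                     _seq_seed(noise_seq))
            image = simulate_acquisition(template, acq_jitter,
                                         out_range=out_range)
            entries.append(
                CohortEntry(
                    subject_id=subject_id,
                    repeat_index=r + 1,
                    plexus=plexus,
                    device=profile.name,
                    processing="none",
                    image=image,
                    truth=truth,
                )
            )
    return CohortDataset(entries)
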