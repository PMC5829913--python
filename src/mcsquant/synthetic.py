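"""Synthetic fluorescence-microscopy scenes with known ground truth.

Generates cellular geometries — a reticular ER network, a plasma-membrane
(PM) compartment and punctate ER–PM membrane contact sites (MCS) — and
renders them into noisy multi-channel confocal/TIRF images and time-lapse
recruitment stacks. Because every structure map is known exactly, each
downstream stage of the pipeline (wavelet masking, compartment intensities,
the MCS index, trace normalization) has a quantitative oracle.

The rendering model is deliberately simple: per-compartment fluorophore
density maps, an isotropic Gaussian PSF, and a Poisson–Gaussian camera model
(shot noise at a configurable photon scale, additive read noise, constant
offset). TIRF optics are emulated only as a geometry change (the PM becomes
the full adherent footprint rather than a boundary band); there is no
evanescent-field depth model and no photobleaching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi


class PunctaPlacementError(ValueError):
    """Requested MCS puncta cannot be placed on the available ER pixels."""


@dataclass(frozen=True)
class NoiseModel:
    """Poisson–Gaussian camera model.

    photon_scale: expected photons at unit fluorophore density (shot noise);
        0 disables the Poisson stage and returns the scaled density.
    read_sigma: Gaussian read noise, counts RMS.
    offset: constant camera offset, counts.
    """

    photon_scale: float = 200.0
    read_sigma: float = 2.0
    offset: float = 100.0

    def __post_init__(self) -> None:
        if self.photon_scale < 0:
            raise ValueError("photon_scale must be >= 0")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")

    def apply(self, density: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        counts = self.photon_scale * np.asarray(density, dtype=float)
        if self.photon_scale > 0:
            counts = rng.poisson(counts).astype(float)
        if self.read_sigma > 0:
            counts = counts + rng.normal(0.0, self.read_sigma, size=counts.shape)
        return counts + self.offset


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and acquisition parameters of one synthetic cell.

    Lengths are in pixels unless suffixed ``_um``. ``er_density`` is the
    expected ER skeleton length per unit area (µm/µm²); typical cortical ER
    in COS-7-like fibroblasts is on the order of 1–3 µm/µm².
    """

    size: int = 128
    pixel_size_um: float = 0.1
    cell_center: tuple[float, float] | None = None  # (y, x); default = field center
    cell_semiaxes: tuple[float, float] | None = None  # (a_y, a_x) px
    er_density: float = 0.15  # µm skeleton per µm² of cell area (see docs/methods.md)
    tubule_width_px: int = 3
    nucleus_radius_px: float | None = None  # default = 0.12 * size
    n_puncta: int = 6
    punctum_radius_px: int = 2
    psf_sigma_px: float = 1.0
    modality: str = "confocal-section"  # or "tirf-footprint"
    pm_band_px: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("size must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.er_density < 0:
            raise ValueError("er_density must be >= 0")
        if self.tubule_width_px <= 0:
            raise ValueError("tubule_width_px must be positive")
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")
        if self.punctum_radius_px <= 0:
            raise ValueError("punctum_radius_px must be positive")
        if self.psf_sigma_px < 0:
            raise ValueError("psf_sigma_px must be >= 0")
        if self.modality not in ("confocal-section", "tirf-footprint"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def resolved_center(self) -> tuple[float, float]:
        if self.cell_center is not None:
            return self.cell_center
        return (self.size / 2.0, self.size / 2.0)

    @property
    def resolved_semiaxes(self) -> tuple[float, float]:
        if self.cell_semiaxes is not None:
            return self.cell_semiaxes
        return (0.34 * self.size, 0.30 * self.size)

    @property
    def resolved_nucleus_radius(self) -> float:
        if self.nucleus_radius_px is not None:
            return self.nucleus_radius_px
        return 0.12 * self.size


@dataclass(frozen=True)
class GroundTruth:
    """Binary structure maps and fluorophore density maps of one scene.

    Invariant: the MCS map is a subset of the ER map support — contact
    sites are ER subdomains, so the ER marker is present wherever the MCS
    marker is.
    """

    config: SceneConfig
    cell_mask: np.ndarray
    er_mask: np.ndarray
    pm_mask: np.ndarray
    mcs_mask: np.ndarray
    er_skeleton: np.ndarray

    def __post_init__(self) -> None:
        shape = (self.config.size, self.config.size)
        for name in ("cell_mask", "er_mask", "pm_mask", "mcs_mask", "er_skeleton"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.mcs_mask & ~self.er_mask):
            raise ValueError("MCS map must be a subset of the ER map support")

    @property
    def er_density_map(self) -> np.ndarray:
        return self.er_mask.astype(float)

    @property
    def mcs_density_map(self) -> np.ndarray:
        return self.mcs_mask.astype(float)

    @property
    def pm_density_map(self) -> np.ndarray:
        return self.pm_mask.astype(float)


_PROFILE_CLASSES = ("fast-transient", "slow-transient", "sustained", "flat")

# Default time constants per profile class, seconds. Chosen to emulate the
# canonical agonist-evoked recruitment kinetics of ER-PM MCS proteins:
# E-Syt1-like (peak ~30 s, back to baseline within ~2 min), STIM1-like
# (peak ~2 min), Nir2-like (slow ~5 min rise, sustained).
_PROFILE_DEFAULTS: dict[str, tuple[float, float]] = {
    "fast-transient": (10.0, 40.0),
    "slow-transient": (45.0, 180.0),
    "sustained": (90.0, math.inf),
    "flat": (10.0, math.inf),
}


@dataclass(frozen=True)
class KineticsProfile:
    """Recruitment time course of the MCS channel, as peak ∆(F_t/F_pre).

    Transient classes follow A·(1−exp(−u/τ_rise))·exp(−u/τ_decay), scaled so
    the peak equals ``amplitude``; ``sustained`` is a saturating exponential
    rise to ``amplitude``; ``flat`` is identically zero.
    """

    profile_class: str = "fast-transient"
    amplitude: float = 0.5
    rise_tau_s: float | None = None
    decay_tau_s: float | None = None
    stim_frame: int = 5

    def __post_init__(self) -> None:
        if self.profile_class not in _PROFILE_CLASSES:
            raise ValueError(f"unknown profile class {self.profile_class!r}")
        if self.profile_class == "flat" and self.amplitude != 0:
            raise ValueError("flat profile requires amplitude 0")
        if self.rise_tau_s is not None and self.rise_tau_s <= 0:
            raise ValueError("rise_tau_s must be positive")
        if self.decay_tau_s is not None and self.decay_tau_s <= 0:
            raise ValueError("decay_tau_s must be positive")
        if self.stim_frame < 0:
            raise ValueError("stim_frame must be >= 0")

    @property
    def rise(self) -> float:
        return self.rise_tau_s if self.rise_tau_s is not None else _PROFILE_DEFAULTS[self.profile_class][0]

    @property
    def decay(self) -> float:
        if self.decay_tau_s is not None:
            return self.decay_tau_s
        return _PROFILE_DEFAULTS[self.profile_class][1]

    def amplitude_at(self, seconds_after_stim: np.ndarray | float) -> np.ndarray:
        """∆(F_t/F_pre) as a function of time since stimulation (s)."""
        u = np.atleast_1d(np.asarray(seconds_after_stim, dtype=float))
        a = np.zeros_like(u)
        pos = u > 0
        if self.profile_class == "flat":
            return a if np.ndim(seconds_after_stim) else a[0]
        tr = self.rise
        if self.profile_class == "sustained":
            a[pos] = self.amplitude * (1.0 - np.exp(-u[pos] / tr))
        else:
            td = self.decay
            # peak of (1-e^{-u/tr})e^{-u/td} is at u* = tr*ln(1+td/tr)
            u_star = tr * math.log1p(td / tr)
            peak = (1.0 - math.exp(-u_star / tr)) * math.exp(-u_star / td)
            f = (1.0 - np.exp(-u[pos] / tr)) * np.exp(-u[pos] / td)
            a[pos] = self.amplitude * f / peak
        return a if np.ndim(seconds_after_stim) else a[0]


def _ellipse_mask(size: int, center: tuple[float, float], semiaxes: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = center
    ay, ax = semiaxes
    return ((yy + 0.5 - cy) / ay) ** 2 + ((xx + 0.5 - cx) / ax) ** 2 <= 1.0


# 4-connected steps keep dilated tubules at their nominal width everywhere
# (diagonal runs would thin a 3 px band to ~2 px).
_STEPS = np.array([(-1, 0), (0, 1), (1, 0), (0, -1)])


def _grow_skeleton(
    allowed: np.ndarray, target_px: int, rng: np.random.Generator,
    spacing_px: int = 4,
) -> np.ndarray:
    """Reticular skeleton from persistent random branching walks on the lattice.

    Walks avoid an exclusion zone of ``spacing_px`` around previously laid
    tubules (emulating the characteristic spacing of the peripheral ER
    polygon network); branches leave their parent at right angles with a
    short grace period so T-junctions can form.
    """
    skel = np.zeros_like(allowed, dtype=bool)
    if target_px <= 0:
        return skel
    allowed_idx = np.argwhere(allowed)
    if allowed_idx.size == 0:
        return skel
    exclusion = np.zeros_like(allowed, dtype=bool)
    spacer = _disk(spacing_px)
    total = 0
    branch_stack: list[tuple[int, int, int]] = []  # (y, x, direction)
    max_iter = 60 * target_px + 2000
    iters = 0
    while total < target_px and iters < max_iter:
        iters += 1
        if branch_stack and rng.random() < 0.6:
            y, x, d = branch_stack.pop()
            d = (d + rng.choice([-1, 1])) % 4  # branches leave at right angles
            grace = spacing_px + 2
        else:
            y, x = allowed_idx[rng.integers(len(allowed_idx))]
            if exclusion[y, x]:
                continue
            d = int(rng.integers(4))
            grace = 0
        walk: list[tuple[int, int]] = []
        for step in range(int(rng.integers(40, 100))):
            if not allowed[y, x] or (step >= grace and exclusion[y, x]):
                break
            walk.append((y, x))
            if len(walk) + total >= target_px:
                break
            if rng.random() < 0.02:
                branch_stack.append((y, x, d))
            if rng.random() < 0.06:
                d = (d + rng.choice([-1, 1])) % 4
            dy, dx = _STEPS[d]
            ny, nx = y + dy, x + dx
            if not (0 <= ny < skel.shape[0] and 0 <= nx < skel.shape[1]):
                break
            y, x = ny, nx
        if len(walk) < 12 and total + len(walk) < target_px:
            continue  # discard stubs; they segment poorly and look unphysiological
        new_total = total
        for py, px_ in walk:
            if not skel[py, px_]:
                skel[py, px_] = True
                new_total += 1
        total = new_total
        mask = np.zeros_like(skel)
        for py, px_ in walk:
            mask[py, px_] = True
        exclusion |= ndi.binary_dilation(mask, structure=spacer)
    return skel


def generate_ground_truth(config: SceneConfig) -> GroundTruth:
    """Grow the seeded ground-truth geometry for one cell.

    The ER skeleton is grown as random branching walks inside the cell
    (excluding a nuclear disc) until the target skeleton length implied by
    ``er_density`` is reached, then dilated to the tubule width. MCS puncta
    are discs centred on ER skeleton pixels with enforced minimum separation
    so they form exactly ``n_puncta`` connected components; the ER support
    is extended to include them (contact sites are ER subdomains).
    """
    rng = np.random.default_rng(config.seed)
    size = config.size
    cell = _ellipse_mask(size, config.resolved_center, config.resolved_semiaxes)
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = config.resolved_center
    nucleus = (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2 <= config.resolved_nucleus_radius**2
    if config.modality == "confocal-section":
        interior = ndi.binary_erosion(cell, iterations=config.pm_band_px)
        pm = cell & ~interior
    else:  # TIRF footprint: whole adherent sheet
        pm = cell.copy()
    allowed = cell & ~nucleus

    area_um2 = float(cell.sum()) * config.pixel_size_um**2
    target_px = int(round(config.er_density * area_um2 / config.pixel_size_um))
    skeleton = _grow_skeleton(allowed, target_px, rng)
    half = config.tubule_width_px // 2
    if half > 0:
        er = ndi.binary_dilation(skeleton, structure=_disk(half))
    else:
        er = skeleton.copy()
    er &= allowed

    mcs = np.zeros_like(er)
    if config.n_puncta > 0:
        centers = _place_puncta(skeleton, config.n_puncta, config.punctum_radius_px, rng)
        disc = _disk(config.punctum_radius_px)
        r = config.punctum_radius_px
        for py, px in centers:
            y0, y1 = py - r, py + r + 1
            x0, x1 = px - r, px + r + 1
            sy0, sx0 = max(0, -y0), max(0, -x0)
            y0, x0 = max(0, y0), max(0, x0)
            sub = disc[sy0 : sy0 + (min(y1, size) - y0), sx0 : sx0 + (min(x1, size) - x0)]
            mcs[y0 : min(y1, size), x0 : min(x1, size)] |= sub
        mcs &= cell
        er = er | mcs  # MCS are ER subdomains

    return GroundTruth(
        config=config,
        cell_mask=cell,
        er_mask=er,
        pm_mask=pm,
        mcs_mask=mcs,
        er_skeleton=skeleton,
    )


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return yy**2 + xx**2 <= radius**2


def _place_puncta(
    skeleton: np.ndarray, n: int, radius: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    candidates = np.argwhere(skeleton)
    if len(candidates) < n:
        raise PunctaPlacementError(
            f"requested {n} puncta but only {len(candidates)} ER pixels are available"
        )
    min_sep2 = float((2 * radius + 2) ** 2)
    chosen: list[tuple[int, int]] = []
    for _ in range(10):  # greedy placement is order-dependent; restart a few times
        order = rng.permutation(len(candidates))
        chosen = []
        for i in order:
            y, x = map(int, candidates[i])
            if all((y - py) ** 2 + (x - px) ** 2 >= min_sep2 for py, px in chosen):
                chosen.append((y, x))
                if len(chosen) == n:
                    return chosen
    raise PunctaPlacementError(
        f"could only place {len(chosen)} of {n} puncta with minimum separation "
        f"{2 * radius + 2} px on the ER skeleton"
    )


def render_scene(
    truth: GroundTruth,
    alpha: float,
    expression: float = 1.0,
    noise: NoiseModel | None = None,
    psf_sigma_px: float | None = None,
    mcs_er_baseline: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Render marker channels plus a test protein mixing ER and MCS pools.

    The test-protein density is ``expression * (alpha*MCS + (1-alpha)*ER)``:
    alpha=0 is a purely reticular (ER-like) protein, alpha=1 a purely
    punctate (MCS-like) one. ``mcs_er_baseline`` adds a faint reticular
    component to the MCS-marker channel (real MCS markers retain some
    general ER signal). Channels are blurred with a Gaussian PSF and passed
    through the noise model; ``noise=None`` returns noise-free densities.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"mixing fraction alpha must be in [0, 1], got {alpha}")
    if expression <= 0:
        raise ValueError("expression must be positive")
    if psf_sigma_px is None:
        psf_sigma_px = truth.config.psf_sigma_px
    er_d = truth.er_density_map
    mcs_d = truth.mcs_density_map
    channels = {
        "er": er_d,
        "mcs": mcs_d + mcs_er_baseline * er_d,
        "test": expression * (alpha * mcs_d + (1.0 - alpha) * er_d),
    }
    if rng is None:
        rng = np.random.default_rng(truth.config.seed + 1)
    out = {}
    for name, dens in channels.items():
        img = ndi.gaussian_filter(dens, psf_sigma_px) if psf_sigma_px > 0 else dens.copy()
        out[name] = noise.apply(img, rng) if noise is not None else img
    return out


def simulate_timelapse(
    truth: GroundTruth,
    profile: KineticsProfile,
    n_frames: int,
    frame_interval_s: float,
    noise: NoiseModel | None = None,
    psf_sigma_px: float | None = None,
    rng: np.random.Generator | None = None,
):
    """Time-lapse of an MCS-recruitment channel over constant ER background.

    Frames before ``profile.stim_frame`` carry amplitude 0. The punctate
    recruitment pattern is scaled so that the in-cell mean intensity at time
    t equals ``(1 + a(t))`` times the pre-stimulation mean; noise-free, the
    recovered ∆(F_t/F_pre) trace therefore equals the profile exactly.
    Returns an :class:`mcsquant.io.ImageStack` with axes (1, T, 1, Y, X).
    """
    from .io import ImageStack  # local import to avoid a cycle

    if profile.stim_frame >= n_frames:
        raise ValueError(
            f"stimulation frame {profile.stim_frame} must be < n_frames {n_frames}"
        )
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    if psf_sigma_px is None:
        psf_sigma_px = truth.config.psf_sigma_px
    if rng is None:
        rng = np.random.default_rng(truth.config.seed + 2)

    base = truth.er_density_map
    pattern = truth.mcs_density_map
    if psf_sigma_px > 0:
        base = ndi.gaussian_filter(base, psf_sigma_px)
        pattern = ndi.gaussian_filter(pattern, psf_sigma_px)
    cell = truth.cell_mask
    base_mean = float(base[cell].mean())
    if base_mean <= 0:
        raise ValueError("ER background is empty; cannot simulate a recruitment trace")
    pat_mean = float(pattern[cell].mean())
    if pat_mean > 0:
        pattern = pattern * (base_mean / pat_mean)
    elif profile.amplitude != 0:
        raise ValueError("profile has non-zero amplitude but the MCS map is empty")

    t0 = profile.stim_frame * frame_interval_s
    times = np.arange(n_frames) * frame_interval_s
    amps = profile.amplitude_at(times - t0)
    frames = np.empty((n_frames,) + base.shape, dtype=float)
    for i, a in enumerate(amps):
        dens = base + a * pattern
        frames[i] = noise.apply(dens, rng) if noise is not None else dens
    data = frames[np.newaxis, :, np.newaxis]
    return ImageStack(
        data=data,
        channels=("recruited",),
        pixel_size_um=truth.config.pixel_size_um,
        frame_interval_s=frame_interval_s,
        modality="tirf-footprint",
    )


def scene_batch_configs(
    base: SceneConfig, n_cells: int, global_seed: int
) -> list[SceneConfig]:
    """Per-cell configs with independent deterministic seed substreams."""
    ss = np.random.SeedSequence(global_seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_cells)]
    return [replace(base, seed=s) for s in seeds]
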