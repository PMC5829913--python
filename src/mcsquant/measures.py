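"""Per-cell quantities: compartment intensities, the MCS index, TIRF/epi
enrichment, normalized recruitment traces, contact-site occupancy, and the
helical-linker length prediction.

All intensity measures operate on a single cell ROI and return
dimensionless ratios. Missing values (empty masks, zero denominators) are
explicit NaNs with a recorded status — never silent zeros — so they
propagate cleanly into the statistics layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .wavelet import CompartmentMask, WaveletParams, normalize_to_cell_mean, segment_compartment

HELICAL_RISE_NM = 0.15  # alpha-helix rise per residue, 1.5 Å
RESIDUES_PER_REPEAT = 5  # EAAAR


@dataclass(frozen=True)
class CompartmentIntensity:
    """Mean reporter intensity in a compartment, relative to the whole cell.

    The reporter is cell-mean-normalized first, so a value of 1 means the
    compartment is indistinguishable from the cell average, and a value of
    10 means all signal sits in a compartment covering 10% of the cell.
    """

    value: float
    compartment: str
    channel: str | None = None
    cell_id: int | None = None
    status: str = "ok"


@dataclass(frozen=True)
class MCSIndexResult:
    """Per-cell MCS index: dev_ER − dev_MCS after per-channel max scaling.

    dev_X is the in-ROI mean absolute deviation between the max-normalized
    test image and marker X. Both deviations lie in [0, 1], the index in
    [−1, 1]; positive = MCS-like, negative = ER-like test protein.
    """

    index: float
    dev_er: float
    dev_mcs: float
    cell_id: int | None = None
    test_channel: str | None = None
    mcs_channel: str | None = None
    er_channel: str | None = None


@dataclass(frozen=True)
class NormalizedTrace:
    """F_t/F_pre trace: per-frame in-ROI mean over its pre-stimulation mean."""

    f_over_fpre: np.ndarray
    delta: np.ndarray  # F_t/F_pre − 1
    time_s: np.ndarray | None
    pre_window: tuple[int, int]
    f_pre: float
    cell_id: int | None = None


def compartment_intensity(
    reporter: np.ndarray,
    mask: CompartmentMask | np.ndarray,
    roi: np.ndarray,
    compartment: str = "compartment",
    channel: str | None = None,
    cell_id: int | None = None,
    normalize: bool = True,
) -> CompartmentIntensity:
    """Mean of the (cell-mean-normalized) reporter within a compartment mask.

    With ``normalize=False`` the reporter is assumed to already have in-ROI
    mean 1. An empty mask yields a NaN value with status ``"empty-mask"``.
    """
    roi = np.asarray(roi, dtype=bool)
    mask_arr = mask.mask if isinstance(mask, CompartmentMask) else np.asarray(mask, dtype=bool)
    if mask_arr.shape != roi.shape:
        raise ValueError("mask and ROI shapes differ")
    img = normalize_to_cell_mean(reporter, roi) if normalize else np.asarray(reporter, float)
    sel = mask_arr & roi
    if not sel.any():
        return CompartmentIntensity(
            value=math.nan, compartment=compartment, channel=channel, cell_id=cell_id,
            status="empty-mask",
        )
    return CompartmentIntensity(
        value=float(img[sel].mean()), compartment=compartment, channel=channel,
        cell_id=cell_id,
    )


def _max_normalize(image: np.ndarray, roi: np.ndarray, quantile: float | None) -> np.ndarray:
    """Scale so the in-ROI maximum (or upper quantile) is 1, clipped to [0, 1]."""
    img = np.clip(np.asarray(image, dtype=float), 0.0, None)
    vals = img[roi]
    scale = float(np.max(vals)) if quantile is None else float(np.percentile(vals, quantile))
    if scale <= 0:
        raise ValueError("channel is all-zero within the ROI; max-normalization undefined")
    return np.clip(img / scale, 0.0, 1.0)


def mcs_index(
    test: np.ndarray,
    mcs: np.ndarray,
    er: np.ndarray,
    roi: np.ndarray,
    max_quantile: float | None = None,
    cell_id: int | None = None,
    channels: tuple[str, str, str] | None = None,
) -> MCSIndexResult:
    """Score a test protein's distribution between ER-like and MCS-like.

    Each channel is scaled to its in-ROI maximum (or, with ``max_quantile``,
    a robust upper percentile such as 99.9 to resist single hot pixels);
    dev_MCS = mean|I_MCS − I_test| and dev_ER = mean|I_ER − I_test| over the
    ROI; the index is dev_ER − dev_MCS.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    for name, img in (("test", test), ("mcs", mcs), ("er", er)):
        if np.asarray(img).shape != roi.shape:
            raise ValueError(f"{name} channel shape does not match the ROI grid")
    i_test = _max_normalize(test, roi, max_quantile)
    i_mcs = _max_normalize(mcs, roi, max_quantile)
    i_er = _max_normalize(er, roi, max_quantile)
    dev_mcs = float(np.abs(i_mcs - i_test)[roi].mean())
    dev_er = float(np.abs(i_er - i_test)[roi].mean())
    names = channels or (None, None, None)
    return MCSIndexResult(
        index=dev_er - dev_mcs, dev_er=dev_er, dev_mcs=dev_mcs, cell_id=cell_id,
        test_channel=names[0], mcs_channel=names[1], er_channel=names[2],
    )


def tirf_epi_ratio(tirf: np.ndarray, epi: np.ndarray, roi: np.ndarray) -> float:
    """Ratio of in-ROI mean intensities, TIRF / epi-illumination.

    Reports enrichment of a protein near the coverslip-proximal PM; both
    images must already be background subtracted.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    epi_mean = float(np.asarray(epi, float)[roi].mean())
    if epi_mean <= 0:
        raise ValueError(f"epi in-ROI mean must be positive, got {epi_mean}")
    return float(np.asarray(tirf, float)[roi].mean()) / epi_mean


def roi_mean_trace(frames: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Per-frame in-ROI mean of a (T, Y, X) array."""
    frames = np.asarray(frames, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    return frames[:, roi].mean(axis=1)


def normalize_timelapse(
    trace: np.ndarray,
    pre_window: tuple[int, int],
    frame_interval_s: float | None = None,
    cell_id: int | None = None,
) -> NormalizedTrace:
    """Normalize a per-frame mean-intensity trace to its pre-stimulation mean.

    ``pre_window`` is a half-open frame range [start, stop). The mean of
    F_t/F_pre over the pre-window is exactly 1 and ∆ = F_t/F_pre − 1.
    """
    trace = np.asarray(trace, dtype=float)
    start, stop = pre_window
    if not 0 <= start < stop <= len(trace):
        raise ValueError(f"pre-window {pre_window} invalid for a {len(trace)}-frame trace")
    f_pre = float(trace[start:stop].mean())
    if f_pre <= 0:
        raise ValueError(f"pre-stimulation mean must be positive, got {f_pre}")
    f = trace / f_pre
    time_s = np.arange(len(trace)) * frame_interval_s if frame_interval_s else None
    return NormalizedTrace(
        f_over_fpre=f, delta=f - 1.0, time_s=time_s, pre_window=(start, stop),
        f_pre=f_pre, cell_id=cell_id,
    )


def frame_average(frames: np.ndarray, window: int) -> np.ndarray:
    """Boxcar-average a (T, Y, X) stack over non-overlapping frame windows.

    Mirrors the practice of averaging a few consecutive frames before trace
    extraction to improve signal to noise; trailing frames that do not fill
    a window are dropped.
    """
    frames = np.asarray(frames, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    n = (len(frames) // window) * window
    return frames[:n].reshape(-1, window, *frames.shape[1:]).mean(axis=1)


def excitation_ratio(
    frames_405: np.ndarray, frames_488: np.ndarray, roi: np.ndarray
) -> np.ndarray:
    """Per-frame ratio of in-ROI means for dual-excitation ratiometric dyes.

    Frames where the 488-excited denominator is non-positive produce NaN
    (declared missing), not an error.
    """
    a = roi_mean_trace(frames_405, roi)
    b = roi_mean_trace(frames_488, roi)
    if len(a) != len(b):
        raise ValueError("405 and 488 stacks have different frame counts")
    out = np.full(len(a), np.nan)
    good = b > 0
    out[good] = a[good] / b[good]
    return out


def mask_overlap_fraction(
    probe_mask: np.ndarray, site_mask: np.ndarray, roi: np.ndarray | None = None
) -> float:
    """Fraction of site pixels also covered by the probe mask (NaN if empty)."""
    probe = np.asarray(probe_mask, dtype=bool)
    site = np.asarray(site_mask, dtype=bool)
    if roi is not None:
        r = np.asarray(roi, dtype=bool)
        probe, site = probe & r, site & r
    n_site = int(site.sum())
    if n_site == 0:
        return math.nan
    return float((probe & site).sum()) / n_site


def occupancy_fraction(
    probe_image: np.ndarray,
    site_mask: CompartmentMask,
    roi: np.ndarray,
    params: WaveletParams | None = None,
) -> float:
    """Fraction of induced contact sites occupied by a probe's fluorescence.

    Occupancy is operationalized as joint wavelet-mask positivity: the probe
    image is segmented with the same wavelet parameters that produced the
    site mask (from the recruiter channel), and the fraction of site pixels
    where the probe mask is also positive is returned. Proteins "squeezed
    out" of the induced sites score near 0; unconstrained ER proteins that
    remain throughout score near 1.
    """
    if params is None:
        params = site_mask.params
    probe_mask = segment_compartment(probe_image, roi, params)
    return mask_overlap_fraction(probe_mask.mask, site_mask.mask, roi)


def linker_length(n_repeats: int) -> float:
    """Predicted length in nm of n tandem EAAAR helical-linker repeats.

    One EAAAR repeat in an alpha-helix spans 5 residues x 1.5 Å rise =
    7.5 Å = 0.75 nm, so HLx2..HLx10 span 1.5-7.5 nm.
    """
    if not isinstance(n_repeats, (int, np.integer)) or isinstance(n_repeats, bool):
        raise TypeError("n_repeats must be an integer")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    return n_repeats * RESIDUES_PER_REPEAT * HELICAL_RISE_NM
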