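"""Spectrum preprocessing: smoothing, baseline removal, variance
stabilization, peak detection, monoisotopic filtering, recalibration,
normalization, alignment and binning into a feature × spot intensity matrix.

The stage order is fixed — smooth → baseline → sqrt → (peaks) → recalibrate →
normalize → align → bin — and each stage stamps a metadata flag so that no
stage can be applied twice.  Every stage is individually switchable in the
pipeline configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import grey_opening, maximum_filter1d
from scipy.signal import savgol_filter

from .spectra_io import PlateLayout, Spectrum

__all__ = [
    "PeakList",
    "IntensityMatrix",
    "smooth_savitzky_golay",
    "remove_baseline_tophat",
    "sqrt_transform",
    "estimate_noise",
    "detect_peaks",
    "filter_monoisotopic",
    "recalibrate_to_reference",
    "normalize",
    "align_peaklists",
    "bin_peaks",
    "average_by_concentration",
    "isotope_lambda",
]

#: Average spacing between isotopic peaks for singly charged organic ions (Th).
ISOTOPE_SPACING = 1.00235


@dataclass
class PeakList:
    """Detected peaks of one spot, sorted by m/z."""

    spot_id: str
    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if not (len(self.mz) == len(self.intensity) == len(self.snr)):
            raise ValueError("peak arrays must have equal length")
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("peak m/z values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.mz)

    def replace(self, mz, intensity, snr, **meta) -> "PeakList":
        md = dict(self.metadata)
        md.update(meta)
        return PeakList(self.spot_id, mz, intensity, snr, md)


@dataclass
class IntensityMatrix:
    """Binned feature × spot intensity table.

    ``values[i, j]`` is the peak intensity of feature ``feature_mz[i]`` in
    spot ``spots[j]`` (0 where the spot has no peak in the bin).  Column
    order follows the attached layout.
    """

    feature_mz: np.ndarray
    spots: list[str]
    values: np.ndarray
    layout: PlateLayout | None = None

    def __post_init__(self) -> None:
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_mz), len(self.spots)):
            raise ValueError("values shape must be (n_features, n_spots)")
        if len(self.feature_mz) > 1 and not np.all(np.diff(self.feature_mz) > 0):
            raise ValueError("feature m/z values must be strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_mz, columns=self.spots)


def _require_not_done(s: Spectrum, flag: str) -> None:
    if s.metadata.get(flag):
        raise ValueError(f"stage {flag!r} already applied to spot {s.spot_id!r}")


def smooth_savitzky_golay(s: Spectrum, half_window: int = 10, poly_order: int = 3) -> Spectrum:
    """Savitzky–Golay smoothing over a window of 2·half_window+1 points.

    Low-order polynomial signals are reproduced exactly; negative filter
    outputs are clipped to zero.
    """
    _require_not_done(s, "smoothed")
    window = 2 * half_window + 1
    if window <= poly_order:
        raise ValueError("window must exceed polynomial order")
    if len(s.intensity) <= window:
        raise ValueError("spectrum shorter than smoothing window")
    smoothed = savgol_filter(s.intensity, window_length=window, polyorder=poly_order)
    return s.replace(intensity=np.clip(smoothed, 0.0, None),
                     metadata={**s.metadata, "smoothed": True})


def remove_baseline_tophat(s: Spectrum, half_window: int = 75) -> Spectrum:
    """TopHat baseline removal: subtract the morphological opening.

    The opening (erosion then dilation with a flat structuring element of
    width 2·half_window+1) is everywhere ≤ the signal, so the output is
    non-negative and never exceeds the input.
    """
    _require_not_done(s, "baseline_removed")
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    opening = grey_opening(s.intensity, size=2 * half_window + 1, mode="nearest")
    corrected = np.clip(s.intensity - opening, 0.0, None)
    return s.replace(intensity=corrected,
                     metadata={**s.metadata, "baseline_removed": True})


def sqrt_transform(s: Spectrum) -> Spectrum:
    """Square-root transform to stabilize intensity variance.

    Applied exactly once per spectrum; a metadata flag guards against double
    application (which would compute a fourth root).
    """
    _require_not_done(s, "sqrt_transformed")
    if np.any(s.intensity < 0):
        raise ValueError("negative intensities; run baseline removal first")
    return s.replace(intensity=np.sqrt(s.intensity),
                     metadata={**s.metadata, "sqrt_transformed": True})


def estimate_noise(s: Spectrum) -> float:
    """Robust noise level: 1.4826 · median(|intensity − median(intensity)|)."""
    if len(s.intensity) < 10:
        raise ValueError("need at least 10 points to estimate noise")
    med = np.median(s.intensity)
    return float(1.4826 * np.median(np.abs(s.intensity - med)))


def detect_peaks(s: Spectrum, snr_threshold: float = 3.0, half_window: int = 10) -> PeakList:
    """Pick local maxima whose elevation above the background exceeds
    ``snr_threshold`` times the MAD noise.

    A point is a peak when it is the maximum within ±half_window points and
    (intensity − median) ≥ snr_threshold · noise, with the MAD noise of
    :func:`estimate_noise`.  Measuring elevation from the spectrum median
    makes the criterion independent of any residual background pedestal left
    by baseline removal; for a spectrum whose background sits at zero it
    reduces to the plain intensity/noise ratio.
    """
    y = s.intensity
    noise = estimate_noise(s)
    floor = float(np.median(y))
    size = 2 * half_window + 1
    local_max = y >= maximum_filter1d(y, size=size, mode="nearest")
    threshold = floor + snr_threshold * noise
    candidate = np.flatnonzero(local_max & (y >= threshold) & (y > 0))
    # two distinct-valued window maxima cannot lie within half_window of each
    # other, so suppression only needs to collapse plateaus: keep the first
    # candidate of every run closer than half_window
    kept: list[int] = []
    for idx in candidate:
        if not kept or idx - kept[-1] > half_window:
            kept.append(int(idx))
    kept_arr = np.asarray(kept, dtype=int)
    snr = ((y[kept_arr] - floor) / noise if noise > 0
           else np.full(len(kept_arr), np.inf))
    # refine apex m/z by the parabola through the three points around the
    # maximum: sub-sample precision instead of grid-step quantization
    apex_mz = s.mz[kept_arr].copy()
    apex_int = y[kept_arr].copy()
    for n, idx in enumerate(kept_arr):
        if 0 < idx < len(y) - 1:
            y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                delta = 0.5 * (y0 - y2) / denom
                if abs(delta) <= 0.5:
                    step = s.mz[idx + 1] - s.mz[idx] if delta >= 0 else s.mz[idx] - s.mz[idx - 1]
                    apex_mz[n] = s.mz[idx] + delta * step
                    apex_int[n] = y1 - 0.25 * (y0 - y2) * delta
    order = np.argsort(apex_mz, kind="stable")
    apex_mz, apex_int, snr = apex_mz[order], apex_int[order], snr[order]
    keep_unique = np.concatenate([[True], np.diff(apex_mz) > 0]) if len(apex_mz) else np.array([], bool)
    return PeakList(
        spot_id=s.spot_id,
        mz=apex_mz[keep_unique],
        intensity=apex_int[keep_unique],
        snr=snr[keep_unique],
        metadata={"concentration": s.concentration, **{k: v for k, v in s.metadata.items()
                                                       if k in ("tic_raw",)}},
    )


def isotope_lambda(mass: float) -> float:
    """Poisson parameter of the averagine-like isotope envelope at ``mass``.

    The expected A+k / A intensity ratio is lambda**k / k!.
    """
    return max(0.000594 * mass - 0.03091, 1e-6)


def filter_monoisotopic(
    p: PeakList,
    charge: int = 1,
    tol_ppm: float = 200.0,
    ratio_tolerance: tuple[float, float] = (0.25, 4.0),
) -> PeakList:
    """Collapse isotope envelopes to their monoisotopic (lowest-m/z) member.

    Peaks spaced by ≈ 1.00235/charge Th are chained into envelopes; a
    satellite is absorbed when its intensity ratio to the envelope head is
    within ``ratio_tolerance`` times the Poisson-expected ratio at that mass.
    One missing satellite is tolerated (an A+1 peak lost below the detection
    threshold does not orphan the A+2 peak); singletons and peaks with
    inconsistent ratios are kept.
    """
    if len(p) == 0:
        return p
    spacing = ISOTOPE_SPACING / charge
    lo, hi = ratio_tolerance
    consumed = np.zeros(len(p), dtype=bool)
    indices = np.arange(len(p))
    keep: list[int] = []
    for i in range(len(p)):
        if consumed[i]:
            continue
        keep.append(i)
        lam = isotope_lambda(p.mz[i])
        misses = 0
        for k in range(1, 5):
            target = p.mz[i] + k * spacing
            tol = tol_ppm * 1e-6 * p.mz[i]
            window = np.flatnonzero(
                (~consumed) & (indices > i) & (np.abs(p.mz - target) <= tol)
            )
            expected = lam**k / math.factorial(k)
            hit = False
            if len(window):
                cand = window[np.argmin(np.abs(p.mz[window] - target))]
                observed = p.intensity[cand] / p.intensity[i]
                if expected > 0 and lo <= observed / expected <= hi:
                    consumed[cand] = True
                    hit = True
            if not hit:
                misses += 1
                if misses >= 2:
                    break
    idx = np.asarray(keep, dtype=int)
    return p.replace(p.mz[idx], p.intensity[idx], p.snr[idx], monoisotopic=True)


def recalibrate_to_reference(
    s: Spectrum, peaks: PeakList, ref_mz: float, tol: float = 0.5
) -> Spectrum:
    """Single-point recalibration: shift the m/z axis onto a reference peak.

    The most intense detected peak within ±tol of ``ref_mz`` defines a
    constant shift ``ref_mz − apex``.  Without a matching peak the spectrum
    is returned unshifted, flagged for QC, with a warning.
    """
    near = np.flatnonzero(np.abs(peaks.mz - ref_mz) <= tol)
    if len(near) == 0:
        warnings.warn(
            f"spot {s.spot_id!r}: no peak within ±{tol} of reference {ref_mz}; not recalibrated"
        )
        return s.replace(metadata={**s.metadata, "recalibration_failed": True})
    apex = peaks.mz[near[np.argmax(peaks.intensity[near])]]
    shift = float(ref_mz - apex)
    return s.replace(mz=s.mz + shift,
                     metadata={**s.metadata, "recalibration_shift": shift})


def normalize(
    s: Spectrum,
    method: str = "tic",
    ref_mz: float | None = None,
    tol: float = 0.5,
) -> Spectrum:
    """Normalize intensities by TIC, median or an internal-standard peak.

    * ``tic`` — divide by the summed intensity (spectrum then sums to 1);
    * ``median`` — divide by the median of the nonzero intensities;
    * ``internal_standard`` — divide by the apex intensity within ±tol of
      ``ref_mz``.

    The divisor is stored as ``metadata['normalization_factor']``.
    """
    _require_not_done(s, "normalized")
    if method == "tic":
        factor = float(np.sum(s.intensity))
    elif method == "median":
        nonzero = s.intensity[s.intensity > 0]
        factor = float(np.median(nonzero)) if len(nonzero) else 0.0
    elif method == "internal_standard":
        if ref_mz is None:
            raise ValueError("internal_standard normalization requires ref_mz")
        window = np.flatnonzero(np.abs(s.mz - ref_mz) <= tol)
        if len(window) == 0:
            raise ValueError(
                f"spot {s.spot_id!r}: no signal within ±{tol} of internal standard {ref_mz}"
            )
        factor = float(np.max(s.intensity[window]))
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if factor <= 0:
        raise ValueError(f"spot {s.spot_id!r}: zero normalization divisor ({method})")
    return s.replace(intensity=s.intensity / factor,
                     metadata={**s.metadata, "normalized": method,
                               "normalization_factor": factor})


# ---------------------------------------------------------------------------
# cross-spot operations

def _greedy_clusters(mz_sorted: np.ndarray, tol_ppm: float) -> list[slice]:
    """Split a sorted m/z array where consecutive gaps exceed tol_ppm."""
    if len(mz_sorted) == 0:
        return []
    gaps = np.diff(mz_sorted)
    limits = tol_ppm * 1e-6 * mz_sorted[:-1]
    breaks = np.flatnonzero(gaps > limits)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [len(mz_sorted)]])
    return [slice(int(a), int(b)) for a, b in zip(starts, ends)]


def align_peaklists(
    pls: list[PeakList], tol_ppm: float = 200.0, min_frequency: float = 0.25
) -> list[PeakList]:
    """Align spots by a per-spot linear m/z warp fitted to shared reference peaks.

    Reference peaks are pooled-peak clusters present in at least
    ``min_frequency`` of the spots; the reference m/z is the cluster median,
    which is robust to a minority of shifted spots.  Each spot's warp
    m/z′ = a·m/z + b is least-squares fitted to its matched (observed,
    reference) pairs; spots with < 2 matches are left unwarped and flagged.
    """
    if len(pls) < 2:
        raise ValueError("alignment requires at least 2 peak lists")
    pooled_mz = np.concatenate([pl.mz for pl in pls])
    pooled_spot = np.concatenate([np.full(len(pl), i) for i, pl in enumerate(pls)])
    order = np.argsort(pooled_mz, kind="stable")
    pooled_mz, pooled_spot = pooled_mz[order], pooled_spot[order]

    min_spots = max(2, int(np.ceil(min_frequency * len(pls))))
    refs = [
        float(np.median(pooled_mz[sl]))
        for sl in _greedy_clusters(pooled_mz, tol_ppm)
        if len(np.unique(pooled_spot[sl])) >= min_spots
    ]
    refs = np.asarray(refs)

    out: list[PeakList] = []
    for pl in pls:
        pairs_obs, pairs_ref = [], []
        for ref in refs:
            tol = tol_ppm * 1e-6 * ref
            near = np.flatnonzero(np.abs(pl.mz - ref) <= tol)
            if len(near):
                pairs_obs.append(pl.mz[near[np.argmin(np.abs(pl.mz[near] - ref))]])
                pairs_ref.append(ref)
        if len(pairs_obs) < 2:
            warnings.warn(f"spot {pl.spot_id!r}: < 2 alignment matches; left unwarped")
            out.append(pl.replace(pl.mz, pl.intensity, pl.snr, alignment_failed=True))
            continue
        a, b = np.polyfit(np.asarray(pairs_obs), np.asarray(pairs_ref), 1)
        out.append(pl.replace(a * pl.mz + b, pl.intensity, pl.snr,
                              warp=(float(a), float(b))))
    return out


def _split_wide(mz: np.ndarray, members: np.ndarray, tol_ppm: float) -> list[np.ndarray]:
    """Recursively split a cluster wider than tol at its largest internal gap."""
    width_ppm = (mz[members[-1]] - mz[members[0]]) / np.mean(mz[members]) * 1e6
    if len(members) < 2 or width_ppm <= tol_ppm:
        return [members]
    gaps = np.diff(mz[members])
    cut = int(np.argmax(gaps)) + 1
    return _split_wide(mz, members[:cut], tol_ppm) + _split_wide(mz, members[cut:], tol_ppm)


def bin_peaks(
    pls: list[PeakList],
    tol_ppm: float = 100.0,
    layout: PlateLayout | None = None,
    spectra: list[Spectrum] | None = None,
) -> IntensityMatrix:
    """Bin peaks across spots into m/z features by greedy single-linkage.

    Pooled peaks are clustered where consecutive gaps stay within ``tol_ppm``;
    clusters wider than the tolerance are split at their largest internal
    gap.  Bin centers are intensity-weighted mean m/z.  If a spot contributes
    several peaks to one bin, the most intense is used.  Column order follows
    the layout when given, otherwise input order; binning is invariant to
    spot permutation.

    When the processed profile ``spectra`` are supplied, a spot with no
    detected peak in a bin gets the spectrum intensity interpolated at the
    bin center instead of 0.  Without this fill-in, detections hovering at
    the SNR threshold drop in and out across replicates and inject spurious
    dose structure; with it, every feature has a measured intensity in every
    spot.  Without ``spectra`` missing entries are 0.
    """
    spot_ids = layout.spots if layout is not None else [pl.spot_id for pl in pls]
    by_spot = {pl.spot_id: pl for pl in pls}
    missing = [sid for sid in spot_ids if sid not in by_spot]
    if missing:
        raise KeyError(f"peak lists missing for spots: {missing}")

    pooled_mz = np.concatenate([by_spot[sid].mz for sid in spot_ids])
    pooled_int = np.concatenate([by_spot[sid].intensity for sid in spot_ids])
    pooled_col = np.concatenate(
        [np.full(len(by_spot[sid]), j) for j, sid in enumerate(spot_ids)]
    )
    order = np.argsort(pooled_mz, kind="stable")
    pooled_mz, pooled_int, pooled_col = pooled_mz[order], pooled_int[order], pooled_col[order]

    clusters: list[np.ndarray] = []
    for sl in _greedy_clusters(pooled_mz, tol_ppm):
        clusters.extend(_split_wide(pooled_mz, np.arange(sl.start, sl.stop), tol_ppm))

    centers, rows = [], []
    for members in clusters:
        weights = pooled_int[members]
        total = np.sum(weights)
        center = (np.sum(pooled_mz[members] * weights) / total
                  if total > 0 else float(np.mean(pooled_mz[members])))
        row = np.zeros(len(spot_ids))
        for m in members:
            col = int(pooled_col[m])
            row[col] = max(row[col], pooled_int[m])
        centers.append(center)
        rows.append(row)
    order = np.argsort(centers, kind="stable")
    centers_arr = np.asarray(centers)[order]
    values = np.asarray(rows)[order] if rows else np.zeros((0, len(spot_ids)))
    # merged duplicates can in principle collide; enforce strict monotonicity
    for i in range(1, len(centers_arr)):
        if centers_arr[i] <= centers_arr[i - 1]:
            centers_arr[i] = np.nextafter(centers_arr[i - 1], np.inf)
    if spectra is not None and len(centers_arr):
        spec_by_spot = {s.spot_id: s for s in spectra}
        for j, sid in enumerate(spot_ids):
            s = spec_by_spot.get(sid)
            if s is None:
                continue
            missing = values[:, j] == 0
            if np.any(missing):
                values[missing, j] = np.interp(
                    centers_arr[missing], s.mz, s.intensity
                )
    return IntensityMatrix(centers_arr, list(spot_ids), values, layout)


def average_by_concentration(
    m: IntensityMatrix, exclude_spots: tuple[str, ...] = ()
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature mean and sample SD over replicates at each concentration.

    Returns ``(concentrations, means, sds, counts)`` with columns in
    ascending concentration order.  Spots in ``exclude_spots`` (e.g. QC
    outliers) enter neither the mean nor the SD; a single remaining
    replicate gets SD 0 by convention (visible through ``counts``).
    """
    if m.layout is None:
        raise ValueError("intensity matrix has no layout attached")
    conc_by_spot = dict(
        zip(m.layout.table["spot_id"], m.layout.table["concentration"])
    )
    keep_cols = [j for j, sid in enumerate(m.spots) if sid not in set(exclude_spots)]
    concs = np.asarray(sorted({float(conc_by_spot[m.spots[j]]) for j in keep_cols}))
    fully_excluded = sorted(
        {float(c) for c in m.layout.table["concentration"].unique()} - set(concs)
    )
    if fully_excluded:
        raise ValueError(
            f"concentration groups fully excluded by QC: {fully_excluded}"
        )
    n_feat = len(m.feature_mz)
    means = np.zeros((n_feat, len(concs)))
    sds = np.zeros((n_feat, len(concs)))
    counts = np.zeros(len(concs), dtype=int)
    for ci, conc in enumerate(concs):
        cols = [j for j in keep_cols if float(conc_by_spot[m.spots[j]]) == conc]
        block = m.values[:, cols]
        counts[ci] = len(cols)
        means[:, ci] = block.mean(axis=1)
        sds[:, ci] = block.std(axis=1, ddof=1) if len(cols) > 1 else 0.0
    return concs, means, sds, counts
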