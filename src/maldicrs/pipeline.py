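"""End-to-end orchestration: spectra → intensity matrix → fits → scores.

The stage order is fixed (smooth → baseline → sqrt → recalibrate →
normalize → peak detection → monoisotopic filter → align → bin); every stage
is individually switchable through :class:`Config`, which mirrors the YAML
configuration of the command-line interface.  The variance-stabilizing sqrt
transform is applied before normalization.

Curve fits use per-concentration replicate means; the FZ and FV quality
factors use replicate-level values (endpoint replicates for FZ, deviation of
all replicates from the fitted curve for FV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .curves import CurveFit, fit_ll4, log2fc, pec50, replicate_rmse
from .preprocess import (
    IntensityMatrix,
    align_peaklists,
    average_by_concentration,
    bin_peaks,
    detect_peaks,
    filter_monoisotopic,
    normalize,
    recalibrate_to_reference,
    remove_baseline_tophat,
    smooth_savitzky_golay,
    sqrt_transform,
)
from .qc import SpotQC, qc_table, spot_summary
from .scoring import FeatureScore, classify, crs, default_fc_scale, fingerprint, fv_factor, fz_factor
from .spectra_io import PlateLayout, Spectrum, attach_layout
from .multivariate import cluster_curve_shapes

__all__ = ["Config", "PipelineResult", "run_pipeline", "score_features"]


@dataclass
class Config:
    """Effective pipeline parameters (YAML keys in dotted notation).

    Defaults follow common MALDI dose-response practice: Savitzky–Golay
    half-window 10 / order 3, TopHat half-window 75 points, sqrt transform
    on, SNR 3 peak picking, monoisotopic filtering on, TIC normalization,
    200 ppm alignment, 100 ppm binning, 25 % minimum reference-peak
    frequency.  Outliers are flagged (not excluded) by default.
    """

    smoothing_enabled: bool = True
    smoothing_half_window: int = 10
    smoothing_order: int = 3
    baseline_enabled: bool = True
    baseline_half_window: int = 75
    sqrt_enabled: bool = True
    peaks_snr: float = 3.0
    peaks_half_window: int = 10
    monoisotopic_enabled: bool = True
    monoisotopic_tol_ppm: float = 200.0
    recal_ref_mz: float | None = None
    recal_tol: float = 0.5
    normalize_method: str = "tic"
    normalize_ref_mz: float | None = None
    normalize_tol: float = 0.5
    align_enabled: bool = True
    align_tol_ppm: float = 200.0
    align_min_frequency: float = 0.25
    bin_tol_ppm: float = 100.0
    bin_min_frequency: float = 0.25
    outlier_mode: str = "flag"          # "flag" or "exclude"
    qc_feature_mz: float | None = None
    cluster_k: int | str = "auto"
    fc_scale: float | None = None        # None: within-dataset max |log2FC|
    seed: int = 0

    _NESTED = {
        "smoothing": ("enabled", "half_window", "order"),
        "baseline": ("enabled", "half_window"),
        "transform": ("sqrt",),
        "peaks": ("snr", "half_window"),
        "monoisotopic": ("enabled", "tol_ppm"),
        "recal": ("ref_mz", "tol"),
        "normalize": ("method", "ref_mz", "tol"),
        "align": ("enabled", "tol_ppm", "min_frequency"),
        "bin": ("tol_ppm", "min_frequency"),
        "qc": ("outlier_mode", "feature_mz"),
        "cluster": ("k",),
        "scoring": ("fc_scale",),
    }

    @classmethod
    def from_dict(cls, raw: dict) -> "Config":
        flat: dict = {}
        for section, value in (raw or {}).items():
            if section == "transform":
                if "sqrt" in value:
                    flat["sqrt_enabled"] = bool(value["sqrt"])
                continue
            if section == "qc":
                if "outlier_mode" in value:
                    flat["outlier_mode"] = value["outlier_mode"]
                if "feature_mz" in value:
                    flat["qc_feature_mz"] = value["feature_mz"]
                continue
            if section == "cluster":
                if "k" in value:
                    flat["cluster_k"] = value["k"]
                continue
            if section == "scoring":
                if "fc_scale" in value:
                    flat["fc_scale"] = value["fc_scale"]
                continue
            if section == "seed":
                flat["seed"] = int(value)
                continue
            if not isinstance(value, dict):
                flat[section] = value
                continue
            for key, sub in value.items():
                flat[f"{section}_{key}"] = sub
        known = set(cls.__dataclass_fields__)
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    matrix: IntensityMatrix
    fits: list[CurveFit]
    scores: list[FeatureScore]
    fingerprint: pd.DataFrame
    qc: list[SpotQC]
    excluded_spots: tuple[str, ...]
    cluster_labels: np.ndarray
    config: Config

    def qc_frame(self):
        return qc_table(self.qc)


def preprocess_spectra(
    spectra: list[Spectrum], config: Config
) -> list[Spectrum]:
    """Apply the per-spectrum stages in their fixed order."""
    out = []
    for s in spectra:
        s = s.replace(metadata={**s.metadata, "tic_raw": s.tic})
        if config.smoothing_enabled:
            s = smooth_savitzky_golay(
                s, config.smoothing_half_window, config.smoothing_order
            )
        if config.baseline_enabled:
            s = remove_baseline_tophat(s, config.baseline_half_window)
        if config.sqrt_enabled:
            s = sqrt_transform(s)
        if config.recal_ref_mz is not None:
            peaks = detect_peaks(s, config.peaks_snr, config.peaks_half_window)
            s = recalibrate_to_reference(s, peaks, config.recal_ref_mz, config.recal_tol)
        if config.normalize_method not in (None, "none"):
            s = normalize(
                s, config.normalize_method, config.normalize_ref_mz, config.normalize_tol
            )
        out.append(s)
    return out


def build_matrix(spectra: list[Spectrum], layout: PlateLayout, config: Config) -> IntensityMatrix:
    """Peak detection, monoisotopic filtering, alignment and binning."""
    peaklists = [
        detect_peaks(s, config.peaks_snr, config.peaks_half_window) for s in spectra
    ]
    if config.monoisotopic_enabled:
        peaklists = [
            filter_monoisotopic(pl, tol_ppm=config.monoisotopic_tol_ppm)
            for pl in peaklists
        ]
    if config.align_enabled and len(peaklists) >= 2:
        peaklists = align_peaklists(
            peaklists, config.align_tol_ppm, config.align_min_frequency
        )
    matrix = bin_peaks(peaklists, config.bin_tol_ppm, layout)
    # drop sporadic features (noise peaks land in bins occupied by only a
    # few spots); a real feature is detected in most replicates
    if config.bin_min_frequency > 0 and len(matrix.feature_mz):
        occupancy = np.mean(matrix.values > 0, axis=1)
        keep = occupancy >= config.bin_min_frequency
        matrix = IntensityMatrix(
            matrix.feature_mz[keep], matrix.spots, matrix.values[keep], layout
        )
    # then fill undetected entries of the surviving features from the
    # processed spectra so threshold dropouts do not fake dose structure
    if len(matrix.feature_mz):
        spec_by_spot = {s.spot_id: s for s in spectra}
        for j, sid in enumerate(matrix.spots):
            s = spec_by_spot[sid]
            missing = matrix.values[:, j] == 0
            if np.any(missing):
                matrix.values[missing, j] = np.interp(
                    matrix.feature_mz[missing], s.mz, s.intensity
                )
    return matrix


def score_features(
    matrix: IntensityMatrix,
    excluded_spots: tuple[str, ...] = (),
    fc_scale: float | None = None,
) -> tuple[list[CurveFit], list[FeatureScore]]:
    """Fit every feature and compute FZ, FV, log2FC, CRS and direction.

    Fits use per-concentration means; FZ uses the replicate values at the
    lowest and highest tested concentrations, FV the RMS deviation of all
    replicate values from the fitted curve.  ``fc_scale`` defaults to the
    within-dataset maximum |log2FC| over regulated candidates.
    """
    layout = matrix.layout
    if layout is None:
        raise ValueError("intensity matrix has no layout attached")
    concs, means, _sds, _counts = average_by_concentration(matrix, excluded_spots)
    conc_by_spot = dict(zip(layout.table["spot_id"], layout.table["concentration"]))
    keep_cols = [j for j, sid in enumerate(matrix.spots) if sid not in set(excluded_spots)]
    spot_conc = np.asarray([float(conc_by_spot[matrix.spots[j]]) for j in keep_cols])
    low_cols = [j for j, c in zip(keep_cols, spot_conc) if c == concs[0]]
    high_cols = [j for j, c in zip(keep_cols, spot_conc) if c == concs[-1]]

    fits: list[CurveFit] = []
    raw_scores: list[dict] = []
    for i, mzv in enumerate(matrix.feature_mz):
        try:
            fit = fit_ll4(concs, means[i], feature_mz=float(mzv))
        except ValueError:
            fit = CurveFit(
                b=0.0, c=float(np.mean(means[i])), d=float(np.mean(means[i])),
                e=float(np.sqrt(concs[0] * concs[-1])) if concs[0] > 0 else 1.0,
                rmse=float(np.std(means[i])), converged=False, feature_mz=float(mzv),
                conc_min=float(concs[0]) if concs[0] > 0 else float("nan"),
                conc_max=float(concs[-1]),
            )
        fits.append(fit)

        high = matrix.values[i, high_cols]
        low = matrix.values[i, low_cols]
        try:
            fz = fz_factor(high, low)
        except ValueError:
            fz = float("nan")
        window = abs(float(np.mean(high)) - float(np.mean(low))) if len(high) and len(low) else 0.0

        if fit.converged:
            rep_values = matrix.values[i, keep_cols]
            rep_rmse = replicate_rmse(fit, spot_conc, rep_values)
            fv = fv_factor(rep_rmse, window) if window > 0 else float("-inf")
            try:
                fc = log2fc(fit)
            except ValueError:
                fc = float("nan")
            p50 = pec50(fit)
        else:
            fv = float("-inf")
            fc = float("nan")
            p50 = float("nan")
        raw_scores.append({"mz": float(mzv), "fz": fz, "fv": fv, "fc": fc, "pec50": p50})

    if fc_scale is None:
        fc_scale = default_fc_scale(
            [r["fz"] for r in raw_scores],
            [r["fv"] for r in raw_scores],
            [np.nan_to_num(r["fc"], nan=0.0) for r in raw_scores],
        )

    scores: list[FeatureScore] = []
    for r in raw_scores:
        value = crs(r["fz"], r["fv"], np.nan_to_num(r["fc"], nan=0.0), fc_scale)
        score = FeatureScore(
            feature_mz=r["mz"],
            fz=r["fz"],
            fv=r["fv"],
            log2fc=float(np.nan_to_num(r["fc"], nan=0.0)),
            crs=round(value, 1),
            direction="none",
            pec50=r["pec50"],
        )
        score.direction = classify(score)
        scores.append(score)
    return fits, scores


def run_pipeline(
    spectra: list[Spectrum],
    layout: PlateLayout,
    config: Config | None = None,
) -> PipelineResult:
    """Run the full analysis on one plate of spectra."""
    config = config or Config()
    spectra = attach_layout(spectra, layout)
    processed = preprocess_spectra(spectra, config)
    matrix = build_matrix(processed, layout, config)

    summaries = spot_summary(
        processed, layout, matrix=matrix, feature_mz=config.qc_feature_mz
    )
    excluded: tuple[str, ...] = ()
    if config.outlier_mode == "exclude":
        excluded = tuple(q.spot_id for q in summaries if q.outlier)

    fits, scores = score_features(matrix, excluded, config.fc_scale)

    n_converged = sum(f.converged for f in fits)
    if n_converged >= 2:
        labels = cluster_curve_shapes(
            fits, k=config.cluster_k, random_state=config.seed
        )
    else:
        labels = np.full(len(fits), -1, dtype=int)
    for score, lab in zip(scores, labels):
        score.cluster_label = int(lab) if lab >= 0 else None

    return PipelineResult(
        matrix=matrix,
        fits=fits,
        scores=scores,
        fingerprint=fingerprint(scores),
        qc=summaries,
        excluded_spots=excluded,
        cluster_labels=labels,
        config=config,
    )
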