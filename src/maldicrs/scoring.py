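"""Assay-quality factors (FZ, FV), the Curve Response Score and fingerprints.

FZ transfers the classical Z′ screening-window statistic to the endpoints of
a dose-response curve: the replicate variability at the lowest and highest
tested concentrations relative to the response window between them.  FV is
the V-factor analogue: the endpoint SDs are replaced by the RMS deviation of
all replicate responses from the fitted LL.4 curve, so it penalizes lack of
fit anywhere along the curve.  The CRS combines FZ, FV and the fold-change
magnitude with equal weights into a 0–100 % score used to rank features; the
per-compound vector of CRS values over all m/z features is the CRS
fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeatureScore",
    "fz_factor",
    "fv_factor",
    "crs",
    "classify",
    "default_fc_scale",
    "fingerprint",
    "compare_fingerprints",
]

FINGERPRINT_COLUMNS = ["mz", "crs_percent", "direction", "pec50", "log2fc"]


@dataclass
class FeatureScore:
    """Scores of one m/z feature; a list of these is a CRS fingerprint."""

    feature_mz: float
    fz: float
    fv: float
    log2fc: float
    crs: float
    direction: str
    pec50: float = float("nan")
    cluster_label: int | None = None


def fz_factor(high_reps, low_reps) -> float:
    """Z′-style window quality from endpoint replicates.

    FZ = 1 − 3·(σ_high + σ_low) / |μ_high − μ_low| with sample SDs.  Equals
    1 for noiseless separated endpoints and falls below 0 when the
    variability bands overlap.  A zero window yields −inf (maximally bad;
    clipped at the CRS stage).
    """
    high = np.asarray(high_reps, dtype=float)
    low = np.asarray(low_reps, dtype=float)
    if len(high) < 2 or len(low) < 2:
        raise ValueError("need at least 2 replicates at each endpoint")
    window = abs(float(np.mean(high)) - float(np.mean(low)))
    if window == 0:
        return float("-inf")
    return 1.0 - 3.0 * (float(np.std(high, ddof=1)) + float(np.std(low, ddof=1))) / window


def fv_factor(rmse: float, window: float) -> float:
    """V-factor-style fit quality: FV = 1 − 6·rmse / window.

    ``rmse`` is the RMS deviation of replicate-level responses from the
    fitted curve and ``window`` the absolute difference of the endpoint
    replicate means.  A zero window yields −inf, as in :func:`fz_factor`.
    """
    if rmse < 0:
        raise ValueError("rmse must be non-negative")
    if window == 0:
        return float("-inf")
    return 1.0 - 6.0 * rmse / abs(window)


def _clip01(value: float) -> float:
    if not np.isfinite(value):
        return 0.0 if value < 0 else 1.0
    return float(min(max(value, 0.0), 1.0))


def crs(fz: float, fv: float, log2fc: float, fc_scale: float) -> float:
    """Curve Response Score in percent.

    Equal-weight mean of three components, each clamped to [0, 1]: FZ, FV
    and |log2FC| / fc_scale, where ``fc_scale`` normalizes the fold change
    to a within-dataset relative rank (see :func:`default_fc_scale`).

    A feature whose FZ and FV components are both 0 has no assay-quality
    support and is nonregulated by definition: its CRS is 0 regardless of
    the fitted fold change, so pure-noise features cannot score.  NaN
    components (e.g. an undefined fold change) count as 0.
    """
    if not fc_scale > 0:
        raise ValueError("fc_scale must be positive")
    fz_c = _clip01(fz) if not np.isnan(fz) else 0.0
    fv_c = _clip01(fv) if not np.isnan(fv) else 0.0
    if fz_c + fv_c == 0.0:
        return 0.0
    fc_c = _clip01(abs(log2fc) / fc_scale) if np.isfinite(log2fc) else 0.0
    return 100.0 * (fz_c + fv_c + fc_c) / 3.0


def default_fc_scale(fzs, fvs, log2fcs) -> float:
    """Dataset-level fold-change normalizer.

    The largest |log2FC| among regulated candidates (features with FZ > 0 or
    FV > 0), so the strongest candidate saturates the fold-change component
    and all others are ranked relative to it within the dataset.  Falls back
    to 1 when no candidate exists (every CRS is then 0 anyway).
    """
    fzs = np.asarray(fzs, dtype=float)
    fvs = np.asarray(fvs, dtype=float)
    fcs = np.abs(np.asarray(log2fcs, dtype=float))
    candidate = (np.nan_to_num(fzs, nan=-np.inf) > 0) | (
        np.nan_to_num(fvs, nan=-np.inf) > 0
    )
    candidate &= np.isfinite(fcs)
    if not np.any(candidate) or np.max(fcs[candidate]) <= 0:
        return 1.0
    return float(np.max(fcs[candidate]))


def classify(score: FeatureScore) -> str:
    """Directional call: ``none`` for CRS = 0, else ``up``/``down`` by the
    sign of the fold change."""
    if score.crs == 0:
        return "none"
    return "up" if score.log2fc > 0 else "down"


def fingerprint(scores: list[FeatureScore]) -> pd.DataFrame:
    """CRS fingerprint: per-feature CRS and direction, ordered by m/z."""
    frame = pd.DataFrame(
        {
            "mz": [s.feature_mz for s in scores],
            "crs_percent": [s.crs for s in scores],
            "direction": [s.direction for s in scores],
            "pec50": [s.pec50 for s in scores],
            "log2fc": [s.log2fc for s in scores],
        },
        columns=FINGERPRINT_COLUMNS,
    )
    return frame.sort_values("mz", kind="stable").reset_index(drop=True)


def compare_fingerprints(
    fingerprints: list[pd.DataFrame],
    labels: list[str] | None = None,
    tol_ppm: float = 200.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join ≥ 2 fingerprints on m/z within tolerance.

    Returns ``(wide, long)``: the wide table has one row per shared feature
    with CRS and pEC50 per compound; the long table lists every feature with
    nonzero CRS in any compound against its pEC50 (the untargeted
    potency-vs-score view).
    """
    if len(fingerprints) < 2:
        raise ValueError("need at least 2 fingerprints to compare")
    if labels is None:
        labels = [f"compound_{i + 1}" for i in range(len(fingerprints))]

    ref = fingerprints[0].sort_values("mz").reset_index(drop=True)
    wide_rows = []
    for _, row in ref.iterrows():
        entry = {"mz": row["mz"],
                 f"crs_{labels[0]}": row["crs_percent"],
                 f"pec50_{labels[0]}": row["pec50"]}
        shared = True
        for fp, lab in zip(fingerprints[1:], labels[1:]):
            diffs = np.abs(fp["mz"].to_numpy() - row["mz"])
            tol = tol_ppm * 1e-6 * row["mz"]
            if diffs.min() > tol:
                shared = False
                break
            j = int(np.argmin(diffs))
            entry[f"crs_{lab}"] = fp["crs_percent"].iloc[j]
            entry[f"pec50_{lab}"] = fp["pec50"].iloc[j]
        if shared:
            wide_rows.append(entry)
    wide = pd.DataFrame(wide_rows)

    long_rows = []
    for fp, lab in zip(fingerprints, labels):
        hits = fp[fp["crs_percent"] > 0]
        for _, row in hits.iterrows():
            long_rows.append(
                {"compound": lab, "mz": row["mz"],
                 "crs_percent": row["crs_percent"], "pec50": row["pec50"],
                 "direction": row["direction"]}
            )
    long = pd.DataFrame(long_rows,
                        columns=["compound", "mz", "crs_percent", "pec50", "direction"])
    return wide, long
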