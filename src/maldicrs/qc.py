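"""Plate-level quality control.

Replicate spots of one condition should be exchangeable; a spot whose total
ion current (or target-feature intensity) deviates grossly — sample carry-
over, matrix crystallization failure, misfires — is flagged with Chauvenet's
criterion: reject a value when n times the two-sided normal tail probability
of its z-score falls below 1/2.  Flagging is single-pass (no iterative
re-testing) and by default informational only; exclusion from averaging and
fitting is opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erfc

from .preprocess import IntensityMatrix
from .spectra_io import PlateLayout, Spectrum

__all__ = ["SpotQC", "chauvenet_statistic", "chauvenet_outliers", "spot_summary", "qc_table"]


@dataclass
class SpotQC:
    """Per-spot QC summary: TIC, optional target-feature intensity and the
    Chauvenet expected count n·P (< 0.5 means outlier)."""

    spot_id: str
    tic: float
    target_intensity: float
    chauvenet_stat: float
    outlier: bool


def chauvenet_statistic(values) -> np.ndarray:
    """Expected count n·P(|Z| ≥ z) for each value in its group.

    z is the value's distance from the group mean in units of the sample SD;
    P is the two-sided standard-normal tail, computed via erfc(z/√2).  A
    zero-SD group returns +inf for every member (nothing can be an outlier).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    sd = np.std(values, ddof=1) if n > 1 else 0.0
    if sd == 0:
        return np.full(n, np.inf)
    z = np.abs(values - np.mean(values)) / sd
    return n * erfc(z / np.sqrt(2.0))


def chauvenet_outliers(values) -> np.ndarray:
    """Boolean mask of Chauvenet outliers within one replicate group.

    Requires n ≥ 4 (the criterion is not meaningful below).  Single pass:
    flagged values are not removed and the remainder re-tested.  The flag
    set is invariant under affine transformation of the values.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("Chauvenet's criterion needs at least 4 values")
    return chauvenet_statistic(values) < 0.5


def spot_summary(
    spectra: list[Spectrum],
    layout: PlateLayout,
    matrix: IntensityMatrix | None = None,
    feature_mz: float | None = None,
    feature_tol: float = 0.5,
) -> list[SpotQC]:
    """Per-spot TIC (pre-normalization) with Chauvenet flags per replicate group.

    The TIC is taken from ``metadata['tic_raw']`` when the pipeline stored it
    before normalization, otherwise from the current intensities.  When
    ``feature_mz`` is given together with the binned matrix, the intensity of
    the nearest feature within ±``feature_tol`` Th is reported (NaN — not
    zero — when no feature is near).

    Outlier decisions are made on the TIC across all spots of one compound
    (the plate map): the TIC is dose-insensitive enough for plate-wide
    comparison, and within a typical 4-replicate group the criterion is
    mathematically unable to flag anything (the largest attainable z-score,
    (n−1)/√n = 1.5, never reaches the rejection region).
    """
    tics = {s.spot_id: float(s.metadata.get("tic_raw", s.tic)) for s in spectra}
    missing = [sid for sid in layout.spots if sid not in tics]
    if missing:
        raise KeyError(f"spectra missing for layout spots: {missing}")

    target: dict[str, float] = {}
    if feature_mz is not None and matrix is not None and len(matrix.feature_mz):
        diffs = np.abs(matrix.feature_mz - feature_mz)
        idx = int(np.argmin(diffs))
        for j, sid in enumerate(matrix.spots):
            target[sid] = (
                float(matrix.values[idx, j]) if diffs[idx] <= feature_tol else float("nan")
            )

    stat = {sid: float("inf") for sid in layout.spots}
    flagged = {sid: False for sid in layout.spots}
    for compound, group in layout.table.groupby("compound_id"):
        spot_ids = list(group["spot_id"])
        if len(spot_ids) < 4:
            continue
        stats = chauvenet_statistic(np.asarray([tics[sid] for sid in spot_ids]))
        for sid, st in zip(spot_ids, stats):
            stat[sid] = float(st)
            flagged[sid] = bool(st < 0.5)

    return [
        SpotQC(
            spot_id=sid,
            tic=tics[sid],
            target_intensity=target.get(sid, float("nan")),
            chauvenet_stat=stat[sid],
            outlier=flagged[sid],
        )
        for sid in layout.spots
    ]


def qc_table(summaries: list[SpotQC]) -> pd.DataFrame:
    """QC summaries as a DataFrame (the exported QC CSV schema)."""
    return pd.DataFrame(
        {
            "spot_id": [q.spot_id for q in summaries],
            "tic": [q.tic for q in summaries],
            "target_intensity": [q.target_intensity for q in summaries],
            "chauvenet_stat": [q.chauvenet_stat for q in summaries],
            "outlier": [q.outlier for q in summaries],
        }
    )
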