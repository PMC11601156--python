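"""Synthetic MALDI dose-response plates with known ground truth.

The simulator emulates the artefact classes the pipeline is built to handle:
a TOF-like uniform m/z axis in profile mode, Gaussian peak profiles with
averagine-like isotope satellites, a smooth additive baseline, multiplicative
spot-to-spot intensity variation (lognormal), additive detector noise, and
injectable gross-outlier spots.  A subset of features follows true LL.4
concentration responses; all remaining features are dose-independent.  Every
plate ships with a truth table, so recovery of potency, effect size and
ranking can be checked end to end without external data.

Defaults model a typical small-molecule screening plate: 8 concentrations in
a 10-fold dilution series (1e-10 to 1e-3, molar), 4 technical replicates,
200 m/z features of which 3 respond, 5 % spot-level intensity scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ISOTOPE_SPACING, isotope_lambda
from .spectra_io import PlateLayout, Spectrum, write_mzml

__all__ = ["ResponderSpec", "SimulationConfig", "simulate_plate", "write_fixture_bundle"]


@dataclass(frozen=True)
class ResponderSpec:
    """Ground-truth LL.4 parameters of one responding feature.

    Orientation: b < 0 rises from c (low dose) to d (high dose); b > 0 falls
    from d to c.
    """

    mz: float
    b: float
    c: float
    d: float
    e: float

    @property
    def direction(self) -> str:
        low_is_c = self.b < 0
        rising = (self.d > self.c) if low_is_c else (self.c > self.d)
        return "up" if rising else "down"

    @property
    def pec50(self) -> float:
        return float(-np.log10(self.e))


def _default_responders() -> tuple[ResponderSpec, ...]:
    # one strong up-regulated, one weaker up-regulated, one down-regulated
    return (
        ResponderSpec(mz=854.10, b=-2.0, c=1.0, d=8.0, e=1e-6),
        ResponderSpec(mz=511.10, b=-2.0, c=1.5, d=6.0, e=3e-7),
        ResponderSpec(mz=349.10, b=2.0, c=1.0, d=7.0, e=1e-6),
    )


@dataclass
class SimulationConfig:
    """Parameters of one simulated plate (see module docstring for defaults)."""

    n_concentrations: int = 8
    n_replicates: int = 4
    dose_range: tuple[float, float] = (1e-10, 1e-3)
    dilution_factor: float | None = None
    n_features: int = 200
    responder_specs: tuple[ResponderSpec, ...] = field(default_factory=_default_responders)
    noise_sd_rel: float = 0.05
    additive_noise_sd: float = 0.05
    baseline_amplitude: float = 1.0
    peak_width_sigma: float = 0.05
    isotope_envelope: bool = True
    mz_range: tuple[float, float] = (300.0, 900.0)
    mz_step: float = 0.02
    outlier_spots: tuple[str, ...] = ()
    outlier_scale: float = 30.0
    compound_id: str = "CMPD-1"
    seed: int = 0

    def __post_init__(self) -> None:
        # accept YAML/dict-style specs and list-typed ranges
        self.responder_specs = tuple(
            s if isinstance(s, ResponderSpec) else ResponderSpec(**s)
            for s in self.responder_specs
        )
        self.dose_range = tuple(self.dose_range)
        self.mz_range = tuple(self.mz_range)
        self.outlier_spots = tuple(self.outlier_spots)
        if self.n_concentrations < 1 or self.n_replicates < 1 or self.n_features < 1:
            raise ValueError("counts must be >= 1")
        if not (0 < self.dose_range[0] < self.dose_range[1]):
            raise ValueError("dose_range must be positive and increasing")
        if len(self.responder_specs) > self.n_features:
            raise ValueError("more responders than features")
        if self.mz_range[0] >= self.mz_range[1] or self.mz_step <= 0:
            raise ValueError("invalid m/z axis")
        if self.noise_sd_rel < 0 or self.additive_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if self.dilution_factor is not None and self.n_concentrations > 1:
            implied = (self.dose_range[1] / self.dose_range[0]) ** (
                1.0 / (self.n_concentrations - 1)
            )
            if abs(self.dilution_factor - implied) > 0.01 * implied:
                raise ValueError(
                    f"dilution_factor {self.dilution_factor} inconsistent with "
                    f"dose_range/n_concentrations (implied {implied:.4g})"
                )
        for spec in self.responder_specs:
            if not (self.mz_range[0] < spec.mz < self.mz_range[1]):
                raise ValueError(f"responder m/z {spec.mz} outside m/z range")
            if spec.e <= 0 or spec.c <= 0 or spec.d <= 0:
                raise ValueError("responder parameters must be positive")

    @property
    def doses(self) -> np.ndarray:
        return np.geomspace(self.dose_range[0], self.dose_range[1], self.n_concentrations)


def _draw_feature_positions(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Non-responder feature m/z, kept >= 3.5 Th apart from everything."""
    min_sep = 3.5
    placed = [s.mz for s in cfg.responder_specs]
    needed = cfg.n_features - len(cfg.responder_specs)
    lo = cfg.mz_range[0] + 5 * cfg.peak_width_sigma + 1.0
    hi = cfg.mz_range[1] - 5 * cfg.peak_width_sigma - 3.0
    out: list[float] = []
    attempts = 0
    while len(out) < needed:
        attempts += 1
        if attempts > 200 * max(needed, 1):
            raise ValueError("could not place features with 3.5 Th separation")
        cand = float(rng.uniform(lo, hi))
        if all(abs(cand - p) >= min_sep for p in placed):
            placed.append(cand)
            out.append(cand)
    return np.asarray(out)


def _ll4(x: float, b: float, c: float, d: float, e: float) -> float:
    return c + (d - c) / (1.0 + np.exp(np.clip(b * (np.log(x) - np.log(e)), -500, 500)))


def _render_peaks(mz_axis, positions, heights, sigma, isotopes: bool):
    signal = np.zeros_like(mz_axis)
    step = mz_axis[1] - mz_axis[0]
    for mu, h in zip(positions, heights):
        sats = [(mu, h)]
        if isotopes:
            lam = isotope_lambda(mu)
            sats += [
                (mu + ISOTOPE_SPACING, h * lam),
                (mu + 2 * ISOTOPE_SPACING, h * lam**2 / 2.0),
            ]
        for pos, amp in sats:
            if amp <= 0:
                continue
            lo = max(int((pos - 5 * sigma - mz_axis[0]) / step), 0)
            hi = min(int((pos + 5 * sigma - mz_axis[0]) / step) + 2, len(mz_axis))
            window = mz_axis[lo:hi]
            signal[lo:hi] += amp * np.exp(-0.5 * ((window - pos) / sigma) ** 2)
    return signal


def simulate_plate(
    cfg: SimulationConfig,
) -> tuple[list[Spectrum], PlateLayout, pd.DataFrame]:
    """Simulate one plate: spectra, layout and ground-truth table.

    The truth table has one row per feature: ``mz``, ``responder``,
    ``b, c, d, e`` (c = d = base intensity for non-responders), ``pec50``
    and ``direction``.  Output is fully determined by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    mz_axis = cfg.mz_range[0] + cfg.mz_step * np.arange(
        int(round((cfg.mz_range[1] - cfg.mz_range[0]) / cfg.mz_step)) + 1
    )

    flat_mz = _draw_feature_positions(cfg, rng)
    flat_height = rng.uniform(2.0, 20.0, size=len(flat_mz))

    truth_rows = [
        {"mz": s.mz, "responder": True, "b": s.b, "c": s.c, "d": s.d, "e": s.e,
         "pec50": s.pec50, "direction": s.direction}
        for s in cfg.responder_specs
    ] + [
        {"mz": float(mzv), "responder": False, "b": 0.0, "c": float(h), "d": float(h),
         "e": float("nan"), "pec50": float("nan"), "direction": "none"}
        for mzv, h in zip(flat_mz, flat_height)
    ]
    truth = (
        pd.DataFrame(truth_rows)
        .sort_values("mz", kind="stable")
        .reset_index(drop=True)
    )

    layout_rows = []
    spectra: list[Spectrum] = []
    spot_index = 0
    sigma_ln = cfg.noise_sd_rel
    for dose in cfg.doses:
        for rep in range(cfg.n_replicates):
            spot_id = f"spot_{spot_index:03d}"
            spot_index += 1
            layout_rows.append(
                {"spot_id": spot_id, "concentration": dose,
                 "replicate_index": rep + 1, "compound_id": cfg.compound_id}
            )
            heights = np.concatenate(
                [
                    [_ll4(dose, s.b, s.c, s.d, s.e) for s in cfg.responder_specs],
                    flat_height,
                ]
            )
            positions = np.concatenate([[s.mz for s in cfg.responder_specs], flat_mz])
            signal = _render_peaks(
                mz_axis, positions, heights, cfg.peak_width_sigma, cfg.isotope_envelope
            )
            rel = (mz_axis - cfg.mz_range[0]) / (cfg.mz_range[1] - cfg.mz_range[0])
            baseline = cfg.baseline_amplitude * (
                1.5 * np.exp(-rel * 4.0) + 0.3 + 0.2 * np.cos(2 * np.pi * rel)
            )
            scale = (
                float(rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln))
                if sigma_ln > 0
                else 1.0
            )
            if spot_id in cfg.outlier_spots:
                scale *= cfg.outlier_scale
            noise = (
                rng.normal(0.0, cfg.additive_noise_sd, size=len(mz_axis))
                if cfg.additive_noise_sd > 0
                else 0.0
            )
            intensity = np.clip(scale * (signal + baseline) + noise, 0.0, None)
            spectra.append(
                Spectrum(
                    mz=mz_axis.copy(),
                    intensity=intensity,
                    spot_id=spot_id,
                    concentration=float(dose),
                    metadata={"mode": "profile", "simulated": True,
                              "spot_scale": scale},
                )
            )
    layout = PlateLayout(pd.DataFrame(layout_rows))
    return spectra, layout, truth


def write_fixture_bundle(cfg: SimulationConfig, out_dir) -> dict[str, Path]:
    """Write one simulated plate as the CLI input contract.

    Produces ``plate.mzml`` (one multi-spectrum file), ``layout.csv`` and
    ``truth.csv`` in ``out_dir``; returns their paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spectra, layout, truth = simulate_plate(cfg)
    paths = {
        "mzml": out_dir / "plate.mzml",
        "layout": out_dir / "layout.csv",
        "truth": out_dir / "truth.csv",
    }
    write_mzml(spectra, paths["mzml"], mode="profile")
    layout.table.to_csv(paths["layout"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths
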