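"""Spectrum, plate-layout and result-table I/O.

Spectra enter the pipeline either from mzML (self-contained reader/writer
for the PSI standard, uncompressed or zlib-compressed binary arrays) or from
a plain two-column text dialect used for small fixtures.  A plate-layout CSV
maps each MALDI target spot to its compound and concentration; the join key
is the mzML spectrum id, matched exactly.  Bruker Flex (``.fid``) raw data is
not read directly — convert to mzML first (e.g. with msconvert).

Concentration units are taken as given: pEC50 values downstream are −log10
of the user's unit, so molar input yields conventional pEC50.
"""

from __future__ import annotations

import base64
import struct
import warnings
import xml.etree.ElementTree as _etree
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "PlateLayout",
    "read_mzml",
    "write_mzml",
    "read_txt_spectrum",
    "read_layout",
    "attach_layout",
    "write_scores_csv",
    "read_scores_csv",
]

SCORE_COLUMNS = [
    "mz",
    "pec50",
    "log2fc",
    "fz",
    "fv",
    "crs_percent",
    "direction",
    "cluster_label",
]


@dataclass
class Spectrum:
    """One spot's mass spectrum.

    Invariants: ``mz`` strictly increasing, ``intensity`` the same length,
    finite and non-negative.  ``metadata`` records processing provenance
    (stage flags, normalization factor, recalibration shift, raw TIC).
    """

    mz: np.ndarray
    intensity: np.ndarray
    spot_id: str = ""
    concentration: float = float("nan")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if len(self.mz) != len(self.intensity):
            raise ValueError(
                f"spot {self.spot_id!r}: mz length {len(self.mz)} != "
                f"intensity length {len(self.intensity)}"
            )
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError(f"spot {self.spot_id!r}: m/z axis not strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError(f"spot {self.spot_id!r}: non-finite intensities")
        if np.any(self.intensity < 0):
            raise ValueError(f"spot {self.spot_id!r}: negative intensities")

    def replace(self, **kwargs) -> "Spectrum":
        """Return a copy with selected fields replaced (metadata is copied)."""
        out = {
            "mz": self.mz,
            "intensity": self.intensity,
            "spot_id": self.spot_id,
            "concentration": self.concentration,
            "metadata": dict(self.metadata),
        }
        out.update(kwargs)
        return Spectrum(**out)

    @property
    def tic(self) -> float:
        """Total ion current: sum of all intensities."""
        return float(np.sum(self.intensity))


@dataclass
class PlateLayout:
    """Spot → (concentration, replicate, compound) mapping for one plate.

    ``table`` columns: spot_id, concentration, replicate_index, compound_id.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"spot_id", "concentration", "replicate_index", "compound_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"layout missing columns: {sorted(missing)}")
        if self.table["spot_id"].duplicated().any():
            dupes = self.table.loc[self.table["spot_id"].duplicated(), "spot_id"]
            raise ValueError(f"duplicate spot_id values: {sorted(set(dupes))}")
        if (self.table["concentration"] < 0).any():
            raise ValueError("negative concentrations in layout")
        self.table = self.table.reset_index(drop=True)

    @property
    def spots(self) -> list[str]:
        return list(self.table["spot_id"])

    @property
    def concentrations(self) -> np.ndarray:
        """Distinct concentrations, ascending."""
        return np.sort(self.table["concentration"].unique())

    def concentration_of(self, spot_id: str) -> float:
        row = self.table.loc[self.table["spot_id"] == spot_id]
        if row.empty:
            raise KeyError(f"spot {spot_id!r} not in layout")
        return float(row["concentration"].iloc[0])

    def replicate_groups(self) -> dict[tuple, list[str]]:
        """Spot ids per (compound_id, concentration) replicate group."""
        groups: dict[tuple, list[str]] = {}
        for _, row in self.table.iterrows():
            key = (row["compound_id"], float(row["concentration"]))
            groups.setdefault(key, []).append(row["spot_id"])
        return groups


# ---------------------------------------------------------------------------
# mzML

def _extract_spot_id(spectrum_id: str) -> str:
    # honour "spot=A1"-style ids; otherwise the id string itself is the spot
    for token in str(spectrum_id).split():
        if token.startswith("spot="):
            return token[len("spot="):]
    return str(spectrum_id)


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


_DTYPE_ACCESSIONS = {"MS:1000523": "d", "MS:1000521": "f"}  # 64-bit / 32-bit float
_ARRAY_ACCESSIONS = {"MS:1000514": "mz", "MS:1000515": "intensity"}


def _decode_binary_array(elem) -> tuple[str | None, np.ndarray | None]:
    """Decode one <binaryDataArray>: returns (role, values)."""
    fmt, role, compressed = "d", None, False
    text = ""
    for child in elem.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc in _DTYPE_ACCESSIONS:
                fmt = _DTYPE_ACCESSIONS[acc]
            elif acc in _ARRAY_ACCESSIONS:
                role = _ARRAY_ACCESSIONS[acc]
            elif acc == "MS:1000574":  # zlib compression
                compressed = True
        elif name == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    values = np.frombuffer(raw, dtype=np.dtype(f"<{fmt}")).astype(float)
    return role, values


def read_mzml(path) -> list[Spectrum]:
    """Read all MS1 spectra from an mzML file, in file order.

    Namespace-agnostic parse of the mzML spectrum list; 32/64-bit float
    arrays, uncompressed or zlib-compressed, are supported.  Profile and
    centroid spectra are both accepted; the mode is recorded in
    ``metadata['mode']``.  A non-monotonic m/z axis is repaired by sorting
    (with a warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mzML file not found: {path}")
    spectra: list[Spectrum] = []
    try:
        tree = _etree.parse(str(path))
    except _etree.ParseError as exc:
        raise ValueError(f"failed to parse mzML file {path}: {exc}") from exc
    for elem in tree.getroot().iter():
        if _localname(elem.tag) != "spectrum":
            continue
        mode = "unknown"
        arrays: dict[str, np.ndarray] = {}
        for child in elem.iter():
            name = _localname(child.tag)
            if name == "cvParam" and child.get("accession") == "MS:1000128":
                mode = "profile"
            elif name == "cvParam" and child.get("accession") == "MS:1000127":
                mode = "centroid"
            elif name == "binaryDataArray":
                role, values = _decode_binary_array(child)
                if role is not None:
                    arrays[role] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(
                f"{path.name}: spectrum {elem.get('id')!r} lacks m/z or intensity array"
            )
        mz, inten = arrays["mz"], arrays["intensity"]
        if len(mz) != len(inten):
            raise ValueError(
                f"{path.name}: spectrum {elem.get('id')!r} has mismatched array lengths"
            )
        if len(mz) > 1 and np.any(np.diff(mz) <= 0):
            warnings.warn(
                f"{path.name}: spectrum {elem.get('id')!r} has a non-monotonic "
                "m/z axis; sorted"
            )
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
            keep = np.concatenate([[True], np.diff(mz) > 0])
            mz, inten = mz[keep], inten[keep]
        spot_id = _extract_spot_id(elem.get("id", f"index={len(spectra)}"))
        spectra.append(
            Spectrum(
                mz=mz,
                intensity=np.clip(inten, 0.0, None),
                spot_id=spot_id,
                metadata={"mode": mode, "source": str(path)},
            )
        )
    return spectra


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="run">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _encode_array(values: np.ndarray, fmt: str) -> str:
    raw = struct.pack(f"<{len(values)}{fmt}", *values)
    return base64.b64encode(raw).decode("ascii")


def write_mzml(spectra: list[Spectrum], path, mode: str = "profile") -> None:
    """Write spectra to a minimal uncompressed mzML file.

    m/z is encoded as 64-bit float, intensity as 32-bit float (the common
    vendor convention); spot ids are stored as ``spot=<id>`` spectrum ids.
    Output is deterministic: no timestamps or environment-dependent fields.
    """
    path = Path(path)
    mode_param = (
        '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>'
        if mode == "profile"
        else '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
    )
    parts = [_MZML_HEADER.format(count=len(spectra))]
    for index, s in enumerate(spectra):
        mz64 = _encode_array(np.asarray(s.mz, dtype=np.float64), "d")
        in32 = _encode_array(np.asarray(s.intensity, dtype=np.float32), "f")
        spot = escape(f"spot={s.spot_id}", {'"': "&quot;"})
        parts.append(
            f"""      <spectrum index="{index}" id="{spot}" defaultArrayLength="{len(s.mz)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        {mode_param}
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(in32)}">
            <cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{in32}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""
        )
    parts.append(_MZML_FOOTER)
    path.write_text("".join(parts))


def read_txt_spectrum(path, spot_id: str | None = None) -> Spectrum:
    """Read a two-column (m/z, intensity) whitespace/tab-separated spectrum."""
    path = Path(path)
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, got {data.shape[1]}")
    order = np.argsort(data[:, 0], kind="stable")
    return Spectrum(
        mz=data[order, 0],
        intensity=np.clip(data[order, 1], 0.0, None),
        spot_id=spot_id or path.stem,
        metadata={"mode": "unknown", "source": str(path)},
    )


# ---------------------------------------------------------------------------
# layouts

def read_layout(path) -> PlateLayout:
    """Read a layout CSV with columns spot_id, concentration[, compound_id].

    ``replicate_index`` is assigned per (compound, concentration) group in
    file order, starting at 1.  Zero concentrations are accepted (vehicle
    control) and treated as the lowest dose downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"layout file not found: {path}")
    table = pd.read_csv(path)
    for col in ("spot_id", "concentration"):
        if col not in table.columns:
            raise ValueError(f"layout {path.name}: missing column {col!r}")
    table["spot_id"] = table["spot_id"].astype(str)
    table["concentration"] = pd.to_numeric(table["concentration"], errors="raise")
    if "compound_id" not in table.columns:
        table["compound_id"] = "compound"
    table["replicate_index"] = (
        table.groupby(["compound_id", "concentration"]).cumcount() + 1
    )
    return PlateLayout(table[["spot_id", "concentration", "replicate_index", "compound_id"]])


def attach_layout(spectra: list[Spectrum], layout: PlateLayout) -> list[Spectrum]:
    """Attach layout concentrations to spectra by exact spot-id match.

    Spectra without a layout row are an error (mismatches are reported, not
    guessed); layout rows without a spectrum produce a warning.
    """
    known = dict(zip(layout.table["spot_id"], layout.table["concentration"]))
    missing = [s.spot_id for s in spectra if s.spot_id not in known]
    if missing:
        raise KeyError(f"spots not present in layout: {missing}")
    unused = set(known) - {s.spot_id for s in spectra}
    if unused:
        warnings.warn(f"layout rows without spectra: {sorted(unused)}")
    return [s.replace(concentration=float(known[s.spot_id])) for s in spectra]


# ---------------------------------------------------------------------------
# result tables

def write_scores_csv(scores, path) -> None:
    """Write per-feature scores, sorted by CRS descending.

    Columns: mz, pec50, log2fc, fz, fv, crs_percent, direction, cluster_label.
    Values round-trip to at least 6 significant digits.
    """
    if not scores:
        raise ValueError("no scores to write")
    rows = []
    for s in scores:
        rows.append(
            {
                "mz": s.feature_mz,
                "pec50": s.pec50,
                "log2fc": s.log2fc,
                "fz": s.fz,
                "fv": s.fv,
                "crs_percent": s.crs,
                "direction": s.direction,
                "cluster_label": s.cluster_label,
            }
        )
    frame = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    frame = frame.sort_values("crs_percent", ascending=False, kind="stable")
    frame.to_csv(path, index=False, float_format="%.6g")


def read_scores_csv(path) -> pd.DataFrame:
    """Read a scores CSV written by :func:`write_scores_csv`."""
    return pd.read_csv(path)
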