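"""MGF / feature-table I/O and library-based dereplication.

The pipeline's contract starts where raw-file feature detection ends: an
MGF file holding one MS/MS spectrum per feature and a CSV quantification
table (feature id, m/z, RT, per-sample intensities). This module reads
and writes both dialects deterministically and performs the
identification step against a small in-house library of authentic
standards: a feature is identified when precursor mass (ppm), retention
time (minutes) and MS/MS similarity (modified cosine) all agree.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _pymgf

from .chemformula import ElementalFormula, mz_deprotonated, parse_formula, ppm_error

__all__ = [
    "MsmsSpectrum",
    "FeatureTable",
    "LibraryEntry",
    "Identification",
    "SpectrumFormatError",
    "read_mgf",
    "write_mgf",
    "read_feature_table",
    "write_feature_table",
    "read_library_json",
    "match_library",
]


class SpectrumFormatError(ValueError):
    """Malformed MGF or feature-table input."""


@dataclass
class MsmsSpectrum:
    """One negative-mode MS/MS spectrum (a molecular-network node).

    Peaks are stored as an (n, 2) float array of (m/z, intensity),
    sorted by ascending m/z with exact-duplicate m/z values merged
    (summed intensity). RT is in minutes.
    """

    feature_id: str
    precursor_mz: float
    rt: float
    peaks: np.ndarray
    charge_mode: str = "1-"

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"{self.feature_id}: precursor m/z must be positive")
        arr = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if np.any(arr[:, 1] < 0):
            raise ValueError(f"{self.feature_id}: negative peak intensity")
        order = np.argsort(arr[:, 0], kind="stable")
        arr = arr[order]
        if len(arr) > 1:
            # merge exact m/z duplicates so m/z is strictly increasing
            uniq, inv = np.unique(arr[:, 0], return_inverse=True)
            merged = np.zeros((len(uniq), 2))
            merged[:, 0] = uniq
            np.add.at(merged[:, 1], inv, arr[:, 1])
            arr = merged
        self.peaks = arr

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]

    def base_peak_intensity(self) -> float:
        return float(self.peaks[:, 1].max()) if len(self.peaks) else 0.0


@dataclass
class FeatureTable:
    """Features x samples intensity matrix with m/z / RT metadata."""

    feature_ids: list[str]
    mz: np.ndarray
    rt: np.ndarray
    samples: list[str]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        n, m = len(self.feature_ids), len(self.samples)
        if self.intensities.shape != (n, m):
            raise ValueError(
                f"intensity matrix shape {self.intensities.shape} != ({n}, {m})"
            )
        # raw tables are non-negative; that is enforced at the I/O boundary
        # (read_feature_table) because normalized tables legitimately hold
        # negative auto-scaled values.

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, index=self.feature_ids, columns=self.samples)
        df.insert(0, "rt", self.rt)
        df.insert(0, "mz", self.mz)
        df.index.name = "feature_id"
        return df


@dataclass
class LibraryEntry:
    """Authentic standard: name, neutral formula, RT, reference MS/MS peaks."""

    name: str
    neutral_formula: ElementalFormula
    rt: float
    reference_peaks: np.ndarray

    def __post_init__(self) -> None:
        self.reference_peaks = np.asarray(self.reference_peaks, dtype=float).reshape(-1, 2)

    @property
    def precursor_mz(self) -> float:
        return mz_deprotonated(self.neutral_formula)


@dataclass
class Identification:
    feature_id: str
    library_name: str
    ppm_error: float
    rt_delta: float
    cosine: float


# ---------------------------------------------------------------------------
# MGF


def _spectrum_to_pyteomics(s: MsmsSpectrum) -> dict:
    return {
        "m/z array": s.mz,
        "intensity array": s.intensity,
        "params": {
            "title": s.feature_id,
            "pepmass": round(s.precursor_mz, 4),
            "rtinseconds": round(s.rt * 60.0, 2),
            "charge": s.charge_mode,
        },
    }


def read_mgf(path: str | Path) -> list[MsmsSpectrum]:
    """Read an MGF file into a list of spectra.

    TITLE becomes the feature id, PEPMASS the precursor m/z, RTINSECONDS
    is converted to minutes. Unbalanced BEGIN/END blocks or a block
    without PEPMASS raise :class:`SpectrumFormatError` naming the block.
    """
    path = Path(path)
    text = path.read_text()
    n_begin = text.count("BEGIN IONS")
    n_end = text.count("END IONS")
    if n_begin != n_end:
        raise SpectrumFormatError(
            f"{path.name}: unbalanced MGF blocks ({n_begin} BEGIN IONS vs {n_end} END IONS)"
        )
    spectra: list[MsmsSpectrum] = []
    with _pymgf.read(io.StringIO(text), use_index=False) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise SpectrumFormatError(f"{path.name}: block {i} has no PEPMASS")
            rt_s = params.get("rtinseconds", 0.0)
            charge = params.get("charge")
            charge_mode = "1-"
            if charge:
                c = charge[0]
                charge_mode = f"{abs(int(c))}{'-' if int(c) < 0 else '+'}"
            title = str(params.get("title", f"spectrum_{i}"))
            peaks = np.column_stack([entry["m/z array"], entry["intensity array"]])
            spectra.append(
                MsmsSpectrum(
                    feature_id=title,
                    precursor_mz=float(pepmass[0]),
                    rt=float(rt_s) / 60.0,
                    peaks=peaks,
                    charge_mode=charge_mode,
                )
            )
    return spectra


_KEY_ORDER = ["title", "pepmass", "rtinseconds", "charge"]


def write_mgf(spectra: Iterable[MsmsSpectrum], path: str | Path) -> None:
    """Serialize spectra to MGF with a fixed field order and precision.

    m/z values are written at 4 decimal places and intensities at 1, so a
    read/write roundtrip is the identity at serialization precision and
    the output is byte-stable across runs.
    """
    path = Path(path)
    with path.open("w") as fh:
        _pymgf.write(
            (_spectrum_to_pyteomics(s) for s in spectra),
            fh,
            key_order=_KEY_ORDER,
            fragment_format="{:.4f} {:.1f}",
            write_charges=False,
            use_numpy=False,
        )


# ---------------------------------------------------------------------------
# Feature table CSV


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature quantification CSV: feature_id, mz, rt, then sample columns."""
    path = Path(path)
    df = pd.read_csv(path)
    required = ["feature_id", "mz", "rt"]
    if list(df.columns[:3]) != required:
        raise SpectrumFormatError(
            f"{path.name}: first columns must be {required}, got {list(df.columns[:3])}"
        )
    samples = [str(c) for c in df.columns[3:]]
    inten = df[df.columns[3:]].to_numpy(dtype=float)
    if np.any(np.isnan(inten)):
        raise SpectrumFormatError(f"{path.name}: ragged or non-numeric intensity rows")
    if np.any(inten < 0):
        raise SpectrumFormatError(f"{path.name}: negative intensities")
    return FeatureTable(
        feature_ids=[str(x) for x in df["feature_id"]],
        mz=df["mz"].to_numpy(dtype=float),
        rt=df["rt"].to_numpy(dtype=float),
        samples=samples,
        intensities=inten,
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.to_frame()
    df.to_csv(Path(path), float_format="%.6g")


# ---------------------------------------------------------------------------
# Spectral library


def read_library_json(path: str | Path) -> list[LibraryEntry]:
    """Read a spectral library from the JSON sidecar dialect.

    Format: list of objects with keys ``name``, ``formula`` (neutral,
    Hill notation), ``rt`` (minutes) and ``peaks`` ([[mz, intensity], ...]).
    """
    entries = json.loads(Path(path).read_text())
    out = []
    for e in entries:
        out.append(
            LibraryEntry(
                name=str(e["name"]),
                neutral_formula=parse_formula(e["formula"]),
                rt=float(e["rt"]),
                reference_peaks=np.asarray(e["peaks"], dtype=float),
            )
        )
    return out


def match_library(
    spectra: Sequence[MsmsSpectrum],
    library: Sequence[LibraryEntry],
    ppm_tol: float = 10.0,
    rt_tol: float = 0.2,
    cosine_min: float = 0.7,
) -> list[Identification]:
    """Identify features against authentic standards.

    A feature matches an entry iff the precursor is within ``ppm_tol`` of
    the entry's theoretical [M-H]^- m/z, retention times agree within
    ``rt_tol`` minutes, and the modified cosine against the reference
    spectrum reaches ``cosine_min``. All qualifying matches are returned,
    ranked by cosine (descending), then |ppm| (ascending), then library
    name — fully deterministic.
    """
    if ppm_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    from .msnetwork import modified_cosine  # deferred: avoid import cycle

    results: list[Identification] = []
    for s in spectra:
        for entry in library:
            theo = entry.precursor_mz
            err = ppm_error(s.precursor_mz, theo)
            drt = s.rt - entry.rt
            if abs(err) > ppm_tol or abs(drt) > rt_tol:
                continue
            ref = MsmsSpectrum(
                feature_id=f"library:{entry.name}",
                precursor_mz=theo,
                rt=entry.rt,
                peaks=entry.reference_peaks,
            )
            score, _ = modified_cosine(s, ref)
            if score < cosine_min:
                continue
            results.append(
                Identification(
                    feature_id=s.feature_id,
                    library_name=entry.name,
                    ppm_error=err,
                    rt_delta=drt,
                    cosine=score,
                )
            )
    results.sort(key=lambda r: (r.feature_id, -r.cosine, abs(r.ppm_error), r.library_name))
    return results


def write_identifications(ids: Sequence[Identification], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "library_name": r.library_name,
                "ppm_error": round(r.ppm_error, 3),
                "rt_delta": round(r.rt_delta, 3),
                "cosine": round(r.cosine, 4),
            }
            for r in ids
        ],
        columns=["feature_id", "library_name", "ppm_error", "rt_delta", "cosine"],
    )
    df.to_csv(Path(path), index=False)
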