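"""Seeded synthetic corpus with the structure the analysis assumes.

Raw LC-MS runs for this kind of sponge chemotyping study are rarely
deposited, so every pipeline stage is exercised against a generated
corpus instead: ~9 samples in two chemotypes, features in the m/z
300-550 range whose MS/MS spectra follow the diagnostic neutral-loss
grammar of the structural classes in :mod:`isomet.fragrules`, per-sample
abundances from a log-normal model with a chemotype-specific mean shift,
and realistic m/z jitter plus low-level noise peaks.

Template precursor formulas are a curated pool of printed triterpenoid
and lipid compositions, not random formulas, so generated precursors are
chemically plausible. Intensity profiles per class are stylized: real
per-class profiles are unpublished.

The one piece of real data packaged here is the printed 16-compound x
9-specimen relative-content matrix (:func:`table3_fixture`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemformula import mz_anion, mz_deprotonated, parse_formula
from .fragrules import _chain_mass  # loss-chain arithmetic shared with the rule engine
from .spectra_io import FeatureTable, LibraryEntry, MsmsSpectrum, write_feature_table, write_mgf

__all__ = [
    "CorpusConfig",
    "GroundTruthEntry",
    "SyntheticCorpus",
    "SpectrumTemplate",
    "TEMPLATES",
    "generate_corpus",
    "corpus_library",
    "table3_fixture",
    "table3_metadata",
]


# ---------------------------------------------------------------------------
# Spectral templates
#
# Each template stands for one compound: a neutral precursor formula, a
# retention time, and a fragment recipe. Fragments are written either as
# neutral-loss chains (so their m/z derives from the precursor exactly the
# way the rule engine computes its targets) or as explicit anion
# compositions for core/sugar/headgroup series ions.


@dataclass(frozen=True)
class SpectrumTemplate:
    name: str
    class_id: str
    formula: str  # neutral composition
    rt: float  # minutes
    losses: tuple[tuple[tuple[str, ...], float], ...]  # (chain, rel intensity)
    fragments: tuple[tuple[str, float], ...] = ()  # (anion composition, rel intensity)

    def peak_list(self) -> np.ndarray:
        """Noise-free theoretical peaks (m/z ascending)."""
        prec = mz_deprotonated(parse_formula(self.formula))
        peaks = [(prec - _chain_mass(chain), inten) for chain, inten in self.losses]
        peaks += [(mz_anion(parse_formula(f)), inten) for f, inten in self.fragments]
        arr = np.array(sorted(peaks), dtype=float)
        return arr

    @property
    def precursor_mz(self) -> float:
        return mz_deprotonated(parse_formula(self.formula))


def _t(name, class_id, formula, rt, losses, fragments=()):
    return SpectrumTemplate(
        name=name,
        class_id=class_id,
        formula=formula,
        rt=rt,
        losses=tuple((tuple(c), float(i)) for c, i in losses),
        fragments=tuple((f, float(i)) for f, i in fragments),
    )


#: Per-class template pools. Chemotype enrichment of classes follows the
#: study design: side-chain acids, RAA-type cores and glycosides dominate
#: chemotype A; 3-hydroxy-4-carboxy cores and acetoxy congeners dominate
#: chemotype B; the remaining classes are shared background.
TEMPLATES: dict[str, list[SpectrumTemplate]] = {
    "SC_ACID": [
        _t("jaspolide F-like", "SC_ACID", "C25H34O4", 13.09,
           [(["CO2"], 100), (["CO2", "CH4"], 85), (["C6H6O2"], 40),
            (["C6H6O2", "CO2"], 35), (["H2O"], 20), (["C2H2O"], 15)]),
        _t("globostelletin I-like", "SC_ACID", "C27H36O4", 14.12,
           [(["CO2"], 100), (["CO2", "CH4"], 85), (["C6H6O2"], 40),
            (["C6H6O2", "CH4"], 30), (["H2O"], 20), (["C2H2O"], 15)]),
    ],
    "SC_ACID_HYDROXY": [
        _t("hydroxy acid congener", "SC_ACID_HYDROXY", "C30H42O6", 11.66,
           [(["CO2"], 100), (["H2O"], 60), (["CO2", "H2O"], 10),
            (["C3H6O"], 30), (["C3H6O", "CO2"], 25), (["CO2", "H2O", "H2O"], 8)]),
        _t("stellettin W-like", "SC_ACID_HYDROXY", "C22H32O6", 10.93,
           [(["CO2"], 100), (["H2O"], 60), (["CO2", "H2O"], 10),
            (["C3H6O"], 30), (["C3H6O", "CO2"], 25), (["CO2", "H2O", "H2O"], 8)]),
    ],
    "CORE_3OH_4COOH": [
        _t("jaspiferal acid", "CORE_3OH_4COOH", "C27H36O5", 10.98,
           [(["H2O"], 50), (["CO"], 10), (["CO2"], 40), (["CO2", "H2O"], 100),
            (["CO2", "H2O", "H2O"], 30), (["CO2", "H2O", "H2O", "CH4"], 60)],
           [("C19H25O", 45), ("C18H25O", 40), ("C15H19O", 35), ("C13H11O", 30)]),
        _t("dihydroxy acid congener", "CORE_3OH_4COOH", "C30H44O6", 8.15,
           [(["H2O"], 50), (["CO2", "H2O"], 100), (["CO2", "H2O", "H2O"], 40),
            (["CO2", "H2O", "H2O", "CH4"], 30), (["CO2"], 35)],
           [("C16H23O", 25), ("C15H19O", 20)]),
    ],
    "CARBONYL_CO": [
        _t("globostelletin N-like", "CARBONYL_CO", "C30H40O5", 11.07,
           [(["CO"], 60), (["CO2"], 100), (["CO", "CO2"], 80),
            (["CO", "CO2", "H2O"], 30), (["H2O"], 20), (["CO", "H2O"], 15)]),
        _t("stellettin S-like", "CARBONYL_CO", "C19H28O3", 11.41,
           [(["CO"], 60), (["CO2"], 100), (["CO", "CO2"], 80),
            (["CO", "CO2", "H2O"], 30), (["H2O"], 20), (["CO", "H2O"], 15)]),
    ],
    "ACETOXY_MOD": [
        _t("stellettin H-like", "ACETOXY_MOD", "C32H44O5", 20.03,
           [(["C2H4O2"], 100), (["C2H4O2", "C2H4O"], 40),
            (["C2H4O2", "CO2"], 70), (["C2H4O2", "CO2", "C2H4O"], 30),
            (["C2H4O2", "CO2", "CH4"], 50), (["C2H4O2", "CO2", "CH4", "C2H4O"], 20)]),
        _t("acetoxy globostellatic-like", "ACETOXY_MOD", "C32H44O7", 11.18,
           [(["C2H4O2"], 100), (["C2H4O2", "C2H4O"], 40),
            (["C2H4O2", "CO2"], 70), (["C2H4O2", "CO2", "C2H4O"], 30),
            (["C2H4O2", "CO2", "CH4"], 50), (["C2H4O2", "CO2", "CH4", "C2H4O"], 20)]),
    ],
    "GLYCOSIDE": [
        _t("rhabdastrelloside A-like", "GLYCOSIDE", "C44H73NO14", 9.53,
           [(["C8H13NO5"], 100), (["C8H13NO5", "C6H10O5"], 80), (["H2O"], 20),
            (["C8H13NO5", "H2O"], 15), (["C8H13NO5", "C6H10O5", "H2O"], 10)],
           [("C8H12NO5", 60), ("C10H16NO7", 40)]),
        _t("dihexoside analog", "GLYCOSIDE", "C42H70O14", 9.69,
           [(["C6H10O5"], 100), (["C6H10O5", "C6H10O5"], 80), (["H2O"], 20),
            (["C6H10O5", "H2O"], 15), (["C6H10O5", "C6H10O5", "H2O"], 10)]),
    ],
    "NITROGENOUS": [
        _t("nitrogenous acid 1", "NITROGENOUS", "C22H31NO4", 7.5,
           [(["CO2"], 100), (["CO2", "CH4"], 80), (["CO2", "C2H3NO"], 60),
            (["CO2", "CH4", "C2H3NO"], 50), (["H2O"], 15), (["CO2", "H2O"], 10)]),
        _t("nitrogenous acid 2", "NITROGENOUS", "C22H33NO5", 8.0,
           [(["CO2"], 100), (["CO2", "CH4"], 80), (["CO2", "C2H3NO"], 60),
            (["CO2", "CH4", "C2H3NO"], 50), (["H2O"], 15), (["CO2", "H2O"], 10)]),
    ],
    "LYSO_PI": [
        # compositions are typical lyso-PI species; the study prints none
        _t("lyso-PI 16:0-like", "LYSO_PI", "C25H49O12P", 3.2,
           [(["C6H10O5"], 50), (["C6H12O6"], 40)],
           [("C6H12O9P", 100), ("C6H10O8P", 80), ("C6H8O7P", 60)]),
        _t("lyso-PI 17:1-like", "LYSO_PI", "C26H49O12P", 3.6,
           [(["C6H10O5"], 50), (["C6H12O6"], 40)],
           [("C6H12O9P", 100), ("C6H10O8P", 80), ("C6H8O7P", 60)]),
    ],
    "CORE_RAA": [
        _t("RAA-like", "CORE_RAA", "C30H40O4", 16.87,
           [(["CO2"], 100), (["CO2", "CH4"], 85)],
           [("C20H29O2", 60), ("C19H25O2", 50), ("C17H25O2", 45),
            ("C16H21O2", 40), ("C15H17O2", 35)]),
        _t("dihydro-RAA-like", "CORE_RAA", "C30H42O4", 16.8,
           [(["CO2"], 100), (["CO2", "CH4"], 85)],
           [("C20H29O2", 60), ("C19H25O2", 50), ("C17H25O2", 45),
            ("C16H21O2", 40), ("C15H17O2", 35)]),
    ],
    "CORE_JASPIFERAL": [
        _t("stellettin K-like", "CORE_JASPIFERAL", "C30H42O4", 17.11,
           [(["H2O"], 40), (["CO2"], 20), (["CH2O2"], 15),
            (["CO2", "H2O"], 30), (["CO2", "H2O", "CH4"], 25)],
           [("C21H29O", 20), ("C19H25O", 100), ("C18H25O", 90),
            ("C15H19O", 80), ("C13H11O", 70)]),
        _t("stellettin K isomer", "CORE_JASPIFERAL", "C30H42O4", 17.25,
           [(["H2O"], 40), (["CO2"], 20), (["CH2O2"], 15),
            (["CO2", "H2O"], 30), (["CO2", "H2O", "CH4"], 25)],
           [("C21H29O", 20), ("C19H25O", 100), ("C18H25O", 90),
            ("C15H19O", 80), ("C13H11O", 70)]),
    ],
    "CORE_OXY": [
        _t("oxygenated core 1", "CORE_OXY", "C30H42O7", 7.49,
           [(["H2O"], 80), (["CO2"], 50), (["CO2", "H2O"], 20), (["C3H6O"], 30)],
           [("C16H23O2", 100), ("C15H19O2", 90)]),
        _t("oxygenated core 2", "CORE_OXY", "C31H46O6", 10.51,
           [(["H2O"], 80), (["CO2"], 50), (["CO2", "H2O"], 20), (["C3H6O"], 30)],
           [("C16H23O2", 100), ("C15H19O2", 90)]),
    ],
}

#: Chemotype in which each enriched class is more abundant.
CLASS_ENRICHMENT: dict[str, str] = {
    "SC_ACID": "A",
    "CORE_RAA": "A",
    "GLYCOSIDE": "A",
    "CORE_3OH_4COOH": "B",
    "ACETOXY_MOD": "B",
}


@dataclass(frozen=True)
class CorpusConfig:
    """Generator settings; the defaults are the study conditions emulated.

    9 samples split 6:3 into chemotypes A and B, 4 features per class,
    0.005 Da fragment m/z jitter (precursors get a fifth of that -- Q-TOF
    precursor mass accuracy is far better than fragment accuracy), 5
    uniform noise peaks per spectrum capped at 5% of the base peak, 20%
    log-normal intensity noise, and a 1.5 log10 abundance contrast
    between chemotypes for enriched classes.
    """

    n_samples: int = 9
    n_chemotype_a: int = 6
    n_features_per_class: Mapping[str, int] | int = 4
    mz_jitter_sd: float = 0.005  # Da, fragment peaks
    rt_jitter_sd: float = 0.02  # minutes
    noise_peaks: int = 5
    intensity_cv: float = 0.2  # log-normal sigma on fragment intensities
    abundance_log10_shift: float = 1.5
    abundance_within_sd: float = 0.3  # log10 units
    base_log10_abundance: float = 5.0
    rng_seed: int = 1

    def features_for(self, class_id: str) -> int:
        if isinstance(self.n_features_per_class, int):
            return self.n_features_per_class
        return int(self.n_features_per_class.get(class_id, 0))

    def validate(self) -> None:
        if self.n_samples < 2 or not (0 < self.n_chemotype_a < self.n_samples):
            raise ValueError("need >=2 samples split into two non-empty chemotypes")
        if self.mz_jitter_sd < 0 or self.noise_peaks < 0 or self.intensity_cv < 0:
            raise ValueError("jitter, noise and cv must be non-negative")
        for cid in TEMPLATES:
            if self.features_for(cid) < 0:
                raise ValueError(f"negative feature count for class {cid}")


@dataclass(frozen=True)
class GroundTruthEntry:
    feature_id: str
    class_id: str
    template: str
    formula: str
    enrichment: str  # "A", "B" or "none"


@dataclass
class SyntheticCorpus:
    spectra: list[MsmsSpectrum]
    feature_table: FeatureTable
    ground_truth: dict[str, GroundTruthEntry]
    chemotypes: dict[str, str]  # sample -> "A"/"B"


def generate_corpus(
    config: CorpusConfig = CorpusConfig(), out_dir: str | Path | None = None
) -> SyntheticCorpus:
    """Generate a corpus; optionally write MGF + feature CSV + truth JSON.

    Output is a pure function of the config (including the seed): the
    same config written twice gives byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    samples = [f"sample_{i + 1:02d}" for i in range(config.n_samples)]
    chemotypes = {
        s: ("A" if i < config.n_chemotype_a else "B") for i, s in enumerate(samples)
    }

    spectra: list[MsmsSpectrum] = []
    truth: dict[str, GroundTruthEntry] = {}
    rows: list[np.ndarray] = []
    mzs: list[float] = []
    rts: list[float] = []
    ids: list[str] = []

    counter = 0
    for class_id in sorted(TEMPLATES):
        pool = TEMPLATES[class_id]
        n_feat = config.features_for(class_id)
        enrichment = CLASS_ENRICHMENT.get(class_id, "none")
        for k in range(n_feat):
            counter += 1
            fid = f"F{counter:04d}"
            tmpl = pool[k % len(pool)]
            prec = tmpl.precursor_mz + rng.normal(0.0, config.mz_jitter_sd / 5.0)
            rt = tmpl.rt + rng.normal(0.0, config.rt_jitter_sd)

            peaks = tmpl.peak_list().copy()
            peaks[:, 0] += rng.normal(0.0, config.mz_jitter_sd, size=len(peaks))
            if config.intensity_cv > 0:
                peaks[:, 1] *= np.exp(
                    rng.normal(0.0, config.intensity_cv, size=len(peaks))
                )
            base = peaks[:, 1].max()
            if config.noise_peaks > 0:
                noise_mz = rng.uniform(80.0, max(prec - 1.0, 81.0), config.noise_peaks)
                noise_int = rng.uniform(0.005, 0.05, config.noise_peaks) * base
                peaks = np.vstack([peaks, np.column_stack([noise_mz, noise_int])])

            spectra.append(
                MsmsSpectrum(feature_id=fid, precursor_mz=prec, rt=rt, peaks=peaks)
            )
            truth[fid] = GroundTruthEntry(
                feature_id=fid,
                class_id=class_id,
                template=tmpl.name,
                formula=tmpl.formula,
                enrichment=enrichment,
            )

            # per-sample abundances: log-normal around a per-chemotype mean
            log10 = np.empty(config.n_samples)
            for si, s in enumerate(samples):
                mu = config.base_log10_abundance
                if enrichment != "none" and chemotypes[s] == enrichment:
                    mu += config.abundance_log10_shift
                log10[si] = mu + rng.normal(0.0, config.abundance_within_sd)
            rows.append(10.0**log10)
            mzs.append(prec)
            rts.append(rt)
            ids.append(fid)

    table = FeatureTable(
        feature_ids=ids,
        mz=np.array(mzs),
        rt=np.array(rts),
        samples=samples,
        intensities=np.array(rows),
    )
    corpus = SyntheticCorpus(
        spectra=spectra, feature_table=table, ground_truth=truth, chemotypes=chemotypes
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mgf(spectra, out / "corpus.mgf")
        write_feature_table(table, out / "features.csv")
        payload = {
            "chemotypes": chemotypes,
            "features": {
                fid: {
                    "class_id": e.class_id,
                    "template": e.template,
                    "formula": e.formula,
                    "enrichment": e.enrichment,
                }
                for fid, e in truth.items()
            },
        }
        (out / "ground_truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return corpus


def corpus_library() -> list[LibraryEntry]:
    """A spectral library of the template compounds (noise-free reference spectra)."""
    entries = []
    for class_id in sorted(TEMPLATES):
        for tmpl in TEMPLATES[class_id]:
            entries.append(
                LibraryEntry(
                    name=tmpl.name,
                    neutral_formula=parse_formula(tmpl.formula),
                    rt=tmpl.rt,
                    reference_peaks=tmpl.peak_list(),
                )
            )
    return entries


# ---------------------------------------------------------------------------
# Printed relative-content matrix (the one real-data fixture)


def _table3_frame() -> pd.DataFrame:
    with resources.files("isomet.data").joinpath("table3.csv").open() as fh:
        return pd.read_csv(fh)


def table3_fixture() -> FeatureTable:
    """The printed 16-compound x 9-specimen relative-content matrix.

    Values are percentages normalized to each compound's maximum across
    samples; feature ids are the standard compounds' names, m/z the
    measured [M-H]^- values, RT in minutes.
    """
    df = _table3_frame()
    samples = [c for c in df.columns if c.startswith("PIBOC")]
    return FeatureTable(
        feature_ids=list(df["compound"]),
        mz=df["mz_measured"].to_numpy(float),
        rt=df["rt"].to_numpy(float),
        samples=samples,
        intensities=df[samples].to_numpy(float),
    )


def table3_metadata() -> pd.DataFrame:
    """Compound names, neutral formulas, RTs and measured [M-H]^- m/z."""
    return _table3_frame()[["compound", "formula", "rt", "mz_measured"]].copy()
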