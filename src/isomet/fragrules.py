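"""Diagnostic neutral-loss and fragment-series rules for structural annotation.

Negative-mode CID of isomalabaricane triterpenoids follows a small
grammar: a free side-chain carboxyl ejects CO2 (and then CH4 from the
adjacent gem-dimethyl); a 3-hydroxy-4-carboxy core is instead dominated
by the combined CO2+H2O loss; acetoxy groups eject acetic acid and
duplicate the fragment ladder 44 Da apart; glycosides shed sugar units
as Y-type ions; lyso-PI lipids give inositol-phosphate headgroup ions.
Each structural class is a weighted bundle of such rules, shipped as
editable JSON (``data/class_rules.json``) so chemists can extend the
grammar without touching code.

A class hypothesis scores the weight-sum of its satisfied rules; any
failed *required* rule or fired *forbidden* rule zeroes the class.
Classes are not mutually exclusive: a spectrum may legitimately be both
a side-chain acid and carry the RAA-type core series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chemformula import (
    ElementalFormula,
    monoisotopic_mass,
    nominal_mass,
    parse_formula,
)
from .spectra_io import MsmsSpectrum

__all__ = [
    "LossMatch",
    "Evidence",
    "Hypothesis",
    "AnnotationResult",
    "AnalogRelation",
    "UNCLASSIFIED",
    "load_class_rules",
    "default_class_rules",
    "detect_losses",
    "classify",
    "nitrogen_parity",
    "pair_analogs",
]

UNCLASSIFIED = "UNCLASSIFIED"

#: Matches below this fraction of the base peak are treated as noise grass.
MIN_REL_INTENSITY = 0.01

#: Nominal-series guard: round(m/z) must lie within this window of the peak.
NOMINAL_GUARD = 0.3

DEFAULT_FRAGMENT_TOL = 0.02  # Da


@dataclass(frozen=True)
class LossMatch:
    chain: tuple[str, ...]
    target_mz: float
    observed_mz: float
    error_da: float
    rel_intensity: float


@dataclass(frozen=True)
class Evidence:
    rule_label: str
    observed_mz: tuple[float, ...]
    error_da: tuple[float, ...]


@dataclass(frozen=True)
class Hypothesis:
    class_id: str
    score: float
    evidence: tuple[Evidence, ...]


@dataclass
class AnnotationResult:
    feature_id: str
    hypotheses: list[Hypothesis]

    @property
    def top_class(self) -> str:
        return self.hypotheses[0].class_id if self.hypotheses else UNCLASSIFIED


def load_class_rules(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def default_class_rules() -> dict:
    """The built-in rule set (one entry per structural class)."""
    with resources.files("isomet.data").joinpath("class_rules.json").open() as fh:
        return json.load(fh)


def _chain_mass(chain: Sequence[str]) -> float:
    return sum(monoisotopic_mass(parse_formula(f)) for f in chain)


def detect_losses(
    s: MsmsSpectrum,
    losses: Sequence[Sequence[str]],
    tol: float = DEFAULT_FRAGMENT_TOL,
) -> list[LossMatch]:
    """Locate the product ions of the given neutral-loss chains.

    For each chain the target m/z is the precursor minus the summed
    monoisotopic loss masses; the match is the most intense peak within
    ``tol`` that clears the 1%-of-base-peak evidence floor. Unmatched
    chains are simply absent from the output.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    out: list[LossMatch] = []
    if len(s.peaks) == 0:
        return out
    base = s.base_peak_intensity()
    for chain in losses:
        target = s.precursor_mz - _chain_mass(chain)
        sel = np.abs(s.mz - target) <= tol
        if base > 0:
            sel &= s.intensity >= MIN_REL_INTENSITY * base
        if not sel.any():
            continue
        idx = np.flatnonzero(sel)
        best = idx[np.argmax(s.intensity[idx])]
        out.append(
            LossMatch(
                chain=tuple(chain),
                target_mz=target,
                observed_mz=float(s.mz[best]),
                error_da=float(s.mz[best] - target),
                rel_intensity=float(s.intensity[best] / base) if base > 0 else 0.0,
            )
        )
    return out


def nitrogen_parity(precursor_mz: float) -> str:
    """Nominal-mass parity of a [M-H]^- precursor: 'even' or 'odd'.

    For CHNO compounds an even nominal anion mass flags an odd nitrogen
    count (nitrogen rule in its negative-ion form).
    """
    return "even" if nominal_mass(precursor_mz) % 2 == 0 else "odd"


def _series_hits(s: MsmsSpectrum, nominal_mzs: Sequence[int]) -> list[tuple[int, float]]:
    """Peaks whose nominal mass equals a series member, within the +-0.3 guard."""
    base = s.base_peak_intensity()
    hits = []
    wanted = set(int(v) for v in nominal_mzs)
    for mz, inten in s.peaks:
        nom = nominal_mass(mz)
        if nom in wanted and abs(mz - nom) <= NOMINAL_GUARD:
            if base > 0 and inten < MIN_REL_INTENSITY * base:
                continue
            hits.append((nom, float(mz)))
            wanted.discard(nom)
    return hits


def _parallel_pairs(
    s: MsmsSpectrum, offset: float, tol: float
) -> list[tuple[float, float]]:
    """Peak pairs (high, low) separated by ``offset`` within ``tol``."""
    base = s.base_peak_intensity()
    mz = s.mz[s.intensity >= MIN_REL_INTENSITY * base] if base > 0 else s.mz
    pairs = []
    for hi in mz:
        lo_target = hi - offset
        near = mz[np.abs(mz - lo_target) <= tol]
        if len(near):
            pairs.append((float(hi), float(near[0])))
    return pairs


def _rank_top_n(s: MsmsSpectrum, mz_value: float, n: int = 3) -> bool:
    """Whether the peak at ``mz_value`` is among the ``n`` most intense peaks."""
    order = np.argsort(-s.intensity, kind="stable")[:n]
    return bool(np.any(np.isclose(s.mz[order], mz_value)))


def _eval_rule(
    rule: Mapping, s: MsmsSpectrum, formula: ElementalFormula | None, tol: float
) -> tuple[bool, Evidence | None]:
    kind = rule["kind"]
    label = rule.get("label", kind)
    if kind == "loss":
        # a rule may give alternative chains ("chains"); first match wins
        chains = rule.get("chains") or [rule["chain"]]
        for chain in chains:
            matches = detect_losses(s, [chain], tol=tol)
            if not matches:
                continue
            m = matches[0]
            if rule.get("base_peak") and not _rank_top_n(s, m.observed_mz, 3):
                continue
            return True, Evidence(label, (m.observed_mz,), (m.error_da,))
        return False, None
    if kind == "series":
        hits = _series_hits(s, rule["nominal_mzs"])
        if len(hits) < int(rule["min_hits"]):
            return False, None
        return True, Evidence(
            label,
            tuple(mz for _, mz in hits),
            tuple(mz - nom for nom, mz in hits),
        )
    if kind == "parallel_series":
        offset = monoisotopic_mass(parse_formula(rule["offset"]))
        pairs = _parallel_pairs(s, offset, tol)
        if len(pairs) < int(rule.get("min_pairs", 3)):
            return False, None
        return True, Evidence(
            label,
            tuple(p for pair in pairs for p in pair),
            tuple(0.0 for pair in pairs for _ in pair),
        )
    if kind == "parity":
        ok = nitrogen_parity(s.precursor_mz) == rule.get("parity", "even")
        return (ok, Evidence(label, (s.precursor_mz,), (0.0,)) if ok else None)
    if kind == "formula_n":
        ok = formula is not None and formula["N"] > 0
        return (ok, Evidence(label, (), ()) if ok else None)
    raise ValueError(f"unknown rule kind: {kind!r}")


def classify(
    s: MsmsSpectrum,
    formula: ElementalFormula | None = None,
    classes: Mapping | None = None,
    tol: float = DEFAULT_FRAGMENT_TOL,
    score_min: float = 0.5,
) -> AnnotationResult:
    """Score every structural class against a spectrum.

    Returns hypotheses with score >= ``score_min`` ranked by score
    (descending) then class id (ascending). A spectrum satisfying no
    class yields an empty hypothesis list (top class = UNCLASSIFIED).
    """
    classes = classes if classes is not None else default_class_rules()
    hypotheses: list[Hypothesis] = []
    for class_id, definition in classes.items():
        score = 0.0
        evidence: list[Evidence] = []
        dead = False
        for rule in definition["rules"]:
            fired, ev = _eval_rule(rule, s, formula, tol)
            if rule.get("forbidden"):
                if fired:
                    dead = True
                    break
                continue
            if fired:
                score += float(rule.get("weight", 0.0))
                if ev is not None:
                    evidence.append(ev)
            elif rule.get("required"):
                dead = True
                break
        if dead or score < score_min:
            continue
        hypotheses.append(Hypothesis(class_id, round(score, 10), tuple(evidence)))
    hypotheses.sort(key=lambda h: (-h.score, h.class_id))
    return AnnotationResult(feature_id=s.feature_id, hypotheses=hypotheses)


# ---------------------------------------------------------------------------
# Analog pairing across features


@dataclass(frozen=True)
class AnalogRelation:
    id_light: str
    id_heavy: str
    relation: str
    delta_formula: str
    rt_shift: float  # rt(heavy) - rt(light), minutes


_ACETYL_RT_WINDOW = (2.5, 3.5)  # min; retention gain from a 3-O-acetyl group

_RELATION_DELTAS: list[tuple[str, ElementalFormula]] = [
    ("ACETYL_OF_KETO", parse_formula("C2H4O")),
    ("ACETYL_OF_HYDROXY", parse_formula("C2H2O")),
    ("DIHYDRO", parse_formula("H2")),
    ("HYDRATE_OR_OH", parse_formula("H2O")),
]


def pair_analogs(
    features: Sequence[tuple[str, ElementalFormula | str | float, float]],
    mass_tol: float = 0.01,
) -> list[AnalogRelation]:
    """Detect typed analog relations between feature pairs.

    Each feature is (id, formula-or-precursor-m/z, RT in minutes). When
    both members carry formulas the composition difference is exact;
    m/z-only features are compared by mass delta within ``mass_tol``.
    Relations: ACETYL_OF_KETO (+C2H4O, RT gain 2.5-3.5 min),
    ACETYL_OF_HYDROXY (+C2H2O, same window), DIHYDRO (+H2),
    HYDRATE_OR_OH (+H2O), ISOMER_OF (same composition, distinct RT).
    Each unordered pair is reported once, lighter member first.
    """
    parsed: list[tuple[str, ElementalFormula | None, float, float]] = []
    for fid, comp, rt in features:
        if isinstance(comp, str):
            comp = parse_formula(comp)
        if isinstance(comp, ElementalFormula):
            parsed.append((fid, comp, monoisotopic_mass(comp), float(rt)))
        else:
            parsed.append((fid, None, float(comp), float(rt)))

    out: list[AnalogRelation] = []
    for i in range(len(parsed)):
        for j in range(i + 1, len(parsed)):
            a, b = parsed[i], parsed[j]
            if a[0] == b[0]:
                continue
            light, heavy = (a, b) if a[2] <= b[2] else (b, a)
            rt_shift = heavy[3] - light[3]
            rel = None
            delta_str = ""
            if light[1] is not None and heavy[1] is not None:
                try:
                    delta = heavy[1] - light[1]
                except Exception:
                    continue
                if not delta:
                    if abs(rt_shift) > 1e-9:
                        rel, delta_str = "ISOMER_OF", ""
                else:
                    for name, ref in _RELATION_DELTAS:
                        if delta == ref:
                            rel, delta_str = name, str(ref)
                            break
            else:
                dmass = heavy[2] - light[2]
                if abs(dmass) <= mass_tol:
                    if abs(rt_shift) > 1e-9:
                        rel, delta_str = "ISOMER_OF", ""
                else:
                    for name, ref in _RELATION_DELTAS:
                        if abs(dmass - monoisotopic_mass(ref)) <= mass_tol:
                            rel, delta_str = name, str(ref)
                            break
            if rel is None:
                continue
            if rel.startswith("ACETYL") and not (
                _ACETYL_RT_WINDOW[0] <= rt_shift <= _ACETYL_RT_WINDOW[1]
            ):
                continue
            out.append(AnalogRelation(light[0], heavy[0], rel, delta_str, rt_shift))
    out.sort(key=lambda r: (r.id_light, r.id_heavy, r.relation))
    return out


def write_annotations(
    results: Sequence[AnnotationResult], path: str | Path
) -> None:
    """Write ranked hypotheses as CSV (feature_id, rank, class_id, score, evidence)."""
    import pandas as pd

    rows = []
    for res in results:
        if not res.hypotheses:
            rows.append(
                {"feature_id": res.feature_id, "rank": 1, "class_id": UNCLASSIFIED,
                 "score": 0.0, "evidence": ""}
            )
            continue
        for rank, h in enumerate(res.hypotheses, start=1):
            ev = "; ".join(
                f"{e.rule_label} @ {','.join(f'{m:.4f}' for m in e.observed_mz)}"
                for e in h.evidence
            )
            rows.append(
                {"feature_id": res.feature_id, "rank": rank, "class_id": h.class_id,
                 "score": h.score, "evidence": ev}
            )
    pd.DataFrame(rows, columns=["feature_id", "rank", "class_id", "score", "evidence"]).to_csv(
        Path(path), index=False
    )
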