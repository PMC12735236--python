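"""Diagnostic neutral-loss rule engine."""

import numpy as np
import pytest

from isomet.chemformula import mz_anion, nominal_mass, parse_formula
from isomet.fragrules import (
    UNCLASSIFIED,
    classify,
    default_class_rules,
    detect_losses,
    nitrogen_parity,
    pair_analogs,
)
from isomet.spectra_io import MsmsSpectrum


def _spec(fid, prec, peaks):
    return MsmsSpectrum(fid, prec, 1.0, np.array(peaks, dtype=float))


def test_detect_losses_jaspolide_f_pattern():
    """CO2 and CO2+CH4 product ions of a side-chain carboxylic acid."""
    s = _spec("R3", 397.2374, [(353.249, 100.0), (337.217, 80.0)])
    matches = detect_losses(s, [["CO2"], ["CO2", "CH4"]])
    assert [m.chain for m in matches] == [("CO2",), ("CO2", "CH4")]
    assert matches[0].observed_mz == pytest.approx(353.249)
    assert abs(matches[0].error_da) < 0.02
    assert abs(matches[1].error_da) < 0.02


def test_detect_losses_empty_and_off_tolerance():
    empty = MsmsSpectrum("e", 397.2374, 1.0, np.empty((0, 2)))
    assert detect_losses(empty, [["CO2"]]) == []
    off = _spec("x", 397.2374, [(353.30, 100.0)])  # 0.05 Da off the CO2 target
    assert detect_losses(off, [["CO2"]], tol=0.02) == []


def test_detect_losses_ignores_noise_grass():
    """Peaks below 1% of the base peak do not count as evidence."""
    s = _spec("x", 397.2374, [(353.2476, 0.5), (200.0, 100.0)])
    assert detect_losses(s, [["CO2"]]) == []


def test_classify_raa_pattern():
    """Carboxylated side chain plus RAA-type core series: both hypotheses."""
    s = _spec(
        "R1",
        463.2854,
        [(419.296, 100.0), (403.264, 80.0), (301.217, 60.0), (285.186, 50.0),
         (261.186, 45.0), (245.154, 40.0), (229.123, 35.0)],
    )
    res = classify(s)
    classes = {h.class_id for h in res.hypotheses}
    assert {"SC_ACID", "CORE_RAA"} <= classes
    assert res.hypotheses[0].score == pytest.approx(1.0)


def test_classify_hydroxy_carboxy_core_pattern():
    """Spectrum dominated by the CO2+H2O loss, lacking the CH4 chain:
    3-hydroxy-4-carboxy core wins, side-chain acid absent."""
    s = _spec(
        "R798",
        439.249,
        [(421.238, 50.0), (411.254, 10.0), (395.259, 40.0), (377.249, 90.0),
         (343.207, 100.0), (269.190, 45.0), (257.190, 40.0), (215.143, 35.0),
         (183.080, 30.0)],
    )
    res = classify(s)
    assert res.top_class == "CORE_3OH_4COOH"
    assert "SC_ACID" not in {h.class_id for h in res.hypotheses}


def test_classify_empty_spectrum_unclassified():
    s = MsmsSpectrum("e", 439.249, 1.0, np.empty((0, 2)))
    res = classify(s)
    assert res.hypotheses == []
    assert res.top_class == UNCLASSIFIED


def test_classify_evidence_is_sound(corpus):
    """Every evidence m/z lies within tolerance of a real spectrum peak."""
    tol = 0.02
    for s in corpus.spectra[:20]:
        res = classify(s)
        for h in res.hypotheses:
            for ev in h.evidence:
                for mz in ev.observed_mz:
                    if mz == pytest.approx(s.precursor_mz):
                        continue  # parity evidence cites the precursor
                    assert np.min(np.abs(s.mz - mz)) <= tol


def test_adding_unrelated_peaks_never_lowers_scores():
    s = _spec("R1", 463.2854, [(419.296, 100.0), (403.264, 80.0)])
    before = {h.class_id: h.score for h in classify(s).hypotheses}
    grown = _spec(
        "R1", 463.2854,
        list(map(tuple, s.peaks)) + [(301.217, 60.0), (285.186, 50.0), (261.186, 45.0)],
    )
    after = {h.class_id: h.score for h in classify(grown).hypotheses}
    for cid, score in before.items():
        assert after.get(cid, 0.0) >= score - 1e-12


def test_removing_required_peak_zeroes_class():
    s = _spec("R1", 463.2854, [(419.296, 100.0), (403.264, 80.0)])
    assert "SC_ACID" in {h.class_id for h in classify(s).hypotheses}
    gone = _spec("R1", 463.2854, [(419.296, 100.0)])
    assert "SC_ACID" not in {h.class_id for h in classify(gone).hypotheses}


def test_rule_weights_sum_to_one_per_class():
    for cid, definition in default_class_rules().items():
        total = sum(r.get("weight", 0.0) for r in definition["rules"] if not r.get("forbidden"))
        assert total == pytest.approx(1.0), cid


def test_nominal_series_anchors_agree_with_formula_arithmetic():
    """Each quoted series integer equals the nearest-integer m/z of its
    printed anion composition."""
    anchors = {
        202: "C8H12NO5",
        262: "C10H16NO7",
        259: "C6H12O9P",
        241: "C6H10O8P",
        223: "C6H8O7P",
        269: "C19H25O",
        257: "C18H25O",
        215: "C15H19O",
        183: "C13H11O",
        247: "C16H23O2",
        231: "C15H19O2",
        301: "C20H29O2",
        285: "C19H25O2",
    }
    for nominal, comp in anchors.items():
        assert nominal_mass(mz_anion(parse_formula(comp))) == nominal


def test_nitrogen_parity():
    assert nitrogen_parity(462.23) == "even"  # N-odd hint for a CHNO anion
    assert nitrogen_parity(463.2854) == "odd"
    assert nitrogen_parity(0.4) == "even"  # degenerate input rounds to 0


def test_pair_analogs_typed_relations():
    feats = [
        ("RAA", "C30H40O4", 16.87),
        ("stellettin H", "C32H44O5", 20.03),
        ("jaspolide F", "C25H34O4", 13.09),
        ("R42", "C25H36O4", 12.33),
        ("17Z-RAA", "C30H40O4", 17.27),
    ]
    rels = {(r.id_light, r.id_heavy): r.relation for r in pair_analogs(feats)}
    assert rels[("RAA", "stellettin H")] == "ACETYL_OF_KETO"
    assert rels[("jaspolide F", "R42")] == "DIHYDRO"
    assert rels[("RAA", "17Z-RAA")] == "ISOMER_OF"


def test_pair_analogs_acetyl_requires_rt_window():
    feats = [("X", "C30H40O4", 16.87), ("Y", "C32H44O5", 17.0)]  # only +0.13 min
    assert pair_analogs(feats) == []


def test_pair_analogs_excludes_self_pairs():
    feats = [("A", "C30H40O4", 16.87), ("A", "C30H40O4", 16.87)]
    assert pair_analogs(feats) == []


def test_pair_analogs_from_mass_only():
    feats = [("A", 463.2857, 16.87), ("B", 465.3013, 16.5)]  # +2.0157 Da
    rels = pair_analogs(feats)
    assert [r.relation for r in rels] == ["DIHYDRO"]
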