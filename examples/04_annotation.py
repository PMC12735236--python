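"""Structural-class annotation with the neutral-loss rule engine.

A side-chain carboxylic acid with the RAA-type core: the CO2 / CO2+CH4
losses and the 301/285/261/245/229 fragment series each fire their class.
Analog pairing then relates standards across acetylation and
hydrogenation.
"""

import numpy as np

from isomet import MsmsSpectrum, classify, pair_analogs

raa = MsmsSpectrum(
    "R1",
    precursor_mz=463.2854,
    rt=16.87,
    peaks=np.array(
        [[419.296, 100.0], [403.264, 80.0], [301.217, 60.0], [285.186, 50.0],
         [261.186, 45.0], [245.154, 40.0], [229.123, 35.0]]
    ),
)
result = classify(raa)
for h in result.hypotheses:
    labels = ", ".join(e.rule_label for e in h.evidence)
    print(f"{h.class_id:10s} score {h.score:.2f}  ({labels})")

print()
relations = pair_analogs(
    [
        ("RAA", "C30H40O4", 16.87),
        ("stellettin H", "C32H44O5", 20.03),
        ("jaspolide F", "C25H34O4", 13.09),
        ("dihydro congener", "C25H36O4", 12.33),
    ]
)
for r in relations:
    print(f"{r.id_light} -> {r.id_heavy}: {r.relation} (+{r.delta_formula}, dRT {r.rt_shift:+.2f} min)")

# The acetylated analog is recognized by the +C2H4O composition shift
# combined with the ~3 min retention gain of a 3-O-acetyl group.
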