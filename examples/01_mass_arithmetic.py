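"""Exact-mass arithmetic for negative-mode ions.

Computes the theoretical [M-H]- m/z of a triterpenoid acid, its
ring-and-double-bond equivalents, the ppm error of a measured value, and
candidate compositions for an observed neutral-loss mass.
"""

from isomet import (
    infer_delta_formula,
    monoisotopic_mass,
    mz_deprotonated,
    parse_formula,
    ppm_error,
    rdbe,
)

acid = parse_formula("C30H40O4")
theo = mz_deprotonated(acid)
print(f"neutral C30H40O4        : {monoisotopic_mass(acid):.4f} Da")
print(f"[M-H]- theoretical m/z  : {theo:.4f}")
print(f"RDBE                    : {rdbe(acid):.0f}")
print(f"measured 463.2850       : {ppm_error(463.2850, theo):+.2f} ppm")

# A 162.0528 Da neutral loss: which composition explains it?
cands = infer_delta_formula(162.0528, tol_ppm=10, bounds={"C": 12, "H": 24, "O": 10})
print(f"162.0528 Da loss        : best candidate {cands[0]} (anhydrohexose)")

# The [M-H]- m/z combines atomic masses and the electron mass; an 11-RDBE
# C30 skeleton and a sub-ppm measured error are what identify the acid.
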