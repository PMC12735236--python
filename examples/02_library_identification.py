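"""Dereplication against a library of authentic standards.

Two isobaric C30H40O4 isomers are told apart purely by retention time;
the MS/MS similarity and the precursor ppm error gate the match.
"""

from isomet import MsmsSpectrum, match_library
from isomet.spectra_io import LibraryEntry
from isomet.chemformula import parse_formula
from isomet.synthcorpus import TEMPLATES

raa_template = TEMPLATES["CORE_RAA"][0]
library = [
    LibraryEntry("RAA", parse_formula("C30H40O4"), 16.87, raa_template.peak_list()),
    LibraryEntry("17Z-RAA", parse_formula("C30H40O4"), 17.27, raa_template.peak_list()),
]

features = [
    MsmsSpectrum("feat_early", 463.2857, 16.87, raa_template.peak_list()),
    MsmsSpectrum("feat_late", 463.2858, 17.27, raa_template.peak_list()),
]

for ident in match_library(features, library, ppm_tol=10, rt_tol=0.2, cosine_min=0.7):
    print(
        f"{ident.feature_id:10s} -> {ident.library_name:8s} "
        f"({ident.ppm_error:+.2f} ppm, dRT {ident.rt_delta:+.2f} min, cosine {ident.cosine:.3f})"
    )

# Each feature matches only its RT partner: with a 0.2 min window the
# 16.87 / 17.27 min isomer pair cannot cross-match.
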