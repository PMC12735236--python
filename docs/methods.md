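# Methods

## Mass arithmetic

Monoisotopic atomic masses (C 12 exactly, H 1.00782503207, N 14.0030740048,
O 15.9949146196, P 30.97376163, S 31.97207100 Da) are hard-coded; the
electron mass (5.4857991e-4 Da) is added to every singly charged anion.
Including the electron is not cosmetic: the theoretical [M−H]⁻ m/z of
C30H40O4 rounds to 463.2854 at 4 decimal places only with it (463.2848
without). Nominal mass is the monoisotopic value rounded to the nearest
integer, matching how fragment ions are conventionally quoted. RDBE is
defined for neutral CHNOPS formulas only (P treated as trivalent; O, S
ignored); for anion compositions it is ill-defined and not offered.

`infer_delta_formula` enumerates the full bounded element lattice rather
than using any pruning heuristics — delta masses of interest are small
(neutral losses, sugar units) and the lattice stays well under 10^5 points,
so exhaustive search is both fast and trivially correct. Candidates are
ordered by |ppm error| then lexicographic formula for determinism.

## Modified cosine and networking

The similarity kernel lets a fragment of spectrum *a* pair with a fragment
of *b* either directly or shifted by Δ = precursor(b) − precursor(a),
within the fragment tolerance (0.02 Da default). When |Δ| ≤ the parent
tolerance (0.01 Da) the spectra are treated as same-mass and only direct
matching applies; this is the package's reading of how the parent-mass
tolerance enters the kernel, and it prevents double-counting near-zero
shifts. Intensities are square-root scaled before L2 normalization (the
usual choice to tame detector dynamic range); pairing is greedy by
descending intensity product with deterministic tie-breaks (lower m/z in
*a*, then *b*). Greedy pairing can in principle fall short of the optimal
assignment; the test suite holds it equal to an exhaustive
maximum-matching oracle on 1000 seeded random pairs of ≤ 8 peaks, and an
independent implementation (matchms) is cross-checked on unambiguous
cases.

Network construction applies, in order: the cosine (> 0.7, strict, i.e.
"above") and matched-peak (≥ 5, i.e. "more than four") thresholds; mutual
top-K (K = 10) with neighbor ranking by cosine descending then partner id;
and the family-size cap (100), removing the lowest-cosine edge of any
oversized component with lexicographic tie-breaking until all components
fit. All parameters are configurable because deployed workflows vary in
whether "more than four" means ≥ 4 or ≥ 5.

## Annotation rule engine

Each structural class is a weighted rule bundle in
`src/isomet/data/class_rules.json`; scoring weights sum to 1 per class,
forbidden rules carry no weight. Rule kinds: neutral-loss chains (target =
precursor − Σ losses, matched to the most intense peak within 0.02 Da;
alternative chains may be listed, first match wins), nominal fragment
series (round(m/z) ∈ series with a ±0.3 Da guard against mid-decade
artifacts), precursor nominal-mass parity (the anion nitrogen rule),
a parallel-series detector (≥ 3 peak pairs offset by the C2H4O mass,
44.0262 Da — an operationalization of "two parallel fragmentation series,
separated by 44 Da", which is never enumerated peak-by-peak), and a
formula-contains-N check. A 1%-of-base-peak evidence floor excludes noise
grass. "Dominated by" for the 3-hydroxy-4-carboxy core class is
operationalized as: the CO2+H2O-loss match ranks in the top 3 peaks by
intensity; no printed threshold exists, and top-3 separates the published
exemplar spectra.

Hypotheses with score ≥ 0.5 are returned ranked by score then class id;
classes are deliberately not mutually exclusive (a spectrum is
legitimately both a side-chain acid and an RAA-type core). Two honest
ambiguities are worth knowing:

* CO2+CH4 and C2H4O2 are isomeric (both 60.0211 Da), so every side-chain
  acid with the CH4 chain also fires the acetoxy acetic-acid-loss rule at
  score 0.5. It never outranks the true class, but it appears in the
  hypothesis list. Resolving it would require intensity or MS3 evidence
  the data model does not carry.
* Glycosides whose terminal sugar is Hex rather than HexNAc are covered by
  alternative first/second-sugar chains; the printed Y-ion bookkeeping for
  the HexNAc glycoside contains a stoichiometric slip in one loss
  annotation, and the engine implements the chemically consistent
  sequential HexNAc-then-Hex reading.

Analog pairing relates features by composition delta (exact when both
formulas are known, else mass delta within 0.01 Da): +C2H4O / +C2H2O for
acetylation of a keto / hydroxy site (requiring a 2.5–3.5 min retention
gain, a window around the single printed 3.2 min exemplar), +H2 for
hydrogenation, +H2O for hydration/hydroxylation, and same-composition
distinct-RT isomers.

## Chemometrics

The normalization chain is fixed in order: per-sample sum normalization
(idempotent), log₁₀ with zeros replaced by half the smallest positive
value in the sum-normalized table (the common MetaboAnalyst-style choice;
only "log-transformed" is specified upstream, base and zero handling are
this package's decisions), then per-feature auto-scaling to zero mean and
unit (ddof = 1) variance, dropping zero-variance rows. PCA is a plain SVD
of the centered samples × features matrix; signs are fixed by forcing the
largest-magnitude loading of each component positive so score plots are
reproducible. Hierarchical clustering defaults to Ward linkage on
Euclidean distance (the default pairing of the platform this stage
emulates); both are configurable since neither is prescribed. The
dendrogram is exported as a Newick string and a merge list; clustering of
both samples and features is available for heatmap ordering.

On the packaged 16 × 9 relative-content matrix this chain cleanly
separates the three Phan Thiet specimens at k = 2 — reassuring, though the
original study clustered its full >1500-feature table, which is not
publicly deposited; reproducing its exact variance percentages is
therefore out of reach and out of scope.

## Synthetic corpus

The generator emulates the study conditions: 9 samples split 6:3 into two
chemotypes, features drawn from 11 structural-class template pools (2
curated templates per class, cycled), 4 features per class by default.
Template precursor compositions come from printed triterpenoid, glycoside
and lipid formulas (the lyso-PI pool uses typical lysophosphatidylinositol
compositions, as none are printed); fragment peaks derive from each
class's loss chains and series-ion compositions through the same formula
arithmetic the rule engine uses, so a noiseless corpus is exactly
on-grammar. Noise model: fragment m/z jitter N(0, 0.005 Da) (precursors
get a fifth of that — Q-TOF precursor accuracy is far better than
fragment accuracy at MS/MS isolation widths), 20% log-normal intensity
noise, and 5 uniform noise peaks per spectrum in [80, precursor − 1] at
0.5–5% of the base peak, straddling the 1% evidence floor so the floor is
actually exercised. Abundances are log-normal with a 1.5 log₁₀
between-chemotype shift for enriched classes (side-chain acids, RAA-type
cores and glycosides in chemotype A; 3-hydroxy-4-carboxy cores and acetoxy
congeners in chemotype B) and 0.3 log₁₀ within-group spread.

Template intensity profiles are stylized (real per-class profiles are
unpublished) and were chosen with wide rank margins so intensity-rank
rules survive the 20% intensity noise. What passing tests show is that the
pipeline recovers structure *of the kind the study describes* under
realistic noise — not that it would reproduce the study's raw-data node
counts or variance fractions, which depend on unavailable acquisitions.
The generator omits chromatographic peak shapes, isotope envelopes,
adducts and in-source fragmentation, all of which the upstream
feature-detection stage handles in real workflows.

## Problem sizes and determinism

Default corpora are 44 spectra × 9 samples — large enough for every
pipeline stage to exercise its filters (the family cap, mutual top-K,
evidence floor) while keeping the full suite fast. Every stochastic step
takes an explicit integer seed through `numpy.random.default_rng`;
identical configs produce byte-identical MGF/CSV/JSON artifacts. Edge
ordering, neighbor ranking, pruning and candidate-formula ordering all
carry explicit tie-breaks, so outputs are stable across platforms.
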