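# isomet

Chemotyping toolkit for untargeted negative-mode LC–MS/MS metabolomics of
isomalabaricane-producing marine sponges (*Rhabdastrella globostellata* and
relatives), usable for any small-molecule study with the same workflow shape.

Marine sponges of this genus produce isomalabaricane triterpenoids — a
pharmacologically interesting family built on a *trans-syn-trans* 6,6,5-
tricyclic core with a variable, often carboxyl-terminated side chain.
Specimens from different sites express distinct *chemotypes*: characteristic
suites of these metabolites. `isomet` implements the complete desk-side
analysis chain that turns MS/MS feature data into chemotype assignments:

1. **Formula/mass arithmetic** (`isomet.chemformula`) — monoisotopic masses
   over CHNOPS, deprotonated-ion m/z (including the electron mass:
   m/z([M−H]⁻) = M − m(H) + mₑ), ring-and-double-bond equivalents
   RDBE = C − H/2 + N/2 + P/2 + 1, ppm errors, and brute-force candidate
   formulas for observed mass deltas within a ppm window.
2. **Spectral I/O and dereplication** (`isomet.spectra_io`) — MGF and
   feature-table CSV reading/writing, and identification against a library
   of authentic standards by precursor ppm + retention time + modified
   cosine.
3. **Feature-based molecular networking** (`isomet.msnetwork`) — the
   modified cosine kernel (fragment pairs match at offset 0 or at the
   precursor-mass difference Δ; greedy one-to-one pairing by descending
   √-intensity product; score = Σ matched √I·√I′ after per-spectrum L2
   normalization), followed by the standard edge filters: cosine > 0.7 with
   ≥ 5 matched peaks, mutual top-10, and a molecular-family cap of 100 nodes
   enforced by weakest-edge removal.
4. **Diagnostic neutral-loss annotation** (`isomet.fragrules`) — a
   declarative rule engine scoring eleven structural classes (side-chain
   acids, hydroxy/carboxy core types, acetoxy and nitrogenous congeners,
   glycosides, lyso-PI lipids, core fragment-series types) from neutral-loss
   chains, nominal fragment series, precursor-parity (nitrogen rule) and
   44-Da parallel-series detectors. Rules live in editable JSON.
5. **Chemometrics** (`isomet.chemometrics`) — the fixed normalization chain
   (sum-normalize per sample → log₁₀ with half-minimum zero replacement →
   auto-scale per feature), SVD-based PCA with a deterministic sign
   convention, and Ward/Euclidean hierarchical clustering.
6. **Synthetic corpus** (`isomet.synthcorpus`) — a seeded generator of
   MGF + feature-table datasets whose spectra follow the class grammar and
   whose abundances follow a two-chemotype log-normal contrast, plus the
   packaged 16-compound × 9-specimen relative-content matrix of authentic
   standards (`table3_fixture`).

A thin CLI (`isomet simulate|identify|network|annotate|chemstats|all`)
chains the stages; the importable API plus the `examples/` scripts are the
primary interface.

## Worked example

```bash
python examples/05_chemometrics.py
```

```
matrix: 16 compounds x 9 specimens
PC1 69.7% / PC2 15.3% of variance
  ...
  PIBOC O66-089   PC1  +4.38  PC2  -0.41
  PIBOC O66-092   PC1  +5.42  PC2  +0.72
  PIBOC O66-109   PC1  +3.23  PC2  +0.03
cluster 1: PIBOC O66-089, PIBOC O66-092, PIBOC O66-109
cluster 2: PIBOC O34-077, PIBOC O49-009, PIBOC O49-030, PIBOC O49-055, PIBOC O63-090, PIBOC O63-136
```

The three Phan Thiet specimens (positive PC1 scores) separate cleanly from
the six site-1–3 specimens and form their own cluster at k = 2: the two
chemotypes of the population, recovered from the printed relative-content
matrix alone. The other examples cover mass arithmetic
(`01_mass_arithmetic.py` prints the theoretical [M−H]⁻ m/z 463.2854 of the
C30H40O4 acid and its 11 RDBE), RT-resolved identification of isobaric
isomers, molecular networking of the synthetic corpus (44 nodes, 10
components, class-pure except for one chemically expected bridge), and
rule-engine annotation.

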