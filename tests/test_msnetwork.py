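"""Modified cosine and molecular-network construction."""

import numpy as np
import pytest

from isomet.msnetwork import (
    MolecularNetwork,
    NetworkEdge,
    NetworkParams,
    build_network,
    modified_cosine,
    network_stats,
    write_graphml,
)
from isomet.spectra_io import MsmsSpectrum

from conftest import exhaustive_modified_cosine, random_spectrum_pair


def _spec(fid, prec, peaks):
    return MsmsSpectrum(fid, prec, 1.0, np.array(peaks, dtype=float))


def test_self_similarity_is_one():
    a = _spec("a", 300.0, [(100, 1), (150, 2), (200, 3)])
    score, n = modified_cosine(a, a)
    assert score == pytest.approx(1.0, abs=1e-12)
    assert n == 3


def test_disjoint_spectra_score_zero():
    a = _spec("a", 300.0, [(100, 1), (150, 2)])
    b = _spec("b", 300.0, [(120, 1), (170, 2)])
    score, n = modified_cosine(a, b)
    assert score == 0.0 and n == 0


def test_precursor_shifted_copy_scores_one():
    """A spectrum whose peaks and precursor are all shifted by the same
    offset matches perfectly through precursor-shift pairing."""
    a = _spec("a", 300.0, [(100, 1), (150, 2), (200, 3)])
    b = _spec("b", 350.0, [(150, 1), (200, 2), (250, 3)])
    score, n = modified_cosine(a, b)
    assert score == pytest.approx(1.0, abs=1e-12)
    assert n == 3


def test_symmetry_and_range(corpus):
    spectra = corpus.spectra[:12]
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            s_ab, n_ab = modified_cosine(spectra[i], spectra[j])
            s_ba, n_ba = modified_cosine(spectra[j], spectra[i])
            assert s_ab == pytest.approx(s_ba, abs=1e-9)
            assert n_ab == n_ba
            assert 0.0 <= s_ab <= 1.0


def test_empty_peak_list_rejected():
    a = _spec("a", 300.0, [(100, 1)])
    b = MsmsSpectrum("b", 300.0, 1.0, np.empty((0, 2)))
    with pytest.raises(ValueError):
        modified_cosine(a, b)


def test_greedy_matches_exhaustive_oracle_on_small_spectra():
    """On 1000 seeded random pairs with <= 8 peaks the greedy pairing
    attains exactly the exhaustive maximum-score matching."""
    rng = np.random.default_rng(12345)
    for _ in range(1000):
        a, b = random_spectrum_pair(rng, max_peaks=8)
        greedy, _ = modified_cosine(a, b)
        optimal, _ = exhaustive_modified_cosine(a, b)
        assert greedy <= optimal + 1e-9
        assert greedy == pytest.approx(optimal, abs=1e-9)


def test_against_matchms_reference_implementation():
    """Cross-check against an independent implementation on spectra with
    well-separated peaks (where the optimal matching is unambiguous)."""
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import ModifiedCosine

    rng = np.random.default_rng(7)
    sim = ModifiedCosine(tolerance=0.02)
    for _ in range(50):
        n_a, n_b = rng.integers(3, 7, size=2)
        prec_a = float(rng.uniform(300, 500))
        prec_b = prec_a + float(rng.uniform(5, 60))
        grid = np.arange(100.0, 290.0, 1.0)
        mz_a = np.sort(rng.choice(grid, n_a, replace=False))
        keep = rng.choice(n_a, size=min(n_a, n_b) // 1, replace=False)[: n_b]
        mz_b = np.sort(mz_a[keep] + np.where(rng.random(len(keep)) < 0.5, prec_b - prec_a, 0.0))
        if len(mz_b) == 0:
            continue
        ia = rng.lognormal(2, 0.5, n_a)
        ib = rng.lognormal(2, 0.5, len(mz_b))
        a = _spec("a", prec_a, np.column_stack([mz_a, ia]))
        b = _spec("b", prec_b, np.column_stack([mz_b, ib]))
        ours, n_ours = modified_cosine(a, b)
        # matchms scores raw intensity products; feed sqrt-intensities so its
        # cosine coincides with the sqrt-scaled kernel used here
        ref = sim.pair(
            matchms.Spectrum(
                mz=a.mz, intensities=np.sqrt(a.intensity), metadata={"precursor_mz": prec_a}
            ),
            matchms.Spectrum(
                mz=b.mz, intensities=np.sqrt(b.intensity), metadata={"precursor_mz": prec_b}
            ),
        )
        assert ours == pytest.approx(float(ref["score"]), abs=1e-6)
        assert n_ours == int(ref["matches"])


# ---------------------------------------------------------------------------
# Network construction


def test_empty_input_empty_network():
    net = build_network([])
    assert net.nodes == [] and net.edges == []
    assert network_stats(net) == (0, 0, {})


def test_two_identical_spectra_form_one_edge():
    peaks = [(100, 1), (150, 2), (200, 3), (250, 4), (280, 5)]
    a, b = _spec("a", 300.0, peaks), _spec("b", 300.0, peaks)
    net = build_network([a, b])
    assert len(net.edges) == 1
    assert net.edges[0].cosine == pytest.approx(1.0)
    assert net.n_singletons == 0


def test_three_nodes_one_edge_stats():
    peaks = [(100, 1), (150, 2), (200, 3), (250, 4), (280, 5)]
    spectra = [
        _spec("a", 300.0, peaks),
        _spec("b", 300.0, peaks),
        _spec("c", 300.0, [(90, 1), (110, 1), (130, 1), (170, 1), (190, 1)]),
    ]
    n, singles, hist = network_stats(build_network(spectra))
    assert (n, singles) == (3, 1)
    assert hist == {2: 1, 1: 1}


def _union_find_components(nodes, edges):
    """Independent connected-components oracle."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        ra, rb = find(e.id_a), find(e.id_b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return sorted((frozenset(c) for c in comps.values()), key=lambda c: (-len(c), min(c)))


def test_network_postconditions_on_corpus(corpus):
    """Edge thresholds, mutual top-K membership and the family-size cap,
    re-verified by direct re-ranking and an independent union-find."""
    params = NetworkParams()
    net = build_network(corpus.spectra, params)

    for e in net.edges:
        assert e.cosine > params.cosine_min
        assert e.n_matched >= params.min_matched_peaks
        assert e.id_a < e.id_b

    # mutual top-K by direct re-ranking
    nbrs = {}
    for e in net.edges:
        nbrs.setdefault(e.id_a, []).append((e.cosine, e.id_b))
        nbrs.setdefault(e.id_b, []).append((e.cosine, e.id_a))
    for e in net.edges:
        for u, v in [(e.id_a, e.id_b), (e.id_b, e.id_a)]:
            ranked = sorted(nbrs[u], key=lambda t: (-t[0], t[1]))
            assert v in {p for _, p in ranked[: params.top_k]}

    # component cap + agreement with union-find oracle
    oracle = _union_find_components(net.nodes, net.edges)
    assert all(len(c) <= params.max_family_size for c in oracle)
    assert [set(c) for c in oracle] == [set(c) for c in net.components()]

    n, singles, hist = network_stats(net)
    assert n == len(corpus.spectra)
    assert singles == sum(1 for c in oracle if len(c) == 1)


def test_family_size_cap_prunes_weakest_edges():
    """With a tiny cap, an over-sized clique is cut by removing its
    lowest-cosine edges, and no retained edge loses score."""
    rng = np.random.default_rng(3)
    base = np.column_stack([np.arange(100, 100 + 8 * 10, 10.0), np.full(8, 10.0)])
    spectra = []
    for i in range(6):
        peaks = base.copy()
        peaks[:, 1] += rng.uniform(0, 3, size=8)
        spectra.append(_spec(f"s{i}", 400.0, peaks))
    uncapped = build_network(spectra, NetworkParams(max_family_size=100))
    capped = build_network(spectra, NetworkParams(max_family_size=3))
    assert all(len(c) <= 3 for c in capped.components())
    kept = {(e.id_a, e.id_b): e.cosine for e in capped.edges}
    orig = {(e.id_a, e.id_b): e.cosine for e in uncapped.edges}
    assert set(kept) <= set(orig)
    for key, cos in kept.items():
        assert cos == pytest.approx(orig[key], abs=1e-12)


def test_corpus_components_keep_acid_and_lipid_families_apart(corpus):
    """Side-chain-acid spectra share the CO2 / CO2+CH4 template and land in
    one component, disjoint from lyso-PI-template spectra."""
    net = build_network(corpus.spectra)
    truth = corpus.ground_truth
    comps = net.components()
    sc_acid = {fid for fid, e in truth.items() if e.class_id == "SC_ACID"}
    lyso = {fid for fid, e in truth.items() if e.class_id == "LYSO_PI"}
    sc_comps = [c for c in comps if c & sc_acid]
    assert len(sc_comps) == 1 and sc_acid <= sc_comps[0]
    assert not any(c & sc_acid and c & lyso for c in comps)


def test_graphml_roundtrip(tmp_path, corpus):
    import networkx as nx

    net = build_network(corpus.spectra)
    p = tmp_path / "net.graphml"
    attrs = {s.feature_id: {"mz": s.precursor_mz, "rt": s.rt} for s in corpus.spectra}
    write_graphml(net, p, node_attrs=attrs)
    g = nx.read_graphml(p)
    assert g.number_of_nodes() == len(net.nodes)
    assert g.number_of_edges() == len(net.edges)

    empty = MolecularNetwork(nodes=[], edges=[])
    p2 = tmp_path / "empty.graphml"
    write_graphml(empty, p2)
    assert nx.read_graphml(p2).number_of_nodes() == 0


def test_params_validation():
    with pytest.raises(ValueError):
        NetworkParams(cosine_min=0.0)
    with pytest.raises(ValueError):
        NetworkParams(fragment_tol=-1)
    with pytest.raises(ValueError):
        build_network([_spec("a", 300, [(1, 1)]), _spec("a", 300, [(1, 1)])])
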