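import numpy as np
import pytest

from isomet.spectra_io import MsmsSpectrum
from isomet.synthcorpus import CorpusConfig, generate_corpus


@pytest.fixture(scope="session")
def corpus():
    """Default seeded corpus (jitter, noise peaks and intensity noise on)."""
    return generate_corpus(CorpusConfig(rng_seed=1))


@pytest.fixture(scope="session")
def noiseless_corpus():
    return generate_corpus(
        CorpusConfig(mz_jitter_sd=0.0, noise_peaks=0, intensity_cv=0.0, rng_seed=1)
    )


def random_spectrum_pair(rng, max_peaks=8, shared=True):
    """A random spectrum pair for matching tests: some peaks shared (possibly
    precursor-shifted), some private, intensities log-normal."""
    n_a = rng.integers(2, max_peaks + 1)
    n_b = rng.integers(2, max_peaks + 1)
    prec_a = rng.uniform(300.0, 550.0)
    delta = rng.uniform(-60.0, 60.0)
    prec_b = prec_a + delta
    mz_a = np.sort(rng.uniform(100.0, prec_a, n_a))
    if shared:
        n_shared = int(rng.integers(0, min(n_a, n_b) + 1))
        take = rng.choice(n_a, size=n_shared, replace=False)
        shifted = rng.random(n_shared) < 0.5
        mz_b_shared = mz_a[take] + np.where(shifted, delta, 0.0)
        mz_b_shared += rng.normal(0.0, 0.005, n_shared)
        mz_b_rest = rng.uniform(100.0, prec_b, n_b - n_shared)
        mz_b = np.concatenate([mz_b_shared, mz_b_rest])
    else:
        mz_b = rng.uniform(100.0, prec_b, n_b)
    mz_b = np.clip(mz_b, 50.0, None)
    a = MsmsSpectrum("a", prec_a, 1.0, np.column_stack([mz_a, rng.lognormal(2, 1, n_a)]))
    b = MsmsSpectrum("b", prec_b, 1.0, np.column_stack([mz_b, rng.lognormal(2, 1, len(mz_b))]))
    return a, b


def exhaustive_modified_cosine(a, b, fragment_tol=0.02, precursor_tol=0.01):
    """Independent oracle: maximum-score one-to-one peak matching by
    exhaustive search (feasible for small spectra only)."""
    delta = b.precursor_mz - a.precursor_mz
    offsets = [0.0] if abs(delta) <= precursor_tol else [0.0, delta]
    sa, sb = np.sqrt(a.intensity), np.sqrt(b.intensity)
    pairs = []
    for i in range(len(sa)):
        for j in range(len(sb)):
            if any(abs(a.mz[i] + off - b.mz[j]) <= fragment_tol for off in offsets):
                pairs.append((i, j, sa[i] * sb[j]))

    best = {"score": 0.0, "n": 0}

    def recurse(k, used_a, used_b, total, count):
        if total > best["score"] or (total == best["score"] and count > best["n"]):
            best["score"], best["n"] = total, count
        if k == len(pairs):
            return
        remaining = sum(p[2] for p in pairs[k:])
        if total + remaining < best["score"]:
            return
        i, j, w = pairs[k]
        if i not in used_a and j not in used_b:
            recurse(k + 1, used_a | {i}, used_b | {j}, total + w, count + 1)
        recurse(k + 1, used_a, used_b, total, count)

    recurse(0, frozenset(), frozenset(), 0.0, 0)
    norm = np.linalg.norm(sa) * np.linalg.norm(sb)
    return (best["score"] / norm if norm else 0.0), best["n"]
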