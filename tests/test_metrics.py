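"""Clustering metrics against independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from scecda.metrics import MetricsReport, acc, ari, casw, clisi, evaluate, nmi, purity


# -- independent oracles (pair enumeration / entropies / permutations) -------

def ari_oracle(pred, truth):
    """Adjusted Rand index by explicit enumeration of all item pairs."""
    n = len(pred)
    ss = sd = ds = dd = 0
    for i in range(n):
        for j in range(i + 1, n):
            sp = pred[i] == pred[j]
            st = truth[i] == truth[j]
            ss += sp and st
            sd += sp and not st
            ds += st and not sp
            dd += (not sp) and (not st)
    total = ss + sd + ds + dd
    index = ss
    expected = (ss + sd) * (ss + ds) / total
    maximum = ((ss + sd) + (ss + ds)) / 2
    if maximum == expected:
        return 1.0 if index == expected else 0.0
    return (index - expected) / (maximum - expected)


def _entropy(labels):
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return -np.sum(p * np.log(p))


def nmi_oracle(pred, truth):
    """Geometric-mean normalized mutual information from count formulas."""
    n = len(pred)
    hp, ht = _entropy(pred), _entropy(truth)
    if hp == 0 or ht == 0:
        return 1.0 if np.array_equal(np.unique(pred, return_inverse=True)[1],
                                     np.unique(truth, return_inverse=True)[1]) else 0.0
    mi = 0.0
    for a in np.unique(pred):
        for b in np.unique(truth):
            nij = np.sum((pred == a) & (truth == b))
            if nij == 0:
                continue
            mi += (nij / n) * np.log(n * nij / (np.sum(pred == a) * np.sum(truth == b)))
    return mi / np.sqrt(hp * ht)


def acc_oracle(pred, truth):
    """Best accuracy over all factorial cluster-to-class relabelings."""
    classes = np.unique(truth)
    clusters = np.unique(pred)
    k = max(len(classes), len(clusters))
    best = 0
    for perm in itertools.permutations(range(k)):
        mapping = {c: perm[i] for i, c in enumerate(clusters)}
        relabeled = np.array([mapping[c] for c in pred])
        idx = {c: i for i, c in enumerate(classes)}
        truth_idx = np.array([idx[t] for t in truth])
        best = max(best, np.mean(relabeled == truth_idx))
    return float(best)


def purity_oracle(pred, truth):
    total = 0
    for c in np.unique(pred):
        members = truth[pred == c]
        total += np.bincount(members).max()
    return total / len(pred)


# -- tests --------------------------------------------------------------------

def test_label_metrics_match_oracles_on_random_pairs():
    rng = np.random.default_rng(0)
    for _ in range(40):
        n = int(rng.integers(8, 40))
        k1, k2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        pred = rng.integers(0, k1, n)
        truth = rng.integers(0, k2, n)
        assert ari(pred, truth) == pytest.approx(ari_oracle(pred, truth), abs=1e-10)
        assert nmi(pred, truth) == pytest.approx(nmi_oracle(pred, truth), abs=1e-10)
        assert acc(pred, truth) == pytest.approx(acc_oracle(pred, truth), abs=1e-10)
        assert purity(pred, truth) == pytest.approx(purity_oracle(pred, truth), abs=1e-10)


def test_ari_known_values():
    assert ari([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)
    assert ari([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)
    # anti-correlated pairing: index 0, expected 2/3, max 2
    assert ari([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(-0.5)


def test_nmi_known_values():
    assert nmi([0, 1, 2, 0], [2, 0, 1, 2]) == pytest.approx(1.0)
    assert nmi([0, 0, 1, 1], [0, 1, 1, 1]) == pytest.approx(
        nmi_oracle(np.array([0, 0, 1, 1]), np.array([0, 1, 1, 1])), abs=1e-12
    )
    # arithmetic-mean normalization differs when the entropies differ
    assert nmi([0, 0, 1, 1], [0, 1, 1, 1], average_method="arithmetic") != pytest.approx(
        nmi([0, 0, 1, 1], [0, 1, 1, 1])
    )


def test_nmi_independent_labels_near_zero():
    rng = np.random.default_rng(1)
    pred = rng.integers(0, 3, 10_000)
    truth = rng.integers(0, 3, 10_000)
    assert nmi(pred, truth) < 0.01


def test_acc_known_values():
    assert acc([1, 1, 0, 0], [0, 0, 1, 1]) == pytest.approx(1.0)
    # constant prediction on a balanced 2-class problem matches one class
    assert acc([0, 0, 0, 0], [0, 0, 1, 1]) == pytest.approx(0.5)
    assert acc([0, 1], [0, 1]) >= 1 / 2  # acc >= 1/n always


def test_purity_known_values():
    assert purity([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)
    assert purity([0, 0, 1, 1], [0, 1, 1, 1]) == pytest.approx(0.75)
    # singleton clusters: degenerate maximum
    assert purity([0, 1, 2, 3], [0, 0, 1, 1]) == pytest.approx(1.0)


def test_metrics_invariant_to_cluster_relabeling():
    rng = np.random.default_rng(2)
    pred = rng.integers(0, 4, 60)
    truth = rng.integers(0, 3, 60)
    perm = rng.permutation(4)
    relabeled = perm[pred]
    for metric in (ari, nmi, acc, purity):
        assert metric(pred, truth) == pytest.approx(metric(relabeled, truth), abs=1e-12)


def test_length_mismatch_raises():
    with pytest.raises(ValueError):
        ari([0, 1], [0, 1, 1])


def test_casw_separated_blobs():
    rng = np.random.default_rng(3)
    H = np.vstack([rng.normal(0, 0.1, (50, 4)), rng.normal(10, 0.1, (50, 4))])
    truth = np.repeat([0, 1], 50)
    assert casw(H, truth) > 0.9
    # shuffling some labels within the geometry lowers the silhouette
    noisy = truth.copy()
    noisy[rng.choice(100, 20, replace=False)] ^= 1
    assert casw(H, noisy) < casw(H, truth)
    # optional rescale maps [-1, 1] onto [0, 1]
    assert casw(H, truth, rescale=True) == pytest.approx((casw(H, truth) + 1) / 2)


def test_casw_single_class_rejected():
    with pytest.raises(ValueError):
        casw(np.zeros((5, 2)), [0, 0, 0, 0, 0])


def test_clisi_pure_neighborhoods():
    rng = np.random.default_rng(4)
    H = np.vstack([rng.normal(0, 0.1, (80, 3)), rng.normal(50, 0.1, (80, 3))])
    truth = np.repeat([0, 1], 80)
    assert clisi(H, truth, perplexity=15) == pytest.approx(1.0, abs=1e-3)


def test_clisi_fully_mixed_labels():
    """Random labels on one well-mixed blob: raw LISI ~ 2, scaled ~ 0."""
    rng = np.random.default_rng(5)
    H = rng.normal(size=(400, 3))
    truth = rng.integers(0, 2, 400)
    assert clisi(H, truth, perplexity=30) == pytest.approx(0.0, abs=0.05)


def test_clisi_contract_errors():
    rng = np.random.default_rng(6)
    H = rng.normal(size=(120, 3))
    with pytest.raises(ValueError):
        clisi(H, np.zeros(120, dtype=int), perplexity=30)  # single type
    with pytest.raises(ValueError):
        clisi(H[:50], rng.integers(0, 2, 50), perplexity=30)  # too few cells


def test_aggregates():
    rep = MetricsReport(ari=0.8, nmi=0.9, acc=0.85, pur=0.95, casw=0.5, clisi_scaled=0.7)
    assert rep.cluster_avg == pytest.approx(0.875)
    assert rep.bio_avg == pytest.approx(0.6)
    assert rep.performance == pytest.approx((4 * rep.cluster_avg + 2 * rep.bio_avg) / 6)
    ones = MetricsReport(1, 1, 1, 1, 1, 1)
    assert ones.cluster_avg == ones.bio_avg == ones.performance == 1.0


def test_evaluate_end_to_end():
    rng = np.random.default_rng(7)
    H = np.vstack([rng.normal(0, 0.2, (70, 4)), rng.normal(8, 0.2, (70, 4))])
    truth = np.repeat([0, 1], 70)
    pred = truth.copy()
    rep = evaluate(H, pred, truth, perplexity=15)
    assert rep.ari == pytest.approx(1.0)
    assert rep.cluster_avg == pytest.approx(1.0)
    assert rep.bio_avg > 0.9
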