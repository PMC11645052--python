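"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (plain Python double loops, direct
formula evaluation) and independent of the package's vectorized code paths,
so they can serve as references in equivalence tests.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from mferobust import CohortSpec, EpochedRecording
from mferobust.cohort import Group
from mferobust.preprocess import AmplitudeState


def fuzzy_entropy_bruteforce(x, m, n, r_abs):
    """O(N^2) reference fuzzy entropy: explicit template double loop."""
    x = [float(v) for v in x]
    big_n = len(x)

    def phi(k, n_templates):
        means = [sum(x[i:i + k]) / k for i in range(big_n - k + 1)]
        total = 0.0
        for i in range(n_templates):
            inner = 0.0
            for j in range(n_templates):
                if j == i:
                    continue
                d = 0.0
                for t in range(k):
                    diff = abs((x[i + t] - means[i]) - (x[j + t] - means[j]))
                    if diff > d:
                        d = diff
                inner += math.exp(-(d ** n) / r_abs)
            total += inner / (n_templates - 1)
        return total / n_templates

    n_templates = big_n - m
    return -math.log(phi(m + 1, n_templates) / phi(m, n_templates))


def contingency_table(labels_true, labels_pred):
    u_vals = sorted(set(labels_true))
    v_vals = sorted(set(labels_pred))
    table = np.zeros((len(u_vals), len(v_vals)), dtype=int)
    for t, p in zip(labels_true, labels_pred):
        table[u_vals.index(t), v_vals.index(p)] += 1
    return table


def v_measure_oracle(labels_true, labels_pred):
    """V-measure from conditional entropies of the contingency table."""
    c = contingency_table(labels_true, labels_pred).astype(float)
    n = c.sum()
    pu = c.sum(axis=1) / n
    pv = c.sum(axis=0) / n

    def entropy(p):
        p = p[p > 0]
        return -np.sum(p * np.log(p))

    h_u, h_v = entropy(pu), entropy(pv)
    p_joint = c / n
    h_u_given_v = 0.0
    h_v_given_u = 0.0
    for i in range(c.shape[0]):
        for j in range(c.shape[1]):
            if p_joint[i, j] > 0:
                h_u_given_v -= p_joint[i, j] * math.log(p_joint[i, j] / pv[j])
                h_v_given_u -= p_joint[i, j] * math.log(p_joint[i, j] / pu[i])
    hom = 1.0 if h_u == 0 else 1.0 - h_u_given_v / h_u
    com = 1.0 if h_v == 0 else 1.0 - h_v_given_u / h_v
    if hom + com == 0:
        return 0.0
    return 2.0 * hom * com / (hom + com)


def ari_oracle(labels_true, labels_pred):
    """ARI from pair counts with the hypergeometric chance expectation."""
    c = contingency_table(labels_true, labels_pred)
    n = c.sum()

    def comb2(v):
        return v * (v - 1) / 2.0

    sum_ij = sum(comb2(v) for v in c.ravel())
    sum_a = sum(comb2(v) for v in c.sum(axis=1))
    sum_b = sum(comb2(v) for v in c.sum(axis=0))
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 0.0
    return (sum_ij - expected) / (max_index - expected)


def ami_oracle(labels_true, labels_pred):
    """AMI with the exact permutation-model E[MI] and arithmetic-mean norm."""
    c = contingency_table(labels_true, labels_pred)
    n = int(c.sum())
    a = c.sum(axis=1)
    b = c.sum(axis=0)

    def entropy(counts):
        p = counts[counts > 0] / n
        return float(-np.sum(p * np.log(p)))

    mi = 0.0
    for i in range(c.shape[0]):
        for j in range(c.shape[1]):
            if c[i, j] > 0:
                mi += (c[i, j] / n) * math.log(n * c[i, j] / (a[i] * b[j]))

    emi = 0.0
    for i in range(c.shape[0]):
        for j in range(c.shape[1]):
            ai, bj = int(a[i]), int(b[j])
            for nij in range(max(1, ai + bj - n), min(ai, bj) + 1):
                term = (nij / n) * math.log(n * nij / (ai * bj))
                log_p = (math.lgamma(ai + 1) + math.lgamma(bj + 1)
                         + math.lgamma(n - ai + 1) + math.lgamma(n - bj + 1)
                         - math.lgamma(n + 1) - math.lgamma(nij + 1)
                         - math.lgamma(ai - nij + 1) - math.lgamma(bj - nij + 1)
                         - math.lgamma(n - ai - bj + nij + 1))
                emi += term * math.exp(log_p)

    h_u, h_v = entropy(a), entropy(b)
    denom = 0.5 * (h_u + h_v) - emi
    if denom == 0:
        return 0.0
    return (mi - emi) / denom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A tiny, fast cohort spec for plumbing tests."""
    return CohortSpec(n_per_group=3, n_channels=3, fs=100.0, duration=12.0,
                      seed=7)


def make_epochs(data, fs=100.0, state=AmplitudeState.RAW, group=Group.HS):
    """Wrap a channels x epochs x samples array into an EpochedRecording."""
    return EpochedRecording(subject_id="T01", group=group,
                            epochs=np.asarray(data, dtype=float), fs=fs,
                            amplitude_state=state)
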