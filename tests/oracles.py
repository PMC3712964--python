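"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the HMM oracle
enumerates all copying paths explicitly, and the Hardy-Weinberg oracle
evaluates the exact conditional distribution through log-gamma closed
forms rather than the package's ratio recurrence.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import gammaln

from localpanel.panels import MISSING


def enumerate_copying_posteriors(obs, typed_idx, panel_alleles, d_cm,
                                 ne, lam):
    """Posterior copying probabilities by brute-force path enumeration.

    Sums the joint probability of every one of H^L copying paths under the
    uniform-switch transition kernel and the match/mismatch emission model;
    feasible for H <= ~5, L <= ~7.
    """
    H, L = panel_alleles.shape
    typed = {int(t): int(o) for t, o in zip(typed_idx, obs)}
    p_ns = [math.exp(-4.0 * ne * (d / 100.0) / H) for d in d_cm]

    def emit(t, state):
        if t not in typed or typed[t] == MISSING:
            return 1.0
        a = panel_alleles[state, t]
        if a == MISSING:
            return 0.5
        return 1.0 - lam if a == typed[t] else lam

    post = np.zeros((L, H))
    for path in itertools.product(range(H), repeat=L):
        p = 1.0 / H * emit(0, path[0])
        for t in range(1, L):
            pns = p_ns[t - 1]
            trans = pns + (1.0 - pns) / H if path[t] == path[t - 1] \
                else (1.0 - pns) / H
            p *= trans * emit(t, path[t])
        for t, s in enumerate(path):
            post[t, s] += p
    post /= post.sum(axis=1, keepdims=True)
    return post


def hwe_enumeration_pvalue(n_hom_ref, n_het, n_hom_alt):
    """Exact HWE p-value from the closed-form conditional distribution.

    P(h | n, n_minor) = n! / (n11! h! n22!) * 2^h * nA! * nB! / (2n)!
    evaluated in log space for every attainable heterozygote count; the
    two-sided p-value sums the masses not exceeding the observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    n_major = 2 * n - n_minor
    hets = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (gammaln(n + 1) - gammaln(hom_minor + 1) - gammaln(hets + 1)
            - gammaln(hom_major + 1) + hets * math.log(2.0)
            + gammaln(n_minor + 1) + gammaln(n_major + 1)
            - gammaln(2 * n + 1))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_het)]
    return min(1.0, float(probs[probs <= obs * (1.0 + 1e-12)].sum()))


def hwe_enumeration_all(n, n_minor):
    """(het_counts, p_values) for every attainable het count, closed form."""
    n_major = 2 * n - n_minor
    hets = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (gammaln(n + 1) - gammaln(hom_minor + 1) - gammaln(hets + 1)
            - gammaln(hom_major + 1) + hets * math.log(2.0)
            + gammaln(n_minor + 1) + gammaln(n_major + 1)
            - gammaln(2 * n + 1))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    pvals = np.array([probs[probs <= p * (1.0 + 1e-12)].sum() for p in probs])
    return hets, np.minimum(pvals, 1.0)


def pearson_r2_formula(x, y):
    """Textbook sum-formula squared Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = math.sqrt((n * np.sum(x * x) - np.sum(x) ** 2)
                    * (n * np.sum(y * y) - np.sum(y) ** 2))
    return (num / den) ** 2
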