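"""Independent brute-force oracles used only by the tests."""

import numpy as np
from scipy.special import expit, gammaln, logit


def individual_cjs_loglik(histories, phi, p, alpha):
    """Individual-level trap-dependent CJS log-likelihood.

    Sums, for every bird and every possible last-alive occasion, the
    probability of its observed history after first capture: survival
    over each interval, then detection at each occasion with probability
    logit^-1(logit(p_t) + alpha * seen_{t-1}) while alive (marking counts
    as seen).  Enumerates latent death occasions directly — no m-array.
    """
    histories = np.asarray(histories)
    phi = np.asarray(phi, dtype=float)
    p = np.asarray(p, dtype=float)
    T = histories.shape[1]
    total = 0.0
    for row in histories:
        occs = np.flatnonzero(row)
        first, last = occs[0], occs[-1]
        like = 0.0
        for last_alive in range(last, T):
            term = np.prod(phi[first:last_alive])
            if last_alive < T - 1:
                term *= 1.0 - phi[last_alive]
            seen_prev = 1  # marking counts as seen
            for t in range(first + 1, last_alive + 1):
                q = expit(logit(p[t]) + alpha * seen_prev)
                term *= q if row[t] else 1.0 - q
                seen_prev = row[t]
            like += term
        total += np.log(like)
    return float(total)


def multinomial_constant(marray_pair):
    """The parameter-free log multinomial coefficients of an m-array pair."""
    const = 0.0
    for m in (marray_pair.seen_prev, marray_pair.not_seen_prev):
        for row in m:
            n = row.sum()
            if n:
                const += gammaln(n + 1) - gammaln(row + 1).sum()
    return float(const)


def random_histories(rng, n_birds, n_occasions):
    """Random small capture histories with at least one sighting each."""
    h = (rng.random((n_birds, n_occasions)) < rng.uniform(0.2, 0.7)).astype(int)
    empty = h.sum(axis=1) == 0
    h[empty, rng.integers(0, n_occasions, size=empty.sum())] = 1
    return h


def random_cjs_params(rng, n_occasions):
    phi = rng.uniform(0.3, 0.95, n_occasions - 1)
    p = rng.uniform(0.2, 0.9, n_occasions)
    alpha = rng.normal(0.0, 1.5)
    return phi, p, alpha
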