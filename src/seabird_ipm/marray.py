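"""Trap-dependence-stratified m-arrays and the CJS multinomial likelihood.

Capture-mark-resight histories of breeding adults are reduced to m-arrays:
for every release (a sighting) at occasion i, the occasion of the next
resighting (or "never seen again") is recorded.  Resighting carries a
one-year trap-dependence structure: the probability of being resighted at
occasion t is higher, by a constant additive logit offset ``alpha``, for
birds that were sighted at occasion t - 1.  Because every m-array release
is itself a sighting, the occasion immediately following a release always
uses the trap-aware rate; later occasions in the row use the baseline
(trap-unaware) rate.

Releases are additionally stratified into two classes by whether the bird
was sighted at the occasion *preceding* its release (the marking occasion
counts as "seen").  Under the constant one-year trap effect this
stratification does not change cell probabilities — both classes were in
hand at release — but it is the sufficient stratification under more
general trap-dependence structures and is kept for audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import expit, gammaln, logit


class TrapClass(Enum):
    SEEN_PREV = "seen_prev"
    NOT_SEEN_PREV = "not_seen_prev"


@dataclass(frozen=True)
class MArrayPair:
    """Pair of m-arrays stratified by sighting status at release - 1.

    Each matrix has shape ``(T, T + 1)`` for ``T`` occasions: entry
    ``[i, j]`` with ``j > i`` counts birds released at occasion ``i`` whose
    next sighting was at occasion ``j``; the final column counts birds never
    seen again.  Rows are strictly upper triangular; each row sums to the
    number of releases at that occasion in that class.
    """

    seen_prev: np.ndarray
    not_seen_prev: np.ndarray

    def __post_init__(self) -> None:
        for m in (self.seen_prev, self.not_seen_prev):
            if m.ndim != 2 or m.shape[1] != m.shape[0] + 1:
                raise ValueError("m-array must have shape (T, T + 1)")
            if (m < 0).any():
                raise ValueError("m-array entries must be non-negative")
            if np.any(np.tril(m[:, :-1]) != 0):
                raise ValueError("resighting at or before release occasion")
        if self.seen_prev.shape != self.not_seen_prev.shape:
            raise ValueError("class matrices must share a shape")

    @property
    def n_occasions(self) -> int:
        return self.seen_prev.shape[0]

    @property
    def releases_seen_prev(self) -> np.ndarray:
        return self.seen_prev.sum(axis=1)

    @property
    def releases_not_seen_prev(self) -> np.ndarray:
        return self.not_seen_prev.sum(axis=1)

    def combined(self) -> np.ndarray:
        """Classical (non-stratified) m-array: the sum of both classes."""
        return self.seen_prev + self.not_seen_prev

    def to_frames(self, years=None):
        """Export both classes as DataFrames (release year x resight year)."""
        import pandas as pd

        T = self.n_occasions
        if years is None:
            years = np.arange(1, T + 1)
        cols = [str(y) for y in years] + ["never"]
        return {
            "seen_prev": pd.DataFrame(self.seen_prev, index=years, columns=cols),
            "not_seen_prev": pd.DataFrame(
                self.not_seen_prev, index=years, columns=cols
            ),
        }

    def export_csv(self, out_dir, years=None) -> dict:
        """Write one audit CSV per trap class; returns the paths."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in self.to_frames(years).items():
            paths[name] = out / f"marray_{name}.csv"
            frame.to_csv(paths[name], index_label="release_year")
        return paths


def build_marray(histories: np.ndarray) -> MArrayPair:
    """Reduce individual capture histories to the stratified m-array pair.

    Parameters
    ----------
    histories
        Binary matrix, individuals x occasions; 1 marks a capture or
        resighting.  Every row must contain at least one 1.
    """
    h = np.asarray(histories)
    if h.ndim != 2:
        raise ValueError("histories must be a 2-D matrix")
    if not np.isin(h, (0, 1)).all():
        raise ValueError("histories must be binary")
    n, T = h.shape
    seen = np.zeros((T, T + 1), dtype=np.int64)
    not_seen = np.zeros((T, T + 1), dtype=np.int64)
    for idx in range(n):
        occs = np.flatnonzero(h[idx])
        if occs.size == 0:
            raise ValueError(f"history {idx} has no captures")
        for k, rel in enumerate(occs):
            # marking counts as seen for the class of the first release
            if rel == occs[0] or h[idx, rel - 1] == 1:
                target = seen
            else:
                target = not_seen
            if k + 1 < occs.size:
                target[rel, occs[k + 1]] += 1
            else:
                target[rel, T] += 1
    return MArrayPair(seen_prev=seen, not_seen_prev=not_seen)


def _check_series(phi_series, p_series):
    phi = np.asarray(phi_series, dtype=float)
    p = np.asarray(p_series, dtype=float)
    if p.shape[0] != phi.shape[0] + 1:
        raise ValueError(
            "need one resighting probability per occasion and one survival "
            "probability per interval (len(p) == len(phi) + 1)"
        )
    if ((phi <= 0) | (phi >= 1)).any() or ((p[1:] <= 0) | (p[1:] >= 1)).any():
        raise ValueError("probabilities must lie strictly in (0, 1)")
    return phi, p


def cell_probabilities(
    phi_series,
    p_series,
    alpha: float,
    klass: TrapClass,
    release_occasion: int,
) -> np.ndarray:
    """First-resighting probabilities for one m-array row.

    ``phi_series[i]`` is survival over the interval occasion i -> i + 1;
    ``p_series[t]`` is the baseline (trap-unaware) resighting probability at
    occasion t (entry 0 is never used).  The occasion immediately after the
    release uses the trap-aware rate ``logit^-1(logit(p) + alpha)`` — the
    bird was sighted at release — while later occasions use the baseline
    rate.  ``klass`` records the stratum of the release; under the constant
    one-year trap effect it does not alter the probabilities.

    Returns a vector of length ``T + 1``: entry j < T is the probability
    that the next sighting is at occasion j (zero for j <= release), and
    entry T is the probability of never being seen again.  Sums to 1.
    """
    if not isinstance(klass, TrapClass):
        raise TypeError("klass must be a TrapClass")
    phi, p = _check_series(phi_series, p_series)
    T = p.shape[0]
    i = int(release_occasion)
    if not 0 <= i < T:
        raise ValueError("release occasion out of range")
    out = np.zeros(T + 1)
    if i == T - 1:
        out[T] = 1.0
        return out
    p_star = expit(logit(p[i + 1]) + alpha)
    out[i + 1] = phi[i] * p_star
    # alive and unseen through occasion j, then resighted at j + 1
    miss = phi[i] * (1.0 - p_star)
    for j in range(i + 2, T):
        out[j] = miss * phi[j - 1] * p[j]
        miss *= phi[j - 1] * (1.0 - p[j])
    out[T] = 1.0 - out[: T].sum()
    return out


def marray_loglik(data: MArrayPair, phi_series, p_series, alpha: float) -> float:
    """Multinomial log-likelihood of the stratified m-array pair.

    Equals the individual-level trap-dependent CJS log-likelihood of the
    underlying histories up to an additive, parameter-free constant (the
    multinomial coefficients).
    """
    phi, p = _check_series(phi_series, p_series)
    T = data.n_occasions
    if p.shape[0] != T:
        raise ValueError("parameter series do not match the m-array size")
    total = 0.0
    for klass, m in (
        (TrapClass.SEEN_PREV, data.seen_prev),
        (TrapClass.NOT_SEEN_PREV, data.not_seen_prev),
    ):
        for i in range(T):
            row = m[i]
            n_rel = row.sum()
            if n_rel == 0:
                continue
            pr = cell_probabilities(phi, p, alpha, klass, i)
            if (row[pr <= 0] > 0).any():
                raise ValueError(
                    f"observed cell with zero probability at release {i}"
                )
            with np.errstate(divide="ignore", invalid="ignore"):
                contrib = np.where(row > 0, row * np.log(np.maximum(pr, 1e-300)), 0.0)
            total += gammaln(n_rel + 1) - gammaln(row + 1).sum() + contrib.sum()
    return float(total)
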