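"""Calling drug-responsive probe-sets across an RI panel.

A probe-set is "responsive" when its per-strain S-score evidence, aggregated
across the whole family, beats a permutation null at a 5% false-discovery
rate.  The aggregation is Fisher's combined probability test
(X = -2 sum ln p_i, chi-square with 2k df), which favours consistent
moderate responses across many strains as well as strong responses in a few.
Significance is then assessed empirically: the S-score matrix is permuted
(probe-set labels shuffled independently within each strain column, which
preserves every strain's score distribution while destroying cross-strain
alignment), the full p-value/Fisher pipeline recomputed, and empirical
p-values converted to q-values with Storey's FDR procedure.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import ConfigurationError, DataError
from .sscore import sscore_pvalues

__all__ = [
    "detection_filter",
    "detection_proxy",
    "fisher_combine",
    "empirical_pvalues",
    "qvalues",
    "ResponsomeTest",
]

logger = logging.getLogger(__name__)


def detection_proxy(expr: pd.DataFrame, floor: float = 6.0) -> pd.DataFrame:
    """Present/absent calls from summarized log2 expression.

    A probe-set is called present in a sample when its log2 expression meets
    the floor — a stand-in for array detection calls when probe-level
    mismatch data is not available.
    """
    return expr >= floor


def detection_filter(detect: pd.DataFrame, cutoff: float = 0.95) -> list[str]:
    """Retain probe-sets not called absent in >= ``cutoff`` of samples.

    ``detect`` holds boolean present calls (probe-sets x samples).  The
    exclusion boundary is inclusive: a probe-set absent in exactly the cutoff
    fraction is dropped.
    """
    if detect.size == 0:
        raise DataError("empty detection table")
    if not 0 < cutoff <= 1:
        raise ConfigurationError("cutoff must be in (0, 1]")
    absent_fraction = 1.0 - detect.astype(bool).mean(axis=1)
    return list(detect.index[absent_fraction < cutoff])


def fisher_combine(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fisher's combined probability test over the last axis.

    Returns ``(X, combined_p)`` with X = -2 sum ln p and the survival
    probability of a chi-square with 2k degrees of freedom.  Zero p-values
    are clamped to the smallest positive float (logged).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p > 1) or np.any(p < 0):
        raise DataError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("clamping %d zero p-value(s) to machine minimum",
                       int(np.sum(p == 0)))
        p = np.maximum(p, np.finfo(float).tiny)
    k = p.shape[-1]
    X = -2.0 * np.log(p).sum(axis=-1)
    return X, stats.chi2.sf(X, df=2 * k)


def empirical_pvalues(S: pd.DataFrame, n_perm: int = 1000,
                      seed: int | None = None) -> pd.Series:
    """Permutation p-values for each probe-set's Fisher statistic.

    Each permutation shuffles probe-set labels independently within every
    strain column of the S-score matrix and recomputes the two-sided
    p-values and Fisher statistics.  The add-one convention keeps p > 0:
    p = (1 + #{perm X >= observed X}) / (n_perm + 1); ties count as >=.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100 (tail too unstable)")
    rng = np.random.default_rng(seed)
    p = np.asarray(sscore_pvalues(S), dtype=float)
    logp = -2.0 * np.log(p)
    x_obs = logp.sum(axis=1)
    exceed = np.zeros(len(x_obs), dtype=np.int64)
    for _ in range(n_perm):
        x_perm = rng.permuted(logp, axis=0).sum(axis=1)
        exceed += x_perm >= x_obs
    emp = (1.0 + exceed) / (n_perm + 1.0)
    return pd.Series(emp, index=S.index, name="empirical_p")


def qvalues(p, lambdas: np.ndarray | None = None) -> np.ndarray | pd.Series:
    """Storey q-values with pi0 estimated over a lambda grid.

    pi0 is the median of ``#{p > lambda} / (m (1 - lambda))`` over
    ``lambdas`` (default 0.05..0.95 step 0.05), capped at 1.  With fewer
    than 100 p-values pi0 falls back to 1, i.e. Benjamini-Hochberg (logged).
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr <= 0) | (arr > 1)):
        raise DataError("p-values must lie in (0, 1]")
    m = arr.size
    if m < 100:
        logger.info("only %d p-values; using pi0 = 1 (Benjamini-Hochberg)", m)
        pi0 = 1.0
    else:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        ests = [np.mean(arr > lam) / (1.0 - lam) for lam in lambdas]
        pi0 = float(min(1.0, max(np.median(ests), 1.0 / m)))
    order = np.argsort(arr, kind="stable")
    ranked = arr[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index, name="q_value")
    return out


class ResponsomeTest(BaseEstimator):
    """Cross-strain responsiveness test over an S-score matrix.

    Fit on a probe-set x strain S-score :class:`~pandas.DataFrame`; each
    probe-set gets a Fisher combined statistic, a permutation empirical
    p-value, and a Storey q-value.  Probe-sets with q <= ``q_cutoff`` are
    called responsive.

    Parameters
    ----------
    n_permutations : int, default 1000
        Label permutations for the empirical null.
    q_cutoff : float, default 0.05
        FDR threshold for the responsive call.
    random_state : int or None
        Seed for the permutation stream.

    Attributes
    ----------
    results_ : DataFrame with columns fisher_x, df, combined_p, empirical_p,
        q_value, responsive.
    responsive_ : list of responsive probe-set ids.
    """

    def __init__(self, n_permutations: int = 1000, q_cutoff: float = 0.05,
                 random_state: int | None = None):
        self.n_permutations = n_permutations
        self.q_cutoff = q_cutoff
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame) or X.empty:
            raise DataError("X must be a non-empty S-score DataFrame")
        k = X.shape[1]
        p = sscore_pvalues(X)
        fisher_x, combined_p = fisher_combine(np.asarray(p))
        emp = empirical_pvalues(X, n_perm=self.n_permutations,
                                seed=self.random_state)
        q = qvalues(emp)
        self.results_ = pd.DataFrame({
            "fisher_x": fisher_x,
            "df": 2 * k,
            "combined_p": combined_p,
            "empirical_p": emp,
            "q_value": q,
            "responsive": q <= self.q_cutoff,
        }, index=X.index)
        self.responsive_ = list(self.results_.index[self.results_["responsive"]])
        return self
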