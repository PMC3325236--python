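"""Trans-band synthetic traits and permutation-adjusted phenotype scans.

A trans-band's coordinated expression variation is condensed into a single
strain-level synthetic trait: the first principal component of the member
probe-sets' centered and scaled expression (PC-trait).  Each PC-trait is
then correlated with a panel of strain phenotypes; significance is assessed
by permuting the PC-trait's sample order 1,000 times and comparing |r|
against the permutation distribution (two-sided, since both positively and
negatively coupled phenotypes are of interest).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import ConfigurationError, DataError

__all__ = ["PCTrait", "PhenoCorrelation", "pc_trait", "phenotype_scan",
           "PhenotypeAssociation"]

logger = logging.getLogger(__name__)


@dataclass
class PCTrait:
    """First principal component of a member x strain expression block."""

    band_id: str
    scores: pd.Series            # strain-indexed, mean 0
    variance_explained: float
    loadings: pd.Series          # per retained member


@dataclass
class PhenoCorrelation:
    phenotype: str
    r: float
    adjusted_p: float
    significant: bool
    n_strains: int


def pc_trait(expr_submatrix: pd.DataFrame, band_id: str = "band") -> PCTrait:
    """PC1 scores of centered, row-scaled member expression.

    Rows (members) are centered and scaled to unit variance; zero-variance
    rows are dropped with a warning.  The loading sign is fixed so the
    majority of loadings are positive, with ties resolved toward positive
    correlation with the member-mean profile.
    """
    if expr_submatrix.shape[0] < 2 or expr_submatrix.shape[1] < 3:
        raise ConfigurationError("need >= 2 members and >= 3 strains")
    X = expr_submatrix.astype(float)
    sd = X.std(axis=1, ddof=1)
    if (sd == 0).any():
        warnings.warn(f"dropping {int((sd == 0).sum())} zero-variance member "
                      "row(s) from the PC-trait")
        X = X.loc[sd > 0]
        sd = sd[sd > 0]
        if X.shape[0] < 2:
            raise DataError("fewer than 2 members with variance")
    Z = X.sub(X.mean(axis=1), axis=0).div(sd, axis=0).to_numpy()
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = U[:, 0]
    scores = s[0] * Vt[0]
    sign = np.sign(np.sum(loadings > 0) - np.sum(loadings < 0))
    if sign == 0:
        mean_profile = Z.mean(axis=0)
        if mean_profile.std() > 0:
            sign = np.sign(np.corrcoef(scores, mean_profile)[0, 1])
        if not np.isfinite(sign) or sign == 0:
            sign = 1.0
    var_exp = float(s[0] ** 2 / np.sum(s ** 2))
    return PCTrait(
        band_id=band_id,
        scores=pd.Series(sign * scores, index=expr_submatrix.columns,
                         name=band_id),
        variance_explained=var_exp,
        loadings=pd.Series(sign * loadings, index=X.index, name=band_id))


def phenotype_scan(pc: PCTrait, phenotypes: pd.DataFrame, n_perm: int = 1000,
                   seed: int | None = None, alpha: float = 0.01,
                   min_shared: int = 5) -> list[PhenoCorrelation]:
    """Permutation-adjusted Pearson correlations of a PC-trait vs phenotypes.

    Missing phenotype values are handled pairwise-complete; phenotypes
    sharing fewer than ``min_shared`` strains with the PC-trait are skipped
    with a warning.  Adjusted p = (1 + #{perm |r| >= |observed r|}) /
    (n_perm + 1) using permutations of the PC-trait's sample order;
    significance is strict (p < alpha).
    """
    rng = np.random.default_rng(seed)
    out = []
    for pheno_id, row in phenotypes.iterrows():
        shared = [s for s in pc.scores.index
                  if s in row.index and np.isfinite(row[s])]
        if len(shared) < min_shared:
            warnings.warn(f"phenotype {pheno_id!r}: only {len(shared)} shared "
                          "strain(s); skipped")
            continue
        x = pc.scores[shared].to_numpy()
        y = row[shared].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"phenotype {pheno_id!r}: zero variance; skipped")
            continue
        r_obs = float(np.corrcoef(x, y)[0, 1])
        xc = (x - x.mean()) / x.std()
        yc = (y - y.mean()) / y.std()
        n = len(shared)
        exceed = 0
        for _ in range(n_perm):
            r_perm = float(xc[rng.permutation(n)] @ yc / n)
            if abs(r_perm) >= abs(r_obs):
                exceed += 1
        p = (1 + exceed) / (n_perm + 1)
        out.append(PhenoCorrelation(str(pheno_id), r_obs, p, p < alpha, n))
    return out


class PhenotypeAssociation(BaseEstimator):
    """Correlate trans-band PC-traits against a phenotype panel.

    Fit on ``{band_id: member expression DataFrame}`` plus a phenotype x
    strain table; fitted attributes hold the PC-traits and a tidy edge list
    of (band, phenotype, r, adjusted p).
    """

    def __init__(self, n_permutations: int = 1000, alpha: float = 0.01,
                 min_shared: int = 5, random_state: int | None = None):
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.min_shared = min_shared
        self.random_state = random_state

    def fit(self, band_expression: dict[str, pd.DataFrame],
            phenotypes: pd.DataFrame):
        ss = np.random.SeedSequence(self.random_state)
        seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in ss.spawn(max(len(band_expression), 1))]
        self.pc_traits_ = {}
        rows = []
        for (band, expr), seed in zip(sorted(band_expression.items()), seeds):
            pc = pc_trait(expr, band_id=band)
            self.pc_traits_[band] = pc
            for c in phenotype_scan(pc, phenotypes, self.n_permutations,
                                    seed, self.alpha, self.min_shared):
                rows.append({"trans_band": band, "phenotype": c.phenotype,
                             "r": c.r, "adjusted_p": c.adjusted_p,
                             "significant": c.significant,
                             "n_strains": c.n_strains})
        self.edges_ = pd.DataFrame(rows)
        return self
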