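"""Single-QTL genome scans by marker regression.

Each expression trait is regressed on the numeric genotype code (B=0, D=1)
at every marker; the evidence for linkage at a marker is the LOD score

    LOD = (n/2) log10(RSS0 / RSS1) = -(n/2) log10(1 - R^2)

comparing the single-marker additive model against the intercept-only model.
With complete RI genotypes this marker regression coincides with
Haley-Knott regression at the markers, so no pseudomarker grid is used.
Genome-wide significance comes from permutations of the strain labels of
the trait (null distribution of the maximum LOD), with the conventional
complex-trait tiers: 'significant' at genome-wide p <= 0.01 and
'suggestive' at p <= 0.63 (the latter corresponds to one false positive
per genome scan).  Peaks within 5 Mb of the regulated gene are classed cis,
all others trans; peak uncertainty is summarized by a 1.5-LOD support
interval extended one marker beyond the drop on each side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import ConfigurationError, DataError, GenotypePanel, MarkerMap

__all__ = [
    "LodCurve",
    "EqtlRecord",
    "hk_scan",
    "genome_wide_p",
    "support_interval",
    "classify_eqtl",
    "EqtlScanner",
]

logger = logging.getLogger(__name__)

_RSS_FLOOR = 1e-12  # floor on 1 - R^2; keeps a perfect fit's LOD finite


@dataclass
class LodCurve:
    """Per-marker LOD profile for one trait."""

    trait: str
    lod: np.ndarray            # aligned with map order
    map: MarkerMap

    @property
    def peak_index(self) -> int:
        # ties resolve to the first (lowest genomic coordinate) marker
        return int(np.argmax(self.lod))

    @property
    def peak_marker(self) -> str:
        return self.map.marker_ids[self.peak_index]

    @property
    def peak_lod(self) -> float:
        return float(self.lod[self.peak_index])


@dataclass
class EqtlRecord:
    """Peak linkage summary for one trait."""

    trait: str
    dataset: str
    peak_marker: str
    chrom: int
    pos_mb: float
    lod: float
    genome_p: float
    tier: str                   # significant | suggestive | none
    eqtl_class: str             # cis | trans
    interval: tuple[int, float, float]   # (chr, start Mb, end Mb)
    annotated: bool = True


def _standardize_genotypes(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardized genotype matrix; monomorphic markers zeroed."""
    G = panel.calls.astype(float)
    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    mono = sd == 0
    if mono.any():
        logger.info("%d monomorphic marker(s): LOD fixed at 0", int(mono.sum()))
    sd_safe = np.where(mono, 1.0, sd)
    Z = (G - mu) / sd_safe
    Z[:, mono] = 0.0
    return Z, mono


def _lod_from_r2(r2: np.ndarray, n: int) -> np.ndarray:
    return -(n / 2.0) * np.log10(np.clip(1.0 - r2, _RSS_FLOOR, 1.0))


def hk_scan(trait, panel: GenotypePanel) -> LodCurve:
    """Marker-regression LOD curve of one trait over the whole map.

    ``trait`` is a strain-indexed vector (Series aligned by strain name, or
    array in panel order) of at least 8 strains.
    """
    name = getattr(trait, "name", None) or "trait"
    if isinstance(trait, pd.Series):
        y = trait.reindex(panel.strains).to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
    if y.shape != (panel.n_strains,) or np.isnan(y).any():
        raise DataError("trait must cover every panel strain with finite values")
    n = panel.n_strains
    if n < 8:
        raise DataError("need at least 8 strains for a genome scan")
    Z, _ = _standardize_genotypes(panel)
    ys = y - y.mean()
    sd = ys.std()
    if sd == 0:
        return LodCurve(str(name), np.zeros(len(panel.map)), panel.map)
    r = (ys / sd) @ Z / n
    return LodCurve(str(name), _lod_from_r2(r ** 2, n), panel.map)


def genome_wide_p(trait, panel: GenotypePanel, n_perm: int = 1000,
                  seed: int | None = None,
                  curve: LodCurve | None = None) -> float:
    """Permutation genome-wide p-value for a trait's peak LOD.

    Strain labels of the trait are shuffled ``n_perm`` times and the maximum
    LOD of each rescan recorded; the add-one convention gives
    p = (1 + #{perm max >= observed max}) / (n_perm + 1).
    """
    if curve is None:
        curve = hk_scan(trait, panel)
    if isinstance(trait, pd.Series):
        y = trait.reindex(panel.strains).to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
    rng = np.random.default_rng(seed)
    n = panel.n_strains
    Z, _ = _standardize_genotypes(panel)
    ys = y - y.mean()
    sd = ys.std()
    if sd == 0:
        return 1.0
    ys = ys / sd
    perms = np.empty((n_perm, n))
    for i in range(n_perm):
        perms[i] = ys[rng.permutation(n)]
    r = perms @ Z / n
    max_lod = _lod_from_r2(r ** 2, n).max(axis=1)
    return float((1 + np.sum(max_lod >= curve.peak_lod)) / (n_perm + 1))


def support_interval(curve: LodCurve, drop: float = 1.5
                     ) -> tuple[int, float, float]:
    """1.5-LOD-drop support interval, bracketed by one extra marker.

    On the peak's chromosome, span the outermost markers with LOD within
    ``drop`` of the peak, then extend one marker further on each side,
    clipping at the chromosome ends.  A flat curve yields the whole
    chromosome.
    """
    if not np.isfinite(curve.peak_lod):
        raise DataError("LOD curve has no finite peak")
    peak = curve.peak_index
    chrom = int(curve.map.chromosomes[peak])
    idx = curve.map.chromosome_slices()[chrom]
    lods = curve.lod[idx]
    within = np.flatnonzero(lods >= curve.peak_lod - drop)
    lo = max(within.min() - 1, 0)
    hi = min(within.max() + 1, len(idx) - 1)
    pos = curve.map.positions_mb[idx]
    return chrom, float(pos[lo]), float(pos[hi])


def classify_eqtl(peak: tuple[int, float],
                  gene_position: tuple[int, float] | None,
                  window_mb: float = 5.0) -> str:
    """cis iff the peak lies on the gene's chromosome within ``window_mb``
    (strict <); an unannotated gene is classed trans (logged)."""
    if gene_position is None:
        logger.info("unannotated gene: classing eQTL as trans")
        return "trans"
    pchr, ppos = peak
    gchr, gpos = gene_position
    if int(pchr) == int(gchr) and abs(float(ppos) - float(gpos)) < window_mb:
        return "cis"
    return "trans"


class EqtlScanner(BaseEstimator):
    """Genome scans with permutation thresholds for a table of traits.

    Fit on a trait x strain DataFrame plus a genotype panel; emits one
    :class:`EqtlRecord` per trait with peak, genome-wide p, tier, cis/trans
    class and support interval.

    Parameters
    ----------
    n_permutations : int, default 1000
    significant, suggestive : float
        Genome-wide p cutoffs for the two tiers (0.01 / 0.63).
    cis_window_mb : float, default 5.0
    lod_drop : float, default 1.5
    dataset : str
        Tag recorded on every record (e.g. "saline" or "sscore").
    random_state : int or None

    Attributes
    ----------
    records_ : list of EqtlRecord
    table_ : tidy DataFrame of the same records.
    """

    def __init__(self, n_permutations: int = 1000, significant: float = 0.01,
                 suggestive: float = 0.63, cis_window_mb: float = 5.0,
                 lod_drop: float = 1.5, dataset: str = "expression",
                 random_state: int | None = None):
        self.n_permutations = n_permutations
        self.significant = significant
        self.suggestive = suggestive
        self.cis_window_mb = cis_window_mb
        self.lod_drop = lod_drop
        self.dataset = dataset
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, panel: GenotypePanel,
            annotation: pd.DataFrame | None = None):
        """Scan every row of ``X``.

        ``annotation`` (indexed like ``X`` with ``chr``/``pos_mb`` columns)
        drives the cis/trans call; rows without annotation are classed trans.
        """
        if self.n_permutations < 100:
            raise ConfigurationError("n_permutations must be >= 100")
        ss = np.random.SeedSequence(self.random_state)
        seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in ss.spawn(len(X))]
        records = []
        for (trait_id, row), seed in zip(X.iterrows(), seeds):
            curve = hk_scan(row, panel)
            p = genome_wide_p(row, panel, n_perm=self.n_permutations,
                              seed=seed, curve=curve)
            tier = ("significant" if p <= self.significant
                    else "suggestive" if p <= self.suggestive else "none")
            peak_i = curve.peak_index
            peak = (int(panel.map.chromosomes[peak_i]),
                    float(panel.map.positions_mb[peak_i]))
            gene_pos, annotated = None, False
            if annotation is not None and trait_id in annotation.index:
                g = annotation.loc[trait_id]
                gene_pos, annotated = (int(g["chr"]), float(g["pos_mb"])), True
            records.append(EqtlRecord(
                trait=str(trait_id), dataset=self.dataset,
                peak_marker=curve.peak_marker, chrom=peak[0], pos_mb=peak[1],
                lod=curve.peak_lod, genome_p=p, tier=tier,
                eqtl_class=classify_eqtl(peak, gene_pos, self.cis_window_mb),
                interval=support_interval(curve, self.lod_drop),
                annotated=annotated))
        self.records_ = records
        self.table_ = pd.DataFrame([{
            "trait": r.trait, "dataset": r.dataset, "peak_marker": r.peak_marker,
            "chr": r.chrom, "pos_mb": r.pos_mb, "lod": r.lod,
            "genome_p": r.genome_p, "tier": r.tier, "class": r.eqtl_class,
            "ci_chr": r.interval[0], "ci_start_mb": r.interval[1],
            "ci_end_mb": r.interval[2]} for r in records]).set_index("trait") \
            if records else pd.DataFrame()
        return self
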