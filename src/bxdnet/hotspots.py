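"""Trans-band hotspot detection by genome binning with a permutation null.

Master regulatory loci reveal themselves as an excess of trans eQTL peaks
piling into a narrow genomic interval.  The genome is split into fixed
10 Mb bins (anchored at 0 on each chromosome, half-open ``[k*10, (k+1)*10)``)
and suggestive-tier eQTL counted per bin.  Chance expectations come from a
permutation null that reassigns every eQTL to a uniformly random marker —
so marker density shapes the null — recording the most populous bin of each
permutation; an observed bin is a significant hotspot when its count
strictly exceeds the 95th percentile of that max-count distribution.

A hotspot's location is refined into a consensus support interval: the
contiguous run of markers contained in at least 80% of the member eQTL's
individual 1.5-LOD support intervals, required to contain the modal member
peak.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import ConfigurationError, GenotypePanel, MarkerMap
from .eqtl import EqtlRecord

__all__ = ["TransBand", "bin_eqtl", "hotspot_test", "consensus_interval",
           "HotspotDetector"]

logger = logging.getLogger(__name__)


def _bin_of(chrom: int, pos_mb: float, width: float) -> tuple[int, float]:
    return int(chrom), float(np.floor(pos_mb / width) * width)


def bin_eqtl(records: list[EqtlRecord], bin_width: float = 10.0
             ) -> Counter:
    """Count eQTL peaks per half-open genome bin [k*w, (k+1)*w)."""
    counts: Counter = Counter()
    for r in records:
        counts[_bin_of(r.chrom, r.pos_mb, bin_width)] += 1
    return counts


def _max_bin_count_null(n_eqtl: int, marker_bins: np.ndarray, n_bins: int,
                        n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Distribution of the most populous bin under random marker assignment."""
    out = np.empty(n_perm)
    for i in range(n_perm):
        picks = rng.integers(0, len(marker_bins), size=n_eqtl)
        out[i] = np.bincount(marker_bins[picks], minlength=n_bins).max()
    return out


def hotspot_test(records: list[EqtlRecord], panel: GenotypePanel,
                 n_perm: int = 10000, seed: int | None = None,
                 bin_width: float = 10.0, percentile: float = 95.0
                 ) -> tuple[dict, float]:
    """Significant hotspot bins under the random-marker permutation null.

    Returns ``({bin: count} for significant bins, threshold)`` where the
    threshold is the stated percentile of the permutation max-count
    distribution and significance is strict (count > threshold).
    """
    if n_perm < 1000:
        logger.warning("n_perm = %d < 1000: hotspot tail quantile is coarse",
                       n_perm)
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    if not records:
        return {}, float("nan")
    counts = bin_eqtl(records, bin_width)
    m = panel.map
    bins = sorted({_bin_of(c, p, bin_width)
                   for c, p in zip(m.chromosomes, m.positions_mb)})
    code = {b: i for i, b in enumerate(bins)}
    marker_bins = np.array([code[_bin_of(c, p, bin_width)]
                            for c, p in zip(m.chromosomes, m.positions_mb)])
    rng = np.random.default_rng(seed)
    null_max = _max_bin_count_null(len(records), marker_bins, len(bins),
                                   n_perm, rng)
    threshold = float(np.percentile(null_max, percentile))
    hits = {b: c for b, c in counts.items() if c > threshold}
    return hits, threshold


def consensus_interval(members: list[EqtlRecord], marker_map: MarkerMap,
                       inclusion: float = 0.8) -> tuple[float, float] | None:
    """Consensus support interval of a trans-band.

    For every marker on the hotspot chromosome, compute the fraction of
    member support intervals containing it; the consensus interval is the
    contiguous run of markers at fraction >= ``inclusion`` that contains the
    modal member peak position.  Returns ``(start_mb, end_mb)`` or ``None``
    (with a warning) when no qualifying run covers the modal peak.
    """
    if len(members) < 2:
        raise ConfigurationError("need >= 2 member eQTL for a consensus interval")
    chrom = Counter(r.chrom for r in members).most_common(1)[0][0]
    idx = marker_map.chromosome_slices()[int(chrom)]
    pos = marker_map.positions_mb[idx]
    onchr = [r for r in members if r.interval[0] == chrom]
    frac = np.zeros(len(pos))
    for r in onchr:
        _, lo, hi = r.interval
        frac += (pos >= lo) & (pos <= hi)
    frac /= max(len(onchr), 1)
    ok = frac >= inclusion
    if not ok.any():
        warnings.warn("no marker lies in the required fraction of member "
                      "support intervals; empty consensus interval")
        return None
    # modal member peak position (ties -> lowest coordinate)
    peaks = Counter(r.pos_mb for r in members if r.chrom == chrom)
    top = max(peaks.values())
    modal = min(p for p, c in peaks.items() if c == top)
    modal_i = int(np.argmin(np.abs(pos - modal)))
    if not ok[modal_i]:
        warnings.warn("modal member peak falls outside every qualifying "
                      "marker run; empty consensus interval")
        return None
    lo = modal_i
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = modal_i
    while hi < len(pos) - 1 and ok[hi + 1]:
        hi += 1
    return float(pos[lo]), float(pos[hi])


@dataclass
class TransBand:
    """A significant hotspot bin and its membership."""

    chromosome: int
    bin_start: float
    bin_end: float
    members: list[EqtlRecord]
    count: int
    threshold: float
    significant: bool
    consensus: tuple[float, float] | None = None
    peak_marker: str | None = None
    network: str | None = None


class HotspotDetector(BaseEstimator):
    """Detect trans-band hotspots from a set of eQTL records.

    Fit on (suggestive-tier trans) eQTL records plus the genotype panel;
    fitted attributes list the significant trans-bands with consensus
    intervals.

    Parameters
    ----------
    bin_width_mb : float, default 10.0
    n_permutations : int, default 10000
    percentile : float, default 95.0
    consensus_inclusion : float, default 0.8
    random_state : int or None

    Attributes
    ----------
    counts_ : Counter of eQTL per bin.
    threshold_ : permutation max-count percentile.
    transbands_ : list of significant TransBand.
    """

    def __init__(self, bin_width_mb: float = 10.0, n_permutations: int = 10000,
                 percentile: float = 95.0, consensus_inclusion: float = 0.8,
                 random_state: int | None = None):
        self.bin_width_mb = bin_width_mb
        self.n_permutations = n_permutations
        self.percentile = percentile
        self.consensus_inclusion = consensus_inclusion
        self.random_state = random_state

    def fit(self, records: list[EqtlRecord], panel: GenotypePanel):
        self.counts_ = bin_eqtl(records, self.bin_width_mb)
        hits, self.threshold_ = hotspot_test(
            records, panel, n_perm=self.n_permutations,
            seed=self.random_state, bin_width=self.bin_width_mb,
            percentile=self.percentile)
        bands = []
        for (chrom, start), count in sorted(hits.items()):
            members = [r for r in records
                       if _bin_of(r.chrom, r.pos_mb, self.bin_width_mb)
                       == (chrom, start)]
            peaks = Counter((r.peak_marker, r.pos_mb) for r in members)
            top = max(peaks.values())
            peak_marker = min((m for m, c in peaks.items() if c == top),
                              key=lambda m: m[1])[0]
            consensus = None
            if len(members) >= 2:
                consensus = consensus_interval(members, panel.map,
                                               self.consensus_inclusion)
            bands.append(TransBand(
                chromosome=chrom, bin_start=start,
                bin_end=start + self.bin_width_mb, members=members,
                count=count, threshold=self.threshold_, significant=True,
                consensus=consensus, peak_marker=peak_marker))
        self.transbands_ = bands
        return self
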