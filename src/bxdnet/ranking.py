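"""Empirical ranking of positional candidate genes under a trans-band.

Genes inside a trans-band's consensus support interval are scored across
four evidence categories: DNA sequence variation (coding and
non-synonymous SNPs between the parental genomes), expression genetics
(a cis eQTL in the basal or differential-response dataset), drug
responsiveness (differential-expression q-value), and network properties
(membership in the trans-band's co-expression network plus scaled
connectivity and centrality of the gene in its resident network).

Because probes were designed against the B6 reference, a SNP under a probe
depresses hybridization of D2 transcripts and can fake a cis eQTL with B6
as the increaser allele; such cis calls carry a penalty, applied only when
B6 is indeed the increaser.  The category point values are configurable;
the defaults weight the four categories comparably.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import ConfigurationError
from .hotspots import TransBand

__all__ = ["RankWeights", "EvidenceBundle", "genes_in_interval",
           "score_candidates", "CandidateRanker"]


@dataclass
class RankWeights:
    """Points per evidence item; the probe-SNP penalty applies at most once."""

    nonsyn_snp: float = 3.0
    coding_snp: float = 1.0
    cis_significant: float = 3.0
    cis_suggestive: float = 1.0
    probe_snp_penalty: float = -2.0
    responsive: float = 2.0
    same_network: float = 2.0
    connectivity_bonus: float = 2.0   # x scaled connectivity
    centrality_bonus: float = 2.0     # x scaled centrality


@dataclass
class EvidenceBundle:
    """All per-gene evidence feeding the ranking."""

    gene: str
    n_coding_snps: int = 0
    n_nonsyn_snps: int = 0
    cis_saline_p: float | None = None
    cis_sscore_p: float | None = None
    probe_has_snp: bool = False
    b6_is_increaser: bool = False
    responsive_q: float | None = None
    network_membership: str | None = None
    scaled_connectivity: float = 0.0
    scaled_centrality: float = 0.0


def genes_in_interval(annotation: pd.DataFrame,
                      interval: tuple[int, float, float]) -> list[str]:
    """Genes annotated inside a closed genomic interval (chr, start, end Mb)."""
    chrom, start, end = interval
    if end < start:
        return []
    hit = ((annotation["chr"] == int(chrom))
           & (annotation["pos_mb"] >= start) & (annotation["pos_mb"] <= end))
    return list(annotation.index[hit])


def _score_one(e: EvidenceBundle, band_network: str | None,
               w: RankWeights, significant: float, suggestive: float,
               q_cutoff: float) -> dict:
    parts = {"snp": 0.0, "cis": 0.0, "response": 0.0, "network": 0.0}
    if e.n_nonsyn_snps > 0:
        parts["snp"] += w.nonsyn_snp
    elif e.n_coding_snps > 0:
        parts["snp"] += w.coding_snp
    cis_ps = [p for p in (e.cis_saline_p, e.cis_sscore_p) if p is not None]
    if cis_ps:
        best = min(cis_ps)
        if best <= significant:
            parts["cis"] += w.cis_significant
        elif best <= suggestive:
            parts["cis"] += w.cis_suggestive
        if e.probe_has_snp and e.b6_is_increaser:
            parts["cis"] += w.probe_snp_penalty
    if e.responsive_q is not None and e.responsive_q <= q_cutoff:
        parts["response"] += w.responsive
    if e.network_membership is not None:
        if band_network is not None and e.network_membership == band_network:
            parts["network"] += w.same_network
        parts["network"] += w.connectivity_bonus * e.scaled_connectivity
        parts["network"] += w.centrality_bonus * e.scaled_centrality
    parts["total"] = sum(parts.values())
    return parts


def score_candidates(interval_genes: list[str],
                     evidence: dict[str, EvidenceBundle],
                     transband: TransBand | None = None,
                     weights: RankWeights | None = None,
                     significant: float = 0.01, suggestive: float = 0.63,
                     q_cutoff: float = 0.05) -> pd.DataFrame:
    """Ranked candidate table for the genes of one interval.

    Genes missing from ``evidence`` score 0.  Ties break by scaled
    connectivity (descending) then gene symbol.  The returned frame carries
    the per-category breakdown and a 1-based ``rank`` column.
    """
    w = weights or RankWeights()
    band_network = transband.network if transband is not None else None
    rows = []
    for g in interval_genes:
        e = evidence.get(g, EvidenceBundle(gene=g))
        parts = _score_one(e, band_network, w, significant, suggestive,
                           q_cutoff)
        rows.append({"gene": g, **parts,
                     "scaled_connectivity": e.scaled_connectivity,
                     "scaled_centrality": e.scaled_centrality,
                     "network": e.network_membership})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table = table.sort_values(
        ["total", "scaled_connectivity", "gene"],
        ascending=[False, False, True], kind="stable").reset_index(drop=True)
    table["rank"] = table.index + 1
    return table


class CandidateRanker(BaseEstimator):
    """Rank positional candidates inside each trans-band consensus interval.

    Fit on a gene annotation plus a per-gene evidence mapping and a list of
    trans-bands; ``rankings_`` maps each band to its ranked candidate table.
    """

    def __init__(self, weights: RankWeights | None = None,
                 significant: float = 0.01, suggestive: float = 0.63,
                 q_cutoff: float = 0.05):
        self.weights = weights
        self.significant = significant
        self.suggestive = suggestive
        self.q_cutoff = q_cutoff

    def fit(self, annotation: pd.DataFrame,
            evidence: dict[str, EvidenceBundle],
            transbands: list[TransBand]):
        if annotation.empty:
            raise ConfigurationError("empty annotation")
        self.rankings_ = {}
        for band in transbands:
            if band.consensus is None:
                continue
            interval = (band.chromosome, *band.consensus)
            genes = genes_in_interval(annotation, interval)
            key = f"chr{band.chromosome}:{band.bin_start:g}-{band.bin_end:g}"
            self.rankings_[key] = score_candidates(
                genes, evidence, band, self.weights,
                self.significant, self.suggestive, self.q_cutoff)
        return self
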