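"""End-to-end orchestration with a structured config and provenance.

``run_all`` wires the stages together: synthetic data (or files on disk) ->
S-scores -> responsome calls -> paraclique networks -> eQTL scans (basal
saline arm and the S-score response dataset) -> trans-band hotspots ->
candidate ranking -> phenotype correlations.  Every stage writes a
tab-delimited table whose header comment records the config hash and seed,
and a JSON manifest summarizes the run.

One global seed is expanded into per-stage seeds through a fixed
``numpy.random.SeedSequence`` spawn order (data, responsome, eqtl-saline,
eqtl-sscore, hotspots, phenocorr), so any stage can be re-run in isolation
with an identical stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .datatypes import ConfigurationError
from .eqtl import EqtlScanner
from .hotspots import HotspotDetector
from .networks import ParacliqueExtractor, ergen_call
from .phenocorr import PhenotypeAssociation
from .ranking import CandidateRanker, EvidenceBundle, RankWeights
from .responsome import ResponsomeTest, detection_filter, detection_proxy
from .simulate import make_dataset
from .sscore import SScoreTransformer

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger(__name__)

_STAGES = ("data", "responsome", "eqtl_saline", "eqtl_sscore", "hotspots",
           "phenocorr")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; serialized verbatim into provenance."""

    seed: int = 0
    # input paths; None means simulate
    geno_path: str | None = None
    saline_path: str | None = None
    ethanol_path: str | None = None
    probe_level_path: str | None = None
    annotation_path: str | None = None
    phenotype_path: str | None = None
    snp_table_path: str | None = None
    # simulation scale
    n_strains: int = 27
    n_probe_sets: int = 2000
    # thresholds
    edge_threshold: float = 0.7
    stringent_threshold: float = 0.9
    glom_factor: float = 0.7
    min_core: int = 5
    min_size: int = 10
    q_cutoff: float = 0.05
    detection_floor: float = 6.0
    detection_cutoff: float = 0.95
    cis_window_mb: float = 5.0
    lod_drop: float = 1.5
    bin_width_mb: float = 10.0
    consensus_inclusion: float = 0.8
    suggestive: float = 0.63
    significant: float = 0.01
    pheno_alpha: float = 0.01
    # permutation counts
    responsome_permutations: int = 1000
    eqtl_permutations: int = 1000
    hotspot_permutations: int = 10000
    phenotype_permutations: int = 1000
    # ranking weights
    rank_weights: dict = field(default_factory=dict)

    def __post_init__(self):
        checks = [
            (0 < self.edge_threshold <= 1, "edge_threshold in (0, 1]"),
            (0 < self.stringent_threshold <= 1, "stringent_threshold in (0, 1]"),
            (0 < self.glom_factor <= 1, "glom_factor in (0, 1]"),
            (0 < self.q_cutoff <= 1 or self.q_cutoff == 0, "q_cutoff in [0, 1]"),
            (0 < self.consensus_inclusion <= 1, "consensus_inclusion in (0, 1]"),
            (0 < self.significant <= self.suggestive <= 1,
             "significant <= suggestive, both in (0, 1]"),
            (self.lod_drop > 0, "lod_drop > 0"),
            (self.bin_width_mb > 0, "bin_width_mb > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigurationError(f"config violates: {msg}")

    def hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(int(self.seed))
        return {name: int(c.generate_state(1)[0] % (2 ** 31))
                for name, c in zip(_STAGES, ss.spawn(len(_STAGES)))}


def _write(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    keep_index = not isinstance(df.index, pd.RangeIndex)
    with open(path, "w") as fh:
        fh.write(f"# config={cfg.hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=keep_index)


def _load_or_simulate(cfg: RunConfig, seed: int):
    if cfg.geno_path is None:
        return make_dataset(seed, n_strains=cfg.n_strains,
                            n_probe_sets=cfg.n_probe_sets)
    from .simulate import SimulatedDataset
    from .datatypes import TruthRecord
    panel = bio.read_geno(cfg.geno_path)
    saline = bio.read_expression(cfg.saline_path)
    ethanol = bio.read_expression(cfg.ethanol_path)
    probes = (bio.read_probe_level(cfg.probe_level_path)
              if cfg.probe_level_path else None)
    annotation = pd.read_csv(cfg.annotation_path, sep="\t", index_col=0) \
        if cfg.annotation_path else None
    phenotypes = pd.read_csv(cfg.phenotype_path, sep="\t", index_col=0) \
        if cfg.phenotype_path else pd.DataFrame()
    return SimulatedDataset(panel, annotation, saline, ethanol, probes,
                            phenotypes, TruthRecord())


def run_all(config: RunConfig, outdir) -> dict:
    """Execute every stage; returns the provenance manifest (also on disk).

    A stage failure raises with a stage tag; tables written before the
    failure are retained.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest: dict = {"config_hash": config.hash(), "seed": config.seed,
                      "stage_seeds": seeds, "stages": {}}
    config.to_yaml(out / "config.yaml")

    stage = "data"
    try:
        data = _load_or_simulate(config, seeds["data"])
        if config.geno_path is None:
            bio.write_geno(data.panel, out / "panel.geno")
            bio.write_expression(data.saline, out / "expression_saline.tsv")
            bio.write_expression(data.ethanol, out / "expression_ethanol.tsv")
            data.truth.to_json(out / "truth.json")
        manifest["stages"]["data"] = {
            "n_strains": data.panel.n_strains,
            "n_probe_sets": int(data.saline.shape[0])}

        stage = "sscore"
        if data.probes is not None and data.probes.arrays:
            sst = SScoreTransformer()
            S = sst.fit(data.probes).transform(data.probes)
        else:
            # contract-preserving fallback when no probe-level data exists:
            # studentized log2 differences per strain
            diff = data.ethanol - data.saline
            S = (diff - diff.mean()) / diff.std(ddof=1)
        _write(S, out / "sscores.tsv", config)
        manifest["stages"]["sscore"] = {"strains": int(S.shape[1])}

        stage = "responsome"
        present = detection_proxy(
            pd.concat([data.saline, data.ethanol], axis=1),
            floor=config.detection_floor)
        retained = detection_filter(present, cutoff=config.detection_cutoff)
        rt = ResponsomeTest(n_permutations=config.responsome_permutations,
                            q_cutoff=config.q_cutoff,
                            random_state=seeds["responsome"])
        rt.fit(S.loc[retained])
        _write(rt.results_, out / "responsome.tsv", config)
        manifest["stages"]["responsome"] = {
            "retained": len(retained), "responsive": len(rt.responsive_)}

        stage = "networks"
        # networks are built on the differential-response (S-score) data:
        # edges reflect coordinated ethanol responses, the substrate of the
        # responsive-gene enrichment call
        px = ParacliqueExtractor(
            edge_threshold=config.edge_threshold,
            stringent_threshold=config.stringent_threshold,
            glom_factor=config.glom_factor, min_core=config.min_core,
            min_size=config.min_size)
        px.fit(S.loc[retained])
        members = px.member_table()
        if not members.empty:
            _write(members.set_index("probe_set"),
                   out / "paracliques.tsv", config)
        ergens = ergen_call(px.paracliques_, rt.responsive_, len(retained))
        _write(pd.DataFrame([vars(e) for e in ergens]
                            ).set_index("paraclique_id")
               if ergens else pd.DataFrame(),
               out / "ergen.tsv", config)
        manifest["stages"]["networks"] = {
            "paracliques": len(px.paracliques_),
            "enriched": sum(e.enriched for e in ergens)}

        stage = "eqtl"
        scans = {}
        for tag, matrix, skey in (("saline", data.saline.loc[retained],
                                   "eqtl_saline"),
                                  ("sscore", S.loc[retained], "eqtl_sscore")):
            sc = EqtlScanner(n_permutations=config.eqtl_permutations,
                             significant=config.significant,
                             suggestive=config.suggestive,
                             cis_window_mb=config.cis_window_mb,
                             lod_drop=config.lod_drop, dataset=tag,
                             random_state=seeds[skey])
            sc.fit(matrix, data.panel, data.annotation)
            scans[tag] = sc
            _write(sc.table_, out / f"eqtl_{tag}.tsv", config)
        manifest["stages"]["eqtl"] = {
            tag: {"significant": int((sc.table_["tier"] == "significant").sum()),
                  "suggestive": int(sc.table_["tier"].isin(
                      ["significant", "suggestive"]).sum())}
            for tag, sc in scans.items()}

        stage = "hotspots"
        suggestive_trans = [
            r for r in scans["sscore"].records_
            if r.tier in ("significant", "suggestive")
            and r.eqtl_class == "trans"]
        hd = HotspotDetector(bin_width_mb=config.bin_width_mb,
                             n_permutations=config.hotspot_permutations,
                             percentile=95.0,
                             consensus_inclusion=config.consensus_inclusion,
                             random_state=seeds["hotspots"])
        hd.fit(suggestive_trans, data.panel)
        for band in hd.transbands_:
            band.network = _dominant_network(band, px)
        band_rows = [{
            "chr": b.chromosome, "bin_start_mb": b.bin_start,
            "bin_end_mb": b.bin_end, "count": b.count,
            "threshold": b.threshold, "peak_marker": b.peak_marker,
            "network": b.network,
            "ci_start_mb": b.consensus[0] if b.consensus else np.nan,
            "ci_end_mb": b.consensus[1] if b.consensus else np.nan}
            for b in hd.transbands_]
        _write(pd.DataFrame(band_rows), out / "transbands.tsv", config)
        bio.write_bed_intervals(
            [(f"band_chr{b.chromosome}_{b.bin_start:g}", b.chromosome,
              *b.consensus) for b in hd.transbands_ if b.consensus],
            out / "transbands.bed")
        manifest["stages"]["hotspots"] = {
            "transbands": [[b.chromosome, b.bin_start] for b in hd.transbands_],
            "threshold": hd.threshold_}

        stage = "ranking"
        evidence = _build_evidence(data, scans, rt, px, config)
        cr = CandidateRanker(
            weights=RankWeights(**config.rank_weights)
            if config.rank_weights else None,
            significant=config.significant, suggestive=config.suggestive,
            q_cutoff=config.q_cutoff)
        if data.annotation is not None and hd.transbands_:
            cr.fit(data.annotation, evidence, hd.transbands_)
            for key, table in cr.rankings_.items():
                _write(table.set_index("gene"),
                       out / f"ranking_{key.replace(':', '_')}.tsv", config)
            manifest["stages"]["ranking"] = {
                key: list(t["gene"].head(3)) for key, t in cr.rankings_.items()}

        stage = "phenocorr"
        if not data.phenotypes.empty and hd.transbands_:
            band_expr = {}
            for b in hd.transbands_:
                traits = [r.trait for r in b.members]
                if len(traits) >= 2:
                    key = f"chr{b.chromosome}:{b.bin_start:g}"
                    band_expr[key] = data.saline.loc[traits]
            pa = PhenotypeAssociation(
                n_permutations=config.phenotype_permutations,
                alpha=config.pheno_alpha,
                random_state=seeds["phenocorr"])
            pa.fit(band_expr, data.phenotypes)
            _write(pa.edges_, out / "phenotype_correlations.tsv", config)
            manifest["stages"]["phenocorr"] = {
                "significant_edges": int(pa.edges_["significant"].sum())
                if not pa.edges_.empty else 0}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _dominant_network(band, extractor: ParacliqueExtractor) -> str | None:
    labels = extractor.labels_
    hits = [labels.get(r.trait) for r in band.members]
    hits = [h for h in hits if h is not None]
    if not hits:
        return None
    return pd.Series(hits).mode().iloc[0]


def _build_evidence(data, scans, rt: ResponsomeTest,
                    px: ParacliqueExtractor, config: RunConfig
                    ) -> dict[str, EvidenceBundle]:
    """Assemble per-gene evidence bundles from stage outputs and SNP tables."""
    snp = pd.read_csv(config.snp_table_path, sep="\t", index_col=0) \
        if config.snp_table_path else None
    topo = {}
    for P in px.paracliques_:
        for v in P.members:
            topo[v] = (P.id, P.scaled_degree.get(v, 0.0),
                       P.scaled_betweenness.get(v, 0.0))
    cis_p = {}
    for tag, sc in scans.items():
        for r in sc.records_:
            if r.eqtl_class == "cis":
                cis_p.setdefault(r.trait, {})[tag] = r.genome_p
    evidence = {}
    for gene in (data.annotation.index if data.annotation is not None else []):
        e = EvidenceBundle(gene=gene)
        if gene in cis_p:
            e.cis_saline_p = cis_p[gene].get("saline")
            e.cis_sscore_p = cis_p[gene].get("sscore")
        if gene in rt.results_.index:
            e.responsive_q = float(rt.results_.loc[gene, "q_value"])
        if gene in topo:
            e.network_membership, e.scaled_connectivity, e.scaled_centrality \
                = topo[gene]
        if snp is not None and gene in snp.index:
            row = snp.loc[gene]
            e.n_coding_snps = int(row.get("n_coding_snps", 0))
            e.n_nonsyn_snps = int(row.get("n_nonsyn_snps", 0))
            e.probe_has_snp = bool(row.get("probe_has_snp", False))
            e.b6_is_increaser = bool(row.get("b6_is_increaser", False))
        evidence[gene] = e
    return evidence
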