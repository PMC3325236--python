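"""Synthetic RI-panel data with planted, recoverable structure.

This module plays the role :mod:`sklearn.datasets`' ``make_*`` helpers play
for estimators: it generates genotypes for a recombinant-inbred family,
probe-level and summarized expression for a saline and an ethanol arm with
planted cis eQTL, trans master loci, co-expressed modules and
ethanol-response effects, and strain phenotypes driven by planted module
activity — together with a :class:`~bxdnet.datatypes.TruthRecord` so every
downstream stage can be tested for parameter recovery without any download.

Genotypes are simulated as independent two-state Markov chains along each
chromosome (the standard first-order model for an RI strain's genome mosaic);
recombination probabilities are specified directly per marker interval rather
than derived from a crossing design, since the pipeline consumes genotypes,
not breeding schemes.

Summarized log2 expression for gene *g* in strain *s* is

    x[g,s] = baseline[g] + a_cis[g]*geno[s, m_cis(g)]
             + a_trans[g]*geno[s, m_master] + sum_k load[g,k]*F[k,s]
             + N(0, noise_sd)

with the ethanol arm adding the planted response terms
``shift[g] + b[g]*geno[s, m(g)]``.  Module latent factors ``F[k,s]`` are
shared between the expression and phenotype generators (both derive them
deterministically from the truth record's seed), so phenotypes really are
driven by the same unobserved module activity that shapes the expression
correlations.

Probe-level intensities mimic Affymetrix probe effects without modelling
summarization internals: ``I = 2**x * affinity_j * exp(N(0, s))`` with
per-probe log-normal affinities (sigma = 0.5) held fixed across arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    ConfigurationError,
    GenotypePanel,
    MarkerMap,
    ProbeLevelArray,
    ProbeLevelExperiment,
    TruthRecord,
)

__all__ = [
    "make_genotypes",
    "make_expression",
    "make_phenotypes",
    "make_annotation",
    "default_truth",
    "make_dataset",
    "SimulatedDataset",
    "module_factors",
]

TREATMENTS = ("saline", "ethanol")

# entropy tags keeping the independent RNG streams of the generator apart
_TAG_FACTORS = 101
_TAG_AFFINITY = 202


def make_genotypes(n_strains: int, marker_map: MarkerMap,
                   recomb_per_interval, seed: int) -> GenotypePanel:
    """Simulate RI genotypes as two-state Markov chains along each chromosome.

    Parameters
    ----------
    n_strains : int
        Number of strains (>= 2).
    marker_map : MarkerMap
        Ordered marker map.
    recomb_per_interval : float or sequence of float
        Probability that adjacent markers disagree, one value per adjacent
        marker pair within a chromosome (``len(map) - n_chromosomes`` values),
        or a scalar applied to every interval.
    seed : int
        RNG seed.
    """
    if n_strains < 2:
        raise ConfigurationError("n_strains must be >= 2")
    slices = marker_map.chromosome_slices()
    n_intervals = sum(len(ix) - 1 for ix in slices.values())
    r = np.asarray(recomb_per_interval, dtype=float)
    if r.ndim == 0:
        r = np.full(n_intervals, float(r))
    if r.size != n_intervals:
        raise ConfigurationError(
            f"expected {n_intervals} recombination probabilities "
            f"(one per adjacent marker pair), got {r.size}")
    if np.any((r < 0) | (r > 1)):
        raise ConfigurationError("recombination probabilities must be in [0, 1]")

    rng = np.random.default_rng(seed)
    calls = np.empty((n_strains, len(marker_map)), dtype=np.int8)
    offset = 0
    for c in sorted(slices):
        idx = slices[c]
        k = len(idx)
        r_chr = r[offset:offset + k - 1]
        offset += k - 1
        state = rng.integers(0, 2, size=n_strains)
        calls[:, idx[0]] = state
        for j in range(1, k):
            flip = rng.random(n_strains) < r_chr[j - 1]
            state = np.where(flip, 1 - state, state)
            calls[:, idx[j]] = state
    strains = [f"RI{i + 1:03d}" for i in range(n_strains)]
    return GenotypePanel(strains, marker_map, calls)


def make_annotation(n_probe_sets: int, marker_map: MarkerMap,
                    seed: int) -> pd.DataFrame:
    """Probe-set -> gene annotation with uniform genomic placement.

    Returns a frame indexed by probe-set id with columns ``gene``, ``chr``
    and ``pos_mb``.  Probe-sets and genes are 1:1 in the synthetic setting.
    """
    rng = np.random.default_rng(seed)
    chrom_max = {c: marker_map.positions_mb[ix].max()
                 for c, ix in marker_map.chromosome_slices().items()}
    chrs = rng.choice(sorted(chrom_max), size=n_probe_sets)
    pos = np.array([rng.uniform(0, chrom_max[c]) for c in chrs])
    ids = [f"ps{i:05d}" for i in range(n_probe_sets)]
    return pd.DataFrame(
        {"gene": [f"Gene{i:05d}" for i in range(n_probe_sets)],
         "chr": chrs.astype(int), "pos_mb": pos},
        index=pd.Index(ids, name="probe_set"))


def module_factors(panel: GenotypePanel, truth: TruthRecord) -> dict[str, np.ndarray]:
    """Latent module activity per strain, derived from the truth seed only.

    Both :func:`make_expression` and :func:`make_phenotypes` call this, so
    the factor realizations they see are identical by construction.
    """
    out = {}
    for i, (name, mod) in enumerate(sorted(truth.modules.items())):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(truth.seed), _TAG_FACTORS, i]))
        out[name] = rng.normal(0.0, mod["factor_sd"], size=panel.n_strains)
    return out


def _marker_index(marker_map: MarkerMap) -> dict[str, int]:
    return {m: i for i, m in enumerate(marker_map.marker_ids)}


def make_expression(panel: GenotypePanel, annotation: pd.DataFrame,
                    truth: TruthRecord, noise_sd: float, seed: int,
                    probes_per_set: int = 11, probe_noise_sd: float = 0.1,
                    affinity_sd: float = 0.5, arm_noise_sd: float = 0.05,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, ProbeLevelExperiment]:
    """Simulate saline and ethanol expression plus probe-level arrays.

    ``noise_sd`` is gene x strain noise shared between a strain's two
    treatment arms (biological strain variation, which cancels out of the
    within-strain treatment comparison), while ``arm_noise_sd`` is the
    smaller arm-specific component (animal pooling and technical variation)
    that does contaminate the differential-response statistics.

    Returns ``(saline, ethanol, probe_experiment)`` where the first two are
    probe-set x strain log2 matrices and the third carries one probe-level
    array per strain x treatment.  ``probes_per_set=0`` skips probe-level
    generation (empty experiment).
    """
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be positive")
    truth.validate(annotation.index, panel.map)
    rng = np.random.default_rng(seed)
    genes = list(annotation.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    midx = _marker_index(panel.map)
    n_g, n_s = len(genes), panel.n_strains

    base = np.full(n_g, 8.0)
    for g, b in truth.baselines.items():
        base[gene_pos[g]] = b
    signal = np.tile(base[:, None], (1, n_s))

    for g, (marker, a) in truth.cis_effects.items():
        signal[gene_pos[g]] += a * panel.calls[:, midx[marker]]
    for marker, targets in truth.trans_masters.items():
        geno = panel.calls[:, midx[marker]]
        for g, a in targets.items():
            signal[gene_pos[g]] += a * geno

    factors = module_factors(panel, truth)
    for name, mod in truth.modules.items():
        f = factors[name]
        for g in mod["genes"]:
            signal[gene_pos[g]] += mod["loadings"][g] * f

    shared = signal + rng.normal(0.0, noise_sd, size=(n_g, n_s))
    saline = shared + rng.normal(0.0, arm_noise_sd, size=(n_g, n_s))
    response = np.zeros((n_g, n_s))
    for g, eff in truth.response_effects.items():
        shift = eff.get("baseline_shift", 0.0)
        row = np.full(n_s, shift)
        if eff.get("marker") is not None:
            row = row + eff.get("genotype_shift", 0.0) * panel.calls[:, midx[eff["marker"]]]
        response[gene_pos[g]] += row
    for name, mod in truth.modules.items():
        if mod.get("arm") == "ethanol":
            f = factors[name]
            for g in mod["genes"]:
                response[gene_pos[g]] += mod["loadings"][g] * f
    ethanol = shared + response + rng.normal(0.0, arm_noise_sd, size=(n_g, n_s))

    saline_df = pd.DataFrame(saline, index=genes, columns=panel.strains)
    ethanol_df = pd.DataFrame(ethanol, index=genes, columns=panel.strains)

    if probes_per_set == 0:
        return saline_df, ethanol_df, ProbeLevelExperiment({})

    # probe affinities: per probe, log-normal, fixed across all arrays
    arng = np.random.default_rng(
        np.random.SeedSequence([int(truth.seed), _TAG_AFFINITY]))
    affinity = np.exp(arng.normal(0.0, affinity_sd, size=(n_g, probes_per_set)))

    arrays: dict[tuple[str, str], ProbeLevelArray] = {}
    for t, mat in (("saline", saline), ("ethanol", ethanol)):
        for s_i, strain in enumerate(panel.strains):
            noise = np.exp(rng.normal(0.0, probe_noise_sd,
                                      size=(n_g, probes_per_set)))
            inten = (2.0 ** mat[:, s_i])[:, None] * affinity * noise
            arrays[(strain, t)] = ProbeLevelArray(genes, inten)
    return saline_df, ethanol_df, ProbeLevelExperiment(arrays)


def module_activity(panel: GenotypePanel, truth: TruthRecord
                    ) -> dict[str, np.ndarray]:
    """Total planted activity of each module per strain.

    Activity = latent factor plus the module-average genetic drive from any
    trans master locus targeting module members — the common signal the
    module's expression actually carries, and what planted phenotypes track.
    """
    act = module_factors(panel, truth)
    midx = _marker_index(panel.map)
    for name, mod in truth.modules.items():
        genes = mod["genes"]
        for marker, targets in truth.trans_masters.items():
            mean_eff = sum(targets.get(g, 0.0) for g in genes) / len(genes)
            if mean_eff:
                act[name] = act[name] + mean_eff * panel.calls[:, midx[marker]]
    return act


def make_phenotypes(panel: GenotypePanel, truth: TruthRecord,
                    n_phenotypes: int, seed: int,
                    noise_sd: float = 0.5) -> pd.DataFrame:
    """Phenotypes as linear combinations of planted module activity plus noise.

    Phenotypes beyond those named in ``truth.phenotype_coefficients`` are pure
    noise; at least one pure-noise phenotype is always included as a negative
    control.  Returns a phenotype x strain frame.
    """
    if n_phenotypes < 1:
        raise ConfigurationError("n_phenotypes must be >= 1")
    rng = np.random.default_rng(seed)
    factors = module_activity(panel, truth)
    names = list(truth.phenotype_coefficients)
    if len(names) >= n_phenotypes:
        # keep room for the pure-noise negative control
        names = names[:n_phenotypes - 1]
    rows, index = [], []
    for name in names:
        coeffs = truth.phenotype_coefficients[name]
        y = np.zeros(panel.n_strains)
        for mod, c in coeffs.items():
            y = y + c * factors[mod]
        rows.append(y + rng.normal(0.0, noise_sd, size=panel.n_strains))
        index.append(name)
    i = 0
    while len(rows) < n_phenotypes:
        rows.append(rng.normal(0.0, noise_sd, size=panel.n_strains))
        index.append(f"noise_phenotype_{i}")
        i += 1
    return pd.DataFrame(rows, index=index, columns=panel.strains)


def _nearest_marker(marker_map: MarkerMap, chrom: int, pos_mb: float) -> str:
    ix = marker_map.chromosome_slices()[int(chrom)]
    d = np.abs(marker_map.positions_mb[ix] - pos_mb)
    return marker_map.marker_ids[ix[int(np.argmin(d))]]


def default_truth(annotation: pd.DataFrame, marker_map: MarkerMap, seed: int,
                  n_modules: int = 3, module_size: int = 40,
                  factor_sd: float = 0.6, n_cis: int = 50,
                  cis_effect: float = 2.0, n_trans_targets: int = 30,
                  trans_effect: float = 1.0, n_responsive: int = 200,
                  response_shift: float = 0.2,
                  response_genotype_shift: float = 0.4) -> TruthRecord:
    """Assemble the default planted structure.

    One module ("M1") doubles as the target set of a trans master locus: its
    members receive both a basal trans effect and a genotype-dependent
    ethanol-response shift at the master marker, so the band is visible in
    the basal and in the differential-response (S-score) eQTL data and the
    module forms an S-score co-expression network.  An explicitly planted
    regulator gene sits at the master marker with a cis eQTL, a
    genotype-dependent ethanol response and module membership — the
    configuration the candidate-ranking stage is meant to recover.

    Defaults: with loading 1 and ``factor_sd`` twice the expression
    ``noise_sd`` of 0.3, the within-module population correlation is 0.8;
    a ``response_shift`` of 0.2 log2 units puts the mean |S-score| of a
    planted responder near 3 under the default probe error model.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    genes = list(annotation.index)
    needed = n_modules * module_size + n_cis + n_responsive + 1
    if len(genes) < needed:
        raise ConfigurationError(
            f"annotation has {len(genes)} genes but the planted structure "
            f"needs at least {needed}; shrink the planted counts")
    truth = TruthRecord(seed=int(seed))

    pool = rng.permutation(len(genes))
    cursor = 0

    def take(k):
        nonlocal cursor
        out = [genes[i] for i in pool[cursor:cursor + k]]
        cursor += k
        return out

    for m in range(n_modules):
        members = take(module_size)
        truth.modules[f"M{m + 1}"] = {
            "genes": members,
            "loadings": {g: 1.0 for g in members},
            "factor_sd": float(factor_sd),
            "arm": "both",
        }

    # master locus: middle marker of chromosome 2; M1 genes are its targets
    ix2 = marker_map.chromosome_slices()[2]
    master = marker_map.marker_ids[ix2[len(ix2) // 2]]
    m1 = truth.modules["M1"]["genes"]
    targets = m1[:n_trans_targets]
    truth.trans_masters[master] = {g: float(trans_effect) for g in targets}
    # genotype-dependent ethanol response of the module at the master locus:
    # this is what makes the trans-band visible in the S-score eQTL data
    for g in targets:
        truth.response_effects[g] = {
            "baseline_shift": 0.0, "marker": master,
            "genotype_shift": float(response_genotype_shift)}

    # the planted regulator: a gene at the master marker, in M1, cis-regulated,
    # ethanol-responsive (its own response is genotype-driven, as expected for
    # a cis-variable regulator)
    mpos = marker_map.positions_mb[marker_map.marker_ids.index(master)]
    mchr = int(marker_map.chromosomes[marker_map.marker_ids.index(master)])
    on_chr = annotation[(annotation["chr"] == mchr)
                        & (~annotation.index.isin(sum(
                            (mod["genes"] for mod in truth.modules.values()), [])))]
    regulator = (on_chr["pos_mb"] - mpos).abs().idxmin()
    truth.modules["M1"]["genes"].append(regulator)
    truth.modules["M1"]["loadings"][regulator] = 1.0
    truth.cis_effects[regulator] = (master, float(cis_effect))
    truth.response_effects[regulator] = {
        "baseline_shift": float(response_shift), "marker": master,
        "genotype_shift": float(response_genotype_shift)}

    planted = set(sum((mod["genes"] for mod in truth.modules.values()), []))
    n_cis_extra = n_resp_extra = 0
    for g in take(n_cis + n_responsive):
        if g in planted:
            continue
        if n_cis_extra < n_cis:
            row = annotation.loc[g]
            marker = _nearest_marker(marker_map, row["chr"], row["pos_mb"])
            truth.cis_effects[g] = (marker, float(cis_effect))
            n_cis_extra += 1
        elif n_resp_extra < n_responsive:
            truth.response_effects[g] = {
                "baseline_shift": float(response_shift) * (1 if rng.random() < 0.5 else -1),
                "marker": None, "genotype_shift": 0.0}
            n_resp_extra += 1

    truth.phenotype_coefficients = {
        "pheno_M1": {"M1": 1.0},
        "pheno_M2": {"M2": 1.0},
    }
    truth.baselines = {}
    return truth


@dataclass
class SimulatedDataset:
    """Everything one end-to-end run needs, plus the ground truth."""

    panel: GenotypePanel
    annotation: pd.DataFrame
    saline: pd.DataFrame
    ethanol: pd.DataFrame
    probes: ProbeLevelExperiment
    phenotypes: pd.DataFrame
    truth: TruthRecord


def make_dataset(seed: int, n_strains: int = 27, n_probe_sets: int = 2000,
                 n_chromosomes: int = 5, markers_per_chr: int = 20,
                 spacing_mb: float = 10.0, recomb: float = 0.25,
                 noise_sd: float = 0.3, n_phenotypes: int = 6,
                 with_probe_level: bool = True,
                 **truth_kwargs) -> SimulatedDataset:
    """One-call generator for the default study conditions.

    The default panel — 27 strains, 5 chromosomes x 20 markers at 10 Mb
    spacing, 2,000 probe-sets — mirrors the scale of a single-brain-region RI
    expression study while remaining desk-sized.
    """
    ss = np.random.SeedSequence(int(seed))
    s_geno, s_annot, s_expr, s_pheno = [int(c.generate_state(1)[0] % (2**31))
                                        for c in ss.spawn(4)]
    marker_map = MarkerMap.regular(n_chromosomes, markers_per_chr, spacing_mb)
    panel = make_genotypes(n_strains, marker_map, recomb, s_geno)
    annotation = make_annotation(n_probe_sets, marker_map, s_annot)
    truth = default_truth(annotation, marker_map, int(seed), **truth_kwargs)
    saline, ethanol, probes = make_expression(
        panel, annotation, truth, noise_sd, s_expr,
        probes_per_set=11 if with_probe_level else 0)
    phenotypes = make_phenotypes(panel, truth, n_phenotypes, s_pheno)
    return SimulatedDataset(panel, annotation, saline, ethanol, probes,
                            phenotypes, truth)
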