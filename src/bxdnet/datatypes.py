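"""Core data containers shared across pipeline stages.

The containers are deliberately thin: a marker map, a genotype panel for a
recombinant-inbred (RI) family, probe-level microarray intensities, and the
ground-truth record emitted by the synthetic-data generator.  Expression
matrices are plain :class:`pandas.DataFrame` objects (probe-sets as rows,
strains as columns) throughout the package.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "GenotypePanel",
    "ProbeLevelArray",
    "ProbeLevelExperiment",
    "TruthRecord",
    "ConfigurationError",
    "DataError",
]


class ConfigurationError(ValueError):
    """Invalid configuration (thresholds, counts, mismatched shapes)."""


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class MarkerMap:
    """Ordered genetic/physical map of markers.

    Parameters
    ----------
    marker_ids : sequence of str
        Unique marker identifiers, in map order.
    chromosomes : sequence of int
        Chromosome of each marker (small positive integers).
    positions_mb : sequence of float
        Physical position of each marker in megabases; strictly increasing
        within each chromosome.
    """

    def __init__(self, marker_ids: Sequence[str], chromosomes: Sequence[int],
                 positions_mb: Sequence[float]):
        marker_ids = list(map(str, marker_ids))
        chromosomes = np.asarray(chromosomes, dtype=int)
        positions_mb = np.asarray(positions_mb, dtype=float)
        if not (len(marker_ids) == len(chromosomes) == len(positions_mb)):
            raise ConfigurationError("marker_ids, chromosomes and positions_mb "
                                     "must have equal length")
        if len(set(marker_ids)) != len(marker_ids):
            raise ConfigurationError("marker_ids must be unique")
        if np.any(chromosomes < 1):
            raise ConfigurationError("chromosomes must be positive integers")
        if np.any(positions_mb < 0):
            raise ConfigurationError("positions_mb must be non-negative")
        for c in np.unique(chromosomes):
            pos = positions_mb[chromosomes == c]
            if np.any(np.diff(pos) <= 0):
                raise ConfigurationError(
                    f"positions must be strictly increasing on chromosome {c}")
        self.marker_ids = marker_ids
        self.chromosomes = chromosomes
        self.positions_mb = positions_mb

    def __len__(self) -> int:
        return len(self.marker_ids)

    def __eq__(self, other) -> bool:
        return (isinstance(other, MarkerMap)
                and self.marker_ids == other.marker_ids
                and np.array_equal(self.chromosomes, other.chromosomes)
                and np.allclose(self.positions_mb, other.positions_mb))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker": self.marker_ids,
            "chr": self.chromosomes,
            "pos_mb": self.positions_mb,
        })

    def chromosome_slices(self) -> dict[int, np.ndarray]:
        """Index arrays of markers per chromosome, in map order."""
        return {int(c): np.flatnonzero(self.chromosomes == c)
                for c in np.unique(self.chromosomes)}

    @classmethod
    def regular(cls, n_chromosomes: int = 5, markers_per_chr: int = 20,
                spacing_mb: float = 10.0) -> "MarkerMap":
        """Evenly spaced map: ``markers_per_chr`` markers every ``spacing_mb``."""
        ids, chrs, pos = [], [], []
        for c in range(1, n_chromosomes + 1):
            for i in range(markers_per_chr):
                ids.append(f"m{c:02d}_{i:03d}")
                chrs.append(c)
                pos.append(i * spacing_mb)
        return cls(ids, chrs, pos)


class GenotypePanel:
    """Biallelic RI genotypes: strains x markers with an ordered map.

    Calls are coded numerically (B=0, D=1) for regression; `calls_df` exposes
    the letter codes.
    """

    CODE_TO_LETTER = {0: "B", 1: "D"}

    def __init__(self, strains: Sequence[str], marker_map: MarkerMap,
                 calls: np.ndarray):
        calls = np.asarray(calls)
        if calls.shape != (len(strains), len(marker_map)):
            raise ConfigurationError(
                f"calls shape {calls.shape} does not match "
                f"{len(strains)} strains x {len(marker_map)} markers")
        if not np.isin(calls, (0, 1)).all():
            raise DataError("genotype calls must be coded 0 (B) or 1 (D)")
        self.strains = list(map(str, strains))
        self.map = marker_map
        self.calls = calls.astype(np.int8)
        if len(self.strains) >= 10:
            freq = self.calls.mean(axis=0)
            bad = np.flatnonzero((freq <= 0) | (freq >= 1))
            if bad.size:
                warnings.warn(
                    f"{bad.size} monomorphic marker(s) in a panel of "
                    f"{len(self.strains)} strains", stacklevel=2)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def calls_df(self) -> pd.DataFrame:
        letters = np.vectorize(self.CODE_TO_LETTER.get)(self.calls)
        return pd.DataFrame(letters, index=self.strains,
                            columns=self.map.marker_ids)

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenotypePanel)
                and self.strains == other.strains
                and self.map == other.map
                and np.array_equal(self.calls, other.calls))


class ProbeLevelArray:
    """One microarray: per-probe-set vectors of linear-scale probe intensities.

    Intensities are stored as a dense (n_probe_sets, n_probes) matrix; every
    probe-set carries the same number of probes (Affymetrix-style, default 11).
    """

    def __init__(self, probe_set_ids: Sequence[str], intensities: np.ndarray):
        intensities = np.asarray(intensities, dtype=float)
        if intensities.ndim != 2:
            raise DataError("intensities must be 2-D (probe-sets x probes)")
        if len(probe_set_ids) != intensities.shape[0]:
            raise DataError("probe_set_ids length does not match intensities")
        if not np.all(intensities > 0):
            raise DataError("probe intensities must be strictly positive")
        self.probe_set_ids = list(map(str, probe_set_ids))
        self.intensities = intensities

    @property
    def probes_per_set(self) -> int:
        return self.intensities.shape[1]


@dataclass
class ProbeLevelExperiment:
    """Collection of probe-level arrays keyed by (strain, treatment)."""

    arrays: dict[tuple[str, str], ProbeLevelArray]

    @property
    def strains(self) -> list[str]:
        seen: dict[str, None] = {}
        for strain, _ in self.arrays:
            seen.setdefault(strain, None)
        return list(seen)

    def get(self, strain: str, treatment: str) -> ProbeLevelArray:
        return self.arrays[(strain, treatment)]


@dataclass
class TruthRecord:
    """Ground truth planted by the synthetic-data generator.

    Attributes
    ----------
    cis_effects : dict
        gene -> (marker_id, additive effect in log2 units).
    trans_masters : dict
        marker_id -> {gene: effect} mapping of master-locus targets.
    modules : dict
        module name -> {"genes": [...], "loadings": {gene: loading},
        "factor_sd": float}.
    response_effects : dict
        gene -> {"baseline_shift": float, "marker": str | None,
        "genotype_shift": float}; the ethanol arm adds baseline_shift plus
        genotype_shift * genotype(marker).
    phenotype_coefficients : dict
        phenotype -> {module name: coefficient}; empty dict = pure noise.
    seed : int
        RNG seed the generator was called with.
    """

    cis_effects: dict = field(default_factory=dict)
    trans_masters: dict = field(default_factory=dict)
    modules: dict = field(default_factory=dict)
    response_effects: dict = field(default_factory=dict)
    phenotype_coefficients: dict = field(default_factory=dict)
    baselines: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self, gene_ids: Sequence[str], marker_map: MarkerMap) -> None:
        genes = set(gene_ids)
        markers = set(marker_map.marker_ids)
        for gene, (marker, _) in self.cis_effects.items():
            if gene not in genes:
                raise ConfigurationError(f"planted cis gene {gene!r} not in annotation")
            if marker not in markers:
                raise ConfigurationError(f"planted cis marker {marker!r} not in map")
        for marker, targets in self.trans_masters.items():
            if marker not in markers:
                raise ConfigurationError(f"planted trans marker {marker!r} not in map")
            missing = set(targets) - genes
            if missing:
                raise ConfigurationError(f"planted trans targets missing: {missing}")
        for name, mod in self.modules.items():
            missing = set(mod["genes"]) - genes
            if missing:
                raise ConfigurationError(f"module {name} genes missing: {missing}")
        for gene, eff in self.response_effects.items():
            if gene not in genes:
                raise ConfigurationError(f"response gene {gene!r} not in annotation")
            if eff.get("marker") is not None and eff["marker"] not in markers:
                raise ConfigurationError(f"response marker {eff['marker']!r} not in map")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        d["cis_effects"] = {g: tuple(v) for g, v in d.get("cis_effects", {}).items()}
        return cls(**d)
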