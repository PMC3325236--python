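"""Readers and writers for the pipeline's on-disk formats.

Genotypes use the GeneNetwork ``.geno`` dialect: ``@``-prefixed metadata
lines, a header row (Chr, Locus, cM, Mb, then strain names) and one row per
marker with single-letter parental codes.  Expression and phenotype
matrices are tab-delimited with row identifiers in the first column.
Probe-level intensities travel as a long-format table.  All writers
round-trip exactly through the matching reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (DataError, GenotypePanel, MarkerMap, ProbeLevelArray,
                        ProbeLevelExperiment)

__all__ = [
    "write_geno", "read_geno",
    "write_expression", "read_expression",
    "write_probe_level", "read_probe_level",
    "write_bed_intervals",
]

_LETTER_TO_CODE = {"B": 0, "D": 1}


def write_geno(panel: GenotypePanel, path, name: str = "synthetic",
               maternal: str = "B6", paternal: str = "D2") -> None:
    """Write a panel in GeneNetwork .geno layout (cM mirrored from Mb)."""
    m = panel.map
    with open(path, "w") as fh:
        fh.write(f"@name:{name}\n@type:riset\n")
        fh.write(f"@mat:{maternal}\n@pat:{paternal}\n")
        fh.write("Chr\tLocus\tcM\tMb\t" + "\t".join(panel.strains) + "\n")
        letters = panel.calls_df
        for j, marker in enumerate(m.marker_ids):
            row = letters[marker]
            fh.write(f"{m.chromosomes[j]}\t{marker}\t{m.positions_mb[j]:g}\t"
                     f"{m.positions_mb[j]:g}\t"
                     + "\t".join(row[s] for s in panel.strains) + "\n")


def read_geno(path) -> GenotypePanel:
    """Parse a GeneNetwork-style .geno file; unknown codes are rejected."""
    strains: list[str] = []
    markers, chroms, pos, rows = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("@", "#")):
                continue
            fields = line.split("\t")
            if not strains:
                if fields[:4] != ["Chr", "Locus", "cM", "Mb"]:
                    raise DataError(f"line {lineno}: unexpected header "
                                    f"{fields[:4]}")
                strains = fields[4:]
                continue
            if len(fields) != 4 + len(strains):
                raise DataError(f"line {lineno}: expected "
                                f"{4 + len(strains)} fields, got {len(fields)}")
            chrom, locus, _cm, mb = fields[:4]
            calls = []
            for s, letter in zip(strains, fields[4:]):
                if letter not in _LETTER_TO_CODE:
                    raise DataError(f"line {lineno}: unknown genotype code "
                                    f"{letter!r} for strain {s}")
                calls.append(_LETTER_TO_CODE[letter])
            markers.append(locus)
            chroms.append(int(chrom))
            pos.append(float(mb))
            rows.append(calls)
    if not rows:
        raise DataError("no marker rows found")
    mmap = MarkerMap(markers, chroms, pos)
    return GenotypePanel(strains, mmap, np.array(rows).T)


def write_expression(expr: pd.DataFrame, path, comment: str | None = None
                     ) -> None:
    """Tab-delimited probe-set x strain matrix, optional # header comment."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        expr.rename_axis("probe_set").to_csv(fh, sep="\t")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise DataError(f"duplicated probe-set id(s): {dup}")
    return df


def write_probe_level(experiment: ProbeLevelExperiment, path) -> None:
    """Long-format table: probe_set_id, probe_index, strain, treatment, intensity."""
    with open(path, "w") as fh:
        fh.write("probe_set_id\tprobe_index\tstrain\ttreatment\tintensity\n")
        for (strain, treatment), arr in experiment.arrays.items():
            for i, ps in enumerate(arr.probe_set_ids):
                for j in range(arr.probes_per_set):
                    fh.write(f"{ps}\t{j}\t{strain}\t{treatment}\t"
                             f"{arr.intensities[i, j]:.6g}\n")


def read_probe_level(path) -> ProbeLevelExperiment:
    df = pd.read_csv(path, sep="\t")
    arrays = {}
    for (strain, treatment), grp in df.groupby(["strain", "treatment"],
                                               sort=False):
        wide = grp.pivot(index="probe_set_id", columns="probe_index",
                         values="intensity")
        if wide.isna().any().any():
            raise DataError(f"unequal probe counts in array "
                            f"({strain}, {treatment})")
        arrays[(str(strain), str(treatment))] = ProbeLevelArray(
            list(wide.index), wide.to_numpy())
    return ProbeLevelExperiment(arrays)


def write_bed_intervals(intervals: list[tuple[str, int, float, float]],
                        path) -> None:
    """BED (0-based half-open, Mb -> bp) export of named genomic intervals.

    ``intervals`` holds (name, chr, start_mb, end_mb) tuples.
    """
    with open(path, "w") as fh:
        for name, chrom, start, end in intervals:
            fh.write(f"chr{chrom}\t{int(round(start * 1e6))}\t"
                     f"{int(round(end * 1e6))}\t{name}\n")
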