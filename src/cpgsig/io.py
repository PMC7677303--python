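"""Readers, writers and validated containers for the pipeline's tabular data.

Three inputs are consumed: a sites x samples beta-value matrix (plain TSV or
the GEO series-matrix text dialect), a two-column sample-label table, and a
four-column probe-annotation table (probe, chromosome, 1-based coordinate,
gene symbol or "-").  All outputs are TSV with headers; numeric fields are
written at 12 significant digits so that every writer/reader pair round-trips
exactly at tested precision.

Sites with any missing beta value are dropped (never imputed) and the count
is logged at INFO level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % float(x)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BetaMatrix:
    """Methylation beta values, one row per CpG probe, one column per sample.

    Every value must lie in [0, 1]; probe and sample identifiers must be
    unique.  Column order is authoritative for sample order downstream.
    """

    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
                raise ValueError(f"duplicate {name} ID: {dup!r}")
        if values.size and (np.isnan(values).any()):
            raise ValueError("beta matrix contains missing values")
        if values.size:
            bad = np.argwhere((values < 0.0) | (values > 1.0))
            if bad.size:
                i, j = bad[0]
                raise ValueError(
                    f"beta value out of [0, 1]: probe {self.probe_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}, value {values[i, j]!r}"
                )
        if len(self.probe_ids) == 0:
            raise ValueError("beta matrix has no sites")

    @property
    def n_sites(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def restrict(self, probes: list[str] | tuple[str, ...]) -> "BetaMatrix":
        """Return the sub-matrix for the given probes, in the given order."""
        index = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probes if p not in index]
        if missing:
            raise KeyError(f"unknown probe(s): {missing[:5]}")
        rows = [index[p] for p in probes]
        return BetaMatrix(tuple(probes), self.sample_ids, self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.probe_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class ClassLabels:
    """Mapping from sample ID to class name; class order is first appearance."""

    labels: Mapping[str, str]
    class_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        labels = dict(self.labels)
        object.__setattr__(self, "labels", labels)
        names = self.class_names or tuple(dict.fromkeys(labels.values()))
        object.__setattr__(self, "class_names", tuple(names))
        if len(self.class_names) < 2:
            raise ValueError("need at least 2 classes")
        unknown = set(labels.values()) - set(self.class_names)
        if unknown:
            raise ValueError(f"labels outside declared classes: {sorted(unknown)}")
        counts = self.class_sizes()
        empty = [c for c, n in counts.items() if n == 0]
        if empty:
            raise ValueError(f"class(es) with no samples: {empty}")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_sizes(self) -> dict[str, int]:
        counts = {c: 0 for c in self.class_names}
        for c in self.labels.values():
            counts[c] += 1
        return counts

    def for_samples(self, sample_ids: tuple[str, ...] | list[str]) -> list[str]:
        """Class name per sample, in the matrix's sample order."""
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise KeyError(f"unlabelled sample(s): {missing[:5]}")
        return [self.labels[s] for s in sample_ids]

    def encode(self, sample_ids: tuple[str, ...] | list[str]) -> np.ndarray:
        """Integer class codes per sample (order of ``class_names``)."""
        code = {c: k for k, c in enumerate(self.class_names)}
        return np.array([code[c] for c in self.for_samples(sample_ids)], dtype=np.int64)


@dataclass(frozen=True)
class ProbeRecord:
    chromosome: str
    coordinate: int
    gene: str

    def __post_init__(self) -> None:
        if self.coordinate < 1:
            raise ValueError(f"coordinate must be >= 1, got {self.coordinate}")


@dataclass(frozen=True)
class ProbeAnnotation:
    """Partial map probe ID -> genomic annotation (hg19-style 1-based coords)."""

    records: Mapping[str, ProbeRecord]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", dict(self.records))

    def lookup(self, probe_id: str) -> ProbeRecord | None:
        """Annotation for a probe, or None when the probe is not annotated."""
        return self.records.get(probe_id)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# input readers
# ---------------------------------------------------------------------------


def _parse_beta_frame(frame: pd.DataFrame) -> BetaMatrix:
    probe_col = frame.columns[0]
    probes = frame[probe_col].astype(str)
    dup = probes[probes.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate probe ID: {dup.iloc[0]!r}")
    samples = tuple(str(c) for c in frame.columns[1:])
    values = frame.drop(columns=[probe_col]).apply(pd.to_numeric, errors="coerce")
    keep = ~values.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%d site(s) dropped for missing values", n_dropped)
    values = values[keep]
    probes = probes[keep]
    if values.empty:
        raise ValueError("no sites remain after dropping rows with missing values")
    arr = values.to_numpy(dtype=float)
    bad = np.argwhere((arr < 0.0) | (arr > 1.0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"beta value out of [0, 1]: probe {probes.iloc[i]!r}, "
            f"sample {samples[j]!r}, value {arr[i, j]}"
        )
    return BetaMatrix(tuple(probes), samples, arr)


def _read_geo_series_matrix(path: Path) -> pd.DataFrame:
    """Extract the data table from a GEO series-matrix text file.

    Metadata lines start with "!"; the table sits between the
    "!series_matrix_table_begin" and "!series_matrix_table_end" markers.
    """
    lines = path.read_text().splitlines()
    try:
        start = next(
            i for i, ln in enumerate(lines) if ln.startswith("!series_matrix_table_begin")
        )
        end = next(
            i for i, ln in enumerate(lines) if ln.startswith("!series_matrix_table_end")
        )
    except StopIteration:
        raise ValueError(f"{path}: series_matrix_table markers not found") from None
    table = [ln.replace('"', "") for ln in lines[start + 1 : end] if ln.strip()]
    from io import StringIO

    return pd.read_csv(StringIO("\n".join(table)), sep="\t")


def read_beta_matrix(path: str | Path, dialect: str = "tsv") -> BetaMatrix:
    """Read a beta-value matrix.

    Parameters
    ----------
    path
        TSV file whose first column is the probe ID and whose header row
        holds sample IDs, or a GEO series-matrix text file.
    dialect
        "tsv" (default) or "geo_series_matrix".
    """
    path = Path(path)
    if dialect == "tsv":
        frame = pd.read_csv(path, sep="\t")
    elif dialect == "geo_series_matrix":
        frame = _read_geo_series_matrix(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _parse_beta_frame(frame)


def read_labels(path: str | Path) -> ClassLabels:
    """Read a two-column (sample_id, class) TSV with header."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, class)")
    sample_col, class_col = frame.columns[:2]
    dup = frame[sample_col][frame[sample_col].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample ID: {dup.iloc[0]!r}")
    labels = dict(zip(frame[sample_col], frame[class_col]))
    return ClassLabels(labels, tuple(dict.fromkeys(frame[class_col])))


def read_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a (probe_id, chromosome, coordinate, gene) TSV with header."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 4:
        raise ValueError(f"{path}: expected four columns")
    probe_col = frame.columns[0]
    dup = frame[probe_col][frame[probe_col].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate probe ID in annotation: {dup.iloc[0]!r}")
    records = {}
    for _, row in frame.iterrows():
        records[str(row.iloc[0])] = ProbeRecord(
            chromosome=str(row.iloc[1]),
            coordinate=int(row.iloc[2]),
            gene=str(row.iloc[3]),
        )
    return ProbeAnnotation(records)


# ---------------------------------------------------------------------------
# output writers / readers (round-trip safe)
# ---------------------------------------------------------------------------


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for probe, row in zip(matrix.probe_ids, matrix.values):
            fh.write(probe + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def write_labels(labels: ClassLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tclass\n")
        for sample, cls in labels.labels.items():
            fh.write(f"{sample}\t{cls}\n")


def write_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tchromosome\tcoordinate\tgene\n")
        for probe, rec in annotation.records.items():
            fh.write(f"{probe}\t{rec.chromosome}\t{rec.coordinate}\t{rec.gene}\n")


def write_ranking(ranking, path: str | Path) -> None:
    """Write an mRMR ranking as (rank, probe_id, score) TSV."""
    with open(path, "w") as fh:
        fh.write("rank\tprobe_id\tscore\n")
        for rank, (probe, score) in enumerate(ranking.entries, start=1):
            fh.write(f"{rank}\t{probe}\t{_fmt(score)}\n")


def read_ranking(path: str | Path):
    from .mrmr import MRMRRanking

    frame = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    entries = tuple(
        (str(p), float(s)) for p, s in zip(frame["probe_id"], frame["score"])
    )
    return MRMRRanking(entries=entries)


def write_curve(curve, path: str | Path) -> None:
    """Write an IFS curve as (r, accuracy) TSV; empty curves are rejected."""
    if not curve.points:
        raise ValueError("cannot write an empty IFS curve")
    with open(path, "w") as fh:
        fh.write("r\taccuracy\n")
        for r, acc in curve.points:
            fh.write(f"{r}\t{_fmt(acc)}\n")


def read_curve(path: str | Path):
    from .ifs import IFSCurve

    frame = pd.read_csv(path, sep="\t")
    return IFSCurve(points=tuple((int(r), float(a)) for r, a in zip(frame["r"], frame["accuracy"])))


def write_signature(table, path: str | Path) -> None:
    """Write a signature table with the canonical column order."""
    with open(path, "w") as fh:
        fh.write("rank\tprobe_id\tchromosome\tcoordinate\tgene\tscore\n")
        for row in table.rows:
            coord = "" if row.coordinate is None else str(row.coordinate)
            fh.write(
                f"{row.rank}\t{row.probe_id}\t{row.chromosome}\t{coord}\t"
                f"{row.gene}\t{_fmt(row.score)}\n"
            )


def read_signature(path: str | Path):
    from .report import SignatureRow, SignatureTable

    frame = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str, "gene": str})
    rows = []
    for _, r in frame.iterrows():
        coord = r["coordinate"]
        coordinate = None if pd.isna(coord) else int(coord)
        chrom = "" if pd.isna(r["chromosome"]) else str(r["chromosome"])
        rows.append(
            SignatureRow(
                rank=int(r["rank"]),
                probe_id=str(r["probe_id"]),
                chromosome=chrom,
                coordinate=coordinate,
                gene=str(r["gene"]),
                score=float(r["score"]),
            )
        )
    return SignatureTable(rows=tuple(rows))
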