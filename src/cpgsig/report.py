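"""Result surfaces: annotated signature table, per-class methylation
summaries, hypermethylation counts, and row-scaled values with sample
clustering for heatmap rendering.

"Hypermethylated in class X" is operationalized as a strictly greater mean
raw beta value in X than in the comparison class; ties (exact equality) are
counted separately so the three counts always partition the site set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .io import BetaMatrix, ClassLabels, ProbeAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureRow:
    rank: int
    probe_id: str
    chromosome: str
    coordinate: int | None
    gene: str
    score: float


@dataclass(frozen=True)
class SignatureTable:
    """Annotated signature sites in ranking order (ranks 1..n contiguous)."""

    rows: tuple[SignatureRow, ...]

    def __post_init__(self) -> None:
        for k, row in enumerate(self.rows, start=1):
            if row.rank != k:
                raise ValueError("signature ranks must be 1..n contiguous")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(r.probe_id for r in self.rows)


@dataclass(frozen=True)
class ClassSummary:
    """Mean beta per (site, class), plus each site's maximal-mean class."""

    means: pd.DataFrame  # index = probe, columns = class names
    top_class: pd.Series

    def mean(self, probe_id: str, class_name: str) -> float:
        return float(self.means.at[probe_id, class_name])


def annotate_signature(ranking_prefix, annotation: ProbeAnnotation) -> SignatureTable:
    """Join ranked (probe, score) pairs to their genomic annotation.

    Probes missing from the annotation get blank chromosome/coordinate and
    gene "-" with a logged warning — partial manifests are tolerated.
    """
    rows = []
    for rank, (probe, score) in enumerate(ranking_prefix, start=1):
        rec = annotation.lookup(probe)
        if rec is None:
            logger.warning("probe %s not annotated", probe)
            rows.append(SignatureRow(rank, probe, "", None, "-", float(score)))
        else:
            rows.append(
                SignatureRow(rank, probe, rec.chromosome, rec.coordinate, rec.gene, float(score))
            )
    return SignatureTable(rows=tuple(rows))


def class_means(
    matrix: BetaMatrix, labels: ClassLabels, sites: list[str] | tuple[str, ...]
) -> ClassSummary:
    """Arithmetic mean beta per selected site per class (raw beta scale)."""
    sub = matrix.restrict(list(sites))
    y = np.array(labels.for_samples(sub.sample_ids))
    means = pd.DataFrame(
        {
            cls: sub.values[:, y == cls].mean(axis=1)
            for cls in labels.class_names
        },
        index=list(sub.probe_ids),
    )
    return ClassSummary(means=means, top_class=means.idxmax(axis=1))


def hypermethylation_count(
    summary: ClassSummary, class_a: str, class_b: str
) -> tuple[int, int, int]:
    """Sites mean-higher in a, mean-higher in b, and exactly tied.

    The three counts always sum to the number of summarized sites.
    """
    for cls in (class_a, class_b):
        if cls not in summary.means.columns:
            raise KeyError(f"unknown class {cls!r}")
    a = summary.means[class_a].to_numpy()
    b = summary.means[class_b].to_numpy()
    return int((a > b).sum()), int((b > a).sum()), int((a == b).sum())


def scale_rows(matrix: BetaMatrix) -> np.ndarray:
    """Per-site z-scores (ddof=1); zero-variance sites map to all zeros."""
    if matrix.n_samples < 2:
        raise ValueError("scaling needs at least 2 samples")
    v = matrix.values
    m = v.mean(axis=1, keepdims=True)
    s = v.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(v)
    np.divide(v - m, s, out=out, where=s > 0)
    return out


def cluster_samples(scaled: np.ndarray) -> tuple[list[int], np.ndarray | None]:
    """Average-linkage hierarchical clustering of sample columns.

    Returns the dendrogram leaf order (column indices) and the scipy merge
    tree; a single sample yields ([0], None).  Euclidean distance on the
    row-scaled values, deterministic given the input.
    """
    scaled = np.asarray(scaled, dtype=float)
    n_samples = scaled.shape[1]
    if n_samples == 1:
        return [0], None
    dist = pdist(scaled.T, metric="euclidean")
    tree = linkage(dist, method="average")
    return [int(i) for i in leaves_list(tree)], tree


def cut_tree_k(tree: np.ndarray, n_samples: int, k: int) -> np.ndarray:
    """Flat cluster assignment from cutting the merge tree into k groups."""
    from scipy.cluster.hierarchy import fcluster

    return fcluster(tree, t=k, criterion="maxclust")


def plot_heatmap(
    scaled: np.ndarray,
    probe_ids,
    sample_ids,
    sample_order: list[int],
    path,
) -> None:
    """Optional figure: row-scaled values with samples in dendrogram order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = scaled[:, sample_order]
    fig, ax = plt.subplots(
        figsize=(max(6, 0.12 * len(sample_order)), max(3, 0.3 * len(probe_ids)))
    )
    im = ax.imshow(ordered, aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_yticks(range(len(probe_ids)), labels=list(probe_ids), fontsize=7)
    ax.set_xticks(range(len(sample_order)), labels=[sample_ids[i] for i in sample_order],
                  rotation=90, fontsize=5)
    fig.colorbar(im, ax=ax, label="scaled methylation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
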