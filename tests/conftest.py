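"""Shared fixtures: brute-force oracles, small fixture files, seeded datasets."""

from __future__ import annotations

from collections import Counter
from math import log

import numpy as np
import pytest

from cpgsig.simulate import SyntheticSpec, generate_dataset

# the published 12-site osteoarthritis signature (hg19 coordinates) used as a
# small real-world annotation fixture
TABLE1_ROWS = [
    # (rank, probe, chromosome, coordinate, gene, score)
    (1, "cg09462924", "2", 66666470, "MEIS1", 0.943),
    (2, "cg22118147", "5", 172144013, "-", 0.263),
    (3, "cg18576667", "15", 27597409, "GABRG3", 0.328),
    (4, "cg07533951", "12", 114879558, "-", 0.284),
    (5, "cg14545975", "9", 137297213, "RXRA", 0.245),
    (6, "cg05877497", "2", 66667946, "MEIS1", 0.264),
    (7, "cg21811143", "2", 119599748, "EN1", 0.219),
    (8, "cg09989996", "1", 753376, "FAM87B", 0.235),
    (9, "cg19738283", "2", 176976802, "HOXD10", 0.244),
    (10, "cg02824888", "12", 115129011, "-", 0.226),
    (11, "cg04288999", "2", 66667852, "MEIS1", 0.238),
    (12, "cg00995986", "2", 66665428, "MEIS1", 0.214),
]

# probes reported hypermethylated in OA knee (9) vs OA hip (3)
KNEE_HYPER = {
    "cg21811143", "cg19738283", "cg00995986", "cg09462924", "cg05877497",
    "cg04288999", "cg07533951", "cg14545975", "cg02824888",
}
HIP_HYPER = {"cg18576667", "cg22118147", "cg09989996"}


def mi_bruteforce(a, b, base: float = 2.0) -> float:
    """Independent full-contingency-table mutual information (pure Python)."""
    a, b = list(a), list(b)
    n = len(a)
    joint = Counter(zip(a, b))
    pa = Counter(a)
    pb = Counter(b)
    total = 0.0
    for (x, y), c in joint.items():
        pxy = c / n
        total += pxy * log(pxy / ((pa[x] / n) * (pb[y] / n)))
    return total / log(base)


@pytest.fixture
def mi_oracle():
    return mi_bruteforce


@pytest.fixture
def annotation_file(tmp_path):
    """Annotation TSV of the published 12-probe signature."""
    path = tmp_path / "annotation.tsv"
    lines = ["probe_id\tchromosome\tcoordinate\tgene"]
    for _, probe, chrom, coord, gene, _ in TABLE1_ROWS:
        lines.append(f"{probe}\t{chrom}\t{coord}\t{gene}")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def small_matrix_file(tmp_path):
    """3 probes x 4 samples, all values in [0, 1]."""
    path = tmp_path / "matrix.tsv"
    path.write_text(
        "probe_id\ts1\ts2\ts3\ts4\n"
        "cgA\t0.1\t0.2\t0.8\t0.9\n"
        "cgB\t0.5\t0.5\t0.5\t0.5\n"
        "cgC\t0.3\t0.7\t0.4\t0.6\n"
    )
    return path


@pytest.fixture(scope="session")
def recovery_dataset():
    """The planted-signal recovery instance used across mRMR/IFS tests."""
    return generate_dataset(
        SyntheticSpec(
            n_per_class=(20, 20, 20),
            n_sites=1000,
            n_informative=10,
            block_copies=2,
            effect=2.0,
            noise_sd=0.5,
            seed=7,
        )
    )


def permute_labels(labels, rng):
    """ClassLabels with the same samples but a permuted class assignment."""
    from cpgsig.io import ClassLabels

    samples = list(labels.labels.keys())
    classes = list(labels.labels.values())
    perm = rng.permutation(len(classes))
    return ClassLabels(
        {s: classes[p] for s, p in zip(samples, perm)}, labels.class_names
    )
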