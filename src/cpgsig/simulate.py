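"""Synthetic three-class methylation data with planted signal and redundancy.

The generator emulates a normalized 450K-style beta-value matrix over K
disease/tissue classes: a handful of informative CpG sites whose class means
are shifted on the logit scale, near-duplicate "redundant" copies of each
informative site (the regime an mRMR redundancy penalty is designed to
punish), and a majority of null sites with no class structure.

Generative model, per sample s in class c:

* informative site i:  beta = expit(logit(b0) + effect * offset_c + e),
  e ~ N(0, noise_sd), offsets (class_index - (K-1)/2) so K=3 gives
  (-1, 0, +1);
* redundant copy of i: parent's logit value + N(0, noise_sd / 4), re-squashed;
* null site:           expit(logit(b0) + e).

All values therefore stay strictly inside (0, 1), and identical specs
(including the seed) produce bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .io import BetaMatrix, ClassLabels

#: class sizes of the cartilage study this generator stands in for
#: (OA hip, control hip, OA knee)
DEFAULT_CLASS_SIZES = (16, 19, 62)
DEFAULT_CLASS_NAMES = ("OA_hip", "control_hip", "OA_knee")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic beta-matrix generator.

    ``effect`` is the between-class shift per unit class offset on the logit
    scale; ``noise_sd`` the within-class logit-scale standard deviation.
    """

    n_per_class: tuple[int, ...] = DEFAULT_CLASS_SIZES
    n_sites: int = 2000
    n_informative: int = 10
    block_copies: int = 2
    effect: float = 2.0
    noise_sd: float = 0.5
    baseline_mean: float = 0.5
    seed: int = 0
    class_names: tuple[str, ...] = field(default=())
    randomize_ids: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_per_class", tuple(int(n) for n in self.n_per_class))
        if len(self.n_per_class) < 2 or any(n < 1 for n in self.n_per_class):
            raise ValueError("n_per_class must hold >= 2 positive counts")
        if self.n_sites < 1 or self.n_informative < 0 or self.block_copies < 0:
            raise ValueError("count fields must be non-negative (n_sites >= 1)")
        if self.n_informative * (1 + self.block_copies) > self.n_sites:
            raise ValueError(
                "n_informative * (1 + block_copies) exceeds n_sites"
            )
        if self.effect <= 0 or self.noise_sd <= 0:
            raise ValueError("effect and noise_sd must be > 0")
        if not 0.0 < self.baseline_mean < 1.0:
            raise ValueError("baseline_mean must lie in (0, 1)")
        names = self.class_names or tuple(
            DEFAULT_CLASS_NAMES[k] if len(self.n_per_class) == 3 else f"class_{k}"
            for k in range(len(self.n_per_class))
        )
        if len(names) != len(self.n_per_class):
            raise ValueError("class_names length must match n_per_class")
        object.__setattr__(self, "class_names", tuple(names))

    @property
    def n_classes(self) -> int:
        return len(self.n_per_class)

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_class)


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated matrix + labels together with the planted ground truth."""

    matrix: BetaMatrix
    labels: ClassLabels
    truth_informative: frozenset[str]
    truth_blocks: dict[str, frozenset[str]]


def class_offsets(n_classes: int) -> np.ndarray:
    """Symmetric per-class logit offsets, class_index - (K-1)/2."""
    return np.arange(n_classes, dtype=float) - (n_classes - 1) / 2.0


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset from the generative model described in the module docs."""
    rng = np.random.default_rng(spec.seed)
    K = spec.n_classes
    n = spec.n_samples
    offsets = class_offsets(K)
    y = np.repeat(np.arange(K), spec.n_per_class)
    base = logit(spec.baseline_mean)

    n_inf = spec.n_informative
    n_cop = n_inf * spec.block_copies
    n_null = spec.n_sites - n_inf - n_cop

    probe_ids: list[str] = []
    rows = np.empty((spec.n_sites, n), dtype=float)
    truth_blocks: dict[str, frozenset[str]] = {}

    r = 0
    for i in range(n_inf):
        mu = base + spec.effect * offsets[y]
        z = mu + rng.normal(0.0, spec.noise_sd, size=n)
        rows[r] = z
        probe_ids.append(f"inf_{i}")
        copies = []
        for j in range(spec.block_copies):
            rows[r + 1 + j] = z + rng.normal(0.0, spec.noise_sd / 4.0, size=n)
            copies.append(f"cop_{i}_{j}")
        probe_ids.extend(copies)
        truth_blocks[f"inf_{i}"] = frozenset(copies)
        r += 1 + spec.block_copies
    for k in range(n_null):
        rows[r] = base + rng.normal(0.0, spec.noise_sd, size=n)
        probe_ids.append(f"null_{k}")
        r += 1

    values = expit(rows)

    if spec.randomize_ids:
        # blinded IDs: the permutation is drawn after all values so the
        # matrix itself is unchanged for a given seed
        perm = rng.permutation(spec.n_sites)
        blinded = [f"cg{perm[i]:08d}" for i in range(spec.n_sites)]
        rename = dict(zip(probe_ids, blinded))
        truth_blocks = {
            rename[p]: frozenset(rename[c] for c in copies)
            for p, copies in truth_blocks.items()
        }
        probe_ids = blinded

    sample_ids = tuple(
        f"{spec.class_names[c]}_{i}"
        for c in range(K)
        for i in range(spec.n_per_class[c])
    )
    matrix = BetaMatrix(tuple(probe_ids), sample_ids, values)
    labels = ClassLabels(
        {s: spec.class_names[c] for s, c in zip(sample_ids, y)},
        spec.class_names,
    )
    return SyntheticDataset(
        matrix=matrix,
        labels=labels,
        truth_informative=frozenset(truth_blocks.keys()),
        truth_blocks=truth_blocks,
    )


def write_truth(dataset: SyntheticDataset, path) -> None:
    """Write the planted ground truth as (probe_id, role, parent) TSV."""
    with open(path, "w") as fh:
        fh.write("probe_id\trole\tparent\n")
        for parent in sorted(dataset.truth_informative):
            fh.write(f"{parent}\tinformative\t-\n")
            for copy in sorted(dataset.truth_blocks[parent]):
                fh.write(f"{copy}\tredundant_copy\t{parent}\n")
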