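"""Synthetic grouped expression data with planted correlation structure.

Generates genes × samples matrices that emulate normalized log2 microarray
data from a two-group (control vs. case) design:

* *blocks* of genes that are equicorrelated multivariate normal within a
  chosen group (``rho_in``), optionally group-specific — in the non-active
  group the same genes are equicorrelated at ``rho_out`` (typically 0,
  i.e. independent);
* *shift genes* whose case-group mean is displaced by a stated number of
  noise standard deviations (planted differential expression);
* all remaining genes independent Gaussian noise.

Equicorrelated blocks are sampled through the one-factor representation
``x = sqrt(rho) * z_block + sqrt(1 - rho) * e``, which is exact for
``rho >= 0`` and keeps the implied covariance positive semi-definite.  For a
bivariate normal with Pearson correlation ρ the population Spearman
correlation is ``(6/π)·asin(ρ/2)`` (≈0.892 at ρ=0.9), so Spearman-based
edge recovery targets sit slightly below ``rho_in``.

Values are emitted on a log2-like intensity scale (baseline mean 8, unit SD
by default), so the normalization operations remain meaningful downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, write_expression

BASELINE_MEAN = 8.0


@dataclass(frozen=True)
class BlockSpec:
    """A planted equicorrelated gene block.

    ``active_group`` selects where the block correlates at ``rho_in``:
    ``"control"``, ``"case"``, or ``"both"``.  In the non-active group the
    block genes are equicorrelated at ``rho_out`` instead (0 = independent).
    """

    gene_indices: tuple[int, ...]
    rho_in: float
    rho_out: float = 0.0
    active_group: str = "both"
    category: str = "adaptive immunity"

    def __post_init__(self) -> None:
        k = len(self.gene_indices)
        if k < 2:
            raise ValueError("a block needs at least 2 genes")
        if len(set(self.gene_indices)) != k:
            raise ValueError("block gene indices must be unique")
        for rho, name in ((self.rho_in, "rho_in"), (self.rho_out, "rho_out")):
            if not 0.0 <= rho < 1.0:
                # negative equicorrelation down to -1/(k-1) would stay PSD but
                # is not meaningful for a co-expression block; reject it
                raise ValueError(f"{name}={rho} outside [0, 1); covariance not accepted")
        if self.rho_out >= self.rho_in:
            raise ValueError("rho_out must be < rho_in")
        if self.active_group not in ("control", "case", "both"):
            raise ValueError(f"invalid active_group: {self.active_group!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int
    n_control: int
    n_case: int
    blocks: tuple[BlockSpec, ...] = ()
    # (gene index, shift in SD units, direction +1/-1)
    shift_genes: tuple[tuple[int, float, int], ...] = ()
    noise_sd: float = 1.0
    category_map: dict[int, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_control, self.n_case) < 1:
            raise ValueError("n_genes, n_control and n_case must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        seen: set[int] = set()
        for b in self.blocks:
            idx = set(b.gene_indices)
            if idx & seen:
                raise ValueError("block gene-index sets must be disjoint")
            seen |= idx
            if max(idx) >= self.n_genes or min(idx) < 0:
                raise ValueError("block gene index out of range")
        for g, _, direction in self.shift_genes:
            if not 0 <= g < self.n_genes:
                raise ValueError(f"shift gene index {g} out of range")
            if direction not in (-1, 1):
                raise ValueError("shift direction must be +1 or -1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted alongside a simulated dataset."""

    block_members: tuple[tuple[int, ...], ...]
    block_categories: tuple[str, ...]
    block_active_groups: tuple[str, ...]
    de_genes: tuple[int, ...]
    rho_targets: tuple[tuple[float, float], ...]  # (control rho, case rho) per block

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "block_members": [list(m) for m in self.block_members],
                    "block_categories": list(self.block_categories),
                    "block_active_groups": list(self.block_active_groups),
                    "de_genes": list(self.de_genes),
                    "rho_targets": [list(t) for t in self.rho_targets],
                },
                indent=2,
            )
        )


def _equicorrelated(rng: np.random.Generator, k: int, n: int, rho: float) -> np.ndarray:
    """k genes × n samples standard-normal draws with pairwise correlation rho."""
    noise = rng.standard_normal((k, n))
    if rho == 0.0:
        return noise
    shared = rng.standard_normal(n)
    return np.sqrt(rho) * shared[None, :] + np.sqrt(1.0 - rho) * noise


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate an expression matrix under ``config``.

    Returns the matrix, a metadata DataFrame (sample_id, group, outcome) and
    the ground truth.  Identical configs (including seed) give bit-identical
    output; all randomness flows through one ``default_rng(seed)`` instance.
    """
    rng = np.random.default_rng(config.seed)
    n_ctrl, n_case = config.n_control, config.n_case
    n = n_ctrl + n_case

    z = np.empty((config.n_genes, n))
    in_block = np.zeros(config.n_genes, dtype=bool)
    # group-wise draws, control columns first
    for b in config.blocks:
        idx = np.asarray(b.gene_indices)
        in_block[idx] = True
        rho_ctrl = b.rho_in if b.active_group in ("control", "both") else b.rho_out
        rho_case = b.rho_in if b.active_group in ("case", "both") else b.rho_out
        z[idx, :n_ctrl] = _equicorrelated(rng, len(idx), n_ctrl, rho_ctrl)
        z[idx, n_ctrl:] = _equicorrelated(rng, len(idx), n_case, rho_case)
    free = ~in_block
    z[free] = rng.standard_normal((int(free.sum()), n))

    values = BASELINE_MEAN + config.noise_sd * z
    for g, shift_sd, direction in config.shift_genes:
        values[g, n_ctrl:] += direction * shift_sd * config.noise_sd

    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    sample_ids = [f"ctrl_{i:02d}" for i in range(n_ctrl)] + [
        f"case_{i:02d}" for i in range(n_case)
    ]
    group = {s: ("control" if s.startswith("ctrl") else "case") for s in sample_ids}
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids), group=group
    )
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": [group[s] for s in sample_ids],
            "outcome": "NA",
        }
    )
    truth = SyntheticTruth(
        block_members=tuple(b.gene_indices for b in config.blocks),
        block_categories=tuple(b.category for b in config.blocks),
        block_active_groups=tuple(b.active_group for b in config.blocks),
        de_genes=tuple(sorted(g for g, _, _ in config.shift_genes)),
        rho_targets=tuple(
            (
                b.rho_in if b.active_group in ("control", "both") else b.rho_out,
                b.rho_in if b.active_group in ("case", "both") else b.rho_out,
            )
            for b in config.blocks
        ),
    )
    return matrix, metadata, truth


def default_config(seed: int = 0) -> SyntheticConfig:
    """Default study conditions: 300 background genes plus one 20-gene
    case-active block (rho_in=0.9), 25 samples per group, 30 genes shifted
    +1 SD in cases; the block is tagged adaptive immunity, background genes
    cycle through the remaining categories.
    """
    from .annotation import CATEGORIES

    n_genes = 320
    block = BlockSpec(
        gene_indices=tuple(range(20)),
        rho_in=0.9,
        rho_out=0.0,
        active_group="case",
        category="adaptive immunity",
    )
    shift = tuple((i, 1.0, 1) for i in range(20, 50))
    cats = [c for c in CATEGORIES if c != "adaptive immunity"]
    category_map = {i: "adaptive immunity" for i in range(20)}
    category_map.update({i: cats[i % len(cats)] for i in range(20, n_genes)})
    return SyntheticConfig(
        n_genes=n_genes,
        n_control=25,
        n_case=25,
        blocks=(block,),
        shift_genes=shift,
        noise_sd=1.0,
        category_map=category_map,
        seed=seed,
    )


def write_dataset(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write expression TSV, metadata TSV and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, metadata, truth = generate_dataset(config)
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.json",
    }
    write_expression(matrix, paths["expression"], paths["metadata"])
    truth.to_json(paths["truth"])
    return paths
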