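"""Expression matrix container and I/O.

The central data structure is :class:`ExpressionMatrix`: a genes × samples
table of log2-scale expression values together with per-sample group labels
(``control`` / ``case``) and an optional outcome label
(``survivor`` / ``nonsurvivor``).  All downstream stages — normalization,
differential expression, enrichment and network construction — operate on
this container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("control", "case")
OUTCOMES = ("survivor", "nonsurvivor")


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns, log2 scale.
    group
        Mapping sample ID -> ``"control"`` or ``"case"``; must cover every
        sample column.
    outcome
        Optional mapping sample ID -> ``"survivor"`` / ``"nonsurvivor"``.
        Samples without an outcome may be absent.
    """

    values: pd.DataFrame
    group: dict[str, str]
    outcome: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ValueError(f"duplicate gene IDs: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = sorted(self.values.columns[self.values.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample IDs: {dupes}")
        missing = [s for s in self.values.columns if s not in self.group]
        if missing:
            raise ValueError(f"samples absent from metadata: {missing}")
        bad = {s: g for s, g in self.group.items() if g not in GROUPS}
        if bad:
            raise ValueError(f"invalid group labels (expect control/case): {bad}")

    # -- basic accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group[s] == group]

    def samples_with_outcome(self, outcome: str) -> list[str]:
        return [s for s in self.values.columns if self.outcome.get(s) == outcome]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values[sample_ids].copy(),
            group={s: self.group[s] for s in sample_ids},
            outcome={s: self.outcome[s] for s in sample_ids if s in self.outcome},
        )

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        present = [g for g in gene_ids if g in self.values.index]
        return ExpressionMatrix(
            values=self.values.loc[present].copy(),
            group=dict(self.group),
            outcome=dict(self.outcome),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression(
    matrix_path: str | Path,
    metadata_path: str | Path,
    missing_policy: str = "drop-gene",
) -> ExpressionMatrix:
    """Read an expression TSV plus sample-metadata TSV.

    The matrix TSV has gene IDs in the first column and one column per
    sample; the metadata TSV has columns ``sample_id``, ``group`` and
    optionally ``outcome`` (NA allowed).  Genes containing any missing
    value are dropped with a logged warning (``missing_policy="drop-gene"``,
    the only policy implemented: correlation and t statistics require
    complete per-gene vectors).
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if values.index.duplicated().any():
        dupes = sorted(values.index[values.index.duplicated()].unique())
        raise ValueError(f"duplicate gene IDs in {matrix_path}: {dupes}")

    if missing_policy != "drop-gene":
        raise ValueError(f"unknown missing-value policy: {missing_policy!r}")
    n_missing_rows = int(values.isna().any(axis=1).sum())
    if n_missing_rows:
        logger.warning(
            "dropping %d gene(s) with missing values (policy=drop-gene)", n_missing_rows
        )
        values = values.dropna(axis=0)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise ValueError("metadata must have columns sample_id and group")
    meta = meta.set_index("sample_id")
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples in matrix absent from metadata: {missing}")

    group = {s: meta.loc[s, "group"] for s in values.columns}
    outcome: dict[str, str] = {}
    if "outcome" in meta.columns:
        for s in values.columns:
            o = meta.loc[s, "outcome"]
            if isinstance(o, str) and o in OUTCOMES:
                outcome[s] = o
    return ExpressionMatrix(values=values.astype(float), group=group, outcome=outcome)


def write_expression(m: ExpressionMatrix, matrix_path: str | Path, metadata_path: str | Path) -> None:
    """Write matrix + metadata TSVs; round-trips through :func:`read_expression`."""
    out = m.values.copy()
    out.index.name = "gene_id"
    # repr-precision floats so read-back reproduces values exactly
    out.to_csv(matrix_path, sep="\t", float_format="%.17g")
    meta = pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "group": [m.group[s] for s in m.sample_ids],
            "outcome": [m.outcome.get(s, "NA") for s in m.sample_ids],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2 every value; requires strictly positive input."""
    vals = m.values.to_numpy()
    if (vals <= 0).any():
        rows, cols = np.nonzero(vals <= 0)
        coords = [(m.gene_ids[r], m.sample_ids[c]) for r, c in zip(rows[:5], cols[:5])]
        raise ValueError(f"nonpositive values at (gene, sample): {coords}")
    return ExpressionMatrix(
        values=pd.DataFrame(np.log2(vals), index=m.values.index, columns=m.values.columns),
        group=dict(m.group),
        outcome=dict(m.outcome),
    )


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization: every column gets the mean-of-sorted-columns
    distribution, assigned by within-column rank; ties receive the mean of
    their tied positions' reference values.  Idempotent on tie-free columns.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    vals = m.values.to_numpy(dtype=float)
    order = np.argsort(vals, axis=0, kind="stable")
    reference = np.sort(vals, axis=0).mean(axis=1)

    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        normed = np.empty_like(col)
        normed[order[:, j]] = reference
        # average reference values over tied input values
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=normed)
        counts = np.bincount(inv)
        out[:, j] = (sums / counts)[inv]
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        group=dict(m.group),
        outcome=dict(m.outcome),
    )


# ---------------------------------------------------------------------------
# Probe collapsing and balanced subsampling
# ---------------------------------------------------------------------------

def collapse_probes(m: ExpressionMatrix, probe_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene.

    Unmapped probes are dropped.  For each gene the probe with maximal mean
    expression is kept (ties broken by lexicographic probe ID), a standard
    deterministic convention for array data.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    means = m.values.mean(axis=1)
    best: dict[str, str] = {}  # gene -> winning probe
    for probe in m.gene_ids:
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        cur = best.get(gene)
        if (
            cur is None
            or means[probe] > means[cur]
            or (means[probe] == means[cur] and probe < cur)
        ):
            best[gene] = probe
    genes = sorted(best)
    values = m.values.loc[[best[g] for g in genes]].copy()
    values.index = pd.Index(genes, name=m.values.index.name)
    return ExpressionMatrix(values=values, group=dict(m.group), outcome=dict(m.outcome))


def balanced_subsample(m: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Randomly select cases without replacement to match the control count.

    All controls are retained; exactly ``n_control`` cases are drawn without
    replacement from a single seeded generator, making the selection
    reproducible.  Column order of the original matrix is preserved.
    """
    controls = m.samples_in_group("control")
    cases = m.samples_in_group("case")
    if len(cases) < len(controls):
        raise ValueError(
            f"fewer cases ({len(cases)}) than controls ({len(controls)}); cannot balance"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(cases, size=len(controls), replace=False))
    keep = [s for s in m.sample_ids if m.group[s] == "control" or s in chosen]
    return m.subset_samples(keep)
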