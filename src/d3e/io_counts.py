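"""Count-table input/output, median-of-ratios normalisation and filtering.

The input is a UTF-8, tab-separated table: the first header field titles the
gene column, the remaining header fields are *group labels* (one per cell;
cells are identified by column position), and each body row is a gene id
followed by one nonnegative integer count per cell::

    GeneID  A   A   B   B
    g1      0   1   2   3

Size factors follow the DESeq median-of-ratios scheme: for every cell j,
``s_j = median_i x_ij / geomean_k(x_ik)`` over the genes that are strictly
positive in every cell (the geometric mean of a row containing a zero is
zero, so such rows cannot contribute a finite ratio).  If spike-in gene ids
are supplied, only spike-in rows enter the median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SizeFactors",
    "CountTableError",
    "SizeFactorError",
    "read_counts",
    "write_counts",
    "size_factors",
    "normalize",
    "filter_unexpressed",
]


class CountTableError(ValueError):
    """Malformed count table (parse or validation failure)."""


class SizeFactorError(ValueError):
    """No gene is eligible for size-factor estimation."""


@dataclass
class CountMatrix:
    """Gene-by-cell count matrix with a group label per cell.

    ``counts`` is genes x cells; raw input is integer, normalised output is
    real-valued.  ``group_of_cell`` maps cell id -> group label.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray
    group_of_cell: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise CountTableError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise CountTableError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise CountTableError("duplicate cell ids")
        if self.counts.size and np.min(self.counts) < 0:
            raise CountTableError("negative counts")
        missing = [c for c in self.cell_ids if c not in self.group_of_cell]
        if missing:
            raise CountTableError(f"cells without a group label: {missing[:5]}")

    # -- convenience -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cell_ids:
            seen.setdefault(self.group_of_cell[c], None)
        return list(seen)

    def cells_in_group(self, group: str) -> list[str]:
        return [c for c in self.cell_ids if self.group_of_cell[c] == group]

    def group_columns(self, group: str) -> np.ndarray:
        idx = [j for j, c in enumerate(self.cell_ids) if self.group_of_cell[c] == group]
        if not idx:
            raise KeyError(f"no cells in group {group!r}")
        return self.counts[:, idx]

    def gene_vector(self, gene_id: str, group: str) -> np.ndarray:
        i = self.gene_ids.index(gene_id)
        return self.group_columns(group)[i]

    def subset_cells(self, cell_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=list(cell_ids),
            counts=self.counts[:, idx].copy(),
            group_of_cell={c: self.group_of_cell[c] for c in cell_ids},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_arrays(
        cls,
        counts: np.ndarray,
        groups: Sequence[str],
        gene_ids: Sequence[str] | None = None,
        cell_ids: Sequence[str] | None = None,
    ) -> "CountMatrix":
        """Build a matrix from an array and per-cell group labels."""
        counts = np.asarray(counts, dtype=float)
        n_genes, n_cells = counts.shape
        if len(groups) != n_cells:
            raise CountTableError("one group label per cell required")
        gene_ids = list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(n_genes)]
        cell_ids = list(cell_ids) if cell_ids is not None else [f"cell{j}" for j in range(n_cells)]
        return cls(gene_ids, cell_ids, counts, dict(zip(cell_ids, groups)))


@dataclass(frozen=True)
class SizeFactors:
    s: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "s", np.asarray(self.s, dtype=float))
        if self.s.ndim != 1 or np.any(~np.isfinite(self.s)) or np.any(self.s <= 0):
            raise SizeFactorError("size factors must be finite and strictly positive")

    def __len__(self) -> int:
        return len(self.s)


def read_counts(path: str | Path, *, sep: str = "\t") -> CountMatrix:
    """Parse a count table; see the module docstring for the dialect."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise CountTableError(f"{path}: empty file or blank header")
        fields = header.rstrip("\n").split(sep)
        labels = fields[1:]
        n_cells = len(labels)
        cell_ids = [f"{lab}_{j}" for j, lab in enumerate(labels)]
        gene_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(sep)
            if len(parts) != n_cells + 1:
                raise CountTableError(
                    f"{path}:{lineno}: expected {n_cells + 1} fields, got {len(parts)}"
                )
            gene_ids.append(parts[0])
            try:
                row = [int(v) for v in parts[1:]]
            except ValueError as exc:
                raise CountTableError(f"{path}:{lineno}: non-integer count ({exc})") from None
            if any(v < 0 for v in row):
                raise CountTableError(f"{path}:{lineno}: negative count")
            rows.append(row)
    counts = np.asarray(rows, dtype=float) if rows else np.empty((0, n_cells))
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise CountTableError(f"{path}: duplicate gene ids {dupes[:5]}")
    return CountMatrix(gene_ids, cell_ids, counts, dict(zip(cell_ids, labels)))


def write_counts(cm: CountMatrix, path: str | Path, *, sep: str = "\t") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(sep.join(["GeneID"] + [cm.group_of_cell[c] for c in cm.cell_ids]) + "\n")
        for i, g in enumerate(cm.gene_ids):
            row = cm.counts[i]
            vals = [("%d" % v) if float(v).is_integer() else repr(float(v)) for v in row]
            fh.write(sep.join([g] + vals) + "\n")


def size_factors(
    cm: CountMatrix, spike_in_ids: Iterable[str] | None = None
) -> SizeFactors:
    """Median-of-ratios size factor per cell.

    Only genes strictly positive in every cell enter the median (optionally
    restricted to spike-ins).
    """
    x = cm.counts
    mask = np.all(x > 0, axis=1)
    if spike_in_ids is not None:
        spikes = set(spike_in_ids)
        mask &= np.asarray([g in spikes for g in cm.gene_ids])
    if not mask.any():
        raise SizeFactorError(
            "no gene with strictly positive counts in every cell"
            + (" among the spike-ins" if spike_in_ids is not None else "")
            + "; disable normalization or provide different spike-ins"
        )
    xe = x[mask]
    log_geomean = np.mean(np.log(xe), axis=1, keepdims=True)
    ratios = np.exp(np.log(xe) - log_geomean)
    return SizeFactors(np.median(ratios, axis=0))


def normalize(cm: CountMatrix, s: SizeFactors) -> CountMatrix:
    """Divide each cell's counts by its size factor; labels preserved."""
    if len(s) != cm.n_cells:
        raise CountTableError("size-factor length does not match number of cells")
    return CountMatrix(
        gene_ids=list(cm.gene_ids),
        cell_ids=list(cm.cell_ids),
        counts=cm.counts / s.s[None, :],
        group_of_cell=dict(cm.group_of_cell),
    )


def filter_unexpressed(cm: CountMatrix) -> CountMatrix:
    """Drop genes with zero counts in every cell; gene order preserved."""
    keep = np.any(cm.counts > 0, axis=1) if cm.n_genes else np.zeros(0, dtype=bool)
    return CountMatrix(
        gene_ids=[g for g, k in zip(cm.gene_ids, keep) if k],
        cell_ids=list(cm.cell_ids),
        counts=cm.counts[keep],
        group_of_cell=dict(cm.group_of_cell),
    )
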