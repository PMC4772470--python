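"""Per-gene significance calling.

Two strategies: Benjamini-Hochberg FDR control at a user level, or an
empirical split-control heuristic — the control group is split into two
disjoint halves that by construction share every gene's distribution, the
chosen test is run between the halves, the smallest p-value p* is recorded,
and a gene in the real comparison is called significant iff its p-value is
strictly below a*p* (default a = 0.1).  The halved control sample size makes
this cut-off less stringent than a full-size negative control would be; a
warning is logged rather than corrected for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .io_counts import CountMatrix

__all__ = ["ThresholdDecision", "bh_calls", "split_control", "empirical_threshold"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdDecision:
    method: str  # "bh" | "empirical"
    critical_p: float
    a: float = 0.1
    p_star: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.critical_p <= 1.0:
            raise ValueError("critical_p must be in [0, 1]")


def bh_calls(pvalues, fdr: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance calls at level ``fdr``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must be in (0, 1)")
    return stats.false_discovery_control(p, method="bh") <= fdr


def split_control(
    cm: CountMatrix, group: str, seed: int | np.random.Generator | None = None
) -> tuple[CountMatrix, CountMatrix]:
    """Randomly partition the cells of ``group`` into two disjoint halves.

    Sizes floor(m/2) and ceil(m/2); the union is the original group;
    reproducible under ``seed``.
    """
    cells = cm.cells_in_group(group)
    if len(cells) < 4:
        raise ValueError(f"group {group!r} needs >= 4 cells to split, has {len(cells)}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    perm = rng.permutation(len(cells))
    half = len(cells) // 2
    a = [cells[i] for i in sorted(perm[:half])]
    b = [cells[i] for i in sorted(perm[half:])]
    return cm.subset_cells(a), cm.subset_cells(b)


def empirical_threshold(
    control_half_a: CountMatrix,
    control_half_b: CountMatrix,
    test_fn: Callable[[np.ndarray, np.ndarray], float],
    a: float = 0.1,
) -> ThresholdDecision:
    """Derive the a*p* cut-off from a split negative control.

    ``test_fn(x, y)`` must return a p-value; it is applied per gene between
    the two halves and p* is the smallest value observed.
    """
    if control_half_a.gene_ids != control_half_b.gene_ids:
        raise ValueError("control halves must share the same genes in the same order")
    if control_half_a.n_genes == 0:
        raise ValueError("no genes in the control")
    if a < 0:
        raise ValueError("a must be >= 0")
    ps = [
        test_fn(control_half_a.counts[i], control_half_b.counts[i])
        for i in range(control_half_a.n_genes)
    ]
    p_star = float(np.min(ps))
    logger.warning(
        "empirical threshold from a half-size negative control (p*=%.3g): the reduced "
        "sample size gives a less stringent cut-off than a full-size control would",
        p_star,
    )
    return ThresholdDecision(
        method="empirical", critical_p=min(a * p_star, 1.0), a=a, p_star=p_star
    )
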