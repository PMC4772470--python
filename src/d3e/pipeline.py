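"""Orchestration of the four-step analysis: normalise -> filter -> test -> fit.

`run_d3e` takes a labelled count matrix and two group labels (group A is the
control: the denominator of fold changes and, for the likelihood-ratio test,
the condition whose fit defines the null likelihood), and produces one
`GeneDEResult` per retained gene.  `DEAnalysis`/`DEResults` wrap the same
computation in a model/results pair with a summary table.

Reproducibility: every stochastic step (Bayesian fits, Monte-Carlo
likelihoods, the control split) is seeded from the master seed; per-gene
seeds are derived from (master seed, gene id) so reordering genes does not
change any result.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import de_tests, estimation
from .de_tests import TestResult
from .io_counts import CountMatrix, filter_unexpressed, normalize, size_factors
from .pb_model import PBParams, DerivedQuantities, derived_quantities
from .thresholding import ThresholdDecision, bh_calls, empirical_threshold, split_control

__all__ = [
    "RunConfig",
    "GeneDEResult",
    "run_d3e",
    "compare_params",
    "write_results",
    "DEAnalysis",
    "DEResults",
    "OUTPUT_COLUMNS",
]


@dataclass(frozen=True)
class RunConfig:
    """Settings for one differential-expression run."""

    test: str = "cvm"  # cvm | ks | lr
    method: str = "mom"  # mom | bayes
    normalize: bool = True
    spike_in_ids: frozenset[str] | None = None
    threshold_method: str = "bh"  # bh | empirical
    fdr: float = 0.05
    a: float = 0.1
    n_mc: int = 1000
    seed: int = 0
    lr_df: int = 6
    rates: dict[str, tuple[float, float]] | None = None  # gene -> (lambda_a, lambda_b)
    bayes_n_iter: int = 3000
    bayes_n_burnin: int = 1000
    burst_frequency_convention: str = "stationary"

    def __post_init__(self) -> None:
        if self.test not in ("cvm", "ks", "lr"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.method not in ("mom", "bayes"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.threshold_method not in ("bh", "empirical"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.n_mc < 1:
            raise ValueError("n_mc must be >= 1")


@dataclass
class GeneDEResult:
    gene_id: str
    test_name: str
    statistic: float
    p_value: float
    significant: bool
    mean_a: float
    mean_b: float
    fold_change: float
    params_a: PBParams | None = None
    params_b: PBParams | None = None
    derived_a: DerivedQuantities | None = None
    derived_b: DerivedQuantities | None = None
    changes: dict[str, float | None] = field(default_factory=dict)
    fit_status_a: str = "ok"
    fit_status_b: str = "ok"


def gene_seed(master_seed: int, gene_id: str) -> np.random.SeedSequence:
    """Order-independent per-gene seed derived from the master seed."""
    return np.random.SeedSequence([master_seed, zlib.crc32(gene_id.encode("utf-8"))])


def compare_params(
    params_a: PBParams,
    params_b: PBParams,
    lambda_a: float | None = None,
    lambda_b: float | None = None,
    *,
    burst_frequency_convention: str = "stationary",
) -> dict[str, float | None]:
    """Log2 changes of the derived quantities between two fits (b relative to a).

    All ratio quantities (duty cycle, burst size, mean, CV, and the
    lambda-normalised burst frequency) are identifiable from snapshot data
    alone.  Absolute-rate quantities — burst frequency in real time and the
    autocorrelation time tau_c — need the degradation rates and are reported
    as None when either lambda is missing.  ``duty_cycle_diff`` is the plain
    difference (the duty cycle is already dimensionless in [0, 1]).
    """
    with_tau = lambda_a is not None and lambda_b is not None
    da = derived_quantities(
        params_a.rescaled_to(lambda_a) if with_tau else params_a,
        burst_frequency_convention=burst_frequency_convention,
        with_tau_c=with_tau,
    )
    db = derived_quantities(
        params_b.rescaled_to(lambda_b) if with_tau else params_b,
        burst_frequency_convention=burst_frequency_convention,
        with_tau_c=with_tau,
    )
    out: dict[str, float | None] = {
        "log2_change_burst_size": math.log2(db.burst_size / da.burst_size),
        "log2_change_burst_freq": math.log2(db.burst_frequency / da.burst_frequency),
        "log2_change_duty_cycle": math.log2(db.duty_cycle / da.duty_cycle),
        "duty_cycle_diff": db.duty_cycle - da.duty_cycle,
        "log2_change_mean": math.log2(db.mean_expression / da.mean_expression),
        "log2_change_cv": math.log2(db.cv / da.cv),
        "log2_change_tau_c": math.log2(db.tau_c / da.tau_c) if with_tau else None,
    }
    return out


def _fit_group(
    x: np.ndarray,
    cfg: RunConfig,
    rng_seed: np.random.SeedSequence,
    *,
    require: bool,
) -> tuple[PBParams | None, str]:
    """Fit (alpha, beta, gamma) to one group's counts; never raises.

    With method "mom" and ``require=True`` (the likelihood-ratio test needs a
    fit), a degenerate moment fit falls back to a short Bayesian chain.
    """
    if cfg.method == "bayes":
        try:
            post = estimation.estimate_bayes(
                x, cfg.bayes_n_iter, cfg.bayes_n_burnin, np.random.default_rng(rng_seed)
            )
            return estimation.point_estimate(post), "ok"
        except Exception as exc:  # all-zero group etc.
            return None, f"bayes_failed:{type(exc).__name__}"
    try:
        fit = estimation.estimate_mom(x)
        if require and not estimation.plausible_fit(fit, x):
            # a fit that cannot generate its own sample would wreck the
            # likelihood ratio; treat like an infeasible inversion
            raise estimation.InfeasibleMomentsError("implausible moment fit")
        return fit, "ok"
    except (estimation.MomentDegeneracyError, estimation.InfeasibleMomentsError) as exc:
        status = (
            "mom_degenerate"
            if isinstance(exc, estimation.MomentDegeneracyError)
            else "mom_infeasible"
        )
        if not require:
            return None, status
        try:
            post = estimation.estimate_bayes(x, 1200, 400, np.random.default_rng(rng_seed))
            return estimation.point_estimate(post), "bayes_fallback"
        except Exception as exc2:
            return None, f"{status};bayes_failed:{type(exc2).__name__}"
    except ValueError as exc:
        return None, f"invalid_input:{type(exc).__name__}"


def _test_gene(
    x_a: np.ndarray,
    x_b: np.ndarray,
    cfg: RunConfig,
    seed_seq: np.random.SeedSequence,
) -> tuple[TestResult, tuple[PBParams | None, str], tuple[PBParams | None, str]]:
    """Run the configured test on one gene; returns the result and both fits."""
    xa = np.rint(x_a)
    xb = np.rint(x_b)
    s_fit_a, s_fit_b, s_mc = seed_seq.spawn(3)
    need_fit = cfg.test == "lr"
    fa = _fit_group(xa, cfg, s_fit_a, require=need_fit)
    fb = _fit_group(xb, cfg, s_fit_b, require=need_fit)
    if cfg.test == "cvm":
        res = de_tests.cvm_test(xa, xb)
    elif cfg.test == "ks":
        res = de_tests.ks_test(xa, xb)
    else:
        if fa[0] is None or fb[0] is None:
            res = TestResult(float("nan"), float("nan"), "lr", len(xa), len(xb))
        else:
            res = de_tests.lr_test(
                xb, fa[0], fb[0], cfg.n_mc, np.random.default_rng(s_mc), df=cfg.lr_df
            )
    return res, fa, fb


def run_d3e(
    cm: CountMatrix,
    group_a: str,
    group_b: str,
    cfg: RunConfig | None = None,
    **cfg_kwargs,
) -> list[GeneDEResult]:
    """Full analysis: normalise, filter, test per gene, fit, threshold.

    ``group_a`` is the control condition.  Returns one result per gene that
    survives the expression filter, in input order.
    """
    cfg = replace(cfg, **cfg_kwargs) if cfg is not None else RunConfig(**cfg_kwargs)
    groups = set(cm.group_of_cell.values())
    for g in (group_a, group_b):
        if g not in groups:
            raise ValueError(f"group {g!r} not present in the count matrix")
    if len(cm.cells_in_group(group_a)) < 2 or len(cm.cells_in_group(group_b)) < 2:
        raise ValueError("both groups need at least 2 cells")

    work = cm
    if cfg.normalize:
        work = normalize(work, size_factors(work, cfg.spike_in_ids))
    work = filter_unexpressed(work)
    if work.n_genes == 0:
        raise ValueError("all genes were filtered out (no expression)")

    a_cols = work.group_columns(group_a)
    b_cols = work.group_columns(group_b)

    # significance threshold from a split negative control, if requested
    decision: ThresholdDecision | None = None
    if cfg.threshold_method == "empirical":
        ss_split = np.random.SeedSequence([cfg.seed, 0x5B17])
        half_a, half_b = split_control(work, group_a, np.random.default_rng(ss_split))

        def control_p(x: np.ndarray, y: np.ndarray) -> float:
            s = np.random.SeedSequence(
                [cfg.seed, zlib.crc32(np.ascontiguousarray(np.rint(np.concatenate([x, y]))).tobytes())]
            )
            res, _, _ = _test_gene(x, y, cfg, s)
            return res.p_value if np.isfinite(res.p_value) else 1.0

        decision = empirical_threshold(half_a, half_b, control_p, cfg.a)

    results: list[GeneDEResult] = []
    for i, gid in enumerate(work.gene_ids):
        seed_seq = gene_seed(cfg.seed, gid)
        res, (pa, st_a), (pb, st_b) = _test_gene(a_cols[i], b_cols[i], cfg, seed_seq)
        mean_a = float(np.mean(a_cols[i]))
        mean_b = float(np.mean(b_cols[i]))
        lam_a = lam_b = None
        if cfg.rates and gid in cfg.rates:
            lam_a, lam_b = cfg.rates[gid]
        changes: dict[str, float | None] = {}
        der_a = der_b = None
        if pa is not None and pb is not None:
            changes = compare_params(
                pa, pb, lam_a, lam_b,
                burst_frequency_convention=cfg.burst_frequency_convention,
            )
        with_tau = lam_a is not None and lam_b is not None
        if pa is not None:
            der_a = derived_quantities(
                pa.rescaled_to(lam_a) if with_tau else pa,
                burst_frequency_convention=cfg.burst_frequency_convention,
                with_tau_c=with_tau,
            )
        if pb is not None:
            der_b = derived_quantities(
                pb.rescaled_to(lam_b) if with_tau else pb,
                burst_frequency_convention=cfg.burst_frequency_convention,
                with_tau_c=with_tau,
            )
        results.append(
            GeneDEResult(
                gene_id=gid,
                test_name=res.test_name,
                statistic=res.statistic,
                p_value=res.p_value,
                significant=False,
                mean_a=mean_a,
                mean_b=mean_b,
                fold_change=mean_b / mean_a if mean_a > 0 else float("nan"),
                params_a=pa,
                params_b=pb,
                derived_a=der_a,
                derived_b=der_b,
                changes=changes,
                fit_status_a=st_a,
                fit_status_b=st_b,
            )
        )

    pvals = np.array([r.p_value for r in results])
    finite = np.isfinite(pvals)
    if cfg.threshold_method == "bh":
        calls = np.zeros(len(results), dtype=bool)
        if finite.any():
            calls[finite] = bh_calls(pvals[finite], cfg.fdr)
    else:
        assert decision is not None
        calls = finite & (pvals < decision.critical_p)
    for r, c in zip(results, calls):
        r.significant = bool(c)
    return results


# ---------------------------------------------------------------------------
# Output table

OUTPUT_COLUMNS = [
    "gene_id", "test", "statistic", "p_value", "significant",
    "mean_a", "mean_b", "fold_change",
    "alpha_a", "beta_a", "gamma_a", "alpha_b", "beta_b", "gamma_b",
    "duty_cycle_a", "duty_cycle_b", "burst_size_a", "burst_size_b",
    "burst_freq_a", "burst_freq_b", "cv_a", "cv_b", "tau_c_a", "tau_c_b",
    "log2_change_burst_size", "log2_change_burst_freq", "log2_change_duty_cycle",
    "log2_change_mean", "log2_change_cv", "log2_change_tau_c",
    "fit_status_a", "fit_status_b",
]


def _row(r: GeneDEResult) -> dict:
    def q(obj, attr):
        return getattr(obj, attr) if obj is not None else None

    return {
        "gene_id": r.gene_id,
        "test": r.test_name,
        "statistic": r.statistic,
        "p_value": r.p_value,
        "significant": r.significant,
        "mean_a": r.mean_a,
        "mean_b": r.mean_b,
        "fold_change": r.fold_change,
        "alpha_a": q(r.params_a, "alpha"), "beta_a": q(r.params_a, "beta"),
        "gamma_a": q(r.params_a, "gamma"),
        "alpha_b": q(r.params_b, "alpha"), "beta_b": q(r.params_b, "beta"),
        "gamma_b": q(r.params_b, "gamma"),
        "duty_cycle_a": q(r.derived_a, "duty_cycle"), "duty_cycle_b": q(r.derived_b, "duty_cycle"),
        "burst_size_a": q(r.derived_a, "burst_size"), "burst_size_b": q(r.derived_b, "burst_size"),
        "burst_freq_a": q(r.derived_a, "burst_frequency"),
        "burst_freq_b": q(r.derived_b, "burst_frequency"),
        "cv_a": q(r.derived_a, "cv"), "cv_b": q(r.derived_b, "cv"),
        "tau_c_a": q(r.derived_a, "tau_c"), "tau_c_b": q(r.derived_b, "tau_c"),
        "log2_change_burst_size": r.changes.get("log2_change_burst_size"),
        "log2_change_burst_freq": r.changes.get("log2_change_burst_freq"),
        "log2_change_duty_cycle": r.changes.get("log2_change_duty_cycle"),
        "log2_change_mean": r.changes.get("log2_change_mean"),
        "log2_change_cv": r.changes.get("log2_change_cv"),
        "log2_change_tau_c": r.changes.get("log2_change_tau_c"),
        "fit_status_a": r.fit_status_a,
        "fit_status_b": r.fit_status_b,
    }


def results_frame(results: Sequence[GeneDEResult]) -> pd.DataFrame:
    return pd.DataFrame([_row(r) for r in results], columns=OUTPUT_COLUMNS)


def write_results(results: Sequence[GeneDEResult], path: str | Path) -> None:
    """Write the per-gene table as TSV; missing values become "NA"."""
    frame = results_frame(results)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


# ---------------------------------------------------------------------------
# Model / Results surface


class DEAnalysis:
    """Differential-expression analysis of one labelled count matrix.

    Build from a `CountMatrix` (or a DataFrame plus per-cell group labels),
    pick the control and test group, and call :meth:`fit`.
    """

    def __init__(self, cm: CountMatrix, group_a: str, group_b: str) -> None:
        self.data = cm
        self.group_a = group_a
        self.group_b = group_b

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, groups, group_a: str, group_b: str):
        cm = CountMatrix.from_arrays(
            frame.to_numpy(), list(groups), gene_ids=list(frame.index),
            cell_ids=list(frame.columns),
        )
        return cls(cm, group_a, group_b)

    def fit(self, cfg: RunConfig | None = None, **cfg_kwargs) -> "DEResults":
        cfg = replace(cfg, **cfg_kwargs) if cfg is not None else RunConfig(**cfg_kwargs)
        results = run_d3e(self.data, self.group_a, self.group_b, cfg)
        return DEResults(self, cfg, results)


@dataclass
class DEResults:
    model: DEAnalysis
    config: RunConfig
    gene_results: list[GeneDEResult]

    def to_frame(self) -> pd.DataFrame:
        return results_frame(self.gene_results)

    def write_tsv(self, path: str | Path) -> None:
        write_results(self.gene_results, path)

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.gene_results)

    def summary(self, top: int = 10) -> str:
        frame = self.to_frame().sort_values("p_value")
        lines = [
            "Differential expression analysis "
            f"({self.model.group_b} vs control {self.model.group_a})",
            f"  test: {self.config.test}   fit method: {self.config.method}   "
            f"threshold: {self.config.threshold_method}",
            f"  genes tested: {len(self.gene_results)}   "
            f"significant: {self.n_significant}",
            "",
            frame.head(top)[
                ["gene_id", "statistic", "p_value", "significant",
                 "fold_change", "log2_change_burst_size", "log2_change_burst_freq"]
            ].to_string(index=False),
        ]
        return "\n".join(lines)
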