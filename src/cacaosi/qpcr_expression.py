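"""Relative qPCR expression by the delta-delta-Ct method.

Target-gene Ct values are normalized against the mean of the reference
genes, then against a calibrator sample (unpollinated ovaries); fold change
is 2^-ddCt, or the efficiency-corrected ratio

    fold = E_target^-dCt(target) / geomean_refs( E_ref^-dCt(ref) )

with dCt(g) = mean Ct of g in the sample minus in the calibrator, when
per-primer amplification efficiencies are given.  With E = 2 everywhere the
corrected formula reduces exactly to 2^-ddCt.

Differential expression between the self-compatible and self-incompatible
reactions is assessed by an exact permutation test on replicate log-fold
means (every assignment of replicates to groups enumerated); an optional
categorical mode dichotomizes replicates at the pooled median and applies
the Fisher exact test instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostic_screen import fisher_exact

__all__ = [
    "CtTable",
    "RelExprResult",
    "relative_expression",
    "differential_test",
]

_ENUM_LIMIT = 20_000


@dataclass
class CtTable:
    """Long-format Ct measurements.

    Columns: ``condition`` (e.g. unpollinated / SC / SI), ``time_window``,
    ``gene``, ``replicate``, ``ct`` (> 0), optional ``efficiency``
    (fold per cycle, in (1, 2.2]).
    """

    data: pd.DataFrame

    REQUIRED = ("condition", "time_window", "gene", "replicate", "ct")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"Ct table needs a {col!r} column")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if "efficiency" in self.data.columns:
            eff = self.data["efficiency"].dropna()
            if ((eff <= 1.0) | (eff > 2.2)).any():
                raise ValueError("amplification efficiency must lie in (1, 2.2]")

    def sample(self, condition: str, time_window: str | None, gene: str) -> pd.DataFrame:
        sel = (self.data["condition"] == condition) & (self.data["gene"] == gene)
        if time_window is not None:
            sel &= self.data["time_window"] == time_window
        return self.data[sel]

    def efficiency(self, gene: str, default: float = 2.0) -> float:
        if "efficiency" not in self.data.columns:
            return default
        eff = self.data.loc[self.data["gene"] == gene, "efficiency"].dropna()
        return float(eff.iloc[0]) if len(eff) else default


@dataclass
class RelExprResult:
    gene: str
    condition: str
    time_window: str | None
    fold: float
    replicate_folds: tuple[float, ...]
    log2_spread: float  # sd of per-replicate log2 folds
    p: float | None = None


def _mean_ct(ct: CtTable, condition: str, tw: str | None, gene: str) -> float:
    rows = ct.sample(condition, tw, gene)
    if rows.empty:
        raise ValueError(
            f"no Ct measurements for gene {gene!r} in condition {condition!r}"
            + (f", window {tw!r}" if tw is not None else "")
        )
    return float(rows["ct"].mean())


def relative_expression(
    ct: CtTable,
    target_gene: str,
    condition: str,
    reference_genes: Sequence[str],
    time_window: str | None = None,
    calibrator_condition: str = "unpollinated",
    calibrator_time_window: str | None = None,
    efficiency_corrected: bool | None = None,
) -> RelExprResult:
    """Fold change of a target gene relative to the calibrator condition.

    ``efficiency_corrected=None`` (default) applies the correction iff the
    table carries an ``efficiency`` column; ``True``/``False`` force it.
    Per-replicate folds are reported against the calibrator mean; the
    headline ``fold`` uses mean Ct values, so the calibrator against itself
    is exactly 1.
    """
    if not reference_genes:
        raise ValueError("at least one reference gene is required")
    if efficiency_corrected is None:
        efficiency_corrected = "efficiency" in ct.data.columns

    def dct(gene: str) -> float:
        return _mean_ct(ct, condition, time_window, gene) - _mean_ct(
            ct, calibrator_condition, calibrator_time_window, gene
        )

    if efficiency_corrected:
        e_t = ct.efficiency(target_gene)
        num = e_t ** (-dct(target_gene))
        log_den = np.mean(
            [-dct(r) * math.log(ct.efficiency(r)) for r in reference_genes]
        )
        fold = float(num / math.exp(log_den))
    else:
        ddct = dct(target_gene) - float(np.mean([dct(r) for r in reference_genes]))
        fold = float(2.0 ** (-ddct))

    # per-replicate folds (plain 2^-ddCt scale) against the calibrator mean
    sample_rows = ct.sample(condition, time_window, target_gene)
    ref_means = {
        r: _mean_ct(ct, condition, time_window, r) for r in reference_genes
    }
    cal_dct = _mean_ct(
        ct, calibrator_condition, calibrator_time_window, target_gene
    ) - float(
        np.mean(
            [
                _mean_ct(ct, calibrator_condition, calibrator_time_window, r)
                for r in reference_genes
            ]
        )
    )
    rep_folds = tuple(
        float(2.0 ** (-(row.ct - float(np.mean(list(ref_means.values()))) - cal_dct)))
        for row in sample_rows.itertuples()
    )
    logs = np.log2(rep_folds) if rep_folds else np.array([0.0])
    return RelExprResult(
        gene=target_gene,
        condition=condition,
        time_window=time_window,
        fold=fold,
        replicate_folds=rep_folds,
        log2_spread=float(np.std(logs, ddof=1)) if len(logs) > 1 else 0.0,
    )


def differential_test(
    folds_a: Sequence[float],
    folds_b: Sequence[float],
    mode: str = "permutation",
    max_enumerate: int = _ENUM_LIMIT,
    seed: int = 0,
) -> float:
    """p-value for a difference in replicate fold changes between groups.

    Default is an exact permutation test on the absolute difference of
    group means of log folds: all C(n_a+n_b, n_a) assignments are
    enumerated (at 3+3 replicates the smallest attainable p is 2/20 = 0.1);
    beyond ``max_enumerate`` assignments a seeded Monte-Carlo sample of
    10 000 permutations is used.  ``mode="fisher"`` instead dichotomizes
    the pooled replicates at their median and applies the Fisher exact
    test to the resulting 2x2 table.
    """
    a = np.asarray(folds_a, dtype=float)
    b = np.asarray(folds_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicates per group")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("fold changes must be positive")
    if mode == "fisher":
        pooled = np.concatenate([a, b])
        cut = float(np.median(pooled))
        table = [
            [int((a > cut).sum()), int((a <= cut).sum())],
            [int((b > cut).sum()), int((b <= cut).sum())],
        ]
        return fisher_exact(table)
    if mode != "permutation":
        raise ValueError(f"unknown mode {mode!r}")
    la, lb = np.log(a), np.log(b)
    pooled = np.concatenate([la, lb])
    n, na = len(pooled), len(la)
    observed = abs(la.mean() - lb.mean())
    n_comb = math.comb(n, na)
    if n_comb <= max_enumerate:
        count = 0
        for idx in itertools.combinations(range(n), na):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            diff = abs(pooled[sel].mean() - pooled[~sel].mean())
            if diff >= observed - 1e-12:
                count += 1
        return count / n_comb
    rng = np.random.default_rng(seed)
    n_draw = 10_000
    count = 1  # the observed assignment
    for _ in range(n_draw):
        perm = rng.permutation(n)
        diff = abs(pooled[perm[:na]].mean() - pooled[perm[na:]].mean())
        if diff >= observed - 1e-12:
            count += 1
    return count / (n_draw + 1)
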