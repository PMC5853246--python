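"""Diagnostic-marker screening for self-compatibility prediction.

Multi-allelic SSR markers tightly linked to the incompatibility loci are in
strong linkage disequilibrium with S alleles, so particular SSR genotypes
(or genotype combinations across up to three markers) and particular
alleles predict the self-compatible (SC) / self-incompatible (SI) status of
a tree.  The screen enumerates observed genotype combinations, tests each
against SC/SI status with a two-sided Fisher exact test, controls the false
discovery rate by Benjamini-Hochberg, and reports the conditional
probabilities P(SC | carries) and P(SC | does not carry).  Allele effects
are screened the same way (presence/absence), and allele dosage (0/1/2
copies) is modeled by a binomial logistic regression, falling back to a
bias-reduced Firth fit under separation.

The exact test and the logistic fits are implemented here from first
principles (hypergeometric enumeration; IRLS maximum likelihood) because
they are the computational core of the screening procedure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._logistic import LogisticFit, fit_logistic

__all__ = [
    "SSRGenotypeTable",
    "PhenotypeTable",
    "GenotypeCombo",
    "ComboTestResult",
    "AllelePresenceResult",
    "AlleleDoseResult",
    "fisher_exact",
    "bh_qvalues",
    "enumerate_combos",
    "combo_screen",
    "allele_presence_screen",
    "allele_dose_fit",
]

#: relative slack when comparing hypergeometric point probabilities
_FISHER_RELTOL = 1e-7


@dataclass
class SSRGenotypeTable:
    """Individuals x markers, each cell an unordered pair of allele sizes.

    Cells are normalized to sorted ``(low, high)`` tuples of positive
    integers; homozygotes are equal pairs; missing cells are NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        def _norm(cell):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                return np.nan
            a, b = cell
            a, b = int(a), int(b)
            if a <= 0 or b <= 0:
                raise ValueError(f"allele sizes must be positive, got {cell}")
            return (a, b) if a <= b else (b, a)

        self.data = self.data.apply(lambda col: col.map(_norm))
        if self.data.index.has_duplicates:
            raise ValueError("duplicate individual ids")

    @property
    def markers(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def individuals(self) -> list[str]:
        return self.data.index.tolist()

    def observed_alleles(self, marker: str) -> list[int]:
        alleles: set[int] = set()
        for cell in self.data[marker].dropna():
            alleles.update(cell)
        return sorted(alleles)

    def dose(self, marker: str, allele: int) -> pd.Series:
        """Copies (0/1/2) of ``allele`` per individual; NaN where missing."""
        return self.data[marker].map(
            lambda cell: np.nan if cell is np.nan else float(cell.count(allele)),
            na_action="ignore",
        )


@dataclass
class PhenotypeTable:
    """SC/SI status (1 = self-compatible) and optional percent fruit set."""

    data: pd.DataFrame  # index individual; columns sc_status[, fruit_set_pct]

    def __post_init__(self) -> None:
        if "sc_status" not in self.data.columns:
            raise ValueError("phenotype table needs an sc_status column")
        vals = self.data["sc_status"].dropna().unique()
        if not set(vals) <= {0, 1}:
            raise ValueError(f"sc_status must be coded 0 (SI) / 1 (SC), got {vals}")
        if "fruit_set_pct" in self.data.columns:
            fs = self.data["fruit_set_pct"].dropna()
            if ((fs < 0) | (fs > 100)).any():
                raise ValueError("fruit_set_pct must lie in [0, 100]")

    @property
    def sc_status(self) -> pd.Series:
        return self.data["sc_status"].dropna().astype(int)


def fisher_exact(table: Sequence[Sequence[int]] | np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    With margins fixed, sums the hypergeometric probabilities of every
    table whose point probability is at most that of the observed table
    (within relative tolerance 1e-7) — the convention of standard
    statistical packages.  A zero margin carries no information: p = 1
    with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        tf = t.astype(float)
        if (tf < 0).any() or not np.allclose(tf, np.round(tf)):
            raise ValueError("cells must be nonnegative integers")
        t = np.round(tf).astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2) == 0 or min(c1, n - c1) == 0:
        warnings.warn("zero margin: table carries no information, p = 1")
        return 1.0
    xs = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(xs, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + _FISHER_RELTOL)].sum())
    return 1.0 if p > 1.0 - 1e-12 else p


def bh_qvalues(
    p: Sequence[float] | np.ndarray, method: str = "bh"
) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    ``method="storey"`` additionally scales by the Storey estimate of the
    null proportion pi0 (lambda = 0.5); BH is the default because pi0
    estimation is unstable at small test counts.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a nonempty 1-d vector")
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    if method == "storey":
        pi0 = min(1.0, float((p > 0.5).mean()) / 0.5) if m else 1.0
        q = np.minimum(q * pi0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown method {method!r}")
    return q


#: a combo is a tuple of (marker, (allele_low, allele_high)) terms
@dataclass(frozen=True)
class GenotypeCombo:
    terms: tuple[tuple[str, tuple[int, int]], ...]

    def __post_init__(self) -> None:
        markers = [m for m, _ in self.terms]
        if len(set(markers)) != len(markers):
            raise ValueError("combo markers must be distinct")
        object.__setattr__(self, "terms", tuple(sorted(self.terms)))

    @property
    def order(self) -> int:
        return len(self.terms)

    def __str__(self) -> str:
        return " & ".join(f"{m}:{g[0]}/{g[1]}" for m, g in self.terms)


def _combo_carriers(
    table: SSRGenotypeTable, markers: Sequence[str]
) -> pd.DataFrame:
    """Complete-case joint genotypes at ``markers``: one row per individual."""
    sub = table.data[list(markers)].dropna()
    return sub


def enumerate_combos(
    table: SSRGenotypeTable,
    max_order: int = 3,
    min_support: int = 3,
) -> list[GenotypeCombo]:
    """All observed genotype combinations at 1..max_order distinct markers.

    Only combinations actually carried by at least ``min_support``
    individuals (complete cases at the involved markers) are returned, in a
    deterministic order (marker names, then allele sizes).
    """
    if not 1 <= max_order <= 3:
        raise ValueError("max_order must be between 1 and 3")
    if len(table.data) == 0:
        raise ValueError("empty genotype table")
    combos: list[GenotypeCombo] = []
    for k in range(1, max_order + 1):
        for markers in itertools.combinations(sorted(table.markers), k):
            sub = _combo_carriers(table, markers)
            if sub.empty:
                continue
            counts = sub.groupby(list(markers)).size()
            for key, n in counts.items():
                if n < min_support:
                    continue
                genos = (key,) if k == 1 else tuple(key)
                combos.append(GenotypeCombo(tuple(zip(markers, genos))))
    combos.sort(key=lambda c: (c.order, c.terms))
    return combos


@dataclass
class ComboTestResult:
    combo: GenotypeCombo
    contingency: np.ndarray  # rows carrier/non-carrier, cols SC/SI
    p: float
    q: float | None
    prob_sc_has: float
    prob_sc_not: float
    n_carriers: int
    separation: bool


def _sc_probs(
    carrier: np.ndarray, sc: np.ndarray
) -> tuple[float, float, bool]:
    """P(SC | carrier) and P(SC | non-carrier) with a separation flag.

    These are the maximum-likelihood probabilities of the single-indicator
    logistic model, which coincide with the empirical group proportions
    (for boundary proportions as the limit of the diverging fit).
    Separation is flagged when either group is phenotype-pure.
    """
    p_has = float(sc[carrier].mean()) if carrier.any() else float("nan")
    p_not = float(sc[~carrier].mean()) if (~carrier).any() else float("nan")
    separation = p_has in (0.0, 1.0) or p_not in (0.0, 1.0)
    return p_has, p_not, separation


def _join_phenotype(
    table: SSRGenotypeTable, phenotype: PhenotypeTable
) -> tuple[SSRGenotypeTable, pd.Series]:
    sc = phenotype.sc_status
    common = table.data.index.intersection(sc.index)
    if sc.loc[common].nunique() < 2:
        raise ValueError("phenotype must contain both SC and SI individuals")
    return SSRGenotypeTable(table.data.loc[common]), sc.loc[common]


def combo_screen(
    table: SSRGenotypeTable,
    phenotype: PhenotypeTable,
    max_order: int = 3,
    min_support: int = 3,
    alpha: float = 0.05,
) -> list[ComboTestResult]:
    """Screen all observed genotype combinations against SC/SI status.

    For every combination, individuals with complete genotypes at the
    involved markers are split into carriers (exact genotype at every
    marker of the combo) and non-carriers; a 2x2 carrier x SC/SI table is
    tested by the Fisher exact test, q-values control the FDR across all
    combinations, and the conditional SC probabilities come from the
    single-indicator logistic fit.  Results are sorted by (q, p).
    """
    if not 1 <= max_order <= 3:
        raise ValueError("max_order must be between 1 and 3")
    geno, sc = _join_phenotype(table, phenotype)
    results: list[ComboTestResult] = []
    for k in range(1, max_order + 1):
        for markers in itertools.combinations(sorted(geno.markers), k):
            sub = _combo_carriers(geno, list(markers))
            if sub.empty:
                continue
            sub_sc = sc.loc[sub.index]
            n_total = len(sub)
            n_sc_total = int(sub_sc.sum())
            agg = sub_sc.groupby([sub[m] for m in markers]).agg(["sum", "size"])
            for key, (n_sc_c, n_c) in agg.iterrows():
                if n_c < min_support:
                    continue
                genos = (key,) if k == 1 else tuple(key)
                combo = GenotypeCombo(tuple(zip(markers, genos)))
                n_sc_c, n_c = int(n_sc_c), int(n_c)
                cont = np.array(
                    [
                        [n_sc_c, n_c - n_sc_c],
                        [n_sc_total - n_sc_c, (n_total - n_c) - (n_sc_total - n_sc_c)],
                    ]
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = fisher_exact(cont)
                p_has = n_sc_c / n_c
                p_not = (
                    (n_sc_total - n_sc_c) / (n_total - n_c)
                    if n_total > n_c
                    else float("nan")
                )
                sep = p_has in (0.0, 1.0) or p_not in (0.0, 1.0)
                results.append(
                    ComboTestResult(
                        combo=combo,
                        contingency=cont,
                        p=p,
                        q=None,
                        prob_sc_has=p_has,
                        prob_sc_not=p_not,
                        n_carriers=n_c,
                        separation=sep,
                    )
                )
    if not results:
        return results
    qs = bh_qvalues([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    results.sort(key=lambda r: (r.q, r.p, r.combo.terms))
    return results


@dataclass
class AllelePresenceResult:
    marker: str
    allele: int
    contingency: np.ndarray
    p: float
    q: float | None
    prob_sc_has: float
    prob_sc_not: float
    n_carriers: int
    separation: bool


def allele_presence_screen(
    table: SSRGenotypeTable, phenotype: PhenotypeTable
) -> list[AllelePresenceResult]:
    """Fisher screen of every allele's presence/absence against SC/SI.

    One 2x2 test per (marker, allele); q-values control the FDR across all
    alleles of all markers.  Results sorted by (q, p).
    """
    geno, sc = _join_phenotype(table, phenotype)
    results: list[AllelePresenceResult] = []
    for marker in geno.markers:
        cells = geno.data[marker].dropna()
        if cells.empty:
            continue
        sub_sc = sc.loc[cells.index].to_numpy()
        for allele in geno.observed_alleles(marker):
            carrier = cells.map(lambda g: allele in g).to_numpy(dtype=bool)
            cont = np.array(
                [
                    [
                        int((sub_sc[carrier] == 1).sum()),
                        int((sub_sc[carrier] == 0).sum()),
                    ],
                    [
                        int((sub_sc[~carrier] == 1).sum()),
                        int((sub_sc[~carrier] == 0).sum()),
                    ],
                ]
            )
            p = fisher_exact(cont)  # zero-margin warning propagates
            p_has, p_not, sep = _sc_probs(carrier, sub_sc)
            results.append(
                AllelePresenceResult(
                    marker=marker,
                    allele=allele,
                    contingency=cont,
                    p=p,
                    q=None,
                    prob_sc_has=p_has,
                    prob_sc_not=p_not,
                    n_carriers=int(carrier.sum()),
                    separation=sep,
                )
            )
    if not results:
        raise ValueError("no testable allele")
    qs = bh_qvalues([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    results.sort(key=lambda r: (r.q, r.p, r.marker, r.allele))
    return results


@dataclass
class AlleleDoseResult:
    marker: str
    allele: int
    dose_counts: np.ndarray  # 3x2: rows dose 0/1/2, cols SC/SI
    p: float  # Fisher p of presence (dose > 0) vs SC/SI
    intercept: float
    slope: float
    prob_sc: tuple[float, float, float]  # P(SC | dose = 0, 1, 2)
    separation: bool
    fit: LogisticFit


def allele_dose_fit(
    table: SSRGenotypeTable,
    phenotype: PhenotypeTable,
    marker: str,
    allele: int,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlleleDoseResult:
    """Logistic dose-response of SC status on allele copy number (0/1/2).

    Maximum-likelihood IRLS fit of logit P(SC) = intercept + slope * dose.
    Under complete or quasi separation (diverging MLE, or a phenotype-pure
    dose group) the fit falls back to the bias-reduced Firth penalty and
    the ``separation`` flag is set.

    Raises
    ------
    ValueError
        If fewer than two distinct doses are observed.
    RuntimeError
        If neither fit converges.
    """
    geno, sc = _join_phenotype(table, phenotype)
    dose = geno.dose(marker, allele).dropna()
    dose = dose.loc[dose.index.intersection(sc.index)]
    y = sc.loc[dose.index].to_numpy(dtype=float)
    d = dose.to_numpy(dtype=float)
    if len(np.unique(d)) < 2:
        raise ValueError(
            f"allele {allele} at {marker}: fewer than two distinct doses observed"
        )
    dose_counts = np.zeros((3, 2), dtype=int)
    for k in (0, 1, 2):
        dose_counts[k, 0] = int(((d == k) & (y == 1)).sum())
        dose_counts[k, 1] = int(((d == k) & (y == 0)).sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        presence = np.array(
            [
                [dose_counts[1:, 0].sum(), dose_counts[1:, 1].sum()],
                [dose_counts[0, 0], dose_counts[0, 1]],
            ]
        )
        p_fisher = fisher_exact(presence)

    X = np.column_stack([np.ones_like(d), d])
    fit = fit_logistic(X, y, tol=tol, max_iter=max_iter)
    pure_group = any(
        row.sum() > 0 and (row[0] == 0 or row[1] == 0) for row in dose_counts
    )
    separation = fit.diverged or pure_group
    if separation:
        fit = fit_logistic(X, y, tol=tol, max_iter=max_iter, firth=True)
    if not fit.converged:
        raise RuntimeError(
            f"logistic fit did not converge for allele {allele} at {marker} "
            f"(firth={fit.firth}, n_iter={fit.n_iter}, coef={fit.coef})"
        )
    grid = np.column_stack([np.ones(3), np.arange(3.0)])
    probs = tuple(float(v) for v in fit.predict(grid))
    return AlleleDoseResult(
        marker=marker,
        allele=allele,
        dose_counts=dose_counts,
        p=p_fisher,
        intercept=float(fit.coef[0]),
        slope=float(fit.coef[1]),
        prob_sc=probs,  # type: ignore[arg-type]
        separation=separation,
        fit=fit,
    )
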