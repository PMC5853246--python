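"""Segregation-distortion scanning and fine-mapping of progeny marker tables.

A progeny marker table holds, per marker (chromosome, bp position), the
a/h/b genotype class of each individual (a = homozygous for the first
parental allele, h = heterozygous, b = homozygous for the second).  Skewed
segregation — departure from the Mendelian 1:2:1 of a selfed F2 — betrays
gamete or zygote selection at a linked incompatibility locus.  The causal
region is delimited by the nearest *informative* flanking markers around a
maximal run of markers in which one genotype class is completely absent
(no recombinant plants).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diagnostic_screen import bh_qvalues

__all__ = [
    "MarkerTable",
    "GenotypeCounts",
    "SegregationResult",
    "AbsentRun",
    "RegionReport",
    "genotype_counts",
    "segregation_test",
    "scan_markers",
    "find_absent_runs",
    "delimit_region",
]

CODES = ("a", "h", "b")

#: outcomes above this the exact multinomial tail falls back to chi-square
_EXACT_ENUM_LIMIT = 2_000_000


@dataclass
class MarkerTable:
    """Ordered markers x individuals with a/h/b/missing codes.

    ``info`` is indexed by marker name with columns ``chromosome`` and
    ``position`` (1-based bp); ``genotypes`` shares the index and has one
    column per individual with values ``'a'``/``'h'``/``'b'`` or NaN.
    Markers are sorted by (chromosome, position) with ties kept in input
    order, so downstream results do not depend on file order.
    """

    info: pd.DataFrame
    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.info.index.equals(self.genotypes.index):
            raise ValueError("info and genotypes must share the marker index")
        if self.info.index.has_duplicates:
            dups = self.info.index[self.info.index.duplicated()].tolist()
            raise ValueError(f"duplicate marker names: {dups}")
        bad = ~(self.genotypes.isin(CODES) | self.genotypes.isna())
        if bad.any().any():
            marker = bad.any(axis=1).idxmax()
            col = bad.loc[marker].idxmax()
            raise ValueError(
                f"invalid genotype code {self.genotypes.loc[marker, col]!r} "
                f"at marker {marker!r}, individual {col!r}"
            )
        order = self.info.assign(_ord=np.arange(len(self.info))).sort_values(
            ["chromosome", "position", "_ord"], kind="stable"
        )
        self.info = order.drop(columns="_ord")
        self.genotypes = self.genotypes.loc[self.info.index]

    @property
    def markers(self) -> list[str]:
        return self.info.index.tolist()

    @property
    def individuals(self) -> list[str]:
        return self.genotypes.columns.tolist()

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, prefix: str = "ind") -> "MarkerTable":
        """Expand per-marker (n_a, n_h, n_b) counts into pseudo-individuals.

        Individuals beyond a marker's genotyped total are set missing; the
        expansion reproduces the counts row for row.  Genotype patterns
        across markers carry no linkage information — use only for
        count-level analyses (tests, runs, region delimiting).
        """
        counts = counts.set_index("marker") if "marker" in counts else counts
        n_ind = int((counts[["n_a", "n_h", "n_b"]].sum(axis=1)).max())
        individuals = [f"{prefix}_{i:04d}" for i in range(1, n_ind + 1)]
        rows = {}
        for marker, row in counts.iterrows():
            codes = (
                ["a"] * int(row["n_a"])
                + ["h"] * int(row["n_h"])
                + ["b"] * int(row["n_b"])
            )
            codes += [None] * (n_ind - len(codes))
            rows[marker] = codes
        geno = pd.DataFrame.from_dict(rows, orient="index", columns=individuals)
        info = counts[["chromosome", "position"]].copy()
        return cls(info=info, genotypes=geno)


@dataclass(frozen=True)
class GenotypeCounts:
    n_a: int
    n_h: int
    n_b: int
    n_missing: int

    @property
    def n_called(self) -> int:
        return self.n_a + self.n_h + self.n_b

    def observed(self) -> tuple[int, int, int]:
        return (self.n_a, self.n_h, self.n_b)

    def of(self, cls: str) -> int:
        return {"a": self.n_a, "h": self.n_h, "b": self.n_b}[cls]


def genotype_counts(table: MarkerTable, marker: str) -> GenotypeCounts:
    """a/h/b/missing counts of one marker over all individuals."""
    if marker not in table.info.index:
        raise KeyError(f"unknown marker {marker!r}")
    row = table.genotypes.loc[marker]
    vc = row.value_counts()
    return GenotypeCounts(
        n_a=int(vc.get("a", 0)),
        n_h=int(vc.get("h", 0)),
        n_b=int(vc.get("b", 0)),
        n_missing=int(row.isna().sum()),
    )


def _exact_multinomial_tail(obs: np.ndarray, p: np.ndarray) -> float:
    """P of all outcomes no more probable than the observed one."""
    n = int(obs.sum())
    k = len(obs)
    if k == 2:
        xs = np.arange(n + 1)
        pmf = stats.binom.pmf(xs, n, p[0])
        p_obs = stats.binom.pmf(obs[0], n, p[0])
        return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-12)].sum()))
    # k == 3: enumerate the simplex
    xs = [(i, j, n - i - j) for i in range(n + 1) for j in range(n - i + 1)]
    arr = np.array(xs)
    pmf = stats.multinomial.pmf(arr, n, p)
    p_obs = stats.multinomial.pmf(obs, n, p)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-12)].sum()))


def segregation_test(
    counts: GenotypeCounts | Sequence[int],
    expected_ratio: Sequence[float],
) -> tuple[float, float]:
    """Goodness-of-fit of observed a/h/b counts to an expected ratio.

    Chi-square with df = (number of classes with nonzero expectation) - 1;
    when any expected count is below 5 an exact multinomial tail probability
    is used instead (sum of outcome probabilities no larger than the
    observed one).  Classes with zero expectation but nonzero observation
    make the fit impossible: statistic = inf, p = 0.

    Returns
    -------
    (statistic, p)
        ``statistic`` is NaN when the exact test is used.
    """
    obs = np.asarray(
        counts.observed() if isinstance(counts, GenotypeCounts) else counts,
        dtype=float,
    )
    ratio = np.asarray(expected_ratio, dtype=float)
    if len(obs) != len(ratio):
        raise ValueError("counts and expected_ratio must have the same length")
    if (ratio < 0).any() or ratio.sum() == 0:
        raise ValueError("expected_ratio must be nonnegative and not all zero")
    impossible = (ratio == 0) & (obs > 0)
    if impossible.any():
        return (math.inf, 0.0)
    keep = ratio > 0
    obs = obs[keep]
    p = ratio[keep] / ratio[keep].sum()
    n = obs.sum()
    if n == 0:
        raise ValueError("no genotyped individuals to test")
    if len(obs) == 1:
        return (0.0, 1.0)
    expected = n * p
    n_outcomes = n + 1 if len(obs) == 2 else (n + 1) * (n + 2) / 2
    if (expected < 5).any() and n_outcomes <= _EXACT_ENUM_LIMIT:
        return (math.nan, _exact_multinomial_tail(obs.astype(int), p))
    statistic = float(((obs - expected) ** 2 / expected).sum())
    pval = float(stats.chi2.sf(statistic, df=len(obs) - 1))
    return (statistic, pval)


@dataclass
class SegregationResult:
    marker: str
    chromosome: str
    position: int
    counts: GenotypeCounts
    expected_ratio: tuple[float, ...]
    statistic: float
    p: float
    q: float | None = None
    distorted: bool | None = None


def scan_markers(
    table: MarkerTable,
    expected_ratio: Sequence[float] = (1, 2, 1),
    alpha: float = 0.05,
    min_calls: int = 20,
) -> list[SegregationResult]:
    """Per-marker segregation tests with BH false-discovery-rate control.

    Markers with fewer than ``min_calls`` non-missing genotypes are not
    testable and are omitted.  A marker is flagged distorted when its BH
    q-value is <= ``alpha``.
    """
    results: list[SegregationResult] = []
    for marker in table.markers:
        c = genotype_counts(table, marker)
        if c.n_called < min_calls:
            continue
        stat, p = segregation_test(c, expected_ratio)
        results.append(
            SegregationResult(
                marker=marker,
                chromosome=str(table.info.loc[marker, "chromosome"]),
                position=int(table.info.loc[marker, "position"]),
                counts=c,
                expected_ratio=tuple(expected_ratio),
                statistic=stat,
                p=p,
            )
        )
    if not results:
        raise ValueError("no testable marker (all below min_calls)")
    qs = bh_qvalues([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
        r.distorted = bool(q <= alpha)
    return results


@dataclass
class AbsentRun:
    """Maximal run of consecutive markers with zero count of one class."""

    chromosome: str
    absent_class: str
    markers: list[str]

    @property
    def first(self) -> str:
        return self.markers[0]

    @property
    def last(self) -> str:
        return self.markers[-1]


def find_absent_runs(
    table: MarkerTable, absent_class: str, min_run: int = 1
) -> list[AbsentRun]:
    """Maximal runs of consecutive markers lacking ``absent_class`` entirely.

    Only markers with at least one non-missing call can attest the absence;
    all-missing markers interrupt nothing and belong to no run.
    """
    if absent_class not in CODES:
        raise ValueError(f"absent_class must be one of {CODES}")
    runs: list[AbsentRun] = []
    for chrom, block in table.info.groupby("chromosome", sort=False):
        current: list[str] = []
        for marker in block.index:
            c = genotype_counts(table, marker)
            if c.n_called > 0 and c.of(absent_class) == 0:
                current.append(marker)
            else:
                if len(current) >= min_run:
                    runs.append(AbsentRun(str(chrom), absent_class, current))
                current = []
        if len(current) >= min_run:
            runs.append(AbsentRun(str(chrom), absent_class, current))
    return runs


@dataclass
class RegionReport:
    """Candidate region delimited by informative flanking markers.

    Flanks are the nearest markers outside the run with a nonzero count of
    the absent class (recombinant plants observed there).  At a chromosome
    end the span is measured from the outermost run marker and the side is
    flagged open.
    """

    chromosome: str
    absent_class: str
    run_first: str
    run_last: str
    left_flank: tuple[str, int] | None
    right_flank: tuple[str, int] | None
    span_bp: int
    span_kb: float
    open_left: bool = False
    open_right: bool = False

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "absent_class": self.absent_class,
            "run_first": self.run_first,
            "run_last": self.run_last,
            "left_flank": list(self.left_flank) if self.left_flank else None,
            "right_flank": list(self.right_flank) if self.right_flank else None,
            "span_bp": self.span_bp,
            "span_kb": self.span_kb,
            "open_left": self.open_left,
            "open_right": self.open_right,
        }


def delimit_region(run: AbsentRun, table: MarkerTable) -> RegionReport:
    """Delimit the region of an absent-class run by informative flanks.

    The span is the plain difference of the flank positions in bp (kb =
    bp/1000), which reproduces printed fine-mapping spans computed the
    same way.
    """
    block = table.info[table.info["chromosome"] == run.chromosome]
    names = block.index.tolist()
    i0, i1 = names.index(run.first), names.index(run.last)

    def _informative(indices: Iterable[int]) -> tuple[str, int] | None:
        for i in indices:
            c = genotype_counts(table, names[i])
            if c.of(run.absent_class) > 0:
                return (names[i], int(block["position"].iloc[i]))
        return None

    left = _informative(range(i0 - 1, -1, -1))
    right = _informative(range(i1 + 1, len(names)))
    left_pos = left[1] if left else int(block["position"].iloc[i0])
    right_pos = right[1] if right else int(block["position"].iloc[i1])
    span = right_pos - left_pos
    return RegionReport(
        chromosome=run.chromosome,
        absent_class=run.absent_class,
        run_first=run.first,
        run_last=run.last,
        left_flank=left,
        right_flank=right,
        span_bp=span,
        span_kb=span / 1000.0,
        open_left=left is None,
        open_right=right is None,
    )
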