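"""Group-wise SSR allele frequencies and variety-specific (private) alleles.

The ancestral self-compatible cacao varieties (Amelonado, Criollo) are
fully homozygous, and some of their SSR alleles near the incompatibility
loci occur in no other genetic group — or leak at low frequency into groups
with known introgression.  Such private alleles flag the self-compatibility
haplotypes directly; where two groups share an allele, an allele at a
second marker that differs between the groups can resolve the haplotype's
origin.

Frequencies are simple allele-count proportions per group (no inbreeding
or null-allele correction; the reference varieties are homozygous, which
makes such corrections moot).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostic_screen import SSRGenotypeTable

__all__ = [
    "GroupedSSRTable",
    "SpecificAlleleReport",
    "Discriminator",
    "allele_frequencies",
    "specific_alleles",
    "haplotype_discriminators",
]


@dataclass
class GroupedSSRTable:
    """SSR genotypes with one genetic-group label per individual."""

    ssr: SSRGenotypeTable
    groups: pd.Series

    def __post_init__(self) -> None:
        missing = self.ssr.data.index.difference(self.groups.index)
        if len(missing):
            raise ValueError(f"individuals without a group label: {list(missing)[:5]}")
        self.groups = self.groups.loc[self.ssr.data.index]


def allele_frequencies(table: GroupedSSRTable) -> pd.DataFrame:
    """Allele frequencies per (group, marker, allele).

    frequency = allele count / (2 x non-missing individuals of the group);
    frequencies sum to 1 over the observed alleles of each (group, marker).
    A (group, marker) with zero non-missing calls is omitted with a warning.
    """
    records = []
    for group, idx in table.groups.groupby(table.groups).groups.items():
        sub = table.ssr.data.loc[idx]
        for marker in table.ssr.markers:
            cells = sub[marker].dropna()
            if cells.empty:
                warnings.warn(
                    f"group {group!r} has no genotyped individual at {marker!r}; "
                    "frequency row omitted"
                )
                continue
            counts: dict[int, int] = {}
            for a, b in cells:
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
            denom = 2 * len(cells)
            for allele in sorted(counts):
                records.append(
                    {
                        "group": group,
                        "marker": marker,
                        "allele": allele,
                        "count": counts[allele],
                        "n_alleles": denom,
                        "freq": counts[allele] / denom,
                    }
                )
    return pd.DataFrame.from_records(
        records, columns=["group", "marker", "allele", "count", "n_alleles", "freq"]
    )


@dataclass
class SpecificAlleleReport:
    """An allele frequent in the target group and (near-)absent elsewhere.

    ``status`` is ``"strict"`` when the allele is entirely absent outside
    the target group, else ``"diagnostic-with-leakage"`` with the groups
    where it leaks (frequency in (0, epsilon]) listed — low-frequency
    leakage typically reflects introgression from the target variety.
    """

    marker: str
    allele: int
    target_group: str
    freq_target: float
    max_freq_elsewhere: float
    leakage_groups: tuple[str, ...]
    status: str

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "allele": self.allele,
            "target_group": self.target_group,
            "freq_target": self.freq_target,
            "max_freq_elsewhere": self.max_freq_elsewhere,
            "leakage_groups": list(self.leakage_groups),
            "status": self.status,
        }


def _freq(freqs: pd.DataFrame, group: str, marker: str, allele: int) -> float:
    row = freqs[
        (freqs["group"] == group)
        & (freqs["marker"] == marker)
        & (freqs["allele"] == allele)
    ]
    return float(row["freq"].iloc[0]) if len(row) else 0.0


def specific_alleles(
    freqs: pd.DataFrame,
    target_group: str,
    epsilon: float = 0.05,
    f_min: float = 0.5,
) -> list[SpecificAlleleReport]:
    """Alleles with frequency >= f_min in the target and <= epsilon elsewhere.

    With ``epsilon = 0`` this is the exact set difference of observed allele
    sets (strictly private alleles).
    """
    groups = freqs["group"].unique()
    if target_group not in groups:
        raise KeyError(f"unknown group {target_group!r}")
    others = [g for g in groups if g != target_group]
    reports: list[SpecificAlleleReport] = []
    target_rows = freqs[(freqs["group"] == target_group) & (freqs["freq"] >= f_min)]
    for _, row in target_rows.iterrows():
        marker, allele = row["marker"], int(row["allele"])
        elsewhere = {g: _freq(freqs, g, marker, allele) for g in others}
        max_else = max(elsewhere.values(), default=0.0)
        if max_else > epsilon:
            continue
        leakage = tuple(sorted(g for g, f in elsewhere.items() if 0.0 < f <= epsilon))
        reports.append(
            SpecificAlleleReport(
                marker=marker,
                allele=allele,
                target_group=target_group,
                freq_target=float(row["freq"]),
                max_freq_elsewhere=max_else,
                leakage_groups=leakage,
                status="strict" if max_else == 0.0 else "diagnostic-with-leakage",
            )
        )
    reports.sort(key=lambda r: (r.marker, r.allele))
    return reports


@dataclass
class Discriminator:
    """A second-marker allele resolving the origin of a shared allele."""

    marker: str
    allele: int
    present_in: str  # the group whose haplotype this allele indicates
    absent_in: str
    freq_present: float
    freq_absent: float


def haplotype_discriminators(
    freqs: pd.DataFrame,
    group_a: str,
    group_b: str,
    shared_allele: tuple[str, int],
    epsilon: float = 0.05,
    f_min: float = 0.5,
) -> list[Discriminator]:
    """Alleles at other markers that separate two groups sharing an allele.

    Both directions are searched and labeled: alleles frequent (>= f_min)
    in one group and (near-)absent (<= epsilon) in the other resolve which
    group a haplotype carrying the shared allele came from.
    """
    shared_marker, shared = shared_allele
    for g in (group_a, group_b):
        if _freq(freqs, g, shared_marker, shared) == 0.0:
            raise ValueError(
                f"shared allele {shared} at {shared_marker!r} absent from group {g!r}"
            )
    out: list[Discriminator] = []
    markers = [m for m in freqs["marker"].unique() if m != shared_marker]
    for marker in markers:
        alleles = sorted(
            freqs[freqs["marker"] == marker]["allele"].unique().astype(int)
        )
        for allele in alleles:
            fa = _freq(freqs, group_a, marker, allele)
            fb = _freq(freqs, group_b, marker, allele)
            if fa >= f_min and fb <= epsilon:
                out.append(Discriminator(marker, allele, group_a, group_b, fa, fb))
            if fb >= f_min and fa <= epsilon:
                out.append(Discriminator(marker, allele, group_b, group_a, fb, fa))
    return out
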