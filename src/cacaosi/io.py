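"""Readers and writers for the pipeline's TSV/YAML/JSON dialects.

All tabular files are tab-delimited UTF-8 with a header row.  Readers
validate rather than coerce: malformed genotype codes or allele cells are
reported with their location.  Positions may be transcribed with embedded
spaces ("4 021 267"), which are stripped.  Missing tokens are ".", "NA"
and the empty string.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .diagnostic_screen import PhenotypeTable, SSRGenotypeTable
from .population_alleles import GroupedSSRTable
from .qpcr_expression import CtTable
from .segregation_scan import CODES, MarkerTable
from .si_model import (
    CrossSpec,
    DiploidGenotype,
    GameticFusionRule,
    SAllele,
    SIModel,
    ZygoticEliminationRule,
)

__all__ = [
    "read_marker_table",
    "write_marker_table",
    "read_ssr_table",
    "write_ssr_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_grouped_ssr_table",
    "read_ct_table",
    "write_ct_table",
    "load_config",
    "build_model",
    "build_cross",
    "write_json",
]

MISSING_TOKENS = {".", "NA", ""}


def _parse_position(raw: str, line: int) -> int:
    cleaned = str(raw).replace(" ", "").replace(" ", "")
    try:
        return int(cleaned)
    except ValueError:
        raise ValueError(f"line {line}: non-numeric position {raw!r}") from None


def read_marker_table(path: str | Path) -> MarkerTable:
    """Read a progeny marker table (marker, chrom, pos, one column per tree)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["marker", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: first columns must be {required}, got "
                         f"{list(df.columns[:3])}")
    if df["marker"].duplicated().any():
        dups = df.loc[df["marker"].duplicated(), "marker"].tolist()
        raise ValueError(f"{path}: duplicate marker names {dups}")
    positions = [
        _parse_position(raw, i + 2) for i, raw in enumerate(df["pos"])
    ]
    individuals = df.columns[3:].tolist()
    geno = {}
    for col in individuals:
        vals = []
        for i, raw in enumerate(df[col]):
            v = raw.strip()
            if v in MISSING_TOKENS:
                vals.append(None)
            elif v in CODES:
                vals.append(v)
            else:
                raise ValueError(
                    f"{path}: line {i + 2}, individual {col!r}: "
                    f"invalid genotype code {raw!r}"
                )
        geno[col] = vals
    info = pd.DataFrame(
        {"chromosome": df["chrom"].tolist(), "position": positions},
        index=pd.Index(df["marker"], name="marker"),
    )
    genotypes = pd.DataFrame(geno, index=info.index)
    return MarkerTable(info=info, genotypes=genotypes)


def write_marker_table(table: MarkerTable, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "marker": table.info.index,
            "chrom": table.info["chromosome"].to_numpy(),
            "pos": table.info["position"].to_numpy(),
        }
    )
    geno = table.genotypes.reset_index(drop=True).fillna(".")
    out = pd.concat([out, geno], axis=1)
    out.to_csv(path, sep="\t", index=False)


def _parse_allele_pair(raw: str, line: int, col: str) -> tuple[int, int] | None:
    v = str(raw).strip()
    if v in MISSING_TOKENS:
        return None
    parts = v.split("/")
    if len(parts) != 2:
        raise ValueError(
            f"line {line}, marker {col!r}: allele cell {raw!r} is not 'a1/a2'"
        )
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError:
        raise ValueError(
            f"line {line}, marker {col!r}: non-numeric allele in {raw!r}"
        ) from None
    return (a, b) if a <= b else (b, a)


def read_ssr_table(path: str | Path) -> SSRGenotypeTable:
    """Read an SSR genotype table (individual, then 'a1/a2' marker columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "individual":
        raise ValueError(f"{path}: first column must be 'individual'")
    markers = [c for c in df.columns[1:] if c != "group"]
    cells = {}
    for col in markers:
        cells[col] = [
            _parse_allele_pair(raw, i + 2, col) for i, raw in enumerate(df[col])
        ]
    data = pd.DataFrame(cells, index=pd.Index(df["individual"], name="individual"))
    return SSRGenotypeTable(data)


def write_ssr_table(
    table: SSRGenotypeTable, path: str | Path, groups: pd.Series | None = None
) -> None:
    out = pd.DataFrame(index=table.data.index)
    for marker in table.markers:
        out[marker] = table.data[marker].map(
            lambda g: f"{g[0]}/{g[1]}", na_action="ignore"
        )
    out = out.fillna(".")
    if groups is not None:
        out["group"] = groups.loc[out.index]
    out.index.name = "individual"
    out.reset_index().to_csv(path, sep="\t", index=False)


def read_phenotype_table(
    path: str | Path, ssr: SSRGenotypeTable | None = None
) -> PhenotypeTable:
    """Read phenotypes (individual, sc_status[, fruit_set_pct]).

    When ``ssr`` is given, phenotyped individuals absent from the SSR table
    are dropped with a warning (they cannot join the screen).
    """
    df = pd.read_csv(path, sep="\t", na_values=sorted(MISSING_TOKENS))
    if "individual" not in df.columns or "sc_status" not in df.columns:
        raise ValueError(f"{path}: need columns individual, sc_status")
    df = df.set_index("individual")
    if ssr is not None:
        unknown = df.index.difference(ssr.data.index)
        if len(unknown):
            warnings.warn(
                f"{len(unknown)} phenotyped individuals absent from the SSR "
                f"table were excluded (e.g. {list(unknown)[:3]})"
            )
            df = df.loc[df.index.intersection(ssr.data.index)]
    return PhenotypeTable(df)


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    table.data.reset_index(names="individual").to_csv(path, sep="\t", index=False)


def read_grouped_ssr_table(path: str | Path) -> GroupedSSRTable:
    """Read an SSR table that carries a 'group' column."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "group" not in df.columns:
        raise ValueError(f"{path}: grouped SSR table needs a 'group' column")
    ssr = read_ssr_table(path)
    groups = pd.Series(
        df["group"].tolist(), index=pd.Index(df["individual"]), name="group"
    )
    return GroupedSSRTable(ssr, groups)


def read_ct_table(path: str | Path) -> CtTable:
    df = pd.read_csv(path, sep="\t", na_values=sorted(MISSING_TOKENS))
    return CtTable(df)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _alleles_from_config(cfg: Mapping) -> dict[str, SAllele]:
    alleles = {}
    for spec in cfg.get("alleles", []):
        alleles[spec["id"]] = SAllele(
            id=spec["id"],
            activity=spec.get("activity", "active"),
            dominance_rank=spec.get("dominance_rank"),
            linked_ssr=tuple(
                (m, int(s)) for m, s in (spec.get("linked_ssr") or {}).items()
            ),
        )
    return alleles


def build_model(cfg: Mapping) -> SIModel:
    """Build an :class:`SIModel` from a config mapping.

    Keys: ``gametic_loci`` (list of locus names, optional scope via
    ``gametic_scope``), ``ch1_elimination_pairs`` as
    ``{locus: [[activator, target], ...]}`` and optional
    ``activator_scope``.
    """
    gametic = {
        locus: GameticFusionRule(expression_scope=cfg.get("gametic_scope", "both"))
        for locus in cfg.get("gametic_loci", [])
    }
    zygotic = {}
    for locus, pairs in (cfg.get("ch1_elimination_pairs") or {}).items():
        zygotic[locus] = ZygoticEliminationRule(
            elimination_pairs=frozenset((a, t) for a, t in pairs),
            activator_scope=cfg.get("activator_scope", "either"),
        )
    return SIModel(gametic_rules=gametic, zygotic_rules=zygotic)


def build_cross(cfg: Mapping, alleles: Mapping[str, SAllele] | None = None) -> CrossSpec:
    """Build a :class:`CrossSpec` from a config mapping.

    ``cross.mother`` / ``cross.father`` map locus -> pair of allele ids
    declared under ``alleles``.
    """
    alleles = alleles if alleles is not None else _alleles_from_config(cfg)
    cross_cfg = cfg["cross"]

    def _parent(side: str) -> dict[str, DiploidGenotype]:
        out = {}
        for locus, pair in cross_cfg[side].items():
            try:
                a, b = (alleles[p] for p in pair)
            except KeyError as e:
                raise ValueError(f"undeclared allele {e} in cross.{side}") from None
            out[locus] = DiploidGenotype(locus, (a, b))
        return out

    return CrossSpec(
        mother=_parent("mother"),
        father=_parent("father"),
        n_offspring=int(cross_cfg.get("n", cfg.get("n", 100))),
        mentor_fraction=float(cross_cfg.get("mentor_fraction", 0.0)),
        baseline_abortion=float(cross_cfg.get("baseline_abortion", 0.10)),
    )


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
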