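"""Seeded generators for every input the analysis pipeline consumes.

Three generators emulate the study's data layers:

* :func:`gen_progeny_marker_table` — a selfed/crossed progeny segregating
  under the incompatibility model, with per-marker recombination against
  the selected locus (reproducing the fine-mapping pattern: a core run of
  markers with one genotype class absent, flanking markers with a few
  recombinant calls) and optional missingness;
* :func:`gen_association_population` — an association panel with K genetic
  subgroups, group-specific SSR allele-frequency profiles, latent
  S-genotypes that determine SC/SI through the dominance engine of
  :mod:`cacaosi.si_model`, and tunable linkage disequilibrium between a
  designated SSR allele and an S allele (the planted diagnostic allele);
* :func:`gen_ct_table` — replicated qPCR Ct measurements with configurable
  per-condition log2 effects and Gaussian cycle noise, references unshifted.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diagnostic_screen import PhenotypeTable, SSRGenotypeTable
from .population_alleles import GroupedSSRTable
from .segregation_scan import MarkerTable
from .si_model import (
    CrossSpec,
    SAllele,
    SIModel,
    DiploidGenotype,
    GameticFusionRule,
    expressed_specificities,
    simulate_progeny,
)

__all__ = [
    "MarkerDef",
    "ProgenySimConfig",
    "AssocPopConfig",
    "gen_progeny_marker_table",
    "gen_association_population",
    "gen_ct_table",
    "default_assoc_config",
    "tsh516_f2_config",
]


@dataclass(frozen=True)
class MarkerDef:
    """A marker tied to a modeled locus by a recombination fraction."""

    name: str
    chromosome: str  # must name a locus of the cross
    position: int
    recomb_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.recomb_fraction <= 0.5:
            raise ValueError("recombination fraction must lie in [0, 0.5]")


@dataclass
class ProgenySimConfig:
    """Progeny marker-table generation: SI model + marker map + noise."""

    model: SIModel
    cross: CrossSpec
    marker_map: Sequence[MarkerDef]
    missingness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must lie in [0, 1)")
        loci = set(self.cross.loci)
        for m in self.marker_map:
            if m.chromosome not in loci:
                raise ValueError(
                    f"marker {m.name!r} is on {m.chromosome!r}, which is not a "
                    f"modeled locus ({sorted(loci)})"
                )


def gen_progeny_marker_table(config: ProgenySimConfig) -> MarkerTable:
    """Simulate a progeny and derive each marker's a/h/b codes.

    The S-locus genotype of each individual is simulated first (including
    gametic-fusion failures and pre-fusion zygote elimination); each marker
    then recombines independently against its locus: per gamete, the marker
    allele follows the haplotype the gamete carries, switched to the other
    parental haplotype with the marker's recombination fraction.  Both
    parents are assumed heterozygous at the markers in coupling phase with
    the S locus, as in the fine-mapping progenies.
    """
    rng = np.random.default_rng(config.seed)
    sim = simulate_progeny(config.cross, config.model, rng)
    off = sim.offspring
    n = len(off)
    individuals = off["individual"].tolist()
    rows: dict[str, list] = {}
    info_rows = []
    for m in config.marker_map:
        locus = m.chromosome
        fidx = off[f"{locus}_maternal_idx"].to_numpy()
        midx = off[f"{locus}_paternal_idx"].to_numpy()
        f_marker = fidx ^ (rng.random(n) < m.recomb_fraction)
        m_marker = midx ^ (rng.random(n) < m.recomb_fraction)
        total = f_marker.astype(int) + m_marker.astype(int)
        codes = np.array(["a", "h", "b"])[total]
        if config.missingness > 0:
            codes = codes.astype(object)
            codes[rng.random(n) < config.missingness] = None
        rows[m.name] = list(codes)
        info_rows.append((m.name, m.chromosome, m.position))
    info = pd.DataFrame(
        info_rows, columns=["marker", "chromosome", "position"]
    ).set_index("marker")
    geno = pd.DataFrame.from_dict(rows, orient="index", columns=individuals)
    return MarkerTable(info=info, genotypes=geno)


def tsh516_f2_config(
    n: int = 877,
    core_markers: int = 5,
    flank_recomb: float = 0.005,
    missingness: float = 0.0,
    seed: int = 0,
) -> ProgenySimConfig:
    """A ready-made selfed-F2 configuration mirroring the fine-mapping design.

    The selfed parent is heterozygous Sf (amorphous, Amelonado-type) /
    S_sca (active) at the chromosome-4 locus under a gametic-fusion rule,
    so the homozygous-active class 'b' is absent among survivors and a:h
    segregates 1:2.  ``core_markers`` fully linked markers sit inside the
    selected region and one flanking marker recombines at
    ``flank_recomb``.
    """
    sf = SAllele("Sf", activity="amorphous", dominance_rank=2)
    s_sca = SAllele("S_sca", activity="active", dominance_rank=1)
    geno = DiploidGenotype("CH4", (sf, s_sca))
    cross = CrossSpec.selfing({"CH4": geno}, n_offspring=n, baseline_abortion=0.0)
    model = SIModel(gametic_rules={"CH4": GameticFusionRule()})
    markers = [
        MarkerDef(f"syn_{i:03d}", "CH4", 10_000 + 5_000 * i, 0.0)
        for i in range(core_markers)
    ]
    markers.insert(0, MarkerDef("syn_flank_l", "CH4", 1_000, flank_recomb))
    markers.append(
        MarkerDef("syn_flank_r", "CH4", 10_000 + 5_000 * core_markers, flank_recomb)
    )
    return ProgenySimConfig(
        model=model, cross=cross, marker_map=markers, missingness=missingness, seed=seed
    )


@dataclass
class AssocPopConfig:
    """Association-panel generation with planted SSR-S-allele LD.

    ``r2`` is the squared haplotype correlation between carrying
    ``ld_allele`` at ``ld_marker`` and carrying ``ld_s_allele`` at the
    latent S locus; by construction the designated SSR allele's frequency
    equals that S allele's frequency.  SC status is assigned
    deterministically from the S genotype: a plant is SC iff it expresses
    no active specificity (dominance ranks decide expression).
    """

    n: int = 710
    group_weights: Mapping[str, float] = field(
        default_factory=lambda: {"Amelonado": 0.3, "Trinitario": 0.45, "Contamana": 0.25}
    )
    s_alleles: tuple[SAllele, ...] = ()
    s_freqs: Mapping[str, float] = field(default_factory=dict)
    ssr_profiles: Mapping[str, Mapping[str, Mapping[int, float]]] = field(
        default_factory=dict
    )
    ld_marker: str = "dSSR_1"
    ld_allele: int = 161
    ld_s_allele: str = "Sf"
    r2: float = 0.9
    missingness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must lie in [0, 1]")
        w = sum(self.group_weights.values())
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError("group weights must sum to 1")
        f = sum(self.s_freqs.values())
        if self.s_freqs and not math.isclose(f, 1.0, abs_tol=1e-9):
            raise ValueError("S-haplotype frequencies must sum to 1")
        for g, profile in self.ssr_profiles.items():
            for marker, freqs in profile.items():
                if not math.isclose(sum(freqs.values()), 1.0, abs_tol=1e-9):
                    raise ValueError(
                        f"SSR profile of group {g!r}, marker {marker!r} "
                        "does not sum to 1"
                    )


def default_assoc_config(n: int = 710, r2: float = 0.9, seed: int = 0) -> AssocPopConfig:
    """Defaults emulating the 710-tree screening panel.

    Three subgroups, eleven SSR markers, the classical six-allele S series
    with the amorphous Sf at frequency 0.40 (so roughly a third of trees
    are SC: Sf/Sf homozygotes plus Sf over the recessive S4/S5), and the
    planted diagnostic allele 161 at marker dSSR_1 in LD with Sf.
    """
    s_alleles = (
        SAllele("S1", dominance_rank=0),
        SAllele("S2", dominance_rank=1),
        SAllele("S3", dominance_rank=1),
        SAllele("Sf", activity="amorphous", dominance_rank=2),
        SAllele("S4", dominance_rank=3),
        SAllele("S5", dominance_rank=4),
    )
    s_freqs = {"S1": 0.15, "S2": 0.15, "S3": 0.10, "Sf": 0.40, "S4": 0.10, "S5": 0.10}
    rng = np.random.default_rng(12345)  # fixed profile-shape seed, not the data seed
    groups = ["Amelonado", "Trinitario", "Contamana"]
    markers = [f"dSSR_{i}" for i in range(1, 12)]
    profiles: dict[str, dict[str, dict[int, float]]] = {}
    for g in groups:
        profiles[g] = {}
        for m in markers:
            n_alleles = 5
            sizes = [120 + 4 * k for k in range(n_alleles)]
            w = rng.dirichlet(np.ones(n_alleles) * 2.0)
            profiles[g][m] = {s: float(p) for s, p in zip(sizes, w)}
    # the designated allele is drawn by the LD construction, keep it out of
    # the profile of its marker
    for g in groups:
        profiles[g]["dSSR_1"] = {
            s: p for s, p in profiles[g]["dSSR_1"].items() if s != 161
        }
        tot = sum(profiles[g]["dSSR_1"].values())
        profiles[g]["dSSR_1"] = {s: p / tot for s, p in profiles[g]["dSSR_1"].items()}
    return AssocPopConfig(
        n=n,
        s_alleles=s_alleles,
        s_freqs=s_freqs,
        ssr_profiles=profiles,
        ld_marker="dSSR_1",
        ld_allele=161,
        ld_s_allele="Sf",
        r2=r2,
        seed=seed,
    )


def gen_association_population(
    config: AssocPopConfig,
) -> tuple[SSRGenotypeTable, PhenotypeTable, GroupedSSRTable, dict]:
    """Draw an association panel and its ground truth.

    Returns the SSR genotype table, the SC/SI phenotype table, the grouped
    table for frequency analyses, and a truth record naming the planted
    diagnostic allele and the latent S genotypes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    alleles = {a.id: a for a in cfg.s_alleles}
    if cfg.ld_s_allele not in alleles:
        raise ValueError(f"LD target S allele {cfg.ld_s_allele!r} not among s_alleles")
    group_names = list(cfg.group_weights)
    groups = rng.choice(
        group_names, size=cfg.n, p=[cfg.group_weights[g] for g in group_names]
    )
    s_ids = list(cfg.s_freqs)
    s_p = np.array([cfg.s_freqs[s] for s in s_ids])
    hap1 = rng.choice(s_ids, size=cfg.n, p=s_p)
    hap2 = rng.choice(s_ids, size=cfg.n, p=s_p)

    # SC iff the S genotype expresses no active specificity
    sc_cache: dict[tuple[str, str], int] = {}

    def _sc(a: str, b: str) -> int:
        key = (a, b) if a <= b else (b, a)
        if key not in sc_cache:
            g = DiploidGenotype("S", (alleles[key[0]], alleles[key[1]]))
            sc_cache[key] = int(len(expressed_specificities(g)) == 0)
        return sc_cache[key]

    sc = np.array([_sc(a, b) for a, b in zip(hap1, hap2)])

    p_target = float(cfg.s_freqs[cfg.ld_s_allele])
    r = math.sqrt(cfg.r2)
    individuals = [f"tree_{i:04d}" for i in range(1, cfg.n + 1)]
    cells: dict[str, list] = {}
    markers = sorted({m for prof in cfg.ssr_profiles.values() for m in prof})
    for marker in markers:
        col = []
        for i in range(cfg.n):
            g = groups[i]
            profile = cfg.ssr_profiles[g][marker]
            sizes = list(profile)
            w = np.array([profile[s] for s in sizes])
            pair = []
            for hap in (hap1[i], hap2[i]):
                if marker == cfg.ld_marker:
                    if rng.random() < r:
                        # coupled draw: designated allele iff the S allele matches
                        if hap == cfg.ld_s_allele:
                            pair.append(cfg.ld_allele)
                        else:
                            pair.append(sizes[rng.choice(len(sizes), p=w)])
                    else:
                        # independent draw from the marginal law
                        if rng.random() < p_target:
                            pair.append(cfg.ld_allele)
                        else:
                            pair.append(sizes[rng.choice(len(sizes), p=w)])
                else:
                    pair.append(sizes[rng.choice(len(sizes), p=w)])
            col.append(tuple(sorted(pair)))
        cells[marker] = col
    data = pd.DataFrame(cells, index=individuals)
    if cfg.missingness > 0:
        mask = rng.random(data.shape) < cfg.missingness
        data = data.mask(pd.DataFrame(mask, index=data.index, columns=data.columns))
    ssr = SSRGenotypeTable(data)
    phen = PhenotypeTable(pd.DataFrame({"sc_status": sc}, index=individuals))
    grouped = GroupedSSRTable(ssr, pd.Series(groups, index=individuals, name="group"))
    truth = {
        "planted_marker": cfg.ld_marker,
        "planted_allele": cfg.ld_allele,
        "s_allele": cfg.ld_s_allele,
        "r2": cfg.r2,
        "n_sc": int(sc.sum()),
        "s_genotypes": list(zip(hap1.tolist(), hap2.tolist())),
    }
    return ssr, phen, grouped, truth


def gen_ct_table(
    effects: Mapping[tuple[str, str, str], float],
    noise_sd: float = 0.2,
    seed: int = 0,
    n_replicates: int = 3,
    reference_genes: Sequence[str] = ("REF1", "REF2"),
    calibrator: tuple[str, str] = ("unpollinated", "0h"),
):
    """Ct table with planted log2 fold effects per (gene, condition, window).

    Target genes get Ct = base - effect + noise (one cycle lower doubles
    expression); reference genes are never shifted.  Returns a
    :class:`~cacaosi.qpcr_expression.CtTable`.
    """
    from .qpcr_expression import CtTable

    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    genes = sorted({g for g, _, _ in effects})
    conditions = sorted({(c, t) for _, c, t in effects}) + [calibrator]
    conditions = sorted(set(conditions))
    base = {g: 24.0 + 0.5 * i for i, g in enumerate(genes)}
    for i, r in enumerate(reference_genes):
        base[r] = 20.0 + 0.5 * i
    records = []
    for cond, tw in conditions:
        for gene in list(genes) + list(reference_genes):
            eff = effects.get((gene, cond, tw), 0.0)
            if gene in reference_genes or (cond, tw) == calibrator:
                eff = 0.0
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                records.append(
                    {
                        "condition": cond,
                        "time_window": tw,
                        "gene": gene,
                        "replicate": rep,
                        "ct": base[gene] - eff + noise,
                    }
                )
    return CtTable(pd.DataFrame.from_records(records))
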