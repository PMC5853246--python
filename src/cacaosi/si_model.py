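"""Two-locus late-acting self-incompatibility model for *Theobroma cacao*.

Cacao self-incompatibility is late-acting: pollen tubes reach the ovary in
compatible and incompatible pollinations alike, and selection happens at the
embryo sac.  Two independent loci are modeled here, each with its own
selection rule family:

* a **gametic-fusion rule** (the chromosome-4 locus): a female/male gamete
  pair fails to fuse when both gametes carry the same specificity and that
  specificity is sporophytically expressed by the parents.  Which allele a
  diploid parent expresses follows a dominance hierarchy
  (classically S0 = S1 > S2 = S3 > Sf > S4 > S5, with Sf amorphous, i.e.
  producing no functional specificity).  Unfused ovules stay unfertilized
  and drive fruit drop.
* a **zygotic-elimination rule** (the chromosome-1 locus): certain
  homozygous zygotes (e.g. Amelonado/Amelonado) are eliminated before the
  gamete-fusion step whenever an activating allele (e.g. the Scavina 6
  allele) is carried by a parent.  Because the elimination acts pre-fusion,
  every ovule is still fertilized and the ovule-abortion rate is unchanged;
  only the genotype ratios among offspring are skewed.

The module provides exact conditional genotype distributions for arbitrary
crosses under these rules, a seeded Monte-Carlo twin of the analytic
calculation, a mentor-pollen mixed-pollination simulator (the technique used
to obtain selfed seed from self-incompatible trees), and an SSR-based
parentage classifier for separating selfed from outcrossed seedlings.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SAllele",
    "DiploidGenotype",
    "GameticFusionRule",
    "ZygoticEliminationRule",
    "SIModel",
    "CrossSpec",
    "GenotypeDistribution",
    "ProgenySimResult",
    "ConfigurationError",
    "FullyIncompatibleCrossError",
    "expressed_specificities",
    "expected_genotype_distribution",
    "expected_unfused_fraction",
    "simulate_progeny",
    "simulate_mixed_pollination",
    "classify_offspring_parentage",
    "classical_alleles",
]

GENOTYPE_CLASSES = ("a", "h", "b")


class ConfigurationError(ValueError):
    """A rule or allele set is incompletely or inconsistently specified."""


class FullyIncompatibleCrossError(RuntimeError):
    """Every gamete combination of a cross is eliminated; no offspring exist."""


@dataclass(frozen=True)
class SAllele:
    """One specificity allele of an incompatibility locus.

    Parameters
    ----------
    id:
        Allele label, e.g. ``"S1"``, ``"Sf"``, ``"S_sca"``.
    activity:
        ``"active"`` alleles produce a functional specificity; ``"amorphous"``
        alleles (such as the Amelonado ``Sf``) produce none and can never
        appear in an expressed-specificity set.
    dominance_rank:
        Position in the sporophytic dominance hierarchy; lower is more
        dominant, equal ranks are codominant.  ``None`` means unranked, which
        is an error wherever dominance matters.
    linked_ssr:
        Optional coupling-phase SSR allele sizes, as ``(marker, size_bp)``
        pairs, e.g. ``(("mSI_103", 223),)`` for the Amelonado CH1 haplotype.
    """

    id: str
    activity: Literal["active", "amorphous"] = "active"
    dominance_rank: int | None = None
    linked_ssr: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.activity not in ("active", "amorphous"):
            raise ConfigurationError(
                f"allele {self.id!r}: activity must be 'active' or 'amorphous', "
                f"got {self.activity!r}"
            )

    @property
    def is_active(self) -> bool:
        return self.activity == "active"

    def marker_allele(self, marker: str) -> int | None:
        """SSR allele size carried in coupling with this S allele, if known."""
        return dict(self.linked_ssr).get(marker)


def classical_alleles() -> dict[str, SAllele]:
    """The classical cacao S-allele series with its published dominance order.

    Ranks encode S0 = S1 > S2 = S3 > Sf > S4 > S5; Sf is amorphous.
    """
    spec = {
        "S0": (0, "active"),
        "S1": (0, "active"),
        "S2": (1, "active"),
        "S3": (1, "active"),
        "Sf": (2, "amorphous"),
        "S4": (3, "active"),
        "S5": (4, "active"),
    }
    return {
        name: SAllele(name, activity=act, dominance_rank=rank)
        for name, (rank, act) in spec.items()
    }


@dataclass(frozen=True)
class DiploidGenotype:
    """Unordered pair of S alleles at one locus.

    The input order of ``alleles`` is preserved (it supplies the default
    a/h/b class reference for crosses) but equality and hashing are
    order-insensitive.
    """

    locus: str
    alleles: tuple[SAllele, SAllele]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ConfigurationError("a diploid genotype has exactly two alleles")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiploidGenotype):
            return NotImplemented
        return self.locus == other.locus and sorted(
            a.id for a in self.alleles
        ) == sorted(a.id for a in other.alleles)

    def __hash__(self) -> int:
        return hash((self.locus, tuple(sorted(a.id for a in self.alleles))))

    @property
    def is_homozygous(self) -> bool:
        return self.alleles[0].id == self.alleles[1].id

    def carries(self, allele_id: str) -> bool:
        return any(a.id == allele_id for a in self.alleles)


def expressed_specificities(genotype: DiploidGenotype) -> frozenset[SAllele]:
    """Sporophytically expressed specificities of a diploid plant.

    The most dominant allele(s) of the pair are expressed; codominant alleles
    (equal rank) are expressed together.  Amorphous alleles are silent even
    when dominant, so e.g. Sf/S4 expresses nothing (S4 and S5 are recessive
    to Sf) and Sf/Sf expresses nothing — both are self-compatible.

    Raises
    ------
    ConfigurationError
        If any allele has no dominance rank.
    """
    for a in genotype.alleles:
        if a.dominance_rank is None:
            raise ConfigurationError(
                f"allele {a.id!r} has no dominance rank; cannot resolve expression"
            )
    top = min(a.dominance_rank for a in genotype.alleles)  # type: ignore[type-var]
    return frozenset(
        a for a in genotype.alleles if a.dominance_rank == top and a.is_active
    )


@dataclass(frozen=True)
class GameticFusionRule:
    """Gamete-fusion failure rule (chromosome-4 style).

    A female gamete carrying allele *s* fails to fuse with a male gamete
    carrying the same *s* iff *s* is sporophytically expressed by the
    parents.  ``expression_scope`` controls whether both parents must
    express *s* (default) or the mother alone; the printed crosses do not
    fully determine this, so it is configurable.
    """

    expression_scope: Literal["both", "mother"] = "both"

    def failure_matrix(
        self, mother: DiploidGenotype, father: DiploidGenotype
    ) -> np.ndarray:
        """2x2 boolean matrix over (maternal haplotype, paternal haplotype)."""
        m_expr = expressed_specificities(mother)
        if self.expression_scope == "both":
            shared = m_expr & expressed_specificities(father)
        else:
            shared = m_expr
        shared_ids = {a.id for a in shared}
        out = np.zeros((2, 2), dtype=bool)
        for i, f in enumerate(mother.alleles):
            for j, m in enumerate(father.alleles):
                out[i, j] = f.id == m.id and f.id in shared_ids
        return out


@dataclass(frozen=True)
class ZygoticEliminationRule:
    """Pre-fusion zygote elimination rule (chromosome-1 style).

    ``elimination_pairs`` is a set of ``(activator, target)`` allele-id
    pairs: the homozygous zygote target/target is eliminated whenever the
    activator allele is carried by a parent in ``activator_scope``.  The
    elimination acts before gamete fusion, so it skews genotype ratios
    without adding ovule abortion.
    """

    elimination_pairs: frozenset[tuple[str, str]]
    activator_scope: Literal["either", "mother", "father"] = "either"

    def elimination_matrix(
        self, mother: DiploidGenotype, father: DiploidGenotype
    ) -> np.ndarray:
        if self.activator_scope == "mother":
            parents = (mother,)
        elif self.activator_scope == "father":
            parents = (father,)
        else:
            parents = (mother, father)
        out = np.zeros((2, 2), dtype=bool)
        for i, f in enumerate(mother.alleles):
            for j, m in enumerate(father.alleles):
                if f.id != m.id:
                    continue
                out[i, j] = any(
                    tgt == f.id and any(p.carries(act) for p in parents)
                    for act, tgt in self.elimination_pairs
                )
        return out


@dataclass
class SIModel:
    """Per-locus selection rules of the incompatibility system."""

    gametic_rules: dict[str, GameticFusionRule] = field(default_factory=dict)
    zygotic_rules: dict[str, ZygoticEliminationRule] = field(default_factory=dict)

    @classmethod
    def none(cls) -> "SIModel":
        """Rule-free model: every cross is purely Mendelian."""
        return cls()


@dataclass
class CrossSpec:
    """A cross (or selfing) between two diploid parents.

    ``class_alleles`` optionally fixes, per locus, which allele counts as
    the 'a'-class reference and which as 'b'; the default is the mother's
    allele pair in its input order.
    """

    mother: Mapping[str, DiploidGenotype]
    father: Mapping[str, DiploidGenotype]
    n_offspring: int = 100
    mentor_fraction: float = 0.0
    baseline_abortion: float = 0.10
    class_alleles: Mapping[str, tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if set(self.mother) != set(self.father):
            raise ConfigurationError("mother and father must share the same loci")
        if not 0.0 <= self.mentor_fraction <= 1.0:
            raise ConfigurationError("mentor_fraction must lie in [0, 1]")
        if not 0.0 <= self.baseline_abortion < 1.0:
            raise ConfigurationError("baseline_abortion must lie in [0, 1)")

    @classmethod
    def selfing(cls, genotypes: Mapping[str, DiploidGenotype], **kw) -> "CrossSpec":
        return cls(mother=dict(genotypes), father=dict(genotypes), **kw)

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.mother)

    def class_reference(self, locus: str) -> tuple[str, str]:
        if self.class_alleles and locus in self.class_alleles:
            return tuple(self.class_alleles[locus])  # type: ignore[return-value]
        pair = self.mother[locus].alleles
        return (pair[0].id, pair[1].id)


def _classify(female_id: str, male_id: str, ref: tuple[str, str]) -> str:
    ref_a, ref_b = ref
    ids = sorted((female_id, male_id))
    if ids == sorted((ref_a, ref_a)):
        return "a"
    if ids == sorted((ref_b, ref_b)):
        return "b"
    if ids == sorted((ref_a, ref_b)):
        return "h"
    return "other"


@dataclass
class GenotypeDistribution:
    """Conditional genotype-class probabilities among surviving offspring."""

    probs: dict[str, dict[str, float]]  # locus -> class -> probability

    def __getitem__(self, locus: str) -> dict[str, float]:
        return self.probs[locus]

    def as_tuple(self, locus: str) -> tuple[float, float, float]:
        p = self.probs[locus]
        return (p.get("a", 0.0), p.get("h", 0.0), p.get("b", 0.0))


def _locus_matrices(
    cross: CrossSpec, model: SIModel, locus: str
) -> tuple[np.ndarray, np.ndarray]:
    """(fail, eliminate) 2x2 boolean matrices over haplotype index pairs."""
    mother = cross.mother[locus]
    father = cross.father[locus]
    fail = np.zeros((2, 2), dtype=bool)
    elim = np.zeros((2, 2), dtype=bool)
    if locus in model.gametic_rules:
        fail = model.gametic_rules[locus].failure_matrix(mother, father)
    if locus in model.zygotic_rules:
        elim = model.zygotic_rules[locus].elimination_matrix(mother, father)
    return fail, elim


def expected_genotype_distribution(
    cross: CrossSpec, model: SIModel
) -> GenotypeDistribution:
    """Exact conditional a/h/b probabilities among surviving offspring.

    Starts from Mendelian gamete-pair probabilities (each haplotype drawn
    with probability 1/2 from each parent), removes pairs failing the
    gametic-fusion rule and zygotes removed by the pre-fusion elimination
    rule, and renormalizes per locus.  Loci are unlinked, so the
    renormalization is exact locus by locus.

    Raises
    ------
    FullyIncompatibleCrossError
        If every gamete combination at some locus is eliminated.
    """
    probs: dict[str, dict[str, float]] = {}
    for locus in cross.loci:
        fail, elim = _locus_matrices(cross, model, locus)
        ref = cross.class_reference(locus)
        mother = cross.mother[locus]
        father = cross.father[locus]
        acc: dict[str, float] = {c: 0.0 for c in GENOTYPE_CLASSES}
        total = 0.0
        for i, f in enumerate(mother.alleles):
            for j, m in enumerate(father.alleles):
                if fail[i, j] or elim[i, j]:
                    continue
                cls = _classify(f.id, m.id, ref)
                acc[cls] = acc.get(cls, 0.0) + 0.25
                total += 0.25
        if total == 0.0:
            raise FullyIncompatibleCrossError(
                f"all gamete combinations eliminated at locus {locus!r}"
            )
        probs[locus] = {c: p / total for c, p in acc.items()}
    return GenotypeDistribution(probs)


def expected_unfused_fraction(cross: CrossSpec, model: SIModel) -> float:
    """Probability that a random ovule's gamete pair fails fusion.

    Computed before any renormalization and excluding baseline abortion.
    With gametic rules at several loci the failures combine independently.
    """
    p_fuse = 1.0
    for locus in cross.loci:
        fail, _ = _locus_matrices(cross, model, locus)
        p_fail = fail.sum() * 0.25
        p_fuse *= 1.0 - p_fail
    return 1.0 - p_fuse


_MAX_REDRAW_ROUNDS = 1000


def _draw_gametes(
    cross: CrossSpec,
    model: SIModel,
    n: int,
    rng: np.random.Generator,
    active: np.ndarray,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], np.ndarray]:
    """Sample haplotype indices per locus for ``n`` ovules.

    Returns (maternal index per locus, paternal index per locus, unfused
    mask).  ``active`` masks ovules that take part at all (not baseline
    aborted).  Gametic-fusion failures mark ovules unfused; zygotes hit by
    an elimination rule are redrawn (full gamete pair) so the ovule is
    still fertilized — the pre-fusion contract.
    """
    fidx = {loc: rng.integers(0, 2, n) for loc in cross.loci}
    midx = {loc: rng.integers(0, 2, n) for loc in cross.loci}
    unfused = np.zeros(n, dtype=bool)
    for locus in cross.loci:
        fail, elim = _locus_matrices(cross, model, locus)
        if fail.any():
            unfused |= active & fail[fidx[locus], midx[locus]]
    fertilized = active & ~unfused
    for locus in cross.loci:
        fail, elim = _locus_matrices(cross, model, locus)
        if not elim.any():
            continue
        reject = elim | fail  # a redraw must not land on a non-fusing pair
        if reject.all():
            raise FullyIncompatibleCrossError(
                f"every zygote at locus {locus!r} is eliminated; redraw cannot succeed"
            )
        bad = fertilized & reject[fidx[locus], midx[locus]]
        rounds = 0
        while bad.any():
            rounds += 1
            if rounds > _MAX_REDRAW_ROUNDS:
                raise FullyIncompatibleCrossError(
                    f"gamete redraw at locus {locus!r} did not terminate"
                )
            k = int(bad.sum())
            fidx[locus][bad] = rng.integers(0, 2, k)
            midx[locus][bad] = rng.integers(0, 2, k)
            bad = fertilized & reject[fidx[locus], midx[locus]]
    return fidx, midx, unfused


@dataclass
class ProgenySimResult:
    """Outcome of a simulated pollination.

    ``offspring`` has one row per fertilized ovule: the a/h/b class and the
    maternal/paternal haplotype index per locus, the pollen source
    (``self``/``mentor``), and a viability flag (mentor embryos are flat and
    nonviable; self embryos in dropped fruits never mature).
    ``ovule_fates`` counts fertilized / unfused / baseline-aborted ovules;
    the three always sum to the total ovule count.
    """

    offspring: pd.DataFrame
    ovule_fates: dict[str, int]
    fruit_retained: np.ndarray | None = None

    @property
    def viable_offspring(self) -> pd.DataFrame:
        if "viable" not in self.offspring.columns:
            return self.offspring
        return self.offspring[self.offspring["viable"]]

    def class_counts(self, locus: str, viable_only: bool = True) -> Counter:
        table = self.viable_offspring if viable_only else self.offspring
        return Counter(table[f"{locus}_class"].dropna())


def _offspring_frame(
    cross: CrossSpec,
    fidx: Mapping[str, np.ndarray],
    midx: Mapping[str, np.ndarray],
    keep: np.ndarray,
) -> pd.DataFrame:
    idx = np.flatnonzero(keep)
    data: dict[str, object] = {"individual": [f"off_{i:05d}" for i in idx]}
    for locus in cross.loci:
        mother = cross.mother[locus]
        father = cross.father[locus]
        ref = cross.class_reference(locus)
        f_ids = np.array([a.id for a in mother.alleles])[fidx[locus][idx]]
        m_ids = np.array([a.id for a in father.alleles])[midx[locus][idx]]
        data[f"{locus}_class"] = [
            _classify(f, m, ref) for f, m in zip(f_ids, m_ids)
        ]
        data[f"{locus}_maternal"] = f_ids
        data[f"{locus}_paternal"] = m_ids
        data[f"{locus}_maternal_idx"] = fidx[locus][idx]
        data[f"{locus}_paternal_idx"] = midx[locus][idx]
    return pd.DataFrame(data)


def simulate_progeny(
    cross: CrossSpec, model: SIModel, seed: int | np.random.Generator
) -> ProgenySimResult:
    """Monte-Carlo twin of :func:`expected_genotype_distribution`.

    Each of ``cross.n_offspring`` ovules is baseline-aborted with
    probability ``cross.baseline_abortion``, then receives a Mendelian
    gamete pair.  Pairs failing a gametic-fusion rule are recorded as
    unfused ovules; zygotes hit by an elimination rule are redrawn so the
    ovule is still fertilized.  Offspring class frequencies converge to the
    analytic conditional distribution.
    """
    if cross.n_offspring < 1:
        raise ConfigurationError("n_offspring must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = cross.n_offspring
    aborted = rng.random(n) < cross.baseline_abortion
    fidx, midx, unfused = _draw_gametes(cross, model, n, rng, ~aborted)
    fertilized = ~aborted & ~unfused
    offspring = _offspring_frame(cross, fidx, midx, fertilized)
    offspring["parentage"] = "self" if cross.mother == cross.father else "cross"
    offspring["viable"] = True
    fates = {
        "fertilized": int(fertilized.sum()),
        "unfused": int(unfused.sum()),
        "baseline_aborted": int(aborted.sum()),
    }
    return ProgenySimResult(offspring=offspring, ovule_fates=fates)


def simulate_mixed_pollination(
    cross: CrossSpec,
    model: SIModel,
    ovules_per_fruit: int,
    retention_threshold: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> ProgenySimResult:
    """Mentor-pollen mixed pollination of ``cross.mother``.

    Each ovule is pollinated by mentor pollen (compatible, heterospecific)
    with probability ``cross.mentor_fraction`` and by the cross's own pollen
    otherwise.  Mentor-fertilized embryos are flat and nonviable but their
    fused ovules count toward fruit retention; a fruit is retained iff its
    fused-ovule proportion is >= ``retention_threshold`` (default 0: mentor
    pollination always rescues the fruit).  Viable offspring are the
    self/cross-derived embryos of retained fruits.

    ``cross.n_offspring`` is the total ovule count; it is rounded up to a
    whole number of fruits of ``ovules_per_fruit`` ovules.
    """
    if ovules_per_fruit < 1:
        raise ConfigurationError("ovules_per_fruit must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_fruits = max(1, math.ceil(cross.n_offspring / ovules_per_fruit))
    n = n_fruits * ovules_per_fruit
    fruit_of = np.repeat(np.arange(n_fruits), ovules_per_fruit)

    aborted = rng.random(n) < cross.baseline_abortion
    mentor = rng.random(n) < cross.mentor_fraction
    self_active = ~aborted & ~mentor
    fidx, midx, unfused = _draw_gametes(cross, model, n, rng, self_active)
    fused = (~aborted & mentor) | (self_active & ~unfused)

    fused_frac = np.bincount(fruit_of, weights=fused, minlength=n_fruits) / float(
        ovules_per_fruit
    )
    retained = fused_frac >= retention_threshold

    self_fert = self_active & ~unfused
    offspring = _offspring_frame(cross, fidx, midx, self_fert)
    self_idx = np.flatnonzero(self_fert)
    offspring["parentage"] = "self" if cross.mother == cross.father else "cross"
    offspring["fruit"] = fruit_of[self_idx]
    offspring["viable"] = retained[fruit_of[self_idx]]

    mentor_idx = np.flatnonzero(~aborted & mentor)
    mentor_rows = pd.DataFrame(
        {
            "individual": [f"off_{i:05d}" for i in mentor_idx],
            "parentage": "mentor",
            "fruit": fruit_of[mentor_idx],
            "viable": False,
        }
    )
    offspring = pd.concat([offspring, mentor_rows], ignore_index=True, sort=False)
    offspring = offspring.sort_values("individual", ignore_index=True)

    fates = {
        "fertilized": int(fused.sum()),
        "unfused": int((self_active & unfused).sum()),
        "baseline_aborted": int(aborted.sum()),
    }
    return ProgenySimResult(
        offspring=offspring, ovule_fates=fates, fruit_retained=retained
    )


SSRProfile = Mapping[str, tuple[int, int] | None]


def classify_offspring_parentage(
    offspring: SSRProfile,
    seed_parent: SSRProfile,
    outcross_parent: SSRProfile,
    markers: Sequence[str] | None = None,
) -> str:
    """Classify a seedling as ``self``, ``outcross`` or ``ambiguous``.

    A seedling is an outcross when at some marker it carries an allele
    absent from the seed parent and present in the outcross parent.  It is
    a self when every allele is derivable from the seed parent and at least
    one marker excludes the outcross parent as pollen donor (no allele
    assignment seed x outcross explains the seedling there).  Anything else
    is ambiguous.

    Raises
    ------
    ValueError
        If no marker is genotyped in all three profiles.
    """
    names = list(markers) if markers is not None else sorted(offspring)
    usable = [
        m
        for m in names
        if offspring.get(m) is not None
        and seed_parent.get(m) is not None
        and outcross_parent.get(m) is not None
    ]
    if not usable:
        raise ValueError("no marker genotyped in offspring and both parents")

    foreign_from_outcross = False
    all_from_seed = True
    excludes_outcross = False
    for m in usable:
        o = offspring[m]
        s = set(seed_parent[m])  # type: ignore[arg-type]
        x = set(outcross_parent[m])  # type: ignore[arg-type]
        for allele in o:  # type: ignore[union-attr]
            if allele not in s:
                all_from_seed = False
                if allele in x:
                    foreign_from_outcross = True
        o1, o2 = o  # type: ignore[misc]
        compatible_with_outcross = (o1 in s and o2 in x) or (o2 in s and o1 in x)
        if not compatible_with_outcross:
            excludes_outcross = True

    if foreign_from_outcross:
        return "outcross"
    if all_from_seed and excludes_outcross:
        return "self"
    return "ambiguous"
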