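"""Combinatorics and population genetics of somatic-incompatibility loci.

Basidiomycete mycelia spend most of their life as heterokaryons: two haploid
nuclei sharing one cytoplasm.  Somatic incompatibility (SI) between two
mycelia is determined by the *sets* of alleles they carry at each
incompatibility locus — two mycelia tolerate each other exactly when, locus
by locus, they carry the same unordered allele set, so that no unmodified
target protein ever meets a foreign reader.

This module answers the quantitative questions that follow from that
predicate: given allele numbers and frequencies, what fraction of randomly
formed heterokaryon pairs is compatible?  It provides three independent
routes — exact enumeration, a closed-form expression, and Monte-Carlo
sampling — plus sibling cohorts (offspring of a single fruiting body) and a
population survey used to gauge how reliably SI identifies clones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "FREQ_TOL",
    "ENUMERATION_CAP",
    "GeneticsError",
    "LocusMismatchError",
    "EnumerationCapError",
    "Locus",
    "Haplotype",
    "Mycelium",
    "CompatibilityResult",
    "SiblingCohort",
    "MCEstimate",
    "SurveyResult",
    "allele_profile",
    "is_compatible",
    "enumerate_haplotypes",
    "enumerate_heterokaryons",
    "sibling_cohort",
    "compatible_fraction_enumerate",
    "compatible_fraction_analytic",
    "compatible_fraction_mc",
    "compatibility_matrix",
    "population_si_survey",
    "percent",
]

#: Tolerance on allele-frequency normalisation.
FREQ_TOL = 1e-12

#: Default cap on the number of ordered genotype *pairs* enumerated exactly.
ENUMERATION_CAP = 10**6


class GeneticsError(ValueError):
    """Base class for validation errors in the genetics layer."""


class LocusMismatchError(GeneticsError):
    """A mycelium does not cover a locus, or partners disagree on loci."""


class EnumerationCapError(GeneticsError):
    """Exact enumeration would exceed the configured state-space cap."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Locus:
    """An incompatibility locus: allele labels with population frequencies."""

    id: str
    alleles: tuple[str, ...]
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(self.alleles))
        object.__setattr__(self, "frequencies", tuple(float(f) for f in self.frequencies))
        if len(self.alleles) < 1:
            raise GeneticsError(f"locus {self.id!r}: needs at least one allele")
        if len(set(self.alleles)) != len(self.alleles):
            raise GeneticsError(f"locus {self.id!r}: allele labels must be unique")
        if len(self.frequencies) != len(self.alleles):
            raise GeneticsError(
                f"locus {self.id!r}: {len(self.alleles)} alleles but "
                f"{len(self.frequencies)} frequencies"
            )
        if any(f < 0 for f in self.frequencies):
            raise GeneticsError(f"locus {self.id!r}: negative allele frequency")
        total = math.fsum(self.frequencies)
        if abs(total - 1.0) > FREQ_TOL:
            raise GeneticsError(
                f"locus {self.id!r}: frequencies sum to {total!r}, not 1"
            )

    @property
    def k(self) -> int:
        """Number of alleles."""
        return len(self.alleles)

    @classmethod
    def uniform(cls, id: str, k: int, prefix: str = "A") -> "Locus":
        """A locus with ``k`` equally frequent alleles labelled e.g. A1..Ak."""
        if k < 1:
            raise GeneticsError("k must be >= 1")
        return cls(id, tuple(f"{prefix}{i + 1}" for i in range(k)), (1.0 / k,) * k)

    def index_of(self, allele: str) -> int:
        try:
            return self.alleles.index(allele)
        except ValueError:
            raise GeneticsError(f"locus {self.id!r}: unknown allele {allele!r}") from None


@dataclass(frozen=True)
class Haplotype:
    """A haploid nucleus: exactly one allele at each covered locus.

    Stored as a sorted tuple of ``(locus_id, allele)`` pairs so that equality
    and hashing are order-insensitive.
    """

    alleles: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        pairs = tuple(sorted((str(l), str(a)) for l, a in self.alleles))
        if len({l for l, _ in pairs}) != len(pairs):
            raise GeneticsError("haplotype carries more than one allele at a locus")
        object.__setattr__(self, "alleles", pairs)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "Haplotype":
        return cls(tuple(mapping.items()))

    def allele_of(self, locus_id: str) -> str:
        for l, a in self.alleles:
            if l == locus_id:
                return a
        raise LocusMismatchError(f"haplotype does not cover locus {locus_id!r}")

    def covers(self, locus_id: str) -> bool:
        return any(l == locus_id for l, _ in self.alleles)


_STAGES = {1: "homokaryon", 2: "heterokaryon", 3: "trikaryon"}


@dataclass(frozen=True)
class Mycelium:
    """A mycelium with 1-3 nuclei (homokaryon, heterokaryon, transient trikaryon)."""

    karyotype: tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "karyotype", tuple(self.karyotype))
        if len(self.karyotype) not in (1, 2, 3):
            raise GeneticsError(
                f"karyotype must have 1-3 nuclei, got {len(self.karyotype)}"
            )

    @property
    def stage(self) -> str:
        return _STAGES[len(self.karyotype)]

    @classmethod
    def from_alleles(cls, locus: Locus | str, *alleles: str) -> "Mycelium":
        """Convenience constructor for single-locus karyotypes.

        ``Mycelium.from_alleles(locus, "A1", "A2")`` is a heterokaryon with
        nuclei A1 and A2 at ``locus``.
        """
        locus_id = locus.id if isinstance(locus, Locus) else str(locus)
        return cls(tuple(Haplotype(((locus_id, a),)) for a in alleles))


@dataclass
class CompatibilityResult:
    """Outcome of a compatibility computation over enumerated genotypes.

    ``matrix`` is ``None`` for routes (analytic, Monte-Carlo) that do not
    enumerate the genotype space.
    """

    compatible_fraction: float
    incompatible_fraction: float
    labels: tuple[str, ...] = ()
    matrix: Optional[np.ndarray] = None
    probabilities: tuple[float, ...] = ()
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.compatible_fraction <= 1.0 + 1e-15):
            raise GeneticsError("compatible_fraction outside [0, 1]")


@dataclass
class SiblingCohort:
    """Heterokaryon offspring of one fruiting body, with genotype probabilities."""

    parent: Mycelium
    genotypes: list[tuple[Haplotype, Haplotype]]
    probabilities: list[float]


@dataclass
class MCEstimate:
    """Monte-Carlo estimate of the compatible fraction with its binomial SE."""

    estimate: float
    standard_error: float
    n_pairs: int
    seed: int


@dataclass
class SurveyResult:
    """Pairwise SI survey of sampled isolates."""

    matrix: np.ndarray
    clone_ids: np.ndarray
    n_groups: int
    false_clonemate_rate: Optional[float]
    n_nonclonal_pairs: int


# ---------------------------------------------------------------------------
# Core predicate
# ---------------------------------------------------------------------------


def allele_profile(m: Mycelium, locus: Locus) -> frozenset[str]:
    """Deduplicated set of alleles the mycelium carries at ``locus``."""
    out = set()
    for h in m.karyotype:
        a = h.allele_of(locus.id)
        if a not in locus.alleles:
            raise GeneticsError(
                f"allele {a!r} not defined for locus {locus.id!r}"
            )
        out.add(a)
    return frozenset(out)


def is_compatible(m1: Mycelium, m2: Mycelium, loci: Sequence[Locus]) -> bool:
    """True iff the two mycelia carry identical allele sets at every locus.

    This is the somatic-compatibility predicate: compatibility is an
    equivalence relation (reflexive, symmetric, transitive) because it is
    set equality locus by locus.
    """
    if not loci:
        raise LocusMismatchError("empty locus list")
    return all(allele_profile(m1, L) == allele_profile(m2, L) for L in loci)


def _profile_signature(m: Mycelium, loci: Sequence[Locus]) -> tuple[frozenset[str], ...]:
    return tuple(allele_profile(m, L) for L in loci)


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


def enumerate_haplotypes(loci: Sequence[Locus]) -> list[tuple[Haplotype, float]]:
    """All haplotypes over ``loci`` with their population probabilities.

    Alleles are drawn independently per locus with the locus frequencies;
    ordering is lexicographic by allele index, first locus major.
    """
    if not loci:
        raise GeneticsError("empty locus list")
    out: list[tuple[Haplotype, float]] = []
    per_locus = [list(zip(L.alleles, L.frequencies)) for L in loci]
    for combo in itertools.product(*per_locus):
        hap = Haplotype(tuple((L.id, a) for L, (a, _) in zip(loci, combo)))
        p = math.prod(f for _, f in combo)
        out.append((hap, p))
    return out


def enumerate_heterokaryons(
    loci: Sequence[Locus],
) -> list[tuple[tuple[Haplotype, Haplotype], float]]:
    """All *ordered* pairs of independent haplotypes with probabilities.

    Ordered pairs (first nucleus x second nucleus) reproduce the row
    structure of published compatibility tables, where A1/A2 and A2/A1 are
    listed separately; cardinality is ``(prod k_i)**2``.
    """
    haps = enumerate_haplotypes(loci)
    return [((h1, h2), p1 * p2) for (h1, p1) in haps for (h2, p2) in haps]


def genotype_label(genotype: tuple[Haplotype, Haplotype], loci: Sequence[Locus]) -> str:
    """Label like ``"A1/A2"`` (multi-locus alleles joined with ``-``)."""
    def hap_label(h: Haplotype) -> str:
        return "-".join(h.allele_of(L.id) for L in loci)

    return f"{hap_label(genotype[0])}/{hap_label(genotype[1])}"


def sibling_cohort(parent: Mycelium, loci: Sequence[Locus]) -> SiblingCohort:
    """Heterokaryon genotypes among offspring of one heterokaryotic parent.

    Each spore inherits either parental allele per locus with probability
    1/2, independently across loci (unlinked); sibling heterokaryons are
    ordered pairs of independent spores.
    """
    if parent.stage != "heterokaryon":
        raise GeneticsError("sibling cohorts are defined for heterokaryotic parents")
    h1, h2 = parent.karyotype
    seg_loci = []
    for L in loci:
        a, b = h1.allele_of(L.id), h2.allele_of(L.id)
        if a == b:
            seg_loci.append(Locus(L.id, (a,), (1.0,)))
        else:
            seg_loci.append(Locus(L.id, (a, b), (0.5, 0.5)))
    genos = enumerate_heterokaryons(seg_loci)
    return SiblingCohort(
        parent=parent,
        genotypes=[g for g, _ in genos],
        probabilities=[p for _, p in genos],
    )


def _enumerated_result(
    loci: Sequence[Locus], cap: int, with_matrix: bool
) -> CompatibilityResult:
    genos = enumerate_heterokaryons(loci)
    n = len(genos)
    if n * n > cap:
        raise EnumerationCapError(
            f"{n * n} ordered genotype pairs exceed the cap of {cap}; "
            "use compatible_fraction_mc instead"
        )
    sigs = [
        _profile_signature(Mycelium((h1, h2)), loci) for (h1, h2), _ in genos
    ]
    probs = np.array([p for _, p in genos])
    # group weights: compatible-pair mass is sum over groups of (sum p)^2
    weight: dict[tuple, float] = {}
    for s, p in zip(sigs, probs):
        weight[s] = weight.get(s, 0.0) + p
    comp = math.fsum(w * w for w in weight.values())
    total = math.fsum(probs) ** 2  # 1 up to rounding
    comp /= total
    matrix = None
    labels: tuple[str, ...] = ()
    if with_matrix:
        codes = {s: i for i, s in enumerate(weight)}
        c = np.array([codes[s] for s in sigs])
        matrix = c[:, None] == c[None, :]
        labels = tuple(genotype_label(g, loci) for g, _ in genos)
    return CompatibilityResult(
        compatible_fraction=comp,
        incompatible_fraction=1.0 - comp,
        labels=labels,
        matrix=matrix,
        probabilities=tuple(probs.tolist()),
        method="enumerate",
    )


def compatible_fraction_enumerate(
    loci: Sequence[Locus], cap: int = ENUMERATION_CAP
) -> CompatibilityResult:
    """Exact probability-weighted compatible fraction by full enumeration.

    Serves as the brute-force oracle for :func:`compatible_fraction_analytic`.
    Raises :class:`EnumerationCapError` when the ordered-pair space exceeds
    ``cap``.
    """
    return _enumerated_result(loci, cap, with_matrix=False)


def compatibility_matrix(
    loci: Sequence[Locus], cap: int = ENUMERATION_CAP
) -> CompatibilityResult:
    """Labeled boolean compatibility matrix over all ordered genotypes.

    Row/column order is the enumeration order (lexicographic by allele
    index, first nucleus major), matching published table layouts.
    """
    return _enumerated_result(loci, cap, with_matrix=True)


# ---------------------------------------------------------------------------
# Analytic and Monte-Carlo routes
# ---------------------------------------------------------------------------


def per_locus_compatible_fraction(locus: Locus) -> float:
    """P(two random ordered-pair genotypes share the same allele set).

    With allele frequencies ``p``: ``sum_i p_i^4 + sum_{i<j} 4 p_i^2 p_j^2``
    — both heterokaryons homozygous for the same allele, or both carrying
    the same unordered heterozygous pair (2 orderings each).  For ``k``
    uniform alleles this collapses to ``(2k - 1) / k^3``.
    """
    p = np.asarray(locus.frequencies)
    homo = float(np.sum(p**4))
    p2 = p**2
    hetero = 2.0 * float(np.sum(np.outer(p2, p2)) - np.sum(p2**2))
    return homo + hetero


def compatible_fraction_analytic(loci: Sequence[Locus]) -> CompatibilityResult:
    """Closed-form compatible fraction; per-locus fractions multiply.

    Loci segregate independently, so the probability that two random
    heterokaryons agree at every locus is the product of the per-locus
    agreement probabilities.  Agrees with exact enumeration to 1e-12.
    """
    if not loci:
        raise GeneticsError("empty locus list")
    comp = math.prod(per_locus_compatible_fraction(L) for L in loci)
    return CompatibilityResult(
        compatible_fraction=comp,
        incompatible_fraction=1.0 - comp,
        method="analytic",
    )


def _sample_profile_codes(
    rng: np.random.Generator, locus: Locus, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n heterokaryon allele sets at one locus, coded as (min, max)."""
    a = rng.choice(locus.k, size=n, p=locus.frequencies)
    b = rng.choice(locus.k, size=n, p=locus.frequencies)
    return np.minimum(a, b), np.maximum(a, b)


def compatible_fraction_mc(
    loci: Sequence[Locus], n_pairs: int, seed: int
) -> MCEstimate:
    """Monte-Carlo estimate of the compatible fraction.

    Draws ``n_pairs`` independent pairs of heterokaryons (each nucleus an
    i.i.d. draw from the allele frequencies) and returns the mean
    compatibility indicator with its binomial standard error.  Reproducible
    for a fixed seed.
    """
    if n_pairs < 1:
        raise GeneticsError("n_pairs must be >= 1")
    if not loci:
        raise GeneticsError("empty locus list")
    rng = np.random.default_rng(seed)
    comp = np.ones(n_pairs, dtype=bool)
    for L in loci:
        lo1, hi1 = _sample_profile_codes(rng, L, n_pairs)
        lo2, hi2 = _sample_profile_codes(rng, L, n_pairs)
        comp &= (lo1 == lo2) & (hi1 == hi2)
    est = float(comp.mean())
    se = math.sqrt(est * (1.0 - est) / n_pairs)
    return MCEstimate(estimate=est, standard_error=se, n_pairs=n_pairs, seed=seed)


# ---------------------------------------------------------------------------
# Population survey
# ---------------------------------------------------------------------------


def population_si_survey(
    loci: Sequence[Locus],
    n_isolates: int,
    clonal_groups: Optional[int] = None,
    seed: int = 0,
) -> SurveyResult:
    """Pairwise SI survey over sampled heterokaryon isolates.

    Samples ``n_isolates`` heterokaryons; if ``clonal_groups`` is given, only
    that many distinct genotypes are drawn and isolates are assigned to them
    round-robin (planted clones).  Reports the number of compatibility
    groups (equivalence classes of the allele-set predicate) and the
    false-clonemate rate: the fraction of non-clonal pairs that are
    nevertheless compatible, whose expectation is the analytic compatible
    fraction.  The rate is ``None`` when no non-clonal pair exists.
    """
    if n_isolates < 2:
        raise GeneticsError("need at least 2 isolates")
    if clonal_groups is not None and clonal_groups < 1:
        raise GeneticsError("clonal_groups must be >= 1")
    if not loci:
        raise GeneticsError("empty locus list")
    rng = np.random.default_rng(seed)
    n_distinct = clonal_groups if clonal_groups is not None else n_isolates
    # per-clone profile codes, one (min, max) pair per locus
    clone_codes = np.empty((n_distinct, 2 * len(loci)), dtype=np.int64)
    for j, L in enumerate(loci):
        lo, hi = _sample_profile_codes(rng, L, n_distinct)
        clone_codes[:, 2 * j] = lo
        clone_codes[:, 2 * j + 1] = hi
    clone_ids = np.arange(n_isolates) % n_distinct
    codes = clone_codes[clone_ids]
    matrix = np.all(codes[:, None, :] == codes[None, :, :], axis=2)
    n_groups = len(np.unique(codes, axis=0))
    nonclonal = clone_ids[:, None] != clone_ids[None, :]
    iu = np.triu_indices(n_isolates, k=1)
    mask = nonclonal[iu]
    n_nc = int(mask.sum())
    rate = float(matrix[iu][mask].mean()) if n_nc else None
    return SurveyResult(
        matrix=matrix,
        clone_ids=clone_ids,
        n_groups=n_groups,
        false_clonemate_rate=rate,
        n_nonclonal_pairs=n_nc,
    )


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------


def percent(fraction: float, ndigits: int = 0) -> float:
    """Fraction as a percentage, rounded half away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(fraction) * 100.0)).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)
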