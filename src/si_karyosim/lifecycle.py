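"""Lifecycle scenarios: recognition-mechanism rule sets, the migration race,
and adjudication against the observed basidiomycete lifecycle.

Basidiomycete biology imposes six observations that any nonself-recognition
mechanism must reproduce:

  C1  an established heterokaryon is viable (two genomes coexist for life);
  C2  genetically distinct heterokaryons show somatic incompatibility (SI);
  C3  matings between unrelated homokaryons succeed (heterokaryon formed);
  C4  Buller matings (heterokaryon x homokaryon) succeed;
  C5  fusion cells die even in sexually compatible homokaryon matings;
  C6  heterokaryon pairs sharing a common nucleus (AB x AC) still show SI.

Five candidate mechanisms are encoded as fate rules over the partners'
karyotypes.  Only the reader/writer post-translational-modification system
*combined with nuclear migration* — a race in which a nucleus escapes the
dying fusion cell and establishes the heterokaryon downstream — satisfies
all six.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dynamics import RWParams, simulate_heterokaryon_fusion
from .genetics import (
    GeneticsError,
    Locus,
    Mycelium,
    allele_profile,
    is_compatible,
)

__all__ = [
    "MODEL_NAMES",
    "CRITERIA",
    "PairingScenario",
    "Outcome",
    "AdjudicationRow",
    "AdjudicationReport",
    "fusion_cell_fate",
    "migration_escape_probability",
    "simulate_escape_mc",
    "simulate_pairing",
    "adjudicate",
    "adjudicate_all",
    "tuft_count_expectation",
]

MODEL_NAMES = (
    "allelic_interaction",
    "nonallelic_interaction",
    "differential_expression_het_only",
    "ptm_reader_writer",
    "ptm_plus_migration",
)

#: Models in which nuclei can escape a dying fusion cell by migration.
_MIGRATION_CAPABLE = {"ptm_plus_migration"}

CRITERIA = {
    "C1": "standalone heterokaryon viable",
    "C2": "distinct heterokaryon pairings show SI",
    "C3": "homokaryon x homokaryon mating succeeds",
    "C4": "Buller mating succeeds",
    "C5": "fusion-cell death occurs in homokaryon matings",
    "C6": "common-nucleus heterokaryon pairings show SI",
}

#: Death time assumed for a lethal fusion cell when no kinetic model is
#: supplied (time units of the dynamics module).
DEFAULT_DEATH_TIME = 5.0


@dataclass(frozen=True)
class PairingScenario:
    """A confrontation between two mycelia at the colony interface."""

    partner1: Mycelium
    partner2: Mycelium
    mating_compatible: bool = True
    migration_rate: float = 1.0     # per-cell rate of a nucleus starting to migrate
    n_fusion_cells: int = 100       # independent anastomoses along the interface
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fusion_cells < 1:
            raise ValueError("n_fusion_cells must be >= 1")
        if self.migration_rate < 0:
            raise ValueError("migration_rate must be non-negative")


@dataclass
class Outcome:
    """Fate of the fusion cells and the resulting mating outcome."""

    fusion_cell_fate: str                      # "survives" | "dies"
    death_time: Optional[float]
    escape_probability: float
    mating_result: str   # stable_common_mycelium | heterokaryon_formed | no_mating | SI_barrier
    formed_heterokaryons: tuple[tuple[str, ...], ...] = ()


@dataclass
class AdjudicationRow:
    """Pass/fail of one recognition model against the six lifecycle criteria."""

    model: str
    criteria: dict[str, bool]
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        self.verdict = "consistent" if all(self.criteria.values()) else "inconsistent"


AdjudicationReport = list[AdjudicationRow]


# ---------------------------------------------------------------------------
# Fate rules
# ---------------------------------------------------------------------------


def _merged_profile_sizes(m1: Mycelium, m2: Mycelium, loci: Sequence[Locus]) -> list[int]:
    return [len(allele_profile(m1, L) | allele_profile(m2, L)) for L in loci]


def fusion_cell_fate(
    model: str, m1: Mycelium, m2: Mycelium, loci: Sequence[Locus]
) -> str:
    """Fate ("survives" / "dies") of the fusion cell under one mechanism.

    - allelic / nonallelic direct protein interaction: the merged cytoplasm
      dies whenever it carries two distinct alleles at any locus — including
      the alleles *within* a single heterokaryon, which is why these
      mechanisms cannot support the heterokaryotic stage.
    - differential expression (recognition only in heterokaryons): the
      machinery is expressed as soon as at least one partner is
      heterokaryotic; it then kills any pairing whose allele sets differ.
      Two homokaryons express nothing and always tolerate each other.
    - reader/writer PTM (with or without migration): the fusion cell dies
      exactly when the partners' allele sets differ at some locus —
      unmodified targets meet a foreign reader — including homokaryon
      pairings with different alleles.  Migration changes the *mating*
      outcome, not the fate of the fusion cell itself.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown recognition model {model!r}")
    if model in ("allelic_interaction", "nonallelic_interaction"):
        dies = any(s >= 2 for s in _merged_profile_sizes(m1, m2, loci))
    elif model == "differential_expression_het_only":
        any_het = m1.stage != "homokaryon" or m2.stage != "homokaryon"
        dies = any_het and not is_compatible(m1, m2, loci)
    else:  # ptm_reader_writer, ptm_plus_migration
        dies = not is_compatible(m1, m2, loci)
    return "dies" if dies else "survives"


# ---------------------------------------------------------------------------
# Migration race
# ---------------------------------------------------------------------------


def migration_escape_probability(
    migration_rate: float, death_time: float, n_fusion_cells: int
) -> float:
    """P(at least one nucleus escapes before its fusion cell dies).

    Migration initiation is an exponential waiting time with rate ``r`` per
    fusion cell, absorbed by deterministic death at ``t_d``: the per-cell
    escape probability is ``p = 1 - exp(-r * t_d)`` and, over ``N``
    independent anastomoses, ``P = 1 - (1 - p) ** N``.  Only a single
    nucleus needs to escape for the mating to succeed.
    """
    if migration_rate < 0:
        raise ValueError("migration_rate must be non-negative")
    if n_fusion_cells < 1:
        raise ValueError("n_fusion_cells must be >= 1")
    if death_time < 0:
        raise ValueError("death_time must be non-negative")
    if math.isinf(death_time):
        return 1.0 if migration_rate > 0 else 0.0
    p = -math.expm1(-migration_rate * death_time)
    return -math.expm1(n_fusion_cells * math.log1p(-p)) if p < 1.0 else 1.0


def simulate_escape_mc(
    migration_rate: float,
    death_time: float,
    n_fusion_cells: int,
    n_replicates: int,
    seed: int,
) -> float:
    """Stochastic check of the escape race: exponential migration clocks vs
    a fixed death time, over many replicate interfaces."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if migration_rate == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    first = rng.exponential(1.0 / migration_rate, size=(n_replicates, n_fusion_cells)).min(axis=1)
    return float((first < death_time).mean())


def tuft_count_expectation(
    n_fusion_cells: int, migration_rate: float, death_time: float
) -> float:
    """Expected number of successful heterokaryotic sectors ("tufts").

    E = N * (1 - exp(-r * t_d)); in the low-migration regime r*t_d << 1
    this is approximately N*r*t_d — few but nonzero tufts, as seen at the
    interaction zone of species with little nuclear migration.
    """
    if migration_rate < 0 or death_time < 0:
        raise ValueError("rates and times must be non-negative")
    if n_fusion_cells < 1:
        raise ValueError("n_fusion_cells must be >= 1")
    if math.isinf(death_time):
        return float(n_fusion_cells) if migration_rate > 0 else 0.0
    return n_fusion_cells * -math.expm1(-migration_rate * death_time)


# ---------------------------------------------------------------------------
# Pairing simulation
# ---------------------------------------------------------------------------


def _single_locus_alleles(m: Mycelium, loci: Sequence[Locus]) -> set[str]:
    if len(loci) != 1:
        raise ValueError(
            "kinetic death times require a single recognition locus"
        )
    return set(allele_profile(m, loci[0]))


def _death_time_for(
    m1: Mycelium,
    m2: Mycelium,
    loci: Sequence[Locus],
    rw_params: Optional[RWParams],
    default_death_time: float,
) -> Optional[float]:
    if rw_params is None:
        return default_death_time
    traj = simulate_heterokaryon_fusion(
        _single_locus_alleles(m1, loci), _single_locus_alleles(m2, loci), rw_params
    )
    return traj.death_time


def simulate_pairing(
    model: str,
    scenario: PairingScenario,
    loci: Sequence[Locus],
    rw_params: Optional[RWParams] = None,
    default_death_time: float = DEFAULT_DEATH_TIME,
    escape_threshold: float = 0.0,
) -> Outcome:
    """Combine fate, death kinetics and migration rules into a mating outcome.

    Migration occurs only *into* a homokaryon partner (nuclei never migrate
    into an established heterokaryon), only when the mating-type loci are
    compatible, and only under a migration-capable model.  Homokaryon x
    homokaryon matings migrate reciprocally; Buller (heterokaryon x
    homokaryon) matings migrate unidirectionally into the homokaryon, the
    fertilizing nucleus drawn uniformly from the heterokaryon's two
    haplotypes.
    """
    m1, m2 = scenario.partner1, scenario.partner2
    fate = fusion_cell_fate(model, m1, m2, loci)
    identical = is_compatible(m1, m2, loci)
    homs = [m for m in (m1, m2) if m.stage == "homokaryon"]
    migration_possible = (
        model in _MIGRATION_CAPABLE
        and scenario.mating_compatible
        and len(homs) >= 1
        and not identical
    )

    if fate == "survives":
        death_time = None
        if identical:
            return Outcome("survives", None, 1.0, "stable_common_mycelium")
        # fusion tolerated between non-identical partners (differential
        # expression between homokaryons): free nuclear exchange
        if scenario.mating_compatible and len(homs) >= 1:
            formed = _formed_heterokaryons(m1, m2, loci, scenario.seed)
            return Outcome("survives", None, 1.0, "heterokaryon_formed", formed)
        return Outcome("survives", None, 0.0, "no_mating")

    death_time = _death_time_for(m1, m2, loci, rw_params, default_death_time)
    td = math.inf if death_time is None else death_time
    if not migration_possible:
        return Outcome("dies", death_time, 0.0, "SI_barrier")
    p_escape = migration_escape_probability(
        scenario.migration_rate, td, scenario.n_fusion_cells
    )
    if p_escape > escape_threshold:
        formed = _formed_heterokaryons(m1, m2, loci, scenario.seed)
        return Outcome("dies", death_time, p_escape, "heterokaryon_formed", formed)
    return Outcome("dies", death_time, p_escape, "no_mating")


def _formed_heterokaryons(
    m1: Mycelium, m2: Mycelium, loci: Sequence[Locus], seed: int
) -> tuple[tuple[str, ...], ...]:
    """Karyotypes (as per-locus allele labels of the single locus, or
    haplotype tuples) of the heterokaryons produced by migration."""
    rng = np.random.default_rng(seed)

    def hap_label(h) -> str:
        return "-".join(h.allele_of(L.id) for L in loci)

    formed = []
    pairs = ((m1, m2), (m2, m1))
    for recipient, donor in pairs:
        if recipient.stage != "homokaryon":
            continue
        donor_haps = donor.karyotype
        if donor.stage == "homokaryon":
            migrant = donor_haps[0]
        else:
            migrant = donor_haps[rng.integers(len(donor_haps))]
        formed.append(tuple(sorted((hap_label(recipient.karyotype[0]), hap_label(migrant)))))
    return tuple(formed)


# ---------------------------------------------------------------------------
# Adjudication
# ---------------------------------------------------------------------------


def adjudicate(
    model: str,
    rw_params: Optional[RWParams] = None,
    migration_rate: float = 1.0,
    n_fusion_cells: int = 100,
) -> AdjudicationRow:
    """Score one recognition mechanism against the six lifecycle criteria.

    The canonical test pairings use a single triallelic recognition locus
    with nuclei A, B, C (a fourth allele D for the fully distinct
    heterokaryon pairing of C2).
    """
    locus = Locus("X", ("A", "B", "C", "D"), (0.25,) * 4)
    loci = [locus]
    hom = lambda a: Mycelium.from_alleles(locus, a)
    het = lambda a, b: Mycelium.from_alleles(locus, a, b)

    def pairing(m1, m2) -> Outcome:
        sc = PairingScenario(
            m1, m2, mating_compatible=True,
            migration_rate=migration_rate, n_fusion_cells=n_fusion_cells,
        )
        return simulate_pairing(model, sc, loci, rw_params=rw_params)

    c1 = fusion_cell_fate(model, het("A", "B"), het("A", "B"), loci) == "survives"
    c2 = pairing(het("A", "B"), het("C", "D")).mating_result == "SI_barrier"
    c3 = pairing(hom("A"), hom("B")).mating_result == "heterokaryon_formed"
    c4 = pairing(het("A", "B"), hom("C")).mating_result == "heterokaryon_formed"
    c5 = fusion_cell_fate(model, hom("A"), hom("B"), loci) == "dies"
    c6 = pairing(het("A", "B"), het("A", "C")).mating_result == "SI_barrier"
    return AdjudicationRow(
        model=model,
        criteria={"C1": c1, "C2": c2, "C3": c3, "C4": c4, "C5": c5, "C6": c6},
    )


def adjudicate_all(
    rw_params: Optional[RWParams] = None,
    migration_rate: float = 1.0,
    n_fusion_cells: int = 100,
) -> AdjudicationReport:
    """Adjudication table over all five candidate mechanisms."""
    return [
        adjudicate(m, rw_params=rw_params, migration_rate=migration_rate,
                   n_fusion_cells=n_fusion_cells)
        for m in MODEL_NAMES
    ]
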