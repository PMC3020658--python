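"""Species proteomic cohesiveness versus random same-genus isolate sets.

A species with N_I sequenced isolates is called proteomically cohesive when
(a) its core proteome is larger than the core proteomes of random sets of
N_I isolates drawn from the same genus, and (b) it has more proteins unique
to it within the genus (present in all N_I isolates and absent from every
other isolate of the genus) than such random sets do. Random sets must not
consist entirely of one species; up to 25 distinct sets are used, or every
valid set when fewer exist. A two-tailed one-sample t-test compares the
random-set mean against the observed value, and exceedance counts report how
many random sets beat the species outright.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

MAX_RANDOM_SETS = 25
# Significance rendering convention: "**" below 0.001, "*" below 0.05.
STAR_P, DOUBLE_STAR_P = 0.05, 0.001


@dataclass(frozen=True)
class GenusComposition:
    """Species makeup of a genus: species label -> number of isolates."""

    species_counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.species_counts.values())

    @staticmethod
    def from_isolates(species_of: Mapping[str, str]) -> "GenusComposition":
        counts: dict[str, int] = {}
        for sp in species_of.values():
            counts[sp] = counts.get(sp, 0) + 1
        return GenusComposition(counts)


def count_valid_sets(composition: GenusComposition, k: int) -> int:
    """Number of k-isolate sets that are not entirely one species.

    C(N, k) minus the mono-species sets contributed by each species.
    """
    if k <= 0:
        raise ValueError("set size must be positive")
    if k > composition.total:
        raise ValueError("set size exceeds the number of isolates")
    total = comb(composition.total, k)
    mono = sum(comb(n, k) for n in composition.species_counts.values())
    return total - mono


def _is_valid(members: Iterable[str], species_of: Mapping[str, str]) -> bool:
    return len({species_of[m] for m in members}) > 1


def sample_random_sets(species_of: Mapping[str, str], k: int,
                       max_sets: int = MAX_RANDOM_SETS,
                       seed: int | np.random.Generator = 0) -> list[frozenset]:
    """Distinct multi-species random sets of k isolates from one genus.

    When at most ``max_sets`` valid sets exist they are all enumerated
    (deterministically, independent of the seed); otherwise sets are sampled
    uniformly over the valid sets, without replacement. The focal species'
    own isolates are eligible members; only fully mono-species sets are
    rejected.
    """
    isolates = sorted(species_of)
    composition = GenusComposition.from_isolates(species_of)
    n_valid = count_valid_sets(composition, k)
    if n_valid < 1:
        raise ValueError("no valid multi-species sets exist")
    if n_valid <= max_sets:
        return [
            frozenset(c) for c in itertools.combinations(isolates, k)
            if _is_valid(c, species_of)
        ]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen: list[frozenset] = []
    seen: set[frozenset] = set()
    while len(chosen) < max_sets:
        members = frozenset(rng.choice(isolates, size=k, replace=False))
        if members in seen or not _is_valid(members, species_of):
            continue
        seen.add(members)
        chosen.append(members)
    return chosen


def one_sample_t_test(values: Sequence[float], observed: float):
    """Two-tailed t-test of the random-set mean against the observed value.

    Returns ``(t, p)``; ``(0.0, 1.0)`` when the values are constant and equal
    to the observed value, and ``(None, None)`` (undefined, rendered "-")
    when they are constant but different.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two random values")
    if float(values.std(ddof=1)) == 0.0:
        if float(values.mean()) == observed:
            return 0.0, 1.0
        return None, None
    res = stats.ttest_1samp(values, popmean=observed)
    return float(res.statistic), float(res.pvalue)


def significance_label(p: float | None) -> str:
    if p is None:
        return "-"
    if p < DOUBLE_STAR_P:
        return "**"
    if p < STAR_P:
        return "*"
    return "n.s."


@dataclass
class CohesivenessResult:
    """One row of the cohesiveness report (core and unique columns)."""

    species: str
    n_isolates: int
    core_observed: int
    core_random_mean: float
    core_p: float | None
    core_exceed: int
    unique_observed: int
    unique_random_mean: float
    unique_p: float | None
    unique_exceed: int
    n_random_sets: int
    random_sets: list[frozenset]
    core_random: list[int]
    unique_random: list[int]

    @property
    def core_significance(self) -> str:
        return significance_label(self.core_p)

    @property
    def unique_significance(self) -> str:
        return significance_label(self.unique_p)

    def as_row(self) -> dict:
        return {
            "species": self.species,
            "N_I": self.n_isolates,
            "NCA": self.core_observed,
            "NCR": round(self.core_random_mean, 1),
            "P_C": self.core_significance,
            "NC_exceed": f"{self.core_exceed}/{self.n_random_sets}",
            "NUA": self.unique_observed,
            "NUR": round(self.unique_random_mean, 1),
            "P_U": self.unique_significance,
            "NU_exceed": f"{self.unique_exceed}/{self.n_random_sets}",
        }


def cohesiveness_analysis(
    species: str,
    species_of: Mapping[str, str],
    core_fn: Callable[[frozenset], int],
    unique_fn: Callable[[frozenset], int],
    max_sets: int = MAX_RANDOM_SETS,
    seed: int | np.random.Generator = 0,
) -> CohesivenessResult:
    """Full cohesiveness row for one species of one genus.

    ``species_of`` maps every isolate of the genus to its species label.
    ``core_fn(set)`` must return the core-proteome size of an isolate set
    (orthology restricted to the set); ``unique_fn(set)`` the number of
    groups present in every set member and in no other isolate of the genus.
    """
    members = frozenset(iso for iso, sp in species_of.items() if sp == species)
    if len(members) < 2:
        raise ValueError(f"species {species} has fewer than two isolates")
    sets = sample_random_sets(species_of, len(members), max_sets=max_sets, seed=seed)
    core_obs = core_fn(members)
    unique_obs = unique_fn(members)
    core_rand = [core_fn(s) for s in sets]
    unique_rand = [unique_fn(s) for s in sets]
    _, core_p = one_sample_t_test(core_rand, core_obs)
    _, unique_p = one_sample_t_test(unique_rand, unique_obs)
    return CohesivenessResult(
        species=species,
        n_isolates=len(members),
        core_observed=core_obs,
        core_random_mean=float(np.mean(core_rand)),
        core_p=core_p,
        core_exceed=sum(1 for v in core_rand if v > core_obs),
        unique_observed=unique_obs,
        unique_random_mean=float(np.mean(unique_rand)),
        unique_p=unique_p,
        unique_exceed=sum(1 for v in unique_rand if v > unique_obs),
        n_random_sets=len(sets),
        random_sets=sets,
        core_random=core_rand,
        unique_random=unique_rand,
    )
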