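"""Canned validation experiments over the synthetic generator.

Each function encodes one study condition — parameter recovery through the
full alignment pipeline, marker-coupling regression behaviour, a planted
cohesive species, and t-test calibration — with fixed problem sizes, so the
test suite and the reproduction script exercise identical setups. All
randomness flows from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .cohesion import CohesivenessResult, cohesiveness_analysis, sample_random_sets
from .markers import MarkerPair, filter_pairs, least_squares_fit, percent_identity
from .pipeline import run_pipeline
from .simulate import SimulationConfig, simulate_pangenome


def _subseed(seed: int, offset: int) -> int:
    return (seed * 1_000 + offset) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Parameter recovery (full alignment pipeline)
# ---------------------------------------------------------------------------

def recovery_config(seed: int) -> SimulationConfig:
    """Default family structure at low divergence, where every within-family
    hit clears the threshold and no between-family hit does."""
    return SimulationConfig(
        within_genus_divergence=0.05,
        between_genus_divergence=0.15,
        seed=_subseed(seed, 1),
    )


def recovery_experiment(seed: int) -> dict:
    """Run the full pipeline and compare against truth-derived counts.

    M = 0.01 instantiates the no-spurious-pass recovery condition (about a
    1% chance of even one chance match anywhere in the experiment).
    """
    pset, _, truth = simulate_pangenome(recovery_config(seed))
    result = run_pipeline(pset, M=0.01)
    pang = result.pangenome
    out: dict = {"n_proteins": len(pset.sequences), "genera": {}}
    for genus, labs in pang.genera().items():
        out["genera"][genus] = {
            "core": pang.core(labs),
            "core_expected": truth.expected_core(genus),
            "unique": pang.genus_unique(genus),
            "unique_expected": truth.expected_unique(genus),
            "singlets": pang.genus_singlets(genus),
            "singlets_expected": truth.expected_singlets(genus),
        }
    out["exact"] = all(
        g["core"] == g["core_expected"]
        and g["unique"] == g["unique_expected"]
        and g["singlets"] == g["singlets_expected"]
        for g in out["genera"].values()
    )
    return out


# ---------------------------------------------------------------------------
# Marker-coupling regression
# ---------------------------------------------------------------------------

def regression_config(seed: int, coupling: float) -> SimulationConfig:
    """One deep genus with tree-correlated accessory content.

    A large dispensable pool lost along the tree makes shared proteins decay
    smoothly with depth; protein length is kept small because the check runs
    on truth-level orthology (sequences are not aligned).
    """
    return SimulationConfig(
        n_genera=1, isolates_per_genus=10, species_per_genus=3,
        n_core_families=50, n_unique_families=0,
        n_dispensable_families=1000, dispensable_mode="tree",
        dispensable_loss_rate=2.5, singlets_per_isolate=5,
        protein_length=30, within_genus_divergence=0.5,
        marker_rate=0.1, marker_coupling=coupling, seed=seed,
    )


def _marker_pairs(marker: dict[str, str], pang) -> list[MarkerPair]:
    labs = sorted(marker)
    pairs = []
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            pairs.append(MarkerPair(
                a, b, percent_identity(marker[a], marker[b]),
                pang.shared(a, b), pang.avg_unique(a, b)))
    return pairs


def regression_r_squared(seed: int, coupling: float) -> tuple[float, float, int]:
    """(R^2 shared, slope shared, n kept pairs) for one simulated genus."""
    _, marker, truth = simulate_pangenome(regression_config(seed, coupling))
    pairs = filter_pairs(_marker_pairs(marker, truth.to_pangenome()))
    fit = least_squares_fit([p.identity for p in pairs],
                            [float(p.shared) for p in pairs])
    return fit.r_squared, fit.slope, fit.n_pairs


def regression_experiment(seed: int, n_replicates: int = 50) -> dict:
    """Coupled R^2 (one run) and mean uncoupled R^2 over replicates."""
    r2_coupled, slope, n_pairs = regression_r_squared(_subseed(seed, 2), 1.0)
    r2_null = [
        regression_r_squared(_subseed(seed, 10 + i), 0.0)[0]
        for i in range(n_replicates)
    ]
    return {
        "r2_coupled": r2_coupled,
        "slope_coupled": slope,
        "n_pairs": n_pairs,
        "mean_r2_uncoupled": float(np.mean(r2_null)),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# Cohesiveness: planted cohesive species, scattered-label null, calibration
# ---------------------------------------------------------------------------

def cohesive_config(seed: int) -> SimulationConfig:
    """One genus, three species of three isolates, each species carrying a
    strong private family set on top of shared core and accessory content."""
    return SimulationConfig(
        n_genera=1, isolates_per_genus=9, species_per_genus=3,
        n_core_families=100, n_unique_families=0,
        n_dispensable_families=60, dispensable_presence_prob=0.5,
        species_core_families=30, singlets_per_isolate=5,
        protein_length=30, within_genus_divergence=0.1, seed=seed,
    )


def cohesive_species_experiment(seed: int) -> CohesivenessResult:
    """Cohesiveness row for a species planted with 30 private families."""
    _, _, truth = simulate_pangenome(cohesive_config(_subseed(seed, 3)))
    pang = truth.to_pangenome()
    (genus, labs), = pang.genera().items()
    species_of = {lab: lab.split("|")[1] for lab in labs}
    focal = sorted(set(species_of.values()))[0]
    return cohesiveness_analysis(
        focal, species_of,
        core_fn=lambda s: pang.core(s),
        unique_fn=lambda s: pang.unique(s, set(labs) - set(s)),
        seed=_subseed(seed, 4),
    )


def scattered_null_config(seed: int) -> SimulationConfig:
    """Homogeneous genus where species labels carry no content signal:
    i.i.d. accessory presence, no species-private families."""
    return SimulationConfig(
        n_genera=1, isolates_per_genus=8, species_per_genus=2,
        n_core_families=50, n_unique_families=0,
        n_dispensable_families=200, dispensable_presence_prob=0.5,
        species_core_families=0, singlets_per_isolate=5,
        protein_length=30, within_genus_divergence=0.1, seed=seed,
    )


def scattered_null_experiment(seed: int, n_replicates: int = 20) -> dict:
    """Scattered-label null: the focal species should look like a random set.

    Returns the fraction of replicates in which the observed unique-proteome
    size strictly exceeds every random set's (expected to be small, about
    1/(m+1) at most).
    """
    outlier = 0
    for i in range(n_replicates):
        _, _, truth = simulate_pangenome(
            scattered_null_config(_subseed(seed, 100 + i)))
        pang = truth.to_pangenome()
        (genus, labs), = pang.genera().items()
        species_of = {lab: lab.split("|")[1] for lab in labs}
        focal = sorted(set(species_of.values()))[0]
        res = cohesiveness_analysis(
            focal, species_of,
            core_fn=lambda s: pang.core(s),
            unique_fn=lambda s: pang.unique(s, set(labs) - set(s)),
            seed=_subseed(seed, 200 + i),
        )
        if res.unique_observed > max(res.unique_random):
            outlier += 1
    return {"outlier_fraction": outlier / n_replicates,
            "n_replicates": n_replicates}


def t_test_calibration_experiment(seed: int, n_replicates: int = 500,
                                  alpha: float = 0.05) -> dict:
    """Rejection rate of the one-sample t-test when its H0 is exactly true.

    A 12-isolate genus with i.i.d. accessory content defines a finite
    population of valid 3-isolate sets; each replicate samples 25 sets and
    tests their mean core size against the exact mean over ALL valid sets.
    Sampling without replacement from the finite pool makes the test mildly
    conservative, so the rate should sit at or just below alpha.
    """
    cfg = SimulationConfig(
        n_genera=1, isolates_per_genus=12, species_per_genus=4,
        n_core_families=30, n_unique_families=0,
        n_dispensable_families=150, dispensable_presence_prob=0.5,
        species_core_families=0, singlets_per_isolate=0,
        protein_length=30, within_genus_divergence=0.1,
        seed=_subseed(seed, 5),
    )
    _, _, truth = simulate_pangenome(cfg)
    pang = truth.to_pangenome()
    (genus, labs), = pang.genera().items()
    species_of = {lab: lab.split("|")[1] for lab in labs}
    # exhaustive core sizes over the valid-set population
    all_sets = sample_random_sets(species_of, 3, max_sets=10**9, seed=0)
    core_of = {s: pang.core(s) for s in all_sets}
    mu = float(np.mean(list(core_of.values())))
    from .cohesion import one_sample_t_test

    rejected = 0
    for i in range(n_replicates):
        sets = sample_random_sets(species_of, 3, max_sets=25,
                                  seed=_subseed(seed, 1000 + i))
        _, p = one_sample_t_test([core_of[s] for s in sets], mu)
        if p is not None and p < alpha:
            rejected += 1
    return {"rejection_rate": rejected / n_replicates,
            "n_replicates": n_replicates, "population_size": len(all_sets),
            "population_mean": mu}
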