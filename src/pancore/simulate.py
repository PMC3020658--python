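"""Synthetic pan-proteome generator with planted orthology structure.

The generator emulates the gene-content structure assumed by genus-level
pan-proteome analyses: housekeeping ("core") protein families carried by every
isolate of every genus, genus-private ("unique") families carried by every
isolate of one genus and absent elsewhere, partially present ("dispensable")
families, per-isolate "singlets" with no relatives, and a slow-clock marker
gene (a 16S rRNA stand-in) whose percent identity is tunably coupled to the
same tree that drives proteome divergence.

Every protein descends from a random ancestral sequence evolved down a random
ultrametric tree (species subtrees nested in genus subtrees nested under a
global root) by per-branch substitution; there are no indels, so family members
stay length-aligned and the marker alignment is gap-free by construction.
Substitutions use a uniform replacement model over the residue alphabet
(a Jukes-Cantor-type model with K=20 for proteins, K=4 for the marker), which
has the closed-form expected difference fraction

    p(d) = (K-1)/K * (1 - exp(-K*d/(K-1)))

for branch length ``d`` in expected substitutions per site.

The marker accumulates a deterministic, infinite-sites number of substitutions
per branch, so pairwise marker differences are exactly additive along the tree:
with ``marker_coupling = 1`` marker identity is a strictly decreasing function
of planted tree depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Isolate, ProteomeSet

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"


def expected_diff_fraction(d: float, k_states: int = 20) -> float:
    """Expected fraction of differing sites after ``d`` substitutions/site."""
    k = k_states
    return (k - 1) / k * (1.0 - math.exp(-k * d / (k - 1)))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic pan-proteome dataset.

    Counts are per genus unless noted; divergences are in expected
    substitutions per site on the planted tree. ``marker_coupling`` is the
    fraction of marker divergence driven by the shared tree (1 = pure clock,
    0 = independent noise). Same seed + config reproduces byte-identical
    output.
    """

    n_genera: int = 2
    isolates_per_genus: int | Sequence[int] = 4
    species_per_genus: int = 2
    species_partition: Mapping[str, str] | None = None
    n_core_families: int = 300
    n_unique_families: int = 50
    n_dispensable_families: int = 100
    dispensable_presence_prob: float = 0.5
    singlets_per_isolate: int = 20
    species_core_families: int = 0
    protein_length: int = 300
    within_genus_divergence: float = 0.1
    between_genus_divergence: float = 0.3
    marker_length: int = 1500
    marker_rate: float = 0.1
    marker_coupling: float = 0.9
    dispensable_mode: str = "iid"  # "iid" or "tree"
    dispensable_loss_rate: float = 1.0
    seed: int = 0

    def isolate_counts(self) -> list[int]:
        if isinstance(self.isolates_per_genus, int):
            return [self.isolates_per_genus] * self.n_genera
        counts = list(self.isolates_per_genus)
        if len(counts) != self.n_genera:
            raise ValueError("isolates_per_genus list length must equal n_genera")
        return counts

    def validate(self) -> None:
        for name in (
            "n_genera", "n_core_families", "n_unique_families",
            "n_dispensable_families", "singlets_per_isolate",
            "species_core_families", "protein_length", "marker_length",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_genera < 1:
            raise ValueError("need at least one genus")
        for c in self.isolate_counts():
            if c < 1:
                raise ValueError("zero isolates in a genus")
        for name in ("dispensable_presence_prob", "marker_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        for name in ("within_genus_divergence", "between_genus_divergence",
                     "marker_rate", "dispensable_loss_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dispensable_mode not in ("iid", "tree"):
            raise ValueError("dispensable_mode must be 'iid' or 'tree'")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    age: float  # height above the leaves; pairwise depth = 2 * age(MRCA)
    children: list["_Node"] = field(default_factory=list)
    label: str | None = None  # isolate label for leaves

    def leaves(self) -> list["_Node"]:
        if not self.children:
            return [self]
        out: list[_Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def _coalesce(nodes: list[_Node], heights: np.ndarray, rng: np.random.Generator) -> _Node:
    """Join random pairs at the given (ascending) heights until one root."""
    nodes = list(nodes)
    for h in heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(_Node(age=float(h), children=[a, b]))
    assert len(nodes) == 1
    return nodes[0]


def _genus_tree(isolates: list[Isolate], age: float, rng: np.random.Generator) -> _Node:
    """Random ultrametric genus tree with species nested below 0.3x the root age.

    The deepest split is pinned at ``age`` so the maximum within-genus pairwise
    depth equals the configured within-genus divergence.
    """
    by_species: dict[str, list[_Node]] = {}
    for iso in isolates:
        by_species.setdefault(iso.species, []).append(_Node(age=0.0, label=iso.label))
    subtrees = []
    for sp in sorted(by_species):
        members = by_species[sp]
        hmax = age if len(by_species) == 1 else 0.3 * age
        heights = np.sort(rng.uniform(0.0, hmax, size=len(members) - 1))
        if len(by_species) == 1 and len(members) > 1:
            heights[-1] = age
        subtrees.append(_coalesce(members, heights, rng))
    if len(subtrees) == 1:
        root = subtrees[0]
        if root.age < age and root.children:
            root.age = age
        return root
    heights = np.sort(rng.uniform(0.6 * age, age, size=len(subtrees) - 1))
    heights[-1] = age
    return _coalesce(subtrees, heights, rng)


def _pair_depths(root: _Node) -> dict[frozenset, float]:
    """Pairwise planted depths: 2 * age of the most recent common ancestor."""
    depths: dict[frozenset, float] = {}

    def visit(node: _Node) -> list[str]:
        if not node.children:
            return [node.label]  # type: ignore[list-item]
        groups = [visit(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        depths[frozenset((a, b))] = 2.0 * node.age
        return [x for g in groups for x in g]

    visit(root)
    return depths


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, d: float, rng: np.random.Generator, k_states: int) -> np.ndarray:
    """Evolve a coded sequence along a branch of length ``d`` subs/site.

    Substitution events arrive as Poisson(L*d); each picks a uniform site and
    replaces the residue with a uniform draw over the other k-1 states.
    """
    out = seq.copy()
    n_events = rng.poisson(len(seq) * d)
    for _ in range(n_events):
        site = rng.integers(len(seq))
        r = rng.integers(k_states - 1)
        if r >= out[site]:
            r += 1
        out[site] = r
    return out


def _decode(seq: np.ndarray, alphabet: str) -> str:
    return "".join(alphabet[c] for c in seq)


def evolve_family(
    ancestor: str,
    depths: Sequence[float],
    rate: float,
    rng: np.random.Generator | int | None = None,
    alphabet: str = AA_ALPHABET,
) -> list[str]:
    """Evolve independent family members from a common ancestor.

    Each member descends from ``ancestor`` along its own branch of length
    ``depth * rate`` expected substitutions per site (no indels, so outputs
    keep the ancestor's length). Substitutions replace the current residue
    with a uniform draw over the rest of the alphabet.
    """
    if not ancestor:
        raise ValueError("empty ancestor sequence")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    index = {c: i for i, c in enumerate(alphabet)}
    try:
        coded = np.array([index[c] for c in ancestor], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"residue {exc} not in alphabet") from None
    return [
        _decode(_mutate(coded, float(depth) * rate, rng, len(alphabet)), alphabet)
        for depth in depths
    ]


def _evolve_on_tree(
    root: _Node,
    ancestor: np.ndarray,
    members: set[str],
    rng: np.random.Generator,
    k_states: int,
) -> dict[str, np.ndarray]:
    """Evolve down the tree, returning sequences for the member leaves only.

    Branches are traversed in a fixed order so results are reproducible; the
    whole tree is evolved even when only a few leaves carry the family, which
    keeps member divergence consistent with the planted depths.
    """
    out: dict[str, np.ndarray] = {}

    def visit(node: _Node, seq: np.ndarray, age: float) -> None:
        if not node.children:
            if node.label in members:
                out[node.label] = seq
            return
        for child in node.children:
            branch = age - child.age
            visit(child, _mutate(seq, branch, rng, k_states), child.age)

    visit(root, ancestor, root.age)
    return out


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------

CATEGORIES = ("core", "unique", "dispensable", "species_core", "singlet")


class PlantedTruth:
    """Ground-truth family table plus the planted tree depths.

    ``table`` has one row per (family, member protein) with columns
    family_id, genus, category, isolate, protein_id; genus is ``*`` for the
    globally shared core families. Every generated protein belongs to exactly
    one family.
    """

    def __init__(self, table: pd.DataFrame, depths: dict[frozenset, float],
                 config: SimulationConfig) -> None:
        self.table = table
        self.depths = depths
        self.config = config

    def category_counts(self) -> pd.Series:
        return self.table.groupby("category")["family_id"].nunique()

    def families(self) -> dict[str, list[tuple[str, str]]]:
        out: dict[str, list[tuple[str, str]]] = {}
        for fid, iso, pid in zip(self.table["family_id"], self.table["isolate"],
                                 self.table["protein_id"]):
            out.setdefault(fid, []).append((iso, pid))
        return out

    def to_groups(self) -> list[set[str]]:
        """Truth-level orthologous groups: one group per family."""
        return [
            {pid for _, pid in members} for members in self.families().values()
        ]

    def to_pangenome(self):
        """Truth-level :class:`~pancore.pangenome.PanGenome`.

        Builds the per-pair edge sets a perfect orthology run would produce
        (a clique over each family's members), so downstream measures can be
        evaluated against planted truth through the same code paths as the
        alignment-based pipeline.
        """
        from .pangenome import PanGenome

        proteins: dict[str, list[str]] = {}
        for iso, pid in zip(self.table["isolate"], self.table["protein_id"]):
            proteins.setdefault(iso, []).append(pid)
        edges: dict[frozenset, set] = {}
        for members in self.families().values():
            for i, (iso_a, pid_a) in enumerate(members):
                for iso_b, pid_b in members[i + 1:]:
                    if iso_a == iso_b:
                        continue
                    edges.setdefault(frozenset((iso_a, iso_b)), set()).add(
                        frozenset((pid_a, pid_b)))
        return PanGenome(proteins, edges)

    def pair_depth(self, iso_a: str, iso_b: str) -> float:
        return self.depths[frozenset((iso_a, iso_b))]

    # Expected pipeline outputs, counted from the truth table itself ------

    def _genus_isolates(self, genus: str) -> list[str]:
        labs = sorted(set(self.table.loc[self.table["isolate"].str.startswith(genus + "|"),
                                         "isolate"]))
        if not labs:
            raise ValueError(f"unknown genus {genus}")
        return labs

    def expected_core(self, genus: str) -> int:
        """Families with >=1 member in every isolate of the genus."""
        isolates = set(self._genus_isolates(genus))
        count = 0
        for members in self.families().values():
            if isolates <= {iso for iso, _ in members}:
                count += 1
        return count

    def expected_unique(self, genus: str) -> int:
        """Families spanning the whole genus with no members elsewhere."""
        isolates = set(self._genus_isolates(genus))
        count = 0
        for members in self.families().values():
            present = {iso for iso, _ in members}
            if isolates <= present and present <= isolates:
                count += 1
        return count

    def expected_singlets(self, genus: str) -> dict[str, int]:
        """Per-isolate counts of families with exactly one member in the genus."""
        isolates = set(self._genus_isolates(genus))
        counts = {iso: 0 for iso in sorted(isolates)}
        for members in self.families().values():
            inside = [(iso, pid) for iso, pid in members if iso in isolates]
            if len(inside) == 1:
                counts[inside[0][0]] += 1
        return counts


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def _presence_iid(isolates: list[str], p: float, rng: np.random.Generator) -> set[str]:
    while True:
        mask = rng.random(len(isolates)) < p
        if mask.sum() >= 2:
            return {iso for iso, m in zip(isolates, mask) if m}


def _presence_tree_loss(root: _Node, rate: float, rng: np.random.Generator) -> set[str]:
    """Family present at the genus root, lost along branches at ``rate``."""
    while True:
        present: set[str] = set()

        def visit(node: _Node, age: float) -> None:
            for child in node.children:
                branch = age - child.age
                if rng.random() < 1.0 - math.exp(-rate * branch):
                    continue  # lost on this branch, whole subtree absent
                if not child.children:
                    present.add(child.label)  # type: ignore[arg-type]
                else:
                    visit(child, child.age)

        if not root.children:
            present.add(root.label)  # type: ignore[arg-type]
        else:
            visit(root, root.age)
        if len(present) >= 2:
            return present


def simulate_pangenome(
    config: SimulationConfig,
) -> tuple[ProteomeSet, dict[str, str], PlantedTruth]:
    """Generate proteomes, an aligned marker, and the planted truth table."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_fam, s_marker = ss.spawn(3)
    rng_tree = np.random.default_rng(s_tree)

    # Isolate roster -------------------------------------------------------
    counts = config.isolate_counts()
    genera: dict[str, list[Isolate]] = {}
    for g in range(config.n_genera):
        genus = f"G{g + 1}"
        isolates = []
        for i in range(counts[g]):
            name = f"iso{i + 1}"
            if config.species_partition is not None:
                sp = config.species_partition[f"{genus}|{name}"]
            else:
                n_sp = min(config.species_per_genus, counts[g])
                sp = f"{genus}sp{(i % n_sp) + 1}"
            isolates.append(Isolate(genus, sp, name))
        genera[genus] = isolates

    # Planted trees --------------------------------------------------------
    genus_age = config.within_genus_divergence / 2.0
    global_age = (config.within_genus_divergence + config.between_genus_divergence) / 2.0
    genus_roots = {
        genus: _genus_tree(isolates, genus_age, rng_tree)
        for genus, isolates in genera.items()
    }
    if config.n_genera == 1:
        global_root = next(iter(genus_roots.values()))
    else:
        global_root = _Node(age=global_age, children=[genus_roots[g] for g in sorted(genus_roots)])
    depths = _pair_depths(global_root)

    # Families -------------------------------------------------------------
    species_core_plan: list[tuple[str, str, list[str]]] = []
    for genus, isolates in genera.items():
        by_sp: dict[str, list[str]] = {}
        for iso in isolates:
            by_sp.setdefault(iso.species, []).append(iso.label)
        for sp in sorted(by_sp):
            if len(by_sp[sp]) >= 2 and config.species_core_families > 0:
                species_core_plan.append((genus, sp, by_sp[sp]))

    n_singlet_families = sum(counts) * config.singlets_per_isolate
    total_families = (
        config.n_core_families
        + config.n_genera * (config.n_unique_families + config.n_dispensable_families)
        + len(species_core_plan) * config.species_core_families
        + n_singlet_families
    )
    fam_streams = iter(s_fam.spawn(total_families)) if total_families else iter([])

    pset = ProteomeSet()
    for genus in sorted(genera):
        for iso in genera[genus]:
            pset.add_isolate(iso)

    rows: list[tuple[str, str, str, str, str]] = []
    fam_counter = 0

    def next_family_rng() -> np.random.Generator:
        return np.random.default_rng(next(fam_streams))

    def emit_family(category: str, genus_label: str, root: _Node,
                    members: set[str]) -> None:
        nonlocal fam_counter
        fam_counter += 1
        fid = f"F{fam_counter:05d}"
        rng = next_family_rng()
        length = max(10, int(rng.poisson(config.protein_length)))
        ancestor = rng.integers(len(AA_ALPHABET), size=length)
        seqs = _evolve_on_tree(root, ancestor, members, rng, len(AA_ALPHABET))
        for iso_label in sorted(members):
            pid = f"{iso_label}|{fid}"
            pset.add_protein(Isolate.from_label(iso_label), pid,
                             _decode(seqs[iso_label], AA_ALPHABET))
            rows.append((fid, genus_label, category, iso_label, pid))

    all_labels = {g: [iso.label for iso in genera[g]] for g in genera}

    for _ in range(config.n_core_families):
        emit_family("core", "*", global_root,
                    {iso.label for g in genera for iso in genera[g]})
    for genus in sorted(genera):
        for _ in range(config.n_unique_families):
            emit_family("unique", genus, genus_roots[genus], set(all_labels[genus]))
        for _ in range(config.n_dispensable_families):
            rng_presence = next_family_rng()
            if config.dispensable_mode == "iid":
                members = _presence_iid(all_labels[genus],
                                        config.dispensable_presence_prob, rng_presence)
            else:
                members = _presence_tree_loss(genus_roots[genus],
                                              config.dispensable_loss_rate, rng_presence)
            fam_counter += 1
            fid = f"F{fam_counter:05d}"
            length = max(10, int(rng_presence.poisson(config.protein_length)))
            ancestor = rng_presence.integers(len(AA_ALPHABET), size=length)
            seqs = _evolve_on_tree(genus_roots[genus], ancestor, members,
                                   rng_presence, len(AA_ALPHABET))
            for iso_label in sorted(members):
                pid = f"{iso_label}|{fid}"
                pset.add_protein(Isolate.from_label(iso_label), pid,
                                 _decode(seqs[iso_label], AA_ALPHABET))
                rows.append((fid, genus, "dispensable", iso_label, pid))
    for genus, sp, labels in species_core_plan:
        for _ in range(config.species_core_families):
            emit_family("species_core", genus, genus_roots[genus], set(labels))
    # Singlets: fresh random sequences, no family ancestor, so no spurious
    # reciprocal hits arise at moderate thresholds.
    for genus in sorted(genera):
        for iso in genera[genus]:
            for _ in range(config.singlets_per_isolate):
                rng = next_family_rng()
                fam_counter += 1
                fid = f"F{fam_counter:05d}"
                length = max(10, int(rng.poisson(config.protein_length)))
                seq = _decode(rng.integers(len(AA_ALPHABET), size=length), AA_ALPHABET)
                pid = f"{iso.label}|{fid}"
                pset.add_protein(iso, pid, seq)
                rows.append((fid, genus, "singlet", iso.label, pid))

    # Marker ---------------------------------------------------------------
    rng_marker = np.random.default_rng(s_marker)
    marker = _simulate_marker(global_root, config, rng_marker)

    table = pd.DataFrame(
        rows, columns=["family_id", "genus", "category", "isolate", "protein_id"]
    )
    return pset, marker, PlantedTruth(table, depths, config)


def _simulate_marker(root: _Node, config: SimulationConfig,
                     rng: np.random.Generator) -> dict[str, str]:
    """Evolve the marker down the tree with deterministic substitution counts.

    Substitutions land on previously unmutated sites (infinite-sites
    allocation) and counts are allocated cumulatively along each
    root-to-leaf path — a branch receives round(L*cum_after) -
    round(L*cum_before) events — so the pairwise difference count is an
    exactly additive, strictly rounding-monotone function of path length.
    The effective branch length interpolates between the planted branch
    (coupling = 1) and, on terminal branches, isolate-specific random noise
    (coupling = 0).
    """
    L = config.marker_length
    root_seq = rng.integers(4, size=L)
    site_order = list(rng.permutation(L))
    leaf_labels = sorted(l.label for l in root.leaves())
    noise = {lab: rng.uniform(0.0, root.age if root.age > 0 else 1.0)
             for lab in leaf_labels}
    out: dict[str, str] = {}
    pointer = [0]

    def mutate(seq: np.ndarray, k: int) -> np.ndarray:
        seq = seq.copy()
        for _ in range(k):
            if pointer[0] >= len(site_order):
                break  # site pool exhausted; additivity degrades gracefully
            site = site_order[pointer[0]]
            pointer[0] += 1
            r = rng.integers(3)
            if r >= seq[site]:
                r += 1
            seq[site] = r
        return seq

    def visit(node: _Node, seq: np.ndarray, age: float, cum: float) -> None:
        if not node.children:
            out[node.label] = _decode(seq, NT_ALPHABET)  # type: ignore[index]
            return
        for child in node.children:
            b = age - child.age
            if child.children:
                b_eff = config.marker_coupling * b
            else:
                b_eff = (config.marker_coupling * b
                         + (1.0 - config.marker_coupling) * noise[child.label])
            cum_after = cum + config.marker_rate * b_eff
            k = int(round(L * cum_after)) - int(round(L * cum))
            visit(child, mutate(seq, k), child.age, cum_after)

    if not root.children:
        out[root.label] = _decode(root_seq, NT_ALPHABET)  # type: ignore[index]
    else:
        visit(root, root_seq, root.age, 0.0)
    return {lab: out[lab] for lab in leaf_labels}


# ---------------------------------------------------------------------------
# Dataset writing (one FASTA per isolate + marker + truth + metadata)
# ---------------------------------------------------------------------------

def write_dataset(pset: ProteomeSet, marker: dict[str, str], truth: PlantedTruth,
                  outdir) -> None:
    from pathlib import Path

    from .io import write_fasta, write_report

    outdir = Path(outdir)
    (outdir / "proteomes").mkdir(parents=True, exist_ok=True)
    pset.write_fasta_dir(outdir / "proteomes")
    write_fasta(marker, outdir / "marker.fasta")
    write_report(truth.table, outdir / "truth.tsv")
    write_report(pset.metadata_frame(), outdir / "metadata.tsv")
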