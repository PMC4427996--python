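"""Synthetic paralog-pair alignments with known character-site truth.

Two scenarios are distinguished for a pair of homologous protein families
(A and B), each split into a common and a rare form:

* ``deep_divergence`` — the rare forms are genuinely ancient: the topology
  is ((commonA, rareA), (commonB, rareB)) rooted at the family split.
  Symplesiomorphies for, say, rare A arise from single substitutions on
  the common-A stem at slowly evolving sites, so their expected count
  scales with the sister stem length.
* ``lba`` — the rare-A clade actually emerged from within common A on a
  long branch (the long-branch-attraction scenario). The bipartition
  required for a rare-A symplesiomorphy does not exist; any apparent one
  must come from convergent substitution, which the simulator measures
  rather than presumes.

Sequences evolve by a uniform-exchange amino-acid process: on a branch of
length t, a site of relative rate r receives a Poisson(r * t * mu) number
of substitutions, each replacing the current residue with a uniform draw
from the other 19. This deliberately simple model (not LG/WAG) keeps
expectations calculable by hand; the character-site argument depends only
on slow sites and topology, not on exchangeability structure. Sites fall
into a fast background class (rate 1) and a slow class (configurable
multiplier, 0 = invariant) that hosts planted character sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np

from paralogsites.io import AMINO_ACIDS, Alignment, TaxonGrouping
from paralogsites.charsites import (
    CharSiteParams,
    SimilarityScheme,
    scan_charsites,
    summarize_calls,
)

_AA = np.array(list(AMINO_ACIDS))
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

GROUPS: tuple[tuple[str, str], ...] = (
    ("A", "common"),
    ("A", "rare"),
    ("B", "common"),
    ("B", "rare"),
)


def _group_key(family: str, form: str) -> str:
    return f"{form}{family}"


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth character site to engineer into the alignment."""

    column: int
    classification: str  # symplesiomorphy | synapomorphy
    ingroup: tuple[str, str]
    defining_residue: str
    background_residue: str

    def __post_init__(self) -> None:
        if self.classification not in ("symplesiomorphy", "synapomorphy"):
            raise ValueError(f"unknown planted classification {self.classification!r}")
        if self.defining_residue == self.background_residue:
            raise ValueError("defining and background residues must differ")
        for r in (self.defining_residue, self.background_residue):
            if r not in _AA_INDEX:
                raise ValueError(f"unknown residue {r!r}")
        if self.ingroup not in GROUPS:
            raise ValueError(f"unknown ingroup {self.ingroup!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Simulator parameters.

    Stem lengths are expected substitutions/site (at rate 1) on the branch
    subtending each group's ancestor; ``family_stem_length`` plays the same
    role for the two family ancestors under the deep-divergence preset.
    Defaults mirror the qualitative shape of the real paralog pair: common
    forms are taxon-rich, rare forms are smaller and sit on long stems.
    """

    preset: str = "deep_divergence"
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "commonA": 20,
            "rareA": 8,
            "commonB": 20,
            "rareB": 8,
        }
    )
    stem_lengths: Mapping[str, float] = field(
        default_factory=lambda: {
            "commonA": 0.6,
            "rareA": 1.2,
            "commonB": 0.3,
            "rareB": 1.2,
        }
    )
    family_stem_length: float = 0.4
    within_group_length: float = 0.3
    n_columns: int = 200
    slow_site_fraction: float = 0.3
    slow_rate_multiplier: float = 0.0
    mutation_rate: float = 1.0
    planted_sites: tuple[PlantedSite, ...] = ()
    plant_in_slow_class: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in ("deep_divergence", "lba"):
            raise ValueError(f"unknown preset {self.preset!r}")
        for key in ("commonA", "rareA", "commonB", "rareB"):
            if self.group_sizes.get(key, 0) < 2:
                raise ValueError(f"group {key!r} needs at least 2 taxa")
            if self.stem_lengths.get(key, 0.0) < 0:
                raise ValueError(f"negative stem length for {key!r}")
        if not 0.0 <= self.slow_site_fraction <= 1.0:
            raise ValueError("slow_site_fraction must be in [0, 1]")
        if self.slow_rate_multiplier < 0 or self.mutation_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_columns < 1:
            raise ValueError("n_columns must be positive")
        cols = [p.column for p in self.planted_sites]
        if len(set(cols)) != len(cols):
            raise ValueError("planted columns must be unique")
        for p in self.planted_sites:
            if not 1 <= p.column <= self.n_columns:
                raise ValueError(f"planted column {p.column} out of range")
        self._check_plants_realizable()

    def _check_plants_realizable(self) -> None:
        for p in self.planted_sites:
            fam, form = p.ingroup
            sister = (fam, "rare" if form == "common" else "common")
            if self.preset == "lba" and fam == "A":
                if p.classification == "symplesiomorphy" and sister == ("A", "common"):
                    raise ValueError(
                        f"planted site {p.column}: a {form} A symplesiomorphy "
                        "requires a monophyletic common-A sister group, but "
                        "under the lba preset rare A is nested inside common A"
                    )
                if p.classification == "synapomorphy" and p.ingroup == ("A", "common"):
                    raise ValueError(
                        f"planted site {p.column}: common A is paraphyletic "
                        "under the lba preset, so a common-A synapomorphy "
                        "cannot arise from a single substitution"
                    )

    def taxa_of(self, family: str, form: str) -> tuple[str, ...]:
        key = _group_key(family, form)
        return tuple(
            f"{key}_{i + 1:02d}" for i in range(self.group_sizes[key])
        )


@dataclass(frozen=True)
class TruthTable:
    """Planted ground truth: column -> (classification, ingroup, residue)."""

    entries: Mapping[int, tuple[str, tuple[str, str], str]]

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_config(cls, config: ScenarioConfig) -> "TruthTable":
        return cls(
            {
                p.column: (p.classification, p.ingroup, p.defining_residue)
                for p in config.planted_sites
            }
        )


def build_scenario_tree(config: ScenarioConfig) -> dendropy.Tree:
    """Construct the scenario tree with configured branch lengths.

    deep_divergence: ((commonA, rareA), (commonB, rareB)) rooted at the
    family split. lba: family B as before, but the rare-A ancestor hangs
    off the common-A ancestor on its (long) stem, nesting rare A inside
    the common-A clade.
    """
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def group_node(family: str, form: str) -> dendropy.Node:
        key = _group_key(family, form)
        node = dendropy.Node()
        node.edge.length = config.stem_lengths[key]
        node.label = key
        for name in config.taxa_of(family, form):
            tip = dendropy.Node()
            tip.taxon = taxa.new_taxon(label=name)
            tip.edge.length = config.within_group_length
            node.add_child(tip)
        return node

    common_a = group_node("A", "common")
    rare_a = group_node("A", "rare")
    common_b = group_node("B", "common")
    rare_b = group_node("B", "rare")

    fam_b = dendropy.Node()
    fam_b.label = "familyB"
    fam_b.edge.length = config.family_stem_length
    fam_b.add_child(common_b)
    fam_b.add_child(rare_b)

    fam_a = dendropy.Node()
    fam_a.label = "familyA"
    fam_a.edge.length = config.family_stem_length
    if config.preset == "deep_divergence":
        fam_a.add_child(common_a)
        fam_a.add_child(rare_a)
    else:  # lba: rare A emerges from within common A
        common_a.add_child(rare_a)
        fam_a.add_child(common_a)

    tree.seed_node.add_child(fam_a)
    tree.seed_node.add_child(fam_b)
    tree.is_rooted = True
    return tree


def evolve_branch(
    states: np.ndarray, length: float, rates: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Evolve integer residue states along one branch.

    Each column i receives ``k_i ~ Poisson(rates[i] * length)``
    substitutions, each replacing the current residue with a uniform draw
    from the other 19. Returns (new states, per-column substitution counts).
    """
    out = states.copy()
    ks = rng.poisson(rates * length)
    for col in np.nonzero(ks)[0]:
        s = out[col]
        for _ in range(ks[col]):
            jump = rng.integers(0, 19)
            s = (s + 1 + jump) % 20
        out[col] = s
    return out, ks


def simulate_alignment(
    config: ScenarioConfig,
) -> tuple[Alignment, TruthTable, TaxonGrouping]:
    """Simulate one alignment under the configured scenario.

    Planted symplesiomorphy columns carry the defining residue at the root
    (shared by ingroup and outgroup) with the sister group's ancestor
    overridden to the background residue — the single substitution on the
    sister stem that the site records. Planted synapomorphy columns carry
    the background residue at the root with the ingroup's ancestor
    overridden to the defining residue. Planted columns sit in the slow
    site class (unless ``plant_in_slow_class`` is off), so at slow rate 0
    truth labels are exact.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_columns

    # site rate classes; planted columns forced slow so truth stays valid
    n_slow = int(round(config.slow_site_fraction * n))
    slow = np.zeros(n, dtype=bool)
    planted_cols = np.array([p.column - 1 for p in config.planted_sites], dtype=int)
    if config.plant_in_slow_class and planted_cols.size:
        slow[planted_cols] = True
    remaining = np.flatnonzero(~slow)
    extra = n_slow - int(slow.sum())
    if extra > 0 and remaining.size:
        chosen = rng.choice(remaining, size=min(extra, remaining.size), replace=False)
        slow[chosen] = True
    rates = np.where(slow, config.slow_rate_multiplier, 1.0) * config.mutation_rate

    # root sequence: uniform, with planted columns pinned
    root = rng.integers(0, 20, size=n)
    overrides: dict[str, dict[int, int]] = {}
    for p in config.planted_sites:
        fam, form = p.ingroup
        sister_key = _group_key(fam, "rare" if form == "common" else "common")
        ingroup_key = _group_key(fam, form)
        j = p.column - 1
        if p.classification == "symplesiomorphy":
            root[j] = _AA_INDEX[p.defining_residue]
            overrides.setdefault(sister_key, {})[j] = _AA_INDEX[p.background_residue]
        else:
            root[j] = _AA_INDEX[p.background_residue]
            overrides.setdefault(ingroup_key, {})[j] = _AA_INDEX[p.defining_residue]

    tree = build_scenario_tree(config)
    states: dict[int, np.ndarray] = {id(tree.seed_node): root}
    tip_rows: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = states[id(node.parent_node)]
        state, _ = evolve_branch(parent_state, node.edge.length or 0.0, rates, rng)
        if node.label in overrides:
            for j, residue in overrides[node.label].items():
                state[j] = residue
        states[id(node)] = state
        if node.taxon is not None:
            tip_rows[node.taxon.label] = "".join(_AA[state])

    assignments: dict[str, tuple[str, str]] = {}
    taxon_order: list[str] = []
    for fam, form in GROUPS:
        for name in config.taxa_of(fam, form):
            assignments[name] = (fam, form)
            taxon_order.append(name)
    alignment = Alignment(
        tuple(taxon_order), tuple(tip_rows[t] for t in taxon_order)
    )
    return alignment, TruthTable.from_config(config), TaxonGrouping(assignments)


@dataclass(frozen=True)
class ExperimentSummary:
    """Replicated simulate-then-scan results."""

    n_replicates: int
    mean_symplesiomorphies: Mapping[tuple[str, str], float]
    replicate_counts: tuple[Mapping[tuple[str, str], int], ...]
    recovery_fraction: float | None  # planted sites exactly recovered

    def rare_common_ratio(self, family: str) -> float:
        common = self.mean_symplesiomorphies.get((family, "common"), 0.0)
        rare = self.mean_symplesiomorphies.get((family, "rare"), 0.0)
        return rare / common if common else float("inf") if rare else float("nan")


def scenario_experiment(
    config: ScenarioConfig,
    n_replicates: int,
    scheme: SimilarityScheme | None = None,
    params: CharSiteParams | None = None,
) -> ExperimentSummary:
    """Simulate `n_replicates` alignments and scan each for character sites.

    Replicates use disjoint sub-seeds derived from ``config.seed``.
    Reported symplesiomorphy counts exclude weak calls. When sites are
    planted, ``recovery_fraction`` is the fraction of planted sites whose
    exact (column, classification, ingroup) call is found, over all
    replicates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(n_replicates) % (
        2**31
    )
    totals: dict[tuple[str, str], float] = {
        (fam, form): 0.0 for fam, form in GROUPS
    }
    per_rep: list[dict[tuple[str, str], int]] = []
    recovered = 0
    planted_total = 0
    for rep in range(n_replicates):
        cfg = replace(config, seed=int(child_seeds[rep]))
        alignment, truth, grouping = simulate_alignment(cfg)
        calls = scan_charsites(alignment, grouping, scheme, params)
        report = summarize_calls(calls)
        counts = {
            (fam, form): report.symplesiomorphy_counts.get((fam, form), 0)
            for fam, form in GROUPS
        }
        per_rep.append(counts)
        for key, v in counts.items():
            totals[key] += v
        found = {
            (c.column, c.classification, c.ingroup)
            for c in calls
            if c.counts_for_headline
        }
        for col, (classification, ingroup, _residue) in truth.entries.items():
            planted_total += 1
            if (col, classification, ingroup) in found:
                recovered += 1
    means = {k: v / n_replicates for k, v in totals.items()}
    recovery = recovered / planted_total if planted_total else None
    return ExperimentSummary(n_replicates, means, tuple(per_rep), recovery)
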