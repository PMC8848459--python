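"""Generative models for the synthetic datasets.

The generator has two tiers that mirror the assumptions of the stages that
consume them:

* a fast *frequency tier* (Balding–Nichols population frequencies plus
  binomial genotype sampling) feeding the clustering and site-pattern
  statistics, and
* a full *coalescent tier* (multispecies coalescent with pulse admixture,
  Jukes–Cantor sequences) feeding the tree and concordance statistics.

:class:`PopulationModel` describes the demography shared by both tiers;
:class:`SimConfig` describes dataset shape and noise;
:class:`SyntheticDataset` bundles the emitted data with its ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from ..containers import GenotypeMatrix, LocusAlignment


@dataclass(frozen=True)
class AdmixtureEvent:
    """A single admixture pulse.

    ``time`` is in coalescent units before the present. Forward in time, a
    fraction ``proportion`` of the ``recipient`` population's lineages
    derive from ``donor`` at that instant.
    """

    time: float
    donor: str
    recipient: str
    proportion: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(
                f"admixture proportion {self.proportion} outside [0, 1]"
            )
        if self.time < 0:
            raise ValueError("admixture time must be nonnegative")


@dataclass(frozen=True)
class HybridSpec:
    """A deliberately constructed admixed individual.

    ``fractions`` are target ancestry proportions over ``parents``;
    ``generation`` is one of ``"F1"``, ``"BC1"`` or ``"clinal"`` and only
    affects how haplotypes are routed in the coalescent tier (an F1 takes
    exactly one haplotype from each parent).
    """

    individual: str
    parents: tuple[str, ...]
    fractions: tuple[float, ...]
    generation: str = "F1"

    def __post_init__(self) -> None:
        if len(self.parents) != len(self.fractions):
            raise ValueError("parents and fractions differ in length")
        if abs(sum(self.fractions) - 1.0) > 1e-8:
            raise ValueError("hybrid ancestry fractions must sum to 1")
        if self.generation not in ("F1", "BC1", "clinal"):
            raise ValueError(f"unknown hybrid generation {self.generation!r}")


class PopulationModel:
    """Population labels, drift, topology and admixture pulses.

    Parameters
    ----------
    populations:
        Sampled population labels (tree tips minus ``ghosts``).
    tree:
        Rooted binary population tree in Newick, branch lengths in
        coalescent units (time scaled so one pair coalesces at rate 1).
        Optional: without a tree the frequency tier treats populations as
        independent draws around a common ancestral frequency (a "star"
        model), which is all the clustering statistics assume.
    drift:
        Per-population Balding–Nichols drift parameter F in (0, 1).
    admixture:
        Pulse events; times must fall within the existence interval of
        both donor and recipient branches when a tree is supplied.
    ghosts:
        Populations that exist in the model (may donate alleles) but are
        excluded from output sampling.
    """

    def __init__(
        self,
        populations: list[str],
        tree: Optional[str] = None,
        drift: Optional[dict[str, float]] = None,
        admixture: Optional[list[AdmixtureEvent]] = None,
        ghosts: Optional[list[str]] = None,
    ) -> None:
        self.populations = list(populations)
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("duplicate population labels")
        self.ghosts = list(ghosts or [])
        self.admixture = list(admixture or [])
        self.drift = dict(drift or {})
        for pop, f in self.drift.items():
            if not 0.0 < f < 1.0:
                raise ValueError(
                    f"drift F for {pop!r} must lie strictly in (0, 1); "
                    f"got {f} (F=0 and F=1 are degenerate)"
                )
        self.newick = tree
        self.tree: Optional[dendropy.Tree] = None
        if tree is not None:
            self.tree = dendropy.Tree.get(
                data=tree, schema="newick", preserve_underscores=True, rooting="force-rooted"
            )
            self._validate_tree()
        self._validate_admixture()

    # -- validation -----------------------------------------------------

    def _validate_tree(self) -> None:
        assert self.tree is not None
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        declared = set(self.populations) | set(self.ghosts)
        missing = declared - tips
        if missing:
            raise ValueError(f"populations not in tree: {sorted(missing)}")
        for node in self.tree.preorder_node_iter():
            n_children = len(node.child_nodes())
            if n_children not in (0, 2) and not (
                node is self.tree.seed_node and n_children == 1
            ):
                raise ValueError("population tree must be binary")

    def branch_interval(self, label: str) -> tuple[float, float]:
        """Existence interval (start, end] of a branch, in time before present.

        For a tip population this runs from 0 to its parent node's age; for
        an internal branch (labelled node) from the node's age to its
        parent's age.
        """
        if self.tree is None:
            return (0.0, np.inf)
        node = self._find_node(label)
        ages = self._node_ages()
        lo = ages[id(node)]
        hi = ages[id(node.parent_node)] if node.parent_node else np.inf
        return (lo, hi)

    def _find_node(self, label: str) -> dendropy.Node:
        assert self.tree is not None
        for node in self.tree.preorder_node_iter():
            name = node.taxon.label if node.taxon else node.label
            if name == label:
                return node
        raise KeyError(f"no branch labelled {label!r} in population tree")

    def _node_ages(self) -> dict[int, float]:
        assert self.tree is not None
        ages: dict[int, float] = {}
        # leaf ages 0; internal ages from child age + child edge length
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                ages[id(node)] = 0.0
            else:
                child = node.child_nodes()[0]
                ages[id(node)] = ages[id(child)] + (child.edge.length or 0.0)
        return ages

    def _validate_admixture(self) -> None:
        if self.tree is None:
            return
        for event in self.admixture:
            for label in (event.donor, event.recipient):
                lo, hi = self.branch_interval(label)
                if not (lo <= event.time < hi):
                    raise ValueError(
                        f"admixture time {event.time} outside existence "
                        f"interval [{lo}, {hi}) of branch {label!r}"
                    )

    def sampled_populations(self) -> list[str]:
        return [p for p in self.populations if p not in self.ghosts]


@dataclass
class SimConfig:
    """Dataset shape and noise knobs for the generator.

    Defaults mirror the study system at desk scale: a few dozen multi-kb
    phased diploid loci, hierarchically structured populations, and
    missingness typical of target-capture data.
    """

    n_loci: int = 60
    locus_length: int = 2000
    mutation_rate: float = 0.01
    samples_per_population: int = 8
    hybrids: list[HybridSpec] = field(default_factory=list)
    site_missingness: float = 0.0
    individual_missingness: float = 0.0
    ambiguity_rate: float = 0.0
    mito_capture: bool = False
    mito_donor: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("site_missingness", "individual_missingness", "ambiguity_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {rate}")
        if self.n_loci < 1 or self.locus_length < 1:
            raise ValueError("need at least one locus of positive length")

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance logs."""
        payload = json.dumps(
            {
                k: (v if not isinstance(v, list) else [repr(x) for x in v])
                for k, v in self.__dict__.items()
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SyntheticDataset:
    """A fully simulated dataset plus its ground truth."""

    alignments: list[LocusAlignment]
    genotypes: GenotypeMatrix
    gene_trees: list[str]
    q_true: pd.DataFrame
    population_map: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        q = self.q_true.to_numpy(dtype=float)
        if q.size and not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q_true rows must sum to 1")
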