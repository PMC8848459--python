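"""Multispecies-coalescent gene-tree simulation with pulse admixture.

Time runs backwards from the present in coalescent units (the scale on
which a single pair of lineages in one population coalesces at rate 1).
Within each population branch, lineages coalesce as a standard
exponential-rate coalescent; at population-split times (viewed backwards)
the daughter branches merge into their parent; at a pulse-admixture event
each lineage currently in the recipient branch jumps to the donor branch
independently with probability equal to the pulse proportion.

Deliberately constructed hybrid individuals are handled at the tips: each
haplotype of a hybrid starts in one of its parent populations, drawn per
locus (an F1 takes exactly one haplotype from each parent).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import HybridSpec, PopulationModel


@dataclass
class _Lineage:
    """A live ancestral lineage: either a tip or a coalesced subtree."""

    label: Optional[str]
    age: float
    children: tuple = ()

    def newick(self, parent_age: float) -> str:
        length = parent_age - self.age
        if not self.children:
            return f"{self.label}:{length:.8g}"
        inner = ",".join(c.newick(self.age) for c in self.children)
        return f"({inner}):{length:.8g}"


@dataclass
class _Branch:
    label: str
    start: float  # age at which the branch begins (toward the present)
    end: float  # age at which it merges into its parent (inf for root)
    parent: Optional[str]
    lineages: list = field(default_factory=list)


def _tree_branches(model: PopulationModel) -> dict[str, _Branch]:
    if model.tree is None:
        raise ValueError("coalescent simulation requires a population tree")
    ages = model._node_ages()
    branches: dict[str, _Branch] = {}
    for i, node in enumerate(model.tree.preorder_node_iter()):
        label = node.taxon.label if node.taxon else (node.label or f"anc{i}")
        node._admix_label = label
    for node in model.tree.preorder_node_iter():
        parent = node.parent_node
        branches[node._admix_label] = _Branch(
            label=node._admix_label,
            start=ages[id(node)],
            end=ages[id(parent)] if parent else np.inf,
            parent=parent._admix_label if parent else None,
        )
    return branches


def _starting_populations(
    samples: dict[str, list[str]],
    hybrids: list[HybridSpec],
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """(haplotype label, starting population) pairs for one locus."""
    hybrid_by_name = {h.individual: h for h in hybrids}
    out: list[tuple[str, str]] = []
    for pop, specimens in samples.items():
        for spec in specimens:
            hyb = hybrid_by_name.get(spec)
            if hyb is None:
                out.append((f"{spec}/1", pop))
                out.append((f"{spec}/2", pop))
            elif hyb.generation == "F1" and len(hyb.parents) == 2:
                out.append((f"{spec}/1", hyb.parents[0]))
                out.append((f"{spec}/2", hyb.parents[1]))
            else:
                for phase in (1, 2):
                    k = rng.choice(len(hyb.parents), p=np.asarray(hyb.fractions))
                    out.append((f"{spec}/{phase}", hyb.parents[k]))
    return out


def simulate_gene_trees(
    model: PopulationModel,
    samples: dict[str, list[str]],
    n_loci: int,
    seed: int,
    hybrids: Optional[list[HybridSpec]] = None,
    haploid: bool = False,
) -> list[str]:
    """Simulate one rooted gene tree (Newick) per locus.

    ``samples`` maps population label to the diploid specimens drawn from
    it; every specimen contributes two haplotype lineages named
    ``<specimen>/1`` and ``<specimen>/2`` (one, ``<specimen>/1``, when
    ``haploid`` is set, as for a maternally inherited locus).
    Branch lengths are in coalescent units; fixed seed gives identical
    output.
    """
    branches = _tree_branches(model)
    unknown = [p for p in samples if p not in branches]
    if unknown:
        raise KeyError(f"samples reference unknown populations: {unknown}")
    hybrids = list(hybrids or [])
    for hyb in hybrids:
        for parent in hyb.parents:
            if parent not in branches:
                raise KeyError(f"hybrid parent {parent!r} not in model")
    rng = np.random.default_rng(seed)
    return [
        _simulate_one_tree(model, branches, samples, hybrids, rng, haploid)
        for _ in range(n_loci)
    ]


def _simulate_one_tree(
    model: PopulationModel,
    branch_template: dict[str, _Branch],
    samples: dict[str, list[str]],
    hybrids: list[HybridSpec],
    rng: np.random.Generator,
    haploid: bool,
) -> str:
    branches = {
        k: _Branch(b.label, b.start, b.end, b.parent)
        for k, b in branch_template.items()
    }
    for hap, pop in _starting_populations(samples, hybrids, rng):
        if haploid and hap.endswith("/2"):
            continue
        branches[pop].lineages.append(_Lineage(label=hap, age=0.0))

    # event queue: population merges and admixture pulses, oldest last
    events: list[tuple[float, int, str, object]] = []
    for b in branches.values():
        if np.isfinite(b.end):
            heapq.heappush(events, (b.end, 0, b.label, "merge"))
    for ev in model.admixture:
        heapq.heappush(events, (ev.time, 1, ev.recipient, ev))

    time = 0.0
    while True:
        horizon = events[0][0] if events else np.inf
        time = _coalesce_until(branches, time, horizon, rng)
        total = sum(len(b.lineages) for b in branches.values())
        if total <= 1 and not events:
            break
        if not events:
            continue
        t_ev, _, label, payload = heapq.heappop(events)
        time = t_ev
        if payload == "merge":
            b = branches[label]
            parent = branches[b.parent]
            parent.lineages.extend(b.lineages)
            b.lineages = []
        else:  # admixture pulse, viewed backwards
            ev = payload
            recipient = branches[ev.recipient]
            stay, move = [], []
            for lin in recipient.lineages:
                (move if rng.random() < ev.proportion else stay).append(lin)
            recipient.lineages = stay
            branches[ev.donor].lineages.extend(move)

    root = next(
        lin for b in branches.values() for lin in b.lineages
    )
    if not root.children:  # single sampled lineage
        return f"({root.newick(root.age)});"
    inner = ",".join(c.newick(root.age) for c in root.children)
    return f"({inner});"


def _coalesce_until(
    branches: dict[str, _Branch],
    time: float,
    horizon: float,
    rng: np.random.Generator,
) -> float:
    """Run within-branch coalescence from ``time`` to ``horizon``."""
    while True:
        rates = {
            k: len(b.lineages) * (len(b.lineages) - 1) / 2.0
            for k, b in branches.items()
            if len(b.lineages) >= 2 and b.start <= time
        }
        total = sum(rates.values())
        if total == 0.0:
            return horizon if np.isfinite(horizon) else time
        wait = rng.exponential(1.0 / total)
        if time + wait >= horizon:
            return horizon
        time += wait
        labels = sorted(rates)
        probs = np.array([rates[k] for k in labels]) / total
        pick = labels[rng.choice(len(labels), p=probs)]
        pool = branches[pick].lineages
        i, j = rng.choice(len(pool), size=2, replace=False)
        i, j = (i, j) if i < j else (j, i)
        merged = _Lineage(label=None, age=time, children=(pool[i], pool[j]))
        pool[j:j + 1] = []
        pool[i] = merged
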