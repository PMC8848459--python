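"""Frequency-tier generator: Balding–Nichols frequencies and genotypes.

This tier generates exactly the structure the clustering and site-pattern
statistics assume: per-population derived-allele frequencies correlated
through a common ancestral frequency, admixed populations as frequency
mixtures, and genotypes as binomial draws from individual-specific mixture
frequencies.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from ..containers import MISSING, GenotypeMatrix
from .model import PopulationModel, SimConfig


def simulate_allele_frequencies(
    model: PopulationModel,
    n_sites: int,
    seed: int,
    ancestral_range: tuple[float, float] = (0.05, 0.95),
    outgroup: Optional[str] = None,
    mode: str = "auto",
) -> pd.DataFrame:
    """Draw per-population derived-allele frequencies at ``n_sites`` sites.

    Two generative modes:

    * ``"star"`` — the classic Balding–Nichols model. For each site an
      ancestral frequency ``p`` is drawn uniformly from
      ``ancestral_range``; each population ``k`` with drift ``F_k`` draws

      ``p_k ~ Beta(p (1 - F_k) / F_k,  (1 - p)(1 - F_k) / F_k)``

      with mean ``p`` and variance ``F_k p (1 - p)``.
    * ``"tree"`` — hierarchical drift along the population tree: each
      branch of length ``t`` (coalescent units) applies a Beta pull with
      ``F = 1 - exp(-t)`` around the parent value, so sister populations
      share ancestral drift. This is the mode whose covariance structure
      the tree-aware site-pattern statistics assume.

    ``"auto"`` picks ``"tree"`` when the model has a population tree.
    Admixture events turn recipients into frequency mixtures
    ``(1 - a) p_recipient + a p_donor`` (in star mode, applied in list
    order to the final frequencies; in tree mode, applied oldest-first
    at the recipient node with the shift propagated to its
    descendants). An ``outgroup`` population, if named, is held fixed at
    frequency 0 so downstream site-pattern code can assume derived-allele
    polarity.

    Returns a DataFrame with populations as rows and sites as columns.
    Ghost populations are simulated (they may donate) and retained here;
    callers decide what to sample.
    """
    rng = np.random.default_rng(seed)
    pops = list(model.populations)
    lo, hi = ancestral_range
    p_anc = rng.uniform(lo, hi, size=n_sites)
    if mode == "auto":
        mode = "tree" if model.tree is not None else "star"

    if mode == "star":
        for pop in pops:
            if pop != outgroup and pop not in model.drift:
                raise ValueError(f"no drift parameter F for population {pop!r}")
        freqs = np.empty((len(pops), n_sites))
        for i, pop in enumerate(pops):
            if pop == outgroup:
                freqs[i] = 0.0
                continue
            freqs[i] = _beta_pull(p_anc, model.drift[pop], rng)
        index = {p: i for i, p in enumerate(pops)}
        for event in model.admixture:
            if event.recipient not in index or event.donor not in index:
                raise KeyError(
                    f"admixture event references unknown population "
                    f"{event.donor!r} or {event.recipient!r}"
                )
            r, d = index[event.recipient], index[event.donor]
            freqs[r] = (
                1.0 - event.proportion
            ) * freqs[r] + event.proportion * freqs[d]
    elif mode == "tree":
        freqs = _tree_frequencies(model, p_anc, rng, pops)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # degenerate ancestral frequencies propagate exactly
    freqs[:, p_anc == 0.0] = 0.0
    freqs[:, p_anc == 1.0] = 1.0
    if outgroup is not None and outgroup in pops:
        freqs[pops.index(outgroup)] = 0.0
    return pd.DataFrame(freqs, index=pops)


def _beta_pull(p: np.ndarray, f: float, rng) -> np.ndarray:
    if not 0.0 < f < 1.0:
        raise ValueError(f"drift F must lie strictly in (0, 1); got {f}")
    scale = (1.0 - f) / f
    a = np.maximum(p * scale, 1e-12)
    b = np.maximum((1.0 - p) * scale, 1e-12)
    return rng.beta(a, b)


def _tree_frequencies(model, p_anc: np.ndarray, rng, pops: list[str]) -> np.ndarray:
    """Hierarchical Balding–Nichols down the population tree."""
    if model.tree is None:
        raise ValueError("tree mode requires a population tree")
    node_freq: dict[int, np.ndarray] = {}
    label_of: dict[int, str] = {}
    for i, node in enumerate(model.tree.preorder_node_iter()):
        label_of[id(node)] = (
            node.taxon.label if node.taxon else (node.label or f"anc{i}")
        )
        if node.parent_node is None:
            node_freq[id(node)] = p_anc.copy()
            continue
        t = node.edge.length or 0.0
        f = 1.0 - np.exp(-t)
        parent = node_freq[id(node.parent_node)]
        if f <= 0.0:
            node_freq[id(node)] = parent.copy()
        else:
            node_freq[id(node)] = _beta_pull(
                np.clip(parent, 1e-9, 1 - 1e-9), min(f, 1 - 1e-9), rng
            )
    by_label = {label_of[k]: k for k in node_freq}
    # pulses oldest-first: shift the recipient node and its descendants
    for event in sorted(model.admixture, key=lambda e: -e.time):
        donor_key = by_label[event.donor]
        recip_key = by_label[event.recipient]
        delta = event.proportion * (node_freq[donor_key] - node_freq[recip_key])
        recip_node = next(
            n for n in model.tree.preorder_node_iter() if id(n) == recip_key
        )
        for node in recip_node.preorder_iter():
            node_freq[id(node)] = np.clip(node_freq[id(node)] + delta, 0.0, 1.0)
    out = np.empty((len(pops), p_anc.size))
    for i, pop in enumerate(pops):
        if pop not in by_label:
            raise KeyError(f"population {pop!r} not in tree")
        out[i] = node_freq[by_label[pop]]
    return out


def simulate_genotypes(
    freqs: pd.DataFrame,
    q_true: pd.DataFrame,
    config: SimConfig,
    n_blocks: Optional[int] = None,
) -> GenotypeMatrix:
    """Sample diploid genotypes from ancestry-weighted mixture frequencies.

    Individual ``i`` with ancestry row ``q_i`` (over the populations in
    ``freqs``) draws ``g_il ~ Binomial(2, sum_k q_ik p_kl)`` at each site
    ``l``. Missingness is applied afterwards: each call is erased with
    probability ``config.site_missingness``, and each individual
    additionally loses calls at its own rate drawn from
    ``config.individual_missingness``.

    Sites are assigned to ``n_blocks`` contiguous pseudo-loci (default:
    ``config.n_loci``) so downstream block-jackknife code has a linkage
    blocking to work with.
    """
    q = q_true.to_numpy(dtype=float)
    if q.shape[1] != freqs.shape[0]:
        raise ValueError(
            f"Q_true has {q.shape[1]} ancestry columns but freqs has "
            f"{freqs.shape[0]} populations"
        )
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("Q_true rows must sum to 1")
    rng = np.random.default_rng(config.seed)
    p = freqs.to_numpy(dtype=float)
    mix = np.clip(q @ p, 0.0, 1.0)  # individuals x sites
    geno = rng.binomial(2, mix).astype(np.int8)

    if config.site_missingness > 0:
        drop = rng.random(geno.shape) < config.site_missingness
        geno[drop] = MISSING
    if config.individual_missingness > 0:
        rates = rng.uniform(0, config.individual_missingness, size=geno.shape[0])
        drop = rng.random(geno.shape) < rates[:, None]
        geno[drop] = MISSING

    n_sites = geno.shape[1]
    n_blocks = n_blocks or config.n_loci
    block = np.minimum(
        (np.arange(n_sites) * n_blocks) // max(n_sites, 1), n_blocks - 1
    )
    sites = pd.DataFrame(
        {
            "locus": [f"block{b:03d}" for b in block],
            "pos": np.arange(n_sites),
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeMatrix(
        specimens=list(q_true.index.astype(str)),
        genotypes=geno,
        sites=sites,
    )
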