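"""Replicated synthetic experiments over the whole pipeline.

Each function runs one seeded replicate of a standard validation
experiment — null calibration of the site-pattern tests, pulse-admixture
estimator consistency, ancestry-coefficient recovery, and the
hybridization-distortion analysis — and returns plain dictionaries of
the quantities of interest. These are the workhorses behind the
acceptance checks and the reproduction script.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .ancestry import (
    AncestryFitConfig,
    AncestryProfile,
    classify_hybrids,
    fit_snmf,
    select_K,
)
from .delimit import (
    clade_admixture_summaries,
    gcf_vs_ancestry,
    imbalance_vs_admixture,
)
from .dstats import allele_freqs, f4_ratio, f_branch, patterson_d
from .simgen import (
    AdmixtureEvent,
    PopulationModel,
    SimConfig,
    simulate_allele_frequencies,
    simulate_dataset,
    simulate_genotypes,
    study_scale_model,
)
from .simgen.scenarios import DistortionExperiment, distortion_experiment
from .treekit import extract_subtree, read_tree


# ---------------------------------------------------------------------------
# null calibration (no gene flow)


def _orient_trio(trio: tuple[str, str, str], model: PopulationModel):
    """Order a trio as (P1, P2, P3) consistent with the species tree:
    the two populations with the most recent common ancestor become
    P1/P2. D is only expected to be centred on zero for tree-consistent
    trios; a mis-rooted trio is asymmetric even without gene flow."""
    tree = read_tree(model.newick)
    ages = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._age = 0.0
        else:
            child = node.child_nodes()[0]
            node._age = child._age + (child.edge.length or 0.0)
    pdm = {}
    taxa = {l.taxon.label: l for l in tree.leaf_node_iter()}
    best_pair, best_age = None, np.inf
    for a, b in combinations(trio, 2):
        mrca = tree.mrca(taxa=[taxa[a].taxon, taxa[b].taxon])
        if mrca._age < best_age:
            best_age, best_pair = mrca._age, (a, b)
    p3 = next(x for x in trio if x not in best_pair)
    return (best_pair[0], best_pair[1], p3)


def null_msc_replicate(
    seed: int,
    n_trios: int = 20,
    n_loci: int = 60,
    locus_length: int = 400,
    per_population: int = 3,
    run_fbranch: bool = True,
) -> dict:
    """One no-gene-flow MSC community: D-statistic Z scores for a sample
    of trios and (optionally) the full f-branch matrix."""
    model = study_scale_model()
    cfg = SimConfig(
        n_loci=n_loci,
        locus_length=locus_length,
        samples_per_population=per_population,
        seed=seed,
    )
    ds = simulate_dataset(model, cfg)
    pm = ds.population_map.set_index("specimen")["population"]
    freqs = allele_freqs(ds.genotypes, pm, outgroup="out")
    pops = [p for p in freqs.populations if p != "out"]
    rng = np.random.default_rng(seed + 1)
    all_trios = [
        _orient_trio(trio, model) for trio in combinations(pops, 3)
    ]
    pick = rng.choice(len(all_trios), size=min(n_trios, len(all_trios)),
                      replace=False)
    z_scores = []
    for k in pick:
        res = patterson_d(freqs, all_trios[k])
        if not res.undefined and np.isfinite(res.z):
            z_scores.append(abs(res.z))
    out = {"abs_z": z_scores}
    if run_fbranch:
        fb = f_branch(read_tree(model.newick), freqs, seed=seed)
        vals = fb.values.to_numpy()
        out["fbranch_values"] = vals[np.isfinite(vals)].tolist()
    return out


# ---------------------------------------------------------------------------
# pulse admixture: estimator consistency and localization


def f4_pulse_replicate(
    seed: int, proportion: float = 0.3, n_sites: int = 50_000,
    per_pop: int = 10,
) -> float:
    """Recover a frequency-tier pulse with the f4-ratio; returns f_hat."""
    pops = ["A", "B", "C", "O"]
    model = PopulationModel(
        pops,
        drift={p: 0.2 for p in pops},
        admixture=[AdmixtureEvent(0.0, "C", "B", proportion)],
    )
    freqs = simulate_allele_frequencies(
        model, n_sites, seed=seed, outgroup="O", mode="star"
    )
    rows, names = [], []
    for k, p in enumerate(pops):
        for i in range(per_pop):
            q = np.zeros(len(pops))
            q[k] = 1.0
            rows.append(q)
            names.append(f"{p}_{i}")
    q_true = pd.DataFrame(rows, index=names, columns=pops)
    gm = simulate_genotypes(freqs, q_true, SimConfig(seed=seed + 1, n_loci=50))
    pm = pd.Series({n: n.rsplit("_", 1)[0] for n in names})
    table = allele_freqs(gm, pm, outgroup="O")
    return f4_ratio(table, "A", "B", "C", seed=seed).f_raw


PULSE_TREE = (
    "(((((A1:2,A2:2):2,(A3:2,A4:2):2):2,"
    "((B1:2,B2:2):2,(B3:2,B4:2):2):2):4,out:10):1)root;"
)


def fbranch_localization_replicate(
    seed: int,
    proportion: float = 0.4,
    donor: str = "B3",
    recipient: str = "A1",
    event_time: float = 1.5,
    n_loci: int = 50,
    locus_length: int = 400,
    per_population: int = 4,
) -> dict:
    """Tip-to-tip pulse under the MSC; does the f-branch maximum land on
    the true (recipient, donor) cell?

    The pulse sits partway up the donor branch: a very recent pulse hands
    the recipient the donor's entire private drift, which makes the
    mirrored (donor-as-recipient) cell nearly as strong — the partial
    symmetry this statistic is known for.
    """
    pops = ["A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4", "out"]
    model = PopulationModel(
        pops,
        tree=PULSE_TREE,
        admixture=[AdmixtureEvent(event_time, donor, recipient, proportion)],
    )
    cfg = SimConfig(
        n_loci=n_loci,
        locus_length=locus_length,
        samples_per_population=per_population,
        seed=seed,
    )
    ds = simulate_dataset(model, cfg)
    pm = ds.population_map.set_index("specimen")["population"]
    freqs = allele_freqs(ds.genotypes, pm, outgroup="out")
    fb = f_branch(read_tree(PULSE_TREE), freqs, seed=seed)
    stacked = fb.values.stack()
    max_cell = stacked.idxmax()
    return {
        "max_cell": tuple(max_cell),
        "true_cell": (recipient, donor),
        "localized": tuple(max_cell) == (recipient, donor),
        "f_at_true": float(fb.values.loc[recipient, donor]),
        "max_value": float(stacked.max()),
    }


def internal_branch_recipient_replicate(
    seed: int, proportion: float = 0.4
) -> dict:
    """Pulse into the ancestor of two tips: the internal-branch row should
    carry a significant f-branch signal for the donor column(s)."""
    pops = ["A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4", "out"]
    # label the (A1,A2) and (B3,B4) ancestors so the event can target them;
    # the donor must be a branch alive at the event time
    newick = PULSE_TREE.replace("(A1:2,A2:2):2", "(A1:2,A2:2)A_12:2")
    newick = newick.replace("(B3:2,B4:2):2", "(B3:2,B4:2)B_34:2")
    model = PopulationModel(
        pops,
        tree=newick,
        admixture=[AdmixtureEvent(2.5, "B_34", "A_12", proportion)],
    )
    cfg = SimConfig(n_loci=50, locus_length=400,
                    samples_per_population=4, seed=seed)
    ds = simulate_dataset(model, cfg)
    pm = ds.population_map.set_index("specimen")["population"]
    freqs = allele_freqs(ds.genotypes, pm, outgroup="out")
    fb = f_branch(read_tree(newick), freqs, seed=seed)
    row = "A1+A2"
    # the ancestral donor's signal surfaces through its descendant tips
    value = float(np.nanmax([fb.values.loc[row, "B3"], fb.values.loc[row, "B4"]]))
    col = "B3" if fb.values.loc[row, "B3"] >= fb.values.loc[row, "B4"] else "B4"
    return {
        "f_value": value,
        "p_value": float(fb.pvals.loc[row, col]),
    }


# ---------------------------------------------------------------------------
# ancestry recovery


def ancestry_recovery_replicate(
    seed: int,
    n_individuals: int = 60,
    n_sites: int = 5000,
    drift: float = 0.2,
    admixed_fraction: float = 0.10,
    with_k_selection: bool = False,
    k_reps: int = 4,
) -> dict:
    """Balding–Nichols recovery: K = 3 ancestry with an F1 appended."""
    pops = ["P1", "P2", "P3"]
    model = PopulationModel(pops, drift={p: drift for p in pops})
    freqs = simulate_allele_frequencies(model, n_sites, seed=seed)
    rng = np.random.default_rng(seed + 7)
    rows, names = [], []
    period = max(2, int(round(1.0 / max(admixed_fraction, 1e-9))))
    for i in range(n_individuals):
        q = np.zeros(3)
        if i % period == period - 1:
            q[:] = rng.dirichlet([1.0, 1.0, 1.0])
        else:
            q[i % 3] = 1.0
        rows.append(q)
        names.append(f"s{i:02d}")
    # one guaranteed F1 hybrid between P1 and P2
    rows.append(np.array([0.5, 0.5, 0.0]))
    names.append("f1_hybrid")
    q_true = pd.DataFrame(rows, index=names, columns=pops)
    gm = simulate_genotypes(freqs, q_true, SimConfig(seed=seed + 1, n_loci=50))
    # weak regularization: the matrix is large and clean, and heavier
    # ridge weight visibly shrinks admixed rows toward the simplex centre
    profile = fit_snmf(gm, AncestryFitConfig(K=3, alpha=1.0, seed=seed + 2))

    cost = -(q_true.to_numpy().T @ profile.Q.to_numpy())
    from scipy.optimize import linear_sum_assignment

    r, c = linear_sum_assignment(cost)
    q_hat = profile.Q.to_numpy()[:, c[np.argsort(r)]]
    mean_abs = float(np.abs(q_hat - q_true.to_numpy()).mean())
    f1_row = np.sort(q_hat[-1])[::-1]
    out = {
        "mean_abs_error": mean_abs,
        "f1_components": (float(f1_row[0]), float(f1_row[1])),
    }
    if with_k_selection:
        sel = select_K(gm, range(1, 6), alpha=10.0, reps=k_reps, seed=seed + 3)
        out["k_selected"] = sel.K
    return out


# ---------------------------------------------------------------------------
# distortion experiment analysis


def distortion_replicate(seed: int, **kwargs) -> dict:
    """One full distortion experiment with its summary statistics."""
    exp = distortion_experiment(seed=seed, **kwargs)
    return analyze_distortion(exp)


def analyze_distortion(exp: DistortionExperiment) -> dict:
    profile = AncestryProfile(
        Q=exp.q_true,
        G=np.zeros((exp.q_true.shape[1], 0, 3)),
        cross_entropy_train=np.nan,
        cross_entropy_val=None,
        alpha=np.nan,
        seed=0,
    )
    calls = classify_hybrids(profile)
    summaries = clade_admixture_summaries(profile, exp.candidate_of, calls)
    imb = imbalance_vs_admixture(exp.tree, exp.candidate_of, summaries)
    env = gcf_vs_ancestry(exp.tree, exp.gene_trees, profile)

    gcf = env.per_specimen
    hyb_depth, pure_depth, hyb_gcf, pure_gcf = [], [], [], []
    for cand in sorted(exp.candidate_of.unique()):
        members = list(exp.candidate_of.index[exp.candidate_of == cand])
        hybrids = [m for m in members if exp.hybrid_of[m]]
        pures = [m for m in members if not exp.hybrid_of[m]]
        if not hybrids:
            continue
        sub = extract_subtree(exp.tree, members)
        depth = {}
        for leaf in sub.leaf_node_iter():
            d, node = 0, leaf.parent_node
            while node is not None:
                d += 1
                node = node.parent_node
            depth[leaf.taxon.label] = d
        ranks = pd.Series(depth).rank()
        hyb_depth += list(ranks[hybrids])
        pure_depth += list(ranks[pures])
        hyb_gcf += [x for x in gcf.reindex(hybrids)["terminal_gcf"] if x == x]
        pure_gcf += [x for x in gcf.reindex(pures)["terminal_gcf"] if x == x]

    rank_p = stats.mannwhitneyu(
        hyb_depth, pure_depth, alternative="less"
    ).pvalue
    maxima = env.envelope.bin_max_gcf
    envelope_cap = bool(len(maxima)) and maxima[-1] == max(maxima)
    return {
        "slope": float(imb.regression.slope),
        "slope_p": float(imb.regression.p_value),
        "r_squared": float(imb.regression.r_squared),
        "envelope_rho": float(env.envelope.spearman_rho),
        "envelope_cap": envelope_cap,
        "rank_p": float(rank_p),
        "hybrid_mean_gcf": float(np.mean(hyb_gcf)),
        "pure_mean_gcf": float(np.mean(pure_gcf)),
        "n_candidates": int(len(imb.per_candidate)),
    }
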