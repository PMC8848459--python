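"""Delimitation rubric and admixture-distortion statistics.

The rule engine turns trees + clusters + hybrid calls into a candidate
table using a fixed, deterministic rubric:

* **R1 (lump)** — previously recognized candidates whose specimens merge
  into a single genetic cluster and are not reciprocally monophyletic
  are collapsed into one candidate named ``X/Y``.
* **R2 (keep / split)** — a cluster that is reciprocally monophyletic
  and geographically distinct is a candidate species; when a prior
  candidate splits into several such clusters, the extras are new.
* **R3 (lineages)** — clusters distinct in ancestry but not reciprocally
  monophyletic, connected by admixture (a configurable fraction of
  members hybrid between them), become phylogeographic lineages within
  the enclosing candidate.
* **R4 (hybrid flag)** — clusters in which no member draws a majority of
  its ancestry from a single source are flagged as putative hybrid
  clusters rather than silently accepted or discarded.

Two statistics quantify how admixture distorts concatenated trees: the
constraint of terminal gene-concordance support by individual ancestry
(triangular envelope), and the regression of candidate-subtree Colless
imbalance (PDA-normalized) on the standard deviation of maximum
individual ancestry within the candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .ancestry import AncestryProfile, HybridCall
from .treekit import colless, extract_subtree, is_monophyletic, terminal_gcf_table


# ---------------------------------------------------------------------------
# rule engine


@dataclass
class DelimitConfig:
    min_hybrid_fraction: float = 0.10  # R3: members hybrid across clusters
    hybrid_cluster_qmax: float = 0.50  # R4: no member with q_max >= this


def delimit(
    tree: dendropy.Tree,
    cluster_assignments: pd.Series | dict[str, str],
    hybrid_calls: Sequence[HybridCall],
    prior_candidates: pd.Series | dict[str, str],
    geo_distinct: Optional[dict[str, bool]] = None,
    config: DelimitConfig = DelimitConfig(),
) -> pd.DataFrame:
    """Apply the delimitation rubric; returns the candidate table.

    ``cluster_assignments`` maps specimen -> genetic cluster,
    ``prior_candidates`` maps specimen -> previously recognized candidate,
    ``geo_distinct`` maps cluster -> whether it is geographically coded
    distinct (geography is an input here, not something this package
    infers). Output rows are ordered deterministically by candidate then
    lineage name; every cluster appears exactly once.
    """
    clusters = (
        cluster_assignments
        if isinstance(cluster_assignments, pd.Series)
        else pd.Series(cluster_assignments)
    )
    priors = (
        prior_candidates
        if isinstance(prior_candidates, pd.Series)
        else pd.Series(prior_candidates)
    )
    geo = geo_distinct or {}
    call_by_spec = {c.specimen: c for c in hybrid_calls}
    missing = [s for s in clusters.index if s not in call_by_spec]
    if missing:
        raise ValueError(f"specimens lacking hybrid calls: {missing[:5]}")

    info: dict[str, dict] = {}
    for cl in sorted(clusters.unique()):
        members = sorted(clusters.index[clusters == cl])
        calls = [call_by_spec[s] for s in members]
        info[cl] = {
            "members": members,
            "priors": sorted({priors.get(s, "-") for s in members}),
            "mono": is_monophyletic(tree, members, rooted=True),
            "hybrid_frac": float(np.mean([c.is_hybrid for c in calls])),
            "max_qmax": max(c.q_max for c in calls),
            "geo": bool(geo.get(cl, True)),
        }

    rows: list[dict] = []
    handled: set[str] = set()

    # R4: clusters of specimens with no majority single-source parent
    for cl, d in info.items():
        if d["max_qmax"] < config.hybrid_cluster_qmax:
            rows.append(
                _row(cl, "-", "hybrid-flagged", d,
                     "no member with majority single-source ancestry")
            )
            handled.add(cl)

    # R1: prior candidates collapsed into a single cluster, not
    # reciprocally monophyletic -> lump
    for cl, d in info.items():
        if cl in handled or len(d["priors"]) < 2:
            continue
        exclusive = all(
            set(priors.index[priors == pr]) <= set(d["members"])
            for pr in d["priors"]
        )
        priors_mono = all(
            is_monophyletic(tree, sorted(priors.index[priors == pr]), rooted=True)
            for pr in d["priors"]
        )
        if exclusive and not priors_mono:
            name = "/".join(d["priors"])
            rows.append(_row(cl, "-", "lumped", d, "prior candidates merged"))
            rows[-1]["candidate"] = name
            handled.add(cl)

    # R3: groups of non-monophyletic clusters sharing a prior candidate
    # and connected by admixture -> lineages within one candidate
    by_prior: dict[str, list[str]] = {}
    for cl, d in info.items():
        if cl in handled:
            continue
        if len(d["priors"]) == 1 and not d["mono"]:
            by_prior.setdefault(d["priors"][0], []).append(cl)
    for prior_name, cls in sorted(by_prior.items()):
        if len(cls) < 2:
            continue
        admixed = any(
            info[cl]["hybrid_frac"] >= config.min_hybrid_fraction for cl in cls
        )
        if not admixed:
            continue
        for i, cl in enumerate(sorted(cls), start=1):
            d = info[cl]
            rows.append(
                _row(cl, f"{prior_name} L{i}", "kept", d,
                     "phylogeographic lineage (non-monophyletic, admixed)")
            )
            rows[-1]["candidate"] = prior_name
            handled.add(cl)

    # R2: monophyletic, geographically distinct clusters -> candidates
    prior_cluster_count: dict[str, int] = {}
    for cl, d in info.items():
        if cl in handled:
            continue
        if d["mono"] and d["geo"]:
            pr = d["priors"][0] if len(d["priors"]) == 1 else "/".join(d["priors"])
            prior_cluster_count[pr] = prior_cluster_count.get(pr, 0) + 1
    seen_prior: dict[str, int] = {}
    for cl in sorted(info):
        d = info[cl]
        if cl in handled:
            continue
        if d["mono"] and d["geo"]:
            pr = d["priors"][0] if len(d["priors"]) == 1 else "/".join(d["priors"])
            seen_prior[pr] = seen_prior.get(pr, 0) + 1
            if prior_cluster_count[pr] > 1 and seen_prior[pr] > 1:
                status = "new"
                name = f"{pr} {_split_suffix(seen_prior[pr])}"
            else:
                status = "kept"
                name = pr
            rows.append(_row(cl, "-", status, d, "reciprocally monophyletic"))
            rows[-1]["candidate"] = name
            handled.add(cl)

    # anything left is unresolved, never silently assigned
    for cl in sorted(info):
        if cl not in handled:
            d = info[cl]
            rows.append(
                _row(cl, "-", "unresolved", d,
                     "cluster neither monophyletic nor admixture-linked")
            )

    table = pd.DataFrame(rows)
    table = table.sort_values(["candidate", "lineage", "cluster"]).reset_index(
        drop=True
    )
    assert sorted(table["cluster"]) == sorted(info), "every cluster appears once"
    return table


def _split_suffix(k: int) -> str:
    # second monophyletic cluster of a prior candidate gets "B", etc.
    return chr(ord("A") + k - 1)


def _row(cluster: str, lineage: str, status: str, d: dict, note: str) -> dict:
    return {
        "cluster": cluster,
        "candidate": cluster,
        "lineage": lineage,
        "status": status,
        "n_specimens": len(d["members"]),
        "monophyletic": d["mono"],
        "hybrid_fraction": round(d["hybrid_frac"], 4),
        "notes": note,
    }


# ---------------------------------------------------------------------------
# clade-level summaries


@dataclass
class CladeAdmixtureSummary:
    candidate: str
    n: int
    sd_qmax: float
    mean_qmax: float
    hybrid_count: int
    excluded: bool = False  # single-specimen candidates carry no SD signal


def clade_admixture_summaries(
    profile: AncestryProfile,
    candidate_of: pd.Series | dict[str, str],
    hybrid_calls: Sequence[HybridCall],
) -> list[CladeAdmixtureSummary]:
    candidate_of = (
        candidate_of if isinstance(candidate_of, pd.Series) else pd.Series(candidate_of)
    )
    call_by_spec = {c.specimen: c for c in hybrid_calls}
    out = []
    for cand in sorted(candidate_of.unique()):
        members = list(candidate_of.index[candidate_of == cand])
        qmax = np.array([profile.Q.loc[m].max() for m in members])
        hybrids = sum(call_by_spec[m].is_hybrid for m in members if m in call_by_spec)
        out.append(
            CladeAdmixtureSummary(
                candidate=cand,
                n=len(members),
                sd_qmax=float(qmax.std(ddof=0)) if len(members) > 1 else 0.0,
                mean_qmax=float(qmax.mean()),
                hybrid_count=int(hybrids),
                excluded=len(members) < 2,
            )
        )
    return out


# ---------------------------------------------------------------------------
# distortion statistics


@dataclass
class EnvelopeResult:
    spearman_rho: float
    p_value: float
    bin_centers: np.ndarray
    bin_max_gcf: np.ndarray
    skipped: bool = False
    reason: str = ""


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    undefined: bool = False


@dataclass
class DistortionReport:
    per_specimen: pd.DataFrame = None  # q_max, terminal gCF
    envelope: EnvelopeResult = None
    pearson_r: float = np.nan
    pearson_p: float = np.nan
    per_candidate: pd.DataFrame = None  # sd_qmax, i_pda
    regression: RegressionResult = None


def gcf_vs_ancestry(
    tree: dendropy.Tree,
    gene_trees: Sequence,
    profile: AncestryProfile,
    n_bins: int = 10,
) -> DistortionReport:
    """Terminal gCF against maximum individual ancestry.

    Highly admixed genomes cannot be placed with high gene-tree
    concordance, so the scatter of (q_max, terminal gCF) is expected to
    be constrained by a triangular envelope: the *maximum* gCF attainable
    rises with q_max. The envelope test bins q_max into deciles, takes
    the maximum gCF per occupied bin, and tests for a nondecreasing trend
    (one-sided Spearman). Pearson correlation over all specimens is
    reported alongside.
    """
    gcf = terminal_gcf_table(tree, gene_trees)
    q_max = profile.Q.max(axis=1)
    table = pd.DataFrame({"q_max": q_max, "terminal_gcf": gcf}).dropna()
    report = DistortionReport(per_specimen=table)
    if len(table) >= 3 and table["q_max"].nunique() > 1:
        r, p = stats.pearsonr(table["q_max"], table["terminal_gcf"])
        report.pearson_r, report.pearson_p = float(r), float(p)
    if len(table) < 10 or table["q_max"].nunique() == 1:
        report.envelope = EnvelopeResult(
            np.nan, np.nan, np.array([]), np.array([]),
            skipped=True,
            reason="fewer than 10 specimens or degenerate ancestry",
        )
        return report
    # fixed deciles of the ancestry scale, not of the observed range
    edges = np.linspace(0.0, 1.0 + 1e-12, n_bins + 1)
    which = np.digitize(table["q_max"], edges) - 1
    centers, maxima = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            centers.append((edges[b] + edges[b + 1]) / 2.0)
            maxima.append(table["terminal_gcf"][sel].max())
    if len(centers) < 3:
        report.envelope = EnvelopeResult(
            np.nan, np.nan, np.array(centers), np.array(maxima),
            skipped=True, reason="too few occupied ancestry bins",
        )
        return report
    rho, p_two = stats.spearmanr(centers, maxima)
    p_one = p_two / 2.0 if rho > 0 else 1.0 - p_two / 2.0
    report.envelope = EnvelopeResult(
        float(rho), float(p_one), np.array(centers), np.array(maxima)
    )
    return report


def imbalance_vs_admixture(
    tree: dendropy.Tree,
    candidate_of: pd.Series | dict[str, str],
    summaries: Sequence[CladeAdmixtureSummary],
) -> DistortionReport:
    """Regress candidate-subtree imbalance on within-candidate admixture.

    Each candidate with >= 3 specimens contributes a point: Colless'
    imbalance of the subtree induced by its members (PDA-normalized)
    against the SD of its members' maximum individual ancestry.
    Single-specimen candidates are excluded; zero variance in SD(q_max)
    leaves the regression flagged undefined.
    """
    candidate_of = (
        candidate_of if isinstance(candidate_of, pd.Series) else pd.Series(candidate_of)
    )
    by_name = {s.candidate: s for s in summaries}
    rows = []
    for cand in sorted(candidate_of.unique()):
        summary = by_name.get(cand)
        if summary is None or summary.excluded:
            continue
        members = sorted(candidate_of.index[candidate_of == cand])
        if len(members) < 3:
            continue
        sub = extract_subtree(tree, members)
        stat = colless(sub, clade_id=cand)
        if stat.excluded:
            continue
        rows.append(
            {"candidate": cand, "sd_qmax": summary.sd_qmax, "i_pda": stat.i_pda,
             "n_tips": stat.n_tips}
        )
    per_candidate = pd.DataFrame(rows)
    report = DistortionReport(per_candidate=per_candidate)
    if len(per_candidate) < 3:
        report.regression = RegressionResult(
            np.nan, np.nan, np.nan, np.nan, len(per_candidate), undefined=True
        )
        return report
    x = per_candidate["sd_qmax"].to_numpy()
    y = per_candidate["i_pda"].to_numpy()
    if np.allclose(x.std(), 0.0):
        report.regression = RegressionResult(
            np.nan, np.nan, np.nan, np.nan, len(x), undefined=True
        )
        return report
    fit = stats.linregress(x, y)
    report.regression = RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
    )
    return report


# ---------------------------------------------------------------------------
# rootward shift of hybrids


@dataclass
class RootwardResult:
    candidate: str
    n_hybrid: int
    n_pure: int
    rank_p: float  # one-sided: hybrids attach closer to the crown
    branch_length_p: float  # one-sided: hybrids on longer terminal branches
    skipped: bool = False
    reason: str = ""


def rootward_shift(
    tree: dendropy.Tree,
    candidate_members: Iterable[str],
    hybrid_calls: Sequence[HybridCall],
    candidate: str = "",
) -> RootwardResult:
    """Are hybrids concentrated in early-diverging positions?

    Within the candidate's induced subtree, each member's divergence rank
    is the number of nodes between the crown and its attachment; a
    one-sided rank-sum test asks whether hybrid members have smaller
    ranks (earlier-diverging) than pure members, and a second one-sided
    test whether their terminal branches are longer.
    """
    members = sorted(candidate_members)
    call_by_spec = {c.specimen: c for c in hybrid_calls}
    hybrids = [m for m in members if call_by_spec[m].is_hybrid]
    pures = [m for m in members if not call_by_spec[m].is_hybrid]
    if len(members) < 4 or not hybrids or not pures:
        return RootwardResult(
            candidate, len(hybrids), len(pures), np.nan, np.nan,
            skipped=True,
            reason="needs >= 4 members including >= 1 hybrid and >= 1 pure",
        )
    sub = extract_subtree(tree, members)
    depth: dict[str, int] = {}
    blen: dict[str, float] = {}
    for leaf in sub.leaf_node_iter():
        d = 0
        node = leaf.parent_node
        while node is not None:
            d += 1
            node = node.parent_node
        depth[leaf.taxon.label] = d
        blen[leaf.taxon.label] = leaf.edge.length or 0.0
    rank_p = stats.mannwhitneyu(
        [depth[m] for m in hybrids],
        [depth[m] for m in pures],
        alternative="less",
    ).pvalue
    bl_p = stats.mannwhitneyu(
        [blen[m] for m in hybrids],
        [blen[m] for m in pures],
        alternative="greater",
    ).pvalue
    return RootwardResult(
        candidate, len(hybrids), len(pures), float(rank_p), float(bl_p)
    )
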