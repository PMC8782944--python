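"""Downstream analysis of per-sample flux distributions: PCA, Ward
hierarchical clustering, subsystem enrichment and ROS / lactate-efflux
readouts."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .fba import FBAError, FluxDistribution
from .model import MetabolicNetwork

logger = logging.getLogger(__name__)


@dataclass
class FluxAnalysis:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # components x reactions
    explained_variance_ratio: np.ndarray
    linkage_matrix: np.ndarray
    dendrogram_order: list[str]
    cluster_labels: pd.Series
    dropped_reactions: list[str]
    standardized: pd.DataFrame
    ros_flux: pd.Series | None = None
    lactate_efflux: pd.Series | None = None


def flux_matrix(distributions: list[FluxDistribution]) -> pd.DataFrame:
    """Samples x reactions flux matrix; errors on mismatched reaction sets."""
    solved = [d for d in distributions if d.fluxes is not None]
    if len(solved) != len(distributions):
        bad = [d.sample_id for d in distributions if d.fluxes is None]
        raise FBAError(f"unsolved distributions: {bad}")
    keys = {tuple(sorted(d.fluxes)) for d in solved}
    if len(keys) != 1:
        raise FBAError("distributions cover different reaction sets")
    return pd.DataFrame(
        [d.fluxes for d in solved], index=[d.sample_id for d in solved]
    )


def analyze_flux_distributions(
    distributions: list[FluxDistribution],
    groups: dict[str, str],
    network: MetabolicNetwork | None = None,
    n_clusters: int = 2,
) -> FluxAnalysis:
    """Standardize fluxes per reaction, run SVD-based PCA and Ward/Euclidean
    agglomerative clustering; attach tagged-reaction readouts when a network
    is supplied (ROS = summed flux through ``ros_producing`` reactions,
    lactate efflux = export-direction flux of the lactate exchange)."""
    X = flux_matrix(distributions)
    if len(X) < 3:
        raise FBAError("need at least 3 samples")
    counts = pd.Series([groups[s] for s in X.index]).value_counts()
    if (counts < 2).any():
        raise FBAError(f"need >= 2 samples per group, got {counts.to_dict()}")

    sd = X.std(axis=0, ddof=0)
    dropped = list(X.columns[sd == 0])
    if dropped:
        logger.info("dropping %d zero-variance reactions", len(dropped))
    kept = X.loc[:, sd > 0]
    Z = (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=0)

    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    scores = U * s
    var = s ** 2
    comps = [f"PC{i + 1}" for i in range(scores.shape[1])]
    scores_df = pd.DataFrame(scores, index=Z.index, columns=comps)
    loadings_df = pd.DataFrame(Vt, index=comps, columns=Z.columns)

    link = linkage(Z.to_numpy(), method="ward", metric="euclidean")
    order = [Z.index[i] for i in leaves_list(link)]
    labels = pd.Series(
        fcluster(link, t=n_clusters, criterion="maxclust"), index=Z.index
    )

    ros = lact = None
    if network is not None:
        ros_rxns = [r.id for r in network.reactions if "ros_producing" in r.tags]
        ros = X[ros_rxns].sum(axis=1) if ros_rxns else pd.Series(0.0, index=X.index)
        lac_ex = network.exchange_for("lactate")
        if lac_ex is not None:
            lact = (-X[lac_ex.id]).clip(lower=0.0)

    return FluxAnalysis(
        scores=scores_df,
        loadings=loadings_df,
        explained_variance_ratio=var / var.sum(),
        linkage_matrix=link,
        dendrogram_order=order,
        cluster_labels=labels,
        dropped_reactions=dropped,
        standardized=Z,
        ros_flux=ros,
        lactate_efflux=lact,
    )


def pc1_silhouette(analysis: FluxAnalysis, groups: dict[str, str]) -> float:
    """Silhouette of the group labels on the first principal component."""
    from sklearn.metrics import silhouette_score

    x = analysis.scores[["PC1"]].to_numpy()
    labels = [groups[s] for s in analysis.scores.index]
    return float(silhouette_score(x, labels))


def subsystem_enrichment(
    selected_reactions: set[str] | list[str],
    network: MetabolicNetwork,
    p_method: str = "tail",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of subsystems in a reaction set.

    Per subsystem the p-value is the upper tail P(X >= overlap) for drawing
    ``len(selected)`` reactions without replacement; Benjamini-Hochberg
    adjusts across subsystems.

    ``p_method`` selects the tail convention: ``tail`` (default,
    conservative P(X >= k)), ``mid`` (mid-p) or ``randomized``
    (P(X > k) + U*P(X = k), exactly uniform under the null — a calibration
    diagnostic, not for inference; requires ``rng``).
    """
    if p_method not in {"tail", "mid", "randomized"}:
        raise FBAError(f"unknown p_method {p_method!r}")
    if p_method == "randomized" and rng is None:
        raise FBAError("randomized p-values need an rng")
    selected = set(selected_reactions)
    if not selected:
        raise FBAError("empty reaction selection")
    all_ids = {r.id for r in network.reactions}
    stray = selected - all_ids
    if stray:
        raise FBAError(f"selection contains unknown reactions: {sorted(stray)}")
    M, n = len(all_ids), len(selected)
    rows = []
    for subsystem in network.subsystems:
        members = {r.id for r in network.reactions if r.subsystem == subsystem}
        K = len(members)
        overlap = len(members & selected)
        tail = float(hypergeom.sf(overlap - 1, M, K, n))
        pmf = float(hypergeom.pmf(overlap, M, K, n))
        if p_method == "tail":
            p = tail
        elif p_method == "mid":
            p = tail - 0.5 * pmf
        else:
            p = tail - float(rng.uniform()) * pmf
        p = float(min(max(p, 0.0), 1.0))
        rows.append({
            "subsystem": subsystem,
            "size": K,
            "overlap": overlap,
            "expected": n * K / M,
            "p": p,
        })
    out = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    out["p_adjusted"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["p_adjusted"] = np.maximum(out["p_adjusted"], out["p"])
    return out
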