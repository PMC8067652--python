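"""Residual co-occurrence: correlations from loadings, network, closeness, niche test."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from microlvm.gllvm import GllvmFit, hpd_widths

logger = logging.getLogger(__name__)


@dataclass
class ResidualNetwork:
    rho: np.ndarray            # (t, t) posterior-median residual correlation
    significance: np.ndarray   # (t, t) bool, credible interval excludes 0
    graph: nx.Graph            # nodes = taxon names, edges = significant pairs
    closeness: pd.Series       # per taxon
    median_cooccurrence: pd.Series  # per taxon, median of its significant rho
    level: float

    @property
    def taxon_names(self) -> list:
        return list(self.closeness.index)


def residual_correlation(fit: GllvmFit, level: float = 0.95):
    """Posterior residual correlations rho = cov2corr(Lambda Lambda') per draw.

    Returns ``(rho_median, significant)`` where an entry is significant iff
    the central ``level`` credible interval of its draws excludes zero.
    Draws in which a taxon has an all-zero loading row are excluded for that
    taxon's entries (logged).
    """
    if fit.d < 1:
        raise ValueError("residual correlations require d >= 1")
    lam = fit.flat("loadings")  # (n, t, d)
    n, t, _ = lam.shape
    norms = np.linalg.norm(lam, axis=2)  # (n, t)
    zero = norms == 0
    if zero.any():
        logger.warning("excluding %d taxon-draws with all-zero loadings", int(zero.sum()))
        norms = np.where(zero, np.nan, norms)
    omega = np.einsum("njd,nkd->njk", lam, lam)
    rho_draws = omega / (norms[:, :, None] * norms[:, None, :])

    alpha = 1.0 - level
    lo = np.nanquantile(rho_draws, alpha / 2, axis=0)
    hi = np.nanquantile(rho_draws, 1 - alpha / 2, axis=0)
    rho = np.nanmedian(rho_draws, axis=0)
    np.fill_diagonal(rho, 1.0)
    significant = (lo > 0) | (hi < 0)
    np.fill_diagonal(significant, False)
    return rho, significant


def build_network(fit: GllvmFit, level: float = 0.95) -> ResidualNetwork:
    """Unweighted, undirected graph over significant residual correlations.

    Edge sign is kept as an attribute; closeness uses hop distance with the
    component-size-scaled convention (isolated nodes get 0).
    """
    rho, significant = residual_correlation(fit, level)
    names = fit.taxon_names
    g = nx.Graph()
    g.add_nodes_from(names)
    t = len(names)
    for j in range(t):
        for k in range(j + 1, t):
            if significant[j, k]:
                g.add_edge(names[j], names[k], rho=float(rho[j, k]),
                           sign=1 if rho[j, k] > 0 else -1)
    med = []
    for j in range(t):
        vals = rho[j, significant[j]]
        med.append(float(np.median(vals)) if vals.size else np.nan)
    net = ResidualNetwork(
        rho=rho, significance=significant, graph=g,
        closeness=closeness(g).reindex(names),
        median_cooccurrence=pd.Series(med, index=names, name="median_cooccurrence"),
        level=level,
    )
    return net


def closeness(graph: nx.Graph) -> pd.Series:
    """Component-scaled closeness centrality (Wasserman-Faust convention).

    For node v in a component of size n_c within a graph of n nodes:
    ``(n_c - 1) / sum(dist) * (n_c - 1) / (n - 1)``; isolated nodes get 0.
    """
    vals = nx.closeness_centrality(graph, wf_improved=True)
    return pd.Series(vals, name="closeness").astype(float)


def niche_regression(fit: GllvmFit, network: ResidualNetwork, covariate: str,
                     prob: float = 0.95) -> dict:
    """OLS of network position on per-taxon HPD width of one coefficient.

    Fits both responses the niche question has been framed with: closeness
    and the median significant residual co-occurrence. Returns a dict with
    one entry per response holding slope, intercept, r_squared and n_taxa.
    """
    widths = hpd_widths(fit, covariate, prob)
    if np.std(widths.to_numpy()) == 0:
        raise ValueError("zero variance in HPD widths")
    out = {"covariate": covariate}
    for response_name, response in (("closeness", network.closeness),
                                    ("median_cooccurrence", network.median_cooccurrence)):
        joined = pd.concat([widths.rename("width"), response.rename("y")], axis=1).dropna()
        if len(joined) < 3:
            out[response_name] = None
            continue
        res = stats.linregress(joined["width"], joined["y"])
        out[response_name] = {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r_squared": float(res.rvalue ** 2),
            "p_value": float(res.pvalue),
            "n_taxa": int(len(joined)),
        }
    return out


def edge_table(network: ResidualNetwork) -> pd.DataFrame:
    """Tidy edge list (taxon_a, taxon_b, rho, sign)."""
    rows = [{"taxon_a": a, "taxon_b": b, "rho": d["rho"], "sign": d["sign"]}
            for a, b, d in network.graph.edges(data=True)]
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "sign"])
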