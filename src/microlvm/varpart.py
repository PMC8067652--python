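"""Per-taxon variance partitioning across covariate groups and the latent component.

For each posterior draw and taxon, the variance over sites of the summed
within-group linear predictor is taken as that group's component (this keeps
within-group covariances inside the group), the latent component is the
variance of the factor term, and proportions are normalized to sum to one;
the cross-group covariance remainder is recorded separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from microlvm.gllvm import GllvmFit

LATENT = "latent"


@dataclass
class VarPartResult:
    proportions: pd.DataFrame      # taxon x (groups..., latent); rows sum to 1
    total_explained: pd.Series     # per taxon, sum over non-latent groups
    covariance_remainder: pd.Series  # mean over draws of 1 - sum(raw proportions)
    groups: list

    def __post_init__(self):
        sums = self.proportions.sum(axis=1).to_numpy()
        assert np.allclose(sums, 1.0, atol=1e-8)


def variance_partition(fit: GllvmFit, groups: dict = None) -> VarPartResult:
    """Decompose each taxon's linear-predictor variance over sites.

    ``groups`` maps every covariate name in the fit to a group label;
    defaults to the grouping stored by the environment builder (each
    covariate its own group when absent).
    """
    if fit.d < 1:
        raise ValueError("variance partitioning requires d >= 1 latent dimensions")
    if groups is None:
        groups = {c: c for c in fit.covariate_names}
    missing = [c for c in fit.covariate_names if c not in groups]
    if missing:
        raise ValueError(f"group map missing covariate(s): {missing}")

    X = fit.X
    beta = fit.flat("beta")          # (n, t, k)
    lam = fit.flat("loadings")       # (n, t, d)
    zs = fit.flat("z")               # (n, s, d)
    n, t, _ = beta.shape

    labels = list(dict.fromkeys(groups[c] for c in fit.covariate_names))
    members = {g: [i for i, c in enumerate(fit.covariate_names) if groups[c] == g]
               for g in labels}

    comp = np.zeros((n, t, len(labels) + 1))
    for gi, g in enumerate(labels):
        idx = members[g]
        # (n, s, t): within-group linear predictor per draw
        part = np.einsum("sk,ntk->nst", X[:, idx], beta[:, :, idx])
        comp[:, :, gi] = part.var(axis=1)
    latent_part = np.einsum("nsd,ntd->nst", zs, lam)
    comp[:, :, -1] = latent_part.var(axis=1)

    full = np.einsum("sk,ntk->nst", X, beta) + latent_part
    total = full.var(axis=1)
    total = np.where(total <= 0, np.nan, total)
    raw = comp / total[:, :, None]
    remainder = 1.0 - np.nansum(raw, axis=2)
    norm = raw / np.nansum(raw, axis=2, keepdims=True)

    prop = pd.DataFrame(np.nanmean(norm, axis=0), index=fit.taxon_names,
                        columns=labels + [LATENT])
    prop = prop.div(prop.sum(axis=1), axis=0)  # renormalize after draw-averaging
    return VarPartResult(
        proportions=prop,
        total_explained=prop[labels].sum(axis=1).rename("total_explained"),
        covariance_remainder=pd.Series(np.nanmean(remainder, axis=0),
                                       index=fit.taxon_names, name="covariance_remainder"),
        groups=labels,
    )


def skewness(values) -> float:
    """Adjusted Fisher-Pearson standardized third moment, g1*sqrt(n(n-1))/(n-2)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if np.var(x) == 0:
        raise ValueError("zero variance")
    return float(stats.skew(x, bias=False))


def varpart_summaries(result: VarPartResult, domains: pd.Series = None,
                      threshold: float = 0.5) -> dict:
    """Per-domain distribution summaries of explained-variance proportions.

    ``domains`` maps taxon name -> domain label ('bacteria'/'fungi'); taxa
    without a label land in 'all'. "Above threshold" uses a strict inequality.
    """
    if domains is None:
        domains = pd.Series("all", index=result.proportions.index)
    out = {}
    for domain in dict.fromkeys(domains):
        names = domains.index[domains == domain]
        te = result.total_explained.loc[names]
        if te.empty:
            continue
        entry = {
            "n_taxa": int(len(te)),
            "mean_explained": float(te.mean()),
            "sd_explained": float(te.std(ddof=1)) if len(te) > 1 else 0.0,
            "n_above_threshold": int((te > threshold).sum()),
            "pct_above_threshold": float(100.0 * (te > threshold).mean()),
            "threshold": threshold,
            "skewness": skewness(te) if len(te) >= 3 and np.var(te) > 0 else None,
            "per_group": {},
        }
        for g in result.groups + [LATENT]:
            vals = result.proportions.loc[names, g]
            q25, q75 = np.percentile(vals, [25, 75], method="linear")
            entry["per_group"][g] = {"median": float(vals.median()),
                                     "q25": float(q25), "q75": float(q75)}
        out[domain] = entry
    return out
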