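"""Bayesian NB latent variable model: fitting, HPD intervals, coefficient calls."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from microlvm._mcmc import run_chain
from microlvm.data_io import CommunityTable, EnvMatrix, TaxonLabel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative defaults: N(0, sd^2) on location parameters,
    N(0, loading_sd^2) (half-normal on positive diagonals) for loadings,
    Exp(rate) on 1/phi.

    Loadings get a tighter default than the other location parameters:
    the per-site effects leave a translation ridge (a constant added to a
    loading column traded against alpha) whose posterior width scales with
    the loading prior SD. Unit scale (matching the N(0,1) latent scores)
    keeps that ridge narrower than per-taxon estimation noise, so residual
    correlations of unrelated taxa do not inherit a shared offset."""

    sd: float = 10.0
    loading_sd: float = 1.0
    phi_inv_rate: float = 0.1


@dataclass(frozen=True)
class SamplerConfig:
    n_chains: int = 4
    n_draws: int = 1000
    n_warmup: int = 1000
    thin: int = 1


@dataclass(frozen=True)
class HpdInterval:
    """Minimal-width interval containing ``prob`` posterior mass."""

    lower: float
    upper: float
    prob: float

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def excludes_zero(self) -> bool:
        return self.lower > 0 or self.upper < 0


def hpd(draws, prob: float = 0.95) -> HpdInterval:
    """Highest-posterior-density interval of a univariate draw vector.

    The minimal-width contiguous window over the sorted draws containing
    ``ceil(prob * n)`` points.
    """
    if not 0 < prob <= 1:
        raise ValueError("prob must be in (0, 1]")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 draws for an HPD interval")
    m = int(np.ceil(prob * n))
    if m >= n:
        return HpdInterval(float(x[0]), float(x[-1]), prob)
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return HpdInterval(float(x[i]), float(x[i + m - 1]), prob)


def _loading_mask(n_taxa: int, d: int) -> np.ndarray:
    """0 = structural zero (upper triangle), 1 = free, 2 = positive diagonal."""
    mask = np.ones((n_taxa, d), dtype=np.int8)
    for j in range(min(n_taxa, d)):
        mask[j, j + 1:] = 0
        mask[j, j] = 2
    return mask


@dataclass
class GllvmFit:
    """Posterior draws and metadata for a fitted model.

    Draw arrays have shape ``(n_chains, n_draws, ...)``; the loading draws
    satisfy the upper-triangle-zero / positive-diagonal constraint in every
    draw and per-site effects are recentred to sum to zero.
    """

    draws: dict
    n_chains: int
    n_draws: int
    diagnostics: dict
    model_spec: dict
    taxa: list
    covariate_names: list
    site_ids: list
    X: np.ndarray
    converged: bool = True

    @property
    def d(self) -> int:
        return self.model_spec["d"]

    @property
    def taxon_names(self) -> list:
        return [t.display_name for t in self.taxa]

    def flat(self, name: str) -> np.ndarray:
        """Draws for ``name`` with chains stacked: (n_chains*n_draws, ...)."""
        a = self.draws[name]
        return a.reshape((a.shape[0] * a.shape[1],) + a.shape[2:])

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savez(outdir / "draws.npz", **self.draws, X=self.X)
        meta = {
            "n_chains": self.n_chains,
            "n_draws": self.n_draws,
            "diagnostics": self.diagnostics,
            "model_spec": self.model_spec,
            "covariate_names": self.covariate_names,
            "site_ids": list(map(str, self.site_ids)),
            "taxa": [
                {"lineage": list(map(list, t.lineage)), "display_name": t.display_name,
                 "resolution_flag": t.resolution_flag}
                for t in self.taxa
            ],
            "converged": self.converged,
        }
        (outdir / "fit.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, outdir) -> "GllvmFit":
        outdir = Path(outdir)
        meta = json.loads((outdir / "fit.json").read_text())
        arrays = np.load(outdir / "draws.npz")
        draws = {k: arrays[k] for k in arrays.files if k != "X"}
        taxa = [
            TaxonLabel(lineage=tuple(map(tuple, t["lineage"])),
                       display_name=t["display_name"],
                       resolution_flag=t["resolution_flag"])
            for t in meta["taxa"]
        ]
        return cls(draws=draws, n_chains=meta["n_chains"], n_draws=meta["n_draws"],
                   diagnostics=meta["diagnostics"], model_spec=meta["model_spec"],
                   taxa=taxa, covariate_names=meta["covariate_names"],
                   site_ids=meta["site_ids"], X=arrays["X"], converged=meta["converged"])


def _initial_values(Y: np.ndarray, X: np.ndarray, d: int, rng):
    s, t = Y.shape
    rowtot = Y.sum(axis=1).astype(float)
    alpha0 = np.log(np.maximum(rowtot, 1.0)) - np.log(max(rowtot.mean(), 1.0))
    colmean = Y.mean(axis=0)
    b00 = np.log(np.maximum(colmean, 0.05))
    beta0_ = np.zeros((t, X.shape[1]))
    mask = _loading_mask(t, d)
    # seed the latent part from an SVD of double-centred log counts so chains
    # start near the dominant co-variation structure instead of a cold zero
    lam0 = np.zeros((t, d))
    z0 = np.zeros((s, d))
    if d > 0:
        R = np.log1p(Y)
        R = R - R.mean(axis=0) - R.mean(axis=1)[:, None] + R.mean()
        U, S, Vt = np.linalg.svd(R, full_matrices=False)
        dd = min(d, len(S))
        z0[:, :dd] = U[:, :dd] * np.sqrt(s)
        lam0[:, :dd] = Vt[:dd].T * (S[:dd] / np.sqrt(s))
        # orient each factor so the anchor taxon's diagonal loading is
        # positive; starting in the mirrored mode leaves the sampler trapped
        # (the positivity constraint blocks the sign flip, and the only
        # likelihood-equivalent escape is a loading-column offset into the
        # per-site effects)
        for l in range(min(dd, t)):
            if lam0[l, l] < 0:
                lam0[:, l] *= -1.0
                z0[:, l] *= -1.0
    lam0 = lam0 + rng.normal(0.0, 0.01, size=(t, d))
    z0 = z0 + rng.normal(0.0, 0.01, size=(s, d))
    lam0[mask == 0] = 0.0
    lam0[mask == 2] = np.abs(lam0[mask == 2]) + 0.05
    u0 = np.zeros(t)
    return alpha0, b00, beta0_, lam0, z0, u0, mask


def _convergence(draws: dict) -> dict:
    """Split-Rhat / ESS summary.

    The convergence flag is driven by the interpreted, likelihood-identified
    blocks (coefficients, intercepts, dispersions). Raw loadings and latent
    scores are identified only up to the constrained rotation/offset, so
    their Rhat is reported informationally via the rotation-invariant
    residual correlations instead.
    """
    import arviz as az

    monitored = {k: draws[k] for k in ("beta", "beta0", "phi") if draws[k].size}
    ds = az.from_dict(posterior=monitored)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    rh = np.concatenate([np.asarray(rhat[v]).ravel() for v in rhat.data_vars])
    es = np.concatenate([np.asarray(ess[v]).ravel() for v in ess.data_vars])
    rh = rh[np.isfinite(rh)]
    es = es[np.isfinite(es)]
    out = {
        "max_rhat": float(np.max(rh)) if rh.size else float("nan"),
        "frac_rhat_gt_1.1": float(np.mean(rh > 1.1)) if rh.size else 0.0,
        "min_ess": float(np.min(es)) if es.size else float("nan"),
        "median_ess": float(np.median(es)) if es.size else float("nan"),
    }
    lam = draws["loadings"]
    if lam.size and lam.shape[2] <= 150:
        norms = np.linalg.norm(lam, axis=3)
        norms = np.where(norms == 0, np.nan, norms)
        rho = np.einsum("cnjd,cnkd->cnjk", lam, lam) / \
            (norms[:, :, :, None] * norms[:, :, None, :])
        iu = np.triu_indices(lam.shape[2], 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rr = np.asarray(az.rhat(az.from_dict(
                posterior={"rho": rho[:, :, iu[0], iu[1]]}))["rho"])
        rr = rr[np.isfinite(rr)]
        if rr.size:
            out["resid_cor_frac_rhat_gt_1.1"] = float(np.mean(rr > 1.1))
    return out


def _identify_site_effects(draws: dict, X: np.ndarray) -> None:
    """Project per-site effects onto the identified subspace, in place.

    With free per-site effects the linear predictor is invariant under
    ``alpha += c0*1 + X c`` compensated through the intercepts and a
    per-covariate constant added to every taxon's coefficient (counts are
    compositional: only between-taxon contrasts are likelihood-identified).
    Each draw is mapped to the representative with alpha orthogonal to
    ``[1, X]``, which removes this ridge noise from all reported blocks.
    """
    s = X.shape[0]
    P = np.column_stack([np.ones(s), X])
    # coef per draw: (chains, draws, k+1)
    pinv = np.linalg.pinv(P)
    coef = np.einsum("rs,cns->cnr", pinv, draws["alpha"])
    draws["alpha"] = draws["alpha"] - np.einsum("sr,cnr->cns", P, coef)
    draws["beta0"] = draws["beta0"] + coef[:, :, :1]
    draws["beta"] = draws["beta"] + coef[:, :, None, 1:]


def fit_gllvm(counts: CommunityTable, env: EnvMatrix, d: int = 2,
              priors: PriorConfig = PriorConfig(),
              sampler: SamplerConfig = SamplerConfig(),
              seed: int = 0, check_convergence: bool = True) -> GllvmFit:
    """Fit the NB latent variable model by adaptive Metropolis-within-Gibbs.

    ``counts`` should be prevalence-filtered and ``env`` standardized.
    Returns posterior draws for per-site effects, intercepts, coefficients,
    loadings (identifiability-constrained), dispersions and latent scores.
    """
    Y = counts.counts.astype(np.float64)
    X = np.asarray(env.values, dtype=np.float64)
    s, t = Y.shape
    if X.shape[0] != s:
        raise ValueError("counts and env disagree on the number of sites")
    if d < 0:
        raise ValueError("d must be >= 0")
    if s < d + 2:
        raise ValueError(f"need at least d+2={d + 2} sites")
    zero_rows = np.flatnonzero(Y.sum(axis=0) == 0)
    if zero_rows.size:
        raise ValueError(
            f"all-zero taxa at columns {zero_rows.tolist()}; apply filter_prevalence first"
        )
    col_means = X.mean(axis=0)
    if np.max(np.abs(col_means)) > 1e-6:
        logger.warning("environment matrix does not look standardized (max |mean|=%.3g)",
                       np.max(np.abs(col_means)))

    rng = np.random.default_rng(seed)
    alpha0, b00, beta0_, lam0, z0, u0, mask = _initial_values(Y, X, d, rng)

    chains = []
    for c in range(sampler.n_chains):
        out = run_chain(Y, X, d, sampler.n_warmup, sampler.n_draws, sampler.thin,
                        int(seed) + 1000 * c + 1, priors.sd, priors.loading_sd,
                        priors.phi_inv_rate, alpha0, b00, beta0_, lam0, z0, u0, mask)
        chains.append(out)

    names = ("alpha", "beta0", "beta", "loadings", "z", "phi")
    draws = {nm: np.stack([ch[i] for ch in chains]) for i, nm in enumerate(names)}
    _identify_site_effects(draws, X)

    diagnostics = _convergence(draws) if check_convergence else {}
    converged = True
    if check_convergence and diagnostics.get("frac_rhat_gt_1.1", 0.0) > 0.05:
        converged = False
        warnings.warn(
            f"possible non-convergence: {diagnostics['frac_rhat_gt_1.1']:.1%} of "
            f"parameters have split-Rhat > 1.1 (max {diagnostics['max_rhat']:.3f})",
            RuntimeWarning,
        )

    model_spec = {
        "family": "negative-binomial",
        "d": int(d),
        "priors": asdict(priors),
        "sampler": asdict(sampler),
        "seed": int(seed),
    }
    return GllvmFit(draws=draws, n_chains=sampler.n_chains, n_draws=sampler.n_draws,
                    diagnostics=diagnostics, model_spec=model_spec,
                    taxa=list(counts.taxa), covariate_names=list(env.covariate_names),
                    site_ids=list(counts.site_ids), X=X, converged=converged)


def classify_coefficients(fit: GllvmFit, prob: float = 0.95) -> pd.DataFrame:
    """Per taxon x covariate significance calls from HPD intervals.

    ``positive`` iff the HPD lower bound exceeds zero, ``negative`` iff the
    upper bound is below zero, otherwise ``ns``. The attached point estimate
    is the posterior median.
    """
    beta = fit.flat("beta")  # (n, t, k)
    rows = []
    for j, taxon in enumerate(fit.taxa):
        for kk, cov in enumerate(fit.covariate_names):
            v = beta[:, j, kk]
            iv = hpd(v, prob)
            call = "positive" if iv.lower > 0 else ("negative" if iv.upper < 0 else "ns")
            rows.append({
                "taxon": taxon.display_name,
                "kingdom": taxon.kingdom,
                "domain": taxon.domain,
                "phylum": taxon.phylum,
                "covariate": cov,
                "median": float(np.median(v)),
                "hpd_lower": iv.lower,
                "hpd_upper": iv.upper,
                "hpd_width": iv.width,
                "call": call,
            })
    return pd.DataFrame(rows)


def hpd_widths(fit: GllvmFit, covariate: str, prob: float = 0.95) -> pd.Series:
    """Per-taxon HPD width of one covariate's coefficient (niche-breadth proxy)."""
    kk = fit.covariate_names.index(covariate)
    beta = fit.flat("beta")
    widths = [hpd(beta[:, j, kk], prob).width for j in range(len(fit.taxa))]
    return pd.Series(widths, index=fit.taxon_names, name=f"hpd_width_{covariate}")
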