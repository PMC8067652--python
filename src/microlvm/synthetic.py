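"""Community generators with known ground truth for recovery testing.

Communities are drawn from the same model class the fitter assumes:
negative-binomial counts whose log-mean is a per-site effect + taxon
intercept + sparse covariate coefficients + low-rank latent loadings.
A Gaussian copula can additionally impose modifier-dependent rank
dependence between chosen taxon pairs while preserving the NB margins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from microlvm.data_io import DEFAULT_GROUPS, CommunityTable, EnvMatrix, InputError, TaxonLabel, standardize

logger = logging.getLogger(__name__)

#: covariates produced by :func:`simulate_environment`, mirroring the model inputs
DEFAULT_COVARIATES = [
    "elevation", "pH", "TC", "TN", "C:N", "TP", "DOC", "E2/E3", "SUVA254",
    "latitude", "longitude",
]

#: linear-predictor cap guarding exp() overflow
ETA_MAX = 30.0


@dataclass(frozen=True)
class ShiftPair:
    """A taxon pair whose rank dependence changes with a modifier covariate."""

    taxon_a: str
    taxon_b: str
    modifier: str
    rho_low: float
    rho_high: float


@dataclass
class GroundTruth:
    """True generative parameters for a simulated community."""

    alpha: np.ndarray        # (s,) per-site effects
    beta0: np.ndarray        # (t,) taxon intercepts
    beta: np.ndarray         # (t, k) covariate coefficients (sparse)
    loadings: np.ndarray     # (t, d) latent loadings
    phi: np.ndarray          # (t,) NB dispersions > 0
    shift_pairs: list = field(default_factory=list)
    z: np.ndarray = None     # (s, d) latent scores, filled by simulate_community

    def __post_init__(self):
        if np.any(np.asarray(self.phi) <= 0):
            raise ValueError("phi must be > 0")
        if self.loadings.ndim != 2:
            raise ValueError("loadings must be (taxa, d)")

    @property
    def d(self) -> int:
        return self.loadings.shape[1]


def _default_correlation(names) -> np.ndarray:
    """Mildly realistic cross-correlation: nutrient variables co-vary with TC."""
    k = len(names)
    corr = np.eye(k)
    pairs = {("TC", "TN"): 0.6, ("TC", "DOC"): 0.4, ("TC", "TP"): 0.35,
             ("TC", "C:N"): 0.3, ("TC", "pH"): -0.3, ("TN", "DOC"): 0.3}
    idx = {n: i for i, n in enumerate(names)}
    for (a, b), r in pairs.items():
        if a in idx and b in idx:
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    return corr


def simulate_environment(n_sites: int, seed: int, covariates=None, corr=None):
    """Draw correlated covariates and standardize them.

    Returns ``(EnvMatrix, raw_frame)`` where the raw frame holds the
    unstandardized values (geography included).
    """
    if covariates is None:
        covariates = list(DEFAULT_COVARIATES)
    if n_sites < 2:
        raise InputError("need at least 2 sites")
    if n_sites < 4:
        logger.warning("n_sites=%d is below the recommended minimum of 4", n_sites)
    k = len(covariates)
    if corr is None:
        corr = _default_correlation(covariates)
    corr = np.asarray(corr, dtype=float)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise InputError("target correlation matrix is not positive definite") from None
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_sites, k)) @ chol.T
    frame = pd.DataFrame(raw, columns=covariates,
                         index=[f"site{i + 1:03d}" for i in range(n_sites)])
    groups = {c: DEFAULT_GROUPS.get(c, c) for c in covariates}
    return standardize(frame, covariates, groups=groups), frame


def _make_taxa(n_taxa: int, frac_fungi: float = 0.4) -> list:
    taxa = []
    n_fungi = int(round(n_taxa * frac_fungi))
    for j in range(n_taxa):
        fungal = j >= n_taxa - n_fungi
        kingdom = "Fungi" if fungal else "Bacteria"
        phylum = (f"Fphylum{(j % 4) + 1}" if fungal else f"Bphylum{(j % 6) + 1}")
        name = f"{'F' if fungal else 'B'}order{j + 1:03d}"
        lineage = (("kingdom", kingdom), ("phylum", phylum),
                   ("class", f"{name}_c"), ("order", name))
        taxa.append(TaxonLabel(lineage=lineage, display_name=name, resolution_flag="order"))
    return taxa


def make_ground_truth(n_sites: int = 43, n_taxa: int = 80, n_covariates: int = 11,
                      d: int = 2, seed: int = 0, beta_values=(0.0, 0.5, 1.0, 2.0),
                      beta_sparsity: float = 0.8, loading_scale: float = 0.8,
                      base_abundance: float = 20.0) -> GroundTruth:
    """Draw a random ground-truth parameter set at desk scale.

    Coefficients are sparse: each entry is zero with probability
    ``beta_sparsity``, otherwise a random sign times a value from
    ``beta_values``.
    """
    rng = np.random.default_rng(seed)
    alpha = rng.normal(0.0, 0.4, size=n_sites)
    alpha -= alpha.mean()
    beta0 = np.log(base_abundance) + rng.normal(0.0, 0.5, size=n_taxa)
    magnitudes = rng.choice([v for v in beta_values if v != 0.0], size=(n_taxa, n_covariates))
    signs = rng.choice([-1.0, 1.0], size=(n_taxa, n_covariates))
    mask = rng.random((n_taxa, n_covariates)) >= beta_sparsity
    beta = magnitudes * signs * mask
    loadings = rng.normal(0.0, loading_scale, size=(n_taxa, d))
    for j in range(min(d, n_taxa)):
        loadings[j, j + 1:] = 0.0
        loadings[j, j] = abs(loadings[j, j]) + 0.1
    phi = rng.uniform(1.0, 5.0, size=n_taxa)
    return GroundTruth(alpha=alpha, beta0=beta0, beta=beta, loadings=loadings, phi=phi)


def linear_predictor(env: EnvMatrix, truth: GroundTruth) -> np.ndarray:
    """Site x taxon log-mean implied by ``truth`` (requires ``truth.z``)."""
    if truth.z is None:
        raise ValueError("ground truth has no latent scores; run simulate_community first")
    return (truth.alpha[:, None] + truth.beta0[None, :]
            + env.values @ truth.beta.T + truth.z @ truth.loadings.T)


def _nb_draw(rng, mean, phi):
    if np.isinf(phi):
        return rng.poisson(mean)
    return rng.negative_binomial(phi, phi / (phi + mean))


def simulate_community(env: EnvMatrix, truth: GroundTruth, seed: int) -> CommunityTable:
    """Sample NB counts from the latent-variable model.

    Latent scores ``z`` are drawn iid standard normal and stored on ``truth``
    so dependent operations (copula injection, oracle checks) can reuse them.
    """
    s = env.n_sites
    t = truth.beta0.shape[0]
    if truth.beta.shape != (t, env.values.shape[1]):
        raise ValueError("beta shape inconsistent with env")
    rng = np.random.default_rng(seed)
    truth.z = rng.standard_normal((s, truth.d))
    eta = linear_predictor(env, truth)
    if np.max(eta) > ETA_MAX:
        raise OverflowError(
            f"linear predictor reaches {np.max(eta):.1f} > {ETA_MAX}; "
            "use smaller coefficients or intercepts"
        )
    mean = np.exp(eta)
    counts = np.empty((s, t), dtype=np.int64)
    for j in range(t):
        counts[:, j] = _nb_draw(rng, mean[:, j], truth.phi[j])
    return CommunityTable(counts=counts, site_ids=list(env.site_ids), taxa=_make_taxa(t))


def inject_conditional_dependence(counts: CommunityTable, env: EnvMatrix,
                                  truth: GroundTruth, pair: ShiftPair,
                                  seed: int) -> CommunityTable:
    """Re-sample one taxon pair with tercile-wise Gaussian-copula dependence.

    Sites in the lower tercile of the modifier get correlation
    ``pair.rho_low``, the upper tercile ``pair.rho_high``, and the middle
    tercile their mean; NB margins are preserved exactly (counts are drawn
    by pushing copula uniforms through each margin's quantile function).
    """
    for rho in (pair.rho_low, pair.rho_high):
        if abs(rho) >= 1:
            raise ValueError("|rho| must be < 1")
    names = counts.taxon_names
    for taxon in (pair.taxon_a, pair.taxon_b):
        if taxon not in names:
            raise KeyError(f"taxon {taxon!r} not in community table")
    if pair.modifier not in env.covariate_names:
        raise KeyError(f"modifier {pair.modifier!r} not in environment matrix")
    ja, jb = names.index(pair.taxon_a), names.index(pair.taxon_b)
    modifier = env.column(pair.modifier)
    lo, hi = np.quantile(modifier, [1 / 3, 2 / 3])
    regime = np.where(modifier <= lo, 0, np.where(modifier > hi, 2, 1))
    rhos = [pair.rho_low, 0.5 * (pair.rho_low + pair.rho_high), pair.rho_high]

    eta = linear_predictor(env, truth)
    mean = np.exp(eta)
    rng = np.random.default_rng(seed)
    new = counts.counts.copy()
    for reg, rho in enumerate(rhos):
        idx = np.flatnonzero(regime == reg)
        if idx.size == 0:
            continue
        cov = np.array([[1.0, rho], [rho, 1.0]])
        g = rng.multivariate_normal(np.zeros(2), cov, size=idx.size)
        u = stats.norm.cdf(g)
        for col, j in ((0, ja), (1, jb)):
            phi = truth.phi[j]
            p = phi / (phi + mean[idx, j])
            new[idx, j] = stats.nbinom.ppf(u[:, col], phi, p).astype(np.int64)
    return CommunityTable(counts=new, site_ids=list(counts.site_ids), taxa=list(counts.taxa))
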