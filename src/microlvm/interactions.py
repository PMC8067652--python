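"""Covariate-adjusted and conditional rank correlations; interaction-shift detection.

The building block is the cumulative probability model (CPM): an ordinal
cumulative-link regression treating every distinct response value as its own
category, fit by Newton-Raphson on the (concave, for logit/probit) ordinal
likelihood. Probability-scale residuals PSR_i = P(Y < y_i | Z) - P(Y > y_i | Z)
from two CPMs give a covariate-adjusted Spearman-type correlation; kernel
smoothing of PSR products along a modifier gives a conditional correlation
curve, whose endpoints define interaction shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats


class CpmError(RuntimeError):
    pass


def _links(link: str):
    if link == "logit":
        G = special.expit

        def g(x):
            e = special.expit(x)
            return e * (1.0 - e)

        def gp(x):
            e = special.expit(x)
            return e * (1.0 - e) * (1.0 - 2.0 * e)

        return G, g, gp
    if link == "probit":
        return special.ndtr, stats.norm.pdf, lambda x: -x * stats.norm.pdf(x)
    raise ValueError(f"unknown link {link!r}")


@dataclass
class CpmFit:
    """A fitted cumulative probability model.

    ``gamma`` holds the M-1 nondecreasing cutpoints for the M distinct
    response values ``y_values``; ``theta`` the covariate coefficients on
    the original covariate scale (P(Y <= y_m | Z) = G(gamma_m - Z theta)).
    """

    y_values: np.ndarray
    gamma: np.ndarray
    theta: np.ndarray
    link: str = "logit"
    n_obs: int = 0
    n_iter: int = 0
    loglik: float = np.nan

    def cdf_leq(self, y, Z=None) -> np.ndarray:
        """P(Y <= y | Z) per observation."""
        G, _, _ = _links(self.link)
        eta = self._eta(Z, np.size(y))
        pos = np.searchsorted(self.y_values, np.asarray(y, dtype=float), side="right")
        out = np.empty(np.size(y), dtype=float)
        M = len(self.y_values)
        inner = (pos > 0) & (pos < M)
        out[pos == 0] = 0.0
        # at or above the top category the cdf cannot be resolved below 1
        out[pos >= M] = 1.0
        out[inner] = G(self.gamma[pos[inner] - 1] - eta[inner])
        # y below the top but above the last cutpoint index handled above
        return out

    def cdf_lt(self, y, Z=None) -> np.ndarray:
        """P(Y < y | Z) per observation."""
        G, _, _ = _links(self.link)
        eta = self._eta(Z, np.size(y))
        pos = np.searchsorted(self.y_values, np.asarray(y, dtype=float), side="left")
        out = np.empty(np.size(y), dtype=float)
        M = len(self.y_values)
        out[pos == 0] = 0.0
        top = pos >= M
        out[top] = 1.0
        inner = (pos > 0) & (pos < M)
        out[inner] = G(self.gamma[pos[inner] - 1] - eta[inner])
        return out

    def _eta(self, Z, n) -> np.ndarray:
        if self.theta.size == 0:
            return np.zeros(n)
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return Z @ self.theta


def fit_cpm(y, Z=None, link: str = "logit", max_iter: int = 100,
            tol: float = 1e-9) -> CpmFit:
    """Maximum-likelihood cumulative-link fit with one category per distinct y.

    With no covariates the fitted cumulative probabilities equal the
    empirical CDF and the cutpoints are set analytically.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise CpmError("response contains non-finite values")
    n = y.size
    if n < 10:
        raise CpmError("need at least 10 observations")
    values, codes = np.unique(y, return_inverse=True)
    M = len(values)
    if M < 2:
        raise CpmError("response is constant")
    G, g, gp = _links(link)
    ginv = special.logit if link == "logit" else stats.norm.ppf

    counts = np.bincount(codes, minlength=M)
    cum = np.cumsum(counts)[:-1] / n
    gamma = ginv(np.clip(cum, 1.0 / (2 * n), 1 - 1.0 / (2 * n)))

    if Z is None or np.size(Z) == 0:
        return CpmFit(y_values=values, gamma=gamma, theta=np.empty(0), link=link,
                      n_obs=n, n_iter=0,
                      loglik=float(np.sum(counts * np.log(counts / n))))

    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != n:
        Z = Z.T
    k = Z.shape[1]
    zm, zs = Z.mean(axis=0), Z.std(axis=0)
    zs[zs == 0] = 1.0
    Zs = (Z - zm) / zs
    theta = np.zeros(k)

    hi_idx = codes          # gamma index for the upper bound (M-1 means +inf)
    lo_idx = codes - 1      # gamma index for the lower bound (-1 means -inf)
    has_hi = codes < M - 1
    has_lo = codes > 0

    def negparts(gamma, theta):
        eta = Zs @ theta
        a = np.where(has_hi, np.take(gamma, hi_idx, mode="clip") - eta, np.inf)
        b = np.where(has_lo, np.take(gamma, lo_idx, mode="clip") - eta, -np.inf)
        GA = np.where(has_hi, G(a), 1.0)
        GB = np.where(has_lo, G(b), 0.0)
        p = np.clip(GA - GB, 1e-300, None)
        return a, b, p

    def loglik(gamma, theta):
        if np.any(np.diff(gamma) <= 0):
            return -np.inf
        _, _, p = negparts(gamma, theta)
        return float(np.sum(np.log(p)))

    ll = loglik(gamma, theta)
    it = 0
    for it in range(1, max_iter + 1):
        a, b, p = negparts(gamma, theta)
        ga = np.where(has_hi, g(np.where(has_hi, a, 0.0)), 0.0)
        gb = np.where(has_lo, g(np.where(has_lo, b, 0.0)), 0.0)
        gpa = np.where(has_hi, gp(np.where(has_hi, a, 0.0)), 0.0)
        gpb = np.where(has_lo, gp(np.where(has_lo, b, 0.0)), 0.0)
        wA = ga / p
        wB = gb / p
        hAA = gpa / p - wA ** 2
        hBB = -gpb / p - wB ** 2
        hAB = wA * wB

        grad = np.zeros(M - 1 + k)
        np.add.at(grad, hi_idx[has_hi], wA[has_hi])
        np.add.at(grad, lo_idx[has_lo], -wB[has_lo])
        grad[M - 1:] = -Zs.T @ (wA - wB)

        H = np.zeros((M - 1 + k, M - 1 + k))
        np.add.at(H, (hi_idx[has_hi], hi_idx[has_hi]), hAA[has_hi])
        np.add.at(H, (lo_idx[has_lo], lo_idx[has_lo]), hBB[has_lo])
        both = has_hi & has_lo
        np.add.at(H, (hi_idx[both], lo_idx[both]), hAB[both])
        np.add.at(H, (lo_idx[both], hi_idx[both]), hAB[both])
        crossA = -(hAA + hAB)[:, None] * Zs
        crossB = -(hBB + hAB)[:, None] * Zs
        gt = np.zeros((M - 1, k))
        np.add.at(gt, hi_idx[has_hi], crossA[has_hi])
        np.add.at(gt, lo_idx[has_lo], crossB[has_lo])
        H[: M - 1, M - 1:] = gt
        H[M - 1:, : M - 1] = gt.T
        H[M - 1:, M - 1:] = Zs.T @ (Zs * (hAA + 2 * hAB + hBB)[:, None])

        if np.max(np.abs(grad)) < tol * max(1.0, abs(ll)):
            break
        try:
            step = linalg.solve(-H + 1e-10 * np.eye(H.shape[0]), grad, assume_a="pos")
        except linalg.LinAlgError:
            step = linalg.lstsq(-H, grad)[0]
        tfac = 1.0
        for _ in range(40):
            new_gamma = gamma + tfac * step[: M - 1]
            new_theta = theta + tfac * step[M - 1:]
            new_ll = loglik(new_gamma, new_theta)
            if new_ll > ll - 1e-12:
                break
            tfac *= 0.5
        else:
            break
        if np.max(np.abs(new_theta)) > 30:
            raise CpmError("coefficients diverged; data may be completely separated")
        improved = new_ll - ll
        gamma, theta, ll = new_gamma, new_theta, new_ll
        if improved < tol:
            break

    # back to the original covariate scale: gamma - Z theta must be invariant
    theta_orig = theta / zs
    gamma_orig = gamma + (zm / zs) @ theta
    return CpmFit(y_values=values, gamma=gamma_orig, theta=theta_orig, link=link,
                  n_obs=n, n_iter=it, loglik=ll)


def psr(fit: CpmFit, y, Z=None) -> np.ndarray:
    """Probability-scale residuals P(Y < y_i | Z_i) - P(Y > y_i | Z_i), in [-1, 1]."""
    y = np.asarray(y, dtype=float).ravel()
    below = fit.cdf_lt(y, Z)
    at_or_below = fit.cdf_leq(y, Z)
    return below + at_or_below - 1.0


def partial_spearman(x, y, Z=None, link: str = "logit", n_boot: int = 1000,
                     seed: int = 0, level: float = 0.95):
    """Covariate-adjusted Spearman-type correlation via PSR products.

    Returns ``(rho, (ci_lower, ci_upper))``; the CI is a seeded nonparametric
    percentile bootstrap over observations (``(nan, nan)`` when n_boot = 0).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must share length")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input variable")

    def estimate(xi, yi, Zi):
        px = psr(fit_cpm(xi, Zi, link), xi, Zi)
        py = psr(fit_cpm(yi, Zi, link), yi, Zi)
        return float(np.corrcoef(px, py)[0, 1])

    Zarr = None if Z is None or np.size(Z) == 0 else np.atleast_2d(np.asarray(Z, float))
    if Zarr is not None and Zarr.shape[0] != x.size:
        Zarr = Zarr.T
    rho = estimate(x, y, Zarr)
    if n_boot <= 0:
        return rho, (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    n = x.size
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            boot[b] = estimate(x[idx], y[idx], None if Zarr is None else Zarr[idx])
        except CpmError:
            boot[b] = np.nan
    alpha = 1 - level
    lo, hi = np.nanquantile(boot, [alpha / 2, 1 - alpha / 2])
    return rho, (float(lo), float(hi))


@dataclass
class ConditionalCurve:
    """Conditional Spearman-type correlation along a modifier."""

    grid: np.ndarray
    rho: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_boot: int
    bandwidth: float
    modifier: np.ndarray = None          # the observed modifier values
    boot_rho: np.ndarray = None          # (n_boot, len(grid))
    meta: dict = field(default_factory=dict)


def _nw_rho(px, py, modifier, grid, bandwidth):
    w = np.exp(-0.5 * ((modifier[None, :] - grid[:, None]) / bandwidth) ** 2)
    num = w @ (px * py)
    den = np.sqrt((w @ px ** 2) * (w @ py ** 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def rule_of_thumb_bandwidth(modifier) -> float:
    """Silverman's rule on the modifier values."""
    m = np.asarray(modifier, dtype=float)
    n = m.size
    sd = np.std(m, ddof=1)
    iqr = np.subtract(*np.percentile(m, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    return float(1.06 * scale * n ** (-1 / 5))


def conditional_spearman(x, y, modifier, Z_adjust=None, grid=None,
                         bandwidth=None, n_boot: int = 1000, seed: int = 0,
                         link: str = "logit", level: float = 0.95) -> ConditionalCurve:
    """Kernel-smoothed conditional correlation of PSRs along a modifier.

    rho(m) = S_w[psr_x psr_y](m) / sqrt(S_w[psr_x^2](m) S_w[psr_y^2](m)) with
    Gaussian-kernel Nadaraya-Watson smoothing over modifier values. The
    default grid is the modifier's 10th..90th percentiles in steps of 10.
    Bootstrap CIs resample sites (refitting the CPMs per resample).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    modifier = np.asarray(modifier, dtype=float).ravel()
    n = x.size
    quantiles = np.arange(0.1, 0.91, 0.1)
    if grid is None:
        grid = np.quantile(modifier, quantiles)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < modifier.min() - 1e-12 or grid.max() > modifier.max() + 1e-12:
        raise ValueError("grid point outside the observed modifier range")
    if bandwidth is None:
        bandwidth = rule_of_thumb_bandwidth(modifier)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")

    Zarr = None if Z_adjust is None or np.size(Z_adjust) == 0 else \
        np.atleast_2d(np.asarray(Z_adjust, float))
    if Zarr is not None and Zarr.shape[0] != n:
        Zarr = Zarr.T

    def curve(xi, yi, Zi, mi):
        px = psr(fit_cpm(xi, Zi, link), xi, Zi)
        py = psr(fit_cpm(yi, Zi, link), yi, Zi)
        return _nw_rho(px, py, mi, grid, bandwidth)

    rho = curve(x, y, Zarr, modifier)
    boot_rho = None
    ci_lo = np.full(grid.size, np.nan)
    ci_hi = np.full(grid.size, np.nan)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot_rho = np.empty((n_boot, grid.size))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                boot_rho[b] = curve(x[idx], y[idx],
                                    None if Zarr is None else Zarr[idx], modifier[idx])
            except CpmError:
                boot_rho[b] = np.nan
        alpha = 1 - level
        ci_lo = np.nanquantile(boot_rho, alpha / 2, axis=0)
        ci_hi = np.nanquantile(boot_rho, 1 - alpha / 2, axis=0)

    return ConditionalCurve(grid=grid, rho=rho, ci_lower=ci_lo, ci_upper=ci_hi,
                            n_boot=n_boot, bandwidth=float(bandwidth),
                            modifier=modifier, boot_rho=boot_rho,
                            meta={"link": link, "level": level})


@dataclass
class ShiftRecord:
    """A detected (or tested) change in conditional correlation along a modifier."""

    pair: tuple
    pairing: str            # Bact-Bact / Fung-Fung / Bact-Fung
    modifier: str
    rho_low: float
    rho_high: float
    direction: str          # 'positive shift' | 'negative shift'
    significant: bool
    diff_ci: tuple = (np.nan, np.nan)
    sign_change: bool = False


def detect_shift(curve: ConditionalCurve, low_q: float = 0.1, high_q: float = 0.9,
                 pair=("x", "y"), pairing: str = "", modifier_name: str = "",
                 level: float = 0.95) -> ShiftRecord:
    """Compare the conditional correlation at two modifier quantiles.

    Significant iff the bootstrap CI of (rho_high - rho_low) excludes zero.
    """
    if curve.modifier is None:
        raise ValueError("curve lacks modifier values")
    q_lo = np.quantile(curve.modifier, low_q)
    q_hi = np.quantile(curve.modifier, high_q)
    i_lo = int(np.argmin(np.abs(curve.grid - q_lo)))
    i_hi = int(np.argmin(np.abs(curve.grid - q_hi)))
    rho_low, rho_high = float(curve.rho[i_lo]), float(curve.rho[i_hi])
    diff_ci = (np.nan, np.nan)
    significant = False
    if curve.boot_rho is not None and curve.n_boot > 0:
        diffs = curve.boot_rho[:, i_hi] - curve.boot_rho[:, i_lo]
        alpha = 1 - level
        lo, hi = np.nanquantile(diffs, [alpha / 2, 1 - alpha / 2])
        diff_ci = (float(lo), float(hi))
        significant = bool(lo > 0 or hi < 0)
    direction = "positive shift" if rho_high >= rho_low else "negative shift"
    return ShiftRecord(pair=tuple(pair), pairing=pairing, modifier=modifier_name,
                       rho_low=rho_low, rho_high=rho_high, direction=direction,
                       significant=significant, diff_ci=diff_ci,
                       sign_change=bool(np.sign(rho_low) * np.sign(rho_high) < 0))


def count_shifts(records) -> pd.DataFrame:
    """Significant-shift counts: rows = domain pairing, columns = modifier x direction."""
    pairings = ["Bact-Bact", "Fung-Fung", "Bact-Fung"]
    modifiers = list(dict.fromkeys(r.modifier for r in records)) or ["-"]
    cols = pd.MultiIndex.from_product([modifiers, ["positive shift", "negative shift"]])
    table = pd.DataFrame(0, index=pairings, columns=cols)
    for r in records:
        if r.significant and r.pairing in pairings:
            table.loc[r.pairing, (r.modifier, r.direction)] += 1
    return table


def phylum_table(counts, min_prevalence: int = 0) -> pd.DataFrame:
    """Site x phylum counts (within-phylum sums of order counts), with domain info.

    Returns a frame whose columns carry a (phylum, domain) MultiIndex.
    """
    cols = {}
    for j, taxon in enumerate(counts.taxa):
        key = (taxon.phylum or taxon.display_name, taxon.domain)
        cols.setdefault(key, np.zeros(counts.n_sites, dtype=np.int64))
        cols[key] += counts.counts[:, j]
    frame = pd.DataFrame(cols, index=counts.site_ids)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["phylum", "domain"])
    if min_prevalence:
        keep = (frame > 0).sum(axis=0) >= min_prevalence
        frame = frame.loc[:, keep]
    return frame


def _pairing(domain_a: str, domain_b: str) -> str:
    if domain_a == domain_b:
        return "Bact-Bact" if domain_a == "bacteria" else "Fung-Fung"
    return "Bact-Fung"


def scan_shifts(counts, env, modifiers=("C:N", "elevation", "pH"),
                n_boot: int = 1000, seed: int = 0, link: str = "logit",
                level: float = 0.95, min_prevalence: int = 5):
    """Shift scan over all phylum pairs for each modifier.

    For each modifier the adjustment set is the remaining modifiers (a
    modifier does not adjust itself). Returns ``(records, curves)``.
    """
    phyla = phylum_table(counts, min_prevalence=min_prevalence)
    keys = list(phyla.columns)
    records, curves = [], {}
    modifiers = [m for m in modifiers if m in env.covariate_names]
    for mi, modifier in enumerate(modifiers):
        mod_vals = env.column(modifier)
        adjust = [m for m in modifiers if m != modifier]
        Z = np.column_stack([env.column(a) for a in adjust]) if adjust else None
        for ia in range(len(keys)):
            for ib in range(ia + 1, len(keys)):
                (pa, da), (pb, db) = keys[ia], keys[ib]
                x = phyla[keys[ia]].to_numpy(float)
                y = phyla[keys[ib]].to_numpy(float)
                if np.unique(x).size < 2 or np.unique(y).size < 2:
                    continue
                pair_seed = seed + 7919 * mi + 13 * (ia * len(keys) + ib)
                try:
                    curve = conditional_spearman(x, y, mod_vals, Z_adjust=Z,
                                                 n_boot=n_boot, seed=pair_seed,
                                                 link=link, level=level)
                except CpmError:
                    continue
                rec = detect_shift(curve, pair=(pa, pb), pairing=_pairing(da, db),
                                   modifier_name=modifier, level=level)
                records.append(rec)
                curves[(modifier, pa, pb)] = curve
    return records, curves
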