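"""Coefficient summaries and the raw soil-variable correlation screen."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def summarize_significant(classified: pd.DataFrame, by: str = "covariate") -> pd.DataFrame:
    """Median and IQR of significant posterior-median coefficients, split by sign.

    Quartiles use the inclusive linear-interpolation convention; this is
    recorded in the ``quartile_method`` column of the output.
    """
    sig = classified[classified["call"] != "ns"]
    rows = []
    for (key, call), grp in sig.groupby([by, "call"], sort=True):
        vals = grp["median"].to_numpy()
        q25, q75 = np.percentile(vals, [25, 75], method="linear")
        rows.append({
            by: key,
            "direction": call,
            "n_orders": int(len(vals)),
            "median": float(np.median(vals)),
            "q25": float(q25),
            "q75": float(q75),
            "quartile_method": "linear",
        })
    return pd.DataFrame(rows, columns=[by, "direction", "n_orders", "median",
                                       "q25", "q75", "quartile_method"])


def count_responders(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts of significant orders per covariate x direction x domain."""
    covs = list(dict.fromkeys(classified["covariate"]))
    rows = []
    sig = classified[classified["call"] != "ns"]
    for cov in covs:
        sub = sig[sig["covariate"] == cov]
        for direction in ("positive", "negative"):
            for domain in ("bacteria", "fungi"):
                n = int(((sub["call"] == direction) & (sub["domain"] == domain)).sum())
                rows.append({"covariate": cov, "direction": direction,
                             "domain": domain, "n_orders": n})
    return pd.DataFrame(rows)


def soil_correlations(metadata: pd.DataFrame, reference: str = "TC") -> pd.DataFrame:
    """Pearson r (with two-sided p) of every numeric covariate vs ``reference``.

    Constant columns yield NA rather than an error.
    """
    num = metadata.select_dtypes("number")
    if reference not in num.columns:
        raise KeyError(f"reference covariate {reference!r} not found")
    if num.shape[0] < 3:
        raise ValueError("need at least 3 sites")
    ref = num[reference].to_numpy(dtype=float)
    rows = []
    for col in num.columns:
        if col == reference:
            continue
        x = num[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(ref)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(ref[ok]) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x[ok], ref[ok])
        rows.append({"covariate": col, "reference": reference,
                     "r": float(r) if np.isfinite(r) else np.nan,
                     "p": float(p) if np.isfinite(p) else np.nan,
                     "n": int(ok.sum())})
    return pd.DataFrame(rows)
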