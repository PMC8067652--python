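"""Reading, filtering and aggregating count tables; covariate derivation and scaling.

Count tables are delimited files with taxa as rows: a ``taxonomy`` column
holding a semicolon-delimited lineage (``k__Bacteria;p__...;c__...;o__...``
dialect or plain names, positional), and one integer count column per site.
Metadata tables hold one row per site with named physicochemical columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ordered taxonomic ranks recognised in lineage strings
RANKS = ("kingdom", "phylum", "class", "order")

_RANK_PREFIXES = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order"}

#: suffix appended to display names of taxa unresolved at the target rank,
#: keyed by the deepest classified rank
RESOLUTION_SUFFIX = {"order": "", "class": "**", "phylum": "*", "kingdom": "*"}

#: default assignment of model covariates to variance-partition groups
DEFAULT_GROUPS = {
    "elevation": "elevation",
    "pH": "pH",
    "TC": "C&N",
    "TN": "C&N",
    "C:N": "C&N",
    "DOC": "organic matter",
    "E2/E3": "organic matter",
    "SUVA254": "organic matter",
    "TP": "P",
    "latitude": "geographic distance",
    "longitude": "geographic distance",
}

#: canonical covariate spellings for case-insensitive metadata matching
_CANONICAL_COVARIATES = [
    "elevation", "pH", "TC", "TN", "TP", "DOC", "A250", "A254", "A365",
    "latitude", "longitude", "C:N", "E2/E3", "SUVA254",
]


class InputError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass(frozen=True)
class TaxonLabel:
    """A taxon with its (possibly truncated) lineage.

    ``resolution_flag`` records the deepest classified rank when the taxon
    could not be resolved at the aggregation rank; display names carry the
    matching ``*`` (phylum) / ``**`` (class) suffix.
    """

    lineage: tuple  # ((rank, name), ...) down to the deepest classified rank
    display_name: str
    resolution_flag: str  # deepest classified rank, e.g. "order"

    @property
    def kingdom(self) -> str:
        return dict(self.lineage).get("kingdom", "")

    @property
    def phylum(self) -> str:
        return dict(self.lineage).get("phylum", "")

    @property
    def domain(self) -> str:
        """Coarse domain: 'fungi' if the kingdom names fungi, else 'bacteria'."""
        return "fungi" if "fungi" in self.kingdom.lower() else "bacteria"


@dataclass
class CommunityTable:
    """Site x taxon table of non-negative integer counts."""

    counts: np.ndarray  # (n_sites, n_taxa) int64
    site_ids: list
    taxa: list  # list[TaxonLabel]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise InputError("counts must be a 2-D site x taxon matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise InputError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise InputError("counts must be non-negative")
        if len(self.site_ids) != self.counts.shape[0]:
            raise InputError("site_ids length does not match counts")
        if len(self.taxa) != self.counts.shape[1]:
            raise InputError("taxa length does not match counts")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise InputError("duplicate site ids")
        names = [t.display_name for t in self.taxa]
        if len(set(names)) != len(names):
            raise InputError("duplicate taxon display names")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def taxon_names(self) -> list:
        return [t.display_name for t in self.taxa]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.site_ids, columns=self.taxon_names)

    def write(self, path) -> None:
        """Write a taxa-as-rows TSV round-trippable via :func:`read_community`."""
        df = pd.DataFrame(
            self.counts.T,
            index=[_lineage_string(t) for t in self.taxa],
            columns=self.site_ids,
        )
        df.index.name = "taxonomy"
        df.to_csv(path, sep="\t")


@dataclass
class EnvMatrix:
    """Standardized site x covariate matrix with back-transformation info."""

    values: np.ndarray  # (n_sites, n_covariates) float
    covariate_names: list
    means: np.ndarray
    sds: np.ndarray
    groups: dict = field(default_factory=dict)
    site_ids: list = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.site_ids is None:
            self.site_ids = list(range(self.values.shape[0]))
        for name in self.covariate_names:
            if name not in self.groups:
                raise InputError(f"covariate {name!r} missing from group map")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.covariate_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.covariate_names)


def _lineage_string(taxon: TaxonLabel) -> str:
    parts = []
    lineage = dict(taxon.lineage)
    for rank in RANKS:
        name = lineage.get(rank, "")
        parts.append(f"{rank[0]}__{name}")
    return ";".join(parts)


def _parse_lineage(raw: str) -> dict:
    """Parse a semicolon-delimited lineage into rank -> name.

    Accepts ``k__Name`` prefixes or bare names assigned positionally.
    Empty fields and placeholder names count as unclassified.
    """
    out = {}
    fields = [f.strip() for f in str(raw).split(";")]
    for pos, fld in enumerate(fields):
        if len(fld) >= 3 and fld[1:3] == "__":
            rank = _RANK_PREFIXES.get(fld[0].lower())
            name = fld[3:].strip()
        else:
            rank = RANKS[pos] if pos < len(RANKS) else None
            name = fld
        if rank is None:
            continue
        low = name.lower()
        if not name or low in {"unclassified", "unidentified", "unknown", "na"}:
            continue
        out[rank] = name
    return out


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_community(path, rank: str = "order") -> CommunityTable:
    """Read a taxa-as-rows count table and aggregate counts to ``rank``.

    Rows unclassified at ``rank`` fall back to their deepest classified rank
    and their display name is suffixed ``**`` (class) or ``*`` (phylum).
    Aggregation sums counts of rows sharing the (possibly truncated) lineage.
    """
    if rank not in RANKS:
        raise InputError(f"unknown rank {rank!r}; expected one of {RANKS}")
    sep = _sep_for(path)
    with open(path) as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise InputError(f"{path}: empty input file")
    header = [h.strip() for h in header_line.rstrip("\n").split(sep)]
    body = header[1:]
    if len(set(c.lower() for c in body)) != len(body):
        raise InputError(f"{path}: duplicate site columns")

    df = pd.read_csv(path, sep=sep)
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise InputError(f"{path}: no data rows or no site columns")
    tax_col = next((c for c in df.columns if c.lower() == "taxonomy"), df.columns[0])
    site_ids = [c for c in df.columns if c != tax_col]
    counts = df[site_ids].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise InputError(f"{path}: non-numeric counts")
    if np.any(~np.isfinite(counts.astype(float))) or np.any(counts != np.floor(counts)):
        raise InputError(f"{path}: counts must be finite integers")
    if np.any(counts < 0):
        raise InputError(f"{path}: negative counts")
    counts = counts.astype(np.int64)

    target_idx = RANKS.index(rank)
    groups: dict = {}
    order: list = []
    for row, raw in enumerate(df[tax_col]):
        lineage = _parse_lineage(raw)
        # truncate to the target rank, falling back to the deepest classified one
        eff_idx = target_idx
        while eff_idx > 0 and RANKS[eff_idx] not in lineage:
            eff_idx -= 1
        if RANKS[eff_idx] not in lineage:
            raise InputError(f"{path}: row {row} has no classified rank: {raw!r}")
        key = tuple((r, lineage[r]) for r in RANKS[: eff_idx + 1] if r in lineage)
        if key not in groups:
            groups[key] = np.zeros(len(site_ids), dtype=np.int64)
            order.append(key)
        groups[key] += counts[row]

    taxa = []
    seen: dict = {}
    for key in order:
        lineage = dict(key)
        deepest = key[-1][0]
        name = key[-1][1] + RESOLUTION_SUFFIX[deepest]
        if name in seen:
            parent = key[-2][1] if len(key) > 1 else deepest
            name = f"{parent}_{name}"
            n = 2
            base = name
            while name in seen:
                name = f"{base}.{n}"
                n += 1
        seen[name] = True
        taxa.append(TaxonLabel(lineage=key, display_name=name, resolution_flag=deepest))

    mat = np.stack([groups[k] for k in order], axis=1)
    return CommunityTable(counts=mat, site_ids=site_ids, taxa=taxa)


def filter_prevalence(table: CommunityTable, min_sites: int = 5) -> CommunityTable:
    """Drop taxa with nonzero counts in fewer than ``min_sites`` sites (inclusive boundary)."""
    if min_sites < 1:
        raise InputError("min_sites must be >= 1")
    prevalence = (table.counts > 0).sum(axis=0)
    keep = prevalence >= min_sites
    if not keep.any():
        raise InputError(
            f"prevalence filter at min_sites={min_sites} removed every taxon; "
            "reduce the threshold"
        )
    return CommunityTable(
        counts=table.counts[:, keep],
        site_ids=list(table.site_ids),
        taxa=[t for t, k in zip(table.taxa, keep) if k],
    )


def read_metadata(path) -> pd.DataFrame:
    """Read a site metadata table, canonicalising covariate column names."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    lookup = {c.lower().replace("_", "").replace("/", "").replace(":", ""): c
              for c in _CANONICAL_COVARIATES}
    renames = {}
    for col in df.columns:
        key = col.lower().replace("_", "").replace("/", "").replace(":", "")
        key = {"e2e3": "e2e3", "cn": "cn", "elev": "elevation"}.get(key, key)
        if key in lookup:
            renames[col] = lookup[key]
    return df.rename(columns=renames)


def derive_covariates(raw: pd.DataFrame, suva_scale: float = 1.0) -> pd.DataFrame:
    """Append C:N = TC/TN, E2/E3 = A250/A365 and SUVA254 = scale * A254/DOC.

    Raises :class:`InputError` naming the offending site and covariate when a
    denominator is zero or negative would make the ratio undefined.
    """
    df = raw.copy()
    cols = {c.lower(): c for c in df.columns}

    def col(name):
        try:
            return df[cols[name.lower()]]
        except KeyError:
            raise InputError(f"metadata is missing required column {name!r}") from None

    for denom_name, num_name, out in (("TN", "TC", "C:N"),
                                      ("A365", "A250", "E2/E3"),
                                      ("DOC", "A254", "SUVA254")):
        denom = col(denom_name)
        bad = denom.index[(denom <= 0) | ~np.isfinite(denom)]
        if len(bad):
            raise InputError(
                f"cannot derive {out}: non-positive {denom_name} at site {bad[0]!r}"
            )
        df[out] = col(num_name) / denom
    df["SUVA254"] = df["SUVA254"] * suva_scale
    return df


def standardize(env: pd.DataFrame, covariates=None, groups=None,
                impute: bool = False) -> EnvMatrix:
    """Center and scale covariates to zero mean / unit sample SD (n-1 denominator)."""
    if covariates is None:
        covariates = [c for c in env.columns if c in DEFAULT_GROUPS]
        if not covariates:
            covariates = list(env.columns)
    missing = [c for c in covariates if c not in env.columns]
    if missing:
        raise InputError(f"metadata is missing covariate column(s) {missing}")
    if env.shape[0] < 2:
        raise InputError("standardization needs at least 2 sites")
    sub = env[covariates].astype(float).copy()
    if sub.isna().any().any():
        if not impute:
            bad = sub.columns[sub.isna().any()].tolist()
            raise InputError(f"missing values in covariates {bad}; pass impute=True to mean-impute")
        logger.warning("mean-imputing %d missing metadata cells", int(sub.isna().sum().sum()))
        sub = sub.fillna(sub.mean())
    values = sub.to_numpy()
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    zero = np.asarray(sds) < 1e-12
    if zero.any():
        raise InputError(f"zero-variance covariate(s): {[c for c, z in zip(covariates, zero) if z]}")
    if groups is None:
        groups = {c: DEFAULT_GROUPS.get(c, c) for c in covariates}
    return EnvMatrix(
        values=(values - means) / sds,
        covariate_names=list(covariates),
        means=means,
        sds=sds,
        groups=dict(groups),
        site_ids=list(env.index),
    )


def unstandardize(env: EnvMatrix) -> pd.DataFrame:
    """Invert :func:`standardize` using the stored means and SDs."""
    raw = env.values * env.sds + env.means
    return pd.DataFrame(raw, index=env.site_ids, columns=env.covariate_names)
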