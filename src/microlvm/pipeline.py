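"""End-to-end orchestration: read -> filter -> standardize -> fit -> summaries ->
variance partition -> residual network -> niche regression -> conditional shifts."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from microlvm import data_io, gllvm, interactions, network, summaries, varpart
from microlvm.gllvm import PriorConfig, SamplerConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    counts_path: str = None
    metadata_path: str = None
    outdir: str = "microlvm_out"
    rank: str = "order"
    min_sites: int = 5
    covariates: list = None            # default: every recognised covariate
    derive: bool = False               # derive C:N, E2/E3, SUVA254 from raw columns
    d: int = 2
    prior_sd: float = 10.0
    phi_inv_rate: float = 0.1
    n_chains: int = 4
    n_draws: int = 1000
    n_warmup: int = 1000
    thin: int = 1
    credible_level: float = 0.95
    groups: dict = None
    modifiers: list = field(default_factory=lambda: ["C:N", "elevation", "pH"])
    n_boot: int = 1000
    seed: int = 0
    suva_scale: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=str)


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the run seed and the stage name."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16)


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a dict of stage outputs.

    Every tidy output is also written under ``config.outdir``. A stage error
    aborts with the stage name; outputs of completed stages are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "runconfig.json").write_text(config.to_json())
    results: dict = {}
    stage = "read"
    t0 = time.time()
    try:
        counts = data_io.read_community(config.counts_path, rank=config.rank)
        meta = data_io.read_metadata(config.metadata_path)
        meta = meta.loc[[s for s in counts.site_ids if s in meta.index]]
        if len(meta) != counts.n_sites:
            raise data_io.InputError("metadata does not cover every count-table site")

        stage = "filter"
        counts = data_io.filter_prevalence(counts, config.min_sites)
        counts.write(out / "filtered_counts.tsv")
        results["counts"] = counts

        stage = "standardize"
        if config.derive:
            meta = data_io.derive_covariates(meta, suva_scale=config.suva_scale)
        env = data_io.standardize(meta, config.covariates, groups=config.groups)
        env.to_frame().to_csv(out / "env_standardized.tsv", sep="\t")
        results["env"] = env

        stage = "fit"
        fit = gllvm.fit_gllvm(
            counts, env, d=config.d,
            priors=PriorConfig(sd=config.prior_sd, phi_inv_rate=config.phi_inv_rate),
            sampler=SamplerConfig(n_chains=config.n_chains, n_draws=config.n_draws,
                                  n_warmup=config.n_warmup, thin=config.thin),
            seed=stage_seed(config.seed, "fit"),
        )
        fit.save(out / "fit")
        results["fit"] = fit
        logger.info("fit done in %.1fs (diagnostics: %s)", time.time() - t0, fit.diagnostics)

        stage = "classify"
        classified = gllvm.classify_coefficients(fit, prob=config.credible_level)
        classified.to_csv(out / "coefficients.tsv", sep="\t", index=False)
        results["classified"] = classified
        summaries.summarize_significant(classified, by="covariate").to_csv(
            out / "coefficient_summaries.tsv", sep="\t", index=False)
        summaries.count_responders(classified).to_csv(
            out / "responder_counts.tsv", sep="\t", index=False)

        stage = "varpart"
        vp = varpart.variance_partition(fit, groups=env.groups)
        tidy = vp.proportions.reset_index(names="taxon").melt(
            id_vars="taxon", var_name="group", value_name="proportion")
        tidy.to_csv(out / "varpart.tsv", sep="\t", index=False)
        domains = pd.Series({t.display_name: t.domain for t in counts.taxa})
        vps = varpart.varpart_summaries(vp, domains=domains)
        (out / "varpart_summary.json").write_text(json.dumps(vps, indent=1))
        results["varpart"] = vp
        results["varpart_summary"] = vps

        stage = "network"
        net = network.build_network(fit, level=config.credible_level)
        network.edge_table(net).to_csv(out / "network_edges.tsv", sep="\t", index=False)
        nx.write_graphml(net.graph, out / "network.graphml")
        pd.concat([net.closeness, net.median_cooccurrence], axis=1).to_csv(
            out / "closeness.tsv", sep="\t")
        results["network"] = net

        stage = "niche_regression"
        regs = []
        for cov in env.covariate_names:
            try:
                entry = network.niche_regression(fit, net, cov, prob=config.credible_level)
            except ValueError:
                continue
            for resp in ("closeness", "median_cooccurrence"):
                if entry.get(resp):
                    regs.append({"covariate": cov, "response": resp, **entry[resp]})
        niche = pd.DataFrame(regs)
        niche.to_csv(out / "niche_regression.tsv", sep="\t", index=False)
        results["niche_regression"] = niche

        stage = "shifts"
        records, curves = interactions.scan_shifts(
            counts, env, modifiers=config.modifiers, n_boot=config.n_boot,
            seed=stage_seed(config.seed, "shifts"), level=config.credible_level,
        )
        rec_df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        rec_df.to_csv(out / "shift_records.tsv", sep="\t", index=False)
        shift_counts = interactions.count_shifts(records)
        shift_counts.to_csv(out / "shift_counts.tsv", sep="\t")
        results["shift_records"] = records
        results["shift_counts"] = shift_counts
        curve_rows = []
        for (modifier, pa, pb), curve in curves.items():
            for gi, gval in enumerate(curve.grid):
                curve_rows.append({"modifier": modifier, "phylum_a": pa, "phylum_b": pb,
                                   "grid": gval, "rho": curve.rho[gi],
                                   "ci_lower": curve.ci_lower[gi],
                                   "ci_upper": curve.ci_upper[gi]})
        pd.DataFrame(curve_rows).to_csv(out / "shift_curves.tsv", sep="\t", index=False)

        stage = "report"
        report = make_report(results, config)
        (out / "report.txt").write_text(report)
        results["report"] = report
    except Exception as exc:  # noqa: BLE001 - stage name is the useful context
        raise PipelineError(stage, exc) from exc
    return results


def _fmt_pct(x):
    return f"{100 * x:.2f}%"


def make_report(results: dict, config: RunConfig = None) -> str:
    """Human-readable summary of whichever stages are present."""
    lines = ["microlvm analysis report", "=" * 24, ""]
    if config is not None:
        lines += [f"settings: d={config.d}, credible level={config.credible_level}, "
                  f"chains={config.n_chains}x{config.n_draws} (+{config.n_warmup} warmup), "
                  f"prevalence filter >= {config.min_sites} sites, seed={config.seed}",
                  "conventions: sample SD standardization, inclusive quartiles, "
                  "posterior-median point estimates, strict > for thresholds", ""]

    if "classified" in results:
        classified = results["classified"]
        lines.append("[coefficients]")
        resp = summaries.count_responders(classified)
        sig = resp[resp["n_orders"] > 0]
        if sig.empty:
            lines.append("  none detected")
        for _, row in sig.iterrows():
            lines.append(f"  {row.covariate}: {row.n_orders} {row.domain} orders {row.direction}")
        summ = summaries.summarize_significant(classified, by="covariate")
        for _, row in summ.iterrows():
            lines.append(f"  {row.covariate} ({row.direction}, n={row.n_orders}): "
                         f"median={row['median']:+.2f}, IQR=[{row.q25:.2f} to {row.q75:.2f}]")
        lines.append("")

    if "varpart_summary" in results:
        lines.append("[variance partitioning]")
        for domain, entry in results["varpart_summary"].items():
            skew = entry["skewness"]
            lines.append(
                f"  {domain}: mean explained {_fmt_pct(entry['mean_explained'])} "
                f"(SD {_fmt_pct(entry['sd_explained'])}); "
                f"{entry['n_above_threshold']} taxa ({entry['pct_above_threshold']:.1f}%) "
                f"above {_fmt_pct(entry['threshold'])}; "
                f"skewness {skew:+.2f}" if skew is not None else f"  {domain}: n/a")
        lines.append("")

    if "network" in results:
        net = results["network"]
        lines.append("[residual network]")
        lines.append(f"  {net.graph.number_of_nodes()} taxa, "
                     f"{net.graph.number_of_edges()} significant edges at level {net.level}")
        lines.append("")

    if "niche_regression" in results and len(results["niche_regression"]):
        lines.append("[niche regression: network position ~ HPD width]")
        for _, row in results["niche_regression"].iterrows():
            lines.append(f"  {row.covariate} ({row.response}): slope={row.slope:+.3f}, "
                         f"r^2={row.r_squared:.2f} (n={row.n_taxa})")
        lines.append("")

    if "shift_counts" in results:
        lines.append("[interaction shifts (significant counts)]")
        table = results["shift_counts"]
        if table.to_numpy().sum() == 0:
            lines.append("  none detected")
        else:
            lines.append(table.to_string())
        lines.append("")

    return "\n".join(lines) + "\n"
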