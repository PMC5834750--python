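"""End-to-end orchestration: cohort -> networks -> metrics -> inference.

``run_pipeline`` executes the full analysis on a directory of
per-subject time series plus a metadata table, writing every stage's
tabular outputs and a machine-readable manifest into the output
directory.  All randomness flows from one master seed through named
substreams, so a rerun with the same configuration reproduces every
numeric output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import connectome as cn
from . import io as fio
from . import metrics as mx
from . import nbs as nb
from . import regions as rg
from . import stats as st
from . import synthetic as syn

log = logging.getLogger("fcnet")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    data_dir: str
    out_dir: str
    band: tuple[float, float] | None = None
    sampling_interval: float = 2.0
    sparsity_min: float = cn.DEFAULT_SPARSITY_MIN
    sparsity_max: float = cn.DEFAULT_SPARSITY_MAX
    sparsity_step: float = cn.DEFAULT_SPARSITY_STEP
    abs_weights: bool = False
    distance_mode: str = mx.RECIPROCAL
    covariates: tuple[str, ...] = cn.DEFAULT_COVARIATES
    component_alpha: float = 0.005
    n_perm: int = 10000
    nbs_alpha: float = 0.05
    gh_mode: str = "gated"
    classifier_rounds: int = clf.DEFAULT_ROUNDS
    classifier_depth: int = clf.DEFAULT_DEPTH
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.sparsity_min > self.sparsity_max or self.sparsity_step <= 0:
            raise ValueError("invalid sparsity range")
        if self.distance_mode not in (mx.RECIPROCAL, mx.LITERAL):
            raise ValueError(f"unknown distance mode {self.distance_mode!r}")
        if not (0 < self.component_alpha < 1):
            raise ValueError("component_alpha must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band) if self.band else None
        d["covariates"] = list(self.covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("band"):
            d["band"] = tuple(d["band"])
        if "covariates" in d:
            d["covariates"] = tuple(d["covariates"])
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def substream_seed(master: int, name: str) -> int:
    """Deterministic named substream seed derived from the master seed."""
    return int(
        np.random.SeedSequence([master, zlib.crc32(name.encode())]).generate_state(1)[0]
        % (2**31)
    )


def simulate_cohort(spec: syn.CohortSpec, data_dir: Path) -> None:
    """Generate a synthetic cohort and write it in pipeline layout."""
    series, meta, truth = syn.generate_cohort(spec)
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    fio.write_cohort(
        data_dir, series, meta, truth, spec.region_names(), spec.sampling_interval
    )
    if spec.n_regions == 90 and spec.lobe_sizes is None:
        rg.write_region_table(rg.default_region_table(), data_dir / "region_table.csv")
    fio.write_json(syn.spec_to_dict(spec), data_dir / "cohort_spec.json")


def _load_inputs(config: RunConfig):
    data_dir = Path(config.data_dir)
    meta_path = data_dir / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata table not found: {meta_path}")
    meta = pd.read_csv(meta_path)
    if "subject_id" not in meta.columns or "group" not in meta.columns:
        raise ValueError("metadata must contain subject_id and group columns")
    table_path = data_dir / "region_table.csv"
    region_table = (
        rg.read_region_table(table_path)
        if table_path.exists()
        else rg.default_region_table()
    )
    series = fio.read_timeseries_dir(
        data_dir / "timeseries",
        meta,
        rg.region_names(region_table),
        config.sampling_interval,
    )
    return meta, region_table, series


def run_pipeline(config: RunConfig) -> dict:
    """Execute connectome -> metrics -> nbs -> stats -> classify.

    Returns the report bundle (tables and result objects); all outputs
    are also written under ``config.out_dir``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta, region_table, series = _load_inputs(config)
    names = rg.region_names(region_table)
    n_regions = len(names)

    if config.band is not None:
        log.info("band-pass filtering %d subjects", len(series))
        series = [cn.bandpass(ts, *config.band) for ts in series]

    log.info("building connectivity matrices")
    mats = [cn.connectivity_from_timeseries(ts) for ts in series]
    mats = cn.regress_covariates(mats, meta, config.covariates)
    conn_dir = out / "connectivity"
    conn_dir.mkdir(exist_ok=True)
    for m, sid in zip(mats, meta["subject_id"]):
        fio.write_connectivity(m, conn_dir / f"{sid}.csv")

    log.info("sparsity sweep and graph metrics")
    grid = cn.sparsity_grid(config.sparsity_min, config.sparsity_max, config.sparsity_step)
    summaries = []
    for m in mats:
        sweep = cn.sparsity_sweep(
            m, config.sparsity_min, config.sparsity_max, config.sparsity_step,
            config.abs_weights,
        )
        summaries.append(mx.subject_metrics(sweep, config.distance_mode))
    auc_table = pd.DataFrame(
        {
            "subject_id": meta["subject_id"],
            "group": meta["group"],
            **{
                f"AUC_{k}": [s.global_auc[k] for s in summaries]
                for k in mx.GLOBAL_METRICS
            },
        }
    )
    fio.write_table(auc_table, out / "auc_summary.csv")
    curves_dir = out / "metric_curves"
    curves_dir.mkdir(exist_ok=True)
    for s, sid in zip(summaries, meta["subject_id"]):
        frame = pd.DataFrame({"sparsity": s.thresholds, **s.curves})
        fio.write_table(frame, curves_dir / f"{sid}.csv")
    nodal_tables = {}
    for k in mx.NODAL_METRICS:
        nodal_tables[k] = pd.DataFrame(
            np.stack([s.nodal_auc[k] for s in summaries]), columns=names
        )
        fio.write_table(
            nodal_tables[k].assign(subject_id=meta["subject_id"]),
            out / f"nodal_auc_{k}.csv",
            region_indexed=True,
        )

    log.info("network-based statistic (%d permutations)", config.n_perm)
    omnibus = nb.nbs_test(
        mats,
        meta["group"],
        design="anova",
        component_alpha=config.component_alpha,
        n_perm=config.n_perm,
        seed=substream_seed(config.seed, "nbs"),
    )
    sig_comps = omnibus.significant(config.nbs_alpha)
    sig_edges = [e for c in sig_comps for e in c.edges]
    posthoc = nb.posthoc_pairwise(
        mats,
        meta["group"],
        sig_edges,
        component_alpha=config.component_alpha,
        n_perm=config.n_perm,
        seed=substream_seed(config.seed, "nbs-posthoc"),
    ) if sig_edges else {}
    edge_rows = []
    for ci, comp in enumerate(omnibus.components):
        for i, j in comp.edges:
            edge_rows.append(
                {
                    "i": i + 1,
                    "j": j + 1,
                    "region_i": names[i],
                    "region_j": names[j],
                    "F": omnibus.stat_map.statistic[i, j],
                    "component": ci + 1,
                    "component_size": comp.size,
                    "corrected_p": comp.corrected_p,
                    "connection_type": nb.classify_connection((i, j), region_table),
                }
            )
    fio.write_table(pd.DataFrame(edge_rows), out / "nbs_edges.csv", region_indexed=True)
    hubs = nb.hub_nodes(sig_edges, n_regions)
    fio.write_table(
        pd.DataFrame(
            {"index": [h + 1 for h in hubs], "region": [names[h] for h in hubs]}
        ),
        out / "nbs_hubs.csv",
        region_indexed=True,
    )
    fio.write_table(
        pd.DataFrame({"max_component_size": omnibus.null_distribution}),
        out / "nbs_null_distribution.csv",
    )
    nbs_summary = {
        "n_permutations": omnibus.n_permutations,
        "component_alpha": omnibus.component_alpha,
        "components": [
            {"size": c.size, "corrected_p": c.corrected_p}
            for c in omnibus.components
        ],
        "significant_components": len(sig_comps),
        "hubs": [names[h] for h in hubs],
        "posthoc": {
            k: [
                {"size": c.size, "corrected_p": c.corrected_p}
                for c in r.components
            ]
            for k, r in posthoc.items()
        },
    }
    fio.write_json(nbs_summary, out / "nbs_summary.json")

    log.info("group statistics")
    report = st.compare_groups(
        auc_table,
        meta["group"],
        nodal=nodal_tables,
        gh_mode=config.gh_mode,
        seed=substream_seed(config.seed, "ks"),
    )
    fio.write_table(report["global"], out / "stats_global.csv")
    fio.write_table(report["posthoc"], out / "stats_posthoc.csv")
    fio.write_table(report["nodal"], out / "stats_nodal.csv", region_indexed=True)
    correlations = st.spearman_scores(auc_table, meta)
    corr_frame = pd.DataFrame(
        [
            {
                "metric": r.metric_name,
                "score": r.score_name,
                "rho": r.rho,
                "p": r.pvalue,
                "p_adj": r.adjusted_p,
                "n": r.n,
            }
            for r in correlations
        ]
    )
    fio.write_table(corr_frame, out / "correlations.csv")

    log.info("classification (leave-one-out)")
    preds, cm, accuracy = clf.loocv(
        auc_table,
        meta["group"],
        n_rounds=config.classifier_rounds,
        tree_depth=config.classifier_depth,
        seed=substream_seed(config.seed, "classifier"),
    )
    fio.write_table(
        pd.DataFrame(
            {
                "subject_id": meta["subject_id"],
                "true_group": meta["group"],
                "predicted_group": preds,
            }
        ),
        out / "predictions.csv",
    )
    cm.to_frame().to_csv(out / "confusion_matrix.csv")
    class_report = clf.classification_report(cm)
    fio.write_table(class_report, out / "classification_report.csv")
    fio.write_json(
        {"loocv_accuracy": accuracy, "classes": cm.classes},
        out / "classification_metrics.json",
    )

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "n_subjects": int(len(meta)),
        "n_regions": int(n_regions),
        "sparsity_grid": grid.tolist(),
        "seeds": {
            name: substream_seed(config.seed, name)
            for name in ("nbs", "nbs-posthoc", "ks", "classifier")
        },
    }
    fio.write_json(manifest, out / "manifest.json")
    return {
        "config": config,
        "meta": meta,
        "region_table": region_table,
        "auc_table": auc_table,
        "nodal_tables": nodal_tables,
        "omnibus": omnibus,
        "posthoc": posthoc,
        "hubs": hubs,
        "stats": report,
        "correlations": correlations,
        "confusion_matrix": cm,
        "accuracy": accuracy,
        "manifest": manifest,
    }


def summarize_report(bundle: dict) -> str:
    """Plain-text digest of a completed pipeline run."""
    lines = []
    config: RunConfig = bundle["config"]
    lines.append(f"fcnet run (config hash {config.hash()})")
    meta = bundle["meta"]
    lines.append(
        "subjects: "
        + ", ".join(f"{g}={c}" for g, c in meta["group"].value_counts().items())
    )
    auc = bundle["auc_table"]
    for metric in ("AUC_Cp", "AUC_Lp", "AUC_Eg", "AUC_Eloc"):
        means = auc.groupby("group", sort=False)[metric].mean()
        joined = ", ".join(f"{g}={v:.4f}" for g, v in means.items())
        lines.append(f"{metric} group means: {joined}")
    omnibus = bundle["omnibus"]
    sig = omnibus.significant(config.nbs_alpha)
    if sig:
        for c in sig:
            lines.append(
                f"NBS component: {c.size} edges, corrected p = {c.corrected_p:.4f}"
            )
        names = list(bundle["region_table"]["name"])
        lines.append(
            "hubs: " + (", ".join(names[h] for h in bundle["hubs"]) or "none")
        )
        types = {}
        table = bundle["region_table"]
        for c in sig:
            for e in c.edges:
                t = nb.classify_connection(e, table)
                types[t] = types.get(t, 0) + 1
        lines.append(
            "connection types: "
            + ", ".join(f"{k}={v}" for k, v in sorted(types.items()))
        )
    else:
        lines.append("NBS: no significant components")
    for r in bundle["correlations"]:
        lines.append(
            f"Spearman {r.metric_name} vs {r.score_name}: rho={r.rho:.3f}, "
            f"p={r.pvalue:.4f}, p_adj={r.adjusted_p:.4f}"
        )
    lines.append(f"LOOCV accuracy: {bundle['accuracy']:.3f}")
    return "\n".join(lines) + "\n"
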