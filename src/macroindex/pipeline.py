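"""End-to-end orchestration: simulate -> cluster -> enrich -> associate ->
index -> concordance -> survival, driven by one YAML config.

Stages communicate through files in the output directory so that any
stage can be re-run or inspected in isolation; the final JSON report
collects every statistic produced, an echo of the configuration, and
input hashes for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import clustering as clus
from . import concordance as conc
from . import enrichment as enr
from . import index as mindex
from . import io as mio
from . import simulate as sim
from . import survival as surv

logger = logging.getLogger("macroindex")

__all__ = ["RunConfig", "run_pipeline", "run_table1"]

STAGES = (
    "simulate",
    "cluster",
    "enrich",
    "associate",
    "index",
    "de",
    "concordance",
    "survival",
    "table1",
)


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # inputs; all optional when the simulate stage is enabled
    expression: str | None = None
    fractions: dict[str, str] = field(default_factory=dict)
    clinical: str | None = None
    gene_sets: str | None = None
    alterations: str | None = None
    # tunables
    simulation: dict = field(default_factory=dict)
    k_min: int = 2
    k_max: int = 6
    n_resample: int = 1000
    subsample_frac: float = 0.8
    ssgsea_alpha: float = 0.25
    alpha: float = 0.05
    n_hits: int = 150
    endpoint: str = "os"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("run config must set a seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_table1(fixture_name: str | None = None) -> dict:
    """Fisher exact p-value for one or all published contingency fixtures."""
    fixtures = sim.table1_fixtures()
    names = [fixture_name] if fixture_name else list(fixtures)
    out = {}
    for name in names:
        res = assoc.fisher_exact_rxc(fixtures[name])
        out[name] = res["p"]
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute enabled stages in dependency order; return the run report.

    Partial failure stops at the failing stage, leaving earlier artifacts
    on disk. Each stage reads its inputs from files written by upstream
    stages (or from the paths in the config).
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": asdict(cfg),
        "provenance": {"stages": [], "input_hashes": {}},
        "results": {},
    }
    enabled = [s for s in STAGES if s in cfg.stages]

    expr = fractions = clinical = gene_sets = alterations = truth = None

    def need(artifact, name, stage):
        if artifact is None:
            raise ValueError(
                f"stage {stage!r} requires the {name!r} artifact; enable the "
                f"producing stage or provide a path in the config"
            )
        return artifact

    if "simulate" in enabled:
        scfg = sim.SimulationConfig(**{"seed": cfg.seed, **cfg.simulation})
        cohort = sim.simulate_cohort(scfg)
        expr, fractions, clinical = cohort.expression, cohort.fraction_set, cohort.clinical
        gene_sets, alterations, truth = cohort.gene_sets, cohort.alterations, cohort.truth
        mio.write_matrix(expr, out_dir / "expression.tsv")
        for name, df in fractions.fractions.items():
            df.to_csv(out_dir / f"fractions_{name}.tsv", sep="\t")
        mio.write_clinical(clinical, out_dir / "clinical.tsv")
        mio.write_gmt(gene_sets, out_dir / "gene_sets.gmt")
        alterations.values.to_csv(out_dir / "alterations.tsv", sep="\t")
        report["provenance"]["stages"].append({"stage": "simulate", "seed": cfg.seed})
        report["results"]["simulate"] = {
            "n_genes": expr.shape[0],
            "n_samples": expr.shape[1],
            "n_hit_up": len(truth.hit_up),
            "n_hit_dn": len(truth.hit_dn),
        }
    else:
        if cfg.expression:
            expr = mio.read_matrix(cfg.expression)
            report["provenance"]["input_hashes"]["expression"] = _hash_file(cfg.expression)
        if cfg.fractions:
            frs = {
                name: pd.read_csv(path, sep="\t", index_col=0)
                for name, path in cfg.fractions.items()
            }
            fractions = mio.FractionSet(frs)
        if cfg.clinical:
            clinical = mio.read_clinical(cfg.clinical)
        if cfg.gene_sets:
            gene_sets = mio.read_gmt(cfg.gene_sets)
        if cfg.alterations:
            alterations = mio.AlterationMatrix(
                pd.read_csv(cfg.alterations, sep="\t", index_col=0)
            )

    macro_groups = None
    if "cluster" in enabled:
        fr = need(fractions, "fractions", "cluster")
        clin = need(clinical, "clinical", "cluster")
        first = fr.algorithm_names[0]
        filtered = clus.filter_fraction_matrix(
            fr.fractions[first], fr.pvalues.get(first)
        )
        model = clus.ConsensusClusterer(
            k_min=cfg.k_min,
            k_max=cfg.k_max,
            n_resample=cfg.n_resample,
            subsample_frac=cfg.subsample_frac,
            random_state=cfg.seed,
        ).fit(filtered.T)
        res = model.result_
        res.assignments[res.chosen_k].rename("cluster").to_csv(
            out_dir / "assignments.tsv", sep="\t"
        )
        model.consensus_.to_csv(out_dir / "consensus_matrix.tsv", sep="\t")
        pd.Series(res.pac_by_k, name="pac").rename_axis("k").to_csv(
            out_dir / "pac.tsv", sep="\t"
        )
        cluster_info = {
            "chosen_k": int(res.chosen_k),
            "pac_by_k": {int(k): float(v) for k, v in res.pac_by_k.items()},
            "n_core": int(res.core_flag.sum()),
        }
        if res.chosen_k == 2:
            m2 = fr.fractions[first].loc[sim.M2_CELL_TYPE]
            macro_groups = clus.assign_macro_groups(
                res.assignments[2], res.core_flag, clin, m2
            )
            macro_groups.labels.to_csv(out_dir / "macro_groups.tsv", sep="\t")
            cluster_info["macro_group_sizes"] = (
                macro_groups.labels.value_counts().to_dict()
            )
        report["provenance"]["stages"].append({"stage": "cluster", "seed": cfg.seed})
        report["results"]["cluster"] = cluster_info

    if "enrich" in enabled:
        e = need(expr, "expression", "enrich")
        gs = need(gene_sets, "gene_sets", "enrich")
        scores = enr.ssgsea_score(e, gs, alpha=cfg.ssgsea_alpha)
        scores.to_csv(out_dir / "ssgsea_scores.tsv", sep="\t")
        report["provenance"]["stages"].append({"stage": "enrich"})
        report["results"]["enrich"] = {"n_sets_scored": int(scores.shape[0])}

    if "associate" in enabled:
        fr = need(fractions, "fractions", "associate")
        scores_path = out_dir / "ssgsea_scores.tsv"
        if not scores_path.exists():
            raise ValueError("stage 'associate' requires ssgsea_scores.tsv from 'enrich'")
        scores = pd.read_csv(scores_path, sep="\t", index_col=0)
        reports = []
        for name, df in fr.fractions.items():
            m2 = df.loc[sim.M2_CELL_TYPE, scores.columns]
            X = scores.T
            kept = assoc.vif_reduce(X)
            reports.append(assoc.fit_m2_regression(m2, X[kept], name))
        cons = assoc.consensus_significance(reports, alpha=cfg.alpha)
        cons.per_algorithm.to_csv(out_dir / "association_coefficients.tsv",
                                  sep="\t", index=False)
        cons.verdicts.rename_axis("feature").to_csv(
            out_dir / "association_verdicts.tsv", sep="\t"
        )
        report["provenance"]["stages"].append({"stage": "associate"})
        report["results"]["associate"] = {
            "n_positive": int((cons.verdicts == "positive").sum()),
            "n_negative": int((cons.verdicts == "negative").sum()),
        }

    macro_idx = None
    if "index" in enabled:
        e = need(expr, "expression", "index")
        macro_idx = mindex.compute_macro_index(e)
        macro_idx.values.rename_axis("sample_id").to_csv(
            out_dir / "macro_index.tsv", sep="\t"
        )
        info = {"n_genes_found": macro_idx.n_genes_found}
        if fractions is not None:
            m2 = fractions.fractions[fractions.algorithm_names[0]].loc[
                sim.M2_CELL_TYPE, macro_idx.values.index
            ]
            rho, p = assoc.spearman(macro_idx.values.to_numpy(), m2.to_numpy())
            info["spearman_vs_m2"] = {"rho": rho, "p": p}
        report["provenance"]["stages"].append({"stage": "index"})
        report["results"]["index"] = info

    de_table = None
    if "de" in enabled:
        e = need(expr, "expression", "de")
        mi = need(macro_idx, "macro_index", "de")
        groups = mindex.split_by_median(mi.values)
        de_table = mindex.differential_expression(e, groups)
        de_table.rename_axis("gene").to_csv(out_dir / "de.tsv", sep="\t")
        n_sig = int((de_table["q"] < cfg.alpha).sum())
        report["provenance"]["stages"].append({"stage": "de"})
        report["results"]["de"] = {"n_significant": n_sig}

    if "concordance" in enabled:
        e = need(expr, "expression", "concordance")
        mi = need(macro_idx, "macro_index", "concordance")
        gs = need(gene_sets, "gene_sets", "concordance")
        if "HIT_UP" not in gs.sets or "HIT_DN" not in gs.sets:
            raise ValueError("concordance stage needs HIT_UP / HIT_DN gene sets")
        res = conc.signature_concordance_auc(
            e, mi, gs["HIT_UP"], gs["HIT_DN"], sig_alpha=cfg.alpha
        )
        res.per_gene.rename_axis("gene").to_csv(out_dir / "concordance.tsv", sep="\t")
        report["provenance"]["stages"].append({"stage": "concordance"})
        report["results"]["concordance"] = {
            "auc": res.auc,
            "n_included": res.n_included,
        }

    if "survival" in enabled:
        clin = need(clinical, "clinical", "survival")
        mi = need(macro_idx, "macro_index", "survival")
        tcol, ecol = f"{cfg.endpoint}_time", f"{cfg.endpoint}_event"
        df = clin.require(tcol, ecol)
        groups = mindex.split_by_median(mi.values.loc[df.index])
        chi2, p = surv.logrank_test(df[tcol], df[ecol], groups)
        cox = surv.cox_univariate(df[tcol], df[ecol], mi.values.loc[df.index])
        fit = surv.km_fit(df[tcol], df[ecol], groups)
        for level, table in fit.groups.items():
            table.to_csv(out_dir / f"km_{level}.tsv", sep="\t", index=False)
        report["provenance"]["stages"].append({"stage": "survival"})
        report["results"]["survival"] = {
            "endpoint": cfg.endpoint,
            "logrank_chi2": chi2,
            "logrank_p": p,
            "cox_coef": cox.coef,
            "cox_p": cox.p,
            "cox_hr": cox.hr,
        }

    if "table1" in enabled:
        report["results"]["table1"] = run_table1()
        report["provenance"]["stages"].append({"stage": "table1"})

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
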