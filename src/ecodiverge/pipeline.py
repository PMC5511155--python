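"""End-to-end orchestration of the inference stack.

Stage order follows the analysis design: outlier scan first (its
neutral/outlier split feeds everything downstream), then diversity and
AMOVA on the total / neutral / positive-outlier locus sets, clustering and
DAPC, ABC scenario inference on the neutral loci only, and finally the
environment association battery.

A single global seed expands into per-stage seeds through a fixed
splitting rule (stage_seed = (seed * 10007 + stage_index) mod 2^31), so
each stage is individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abc_infer, coalsim, env_association, genodata, outlier_scan
from . import popgen_stats, structure_dapc, synthdata

log = logging.getLogger(__name__)

STAGES = ("outliers", "diversity", "amova", "clustering", "dapc", "abc",
          "envassoc")

_DEFAULTS = {
    "seed": 0,
    "stages": list(STAGES),
    "genotypes": None,            # GenePop path; None -> synthetic fixture
    "grouping": None,             # grouping CSV path
    "env_populations": None,      # CSV path; None -> synthetic fixture
    "outliers": {"iterations": 4000, "thinning": 10, "burn_in": 800,
                 "prior_odds": 10.0, "po_threshold": 10.0,
                 "q_threshold": 0.05},
    "clustering": {"k_range": [1, 4], "n_runs": 3,
                   "burn_in": 300, "iterations": 800},
    "dapc": {"n_pcs": 2},
    "amova": {"n_perm": 999},
    "abc": {"models": ["CI", "AM", "SC", "CM"], "n_per_model": 1000,
            "n_loci": 15, "n_keep": 500, "n_components": 5},
    "envassoc": {"n_perm": 999, "vif_threshold": 10.0},
}


def _merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(_DEFAULTS))
    for key, val in user.items():
        if key not in cfg:
            raise ValueError(f"unknown config key: {key!r}")
        if isinstance(cfg[key], dict):
            for k2, v2 in val.items():
                if k2 not in cfg[key]:
                    raise ValueError(f"unknown config key: {key}.{k2}")
                cfg[key][k2] = v2
        else:
            cfg[key] = val
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge_config(user)


def stage_seed(seed: int, stage: str) -> int:
    return (seed * 10007 + STAGES.index(stage)) % (2 ** 31)


@dataclass
class PipelineResult:
    config: dict
    outputs: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(float_format="%.10g").encode()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the configured stages; returns results and a manifest.

    The manifest records the effective configuration, per-stage seeds and
    content hashes of every tabular output, so a re-run with the same
    config is verifiably byte-identical.
    """
    cfg = _merge_config(config)
    seed = int(cfg["seed"])
    res = PipelineResult(config=cfg)
    out = res.outputs
    manifest = {"config": cfg, "stage_seeds": {}, "hashes": {}}

    # ------------------------------------------------------------- inputs
    if cfg["genotypes"] is not None:
        ds = genodata.read_genepop(cfg["genotypes"], grouping=cfg["grouping"])
        partition_truth = None
    else:
        fx = synthdata.make_genotype_fixture(seed=seed)
        ds = fx.dataset
        partition_truth = fx.partition
        out["fixture_truth"] = fx.truth
    if cfg["env_populations"] is not None:
        env_pop = pd.read_csv(cfg["env_populations"], index_col=0)
        env_fx = None
    else:
        env_fx = synthdata.make_env_fixture(seed=seed)
        env_pop = env_fx["populations"]

    active = list(cfg["stages"])
    for st in active:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}")
        manifest["stage_seeds"][st] = stage_seed(seed, st)

    # --------------------------------------------------------- outlier scan
    partition = partition_truth
    if "outliers" in active:
        oc = cfg["outliers"]
        chain = outlier_scan.fit_outlier_scan(
            ds, iterations=oc["iterations"], thinning=oc["thinning"],
            burn_in=oc["burn_in"], prior_odds=oc["prior_odds"],
            seed=stage_seed(seed, "outliers"))
        report = outlier_scan.classify_outliers(
            chain, po_threshold=oc["po_threshold"],
            q_threshold=oc["q_threshold"])
        out["outlier_report"] = report.table
        partition = genodata.LocusPartition(
            neutral=set(report.neutral),
            positive_outliers=set(report.positive),
            balancing_outliers=set(report.balancing))
        out["partition"] = partition
    if partition is None:
        partition = genodata.LocusPartition(neutral=set(ds.locus_names))

    neutral_ds = ds.subset_loci(sorted(partition.neutral)) \
        if partition.neutral else ds
    datasets = {"total": ds, "neutral": neutral_ds}
    if partition.positive_outliers:
        datasets["positive_outliers"] = ds.subset_loci(
            sorted(partition.positive_outliers))

    # -------------------------------------------------- diversity and AMOVA
    if "diversity" in active:
        out["diversity"] = popgen_stats.diversity_table(ds)
    if "amova" in active:
        tabs = {}
        for name, d in datasets.items():
            try:
                r = popgen_stats.amova(d, n_perm=cfg["amova"]["n_perm"],
                                       seed=stage_seed(seed, "amova"))
                tabs[name] = r.to_frame()
            except ValueError as exc:
                log.warning("AMOVA on %s failed: %s", name, exc)
        out["amova"] = tabs
        out["pairwise_fst"] = popgen_stats.pairwise_fst(neutral_ds)

    # ---------------------------------------------------------- clustering
    if "clustering" in active:
        cc = cfg["clustering"]
        runs = []
        k_lo, k_hi = cc["k_range"]
        base = stage_seed(seed, "clustering")
        for K in range(k_lo, k_hi + 1):
            for rep in range(cc["n_runs"]):
                runs.append(structure_dapc.admixture_mcmc(
                    neutral_ds, K, burn_in=cc["burn_in"],
                    iterations=cc["iterations"],
                    seed=(base + 101 * K + rep) % (2 ** 31)))
        out["structure_runs"] = runs
        out["delta_k"] = structure_dapc.evanno_deltaK(runs).table
        best_k = structure_dapc.evanno_deltaK(runs).best_k
        same_k = [r for r in runs if r.K == best_k]
        _, _, mean_q = structure_dapc.align_runs(same_k)
        out["mean_Q"] = pd.DataFrame(
            mean_q, index=ds.individual_ids,
            columns=[f"cluster{i + 1}" for i in range(best_k)])
    if "dapc" in active:
        out["dapc_species"] = structure_dapc.dapc_fit(
            neutral_ds, "species", n_pcs=cfg["dapc"]["n_pcs"])

    # ----------------------------------------------------------------- ABC
    if "abc" in active:
        ac = cfg["abc"]
        ref = abc_infer.build_reference_table(
            ac["models"], ac["n_per_model"], ac["n_loci"],
            seed=stage_seed(seed, "abc"))
        obs = abc_infer.summary_stats(neutral_ds)
        out["abc"] = abc_infer.abc_analysis(
            ref, obs, n_components=ac["n_components"], n_keep=ac["n_keep"])

    # ------------------------------------------------- environment battery
    if "envassoc" in active:
        ec = cfg["envassoc"]
        es = stage_seed(seed, "envassoc")
        env_ind = synthdata.env_for_individuals(ds, env_pop)
        keep, vlog = env_association.vif_prune(
            env_ind.select_dtypes(include=[np.number]),
            threshold=ec["vif_threshold"])
        pca = env_association.pca_env(env_ind, keep)
        kw = env_association.kw_species_test(pca.scores.iloc[:, :3],
                                             ds.species)
        X = genodata.genotype_matrix(neutral_ds)
        X = X - X.mean(axis=0)
        u, s, _ = np.linalg.svd(X, full_matrices=False)
        geno_pcs = pd.DataFrame(
            (u[:, :2] * s[:2]), index=ds.individual_ids,
            columns=["PC1", "PC2"])
        ord_res = env_association.dbrda(geno_pcs, env_ind[keep],
                                        n_perm=ec["n_perm"], seed=es)
        out["envassoc"] = {
            "vif_retained": keep, "vif_log": vlog,
            "pca_percent": pca.percent_variance, "kw": kw,
            "dbrda": ord_res,
            "glm_axes": env_association.glm_on_axis(
                env_ind[keep], ord_res.site_scores.iloc[:, :2]),
            "logistic_pcs": env_association.logistic_species(
                pca.scores.iloc[:, :3], ds.species),
        }

    # ------------------------------------------------------------ manifest
    for key, val in out.items():
        if isinstance(val, pd.DataFrame):
            manifest["hashes"][key] = _hash_frame(val)
    res.manifest = manifest
    if out_dir is not None:
        write_outputs(res, out_dir)
    return res


def write_outputs(res: PipelineResult, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for key, val in res.outputs.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out_dir / f"{key}.csv")
        elif key == "amova":
            for name, tab in val.items():
                tab.to_csv(out_dir / f"amova_{name}.csv")
        elif key == "abc":
            payload = {
                "relative_density": val.relative_density,
                "log_marginal": val.log_marginal,
                "best_model": val.best_model,
                "posterior_summary": val.posterior_summary,
            }
            (out_dir / "abc.json").write_text(
                json.dumps(payload, indent=2, default=str))
    (out_dir / "manifest.json").write_text(
        json.dumps(res.manifest, indent=2, default=str))
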