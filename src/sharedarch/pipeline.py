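"""End-to-end orchestration of the phenotypic and genetic arms.

The phenotypic arm runs: sparse-variable exclusion -> chained imputation ->
PCA with cumulative-variance retention -> FDR-corrected block correlations
-> confound residualization -> four CCA models (simple/unique x two
behavioural sides) -> loading permutation tests -> cross-model variate
matching.  The genetic arm runs: pairwise LD-score regressions within each
construct -> one-factor model per construct -> factor-external genetic
correlations with a declared FDR family -> latent-causality screening.

Every artifact is regenerable from the config and seeds alone; stage
intermediates are persisted in the module text dialects so any stage can be
rerun standalone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd

from . import cca, decompose, gsem, impute, lcv, ldsr, syndata
from .tables import PhenotypeTable, _jsonable

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def _write_run_log(out: Path, stage: str, wall_s: float) -> None:
    """Versions, stage and wall-time go in a side log, kept out of the
    report so seeded reruns stay byte-identical."""
    import sharedarch
    log_path = out / "run_log.json"
    log = json.loads(log_path.read_text()) if log_path.exists() else {}
    log[stage] = {"wall_time_s": wall_s, "version": sharedarch.__version__,
                  "numpy": np.__version__, "pandas": pd.__version__}
    log_path.write_text(json.dumps(log, indent=1))


def remaining_sample(n_initial: int, exclusions: list[int]) -> int:
    """Cohort size after applying successive exclusion counts."""
    n = int(n_initial)
    for e in exclusions:
        n -= int(e)
    if n < 0:
        raise ValueError("exclusions exceed the initial sample")
    return n


def _model_summary(model: cca.CCAModel) -> dict:
    return {
        "tag": model.tag,
        "correlations": model.correlations.tolist(),
        "p_values": None if model.p_values is None else model.p_values.tolist(),
        "n_significant": len(model.significant_variates()),
        "confounds": model.confound_names,
    }


def run_phenotypic(cohort: syndata.Cohort, n_perm: int = 1000,
                   fdr_q: float = 0.05, cum_var: float = 0.50,
                   seed: int = 0, out_dir: str | Path | None = None,
                   impute_spec: impute.ImputationSpec | None = None) -> dict:
    """Run the full phenotypic arm on a cohort; returns the report dict."""
    t0 = time.time()
    spec = impute_spec or impute.ImputationSpec(seed=seed)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": seed,
                    "stages": {}}

    mh, dropped = impute.exclude_sparse_variables(cohort.mh_items)
    report["stages"]["exclude_sparse"] = {
        "dropped": dropped, "retained": len(mh.variables)}

    mh_complete = impute.pmm_impute(mh, spec)
    conf = impute.pmm_impute(cohort.confounds, spec)
    conf = impute.categorical_impute(conf, spec)
    conf_coded = impute.dummy_code(conf)

    pca = decompose.retain_components(decompose.fit_pca(mh_complete), cum_var)
    report["stages"]["pca"] = {
        "n_retained": pca.n_retained,
        "explained_variance": pca.explained_variance[: pca.n_retained].tolist(),
        "cumulative": float(np.sum(pca.explained_variance[: pca.n_retained])),
    }

    grid = decompose.correlate_blocks(pca, cohort.pa, q=fdr_q)
    report["stages"]["correlations"] = {
        "shape": list(grid.r.shape),
        "n_tests": int(grid.p.notna().sum().sum()),
        "n_significant": int(grid.significant.sum().sum()),
    }

    brain_res = cca.residualize(cohort.brain, conf_coded)
    scores = PhenotypeTable(pca.retained_scores())
    mh_res = cca.residualize(scores, conf_coded)
    pa_res = cca.residualize(cohort.pa, conf_coded)

    models = {
        "simple_mh": cca.fit_with_inference(
            brain_res, mh_res, n_perm=n_perm, seed=seed, tag="simple_mh",
            confound_names=list(conf_coded.variables)),
        "simple_pa": cca.fit_with_inference(
            brain_res, pa_res, n_perm=n_perm, seed=seed + 1, tag="simple_pa",
            confound_names=list(conf_coded.variables)),
        "unique_mh": cca.unique_model(
            cohort.brain, scores, cohort.pa, conf_coded, n_perm=n_perm,
            seed=seed + 2, tag="unique_mh"),
        "unique_pa": cca.unique_model(
            cohort.brain, cohort.pa, scores, conf_coded, n_perm=n_perm,
            seed=seed + 3, tag="unique_pa"),
    }
    report["models"] = {k: _model_summary(m) for k, m in models.items()}

    loadings = {}
    for name, model in models.items():
        nulls = cca.loading_significance(model, n_perm=n_perm, seed=seed + 7)
        loadings[name] = nulls
        report["models"][name]["loading_significant"] = (
            {} if nulls.p_values.empty
            else nulls.significant.any(axis=1).to_dict())

    matches = {}
    for a, b in (("simple_mh", "simple_pa"), ("unique_mh", "unique_pa"),
                 ("simple_mh", "unique_mh"), ("simple_pa", "unique_pa")):
        matches[f"{a}~{b}"] = cca.match_variates(models[a], models[b])
    report["matching"] = {k: v.to_dict(orient="records")
                          for k, v in matches.items()}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        grid.to_tsv(out / "correlation_grid.tsv")
        for name, model in models.items():
            model.loadings_y.to_csv(out / f"loadings_brain_{name}.tsv",
                                    sep="\t")
        (out / "phenotypic_report.json").write_text(
            json.dumps(_jsonable(report), indent=1))
        _write_run_log(out, "phenotypic", time.time() - t0)
    report["_models"] = models
    report["_loadings"] = loadings
    report["_grid"] = grid
    return report


def run_genetic(mh_sumstats: list[pd.DataFrame],
                pa_sumstats: list[pd.DataFrame],
                ld: pd.DataFrame,
                mh_labels: list[str] | None = None,
                pa_labels: list[str] | None = None,
                fdr_q: float = 0.05, n_blocks: int = 200,
                gcp_threshold: float = 0.425,
                out_dir: str | Path | None = None) -> dict:
    """Run the genetic arm; returns the report dict."""
    t0 = time.time()
    mh_labels = mh_labels or [f"mh{i + 1}" for i in range(len(mh_sumstats))]
    pa_labels = pa_labels or [f"pa{i + 1}" for i in range(len(pa_sumstats))]
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "stages": {}}

    gc_mh = ldsr.build_genetic_covariance(mh_sumstats, ld, mh_labels,
                                          n_blocks=n_blocks)
    gc_pa = ldsr.build_genetic_covariance(pa_sumstats, ld, pa_labels,
                                          n_blocks=n_blocks)
    report["stages"]["ldsr"] = {
        "mh_rg": gc_mh.rg_matrix().to_dict(),
        "pa_rg": gc_pa.rg_matrix().to_dict(),
        "mh_h2": np.diag(gc_mh.S.to_numpy()).tolist(),
        "pa_h2": np.diag(gc_pa.S.to_numpy()).tolist(),
    }

    factor_mh = gsem.fit_common_factor(gc_mh)
    factor_pa = gsem.fit_common_factor(gc_pa)
    report["stages"]["gsem"] = {
        "mh": {"loadings": factor_mh.loadings.to_dict(),
               "cfi": factor_mh.cfi, "srmr": factor_mh.srmr},
        "pa": {"loadings": factor_pa.loadings.to_dict(),
               "cfi": factor_pa.cfi, "srmr": factor_pa.srmr},
    }

    # factor-external correlations: joint matrix over all phenotypes
    gc_all = ldsr.build_genetic_covariance(
        mh_sumstats + pa_sumstats, ld, mh_labels + pa_labels,
        n_blocks=n_blocks)
    family = {}
    for ext in pa_labels:
        fm = gsem.factor_external_rg(gc_all, mh_labels, ext)
        fe = fm.factor_external
        family[("factor", ext)] = SimpleNamespace(**fe)
    # second family half: the held-out single indicator vs each external
    single = mh_labels[-1]
    for ext in pa_labels:
        res = gc_all.pair_results.get((single, ext)) \
            or gc_all.pair_results.get((ext, single))
        if res is not None:
            family[(single, ext)] = res
    fdr_table = ldsr.fdr_correct_pairs(family, q=fdr_q)
    report["stages"]["factor_external"] = fdr_table.to_dict(orient="records")

    # causal screening for significant factor-external pairs
    causal = []
    sig_pairs = fdr_table[fdr_table["significant"]]
    for _, row in sig_pairs.iterrows():
        left, ext = row["pair"].split("/")
        idx1 = mh_labels.index(left) if left in mh_labels else 0
        ss1 = mh_sumstats[idx1]
        ss2 = pa_sumstats[pa_labels.index(ext)]
        try:
            res = lcv.estimate_gcp(ss1, ss2, ld)
        except ValueError as err:
            logger.warning("LCV skipped for %s: %s", row["pair"], err)
            continue
        causal.append({"pair": row["pair"], "gcp": res.gcp, "se": res.se,
                       "p": res.p, "rg": res.rg,
                       "causal": bool(abs(res.gcp) > gcp_threshold
                                      and res.p < 0.05)})
    report["stages"]["lcv"] = causal

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gc_mh.rg_matrix().to_csv(out / "rg_mh.tsv", sep="\t")
        gc_pa.rg_matrix().to_csv(out / "rg_pa.tsv", sep="\t")
        factor_mh.to_tsv(out / "factor_mh.tsv")
        factor_pa.to_tsv(out / "factor_pa.tsv")
        fdr_table.to_csv(out / "factor_external.tsv", sep="\t", index=False)
        (out / "genetic_report.json").write_text(
            json.dumps(_jsonable(report), indent=1))
        _write_run_log(out, "genetic", time.time() - t0)
    report["_gc"] = {"mh": gc_mh, "pa": gc_pa, "all": gc_all}
    report["_factors"] = {"mh": factor_mh, "pa": factor_pa}
    return report
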