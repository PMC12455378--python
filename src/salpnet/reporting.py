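"""Pipeline orchestration, summary tables, and the run manifest.

``run_pipeline`` drives generation (or ingestion) -> cohort -> networks ->
exposure -> models -> tables, writing every output as a delimited text
file plus a JSON manifest with content hashes, seeds, parameters, and
per-stage row counts.  Reruns with the same config reproduce the output
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import exposure as exposure_mod
from . import model as model_mod
from . import network as network_mod
from .codes import CodeDictionary, default_codes
from .config import PipelineConfig
from .synthetic import generate_world, write_synthetic

__all__ = [
    "percentage",
    "make_cohort_table",
    "run_pipeline",
    "REFERENCE_OS_COUNTS",
]

# Benchmark numerator/denominator pairs from a national commercial-claims
# tubal-sterilization cohort (2020-2022 follow-up era): overall OS counts
# per setting, and OS counts among patients of surgeons in the lowest and
# highest peer-exposure quartiles.  Used to validate the display-percentage
# arithmetic against the published values.
REFERENCE_OS_COUNTS: dict[str, tuple[int, int]] = {
    "os_pct_overall_postpartum": (353, 4520),
    "os_pct_overall_interval": (902, 3376),
    "os_pct_q1_postpartum": (61, 1097),
    "os_pct_q4_postpartum": (164, 1202),
    "os_pct_q1_interval": (156, 808),
    "os_pct_q4_interval": (353, 835),
}


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Display percentage, rounded half-away-from-zero to ``decimals``.

    Matches the convention of printed cohort tables (e.g. 353 of 4520
    -> 7.8).
    """
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    scale = 10**decimals
    value = 100.0 * numerator / denominator
    return float(np.floor(value * scale + 0.5) / scale)


_TABLE_COVARIATES = [
    "quartile",
    "age_band",
    "mode_of_delivery",
    "bmi_class",
    "smoking",
    "elixhauser_class",
    "metro",
    "region",
    "sdi_class",
    "year",
]


def make_cohort_table(dataset: pd.DataFrame) -> pd.DataFrame:
    """Characteristics of patients by OS outcome, with univariate tests.

    One row block per characteristic: counts and within-column
    percentages for overall / OS / no-OS, plus the chi-square P value
    (categorical) or rank-sum P value (surgeon volume, reported as
    median (IQR)).
    """
    from scipy import stats

    y = dataset["os_flag"].astype(bool)
    n, n_yes, n_no = len(dataset), int(y.sum()), int((~y).sum())
    rows = []
    for cov in _TABLE_COVARIATES:
        if cov not in dataset.columns:
            continue
        x = dataset[cov]
        levels = sorted(x.dropna().unique(), key=str)
        if len(levels) < 2:
            rows.append(
                {
                    "characteristic": cov,
                    "level": str(levels[0]) if levels else "",
                    "n_overall": n,
                    "n_os": n_yes,
                    "n_no_os": n_no,
                    "pct_overall": 100.0,
                    "pct_os": 100.0,
                    "pct_no_os": 100.0,
                    "p_value": np.nan,
                    "note": "single level; test skipped",
                }
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = pd.crosstab(x, y)
            try:
                _, p, _, _ = stats.chi2_contingency(table)
            except ValueError:
                p = np.nan
        for i, lv in enumerate(levels):
            mask = x == lv
            rows.append(
                {
                    "characteristic": cov,
                    "level": str(lv),
                    "n_overall": int(mask.sum()),
                    "n_os": int((mask & y).sum()),
                    "n_no_os": int((mask & ~y).sum()),
                    "pct_overall": percentage(int(mask.sum()), n),
                    "pct_os": percentage(int((mask & y).sum()), n_yes) if n_yes else np.nan,
                    "pct_no_os": percentage(int((mask & ~y).sum()), n_no) if n_no else np.nan,
                    "p_value": float(p) if i == 0 else np.nan,
                    "note": "",
                }
            )
    if "surgeon_volume" in dataset.columns:
        v = dataset["surgeon_volume"]
        med = lambda s: f"{s.median():g} ({s.quantile(0.25):g}-{s.quantile(0.75):g})"
        stat_p = (
            stats.ranksums(v[y], v[~y]).pvalue if n_yes and n_no else np.nan
        )
        rows.append(
            {
                "characteristic": "surgeon_volume",
                "level": f"median (IQR): {med(v)} | OS {med(v[y])} | no-OS {med(v[~y])}",
                "n_overall": n,
                "n_os": n_yes,
                "n_no_os": n_no,
                "pct_overall": np.nan,
                "pct_os": np.nan,
                "pct_no_os": np.nan,
                "p_value": float(stat_p),
                "note": "rank-sum test",
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, float_format="%.10g") -> Path:
    df.to_csv(path, index=False, float_format=float_format)
    return path


def run_pipeline(config: PipelineConfig, codes: CodeDictionary | None = None) -> dict:
    """Execute every stage and write outputs + manifest under output_dir."""
    codes = codes or default_codes()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    outputs: dict[str, Path] = {}

    def stage(name, **counts):
        stages.append({"stage": name, **counts})

    # 1. data ---------------------------------------------------------------
    if config.input_dir:
        ind = Path(config.input_dir)
        claims = pd.read_csv(ind / "claims.csv", dtype={"code": str})
        enrollment = pd.read_csv(ind / "enrollment.csv")
        attributes = pd.read_csv(ind / "attributes.csv")
        world = None
    else:
        world = generate_world(config.synthetic, codes)
        paths = write_synthetic(world, outdir / "synthetic")
        outputs.update({f"synthetic/{k}": p for k, p in paths.items()})
        claims, enrollment, attributes = world.claims, world.enrollment, world.attributes
    syn = config.synthetic
    stage("data", n_claims=len(claims), n_enrollees=attributes["enrollee_id"].nunique())

    # 2. cohorts ------------------------------------------------------------
    t1_cohort, t1_report, t1_rejects = cohort_mod.build_cohort(
        claims, enrollment, attributes, codes, "T1", syn.t1_span
    )
    t2_cohort, t2_report, t2_rejects = cohort_mod.build_cohort(
        claims, enrollment, attributes, codes, "T2", syn.t2_span
    )
    t1_candidates, _ = cohort_mod.identify_sterilization_encounters(
        claims, codes, "T1", syn.t1_span
    )
    index_dates = cohort_mod.assign_index_dates(
        attributes, enrollment, t1_candidates, syn.t1_span, config.index_date_seed
    )
    outputs["attrition_t1"] = _write(t1_report.to_frame(), outdir / "attrition_t1.csv")
    outputs["attrition_t2"] = _write(t2_report.to_frame(), outdir / "attrition_t2.csv")
    outputs["rejects_t1"] = _write(t1_rejects, outdir / "rejects_t1.csv")
    outputs["rejects_t2"] = _write(t2_rejects, outdir / "rejects_t2.csv")
    outputs["index_dates"] = _write(index_dates, outdir / "index_dates.csv")
    cohort_cols = [c for c in t2_cohort.columns if c != "codes"]
    outputs["cohort_t1"] = _write(t1_cohort[cohort_cols], outdir / "cohort_t1.csv")
    outputs["cohort_t2"] = _write(t2_cohort[cohort_cols], outdir / "cohort_t2.csv")
    stage(
        "cohort",
        n_t1_eligible=len(t1_cohort),
        n_t2_eligible=len(t2_cohort),
        n_sharing_sample=int(index_dates["in_sharing_sample"].sum()),
    )

    # 3. networks -----------------------------------------------------------
    sample = set(index_dates.loc[index_dates["in_sharing_sample"], "enrollee_id"])
    net = network_mod.build_networks(
        claims,
        syn.t1_span,
        sample_enrollees=sample,
        cap=config.cap,
        min_patients=config.min_patients,
        min_shared=config.min_shared,
        seed=config.louvain_seed,
        resolution=config.resolution,
        weighted=config.weighted_modularity,
    )
    summary = network_mod.summarize_networks(
        net.partitions, net.graphs, t1_cohort[["surgeon_id"]]
    )
    outputs["network_membership"] = _write(net.membership, outdir / "network_membership.csv")
    outputs["network_summary"] = _write(summary, outdir / "network_summary.csv")
    graph_paths = network_mod.export_graphs(net, outdir / "graphs")
    outputs.update({f"graphs/{k}": Path(v) for k, v in graph_paths.items()})
    stage(
        "network",
        n_nodes=sum(g.number_of_nodes() for g in net.graphs.values()),
        n_edges=sum(g.number_of_edges() for g in net.graphs.values()),
        n_networks=len(summary),
    )

    # 4. exposure -----------------------------------------------------------
    profiles = exposure_mod.profile_surgeons(t1_cohort, net.membership)
    exposures = exposure_mod.compute_exposures(profiles, config.min_peer_volume)
    nonuser_t2_surgeons = profiles.loc[profiles["baseline_nonuser"], "physician_id"]
    if config.pool_quartiles:
        cuts, exposures = exposure_mod.assign_quartiles(exposures, nonuser_t2_surgeons)
    else:
        cuts, exposures = exposure_mod.assign_quartiles(exposures)
    outputs["surgeon_profiles"] = _write(profiles, outdir / "surgeon_profiles.csv")
    outputs["exposures"] = _write(exposures, outdir / "exposures.csv")
    stage(
        "exposure",
        n_profiled=len(profiles),
        n_with_exposure=int(exposures["mean_peer_os_rate"].notna().sum()),
        quartile_cuts=list(np.round(cuts, 10)),
    )

    # 5. analysis datasets + models ----------------------------------------
    densities = summary.set_index("network_id")["density"]
    results: dict[str, dict] = {}
    for setting in ("postpartum", "interval"):
        ds = exposure_mod.assemble_analysis_dataset(t2_cohort, profiles, exposures, setting)
        outputs[f"analysis_{setting}"] = _write(
            ds[[c for c in ds.columns if c != "codes"]], outdir / f"analysis_{setting}.csv"
        )
        res: dict = {"n": len(ds)}
        enough = (
            len(ds) >= 50
            and ds["os_flag"].nunique() == 2
            and ds["network_id"].nunique() >= 2
            and ds["quartile"].nunique() >= 2
        )
        if enough:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                retained, screen = model_mod.univariate_screen(
                    ds, alpha=config.alpha_screen
                )
                screen_df = pd.DataFrame([dataclasses.asdict(s) for s in screen])
                fit = model_mod.fit_nested_logistic(
                    ds,
                    model_mod.ModelSpec(fixed_effects=retained),
                    method=config.fit_method,
                )
                null = model_mod.fit_null_model(ds, method=config.fit_method)
                dec = model_mod.variance_decomposition(
                    null,
                    ds,
                    n_boot=config.bootstrap_reps,
                    seed=config.bootstrap_seed,
                )
            outputs[f"screen_{setting}"] = _write(screen_df, outdir / f"screen_{setting}.csv")
            outputs[f"fit_{setting}"] = _write(
                fit.params.round(6), outdir / f"fit_{setting}.csv"
            )
            outputs[f"variance_{setting}"] = _write(
                dec.as_frame().round(6), outdir / f"variance_{setting}.csv"
            )
            forest = fit.params[fit.params["term"].str.startswith("quartile[")]
            outputs[f"forest_{setting}"] = _write(
                forest.round(6), outdir / f"forest_{setting}.csv"
            )
            res.update(
                converged=fit.converged,
                sigma2_surgeon=null.sigma2_surgeon,
                sigma2_network=null.sigma2_network,
                retained_covariates=retained,
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, wald, wald_p = model_mod.density_interaction_fit(
                        ds, model_mod.ModelSpec(fixed_effects=retained), densities,
                        method=config.fit_method,
                    )
                res.update(density_interaction_wald=wald, density_interaction_p=wald_p)
            except (ValueError, np.linalg.LinAlgError) as err:
                res.update(density_interaction_error=str(err))
        else:
            res["skipped"] = "dataset too small or degenerate for modeling"
        table = make_cohort_table(ds) if len(ds) else pd.DataFrame()
        outputs[f"cohort_table_{setting}"] = _write(
            table, outdir / f"cohort_table_{setting}.csv"
        )
        results[setting] = res
    stage("model", **{k: v.get("n", 0) for k, v in results.items()})
    stage("report", n_outputs=len(outputs))

    # 6. manifest -----------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "stages": stages,
        "results": results,
        "outputs": {
            name: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for name, p in sorted(outputs.items())
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_jsonable) + "\n"
    )
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
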