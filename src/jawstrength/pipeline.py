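"""End-to-end pipeline: from a study bundle to the report tables.

Stages (each writes restartable CSV artifacts when an output directory is
configured):

1. ``linear``   — scaled PCA of the five measurements, sequential MANOVA
   (method, location, interaction), per-population morphospace distances
   and shrinkage/age correlations.
2. ``gmm``      — sliding-semilandmark GPA (dentary) and fixed-landmark GPA
   (mandible), shape PCA, Procrustes ANOVA, population mean shapes.
3. ``warp``     — TPS warp of the reference meshes to each population mean,
   scaled to average population size and canonically oriented.
4. ``ma``       — lever mechanical advantage per population (weighted total
   and adductor-only), plus the same from a pre-measured lever table.
5. ``fe``       — tet meshing and linear-elastic strength scores for the
   three load cases.
6. ``validate`` — log-scale population summaries, Kendall correlations of
   in silico vs in vivo, and RRPP bite~size*method models with z-scored
   variants.

The pipeline is a pure function of (inputs, config, seed): rerunning with
the same seed reproduces every table exactly.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import JawstrengthError, StudyConfig, records_frame
from .linear_morpho import (
    manova_pillai,
    scaled_pca,
    shrinkage_correlations,
    shrinkage_summary,
)
from .gmm import gpa, mean_shape, procrustes_anova, shape_pca, slide_semilandmarks
from .warping import WarpedJaw, fit_tps, scale_and_orient, warp_mesh
from .mechanical_advantage import (
    adductor_ma,
    default_muscles,
    levers_from_table,
    measure_levers,
    weighted_ma,
)
from .fe_strength import (
    Material,
    build_load_case,
    solve_elasticity,
    strength_score,
    tetrahedralise,
)
from .validation_stats import (
    kendall_tau_b,
    normality_check,
    rrpp_lm,
    summarise_populations,
    zscore_standardise,
)
from .synthetic_data import (
    BITE_LANDMARK,
    HINGE_LANDMARK,
    GeneratorParams,
    StudyBundle,
    generate_study,
    jaw_muscle_geometry,
)

__all__ = ["ReportBundle", "PipelineStageError", "run_pipeline"]


class PipelineStageError(JawstrengthError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ReportBundle:
    """Machine-readable result tables plus the run log."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    verdicts: dict[str, dict] = field(default_factory=dict)
    run_log: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv")
        payload = {"run_log": self.run_log, "verdicts": self.verdicts}
        (out / "run.json").write_text(json.dumps(payload, indent=2, default=str))


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except JawstrengthError as exc:
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


@_stage("linear")
def _run_linear(bundle: StudyBundle, config: StudyConfig, rng) -> dict:
    records = bundle.records
    pca = scaled_pca(records)
    df = records_frame(records)
    manova = manova_pillai(
        np.array([r.measurements for r in records]),
        df["method"].to_numpy(),
        df["population"].to_numpy(),
    )
    shrink = shrinkage_summary(
        records,
        pca.scores,
        df["method"].to_numpy(),
        df["population"].to_numpy(),
        n_perm=config.n_permutations,
        rng=rng,
    )
    corr = shrinkage_correlations(shrink)
    pca_summary = pd.DataFrame(
        {
            "variance_fraction": pca.variance_fraction,
            **{
                f"loading_{v}": pca.loadings[i]
                for i, v in enumerate(pca.variables)
            },
        },
        index=[f"PC{i + 1}" for i in range(len(pca.variance_fraction))],
    )
    return {
        "pca": pca,
        "tables": {
            "linear_pca_summary": pca_summary,
            "manova": manova,
            "shrinkage": shrink,
            "shrinkage_correlations": corr,
        },
    }


@_stage("gmm")
def _run_gmm(bundle: StudyBundle, config: StudyConfig, rng) -> dict:
    meta = bundle.specimen_meta
    pops = sorted(meta["population"].unique())
    sample_mask = (
        np.ones(len(meta), dtype=bool)
        if config.sex_filter == "total"
        else (meta["sex"] == "male").to_numpy()
    )
    out: dict = {"tables": {}, "fits": {}, "means": {}, "sizes": {}}
    for bone, sets in (("mandible", bundle.mandible_sets), ("dentary", bundle.dentary_sets)):
        if bone == "mandible":
            configs = np.stack([ls.fixed for ls in sets])
            fit = gpa(configs)
        else:
            configs, fit, _ = slide_semilandmarks(
                sets,
                n_iterations=config.n_slide_iterations,
                semilandmark_range=config.semilandmark_range,
            )
        space = shape_pca(fit)
        anova = procrustes_anova(
            fit, meta["population"].to_numpy(), n_perm=config.n_permutations, rng=rng
        )
        out["tables"][f"shape_pca_{bone}"] = pd.DataFrame(
            {"variance_fraction": space.variance_fraction},
            index=[f"PC{i + 1}" for i in range(space.n_axes)],
        )
        out["tables"][f"procrustes_anova_{bone}"] = anova
        out["fits"][bone] = fit
        # population means (of the configured sample) and average sizes,
        # measured as the anterior-posterior landmark distance in original mm
        means, sizes = {}, {}
        for pop in pops:
            idx = np.where((meta["population"] == pop).to_numpy() & sample_mask)[0]
            if idx.size == 0:
                raise JawstrengthError(
                    f"population {pop!r} has no {config.sex_filter} specimens"
                )
            means[pop] = mean_shape(fit, idx)
            a_idx, p_idx = (0, 2)
            sizes[pop] = float(
                np.mean(
                    [
                        np.linalg.norm(configs[i][a_idx] - configs[i][p_idx])
                        for i in idx
                    ]
                )
            )
        out["means"][bone] = means
        out["sizes"][bone] = sizes
    return out


@_stage("warp")
def _run_warp(bundle: StudyBundle, config: StudyConfig, gmm_out: dict) -> dict:
    jaws: dict[str, dict[str, WarpedJaw]] = {"mandible": {}, "dentary": {}}
    ref = {
        "mandible": (bundle.reference_mandible, bundle.reference_mandible_landmarks),
        "dentary": (
            bundle.reference_dentary,
            None,  # assembled below to match the slid configuration layout
        ),
    }
    # reference dentary landmarks must match the mean-shape layout; recover
    # the per-curve semilandmark count from the mean shape itself
    from .gmm import resample_curve

    rd = bundle.reference_dentary_landmarks
    k_mean = next(iter(gmm_out["means"]["dentary"].values())).shape[0]
    per_curve = (k_mean - rd.fixed.shape[0]) // len(rd.curves)
    targets = [per_curve] * len(rd.curves)
    dent_ref_lms = np.vstack(
        [rd.fixed, *[resample_curve(c, t) for c, t in zip(rd.curves, targets)]]
    )
    ref["dentary"] = (bundle.reference_dentary, dent_ref_lms)

    rows = []
    for bone in ("dentary", "mandible"):
        mesh, ref_lms = ref[bone]
        for pop, mean in gmm_out["means"][bone].items():
            tps = fit_tps(ref_lms, mean)
            warped = warp_mesh(tps, mesh)
            jaw = WarpedJaw(pop, bone, config.sex_filter, warped, tps(ref_lms))
            jaw = scale_and_orient(jaw, gmm_out["sizes"][bone][pop])
            jaws[bone][pop] = jaw
            rows.append(
                {
                    "population": pop,
                    "bone": bone,
                    "sample": config.sex_filter,
                    "scale_length_mm": jaw.scale_length,
                    "bending_energy": tps.bending_energy,
                }
            )
    return {"jaws": jaws, "tables": {"warp_report": pd.DataFrame(rows)}}


@_stage("ma")
def _run_ma(bundle: StudyBundle, config: StudyConfig, warp_out: dict) -> dict:
    rows = []
    for pop, jaw in warp_out["jaws"]["mandible"].items():
        lm = jaw.landmarks
        ins, lines = jaw_muscle_geometry(lm)
        muscles = default_muscles(ins, lines, config.muscle_weights)
        levers = measure_levers(lm[HINGE_LANDMARK], lm[BITE_LANDMARK], muscles)
        rows.append(
            {
                "population": pop,
                "total_ma": weighted_ma(levers, config.muscle_weights),
                "adductor_ma": adductor_ma(levers),
            }
        )
    ma = pd.DataFrame(rows).set_index("population").sort_index()
    # independent route: pre-measured lever table (if provided)
    if bundle.lever_table is not None and len(bundle.lever_table):
        vals = []
        for pop in ma.index:
            levers = levers_from_table(bundle.lever_table, pop)
            vals.append(weighted_ma(levers, config.muscle_weights))
        ma["total_ma_from_table"] = vals
    return {"tables": {"ma_table": ma}, "ma": ma}


@_stage("fe")
def _run_fe(bundle: StudyBundle, config: StudyConfig, warp_out: dict) -> dict:
    material = Material(config.young_modulus, config.poisson_ratio)
    rows = []
    for pop in sorted(warp_out["jaws"]["dentary"]):
        row = {"population": pop}
        for bone, cases in (
            ("dentary", ["dentary_bite_load"]),
            ("mandible", ["mandible_muscle_load", "mandible_no_muscle"]),
        ):
            jaw = warp_out["jaws"][bone][pop]
            length = jaw.scale_length
            tet = tetrahedralise(jaw.mesh, config.fe_edge_fraction * length)
            lm = jaw.landmarks
            bite = lm[BITE_LANDMARK if bone == "mandible" else 1]
            ins, lines = jaw_muscle_geometry(lm) if bone == "mandible" else (None, None)
            muscles = (
                default_muscles(ins, lines, config.muscle_weights)
                if bone == "mandible"
                else None
            )
            for case_name in cases:
                case = build_load_case(case_name, tet, bite, muscles)
                res = solve_elasticity(tet, material, case)
                row[f"strength_{case_name}"] = strength_score(
                    res, config.stress_quantile
                )
        rows.append(row)
    fe = pd.DataFrame(rows).set_index("population")
    return {"tables": {"fe_table": fe}, "fe": fe}


@_stage("validate")
def _run_validate(
    bundle: StudyBundle, config: StudyConfig, gmm_out, ma_out, fe_out, rng
) -> dict:
    strengths = ma_out["ma"][["total_ma", "adductor_ma"]].copy()
    strengths["fe_dentary"] = fe_out["fe"]["strength_dentary_bite_load"]
    strengths["fe_mandible_muscles"] = fe_out["fe"]["strength_mandible_muscle_load"]
    strengths["fe_mandible_no_muscles"] = fe_out["fe"]["strength_mandible_no_muscle"]
    strengths["dentary_length"] = pd.Series(gmm_out["sizes"]["dentary"])
    strengths["mandible_length"] = pd.Series(gmm_out["sizes"]["mandible"])
    summary = summarise_populations(bundle.records, strengths, config.sex_filter)

    estimates = {
        "total_ma": "mandible_length",
        "adductor_ma": "mandible_length",
        "fe_dentary": "dentary_length",
        "fe_mandible_muscles": "mandible_length",
        "fe_mandible_no_muscles": "mandible_length",
    }
    kend_rows, anova_tables, verdicts = [], {}, {}
    bite = summary["log_bite"].to_numpy()
    for est, size_col in estimates.items():
        vals = summary[f"log_{est}"].to_numpy()
        kr = kendall_tau_b(vals, bite)
        kend_rows.append(
            {
                "estimate": est,
                "statistic": kr.statistic,
                "statistic_name": kr.statistic_name,
                "tau": kr.tau,
                "p": kr.p,
                "ties": kr.ties,
            }
        )
        y = np.concatenate([bite, vals])
        size = np.concatenate(
            [summary["log_size_vivo"].to_numpy(), summary[f"log_{size_col}"].to_numpy()]
        )
        method = np.array(["in_vivo"] * len(bite) + ["in_silico"] * len(vals))
        table, verdict = rrpp_lm(y, size, method, config.n_permutations, rng)
        anova_tables[f"anova_{est}"] = table
        z = zscore_standardise(y, method)
        table_z, verdict_z = rrpp_lm(z, size, method, config.n_permutations, rng)
        anova_tables[f"anova_{est}_zscored"] = table_z
        verdicts[est] = {"raw": verdict, "zscored": verdict_z}
    w_bite, p_bite = normality_check(bite)
    tables = {
        "population_summary": summary,
        "kendall_table": pd.DataFrame(kend_rows).set_index("estimate"),
        **anova_tables,
    }
    return {
        "tables": tables,
        "verdicts": verdicts,
        "normality": {"W": w_bite, "p": p_bite},
    }


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


STAGES = ("linear", "gmm", "warp", "ma", "fe", "validate")


def run_pipeline(
    config: StudyConfig,
    bundle: StudyBundle | None = None,
    generator_params: GeneratorParams | None = None,
    stop_after: str | None = None,
) -> ReportBundle:
    """Run the full analysis and return the report bundle.

    Inputs are taken from ``bundle`` if given; otherwise a synthetic study
    is generated from ``generator_params`` (seeded from the config).
    ``stop_after`` truncates the run after the named stage (one of
    ``STAGES``), writing only the tables produced so far.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise JawstrengthError(f"unknown stage {stop_after!r}; choose from {STAGES}")
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in seeds]
    if bundle is None:
        params = generator_params or GeneratorParams(seed=config.seed)
        bundle = generate_study(params)

    report = ReportBundle()
    report.run_log = {
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "sex_filter": config.sex_filter,
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "gpa_tolerance": 1e-10,
        "fe_edge_fraction": config.fe_edge_fraction,
        "stress_quantile": config.stress_quantile,
    }

    def finish() -> ReportBundle:
        if config.out_dir is not None:
            report.write(config.out_dir)
        return report

    linear = _run_linear(bundle, config, rngs[0])
    report.tables.update(linear["tables"])
    if stop_after == "linear":
        return finish()
    gmm_out = _run_gmm(bundle, config, rngs[1])
    report.tables.update(gmm_out["tables"])
    if stop_after == "gmm":
        return finish()
    warp_out = _run_warp(bundle, config, gmm_out)
    report.tables.update(warp_out["tables"])
    if stop_after == "warp":
        return finish()
    ma_out = _run_ma(bundle, config, warp_out)
    report.tables.update(ma_out["tables"])
    if stop_after == "ma":
        return finish()
    fe_out = _run_fe(bundle, config, warp_out)
    report.tables.update(fe_out["tables"])
    if stop_after == "fe":
        return finish()
    val = _run_validate(bundle, config, gmm_out, ma_out, fe_out, rngs[2])
    report.tables.update(val["tables"])
    report.verdicts = val["verdicts"]
    report.run_log["normality_bite"] = val["normality"]
    return finish()
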