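"""Seeded, configured pipeline runs.

Orchestrates phantom/cohort generation, structural parameters, FE strength,
fracture adjudication, the statistical battery and the anatomical surface
maps into one reproducible run directory with a checksummed manifest.
Stages run in dependency order; a stage whose upstream artifact is missing
fails with an error naming that stage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from . import stats as hstats
from .cohort import CohortConfig, generate_cohort_table, generate_vertex_maps, \
    reference_roster
from .fe import MaterialLaw
from .fractures import apply_cohort_filters, classify_event
from .maps import local_ct_vbmd, nodewise_compare
from .phantom import PhantomConfig, generate_phantom
from .structural import cortical_surface_measures, structural_params

log = logging.getLogger(__name__)

ALL_STAGES = ("phantom", "cohort", "params", "strength", "adjudicate",
              "stats", "maps")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_subjects: int = 740
    out_dir: str = "hipfe_run"
    stages: tuple = ALL_STAGES
    n_param_subjects: int = 5     # phantoms passed through structural params
    n_fe_subjects: int = 2        # phantoms solved with the FE model
    fe_increments: int = 10
    phantom: PhantomConfig = PhantomConfig()
    material: MaterialLaw = MaterialLaw()

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(n_subjects=self.n_subjects, seed=self.seed,
                            phantom=self.phantom)


def _render_reclass(pdta, path):
    """Strength-vs-T-score scatter with osteoporosis/osteopenia and
    fragile/very-fragile threshold lines; fracture cases highlighted."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    tab = pdta.table
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    ctrl = tab[tab.event == 0]
    case = tab[tab.event == 1]
    ax.scatter(ctrl.t_score, ctrl.strength, s=8, c="0.7", label="no fracture")
    hip = case[case.get("site", pd.Series(index=case.index, dtype=object))
               == "proximal_femur"] if "site" in case else case.iloc[0:0]
    other = case.drop(hip.index) if len(hip) else case
    ax.scatter(other.t_score, other.strength, s=14, c="tab:orange",
               label="fracture")
    if len(hip):
        ax.scatter(hip.t_score, hip.strength, s=18, c="tab:red",
                   label="hip fracture")
    for t in pdta.t_thresholds:
        ax.axvline(t, color="k", lw=0.8, ls="--")
    for s in pdta.strength_thresholds:
        ax.axhline(s, color="k", lw=0.8, ls=":")
    ax.set_xlabel("T-score (SD)")
    ax.set_ylabel("fall strength (N)")
    ax.set_title(f"reclassification, outcome={pdta.outcome}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _require(path: Path, stage: str, needed_by: str):
    if not path.exists():
        raise FileNotFoundError(
            f"stage {needed_by!r} requires the output of stage {stage!r} "
            f"({path.name}); run it first or enable it in the config")


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages; returns the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = hio.config_hash(config)
    outputs: dict[str, Path] = {}
    stages = set(config.stages)

    def table_path(name):
        return out / f"{name}.csv"

    if "phantom" in stages:
        ph = generate_phantom(config.phantom, 0.0, seed=config.seed)
        p_img = out / "phantom_mean.mhd"
        hio.write_image(ph.image, ph.spacing, ph.origin, p_img)
        p_mesh = out / "phantom_mesh.ply"
        hio.write_mesh(ph.mesh, p_mesh)
        outputs["phantom_image"] = p_img
        outputs["phantom_raw"] = p_img.with_suffix(".raw")
        outputs["phantom_mesh"] = p_mesh
        log.info("phantom stage: wrote %s", p_img)

    if "cohort" in stages:
        df = generate_cohort_table(config.cohort_config())
        hio.write_table(df, table_path("cohort"), config.seed, chash, "cohort")
        outputs["cohort"] = table_path("cohort")
        log.info("cohort stage: %d subjects, %d LT events, %d MOF",
                 len(df), df.event_lt.sum(), df.event_mof.sum())

    if "params" in stages:
        _require(table_path("cohort"), "cohort", "params")
        df = hio.read_table(table_path("cohort"))
        rows = []
        for i in range(min(config.n_param_subjects, len(df))):
            ph = generate_phantom(config.phantom, df.latent_quality[i],
                                  seed=config.seed + i)
            sp = structural_params(ph)
            row = dataclasses.asdict(sp)
            row["id"] = df.id[i]
            rows.append(row)
        hio.write_table(pd.DataFrame(rows), table_path("structural_params"),
                        config.seed, chash, "params")
        outputs["structural_params"] = table_path("structural_params")

    if "strength" in stages:
        _require(table_path("cohort"), "cohort", "strength")
        from .fe import build_fe_model, reposition_fall, reposition_stance, \
            solve_strength
        df = hio.read_table(table_path("cohort"))
        rows, curves = [], []
        for i in range(min(config.n_fe_subjects, len(df))):
            ph = generate_phantom(config.phantom, df.latent_quality[i],
                                  seed=config.seed + i)
            res = {}
            for case, repose in (("fall", reposition_fall),
                                 ("stance", reposition_stance)):
                posed, _ = repose(ph)
                model = build_fe_model(posed, case, config.material)
                res[case] = solve_strength(model, config.fe_increments,
                                           law=config.material)
                for d, f in zip(res[case].displacement_steps,
                                res[case].reaction_force):
                    curves.append({"id": df.id[i], "load_case": case,
                                   "displacement_mm": d, "reaction_n": f})
            rows.append({"id": df.id[i],
                         "strength_fall_fe": res["fall"].strength,
                         "strength_stance_fe": res["stance"].strength})
        hio.write_table(pd.DataFrame(rows), table_path("fe_strength"),
                        config.seed, chash, "strength")
        hio.write_table(pd.DataFrame(curves), table_path("fe_curves"),
                        config.seed, chash, "strength")
        outputs["fe_strength"] = table_path("fe_strength")
        outputs["fe_curves"] = table_path("fe_curves")

    if "adjudicate" in stages:
        roster = reference_roster()
        analysis, counts = apply_cohort_filters(roster)
        n_lt = n_mof = 0
        for entry in analysis:
            cls = [classify_event(ev) for ev in entry.events]
            if any(c.is_lt for c in cls):
                n_lt += 1
            if any(c.is_mof for c in cls):
                n_mof += 1
        summary = {"recruited": len(roster), "analyzed": len(analysis),
                   "exclusions": counts, "lt_fractures": n_lt, "mof": n_mof}
        import json
        p = out / "adjudication.json"
        p.write_text(json.dumps(summary, indent=2))
        outputs["adjudication"] = p

    if "stats" in stages:
        _require(table_path("cohort"), "cohort", "stats")
        df = hio.read_table(table_path("cohort"))
        predictors = ["th_abmd", "fn_abmd", "strength_fall", "strength_stance",
                      "th_vbmd", "fn_vbmd", "th_tb_vbmd", "fn_tb_vbmd",
                      "th_ct_vbmd", "fn_ct_vbmd", "th_ct_sbmd", "fn_ct_sbmd",
                      "th_cth", "fn_cth", "fn_csa", "fn_csmi", "fn_z"]

        # baseline group comparison (controls vs LT cases vs MOF cases)
        rows = []
        controls = df[df.event_lt == 0]
        for pred in predictors + ["age", "bmi"]:
            row = {"parameter": pred,
                   "control_mean": controls[pred].mean(),
                   "control_sd": controls[pred].std()}
            for outc in ("lt", "mof"):
                cases = df[df[f"event_{outc}"] == 1]
                row[f"{outc}_mean"] = cases[pred].mean()
                row[f"{outc}_sd"] = cases[pred].std()
                row[f"{outc}_p"] = hstats.group_compare(controls[pred], cases[pred])
            rows.append(row)
        hio.write_table(pd.DataFrame(rows), table_path("group_compare"),
                        config.seed, chash, "stats")
        outputs["group_compare"] = table_path("group_compare")

        rows = []
        for pred in predictors:
            for outc in ("lt", "mof"):
                f = hstats.cox_per_sd(df, pred, outc)
                rows.append({"predictor": pred, "outcome": outc,
                             "hr_per_sd": f.hr_per_sd_decrease,
                             "ci_lo": f.ci95[0], "ci_hi": f.ci95[1],
                             "p": f.p_value, "c_index": f.c_index})
        hio.write_table(pd.DataFrame(rows), table_path("cox_per_sd"),
                        config.seed, chash, "stats")
        outputs["cox_per_sd"] = table_path("cox_per_sd")

        # age-adjusted discrimination of the best parameters vs aBMD
        rows = []
        for outc in ("lt", "mof"):
            ref_fits = {r: hstats.cox_per_sd(df, p, outc, adjust_age=True)
                        for r, p in (("th_abmd", "th_abmd"),
                                     ("fn_abmd", "fn_abmd"))}
            for pred in ("th_abmd", "fn_abmd", "strength_fall", "th_vbmd",
                         "th_tb_vbmd"):
                f = hstats.cox_per_sd(df, pred, outc, adjust_age=True)
                row = {"predictor": pred, "outcome": outc,
                       "hr_per_sd": f.hr_per_sd_decrease, "p": f.p_value,
                       "c_index": f.c_index, "c_lo": f.c_index_ci[0],
                       "c_hi": f.c_index_ci[1]}
                for ref_name, ref in ref_fits.items():
                    row[f"p_vs_{ref_name}"] = (
                        np.nan if pred == ref_name
                        else hstats.compare_c(f, ref))
                rows.append(row)
        hio.write_table(pd.DataFrame(rows), table_path("c_comparison"),
                        config.seed, chash, "stats")
        outputs["c_comparison"] = table_path("c_comparison")

        sweep = hstats.nri_sweep(df)
        hio.write_table(sweep, table_path("nri_sweep"), config.seed, chash, "stats")
        outputs["nri_sweep"] = table_path("nri_sweep")

        rows = []
        for rule in hstats.THRESHOLD_RULES:
            for outc in ("lt", "mof"):
                try:
                    f = hstats.threshold_cox(df, rule, outc)
                except (ValueError, RuntimeError) as exc:
                    log.warning("threshold model %s/%s skipped: %s", rule, outc, exc)
                    continue
                rows.append({"rule": rule, "outcome": outc,
                             "hr": f.hr_per_sd_decrease, "ci_lo": f.ci95[0],
                             "ci_hi": f.ci95[1], "p": f.p_value,
                             "c_index": f.c_index})
        hio.write_table(pd.DataFrame(rows), table_path("threshold_cox"),
                        config.seed, chash, "stats")
        outputs["threshold_cox"] = table_path("threshold_cox")

        for outc in ("lt", "mof"):
            pdta = hstats.reclass_plot_data(df, outc)
            hio.write_table(pdta.table, table_path(f"reclass_{outc}"),
                            config.seed, chash, "stats")
            outputs[f"reclass_{outc}"] = table_path(f"reclass_{outc}")
            png = out / f"reclass_{outc}.png"
            _render_reclass(pdta, png)
            outputs[f"reclass_{outc}_png"] = png

    if "maps" in stages:
        _require(table_path("cohort"), "cohort", "maps")
        df = hio.read_table(table_path("cohort"))
        template = generate_phantom(config.phantom, 0.0, seed=config.seed)
        cth0, sbmd0, _ = cortical_surface_measures(template)
        ok = np.isfinite(cth0) & np.isfinite(sbmd0)
        cth0 = np.where(ok, cth0, np.nanmean(cth0))
        sbmd0 = np.where(ok, sbmd0, np.nanmean(sbmd0))
        cth_maps, sbmd_maps = generate_vertex_maps(
            df, cth0, sbmd0, config.cohort_config())
        case = df.event_mof.to_numpy() == 1
        if case.sum() >= 2 and (~case).sum() >= 2:
            from .maps import render_map, write_map_ply
            for name, maps_arr in (("cth", cth_maps), ("sbmd", sbmd_maps),
                                   ("ct_vbmd", local_ct_vbmd(sbmd_maps, cth_maps))):
                m = nodewise_compare(maps_arr[case], maps_arr[~case], name)
                hio.write_table(m.to_frame(), table_path(f"map_{name}"),
                                config.seed, chash, "maps")
                outputs[f"map_{name}"] = table_path(f"map_{name}")
                ply = out / f"map_{name}.ply"
                write_map_ply(template.mesh, m, ply)
                outputs[f"map_{name}_ply"] = ply
                png = out / f"map_{name}.png"
                render_map(template.mesh, m, png)
                outputs[f"map_{name}_png"] = png
        else:
            log.warning("maps stage skipped: fewer than 2 cases or controls")

    manifest = hio.write_manifest(outputs, out / "manifest.json",
                                  config.seed, chash)
    return manifest
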