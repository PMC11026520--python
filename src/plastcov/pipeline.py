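"""One-command end-to-end driver.

Stage order mirrors the analysis sequence: synthesize (optional) ->
change-matrix construction and deconfounding -> PLSC with permutation
significance -> bootstrap hemisphere contrast -> phenome-wide screen and
mode retention -> age-binned ranking and expression trends. All randomness
derives from the single run seed through named per-stage substreams, so a
rerun with the same config reproduces every output bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import deconfound, io, phewas, plsc, ranking, synth
from .config import RunConfig
from .contrast import bootstrap_hemisphere_contrast, select_lateralized
from .registry import amygdala_labels, brain_labels, split_hemispheres

log = logging.getLogger("plastcov")

STAGES = ("synth", "deconfound", "plsc", "contrast", "phewas", "ranking")


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {name: int(s % 2**31) for name, s in zip(STAGES, state)}


def _synth_config(cfg: RunConfig, seed: int) -> synth.SynthConfig:
    K = cfg.n_modes
    asym = np.zeros((K, 9))
    asym[0, :] = np.asarray(cfg.asymmetry_mode_1, dtype=float)
    phen_spec = []
    for i in range(cfg.n_phenotypes):
        mode = i % K if i < 3 * K else None  # first few coupled, rest noise
        phen_spec.append(
            synth.PhenotypeSpec(
                mode=mode,
                effect=cfg.phenotype_effect if mode is not None else 0.0,
                datatype=["numerical", "binary", "categorical-ordered"][i % 3],
                missing_rate=0.05,
                category=f"domain_{i % 11 + 1}",
            )
        )
    return synth.SynthConfig(
        n_subjects=cfg.n_subjects,
        n_modes=K,
        mode_strengths=list(cfg.mode_strengths)[:K],
        noise_sd=cfg.noise_sd,
        confound_effects=dict(cfg.confound_effects),
        asymmetry=asym,
        phenotype_spec=phen_spec,
        seed=seed,
    )


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages, writing TSV/JSON outputs and a checksum manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    timings: dict[str, float] = {}
    t0 = time.time()

    def _tick(stage: str) -> None:
        timings[stage] = round(time.time() - t0, 3)
        log.info("stage %s done at %.1fs", stage, timings[stage])

    try:
        # --- synth (or load) ---
        if cfg.cohort_csv:
            cohort = io.read_table(cfg.cohort_csv)
        else:
            scfg = _synth_config(cfg, seeds["synth"])
            cohort, _truth = synth.generate_cohort(scfg)
            io.write_table(cohort, out / "cohort.csv")
        _tick("synth")

        # --- deconfound ---
        am_labels = amygdala_labels()
        br_labels = brain_labels()
        am_raw, am_std = deconfound.prepare_change_matrix(
            cohort, am_labels, cfg.include_site, cfg.include_position
        )
        _, br_std = deconfound.prepare_change_matrix(
            cohort, br_labels, cfg.include_site, cfg.include_position
        )
        io.write_change_matrix(am_std, out / "am_change_std.tsv")
        io.write_change_matrix(br_std, out / "brain_change_std.tsv")
        io.write_change_matrix(am_raw, out / "am_change_raw.tsv")
        _tick("deconfound")

        # --- plsc ---
        L = cfg.n_pls_modes
        model = plsc.fit_plsc_with_significance(
            am_std, br_std, L,
            n_perm=cfg.n_perm,
            seed=np.random.default_rng(seeds["plsc"]),
        )
        io.write_table(model.V, out / "plsc_V.tsv")
        io.write_table(model.U, out / "plsc_U.tsv")
        io.write_table(model.LX, out / "plsc_scores_x.tsv")
        io.write_table(model.LY, out / "plsc_scores_y.tsv")
        (out / "plsc_summary.json").write_text(
            json.dumps(
                {
                    "singular_values": model.singular_values.tolist(),
                    "mode_correlations": model.mode_correlations.tolist(),
                    "explained_covariance_fraction": model.explained_covariance_fraction.tolist(),
                    "perm_pvalues": model.perm_pvalues.tolist(),
                    "n_perm": cfg.n_perm,
                },
                indent=2,
            )
        )
        _tick("plsc")

        # --- contrast ---
        left_labels, right_labels = split_hemispheres(am_labels)
        am_left = am_std.subset(left_labels)
        am_right = am_std.subset(right_labels)
        boot = bootstrap_hemisphere_contrast(
            am_left, am_right, br_std, L,
            n_boot=cfg.n_boot,
            seed=np.random.default_rng(seeds["contrast"]),
            lower_pct=cfg.ci_lower_pct,
            upper_pct=cfg.ci_upper_pct,
        )
        io.write_table(boot.table("amygdala"), out / "contrast_amygdala.tsv", index=False)
        io.write_table(boot.table("brain"), out / "contrast_brain.tsv", index=False)
        io.write_table(select_lateralized(boot), out / "contrast_selected.tsv", index=False)
        _tick("contrast")

        # --- phewas ---
        phen_cols = [c for c in cohort.columns if c.startswith("phen_")]
        scfg_dtypes = {c: "numerical" for c in phen_cols}
        if not cfg.cohort_csv:
            for i, c in enumerate(phen_cols):
                scfg_dtypes[c] = ["numerical", "binary", "categorical-ordered"][i % 3]
        raw_phen = phewas.PhenotypeTable(
            values=cohort[phen_cols],
            datatypes=scfg_dtypes,
            categories={c: f"domain_{i % 11 + 1}" for i, c in enumerate(phen_cols)},
        )
        harm = phewas.harmonize(raw_phen, min_complete=min(500, cfg.n_subjects // 2))
        results = [
            phewas.screen(model.LY.iloc[:, l], harm, alpha=cfg.alpha, fdr_q=cfg.fdr_q)
            for l in range(L)
        ]
        retained = phewas.select_modes(
            model.perm_pvalues, results, perm_alpha=cfg.perm_alpha
        )
        for l, res in enumerate(results):
            io.write_table(res.table, out / f"phewas_mode_{l + 1}.tsv", index=False)
            io.write_table(
                phewas.manhattan_table(res), out / f"manhattan_mode_{l + 1}.tsv",
                index=False,
            )
        io.write_table(
            pd.DataFrame(harm.drop_log), out / "phewas_drop_log.tsv", index=False
        )
        (out / "retained_modes.json").write_text(
            json.dumps({"retained_modes": [l + 1 for l in retained]})
        )
        _tick("phewas")

        # --- ranking ---
        rank = ranking.rank_subregion_change(
            am_raw, cohort["cov_age"], bins=cfg.age_bins
        )
        io.write_table(rank.table, out / "ranking.tsv", index=False)
        mode_for_trend = (retained[0] if retained else 0)
        trend = ranking.expression_trend(
            model.LY.iloc[:, mode_for_trend],
            cohort["cov_age"],
            cohort["cov_sex"],
            n_boot=max(100, cfg.n_boot),
            seed=np.random.default_rng(seeds["ranking"]),
        )
        io.write_table(trend.cells, out / "trend_cells.tsv", index=False)
        io.write_table(trend.lines, out / "trend_lines.tsv", index=False)
        _tick("ranking")
    except Exception as exc:
        done = list(timings)
        stage = STAGES[len(done)] if len(done) < len(STAGES) else "finalize"
        raise RuntimeError(
            f"pipeline aborted in stage {stage!r} (completed: {done}); "
            f"partial outputs retained in {out}"
        ) from exc

    io.write_manifest(
        out,
        {
            "seed": cfg.seed,
            "stage_seeds": seeds,
            "timings_s": timings,
            "config": cfg.__dict__,
        },
    )
    return out
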