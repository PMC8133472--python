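"""End-to-end pipeline: regions -> standardization -> null tests -> ordination -> summaries.

One master seed drives every stage; per-stage (and per-region) seeds are
derived by stable hashing of stage labels, so two runs with the same
config and seed produce identical result tables.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import OccurrenceMatrix, RegionSpec, SpeciesInfo, Survey
from .io import RunConfig, file_digest, read_dataset
from .ordination import (
    dbrda_marginal,
    env_distance,
    env_pcoa_axes,
    survey_turnover_distance,
    turnover_env_regression,
)
from .regions import build_regions, comparison_pairs
from .resampling import fisher_combine, null_test, standardized_subsample
from .summaries import rarity_filter, richness_comparison, venn_shares
from .synthetic import GeneratorParams, generate_dataset

__all__ = ["derive_seed", "run_pipeline", "load_inputs"]

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, label: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def load_inputs(
    config: RunConfig,
) -> tuple[OccurrenceMatrix, list[Survey], list[SpeciesInfo], dict | None]:
    """Load the configured input tables, or simulate when none are given."""
    if config.occurrence and config.surveys:
        occ, surveys, species = read_dataset(
            config.occurrence, config.surveys, config.species
        )
        return occ, surveys, species, None
    overrides = dict(config.simulate or {})
    overrides.setdefault("seed", derive_seed(config.seed, "simulate"))
    params = GeneratorParams(**overrides)
    occ, surveys, species, truth = generate_dataset(params)
    return occ, surveys, species, truth


def _env_table(surveys: Sequence[Survey], env_vars: list[str] | None) -> pd.DataFrame:
    rows = {s.survey_id: s.env for s in surveys}
    table = pd.DataFrame.from_dict(rows, orient="index")
    if env_vars:
        missing = set(env_vars) - set(table.columns)
        if missing:
            raise ValueError(f"configured env variables absent: {sorted(missing)}")
        table = table[list(env_vars)]
    return table


def _region_matrix(
    occ: OccurrenceMatrix, region: RegionSpec, min_occ: int
) -> OccurrenceMatrix:
    # min_occ = 1 makes the filter the identity on the region submatrix
    return rarity_filter(occ, region, min_occ=min_occ)


STAGES = ("regions", "beta", "env", "richness", "venn", "dbrda")


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    stages: Sequence[str] | None = None,
) -> Path:
    """Run the selected stages (default: all) for every configured buffer.

    Result tables are written per buffer radius; one manifest records the
    config, master seed and derived stage seeds.
    """
    selected = set(STAGES if stages is None else stages)
    unknown = selected - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)} (choose from {STAGES})")
    need_std = bool(selected & {"beta", "env", "richness"})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    occ, surveys, species, truth = load_inputs(config)
    env_table = _env_table(surveys, config.env_vars)

    stage_seeds: dict[str, int] = {}
    for buffer_km in config.buffer_km:
        tag = f"{buffer_km:g}km"
        regions = build_regions(surveys, buffer_km)
        pairs = comparison_pairs(regions)
        regions_by_id = {r.region_id: r for r in regions}
        if "regions" in selected:
            pd.DataFrame(
                [
                    {
                        "region_id": r.region_id,
                        "focal_pa": r.focal_pa,
                        "focal_level": r.focal_level,
                        "buffer_km": r.buffer_km,
                        "n_SPA": len(r.members.get("SPA", [])),
                        "n_RA": len(r.members.get("RA", [])),
                        "n_NPA": len(r.members.get("NPA", [])),
                        "usable": r.usable,
                    }
                    for r in regions
                ]
            ).to_csv(out / f"regions_{tag}.csv", index=False)

        # ---- standardized beta + curveball null tests -----------------
        beta_seed = derive_seed(config.seed, f"beta:{tag}")
        stage_seeds[f"beta:{tag}"] = beta_seed
        beta_rows = []
        std_results = []
        if need_std:
            for pair in pairs:
                region = regions_by_id[pair.region_id]
                mat = _region_matrix(occ, region, config.min_occurrence)
                pair_seed = derive_seed(beta_seed, f"{pair.region_id}:{pair.label}")
                obs = standardized_subsample(
                    pair, mat, config.n_subsample_iter, pair_seed
                )
                std_results.append(obs)
                if "beta" not in selected:
                    continue
                summaries = null_test(
                    pair,
                    mat,
                    n_null=config.n_null,
                    n_iter=config.n_subsample_iter,
                    rng_seed=pair_seed,
                    observed=obs,
                )
                row: dict[str, Any] = {
                    "region_id": pair.region_id,
                    "pair": pair.label,
                    "n_per_side": obs.n_per_side,
                    "delta_s": obs.delta_s,
                }
                for comp, s in summaries.items():
                    row[comp] = s.observed
                    row[f"ses_{comp}"] = s.ses
                    row[f"p_{comp}"] = s.p_value
                    row[f"p_greater_{comp}"] = s.p_greater
                    row[f"p_less_{comp}"] = s.p_less
                beta_rows.append(row)
        if "beta" in selected:
            beta_frame = pd.DataFrame(beta_rows)
            beta_frame.to_csv(out / f"beta_ses_{tag}.csv", index=False)

            # Fisher combination across regions per pair type
            fisher: dict[str, dict[str, dict[str, float]]] = {}
            if not beta_frame.empty:
                for label, grp in beta_frame.groupby("pair"):
                    fisher[label] = {}
                    for comp in ("total", "turnover", "nestedness"):
                        stat, p = fisher_combine(grp[f"p_{comp}"].tolist())
                        fisher[label][comp] = {
                            "statistic": stat,
                            "p": p,
                            "k": int(len(grp)),
                        }
            with open(out / f"fisher_{tag}.json", "w") as fh:
                json.dump(fisher, fh, indent=2, sort_keys=True)

        # ---- environmental distance + turnover regressions ------------
        if "env" in selected:
            env_seed = derive_seed(config.seed, f"env:{tag}")
            stage_seeds[f"env:{tag}"] = env_seed
            env_rows = []
            for pair, obs in zip(pairs, std_results):
                res = env_distance(
                    pair,
                    env_table,
                    config.n_subsample_iter,
                    derive_seed(env_seed, f"{pair.region_id}:{pair.label}"),
                )
                if res is None:
                    continue
                env_rows.append(
                    {
                        "region_id": pair.region_id,
                        "pair": pair.label,
                        "env_distance": res.env_distance,
                        "turnover": obs.beta.turnover,
                        "delta_s": obs.delta_s,
                    }
                )
            env_frame = pd.DataFrame(env_rows)
            env_frame.to_csv(out / f"env_distance_{tag}.csv", index=False)
            reg_rows = []
            if not env_frame.empty:
                for label, grp in env_frame.groupby("pair"):
                    if len(grp) < 3 or grp["env_distance"].std() == 0:
                        logger.warning(
                            "pair type %s: regression skipped (n=%d)", label, len(grp)
                        )
                        continue
                    fit = turnover_env_regression(
                        list(zip(grp["env_distance"], grp["turnover"]))
                    )
                    fit["pair"] = label
                    reg_rows.append(fit)
            pd.DataFrame(reg_rows).to_csv(
                out / f"env_regression_{tag}.csv", index=False
            )

        # ---- richness comparisons -------------------------------------
        if "richness" in selected:
            rich_rows = []
            by_label: dict[str, list] = {}
            for obs in std_results:
                by_label.setdefault(obs.pair.label, []).append(obs)
            for label, group in sorted(by_label.items()):
                if len(group) < 2:
                    logger.warning("pair type %s: <2 regions, Wilcoxon skipped", label)
                    continue
                res = richness_comparison(group)
                res["pair"] = label
                rich_rows.append(res)
            pd.DataFrame(rich_rows).to_csv(out / f"richness_{tag}.csv", index=False)

        # ---- Venn gamma shares ----------------------------------------
        if "venn" in selected:
            venn_seed = derive_seed(config.seed, f"venn:{tag}")
            stage_seeds[f"venn:{tag}"] = venn_seed
            venn_rows = []
            for region in regions:
                if any(
                    not region.members.get(lv) for lv in ("SPA", "RA", "NPA")
                ):
                    logger.info(
                        "region %s lacks a protection level: no Venn analysis",
                        region.region_id,
                    )
                    continue
                for threat in (None, "Imperiled", "NotThreatened"):
                    shares = venn_shares(
                        region,
                        occ,
                        config.n_subsample_iter,
                        derive_seed(venn_seed, f"{region.region_id}:{threat}"),
                        threat_filter=threat,
                        species_info=species,
                    )
                    if shares is None:
                        continue
                    row = {
                        "region_id": region.region_id,
                        "threat_group": threat or "all",
                        "gamma": shares.gamma,
                    }
                    row.update(shares.shares)
                    venn_rows.append(row)
            pd.DataFrame(venn_rows).to_csv(out / f"venn_{tag}.csv", index=False)

        # ---- partial dbRDA per SPA-focal region -----------------------
        if "dbrda" not in selected:
            continue
        dbrda_seed = derive_seed(config.seed, f"dbrda:{tag}")
        stage_seeds[f"dbrda:{tag}"] = dbrda_seed
        dbrda_rows = []
        for region in regions:
            if region.focal_level != "SPA" or not region.usable:
                continue
            members = [s for s in region.member_ids if s in env_table.index]
            complete = env_table.loc[members].dropna().index.tolist()
            if len(complete) < 6:
                logger.warning(
                    "region %s: dbRDA skipped (<6 env-complete surveys)",
                    region.region_id,
                )
                continue
            prot = pd.Series(
                {
                    s.survey_id: s.protection
                    for s in surveys
                    if s.survey_id in complete
                }
            ).loc[complete]
            if prot.nunique() < 2:
                continue
            sub = occ.submatrix(complete)
            response = survey_turnover_distance(sub)
            dummies = pd.get_dummies(prot, drop_first=True).to_numpy(dtype=float)
            try:
                env_axes = env_pcoa_axes(env_table.loc[complete])
                result = dbrda_marginal(
                    response,
                    {"protection": dummies, "environment": env_axes},
                    n_perm=config.n_perm,
                    rng_seed=derive_seed(dbrda_seed, region.region_id),
                )
            except ValueError as exc:
                logger.warning("region %s: dbRDA skipped (%s)", region.region_id, exc)
                continue
            prot_share = result.marginal["protection"]["r2_share"]
            env_share = result.marginal["environment"]["r2_share"]
            joint = prot_share + env_share
            dbrda_rows.append(
                {
                    "region_id": region.region_id,
                    "n_surveys": len(complete),
                    "f_stat": result.f_stat,
                    "r2": result.r2,
                    "adj_r2": result.adj_r2,
                    "perm_p": result.perm_p,
                    "protection_share": prot_share,
                    "environment_share": env_share,
                    "protection_p": result.marginal["protection"]["perm_p"],
                    "environment_p": result.marginal["environment"]["perm_p"],
                    "protection_pct_of_joint": 100 * prot_share / joint if joint > 0 else np.nan,
                    "environment_pct_of_joint": 100 * env_share / joint if joint > 0 else np.nan,
                }
            )
        pd.DataFrame(dbrda_rows).to_csv(out / f"dbrda_{tag}.csv", index=False)

    # ---- run manifest --------------------------------------------------
    manifest = {
        "config": dataclasses.asdict(config),
        "master_seed": config.seed,
        "stage_seeds": stage_seeds,
        "package_version": __version__,
        "input_digests": {
            key: file_digest(path)
            for key, path in (
                ("occurrence", config.occurrence),
                ("surveys", config.surveys),
                ("species", config.species),
            )
            if path
        },
        "simulated": truth is not None,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if truth is not None:
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
    return out
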