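"""End-to-end orchestration: matrix construction through GLM selection.

One configuration drives the full analysis chain -- incidence matrix,
Chao2 completeness, Jaccard/UPGMA/SIMPROF biogeographic groups, Rapoport
randomized regression, mid-domain-effect envelopes (with and without
replacement), NODF/T/BR nestedness tests, C-score/SIM9 co-occurrence and
AICc-ranked Poisson GLMs -- writing one CSV per stage plus a
machine-readable JSON summary and a plain-text log.  Every stage has its
own recorded seed derived from the master seed, so a rerun of the same
config reproduces all outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cooccurrence import cooccurrence_test
from .core_io import (
    BandDomain,
    ranges_to_incidence,
    read_covariates_csv,
    read_ranges_csv,
    richness_per_band,
    write_matrix_csv,
)
from .glm_selection import rank_single_predictors, stepwise_aicc
from .gradient_stats import chao2, rapoport_test
from .mde_null import mde_deviations, simulate_mde
from .nestedness import nestedness_null_test
from .similarity_clustering import (
    jaccard_similarity,
    significant_groups,
    simprof_tree,
    upgma,
)
from .synthetic_data import GeneratorConfig, gen_covariates, gen_ranges

__all__ = ["RunConfig", "run_pipeline"]

STAGES = (
    "matrix",
    "chao2",
    "cluster",
    "rapoport",
    "mde",
    "nestedness",
    "cooccurrence",
    "glm",
)

# Desk-scale defaults; --paper-scale raises the stochastic stages to the
# 50,000-iteration budgets used in the original analysis.
_DESK_ITER = {
    "rapoport": 5000,
    "mde": 5000,
    "nestedness": 2000,
    "cooccurrence": 2000,
    "simprof": 999,
}
_PAPER_ITER = {
    "rapoport": 50_000,
    "mde": 50_000,
    "nestedness": 50_000,
    "cooccurrence": 50_000,
    "simprof": 50_000,
}


@dataclass
class RunConfig:
    out_dir: str = "macronull_run"
    seed: int = 0
    domain_north: int = 18
    domain_south: int = 56
    ranges_csv: str | None = None
    covariates_csv: str | None = None
    signed_latitudes: bool = False
    synthetic_species: int = 84
    alpha: float = 0.05
    paper_scale: bool = False
    iterations: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def n_iter(self, stage: str) -> int:
        base = _PAPER_ITER if self.paper_scale else _DESK_ITER
        return int(self.iterations.get(stage, base[stage]))

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    @property
    def domain(self) -> BandDomain:
        return BandDomain(self.domain_north, self.domain_south)


def _stage_seeds(master: int) -> dict[str, int]:
    rng = np.random.default_rng(master)
    return {s: int(rng.integers(0, 2**31 - 1)) for s in STAGES}


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages; returns the summary dict (also written to
    ``summary.json``).  Any stage failure aborts with the stage named."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("macronull.pipeline")
    log.setLevel(logging.INFO)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    seeds = _stage_seeds(config.seed)
    summary: dict = {
        "version": __version__,
        "numpy": np.__version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "paper_scale": config.paper_scale,
        "stages": {},
    }
    t0 = time.time()
    log.info("macronull %s, master seed %d", __version__, config.seed)
    current = "matrix"
    try:
        domain = config.domain
        if config.ranges_csv:
            ranges = read_ranges_csv(config.ranges_csv, signed=config.signed_latitudes)
            log.info("loaded %d ranges from %s", len(ranges), config.ranges_csv)
        else:
            ranges = gen_ranges(
                GeneratorConfig(
                    n_species=config.synthetic_species,
                    domain=domain,
                    seed=seeds["matrix"],
                )
            )
            log.info("generated %d synthetic ranges", len(ranges))
        matrix = ranges_to_incidence(ranges, domain)
        write_matrix_csv(matrix, out / "matrix.csv")
        richness = richness_per_band(matrix)
        pd.DataFrame({"band": matrix.col_labels, "richness": richness}).to_csv(
            out / "richness.csv", index=False
        )
        summary["stages"]["matrix"] = {
            "n_species": matrix.shape[0],
            "n_bands": matrix.shape[1],
            "fill": matrix.fill,
            "max_richness_band": int(matrix.col_labels[int(richness.argmax())]),
        }

        if config.enabled("chao2"):
            current = "chao2"
            res = chao2(matrix)
            pd.DataFrame([res.__dict__]).to_csv(out / "chao2.csv", index=False)
            summary["stages"]["chao2"] = dict(res.__dict__)
            log.info("chao2: S_obs=%d S_est=%.2f", res.s_obs, res.s_est)

        if config.enabled("cluster"):
            current = "cluster"
            sim = jaccard_similarity(matrix)
            dend = upgma(sim)
            dend = simprof_tree(
                matrix,
                dend,
                alpha=config.alpha,
                n_perm=config.n_iter("simprof"),
                seed=seeds["cluster"],
            )
            groups = significant_groups(dend)
            rows = [
                {"band": band, "group": gi + 1}
                for gi, grp in enumerate(groups)
                for band in grp
            ]
            pd.DataFrame(rows).to_csv(out / "cluster_groups.csv", index=False)
            (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
            summary["stages"]["cluster"] = {
                "n_groups": len(groups),
                "dropped_bands": sim.attrs["dropped_bands"],
            }
            log.info("cluster: %d SIMPROF groups", len(groups))

        if config.enabled("rapoport"):
            current = "rapoport"
            res = rapoport_test(
                ranges, n_perm=config.n_iter("rapoport"), seed=seeds["rapoport"]
            )
            pd.DataFrame([res.__dict__]).to_csv(out / "rapoport.csv", index=False)
            summary["stages"]["rapoport"] = dict(res.__dict__)
            log.info(
                "rapoport: slope=%.4f r=%.3f p=%.4f", res.slope, res.r, res.p_perm
            )

        if config.enabled("mde"):
            current = "mde"
            frames = []
            summary["stages"]["mde"] = {}
            for mode in ("without", "with"):
                env = simulate_mde(
                    ranges,
                    domain,
                    mode=mode,
                    n_sim=config.n_iter("mde"),
                    seed=seeds["mde"],
                )
                flags = dict(mde_deviations(env))
                frames.append(
                    pd.DataFrame(
                        {
                            "band": env.bands,
                            "observed": env.observed,
                            "mean": env.mean_sim,
                            "lower95": env.lower95,
                            "upper95": env.upper95,
                            "flag": [
                                flags.get(int(b), "inside") for b in env.bands
                            ],
                            "mode": mode,
                        }
                    )
                )
                summary["stages"]["mde"][mode] = {
                    "coverage": env.coverage,
                    "deviations": mde_deviations(env),
                }
                log.info("mde (%s): coverage=%.3f", mode, env.coverage)
            pd.concat(frames).to_csv(out / "mde_envelope.csv", index=False)

        if config.enabled("nestedness"):
            current = "nestedness"
            rows = []
            for metric in ("T", "BR", "NODF_total", "NODF_cols", "NODF_rows"):
                res = nestedness_null_test(
                    matrix,
                    metric=metric,
                    null_model="fixed-equiprobable",
                    n_iter=config.n_iter("nestedness"),
                    seed=seeds["nestedness"],
                )
                rows.append(
                    {
                        "metric": metric,
                        "observed": res.observed,
                        "null_mean": res.null_mean,
                        "ci_lo": res.null_ci95[0],
                        "ci_hi": res.null_ci95[1],
                        "p_value": res.p_value,
                    }
                )
                log.info(
                    "nestedness %s: obs=%.3f null=%.3f p=%.5f",
                    metric,
                    res.observed,
                    res.null_mean,
                    res.p_value,
                )
            pd.DataFrame(rows).to_csv(out / "nestedness.csv", index=False)
            summary["stages"]["nestedness"] = rows

        if config.enabled("cooccurrence"):
            current = "cooccurrence"
            res = cooccurrence_test(
                matrix, n_iter=config.n_iter("cooccurrence"), seed=seeds["cooccurrence"]
            )
            pd.DataFrame([res.__dict__]).to_csv(
                out / "cooccurrence.csv", index=False
            )
            summary["stages"]["cooccurrence"] = dict(res.__dict__)
            log.info(
                "cooccurrence: C=%.4f null=%.4f SES=%.2f",
                res.observed_cscore,
                res.null_mean,
                res.ses,
            )

        if config.enabled("glm"):
            current = "glm"
            if config.covariates_csv:
                cov = read_covariates_csv(config.covariates_csv, domain)
            else:
                cov = gen_covariates(domain, seed=seeds["glm"])
                log.info("generated synthetic covariate table")
            ranked = rank_single_predictors(richness, cov)
            pd.DataFrame(
                [
                    {
                        "predictor": f.predictors[0],
                        "df": f.k,
                        "loglik": f.loglik,
                        "aicc": f.aicc,
                        "delta_aicc": f.delta_aicc,
                        "pseudo_r2_mcfadden": f.pseudo_r2_mcfadden,
                        "pseudo_r2_nagelkerke": f.pseudo_r2_nagelkerke,
                    }
                    for f in ranked
                ]
            ).to_csv(out / "glm_rank.csv", index=False)
            full = stepwise_aicc(richness, cov)
            pd.DataFrame(
                {
                    "term": full.coefficients.index,
                    "estimate": full.coefficients.to_numpy(),
                    "std_error": full.std_errors.to_numpy(),
                    "z_value": full.z_values.to_numpy(),
                    "p_value": full.p_values.to_numpy(),
                }
            ).to_csv(out / "glm_full.csv", index=False)
            summary["stages"]["glm"] = {
                "best_single": ranked[0].predictors[0],
                "best_single_aicc": ranked[0].aicc,
                "best_single_pseudo_r2_nagelkerke": ranked[0].pseudo_r2_nagelkerke,
                "stepwise_predictors": list(full.predictors),
                "stepwise_aicc": full.aicc,
                "stepwise_pseudo_r2_nagelkerke": full.pseudo_r2_nagelkerke,
            }
            log.info(
                "glm: best single=%s, stepwise keeps %d predictors",
                ranked[0].predictors[0],
                len(full.predictors),
            )
    except Exception:
        log.exception("stage %r failed; aborting", current)
        summary["failed_stage"] = current
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        handler.close()
        log.removeHandler(handler)
        raise RuntimeError(f"pipeline stage {current!r} failed") from None
    summary["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    log.info("done in %.1fs", summary["elapsed_s"])
    handler.close()
    log.removeHandler(handler)
    return summary
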