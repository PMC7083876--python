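"""End-to-end orchestration: data -> diversity -> het-excess -> ABC -> loss.

A :class:`RunConfig` (constructible from YAML) fixes the input (a file or a
synthetic preset), per-stage parameters and a single global seed; every
stochastic stage derives its own seed deterministically from the global
seed and the stage name, so a re-run with the same config reproduces every
number.  Outputs are CSV reports, a machine-readable ``summary.json`` and a
log with per-stage wall times; every file is stamped with the seed and a
hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abc_inference import (MODEL_BOTTLENECK, PriorSet, abc_reject,
                            build_reference_table, cv_model_selection,
                            cv_parameter_estimation, goodness_of_fit,
                            model_posterior, posterior_predictive_check)
from .dataset import read_csv, read_genepop, write_genepop
from .diversity_loss import loss_grid, loss_scenarios
from .het_excess import het_excess_test
from .simulator import MutationModel
from .sumstats import (abc_target_from_population, pairwise_fst,
                       per_locus_diversity, private_alleles,
                       rarefied_allelic_richness)
from .synthetic import constant_preset, fur_seal_preset, generate_multipop_dataset

__all__ = ["RunConfig", "run_full_analysis", "stage_seed"]


def _default_het():
    return {"n_iter": 500}


def _default_abc():
    return {"n_sims_per_model": 4000, "tolerance": 0.02, "n_ind": None,
            "cv_model_pseudo": 100, "cv_param_pseudo": 100,
            "cv_param_tolerance": 0.02, "ppc_draws": 200, "gof_null": 50,
            "save_reference_table": False}


def _default_loss():
    return {"n_sims": 1500, "ne_hists": [1000.0, 10000.0, 50000.0],
            "ne_bot": 200.0, "duration": 10.0, "grid": False,
            "grid_sims_per_cell": 200}


@dataclass
class RunConfig:
    seed: int
    out_dir: str
    preset: str | None = "fur_seal"
    preset_scale: float = 1.0
    input_path: str | None = None
    input_format: str = "auto"
    het_excess: dict = field(default_factory=_default_het)
    abc: dict = field(default_factory=_default_abc)
    loss: dict = field(default_factory=_default_loss)

    def __post_init__(self):
        if self.preset is None and self.input_path is None:
            raise ValueError("either a synthetic preset or an input path is required")
        self.het_excess = {**_default_het(), **self.het_excess}
        self.abc = {**_default_abc(), **self.abc}
        self.loss = {**_default_loss(), **self.loss}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage 31-bit seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1) + 1


def _load_dataset(cfg: RunConfig):
    if cfg.input_path is not None:
        path = Path(cfg.input_path)
        fmt = cfg.input_format
        if fmt == "auto":
            fmt = "csv" if path.suffix.lower() == ".csv" else "genepop"
        return read_csv(path) if fmt == "csv" else read_genepop(path)
    if cfg.preset == "fur_seal":
        preset = fur_seal_preset(scale=cfg.preset_scale)
    elif cfg.preset == "constant":
        preset = constant_preset(scale=cfg.preset_scale)
    else:
        raise ValueError(f"unknown preset {cfg.preset!r}")
    return generate_multipop_dataset(preset, stage_seed(cfg.seed, "synthetic"))


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage and return the JSON-style summary dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    stamp = f"demosat {__version__}; seed={cfg.seed}; config={chash}"
    log_path = out / "run.log"
    summary: dict = {"seed": cfg.seed, "config_hash": chash,
                     "version": __version__}

    def log(msg):
        with open(log_path, "a") as fh:
            fh.write(msg + "\n")

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                if exc[0] is None:
                    log(f"stage {name}: {time.perf_counter() - self.t0:.2f}s "
                        f"(seed {stage_seed(cfg.seed, name)})")
        return _Timer()

    log(f"run start: {stamp}")
    try:
        with stage("load"):
            data = _load_dataset(cfg)
            write_genepop(data, out / "dataset.gen", title=stamp)

        with stage("diversity"):
            summary["diversity"] = _diversity_stage(cfg, data, out, stamp)

        with stage("het_excess"):
            summary["het_excess"] = _het_excess_stage(cfg, data, out, stamp)

        with stage("abc"):
            summary["abc"] = _abc_stage(cfg, data, out, stamp)

        with stage("loss"):
            summary["loss"] = _loss_stage(cfg, out, stamp)
    except Exception as err:  # partial outputs stay on disk for debugging
        log(f"FAILED: {err}")
        raise
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    log("run complete")
    return summary


def _diversity_stage(cfg, data, out, stamp) -> dict:
    pops = data.populations()
    seed = stage_seed(cfg.seed, "diversity")
    rows = []
    for pop in pops:
        sub = data.for_population(pop)
        div = per_locus_diversity(sub)
        g = min(20, int(min(np.sum(sub.alleles[:, l, :] != -1)
                            for l in range(sub.n_loci))))
        ar, ar_mean = rarefied_allelic_richness(sub, g=g)
        rows.append({
            "population": pop, "sample_size": sub.n_individuals,
            "A_r": ar_mean, "A_r_sd": float(np.std(ar, ddof=1)),
            "Ho": div.means["Ho"], "Ho_sd": div.sds["Ho"],
            "M_ratio": div.means["M_ratio"], "M_ratio_sd": div.sds["M_ratio"],
            "Fis": div.means["Fis"], "Fis_sd": div.sds["Fis"],
        })
    table = pd.DataFrame(rows).set_index("population")
    if len(pops) >= 2:
        table["private_alleles"] = private_alleles(data)
        fst = pairwise_fst(data, n_bootstrap=200, seed=seed)
        with open(out / "fst.csv", "w") as fh:
            fh.write(f"# {stamp}\n")
            fst.fst.to_csv(fh)
    with open(out / "diversity.csv", "w") as fh:
        fh.write(f"# {stamp}\n")
        table.to_csv(fh)
    return {pop: {k: (v if isinstance(v, (int, str)) else float(v))
                  for k, v in rec.items() if k != "population"}
            for pop, rec in table.to_dict("index").items()}


def _het_excess_stage(cfg, data, out, stamp) -> dict:
    seed = stage_seed(cfg.seed, "het_excess")
    mut = MutationModel.tpm80()
    results = {}
    for i, pop in enumerate(data.populations()):
        res = het_excess_test(data.for_population(pop), mut,
                              n_iter=cfg.het_excess["n_iter"], seed=seed + i)
        res.to_csv(out / f"het_excess_{pop}.csv", header_comment=stamp)
        results[pop] = {
            "prop_het_exc": res.prop_het_exc,
            "n_loci_excess": res.n_loci_excess,
            "p_sign": res.p_sign, "p_std_diff": res.p_std_diff,
            "p_wilcoxon": res.p_wilcoxon,
        }
    return results


def _abc_stage(cfg, data, out, stamp) -> dict:
    c = cfg.abc
    seed = stage_seed(cfg.seed, "abc")
    pops = data.populations()
    n_ind = c["n_ind"] or min(int(np.sum(data.pop_labels == p)) for p in pops)
    priors = PriorSet()
    table = build_reference_table(priors, c["n_sims_per_model"], seed,
                                  n_ind=n_ind, n_loci=data.n_loci)
    if c["save_reference_table"]:
        table.save_csv(out / "reference_table.csv")
    from .abc_inference import ReferenceTable
    bot_table = ReferenceTable(df=table.model_rows(MODEL_BOTTLENECK).reset_index(drop=True),
                               n_ind=n_ind, n_loci=data.n_loci, priors=priors)
    result: dict = {"n_ind": n_ind, "n_sims_per_model": c["n_sims_per_model"]}

    cv_m = cv_model_selection(table, n_pseudo=c["cv_model_pseudo"],
                              tolerance=c["tolerance"], seed=seed + 1)
    cv_p = cv_parameter_estimation(bot_table, n_pseudo=c["cv_param_pseudo"],
                                   tolerance=c["cv_param_tolerance"], seed=seed + 2)
    cv_m.confusion.to_csv(out / "cv_model_confusion.csv")
    cv_p.prediction_error.to_csv(out / "cv_prediction_error.csv")
    result["cv_model_correct_rate"] = {k: float(v)
                                       for k, v in cv_m.correct_rate.items()}
    result["cv_prediction_error"] = {k: float(v)
                                     for k, v in cv_p.prediction_error.items()}

    per_pop = {}
    for i, pop in enumerate(pops):
        target = abc_target_from_population(data, pop, n_ind, seed + 10 + i)
        mp = model_posterior(target, table, c["tolerance"])
        post = abc_reject(target, bot_table, c["tolerance"])
        ne_bot = post.accepted["ne_bot"].to_numpy()
        with open(out / f"posterior_ne_bot_{pop}.csv", "w") as fh:
            fh.write(f"# {stamp}\n")
            post.accepted[["ne_bot", "ne_hist", "mu", "gsm_par"]].to_csv(fh, index=False)
        ppc = posterior_predictive_check(post, n_ind, data.n_loci,
                                         n_draws=c["ppc_draws"], seed=seed + 20 + i)
        gof = goodness_of_fit(target, bot_table, c["tolerance"],
                              n_null=c["gof_null"], seed=seed + 30 + i)
        per_pop[pop] = {
            "p_bottleneck": float(mp[MODEL_BOTTLENECK]),
            "ne_bot_median": float(np.median(ne_bot)),
            "ne_bot_mode": _kde_mode(ne_bot),
            "ppc_two_sided": {k: float(v) for k, v in ppc.two_sided.items()},
            "gof_p": gof,
        }
    result["populations"] = per_pop
    return result


def _kde_mode(values: np.ndarray) -> float:
    from scipy.stats import gaussian_kde
    if np.unique(values).size < 3:
        return float(np.median(values))
    kde = gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def _loss_stage(cfg, out, stamp) -> dict:
    c = cfg.loss
    seed = stage_seed(cfg.seed, "loss")
    scen = loss_scenarios(seed, ne_hists=tuple(c["ne_hists"]), ne_bot=c["ne_bot"],
                          duration=c["duration"], n_sims=c["n_sims"])
    rows = [{"ne_hist": ne, "loss": r.loss, "se": r.se,
             "mean_k_bottleneck": r.mean_k_bottleneck,
             "mean_k_constant": r.mean_k_constant, "het_loss": r.het_loss}
            for ne, r in scen.items()]
    with open(out / "loss_scenarios.csv", "w") as fh:
        fh.write(f"# {stamp}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
    result = {str(int(ne)): {"loss": r.loss, "se": r.se, "het_loss": r.het_loss}
              for ne, r in scen.items()}
    if c["grid"]:
        grid = loss_grid(seed + 1, n_sims_per_cell=c["grid_sims_per_cell"])
        grid.to_csv(out / "loss_grid.csv", header_comment=stamp)
        grid.plot_heatmap(out / "loss_grid.png")
        result["grid_max_loss"] = float(grid.loss.max())
    return result
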