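"""Rejection-ABC over bottleneck and constant-size demographies.

Prior sampling, reference-table construction (parameter draws joined to the
three summary statistics of each simulated dataset), simple-rejection
posteriors, model posterior probabilities, leave-one-out cross-validation of
model selection and of parameter estimation, posterior predictive checks and
a distance-based goodness-of-fit test.

Distances are Euclidean on summary statistics, each scaled by its median
absolute deviation across the full reference table; rejection retains the
``tolerance`` fraction of rows with the smallest distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from ._util import as_rng, kernel_seed
from .sumstats import SummaryVector

__all__ = [
    "PriorSet", "ReferenceTable", "AbcPosterior", "CvModelResult", "CvParamResult",
    "MODEL_BOTTLENECK", "MODEL_CONSTANT", "sample_priors", "simulate_summaries",
    "build_reference_table", "abc_reject", "model_posterior",
    "cv_model_selection", "cv_parameter_estimation",
    "posterior_predictive_check", "goodness_of_fit",
]

MODEL_BOTTLENECK = "bottleneck"
MODEL_CONSTANT = "non_bottleneck"

STAT_COLS = ["k_mean", "prop_low_freq", "m_ratio"]
PARAM_COLS = ["ne_cur", "ne_hist", "ne_bot", "t_bot_start", "t_bot_end",
              "t_hist", "mu", "gsm_par"]


@dataclass(frozen=True)
class PriorSet:
    """Priors of the demographic and mutational parameters.

    Current and historical effective sizes are log-normal (parameters on the
    natural-log scale); the bottleneck size, all times, the mutation rate and
    the multistep proportion are uniform.  Bottleneck draws are constrained
    to ``t_bot_start > t_bot_end`` by rejection-resampling.
    """

    ne_log_mean: float = 10.5
    ne_log_sd: float = 1.0
    ne_bot: tuple = (1.0, 600.0)
    t_bot_start: tuple = (10.0, 40.0)
    t_bot_end: tuple = (1.0, 20.0)
    t_hist: tuple = (10.0, 40.0)
    mu: tuple = (1e-5, 1e-4)
    gsm_par: tuple = (0.0, 0.3)

    @classmethod
    def verbal(cls) -> "PriorSet":
        """Alternative Ne prior matching a median of ~6,700 with ~90% of the
        mass between 3,000 and 15,000 (logmean ln(6708), logsd 0.489)."""
        return cls(ne_log_mean=float(np.log(6708.0)), ne_log_sd=0.489)

    def to_dict(self) -> dict:
        return {
            "ne_log_mean": self.ne_log_mean, "ne_log_sd": self.ne_log_sd,
            "ne_bot": list(self.ne_bot), "t_bot_start": list(self.t_bot_start),
            "t_bot_end": list(self.t_bot_end), "t_hist": list(self.t_hist),
            "mu": list(self.mu), "gsm_par": list(self.gsm_par),
        }


def sample_priors(priors: PriorSet, model: str, n: int, seed) -> pd.DataFrame:
    """Draw n valid parameter vectors for one model.

    Columns not used by a model (e.g. ne_bot for the constant model) are NaN.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = as_rng(seed)
    df = pd.DataFrame(index=range(n), columns=PARAM_COLS, dtype=float)
    df["ne_cur"] = rng.lognormal(priors.ne_log_mean, priors.ne_log_sd, n)
    df["ne_hist"] = rng.lognormal(priors.ne_log_mean, priors.ne_log_sd, n)
    df["mu"] = rng.uniform(*priors.mu, n)
    df["gsm_par"] = rng.uniform(*priors.gsm_par, n)
    if model == MODEL_BOTTLENECK:
        df["ne_bot"] = rng.uniform(*priors.ne_bot, n)
        ts = rng.uniform(*priors.t_bot_start, n)
        te = rng.uniform(*priors.t_bot_end, n)
        bad = ts <= te
        while bad.any():
            m = int(bad.sum())
            ts[bad] = rng.uniform(*priors.t_bot_start, m)
            te[bad] = rng.uniform(*priors.t_bot_end, m)
            bad = ts <= te
        df["t_bot_start"] = ts
        df["t_bot_end"] = te
    elif model == MODEL_CONSTANT:
        df["t_hist"] = rng.uniform(*priors.t_hist, n)
    else:
        raise ValueError(f"unknown model {model!r}")
    df["model"] = model
    return df


def _epoch_arrays(params: pd.DataFrame):
    """Per-row piecewise-constant demography arrays for the batch kernel."""
    n = params.shape[0]
    starts = np.zeros((n, 3))
    sizes = np.ones((n, 3))
    n_ep = np.empty(n, dtype=np.int64)
    is_bot = (params["model"] == MODEL_BOTTLENECK).to_numpy()
    sizes[:, 0] = params["ne_cur"].to_numpy()
    if is_bot.any():
        starts[is_bot, 1] = params.loc[is_bot, "t_bot_end"].to_numpy()
        starts[is_bot, 2] = params.loc[is_bot, "t_bot_start"].to_numpy()
        sizes[is_bot, 1] = params.loc[is_bot, "ne_bot"].to_numpy()
        sizes[is_bot, 2] = params.loc[is_bot, "ne_hist"].to_numpy()
        n_ep[is_bot] = 3
    if (~is_bot).any():
        starts[~is_bot, 1] = params.loc[~is_bot, "t_hist"].to_numpy()
        sizes[~is_bot, 1] = params.loc[~is_bot, "ne_hist"].to_numpy()
        n_ep[~is_bot] = 2
    return starts, sizes, n_ep


def simulate_summaries(params: pd.DataFrame, n_ind: int, n_loci: int, seed,
                       chunk_size: int = 5000) -> np.ndarray:
    """Simulate each parameter row; return (n, 4) array of summary statistics
    (mean k, prop <5% alleles, mean M-ratio, mean He)."""
    rng = as_rng(seed)
    _kernels.seed_rng(kernel_seed(rng))
    starts, sizes, n_ep = _epoch_arrays(params)
    mus = params["mu"].to_numpy(dtype=np.float64)
    gsm = params["gsm_par"].to_numpy(dtype=np.float64)
    out = np.empty((params.shape[0], 4))
    n_copies = 2 * n_ind
    for beg in range(0, params.shape[0], chunk_size):
        end = min(beg + chunk_size, params.shape[0])
        _kernels.sim_summary_batch(
            n_copies, n_loci, starts[beg:end], sizes[beg:end], n_ep[beg:end],
            mus[beg:end], gsm[beg:end], gsm[beg:end], out[beg:end])
    return out


@dataclass
class ReferenceTable:
    """Parameter draws joined to summary statistics, labelled by model."""

    df: pd.DataFrame
    n_ind: int
    n_loci: int
    seed: int | None = None
    priors: PriorSet = field(default_factory=PriorSet)

    @property
    def stats(self) -> np.ndarray:
        return self.df[STAT_COLS].to_numpy(dtype=np.float64)

    def model_rows(self, model: str) -> pd.DataFrame:
        return self.df[self.df["model"] == model]

    def save_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# demosat reference table; n_ind={self.n_ind} "
                     f"n_loci={self.n_loci} seed={self.seed}\n")
            fh.write(f"# priors: {self.priors.to_dict()}\n")
            self.df.to_csv(fh, index=False)

    @classmethod
    def load_csv(cls, path, n_ind: int | None = None, n_loci: int | None = None
                 ) -> "ReferenceTable":
        meta = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for token in first.lstrip("# ").split():
                    if "=" in token:
                        k, v = token.split("=")
                        meta[k] = v
        df = pd.read_csv(path, comment="#")
        return cls(df=df,
                   n_ind=n_ind or int(meta.get("n_ind", 0)),
                   n_loci=n_loci or int(meta.get("n_loci", 0)),
                   seed=None if meta.get("seed") in (None, "None") else int(meta["seed"]))


def build_reference_table(priors: PriorSet, n_sims_per_model: int, seed,
                          n_ind: int = 181, n_loci: int = 39,
                          models=(MODEL_BOTTLENECK, MODEL_CONSTANT)) -> ReferenceTable:
    """Simulate ``n_sims_per_model`` datasets under each model."""
    if n_sims_per_model < 1:
        raise ValueError("n_sims_per_model must be at least 1")
    rng = as_rng(seed)
    frames = []
    for model in models:
        params = sample_priors(priors, model, n_sims_per_model, rng)
        summ = simulate_summaries(params, n_ind, n_loci, rng)
        params[STAT_COLS[0]] = summ[:, 0]
        params[STAT_COLS[1]] = summ[:, 1]
        params[STAT_COLS[2]] = summ[:, 2]
        params["he_mean"] = summ[:, 3]
        frames.append(params)
    df = pd.concat(frames, ignore_index=True)
    return ReferenceTable(df=df, n_ind=n_ind, n_loci=n_loci,
                          seed=seed if isinstance(seed, int) else None, priors=priors)


# ---------------------------------------------------------------------------
# Rejection

def _as_target_array(target) -> np.ndarray:
    if isinstance(target, SummaryVector):
        return target.as_array()
    arr = np.asarray(target, dtype=np.float64).reshape(-1)
    if arr.size != 3:
        raise ValueError("target must provide the three summary statistics")
    return arr


def _mad_scale(stats: np.ndarray) -> np.ndarray:
    med = np.median(stats, axis=0)
    scale = np.median(np.abs(stats - med), axis=0)
    if np.any(scale == 0):
        warnings.warn("zero MAD in a summary statistic; falling back to SD scaling")
        sd = stats.std(axis=0)
        scale = np.where(scale == 0, np.where(sd == 0, 1.0, sd), scale)
    return scale


@dataclass
class AbcPosterior:
    """Accepted reference-table rows, sorted by distance to the target."""

    accepted: pd.DataFrame
    distances: np.ndarray
    tolerance: float
    target: np.ndarray
    scale: np.ndarray


def abc_reject(target, table: ReferenceTable, tolerance: float) -> AbcPosterior:
    """Retain the ``tolerance`` fraction of rows closest to the target."""
    if not (0 < tolerance <= 1):
        raise ValueError("tolerance must be in (0, 1]")
    if table.df.shape[0] == 0:
        raise ValueError("empty reference table")
    t = _as_target_array(target)
    stats = table.stats
    scale = _mad_scale(stats)
    dist = np.sqrt(np.sum(((stats - t) / scale) ** 2, axis=1))
    n_keep = max(1, int(round(tolerance * stats.shape[0])))
    order = np.argsort(dist, kind="stable")[:n_keep]
    return AbcPosterior(accepted=table.df.iloc[order].reset_index(drop=True),
                        distances=dist[order], tolerance=tolerance, target=t,
                        scale=scale)


def model_posterior(target, table: ReferenceTable, tolerance: float) -> pd.Series:
    """Posterior model probabilities = acceptance fractions per model."""
    post = abc_reject(target, table, tolerance)
    models = [MODEL_BOTTLENECK, MODEL_CONSTANT]
    counts = post.accepted["model"].value_counts()
    probs = np.array([counts.get(m, 0) for m in models], dtype=float)
    return pd.Series(probs / probs.sum(), index=models, name="posterior_prob")


# ---------------------------------------------------------------------------
# Cross-validation

@dataclass
class CvModelResult:
    """Leave-one-out model-selection diagnostics."""

    confusion: pd.DataFrame           # true model x assigned model counts
    correct_rate: pd.Series           # per true model
    mean_posterior: pd.DataFrame      # mean posterior prob per true model
    records: pd.DataFrame


@dataclass
class CvParamResult:
    """Leave-one-out parameter-estimation diagnostics.

    ``prediction_error[p]`` = sum_i (median_i - true_i)^2 / (n * Var(true)),
    so an uninformative estimator scores ~1 and a perfect one 0.
    """

    prediction_error: pd.Series
    estimates: pd.DataFrame           # columns true_<p>, est_<p>


def _loo_distances(stats: np.ndarray, scale: np.ndarray, idx: int) -> np.ndarray:
    d = np.sqrt(np.sum(((stats - stats[idx]) / scale) ** 2, axis=1))
    d[idx] = np.inf  # leave the pseudo-observed row out
    return d


def cv_model_selection(table: ReferenceTable, n_pseudo: int = 100,
                       tolerance: float = 0.01, seed=None) -> CvModelResult:
    """Classify held-out rows (balanced across models) by rejection ABC."""
    rng = as_rng(seed)
    stats = table.stats
    scale = _mad_scale(stats)
    models = np.asarray(table.df["model"])
    n_keep = max(1, int(round(tolerance * (stats.shape[0] - 1))))
    recs = []
    per_model = n_pseudo // 2
    for model in (MODEL_BOTTLENECK, MODEL_CONSTANT):
        pool = np.where(models == model)[0]
        chosen = rng.choice(pool, size=min(per_model, pool.size), replace=False)
        for idx in chosen:
            d = _loo_distances(stats, scale, int(idx))
            keep = np.argpartition(d, n_keep)[:n_keep]
            p_bot = float(np.mean(models[keep] == MODEL_BOTTLENECK))
            if p_bot == 0.5:  # ties carry no information; break at random
                assigned = (MODEL_BOTTLENECK, MODEL_CONSTANT)[int(rng.integers(2))]
            else:
                assigned = MODEL_BOTTLENECK if p_bot > 0.5 else MODEL_CONSTANT
            recs.append((model, assigned, p_bot, 1.0 - p_bot))
    records = pd.DataFrame(recs, columns=["true_model", "assigned", "p_bottleneck",
                                          "p_non_bottleneck"])
    confusion = pd.crosstab(records["true_model"], records["assigned"]).reindex(
        index=[MODEL_BOTTLENECK, MODEL_CONSTANT],
        columns=[MODEL_BOTTLENECK, MODEL_CONSTANT], fill_value=0)
    correct = pd.Series({m: confusion.loc[m, m] / confusion.loc[m].sum()
                         for m in confusion.index}, name="correct_rate")
    mean_post = records.groupby("true_model")[["p_bottleneck", "p_non_bottleneck"]].mean()
    return CvModelResult(confusion=confusion, correct_rate=correct,
                         mean_posterior=mean_post, records=records)


def cv_parameter_estimation(table: ReferenceTable, n_pseudo: int = 1000,
                            tolerance: float = 5e-3, seed=None,
                            params: list | None = None) -> CvParamResult:
    """Variance-normalised prediction error of posterior-median estimates."""
    df = table.df
    models = df["model"].unique()
    if len(models) != 1:
        raise ValueError("cv_parameter_estimation expects a single-model table; "
                         "filter with model_rows() first")
    if params is None:
        params = [p for p in PARAM_COLS if df[p].notna().all()]
    rng = as_rng(seed)
    stats = table.stats
    scale = _mad_scale(stats)
    values = df[params].to_numpy(dtype=np.float64)
    n_keep = max(1, int(round(tolerance * (stats.shape[0] - 1))))
    chosen = rng.choice(stats.shape[0], size=min(n_pseudo, stats.shape[0]),
                        replace=False)
    true_rows = []
    est_rows = []
    for idx in chosen:
        d = _loo_distances(stats, scale, int(idx))
        keep = np.argpartition(d, n_keep)[:n_keep]
        true_rows.append(values[idx])
        est_rows.append(np.median(values[keep], axis=0))
    true_arr = np.asarray(true_rows)
    est_arr = np.asarray(est_rows)
    n = true_arr.shape[0]
    epred = ((est_arr - true_arr) ** 2).sum(axis=0) / (n * true_arr.var(axis=0, ddof=1))
    est_df = pd.DataFrame(
        np.hstack([true_arr, est_arr]),
        columns=[f"true_{p}" for p in params] + [f"est_{p}" for p in params])
    return CvParamResult(prediction_error=pd.Series(epred, index=params,
                                                    name="E_pred"),
                         estimates=est_df)


# ---------------------------------------------------------------------------
# Posterior predictive check and goodness of fit

@dataclass
class PpcResult:
    simulated: pd.DataFrame
    tail_prob: pd.Series        # P(simulated <= observed) per statistic
    two_sided: pd.Series


def posterior_predictive_check(posterior: AbcPosterior, n_ind: int, n_loci: int,
                               n_draws: int = 1000, seed=None) -> PpcResult:
    """Re-simulate summary statistics from joint posterior parameter draws.

    Accepted rows are resampled whole (preserving parameter correlations).
    """
    if posterior.accepted.shape[0] == 0:
        raise ValueError("empty posterior")
    rng = as_rng(seed)
    idx = rng.integers(0, posterior.accepted.shape[0], size=n_draws)
    params = posterior.accepted.iloc[idx].reset_index(drop=True)
    summ = simulate_summaries(params, n_ind, n_loci, rng)
    sim = pd.DataFrame(summ[:, :3], columns=STAT_COLS)
    obs = posterior.target
    tail = pd.Series({c: float(np.mean(sim[c].to_numpy() <= obs[i]))
                      for i, c in enumerate(STAT_COLS)}, name="tail_prob")
    two = (2 * np.minimum(tail, 1 - tail)).clip(upper=1.0)
    two.name = "two_sided"
    return PpcResult(simulated=sim, tail_prob=tail, two_sided=two)


def goodness_of_fit(target, table: ReferenceTable, tolerance: float,
                    n_null: int = 100, seed=None) -> float:
    """Distance-based goodness-of-fit p-value.

    The statistic is the median scaled distance of accepted rows to the
    target; its null distribution is built from pseudo-observed table rows.
    p = (1 + #{null >= observed}) / (1 + n_null), hence always in (0, 1].
    """
    rng = as_rng(seed)
    t = _as_target_array(target)
    stats = table.stats
    scale = _mad_scale(stats)
    n_keep = max(1, int(round(tolerance * stats.shape[0])))

    def stat_for(target_arr, exclude=None):
        d = np.sqrt(np.sum(((stats - target_arr) / scale) ** 2, axis=1))
        if exclude is not None:
            d[exclude] = np.inf
        keep = np.partition(d, n_keep - 1)[:n_keep]
        return float(np.median(keep))

    observed = stat_for(t)
    null_idx = rng.choice(stats.shape[0], size=min(n_null, stats.shape[0]),
                          replace=False)
    null = np.array([stat_for(stats[i], exclude=int(i)) for i in null_idx])
    return float((1 + np.sum(null >= observed)) / (1 + null.size))
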