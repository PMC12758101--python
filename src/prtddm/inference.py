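"""Hierarchical Bayesian estimation of the Action-DDM by MCMC.

Subject-level parameters are drawn from group-level normal distributions
on an unconstrained link scale (logit learning rate, log boundary
separation, identity otherwise); group means get weakly-informative normal
priors and group SDs half-normal priors.  Sampling is adaptive
Metropolis-within-Gibbs: random-walk Metropolis for subject parameters
(step sizes tuned to ~0.44 acceptance during burn-in), conjugate normal
updates for group means, and log-scale Metropolis for group SDs.  The
centered parameterization is used deliberately: with 200 informative
trials per subject it mixes better than a non-centered one and admits the
conjugate mean update.

Convergence is monitored with the split-chain Gelman-Rubin statistic
(threshold 1.1) and effective sample sizes.  Model comparison uses WAIC
computed from pointwise (per-trial) log-likelihoods, reported with a
standard error; ranking ties within one SE are reported, not broken.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels as _k
from .core import (
    PARAM_NAMES,
    ActionDDMParams,
    ModelVariant,
    link_to_params,
    make_variant,
    params_to_link,
    trials_to_arrays,
)
from .task import SubjectData

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "ConvergenceReport",
    "ComparisonTable",
    "fit_hierarchical",
    "fit_subject",
    "rhat",
    "compare_models",
    "waic",
    "extract_subject_estimates",
]

#: group-mean hyperprior (normal, link scale) and group-SD half-normal scales
PRIOR_MEAN_LOC = {"alpha": -1.5, "B_v": 0.0, "B_z": 0.0, "v_intercept": 1.0,
                  "a": 0.0, "t": 0.3}
PRIOR_MEAN_SCALE = {"alpha": 1.5, "B_v": 2.0, "B_z": 2.0, "v_intercept": 2.0,
                    "a": 1.0, "t": 0.5}
PRIOR_SD_SCALE = {"alpha": 1.0, "B_v": 1.0, "B_z": 1.0, "v_intercept": 1.0,
                  "a": 0.5, "t": 0.15}

RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings.  ``paper`` profile: 3 runs of 10,000 iterations with
    5,000 burn-in, every 5th retained; ``fast`` profile: 3 shorter adaptive
    chains for desk-scale work."""

    chains: int = 3
    iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0

    @classmethod
    def paper(cls, seed: int = 0) -> "MCMCConfig":
        return cls(seed=seed)

    @classmethod
    def fast(cls, seed: int = 0) -> "MCMCConfig":
        return cls(chains=3, iterations=4_200, burn_in=1_500, thin=3, seed=seed)

    @property
    def n_kept(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorDraws:
    """MCMC output: group-level and subject-level draws (link scale).

    ``group_mean``/``group_sd``: (chains, draws, 6); ``subject``:
    (chains, draws, n_subjects, 6).  ``free`` marks sampled parameters.
    """

    group_mean: np.ndarray
    group_sd: np.ndarray
    subject: np.ndarray
    subject_ids: list
    variant: ModelVariant
    config: MCMCConfig
    free: np.ndarray
    literal_sign: bool = False

    @property
    def n_subjects(self) -> int:
        return self.subject.shape[2]

    def flat_subject(self) -> np.ndarray:
        """Subject draws pooled over chains: (total_draws, n_subjects, 6)."""
        c, d, n, p = self.subject.shape
        return self.subject.reshape(c * d, n, p)

    def parameter_series(self) -> dict:
        """Named per-chain draw series for every sampled scalar parameter."""
        out = {}
        for j, p in enumerate(PARAM_NAMES):
            if not self.free[j]:
                continue
            out[f"mu_{p}"] = self.group_mean[:, :, j]
            out[f"sd_{p}"] = self.group_sd[:, :, j]
            for i, sid in enumerate(self.subject_ids):
                out[f"{p}[{sid}]"] = self.subject[:, :, i, j]
        return out

    def save(self, path: str | Path) -> None:
        """Persist draws and metadata as .npz + JSON sidecar."""
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            group_mean=self.group_mean,
            group_sd=self.group_sd,
            subject=self.subject,
            free=self.free,
        )
        meta = {
            "subject_ids": list(self.subject_ids),
            "variant": self.variant.name,
            "literal_sign": self.literal_sign,
            "config": self.config.__dict__,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


@dataclass
class ConvergenceReport:
    """Per-parameter split-chain R-hat and effective sample sizes."""

    rhat: pd.Series
    ess: pd.Series
    max_rhat: float
    converged: bool
    threshold: float = RHAT_THRESHOLD

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "max_rhat": self.max_rhat,
                    "converged": bool(self.converged),
                    "threshold": self.threshold,
                    "rhat": self.rhat.to_dict(),
                    "ess": self.ess.to_dict(),
                },
                indent=2,
            )
        )


def rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``draws`` is (chains, iterations).  Each chain is split in half, the
    between- and within-chain variances of the resulting 2m sequences are
    compared.  Identical chains give 1.0; chains stuck at distinct
    constants give infinity (flagged by the zero within-chain variance
    limit).
    """
    x = np.asarray(draws, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need (chains >= 2, draws >= 2)")
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _pack_data(data: list[SubjectData], min_trials: int = 1):
    """Pad subject trial arrays into rectangular kernel inputs."""
    packed = [trials_to_arrays(s.trials) for s in data]
    ntr = np.array([len(p[0]) for p in packed], dtype=np.int64)
    for s, n in zip(data, ntr):
        if n < min_trials:
            raise ValueError(
                f"subject {s.subject_id!r} has {n} trials; need >= {min_trials}"
            )
    mx = int(ntr.max())
    nsub = len(data)
    stim = np.zeros((nsub, mx), dtype=np.int8)
    resp = np.zeros((nsub, mx), dtype=np.int8)
    rt = np.zeros((nsub, mx), dtype=np.float64)
    rew = np.zeros((nsub, mx), dtype=np.int8)
    valid = np.zeros((nsub, mx), dtype=np.bool_)
    for i, (st, rs, r, rw, va) in enumerate(packed):
        stim[i, : ntr[i]] = st
        resp[i, : ntr[i]] = rs
        rt[i, : ntr[i]] = r
        rew[i, : ntr[i]] = rw
        valid[i, : ntr[i]] = va
    return stim, resp, rt, rew, valid, ntr


def _initial_state(
    data_rt: np.ndarray,
    valid: np.ndarray,
    variant: ModelVariant,
    rng: np.random.Generator,
    nsub: int,
):
    """Chain-specific jittered initialization on the link scale."""
    mu0 = np.array([PRIOR_MEAN_LOC[p] for p in PARAM_NAMES])
    sig0 = np.array([PRIOR_SD_SCALE[p] for p in PARAM_NAMES]) * 0.5
    # start v_intercept positive and t safely below each subject's min RT
    mu0[3] = 1.5
    free = variant.free_mask
    fixed_link = np.zeros(6)
    for name, val in variant.fixed.items():
        fixed_link[PARAM_NAMES.index(name)] = val  # identity-link params only
    theta0 = np.empty((nsub, 6))
    min_rt = np.array(
        [
            data_rt[i][valid[i]].min() if valid[i].any() else 1.0
            for i in range(nsub)
        ]
    )
    for j in range(6):
        if not free[j] and not (variant.tied and j == 2):
            theta0[:, j] = fixed_link[j]
        else:
            theta0[:, j] = mu0[j] + 0.1 * rng.standard_normal(nsub)
    theta0[:, 5] = np.minimum(0.6 * min_rt, 0.4) * (1 + 0.05 * rng.standard_normal(nsub))
    mu0 = mu0 + 0.1 * rng.standard_normal(6)
    mu0[5] = float(np.mean(theta0[:, 5]))
    if variant.tied:
        theta0[:, 2] = theta0[:, 1]
    return mu0, sig0, theta0


def fit_hierarchical(
    data: list[SubjectData],
    variant: str | ModelVariant = "full",
    mcmc: MCMCConfig | None = None,
    literal_sign: bool = False,
    min_trials: int = 50,
) -> tuple[PosteriorDraws, ConvergenceReport]:
    """Fit the hierarchical Action-DDM (or a lesioned variant) by MCMC.

    Runs ``mcmc.chains`` independent chains and reports split-chain R-hat
    for every sampled parameter (group means, group SDs and subject-level
    parameters).  Non-convergence (max R-hat above 1.1) emits a warning;
    draws are returned either way.
    """
    variant = make_variant(variant)
    mcmc = mcmc or MCMCConfig.fast()
    stim, resp, rt, rew, valid, ntr = _pack_data(data, min_trials)
    nsub = len(data)
    free = variant.free_mask
    m0 = np.array([PRIOR_MEAN_LOC[p] for p in PARAM_NAMES])
    s0 = np.array([PRIOR_MEAN_SCALE[p] for p in PARAM_NAMES])
    sscale = np.array([PRIOR_SD_SCALE[p] for p in PARAM_NAMES])

    gm, gs, su = [], [], []
    root = np.random.SeedSequence(mcmc.seed)
    for c, ss in enumerate(root.spawn(mcmc.chains)):
        rng = np.random.default_rng(ss)
        mu0, sig0, theta0 = _initial_state(rt, valid, variant, rng, nsub)
        dmu, dsig, dth = _k.run_chain(
            stim, resp, rt, rew, valid, ntr,
            free, variant.tied, literal_sign,
            m0, s0, sscale,
            mcmc.iterations, mcmc.burn_in, mcmc.thin,
            int(rng.integers(0, 2**31 - 1)),
            mu0, sig0, theta0,
        )
        gm.append(dmu)
        gs.append(dsig)
        su.append(dth)
    draws = PosteriorDraws(
        group_mean=np.stack(gm),
        group_sd=np.stack(gs),
        subject=np.stack(su),
        subject_ids=[s.subject_id for s in data],
        variant=variant,
        config=mcmc,
        free=free,
        literal_sign=literal_sign,
    )
    report = convergence_report(draws)
    if not report.converged:
        warnings.warn(
            f"MCMC may not have converged: max R-hat {report.max_rhat:.3f} "
            f"> {report.threshold}",
            stacklevel=2,
        )
    return draws, report


def convergence_report(draws: PosteriorDraws) -> ConvergenceReport:
    """Split-chain R-hat and bulk ESS for every sampled parameter."""
    series = draws.parameter_series()
    rh = pd.Series({k: rhat(v) for k, v in series.items()})
    import arviz as az

    ess = pd.Series(
        {k: float(az.ess(np.asarray(v), method="bulk")) for k, v in series.items()}
    )
    mx = float(rh.max())
    return ConvergenceReport(rhat=rh, ess=ess, max_rhat=mx, converged=mx <= RHAT_THRESHOLD)


def fit_subject(
    subject: SubjectData,
    variant: str | ModelVariant = "full",
    mcmc: MCMCConfig | None = None,
    literal_sign: bool = False,
) -> tuple[np.ndarray, ConvergenceReport]:
    """Non-hierarchical single-subject fit with fixed weak priors.

    Returns draws of shape (chains, kept, 6) on the link scale.
    """
    variant = make_variant(variant)
    mcmc = mcmc or MCMCConfig.fast()
    stim, resp, rt, rew, valid = trials_to_arrays(subject.trials)
    prior_m = np.array([PRIOR_MEAN_LOC[p] for p in PARAM_NAMES])
    prior_s = np.array([PRIOR_MEAN_SCALE[p] for p in PARAM_NAMES])
    free = variant.free_mask
    chains = []
    root = np.random.SeedSequence(mcmc.seed)
    for ss in root.spawn(mcmc.chains):
        rng = np.random.default_rng(ss)
        th0 = prior_m + 0.1 * rng.standard_normal(6)
        th0[3] = 1.5
        th0[5] = min(0.6 * float(rt[valid].min()) if valid.any() else 0.3, 0.4)
        for name, val in variant.fixed.items():
            th0[PARAM_NAMES.index(name)] = val
        if variant.tied:
            th0[2] = th0[1]
        chains.append(
            _k.run_subject_chain(
                stim, resp, rt, rew, valid, len(stim),
                free, variant.tied, literal_sign,
                prior_m, prior_s,
                mcmc.iterations, mcmc.burn_in, mcmc.thin,
                int(rng.integers(0, 2**31 - 1)), th0,
            )
        )
    arr = np.stack(chains)
    rh = pd.Series(
        {
            PARAM_NAMES[j]: rhat(arr[:, :, j])
            for j in range(6)
            if free[j] or (variant.tied and j == 1)
        }
    )
    import arviz as az

    ess = pd.Series(
        {
            PARAM_NAMES[j]: float(az.ess(arr[:, :, j], method="bulk"))
            for j in range(6)
            if free[j]
        }
    )
    mx = float(rh.max())
    return arr, ConvergenceReport(rhat=rh, ess=ess, max_rhat=mx, converged=mx <= RHAT_THRESHOLD)


def extract_subject_estimates(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior means and central 95% intervals per subject (natural scale).

    Returns a DataFrame keyed by ``subject_id`` with columns
    ``<param>``, ``<param>_lo``, ``<param>_hi``.
    """
    flat = draws.flat_subject()  # (draws, nsub, 6)
    nat = np.empty_like(flat)
    nat[:, :, :] = flat
    nat[:, :, 0] = 1.0 / (1.0 + np.exp(-flat[:, :, 0]))
    nat[:, :, 4] = np.exp(flat[:, :, 4])
    rows = {}
    for i, sid in enumerate(draws.subject_ids):
        row = {}
        for j, p in enumerate(PARAM_NAMES):
            v = nat[:, i, j]
            row[p] = float(v.mean())
            lo, hi = np.percentile(v, [2.5, 97.5])
            row[f"{p}_lo"] = float(lo)
            row[f"{p}_hi"] = float(hi)
        rows[sid] = row
    out = pd.DataFrame(rows).T
    out.index.name = "subject_id"
    return out


@dataclass
class ComparisonTable:
    """WAIC model comparison across variants (higher elpd is better)."""

    table: pd.DataFrame  # index: variant; columns elpd, se, p_waic, rank, d_elpd, d_se

    def best(self) -> str:
        return str(self.table.index[0])


def waic(
    draws: PosteriorDraws, data: list[SubjectData], max_draws: int = 400
) -> tuple[float, float, float]:
    """WAIC from pointwise per-trial log-likelihoods.

    Returns (elpd_waic, se, p_waic).  ``max_draws`` thins the pooled
    posterior for the pointwise evaluation.
    """
    stim, resp, rt, rew, valid, ntr = _pack_data(data)
    flat = draws.flat_subject()
    if len(flat) > max_draws:
        idx = np.linspace(0, len(flat) - 1, max_draws).astype(int)
        flat = flat[idx]
    ll = _k.pointwise_loglik(
        stim, resp, rt, rew, valid, ntr, flat, draws.literal_sign
    )  # (draws, points)
    nmax = ll.max(axis=0)
    lppd_i = nmax + np.log(np.exp(ll - nmax).mean(axis=0))
    p_i = ll.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    n = ll.shape[1]
    se = float(np.sqrt(n * elpd_i.var(ddof=1)))
    return float(elpd_i.sum()), se, float(p_i.sum())


def compare_models(
    data: list[SubjectData],
    variants: list | tuple = None,
    mcmc: MCMCConfig | None = None,
    fits: dict | None = None,
) -> ComparisonTable:
    """Fit each variant to the same data and rank by WAIC.

    ``fits`` may supply pre-computed :class:`PosteriorDraws` keyed by
    variant name (every requested variant must then be present).  The
    table reports elpd differences from the best model with the paired
    pointwise SE of the difference; differences within one SE are ties.
    """
    from .core import VARIANT_NAMES

    names = [make_variant(v).name for v in (variants or VARIANT_NAMES)]
    if "full" not in names:
        raise ValueError("the full model must be included as reference")
    results = {}
    elpd_pointwise = {}
    stim, resp, rt, rew, valid, ntr = _pack_data(data)
    for name in names:
        if fits is not None:
            if name not in fits:
                raise ValueError(f"missing fit for variant {name!r}")
            dr = fits[name]
        else:
            dr, _ = fit_hierarchical(data, name, mcmc)
        flat = dr.flat_subject()
        if len(flat) > 400:
            idx = np.linspace(0, len(flat) - 1, 400).astype(int)
            flat = flat[idx]
        ll = _k.pointwise_loglik(stim, resp, rt, rew, valid, ntr, flat, dr.literal_sign)
        nmax = ll.max(axis=0)
        lppd_i = nmax + np.log(np.exp(ll - nmax).mean(axis=0))
        p_i = ll.var(axis=0, ddof=1)
        elpd_i = lppd_i - p_i
        n = ll.shape[1]
        results[name] = {
            "elpd_waic": float(elpd_i.sum()),
            "se": float(np.sqrt(n * elpd_i.var(ddof=1))),
            "p_waic": float(p_i.sum()),
        }
        elpd_pointwise[name] = elpd_i
    tab = pd.DataFrame(results).T.sort_values("elpd_waic", ascending=False)
    best = tab.index[0]
    d, dse, tie = [], [], []
    for name in tab.index:
        diff = elpd_pointwise[best] - elpd_pointwise[name]
        d.append(float(diff.sum()))
        s = float(np.sqrt(len(diff) * diff.var(ddof=1))) if name != best else 0.0
        dse.append(s)
        tie.append(name != best and d[-1] <= s)
    tab["d_elpd"] = d
    tab["d_se"] = dse
    tab["tied_with_best"] = tie
    tab["rank"] = np.arange(1, len(tab) + 1)
    return ComparisonTable(table=tab)
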