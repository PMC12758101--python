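"""Posterior predictive checks and parameter recovery.

The PPC harness re-simulates each subject from draws of their posterior
(by default 20 datasets per subject, 200 trials each) and compares
simulated to observed behavior on the statistics that characterize PRT
performance: accuracy by stimulus type for fast vs slow responses,
response bias and discriminability over eight 25-trial bins, and RT
summaries over four 50-trial bins (correct and error RTs separately; the
sign-flip of error RTs is a plotting convention only).  Observed and
simulated statistics go through the same code path (:mod:`prtddm.stats`).

The recovery harness simulates one session per row of a ground-truth
parameter table, refits (hierarchically by default, per-subject
optionally) and correlates truths with posterior means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ActionDDMParams, PARAM_NAMES, link_to_params
from .inference import (
    MCMCConfig,
    PosteriorDraws,
    extract_subject_estimates,
    fit_hierarchical,
    fit_subject,
)
from .simulate import simulate_subject
from .stats import (
    accuracy_counts,
    discriminability,
    response_bias,
    rt_speed_contrast,
)
from .task import SubjectData, generate_schedule

__all__ = [
    "PPCReport",
    "RecoveryReport",
    "posterior_predictive",
    "parameter_recovery",
    "bias_trajectory",
    "rt_bin_summary",
]

N_BIAS_BINS = 8
BIAS_BIN_TRIALS = 25
N_RT_BINS = 4
RT_BIN_TRIALS = 50


def bias_trajectory(trials: pd.DataFrame, base: float = 10.0) -> pd.DataFrame:
    """Response bias and discriminability in successive 25-trial bins."""
    rows = []
    for b in range(N_BIAS_BINS):
        sl = trials.iloc[b * BIAS_BIN_TRIALS : (b + 1) * BIAS_BIN_TRIALS]
        rc, ri, lc, li = accuracy_counts(sl)
        rows.append(
            {
                "bin": b + 1,
                "response_bias": response_bias(rc, ri, lc, li, base),
                "discriminability": discriminability(rc, ri, lc, li, base),
            }
        )
    return pd.DataFrame(rows)


def rt_bin_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean correct/error RT by stimulus in successive 50-trial bins."""
    rows = []
    for b in range(N_RT_BINS):
        sl = trials.iloc[b * RT_BIN_TRIALS : (b + 1) * RT_BIN_TRIALS]
        df = sl[sl["response"] != "none"]
        if "valid" in df.columns:
            df = df[df["valid"]]
        row = {"bin": b + 1}
        for stimulus in ("rich", "lean"):
            s = df[df["stimulus"] == stimulus]
            for label, mask in (("correct", s["correct"]), ("error", ~s["correct"])):
                v = s.loc[mask, "rt"]
                row[f"{stimulus}_{label}_rt"] = float(v.mean()) if len(v) else np.nan
                row[f"{stimulus}_{label}_n"] = int(len(v))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PPCReport:
    """Observed-vs-simulated posterior predictive summaries.

    ``speed_accuracy``: accuracy by stimulus x fast/slow, observed and
    simulated means; ``trajectory``: per-bin response bias and
    discriminability; ``rt_bins``: per-bin correct/error RT means;
    ``discrepancy``: observed minus simulated for each statistic.
    """

    speed_accuracy: pd.DataFrame
    trajectory: pd.DataFrame
    rt_bins: pd.DataFrame
    n_datasets: int
    n_subjects: int

    @property
    def discrepancy(self) -> pd.DataFrame:
        rows = []
        for df, keys in (
            (self.speed_accuracy, ["speed", "measure"]),
            (self.trajectory, ["bin", "measure"]),
            (self.rt_bins, ["bin", "measure"]),
        ):
            for _, r in df.iterrows():
                rows.append(
                    {
                        "statistic": ":".join(str(r[k]) for k in keys),
                        "observed": r["observed"],
                        "simulated": r["simulated"],
                        "difference": r["observed"] - r["simulated"],
                    }
                )
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "n_datasets": self.n_datasets,
            "n_subjects": self.n_subjects,
            "speed_accuracy": self.speed_accuracy.to_dict(orient="records"),
            "trajectory": self.trajectory.to_dict(orient="records"),
            "rt_bins": self.rt_bins.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=2))

    def plot(self, path: str | Path | None = None):
        """Three-panel observed-vs-simulated figure."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
        sa = self.speed_accuracy.pivot_table(
            index="speed", columns="measure", values=["observed", "simulated"]
        )
        sa.plot.bar(ax=axes[0], rot=0)
        axes[0].set_ylabel("accuracy")
        axes[0].set_title("accuracy by RT speed")
        tr = self.trajectory
        for meas, color in (("response_bias", "C0"), ("discriminability", "C1")):
            m = tr[tr["measure"] == meas]
            axes[1].plot(m["bin"], m["observed"], "o-", color=color, label=f"{meas} obs")
            axes[1].plot(m["bin"], m["simulated"], "s--", color=color, alpha=0.6,
                         label=f"{meas} sim")
        axes[1].set_xlabel("25-trial bin")
        axes[1].legend(fontsize=7)
        axes[1].set_title("bias / discriminability over bins")
        rb = self.rt_bins
        for meas in rb["measure"].unique():
            m = rb[rb["measure"] == meas]
            sign = -1.0 if "error" in meas else 1.0
            axes[2].plot(m["bin"], sign * m["observed"], "o-", label=f"{meas} obs")
            axes[2].plot(m["bin"], sign * m["simulated"], "s--", alpha=0.6)
        axes[2].set_xlabel("50-trial bin")
        axes[2].set_ylabel("RT (s; errors flipped)")
        axes[2].legend(fontsize=6)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def _subject_statistics(trials: pd.DataFrame) -> dict:
    """All PPC statistics for one dataset (observed or simulated)."""
    sa = rt_speed_contrast(trials)
    traj = bias_trajectory(trials)
    rtb = rt_bin_summary(trials)
    out = {}
    for speed in ("fast", "slow"):
        out[("speed", speed, "rich_acc")] = sa.loc[speed, "rich_acc"]
        out[("speed", speed, "lean_acc")] = sa.loc[speed, "lean_acc"]
        out[("speed", speed, "contrast")] = sa.loc[speed, "contrast"]
    for _, r in traj.iterrows():
        out[("traj", int(r["bin"]), "response_bias")] = r["response_bias"]
        out[("traj", int(r["bin"]), "discriminability")] = r["discriminability"]
    for _, r in rtb.iterrows():
        for m in ("rich_correct_rt", "lean_correct_rt", "rich_error_rt", "lean_error_rt"):
            out[("rt", int(r["bin"]), m)] = r[m]
    return out


def posterior_predictive(
    draws: PosteriorDraws,
    data: list[SubjectData],
    n_datasets: int = 20,
    n_trials: int = 200,
    seed: int = 0,
    reward_mode: str = "replay",
) -> PPCReport:
    """Simulate from subject posteriors and compare with the data.

    For each subject, ``n_datasets`` parameter draws are taken from their
    posterior and one ``n_trials``-trial session is simulated per draw.
    ``reward_mode='replay'`` reuses each subject's own schedule (stimulus
    order and scheduled rewards); ``'redraw'`` generates a fresh schedule
    per simulated dataset.
    """
    if [s.subject_id for s in data] != list(draws.subject_ids):
        raise ValueError("draws and data subjects do not match")
    if reward_mode not in ("replay", "redraw"):
        raise ValueError("reward_mode must be 'replay' or 'redraw'")
    rng = np.random.default_rng(seed)
    flat = draws.flat_subject()
    obs_rows, sim_rows = [], []
    for i, subj in enumerate(data):
        obs_rows.append(_subject_statistics(subj.trials.iloc[:n_trials]))
        idx = rng.integers(0, len(flat), size=n_datasets)
        for d in idx:
            params = link_to_params(flat[d, i])
            if reward_mode == "replay":
                sched = subj.trials.iloc[:n_trials][
                    ["block", "trial", "stimulus", "mouth", "reward_scheduled"]
                ].reset_index(drop=True)
            else:
                sched = generate_schedule(rng).iloc[:n_trials]
            sim = simulate_subject(params, sched, rng, subject_id=subj.subject_id)
            sim_rows.append(_subject_statistics(sim.trials))
    obs = pd.DataFrame(obs_rows).mean()
    sim = pd.DataFrame(sim_rows).mean()

    def collect(kind, key_name):
        rows = []
        for key in obs.index:
            if key[0] != kind:
                continue
            rows.append(
                {
                    key_name: key[1],
                    "measure": key[2],
                    "observed": obs[key],
                    "simulated": sim[key],
                }
            )
        return pd.DataFrame(rows)

    return PPCReport(
        speed_accuracy=collect("speed", "speed"),
        trajectory=collect("traj", "bin"),
        rt_bins=collect("rt", "bin"),
        n_datasets=n_datasets,
        n_subjects=len(data),
    )


@dataclass
class RecoveryReport:
    """Truth-vs-estimate agreement per parameter."""

    table: pd.DataFrame  # index: parameter; columns r, bias, rmse
    scatter: pd.DataFrame  # subject_id, parameter, truth, estimate
    n_subjects: int
    non_converged: int

    def r(self, param: str) -> float:
        return float(self.table.loc[param, "r"])


def parameter_recovery(
    truths: pd.DataFrame,
    fit_config: MCMCConfig | None = None,
    mode: str = "hierarchical",
    seed: int = 0,
    delivery_rule: str = "bernoulli",
    variant: str = "full",
) -> RecoveryReport:
    """Simulate one session per truth row, refit, and correlate.

    ``truths`` needs the six parameter columns (plus optional
    ``subject_id``).  ``mode`` selects hierarchical (default) or
    per-subject refitting.  Non-convergent refits are counted and
    reported, never dropped.
    """
    if mode not in ("hierarchical", "per_subject"):
        raise ValueError("mode must be 'hierarchical' or 'per_subject'")
    fit_config = fit_config or MCMCConfig.fast()
    rng = np.random.default_rng(seed)
    ids = (
        truths["subject_id"].astype(str).tolist()
        if "subject_id" in truths.columns
        else [f"S{i:03d}" for i in range(len(truths))]
    )
    subjects = []
    for i, sid in enumerate(ids):
        params = ActionDDMParams(**{p: float(truths.iloc[i][p]) for p in PARAM_NAMES})
        sched = generate_schedule(rng, delivery_rule=delivery_rule)
        subjects.append(
            simulate_subject(params, sched, rng, subject_id=sid,
                             delivery_rule=delivery_rule)
        )
    non_conv = 0
    if mode == "hierarchical":
        draws, rep = fit_hierarchical(subjects, variant, fit_config)
        non_conv = int(not rep.converged)
        est = extract_subject_estimates(draws)
    else:
        rows = {}
        for k, s in enumerate(subjects):
            cfg = MCMCConfig(
                chains=fit_config.chains,
                iterations=fit_config.iterations,
                burn_in=fit_config.burn_in,
                thin=fit_config.thin,
                seed=fit_config.seed + k,
            )
            arr, rep = fit_subject(s, variant, cfg)
            non_conv += int(not rep.converged)
            flat = arr.reshape(-1, 6)
            nat = np.column_stack(
                [
                    1.0 / (1.0 + np.exp(-flat[:, 0])),
                    flat[:, 1], flat[:, 2], flat[:, 3],
                    np.exp(flat[:, 4]), flat[:, 5],
                ]
            )
            rows[s.subject_id] = dict(zip(PARAM_NAMES, nat.mean(axis=0)))
        est = pd.DataFrame(rows).T

    scatter_rows = []
    stats_rows = {}
    for p in PARAM_NAMES:
        tr = truths[p].to_numpy(dtype=float)
        es = est.loc[ids, p].to_numpy(dtype=float)
        for sid, a, b in zip(ids, tr, es):
            scatter_rows.append(
                {"subject_id": sid, "parameter": p, "truth": a, "estimate": b}
            )
        stats_rows[p] = {
            "r": float(np.corrcoef(tr, es)[0, 1]) if np.std(tr) > 0 else np.nan,
            "bias": float(np.mean(es - tr)),
            "rmse": float(np.sqrt(np.mean((es - tr) ** 2))),
        }
    return RecoveryReport(
        table=pd.DataFrame(stats_rows).T,
        scatter=pd.DataFrame(scatter_rows),
        n_subjects=len(ids),
        non_converged=non_conv,
    )
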