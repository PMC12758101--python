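"""Probabilistic Reward Task (PRT) data model, schedule generation, QC and IO.

The PRT is a signal-detection task: on each trial a face with a short or a
long mouth is flashed and the participant reports which was shown.  Correct
identifications of one stimulus (the "rich" stimulus) are rewarded three
times more often than correct identifications of the other ("lean")
stimulus, which induces a response bias toward the rich response.

A session is two 100-trial blocks with 50 rich and 50 lean trials per block
in randomized order.  Trial tables are stored as delimited text with RTs in
milliseconds on disk; in memory RTs are seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TRIALS_PER_BLOCK",
    "N_BLOCKS",
    "RESPONSE_DEADLINE",
    "SubjectData",
    "QCReport",
    "generate_schedule",
    "apply_quality_control",
    "read_trials",
    "write_trials",
]

TRIALS_PER_BLOCK = 100
N_BLOCKS = 2
#: per-block trial count of each stimulus type (equal rich/lean frequency)
STIM_PER_BLOCK = TRIALS_PER_BLOCK // 2
#: response deadline in seconds
RESPONSE_DEADLINE = 2.0
#: scheduled-reward probabilities on correct responses (rich = 3 x lean)
P_REWARD_RICH = 0.60
P_REWARD_LEAN = 0.20
#: exact per-block scheduled-reward counts under the queued delivery rule
QUEUED_RICH_PER_BLOCK = 30
QUEUED_LEAN_PER_BLOCK = 10

#: canonical column order of an in-memory trial table
SCHEDULE_COLUMNS = ["block", "trial", "stimulus", "mouth", "reward_scheduled"]
TRIAL_COLUMNS = SCHEDULE_COLUMNS + ["response", "rt", "correct", "reward"]
#: on-disk column order (rt in milliseconds)
FILE_COLUMNS = [
    "subject", "block", "trial", "stimulus", "mouth",
    "response", "rt_ms", "reward",
]


@dataclass
class SubjectData:
    """One participant's PRT session plus optional covariates.

    ``trials`` is a DataFrame with columns :data:`TRIAL_COLUMNS` (a pure
    schedule may omit the behavioral columns).  ``valid`` is added by
    :func:`apply_quality_control`.
    """

    subject_id: str
    trials: pd.DataFrame
    group: str | None = None
    symptom_score: float | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        t = self.trials["trial"].to_numpy()
        if len(t) == 0:
            raise ValueError("subject has no trials")
        if not np.all(np.diff(t) > 0):
            raise ValueError("trial index must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def valid_trials(self) -> pd.DataFrame:
        if "valid" not in self.trials.columns:
            return self.trials
        return self.trials[self.trials["valid"]]


@dataclass
class QCReport:
    subject_id: str
    n_trials: int
    n_no_response: int
    n_rt_too_fast: int
    n_rt_too_slow: int
    invalid_fraction: float
    exclude_subject: bool

    @property
    def n_invalid(self) -> int:
        return self.n_no_response + self.n_rt_too_fast + self.n_rt_too_slow


def generate_schedule(
    seed: int | np.random.Generator,
    counterbalance: str = "short_rich",
    delivery_rule: str = "bernoulli",
    p_rich: float = P_REWARD_RICH,
    p_lean: float = P_REWARD_LEAN,
) -> pd.DataFrame:
    """Generate one PRT session schedule (2 blocks x 100 trials).

    Each block holds 50 rich and 50 lean trials in random order.  The
    ``reward_scheduled`` flag marks trials on which a reward is available
    provided the response is correct; rich-correct trials are scheduled
    3x as often as lean-correct trials.

    Parameters
    ----------
    seed
        Integer seed or an existing :class:`numpy.random.Generator`.
    counterbalance
        ``short_rich`` or ``long_rich`` — which mouth length is assigned to
        the rich condition.
    delivery_rule
        ``bernoulli`` draws ``reward_scheduled`` per trial with probability
        ``p_rich``/``p_lean``; ``queued`` fixes exact per-block counts
        (30 rich, 10 lean) — undelivered rewards are re-queued at
        simulation/delivery time.
    """
    if counterbalance not in ("short_rich", "long_rich"):
        raise ValueError(f"unknown counterbalance {counterbalance!r}")
    if delivery_rule not in ("bernoulli", "queued"):
        raise ValueError(f"unknown delivery_rule {delivery_rule!r}")
    if not (0.0 < p_lean < 1.0 and 0.0 < p_rich < 1.0):
        raise ValueError("reward probabilities must lie in (0, 1)")
    if abs(p_rich - 3.0 * p_lean) > 1e-12:
        raise ValueError(
            "task design requires a 3:1 reward asymmetry: p_rich == 3 * p_lean"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    blocks = []
    for block in range(1, N_BLOCKS + 1):
        stim = np.array(["rich"] * STIM_PER_BLOCK + ["lean"] * STIM_PER_BLOCK)
        rng.shuffle(stim)
        is_rich = stim == "rich"
        if delivery_rule == "bernoulli":
            p = np.where(is_rich, p_rich, p_lean)
            scheduled = rng.random(TRIALS_PER_BLOCK) < p
        else:  # queued: exact counts per block
            scheduled = np.zeros(TRIALS_PER_BLOCK, dtype=bool)
            rich_idx = np.flatnonzero(is_rich)
            lean_idx = np.flatnonzero(~is_rich)
            scheduled[rng.choice(rich_idx, QUEUED_RICH_PER_BLOCK, replace=False)] = True
            scheduled[rng.choice(lean_idx, QUEUED_LEAN_PER_BLOCK, replace=False)] = True
        blocks.append(
            pd.DataFrame(
                {
                    "block": block,
                    "trial": np.arange(1, TRIALS_PER_BLOCK + 1)
                    + (block - 1) * TRIALS_PER_BLOCK,
                    "stimulus": stim,
                    "reward_scheduled": scheduled,
                }
            )
        )
    out = pd.concat(blocks, ignore_index=True)
    if counterbalance == "short_rich":
        out["mouth"] = np.where(out["stimulus"] == "rich", "short", "long")
    else:
        out["mouth"] = np.where(out["stimulus"] == "rich", "long", "short")
    out.attrs["delivery_rule"] = delivery_rule
    out.attrs["counterbalance"] = counterbalance
    return out[SCHEDULE_COLUMNS]


def apply_quality_control(
    subject: SubjectData,
    rt_min: float = 0.150,
    rt_max: float = RESPONSE_DEADLINE,
    max_invalid_frac: float = 0.20,
) -> tuple[SubjectData, QCReport]:
    """Flag invalid trials and decide subject-level exclusion.

    A trial is invalid if no response was made or its RT falls outside
    ``[rt_min, rt_max]`` seconds.  Invalid trials are kept in the table
    (flagged ``valid=False``) so that any feedback they produced can still
    drive learning; they are excluded from the likelihood downstream.  The
    subject is flagged for exclusion when the invalid fraction exceeds
    ``max_invalid_frac``.  Idempotent.
    """
    df = subject.trials.copy()
    if len(df) == 0:
        raise ValueError("empty trial list")
    no_resp = df["response"].to_numpy() == "none"
    rt = df["rt"].to_numpy(dtype=float)
    too_fast = (~no_resp) & (rt < rt_min)
    too_slow = (~no_resp) & (rt > rt_max)
    df["valid"] = ~(no_resp | too_fast | too_slow)
    frac = float(1.0 - df["valid"].mean())
    report = QCReport(
        subject_id=subject.subject_id,
        n_trials=len(df),
        n_no_response=int(no_resp.sum()),
        n_rt_too_fast=int(too_fast.sum()),
        n_rt_too_slow=int(too_slow.sum()),
        invalid_fraction=frac,
        exclude_subject=frac > max_invalid_frac,
    )
    return replace(subject, trials=df), report


class TrialTableError(ValueError):
    """Raised when a trial table on disk violates the format contract."""


def write_trials(subjects: Iterable[SubjectData] | SubjectData, path: str | Path) -> None:
    """Write subjects to one CSV trial table (RT in integer-free ms)."""
    if isinstance(subjects, SubjectData):
        subjects = [subjects]
    frames = []
    for s in subjects:
        df = s.trials.copy()
        df.insert(0, "subject", s.subject_id)
        df["rt_ms"] = df["rt"] * 1000.0
        frames.append(df[FILE_COLUMNS + ["reward_scheduled"]])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


def read_trials(path: str | Path) -> list[SubjectData]:
    """Read a CSV trial table into :class:`SubjectData` records.

    RTs are converted from milliseconds to seconds.  Missing columns,
    non-monotone trial indices and out-of-range RTs raise
    :class:`TrialTableError` naming the offending column or subject.
    """
    df = pd.read_csv(path)
    missing = [c for c in FILE_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"missing required column(s): {', '.join(missing)}")
    if "reward_scheduled" not in df.columns:
        df["reward_scheduled"] = df["reward"].astype(bool)
    bad_rt = df["rt_ms"].dropna()
    if ((bad_rt < 0) | (bad_rt > 60_000)).any():
        raise TrialTableError("column rt_ms outside representable range [0, 60000]")
    out: list[SubjectData] = []
    for sid, g in df.groupby("subject", sort=False):
        g = g.reset_index(drop=True)
        t = g["trial"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise TrialTableError(f"non-monotone trial index for subject {sid!r}")
        trials = g[["block", "trial", "stimulus", "mouth", "reward_scheduled"]].copy()
        trials["response"] = g["response"].fillna("none")
        trials["rt"] = g["rt_ms"] / 1000.0
        trials["correct"] = (trials["response"] == trials["stimulus"]) & (
            trials["response"] != "none"
        )
        trials["reward"] = g["reward"].astype(int)
        out.append(SubjectData(subject_id=str(sid), trials=trials[TRIAL_COLUMNS]))
    return out
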