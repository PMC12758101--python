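"""Signal-detection performance statistics and comparison utilities.

Response bias and discriminability are the PRT's standard signal-detection
readouts, computed from the 2x2 table of stimulus (rich/lean) by accuracy
(correct/incorrect) counts with a 0.5 count correction:

    response bias   = 1/2 log( (Rich_c + .5)(Lean_i + .5) / (Rich_i + .5)(Lean_c + .5) )
    discriminability = 1/2 log( (Rich_c + .5)(Lean_c + .5) / (Rich_i + .5)(Lean_i + .5) )

Base-10 logs by default (this reproduces the conventional magnitude range,
e.g. discriminability near 0.66 at ~80% accuracy); natural logs available
via ``base``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task import SubjectData

__all__ = [
    "response_bias",
    "discriminability",
    "accuracy_counts",
    "behavioral_summary",
    "rt_speed_contrast",
    "split_half_reliability",
    "group_compare",
    "symptom_correlation",
    "median_age_split",
    "BehavioralSummary",
    "ReliabilityReport",
]


def _log(x: np.ndarray | float, base: float) -> np.ndarray | float:
    return np.log(x) / np.log(base)


def response_bias(
    rich_correct: float,
    rich_incorrect: float,
    lean_correct: float,
    lean_incorrect: float,
    base: float = 10.0,
) -> float:
    """Log-odds asymmetry favoring the rich response (0.5-corrected)."""
    num = (rich_correct + 0.5) * (lean_incorrect + 0.5)
    den = (rich_incorrect + 0.5) * (lean_correct + 0.5)
    return float(0.5 * _log(num / den, base))


def discriminability(
    rich_correct: float,
    rich_incorrect: float,
    lean_correct: float,
    lean_incorrect: float,
    base: float = 10.0,
) -> float:
    """Log-odds measure of perceptual accuracy independent of bias."""
    num = (rich_correct + 0.5) * (lean_correct + 0.5)
    den = (rich_incorrect + 0.5) * (lean_incorrect + 0.5)
    return float(0.5 * _log(num / den, base))


def accuracy_counts(trials: pd.DataFrame) -> tuple[int, int, int, int]:
    """(rich_correct, rich_incorrect, lean_correct, lean_incorrect) counts.

    Only responded trials (and only QC-valid ones, if flagged) count.
    """
    df = trials
    if "valid" in df.columns:
        df = df[df["valid"]]
    df = df[df["response"] != "none"]
    rich = df["stimulus"] == "rich"
    cor = df["correct"].astype(bool)
    return (
        int((rich & cor).sum()),
        int((rich & ~cor).sum()),
        int((~rich & cor).sum()),
        int((~rich & ~cor).sum()),
    )


@dataclass
class BehavioralSummary:
    """Per-block and session-average PRT performance statistics."""

    subject_id: str
    table: pd.DataFrame  # rows: block 1, block 2, average
    bias_change: float | None  # block2 - block1 response bias

    def row(self, block: str) -> pd.Series:
        return self.table.loc[block]


def _summarize_block(trials: pd.DataFrame, base: float) -> dict:
    rc, ri, lc, li = accuracy_counts(trials)
    df = trials
    if "valid" in df.columns:
        df = df[df["valid"]]
    df = df[df["response"] != "none"]
    rich = df["stimulus"] == "rich"
    cor = df["correct"].astype(bool)

    def mean_rt(mask):
        v = df.loc[mask, "rt"]
        return float(v.mean()) if len(v) else np.nan

    return {
        "response_bias": response_bias(rc, ri, lc, li, base),
        "discriminability": discriminability(rc, ri, lc, li, base),
        "rich_acc": rc / (rc + ri) if rc + ri else np.nan,
        "lean_acc": lc / (lc + li) if lc + li else np.nan,
        "rich_rt": mean_rt(rich),
        "lean_rt": mean_rt(~rich),
        "rich_correct_rt": mean_rt(rich & cor),
        "lean_correct_rt": mean_rt(~rich & cor),
        "rich_error_rt": mean_rt(rich & ~cor),
        "lean_error_rt": mean_rt(~rich & ~cor),
    }


def behavioral_summary(
    subject: SubjectData,
    base: float = 10.0,
    average: str = "pooled",
) -> BehavioralSummary:
    """Block-wise and session-average performance statistics.

    ``average='pooled'`` computes the session row from counts pooled over
    blocks; ``average='mean'`` averages the two block-level statistics.
    """
    if average not in ("pooled", "mean"):
        raise ValueError("average must be 'pooled' or 'mean'")
    trials = subject.trials
    rows = {}
    for b in sorted(trials["block"].unique()):
        rows[f"block{b}"] = _summarize_block(trials[trials["block"] == b], base)
    if average == "pooled" or len(rows) == 1:
        rows["average"] = _summarize_block(trials, base)
    else:
        rows["average"] = pd.DataFrame(rows.values()).mean().to_dict()
    table = pd.DataFrame(rows).T
    change = None
    if "block1" in rows and "block2" in rows:
        change = float(rows["block2"]["response_bias"] - rows["block1"]["response_bias"])
    return BehavioralSummary(subject_id=subject.subject_id, table=table, bias_change=change)


def rt_speed_contrast(
    subject: SubjectData | pd.DataFrame,
    fast_q: float = 0.1,
    slow_q: float = 0.9,
    min_cell: int = 5,
) -> pd.DataFrame:
    """Accuracy by stimulus type for fast vs slow responses.

    Fast (slow) trials are those below the ``fast_q`` (above the
    ``slow_q``) quantile of the subject's own valid-RT distribution.  The
    returned frame has rows ``fast``/``slow`` with rich/lean accuracies,
    their difference (the bias-by-speed signature), trial counts, and a
    ``reliable`` flag (False when any cell holds fewer than ``min_cell``
    trials).
    """
    trials = subject.trials if isinstance(subject, SubjectData) else subject
    df = trials
    if "valid" in df.columns:
        df = df[df["valid"]]
    df = df[df["response"] != "none"].copy()
    lo, hi = df["rt"].quantile([fast_q, slow_q])
    out = {}
    for name, mask in (("fast", df["rt"] <= lo), ("slow", df["rt"] >= hi)):
        sel = df[mask]
        rich = sel[sel["stimulus"] == "rich"]
        lean = sel[sel["stimulus"] == "lean"]
        ra = rich["correct"].mean() if len(rich) else np.nan
        la = lean["correct"].mean() if len(lean) else np.nan
        out[name] = {
            "rich_acc": ra,
            "lean_acc": la,
            "contrast": ra - la,
            "n_rich": len(rich),
            "n_lean": len(lean),
            "reliable": min(len(rich), len(lean)) >= min_cell,
        }
    return pd.DataFrame(out).T


@dataclass
class ReliabilityReport:
    """Split-half (block1 vs block2) agreement of a per-subject measure."""

    r: float
    spearman_brown: float
    icc: float
    n: int
    flag: str | None = None


def split_half_reliability(block1: np.ndarray, block2: np.ndarray) -> ReliabilityReport:
    """Pearson r, Spearman-Brown r_sb = 2r/(1+r), and ICC across subjects.

    ICC is the two-way random-effects, absolute-agreement, single-measure
    form (ICC2,1).  Degenerate (zero-variance) halves are flagged.
    """
    x = np.asarray(block1, float)
    y = np.asarray(block2, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("block1 and block2 must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired subjects")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return ReliabilityReport(np.nan, np.nan, np.nan, n, flag="zero variance")
    if np.allclose(x, y):
        # pingouin's ICC is undefined at exactly zero residual variance
        return ReliabilityReport(1.0, 1.0, 1.0, n)
    r = float(sps.pearsonr(x, y)[0])
    rsb = 2.0 * r / (1.0 + r)
    import pingouin as pg

    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["b1", "b2"], n),
            "score": np.concatenate([x, y]),
        }
    )
    icc_tab = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="score"
    ).set_index("Type")
    # two-way random, absolute agreement, single measure; label differs
    # across pingouin versions
    key = "ICC(A,1)" if "ICC(A,1)" in icc_tab.index else "ICC2"
    icc = float(icc_tab.loc[key, "ICC"])
    return ReliabilityReport(r, rsb, icc, n)


def group_compare(values_by_group: dict) -> dict:
    """Welch two-sample t-test with Cohen's d between two groups."""
    if len(values_by_group) != 2:
        raise ValueError("group_compare expects exactly two groups")
    (n1, x), (n2, y) = values_by_group.items()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 subjects per group")
    flag = None
    if np.std(x, ddof=1) == 0.0 and np.std(y, ddof=1) == 0.0:
        flag = "degenerate variance"
        t, p = (0.0, 1.0) if np.mean(x) == np.mean(y) else (np.inf, 0.0)
    else:
        t, p = sps.ttest_ind(x, y, equal_var=False)
    sp = np.sqrt(
        ((len(x) - 1) * np.var(x, ddof=1) + (len(y) - 1) * np.var(y, ddof=1))
        / (len(x) + len(y) - 2)
    )
    d = (np.mean(x) - np.mean(y)) / sp if sp > 0 else np.nan
    return {
        "groups": (n1, n2),
        "t": float(t),
        "p": float(p),
        "cohens_d": float(d),
        "flag": flag,
    }


def symptom_correlation(values, scores) -> dict:
    """Pearson correlation between a measure and a symptom score."""
    x = np.asarray(values, float)
    y = np.asarray(scores, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return {"r": np.nan, "p": np.nan, "n": len(x), "flag": "degenerate variance"}
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(x), "flag": None}


def median_age_split(ages: pd.Series | np.ndarray) -> np.ndarray:
    """Boolean mask of the younger subgroup under a median split.

    Ties at the median are assigned to the younger group.
    """
    a = np.asarray(ages, float)
    return a <= np.median(a)
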