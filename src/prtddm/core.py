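"""Action-DDM trial-level model and Wiener first-passage-time likelihood.

The Action-DDM couples delta-rule learning of *response-outcome* values to
a drift-diffusion choice process.  Each response option (rich / lean)
carries an expected value Q updated after feedback for the chosen response:

    Q_{t+1}(chosen) = Q_t(chosen) + alpha * (r - Q_t(chosen)),  r in {0, 1}

The value difference dQ_t = Q(rich) - Q(lean) modulates the diffusion on
the next choice in two ways: it shifts the drift rate through B_v and the
relative starting point through B_z (a two-option softmax of B_z*Q, i.e. a
logistic of B_z*dQ).  The upper boundary is the rich response, the lower
the lean response; the stimulus signs the drift-rate intercept so that
evidence accumulates toward the correct boundary:

    v_t = s * v_intercept + B_v * dQ_t,     s = +1 (rich) / -1 (lean)
    z_t = exp(B_z Q_rich) / (exp(B_z Q_rich) + exp(B_z Q_lean))

At the start of a session dQ = 0, so v_t = s * v_intercept and z_t = 0.5.
The likelihood of each (response, RT) pair is the Wiener first-passage-time
density with trial-varying v_t and z_t.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import _kernels as _k
from .task import SubjectData

__all__ = [
    "ActionDDMParams",
    "TrialLatents",
    "ModelVariant",
    "VARIANT_NAMES",
    "PARAM_NAMES",
    "q_update",
    "trial_latents",
    "wfpt_logpdf",
    "subject_loglik",
    "make_variant",
    "params_to_link",
    "link_to_params",
]

#: natural-scale parameter order used throughout the package
PARAM_NAMES = ("alpha", "B_v", "B_z", "v_intercept", "a", "t")

#: link functions per parameter: logit(alpha), log(a), identity otherwise
LINKS = ("logit", "identity", "identity", "identity", "log", "identity")


@dataclass(frozen=True)
class ActionDDMParams:
    """Subject-level Action-DDM parameters (natural scale).

    alpha : learning rate in [0, 1]
    B_v : weight of the value difference on drift rate
    B_z : weight of the value difference on starting-point bias
    v_intercept : baseline drift rate (stimulus processing efficiency)
    a : boundary separation (> 0)
    t : non-decision time in seconds (>= 0)
    """

    alpha: float
    B_v: float
    B_z: float
    v_intercept: float
    a: float
    t: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.a <= 0.0:
            raise ValueError("boundary separation a must be positive")
        if self.t < 0.0:
            raise ValueError("non-decision time t must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha, self.B_v, self.B_z, self.v_intercept, self.a, self.t]
        )


class TrialLatents(NamedTuple):
    """Trial-wise computed quantities (values before the choice)."""

    q_rich: float
    q_lean: float
    delta_q: float
    v_t: float
    z_t: float


@dataclass(frozen=True)
class ModelVariant:
    """A restriction of the full Action-DDM.

    ``fixed`` maps parameter names to pinned values; ``tied`` ties
    B_z = B_v (a single shared value weight B).
    """

    name: str
    description: str
    fixed: dict
    tied: bool = False

    @property
    def free_mask(self) -> np.ndarray:
        free = np.array([p not in self.fixed for p in PARAM_NAMES])
        if self.tied:
            free[PARAM_NAMES.index("B_z")] = False
        return free

    def constrain(self, params: ActionDDMParams) -> ActionDDMParams:
        """Apply the restriction to a full parameter set."""
        out = replace(params, **self.fixed)
        if self.tied:
            out = replace(out, B_z=out.B_v)
        return out


_VARIANTS = {
    "full": ModelVariant("full", "full Action-DDM (free B_v and B_z)", {}),
    "no_value_drift": ModelVariant(
        "no_value_drift", "value differences do not influence drift rate (B_v = 0)",
        {"B_v": 0.0},
    ),
    "no_value_start": ModelVariant(
        "no_value_start",
        "value differences do not influence starting point (B_z = 0)",
        {"B_z": 0.0},
    ),
    "unweighted_drift": ModelVariant(
        "unweighted_drift", "drift modulation not scaled by a free weight (B_v = 1)",
        {"B_v": 1.0},
    ),
    "unweighted_start": ModelVariant(
        "unweighted_start",
        "starting-point modulation not scaled by a free weight (B_z = 1)",
        {"B_z": 1.0},
    ),
    "shared_B": ModelVariant(
        "shared_B", "one shared weight B for both drift and starting point",
        {}, tied=True,
    ),
}

VARIANT_NAMES = tuple(_VARIANTS)


def make_variant(name: str | ModelVariant) -> ModelVariant:
    """Look up a model variant by name."""
    if isinstance(name, ModelVariant):
        return name
    try:
        return _VARIANTS[name]
    except KeyError:
        raise ValueError(
            f"unknown variant {name!r}; valid variants: {', '.join(VARIANT_NAMES)}"
        ) from None


def q_update(q: float, r: int, alpha: float) -> float:
    """Delta-rule update of the chosen response's expected value."""
    return q + alpha * (r - q)


def trial_latents(
    q_rich: float,
    q_lean: float,
    params: ActionDDMParams,
    stimulus: str = "rich",
    literal_sign: bool = False,
) -> TrialLatents:
    """Drift rate and starting point implied by the current Q values.

    The signed drift points toward the upper (rich) boundary.  By default
    the stimulus signs only the intercept; with ``literal_sign`` the whole
    drift expression is signed by the stimulus.
    """
    s = 1.0 if stimulus == "rich" else -1.0
    dq, z, v = _k._trial_drift_start(
        q_rich, q_lean, s, params.alpha, params.B_v, params.B_z,
        params.v_intercept, literal_sign,
    )
    return TrialLatents(q_rich=q_rich, q_lean=q_lean, delta_q=dq, v_t=v, z_t=z)


def wfpt_logpdf(
    rt: float, boundary: str, v: float, a: float, z: float, t: float
) -> float:
    """Log Wiener first-passage-time density at the named boundary.

    ``rt`` is the observed response time (seconds); ``t`` is subtracted to
    give decision time.  Returns -inf for impossible observations
    (rt <= t).  Accurate to well below 1e-6 in absolute density via
    small-time/large-time series switching.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    return float(_k.wfpt_logpdf_signed(rt - t, v, a, z, boundary == "upper"))


_STIM_CODE = {"rich": 1, "lean": -1}
_RESP_CODE = {"rich": 1, "lean": -1, "none": 0}


def trials_to_arrays(trials: pd.DataFrame):
    """Pack a trial table into the typed arrays the kernels consume."""
    t = trials["trial"].to_numpy()
    if not np.all(np.diff(t) > 0):
        raise ValueError("trials must be in chronological order")
    stim = trials["stimulus"].map(_STIM_CODE).to_numpy(dtype=np.int8)
    resp = trials["response"].map(_RESP_CODE).to_numpy(dtype=np.int8)
    rt = trials["rt"].to_numpy(dtype=np.float64)
    rt = np.where(np.isnan(rt), 0.0, rt)
    reward = trials["reward"].to_numpy(dtype=np.int8)
    if "valid" in trials.columns:
        valid = trials["valid"].to_numpy(dtype=np.bool_)
    else:
        valid = resp != 0
    return stim, resp, rt, reward, valid


def subject_loglik(
    subject: SubjectData | pd.DataFrame,
    params: ActionDDMParams,
    literal_sign: bool = False,
    return_latents: bool = False,
):
    """Sequential Action-DDM log-likelihood of one subject's session.

    Q values are updated after every responded trial (feedback was shown
    even if the trial is later QC-invalid); only valid responded trials
    contribute likelihood terms.  Returns the total log-likelihood, and
    with ``return_latents`` also a DataFrame of the trial-wise latents
    (q_rich, q_lean, delta_q, v_t, z_t, loglik).
    """
    trials = subject.trials if isinstance(subject, SubjectData) else subject
    stim, resp, rt, reward, valid = trials_to_arrays(trials)
    n = len(stim)
    out_ll = np.empty(n)
    out_qr = np.empty(n)
    out_ql = np.empty(n)
    out_v = np.empty(n)
    out_z = np.empty(n)
    total = _k.trial_loglik_fill(
        stim, resp, rt, reward, valid,
        params.alpha, params.B_v, params.B_z, params.v_intercept,
        params.a, params.t, literal_sign,
        out_ll, out_qr, out_ql, out_v, out_z,
    )
    if not return_latents:
        return float(total)
    lat = pd.DataFrame(
        {
            "trial": trials["trial"].to_numpy(),
            "q_rich": out_qr,
            "q_lean": out_ql,
            "delta_q": out_qr - out_ql,
            "v_t": out_v,
            "z_t": out_z,
            "loglik": out_ll,
        }
    )
    return float(total), lat


def params_to_link(params: ActionDDMParams | np.ndarray) -> np.ndarray:
    """Map natural-scale parameters to the unconstrained link scale."""
    arr = params.as_array() if isinstance(params, ActionDDMParams) else np.asarray(params, float)
    out = arr.astype(float).copy()
    eps = 1e-9
    p = np.clip(out[0], eps, 1 - eps)
    out[0] = np.log(p / (1 - p))
    out[4] = np.log(out[4])
    return out


def link_to_params(theta: np.ndarray) -> ActionDDMParams:
    """Map link-scale values back to an :class:`ActionDDMParams`."""
    th = np.asarray(theta, float)
    return ActionDDMParams(
        alpha=float(1.0 / (1.0 + np.exp(-th[0]))),
        B_v=float(th[1]),
        B_z=float(th[2]),
        v_intercept=float(th[3]),
        a=float(np.exp(th[4])),
        t=float(th[5]),
    )
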