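"""Cox partial-likelihood risk head on the cVAE latent space, plus evaluation.

The risk head is a single fully connected layer from the 64-d latent to a
scalar, squashed by a sigmoid so the score r lies in (0, 1).  The sigmoid
prevents the exp(r) terms of the partial likelihood from overflowing while
leaving the risk ordering unchanged (sigmoid is strictly increasing).

The survival loss is the negative, batch-averaged log partial likelihood

    L_surv = -(1/N) sum_i  delta_i * ( r_i - log sum_{j : t_j >= t_i} exp(r_j) )

with Breslow handling of tied event times (tied subjects share the full risk
set).  The joint objective adds it to the ELBO terms with equal weights:
L_total = L_recon + L_KL + L_surv.

Evaluation: Harrell's concordance index (own implementation; comparable pairs
are (i, j) with t_i < t_j and delta_i = 1, risk ties count 1/2),
Kaplan-Meier curves with Greenwood log-log 95% CIs (via lifelines), and
median-risk two-group stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cvae import CVAE, ConditionSchema, ModelConfig
from .errors import DataTooSmall
from .nn import Adam, Dense, sigmoid

__all__ = [
    "SurvivalRecord",
    "records_to_arrays",
    "RiskHead",
    "SurvivalHook",
    "cox_loss",
    "cox_loss_and_grad",
    "total_loss",
    "concordance_index",
    "kaplan_meier",
    "stratify_by_median",
    "JointModel",
    "train_joint",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Follow-up for one subject: time (days, > 0), event flag, optional subtype."""

    subject_id: str
    time: float
    event: int
    subtype: Optional[str] = None

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("follow-up time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def records_to_arrays(records: Sequence[SurvivalRecord]) -> Tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


class RiskHead:
    """sigmoid(w . z + b): one fully connected layer from latent to (0, 1).

    Weights start at zero (every subject scores 0.5), so early training cannot
    saturate the sigmoid on minibatch noise: with saturated scores the Cox
    gradient vanishes and the head would freeze in a poor direction.
    """

    def __init__(self, latent_dim: int = 64, rng: Optional[np.random.Generator] = None):
        self.layer = Dense(latent_dim, 1, np.random.default_rng(rng))
        self.layer.W[:] = 0.0
        self.layer.b[:] = 0.0

    def score(self, z: np.ndarray) -> np.ndarray:
        """Risk score(s) in (0, 1) for latent vector(s) z."""
        zb = np.atleast_2d(np.asarray(z, dtype=float))
        r = sigmoid(self.layer.forward(zb)).ravel()
        return float(r[0]) if np.asarray(z).ndim == 1 else r

    @property
    def params_and_grads(self):
        return self.layer.params_and_grads


def _risk_set_log_denominators(times: np.ndarray, risks: np.ndarray) -> np.ndarray:
    """log sum_{j : t_j >= t_i} exp(r_j) for every i, Breslow ties."""
    n = times.size
    order = np.argsort(-times, kind="stable")
    ts, rs = times[order], risks[order]
    cum = np.logaddexp.accumulate(rs)
    denom_sorted = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        denom_sorted[i:j + 1] = cum[j]  # tied times share the full risk set
        i = j + 1
    denom = np.empty(n)
    denom[order] = denom_sorted
    return denom


def cox_loss_and_grad(
    risks: np.ndarray, times: np.ndarray, events: np.ndarray
) -> Tuple[float, np.ndarray]:
    """Negative batch-averaged log partial likelihood and its gradient in r.

    Returns (0, zeros) with a warning when the batch contains no events.
    """
    r = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    n = r.size
    if n < 2:
        raise ValueError("need at least two subjects")
    if d.sum() == 0:
        warnings.warn("batch contains no events; Cox loss is 0", stacklevel=2)
        return 0.0, np.zeros(n)
    denom = _risk_set_log_denominators(t, r)
    loss = -float(np.sum(d * (r - denom))) / n

    # grad_k = -(1/N) [ delta_k - exp(r_k) * sum_{i events, t_i <= t_k} 1/S_i ]
    order = np.argsort(-t, kind="stable")
    ts, ds = t[order], d[order]
    inv_S = ds * np.exp(-denom[order])
    rev_cum = np.cumsum(inv_S[::-1])[::-1]  # sum over positions >= p
    # map each subject to the first position of its tie group (t_k >= t_i incl. ties)
    A_sorted = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        A_sorted[i:j + 1] = rev_cum[i]
        i = j + 1
    A = np.empty(n)
    A[order] = A_sorted
    grad = -(d - np.exp(r) * A) / n
    return loss, grad


def cox_loss(risks, times=None, events=None, records: Optional[Sequence[SurvivalRecord]] = None) -> float:
    """Survival loss of a batch; accepts (times, events) arrays or records."""
    if records is not None:
        times, events = records_to_arrays(records)
    loss, _ = cox_loss_and_grad(risks, times, events)
    return loss


def total_loss(recon: float, kl: float, surv: float, weights: Tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """Joint objective: weighted sum of the three terms (equal weights by default)."""
    return weights[0] * recon + weights[1] * kl + weights[2] * surv


def concordance_index(risks, times=None, events=None, records: Optional[Sequence[SurvivalRecord]] = None) -> float:
    """Harrell's C: fraction of comparable pairs ranked correctly by risk.

    A pair (i, j) is comparable when t_i < t_j and subject i had the event;
    it is concordant when r_i > r_j, and risk ties count 1/2.  Returns 0.5
    (with a warning) when no pair is comparable.
    """
    if records is not None:
        times, events = records_to_arrays(records)
    r = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=bool)
    earlier = t[:, None] < t[None, :]
    comparable = earlier & d[:, None]
    n_comp = int(comparable.sum())
    if n_comp == 0:
        warnings.warn("no comparable pairs; returning C = 0.5", stacklevel=2)
        return 0.5
    higher = r[:, None] > r[None, :]
    tied = r[:, None] == r[None, :]
    num = (comparable & higher).sum() + 0.5 * (comparable & tied).sum()
    return float(num / n_comp)


def kaplan_meier(
    times=None, events=None, records: Optional[Sequence[SurvivalRecord]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Product-limit survival estimate with Greenwood log-log 95% CI.

    Returns a DataFrame with columns time, survival, ci_lower, ci_upper,
    starting at S(0) = 1; ``survival`` is non-increasing and the CI brackets it.
    """
    from lifelines import KaplanMeierFitter

    if records is not None:
        times, events = records_to_arrays(records)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    ci = kmf.confidence_interval_survival_function_
    out = pd.DataFrame({
        "time": kmf.survival_function_.index.to_numpy(dtype=float),
        "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
        "ci_lower": ci.iloc[:, 0].to_numpy(),
        "ci_upper": ci.iloc[:, 1].to_numpy(),
    })
    return out


def stratify_by_median(risks) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean masks (low, high) splitting subjects at the median risk.

    Subjects exactly at the median go to the low-risk group, so when all risks
    are identical everyone is low-risk.
    """
    r = np.asarray(risks, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two subjects to stratify")
    med = np.median(r)
    high = r > med
    return ~high, high


class SurvivalHook:
    """Adapter wiring the risk head + Cox loss into the cVAE training loop.

    For every batch it scores the posterior mean mu, evaluates the
    within-batch Cox loss, backpropagates into the head's parameters, and
    hands the gradient with respect to mu back to the encoder backward pass.
    Scoring mu rather than a sampled z keeps the representation the head is
    fit on identical to the one used at evaluation time and free of sampling
    noise (the posterior sigma is of the same order as the mu spread, so a
    head fit on sampled z would be fit to a noise-diluted signal).
    """

    def __init__(
        self,
        head: RiskHead,
        times: np.ndarray,
        events: np.ndarray,
        weight: float = 1.0,
        lr: float = 2e-3,
        weight_decay: float = 1e-2,
    ):
        self.head = head
        self.times = np.asarray(times, dtype=float)
        self.events = np.asarray(events, dtype=int)
        self.weight = weight
        # Ridge penalty on the head weights.  The Cox partial likelihood of a
        # sigmoid-bounded score is maximized by pushing every score to 0 or 1,
        # i.e. the unpenalized optimum saturates the sigmoid and kills its own
        # gradient; a small L2 term keeps the head in the responsive regime.
        self.weight_decay = weight_decay
        # The head gets its own, faster optimizer: it is a 65-parameter linear
        # model chasing a representation that moves under the ELBO gradients,
        # so it can afford a larger step size than the network body.  Its lr
        # is decayed linearly over the run (see set_epoch) so the final head
        # is a converged fit rather than the last step of a noisy walk over
        # within-batch risk sets.
        self.base_lr = lr
        self.optimizer = Adam(self.head.params_and_grads, lr=lr)

    def set_epoch(self, epoch: int, n_epochs: int) -> None:
        frac = epoch / max(n_epochs - 1, 1)
        self.optimizer.lr = self.base_lr * max(1.0 - frac, 0.02)

    def loss_and_grad(self, mu: np.ndarray, idx: np.ndarray) -> Tuple[float, np.ndarray]:
        a = self.head.layer.forward(mu)
        r = sigmoid(a).ravel()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # event-free batches contribute 0
            loss, grad_r = cox_loss_and_grad(r, self.times[idx], self.events[idx])
        da = (self.weight * grad_r * r * (1.0 - r))[:, None]
        dmu = self.head.layer.backward(da)
        self.head.layer.gW += self.weight_decay * self.head.layer.W
        return self.weight * loss, dmu

    def zero_grad(self) -> None:
        self.head.layer.zero_grad()

    @property
    def params_and_grads(self):
        return self.head.params_and_grads


def refit_head(
    head: RiskHead,
    mu: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    n_iter: int = 800,
    lr: float = 0.02,
    weight_decay: float = 1e-2,
) -> RiskHead:
    """Converge the risk head on frozen posterior means with full-batch Cox loss.

    The minibatch survival gradient used during joint training is noisy (risk
    sets are formed within each shuffled batch), so the head parameters at the
    final step are a sample from the SGD stationary distribution rather than a
    converged fit.  This pass restarts the head from zero and minimizes the
    same ridge-penalized L_surv over the whole training set, deterministically,
    with the representation held fixed.
    """
    head.layer.W[:] = 0.0
    head.layer.b[:] = 0.0
    opt = Adam(head.params_and_grads, lr=lr)
    for _ in range(n_iter):
        head.layer.zero_grad()
        a = head.layer.forward(mu)
        r = sigmoid(a).ravel()
        _, grad_r = cox_loss_and_grad(r, times, events)
        head.layer.backward((grad_r * r * (1.0 - r))[:, None])
        head.layer.gW += weight_decay * head.layer.W
        opt.step()
    return head


@dataclass
class JointModel:
    """A trained cVAE plus its survival risk head."""

    cvae: CVAE
    risk_head: RiskHead

    def risk_scores(self, beats: np.ndarray, conds: np.ndarray) -> np.ndarray:
        """Deterministic risk scores from the posterior mean mu (no sampling)."""
        state = self.cvae.encode(beats, conds)
        return np.atleast_1d(self.risk_head.score(state.mu))

    def save(self, path: str) -> None:
        self.cvae.save(path)
        with np.load(path) as data:
            arrays = dict(data)
        arrays["risk_W"] = self.risk_head.layer.W
        arrays["risk_b"] = self.risk_head.layer.b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "JointModel":
        model = CVAE.load(path)
        head = RiskHead(model.config.latent_dim, rng=0)
        with np.load(path) as data:
            head.layer.W = data["risk_W"].copy()
            head.layer.b = data["risk_b"].copy()
        return cls(model, head)


def train_joint(
    beats: np.ndarray,
    conds: np.ndarray,
    records: Sequence[SurvivalRecord],
    schema: ConditionSchema,
    config: Optional[ModelConfig] = None,
    surv_weight: float = 1.0,
    verbose: bool = False,
) -> JointModel:
    """Jointly optimize L_recon + L_KL + L_surv over (beat, condition, survival).

    The Cox loss is computed within each shuffled batch (batch composition
    therefore affects gradients and is governed by the config seed); risk
    scores at evaluation time come from the posterior mean.
    """
    config = config or ModelConfig()
    times, events = records_to_arrays(records)
    if len(records) != np.asarray(beats).shape[0]:
        raise DataTooSmall("survival records must match the number of beats")
    model = CVAE(schema, config)
    head = RiskHead(config.latent_dim, rng=np.random.default_rng(config.seed + 1))
    hook = SurvivalHook(head, times, events, weight=surv_weight)
    model.fit(beats, conds, survival_hook=hook, verbose=verbose)
    # final full-batch convergence pass of L_surv on the frozen representation
    mu = model.encode(beats, conds).mu
    refit_head(head, mu, times, events)
    return JointModel(model, head)
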