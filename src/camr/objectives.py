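"""The five training losses and their weighted combination.

* Cox partial-likelihood loss (Breslow ties, risk sets T_j >= T_i,
  event-averaged, optional L1 penalty on the survival head).
* Fake adversarial loss L_f: pushes the shared encoder to make the two
  source modalities look like the target modality to the discriminators.
* True adversarial loss L_t: the discriminators' own objective — label the
  target modality true and each source modality false.
* Orthogonality loss: squared Frobenius norm of H_mc^T H_mu per modality,
  separating the common and private subspaces.
* Reconstruction loss: squared L2 distance between decoder output and the
  original input features, averaged per patient, summed over modalities.

Every loss accepts numpy arrays or autodiff tensors; with plain arrays a
float is returned, with tensors a differentiable scalar node.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autodiff import Tensor, as_tensor
from .data_model import SurvivalLabels

PROB_EPS = 1e-7


@dataclasses.dataclass
class LossWeights:
    """Weights of the total objective L = L_Cox + alpha L_adv + beta L_rec
    + gamma L_orth. Defaults follow the reference setting (0.6, 0.8, 0.05);
    lambda_l1 scales the survival head's L1 penalty."""

    alpha: float = 0.6
    beta: float = 0.8
    gamma: float = 0.05
    lambda_l1: float = 1e-5

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma, self.lambda_l1) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclasses.dataclass
class LossReport:
    """Loss components for one batch/epoch (floats, for logging)."""

    cox: float
    adv_fake: float
    adv_true: float
    rec: float
    orth: float
    total: float
    batch_size: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _maybe_item(x: Tensor, want_tensor: bool):
    return x if want_tensor else x.item()


def _check_probs(*prob_arrays) -> bool:
    """Validate ranges; return True if any input is a Tensor."""
    any_tensor = any(isinstance(p, Tensor) for p in prob_arrays)
    for p in prob_arrays:
        v = p.value if isinstance(p, Tensor) else np.asarray(p, dtype=float)
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("discriminator outputs must lie in [0, 1]")
    return any_tensor


def _clamped_log(p) -> Tensor:
    return as_tensor(p).clamp(PROB_EPS, 1.0 - PROB_EPS).log()


def adversarial_fake_loss(d1_on_p, d2_on_c):
    """Generator-side loss: mean of -log D1(h_Pc) - log D2(h_Cc)."""
    want = _check_probs(d1_on_p, d2_on_c)
    loss = -(_clamped_log(d1_on_p).mean()) - (_clamped_log(d2_on_c).mean())
    return _maybe_item(loss, want)


def adversarial_true_loss(d1_on_p, d1_on_g, d2_on_c, d2_on_g):
    """Discriminator-side loss: source rows labelled false, target (gene
    expression) rows labelled true, for both discriminators."""
    want = _check_probs(d1_on_p, d1_on_g, d2_on_c, d2_on_g)
    one = Tensor(1.0)
    loss = (
        -( (one - as_tensor(d1_on_p)).clamp(PROB_EPS, 1 - PROB_EPS).log().mean() )
        - _clamped_log(d1_on_g).mean()
        - ( (one - as_tensor(d2_on_c)).clamp(PROB_EPS, 1 - PROB_EPS).log().mean() )
        - _clamped_log(d2_on_g).mean()
    )
    return _maybe_item(loss, want)


def orthogonality_loss(h_c_list, h_u_list):
    """Sum over modalities of ||H_mc^T H_mu||_F^2."""
    if len(h_c_list) != len(h_u_list):
        raise ValueError("need one specific matrix per invariant matrix")
    want = any(isinstance(h, Tensor) for h in (*h_c_list, *h_u_list))
    total = Tensor(0.0)
    for hc, hu in zip(h_c_list, h_u_list):
        hc, hu = as_tensor(hc), as_tensor(hu)
        if hc.value.shape[0] != hu.value.shape[0]:
            raise ValueError(f"row mismatch: {hc.value.shape} vs {hu.value.shape}")
        total = total + (hc.T @ hu).square().sum()
    return _maybe_item(total, want)


def reconstruction_loss(f_hat_list, f_list):
    """Sum over modalities of the mean-per-patient squared Euclidean
    distance between reconstruction and input."""
    if len(f_hat_list) != len(f_list):
        raise ValueError("need one reconstruction per input block")
    want = any(isinstance(h, Tensor) for h in (*f_hat_list, *f_list))
    total = Tensor(0.0)
    for fh, f in zip(f_hat_list, f_list):
        fh, f = as_tensor(fh), as_tensor(f)
        if fh.value.shape != f.value.shape:
            raise ValueError(f"shape mismatch: {fh.value.shape} vs {f.value.shape}")
        total = total + (fh - f).square().sum(axis=1).mean()
    return _maybe_item(total, want)


def cox_loss(risk, labels: SurvivalLabels, lambda_l1: float = 0.0,
             params_l1_norm=0.0, reduction: str = "mean"):
    """Negative Cox log partial likelihood.

    Risk sets are {j : T_j >= T_i} (Breslow convention for ties); the
    log-sum-exp is stabilized by subtracting the max risk. With lambda_l1
    > 0, adds lambda_l1 * params_l1_norm (typically the L1 norm of the
    survival-head weights). `reduction` is "mean" (average over events, so
    the magnitude is batch-size-stable — the training default) or "sum"
    (the plain negative log partial likelihood).
    """
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")
    want = isinstance(risk, Tensor) or isinstance(params_l1_norm, Tensor)
    r = as_tensor(risk)
    if r.value.ndim != 1:
        r = r.reshape(-1)
    n = r.value.shape[0]
    if n != len(labels):
        raise ValueError(f"risk length {n} does not match labels ({len(labels)})")
    if n < 2:
        raise ValueError("need at least two patients")
    events = np.flatnonzero(labels.event == 1)
    if events.size == 0:
        raise ValueError("Cox partial likelihood undefined with zero events")

    t = labels.time
    # mask[k, j] = 1 iff patient j is at risk at the k-th event's time
    mask = Tensor((t[None, :] >= t[events, None]).astype(float))
    c = float(r.value.max())  # detached stabilizer
    exp_r = (r - c).exp()
    log_denom = (mask @ exp_r.reshape(-1, 1)).reshape(-1).log() + c
    r_events = r[events]
    nll = -(r_events - log_denom).sum()
    if reduction == "mean":
        nll = nll / events.size
    if lambda_l1 > 0:
        nll = nll + float(lambda_l1) * as_tensor(params_l1_norm)
    return _maybe_item(nll, want)


def total_loss(cox, adv, rec, orth, weights: LossWeights):
    """L_total = L_Cox + alpha L_adv + beta L_rec + gamma L_orth, where
    `adv` is the adversarial component of the current optimization phase."""
    parts = [cox, adv, rec, orth]
    want = any(isinstance(p, Tensor) for p in parts)
    vals = [p.value if isinstance(p, Tensor) else p for p in parts]
    if not all(np.all(np.isfinite(v)) for v in vals):
        raise ValueError("non-finite loss component")
    out = (as_tensor(cox) + weights.alpha * as_tensor(adv)
           + weights.beta * as_tensor(rec) + weights.gamma * as_tensor(orth))
    return _maybe_item(out, want)
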