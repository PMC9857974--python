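"""Cross-modality fusion module (CMFM): gated attention over the
modality-invariant representations followed by low-rank multimodal fusion.

The gate computes, for each modality m, an attention vector
``alpha_m = w_m (h_Pc (+) h_Gc (+) h_Cc)`` from the concatenation of all
three invariant representations and modulates a linear transform of that
modality's representation: ``hhat_mc = ReLU(alpha_m * h'_mc)``. The fused
representation is then the elementwise product across modalities of
per-modality sums of low-rank factor maps,
``h_c = prod_m sum_i (W_mi hhat_mc)``, a low-rank stand-in for a full
multilinear fusion tensor. A plain-concatenation path is kept as the
ablation baseline.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, as_tensor, concat
from .data_model import MODALITIES


class FusionParameters:
    """Learnable parameters of the fusion module.

    gate_m: 3d -> d linear map producing alpha_m; pregate_m: d -> d FC
    layer producing h'_mc; lowrank_m: rank maps d -> d whose sum is the
    modality's fusion factor. `lmf_append_one` appends a constant-1
    coordinate to each gated vector before the factor maps (the variant
    used by the cited low-rank fusion method, retaining lower-order
    interaction terms); disabled by default.
    """

    def __init__(self, latent_dim: int, rank: int = 4, seed: int = 0,
                 lmf_append_one: bool = False, gate_sigmoid: bool = False):
        if rank < 1:
            raise ValueError("fusion rank must be >= 1")
        self.latent_dim = latent_dim
        self.rank = rank
        self.lmf_append_one = lmf_append_one
        self.gate_sigmoid = gate_sigmoid
        rng = np.random.default_rng(seed)
        d = latent_dim
        din = d + 1 if lmf_append_one else d
        p: dict[str, Tensor] = {}
        for m in MODALITIES:
            b3 = 1.0 / np.sqrt(3 * d)
            p[f"gate_{m}.W"] = Tensor(rng.uniform(-b3, b3, size=(3 * d, d)),
                                      requires_grad=True)
            bd = 1.0 / np.sqrt(d)
            p[f"pregate_{m}.W"] = Tensor(rng.uniform(-bd, bd, size=(d, d)),
                                         requires_grad=True)
            p[f"pregate_{m}.b"] = Tensor(np.zeros(d), requires_grad=True)
            bi = 1.0 / np.sqrt(din)
            for i in range(rank):
                p[f"lowrank_{m}.W{i}"] = Tensor(rng.uniform(-bi, bi, size=(din, d)),
                                                requires_grad=True)
        # linear 3d -> d map used only by the concatenation baseline
        b3 = 1.0 / np.sqrt(3 * d)
        p["concat_proj.W"] = Tensor(rng.uniform(-b3, b3, size=(3 * d, d)),
                                    requires_grad=True)
        self.params = p


def _as_three(h_list) -> list[Tensor]:
    hs = [as_tensor(h) for h in h_list]
    shapes = {h.value.shape for h in hs}
    if len(hs) != 3:
        raise ValueError("expected three modality matrices")
    if any(h.value.ndim != 2 for h in hs):
        raise ValueError("modality matrices must be 2-D")
    if len({h.value.shape[0] for h in hs}) != 1:
        raise ValueError(f"row counts differ across modalities: {sorted(shapes)}")
    return hs


def gate(params: FusionParameters, h_pc, h_gc, h_cc) -> tuple[Tensor, Tensor, Tensor]:
    """Gating attention: returns the three gated matrices hhat_mc (n x d),
    elementwise nonnegative by the ReLU."""
    hs = _as_three([h_pc, h_gc, h_cc])
    joint = concat(hs, axis=1)
    out = []
    for m, h in zip(MODALITIES, hs):
        alpha = joint @ params.params[f"gate_{m}.W"]
        if params.gate_sigmoid:
            alpha = alpha.sigmoid()
        h_prime = h @ params.params[f"pregate_{m}.W"] + params.params[f"pregate_{m}.b"]
        out.append((alpha * h_prime).relu())
    return tuple(out)


def fuse_low_rank(params: FusionParameters, gated) -> Tensor:
    """Low-rank fusion: h_c = prod_m (sum_i gated_m @ W_mi), the elementwise
    product across modalities of each modality's summed factor images."""
    hs = _as_three(gated)
    factors = []
    for m, h in zip(MODALITIES, hs):
        if params.lmf_append_one:
            ones = Tensor(np.ones((h.value.shape[0], 1)))
            h = concat([h, ones], axis=1)
        s = h @ params.params[f"lowrank_{m}.W0"]
        for i in range(1, params.rank):
            s = s + h @ params.params[f"lowrank_{m}.W{i}"]
        factors.append(s)
    return factors[0] * factors[1] * factors[2]


def fuse_concat(gated, proj: Tensor | None = None) -> Tensor:
    """Row-wise concatenation in modality order P, G, C (the ablation
    baseline). If `proj` is given (3d -> d), the result is projected back to
    width d so downstream widths stay fixed."""
    hs = _as_three(gated)
    out = concat(hs, axis=1)
    if proj is not None:
        out = out @ proj
    return out
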