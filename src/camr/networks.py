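"""Trainable function families: shared/specific encoders, discriminators,
reconstruction decoders and the survival head.

All networks are fully connected. A single shared encoder maps every
modality's feature vector into the common d-dimensional subspace (the
modality-invariant representation); three per-modality encoders with
disjoint parameters produce the modality-specific representations; two
discriminators distinguish the target modality (gene expression) from each
source modality in the common subspace; per-modality decoders reconstruct
the input from the fused and the specific representation; and the survival
head maps the 4d concatenated representation to a scalar risk score through
four ReLU layers (900, 256, 64, 15 nodes by default) plus a final linear
Cox layer.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from ._autodiff import Tensor, as_tensor, concat
from .data_model import MODALITIES

_ACTIVATIONS = {"relu", "tanh", "sigmoid"}


@dataclasses.dataclass
class NetworkConfig:
    """Architecture settings. `latent_dim` defaults to 225 so that the
    4d-wide concatenated representation matches the survival head's first
    width of 900."""

    input_dim: int = 80
    latent_dim: int = 225
    shared_encoder_widths: Sequence[int] = (256,)
    specific_encoder_widths: Sequence[int] = (256,)
    discriminator_widths: Sequence[int] = (64,)
    decoder_widths: Sequence[int] = (256,)
    survival_head_widths: Sequence[int] = (900, 256, 64, 15)
    activation: str = "relu"
    fusion_rank: int = 4

    def validate(self) -> None:
        all_widths = (list(self.shared_encoder_widths) + list(self.specific_encoder_widths)
                      + list(self.discriminator_widths) + list(self.decoder_widths)
                      + list(self.survival_head_widths))
        if any(w <= 0 for w in all_widths) or self.latent_dim <= 0 or self.input_dim <= 0:
            raise ValueError("all layer widths must be positive")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.fusion_rank < 1:
            raise ValueError("fusion_rank must be >= 1")


@dataclasses.dataclass
class RepresentationSet:
    """Per-batch latent representations (one row per patient)."""

    invariant: dict[str, Tensor]
    gated: dict[str, Tensor]
    fused: Tensor
    specific: dict[str, Tensor]
    concatenated: Tensor


def _activate(x: Tensor, name: str) -> Tensor:
    if name == "relu":
        return x.relu()
    if name == "tanh":
        return x.tanh()
    return x.sigmoid()


def _init_mlp(rng: np.random.Generator, params: dict[str, Tensor], prefix: str,
              widths: Sequence[int], final_scale: float = 0.1) -> None:
    """Fan-in-scaled uniform weights, zero biases.

    The output layer is damped by `final_scale` so every network starts with
    small outputs: risks begin near zero, discriminators near 0.5, and the
    quadratic orthogonality penalty starts small instead of dominating the
    first epochs.
    """
    n_layers = len(widths) - 1
    for i, (fan_in, fan_out) in enumerate(zip(widths[:-1], widths[1:])):
        bound = 1.0 / np.sqrt(fan_in)
        if i == n_layers - 1:
            bound *= final_scale
        w = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        params[f"{prefix}.W{i}"] = Tensor(w, requires_grad=True)
        params[f"{prefix}.b{i}"] = Tensor(np.zeros(fan_out), requires_grad=True)


def _mlp_forward(params: dict[str, Tensor], prefix: str, x: Tensor,
                 n_layers: int, activation: str,
                 final: str | None = None) -> Tensor:
    h = x
    for i in range(n_layers):
        h = h @ params[f"{prefix}.W{i}"] + params[f"{prefix}.b{i}"]
        if i < n_layers - 1:
            h = _activate(h, activation)
        elif final is not None:
            h = _activate(h, final)
    return h


class CamrParameters:
    """All named parameter groups of the model.

    Groups: ``shared`` (encoder theta), ``spec_P/G/C`` (specific encoders),
    ``disc1``/``disc2`` (discriminators), ``dec_P/G/C`` (decoders),
    ``head`` (survival head). Fusion parameters live in
    :class:`camr.fusion.FusionParameters` and can be merged for optimization.
    """

    DISCRIMINATOR_GROUPS = ("disc1", "disc2")

    def __init__(self, config: NetworkConfig, seed: int = 0,
                 head_input_width: int | None = None):
        config.validate()
        self.config = config
        self.seed = seed
        d = config.latent_dim
        # fused h_c + three specific vectors -> 4d, unless a variant feeds
        # the fused representation alone (width d)
        self.head_input_width = 4 * d if head_input_width is None else head_input_width
        rng = np.random.default_rng(seed)
        p: dict[str, Tensor] = {}
        enc = [config.input_dim, *config.shared_encoder_widths, d]
        _init_mlp(rng, p, "shared", enc)
        for m in MODALITIES:
            _init_mlp(rng, p, f"spec_{m}",
                      [config.input_dim, *config.specific_encoder_widths, d])
        for name in self.DISCRIMINATOR_GROUPS:
            _init_mlp(rng, p, name, [d, *config.discriminator_widths, 1])
        for m in MODALITIES:
            _init_mlp(rng, p, f"dec_{m}",
                      [2 * d, *config.decoder_widths, config.input_dim])
        _init_mlp(rng, p, "head", [self.head_input_width, *config.survival_head_widths, 1])
        self.params = p

    # -- group helpers -----------------------------------------------------
    def group(self, prefix: str) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if k.startswith(prefix + ".")}

    def discriminator_names(self) -> set[str]:
        return {k for k in self.params
                if k.split(".")[0] in self.DISCRIMINATOR_GROUPS}

    def head_l1_norm(self) -> Tensor:
        terms = [t.abs().sum() for k, t in self.params.items() if k.startswith("head.W")]
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        return total

    def _n_layers(self, prefix: str) -> int:
        return sum(1 for k in self.params if k.startswith(prefix + ".W"))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        manifest = {
            "seed": self.seed,
            "head_input_width": self.head_input_width,
            "config": dataclasses.asdict(self.config),
            "arrays": {k: v.value.tolist() for k, v in self.params.items()},
        }
        path.write_text(json.dumps(manifest))

    @classmethod
    def load(cls, path: str | Path) -> "CamrParameters":
        try:
            manifest = json.loads(Path(path).read_text())
            cfg_dict = manifest["config"]
            arrays = manifest["arrays"]
        except (json.JSONDecodeError, KeyError) as exc:
            raise ValueError(f"corrupt or truncated checkpoint {path}: {exc}") from exc
        cfg = NetworkConfig(**cfg_dict)
        for key in ("shared_encoder_widths", "specific_encoder_widths",
                    "discriminator_widths", "decoder_widths", "survival_head_widths"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        obj = cls(cfg, seed=manifest["seed"],
                  head_input_width=manifest.get("head_input_width"))
        if set(arrays) != set(obj.params):
            raise ValueError(f"checkpoint {path} parameter groups do not match config")
        for k, v in arrays.items():
            obj.params[k].value = np.asarray(v, dtype=np.float64)
        return obj


# ------------------------------------------------------------- operations


def _check_width(x: Tensor, expected: int, what: str) -> None:
    if x.value.ndim != 2 or x.value.shape[1] != expected:
        raise ValueError(f"{what}: expected width {expected}, got shape {x.value.shape}")


def encode_invariant(params: CamrParameters, block_batch, modality_tag: str) -> Tensor:
    """Shared-encoder forward pass: the same parameters theta are applied to
    every modality, so the output depends on the modality only through its
    input."""
    if modality_tag not in MODALITIES:
        raise ValueError(f"unknown modality tag {modality_tag!r}")
    x = as_tensor(block_batch)
    _check_width(x, params.config.input_dim, "encode_invariant input")
    return _mlp_forward(params.params, "shared", x,
                        params._n_layers("shared"), params.config.activation)


def encode_specific(params: CamrParameters, block_batch, modality_tag: str) -> Tensor:
    """Per-modality encoder with its own disjoint parameter group."""
    if modality_tag not in MODALITIES:
        raise ValueError(f"unknown modality tag {modality_tag!r}")
    x = as_tensor(block_batch)
    _check_width(x, params.config.input_dim, "encode_specific input")
    prefix = f"spec_{modality_tag}"
    return _mlp_forward(params.params, prefix, x,
                        params._n_layers(prefix), params.config.activation)


def discriminate(params: CamrParameters, h, which: int) -> Tensor:
    """Per-row probability (0, 1) that a common-subspace row comes from the
    target modality (gene expression). `which` selects D1 (vs image) or D2
    (vs copy number)."""
    if which not in (1, 2):
        raise ValueError("which must be 1 or 2")
    x = as_tensor(h)
    _check_width(x, params.config.latent_dim, "discriminator input")
    prefix = f"disc{which}"
    logits = _mlp_forward(params.params, prefix, x,
                          params._n_layers(prefix), params.config.activation)
    return logits.sigmoid().reshape(-1)


def decode(params: CamrParameters, h_c, h_mu, modality_tag: str) -> Tensor:
    """Reconstruct the modality input from fused + specific representations
    (concatenated in that order, width 2d)."""
    if modality_tag not in MODALITIES:
        raise ValueError(f"unknown modality tag {modality_tag!r}")
    hc, hu = as_tensor(h_c), as_tensor(h_mu)
    d = params.config.latent_dim
    _check_width(hc, d, "decode fused input")
    _check_width(hu, d, "decode specific input")
    x = concat([hc, hu], axis=1)
    prefix = f"dec_{modality_tag}"
    return _mlp_forward(params.params, prefix, x,
                        params._n_layers(prefix), params.config.activation)


def predict_risk(params: CamrParameters, h) -> Tensor:
    """Survival head: ReLU stack over the concatenated representation, then
    a single linear Cox output. Higher score = higher hazard."""
    x = as_tensor(h)
    _check_width(x, params.head_input_width, "survival head input")
    out = _mlp_forward(params.params, "head", x, params._n_layers("head"), "relu")
    return out.reshape(-1)
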