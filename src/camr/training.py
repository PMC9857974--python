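"""Alternating adversarial training, model selection and the 5-fold
cross-validation / ablation harness.

Each training step has two phases. Phase A updates only the two
discriminators by minimizing the true adversarial loss L_t (the shared
encoder is held fixed). Phase B freezes the discriminators and updates
every other parameter group by minimizing
``L_Cox + alpha L_f + beta L_rec + gamma L_orth``; disabling a loss is
identical to giving it weight zero. Model selection tracks the validation
C-index per epoch and returns the parameters of the best epoch (earlier
epoch wins ties); early stopping aborts after `early_stopping_patience`
epochs without improvement.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor, concat
from .data_model import MODALITIES, FoldSplit, MultimodalCohort, make_fold_splits
from .evaluation import alignment_distance, concordance_index, evaluate_risk
from .fusion import FusionParameters, fuse_concat, fuse_low_rank, gate
from .networks import (CamrParameters, NetworkConfig, decode, encode_invariant,
                       encode_specific, discriminate, predict_risk)
from .objectives import (LossReport, LossWeights, adversarial_fake_loss,
                         adversarial_true_loss, cox_loss, orthogonality_loss,
                         reconstruction_loss)

FUSION_VARIANTS = ("concat", "lmf", "cmfm")


@dataclasses.dataclass
class TrainConfig:
    """Training settings; defaults follow the package's reference setup
    (Adam, lr 1e-3, full batch, 300 epochs, patience 30, target modality
    gene expression)."""

    epochs: int = 300
    batch_size: int | None = None  # None = full batch
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    disc_steps_per_gen_step: int = 1
    loss_weights: LossWeights = dataclasses.field(default_factory=LossWeights)
    enabled_losses: frozenset[str] = frozenset({"adv", "rec", "orth"})
    fusion_variant: str = "cmfm"
    concat_specific: bool = True  # feed h_c (+) specific reps (4d) to the head
    target_modality: str = "G"
    early_stopping_patience: int = 30
    seed: int = 0
    network: NetworkConfig = dataclasses.field(default_factory=NetworkConfig)

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.early_stopping_patience > self.epochs:
            raise ValueError("patience cannot exceed epochs")
        if self.fusion_variant not in FUSION_VARIANTS:
            raise ValueError(f"fusion_variant must be one of {FUSION_VARIANTS}")
        if self.target_modality not in MODALITIES:
            raise ValueError(f"target_modality must be one of {MODALITIES}")
        if self.disc_steps_per_gen_step < 1:
            raise ValueError("disc_steps_per_gen_step must be >= 1")
        if not self.enabled_losses <= {"adv", "rec", "orth"}:
            raise ValueError("enabled_losses must be a subset of {'adv','rec','orth'}")
        self.network.validate()


@dataclasses.dataclass
class TrainedModel:
    """A trained fold: parameters at the best validation epoch plus logs."""

    net: CamrParameters
    fusion: FusionParameters
    config: TrainConfig
    best_epoch: int
    best_val_cindex: float
    training_log: list[dict]


def _effective_weights(config: TrainConfig) -> tuple[float, float, float]:
    w = config.loss_weights
    alpha = w.alpha if "adv" in config.enabled_losses else 0.0
    beta = w.beta if "rec" in config.enabled_losses else 0.0
    gamma = w.gamma if "orth" in config.enabled_losses else 0.0
    return alpha, beta, gamma


def _source_modalities(target: str) -> tuple[str, str]:
    return tuple(m for m in MODALITIES if m != target)


def forward_representations(net: CamrParameters, fus: FusionParameters,
                            blocks: dict[str, np.ndarray], config: TrainConfig):
    """Full forward pass; returns (invariant, fused, specific, risk)."""
    inv = {m: encode_invariant(net, blocks[m], m) for m in MODALITIES}
    triple = (inv["P"], inv["G"], inv["C"])
    if config.fusion_variant == "cmfm":
        gated = gate(fus, *triple)
        fused = fuse_low_rank(fus, gated)
    elif config.fusion_variant == "lmf":
        fused = fuse_low_rank(fus, triple)
    else:  # concat baseline, projected back to width d
        fused = fuse_concat(triple, proj=fus.params["concat_proj.W"])
    spec = {m: encode_specific(net, blocks[m], m) for m in MODALITIES}
    if config.concat_specific:
        h = concat([fused, spec["P"], spec["G"], spec["C"]], axis=1)
    else:
        h = fused
    risk = predict_risk(net, h)
    return inv, fused, spec, risk


def _score(net, fus, blocks, config) -> tuple[np.ndarray, list[np.ndarray]]:
    inv, _, _, risk = forward_representations(net, fus, blocks, config)
    return risk.value.copy(), [inv[m].value.copy() for m in MODALITIES]


def _subset_blocks(cohort: MultimodalCohort, idx: np.ndarray) -> dict[str, np.ndarray]:
    return {m: cohort.blocks[m].features[idx] for m in MODALITIES}


def _snapshot(params: dict[str, Tensor]) -> dict[str, np.ndarray]:
    return {k: v.value.copy() for k, v in params.items()}


def _restore(params: dict[str, Tensor], snap: dict[str, np.ndarray]) -> None:
    for k, v in snap.items():
        params[k].value = v.copy()


def train_fold(cohort: MultimodalCohort, split: FoldSplit,
               config: TrainConfig) -> TrainedModel:
    """Train one cross-validation fold; deterministic given config.seed."""
    config.validate()
    if config.optimizer_name.lower() != "adam":
        raise ValueError(f"unsupported optimizer {config.optimizer_name!r}")
    train_idx = cohort.index_of(split.train_ids)
    val_idx = cohort.index_of(split.val_ids)
    train_labels = cohort.labels.subset(train_idx)
    val_labels = cohort.labels.subset(val_idx)
    if train_labels.event.sum() == 0:
        raise ValueError("training split has no events; Cox loss undefined")

    d = config.network.latent_dim
    head_width = 4 * d if config.concat_specific else d
    net = CamrParameters(config.network, seed=config.seed,
                         head_input_width=head_width)
    fus = FusionParameters(d, rank=config.network.fusion_rank,
                           seed=config.seed + 1)
    all_params = {**net.params, **{f"fus::{k}": v for k, v in fus.params.items()}}
    disc_names = net.discriminator_names()
    gen_names = set(all_params) - disc_names
    opt = Adam(all_params, lr=config.learning_rate)

    xb_train = _subset_blocks(cohort, train_idx)
    xb_val = _subset_blocks(cohort, val_idx)
    alpha, beta, gamma = _effective_weights(config)
    src1, src2 = _source_modalities(config.target_modality)
    tgt = config.target_modality
    rng = np.random.default_rng(config.seed + 7)

    best = (-np.inf, -1)  # (val cindex, epoch)
    best_snap = None
    log: list[dict] = []
    since_best = 0
    n_train = len(train_idx)

    for epoch in range(config.epochs):
        if config.batch_size is None or config.batch_size >= n_train:
            batches = [np.arange(n_train)]
        else:
            order = rng.permutation(n_train)
            batches = [order[i:i + config.batch_size]
                       for i in range(0, n_train, config.batch_size)]
        ep = {"cox": 0.0, "adv_fake": 0.0, "adv_true": 0.0, "rec": 0.0,
              "orth": 0.0, "total": 0.0}
        n_used = 0
        for batch in batches:
            labels_b = train_labels.subset(batch)
            if labels_b.event.sum() == 0:
                continue  # partial likelihood undefined on this minibatch
            xb = {m: xb_train[m][batch] for m in MODALITIES}

            # Phase A: discriminators only
            adv_true_val = 0.0
            if alpha > 0:
                for _ in range(config.disc_steps_per_gen_step):
                    inv = {m: encode_invariant(net, xb[m], m) for m in MODALITIES}
                    lt = adversarial_true_loss(
                        discriminate(net, inv[src1], 1),
                        discriminate(net, inv[tgt], 1),
                        discriminate(net, inv[src2], 2),
                        discriminate(net, inv[tgt], 2),
                    )
                    opt.zero_grad()
                    lt.backward()
                    opt.step(only=disc_names)
                    adv_true_val = lt.item()

            # Phase B: everything except the discriminators
            inv, fused, spec, risk = forward_representations(net, fus, xb, config)
            l_cox = cox_loss(risk, labels_b, config.loss_weights.lambda_l1,
                             net.head_l1_norm())
            loss = l_cox
            lf_val = 0.0
            if alpha > 0:
                lf = adversarial_fake_loss(discriminate(net, inv[src1], 1),
                                           discriminate(net, inv[src2], 2))
                loss = loss + alpha * lf
                lf_val = lf.item()
            rec_val = 0.0
            if beta > 0:
                recons = [decode(net, fused, spec[m], m) for m in MODALITIES]
                lrec = reconstruction_loss(recons, [Tensor(xb[m]) for m in MODALITIES])
                loss = loss + beta * lrec
                rec_val = lrec.item()
            orth_val = 0.0
            if gamma > 0:
                lorth = orthogonality_loss([inv[m] for m in MODALITIES],
                                           [spec[m] for m in MODALITIES])
                loss = loss + gamma * lorth
                orth_val = lorth.item()
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step(only=gen_names)

            w = len(batch)
            n_used += w
            ep["cox"] += w * l_cox.item()
            ep["adv_fake"] += w * lf_val
            ep["adv_true"] += w * adv_true_val
            ep["rec"] += w * rec_val
            ep["orth"] += w * orth_val
            ep["total"] += w * loss.item()
        if n_used == 0:
            raise RuntimeError("no usable batches (every minibatch lacked events)")
        for k in ep:
            ep[k] /= n_used

        val_risk, val_inv = _score(net, fus, xb_val, config)
        try:
            val_c, _ = concordance_index(val_risk, val_labels)
        except ValueError:
            val_c = 0.5
        report = LossReport(cox=ep["cox"], adv_fake=ep["adv_fake"],
                            adv_true=ep["adv_true"], rec=ep["rec"],
                            orth=ep["orth"], total=ep["total"],
                            batch_size=n_used)
        log.append({"epoch": epoch, **report.to_dict(), "val_cindex": val_c,
                    "alignment_distance": alignment_distance(*val_inv)})

        if val_c > best[0]:
            best = (val_c, epoch)
            best_snap = _snapshot(all_params)
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stopping_patience:
                break

    if best_snap is not None:
        _restore(all_params, best_snap)
    return TrainedModel(net=net, fusion=fus, config=config,
                        best_epoch=best[1], best_val_cindex=best[0],
                        training_log=log)


def score_cohort(model: TrainedModel, cohort: MultimodalCohort,
                 idx: np.ndarray | None = None) -> tuple[np.ndarray, list[np.ndarray]]:
    """Risk scores (and per-modality invariant representations) for a cohort
    subset at the trained parameters."""
    if idx is None:
        idx = np.arange(cohort.n_patients)
    blocks = _subset_blocks(cohort, idx)
    return _score(model.net, model.fusion, blocks, model.config)


def run_cross_validation(cohort: MultimodalCohort, config: TrainConfig,
                         seed: int | None = None):
    """5-fold CV: train on each fold, select on validation, evaluate on the
    held-out test set. Returns (per-fold list of (model, report, test_ids),
    summary dict with mean/sd of C-index and AUC)."""
    config.validate()
    seed = config.seed if seed is None else seed
    splits = make_fold_splits(cohort, seed)
    results = []
    for split in splits:
        fold_cfg = dataclasses.replace(config, seed=seed * 100 + split.fold_index)
        model = train_fold(cohort, split, fold_cfg)
        test_idx = cohort.index_of(split.test_ids)
        risk, inv = score_cohort(model, cohort, test_idx)
        report = evaluate_risk(risk, cohort.labels.subset(test_idx),
                               invariant_reps=inv)
        results.append((model, report, split.test_ids))
    cis = [r.cindex for _, r, _ in results]
    aucs = [r.auc for _, r, _ in results]
    summary = {
        "cindex_mean": float(np.mean(cis)), "cindex_sd": float(np.std(cis)),
        "auc_mean": float(np.nanmean(aucs)), "auc_sd": float(np.nanstd(aucs)),
    }
    return results, summary


# ------------------------------------------------ reference configurations


def synthetic_reference_network(input_dim: int = 80) -> NetworkConfig:
    """The network shape used for synthetic-cohort experiments: a scaled
    replica of the default architecture (latent width 32 instead of 225,
    survival head 64/32/16/8 instead of 900/256/64/15) sized to the
    synthetic cohorts' 80 features and a few hundred patients."""
    return NetworkConfig(
        input_dim=input_dim, latent_dim=32,
        shared_encoder_widths=(128,), specific_encoder_widths=(128,),
        discriminator_widths=(32,), decoder_widths=(128,),
        survival_head_widths=(64, 32, 16, 8), fusion_rank=4,
    )


def synthetic_reference_config(seed: int = 0, **overrides) -> TrainConfig:
    """Reference training settings for synthetic-cohort experiments."""
    base = dict(epochs=400, early_stopping_patience=80, learning_rate=1e-3,
                network=synthetic_reference_network(), seed=seed)
    base.update(overrides)
    return TrainConfig(**base)


# ------------------------------------------------------------- checkpoints


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained fold (network + fusion parameters + config)."""
    cfg = dataclasses.asdict(model.config)
    cfg["enabled_losses"] = sorted(model.config.enabled_losses)
    payload = {
        "config": cfg,
        "best_epoch": model.best_epoch,
        "best_val_cindex": model.best_val_cindex,
        "net_seed": model.net.seed,
        "head_input_width": model.net.head_input_width,
        "net_arrays": {k: v.value.tolist() for k, v in model.net.params.items()},
        "fusion": {
            "rank": model.fusion.rank,
            "lmf_append_one": model.fusion.lmf_append_one,
            "gate_sigmoid": model.fusion.gate_sigmoid,
            "arrays": {k: v.value.tolist() for k, v in model.fusion.params.items()},
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedModel:
    """Inverse of :func:`save_model`."""
    try:
        payload = json.loads(Path(path).read_text())
        cfg_dict = payload["config"]
        net_arrays = payload["net_arrays"]
        fus_dict = payload["fusion"]
    except (json.JSONDecodeError, KeyError) as exc:
        raise ValueError(f"corrupt or truncated checkpoint {path}: {exc}") from exc
    net_cfg = NetworkConfig(**{**cfg_dict.pop("network"),})
    config = TrainConfig(
        network=net_cfg,
        loss_weights=LossWeights(**cfg_dict.pop("loss_weights")),
        **{**cfg_dict, "enabled_losses": frozenset(cfg_dict.pop("enabled_losses"))},
    )
    net = CamrParameters(net_cfg, seed=payload["net_seed"],
                         head_input_width=payload["head_input_width"])
    if set(net_arrays) != set(net.params):
        raise ValueError(f"checkpoint {path}: parameter groups do not match config")
    for k, v in net_arrays.items():
        net.params[k].value = np.asarray(v, dtype=np.float64)
    fus = FusionParameters(net_cfg.latent_dim, rank=fus_dict["rank"],
                           lmf_append_one=fus_dict["lmf_append_one"],
                           gate_sigmoid=fus_dict["gate_sigmoid"])
    if set(fus_dict["arrays"]) != set(fus.params):
        raise ValueError(f"checkpoint {path}: fusion parameters do not match config")
    for k, v in fus_dict["arrays"].items():
        fus.params[k].value = np.asarray(v, dtype=np.float64)
    return TrainedModel(net=net, fusion=fus, config=config,
                        best_epoch=payload["best_epoch"],
                        best_val_cindex=payload["best_val_cindex"],
                        training_log=[])


# ---------------------------------------------------------------- ablation

LOSS_VARIANTS: dict[str, frozenset[str]] = {
    "B0_cox_only": frozenset(),
    "B1_adv": frozenset({"adv"}),
    "B2_rec": frozenset({"rec"}),
    "B3_orth": frozenset({"orth"}),
    "B4_adv_orth": frozenset({"adv", "orth"}),
    "B5_adv_rec": frozenset({"adv", "rec"}),
    "B6_rec_orth": frozenset({"rec", "orth"}),
    "full_all_losses": frozenset({"adv", "rec", "orth"}),
}

FUSION_ABLATION: dict[str, dict] = {
    "concat": {"fusion_variant": "concat", "concat_specific": False},
    "lmf": {"fusion_variant": "lmf", "concat_specific": False},
    "cmfm": {"fusion_variant": "cmfm", "concat_specific": False},
    "cmfm_star": {"fusion_variant": "cmfm", "concat_specific": True},
}


def run_ablation_grid(cohort: MultimodalCohort,
                      base_config: TrainConfig) -> pd.DataFrame:
    """Run the 8 loss-subset variants and the 4 fusion variants under a
    shared seed; one row per variant with mean/sd of C-index and AUC."""
    rows = []
    for name, losses in LOSS_VARIANTS.items():
        cfg = dataclasses.replace(base_config, enabled_losses=losses)
        _, summary = run_cross_validation(cohort, cfg)
        rows.append({"variant": name, "kind": "loss_subset", **summary})
    for name, overrides in FUSION_ABLATION.items():
        cfg = dataclasses.replace(base_config, **overrides)
        _, summary = run_cross_validation(cohort, cfg)
        rows.append({"variant": name, "kind": "fusion", **summary})
    return pd.DataFrame(rows)
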