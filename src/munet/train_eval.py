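"""Training loop, prediction workflow and the simulation experiment harness.

Training minimizes the root-mean squared-error loss

    L = sqrt( (1/R) sum_r || T_r - net(x_r) ||^2 )

over R low-count noise-realization input sets of a single training
subject simultaneously (full-batch gradient steps with Adam), which is
proportional to the sample NRMSE of the prediction set against the
target. An l1 variant (mean absolute error per voxel) is available for
comparison. Validation loss on a different subject is evaluated every
epoch; training stops when it has not improved for ``patience_epochs``
epochs (or at ``max_epochs``) and the best-validation weights are
restored.

The experiment harness reproduces the simulation-study pipeline end to
end: phantom generation, acquisition simulation at a configured count
level, MLEM reconstruction with and without resolution modeling,
NRMSE-grid optimization of the Gaussian post-smoothing and guided-NLM
reference filters on the training subject only, micro-net (and
optionally U-net) training, and bias/std/NRMSE evaluation of every
method on held-out test subjects.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import filters, metrics, nets, petsim, phantom
from ._conv import Adam

__all__ = [
    "TrainConfig", "TrainRecord", "TrainingDivergedError", "loss", "train",
    "predict", "ExperimentConfig", "ExperimentResult", "run_experiment",
    "ablate_channels", "architecture_sweep", "desk_config",
]


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    """Optimization settings (defaults follow the full-scale protocol)."""

    learning_rate: float = 1e-3
    optimizer: str = "adam"
    patience_epochs: int = 10_000
    n_realizations: int = 2
    loss_norm: str = "l2"
    seed: int = 0
    max_epochs: int = 100_000

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.loss_norm not in ("l2", "l1"):
            raise ValueError("loss_norm must be 'l2' or 'l1'")


@dataclass
class TrainRecord:
    train_loss: list
    val_loss: list
    best_epoch: int
    best_weights: nets.WeightSet
    n_epochs: int
    stopped_early: bool
    wall_time_s: float = 0.0


def loss(preds, targets, norm: str = "l2") -> float:
    """Eq.-style training loss over R prediction/target pairs."""
    p = np.asarray(preds, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"prediction shape {p.shape} != target shape {t.shape}")
    if p.ndim < 1:
        raise ValueError("need at least one realization")
    R = p.shape[0]
    d = (t - p).reshape(R, -1)
    if norm == "l2":
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
    if norm == "l1":
        return float(np.mean(np.abs(d)))
    raise ValueError("norm must be 'l2' or 'l1'")


def _loss_and_grad(preds: np.ndarray, targets: np.ndarray, norm: str):
    R = preds.shape[0]
    d = (preds - targets).astype(np.float64)
    if norm == "l2":
        L = np.sqrt(np.mean(np.sum(d.reshape(R, -1) ** 2, axis=1)))
        g = d / (R * max(L, 1e-30))
    else:
        J = d[0].size
        L = np.abs(d).mean()
        g = np.sign(d) / (R * J)
    return float(L), g.astype(np.float32)


def train(net, train_inputs: np.ndarray, train_targets: np.ndarray,
          val_inputs: np.ndarray, val_targets: np.ndarray,
          cfg: TrainConfig) -> TrainRecord:
    """Full-batch Adam with early stopping on validation loss.

    ``train_inputs``: (R, C, D, H, W); ``train_targets``: (R, D, H, W)
    (a shared target may be broadcast beforehand); validation likewise
    with its own R (usually 1), from a different subject. The weights
    achieving minimum validation loss are restored into ``net``.
    """
    tx = np.ascontiguousarray(train_inputs, dtype=np.float32)
    tt = np.asarray(train_targets, dtype=np.float32)
    vx = np.ascontiguousarray(val_inputs, dtype=np.float32)
    vt = np.asarray(val_targets, dtype=np.float32)
    if tt.ndim == tx.ndim - 2:  # shared target
        tt = np.broadcast_to(tt, (tx.shape[0],) + tt.shape)
    if vt.ndim == vx.ndim - 2:
        vt = np.broadcast_to(vt, (vx.shape[0],) + vt.shape)
    tt = tt[:, None]  # channel axis
    vt = vt[:, None]

    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    net.enable_input_col_cache()  # inputs are fixed across epochs
    t0 = time.time()
    train_hist, val_hist = [], []
    best_val, best_epoch, best_w = np.inf, -1, None
    stopped = False
    for epoch in range(1, cfg.max_epochs + 1):
        preds = net.forward(tx)
        L, dpred = _loss_and_grad(preds, tt, cfg.loss_norm)
        if not np.isfinite(L):
            raise TrainingDivergedError(
                f"non-finite training loss at epoch {epoch} "
                f"(lr={cfg.learning_rate}, loss_norm={cfg.loss_norm})")
        net.backward(dpred)
        opt.step(net.gradients())
        vpred = net.forward(vx)
        Lv = loss(vpred, vt, cfg.loss_norm)
        train_hist.append(L)
        val_hist.append(Lv)
        if Lv < best_val:
            best_val, best_epoch = Lv, epoch
            best_w = net.get_weights()
        if epoch - best_epoch >= cfg.patience_epochs:
            stopped = True
            break
    net.set_weights(best_w)
    net.trained = True
    net.clear_caches()
    return TrainRecord(train_loss=train_hist, val_loss=val_hist,
                       best_epoch=best_epoch, best_weights=best_w,
                       n_epochs=len(train_hist), stopped_early=stopped,
                       wall_time_s=time.time() - t0)


def predict(net, mlem_img, mlem_rm_img, t1_img, *, nlm_omega: float,
            nlm_window: int = 5, require_trained: bool = True) -> np.ndarray:
    """Normalize raw channels, run the network, rescale total intensity.

    The ELU output layer bounds the normalized prediction below by -1,
    so the (pre-rescale) output is bounded below by minus the target
    scale; non-negativity is not strictly enforced.
    """
    if require_trained and not getattr(net, "trained", False):
        raise ValueError("network has not been trained; pass require_trained=False "
                         "to predict with explicitly constructed weights")
    x, norm = nets.normalize_inputs(mlem_img, mlem_rm_img, t1_img,
                                    nlm_omega=nlm_omega, nlm_window=nlm_window)
    out = net.forward(x[None])[0, 0].astype(np.float64)
    return nets.rescale_output(out, norm)


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Declarative description of a full simulation study."""

    shape: tuple = (64, 64, 64)
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    n_lesions: int = 2
    n_angles: int = 48
    total_counts: int = 300_000          # low count level
    std_total_counts: int = 3_000_000    # standard count level (target mode std_recon)
    randoms_fraction: float = 0.26
    scatter_fraction: float = 0.28
    psf_fwhm_mm: float = 4.5
    rm_fwhm_mm: float = 4.5
    n_iter: int = 100
    n_iter_rm: int = 300
    n_train_realizations: int = 2
    n_val_realizations: int = 1
    n_test_subjects: int = 2
    n_test_realizations: int = 10
    target: str = "truth"                # 'truth' or 'std_recon'
    ps_grid: tuple = (0.0, 12.0, 0.1)    # start, stop, step (mm FWHM)
    nlm_exp_grid: tuple = (-5.0, 5.0, 0.01)  # exponents of 10 for Omega
    nlm_window: int = 5
    learning_rate: float = 1e-3
    unet_learning_rate: Optional[float] = None  # defaults to learning_rate
    init_fan_in: str = "paper"  # He-init convention: 'paper' or 'standard'
    loss_norm: str = "l2"
    max_epochs: int = 100_000
    patience_epochs: int = 10_000
    train_unet: bool = True
    max_epochs_unet: Optional[int] = None
    patience_epochs_unet: Optional[int] = None
    mlem_checkpoints: tuple = ()
    recon_dtype: str = "float32"
    overfit_gap_threshold: float = 0.25  # relative train/val gap for the micro-net
    seed: int = 0

    def ps_values(self) -> np.ndarray:
        a, b, s = self.ps_grid
        return np.round(np.arange(a, b + 1e-9, s), 10)

    def nlm_values(self) -> np.ndarray:
        a, b, s = self.nlm_exp_grid
        return 10.0 ** np.arange(a, b + 1e-9, s)


def desk_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """Desk-scale 64^3 study sized for a single CPU core.

    Uses the suggested scaled count levels (1:10:100 preserved), MLEM
    iterations scaled to 50/150 keeping the 1:3 no-RM:RM ratio, a
    coarser NLM exponent grid, and three training noise realizations.
    The optimization schedule is compressed to fit the core-minutes the
    study is given: the micro-net takes larger Adam steps (5e-3) over
    50 full-batch epochs, the standard He fan-in (the volume-less
    printed variant saturates the wide sigmoid layer at init), and the
    U-net comparator trains at its largest stable step size (1e-3).
    See docs/methods.md for what these budgets do and do not reach.
    """
    cfg = ExperimentConfig(
        seed=seed,
        n_iter=50, n_iter_rm=150,
        n_train_realizations=3,
        nlm_exp_grid=(-2.0, 2.0, 0.1),
        learning_rate=5e-3, unet_learning_rate=1e-3,
        init_fan_in="standard",
        max_epochs=50, patience_epochs=40,
        max_epochs_unet=8, patience_epochs_unet=8,
        mlem_checkpoints=(2, 5, 10, 20, 35, 50, 75, 100, 150),
    )
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    return cfg


@dataclass
class ExperimentResult:
    methods: pd.DataFrame            # per-subject and mean metrics per method
    curves: pd.DataFrame             # bias-vs-std sweep points
    params: dict                     # optimized filter params, net metadata
    train_records: dict              # name -> TrainRecord
    provenance: dict

    def method_nrmse(self, method: str) -> float:
        df = self.methods
        row = df[(df.method == method) & (df.subject == "mean")]
        return float(row.nrmse_pct.iloc[0])


@dataclass
class _Subject:
    name: str
    phantom: phantom.PhantomSet
    recon: np.ndarray        # (R, ...) activity units, no RM
    recon_rm: np.ndarray     # (R, ...) activity units, RM
    history: dict            # checkpoints for the iterate curve (no-RM, RM)
    target: np.ndarray       # training/optimization target volume


def _simulate_subject(name, phan, geom, cfg: ExperimentConfig, n_real, seed,
                      checkpoints=(), dtype=np.float32) -> _Subject:
    ccfg = petsim.CountConfig(total_counts=cfg.total_counts,
                              randoms_fraction=cfg.randoms_fraction,
                              scatter_fraction=cfg.scatter_fraction,
                              seed=seed, psf_fwhm_mm=cfg.psf_fwhm_mm)
    sinos = petsim.simulate_realizations(phan.tau, geom, phan.mu_map, ccfg, n_real)
    scale = sinos[0].count_scale
    cps = [c for c in checkpoints if c <= cfg.n_iter]
    cps_rm = [c for c in checkpoints if c <= cfg.n_iter_rm]
    res = petsim.mlem_batch(sinos, n_iter=cfg.n_iter, checkpoints=cps, dtype=dtype)
    res_rm = petsim.mlem_batch(sinos, rm_fwhm_mm=cfg.rm_fwhm_mm,
                               n_iter=cfg.n_iter_rm, checkpoints=cps_rm, dtype=dtype)
    history = {"mlem": {k: v / scale for k, v in res.history.items()},
               "mlem_rm": {k: v / scale for k, v in res_rm.history.items()}}

    if cfg.target == "truth":
        target = phan.tau
    elif cfg.target == "std_recon":
        std_cfg = petsim.CountConfig(total_counts=cfg.std_total_counts,
                                     randoms_fraction=cfg.randoms_fraction,
                                     scatter_fraction=cfg.scatter_fraction,
                                     seed=seed + 1_000_003,
                                     psf_fwhm_mm=cfg.psf_fwhm_mm)
        std_sino = petsim.simulate_prompts(phan.tau, geom, phan.mu_map, std_cfg)
        std_res = petsim.mlem(std_sino, n_iter=cfg.n_iter, dtype=dtype)
        target = std_res.image / std_sino.count_scale
    else:
        raise ValueError("target must be 'truth' or 'std_recon'")
    return _Subject(name=name, phantom=phan,
                    recon=res.image / scale, recon_rm=res_rm.image / scale,
                    history=history, target=np.asarray(target, dtype=np.float64))


def _build_input_stack(subj: _Subject, omega_raw: float, window: int):
    """Normalized 4-channel inputs for every realization of a subject."""
    stacks, norms = [], []
    t1 = subj.phantom.mr_t1
    for r in range(subj.recon.shape[0]):
        # Omega was optimized on the raw guide; the channel filters the
        # standardized guide, so rescale by this set's T1 std (the filter
        # is invariant under joint guide/Omega scaling).
        omega_std = omega_raw / t1.std()
        x, norm = nets.normalize_inputs(subj.recon[r], subj.recon_rm[r], t1,
                                        nlm_omega=omega_std, nlm_window=window)
        stacks.append(x)
        norms.append(norm)
    return np.stack(stacks), norms


def _prepare_study(cfg: ExperimentConfig):
    ss = np.random.SeedSequence([int(cfg.seed), 0xE8B])
    sub_seeds = ss.generate_state(3 + cfg.n_test_subjects).astype(np.int64) % (2**31)
    geom = petsim.default_geometry(cfg.shape, cfg.voxel_size_mm, n_angles=cfg.n_angles)
    dtype = np.dtype(cfg.recon_dtype)

    subjects = {}
    phan_train = phantom.make_phantom(cfg.shape, cfg.voxel_size_mm, cfg.n_lesions,
                                      seed=int(sub_seeds[0]))
    subjects["train"] = _simulate_subject("train", phan_train, geom, cfg,
                                          cfg.n_train_realizations,
                                          seed=int(sub_seeds[1]), dtype=dtype)
    phan_val = phantom.make_phantom(cfg.shape, cfg.voxel_size_mm, cfg.n_lesions,
                                    seed=int(sub_seeds[0]) + 17)
    subjects["val"] = _simulate_subject("val", phan_val, geom, cfg,
                                        cfg.n_val_realizations,
                                        seed=int(sub_seeds[2]), dtype=dtype)
    for i in range(cfg.n_test_subjects):
        phan_t = phantom.make_phantom(cfg.shape, cfg.voxel_size_mm, cfg.n_lesions,
                                      seed=int(sub_seeds[0]) + 101 + i)
        subjects[f"test{i}"] = _simulate_subject(
            f"test{i}", phan_t, geom, cfg, cfg.n_test_realizations,
            seed=int(sub_seeds[3 + i]),
            checkpoints=cfg.mlem_checkpoints if i == 0 else (), dtype=dtype)
    return geom, subjects


def _optimize_filters(cfg: ExperimentConfig, train_subj: _Subject):
    """Grid-optimize PS (on both recon types) and NLM on training data only."""
    vs = cfg.voxel_size_mm
    tgt = train_subj.target
    ps_vals = cfg.ps_values()
    nlm_vals = cfg.nlm_values()
    fwhm_plain, curve_ps = filters.optimize_filter_param(
        list(train_subj.recon), tgt, ps_vals, "ps", voxel_size_mm=vs)
    fwhm_rm, curve_ps_rm = filters.optimize_filter_param(
        list(train_subj.recon_rm), tgt, ps_vals, "ps", voxel_size_mm=vs)
    omega, curve_nlm = filters.optimize_filter_param(
        list(train_subj.recon_rm), tgt, nlm_vals, "nlm",
        guide=train_subj.phantom.mr_t1, window=cfg.nlm_window)
    return {"ps_fwhm_mm": fwhm_plain, "ps_rm_fwhm_mm": fwhm_rm, "nlm_omega": omega,
            "ps_curve": (ps_vals, curve_ps), "ps_rm_curve": (ps_vals, curve_ps_rm),
            "nlm_curve": (nlm_vals, curve_nlm)}


def _method_images(subj: _Subject, cfg: ExperimentConfig, opt: dict,
                   trained: dict) -> dict:
    """Per-method reconstruction sets (R, ...) for one subject."""
    vs = cfg.voxel_size_mm
    out = {
        "mlem": subj.recon,
        "mlem_rm": subj.recon_rm,
        "ps": np.stack([filters.gaussian_ps(v, opt["ps_fwhm_mm"], vs)
                        for v in subj.recon]),
        "ps_rm": np.stack([filters.gaussian_ps(v, opt["ps_rm_fwhm_mm"], vs)
                           for v in subj.recon_rm]),
        "nlm": filters._nlm_multi(np.asarray(subj.recon_rm, dtype=np.float64),
                                  subj.phantom.mr_t1, opt["nlm_omega"],
                                  cfg.nlm_window),
    }
    if trained:
        omega_std = opt["nlm_omega"] / subj.phantom.mr_t1.std()
        preds: dict[str, list] = {name: [] for name in trained}
        for r in range(subj.recon.shape[0]):
            x, norm = nets.normalize_inputs(subj.recon[r], subj.recon_rm[r],
                                            subj.phantom.mr_t1,
                                            nlm_omega=omega_std,
                                            nlm_window=cfg.nlm_window)
            for name, net in trained.items():
                raw = net.forward(x[None])[0, 0].astype(np.float64)
                preds[name].append(nets.rescale_output(raw, norm))
        for name in trained:
            out[name] = np.stack(preds[name])
    return out


def _metrics_rows(images: dict, subj: _Subject, truth: np.ndarray) -> list[dict]:
    rows = []
    for method, imgs in images.items():
        mt = metrics.metrics_triple(list(imgs), truth, target_id="truth")
        rows.append(dict(method=method, subject=subj.name, count_level="low",
                         target="truth", b_pct=mt.bias_pct, sigma_pct=mt.std_pct,
                         nrmse_pct=mt.nrmse_pct, param_value=np.nan))
    return rows


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """End-to-end simulation study (see module docstring)."""
    t0 = time.time()
    geom, subjects = _prepare_study(cfg)
    train_subj, val_subj = subjects["train"], subjects["val"]
    opt = _optimize_filters(cfg, train_subj)

    window = cfg.nlm_window
    tx, _ = _build_input_stack(train_subj, opt["nlm_omega"], window)
    vx, _ = _build_input_stack(val_subj, opt["nlm_omega"], window)
    # target normalized to unit variance, mean untouched
    t_scale = train_subj.target.std()
    v_scale = val_subj.target.std()
    tt = (train_subj.target / t_scale).astype(np.float32)
    vt = (val_subj.target / v_scale).astype(np.float32)

    tcfg = TrainConfig(learning_rate=cfg.learning_rate,
                       patience_epochs=cfg.patience_epochs,
                       n_realizations=cfg.n_train_realizations,
                       loss_norm=cfg.loss_norm, seed=cfg.seed,
                       max_epochs=cfg.max_epochs)
    munet = nets.build_munet(seed=cfg.seed, fan_in=cfg.init_fan_in)
    records = {}
    records["munet"] = train(munet, tx, np.broadcast_to(tt, (tx.shape[0],) + tt.shape),
                             vx, vt[None], tcfg)
    trained = {"munet": munet}
    if cfg.train_unet:
        ucfg = TrainConfig(learning_rate=cfg.unet_learning_rate or cfg.learning_rate,
                           patience_epochs=cfg.patience_epochs_unet or cfg.patience_epochs,
                           n_realizations=cfg.n_train_realizations,
                           loss_norm=cfg.loss_norm, seed=cfg.seed,
                           max_epochs=cfg.max_epochs_unet or cfg.max_epochs)
        unet = nets.build_unet(seed=cfg.seed, fan_in=cfg.init_fan_in)
        records["unet"] = train(unet, tx, np.broadcast_to(tt, (tx.shape[0],) + tt.shape),
                                vx, vt[None], ucfg)
        trained["unet"] = unet

    rows, curve_rows = [], []
    per_method: dict[str, list] = {}
    for key, subj in subjects.items():
        if not key.startswith("test"):
            continue
        truth = subj.phantom.tau
        images = _method_images(subj, cfg, opt, trained)
        rows.extend(_metrics_rows(images, subj, truth))
        for method, imgs in images.items():
            per_method.setdefault(method, []).append(
                metrics.metrics_triple(list(imgs), truth))
        # bias-vs-std sweep curves on the first test subject
        if key == "test0":
            for mname in ("mlem", "mlem_rm"):
                for k, imgs in sorted(subj.history[mname].items()):
                    mt = metrics.metrics_triple(list(imgs), truth)
                    curve_rows.append(dict(method=f"{mname}_iterates", param_value=k,
                                           b_pct=mt.bias_pct, sigma_pct=mt.std_pct,
                                           nrmse_pct=mt.nrmse_pct))
            for pname, src in (("ps_sweep", subj.recon), ("ps_rm_sweep", subj.recon_rm)):
                for fw in cfg.ps_values()[::max(1, len(cfg.ps_values()) // 25)]:
                    sm = [filters.gaussian_ps(v, fw, cfg.voxel_size_mm) for v in src]
                    mt = metrics.metrics_triple(sm, truth)
                    curve_rows.append(dict(method=pname, param_value=fw,
                                           b_pct=mt.bias_pct, sigma_pct=mt.std_pct,
                                           nrmse_pct=mt.nrmse_pct))
            nv = cfg.nlm_values()
            for om in nv[::max(1, len(nv) // 25)]:
                sm = filters._nlm_multi(np.asarray(subj.recon_rm, dtype=np.float64),
                                        subj.phantom.mr_t1, om, window)
                mt = metrics.metrics_triple(list(sm), truth)
                curve_rows.append(dict(method="nlm_sweep", param_value=om,
                                       b_pct=mt.bias_pct, sigma_pct=mt.std_pct,
                                       nrmse_pct=mt.nrmse_pct))
            for name in trained:
                imgs = images[name]
                mt = metrics.metrics_triple(list(imgs), truth)
                curve_rows.append(dict(method=f"{name}_point", param_value=np.nan,
                                       b_pct=mt.bias_pct, sigma_pct=mt.std_pct,
                                       nrmse_pct=mt.nrmse_pct))

    for method, triples in per_method.items():
        rows.append(dict(method=method, subject="mean", count_level="low",
                         target="truth",
                         b_pct=float(np.mean([t.bias_pct for t in triples])),
                         sigma_pct=float(np.mean([t.std_pct for t in triples])),
                         nrmse_pct=float(np.mean([t.nrmse_pct for t in triples])),
                         param_value=np.nan))

    params = {"ps_fwhm_mm": opt["ps_fwhm_mm"], "ps_rm_fwhm_mm": opt["ps_rm_fwhm_mm"],
              "nlm_omega": opt["nlm_omega"],
              "munet_parameters": nets.count_parameters(nets.MuNetSpec()),
              "munet_receptive_field": nets.receptive_field(nets.MuNetSpec()),
              "unet_parameters": trained["unet"].n_parameters() if "unet" in trained else None}
    prov = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(cfg).items()},
            "wall_time_s": time.time() - t0}
    return ExperimentResult(methods=pd.DataFrame(rows),
                            curves=pd.DataFrame(curve_rows),
                            params=params, train_records=records, provenance=prov)


def ablate_channels(cfg: ExperimentConfig, channels_to_zero: tuple,
                    _study=None) -> pd.DataFrame:
    """Retrain with selected input channels zeroed; report test metrics.

    ``channels_to_zero`` is a subset of :data:`munet.nets.CHANNEL_NAMES`
    (empty = baseline). The architecture is unchanged; the channels are
    substituted by zeros at train and test time.
    """
    bad = set(channels_to_zero) - set(nets.CHANNEL_NAMES)
    if bad:
        raise ValueError(f"unknown channels {sorted(bad)}")
    if set(channels_to_zero) == set(nets.CHANNEL_NAMES):
        raise ValueError("cannot zero all input channels")
    geom, subjects = _study if _study is not None else _prepare_study(cfg)
    train_subj, val_subj = subjects["train"], subjects["val"]
    opt = _optimize_filters(cfg, train_subj)
    idx = [nets.CHANNEL_NAMES.index(c) for c in channels_to_zero]

    def zero(x):
        x = x.copy()
        x[:, idx] = 0.0
        return x

    tx, _ = _build_input_stack(train_subj, opt["nlm_omega"], cfg.nlm_window)
    vx, _ = _build_input_stack(val_subj, opt["nlm_omega"], cfg.nlm_window)
    tt = (train_subj.target / train_subj.target.std()).astype(np.float32)
    vt = (val_subj.target / val_subj.target.std()).astype(np.float32)
    tcfg = TrainConfig(learning_rate=cfg.learning_rate,
                       patience_epochs=cfg.patience_epochs,
                       n_realizations=cfg.n_train_realizations,
                       loss_norm=cfg.loss_norm, seed=cfg.seed, max_epochs=cfg.max_epochs)
    net = nets.build_munet(seed=cfg.seed, fan_in=cfg.init_fan_in)
    train(net, zero(tx), np.broadcast_to(tt, (tx.shape[0],) + tt.shape),
          zero(vx), vt[None], tcfg)

    rows = []
    for key, subj in subjects.items():
        if not key.startswith("test"):
            continue
        preds = []
        for r in range(subj.recon.shape[0]):
            x, norm = nets.normalize_inputs(
                subj.recon[r], subj.recon_rm[r], subj.phantom.mr_t1,
                nlm_omega=opt["nlm_omega"] / subj.phantom.mr_t1.std(),
                nlm_window=cfg.nlm_window)
            x = zero(x[None])[0]
            out = net.forward(x[None])[0, 0].astype(np.float64)
            preds.append(nets.rescale_output(out, norm))
        mt = metrics.metrics_triple(preds, subj.phantom.tau)
        rows.append(dict(zeroed=",".join(sorted(channels_to_zero)) or "none",
                         subject=subj.name, b_pct=mt.bias_pct,
                         sigma_pct=mt.std_pct, nrmse_pct=mt.nrmse_pct))
    return pd.DataFrame(rows)


def _sweep_spec(n_layers: int, n_kernels: int) -> nets.MuNetSpec:
    """Architecture-family member: widths {5, 3, ..., 3, 1}, final 1 kernel."""
    if n_layers == 1:
        layers = [nets.LayerSpec(1, 5, "elu")]
    else:
        widths = [5] + [3] * (n_layers - 2) + [1]
        layers = [nets.LayerSpec(n_kernels, w, "sigmoid") for w in widths[:-1]]
        layers.append(nets.LayerSpec(1, widths[-1], "elu"))
    return nets.MuNetSpec(layers=layers)


def architecture_sweep(cfg: ExperimentConfig, layer_counts=(1, 2, 3, 4),
                       kernel_counts=(1, 2, 4, 8, 16, 32), max_params=5_000_000,
                       _study=None) -> pd.DataFrame:
    """Test NRMSE for a grid of depths J and per-layer kernel counts n_j.

    All hidden layers share ``n_j``; the final layer always has one
    kernel. Combinations whose parameter count exceeds ``max_params``
    are skipped (recorded as NaN).
    """
    geom, subjects = _study if _study is not None else _prepare_study(cfg)
    train_subj, val_subj = subjects["train"], subjects["val"]
    opt = _optimize_filters(cfg, train_subj)
    tx, _ = _build_input_stack(train_subj, opt["nlm_omega"], cfg.nlm_window)
    vx, _ = _build_input_stack(val_subj, opt["nlm_omega"], cfg.nlm_window)
    tt = (train_subj.target / train_subj.target.std()).astype(np.float32)
    vt = (val_subj.target / val_subj.target.std()).astype(np.float32)
    tcfg = TrainConfig(learning_rate=cfg.learning_rate,
                       patience_epochs=cfg.patience_epochs,
                       n_realizations=cfg.n_train_realizations,
                       loss_norm=cfg.loss_norm, seed=cfg.seed, max_epochs=cfg.max_epochs)

    rows = []
    for J in layer_counts:
        for n in (kernel_counts if J > 1 else [1]):
            spec = _sweep_spec(J, n)
            n_par = nets.count_parameters(spec)
            if n_par > max_params:
                rows.append(dict(n_layers=J, n_kernels=n, n_parameters=n_par,
                                 nrmse_pct=np.nan, skipped=True))
                continue
            net = nets.MuNet(spec, seed=cfg.seed, fan_in=cfg.init_fan_in)
            assert net.n_parameters() == n_par
            train(net, tx, np.broadcast_to(tt, (tx.shape[0],) + tt.shape),
                  vx, vt[None], tcfg)
            trip = []
            for key, subj in subjects.items():
                if not key.startswith("test"):
                    continue
                preds = [predict(net, subj.recon[r], subj.recon_rm[r],
                                 subj.phantom.mr_t1,
                                 nlm_omega=opt["nlm_omega"] / subj.phantom.mr_t1.std(),
                                 nlm_window=cfg.nlm_window)
                         for r in range(subj.recon.shape[0])]
                trip.append(metrics.nrmse(preds, subj.phantom.tau))
            rows.append(dict(n_layers=J, n_kernels=n, n_parameters=n_par,
                             nrmse_pct=float(np.mean(trip)), skipped=False))
    return pd.DataFrame(rows)
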