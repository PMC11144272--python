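"""Conditional denoising-diffusion core for EM restoration.

A conditional DDPM: the forward process gradually replaces a clean target
patch x0 with Gaussian noise, ``x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps``;
the network eps_theta(x_t, t, cond) predicts the injected noise given the raw
conditioning image(s), and restoration runs the learned reverse chain from
pure noise.  Two features are specific to this package's task:

* a *difficulty-aware* heteroscedastic objective — the network carries a
  second head predicting a per-pixel difficulty map phi > 0 and is trained on
  ``|eps - eps_hat|^2 / (2 phi^2) + log phi`` so extremely noisy patches stop
  dominating the gradient (the per-pixel optimum is phi* = |eps - eps_hat|);
* a *channel embedding* — a sinusoidal encoding of an integer slice index
  j in [1, R] added to the timestep embedding, which lets a single 2D network
  generate any of the R intermediate layers between two volume slices.

Images are mapped to [-1, 1] for diffusion and back to [0, 1] outside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from . import nn
from .nn import Tensor, no_grad

__all__ = [
    "NoiseSchedule",
    "DiffusionSample",
    "TrainConfig",
    "NetConfig",
    "UNet",
    "build_schedule",
    "forward_noise",
    "difficulty_loss",
    "reverse_step",
    "sample",
    "channel_embed",
    "sinusoidal_embedding",
    "make_network",
    "train",
    "finetune",
    "save_checkpoint",
    "load_checkpoint",
    "to_model_range",
    "from_model_range",
]


def to_model_range(img: np.ndarray) -> np.ndarray:
    """[0, 1] image -> [-1, 1] diffusion-space image."""
    return np.asarray(img, dtype=float) * 2.0 - 1.0


def from_model_range(x: np.ndarray) -> np.ndarray:
    """[-1, 1] diffusion-space image -> clipped [0, 1] image."""
    return np.clip((np.asarray(x, dtype=float) + 1.0) / 2.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# schedule and forward process
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSchedule:
    """Diffusion constants indexed by timestep t = 1..T (index 0 unused)."""

    T: int
    beta: np.ndarray       # (T+1,), beta[0] = 0 sentinel
    alpha: np.ndarray      # 1 - beta
    alpha_bar: np.ndarray  # cumulative product of alpha[1..t]
    sigma2: np.ndarray     # reverse-step injected variance, 1 - alpha[t]


def build_schedule(T: int = 1000, beta_min: float = 1e-4,
                   beta_max: float = 0.02, kind: str = "linear"
                   ) -> NoiseSchedule:
    """Linear (default) or cosine beta ramp over T steps."""
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T}")
    if not (0.0 < beta_min < beta_max < 1.0):
        raise ValueError(
            f"need 0 < beta_min < beta_max < 1, got {beta_min}, {beta_max}")
    if kind == "linear":
        betas = np.linspace(beta_min, beta_max, T)
    elif kind == "cosine":
        # squared-cosine alpha_bar target, betas clipped into bounds
        s = 0.008
        ts = np.arange(T + 1) / T
        ab = np.cos((ts + s) / (1 + s) * np.pi / 2) ** 2
        betas = np.clip(1 - ab[1:] / ab[:-1], beta_min, beta_max)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    beta = np.concatenate([[0.0], betas])
    alpha = 1.0 - beta
    alpha_bar = np.concatenate([[1.0], np.cumprod(alpha[1:])])
    return NoiseSchedule(T=T, beta=beta, alpha=alpha, alpha_bar=alpha_bar,
                         sigma2=beta.copy())


def forward_noise(x0: np.ndarray, t: int, eps: np.ndarray,
                  schedule: NoiseSchedule) -> np.ndarray:
    """x_t = sqrt(abar_t) x0 + sqrt(1 - abar_t) eps."""
    if not 1 <= t <= schedule.T:
        raise IndexError(f"t must be in [1, {schedule.T}], got {t}")
    ab = schedule.alpha_bar[t]
    return np.sqrt(ab) * np.asarray(x0) + np.sqrt(1.0 - ab) * np.asarray(eps)


@dataclass
class DiffusionSample:
    """One training instance: target x0, condition stack, optional index j."""

    x0: np.ndarray            # (H, W) in [-1, 1]
    cond: np.ndarray          # (C, H, W) in [-1, 1]
    j: int | None = None      # slice index in [1, R] for volume interpolation


def difficulty_loss(eps, eps_hat, phi):
    """Mean over pixels of |eps - eps_hat|^2 / (2 phi^2) + log(phi).

    Accepts numpy arrays (returns float) or tape Tensors (returns Tensor).
    With phi == 1 this reduces to half the plain MSE.
    """
    if isinstance(eps_hat, Tensor) or isinstance(phi, Tensor):
        eps = eps if isinstance(eps, Tensor) else Tensor(eps)
        e = eps - eps_hat
        return (e * e / (2.0 * phi * phi) + phi.log()).mean()
    eps, eps_hat, phi = map(np.asarray, (eps, eps_hat, phi))
    if np.any(phi <= 0):
        raise ValueError("difficulty map phi must be strictly positive")
    e = eps - eps_hat
    return float(np.mean(e ** 2 / (2.0 * phi ** 2) + np.log(phi)))


# ---------------------------------------------------------------------------
# embeddings and network
# ---------------------------------------------------------------------------

def sinusoidal_embedding(value: float, dim: int) -> np.ndarray:
    """Standard transformer-style sinusoidal encoding of a scalar."""
    if dim % 2 != 0:
        raise ValueError("embedding dim must be even")
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / half)
    ang = value * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)])


def channel_embed(j: int, R: int, dim: int) -> np.ndarray:
    """Sinusoidal encoding of the slice index j in [1, R]."""
    if not 1 <= j <= R:
        raise ValueError(f"channel index j={j} outside [1, {R}]")
    return sinusoidal_embedding(float(j), dim)


@dataclass(frozen=True)
class NetConfig:
    base_width: int = 8
    cond_channels: int = 1
    emb_dim: int = 32
    logphi_clip: float = 10.0
    seed: int = 0


class UNet(nn.Module):
    """U-shaped eps/phi predictor: 2 encoder levels, bottleneck, 2 decoder
    levels with skip connections, FiLM-style additive conditioning on the
    (timestep + slice-index) embedding, and two 1x1 heads.

    Parameters are partitioned into the named groups
    {encoder, bottleneck, decoder, heads}; fine-tuning updates everything
    except the encoder.
    """

    def __init__(self, config: NetConfig):
        if config.base_width < 1 or config.cond_channels < 1:
            raise ValueError("invalid network config")
        if config.emb_dim % 2 != 0:
            raise ValueError("emb_dim must be even")
        self.config = config
        rng = np.random.default_rng(config.seed)
        w, d = config.base_width, config.emb_dim
        cin = 1 + config.cond_channels

        def gain(c):
            return nn.Parameter(np.ones((1, c, 1, 1), dtype=np.float32))

        self.stem = nn.Conv2d(cin, w, 3, rng)
        self.enc1 = nn.Conv2d(w, 2 * w, 3, rng)
        self.film0 = nn.Linear(d, w, rng)
        self.film1 = nn.Linear(d, 2 * w, rng)
        self.gain0 = gain(w)
        self.gain1 = gain(2 * w)

        self.emb1 = nn.Linear(d, d, rng)
        self.emb2 = nn.Linear(d, d, rng)
        self.bot1 = nn.Conv2d(2 * w, 2 * w, 3, rng)
        self.bot2 = nn.Conv2d(2 * w, 2 * w, 3, rng)
        self.filmb = nn.Linear(d, 2 * w, rng)
        self.gainb = gain(2 * w)

        self.dec1 = nn.Conv2d(4 * w, 2 * w, 3, rng)
        self.dec2 = nn.Conv2d(3 * w, w, 3, rng)
        self.filmd1 = nn.Linear(d, 2 * w, rng)
        self.filmd2 = nn.Linear(d, w, rng)
        self.gaind1 = gain(2 * w)
        self.gaind2 = gain(w)

        # zero-initialised heads: eps_hat = 0 and phi = exp(0) = 1 at the
        # start of training, which keeps the first loss steps bounded
        self.head_eps = nn.Conv2d(w, 1, 1, rng)
        self.head_phi = nn.Conv2d(w, 1, 1, rng)
        for head in (self.head_eps, self.head_phi):
            head.w.data[:] = 0.0
            head.b.data[:] = 0.0

    # -- parameter bookkeeping --------------------------------------------
    _GROUPS = {
        "encoder": ("stem", "enc1", "film0", "film1", "gain0", "gain1"),
        "bottleneck": ("emb1", "emb2", "bot1", "bot2", "filmb", "gainb"),
        "decoder": ("dec1", "dec2", "filmd1", "filmd2", "gaind1", "gaind2"),
        "heads": ("head_eps", "head_phi"),
    }

    def parameter_groups(self) -> dict[str, dict[str, nn.Parameter]]:
        all_params = self.parameters()
        groups: dict[str, dict[str, nn.Parameter]] = {}
        for gname, prefixes in self._GROUPS.items():
            groups[gname] = {
                k: p for k, p in all_params.items()
                if k.split(".")[0] in prefixes
            }
        return groups

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for k, p in params.items():
            p.data = np.array(state[k], dtype=p.data.dtype)

    # -- forward -----------------------------------------------------------
    def _embedding(self, t, j, batch: int) -> Tensor:
        d = self.config.emb_dim
        t = np.broadcast_to(np.asarray(t, dtype=float), (batch,))
        emb = np.stack([sinusoidal_embedding(ti, d) for ti in t])
        if j is not None:
            jarr = np.broadcast_to(np.asarray(j, dtype=float), (batch,))
            emb = emb + np.stack(
                [sinusoidal_embedding(ji, d) for ji in jarr])
        h = self.emb1(Tensor(emb.astype(np.float32))).silu()
        return self.emb2(h).silu()

    @staticmethod
    def _film(x: Tensor, lin: nn.Linear, emb: Tensor) -> Tensor:
        bias = lin(emb)  # (N, C)
        n, c = bias.data.shape
        return x + bias.reshape(n, c, 1, 1)

    def __call__(self, x_t: np.ndarray | Tensor,
                 cond: np.ndarray | Tensor, t, j=None
                 ) -> tuple[Tensor, Tensor]:
        """Predict (eps_hat, phi) for x_t (N,1,H,W) given cond (N,C,H,W)."""
        if not isinstance(x_t, Tensor):
            x_t = Tensor(np.asarray(x_t, dtype=np.float32))
        if not isinstance(cond, Tensor):
            cond = Tensor(np.asarray(cond, dtype=np.float32))
        if x_t.data.ndim != 4 or cond.data.ndim != 4 or \
                cond.data.shape[1] != self.config.cond_channels:
            raise ValueError("expected x_t (N,1,H,W) and cond (N,C,H,W)")
        n = x_t.data.shape[0]
        emb = self._embedding(t, j, n)

        def block(h, conv, gainp, film):
            return self._film(nn.spatial_rms_norm(conv(h), gainp),
                              film, emb).silu()

        h0 = block(nn.concat_channels([x_t, cond]), self.stem, self.gain0,
                   self.film0)
        h1 = block(nn.avg_pool2(h0), self.enc1, self.gain1, self.film1)

        hb = block(nn.avg_pool2(h1), self.bot1, self.gainb, self.filmb)
        hb = self.bot2(hb).silu()

        hd = block(nn.concat_channels([nn.upsample2(hb), h1]), self.dec1,
                   self.gaind1, self.filmd1)
        hd = block(nn.concat_channels([nn.upsample2(hd), h0]), self.dec2,
                   self.gaind2, self.filmd2)

        eps_hat = self.head_eps(hd)
        logphi = self.head_phi(hd).clip(-self.config.logphi_clip,
                                        self.config.logphi_clip)
        return eps_hat, logphi.exp()


def make_network(config: NetConfig) -> UNet:
    """Build the two-head conditional U-Net (deterministic given seed)."""
    return UNet(config)


# ---------------------------------------------------------------------------
# reverse process
# ---------------------------------------------------------------------------

def reverse_step(x_t: np.ndarray, t: int, cond: np.ndarray, j,
                 net, schedule: NoiseSchedule,
                 rng: np.random.Generator,
                 clip_denoised: bool = True) -> np.ndarray:
    """One reverse transition x_t -> x_{t-1}.

    ``x_{t-1} = (x_t - (1-a_t)/sqrt(1-abar_t) * eps_hat) / sqrt(a_t) + eta``
    with eta ~ N(0, (1 - a_t) I) for t > 1 and eta = 0 at the final step so
    the point estimate is noise-free.  With ``clip_denoised`` (the standard
    sampling stabiliser) the x0 implied by eps_hat is clamped to the valid
    [-1, 1] image range before the transition mean is formed; predictions
    already in range are untouched.
    """
    if not 1 <= t <= schedule.T:
        raise IndexError(f"t must be in [1, {schedule.T}], got {t}")
    a = schedule.alpha[t]
    ab = schedule.alpha_bar[t]
    with no_grad():
        eps_hat, _ = net(x_t[None, None], cond[None], t, j)
    eps_hat = eps_hat.data[0, 0]
    if eps_hat.shape != x_t.shape:
        raise ValueError("network output shape does not match x_t")
    if clip_denoised:
        x0_hat = (x_t - np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(ab)
        x0_hat = np.clip(x0_hat, -1.0, 1.0)
        eps_hat = (x_t - np.sqrt(ab) * x0_hat) / np.sqrt(1.0 - ab)
    mean = (x_t - (1.0 - a) / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(a)
    if t > 1:
        mean = mean + rng.standard_normal(x_t.shape) * np.sqrt(1.0 - a)
    return mean


def sample(cond: np.ndarray, j, net, schedule: NoiseSchedule,
           seed: int, return_phi: bool = False):
    """Draw one restored patch: start at x_T ~ N(0, I), run the reverse
    chain guided by ``cond``.  Deterministic given the seed.  When
    ``return_phi`` is set, also return the difficulty map of the final step.
    """
    cond = np.asarray(cond, dtype=float)
    if cond.ndim == 2:
        cond = cond[None]
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(cond.shape[1:])
    for t in range(schedule.T, 0, -1):
        x = reverse_step(x, t, cond, j, net, schedule, rng)
    if return_phi:
        with no_grad():
            _, phi = net(x[None, None], cond[None], 0, j)
        return x, phi.data[0, 0]
    return x


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    learning_rate: float = 5e-5
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 20
    finetune: bool = False
    finetune_lr: float = 1e-5
    finetune_epochs: int = 200
    augment: tuple[str, ...] = ("flip", "rotate90", "gaussian_blur")
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.finetune_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


def _augment_sample(x0, cond, rng, kinds):
    if "flip" in kinds:
        if rng.random() < 0.5:
            x0, cond = x0[::-1], cond[:, ::-1]
        if rng.random() < 0.5:
            x0, cond = x0[:, ::-1], cond[:, :, ::-1]
    if "rotate90" in kinds and x0.shape[0] == x0.shape[1]:
        k = rng.integers(0, 4)
        if k:
            x0 = np.rot90(x0, k)
            cond = np.rot90(cond, k, axes=(1, 2))
    if "gaussian_blur" in kinds and rng.random() < 0.3:
        sig = rng.uniform(0.2, 1.0)
        x0 = gaussian_filter(x0, sig)
        cond = gaussian_filter(cond, (0, sig, sig))
    return np.ascontiguousarray(x0), np.ascontiguousarray(cond)


def _epoch_loss(net, batch_samples, schedule, rng, kinds):
    """Forward one minibatch, return (loss Tensor, eps arrays)."""
    xs, conds, ts, js = [], [], [], []
    epss = []
    for s in batch_samples:
        x0, cond = _augment_sample(s.x0, s.cond, rng, kinds)
        t = int(rng.integers(1, schedule.T + 1))
        eps = rng.standard_normal(x0.shape)
        xs.append(forward_noise(x0, t, eps, schedule))
        conds.append(cond)
        ts.append(t)
        js.append(0 if s.j is None else s.j)
        epss.append(eps)
    has_j = any(s.j is not None for s in batch_samples)
    eps_hat, phi = net(np.stack(xs)[:, None], np.stack(conds),
                       np.array(ts), np.array(js) if has_j else None)
    eps_arr = np.stack(epss)[:, None]
    return difficulty_loss(Tensor(eps_arr), eps_hat, phi)


def _val_loss(net, samples, schedule, seed):
    rng = np.random.default_rng(seed)
    with no_grad():
        losses = []
        for i in range(0, len(samples), 16):
            batch = samples[i:i + 16]
            xs, conds, ts, js, epss = [], [], [], [], []
            for s in batch:
                t = int(rng.integers(1, schedule.T + 1))
                eps = rng.standard_normal(s.x0.shape)
                xs.append(forward_noise(s.x0, t, eps, schedule))
                conds.append(s.cond)
                ts.append(t)
                js.append(0 if s.j is None else s.j)
                epss.append(eps)
            has_j = any(s.j is not None for s in batch)
            eps_hat, phi = net(np.stack(xs)[:, None], np.stack(conds),
                               np.array(ts),
                               np.array(js) if has_j else None)
            losses.append(difficulty_loss(np.stack(epss)[:, None],
                                          eps_hat.data, phi.data))
    return float(np.mean(losses))


def train(net: UNet, dataset: list[DiffusionSample], config: TrainConfig,
          schedule: NoiseSchedule,
          trainable_groups: tuple[str, ...] | None = None
          ) -> tuple[UNet, dict]:
    """Train (or fine-tune) the network with Adam on the difficulty loss.

    Each step draws a random timestep (and uses the sample's slice index j if
    present), applies the configured augmentations and minimizes the
    difficulty-aware objective.  The checkpoint with the best validation loss
    within the patience window is restored at the end.  Returns the net and a
    history dict with per-epoch train/val losses.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(config.val_fraction * len(dataset)))) \
        if len(dataset) > 2 else 0
    order = rng.permutation(len(dataset))
    val = [dataset[i] for i in order[:n_val]]
    trainset = [dataset[i] for i in order[n_val:]] or list(dataset)

    groups = net.parameter_groups()
    if trainable_groups is None:
        trainable_groups = tuple(groups)
    params: dict[str, nn.Parameter] = {}
    for g in trainable_groups:
        params.update({f"{g}:{k}": p for k, p in groups[g].items()})
    lr = config.finetune_lr if config.finetune else config.learning_rate
    epochs = config.finetune_epochs if config.finetune else config.max_epochs
    opt = nn.Adam(params, lr=lr)

    history = {"train": [], "val": []}
    best_val, best_state, since_best = np.inf, net.state_dict(), 0
    for _epoch in range(epochs):
        idx = rng.permutation(len(trainset))
        epoch_losses = []
        for i in range(0, len(idx), config.batch_size):
            batch = [trainset[k] for k in idx[i:i + config.batch_size]]
            loss = _epoch_loss(net, batch, schedule, rng, config.augment)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history["train"].append(float(np.mean(epoch_losses)))
        if val:
            vl = _val_loss(net, val, schedule, config.seed + 1)
            history["val"].append(vl)
            if vl < best_val - 1e-12:
                best_val, best_state, since_best = vl, net.state_dict(), 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
        else:
            best_state = net.state_dict()
    net.load_state_dict(best_state)
    return net, history


def finetune(net: UNet, dataset: list[DiffusionSample],
             config: TrainConfig, schedule: NoiseSchedule
             ) -> tuple[UNet, dict]:
    """Adapt a pre-trained net to a new domain from very little data.

    Only the decoder, bottleneck and head parameter groups are updated; the
    encoder is frozen bit-for-bit.  Defaults: lr 1e-5 over 200 epochs.
    """
    cfg = TrainConfig(**{**asdict(config), "finetune": True})
    return train(net, dataset, cfg, schedule,
                 trainable_groups=("bottleneck", "decoder", "heads"))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, net: UNet,
                    schedule: NoiseSchedule, extra: dict | None = None):
    """Save weights + net config + schedule parameters as an .npz file."""
    meta = {
        "net_config": asdict(net.config),
        "schedule": {"T": schedule.T},
        "groups": {g: sorted(ps) for g, ps in
                   ((g, list(d)) for g, d in net.parameter_groups().items())},
        "extra": extra or {},
    }
    arrays = {f"param/{k}": v for k, v in net.state_dict().items()}
    arrays["beta"] = schedule.beta
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> tuple[UNet, NoiseSchedule, dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        beta = z["beta"]
        state = {k[len("param/"):]: z[k] for k in z.files
                 if k.startswith("param/")}
    cfg = NetConfig(**{**meta["net_config"],
                       "cond_channels": int(meta["net_config"]["cond_channels"])})
    net = UNet(cfg)
    net.load_state_dict(state)
    alpha = 1.0 - beta
    alpha_bar = np.concatenate([[1.0], np.cumprod(alpha[1:])])
    schedule = NoiseSchedule(T=int(meta["schedule"]["T"]), beta=beta,
                             alpha=alpha, alpha_bar=alpha_bar,
                             sigma2=beta.copy())
    return net, schedule, meta["extra"]
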