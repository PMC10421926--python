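"""Wasserstein GAN with gradient penalty over encoder states.

The generator maps standard-normal vectors z to synthetic latents; the
critic scores latents, trained to maximize mean D(real) - mean D(fake)
minus a penalty pushing its input-gradient norm toward 1 on random
per-sample interpolates between real and fake batches.  At synthesis time
the generator is the sole source of randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autoencoder import LatentDataset, TrainingConfig
from .nn import MLP, Adam, Module, Tensor, grad, sqrt, tmean, tsum


class Generator(Module):
    """MLP from z (d_z) to latent space (d_e), with an output affine map
    initialized to the real latents' mean/scale for faster convergence."""

    def __init__(self, d_z: int, d_e: int, rng: np.random.Generator,
                 width: int = 256, depth: int = 3,
                 out_shift: np.ndarray | None = None,
                 out_scale: np.ndarray | None = None):
        sizes = [d_z] + [width] * (depth - 1) + [d_e]
        self.net = MLP(sizes, rng)
        self.d_z, self.d_e = d_z, d_e
        self.shift = Tensor(np.zeros(d_e) if out_shift is None else out_shift)
        self.scale = Tensor(np.ones(d_e) if out_scale is None else out_scale)

    def __call__(self, z: Tensor) -> Tensor:
        return self.net(z) * self.scale + self.shift


class Critic(Module):
    def __init__(self, d_e: int, rng: np.random.Generator, width: int = 256, depth: int = 3):
        sizes = [d_e] + [width] * (depth - 1) + [1]
        self.net = MLP(sizes, rng)

    def __call__(self, e: Tensor) -> Tensor:
        return self.net(e)


@dataclass
class GanPair:
    generator: Generator
    critic: Critic
    history: dict[str, list[float]] = field(default_factory=dict)


def gradient_penalty(critic, e_real: np.ndarray, e_fake, eta: float,
                     rng: np.random.Generator) -> Tensor:
    """eta * mean over the batch of (||grad D(e_tilde)|| - 1)^2.

    ``e_tilde`` is the per-sample interpolate eps*real + (1-eps)*fake with
    one scalar eps ~ U[0,1] per sample.  The returned Tensor carries the
    graph needed to differentiate the penalty with respect to the critic's
    parameters.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    fake = e_fake.data if isinstance(e_fake, Tensor) else np.asarray(e_fake)
    if fake.shape != e_real.shape:
        raise ValueError("real and fake batches must have the same shape")
    eps = rng.uniform(size=(e_real.shape[0], 1))
    e_tilde = Tensor(eps * e_real + (1 - eps) * fake, requires_grad=True)
    score = tsum(critic(e_tilde))
    (g,) = grad(score, [e_tilde], create_graph=True)
    norm = sqrt(tsum(g * g, axis=1) + Tensor(1e-12))
    return Tensor(eta) * tmean((norm - Tensor(1.0)) ** 2)


def sample_latents(generator: Generator, m: int, rng: np.random.Generator) -> np.ndarray:
    """Draw M synthetic latents from z ~ N(0, I); arbitrary M supported."""
    if m <= 0:
        raise ValueError("number of samples must be positive")
    out = []
    for start in range(0, m, 4096):
        z = rng.standard_normal((min(4096, m - start), generator.d_z))
        out.append(generator(Tensor(z)).data)
    return np.concatenate(out, axis=0)


def sliced_wasserstein(a: np.ndarray, b: np.ndarray, n_proj: int = 64,
                       rng: np.random.Generator | None = None) -> float:
    """Mean 1-D Wasserstein distance over random projections."""
    rng = rng or np.random.default_rng(0)
    d = a.shape[1]
    proj = rng.standard_normal((d, n_proj))
    proj /= np.linalg.norm(proj, axis=0, keepdims=True)
    n = min(len(a), len(b))
    pa = np.sort(a[:n] @ proj, axis=0)
    pb = np.sort(b[:n] @ proj, axis=0)
    return float(np.abs(pa - pb).mean())


def train_wgan_gp(latents: LatentDataset, config: TrainingConfig,
                  checkpoint: str = "swd") -> GanPair:
    """Adversarial training in latent space; deterministic per seed.

    ``checkpoint`` selects the returned generator: ``"final"`` keeps the
    last iterate; ``"swd"`` (default) evaluates the sliced-Wasserstein
    distance between real and generated latents every 50 generator steps
    and returns the best iterate — WGAN training orbits the target rather
    than converging to it, and distance-based selection picks a point on
    the orbit close to the data."""
    e = np.asarray(latents.latents, dtype=np.float64)
    if not np.all(np.isfinite(e)):
        raise ValueError("latents must be finite")
    n, d_e = e.shape
    d_z = config.d_z or d_e
    rng = np.random.default_rng(config.seed + 2)
    # train in standardized latent space (isotropic scale suits the
    # gradient penalty); the returned generator destandardizes
    mu, sd = e.mean(axis=0), e.std(axis=0) + 1e-6
    e = (e - mu) / sd
    G = Generator(d_z, d_e, rng, width=config.gan_width, depth=config.gan_depth)
    D = Critic(d_e, rng, width=config.gan_width, depth=config.gan_depth)
    # WGAN-GP convention: low beta1
    opt_g = Adam(G.parameters(), lr=config.gan_learning_rate, betas=(0.5, 0.9))
    opt_d = Adam(D.parameters(), lr=config.gan_learning_rate, betas=(0.5, 0.9))
    bs = min(config.gan_batch_size, n)
    history = {"critic": [], "generator": [], "penalty": [], "swd": []}
    if checkpoint not in ("final", "swd"):
        raise ValueError(f"unknown checkpoint rule {checkpoint!r}")
    eval_rng = np.random.default_rng(config.seed + 3)
    ref = e[eval_rng.permutation(n)[: min(n, 1024)]]
    best = (np.inf, None)

    for it in range(config.gan_iters):
        for _ in range(config.critic_steps):
            real = e[rng.integers(0, n, size=bs)]
            z = rng.standard_normal((bs, d_z))
            fake = G(Tensor(z)).data  # critic step: generator held fixed
            gp = gradient_penalty(D, real, fake, config.eta, rng)
            d_loss = tmean(D(Tensor(fake))) - tmean(D(Tensor(real))) + gp
            grads = grad(d_loss, D.parameters())
            opt_d.step([g.data for g in grads])
        z = rng.standard_normal((bs, d_z))
        g_loss = -tmean(D(G(Tensor(z))))
        grads = grad(g_loss, G.parameters())
        opt_g.step([g.data for g in grads])
        if not (np.isfinite(d_loss.data) and np.isfinite(g_loss.data)):
            raise RuntimeError(f"GAN diverged at iter {it}; critic trace={history['critic'][-20:]}")
        history["critic"].append(float(d_loss.data))
        history["generator"].append(float(g_loss.data))
        history["penalty"].append(float(gp.data))
        if checkpoint == "swd" and (it % 25 == 24 or it == config.gan_iters - 1):
            sample = G(Tensor(eval_rng.standard_normal((len(ref), d_z)))).data
            swd = sliced_wasserstein(ref, sample, rng=np.random.default_rng(config.seed + 4))
            history["swd"].append(swd)
            if swd < best[0]:
                best = (swd, [p.data.copy() for p in G.parameters()])
    if checkpoint == "swd" and best[1] is not None:
        for p, w in zip(G.parameters(), best[1]):
            p.data = w
    G.shift = Tensor(mu)
    G.scale = Tensor(sd)
    return GanPair(G, D, history)
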