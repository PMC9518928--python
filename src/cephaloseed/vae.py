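"""Shape VAE and the local-to-global landmark estimation map.

The semi-supervised core of the pipeline.  A variational autoencoder learns a
low-dimensional latent representation z of normalized landmark vectors
(dimension 270 for all 90 landmarks at the coarse stage, 138 for the 46
cranial landmarks at the fine cranial stage).  A separate fully-connected
regressor Phi maps a small reference subvector (30-dim for the 10 reference
landmarks; 33-dim for the 8 cranial references plus the 3 finely detected
midsagittal landmarks) to the latent code, so that decoding Phi's output
estimates the full configuration from partial knowledge:

    R_coarse = D(Phi(R_ref)).

Training minimizes reconstruction error plus a KL term against N(0, I), with
full-batch Adam.  The encoder produces (mu, sigma) through three hidden ReLU
layers and two linear heads; sampling uses the reparameterization z = mu +
sigma * h with h ~ N(0, I).  The sigma head is parameterized as log-variance
(sigma = exp(logvar/2)) so positivity holds by construction.

Phi targets are built with the encoder in deterministic mode (z = mu): the
unpaired landmark sets contribute (Sub(R), E(R)) pairs, the paired subjects
contribute (detected references, E(R)) pairs, which is how landmark-only data
with no CT volumes still trains the local-to-global map.

Two KL forms are exposed.  ``standard`` is the usual Gaussian form
(1/2) sum(mu^2 + sigma^2 - log sigma^2 - 1); ``as_printed`` replaces
log sigma^2 by log sigma, a variant sometimes printed for this objective
(it differs only by a sigma-dependent constant factor in the penalty and
can go negative).  ``standard`` is the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .landmarks import FrameError, LandmarkSet
from .registry import LandmarkRegistry

KL_FORMS = ("standard", "as_printed")

DEFAULT_COARSE_WIDTHS = (128, 64, 32)
DEFAULT_CRANIAL_WIDTHS = (96, 48, 24)
DEFAULT_PHI_WIDTHS = (64, 32)


@dataclass
class TrainConfig:
    """Hyperparameters for one training stage (full-batch Adam)."""

    epochs: int
    learning_rate: float
    latent_dim: int = 9
    seed: int = 0
    kl_form: str = "standard"
    hidden_widths: tuple[int, ...] = DEFAULT_COARSE_WIDTHS
    batch_mode: str = "full"

    def __post_init__(self):
        if self.kl_form not in KL_FORMS:
            raise ValueError(f"kl_form must be one of {KL_FORMS}")
        if self.batch_mode != "full":
            raise ValueError("only full-batch training is supported")

    def scaled(self, epoch_factor: float) -> "TrainConfig":
        return replace(self, epochs=max(1, int(round(self.epochs * epoch_factor))))


@dataclass
class LatentCode:
    z: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive elementwise")


def kl_divergence(mu, sigma, form: str = "standard") -> float:
    """KL divergence of N(mu, diag(sigma^2)) from N(0, I).

    ``standard``: (1/2) sum(mu^2 + sigma^2 - log sigma^2 - 1), always >= 0.
    ``as_printed``: (1/2) sum(mu^2 + sigma^2 - log sigma - 1).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if form == "standard":
        return float(0.5 * np.sum(mu ** 2 + sigma ** 2 - 2.0 * np.log(sigma) - 1.0))
    if form == "as_printed":
        return float(0.5 * np.sum(mu ** 2 + sigma ** 2 - np.log(sigma) - 1.0))
    raise ValueError(f"unknown kl form {form!r}")


class VaeModel:
    """Encoder/decoder over normalized landmark vectors of a fixed name list."""

    def __init__(self, names: list[str], cfg: TrainConfig,
                 registry: LandmarkRegistry):
        self.names = list(names)
        self.cfg = cfg
        self.registry = registry
        self.input_dim = 3 * len(self.names)
        d = cfg.latent_dim
        if d >= self.input_dim:
            raise ValueError("latent_dim must be smaller than the input dimension")
        w = list(cfg.hidden_widths)
        rng = np.random.default_rng(cfg.seed)
        self.trunk = nn.mlp([self.input_dim] + w, rng, final_activation=True)
        self.mu_head = nn.Dense(w[-1], d, rng)
        self.logvar_head = nn.Dense(w[-1], d, rng)
        self.decoder = nn.mlp([d] + w[::-1] + [self.input_dim], rng)
        # input standardization (fitted during training); scale is a single
        # scalar so geometry is preserved
        self.x_mean = np.zeros(self.input_dim)
        self.x_scale = 1.0
        self.loss_curve: list[float] = []

    @property
    def latent_dim(self) -> int:
        return self.cfg.latent_dim

    def params(self) -> list[nn.Param]:
        return (self.trunk.params() + self.mu_head.params()
                + self.logvar_head.params() + self.decoder.params())

    # -- inference --------------------------------------------------------

    def _standardize(self, r: np.ndarray) -> np.ndarray:
        return (r - self.x_mean) / self.x_scale

    def _encode_heads(self, xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = self.trunk.forward(xs)
        mu = self.mu_head.forward(h)
        logvar = self.logvar_head.forward(h)
        return mu, logvar

    def encode(self, r, noise_seed: int | None = None) -> LatentCode:
        """Encode one landmark vector; deterministic (z = mu) when no seed."""
        r = np.asarray(r, dtype=float).reshape(1, -1)
        if r.shape[1] != self.input_dim:
            raise ValueError(f"expected vector of length {self.input_dim}, got {r.shape[1]}")
        mu, logvar = self._encode_heads(self._standardize(r))
        sigma = np.exp(0.5 * logvar)
        if noise_seed is None:
            z = mu.copy()
        else:
            h = np.random.default_rng(noise_seed).standard_normal(mu.shape)
            z = mu + sigma * h
        return LatentCode(z=z[0], mu=mu[0], sigma=sigma[0])

    def decode(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float).reshape(1, -1)
        if z.shape[1] != self.latent_dim:
            raise ValueError(f"expected latent of length {self.latent_dim}")
        xs = self.decoder.forward(z)
        return (xs * self.x_scale + self.x_mean)[0]

    def reconstruct(self, r) -> np.ndarray:
        return self.decode(self.encode(r).z)

    # -- vector <-> LandmarkSet -------------------------------------------

    def vector_of(self, lm: LandmarkSet) -> np.ndarray:
        if lm.frame != "normalized":
            raise FrameError("VAE operates on normalized-frame landmarks")
        return lm.to_vector(self.names)

    def set_of(self, vec: np.ndarray) -> LandmarkSet:
        return LandmarkSet.from_vector(vec, self.names, frame="normalized",
                                       registry=self.registry)


def train_vae(data: list[np.ndarray] | np.ndarray, cfg: TrainConfig,
              names: list[str], registry: LandmarkRegistry) -> VaeModel:
    """Train a shape VAE on normalized landmark vectors (full-batch Adam).

    The loss is the sum over the dataset of squared reconstruction error (in
    mm^2, i.e. measured on the unstandardized scale) plus the KL term of
    ``cfg.kl_form``.  Reproducible: the parameter init and the per-epoch
    reparameterization noise both derive from ``cfg.seed``.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 training vectors")
    model = VaeModel(names, cfg, registry)
    if x.shape[1] != model.input_dim:
        raise ValueError(f"vectors have length {x.shape[1]}, expected {model.input_dim}")

    model.x_mean = x.mean(axis=0)
    centered = x - model.x_mean
    model.x_scale = float(centered.std()) or 1.0
    xs = centered / model.x_scale
    scale2 = model.x_scale ** 2

    noise_rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    n = xs.shape[0]
    for epoch in range(cfg.epochs):
        opt.zero_grad()
        h_trunk = model.trunk.forward(xs)
        mu = model.mu_head.forward(h_trunk)
        logvar = model.logvar_head.forward(h_trunk)
        sigma = np.exp(0.5 * logvar)
        h = noise_rng.standard_normal(mu.shape)
        z = mu + sigma * h
        recon = model.decoder.forward(z)
        resid = recon - xs
        recon_loss = scale2 * float(np.sum(resid ** 2))
        if cfg.kl_form == "standard":
            kl = 0.5 * np.sum(mu ** 2 + np.exp(logvar) - logvar - 1.0)
            dkl_dlogvar = 0.5 * (np.exp(logvar) - 1.0)
        else:  # as_printed: log sigma = logvar / 2
            kl = 0.5 * np.sum(mu ** 2 + np.exp(logvar) - 0.5 * logvar - 1.0)
            dkl_dlogvar = 0.5 * np.exp(logvar) - 0.25
        loss = recon_loss + float(kl)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite VAE loss at epoch {epoch}: recon={recon_loss}, kl={kl}")

        dz = model.decoder.backward(2.0 * scale2 * resid)
        dmu = dz + mu
        dlogvar = dz * h * 0.5 * sigma + dkl_dlogvar
        g_trunk = model.mu_head.backward(dmu) + model.logvar_head.backward(dlogvar)
        model.trunk.backward(g_trunk)
        opt.step()
        model.loss_curve.append(loss / n)
    return model


@dataclass
class PhiModel:
    """Fully-connected map from a reference subvector to the VAE latent code."""

    net: nn.Sequential
    input_names: list[str]
    latent_dim: int
    cfg: TrainConfig
    x_mean: np.ndarray = field(default=None)
    x_scale: float = 1.0
    loss_curve: list[float] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return 3 * len(self.input_names)

    def predict(self, r_partial: np.ndarray) -> np.ndarray:
        r = np.asarray(r_partial, dtype=float).reshape(1, -1)
        if r.shape[1] != self.input_dim:
            raise ValueError(f"expected vector of length {self.input_dim}, got {r.shape[1]}")
        xs = (r - self.x_mean) / self.x_scale
        return self.net.forward(xs)[0]


def make_phi_pairs(paired_refs: list[LandmarkSet] | None,
                   paired_full: list[LandmarkSet] | None,
                   unpaired_full: list[LandmarkSet],
                   vae: VaeModel,
                   input_names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Build (reference-vector, latent-target) training pairs for Phi.

    Paired subjects contribute their *detected* reference vector with the
    latent code of their labeled full configuration; unpaired subjects
    contribute the subsampled references of their own landmark set.  Targets
    use the deterministic encoder (z = mu).  All sets must be in the
    normalized frame.
    """
    paired_refs = paired_refs or []
    paired_full = paired_full or []
    if len(paired_refs) != len(paired_full):
        raise ValueError("paired_refs and paired_full must have equal lengths")
    xs, zs = [], []
    for refs, full in zip(paired_refs, paired_full):
        for lm in (refs, full):
            if lm.frame != "normalized":
                raise FrameError("make_phi_pairs requires normalized-frame landmarks")
        xs.append(refs.to_vector(input_names))
        zs.append(vae.encode(vae.vector_of(full)).z)
    for full in unpaired_full:
        if full.frame != "normalized":
            raise FrameError("make_phi_pairs requires normalized-frame landmarks")
        xs.append(full.to_vector(input_names))
        zs.append(vae.encode(vae.vector_of(full)).z)
    return np.asarray(xs), np.asarray(zs)


def train_phi(pairs: tuple[np.ndarray, np.ndarray], vae: VaeModel,
              cfg: TrainConfig, input_names: list[str],
              hidden_widths: tuple[int, ...] = DEFAULT_PHI_WIDTHS) -> PhiModel:
    """Fit Phi by least squares on latent targets; the VAE stays frozen."""
    x, z = np.asarray(pairs[0], dtype=float), np.asarray(pairs[1], dtype=float)
    if x.shape[0] != z.shape[0]:
        raise ValueError("pair arrays must have equal first dimensions")
    if z.shape[1] != vae.latent_dim:
        raise ValueError("latent targets do not match the VAE latent dimension")
    rng = np.random.default_rng(cfg.seed)
    net = nn.mlp([x.shape[1]] + list(hidden_widths) + [vae.latent_dim], rng)
    phi = PhiModel(net=net, input_names=list(input_names),
                   latent_dim=vae.latent_dim, cfg=cfg)
    phi.x_mean = x.mean(axis=0)
    phi.x_scale = float((x - phi.x_mean).std()) or 1.0
    xs = (x - phi.x_mean) / phi.x_scale
    phi.loss_curve = nn.train_regressor(net, xs, z, cfg.epochs, cfg.learning_rate)
    return phi


def local_to_global(phi: PhiModel, vae: VaeModel,
                    r_partial: LandmarkSet | np.ndarray) -> LandmarkSet:
    """Estimate the stage's full landmark set from a reference subvector."""
    if isinstance(r_partial, LandmarkSet):
        if r_partial.frame != "normalized":
            raise FrameError("local_to_global requires normalized-frame landmarks")
        vec = r_partial.to_vector(phi.input_names)
    else:
        vec = np.asarray(r_partial, dtype=float).reshape(-1)
    z = phi.predict(vec)
    return vae.set_of(vae.decode(z))


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(path, vae: VaeModel, phi: PhiModel | None = None) -> None:
    """Single-file .npz archive with weights, widths, and the registry hash."""
    meta = {
        "names": vae.names,
        "cfg": {"epochs": vae.cfg.epochs, "learning_rate": vae.cfg.learning_rate,
                "latent_dim": vae.cfg.latent_dim, "seed": vae.cfg.seed,
                "kl_form": vae.cfg.kl_form,
                "hidden_widths": list(vae.cfg.hidden_widths)},
        "registry_hash": vae.registry.content_hash(),
        "x_scale": vae.x_scale,
        "has_phi": phi is not None,
    }
    arrays = {"x_mean": vae.x_mean}
    for i, p in enumerate(vae.params()):
        arrays[f"vae_{i}"] = p.value
    if phi is not None:
        meta["phi"] = {
            "input_names": phi.input_names,
            "cfg": {"epochs": phi.cfg.epochs, "learning_rate": phi.cfg.learning_rate,
                    "latent_dim": phi.cfg.latent_dim, "seed": phi.cfg.seed},
            "x_scale": phi.x_scale,
        }
        arrays["phi_x_mean"] = phi.x_mean
        for i, p in enumerate(phi.net.params()):
            arrays[f"phi_{i}"] = p.value
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path, registry: LandmarkRegistry
                    ) -> tuple[VaeModel, PhiModel | None]:
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        if meta["registry_hash"] != registry.content_hash():
            raise ValueError("checkpoint was trained against a different registry")
        c = meta["cfg"]
        cfg = TrainConfig(epochs=c["epochs"], learning_rate=c["learning_rate"],
                          latent_dim=c["latent_dim"], seed=c["seed"],
                          kl_form=c["kl_form"],
                          hidden_widths=tuple(c["hidden_widths"]))
        vae = VaeModel(meta["names"], cfg, registry)
        vae.x_mean = f["x_mean"]
        vae.x_scale = float(meta["x_scale"])
        for i, p in enumerate(vae.params()):
            p.value = f[f"vae_{i}"].copy()
        phi = None
        if meta.get("has_phi"):
            pm = meta["phi"]
            pc = pm["cfg"]
            pcfg = TrainConfig(epochs=pc["epochs"], learning_rate=pc["learning_rate"],
                               latent_dim=pc["latent_dim"], seed=pc["seed"])
            weights = []
            i = 0
            while f"phi_{i}" in f:
                weights.append(f[f"phi_{i}"].copy())
                i += 1
            # widths recoverable from the dense weight shapes (W, b pairs)
            w_mats = weights[0::2]
            widths = [w.shape[0] for w in w_mats] + [w_mats[-1].shape[1]]
            rng = np.random.default_rng(pcfg.seed)
            net = nn.mlp(widths, rng)
            nn.set_weights(net, weights)
            phi = PhiModel(net=net, input_names=pm["input_names"],
                           latent_dim=pcfg.latent_dim, cfg=pcfg,
                           x_mean=f["phi_x_mean"], x_scale=float(pm["x_scale"]))
    return vae, phi
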