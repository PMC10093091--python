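"""Adversarial patch generation and latent-space selection of aggressive
patches.

The generator is trained on real tissue patches and sampled to produce an
arbitrarily large pool of synthetic patches.  A separate encoder — a small
patch classifier fitted to the weak aggressive/non-aggressive labels, whose
penultimate layer serves as the embedding — maps real and generated patches
into one feature space, and generated patches are kept only if they lie
near real aggressive patches there: mean cosine similarity to the k nearest
real aggressive embeddings must reach a threshold AND the patch must be
closer (in cosine) to the aggressive class centroid than to the
non-aggressive one.

Both networks are deliberately small, backbone-agnostic stand-ins wired
through the same contracts a large pretrained backbone would use.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.transform import resize
from sklearn.decomposition import PCA

from ._nn import MLP, Adam, fit_binary
from .types import Patch

__all__ = [
    "GANConfig", "EncoderConfig", "GeneratorHandle", "EncoderHandle",
    "patch_features", "train_generator", "sample_patches",
    "finetune_encoder", "cosine_similarity", "select_aggressive_generated",
]

#: side length patches are downscaled to before entering any network
FEATURE_SIZE = 16
#: window (at native patch resolution) of the local-contrast texture map
_TEXTURE_WINDOW = 5


def _lowres_rgb(px: np.ndarray, size: int) -> np.ndarray:
    if px.shape[0] != size:
        return resize(px.astype(np.float64) / 255.0, (size, size, 3),
                      anti_aliasing=True, mode="reflect")
    return px.astype(np.float64) / 255.0


def _texture_map(px: np.ndarray, size: int) -> np.ndarray:
    """Downscaled local standard deviation of luminance.

    Nuclear density, pleomorphism and necrosis express themselves as local
    contrast at the nucleus scale, which plain downscaling averages away;
    this channel preserves it for the small dense backbones.
    """
    lum = (0.299 * px[..., 0] + 0.587 * px[..., 1]
           + 0.114 * px[..., 2]).astype(np.float64) / 255.0
    m1 = uniform_filter(lum, size=_TEXTURE_WINDOW, mode="reflect")
    m2 = uniform_filter(lum * lum, size=_TEXTURE_WINDOW, mode="reflect")
    local_sd = np.sqrt(np.maximum(m2 - m1 * m1, 0.0))
    if local_sd.shape[0] != size:
        local_sd = resize(local_sd, (size, size), anti_aliasing=True,
                          mode="reflect")
    return local_sd


def patch_features(patches, size: int = FEATURE_SIZE,
                   include_texture: bool = True) -> np.ndarray:
    """Feature matrix: downscaled RGB in [0, 1] plus a local-contrast map.

    With ``include_texture`` (the encoder/classifier default) each patch
    yields ``size*size*3`` colour features concatenated with ``size*size``
    texture features; without it (the generator's pixel space) only the
    colour part is returned.
    """
    n_col = size * size * 3
    n_feat = n_col + (size * size if include_texture else 0)
    feats = np.empty((len(patches), n_feat))
    for i, p in enumerate(patches):
        px = p.pixels if isinstance(p, Patch) else np.asarray(p)
        feats[i, :n_col] = _lowres_rgb(px, size).ravel()
        if include_texture:
            feats[i, n_col:] = _texture_map(px, size).ravel()
    return feats


@dataclass
class GANConfig:
    latent_dim: int = 32
    image_size: int = FEATURE_SIZE   # native sampling resolution
    hidden: int = 64
    disc_hidden: int = 32
    n_components: int = 40           # PCA compression of the patch space
    bound: float = 4.0               # soft tanh bound on whitened coords
    epochs: int = 400
    batch_size: int = 64
    lr: float = 1e-3
    seed: int = 0


@dataclass
class EncoderConfig:
    hidden: tuple = (64, 32)
    epochs: int = 60
    batch_size: int = 32
    lr: float = 2e-3
    seed: int = 0


class GeneratorHandle:
    """Trained generator: maps latent vectors to RGB patches.

    The generator operates on a PCA-compressed patch representation: its
    network emits whitened principal-component coordinates (soft-bounded by
    a scaled tanh), which are decoded back to pixel space and completed
    with residual noise matched to the training data's per-pixel
    reconstruction residuals.  Sampling is deterministic given z (the
    residual noise is seeded from z itself).
    """

    def __init__(self, net: MLP, config: GANConfig, pca_mean, pca_components,
                 coord_scale, residual_sd, history: dict):
        self.net = net
        self.config = config
        self.pca_mean = pca_mean
        self.pca_components = pca_components     # (k, dim)
        self.coord_scale = coord_scale           # per-component std
        self.residual_sd = residual_sd           # per-pixel residual std
        self.history = history
        self.latent_dim = config.latent_dim
        self.image_size = config.image_size

    def sample_coords(self, z: np.ndarray) -> np.ndarray:
        """Whitened PC coordinates for latent batch z."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        b = self.config.bound
        return b * np.tanh(self.net.forward(z) / b)

    def sample_images(self, z: np.ndarray) -> np.ndarray:
        """Deterministic map z -> (n, S, S, 3) uint8 images."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        coords = self.sample_coords(z) * self.coord_scale
        flat = coords @ self.pca_components + self.pca_mean
        noise_seed = zlib.crc32(np.ascontiguousarray(z).tobytes()) % (2**31)
        noise_rng = np.random.default_rng(noise_seed)
        flat = flat + noise_rng.standard_normal(flat.shape) * self.residual_sd
        imgs = np.clip(flat, 0.0, 1.0).reshape(-1, FEATURE_SIZE,
                                               FEATURE_SIZE, 3)
        s = self.image_size
        if s != FEATURE_SIZE:
            imgs = np.stack([resize(im, (s, s, 3), anti_aliasing=False,
                                    mode="reflect") for im in imgs])
        return np.clip(imgs * 255.0, 0, 255).astype(np.uint8)


class EncoderHandle:
    """Weak-label patch encoder; embeddings from the penultimate layer.

    Input features are standardised with the training-set statistics
    stored on the handle, so embeddings are deterministic functions of the
    learned parameters.
    """

    def __init__(self, net: MLP, config: EncoderConfig, feat_mean,
                 feat_sd, history: dict):
        self.net = net
        self.config = config
        self.feat_mean = feat_mean
        self.feat_sd = feat_sd
        self.history = history

    @property
    def embedding_dim(self) -> int:
        return self.net.sizes[-2]

    def _features(self, patches) -> np.ndarray:
        return (patch_features(patches) - self.feat_mean) / self.feat_sd

    def embed(self, patches) -> np.ndarray:
        """(n, embedding_dim) feature matrix."""
        return self.net.hidden(self._features(patches))

    def predict(self, patches) -> np.ndarray:
        return self.net.forward(self._features(patches)).ravel()


def _held_out_disc_accuracy(real: np.ndarray, fake: np.ndarray,
                            seed: int) -> float:
    """Accuracy of a freshly trained small discriminator on held-out
    real-vs-generated features (50/50 train/test split)."""
    n = min(len(real), len(fake))
    if n < 4:
        return float("nan")
    X = np.vstack([real[:n], fake[:n]])
    y = np.concatenate([np.ones(n), np.zeros(n)])
    mu, sd = X.mean(axis=0), X.std(axis=0) + 1e-8
    Xs = (X - mu) / sd
    idx = np.random.default_rng(seed).permutation(len(X))
    tr, te = idx[:len(X) // 2], idx[len(X) // 2:]
    net = MLP((X.shape[1], 32, 1), out="sigmoid", seed=seed)
    fit_binary(net, Xs[tr], y[tr], epochs=30, batch_size=32, lr=2e-3,
               seed=seed + 1)
    return float(np.mean((net.forward(Xs[te]).ravel() > 0.5) == y[te]))


def train_generator(patches, config: GANConfig | None = None
                    ) -> GeneratorHandle:
    """Train the adversarial patch generator on real patches.

    The patch space is first compressed by PCA; the discriminator is
    trained with the least-squares adversarial objective on whitened
    coordinates, while the generator minimises a feature-matching loss on
    the discriminator's hidden layer (the standard stabiliser for
    adversarial training on small sample sizes).  An 80/20
    train/validation split is used; the handle records the loss
    trajectories and the accuracy with which a freshly trained small
    discriminator separates held-out real patches from generated ones.
    Raises on fewer than 100 patches, non-uniform patch sizes, or
    numerical divergence.
    """
    config = config or GANConfig()
    if len(patches) < 100:
        raise ValueError(f"need >= 100 patches to train a generator, "
                         f"got {len(patches)}")
    sizes = {p.pixels.shape[0] if isinstance(p, Patch) else p.shape[0]
             for p in patches}
    if len(sizes) != 1:
        raise ValueError(f"non-uniform patch sizes: {sorted(sizes)}")
    X = patch_features(patches, include_texture=False)
    X_full = patch_features(patches)  # incl. texture, for the sanity check
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(X))
    n_train = int(round(0.8 * len(X)))
    X_train, X_val = X[order[:n_train]], X[order[n_train:]]
    X_val_full = X_full[order[n_train:]]

    k = min(config.n_components, n_train - 1, X.shape[1])
    pca = PCA(n_components=k, random_state=config.seed).fit(X_train)
    coords = pca.transform(X_train)
    scale = coords.std(axis=0) + 1e-9
    Cw = coords / scale
    residual_sd = (X_train - pca.inverse_transform(coords)).std(axis=0)
    b = config.bound

    gen = MLP((config.latent_dim, config.hidden, config.hidden, k),
              out="linear", seed=config.seed)
    disc = MLP((k, config.disc_hidden, 1), out="linear",
               seed=config.seed + 1)
    opt_g = Adam(gen, lr=config.lr)
    opt_d = Adam(disc, lr=config.lr)

    g_losses, d_losses = [], []
    for epoch in range(config.epochs):
        perm = rng.permutation(n_train)
        for start in range(0, n_train, config.batch_size):
            xb = Cw[perm[start:start + config.batch_size]]
            m = len(xb)
            z = rng.standard_normal((m, config.latent_dim))
            fake = b * np.tanh(gen.forward(z) / b)

            # discriminator step (least-squares): real -> 1, fake -> 0
            d_real, cache_r = disc.forward(xb, cache=True)
            grads_r, _ = disc.backward((d_real - 1.0) / m, cache_r)
            d_fake, cache_f = disc.forward(fake, cache=True)
            grads_f, _ = disc.backward(d_fake / m, cache_f)
            opt_d.step([(gr[0] + gf[0], gr[1] + gf[1])
                        for gr, gf in zip(grads_r, grads_f)])
            d_loss = 0.5 * (float(np.mean((d_real - 1.0) ** 2))
                            + float(np.mean(d_fake ** 2)))

            # generator step: match discriminator hidden features of reals
            z = rng.standard_normal((m, config.latent_dim))
            raw, cache_g = gen.forward(z, cache=True)
            out = b * np.tanh(raw / b)
            f_real = disc.hidden(xb).mean(axis=0)
            _, (zs_d, acts_d) = disc.forward(out, cache=True)
            diff = acts_d[1].mean(axis=0) - f_real
            g_loss = float(diff @ diff)
            d_feat = np.tile(2.0 * diff / m, (m, 1)) * (zs_d[0] > 0)
            d_input = d_feat @ disc.W[0].T
            grads_g, _ = gen.backward(d_input * (1.0 - (out / b) ** 2),
                                      cache_g)
            opt_g.step(grads_g)

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise RuntimeError(
                    f"adversarial training diverged at epoch {epoch} "
                    f"(d_loss={d_loss}, g_loss={g_loss})")
            d_losses.append(d_loss)
            g_losses.append(g_loss)

    handle = GeneratorHandle(gen, config, pca.mean_, pca.components_,
                             scale, residual_sd,
                             {"g_loss": g_losses, "d_loss": d_losses,
                              "n_train": n_train, "n_val": len(X_val)})
    z_val = rng.standard_normal((max(len(X_val), 100), config.latent_dim))
    fake_feats = patch_features(handle.sample_images(z_val).astype(np.uint8))
    handle.history["val_disc_accuracy"] = _held_out_disc_accuracy(
        X_val_full if len(X_val_full) >= 4 else X_full, fake_feats,
        seed=config.seed + 7)
    return handle


def sample_patches(gen: GeneratorHandle, n: int, seed: int = 0) -> list[Patch]:
    """Draw ``n`` unlabeled patches from the generator (seeded)."""
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, gen.latent_dim))
    images = gen.sample_images(z)
    return [Patch(pixels=img, tissue_fraction=1.0, core_id="GAN",
                  row=0, col=0, patient_id="GAN",
                  weak_label="unlabeled") for img in images]


def finetune_encoder(patches, config: EncoderConfig | None = None
                     ) -> EncoderHandle:
    """Fit the weak-label patch classifier whose hidden layer is the
    embedding space.

    Patches must carry both weak labels ({aggressive, non-aggressive});
    aggressive maps to class 1.
    """
    config = config or EncoderConfig()
    labels = np.array([p.weak_label for p in patches])
    present = set(labels)
    if not {"aggressive", "non-aggressive"} <= present:
        raise ValueError(
            f"need both weak labels present, got {sorted(present)}")
    X = patch_features(patches)
    y = (labels == "aggressive").astype(float)
    mu, sd = X.mean(axis=0), X.std(axis=0) + 1e-8
    net = MLP((X.shape[1],) + tuple(config.hidden) + (1,), out="sigmoid",
              seed=config.seed)
    losses = fit_binary(net, (X - mu) / sd, y, epochs=config.epochs,
                        batch_size=config.batch_size, lr=config.lr,
                        seed=config.seed + 1)
    return EncoderHandle(net, config, mu, sd, {"loss": losses})


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """cos(u, v) = u.v / (|u||v|); raises on a zero-norm vector."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-300)
    Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-300)
    return np.clip(An @ Bn.T, -1.0, 1.0)


def select_aggressive_generated(gen_embeddings, real_aggressive_embeddings,
                                real_nonaggressive_embeddings,
                                tau: float = 0.5, k: int = 5) -> np.ndarray:
    """Indices of generated patches that live in the aggressive region of
    the latent space.

    A generated embedding is selected iff (a) the mean cosine similarity to
    its k nearest real aggressive embeddings is >= ``tau`` and (b) it is
    more cosine-similar to the aggressive class centroid than to the
    non-aggressive centroid.  Indices are returned sorted by criterion (a),
    descending.  The rule is invariant to positive rescaling of all
    embeddings and the selected set shrinks monotonically as tau grows.
    """
    G = np.atleast_2d(np.asarray(gen_embeddings, dtype=np.float64))
    if G.size == 0 or len(G) == 0:
        return np.array([], dtype=int)
    A = np.atleast_2d(np.asarray(real_aggressive_embeddings,
                                 dtype=np.float64))
    N = np.atleast_2d(np.asarray(real_nonaggressive_embeddings,
                                 dtype=np.float64))
    if len(A) == 0 or len(N) == 0:
        raise ValueError("both real reference sets must be nonempty")
    sims = _cosine_matrix(G, A)
    kk = min(k, sims.shape[1])
    top = np.sort(sims, axis=1)[:, -kk:]
    knn_sim = top.mean(axis=1)
    cen_a = A.mean(axis=0, keepdims=True)
    cen_n = N.mean(axis=0, keepdims=True)
    margin = (_cosine_matrix(G, cen_a).ravel()
              > _cosine_matrix(G, cen_n).ravel())
    selected = np.flatnonzero((knn_sim >= tau) & margin)
    return selected[np.argsort(-knn_sim[selected], kind="stable")]
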