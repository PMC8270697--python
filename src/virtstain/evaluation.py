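"""Distributional image-quality metrics and the visual-simulation harness.

FID is the Fréchet distance between Gaussians fitted to embedding features;
IS is the exponentiated mean KL divergence between per-image conditional
class distributions and their marginal; MS (Mode Score) additionally
penalizes divergence between the generated and real marginals:

    MS = exp( E_x[KL(p(y|x) || p*(y))] - KL(pbar(y) || p*(y)) )

Embedders are pluggable so the metric arithmetic is verifiable without
pretrained networks: string embedders flatten or pool pixels; a trained
:class:`TileClassifier` provides class probabilities (for IS/MS) and
penultimate features (for FID) in the full pipeline. Because a
lower-is-better reading of raw IS is incoherent, reports carry
``is_gap = |IS_fake - IS_real|`` alongside the raw score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .nn import Tensor, backward, no_grad
from .types import ImageTile, MetricReport

__all__ = [
    "FeatureSet",
    "ProbSet",
    "embed",
    "fid",
    "inception_score",
    "mode_score",
    "TileClassifier",
    "train_visual_classifier",
    "visual_simulation_accuracy",
    "evaluate_tiles",
]


@dataclass
class FeatureSet:
    features: np.ndarray  # n x d
    embedder: str

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be an n x d matrix")

    @property
    def n(self):
        return self.features.shape[0]

    @property
    def mu(self) -> np.ndarray:
        return self.features.mean(axis=0)

    @property
    def sigma(self) -> np.ndarray:
        if self.n < 2:
            raise ValueError("covariance needs n >= 2")
        return np.cov(self.features, rowvar=False).reshape(
            self.features.shape[1], self.features.shape[1])


@dataclass
class ProbSet:
    probs: np.ndarray  # n x K rows on the simplex
    embedder: str = "probs"

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2:
            raise ValueError("probs must be an n x K matrix")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("rows must sum to 1 within 1e-6")

    @property
    def n(self):
        return self.probs.shape[0]


def _tiles_to_array(tiles) -> np.ndarray:
    arrs = [t.data if isinstance(t, ImageTile) else np.asarray(t) for t in tiles]
    return np.stack(arrs)


def embed(tiles, embedder="flatten"):
    """Map tiles to a :class:`FeatureSet` or :class:`ProbSet`.

    String embedders: ``"flatten"`` (raw pixel vectors), ``"mean_color"``
    (per-channel means), ``"pool4"``/``"pool8"`` (average-pool to k x k then
    flatten). Objects must expose ``kind`` ("features" or "probs"), ``name``
    and be callable on an (N, H, W, 3) array.
    """
    tiles = list(tiles)
    if not tiles:
        raise ValueError("cannot embed an empty tile list")
    X = _tiles_to_array(tiles)
    if isinstance(embedder, str):
        if embedder == "flatten":
            feats = X.reshape(X.shape[0], -1)
        elif embedder == "mean_color":
            feats = X.mean(axis=(1, 2))
        elif embedder.startswith("pool"):
            k = int(embedder[4:])
            N, H, W, C = X.shape
            if H % k or W % k:
                raise ValueError(f"tile size {(H, W)} not divisible into {k}x{k} cells")
            feats = X.reshape(N, k, H // k, k, W // k, C).mean(axis=(2, 4)).reshape(N, -1)
        else:
            raise ValueError(f"unknown embedder {embedder!r}")
        return FeatureSet(feats, embedder)
    out = embedder(X)
    if embedder.kind == "probs":
        return ProbSet(out, getattr(embedder, "name", "probs"))
    return FeatureSet(out, getattr(embedder, "name", "features"))


def _sqrt_psd(m: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh((m + m.T) / 2.0)
    if np.any(vals < -tol * max(1.0, abs(vals).max())):
        raise FloatingPointError("covariance product is not PSD after symmetrization")
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(real: FeatureSet, fake: FeatureSet) -> float:
    """Fréchet distance ||mu1-mu2||^2 + tr(S1 + S2 - 2 (S1 S2)^1/2)."""
    if real.features.shape[1] != fake.features.shape[1]:
        raise ValueError("feature dimensions differ")
    mu1, mu2 = real.mu, fake.mu
    s1, s2 = real.sigma, fake.sigma
    s1_half = _sqrt_psd(s1)
    cross = _sqrt_psd(s1_half @ s2 @ s1_half)  # same trace as (s1 s2)^1/2
    val = float(np.sum((mu1 - mu2) ** 2) + np.trace(s1) + np.trace(s2)
                - 2.0 * np.trace(cross))
    return max(val, 0.0)


def _kl_rows(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Row-wise KL(p_i || q) with 0 log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * (np.log(p) - np.log(q)), 0.0)
    return terms.sum(axis=1)


def inception_score(p: ProbSet, splits: int = 1) -> float:
    """exp of the mean conditional-vs-marginal KL, averaged over splits."""
    if splits < 1:
        raise ValueError("splits must be >= 1")
    if p.n < splits:
        raise ValueError("fewer rows than splits")
    scores = []
    for chunk in np.array_split(p.probs, splits):
        marginal = chunk.mean(axis=0)
        scores.append(np.exp(_kl_rows(chunk, marginal).mean()))
    return float(np.mean(scores))


def mode_score(p_fake: ProbSet, p_real: ProbSet) -> float:
    """Mode Score against the real marginal (see module docstring)."""
    if p_fake.probs.shape[1] != p_real.probs.shape[1]:
        raise ValueError("class counts differ")
    marg_real = p_real.probs.mean(axis=0)
    marg_fake = p_fake.probs.mean(axis=0)
    cond = _kl_rows(p_fake.probs, marg_real).mean()
    between = _kl_rows(marg_fake[None, :], marg_real)[0]
    return float(np.exp(cond - between))


# ---------------------------------------------------------------------------
# visual-simulation harness


class _SmallConvNet(nn.Module):
    """Reduced classification backbone: two strided convs, global average
    pooling, linear head. Stands in for the full-scale VGG-style classifier
    at desk scale."""

    def __init__(self, n_classes: int, width: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(3, width, 3, stride=2, padding=1, rng=rng)
        self.conv2 = nn.Conv2d(width, 2 * width, 3, stride=2, padding=1, rng=rng)
        self.fc = nn.Linear(2 * width, n_classes, rng=rng)

    def features(self, x: Tensor) -> Tensor:
        h = self.conv1(x).leaky_relu(0.2)
        h = self.conv2(h).leaky_relu(0.2)
        return h.mean(axis=(2, 3))

    def forward(self, x: Tensor) -> Tensor:
        return self.fc(self.features(x))


def _softmax_xent(logits: Tensor, labels: np.ndarray) -> Tensor:
    m = logits.max(axis=1, keepdims=True)
    lse = m + (logits - m).exp().sum(axis=1, keepdims=True).log()
    logp = logits - lse
    picked = logp[np.arange(len(labels)), labels]
    return -picked.mean()


class TileClassifier(BaseEstimator, ClassifierMixin):
    """Tumor-type classifier over stained tiles (reduced architecture).

    Parameters
    ----------
    width : base channel width of the conv backbone.
    pool_to : input tiles are average-pooled to this square size first.
    epochs, batch_size, lr : optimization knobs.
    random_state : seeds init and batching.
    """

    def __init__(self, width=12, pool_to=16, epochs=60, batch_size=32,
                 lr=5e-3, random_state=0):
        self.width = width
        self.pool_to = pool_to
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.random_state = random_state

    def _prep(self, tiles) -> np.ndarray:
        X = _tiles_to_array(tiles)  # N, H, W, 3
        N, H, W, C = X.shape
        k = H // self.pool_to
        if k > 1:
            X = X.reshape(N, self.pool_to, k, self.pool_to, k, C).mean(axis=(2, 4))
        return X.transpose(0, 3, 1, 2)

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        self.classes_ = classes
        idx_of = {c: i for i, c in enumerate(classes)}
        yy = np.array([idx_of[c] for c in y])
        Xp = self._prep(X)
        rng = np.random.default_rng(self.random_state)
        self.net_ = _SmallConvNet(classes.size, self.width, rng)
        params = list(self.net_.parameters())
        opt = nn.Adam(params, lr=self.lr, betas=(0.9, 0.999))
        n = len(Xp)
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                sel = order[start:start + self.batch_size]
                logits = self.net_(Tensor(Xp[sel]))
                loss = _softmax_xent(logits, yy[sel])
                opt.zero_grad()
                backward(loss, params)
                opt.step()
                self.loss_curve_.append(loss.item())
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        with no_grad():
            return self.net_(Tensor(self._prep(X))).data

    def predict_proba(self, X) -> np.ndarray:
        z = self.decision_function(X)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    # embedder protocol -------------------------------------------------
    @property
    def prob_embedder(self):
        clf = self

        class _E:
            kind = "probs"
            name = "tile_classifier.probs"

            def __call__(self, X):
                return clf.predict_proba(X)

        return _E()

    @property
    def feature_embedder(self):
        clf = self

        class _E:
            kind = "features"
            name = "tile_classifier.features"

            def __call__(self, X):
                with no_grad():
                    return clf.net_.features(Tensor(clf._prep(X))).data

        return _E()


def train_visual_classifier(labeled_tiles, labels=None, **params) -> TileClassifier:
    """Fit a :class:`TileClassifier`; ``labeled_tiles`` may be (tiles, labels)
    or the tiles with ``labels`` given separately."""
    if labels is None:
        labeled_tiles, labels = labeled_tiles
    return TileClassifier(**params).fit(labeled_tiles, labels)


def visual_simulation_accuracy(clf, generated_tiles, true_labels) -> float:
    """Fraction of generated tiles classified as their real tile's label."""
    generated_tiles = list(generated_tiles)
    true_labels = np.asarray(true_labels)
    if len(generated_tiles) == 0:
        raise ValueError("no tiles to evaluate")
    if len(generated_tiles) != len(true_labels):
        raise ValueError("tiles and labels differ in length")
    return float(np.mean(clf.predict(generated_tiles) == true_labels))


def evaluate_tiles(real_tiles, fake_tiles, feature_embedder="pool8",
                   prob_embedder=None, clf: TileClassifier | None = None) -> MetricReport:
    """Full metric report for two tile sets.

    Without a classifier, IS/MS fall back to softmax probabilities over
    mean-color features so the report is self-contained; with one, the
    classifier's probabilities and penultimate features are used.
    """
    if clf is not None:
        feature_embedder = clf.feature_embedder
        prob_embedder = clf.prob_embedder
    f_real = embed(real_tiles, feature_embedder)
    f_fake = embed(fake_tiles, feature_embedder)
    if prob_embedder is None:
        prob_embedder = _color_prob_embedder()
    p_real = embed(real_tiles, prob_embedder)
    p_fake = embed(fake_tiles, prob_embedder)
    fid_v = fid(f_real, f_fake)
    is_fake = inception_score(p_fake)
    is_real = inception_score(p_real)
    ms = mode_score(p_fake, p_real)
    return MetricReport(
        fid=fid_v, is_score=is_fake, ms=ms, is_gap=abs(is_fake - is_real),
        n_real=f_real.n, n_fake=f_fake.n,
        embedder=getattr(feature_embedder, "name", str(feature_embedder)),
    )


def _color_prob_embedder():
    class _E:
        kind = "probs"
        name = "color_softmax"

        def __call__(self, X):
            z = X.mean(axis=(1, 2)) * 8.0
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)

    return _E()
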