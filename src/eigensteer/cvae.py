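"""Label-conditioned variational autoencoder for expression profiles.

Encoder: profile concatenated with the one-hot phenotype label -> 256 -> 128
(ReLU) -> latent mean and log-variance.  Decoder: latent vector concatenated
with the label -> mirrored hidden layers -> sigmoid head on the gene
dimension.  Classifier: a single linear map from the latent posterior mean to
two logits.  Training minimizes a weighted sum of reconstruction loss (binary
cross-entropy on min-max-scaled data), the standard-Gaussian KL of the latent
posterior, and the classifier cross-entropy, with Adam at learning rate 1e-4.

Generation fits one product-Gaussian-kernel KDE per phenotype class on the
latent posterior means (bandwidth 0.2), draws latent points per class, decodes
them with the class label, and inverse-scales back to the log-NTPM scale.

Implemented directly on NumPy arrays (manual gradients): the networks are
small enough that CPU matrix products dominate and no autodiff framework is
needed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ttest_ind

from .curation import NormalizedExpression, encode_labels

__all__ = [
    "CvaeConfig",
    "CvaeModel",
    "ScalingBounds",
    "LatentEmbedding",
    "GeneratedProfiles",
    "scale_to_unit",
    "inverse_scale",
    "loss",
    "train",
    "encode",
    "sample_profiles",
    "auroc_retention",
    "auroc_from_pvalues",
    "save_model",
    "load_model",
]

CHECKPOINT_SCHEMA = 1


@dataclass
class CvaeConfig:
    latent_dim: int = 16
    hidden_sizes: tuple[int, int] = (256, 128)
    learning_rate: float = 1e-4
    epochs: int = 500
    batch_size: int = 50
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)  # recon, kl, class
    kde_bandwidth: float = 0.2
    seed: int = 0
    recon_loss: str = "bce"  # or "mse"

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.loss_weights):
            raise ValueError("loss weights must be positive")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if self.recon_loss not in ("bce", "mse"):
            raise ValueError("recon_loss must be 'bce' or 'mse'")
        if not 500 <= self.epochs <= 10_000:
            warnings.warn(f"epochs={self.epochs} outside the usual range [500, 1e4]")
        if not 50 <= self.batch_size <= 200:
            warnings.warn(f"batch_size={self.batch_size} outside the usual range [50, 200]")


@dataclass
class ScalingBounds:
    mins: np.ndarray
    maxs: np.ndarray
    constant: np.ndarray  # mask of constant genes (mapped to 0.5)


@dataclass
class CvaeModel:
    params: dict[str, np.ndarray]
    config: CvaeConfig
    bounds: ScalingBounds
    n_genes: int

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim


@dataclass
class LatentEmbedding:
    coordinates: np.ndarray  # samples x latent_dim posterior means
    labels: np.ndarray


@dataclass
class GeneratedProfiles:
    values: np.ndarray  # samples x genes, log-NTPM scale
    labels: np.ndarray  # balanced binary
    latent: np.ndarray | None = None  # KDE draws the profiles were decoded from


# ---------------------------------------------------------------------------
# scaling


def scale_to_unit(values: np.ndarray) -> tuple[np.ndarray, ScalingBounds]:
    """Per-gene min-max map into [0,1]; constant genes map to 0.5."""
    values = np.asarray(values, dtype=float)
    mins = values.min(axis=0)
    maxs = values.max(axis=0)
    constant = maxs == mins
    span = np.where(constant, 1.0, maxs - mins)
    scaled = (values - mins) / span
    scaled[:, constant] = 0.5
    return scaled, ScalingBounds(mins=mins, maxs=maxs, constant=constant)


def inverse_scale(scaled: np.ndarray, bounds: ScalingBounds) -> np.ndarray:
    span = np.where(bounds.constant, 0.0, bounds.maxs - bounds.mins)
    return scaled * span + bounds.mins


# ---------------------------------------------------------------------------
# network primitives


def _init_params(n_genes: int, config: CvaeConfig, rng: np.random.Generator) -> dict:
    h1, h2 = config.hidden_sizes
    L = config.latent_dim

    def glorot(n_in: int, n_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-limit, limit, size=(n_in, n_out))

    return {
        "enc_W1": glorot(n_genes + 2, h1), "enc_b1": np.zeros(h1),
        "enc_W2": glorot(h1, h2), "enc_b2": np.zeros(h2),
        "enc_Wmu": glorot(h2, L), "enc_bmu": np.zeros(L),
        "enc_Wlv": glorot(h2, L), "enc_blv": np.zeros(L),
        "dec_W1": glorot(L + 2, h2), "dec_b1": np.zeros(h2),
        "dec_W2": glorot(h2, h1), "dec_b2": np.zeros(h1),
        "dec_Wout": glorot(h1, n_genes), "dec_bout": np.zeros(n_genes),
        "clf_W": glorot(L, 2), "clf_b": np.zeros(2),
    }


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _encode_forward(params: dict, x: np.ndarray, onehot: np.ndarray) -> dict:
    xin = np.hstack([x, onehot])
    a1 = xin @ params["enc_W1"] + params["enc_b1"]
    h1 = np.maximum(a1, 0.0)
    a2 = h1 @ params["enc_W2"] + params["enc_b2"]
    h2 = np.maximum(a2, 0.0)
    mu = h2 @ params["enc_Wmu"] + params["enc_bmu"]
    lv = np.clip(h2 @ params["enc_Wlv"] + params["enc_blv"], -15.0, 15.0)
    return {"xin": xin, "a1": a1, "h1": h1, "a2": a2, "h2": h2, "mu": mu, "lv": lv}


def _decode_forward(params: dict, z: np.ndarray, onehot: np.ndarray) -> dict:
    zin = np.hstack([z, onehot])
    a1 = zin @ params["dec_W1"] + params["dec_b1"]
    g1 = np.maximum(a1, 0.0)
    a2 = g1 @ params["dec_W2"] + params["dec_b2"]
    g2 = np.maximum(a2, 0.0)
    logits = g2 @ params["dec_Wout"] + params["dec_bout"]
    return {"zin": zin, "a1": a1, "g1": g1, "a2": a2, "g2": g2,
            "logits": logits, "xhat": _sigmoid(logits)}


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _loss_terms(
    x: np.ndarray, onehot: np.ndarray, enc: dict, dec: dict, clf_logits: np.ndarray,
    recon_kind: str,
) -> tuple[float, float, float]:
    B, G = x.shape
    logits = dec["logits"]
    if recon_kind == "bce":
        # stable BCE-with-logits, mean over batch and genes
        recon = float(
            np.mean(np.maximum(logits, 0.0) - logits * x + np.log1p(np.exp(-np.abs(logits))))
        )
    else:
        recon = float(np.mean((dec["xhat"] - x) ** 2))
    mu, lv = enc["mu"], enc["lv"]
    kl = float(0.5 * np.mean(np.sum(np.exp(lv) + mu**2 - 1.0 - lv, axis=1)))
    probs = _softmax(clf_logits)
    picked = np.clip(probs[np.arange(B), np.argmax(onehot, axis=1)], 1e-300, None)
    cls = float(-np.mean(np.log(picked)))
    return recon, kl, cls


def loss(
    model: CvaeModel,
    batch: np.ndarray,
    labels: np.ndarray,
    weights: tuple[float, float, float] | None = None,
) -> tuple[float, float, float, float]:
    """(total, recon, kl, class) on a unit-scaled batch; deterministic (z = mu).

    Raises on a non-finite value, naming the offending term.
    """
    weights = weights or model.config.loss_weights
    onehot = encode_labels(labels)
    enc = _encode_forward(model.params, np.asarray(batch, dtype=float), onehot)
    dec = _decode_forward(model.params, enc["mu"], onehot)
    clf_logits = enc["mu"] @ model.params["clf_W"] + model.params["clf_b"]
    recon, kl, cls = _loss_terms(batch, onehot, enc, dec, clf_logits,
                                 model.config.recon_loss)
    for name, value in (("reconstruction", recon), ("kl", kl), ("classification", cls)):
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite {name} loss")
    w_r, w_k, w_c = weights
    return w_r * recon + w_k * kl + w_c * cls, recon, kl, cls


def _backward(
    params: dict,
    x: np.ndarray,
    onehot: np.ndarray,
    enc: dict,
    dec: dict,
    clf_logits: np.ndarray,
    eps: np.ndarray,
    weights: tuple[float, float, float],
    recon_kind: str,
) -> dict[str, np.ndarray]:
    """Gradients of the weighted total loss w.r.t. every parameter."""
    B, G = x.shape
    L = enc["mu"].shape[1]
    w_r, w_k, w_c = weights
    grads = {}

    # --- decoder / reconstruction
    if recon_kind == "bce":
        dlogits = w_r * (dec["xhat"] - x) / (B * G)
    else:
        dxhat = w_r * 2.0 * (dec["xhat"] - x) / (B * G)
        dlogits = dxhat * dec["xhat"] * (1.0 - dec["xhat"])
    grads["dec_Wout"] = dec["g2"].T @ dlogits
    grads["dec_bout"] = dlogits.sum(axis=0)
    dg2 = dlogits @ params["dec_Wout"].T
    dg2 *= dec["a2"] > 0
    grads["dec_W2"] = dec["g1"].T @ dg2
    grads["dec_b2"] = dg2.sum(axis=0)
    dg1 = dg2 @ params["dec_W2"].T
    dg1 *= dec["a1"] > 0
    grads["dec_W1"] = dec["zin"].T @ dg1
    grads["dec_b1"] = dg1.sum(axis=0)
    dzin = dg1 @ params["dec_W1"].T
    dz = dzin[:, :L]  # gradient w.r.t. the sampled latent point

    # --- classifier (on the posterior mean)
    probs = _softmax(clf_logits)
    dclf = w_c * (probs - onehot) / B
    grads["clf_W"] = enc["mu"].T @ dclf
    grads["clf_b"] = dclf.sum(axis=0)

    # --- latent: z = mu + exp(lv/2) * eps; KL terms
    mu, lv = enc["mu"], enc["lv"]
    dmu = dz + dclf @ params["clf_W"].T + w_k * mu / B
    dlv = dz * eps * 0.5 * np.exp(0.5 * lv) + w_k * 0.5 * (np.exp(lv) - 1.0) / B

    # --- encoder
    grads["enc_Wmu"] = enc["h2"].T @ dmu
    grads["enc_bmu"] = dmu.sum(axis=0)
    grads["enc_Wlv"] = enc["h2"].T @ dlv
    grads["enc_blv"] = dlv.sum(axis=0)
    dh2 = dmu @ params["enc_Wmu"].T + dlv @ params["enc_Wlv"].T
    dh2 *= enc["a2"] > 0
    grads["enc_W2"] = enc["h1"].T @ dh2
    grads["enc_b2"] = dh2.sum(axis=0)
    dh1 = dh2 @ params["enc_W2"].T
    dh1 *= enc["a1"] > 0
    grads["enc_W1"] = enc["xin"].T @ dh1
    grads["enc_b1"] = dh1.sum(axis=0)
    return grads


def train(
    config: CvaeConfig,
    expr: NormalizedExpression | np.ndarray,
    labels: np.ndarray | None = None,
) -> tuple[CvaeModel, dict[str, list[float]]]:
    """Train on log-NTPM expression; returns the model and per-epoch loss trace.

    Deterministic given ``config.seed`` (fixed initialization, shuffling, and
    reparameterization noise streams).  Divergence (a non-finite loss) aborts
    with the epoch index.
    """
    if isinstance(expr, NormalizedExpression):
        values, labels = expr.values, expr.labels
    else:
        values = np.asarray(expr, dtype=float)
        if labels is None:
            raise ValueError("labels are required when passing a bare matrix")
    labels = np.asarray(labels, dtype=int)
    if min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per class")

    scaled, bounds = scale_to_unit(values)
    onehot = encode_labels(labels)
    m, n_genes = scaled.shape
    rng = np.random.default_rng(config.seed)
    params = _init_params(n_genes, config, rng)

    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    step = 0

    trace: dict[str, list[float]] = {"total": [], "recon": [], "kl": [], "class": []}
    batch = min(config.batch_size, m)
    for epoch in range(config.epochs):
        order = rng.permutation(m)
        ep = {"total": 0.0, "recon": 0.0, "kl": 0.0, "class": 0.0}
        n_batches = 0
        for start in range(0, m, batch):
            idx = order[start : start + batch]
            x, y = scaled[idx], onehot[idx]
            enc = _encode_forward(params, x, y)
            eps = rng.standard_normal(enc["mu"].shape)
            z = enc["mu"] + np.exp(0.5 * enc["lv"]) * eps
            dec = _decode_forward(params, z, y)
            clf_logits = enc["mu"] @ params["clf_W"] + params["clf_b"]
            recon, kl, cls = _loss_terms(x, y, enc, dec, clf_logits, config.recon_loss)
            w_r, w_k, w_c = config.loss_weights
            total = w_r * recon + w_k * kl + w_c * cls
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            grads = _backward(params, x, y, enc, dec, clf_logits, eps,
                              config.loss_weights, config.recon_loss)
            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for k, g in grads.items():
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                params[k] -= lr_t * adam_m[k] / (np.sqrt(adam_v[k]) + adam_eps)
            for key, val in zip(("total", "recon", "kl", "class"), (total, recon, kl, cls)):
                ep[key] += val
            n_batches += 1
        for key in trace:
            trace[key].append(ep[key] / n_batches)

    model = CvaeModel(params=params, config=config, bounds=bounds, n_genes=n_genes)
    return model, trace


def encode(
    model: CvaeModel, expr: NormalizedExpression | np.ndarray,
    labels: np.ndarray | None = None,
) -> LatentEmbedding:
    """Posterior means of the latent code (no sampling)."""
    if isinstance(expr, NormalizedExpression):
        values, labels = expr.values, expr.labels
    else:
        values = np.asarray(expr, dtype=float)
        if labels is None:
            raise ValueError("labels are required when passing a bare matrix")
    if values.shape[1] != model.n_genes:
        raise ValueError(
            f"input has {values.shape[1]} genes but the model expects {model.n_genes}"
        )
    scaled, _ = _apply_bounds(values, model.bounds)
    enc = _encode_forward(model.params, scaled, encode_labels(labels))
    return LatentEmbedding(coordinates=enc["mu"], labels=np.asarray(labels, dtype=int))


def _apply_bounds(values: np.ndarray, bounds: ScalingBounds) -> tuple[np.ndarray, None]:
    span = np.where(bounds.constant, 1.0, bounds.maxs - bounds.mins)
    scaled = (values - bounds.mins) / span
    scaled[:, bounds.constant] = 0.5
    return scaled, None


def decode(model: CvaeModel, z: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Decode latent points with their class labels back to the log-NTPM scale."""
    dec = _decode_forward(model.params, np.asarray(z, dtype=float), encode_labels(labels))
    return inverse_scale(dec["xhat"], model.bounds)


def sample_profiles(
    model: CvaeModel,
    embedding: LatentEmbedding,
    n_per_class: int,
    bandwidth: float | None = None,
    seed: int = 0,
) -> GeneratedProfiles:
    """KDE-sample the latent space per class and decode, equal class counts.

    One product-Gaussian-kernel KDE per class is fit on the embedded posterior
    means; sampling picks an embedded point uniformly and adds N(0, bw^2)
    noise per latent dimension.
    """
    if bandwidth is None:
        bandwidth = model.config.kde_bandwidth
    rng = np.random.default_rng(seed)
    blocks, labels_out = [], []
    for cls in (0, 1):
        pts = embedding.coordinates[embedding.labels == cls]
        # a single point is only meaningful in the degenerate bandwidth-0 KDE
        min_pts = 1 if bandwidth == 0 else 2
        if len(pts) < min_pts:
            raise ValueError(
                f"class {cls} has {len(pts)} embedded points; need >= {min_pts}"
            )
        idx = rng.integers(0, len(pts), size=n_per_class)
        z = pts[idx] + bandwidth * rng.standard_normal((n_per_class, pts.shape[1]))
        blocks.append(z)
        labels_out.append(np.full(n_per_class, cls, dtype=int))
    z_all = np.vstack(blocks)
    labels_all = np.concatenate(labels_out)
    return GeneratedProfiles(
        values=decode(model, z_all, labels_all), labels=labels_all, latent=z_all
    )


# ---------------------------------------------------------------------------
# validation: retention of differential-expression structure


def auroc_retention(
    original: NormalizedExpression | GeneratedProfiles,
    reconstructed: NormalizedExpression | GeneratedProfiles,
) -> tuple[float, np.ndarray]:
    """AUROC of the reconstruction's recovery of original t-test rankings.

    Per-gene two-sample t-tests (baseline vs variant) are run on both
    datasets.  Genes are ranked by p-value in each; sweeping a matched
    significance rank k, the true-positive rate is the fraction of the k
    original-significant genes also among the reconstruction's top k, and the
    false-positive rate is the fraction of non-significant genes the
    reconstruction selects.  Returns the trapezoidal area and curve points
    (columns: FPR, TPR).
    """
    p_orig = _gene_pvalues(original)
    p_recon = _gene_pvalues(reconstructed)
    return auroc_from_pvalues(p_orig, p_recon)


def auroc_from_pvalues(
    p_orig: np.ndarray, p_recon: np.ndarray
) -> tuple[float, np.ndarray]:
    """Matched-rank retention AUROC from two per-gene p-value vectors."""
    p_orig = np.asarray(p_orig, dtype=float)
    p_recon = np.asarray(p_recon, dtype=float)
    if p_orig.shape != p_recon.shape:
        raise ValueError("original and reconstructed must share the same gene set")
    G = len(p_orig)

    order_o = np.lexsort((np.arange(G), p_orig))
    order_r = np.lexsort((np.arange(G), p_recon))
    rank_o = np.empty(G, dtype=int)
    rank_o[order_o] = np.arange(G)
    rank_r = np.empty(G, dtype=int)
    rank_r[order_r] = np.arange(G)

    tpr = np.zeros(G + 1)
    fpr = np.zeros(G + 1)
    hits = 0
    for k in range(1, G + 1):
        a = order_r[k - 1]  # newly selected by the reconstruction
        b = order_o[k - 1]  # newly significant in the original
        if rank_o[a] <= k - 1:
            hits += 1
        if b != a and rank_r[b] <= k - 2:
            hits += 1
        tpr[k] = hits / k
        fpr[k] = (k - hits) / (G - k) if k < G else 1.0
    tpr[G] = 1.0
    auroc = float(np.trapezoid(tpr, fpr))
    return auroc, np.column_stack([fpr, tpr])


def _gene_pvalues(data: NormalizedExpression | GeneratedProfiles) -> np.ndarray:
    values = data.values
    labels = np.asarray(data.labels, dtype=int)
    base = values[labels == 0]
    var = values[labels == 1]
    if len(base) < 2 or len(var) < 2:
        raise ValueError("need at least 2 samples per class for t-tests")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = ttest_ind(base, var, axis=0)
    return np.nan_to_num(res.pvalue, nan=1.0)


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: CvaeModel, path: str) -> None:
    """Single-file checkpoint (npz) with parameters, config and scaling bounds."""
    cfg = {
        "latent_dim": model.config.latent_dim,
        "hidden_sizes": list(model.config.hidden_sizes),
        "learning_rate": model.config.learning_rate,
        "epochs": model.config.epochs,
        "batch_size": model.config.batch_size,
        "loss_weights": list(model.config.loss_weights),
        "kde_bandwidth": model.config.kde_bandwidth,
        "seed": model.config.seed,
        "recon_loss": model.config.recon_loss,
    }
    np.savez(
        path,
        schema=np.array(CHECKPOINT_SCHEMA),
        config_json=np.array(json.dumps(cfg)),
        n_genes=np.array(model.n_genes),
        bounds_mins=model.bounds.mins,
        bounds_maxs=model.bounds.maxs,
        bounds_constant=model.bounds.constant,
        **{f"param_{k}": v for k, v in model.params.items()},
    )


def load_model(path: str) -> CvaeModel:
    with np.load(path, allow_pickle=False) as data:
        if int(data["schema"]) != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {int(data['schema'])}")
        cfg_dict = json.loads(str(data["config_json"]))
        cfg_dict["hidden_sizes"] = tuple(cfg_dict["hidden_sizes"])
        cfg_dict["loss_weights"] = tuple(cfg_dict["loss_weights"])
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            config = CvaeConfig(**cfg_dict)
        params = {
            k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")
        }
        bounds = ScalingBounds(
            mins=data["bounds_mins"],
            maxs=data["bounds_maxs"],
            constant=data["bounds_constant"],
        )
        return CvaeModel(
            params=params, config=config, bounds=bounds, n_genes=int(data["n_genes"])
        )
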