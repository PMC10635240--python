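"""AI-enhanced classification of nucleus D images.

Pipeline: preprocess (crop, pad square, resize, min-max normalize) ->
deterministic texture-bank feature extraction (an optional pretrained CNN
backbone can be plugged in) -> autoencoder dimensionality reduction ->
per-patient aggregation of latents -> grid-searched random forest ->
repeated stratified k-fold cross-validation at the patient level with
ROC optimal-cutpoint selection per fold.

Everything that learns (scaler, autoencoder, forest, grid search, cutpoint)
is fit inside training folds only; all nuclei of a patient stay in the same
fold so patient identity cannot leak across the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from skimage.feature import graycomatrix, graycoprops
from skimage.transform import resize
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold, StratifiedKFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .core import DMap

__all__ = [
    "FeatureMatrix",
    "LatentMatrix",
    "CVReport",
    "Autoencoder",
    "preprocess_nucleus",
    "extract_features",
    "fit_autoencoder",
    "train_rf",
    "cross_validate",
    "optimal_cutpoint",
    "DEFAULT_RF_GRID",
]

DEFAULT_RF_GRID: dict[str, list] = {
    "n_estimators": [100, 500],
    "max_depth": [None, 10],
    "max_features": ["sqrt", 0.333],
}


@dataclass
class FeatureMatrix:
    """Per-nucleus feature rows with identity links back to the cohort."""

    values: np.ndarray
    row_ids: list[tuple[str, int]]  # (patient_id, nucleus_id)
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids must have one entry per row")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix must be finite (no missing values)")


@dataclass
class LatentMatrix:
    values: np.ndarray
    row_ids: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("latent matrix must be 2-D")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids must have one entry per row")


@dataclass
class CVReport:
    """Per-fold diagnostics from repeated stratified cross-validation."""

    folds: pd.DataFrame  # repeat, fold, auc, sensitivity, specificity, threshold
    k: int
    repeats: int

    def __post_init__(self) -> None:
        if len(self.folds) != self.k * self.repeats:
            raise ValueError("fold count must equal k * repeats")
        for col in ("auc", "sensitivity", "specificity"):
            v = self.folds[col].to_numpy()
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{col} must lie in [0, 1]")

    @property
    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for col in ("auc", "sensitivity", "specificity"):
            out[col] = {
                "mean": float(self.folds[col].mean()),
                "sd": float(self.folds[col].std(ddof=1)),
            }
        return out


# ---------------------------------------------------------------------------
# preprocessing and feature extraction
# ---------------------------------------------------------------------------

def preprocess_nucleus(
    dmap: DMap, mask: np.ndarray, label: int, out_side: int = 224
) -> np.ndarray:
    """Crop one nucleus, pad to square, resize, min-max normalize to [0, 1].

    Normalization happens after the resize using the in-nucleus min/max of
    the resized image, so the output range is exactly [0, 1]; a constant-
    valued nucleus maps to 0.5 everywhere in the nucleus (avoids a 0/0).
    Background is 0. Before resizing, background pixels are filled with the
    in-nucleus mean so interpolation does not bleed background values into
    the nucleus boundary.
    """
    mask = np.asarray(mask)
    in_label = (mask == label) & dmap.mask & np.isfinite(dmap.values)
    if not in_label.any():
        raise ValueError(f"label {label} has no valid pixels")
    rows = np.any(in_label, axis=1).nonzero()[0]
    cols = np.any(in_label, axis=0).nonzero()[0]
    r0, r1, c0, c1 = rows[0], rows[-1] + 1, cols[0], cols[-1] + 1
    crop_mask = in_label[r0:r1, c0:c1]
    fill = float(dmap.values[in_label].mean())
    crop_vals = np.where(crop_mask, dmap.values[r0:r1, c0:c1], fill)

    h, w = crop_vals.shape
    side = max(h, w)
    top, left = (side - h) // 2, (side - w) // 2
    square = np.full((side, side), fill, dtype=np.float64)
    square[top : top + h, left : left + w] = crop_vals
    square_mask = np.zeros((side, side), dtype=np.float64)
    square_mask[top : top + h, left : left + w] = crop_mask

    vals = resize(square, (out_side, out_side), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)
    body = resize(square_mask, (out_side, out_side), order=1, mode="constant",
                  anti_aliasing=False, preserve_range=True) >= 0.5
    out = np.zeros((out_side, out_side), dtype=np.float64)
    if body.any():
        lo, hi = float(vals[body].min()), float(vals[body].max())
        out[body] = (vals[body] - lo) / (hi - lo) if hi > lo else 0.5
    return out


_GLCM_DISTANCES = (1, 2, 3, 4, 5)
_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
_GLCM_LEVELS = 32
_N_FREQ_BANDS = 8


def _texture_bank_row(img: np.ndarray) -> np.ndarray:
    """Deterministic texture features, exactly invariant under 90-degree rotation.

    Intensity moments; gradient energy; gray-level co-occurrence contrast,
    homogeneity, correlation, energy and entropy at five symmetric offset
    distances averaged over the four principal angles; and ring-averaged
    spatial-frequency power in fixed radial bands.
    """
    flat = img.ravel()
    sd = float(flat.std())
    moments = [float(flat.mean()), sd, float(sps.skew(flat)) if sd > 0 else 0.0,
               float(sps.kurtosis(flat)) if sd > 0 else 0.0]

    gy, gx = np.gradient(img)
    grad_energy = float(np.mean(gx**2 + gy**2))

    q = np.clip((img * (_GLCM_LEVELS - 1)).round().astype(np.uint8), 0, _GLCM_LEVELS - 1)
    glcm = graycomatrix(q, distances=_GLCM_DISTANCES, angles=_GLCM_ANGLES,
                        levels=_GLCM_LEVELS, symmetric=True, normed=True)
    cooc = []
    for prop in ("contrast", "homogeneity", "correlation", "energy"):
        cooc.extend(graycoprops(glcm, prop).mean(axis=1).tolist())
    logp = np.zeros_like(glcm)
    np.log2(glcm, out=logp, where=glcm > 0)
    entropy = -(glcm * logp).sum(axis=(0, 1)).mean(axis=1)  # per distance
    cooc.extend(entropy.tolist())

    power = np.abs(np.fft.fftshift(np.fft.fft2(img))) ** 2
    side = img.shape[0]
    center = side // 2
    yy, xx = np.ogrid[:side, :side]
    radius = np.sqrt((yy - center) ** 2 + (xx - center) ** 2)
    edges = np.linspace(0, center, _N_FREQ_BANDS + 1)
    bands = []
    for i in range(_N_FREQ_BANDS):
        sel = (radius >= edges[i]) & (radius < edges[i + 1])
        bands.append(float(power[sel].mean()) if sel.any() else 0.0)
    total = sum(bands)
    bands = [b / total if total > 0 else 0.0 for b in bands]

    return np.array(moments + [grad_energy] + cooc + bands)


def _texture_feature_names() -> list[str]:
    names = ["mean", "sd", "skewness", "kurtosis", "gradient_energy"]
    for prop in ("contrast", "homogeneity", "correlation", "energy", "entropy"):
        names += [f"glcm_{prop}_d{d}" for d in _GLCM_DISTANCES]
    names += [f"freq_band_{i}" for i in range(_N_FREQ_BANDS)]
    return names


def extract_features(
    images: list[np.ndarray],
    row_ids: list[tuple[str, int]] | None = None,
    extractor: str = "texture_bank",
) -> FeatureMatrix:
    """Per-nucleus feature vectors from preprocessed square images."""
    if not images:
        raise ValueError("no images given")
    shape = images[0].shape
    if any(im.shape != shape for im in images):
        raise ValueError("all images must share the same size")
    if row_ids is None:
        row_ids = [("", i) for i in range(len(images))]
    if extractor == "texture_bank":
        rows = np.stack([_texture_bank_row(np.asarray(im, float)) for im in images])
        return FeatureMatrix(rows, list(row_ids), _texture_feature_names())
    if extractor == "pretrained_cnn":
        return _pretrained_cnn_features(images, list(row_ids))
    raise ValueError(f"unknown extractor {extractor!r}")


def nucleus_feature_matrix(
    dmap: DMap,
    mask: np.ndarray,
    labels: list[int],
    patient_id: str,
    out_side: int = 32,
    extractor: str = "texture_bank",
) -> FeatureMatrix:
    """Full per-nucleus feature rows for one D map.

    Texture features of the preprocessed (min-max normalized) nucleus image,
    with the raw-scale nucleus D mean and SD appended: per-nucleus
    normalization removes the absolute packing-scaling level, which is
    itself the primary biomarker, so the raw-scale summary is kept as an
    explicit feature pair.
    """
    mask = np.asarray(mask)
    images, raw_stats, ids = [], [], []
    for label in labels:
        images.append(preprocess_nucleus(dmap, mask, label, out_side=out_side))
        sel = (mask == label) & dmap.mask & ~dmap.out_of_range_flags & np.isfinite(dmap.values)
        vals = dmap.values[sel]
        if vals.size == 0:
            raise ValueError(f"label {label} has no unclipped pixels")
        raw_stats.append([float(vals.mean()), float(vals.std())])
        ids.append((patient_id, int(label)))
    texture = extract_features(images, row_ids=ids, extractor=extractor)
    values = np.hstack([texture.values, np.asarray(raw_stats)])
    return FeatureMatrix(values, ids, texture.feature_names + ["raw_d_mean", "raw_d_sd"])


def _pretrained_cnn_features(images, row_ids) -> FeatureMatrix:
    """Optional plug-in: global-average-pooled final convolutional activations
    of a pretrained backbone. Requires torch/torchvision with local weights."""
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:  # pragma: no cover - plug-in path
        raise ImportError(
            "the pretrained_cnn extractor needs torch and torchvision with "
            "pretrained weights available locally; use the default "
            "'texture_bank' extractor for a self-contained run"
        ) from exc
    raise NotImplementedError(  # pragma: no cover
        "pretrained backbone plug-in: wire your backbone's final conv stage here"
    )


# ---------------------------------------------------------------------------
# autoencoder
# ---------------------------------------------------------------------------

@dataclass
class Autoencoder:
    """Fully connected autoencoder with a linear bottleneck.

    A single hidden layer of width ``latent_dim`` with identity activation,
    trained to reconstruct standardized features under mean-squared error;
    the encoder output (the hidden activations) is the latent representation.
    """

    scaler: StandardScaler
    net: MLPRegressor
    latent_dim: int
    reconstruction_mse: float

    def transform(self, x: np.ndarray) -> np.ndarray:
        xs = self.scaler.transform(np.asarray(x, dtype=np.float64))
        return xs @ self.net.coefs_[0] + self.net.intercepts_[0]


def fit_autoencoder(
    features: FeatureMatrix | np.ndarray,
    latent_dim: int = 32,
    epochs: int = 400,
    seed: int = 0,
) -> tuple[Autoencoder, LatentMatrix]:
    """Train the autoencoder and return the encoder with the latent rows."""
    if isinstance(features, FeatureMatrix):
        x, row_ids = features.values, features.row_ids
    else:
        x = np.asarray(features, dtype=np.float64)
        row_ids = [("", i) for i in range(x.shape[0])]
    n, p = x.shape
    if latent_dim >= p:
        raise ValueError("latent_dim must be smaller than the feature count")
    if n < latent_dim:
        raise ValueError("need at least latent_dim rows to fit the autoencoder")
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    net = MLPRegressor(
        hidden_layer_sizes=(latent_dim,),
        activation="identity",
        solver="lbfgs",
        max_iter=epochs,
        random_state=seed,
        tol=1e-8,
    )
    with warnings.catch_warnings():
        # epochs is a fixed training budget; quality is tracked via
        # reconstruction_mse, not the optimizer's own stopping rule
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        net.fit(xs, xs)
    mse = float(np.mean((net.predict(xs) - xs) ** 2))
    enc = Autoencoder(scaler=scaler, net=net, latent_dim=latent_dim,
                      reconstruction_mse=mse)
    return enc, LatentMatrix(enc.transform(x), list(row_ids))


# ---------------------------------------------------------------------------
# classification and cross-validation
# ---------------------------------------------------------------------------

def train_rf(
    latents: np.ndarray,
    labels: np.ndarray,
    grid: dict[str, list] | None = None,
    seed: int = 0,
    inner_cv: int = 3,
) -> tuple[RandomForestClassifier, dict]:
    """Grid-searched random forest on per-patient latent vectors.

    The inner grid search runs stratified CV on the training data only.
    ``grid=None`` uses the default two-point grid per hyperparameter.
    """
    x = np.asarray(latents, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need both classes present to train the classifier")
    grid = grid if grid is not None else DEFAULT_RF_GRID
    n_splits = min(inner_cv, int(np.bincount(y).min()))
    needs_search = any(len(v) > 1 for v in grid.values())
    if needs_search:
        if n_splits < 2:
            raise ValueError("too few samples per class for the inner grid search")
        search = GridSearchCV(
            RandomForestClassifier(random_state=seed),
            grid,
            cv=StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed),
            scoring="roc_auc",
        )
        search.fit(x, y)
        return search.best_estimator_, dict(search.best_params_)
    fixed = {key: v[0] for key, v in grid.items()}
    model = RandomForestClassifier(random_state=seed, **fixed).fit(x, y)
    return model, fixed


def optimal_cutpoint(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Threshold maximizing total correct classifications (score >= t -> case).

    Candidates are the midpoints between adjacent sorted unique scores plus
    one threshold below the minimum (everything called case) and one above
    the maximum (everything called control); ties break toward the lower
    threshold, i.e. toward higher sensitivity. Returns
    (threshold, sensitivity, specificity).
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    best = None
    for t in candidates:  # ascending; strict > keeps the lowest optimal threshold
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        if best is None or tp + tn > best[0]:
            best = (tp + tn, t, tp / n_pos, tn / n_neg)
    _, threshold, sens, spec = best
    return float(threshold), float(sens), float(spec)


def _aggregate_latents(latents: LatentMatrix) -> tuple[np.ndarray, list[str]]:
    """Mean latent vector per patient, in first-appearance order."""
    order: list[str] = []
    buckets: dict[str, list[int]] = {}
    for i, (pid, _) in enumerate(latents.row_ids):
        if pid not in buckets:
            buckets[pid] = []
            order.append(pid)
        buckets[pid].append(i)
    agg = np.stack([latents.values[buckets[pid]].mean(axis=0) for pid in order])
    return agg, order


def cross_validate(
    features: FeatureMatrix,
    patient_labels: dict[str, int],
    k: int = 4,
    repeats: int = 5,
    seed: int = 0,
    latent_dim: int = 16,
    epochs: int = 300,
    grid: dict[str, list] | None = None,
    passthrough: list[str] | None = None,
    aggregate: str = "score",
) -> CVReport:
    """Repeated stratified k-fold cross-validation at the patient level.

    Splits patients (all nuclei of a patient stay together); for each of the
    k x repeats folds the scaler, autoencoder and grid-searched forest are
    fit on training-fold nuclei only, held-out patients are scored, and AUC
    plus optimal-cutpoint sensitivity and specificity are recorded.

    ``aggregate`` selects where nuclei are pooled into a patient:
    "score" (default) trains the forest on nucleus-level latents with the
    patient's label and averages the held-out nucleus scores per patient;
    "latent" averages latents per patient first and trains the forest on
    one row per patient. Score aggregation trains on far more rows and
    yields smoother patient scores.

    ``passthrough`` names feature columns that bypass the autoencoder and
    are appended unchanged to the latent representation — used for
    low-dimensional biomarker summaries (e.g. the raw-scale nucleus D mean)
    that the compression step should not dilute.
    """
    if aggregate not in ("score", "latent"):
        raise ValueError("aggregate must be 'score' or 'latent'")
    patients = sorted(patient_labels)
    y_pat = np.array([patient_labels[p] for p in patients], dtype=int)
    counts = np.bincount(y_pat, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs at least k={k} patients")
    rows_by_patient: dict[str, list[int]] = {}
    for i, (pid, _) in enumerate(features.row_ids):
        rows_by_patient.setdefault(pid, []).append(i)
    missing = [p for p in patients if p not in rows_by_patient]
    if missing:
        raise ValueError(f"patients without feature rows: {missing[:5]}")

    passthrough = passthrough or []
    unknown = set(passthrough) - set(features.feature_names)
    if unknown:
        raise ValueError(f"passthrough columns not in feature matrix: {sorted(unknown)}")
    pass_idx = [features.feature_names.index(name) for name in passthrough]
    ae_idx = [i for i in range(features.values.shape[1]) if i not in pass_idx]

    def _encode(enc: Autoencoder, rows: np.ndarray) -> np.ndarray:
        latent = enc.transform(features.values[np.ix_(rows, ae_idx)])
        if pass_idx:
            latent = np.hstack([latent, features.values[np.ix_(rows, pass_idx)]])
        return latent

    splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    records = []
    for fold_idx, (tr, te) in enumerate(splitter.split(np.zeros(len(patients)), y_pat)):
        tr_pat = [patients[i] for i in tr]
        te_pat = [patients[i] for i in te]
        tr_rows = np.concatenate([rows_by_patient[p] for p in tr_pat])
        te_rows = np.concatenate([rows_by_patient[p] for p in te_pat])

        enc, _ = fit_autoencoder(
            features.values[np.ix_(tr_rows, ae_idx)],
            latent_dim=latent_dim, epochs=epochs, seed=seed,
        )
        tr_lat = LatentMatrix(
            _encode(enc, tr_rows), [features.row_ids[i] for i in tr_rows]
        )
        te_lat = LatentMatrix(
            _encode(enc, te_rows), [features.row_ids[i] for i in te_rows]
        )
        if aggregate == "latent":
            x_tr, tr_order = _aggregate_latents(tr_lat)
            y_tr = np.array([patient_labels[p] for p in tr_order], dtype=int)
            model, _ = train_rf(x_tr, y_tr, grid=grid, seed=seed)
            x_te, te_order = _aggregate_latents(te_lat)
            scores = model.predict_proba(x_te)[:, list(model.classes_).index(1)]
        else:
            y_nuc = np.array([patient_labels[pid] for pid, _ in tr_lat.row_ids], dtype=int)
            model, _ = train_rf(tr_lat.values, y_nuc, grid=grid, seed=seed)
            nucleus_scores = model.predict_proba(te_lat.values)[
                :, list(model.classes_).index(1)
            ]
            per_patient: dict[str, list[float]] = {}
            te_order = []
            for (pid, _), s in zip(te_lat.row_ids, nucleus_scores):
                if pid not in per_patient:
                    per_patient[pid] = []
                    te_order.append(pid)
                per_patient[pid].append(float(s))
            scores = np.array([np.mean(per_patient[p]) for p in te_order])
        y_te = np.array([patient_labels[p] for p in te_order], dtype=int)
        auc = float(roc_auc_score(y_te, scores)) if np.unique(y_te).size > 1 else float("nan")
        threshold, sens, spec = optimal_cutpoint(scores, y_te)
        records.append(
            {
                "repeat": fold_idx // k,
                "fold": fold_idx % k,
                "auc": auc,
                "sensitivity": sens,
                "specificity": spec,
                "threshold": threshold,
            }
        )
    return CVReport(folds=pd.DataFrame.from_records(records), k=k, repeats=repeats)
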