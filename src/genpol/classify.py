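"""Feature separability, SVM classification, accuracy reporting, and the
transmit-ellipse sweep / phenology-curve analyses.

The classification chain mirrors a standard multi-temporal crop-mapping
workflow: build per-date alpha / delta-alpha feature rasters for a chosen
polarimetric mode, rank features by a two-class separability score
("difference degree": the standardized mean difference between the two
rice classes on training pixels), keep the top k, z-score them on
training statistics, and classify every pixel with an RBF-kernel SVM
(C = 100, gamma = 1 / number of input features).  Accuracy is assessed on
verification parcels only, with producer's/user's accuracy, their mean,
overall accuracy and the kappa coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from genpol.compact import general_cp_field, mode_wave, transmit_wave
from genpol.decompose import DecompResult, decompose_cp, decompose_fp
from genpol.exceptions import DomainError, ValidationError
from genpol.io import LabelMask, ScatteringImage


# ---------------------------------------------------------------------------
# feature stacks
# ---------------------------------------------------------------------------

@dataclass
class FeatureStack:
    """Named, co-registered real feature rasters (parameter x date)."""

    features: dict[str, np.ndarray]
    dates: list[str]
    mode: str

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.features.values()}
        if len(shapes) > 1:
            raise ValidationError(f"feature rasters not co-registered: {shapes}")

    @property
    def names(self) -> list[str]:
        return list(self.features)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.features.values())).shape

    def matrix(self, names: list[str], pixel_mask: np.ndarray) -> np.ndarray:
        """(n_pixels, n_features) design matrix over a boolean mask."""
        return np.column_stack([self.features[n][pixel_mask] for n in names])


def decompose_mode(img: ScatteringImage, mode: str,
                   window: int | None = 7,
                   wave_angles: tuple[float, float] | None = None
                   ) -> DecompResult:
    """Run the decomposition for one image under a named mode.

    mode is 'fp', 'pi4', 'ctlr' or 'general' (the latter requires
    wave_angles = (theta, chi) in radians).
    """
    if mode == "fp":
        return decompose_fp(img, window)
    if mode in ("pi4", "ctlr"):
        return decompose_cp(general_cp_field(img, mode_wave(mode)), window)
    if mode == "general":
        if wave_angles is None:
            raise DomainError("mode 'general' needs wave_angles=(theta, chi)")
        wave = transmit_wave(*wave_angles)
        return decompose_cp(general_cp_field(img, wave), window)
    raise DomainError(f"unknown mode {mode!r}")


def feature_stack(images: list[ScatteringImage], mode: str,
                  window: int | None = 7,
                  wave_angles: tuple[float, float] | None = None
                  ) -> FeatureStack:
    """Per-date alpha and delta-alpha rasters as one named stack.

    Names follow the token pattern ``alpha_B_<date>`` / ``dalpha_B_<date>``
    with the image's date tag (e.g. alpha_B_1103 for the final date).
    """
    feats: dict[str, np.ndarray] = {}
    dates = []
    for i, img in enumerate(images):
        tag = img.date_tag or f"d{i}"
        dates.append(tag)
        res = decompose_mode(img, mode, window, wave_angles)
        feats[f"alpha_B_{tag}"] = res.alpha.masked()
        feats[f"dalpha_B_{tag}"] = res.delta_alpha.masked()
    return FeatureStack(features=feats, dates=dates, mode=mode)


# ---------------------------------------------------------------------------
# separability ranking
# ---------------------------------------------------------------------------

def difference_degree(feature: np.ndarray, mask: LabelMask,
                      class_a: int, class_b: int,
                      min_pixels: int = 30) -> float:
    """Two-class separability |mean_a - mean_b| / sqrt(var_a + var_b)
    over training pixels.  0 for identical distributions; invariant to
    affine rescaling of the feature."""
    vals = []
    for cid in (class_a, class_b):
        m = mask.class_mask(cid, split="train")
        x = feature[m]
        x = x[np.isfinite(x)]
        if x.size == 0:
            raise DomainError(
                f"class {mask.class_names[cid - 1]!r} has no training pixels")
        if x.size < min_pixels:
            raise DomainError(
                f"class {mask.class_names[cid - 1]!r} has only {x.size} "
                f"training pixels (need >= {min_pixels})")
        vals.append(x)
    a, b = vals
    denom = np.sqrt(a.var() + b.var())
    if denom == 0:
        return 0.0 if a.mean() == b.mean() else np.inf
    return float(abs(a.mean() - b.mean()) / denom)


@dataclass
class SeparabilityTable:
    """Per-feature difference-degree scores and the induced ranking."""

    scores: dict[str, float]
    ranking: list[str]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.ranking,
                             "score": [self.scores[n] for n in self.ranking]})


def rank_features(stack: FeatureStack, mask: LabelMask,
                  class_a: int, class_b: int,
                  metric=difference_degree) -> SeparabilityTable:
    """Score every feature; ties broken by lexicographic feature name."""
    scores = {n: metric(stack.features[n], mask, class_a, class_b)
              for n in sorted(stack.names)}
    ranking = sorted(scores, key=lambda n: (-scores[n], n))
    return SeparabilityTable(scores=scores, ranking=ranking)


def select_optimal_features(stack: FeatureStack, mask: LabelMask,
                            class_a: int, class_b: int, k: int = 8,
                            metric=difference_degree) -> list[str]:
    """Top-k feature names by difference degree between two classes."""
    if k <= 0:
        raise DomainError("k must be positive")
    if k > len(stack.names):
        raise DomainError(f"k={k} exceeds {len(stack.names)} features")
    return rank_features(stack, mask, class_a, class_b, metric).ranking[:k]


# ---------------------------------------------------------------------------
# SVM classification
# ---------------------------------------------------------------------------

@dataclass
class ClassifierConfig:
    """RBF-kernel SVM settings: penalty C = 100, gamma defaulting to the
    reciprocal of the number of input features, probability threshold 0
    (every pixel receives a label)."""

    kernel: str = "rbf"
    C: float = 100.0
    gamma: float | None = None
    probability_threshold: float = 0.0
    max_train_pixels: int | None = None

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValidationError("C must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValidationError("gamma must be positive")


def train_and_classify(stack: FeatureStack, names: list[str],
                       mask: LabelMask, cfg: ClassifierConfig | None = None,
                       seed: int = 0) -> np.ndarray:
    """Fit the SVM on training parcels and predict the full raster.

    Features are z-scored with training-set statistics.  Pixels with any
    non-finite feature stay 0 (unclassified).  Deterministic for a fixed
    seed.
    """
    cfg = cfg or ClassifierConfig()
    train = mask.train_mask()
    finite = np.ones(stack.shape, dtype=bool)
    for n in names:
        finite &= np.isfinite(stack.features[n])
    train = train & finite
    x_train = stack.matrix(names, train)
    y_train = mask.labels[train]
    classes = np.unique(y_train)
    if classes.size < 2:
        raise DomainError("training set contains a single class")
    rng = np.random.default_rng(seed)
    if cfg.max_train_pixels is not None and y_train.size > cfg.max_train_pixels:
        pick = rng.choice(y_train.size, cfg.max_train_pixels, replace=False)
        pick.sort()
        x_train, y_train = x_train[pick], y_train[pick]
    mu, sd = x_train.mean(axis=0), x_train.std(axis=0)
    sd[sd == 0] = 1.0
    gamma = cfg.gamma if cfg.gamma is not None else 1.0 / len(names)
    svm = SVC(kernel=cfg.kernel, C=cfg.C, gamma=gamma,
              random_state=int(seed) & 0x7FFFFFFF)
    svm.fit((x_train - mu) / sd, y_train)
    pred = np.zeros(stack.shape, dtype=np.int32)
    x_all = stack.matrix(names, finite)
    pred[finite] = svm.predict((x_all - mu) / sd)
    return pred


def two_stage_classify(stack: FeatureStack, names: list[str],
                       mask: LabelMask, rice_classes: tuple[int, int],
                       cfg: ClassifierConfig | None = None,
                       seed: int = 0) -> np.ndarray:
    """Two-pass scheme: first a 4-class pass with the rice classes merged,
    then a rice-only pass that splits the predicted rice area into the two
    rice types."""
    a, b = rice_classes
    merged = mask.labels.copy()
    merged[merged == b] = a
    mask4 = LabelMask(merged, mask.class_names, parcel_ids=mask.parcel_ids,
                      split=mask.split)
    stage1 = train_and_classify(stack, names, mask4, cfg, seed)

    rice_only = np.where(np.isin(mask.labels, rice_classes), mask.labels, 0)
    mask_rice = LabelMask(rice_only, mask.class_names,
                          parcel_ids=np.where(rice_only > 0, mask.parcel_ids, 0),
                          split=mask.split)
    stage2 = train_and_classify(stack, names, mask_rice, cfg, seed)

    out = stage1.copy()
    rice_pred = stage1 == a
    out[rice_pred] = stage2[rice_pred]
    return out


# ---------------------------------------------------------------------------
# accuracy assessment
# ---------------------------------------------------------------------------

@dataclass
class AccuracyReport:
    """Confusion matrix over verification pixels plus the derived scores.

    confusion[i, j] counts reference class i+1 predicted as class j+1.
    PA (producer's accuracy) conditions on the reference class, UA
    (user's accuracy) on the prediction; average accuracy is (PA+UA)/2.
    Classes absent from the verification set carry NaN scores.
    """

    confusion: np.ndarray
    class_names: list[str]
    pa: np.ndarray
    ua: np.ndarray
    average: np.ndarray
    oa: float
    kappa: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"class": self.class_names,
                             "PA%": self.pa, "UA%": self.ua,
                             "average%": self.average})


def confusion_matrix(reference: np.ndarray, predicted: np.ndarray,
                     n_classes: int) -> np.ndarray:
    """Counts of (reference, predicted) label pairs, labels 1..K."""
    idx = (reference.astype(np.int64) - 1) * n_classes \
        + (predicted.astype(np.int64) - 1)
    return np.bincount(idx, minlength=n_classes * n_classes) \
        .reshape(n_classes, n_classes)


def average_accuracy(pa: float, ua: float) -> float:
    """Mean of producer's and user's accuracy (percent)."""
    return 0.5 * (pa + ua)


def accuracy_report(pred: np.ndarray, mask: LabelMask) -> AccuracyReport:
    """Score a prediction raster on the verification parcels."""
    verify = mask.verify_mask() & (pred > 0)
    ref, hat = mask.labels[verify], pred[verify]
    if ref.size == 0:
        raise DomainError("no verification pixels")
    k = len(mask.class_names)
    cm = confusion_matrix(ref, hat, k)
    n = cm.sum()
    ref_counts = cm.sum(axis=1).astype(float)
    pred_counts = cm.sum(axis=0).astype(float)
    diag = np.diag(cm).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = 100.0 * diag / ref_counts
        ua = 100.0 * diag / pred_counts
    pa[ref_counts == 0] = np.nan
    ua[pred_counts == 0] = np.nan
    oa = float(diag.sum() / n)
    pe = float((ref_counts * pred_counts).sum() / (n * n))
    kappa = 1.0 if abs(1 - pe) < 1e-15 else (oa - pe) / (1 - pe)
    return AccuracyReport(confusion=cm, class_names=list(mask.class_names),
                          pa=pa, ua=ua, average=0.5 * (pa + ua),
                          oa=100.0 * oa, kappa=float(kappa))


# ---------------------------------------------------------------------------
# transmit-ellipse sweeps and phenology curves
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Per-class decomposition statistics along a (theta, chi) grid."""

    table: pd.DataFrame             # columns: theta, chi, class, alpha_mean,
                                    # alpha_std, dalpha_mean, dalpha_std
    axis: str
    excluded: list[float] = field(default_factory=list)


def parameter_sweep(img: ScatteringImage, mask: LabelMask, axis: str,
                    fixed: float, step: float = np.radians(5.0),
                    window: int | None = 7) -> SweepResult:
    """Sweep one transmit-ellipse angle, holding the other fixed.

    axis 'chi_at_fixed_theta' varies chi over [-pi/4, pi/4]; axis
    'theta_at_fixed_chi' varies theta over [-pi/2, pi/2].  Grid points
    violating the a != 0, b != 0 guard are recorded in ``excluded``.
    """
    if axis == "chi_at_fixed_theta":
        grid = np.arange(-np.pi / 4, np.pi / 4 + step / 2, step)
        waves = [(fixed, g) for g in grid]
    elif axis == "theta_at_fixed_chi":
        grid = np.arange(-np.pi / 2, np.pi / 2 + step / 2, step)
        waves = [(g, fixed) for g in grid]
    else:
        raise DomainError(f"unknown sweep axis {axis!r}")
    rows, excluded = [], []
    for (theta, chi), g in zip(waves, grid):
        wave = transmit_wave(theta, chi)
        if not wave.is_admissible:
            excluded.append(float(g))
            continue
        res = decompose_cp(general_cp_field(img, wave), window)
        a, d = res.alpha.masked(), res.delta_alpha.masked()
        for cid, name in enumerate(mask.class_names, start=1):
            m = mask.class_mask(cid)
            av, dv = a[m], d[m]
            av, dv = av[np.isfinite(av)], dv[np.isfinite(dv)]
            if av.size == 0:
                continue
            rows.append({"theta": theta, "chi": chi, "class": name,
                         "alpha_mean": av.mean(), "alpha_std": av.std(),
                         "dalpha_mean": dv.mean(), "dalpha_std": dv.std()})
    if not rows:
        raise DomainError("empty admissible sweep grid")
    return SweepResult(table=pd.DataFrame(rows), axis=axis, excluded=excluded)


def trend_flags(values: np.ndarray, threshold: float = 2.0) -> list[str]:
    """Classify consecutive differences as rise / drop / flat (degrees)."""
    out = []
    for d in np.diff(np.asarray(values, dtype=float)):
        out.append("rise" if d > threshold else
                   "drop" if d < -threshold else "flat")
    return out


def temporal_curves(results_by_mode: dict[str, list[DecompResult]],
                    mask: LabelMask, dates: list[str] | None = None
                    ) -> pd.DataFrame:
    """Per-class, per-mode trajectories of parcel-mean alpha / delta-alpha.

    ``results_by_mode`` maps a mode label to the six per-date
    decomposition results.  Returns a tidy frame with class means, spread
    and trend flags relative to the previous date.
    """
    rows = []
    for mode, results in results_by_mode.items():
        n = len(results)
        if dates is not None and len(dates) != n:
            raise DomainError("dates/results length mismatch")
        for cid, name in enumerate(mask.class_names, start=1):
            m = mask.class_mask(cid)
            means_a, means_d, stds_a = [], [], []
            for res in results:
                a = res.alpha.masked()[m]
                d = res.delta_alpha.masked()[m]
                a, d = a[np.isfinite(a)], d[np.isfinite(d)]
                means_a.append(a.mean())
                stds_a.append(a.std())
                means_d.append(d.mean())
            flags = ["-"] + trend_flags(means_a)
            for i in range(n):
                rows.append({
                    "mode": mode, "class": name,
                    "date": dates[i] if dates else str(i),
                    "alpha_mean": means_a[i], "alpha_std": stds_a[i],
                    "dalpha_mean": means_d[i], "alpha_trend": flags[i]})
    return pd.DataFrame(rows)
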