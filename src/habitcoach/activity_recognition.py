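"""Accelerometer-based activity recognition.

Windows of tri-axial accelerometer samples are summarized by statistical
features (mean, variance, zero-crossing rate per axis and for the signal
magnitude) and classified into the four everyday activities — walking,
running, stationary, driving — by a bank of per-class Gaussian mixture
models: one mixture is fitted per class by EM and a window is assigned to
the class maximizing prior-weighted likelihood.

Manually logged exercises never pass through this classifier; they enter
the life log directly with their MET-table label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

#: Canonical label order; also the deterministic tie-break order.
CLASS_ORDER = ("stationary", "walking", "running", "driving")

N_FEATURES = 12  # 3 statistics x (3 axes + magnitude)


@dataclass(frozen=True)
class FeatureVector:
    """Per-window statistical summary of a tri-axial accelerometer window.

    ``values`` is laid out as (mean, variance, zcr) for ax, ay, az, then
    magnitude; units g, g^2 and crossings/second respectively.
    """

    values: np.ndarray
    window_start: np.datetime64 | None = None
    window_length_s: float = 1.0

    def __post_init__(self):
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have {N_FEATURES} entries")


def _zero_crossing_rate(x: np.ndarray, duration_s: float) -> float:
    """Sign changes per second of the mean-removed signal.

    Exact zeros are treated as positive so a signal touching zero without
    crossing it is not double counted.
    """
    centered = x - x.mean()
    s = np.where(centered >= 0, 1, -1)
    crossings = int(np.count_nonzero(s[1:] != s[:-1]))
    return crossings / duration_s


def extract_features(
    window: np.ndarray,
    sample_rate_hz: float,
    window_start: np.datetime64 | None = None,
) -> FeatureVector:
    """Summarize an (n, 3) accelerometer window into a 12-d feature vector.

    Means and variances are the sample moments (population variance, so a
    single-sample window yields variance 0); the zero-crossing rate counts
    sign changes of each mean-removed channel divided by window duration.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != 3:
        raise ValueError("window must be an (n, 3) array of ax, ay, az samples")
    n = window.shape[0]
    if n == 0:
        raise ValueError("empty window")
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be > 0")
    duration_s = n / sample_rate_hz
    magnitude = np.linalg.norm(window, axis=1)
    channels = [window[:, 0], window[:, 1], window[:, 2], magnitude]
    vals = np.empty(N_FEATURES)
    for i, ch in enumerate(channels):
        vals[3 * i] = ch.mean()
        vals[3 * i + 1] = ch.var()
        vals[3 * i + 2] = _zero_crossing_rate(ch, duration_s) if n > 1 else 0.0
    return FeatureVector(vals, window_start=window_start, window_length_s=duration_s)


def extract_features_batch(stream: np.ndarray, window_samples: int, sample_rate_hz: float) -> np.ndarray:
    """Feature matrix for consecutive non-overlapping windows of a stream.

    Trailing samples that do not fill a window are dropped. Returns an
    (n_windows, 12) array.
    """
    stream = np.asarray(stream, dtype=float)
    n_win = stream.shape[0] // window_samples
    out = np.empty((n_win, N_FEATURES))
    for i in range(n_win):
        sl = stream[i * window_samples : (i + 1) * window_samples]
        out[i] = extract_features(sl, sample_rate_hz).values
    return out


class GmmClassifier:
    """Bank of per-class Gaussian mixtures with empirical class priors.

    One diagonal-covariance mixture of ``n_components`` Gaussians is fitted
    per class by EM (k-means initialization, fixed seed), and classification
    takes the arg-max of ``log prior + mixture log-likelihood``. Ties are
    broken by the fixed class order (stationary < walking < running <
    driving, then lexicographic for any extra labels).
    """

    def __init__(self, n_components: int = 2, seed: int = 0):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.n_components = n_components
        self.seed = seed
        self.classes_: tuple[str, ...] = ()
        self._mixtures: dict[str, GaussianMixture] = {}
        self._log_priors: dict[str, float] = {}

    @staticmethod
    def _class_sort_key(label: str):
        try:
            return (0, CLASS_ORDER.index(label))
        except ValueError:
            return (1, label)

    def fit(self, features: np.ndarray, labels) -> "GmmClassifier":
        X = np.asarray(features, dtype=float)
        y = np.asarray(labels)
        if X.ndim != 2:
            raise ValueError("features must be a 2-d array")
        classes = sorted(set(y.tolist()), key=self._class_sort_key)
        for cls in classes:
            n_cls = int(np.sum(y == cls))
            if n_cls < 2:
                raise ValueError(f"class {cls!r} has {n_cls} example(s); need >= 2")
        self.classes_ = tuple(classes)
        self._mixtures = {}
        self._log_priors = {}
        n_total = len(y)
        for cls in classes:
            Xc = X[y == cls]
            k = min(self.n_components, Xc.shape[0])
            gm = GaussianMixture(
                n_components=k,
                covariance_type="diag",
                random_state=self.seed,
                reg_covar=1e-9,
                n_init=1,
            )
            gm.fit(Xc)
            self._mixtures[cls] = gm
            self._log_priors[cls] = float(np.log(Xc.shape[0] / n_total))
        return self

    @property
    def is_fitted(self) -> bool:
        return bool(self._mixtures)

    def log_likelihoods(self, features: np.ndarray) -> np.ndarray:
        """Per-class prior-weighted log-likelihoods, shape (n, n_classes)."""
        if not self.is_fitted:
            raise RuntimeError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != self._mixtures[self.classes_[0]].means_.shape[1]:
            raise ValueError("feature dimensionality mismatch")
        ll = np.empty((X.shape[0], len(self.classes_)))
        for j, cls in enumerate(self.classes_):
            ll[:, j] = self._mixtures[cls].score_samples(X) + self._log_priors[cls]
        return ll

    def classify(self, features: np.ndarray) -> np.ndarray:
        """Labels for one feature vector or a batch, in input order."""
        ll = self.log_likelihoods(features)
        # argmax takes the first maximum, and classes_ is in tie-break order
        idx = np.argmax(ll, axis=1)
        return np.asarray(self.classes_, dtype=object)[idx]

    def classify_one(self, feature: FeatureVector | np.ndarray) -> str:
        vals = feature.values if isinstance(feature, FeatureVector) else feature
        return str(self.classify(vals.reshape(1, -1))[0])
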