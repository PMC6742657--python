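"""Distribution-level summaries of omics responses.

Gaussian fits to fold-change histograms (the "width" headline number is the
fitted sigma; FWHM is also reported), median-centering of transcript fold
changes, squared Pearson correlation between transcript and protein changes,
and K-means clustering of protein time courses with silhouette-based
selection of the cluster count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)


def center_log_fold_changes(fcs) -> np.ndarray:
    """Median-center log fold changes (assumes most genes unperturbed)."""
    x = np.asarray(fcs, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("no finite fold changes to center")
    med = np.median(x[finite])
    return x - med


@dataclass(frozen=True)
class GaussianFit:
    amplitude: float
    center: float  # log2 units
    width: float  # sigma of the fitted Gaussian, log2 units
    fit_rmse: float

    @property
    def fwhm(self) -> float:
        return 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.width


def fit_gaussian_to_histogram(values, bin_width: float = 0.1) -> GaussianFit:
    """Nonlinear least-squares fit of A*exp(-(x-mu)^2/(2 sigma^2)) to the
    histogram of ``values`` with fixed bin width."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise ValueError("need >= 50 finite values for a histogram fit")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    a0, mu0, sd0 = float(counts.max()), float(x.mean()), float(x.std())

    def gauss(t, a, mu, sd):
        return a * np.exp(-((t - mu) ** 2) / (2.0 * sd**2))

    try:
        popt, _ = optimize.curve_fit(
            gauss, centers, counts, p0=[a0, mu0, max(sd0, bin_width)], maxfev=10000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Gaussian fit failed to converge (initializer A={a0}, mu={mu0:.4g}, sigma={sd0:.4g})"
        ) from exc
    a, mu, sd = popt
    resid = counts - gauss(centers, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return GaussianFit(amplitude=float(abs(a)), center=float(mu), width=float(abs(sd)), fit_rmse=rmse)


def transcript_protein_correlation(transcript_fc, protein_fc) -> float:
    """Squared Pearson correlation between paired transcript and protein
    log2 fold changes."""
    x = np.asarray(transcript_fc, dtype=float)
    y = np.asarray(protein_fc, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the paired vectors")
    r = sps.pearsonr(x, y).statistic
    return float(r * r)


@dataclass
class ClusteringResult:
    k_selected: int
    centroids: np.ndarray  # k x timepoints
    labels: np.ndarray  # 1-based cluster labels per protein
    selection_score: dict  # candidate k -> mean silhouette
    inertia: float
    seed: int
    degenerate: bool = False
    dropped_rows: int = 0
    row_index: np.ndarray = field(default=None, repr=False)


def cluster_timecourse(matrix, k_range=range(2, 9), restarts: int = 10, seed: int = 0) -> ClusteringResult:
    """K-means over protein time courses; the cluster count maximizes the
    mean Euclidean silhouette over ``k_range``. Rows with missing timepoints
    are dropped (logged). Deterministic under a fixed seed."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be proteins x timepoints")
    complete = np.isfinite(X).all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("dropping %d row(s) with missing timepoints", dropped)
    Xc = X[complete]
    n = Xc.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if not ks or min(ks) < 2:
        raise ValueError("k_range must contain integers >= 2")
    if max(ks) > n // 2:
        raise ValueError(f"largest candidate k {max(ks)} exceeds n/2 = {n // 2}")

    if np.allclose(Xc, Xc[0]):
        # all rows identical: any partition has zero within-cluster variance
        logger.warning("degenerate geometry: all rows identical; selection flagged")
        return ClusteringResult(
            k_selected=1,
            centroids=Xc[:1].copy(),
            labels=np.ones(n, dtype=int),
            selection_score={},
            inertia=0.0,
            seed=seed,
            degenerate=True,
            dropped_rows=dropped,
            row_index=np.where(complete)[0],
        )

    scores, models = {}, {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        labels = km.fit_predict(Xc)
        scores[k] = float(silhouette_score(Xc, labels, metric="euclidean"))
        models[k] = km
    k_best = max(ks, key=lambda k: (scores[k], -k))
    km = models[k_best]
    return ClusteringResult(
        k_selected=k_best,
        centroids=km.cluster_centers_.copy(),
        labels=km.labels_ + 1,
        selection_score=scores,
        inertia=float(km.inertia_),
        seed=seed,
        dropped_rows=dropped,
        row_index=np.where(complete)[0],
    )
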