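"""Cross-recurrence quantification analysis (CRQA).

The two movement series are reconstructed in a shared state space by
time-delay embedding; a cross-recurrence matrix marks every pair of
embedded points closer than a radius. Two summary statistics are used:

* %REC (recurrence rate): percentage of recurrent point pairs, an index of
  shared activity / stochastic noise;
* MaxLine: the longest diagonal run of recurrent points, an index of
  coupling strength.

Embedding parameters follow the standard protocol: the delay is the first
minimum of the average mutual information (AMI) of the series, and the
embedding dimension is the first minimum of the false-nearest-neighbour
(FNN) fraction. Both series are z-scored before embedding so the radius is
expressed in pooled-SD units; because the printed radius of any one study
depends on that unit choice, the primary mechanism here is a bisection
tuner that selects the radius achieving a target recurrence rate
(default 5%).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import (
    AlignmentError,
    DegenerateSignalError,
    EmptyInputError,
    TooShortError,
    TuningError,
)

__all__ = [
    "CRQAParams",
    "EmbeddedSeries",
    "CRQAResult",
    "RadiusTuning",
    "average_mutual_information",
    "select_delay",
    "false_nearest_neighbours",
    "select_embedding_dim",
    "estimate_embedding_params",
    "embed",
    "cross_recurrence_matrix",
    "recurrence_rate",
    "maxline",
    "tune_radius",
    "crqa_metrics",
    "export_recurrence_plot",
]


@dataclass(frozen=True)
class CRQAParams:
    """CRQA settings.

    delay/dim of ``None`` mean "estimate from the data" (AMI / FNN).
    ``radius`` of ``None`` means "tune to target_rr"; a fixed radius is in
    z-score units because series are standardised before embedding.
    """

    delay: int | None = None
    dim: int | None = None
    radius: float | None = None
    min_line: int = 2
    target_rr: float = 5.0
    rr_tol: float = 0.5
    max_lag: int = 100
    max_dim: int = 10

    def __post_init__(self) -> None:
        if self.delay is not None and self.delay < 1:
            raise ValueError("delay must be >= 1")
        if self.dim is not None and self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.min_line < 2:
            raise ValueError("min_line must be >= 2")
        if not 0 < self.target_rr < 100:
            raise ValueError("target_rr must lie in (0, 100)")


@dataclass
class EmbeddedSeries:
    """Delay-embedded series: points[t] = (x_t, x_{t+d}, ..., x_{t+(m-1)d})."""

    points: np.ndarray  # (n_embedded, dim)
    dim: int
    delay: int

    @property
    def n_embedded(self) -> int:
        return self.points.shape[0]


@dataclass
class CRQAResult:
    """Per-trial cross-recurrence summary."""

    rec_pct: float
    maxline: int
    radius_used: float
    n_x: int
    n_y: int
    delay: int
    dim: int


@dataclass
class RadiusTuning:
    """Outcome of the recurrence-rate radius tuner."""

    radius: float
    rec_pct: float
    n_iter: int


# ---------------------------------------------------------------------------
# embedding-parameter estimation


def _mi_bits(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def average_mutual_information(x: np.ndarray, max_lag: int) -> np.ndarray:
    """AMI (bits) between x(t) and x(t+tau) for tau = 0..max_lag.

    Joint distributions use equal-width histograms with ceil(sqrt(N-tau))
    bins capped at 64, a standard bias/variance compromise.
    """
    x = np.asarray(x, float)
    n = len(x)
    if not 1 <= max_lag < n:
        raise TooShortError(f"need N > max_lag >= 1 (N={n}, max_lag={max_lag})")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("constant series has no mutual information")
    ami = np.empty(max_lag + 1)
    for tau in range(max_lag + 1):
        a = x[: n - tau]
        b = x[tau:]
        bins = min(64, int(np.ceil(np.sqrt(n - tau))))
        ami[tau] = _mi_bits(a, b, bins)
    return ami


def select_delay(ami_curve: np.ndarray) -> int:
    """Smallest lag at the first local minimum of the AMI curve.

    Falls back to the global minimum over tau >= 1 (with a warning) if the
    curve has no interior local minimum.
    """
    ami = np.asarray(ami_curve, float)
    if len(ami) < 3:
        raise TooShortError("AMI curve needs at least 3 lags")
    for tau in range(1, len(ami) - 1):
        if ami[tau] < ami[tau - 1] and ami[tau] <= ami[tau + 1]:
            return tau
    tau = int(np.argmin(ami[1:]) + 1)
    warnings.warn(
        "AMI curve has no local minimum within max_lag; using its global "
        f"minimum at lag {tau}", stacklevel=2,
    )
    return tau


def false_nearest_neighbours(
    x: np.ndarray,
    delay: int,
    max_dim: int,
    rtol: float = 15.0,
    atol: float = 2.0,
) -> np.ndarray:
    """Fraction of false nearest neighbours for dimensions 1..max_dim.

    Kennel criterion: the nearest neighbour of a point in dimension d is
    false if either the distance-increase ratio when moving to d+1 exceeds
    ``rtol``, or the (d+1)-dimensional distance exceeds ``atol`` times the
    series standard deviation.
    """
    x = np.asarray(x, float)
    sd = x.std()
    if sd == 0:
        raise DegenerateSignalError("constant series")
    fractions = np.empty(max_dim)
    for d in range(1, max_dim + 1):
        m = len(x) - d * delay  # points embeddable at both d and d+1
        if m < 2:
            raise TooShortError(
                f"series too short for FNN at dim {d + 1} (delay {delay})"
            )
        emb = embed(x, d, delay).points[:m]
        dist, idx = cKDTree(emb).query(emb, k=2)
        nn = idx[:, 1]
        r_d = dist[:, 1]
        extra = np.abs(x[np.arange(m) + d * delay] - x[nn + d * delay])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(r_d > 0, extra / r_d, np.where(extra > 0, np.inf, 0.0))
        r_d1 = np.sqrt(r_d**2 + extra**2)
        fractions[d - 1] = np.mean((ratio > rtol) | (r_d1 > atol * sd))
    return fractions


def select_embedding_dim(fnn_curve: np.ndarray, threshold: float = 0.01) -> int:
    """Dimension at the first local minimum of the FNN curve.

    Fallbacks, in order: first dimension with fraction < ``threshold``,
    else the global minimum (with a warning). Dimensions are 1-indexed.
    """
    fnn = np.asarray(fnn_curve, float)
    if len(fnn) == 0:
        raise EmptyInputError("empty FNN curve")
    if len(fnn) == 1:
        return 1
    for i in range(1, len(fnn) - 1):
        if fnn[i] < fnn[i - 1] and fnn[i] <= fnn[i + 1]:
            return i + 1
    below = np.flatnonzero(fnn < threshold)
    if below.size:
        return int(below[0]) + 1
    dim = int(np.argmin(fnn)) + 1
    warnings.warn(
        "FNN curve has no local minimum and never drops below "
        f"{threshold}; using its global minimum at dim {dim}", stacklevel=2,
    )
    return dim


def estimate_embedding_params(
    x: np.ndarray, params: CRQAParams | None = None
) -> tuple[int, int]:
    """(delay, dim) for one series via first-minimum AMI then FNN."""
    p = params or CRQAParams()
    delay = p.delay
    if delay is None:
        delay = select_delay(average_mutual_information(x, p.max_lag))
    dim = p.dim
    if dim is None:
        dim = select_embedding_dim(false_nearest_neighbours(x, delay, p.max_dim))
    return delay, dim


# ---------------------------------------------------------------------------
# recurrence machinery


def embed(x: np.ndarray, dim: int, delay: int) -> EmbeddedSeries:
    """Time-delay embedding; n_embedded = N - (dim - 1) * delay."""
    x = np.asarray(x, float)
    n = len(x) - (dim - 1) * delay
    if n < 1:
        raise TooShortError(
            f"cannot embed {len(x)} samples at dim={dim}, delay={delay}"
        )
    cols = [x[i * delay : i * delay + n] for i in range(dim)]
    return EmbeddedSeries(points=np.column_stack(cols), dim=dim, delay=delay)


def _distance_matrix(ex: EmbeddedSeries, ey: EmbeddedSeries) -> np.ndarray:
    if ex.dim != ey.dim:
        raise AlignmentError(f"embedding dims differ: {ex.dim} vs {ey.dim}")
    return cdist(ex.points, ey.points)


def cross_recurrence_matrix(
    ex: EmbeddedSeries, ey: EmbeddedSeries, radius: float
) -> np.ndarray:
    """Boolean matrix R[i, j] = (euclidean distance(ex_i, ey_j) <= radius)."""
    return _distance_matrix(ex, ey) <= radius


def recurrence_rate(R: np.ndarray) -> float:
    """100 x (number of recurrent pairs) / (n_x * n_y)."""
    R = np.asarray(R)
    if R.size == 0:
        raise EmptyInputError("empty recurrence matrix")
    return 100.0 * float(np.count_nonzero(R)) / R.size


def _longest_run(d: np.ndarray) -> int:
    """Longest run of True in a 1-D boolean array."""
    if not d.any():
        return 0
    padded = np.concatenate(([False], d, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int(np.max(edges[1::2] - edges[0::2]))


def maxline(R: np.ndarray, min_line: int = 2) -> int:
    """Longest diagonal run of recurrent points over all diagonals.

    Runs shorter than ``min_line`` count as 0. Cross-recurrence between
    distinct signals has no identity-line artefact, so every diagonal is
    included (Theiler window 0).
    """
    R = np.asarray(R, dtype=bool)
    n_x, n_y = R.shape
    best = 0
    for off in range(-(n_x - 1), n_y):
        d = np.diagonal(R, offset=off)
        if len(d) > best and d.any():
            run = _longest_run(d)
            if run > best:
                best = run
    return best if best >= min_line else 0


def tune_radius(
    ex: EmbeddedSeries,
    ey: EmbeddedSeries,
    target_rr: float = 5.0,
    tol: float = 0.5,
    max_iter: int = 60,
) -> RadiusTuning:
    """Bisect the radius so the recurrence rate hits ``target_rr`` percent.

    Exploits exact monotonicity of the recurrence rate in the radius.
    Raises :class:`TuningError` (reporting the closest achieved rate) if
    the target is unattainable within the iteration budget, e.g. when
    coincident points force a nonzero floor on the rate.
    """
    if not 0 < target_rr <= 100:
        raise TuningError("target_rr must lie in (0, 100]")
    D = _distance_matrix(ex, ey)
    hi = float(D.max())
    if abs(100.0 - target_rr) <= tol:
        return RadiusTuning(radius=hi, rec_pct=100.0, n_iter=0)
    lo = 0.0
    best = RadiusTuning(radius=hi, rec_pct=100.0, n_iter=0)
    for it in range(1, max_iter + 1):
        mid = (lo + hi) / 2.0
        rr = 100.0 * np.count_nonzero(D <= mid) / D.size
        if abs(rr - target_rr) < abs(best.rec_pct - target_rr):
            best = RadiusTuning(radius=mid, rec_pct=rr, n_iter=it)
        if abs(rr - target_rr) <= tol:
            return RadiusTuning(radius=mid, rec_pct=rr, n_iter=it)
        if rr < target_rr:
            lo = mid
        else:
            hi = mid
    raise TuningError(
        f"could not reach recurrence rate {target_rr}% +/- {tol} within "
        f"{max_iter} iterations; closest achieved {best.rec_pct:.4g}%",
        closest_rate=best.rec_pct,
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std()
    if sd == 0:
        raise DegenerateSignalError("constant series cannot be z-scored")
    return (x - x.mean()) / sd


def crqa_metrics(
    x: np.ndarray,
    y: np.ndarray,
    params: CRQAParams | None = None,
    delay: int | None = None,
    dim: int | None = None,
) -> CRQAResult:
    """Full CRQA of two series: z-score, embed, pick radius, summarise.

    ``delay``/``dim`` override the params (e.g. a shared study-level
    setting); otherwise params' fixed values or AMI/FNN estimates on the
    first series are used. The radius comes from ``params.radius`` if set,
    else from the recurrence-rate tuner.
    """
    p = params or CRQAParams()
    xz, yz = _zscore(x), _zscore(y)
    if delay is None or dim is None:
        est_delay, est_dim = estimate_embedding_params(xz, p)
        delay = delay if delay is not None else est_delay
        dim = dim if dim is not None else est_dim
    ex = embed(xz, dim, delay)
    ey = embed(yz, dim, delay)
    if p.radius is not None:
        radius = p.radius
    else:
        radius = tune_radius(ex, ey, p.target_rr, p.rr_tol).radius
    R = cross_recurrence_matrix(ex, ey, radius)
    return CRQAResult(
        rec_pct=recurrence_rate(R),
        maxline=maxline(R, p.min_line),
        radius_used=float(radius),
        n_x=ex.n_embedded,
        n_y=ey.n_embedded,
        delay=delay,
        dim=dim,
    )


def export_recurrence_plot(R: np.ndarray, csv_path=None, png_path=None) -> None:
    """Diagnostic export of a recurrence matrix as 0/1 CSV and/or an image."""
    R = np.asarray(R, dtype=np.int8)
    if csv_path is not None:
        np.savetxt(csv_path, R, fmt="%d", delimiter=",")
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(R.T, origin="lower", cmap="binary", interpolation="none")
        ax.set_xlabel("x (embedded index)")
        ax.set_ylabel("y (embedded index)")
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
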