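"""Statistical core of the feature-assisted tracker.

Object motion through the N-dimensional feature space is modelled as a
Gaussian random walk: x_{t+1} = x_t + DX_t with DX_t ~ N(mu_t, Sigma_t(Dx)).
The frame-wide distribution of raw feature vectors supplies a second
covariance, Sigma_t(x), describing the dynamic range the objects occupy.

Three quantities are derived from these statistics:

* the *trackability* r_t (bits/object), the identity-discriminating
  information available per object between two frames,

      r_t = 1/2 log2(|Sigma_t(x)| / |Sigma_t(Dx)|)
            + N/2 log2(6*pi*e) - log2(n_o,t);

* the *whitening* transform dx -> L^{-1}(dx - mu) (L the Cholesky factor of
  Sigma_t(Dx)), whose Euclidean norm is the Mahalanobis link score; and

* the *adaptive threshold* beta_t, the Mahalanobis radius at which the
  expected number of spurious competitors inside the acceptance ball equals
  a user-chosen static threshold P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.stats import chi2

from .features import FeatureSpec, FeatureTable

LOG2_6PIE = math.log2(6 * math.pi * math.e)

#: ridge added to covariance diagonals, relative to each feature's variance
RIDGE_REL = 1e-6
#: absolute ridge floor for exactly degenerate features
RIDGE_ABS = 1e-12


class InsufficientTrainingError(ValueError):
    """Raised when too few training links exist to fit the Gaussian model."""


def regularize_covariance(S: np.ndarray) -> np.ndarray:
    """Add a small diagonal ridge so the covariance is positive-definite.

    The ridge is ``RIDGE_REL`` relative to each feature's own variance, with
    an absolute floor of ``RIDGE_ABS`` for exactly degenerate features.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    ridge = np.maximum(RIDGE_REL * np.abs(np.diag(S)), RIDGE_ABS)
    return S + np.diag(ridge)


def _chol_lower(S: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "covariance is not positive-definite; regularize before use"
        ) from exc


@dataclass
class DisplacementModel:
    """Per frame-pair Gaussian motion model and derived link statistics."""

    frame_pair: tuple
    mu: np.ndarray
    sigma_delta: np.ndarray
    sigma_x: np.ndarray
    n_o: int
    n_train: int
    r: float | None = None
    beta: float | None = None
    _chol: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.sigma_delta = np.atleast_2d(np.asarray(self.sigma_delta, dtype=float))
        self.sigma_x = np.atleast_2d(np.asarray(self.sigma_x, dtype=float))
        n = self.mu.size
        if self.sigma_delta.shape != (n, n) or self.sigma_x.shape != (n, n):
            raise ValueError("covariance shapes do not match mu")

    @property
    def n_features(self) -> int:
        return self.mu.size

    @property
    def cholesky(self) -> np.ndarray:
        """Lower-triangular Cholesky factor of sigma_delta (cached)."""
        if self._chol is None:
            self._chol = _chol_lower(self.sigma_delta)
        return self._chol

    def logdet_ratio(self) -> float:
        """ln(|sigma_x| / |sigma_delta|)."""
        s1, ld_x = np.linalg.slogdet(self.sigma_x)
        s2, ld_d = np.linalg.slogdet(self.sigma_delta)
        if s1 <= 0 or s2 <= 0:
            raise ValueError("covariances must be positive-definite")
        return ld_x - ld_d


# ---------------------------------------------------------------------------
# displacement extraction and training-link selection
# ---------------------------------------------------------------------------

def compute_displacements(table_t: FeatureTable, table_t1: FeatureTable,
                          links, spec: FeatureSpec) -> np.ndarray:
    """Feature displacements x_{t+1} - x_t for every link, wrap-aware.

    Circular features are differenced into (-period/2, period/2]; periodic
    centroid coordinates use the minimum-image convention.  A link that
    references a missing object id is rejected with the link identified.
    """
    row_t = table_t.row_of()
    row_t1 = table_t1.row_of()
    df = links.df if hasattr(links, "df") else links
    i_rows, j_rows = [], []
    for ff, i, ft, j in zip(df["frame_from"], df["id_from"], df["frame_to"], df["id_to"]):
        if int(i) not in row_t:
            raise KeyError(f"link ({ff},{i})->({ft},{j}): id {i} absent from frame {table_t.frame}")
        if int(j) not in row_t1:
            raise KeyError(f"link ({ff},{i})->({ft},{j}): id {j} absent from frame {table_t1.frame}")
        i_rows.append(row_t[int(i)])
        j_rows.append(row_t1[int(j)])
    if not i_rows:
        return np.empty((0, spec.n_features))
    d = table_t1.X[np.array(j_rows)] - table_t.X[np.array(i_rows)]
    return spec.wrap_differences(d)


def select_training_links(links, F: float):
    """Keep the fraction F of links with the smallest centroid displacement.

    Exactly ceil(F * n) links are returned; ties are broken by
    (frame_from, id_from, id_to) so the selection is deterministic.
    """
    from .tracker import LinkSet  # local import to avoid a cycle

    if not (0 < F <= 1):
        raise ValueError("F must lie in (0, 1]")
    df = links.df
    if len(df) == 0:
        raise InsufficientTrainingError("no putative links to train on")
    order = np.lexsort((df["id_to"].to_numpy(), df["id_from"].to_numpy(),
                        df["frame_from"].to_numpy(), df["score"].to_numpy()))
    k = math.ceil(F * len(df))
    return LinkSet(df.iloc[order[:k]].reset_index(drop=True))


def fit_displacement_model(displacements: np.ndarray, table_t1: FeatureTable,
                           n_o: int, frame_pair=(0, 1)) -> DisplacementModel:
    """Fit mu, Sigma(Dx) from training displacements and Sigma(x) from a frame.

    Requires at least N+1 displacements (pool over neighbouring frame pairs
    first if a single pair is too sparse).  Both covariances receive the
    diagonal ridge of :func:`regularize_covariance`.
    """
    d = np.atleast_2d(np.asarray(displacements, dtype=float))
    n_feat = d.shape[1]
    if d.shape[0] < n_feat + 1:
        raise InsufficientTrainingError(
            f"insufficient training links: {d.shape[0]} < N+1 = {n_feat + 1}")
    mu = d.mean(axis=0)
    sigma_delta = regularize_covariance(np.cov(d, rowvar=False, ddof=1))
    sigma_x = regularize_covariance(np.cov(table_t1.X, rowvar=False, ddof=1))
    return DisplacementModel(frame_pair=tuple(frame_pair), mu=mu,
                             sigma_delta=sigma_delta, sigma_x=sigma_x,
                             n_o=int(n_o), n_train=d.shape[0])


# ---------------------------------------------------------------------------
# trackability, whitening, adaptive threshold
# ---------------------------------------------------------------------------

def trackability(sigma_x: np.ndarray, sigma_delta: np.ndarray, n_o: int) -> float:
    """Identity-discriminating information in bits/object for one frame pair.

    With a single feature this reduces to
    ``1/2 log2(var(x)/var(dx)) + 1/2 log2(6*pi*e)`` for a lone object.
    """
    if n_o < 1:
        raise ValueError("n_o must be >= 1")
    m = DisplacementModel(frame_pair=(0, 1), mu=np.zeros(np.atleast_2d(sigma_x).shape[0]),
                          sigma_delta=sigma_delta, sigma_x=sigma_x, n_o=n_o, n_train=0)
    _chol_lower(m.sigma_x)   # SPD checks: caller must regularize first
    _chol_lower(m.sigma_delta)
    n_feat = m.n_features
    return (0.5 * m.logdet_ratio() / math.log(2)
            + 0.5 * n_feat * LOG2_6PIE - math.log2(n_o))


def normalize_displacement(dx: np.ndarray, model: DisplacementModel):
    """Whiten displacements with the fitted model.

    Returns ``(whitened, norm)`` where ``whitened = L^{-1} (dx - mu)`` and
    ``norm`` is its Euclidean length — the Mahalanobis distance of the link.
    Accepts a single displacement or a stack with features on the last axis.
    """
    dx = np.asarray(dx, dtype=float)
    single = dx.ndim == 1
    d = np.atleast_2d(dx) - model.mu
    w = solve_triangular(model.cholesky, d.T, lower=True).T
    norms = np.linalg.norm(w, axis=1)
    if single:
        return w[0], float(norms[0])
    return w, norms


def adaptive_threshold(model: DisplacementModel, P: float) -> float:
    """Mahalanobis acceptance radius beta_t for a static threshold P.

    beta solves E_spurious(beta) = P where E_spurious is the expected number
    of spurious competitors inside the radius-beta ball of normalized feature
    space: n_o * V_N(beta) / V_cloud, with V_N the volume of the N-ball and
    V_cloud = (2*pi*e)^{N/2} sqrt(|sigma_x|/|sigma_delta|) the
    Gaussian-equivalent volume of the object cloud in normalized units.
    The closed form is capped at the sqrt of the chi^2_N 0.999 quantile, so
    beta grows with P and with the information ratio, and shrinks as the
    number of objects grows.
    """
    if P <= 0:
        raise ValueError("P must be positive")
    n_feat = model.n_features
    ln_v_cloud = 0.5 * n_feat * math.log(2 * math.pi * math.e) + 0.5 * model.logdet_ratio()
    ln_beta = (math.log(P) + ln_v_cloud + math.lgamma(n_feat / 2 + 1)
               - math.log(model.n_o) - 0.5 * n_feat * math.log(math.pi)) / n_feat
    cap = math.sqrt(chi2.ppf(0.999, df=n_feat))
    return float(min(math.exp(ln_beta), cap))


def expected_spurious(model: DisplacementModel, beta: float) -> float:
    """E_spurious(beta): expected competitors within Mahalanobis radius beta."""
    n_feat = model.n_features
    ln_vn = 0.5 * n_feat * math.log(math.pi) + n_feat * math.log(beta) - math.lgamma(n_feat / 2 + 1)
    ln_v_cloud = 0.5 * n_feat * math.log(2 * math.pi * math.e) + 0.5 * model.logdet_ratio()
    return model.n_o * math.exp(ln_vn - ln_v_cloud)


# ---------------------------------------------------------------------------
# trackability report
# ---------------------------------------------------------------------------

@dataclass
class TrackabilityReport:
    """Per-frame trackability series with low-information frames flagged."""

    frames: np.ndarray
    r: np.ndarray
    beta: np.ndarray
    n_o: np.ndarray
    n_train: np.ndarray
    flags: np.ndarray  # frame numbers flagged as low-information

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({
            "frame": self.frames, "r_bits": self.r, "beta": self.beta,
            "n_objects": self.n_o, "n_train": self.n_train,
        })
        df["flagged"] = np.isin(self.frames, self.flags)
        return df


def build_trackability_report(models, drop_bits: float = 1.0,
                              window: int = 21) -> TrackabilityReport:
    """Collect per-pair statistics and flag frames with anomalously low r.

    A frame is flagged when its trackability falls more than ``drop_bits``
    below the centred running median of the series over ``window`` frames.
    """
    if not models:
        raise ValueError("need at least one fitted model")
    models = sorted(models, key=lambda m: m.frame_pair[0])
    frames = np.array([m.frame_pair[0] for m in models])
    r = np.array([m.r for m in models], dtype=float)
    beta = np.array([m.beta if m.beta is not None else np.nan for m in models])
    n_o = np.array([m.n_o for m in models])
    n_train = np.array([m.n_train for m in models])
    med = running_median(r, window)
    flags = frames[r < med - drop_bits]
    return TrackabilityReport(frames, r, beta, n_o, n_train, flags)


def running_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centred sliding median, truncated (not padded) at the series edges."""
    values = np.asarray(values, dtype=float)
    half = window // 2
    out = np.empty_like(values)
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out[i] = np.median(values[lo:hi])
    return out
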