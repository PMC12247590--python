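"""The comICA algorithm.

Multiple evoked recordings of the same subject are stacked along the channel
axis and decomposed with temporal ICA,

    x = A . s,

so every independent time course ``s_i`` is shared by construction and the
recording-specific information lives entirely in the mixing matrix ``A``
(shape ``(M * n_sens, N)``).  Column ``i`` of ``A`` splits into ``M``
spatial (field) patterns ``a_{i,k}``, one per recording; a component is
*reproducible* when those patterns agree across recordings.  Agreement is
measured by the metric-weighted cosine similarity of the centered patterns,

    d_{h,j} = (a_h' C+ a_j) / sqrt((a_h' C+ a_h) (a_j' C+ a_j)),

where ``C+`` is the Moore-Penrose pseudoinverse of the covariance of all
``M * N`` centered patterns (or the identity for the plain cosine).  The
pairwise similarities form a matrix ``D`` whose diagonal ``M x M`` blocks
``B_i`` compare the patterns of one component across recordings; component
``i`` is retained when every entry of ``B_i`` exceeds a threshold, and the
retained components are inverted back into the recordings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA

from .evoked_data import EvokedRecording

logger = logging.getLogger("comica")

__all__ = [
    "ConcatenatedSet",
    "Decomposition",
    "SpatialPatternSet",
    "SpatialMetric",
    "DistanceMatrix",
    "SelectionResult",
    "ReconstructedSet",
    "ComICA",
    "concatenate",
    "center",
    "decompose",
    "extract_spatial_patterns",
    "estimate_metric",
    "pairwise_similarity",
    "select_components",
    "reconstruct",
    "run_comica",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ConcatenatedSet:
    """Spatially concatenated recordings: ``x`` is ``(M * n_sens, n_times)``.

    Row block ``k`` (rows ``k*n_sens .. (k+1)*n_sens``) holds recording
    ``k``'s channels in input order.  ``row_means`` holds the per-row means
    removed by :func:`center` (zeros before centering).
    """

    x: np.ndarray
    M: int
    n_sens: int
    row_means: np.ndarray
    recordings_meta: list = field(default_factory=list)

    def block(self, k: int) -> slice:
        """Row range of recording ``k``."""
        if not 0 <= k < self.M:
            raise IndexError(f"recording index {k} out of range [0, {self.M})")
        return slice(k * self.n_sens, (k + 1) * self.n_sens)

    @property
    def block_index(self):
        return {k: self.block(k) for k in range(self.M)}

    @property
    def n_times(self) -> int:
        return self.x.shape[1]


@dataclass
class Decomposition:
    """ICA factorization ``x ~ A . s`` of the centered concatenated data."""

    A: np.ndarray          # (M*n_sens, N) mixing matrix
    s: np.ndarray          # (N, n_times) independent time courses
    explained_variance: np.ndarray  # per-component fraction of data variance
    solver_seed: int | None

    @property
    def N(self) -> int:
        return self.A.shape[1]


@dataclass
class SpatialPatternSet:
    """Recording-specific spatial patterns ``a_{i,k}`` and their centered versions.

    ``patterns`` has shape ``(N, M, n_sens)``; ``centered`` is the same minus
    the grand mean over all ``M * N`` patterns.
    """

    patterns: np.ndarray
    centered: np.ndarray
    grand_mean: np.ndarray

    @property
    def N(self) -> int:
        return self.patterns.shape[0]

    @property
    def M(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_sens(self) -> int:
        return self.patterns.shape[2]

    def flat_centered(self) -> np.ndarray:
        """Centered patterns flattened component-major: row ``i*M + k`` is ``a_{i,k}``."""
        return self.centered.reshape(self.N * self.M, self.n_sens)


@dataclass
class SpatialMetric:
    """The similarity metric: ``C_plus`` weights the quadratic forms in the cosine."""

    C: np.ndarray
    C_plus: np.ndarray
    rank: int
    mode: str  # "weighted" | "identity"


@dataclass
class DistanceMatrix:
    """Pairwise pattern similarities, component-major ordering.

    ``D[h, j]`` compares flattened patterns ``h`` and ``j``; the ``M x M``
    diagonal blocks ``B_i`` compare component ``i``'s patterns across
    recordings.
    """

    D: np.ndarray
    M: int
    N: int
    zero_norm_flags: np.ndarray  # patterns with zero metric-norm (similarity set to 0)

    def block(self, i: int) -> np.ndarray:
        """The ``M x M`` block ``B_i`` of component ``i``."""
        sl = slice(i * self.M, (i + 1) * self.M)
        return self.D[sl, sl]

    def off_block_values(self) -> np.ndarray:
        """All entries of ``D`` outside every diagonal block ``B_i``."""
        mask = np.ones_like(self.D, dtype=bool)
        for i in range(self.N):
            sl = slice(i * self.M, (i + 1) * self.M)
            mask[sl, sl] = False
        return self.D[mask]


@dataclass
class SelectionResult:
    """Outcome of reproducibility-based component selection."""

    retained: tuple
    threshold_used: float
    mode: str  # "fixed_threshold" | "distribution_quantile"
    per_block_min: np.ndarray
    alpha: float | None = None


@dataclass
class ReconstructedSet:
    """Concatenated reconstruction from the retained components, plus the split recordings."""

    x_tilde: np.ndarray
    recordings: list
    means_restored: bool
    retained: tuple


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def concatenate(recordings) -> ConcatenatedSet:
    """Stack ``M >= 2`` evoked recordings along the channel axis.

    All recordings must agree in channel count and order, number of samples,
    sampling frequency, and epoch start time.
    """
    recordings = list(recordings)
    if len(recordings) < 2:
        raise ValueError("comICA needs at least two recordings")
    ref = recordings[0]
    for idx, rec in enumerate(recordings[1:], start=1):
        if rec.data.shape != ref.data.shape:
            raise ValueError(
                f"recording {idx} has shape {rec.data.shape}, "
                f"recording 0 has {ref.data.shape}"
            )
        if rec.sensors.channel_ids != ref.sensors.channel_ids:
            raise ValueError(
                f"recording {idx} channel order differs from recording 0; "
                "run align_channels first"
            )
        if not np.isclose(rec.sfreq, ref.sfreq) or not np.isclose(rec.tmin, ref.tmin):
            raise ValueError(
                f"recording {idx} timing (sfreq={rec.sfreq}, tmin={rec.tmin}) "
                f"differs from recording 0 (sfreq={ref.sfreq}, tmin={ref.tmin})"
            )
    x = np.vstack([rec.data for rec in recordings])
    logger.debug("concatenate: M=%d, n_sens=%d, n_times=%d",
                 len(recordings), ref.n_sens, ref.n_times)
    return ConcatenatedSet(
        x=x,
        M=len(recordings),
        n_sens=ref.n_sens,
        row_means=np.zeros(x.shape[0]),
        recordings_meta=[
            dict(sfreq=r.sfreq, tmin=r.tmin, sensors=r.sensors,
                 n_trials_averaged=r.n_trials_averaged, comment=r.comment)
            for r in recordings
        ],
    )


def center(concat: ConcatenatedSet) -> ConcatenatedSet:
    """Remove each row's temporal mean, storing it for later restoration."""
    means = concat.x.mean(axis=1)
    return ConcatenatedSet(
        x=concat.x - means[:, None],
        M=concat.M,
        n_sens=concat.n_sens,
        row_means=concat.row_means + means,
        recordings_meta=concat.recordings_meta,
    )


def _numerical_rank(x: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(x))


def decompose(concat: ConcatenatedSet, n_components="full", seed=None,
              max_iter=1000, tol=1e-4) -> Decomposition:
    """Temporal ICA of the centered concatenated data.

    Uses a fixed-point negentropy-maximization solver (FastICA, log-cosh
    contrast) after PCA whitening.  Components are returned in descending
    order of the data variance explained by their rank-1 contribution
    ``A[:, i] s[i]``, with source signs normalized so each time course's
    largest-magnitude sample is positive.

    ``n_components="full"`` keeps the numerical rank of the data.
    """
    x = concat.x
    rank = _numerical_rank(x)
    if n_components == "full" or n_components is None:
        n_comp = rank
    else:
        n_comp = int(n_components)
        if n_comp < 1:
            raise ValueError("n_components must be positive")
        if n_comp > rank:
            raise ValueError(
                f"requested {n_comp} components but the centered data has "
                f"numerical rank {rank}"
            )
    if n_comp > min(x.shape):
        raise ValueError(
            f"n_components={n_comp} exceeds min(M*n_sens, n_times)={min(x.shape)}"
        )

    # temporal ICA: time points are samples, stacked channels are features
    ica = FastICA(
        n_components=n_comp,
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        sources = ica.fit_transform(x.T)      # (n_times, N)
    A = ica.mixing_                            # (M*n_sens, N)
    s = sources.T                              # (N, n_times)

    # order by explained variance of each rank-1 contribution
    total_var = float((x ** 2).sum())
    contrib = (A ** 2).sum(axis=0) * (s ** 2).sum(axis=1)
    order = np.argsort(contrib)[::-1]
    A, s, contrib = A[:, order], s[order], contrib[order]

    # sign convention: largest-magnitude sample of each source is positive
    signs = np.sign(s[np.arange(len(s)), np.abs(s).argmax(axis=1)])
    signs[signs == 0] = 1.0
    s = s * signs[:, None]
    A = A * signs[None, :]

    explained = contrib / total_var if total_var > 0 else np.zeros(n_comp)
    logger.debug("decompose: rank=%d, N=%d, explained=%s", rank, n_comp,
                 np.round(explained, 4))
    return Decomposition(A=A, s=s, explained_variance=explained,
                         solver_seed=seed)


def extract_spatial_patterns(decomp: Decomposition, M: int,
                             n_sens: int) -> SpatialPatternSet:
    """Split each mixing-matrix column into its ``M`` per-recording field patterns.

    ``a_{i,k}`` is rows ``k*n_sens .. (k+1)*n_sens`` of column ``i`` of ``A``.
    Centering subtracts the grand mean pattern over all ``M * N`` patterns.
    """
    A = decomp.A
    if A.shape[0] != M * n_sens:
        raise ValueError(
            f"mixing matrix has {A.shape[0]} rows, expected M*n_sens="
            f"{M * n_sens}"
        )
    N = A.shape[1]
    # (N, M, n_sens): pattern[i, k] = A[k*n_sens:(k+1)*n_sens, i]
    patterns = A.T.reshape(N, M, n_sens)
    grand_mean = patterns.reshape(N * M, n_sens).mean(axis=0)
    return SpatialPatternSet(
        patterns=patterns,
        centered=patterns - grand_mean,
        grand_mean=grand_mean,
    )


def estimate_metric(patterns: SpatialPatternSet, mode="weighted",
                    rank_tol=1e-10) -> SpatialMetric:
    """Covariance of the centered patterns and its pseudoinverse.

    ``C = (1 / (M N)) sum_{i,k} a_centered_{i,k} a_centered_{i,k}'``; with
    only ``M * N`` samples in an ``n_sens``-dimensional space ``C`` is
    usually rank-deficient, hence the Moore-Penrose pseudoinverse with
    eigenvalues below ``rank_tol * lambda_max`` truncated.  ``mode="identity"``
    bypasses estimation (plain cosine similarity).
    """
    n_sens = patterns.n_sens
    if mode == "identity":
        return SpatialMetric(C=np.eye(n_sens), C_plus=np.eye(n_sens),
                             rank=n_sens, mode="identity")
    if mode != "weighted":
        raise ValueError(f"unknown metric mode {mode!r}")
    flat = patterns.flat_centered()
    if flat.shape[0] < 2:
        raise ValueError("weighted metric needs at least two patterns (M*N >= 2)")
    if not np.any(flat):
        raise ValueError("all centered patterns are zero: degenerate metric")
    C = flat.T @ flat / flat.shape[0]
    evals, evecs = linalg.eigh(C)
    cutoff = rank_tol * evals.max()
    keep = evals > cutoff
    rank = int(keep.sum())
    inv = np.zeros_like(evals)
    inv[keep] = 1.0 / evals[keep]
    C_plus = (evecs * inv) @ evecs.T
    logger.debug("estimate_metric: rank %d of %d", rank, n_sens)
    return SpatialMetric(C=C, C_plus=C_plus, rank=rank, mode="weighted")


def pairwise_similarity(patterns: SpatialPatternSet,
                        metric: SpatialMetric) -> DistanceMatrix:
    """Metric-weighted cosine similarity between every pair of spatial patterns.

    Entries lie in ``[-1, 1]``: 1 for parallel patterns (equal up to a
    positive scale), -1 for antiparallel, 0 for metric-orthogonal.  Patterns
    with zero metric-norm get similarity 0 against everything (flagged);
    their diagonal entry stays 1 by convention.

    In ``weighted`` mode the cosine is evaluated on the centered patterns,
    whose covariance defines the metric (a Mahalanobis-style construction).
    The ``identity`` (unweighted) mode is the plain cosine between the raw
    field patterns — the similarity of the topographies as measured, which
    is the variant the low-component simulation protocol uses.  With few
    patterns (small ``M * N``) the grand mean contains a large share of any
    pattern common to all recordings, so centering there would suppress
    exactly the reproducible structure the comparison looks for.
    """
    flat = (patterns.flat_centered() if metric.mode == "weighted"
            else patterns.patterns.reshape(-1, patterns.n_sens))
    if metric.C_plus.shape[0] != patterns.n_sens:
        raise ValueError("metric dimension does not match pattern length")
    G = flat @ metric.C_plus @ flat.T
    norms2 = np.diag(G).copy()
    zero = norms2 <= 0
    safe = np.where(zero, 1.0, norms2)
    D = G / np.sqrt(np.outer(safe, safe))
    D = np.clip((D + D.T) / 2.0, -1.0, 1.0)  # enforce exact symmetry/range
    np.fill_diagonal(D, 1.0)
    if zero.any():
        D[zero, :] = 0.0
        D[:, zero] = 0.0
        np.fill_diagonal(D, 1.0)
        logger.warning("pairwise_similarity: %d zero-norm pattern(s) flagged",
                       int(zero.sum()))
    return DistanceMatrix(D=D, M=patterns.M, N=patterns.N,
                          zero_norm_flags=zero)


MIN_NULL_SAMPLES = 20  # off-block entries required for quantile-mode selection


def select_components(dist: DistanceMatrix, mode="fixed_threshold",
                      threshold=0.9, alpha=0.05) -> SelectionResult:
    """Retain components whose cross-recording block entries all exceed a threshold.

    ``fixed_threshold`` applies ``threshold`` directly (the simulation study
    uses 0.9).  ``distribution_quantile`` derives the threshold from the data:
    the off-block entries of ``D`` — similarities between patterns of
    *different* components — form an empirical null, and the ``1 - alpha``
    quantile of that null is the threshold (alpha defaults to 0.05).  With few
    components the null is too small to be meaningful and an error directs the
    caller to fixed-threshold mode.
    """
    per_block_min = np.array([dist.block(i).min() for i in range(dist.N)])
    if mode == "fixed_threshold":
        if not (-1.0 < threshold <= 1.0):
            raise ValueError("threshold must lie in (-1, 1]")
        thr = float(threshold)
        used_alpha = None
    elif mode == "distribution_quantile":
        if not (0.0 < alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        null = dist.off_block_values()
        if null.size < MIN_NULL_SAMPLES:
            raise ValueError(
                f"only {null.size} off-block similarities available "
                f"(< {MIN_NULL_SAMPLES}); too few components for a reliable "
                "null distribution — use fixed_threshold mode"
            )
        thr = float(np.quantile(null, 1.0 - alpha))
        used_alpha = float(alpha)
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    retained = tuple(int(i) for i in np.flatnonzero(per_block_min > thr))
    logger.debug("select_components: mode=%s, threshold=%.4f, retained=%s",
                 mode, thr, retained)
    return SelectionResult(retained=retained, threshold_used=thr, mode=mode,
                           per_block_min=per_block_min, alpha=used_alpha)


def reconstruct(decomp: Decomposition, selection: SelectionResult,
                concat: ConcatenatedSet, restore_means=True) -> ReconstructedSet:
    """Invert the decomposition on the retained components and split per recording.

    An empty retained set yields the all-zero signal (plus the row means if
    ``restore_means``); this is allowed and logged.
    """
    idx = list(selection.retained)
    if any(i < 0 or i >= decomp.N for i in idx):
        raise ValueError(f"retained indices {idx} out of range for N={decomp.N}")
    if idx:
        x_tilde = decomp.A[:, idx] @ decomp.s[idx]
    else:
        x_tilde = np.zeros_like(concat.x)
        logger.warning("reconstruct: empty retained set, output is the zero signal")
    if restore_means:
        x_tilde = x_tilde + concat.row_means[:, None]
    from .evoked_data import SensorArray

    recordings = []
    for k in range(concat.M):
        meta = (concat.recordings_meta[k] if k < len(concat.recordings_meta)
                else {})
        sensors = meta.get("sensors") or SensorArray.generic(concat.n_sens)
        recordings.append(
            EvokedRecording(
                data=x_tilde[concat.block(k)].copy(),
                sfreq=meta.get("sfreq", 1.0),
                tmin=meta.get("tmin", 0.0),
                sensors=sensors,
                n_trials_averaged=meta.get("n_trials_averaged", 0),
                comment=meta.get("comment", ""),
            )
        )
    return ReconstructedSet(x_tilde=x_tilde, recordings=recordings,
                            means_restored=bool(restore_means),
                            retained=tuple(idx))


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class ComICA(BaseEstimator, TransformerMixin):
    """Combined ICA across repeated recordings of the same subject.

    Fits temporal ICA to spatially concatenated recordings, scores the
    cross-recording reproducibility of every component's spatial patterns
    with a (weighted) cosine similarity, and reconstructs the recordings
    from the reproducible components only.

    Parameters
    ----------
    n_components : int or "full"
        Number of independent components; ``"full"`` uses the numerical rank
        of the centered concatenated data.
    metric : {"weighted", "identity"}
        ``"weighted"`` uses the pseudoinverse of the pattern covariance as
        the inner-product metric; ``"identity"`` is the plain cosine
        (recommended when ``M * N`` is small, as in the 3-component
        simulation protocol).
    selection : {"fixed_threshold", "distribution_quantile"}
        Fixed similarity threshold, or a threshold at the ``1 - alpha``
        quantile of the off-block (different-component) similarities.
    threshold : float
        Fixed-mode similarity threshold in ``(-1, 1]``.
    alpha : float
        Quantile-mode significance level.
    restore_means : bool
        Add the removed per-row means back into the reconstruction.
    rank_tol : float
        Relative eigenvalue cutoff for the metric pseudoinverse.
    random_state : int or None
        Seed for the ICA solver.

    Attributes
    ----------
    mixing_ : ndarray of shape (M * n_sens, N)
    sources_ : ndarray of shape (N, n_times)
    explained_variance_ratio_ : ndarray of shape (N,)
    patterns_ : SpatialPatternSet
    metric_ : SpatialMetric
    similarity_ : DistanceMatrix
    selection_ : SelectionResult
    retained_ : tuple of retained component indices
    threshold_used_ : float
    reconstruction_ : ReconstructedSet

    Examples
    --------
    >>> est = ComICA(n_components=3, metric="identity", threshold=0.9,
    ...              random_state=0)
    >>> cleaned = est.fit_transform([run1, run2])   # doctest: +SKIP
    """

    def __init__(self, n_components="full", metric="weighted",
                 selection="fixed_threshold", threshold=0.9, alpha=0.05,
                 restore_means=True, rank_tol=1e-10, max_iter=1000,
                 tol=1e-4, random_state=None):
        self.n_components = n_components
        self.metric = metric
        self.selection = selection
        self.threshold = threshold
        self.alpha = alpha
        self.restore_means = restore_means
        self.rank_tol = rank_tol
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _as_recordings(self, X):
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], EvokedRecording):
            return list(X)
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 3:
            raise ValueError(
                "X must be a list of EvokedRecording or an array of shape "
                "(M, n_sens, n_times)"
            )
        from .evoked_data import SensorArray
        sens = SensorArray.generic(arr.shape[1])
        return [EvokedRecording(a, sfreq=1.0, tmin=0.0, sensors=sens)
                for a in arr]

    def fit(self, X, y=None):
        """Run the full pipeline on ``X`` (list of recordings or (M, n_sens, T) array)."""
        recordings = self._as_recordings(X)
        stage = "concatenate"
        try:
            concat = concatenate(recordings)
            stage = "center"
            concat = center(concat)
            stage = "decompose"
            decomp = decompose(concat, self.n_components, self.random_state,
                               self.max_iter, self.tol)
            stage = "extract_spatial_patterns"
            patt = extract_spatial_patterns(decomp, concat.M, concat.n_sens)
            stage = "estimate_metric"
            met = estimate_metric(patt, self.metric, self.rank_tol)
            stage = "pairwise_similarity"
            dist = pairwise_similarity(patt, met)
            stage = "select_components"
            sel = select_components(dist, self.selection, self.threshold,
                                    self.alpha)
            stage = "reconstruct"
            rec = reconstruct(decomp, sel, concat, self.restore_means)
        except Exception as err:
            raise type(err)(f"[stage: {stage}] {err}") from err

        self.concat_ = concat
        self.mixing_ = decomp.A
        self.sources_ = decomp.s
        self.decomposition_ = decomp
        self.explained_variance_ratio_ = decomp.explained_variance
        self.patterns_ = patt
        self.metric_ = met
        self.similarity_ = dist
        self.selection_ = sel
        self.retained_ = sel.retained
        self.threshold_used_ = sel.threshold_used
        self.reconstruction_ = rec
        self.n_components_ = decomp.N
        return self

    def transform(self, X=None):
        """Project data onto the retained components.

        With ``X=None`` returns the recordings reconstructed during ``fit``.
        Otherwise ``X`` (same layout as in ``fit``) is centered, projected
        through ``A_r pinv(A)_r`` and mean-restored per the fitted options.
        """
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "reconstruction_")
        if X is None:
            return self.reconstruction_.recordings
        recordings = self._as_recordings(X)
        concat = center(concatenate(recordings))
        idx = list(self.retained_)
        unmix = np.linalg.pinv(self.mixing_)
        proj = (self.mixing_[:, idx] @ unmix[idx]) if idx else np.zeros(
            (self.mixing_.shape[0], self.mixing_.shape[0]))
        x_t = proj @ concat.x
        if self.restore_means:
            x_t = x_t + concat.row_means[:, None]
        sel = SelectionResult(tuple(idx), self.threshold_used_,
                              self.selection_.mode,
                              self.selection_.per_block_min,
                              self.selection_.alpha)
        out = []
        for k in range(concat.M):
            meta = concat.recordings_meta[k]
            out.append(EvokedRecording(
                data=x_t[concat.block(k)].copy(), sfreq=meta["sfreq"],
                tmin=meta["tmin"], sensors=meta["sensors"],
                n_trials_averaged=meta["n_trials_averaged"],
                comment=meta["comment"]))
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(None)

    def diagnostics(self) -> dict:
        """Summary of the fitted pipeline (JSON-serializable)."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "reconstruction_")
        return {
            "n_components": int(self.n_components_),
            "retained": [int(i) for i in self.retained_],
            "threshold_used": float(self.threshold_used_),
            "selection_mode": self.selection_.mode,
            "metric_mode": self.metric_.mode,
            "metric_rank": int(self.metric_.rank),
            "explained_variance": [float(v) for v in
                                   self.explained_variance_ratio_],
            "per_block_min": [float(v) for v in self.selection_.per_block_min],
            "means_restored": bool(self.reconstruction_.means_restored),
        }


def run_comica(recordings, n_components="full", metric="weighted",
               selection="fixed_threshold", threshold=0.9, alpha=0.05,
               restore_means=True, seed=None, rank_tol=1e-10):
    """Functional one-shot interface: returns ``(ReconstructedSet, diagnostics)``.

    Composes concatenate -> center -> decompose -> extract_spatial_patterns
    -> estimate_metric -> pairwise_similarity -> select_components ->
    reconstruct; the diagnostics dict additionally carries the similarity
    matrix ``D``.
    """
    est = ComICA(n_components=n_components, metric=metric, selection=selection,
                 threshold=threshold, alpha=alpha, restore_means=restore_means,
                 rank_tol=rank_tol, random_state=seed)
    est.fit(recordings)
    diag = est.diagnostics()
    diag["D"] = est.similarity_.D
    return est.reconstruction_, diag
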