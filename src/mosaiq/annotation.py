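"""Unsupervised clone annotation: dosage labels from expression + spatial context.

Each nucleus carries 0, 1 or 2 copies of the gene encoding the clonal
marker, and its log fluorescence level X = ln x is modelled as a mixture of
K >= 3 normal components over the joint variable (X, Y), where Y is the mean
log level over the cell's spatial neighborhood.  The pipeline:

1. estimate the length scale over which expression stays correlated, from
   the exponential decay of the radial correlation function psi(delta);
2. sample the neighborhood context Y within that radius and fit diagonal
   bivariate normal mixtures over (X, Y) by EM, selecting K by BIC;
3. group the K component means e^mu into three dosage classes by 1-D
   k-means, giving the component -> dosage map f;
4. build a Delaunay cell graph weighted by expression similarity
   w_ij = exp(-|X_i - X_j| / <|dX|>), detect hierarchical Infomap
   communities, and recompute the context as the community mean;
5. diffuse the component posteriors across the graph through the
   Katz-style linear system p_hat = (I - alpha W)^-1 (1 - alpha) p;
6. label each cell f(argmax_k p_hat), with confidence = total diffused
   posterior of the winning dosage; low-confidence labels (< 0.8) fall
   back to the marginal classifier that ignores spatial context.

The approach lets locally consistent neighborhoods override isolated
fluctuations in marker expression, which is what makes annotation reliable
when dosage distributions overlap.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field, replace

import igraph as ig
import numpy as np
from scipy import sparse
from scipy.optimize import curve_fit
from scipy.sparse.linalg import splu
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .data import MeasurementTable
from .errors import (
    AttenuationError,
    FitError,
    InsufficientComponentsError,
    PrecondError,
    ZeroVarianceError,
)
from .geometry import delaunay_edges

# ψ(δ) estimation: equal-count separation bins, moving-average smoothing,
# and a cap on the number of pairs evaluated (subsampled, seeded).  The bin
# count sets the shortest resolvable correlation scale (the first-bin
# distance quantile); 200 bins resolve scales near the cell spacing.
PSI_N_BINS = 200
PSI_SMOOTH_WINDOW = 5
PSI_MAX_PAIRS = 500_000

VARIANCE_FLOOR = 1e-8


def bic_score(n_obs: int, n_params: int, loglik: float) -> float:
    """Bayesian information criterion: ln(N) q - 2 ln(L_hat)."""
    return float(np.log(n_obs) * n_params - 2.0 * loglik)


def edge_weights(E: np.ndarray) -> np.ndarray:
    """Similarity weights w = exp(-E / <E>) from absolute log fold-changes.

    Weights lie in (0, 1], equal 1 for identical expression, and e^-1 for an
    edge whose fold-change matches the mean; a constant-expression graph
    (mean 0) gets unit weights.
    """
    E = np.asarray(E, dtype=float)
    mean_E = E.mean()
    return np.exp(-E / mean_E) if mean_E > 0 else np.ones(len(E))


@dataclass
class AnnotationConfig:
    """Tunable parameters of the annotation pipeline."""

    marker_channel: int = 1
    k_min: int = 3                 # BIC sweep lower bound
    k_max: int = 8                 # BIC sweep upper bound
    n_labels: int = 3              # dosage classes (2 for binary mosaics)
    alpha_frac: float = 0.9        # attenuation as fraction of 1/rho(W)
    edge_quantile: float = 0.95    # Delaunay edge-length filter
    confidence_threshold: float = 0.8
    log_floor_frac: float = 0.01   # floor for ln(): fraction of positive median
    use_communities: bool = True
    seed: int = 0


# ---------------------------------------------------------------------------
# spatial correlation of expression
# ---------------------------------------------------------------------------


@dataclass
class SpatialCorrelation:
    """Binned radial correlation psi(delta) and its exponential decay length."""

    bin_centers: np.ndarray
    psi: np.ndarray
    psi_smooth: np.ndarray
    decay_length: float

    def __call__(self, delta):
        return np.interp(delta, self.bin_centers, self.psi_smooth)


def spatial_correlation(
    positions: np.ndarray, X: np.ndarray, seed: int | None = None
) -> SpatialCorrelation:
    """Radial correlation function of expression and its decay length.

    psi(delta) = <(X_i - mu)(X_j - mu)>_{|r_i - r_j| in bin(delta)} / var(X),
    estimated over equal-count separation bins (pairs subsampled above
    ``PSI_MAX_PAIRS``), smoothed by a moving average, and summarised by the
    1/rate of a least-squares exponential-decay fit.
    """
    positions = np.asarray(positions, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n < 50:
        raise PrecondError(f"need >= 50 cells for correlation scale (got {n})")
    var = X.var()
    if var == 0:
        raise ZeroVarianceError("expression is constant; no correlation scale")
    rng = np.random.default_rng(seed)
    n_pairs = n * (n - 1) // 2
    if n_pairs <= PSI_MAX_PAIRS:
        ii, jj = np.triu_indices(n, k=1)
    else:
        ii = rng.integers(0, n, size=PSI_MAX_PAIRS)
        jj = rng.integers(0, n, size=PSI_MAX_PAIRS)
        keep = ii != jj
        ii, jj = ii[keep], jj[keep]
    d = np.linalg.norm(positions[ii] - positions[jj], axis=1)
    dev = X - X.mean()
    prod = dev[ii] * dev[jj] / var
    order = np.argsort(d, kind="stable")
    d, prod = d[order], prod[order]
    n_bins = min(PSI_N_BINS, max(2, len(d) // 20))
    splits = np.array_split(np.arange(len(d)), n_bins)
    centers = np.array([d[s].mean() for s in splits if len(s)])
    psi = np.array([prod[s].mean() for s in splits if len(s)])
    w = min(PSI_SMOOTH_WINDOW, len(psi))
    kernel = np.ones(w) / w
    smooth = np.convolve(psi, kernel, mode="same")
    decay = _fit_decay_length(centers, smooth)
    return SpatialCorrelation(centers, psi, smooth, decay)


def _fit_decay_length(delta: np.ndarray, psi: np.ndarray) -> float:
    """1/rate of a least-squares fit of a*exp(-delta/L).

    The decay length is a correlation scale within the imaged field, so the
    fit is bounded by the span of observed separations; a fit that runs into
    that bound (a flat, structureless curve) falls back to the first 1/e
    crossing of the smoothed curve, which keeps the neighborhood radius at
    the scale the data actually support.
    """

    def model(d, a, L):
        return a * np.exp(-d / L)

    span = delta.max() - delta.min() or 1.0

    def crossing():
        target = max(psi[0], 1e-12) / np.e
        below = np.flatnonzero(psi <= target)
        if len(below):
            return float(max(delta[below[0]], 1e-6 * span))
        return float(span / 2)

    try:
        popt, _ = curve_fit(
            model,
            delta,
            psi,
            p0=(max(psi[0], 0.1), span / 5),
            bounds=((0, 1e-6 * span), (np.inf, span)),
            maxfev=5000,
        )
    except Exception:
        return crossing()
    L = float(popt[1])
    if L > 0.9 * span:  # bound-saturated fit: no resolvable decay
        return crossing()
    return L


def sample_context(
    positions: np.ndarray, X: np.ndarray, radius: float
) -> np.ndarray:
    """Mean expression over all cells within ``radius``, excluding the cell.

    Cells with no neighbor inside the radius fall back to their own X.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    positions = np.asarray(positions, dtype=float)
    X = np.asarray(X, dtype=float)
    from scipy.spatial import cKDTree

    tree = cKDTree(positions)
    Y = np.empty_like(X)
    for i, nbrs in enumerate(tree.query_ball_point(positions, r=radius)):
        others = [j for j in nbrs if j != i]
        Y[i] = X[others].mean() if others else X[i]
    return Y


# ---------------------------------------------------------------------------
# mixture model (diagonal bivariate normal, EM, BIC selection)
# ---------------------------------------------------------------------------


@dataclass
class MixtureModel:
    """K-component mixture over (X, Y) with diagonal covariances.

    ``means[k]`` and ``variances[k]`` are 2-vectors (X axis first).  The
    component -> dosage map ``dosage_map`` is filled in by
    :func:`map_components`.  ``trace`` holds the per-iteration
    log-likelihood of the winning EM run (non-decreasing by construction).
    """

    weights: np.ndarray            # (K,)
    means: np.ndarray              # (K, 2)
    variances: np.ndarray          # (K, 2)
    loglik: float
    bic: float
    n_obs: int
    trace: list = field(default_factory=list)
    dosage_map: np.ndarray | None = None

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def n_params(self) -> int:
        # K-1 free weights + per component 2 means + 2 variances
        return self.K - 1 + 4 * self.K

    def log_component_densities(self, X, Y) -> np.ndarray:
        """(N, K) log lambda_k N(X, Y | theta_k)."""
        Z = np.column_stack([np.asarray(X, float), np.asarray(Y, float)])
        out = np.empty((len(Z), self.K))
        for k in range(self.K):
            out[:, k] = (
                np.log(self.weights[k])
                - 0.5 * np.sum(np.log(2 * np.pi * self.variances[k]))
                - 0.5 * np.sum((Z - self.means[k]) ** 2 / self.variances[k], axis=1)
            )
        return out

    def posterior(self, X, Y) -> np.ndarray:
        """p(k | X_i, Y_i), rows summing to one."""
        log_d = self.log_component_densities(X, Y)
        return np.exp(log_d - logsumexp(log_d, axis=1, keepdims=True))

    def marginal_log_densities(self, X) -> np.ndarray:
        """(N, K) log lambda_k N(X | mu_k, sigma2_k) on the X axis only."""
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), self.K))
        for k in range(self.K):
            v = self.variances[k, 0]
            out[:, k] = (
                np.log(self.weights[k])
                - 0.5 * np.log(2 * np.pi * v)
                - 0.5 * (X - self.means[k, 0]) ** 2 / v
            )
        return out

    def marginal_posterior(self, X) -> np.ndarray:
        log_d = self.marginal_log_densities(X)
        return np.exp(log_d - logsumexp(log_d, axis=1, keepdims=True))


def _em_fit(Z, K, rng, max_iter=500, tol=1e-6, n_restarts=5):
    """Best-of-restarts EM fit of a K-component diagonal normal mixture.

    A run is degenerate (and restarted with jitter) when a component's
    effective count drops below two observations — the signature of a
    likelihood spike on a single point.  Component variances are floored at
    a small fraction of the overall variance so genuinely tight components
    (e.g. zero-ambiguity data) survive with a bounded likelihood.
    """
    n = len(Z)
    var_floor = np.maximum(1e-6 * Z.var(axis=0), VARIANCE_FLOOR)
    best = None
    for restart in range(n_restarts):
        # k-means initialisation with small jitter on the restarts: the
        # k-means basin tracks the data's cluster structure, which matters
        # more than raw likelihood when components overlap heavily (wider
        # random restarts reach higher-likelihood but dosage-meaningless
        # optima on high-ambiguity data)
        km = KMeans(
            n_clusters=K, n_init=3, random_state=int(rng.integers(2**31))
        ).fit(Z)
        means = km.cluster_centers_.copy()
        if restart > 0:
            means = means + rng.normal(
                scale=0.05 * (Z.std(axis=0) + 1e-12), size=means.shape
            )
        variances = np.tile(Z.var(axis=0) + 1e-6, (K, 1))
        weights = np.bincount(km.labels_, minlength=K).astype(float)
        weights = np.clip(weights, 1, None)
        weights /= weights.sum()
        trace = []
        failed = False
        Z2 = Z**2
        for _ in range(max_iter):
            # E step (broadcast over components; diagonal Gaussian log pdf)
            log_d = (
                np.log(weights)
                - 0.5 * np.sum(np.log(2 * np.pi * variances), axis=1)
                - 0.5 * (
                    Z2 @ (1.0 / variances.T)
                    - 2.0 * (Z @ (means / variances).T)
                    + np.sum(means**2 / variances, axis=1)
                )
            )
            peak = log_d.max(axis=1)
            norm = peak + np.log(np.exp(log_d - peak[:, None]).sum(axis=1))
            loglik = float(norm.sum())
            resp = np.exp(log_d - norm[:, None])
            trace.append(loglik)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                break
            # M step
            nk = resp.sum(axis=0)
            if np.any(nk < 2.0):
                failed = True
                break
            weights = nk / n
            means = (resp.T @ Z) / nk[:, None]
            second = (resp.T @ Z2) / nk[:, None]
            variances = np.maximum(second - means**2, var_floor)
        if failed:
            continue
        if best is None or trace[-1] > best.loglik:
            bic = bic_score(n, K - 1 + 4 * K, trace[-1])
            best = MixtureModel(
                weights=weights.copy(),
                means=means.copy(),
                variances=variances.copy(),
                loglik=trace[-1],
                bic=bic,
                n_obs=n,
                trace=trace,
            )
    return best


def fit_mixture(
    X: np.ndarray,
    Y: np.ndarray,
    k_range=range(3, 9),
    seed: int | None = None,
) -> MixtureModel:
    """EM fit over (X, Y) for each K in ``k_range``; return the min-BIC model.

    BIC = ln(N) q_K - 2 ln(L_hat) with q_K = 5K - 1 for the diagonal
    bivariate model.  Degenerate EM runs (vanishing responsibilities) are
    retried with jittered initialisations; if every restart fails for every
    K a :class:`FitError` is raised with the last iteration trace.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("X and Y must be finite")
    Z = np.column_stack([X, Y])
    k_range = [k for k in k_range if len(Z) >= 10 * k]
    if not k_range:
        raise PrecondError("sample too small for the requested component range")
    rng = np.random.default_rng(seed)
    best = None
    for K in k_range:
        model = _em_fit(Z, K, rng)
        if model is not None and (best is None or model.bic < best.bic):
            best = model
    if best is None:
        raise FitError("EM failed for every component count", trace=[])
    return best


def map_components(model: MixtureModel, n_labels: int = 3) -> np.ndarray:
    """Component -> dosage map via 1-D k-means on the linear means e^mu.

    Components are clustered as distributions: each mean is weighted by its
    mixture weight, so a heavy component anchors its own dosage group rather
    than being absorbed by light neighbors.  Groups are ordered by ascending
    mean, so the lowest-expression group maps to dosage 0 and the highest to
    ``n_labels - 1``.  Returns the map as an int array of length K and
    stores it on the model.
    """
    if model.K < n_labels:
        raise InsufficientComponentsError(
            f"{model.K} components cannot be split into {n_labels} dosage groups"
        )
    scale = np.exp(model.means[:, 0]).reshape(-1, 1)
    km = KMeans(n_clusters=n_labels, n_init=10, random_state=0).fit(
        scale, sample_weight=model.weights
    )
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(n_labels, dtype=int)
    relabel[order] = np.arange(n_labels)
    f = relabel[km.labels_]
    model.dosage_map = f
    return f


def classify_marginal(X: np.ndarray, model: MixtureModel) -> np.ndarray:
    """Dosages from the X-axis marginal alone: f(argmax_k p(k|X)).

    Ties break toward the lower component index (np.argmax convention).
    """
    if model.dosage_map is None:
        raise PrecondError("call map_components before classification")
    post = model.marginal_posterior(X)
    return model.dosage_map[np.argmax(post, axis=1)]


# ---------------------------------------------------------------------------
# cell graph, communities, diffusion
# ---------------------------------------------------------------------------


@dataclass
class CellGraph:
    """Expression-weighted Delaunay adjacency over cells.

    w_ij = exp(-E_ij / <E>) with E_ij = |X_i - X_j| and <E> the mean over
    retained edges; weights lie in (0, 1] and equal 1 for identical levels.
    """

    positions: np.ndarray
    X: np.ndarray
    edges: np.ndarray              # (M, 2)
    weights: np.ndarray            # (M,)
    community: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.X)

    def weight_matrix(self) -> sparse.csr_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        W = sparse.coo_matrix(
            (
                np.concatenate([self.weights, self.weights]),
                (np.concatenate([i, j]), np.concatenate([j, i])),
            ),
            shape=(self.n, self.n),
        )
        return W.tocsr()

    def spectral_radius(self) -> float:
        W = self.weight_matrix()
        if self.n <= 2 or W.nnz == 0:
            return float(np.abs(W.toarray()).sum(axis=1).max()) if W.nnz else 0.0
        from scipy.sparse.linalg import eigsh

        try:
            val = eigsh(W.asfptype(), k=1, which="LA", return_eigenvectors=False,
                        maxiter=5000)
            return float(abs(val[0]))
        except Exception:
            # power iteration fallback
            v = np.ones(self.n) / np.sqrt(self.n)
            for _ in range(200):
                v2 = W @ v
                nrm = np.linalg.norm(v2)
                if nrm == 0:
                    return 0.0
                v = v2 / nrm
            return float(np.linalg.norm(W @ v))


def build_cell_graph(
    positions: np.ndarray,
    X: np.ndarray,
    max_edge_quantile: float = 0.95,
) -> CellGraph:
    """Delaunay graph with length filter and expression-similarity weights."""
    positions = np.asarray(positions, dtype=float)
    X = np.asarray(X, dtype=float)
    edges, _ = delaunay_edges(positions, max_edge_quantile)
    E = np.abs(X[edges[:, 0]] - X[edges[:, 1]])
    return CellGraph(positions=positions, X=X, edges=edges, weights=edge_weights(E))


def _community_levels(graph: CellGraph, seed: int) -> list[np.ndarray]:
    """Hierarchy of partitions, finest (Infomap) to coarsest.

    Level 0 is the flat Infomap partition of the cell graph; coarser levels
    come from re-running Infomap on the quotient graph of communities
    (edge weights aggregated), with a greedy strongest-pair merge whenever
    Infomap stops coarsening, until a single community remains.
    """
    ig_rng = _random.Random(seed)
    ig.set_random_number_generator(ig_rng)
    g = ig.Graph(n=graph.n, edges=[tuple(e) for e in graph.edges])
    g.es["weight"] = list(graph.weights)
    membership = np.array(
        g.community_infomap(edge_weights="weight").membership
    )
    levels = [membership.copy()]
    current = membership
    while len(np.unique(current)) > 1:
        k = len(np.unique(current))
        # quotient graph over current communities
        q_edges = {}
        for (a, b), w in zip(graph.edges, graph.weights):
            ca, cb = current[a], current[b]
            if ca == cb:
                continue
            key = (min(ca, cb), max(ca, cb))
            q_edges[key] = q_edges.get(key, 0.0) + w
        if not q_edges:
            break
        q = ig.Graph(n=k, edges=list(q_edges.keys()))
        q.es["weight"] = list(q_edges.values())
        sub = np.array(q.community_infomap(edge_weights="weight").membership)
        if len(np.unique(sub)) >= k:
            # Infomap stalled: merge the strongest-linked community pair
            (ca, cb) = max(q_edges, key=q_edges.get)
            sub = np.arange(k)
            sub[sub == cb] = ca
            sub = np.unique(sub, return_inverse=True)[1]
        current = sub[current]
        # renumber consecutively
        current = np.unique(current, return_inverse=True)[1]
        levels.append(current.copy())
        if len(levels) > 64:  # safety against pathological oscillation
            break
    return levels


def _mean_community_extent(positions: np.ndarray, membership: np.ndarray) -> float:
    """Mean over communities of 2x the RMS distance to the centroid."""
    extents = []
    for c in np.unique(membership):
        pts = positions[membership == c]
        if len(pts) < 2:
            extents.append(0.0)
            continue
        centroid = pts.mean(axis=0)
        extents.append(2.0 * float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean())))
    return float(np.mean(extents))


def detect_communities(
    graph: CellGraph, decay_length: float, seed: int = 0
) -> np.ndarray:
    """Hierarchical Infomap communities cut at the correlation length scale.

    The chosen partition is the coarsest hierarchy level whose mean
    community spatial extent stays below ``decay_length``; if even the
    finest level exceeds it, the finest level is returned.  Every cell is
    assigned exactly one community; singletons are allowed.
    """
    levels = _community_levels(graph, seed)
    chosen = levels[0]
    for membership in levels:
        if _mean_community_extent(graph.positions, membership) < decay_length:
            chosen = membership
        else:
            break
    graph.community = chosen
    return chosen


def community_context(X: np.ndarray, communities: np.ndarray) -> np.ndarray:
    """Y_c[i] = mean expression over cell i's community (including i)."""
    X = np.asarray(X, dtype=float)
    communities = np.asarray(communities)
    Y = np.empty_like(X)
    for c in np.unique(communities):
        sel = communities == c
        Y[sel] = X[sel].mean()
    return Y


def diffuse_posteriors(
    graph: CellGraph, p: np.ndarray, alpha: float
) -> np.ndarray:
    """Katz-style diffusion p_hat = (I - alpha W)^-1 (1 - alpha) p.

    Solved column-wise (per mixture component) by sparse LU, then
    renormalized per cell so each row sums to one (the linear map does not
    preserve row-stochasticity for a general weight matrix; the argmax is
    unaffected but confidences need a probability scale).

    Raises
    ------
    AttenuationError
        If alpha * rho(W) >= 1 so the system is singular or divergent.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if alpha == 0:
        return p.copy()
    rho = graph.spectral_radius()
    if rho > 0 and alpha * rho >= 1:
        raise AttenuationError(
            f"alpha={alpha:.4g} with spectral radius {rho:.4g}: alpha*rho >= 1"
        )
    W = graph.weight_matrix()
    A = (sparse.identity(graph.n, format="csc") - alpha * W.tocsc())
    try:
        lu = splu(A)
    except RuntimeError as exc:
        raise AttenuationError(f"singular diffusion system: {exc}") from exc
    p_hat = np.column_stack(
        [lu.solve((1 - alpha) * p[:, k]) for k in range(p.shape[1])]
    )
    p_hat = np.clip(p_hat, 0, None)
    rowsum = p_hat.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return p_hat / rowsum


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class AnnotationResult:
    """Diagnostics from one annotation run."""

    model: MixtureModel
    correlation: SpatialCorrelation
    graph: CellGraph
    communities: np.ndarray | None
    context: np.ndarray
    posteriors: np.ndarray
    diffused: np.ndarray
    dosages: np.ndarray
    confidence: np.ndarray
    marginal_dosages: np.ndarray
    fallback: np.ndarray          # cells that received the marginal label
    alpha: float


def log_expression(levels: np.ndarray, floor_frac: float = 0.01) -> np.ndarray:
    """X = ln(level) with sub-floor values clipped to a small positive floor.

    Background subtraction can push corrected levels to or below zero; they
    are clipped to ``floor_frac`` times the median positive level so the log
    stays finite without discarding cells.
    """
    levels = np.asarray(levels, dtype=float)
    positive = levels[levels > 0]
    if len(positive) == 0:
        raise ZeroVarianceError("no positive expression levels")
    eps = floor_frac * np.median(positive)
    return np.log(np.clip(levels, eps, None))


def annotate_detailed(
    table: MeasurementTable, config: AnnotationConfig | None = None
) -> tuple[MeasurementTable, AnnotationResult]:
    """Run the full annotation pipeline; return labeled table + diagnostics.

    Any stage failure propagates as an exception and leaves the input table
    unmodified (all work happens on a copy).
    """
    if config is None:
        config = AnnotationConfig()
    if len(table) < 50:
        raise PrecondError(f"need >= 50 cells to annotate (got {len(table)})")
    positions = table.positions
    X = log_expression(table.level(config.marker_channel), config.log_floor_frac)

    corr = spatial_correlation(positions, X, seed=config.seed)
    # The context radius is the correlation decay length, floored at twice
    # the median nearest-neighbor spacing: a radius below the cell spacing
    # would leave cells neighborless, collapse Y onto X, and degenerate the
    # diagonal-covariance mixture on the X = Y line.
    from scipy.spatial import cKDTree

    nn = cKDTree(positions).query(positions, k=2)[0][:, 1]
    radius = max(corr.decay_length, 2.0 * float(np.median(nn)))
    Y = sample_context(positions, X, radius=radius)
    model = fit_mixture(
        X, Y, k_range=range(config.k_min, config.k_max + 1), seed=config.seed
    )
    f = map_components(model, n_labels=config.n_labels)

    graph = build_cell_graph(positions, X, config.edge_quantile)
    communities = None
    context = Y
    if config.use_communities:
        communities = detect_communities(graph, radius, seed=config.seed)
        sizes = np.bincount(np.unique(communities, return_inverse=True)[1])
        if sizes.mean() > 1:
            context = community_context(X, communities)
        else:
            communities = None  # degenerate partition: radius context retained

    p = model.posterior(X, context)
    rho = graph.spectral_radius()
    alpha = config.alpha_frac / rho if rho > 0 else 0.0
    p_hat = diffuse_posteriors(graph, p, alpha)

    components = np.argmax(p_hat, axis=1)
    dosages = f[components]
    confidence = np.array(
        [p_hat[i, f == m].sum() for i, m in enumerate(dosages)]
    )

    marginal_post = model.marginal_posterior(X)
    marginal_dosages = f[np.argmax(marginal_post, axis=1)]
    marginal_conf = np.array(
        [marginal_post[i, f == m].sum() for i, m in enumerate(marginal_dosages)]
    )

    fallback = confidence < config.confidence_threshold
    dosages = np.where(fallback, marginal_dosages, dosages)
    confidence = np.where(fallback, marginal_conf, confidence)
    confidence = np.clip(confidence, 0.0, 1.0)

    out = table.data.copy()
    out["dosage"] = np.asarray(dosages, dtype="int64")
    out["dosage"] = out["dosage"].astype("Int64")
    out["confidence"] = confidence
    labeled = MeasurementTable(out)
    result = AnnotationResult(
        model=model,
        correlation=corr,
        graph=graph,
        communities=communities,
        context=context,
        posteriors=p,
        diffused=p_hat,
        dosages=dosages,
        confidence=confidence,
        marginal_dosages=marginal_dosages,
        fallback=fallback,
        alpha=alpha,
    )
    return labeled, result


def annotate(
    table: MeasurementTable, config: AnnotationConfig | None = None
) -> MeasurementTable:
    """Label every nucleus with a clonal-marker dosage and a confidence."""
    labeled, _ = annotate_detailed(table, config)
    return labeled
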