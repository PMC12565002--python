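"""Community-ecology statistics, implemented from first principles.

Alpha diversity (bias-corrected Chao1, Shannon), Bray-Curtis
dissimilarities, principal coordinates analysis (PCoA), PERMANOVA
(ADONIS), the Mantel test, redundancy analysis (RDA) with an optional
Hellinger transform, and envfit-style fitting of a single environmental
variable onto an ordination plane.

Permutation p-values use the (1 + exceedances) / (1 + n_perm) estimator so
p never reaches zero, and every permutation stream is seeded explicitly so
results are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError
from .soil_tables import AbundanceTable, IndicatorTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "MantelResult",
    "EnvfitResult",
    "chao1",
    "shannon",
    "bray_curtis",
    "euclidean_distance",
    "pcoa",
    "permanova",
    "mantel",
    "rda",
    "envfit",
]

_EPS = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix with sample labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if np.isnan(d).any():
            raise ValidationError("distance matrix contains NaN")
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if np.abs(d - d.T).max() > 1e-12:
            raise ValidationError("distance matrix is not symmetric (tol 1e-12)")
        if np.abs(np.diag(d)).max() > 0:
            raise ValidationError("distance matrix diagonal must be zero")
        if d.min() < 0:
            raise ValidationError("distances must be non-negative")
        self.d = d

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Strict lower triangle, row-major."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.d[i, j]


@dataclass
class OrdinationResult:
    """Sample scores, eigenvalues and percent variance for PCoA / RDA axes."""

    scores: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # descending, retained axes only
    percent_explained: np.ndarray
    kind: str  # "pcoa" | "rda-constrained"
    negative_eigenvalue_mass: float = 0.0
    total_variance: float | None = None  # RDA: total inertia of transformed Y


@dataclass
class PermanovaResult:
    pseudo_f: float
    p: float
    n_perm: int
    status: str = "ok"  # "ok" | "degenerate"


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


@dataclass
class EnvfitResult:
    r2: float
    p: float
    n_perm: int


def chao1(counts, rounding: bool = False) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1 - 1) / (2(F2 + 1)).

    ``counts`` are per-taxon abundances; non-integers raise unless
    ``rounding`` is set, in which case they are rounded first.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValidationError("counts must be non-negative")
    if not np.allclose(c, np.round(c), atol=1e-9):
        if not rounding:
            raise ValidationError("chao1 needs integer counts (pass rounding=True to round)")
        c = np.round(c)
    c = np.round(c)
    s_obs = float((c > 0).sum())
    f1 = float((c == 1).sum())
    f2 = float((c == 2).sum())
    return s_obs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))


def shannon(proportions) -> float:
    """Shannon diversity H = -sum p ln p, in nats (0 ln 0 := 0)."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValidationError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValidationError(f"proportions must sum to 1, got {p.sum()!r}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def bray_curtis(table: AbundanceTable | pd.DataFrame | np.ndarray) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity: sum|x - y| / sum(x + y)."""
    if isinstance(table, AbundanceTable):
        labels, x = table.sample_ids, table.values
    elif isinstance(table, pd.DataFrame):
        labels, x = [str(i) for i in table.index], table.to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
        labels = [str(i) for i in range(len(x))]
    if (x < 0).any():
        raise ValidationError("abundances must be non-negative")
    row_sums = x.sum(axis=1)
    if (row_sums <= 0).any():
        bad = [labels[i] for i in np.flatnonzero(row_sums <= 0)]
        raise ValidationError(f"all-zero sample(s): {bad}")
    n = len(x)
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        tot = (x[i] + x[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = diff / tot
    d = d + d.T
    return DistanceMatrix(labels=labels, d=d)


def euclidean_distance(frame: pd.DataFrame | np.ndarray) -> DistanceMatrix:
    """Pairwise Euclidean distances of a samples x variables matrix."""
    if isinstance(frame, pd.DataFrame):
        labels, x = [str(i) for i in frame.index], frame.to_numpy(dtype=float)
    else:
        x = np.asarray(frame, dtype=float)
        labels = [str(i) for i in range(len(x))]
    sq = (x**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * x @ x.T, 0.0)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(labels=labels, d=d)


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Classical (metric) multidimensional scaling by Gower double-centering.

    B = -1/2 J D^2 J is eigendecomposed; coordinates are eigenvectors
    scaled by sqrt(eigenvalue) for the positive eigenvalues. Negative
    eigenvalues (non-Euclidean dissimilarities) are excluded from both the
    coordinates and the percent-explained denominator; their total
    magnitude is reported as a diagnostic.
    """
    n = dist.n
    d2 = dist.d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = 0.5 * (b + b.T)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(abs(eigval[0]), 1.0) * 1e-10
    pos = eigval > tol
    neg_mass = float(np.abs(eigval[eigval < -tol]).sum())
    e = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(e)
    pct = 100.0 * e / e.sum() if e.size else np.array([])
    scores = pd.DataFrame(
        coords,
        index=pd.Index(dist.labels, name="sample_id"),
        columns=[f"Axis{k + 1}" for k in range(coords.shape[1])],
    )
    return OrdinationResult(
        scores=scores,
        eigenvalues=e,
        percent_explained=pct,
        kind="pcoa",
        negative_eigenvalue_mass=neg_mass,
    )


def _ss_within(d2: np.ndarray, label_matrix: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Within-group sum of squared distances for a stack of label matrices.

    ``label_matrix``: (n_perm, n) integer group codes; returns (n_perm,).
    """
    out = np.zeros(label_matrix.shape[0])
    for g in range(len(sizes)):
        z = (label_matrix == g).astype(float)
        out += ((z @ d2) * z).sum(axis=1) / (2.0 * sizes[g])
    return out


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    strict: bool = True,
) -> PermanovaResult:
    """Permutational multivariate ANOVA (ADONIS) on a distance matrix.

    pseudo-F = (SS_between / (k-1)) / (SS_within / (n-k)) from the
    distance-based partition; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm),
    permuting group labels under ``seed``.
    """
    labels = np.asarray([str(g) for g in groups])
    if len(labels) != dist.n:
        raise ValidationError("groups length must match the distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    sizes = np.bincount(codes)
    if len(uniq) < 2 or sizes.min() < 2:
        raise ValidationError("need >= 2 groups with >= 2 members each")
    if n_perm < 99:
        if strict:
            raise ValidationError(f"n_perm = {n_perm} < 99 refused in strict mode")
        warnings.warn(f"n_perm = {n_perm} is too small for stable p-values", stacklevel=2)

    n, k = dist.n, len(uniq)
    d2 = dist.d**2
    ss_total = d2[np.tril_indices(n, k=-1)].sum() / n
    ss_w = float(_ss_within(d2, codes[None, :], sizes)[0])
    ss_b = ss_total - ss_w

    off = dist.d[np.tril_indices(n, k=-1)]
    if off.size and (off.max() - off.min()) <= 1e-12:
        # every pair equidistant: the partition carries no information
        f_obs = (ss_b / (k - 1)) / (ss_w / (n - k)) if ss_w > _EPS else float("nan")
        return PermanovaResult(pseudo_f=f_obs, p=1.0, n_perm=n_perm, status="degenerate")
    if ss_w <= _EPS:
        status = "degenerate" if ss_b <= _EPS else "ok"
        f_obs = float("nan") if ss_b <= _EPS else float("inf")
    else:
        f_obs = (ss_b / (k - 1)) / (ss_w / (n - k))
        status = "ok"

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    ss_w_perm = _ss_within(d2, perms, sizes)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = ((ss_total - ss_w_perm) / (k - 1)) / (ss_w_perm / (n - k))
    exceed = int(np.sum(f_perm >= f_obs)) if np.isfinite(f_obs) else int(np.sum(np.isinf(f_perm)))
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PermanovaResult(pseudo_f=float(f_obs), p=float(p), n_perm=n_perm, status=status)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel test: Pearson r of the two lower triangles, one-tailed
    (r >= observed) p by simultaneous row/column permutation of ``d2``."""
    if d1.labels != d2.labels:
        raise ValidationError("distance matrices must share labels in the same order")
    x = d1.condensed()
    y = d2.condensed()
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("a distance matrix has zero variance in its lower triangle")
    r_obs = float(np.corrcoef(x, y)[0, 1])

    rng = np.random.default_rng(seed)
    n = d1.n
    il, jl = np.tril_indices(n, k=-1)
    xc = x - x.mean()
    xnorm = np.sqrt((xc**2).sum())
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = d2.d[np.ix_(perm, perm)][il, jl]
        yc = yp - yp.mean()
        r = float(xc @ yc / (xnorm * np.sqrt((yc**2).sum())))
        if r >= r_obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm)


def hellinger(x: np.ndarray) -> np.ndarray:
    """Hellinger transform: square root of row proportions."""
    sums = x.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValidationError("all-zero sample in abundance matrix")
    return np.sqrt(x / sums)


def rda(
    y: AbundanceTable | pd.DataFrame,
    x: IndicatorTable | pd.DataFrame,
    transform: str = "hellinger",
) -> OrdinationResult:
    """Redundancy analysis: PCA of the fitted values of Y ~ X.

    Y is optionally Hellinger-transformed then column-centered; X is
    column-centered. Constrained axis eigenvalues are the variances of the
    PCA of the fitted values; ``percent_explained`` is each axis eigenvalue
    over the *total* variance of transformed Y, so the constrained axes sum
    to the fraction of community variance explained by the environment.
    """
    yf = y.data if isinstance(y, AbundanceTable) else y
    xf = x.data if isinstance(x, IndicatorTable) else x
    if list(yf.index) != list(xf.index):
        raise ValidationError("response and explanatory tables must share sample order")
    ym = yf.to_numpy(dtype=float)
    xm = xf.to_numpy(dtype=float)
    n, q = xm.shape
    if n <= q + 1:
        raise ValidationError(f"need n_samples > n_explanatory + 1 (n={n}, q={q})")
    if transform not in ("hellinger", "none"):
        raise ValidationError(f"transform must be 'hellinger' or 'none', got {transform!r}")
    if transform == "hellinger":
        ym = hellinger(ym)

    yc = ym - ym.mean(axis=0)
    xc = xm - xm.mean(axis=0)
    rank = np.linalg.matrix_rank(xc)
    if rank < q:
        _, r_qr, piv = _qr_pivot(xc)
        collinear = [str(xf.columns[j]) for j in piv[rank:]]
        raise ValidationError(f"explanatory matrix is rank-deficient; collinear column(s): {collinear}")

    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ beta
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > max(eig[0], _EPS) * 1e-12 if eig.size else np.zeros(0, bool)
    eig = eig[keep]
    scores_m = u[:, keep] * s[keep]
    total_var = float((yc**2).sum() / (n - 1))
    pct = 100.0 * eig / total_var
    scores = pd.DataFrame(
        scores_m,
        index=pd.Index([str(i) for i in yf.index], name="sample_id"),
        columns=[f"RDA{k + 1}" for k in range(scores_m.shape[1])],
    )
    return OrdinationResult(
        scores=scores,
        eigenvalues=eig,
        percent_explained=pct,
        kind="rda-constrained",
        total_variance=total_var,
    )


def _qr_pivot(a: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(a, pivoting=True)
    return q, r, piv


def envfit(
    ordination: OrdinationResult,
    variable,
    n_perm: int = 999,
    seed: int = 0,
) -> EnvfitResult:
    """Fit one environmental variable onto the first two ordination axes.

    R^2 is the squared multiple correlation of the variable regressed on
    the two axis scores; p comes from permuting the variable across
    samples (one-tailed, R^2_perm >= R^2_obs).
    """
    if ordination.scores.shape[1] < 2:
        raise ValidationError("ordination must have >= 2 axes for envfit")
    v = np.asarray(variable, dtype=float)
    if len(v) != len(ordination.scores):
        raise ValidationError("variable length must match the ordination samples")
    if v.std() == 0:
        raise DegenerateDataError("constant variable has no direction to fit")
    axes = ordination.scores.iloc[:, :2].to_numpy()
    ac = axes - axes.mean(axis=0)
    # orthonormal basis of the axis plane -> R^2 by projection
    qbasis, _ = np.linalg.qr(ac)

    def r2_of(vec: np.ndarray) -> float:
        vc = vec - vec.mean()
        denom = float(vc @ vc)
        proj = qbasis.T @ vc
        return float(proj @ proj) / denom

    r2_obs = r2_of(v)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if r2_of(rng.permutation(v)) >= r2_obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return EnvfitResult(r2=float(r2_obs), p=float(p), n_perm=n_perm)
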