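"""Nonmetric multidimensional scaling of similarity ratings.

Mean 1-10 similarity ratings are reverse-scaled into dissimilarities
(d_ij = min(s) + max(s) - s_ij) and embedded with SMACOF: alternating
pool-adjacent-violators monotone regression of configuration distances onto
dissimilarity ranks, and Guttman-transform coordinate updates, minimizing
Kruskal stress-1 = sqrt(sum (dhat - rho)^2 / sum rho^2) over i < j.

Also provides the surrounding inference machinery: Shepard data, stress vs
dimensionality scans, permutation tests on the dissimilarities, rater
bootstrap confidence regions and random-start robustness studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .procrustes import procrustes_align

logger = logging.getLogger(__name__)

BLOCKS = ("D2D", "G2G", "D2G")

#: Kruskal's conventional stress-1 interpretation bands.
STRESS_BANDS = {"poor": 0.20, "fair": 0.10}


# ---------------------------------------------------------------------------
# Similarity study container
# ---------------------------------------------------------------------------


@dataclass
class SimilarityStudy:
    """Rater-level pairwise similarity ratings (long format).

    Columns: ``rater_id, image_a, image_b, block, rating`` with ratings in
    1..10 and block one of D2D / G2G / D2G. Within-type blocks include
    self-pairings; the D2G block is a full ordered grid.
    """

    ratings: pd.DataFrame

    def __post_init__(self) -> None:
        required = ("rater_id", "image_a", "image_b", "block", "rating")
        missing = [c for c in required if c not in self.ratings.columns]
        if missing:
            raise ValueError(f"ratings table missing columns: {missing}")
        if not self.ratings["rating"].between(1, 10).all():
            raise ValueError("ratings outside 1..10")
        bad = set(self.ratings["block"]) - set(BLOCKS)
        if bad:
            raise ValueError(f"unknown blocks: {sorted(bad)}")

    def block(self, name: str) -> pd.DataFrame:
        if name not in BLOCKS:
            raise ValueError(f"unknown block {name!r}")
        return self.ratings[self.ratings["block"] == name]

    def raters(self, block: str) -> list:
        return sorted(self.block(block)["rater_id"].unique().tolist())

    def items(self, block: str) -> list:
        df = self.block(block)
        return sorted(set(df["image_a"]) | set(df["image_b"]))


@dataclass
class MeanRatingResult:
    matrix: pd.DataFrame  # items x items mean similarity
    diagonal_summary: dict
    off_diagonal_summary: dict


@dataclass(frozen=True)
class DissimilarityMatrix:
    d: np.ndarray
    scale_min: float
    scale_max: float

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.all(np.isfinite(d)):
            raise ValueError("dissimilarity matrix must be finite")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class MDSConfiguration:
    coords: np.ndarray  # n x R, column-centered
    stress1: float
    disparities: np.ndarray  # condensed, ordered as squareform/pdist
    iterations: int
    converged: bool
    init: str
    seed: int | None
    stress_history: list = field(default_factory=list)


@dataclass
class ShepardData:
    """Triples (dissimilarity, configuration distance, disparity), sorted by
    dissimilarity rank."""

    dissimilarity: np.ndarray
    distance: np.ndarray
    disparity: np.ndarray

    def stress1(self) -> float:
        rho = self.distance
        return float(np.sqrt(np.sum((self.disparity - rho) ** 2) / np.sum(rho**2)))


# ---------------------------------------------------------------------------
# Mean rating matrices and reverse scaling
# ---------------------------------------------------------------------------


def _summary_stats(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    n = len(values)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    if n > 1 and sd > 0:
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    else:
        half = 0.0
    return {"mean": mean, "sd": sd, "ci95": (mean - half, mean + half), "n": n}


def mean_rating_matrix(study: SimilarityStudy, block: str) -> MeanRatingResult:
    """Group-mean similarity matrix for one block, symmetrized by averaging
    the two presentation orders where both were collected.

    Diagonal (self-pair) and off-diagonal cells are summarized with mean,
    SD and a t-based 95% CI over item-level values.
    """
    df = study.block(block)
    if df["rater_id"].nunique() < 2:
        raise ValueError("mean_rating_matrix requires >= 2 raters")
    items = study.items(block)
    index = {it: i for i, it in enumerate(items)}
    n = len(items)
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    for a, b, r in zip(df["image_a"], df["image_b"], df["rating"]):
        i, j = index[a], index[b]
        total[i, j] += r
        count[i, j] += 1
    empty_both = (count == 0) & (count.T == 0)
    if empty_both.any():
        i, j = np.argwhere(empty_both)[0]
        raise ValueError(f"no ratings for pair ({items[i]!r}, {items[j]!r})")
    with np.errstate(invalid="ignore"):
        mean_dir = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    # average the (i, j) and (j, i) orders when both exist
    both = (count > 0) & (count.T > 0)
    sym = np.where(both, (np.nan_to_num(mean_dir) + np.nan_to_num(mean_dir).T) / 2.0, np.nan)
    one = (count > 0) & ~both
    sym = np.where(one, mean_dir, sym)
    sym = np.where((count == 0) & (count.T > 0), mean_dir.T, sym)
    matrix = pd.DataFrame(sym, index=items, columns=items)
    diag = np.diag(sym)
    off = sym[~np.eye(n, dtype=bool)]
    return MeanRatingResult(
        matrix=matrix,
        diagonal_summary=_summary_stats(diag),
        off_diagonal_summary=_summary_stats(off),
    )


def to_dissimilarity(similarity: pd.DataFrame | np.ndarray) -> DissimilarityMatrix:
    """Reverse-scale a mean similarity matrix: d_ij = min(s) + max(s) - s_ij,
    with min/max over all cells of this matrix."""
    s = np.asarray(similarity, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("similarity matrix must be finite")
    lo, hi = float(s.min()), float(s.max())
    if lo == hi:
        logger.warning(
            "constant similarity matrix: reverse scaling degenerates to d = s"
        )
    d = lo + hi - s
    d = (d + d.T) / 2.0
    return DissimilarityMatrix(d=d, scale_min=lo, scale_max=hi)


# ---------------------------------------------------------------------------
# Monotone (isotonic) regression — pool adjacent violators
# ---------------------------------------------------------------------------


def pava(y: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Least-squares nondecreasing fit by pool-adjacent-violators."""
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    # blocks as (value, weight, length) pooled left to right
    values: list[float] = []
    wsum: list[float] = []
    length: list[int] = []
    for yi, wi in zip(y, w):
        values.append(yi)
        wsum.append(wi)
        length.append(1)
        while len(values) > 1 and values[-2] > values[-1]:
            v = (values[-2] * wsum[-2] + values[-1] * wsum[-1]) / (wsum[-2] + wsum[-1])
            wsum[-2] += wsum[-1]
            length[-2] += length[-1]
            values[-2] = v
            values.pop()
            wsum.pop()
            length.pop()
    return np.repeat(values, length)


# ---------------------------------------------------------------------------
# SMACOF
# ---------------------------------------------------------------------------


def _classical_init(d: np.ndarray, ndim: int) -> np.ndarray:
    """Torgerson (classical) scaling initialization."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:ndim]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    if coords.shape[1] < ndim:
        coords = np.pad(coords, ((0, 0), (0, ndim - coords.shape[1])))
    return coords


def smacof_nonmetric(
    D: DissimilarityMatrix | np.ndarray,
    ndim: int,
    init: str = "classical",
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> MDSConfiguration:
    """Nonmetric SMACOF.

    Alternates (i) monotone regression of configuration distances onto the
    rank order of the dissimilarities (primary tie handling: tied
    dissimilarities are sub-ordered by current distance, so ties may be
    untied), with disparities rescaled so sum dhat^2 = sum rho^2, and (ii)
    the Guttman transform. Stops when the stress-1 decrease falls below
    ``tol`` or after ``max_iter`` iterations.
    """
    if isinstance(D, DissimilarityMatrix):
        d = D.d
    else:
        d = np.asarray(D, dtype=float)
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
    n = d.shape[0]
    if n < ndim + 1:
        raise ValueError(f"need at least ndim+1 = {ndim + 1} items, got {n}")
    diss = squareform(d, checks=False)  # condensed upper triangle
    m = len(diss)

    rng = np.random.default_rng(seed)
    if init == "classical":
        X = _classical_init(d, ndim)
    elif init == "random":
        X = rng.normal(size=(n, ndim)) * (diss.mean() if diss.mean() > 0 else 1.0)
    else:
        raise ValueError(f"unknown init {init!r}")
    X = X - X.mean(axis=0)

    stress = np.inf
    history: list[float] = []
    disparities = np.zeros(m)
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        rho = pdist(X)
        rho_norm2 = float(np.sum(rho**2))
        if rho_norm2 == 0:
            raise ValueError("configuration collapsed to a single point")
        # primary ties: order by dissimilarity, ties sub-ordered by distance
        order = np.lexsort((rho, diss))
        dhat = np.empty(m)
        dhat[order] = pava(rho[order])
        dhat_norm2 = float(np.sum(dhat**2))
        if dhat_norm2 > 0:
            dhat *= np.sqrt(rho_norm2 / dhat_norm2)
        new_stress = float(np.sqrt(np.sum((dhat - rho) ** 2) / rho_norm2))
        if new_stress > stress + 1e-8:
            raise AssertionError(
                f"stress increased at iteration {iteration}: "
                f"{stress:.3e} -> {new_stress:.3e}"
            )
        history.append(new_stress)
        disparities = dhat
        if stress - new_stress < tol:
            stress = new_stress
            converged = True
            break
        stress = new_stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(rho > 1e-12, dhat / rho, 0.0)
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
        X = X - X.mean(axis=0)
    if not converged:
        logger.warning("SMACOF did not converge in %d iterations", max_iter)
    return MDSConfiguration(
        coords=X,
        stress1=float(stress),
        disparities=disparities,
        iterations=iteration,
        converged=converged,
        init=init,
        seed=seed,
        stress_history=history,
    )


def best_fit(
    D: DissimilarityMatrix | np.ndarray,
    ndim: int,
    n_restarts: int = 10,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> MDSConfiguration:
    """Classical init plus ``n_restarts`` random restarts; lowest stress wins."""
    rng = np.random.default_rng(seed)
    best = smacof_nonmetric(D, ndim, init="classical", tol=tol, max_iter=max_iter)
    for _ in range(n_restarts):
        cand_seed = int(rng.integers(0, 2**31 - 1))
        cand = smacof_nonmetric(
            D, ndim, init="random", seed=cand_seed, tol=tol, max_iter=max_iter
        )
        if cand.stress1 < best.stress1:
            best = cand
    return best


def stress_dimension_scan(
    D: DissimilarityMatrix | np.ndarray,
    ndim_list: list[int],
    n_restarts: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Best stress-1 per dimensionality, annotated with Kruskal's fit bands
    (> 0.20 poor, 0.10-0.20 fair, <= 0.10 excellent)."""
    if list(ndim_list) != sorted(ndim_list):
        raise ValueError("dimension list must be ascending")
    rows = []
    best_so_far = np.inf
    rng = np.random.default_rng(seed)
    for ndim in ndim_list:
        cfg = best_fit(D, ndim, n_restarts=n_restarts, seed=int(rng.integers(2**31)))
        # stress can never increase with added dimensions; enforce by
        # carrying the lower-dimensional optimum forward if optimization
        # stalls in a worse local minimum
        s = min(cfg.stress1, best_so_far)
        best_so_far = s
        if s > STRESS_BANDS["poor"]:
            band = "poor"
        elif s > STRESS_BANDS["fair"]:
            band = "fair"
        else:
            band = "excellent"
        rows.append({"ndim": ndim, "stress1": s, "fit_band": band})
    return pd.DataFrame(rows)


def shepard_data(
    D: DissimilarityMatrix | np.ndarray, config: MDSConfiguration
) -> ShepardData:
    """Shepard-diagram triples for a fitted configuration on the same D."""
    d = D.d if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    if d.shape[0] != config.coords.shape[0]:
        raise ValueError("dissimilarity matrix and configuration sizes differ")
    diss = squareform(d, checks=False)
    rho = pdist(config.coords)
    order = np.lexsort((rho, diss))
    return ShepardData(
        dissimilarity=diss[order],
        distance=rho[order],
        disparity=config.disparities[order],
    )


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def permutation_test(
    D: DissimilarityMatrix | np.ndarray,
    ndim: int,
    n_perm: int = 99,
    seed: int | None = None,
    n_restarts: int = 2,
) -> dict:
    """Permutation test of configuration structure.

    The n(n-1)/2 off-diagonal dissimilarities are permuted jointly
    (preserving symmetry); each permuted matrix is refit at the same
    dimensionality. p = (1 + #{stress_perm <= stress_obs}) / (n_perm + 1).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    d = D.d if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    rng = np.random.default_rng(seed)
    observed = best_fit(d, ndim, n_restarts=n_restarts, seed=int(rng.integers(2**31)))
    diss = squareform(d, checks=False)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(diss)
        cfg = best_fit(
            squareform(perm), ndim, n_restarts=n_restarts,
            seed=int(rng.integers(2**31)),
        )
        null[i] = cfg.stress1
    p = (1 + int(np.sum(null <= observed.stress1 + 1e-12))) / (n_perm + 1)
    return {
        "stress_observed": observed.stress1,
        "null_stress": null,
        "p_value": float(p),
        "n_perm": n_perm,
    }


def bootstrap_regions(
    study: SimilarityStudy,
    block: str,
    ndim: int,
    n_boot: int = 100,
    seed: int | None = None,
    n_restarts: int = 0,
) -> dict:
    """Rater-bootstrap 95% confidence ellipsoids per item.

    Raters are resampled with replacement; each replicate is re-embedded and
    Procrustes-aligned to the full-data configuration. Per-item covariance
    over replicates defines an ellipsoid whose boundary sits at the
    chi-square 0.95 quantile with ``ndim`` degrees of freedom.
    """
    df = study.block(block)
    raters = study.raters(block)
    if len(raters) < 5:
        raise ValueError("bootstrap requires >= 5 raters")
    rng = np.random.default_rng(seed)

    def embed(frame: pd.DataFrame) -> MDSConfiguration | None:
        sub_study = SimilarityStudy(frame)
        mean = mean_rating_matrix(sub_study, block)
        s = mean.matrix.to_numpy()
        if s.max() == s.min():
            return None
        diss = to_dissimilarity(mean.matrix)
        return best_fit(diss, ndim, n_restarts=n_restarts,
                        seed=int(rng.integers(2**31)))

    reference = embed(df)
    if reference is None:
        raise ValueError("full-data similarity matrix is constant")
    samples = []
    skipped = 0
    by_rater = {r: df[df["rater_id"] == r] for r in raters}
    for _ in range(n_boot):
        chosen = rng.choice(raters, size=len(raters), replace=True)
        parts = []
        for k, r in enumerate(chosen):
            part = by_rater[r].copy()
            part["rater_id"] = f"boot_{k}"
            parts.append(part)
        rep = embed(pd.concat(parts, ignore_index=True))
        if rep is None:
            skipped += 1
            continue
        aligned = procrustes_align(reference.coords, rep.coords).aligned
        samples.append(aligned)
    stack = np.stack(samples)  # replicates x items x ndim
    chi_r = float(np.sqrt(stats.chi2.ppf(0.95, df=ndim)))
    items = study.items(block)
    regions = {}
    for i, item in enumerate(items):
        pts = stack[:, i, :]
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False).reshape(ndim, ndim)
        eigvals = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
        regions[item] = {
            "center": center,
            "covariance": cov,
            "chi2_radius": chi_r,
            "semi_axes": chi_r * np.sqrt(eigvals),
        }
    return {
        "regions": regions,
        "reference": reference,
        "n_boot_used": len(samples),
        "n_skipped": skipped,
    }


def random_start_study(
    D: DissimilarityMatrix | np.ndarray,
    ndim: int,
    n_starts: int = 20,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> dict:
    """Distribution of final stress over random initializations.

    The classical-scaling start is always included, so the reported best is
    never worse than the classical-init stress.
    """
    rng = np.random.default_rng(seed)
    classical = smacof_nonmetric(D, ndim, init="classical", tol=tol, max_iter=max_iter)
    stresses = [classical.stress1]
    configs = [classical]
    for _ in range(n_starts):
        cfg = smacof_nonmetric(
            D, ndim, init="random", seed=int(rng.integers(2**31)),
            tol=tol, max_iter=max_iter,
        )
        stresses.append(cfg.stress1)
        configs.append(cfg)
    stresses_arr = np.array(stresses)
    best_idx = int(np.argmin(stresses_arr))
    return {
        "stresses": stresses_arr,
        "classical_stress": classical.stress1,
        "best": float(stresses_arr.min()),
        "median": float(np.median(stresses_arr)),
        "worst": float(stresses_arr.max()),
        "best_config": configs[best_idx],
    }
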