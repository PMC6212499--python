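"""Class-prior estimation and posterior calibration for PU-trained scores.

A classifier trained positive-vs-unlabeled produces scores whose
unlabeled distribution is a two-component mixture: a fraction ``alpha``
of true positives scored like the labeled positives, plus ``1 - alpha``
true negatives. This module estimates the mixture proportion from the
two score samples with a binned-likelihood scan (the AlphaMax family of
mixture-proportion estimators): the unlabeled histogram is modeled as
``alpha * f_pos + (1 - alpha) * f_neg`` with ``f_pos`` tied to the
labeled-positive histogram (both histograms are treated as samples and
fitted jointly, so positive-sample tail noise is not mistaken for
mixture evidence) and ``f_neg`` a free per-bin density. For every
candidate proportion on a grid, the likelihood is profiled over the
densities by alternating exact block maximizations; the
profile log-likelihood is flat up to the identifiable proportion and
falls off beyond it, and the estimate is taken at the elbow of that
curve — implemented as the largest candidate whose fit stays within a
fixed log-likelihood deficit of the saturated fit.

The symmetric run with roles reversed estimates ``beta``, the fraction
of mislabeled instances among the labeled positives. Scores are then
mapped to posterior probabilities of being a true positive,
``alpha * f_pos(s) / f_unl(s)`` per bin; the mean posterior over a
score population estimates its fraction of positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Log-likelihood deficit (nats) tolerated when locating the curve elbow.
DEFICIT_TOL = 3.0


@dataclass
class ScoreDensities:
    """Shared-binning score histograms for positives and unlabeled."""

    edges: np.ndarray
    pos: np.ndarray
    unl: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        self.unl = np.asarray(self.unl, dtype=float)
        n_bins = self.edges.size - 1
        if self.pos.size != n_bins or self.unl.size != n_bins:
            raise ValueError("densities must have one value per bin")
        for name, d in (("pos", self.pos), ("unl", self.unl)):
            if not np.isclose(d.sum(), 1.0):
                raise ValueError(f"{name} density must sum to 1 over bins")


@dataclass
class PriorEstimate:
    """Mixture-proportion estimates with likelihood-curve diagnostics."""

    alpha: float
    grid: np.ndarray
    curve: np.ndarray
    densities: Optional[ScoreDensities] = None
    beta: Optional[float] = None
    unstable: bool = False


def _bin_counts(scores: np.ndarray, edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(scores, bins=edges)
    return counts.astype(float)


def _profile_loglik(counts: np.ndarray, known: np.ndarray, weight: float) -> float:
    """Maximize sum(counts * log(weight*known + (1-weight)*q)) over simplex q.

    KKT water-filling: active bins satisfy q_b = counts_b/mu - weight*known_b
    / (1-weight); mu is found by bisection on the simplex constraint.
    """
    N = counts.sum()
    if N == 0:
        raise ValueError("empty score histogram")
    nz = counts > 0
    if weight <= 0.0:
        return float(np.sum(counts[nz] * np.log(counts[nz] / N)))
    if weight >= 1.0:
        if np.any(known[nz] <= 0):
            return -np.inf
        return float(np.sum(counts[nz] * np.log(known[nz])))
    ratio = weight * known / (1.0 - weight)
    lo, hi = 1e-12, 2.0 * N
    for _ in range(100):
        mu = 0.5 * (lo + hi)
        if np.sum(np.maximum(0.0, counts / mu - ratio)) > 1.0:
            lo = mu
        else:
            hi = mu
    q = np.maximum(0.0, counts / (0.5 * (lo + hi)) - ratio)
    total = q.sum()
    if total > 0:
        q /= total
    dens = weight * known + (1.0 - weight) * q
    if np.any(dens[nz] <= 0):
        return -np.inf
    return float(np.sum(counts[nz] * np.log(dens[nz])))


def _joint_profile_loglik(
    m: np.ndarray,
    n: np.ndarray,
    w: float,
    f0: Optional[np.ndarray] = None,
    q0: Optional[np.ndarray] = None,
    max_iter: int = 60,
    atol: float = 1e-4,
) -> tuple:
    """Profile log-likelihood of mixture weight ``w`` treating both
    histograms as samples; returns (loglik, f, q) for warm starts.

    Maximizes ``sum(m*log f) + sum(n*log(w*f + (1-w)*q))`` over simplex
    densities ``f`` (positives) and ``q`` (negatives) by alternating
    exact block maximizations (the objective is jointly concave). Fitting
    ``f`` jointly, rather than plugging in the raw positive histogram,
    keeps singleton tail bins of the positive sample from masquerading
    as evidence against large mixture weights.
    """
    M, N = m.sum(), n.sum()
    if M == 0 or N == 0:
        raise ValueError("empty score histogram")
    mz, nz = m > 0, n > 0
    if w <= 0.0:
        L = float(np.sum(m[mz] * np.log(m[mz] / M)) + np.sum(n[nz] * np.log(n[nz] / N)))
        return L, m / M, n / N
    if w >= 1.0:
        t = m + n
        f = t / t.sum()
        L = float(np.sum(t[t > 0] * np.log(f[t > 0])))
        return L, f, n / N

    f = m / M if f0 is None else f0.copy()
    q = n / N if q0 is None else q0.copy()

    def q_step(f_cur: np.ndarray) -> np.ndarray:
        # water-filling: active bins satisfy q_b = n_b/mu - w f_b/(1-w)
        ratio = w * f_cur / (1.0 - w)
        lo, hi = 1e-12, 2.0 * N
        for _ in range(60):
            mu = 0.5 * (lo + hi)
            if np.sum(np.maximum(0.0, n / mu - ratio)) > 1.0:
                lo = mu
            else:
                hi = mu
        qq = np.maximum(0.0, n / (0.5 * (lo + hi)) - ratio)
        s = qq.sum()
        return qq / s if s > 0 else qq

    def f_step(q_cur: np.ndarray) -> np.ndarray:
        # per-bin KKT condition is quadratic in f_b; mu found by bisection
        c = (1.0 - w) * q_cur

        def f_of(mu: float) -> np.ndarray:
            b = mu * c - (m + n) * w
            disc = b * b + 4.0 * mu * w * m * c
            return np.maximum((-b + np.sqrt(disc)) / (2.0 * mu * w), 0.0)

        lo, hi = 1e-12, 2.0 * (M + N)
        for _ in range(60):
            mu = 0.5 * (lo + hi)
            if f_of(mu).sum() > 1.0:
                lo = mu
            else:
                hi = mu
        ff = f_of(0.5 * (lo + hi))
        s = ff.sum()
        return ff / s if s > 0 else ff

    def objective(f_cur: np.ndarray, q_cur: np.ndarray) -> float:
        dens = w * f_cur + (1.0 - w) * q_cur
        if np.any(f_cur[mz] <= 0) or np.any(dens[nz] <= 0):
            return -np.inf
        return float(np.sum(m[mz] * np.log(f_cur[mz])) + np.sum(n[nz] * np.log(dens[nz])))

    prev = objective(f, q)
    for _ in range(max_iter):
        q = q_step(f)
        f = f_step(q)
        cur = objective(f, q)
        if np.isfinite(cur) and np.isfinite(prev) and abs(cur - prev) <= atol:
            prev = cur
            break
        prev = cur
    return prev, f, q


def _profile_curve(cpos: np.ndarray, cunl: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Joint profile log-likelihood along the grid (warm-started)."""
    curve = np.empty(grid.size)
    f = q = None
    for i, w in enumerate(grid):
        curve[i], f, q = _joint_profile_loglik(cpos, cunl, float(w), f, q)
    return curve


def _elbow(grid: np.ndarray, curve: np.ndarray, tol: float = DEFICIT_TOL) -> float:
    """Elbow of the profile-likelihood curve: the curve is flat (within
    noise) up to the identifiable proportion and falls beyond it, so the
    estimate is the largest grid point whose deficit from the maximum
    stays within ``tol`` nats."""
    deficit = np.nanmax(curve[np.isfinite(curve)]) - curve
    deficit[~np.isfinite(curve)] = np.inf
    ok = np.flatnonzero(deficit <= tol)
    return float(grid[ok[-1]])


def _indistinguishable(cpos: np.ndarray, cunl: np.ndarray, curve: np.ndarray) -> bool:
    """True when the full-weight fit is consistent with two-sample
    multinomial noise: the likelihood-ratio deficit at weight 1 stays
    below a chi-square bound on the occupied bins. The mixture
    proportion is then unidentifiable at the upper boundary."""
    from scipy.stats import chi2

    finite = np.isfinite(curve)
    if not finite.any() or not np.isfinite(curve[-1]):
        return False
    end_deficit = curve[finite].max() - curve[-1]
    dof = max(int(np.count_nonzero((cpos + cunl) > 0)) - 1, 1)
    return bool(2.0 * end_deficit <= chi2.ppf(0.999, dof))


def _validate_scores(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError(f"{name} score vector is empty")
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError(f"{name} scores must lie in [0, 1]")
    return x


def estimate_alpha(
    pos_scores: np.ndarray,
    unl_scores: np.ndarray,
    n_bins: int = 50,
    grid_step: float = 0.01,
) -> PriorEstimate:
    """Estimate the fraction of true positives hidden in the unlabeled set.

    Fewer than 50 scores on either side flags the estimate unstable, as
    does a flat likelihood curve (unidentifiable mixture).
    """
    pos_scores = _validate_scores(pos_scores, "positive")
    unl_scores = _validate_scores(unl_scores, "unlabeled")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    cpos = _bin_counts(pos_scores, edges)
    cunl = _bin_counts(unl_scores, edges)
    f_pos = cpos / cpos.sum()
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    curve = _profile_curve(cpos, cunl, grid)
    if _indistinguishable(cpos, cunl, curve):
        alpha, unstable = float(grid[-1]), True
    else:
        alpha = _elbow(grid, curve)
        unstable = False
    unstable = unstable or pos_scores.size < 50 or unl_scores.size < 50
    densities = ScoreDensities(edges, f_pos, cunl / cunl.sum())
    return PriorEstimate(alpha, grid, curve, densities, unstable=unstable)


def recover_negative_density(densities: ScoreDensities, alpha: float) -> np.ndarray:
    """Per-bin negative density implied by the mixture: clip((f_unl − α·f_pos)/(1−α))."""
    if alpha >= 0.99:
        raise ValueError("alpha too close to 1: negative density unrecoverable")
    q = np.maximum(0.0, (densities.unl - alpha * densities.pos) / (1.0 - alpha))
    total = q.sum()
    if total == 0:
        raise ValueError("recovered negative density is identically zero")
    return q / total


def estimate_beta(
    pos_scores: np.ndarray,
    unl_scores: np.ndarray,
    alpha: float,
    n_bins: int = 50,
    grid_step: float = 0.01,
) -> PriorEstimate:
    """Estimate the mislabeled fraction among the labeled positives.

    Symmetric AlphaMax run: the labeled-positive histogram is modeled as
    ``(1 − β)·f_truepos + β·f_neg`` with the negative density recovered
    from the unlabeled mixture at the given ``alpha`` and the true
    positive density free.
    """
    pos_scores = _validate_scores(pos_scores, "positive")
    unl_scores = _validate_scores(unl_scores, "unlabeled")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    cpos = _bin_counts(pos_scores, edges)
    cunl = _bin_counts(unl_scores, edges)
    densities = ScoreDensities(edges, cpos / cpos.sum(), cunl / cunl.sum())
    f_neg = recover_negative_density(densities, alpha)
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    curve = np.array([_profile_loglik(cpos, f_neg, w) for w in grid])
    beta = _elbow(grid, curve)
    unstable = pos_scores.size < 50 or unl_scores.size < 50
    return PriorEstimate(alpha, grid, curve, densities, beta=beta, unstable=unstable)


def posterior_transform(
    scores: np.ndarray, alpha: float, densities: ScoreDensities
) -> np.ndarray:
    """Map scores to posterior probabilities of being a true positive.

    Per bin the posterior is ``alpha * f_pos / f_unl`` clipped to [0, 1];
    a query falling in a bin with no unlabeled mass borrows the nearest
    non-empty bin. The mean of the returned vector estimates the
    fraction of positives in the scored population.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    n_bins = densities.unl.size
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = alpha * densities.pos / densities.unl
    nonempty = densities.unl > 0
    if not nonempty.any():
        raise ValueError("unlabeled density is empty")
    # nearest non-empty bin fallback
    idx_nonempty = np.flatnonzero(nonempty)
    for b in np.flatnonzero(~nonempty):
        nearest = idx_nonempty[np.argmin(np.abs(idx_nonempty - b))]
        ratio[b] = ratio[nearest]
    ratio = np.clip(ratio, 0.0, 1.0)
    bins = np.clip(np.digitize(scores, densities.edges[1:-1], right=False), 0, n_bins - 1)
    return ratio[bins]
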