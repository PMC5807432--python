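"""Nonparametric cluster-mass permutation inference (Maris-Oostenveld style).

Observed statistic maps (pointwise one-sample t on per-subject condition
differences) are thresholded at the two-tailed critical t; contiguous
suprathreshold regions of uniform sign become clusters whose mass is the sum
of member t-values.  The null distribution collects, per permutation, the
maximum absolute cluster mass over the whole (sign-flipped) map, pooling the
positive and negative tails into a single max-|mass| null.  The Monte Carlo
p-value of an observed cluster is the fraction of permutations whose maximum
mass is strictly larger in magnitude.

For paired designs, independently swapping (or not) each subject's pair of
condition maps — the constrained label shuffle in which no subject's two maps
ever land in the same condition — is identical to randomly negating that
subject's difference map, so both the time-domain (sign-flip) and the
time-frequency (label-shuffle) tests share one sign-flip core and agree
permutation-for-permutation under the same seed.

Two-dimensional per-subject time-frequency maps are smoothed with a discrete
5x5 Gaussian (sigma = 2 pixels, unit-sum kernel, reflect padding) *before*
statistics; t-maps are never smoothed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .phase_locking import PhaseLockingMap
from .preproc import ContrastWave


@dataclass
class PermutationConfig:
    """Settings of the cluster permutation machinery.

    ``alpha_crit`` forms the cluster threshold on the t-map; ``cluster_alpha``
    is the significance level applied to cluster Monte Carlo p-values.  With
    ``exhaustive`` all 2^n sign patterns are enumerated instead of sampled
    (feasible for small cohorts, and then equal to the exact permutation
    test).  ``plus_one`` switches the p-value from the strict-larger k/n rule
    to the positively biased (k+1)/(n+1) estimator.
    """

    n_permutations: int = 5000
    alpha_crit: float = 0.05
    cluster_alpha: float = 0.05
    connectivity: str = "4"  # "4" or "8" neighbors for 2D maps
    smoothing_kernel: int = 5
    smoothing_sigma: float = 2.0
    seed: int = 0
    exhaustive: bool = False
    plus_one: bool = False

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        for a in (self.alpha_crit, self.cluster_alpha):
            if not (0 < a < 1):
                raise ValueError("alpha values must lie in (0, 1)")
        if self.connectivity not in ("4", "8"):
            raise ValueError("connectivity must be '4' or '8'")


@dataclass
class StatMap:
    """Pointwise t-statistics (1D time series or 2D frequency-by-time map)."""

    t_values: np.ndarray
    df: int
    times: np.ndarray | None = None
    freqs: np.ndarray | None = None

    def __post_init__(self):
        self.t_values = np.asarray(self.t_values, float)
        if not np.all(np.isfinite(self.t_values)):
            raise ValueError("non-finite t-values")


@dataclass
class Cluster:
    """A contiguous suprathreshold region with summed-t mass."""

    indices: tuple[np.ndarray, ...]  # per-axis member indices (np.nonzero style)
    sign: int  # +1 or -1
    mass: float
    p: float | None = None

    @property
    def size(self) -> int:
        return int(self.indices[0].size)

    def centroid(self) -> tuple[float, ...]:
        """Unweighted mean position of the member points, in index units."""
        return tuple(float(ix.mean()) for ix in self.indices)


def _t_from_diffs(diffs: np.ndarray) -> np.ndarray:
    """One-sample t over the first axis; zero-variance points get t = 0."""
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    var = diffs.var(axis=0, ddof=1)
    t = np.zeros_like(m)
    ok = var > 0
    t[ok] = m[ok] / np.sqrt(var[ok] / n)
    return t


def paired_t_map(maps_a, maps_b) -> StatMap:
    """Pointwise paired t between two aligned sets of per-subject maps.

    Accepts lists of PhaseLockingMap (aligned axes enforced) or plain
    arrays stacked with subjects on the first axis.  df = n_subjects - 1.
    """
    a, axes = _stack_maps(maps_a)
    b, axes_b = _stack_maps(maps_b)
    if a.shape != b.shape:
        raise ValueError(f"map stacks are misaligned: {a.shape} vs {b.shape}")
    if axes is not None and axes_b is not None:
        if not (np.array_equal(axes[0], axes_b[0]) and np.allclose(axes[1], axes_b[1])):
            raise ValueError("frequency/time axes of the two map sets do not match")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    t = _t_from_diffs(a - b)
    freqs, times = axes if axes is not None else (None, None)
    return StatMap(t_values=t, df=n - 1, times=times, freqs=freqs)


def _stack_maps(maps) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray] | None]:
    if isinstance(maps, np.ndarray):
        return np.asarray(maps, float), None
    first = maps[0]
    if isinstance(first, PhaseLockingMap):
        ref_f, ref_t = first.freqs, first.times
        for m in maps[1:]:
            if not (np.array_equal(m.freqs, ref_f) and np.allclose(m.times, ref_t)):
                raise ValueError("per-subject maps have misaligned axes")
        arr = np.stack([np.where(m.mask, 0.0, m.values) for m in maps])
        return arr, (ref_f, ref_t)
    return np.stack([np.asarray(m, float) for m in maps]), None


def cluster_forming_threshold(alpha: float, df: int, two_tailed: bool = True) -> float:
    """Critical t of Student's distribution used to form clusters."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    if df < 1:
        raise ValueError("df must be >= 1")
    if alpha == 1.0:
        return 0.0
    q = 1 - alpha / 2 if two_tailed else 1 - alpha
    return float(stats.t.ppf(q, df))


def gaussian_kernel(size: int = 5, sigma: float = 2.0) -> np.ndarray:
    """Discrete, unit-sum 2D Gaussian kernel of odd ``size``."""
    if size % 2 != 1 or size < 1:
        raise ValueError("kernel size must be a positive odd integer")
    x = np.arange(size) - size // 2
    g = np.exp(-(x ** 2) / (2 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def smooth_map(values: np.ndarray, kernel_size: int = 5, sigma: float = 2.0) -> np.ndarray:
    """Gaussian image smoothing with reflect padding at the borders."""
    values = np.asarray(values, float)
    if values.ndim != 2:
        raise ValueError("smooth_map expects a 2D map")
    if min(values.shape) < kernel_size:
        raise ValueError(
            f"map of shape {values.shape} is smaller than the {kernel_size}x{kernel_size} kernel"
        )
    return ndimage.correlate(values, gaussian_kernel(kernel_size, sigma), mode="reflect")


def _label_structure(ndim: int, connectivity: str) -> np.ndarray:
    if ndim == 1:
        return np.ones(3, dtype=int)
    if connectivity == "4":
        return ndimage.generate_binary_structure(2, 1)
    return ndimage.generate_binary_structure(2, 2)


def find_clusters(stat_map: StatMap | np.ndarray, threshold: float,
                  connectivity: str = "4") -> list[Cluster]:
    """Maximal connected components of t > +threshold and t < -threshold.

    Positive and negative clusters are formed separately; for 2D maps the
    default contiguity is 4-neighbor (no diagonals).
    """
    t = stat_map.t_values if isinstance(stat_map, StatMap) else np.asarray(stat_map, float)
    if threshold <= 0 and threshold != 0.0:
        raise ValueError("threshold must be nonnegative")
    structure = _label_structure(t.ndim, connectivity)
    clusters: list[Cluster] = []
    for sign in (1, -1):
        supra = t > threshold if sign == 1 else t < -threshold
        labelled, n = ndimage.label(supra, structure=structure)
        for k in range(1, n + 1):
            idx = np.nonzero(labelled == k)
            clusters.append(Cluster(indices=idx, sign=sign, mass=float(t[idx].sum())))
    return clusters


def monte_carlo_p(observed_mass: float, null_max_masses: np.ndarray,
                  plus_one: bool = False) -> float:
    """Fraction of null maxima strictly larger in magnitude than the observed mass.

    With the strict rule the smallest attainable p is exactly 0 (no permuted
    data set produced a larger cluster); ``plus_one`` gives the (k+1)/(n+1)
    estimator whose minimum is 1/(n+1).
    """
    null = np.asarray(null_max_masses, float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    # ties at floating-point roundoff (e.g. the identity permutation) are not
    # "larger"; compare with a tiny relative tolerance
    m = abs(observed_mass)
    k = int(np.sum(null > m + 1e-9 * max(1.0, m)))
    if plus_one:
        return (k + 1) / (null.size + 1)
    return k / null.size


def _sign_matrix(n_subjects: int, config: PermutationConfig) -> np.ndarray:
    if config.exhaustive:
        if n_subjects > 20:
            raise ValueError("exhaustive enumeration is limited to <= 20 subjects")
        return np.array(list(itertools.product((1.0, -1.0), repeat=n_subjects)))
    rng = np.random.default_rng(config.seed)
    return rng.choice([1.0, -1.0], size=(config.n_permutations, n_subjects))


def _null_max_masses(diffs2d: np.ndarray, shape: tuple[int, ...], threshold: float,
                     connectivity: str, signs: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Max |cluster mass| per sign-flip permutation, fully vectorized t-maps.

    For sign flips s_i in {-1, +1}, sum d_i^2 is invariant, so the permuted
    t-map is a pure function of the permuted mean: t = m / sqrt((ss/n - m^2)
    * n / (n-1) / n), computed for a whole block of permutations with one
    matrix product.
    """
    n, k = diffs2d.shape
    sumsq = (diffs2d ** 2).sum(axis=0)
    maxima = np.empty(signs.shape[0])
    structure = _label_structure(len(shape), connectivity)
    for start in range(0, signs.shape[0], chunk):
        block = signs[start:start + chunk]
        m = block @ diffs2d / n  # perms x points
        var = (sumsq[None, :] - n * m ** 2) / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(var > 0, m / np.sqrt(var / n), 0.0)
        for j in range(t.shape[0]):
            tm = t[j].reshape(shape)
            best = 0.0
            for sign in (1, -1):
                supra = tm > threshold if sign == 1 else tm < -threshold
                labelled, nlab = ndimage.label(supra, structure=structure)
                if nlab:
                    sums = ndimage.sum_labels(tm, labelled, index=np.arange(1, nlab + 1))
                    best = max(best, float(np.abs(sums).max()))
            maxima[start + j] = best
    return maxima


def _cluster_permutation_core(diffs: np.ndarray, config: PermutationConfig) -> list[Cluster]:
    """Shared engine: observed clusters + sign-flip max-|mass| null + p-values."""
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for a permutation test")
    shape = diffs.shape[1:]
    df = n - 1
    threshold = cluster_forming_threshold(config.alpha_crit, df)
    t_obs = _t_from_diffs(diffs)
    clusters = find_clusters(t_obs, threshold, config.connectivity)
    if not clusters:
        return []
    signs = _sign_matrix(n, config)
    null = _null_max_masses(diffs.reshape(n, -1), shape, threshold, config.connectivity, signs)
    for cl in clusters:
        cl.p = monte_carlo_p(cl.mass, null, plus_one=config.plus_one)
    return sorted(clusters, key=lambda c: abs(c.mass), reverse=True)


def permutation_test_time(contrast_waves, config: PermutationConfig) -> list[Cluster]:
    """Sign-flip cluster test on per-subject 1D contrast waves.

    ``contrast_waves`` is a list of ContrastWave (one per subject, one ROI)
    or an array of shape (subjects, samples).  Each observed cluster receives
    a Monte Carlo p; clusters with p <= cluster_alpha are significant.
    """
    if isinstance(contrast_waves, np.ndarray):
        diffs = np.asarray(contrast_waves, float)
    else:
        arrs = []
        for w in contrast_waves:
            arrs.append(w.values if isinstance(w, ContrastWave) else np.asarray(w, float))
        lengths = {a.shape[-1] for a in arrs}
        if len(lengths) != 1:
            raise ValueError("contrast waves have unequal lengths")
        diffs = np.stack(arrs)
    if diffs.ndim != 2:
        raise ValueError("expected (subjects, samples) contrast waves")
    return _cluster_permutation_core(diffs, config)


def permutation_test_tf(maps_a, maps_b, config: PermutationConfig,
                        smooth: bool = True) -> list[Cluster]:
    """Constrained label-shuffle cluster test on paired 2D phase-locking maps.

    Per-subject maps are Gaussian-smoothed first; the null is built by
    independently swapping (or not) each subject's (A, B) pair, implemented
    as a sign flip of the subject's difference map (the two constructions are
    identical, see the module docstring).
    """
    a, _ = _stack_maps(maps_a)
    b, _ = _stack_maps(maps_b)
    if a.shape != b.shape:
        raise ValueError(f"unpaired subjects or misaligned maps: {a.shape} vs {b.shape}")
    if a.ndim != 3:
        raise ValueError("expected (subjects, freqs, times) map stacks")
    if smooth:
        a = np.stack([smooth_map(m, config.smoothing_kernel, config.smoothing_sigma) for m in a])
        b = np.stack([smooth_map(m, config.smoothing_kernel, config.smoothing_sigma) for m in b])
    return _cluster_permutation_core(a - b, config)


def significant(clusters: list[Cluster], alpha: float = 0.05) -> list[Cluster]:
    """Clusters whose Monte Carlo p is at or below alpha."""
    return [c for c in clusters if c.p is not None and c.p <= alpha]
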