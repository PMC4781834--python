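"""Statistical assessment of averaged connectivity and cluster significance.

Three ingredients decide whether an extracted cluster is a significant
sub-network:

1. a voxel-pair one-sample t-test on the per-subject thresholded CC values,
   summarized as a *lower envelope* of the t-vs-meanCC scatter: the envelope
   maps a cluster's minimum internal mean CC to an upper limit on the
   voxel-wise p-value;
2. a Monte-Carlo simulation of smoothed Gaussian noise on the analysis mask
   (the classic cluster-extent / "AlphaSim" construction): for a voxel-wise p,
   the smallest cluster extent S_min whose family-wise probability of
   occurring anywhere in the mask is <= alpha;
3. the decision rule: a cluster of size S with minimum internal mean CC c is
   significant iff S >= max(size_floor, S_min(c)) — by default FWER p <= 0.01
   with an extent floor of 12 voxels.

Split-half utilities support variability analysis of the group-averaged matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps

from .connectivity import CCMatrix, MeanCCMatrix, group_average
from .volumes import GrayMask

__all__ = [
    "SignificanceConfig",
    "Envelope",
    "FWERCurve",
    "pair_t_test",
    "moments",
    "lower_envelope",
    "cluster_size_threshold",
    "fwer_curve",
    "is_significant",
    "split_half",
    "null_cc_tail",
    "null_mean_cc_tail",
    "analytic_envelope",
]

_STRUCTURES = {
    "faces": ndimage.generate_binary_structure(3, 1),
    "faces+edges": ndimage.generate_binary_structure(3, 2),
    "faces+edges+corners": ndimage.generate_binary_structure(3, 3),
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SignificanceConfig:
    """FWER control parameters.

    ``n_iterations`` defaults to a desk-scale 10^4 (large-scale analyses use
    10^6; the S_min confidence band widens accordingly).  ``connectivity_rule``
    names the voxel adjacency used to form clusters; face adjacency is the most
    conservative standard choice.
    """

    alpha_fwer: float = 0.01
    size_floor: int = 12
    n_iterations: int = 10_000
    connectivity_rule: str = "faces"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha_fwer < 1:
            raise ValueError("alpha_fwer must lie in (0, 1)")
        if self.size_floor < 1 or self.n_iterations < 1:
            raise ValueError("size_floor and n_iterations must be >= 1")
        if self.connectivity_rule not in _STRUCTURES:
            raise ValueError(f"unknown connectivity_rule {self.connectivity_rule!r}")


def pair_t_test(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t against 0 per voxel pair over the subject axis.

    ``stack`` is (n_subjects, n_pairs) of thresholded CC values.  Returns
    (t, p) with df = n_subjects - 1 and two-sided p; zero-variance pairs get
    t = +/-inf (p = 0) when their mean is nonzero and t = 0 (p = 1) otherwise.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim == 1:
        stack = stack[:, None]
    n = stack.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    t = np.empty_like(mean)
    zero_sd = sd < 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        t[~zero_sd] = mean[~zero_sd] / (sd[~zero_sd] / np.sqrt(n))
    t[zero_sd & (mean != 0)] = np.sign(mean[zero_sd & (mean != 0)]) * np.inf
    t[zero_sd & (mean == 0)] = 0.0
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    return t, p


def moments(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample skewness and Fisher excess kurtosis per voxel pair.

    Conventions: third/fourth standardized central moments without bias
    correction; a normal sample has skewness ~ 0 and kurtosis ~ 0.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim == 1:
        stack = stack[:, None]
    if stack.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if np.any(stack.std(axis=0) < 1e-300):
        raise ValueError("zero variance: moments are undefined")
    skew = sps.skew(stack, axis=0, bias=True)
    kurt = sps.kurtosis(stack, axis=0, fisher=True, bias=True)
    return skew, kurt


@dataclass
class Envelope:
    """Monotone map from minimum mean CC to a voxel-wise p upper limit.

    Built from the lower boundary of the t-vs-CC scatter: minimum t per
    equal-width CC bin, made non-decreasing across bins, then converted to a
    one-sided p at df degrees of freedom.
    """

    cc_centers: np.ndarray
    t_min: np.ndarray
    p: np.ndarray
    df: int

    def p_at(self, cc: float) -> float:
        """Voxel-wise p upper limit at a given minimum CC (step lookup,
        clamped to the envelope's domain)."""
        idx = int(np.clip(np.searchsorted(self.cc_centers, cc, side="right") - 1, 0, len(self.p) - 1))
        return float(self.p[idx])


def lower_envelope(t_values: np.ndarray, cc_values: np.ndarray, bin_width: float = 0.01, df: int = 1) -> Envelope:
    """Lower boundary of the t-vs-meanCC scatter as a monotone envelope."""
    t_values = np.asarray(t_values, dtype=np.float64)
    cc_values = np.asarray(cc_values, dtype=np.float64)
    if t_values.size == 0 or t_values.shape != cc_values.shape:
        raise ValueError("need matching, nonempty t and cc arrays")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(cc_values.min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((cc_values.max() - lo) / bin_width + 1e-9)))
    edges = lo + np.arange(n_bins + 1) * bin_width
    which = np.clip(np.digitize(cc_values, edges) - 1, 0, n_bins - 1)
    centers_all = edges[:-1] + bin_width / 2
    centers, tmins = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            centers.append(centers_all[b])
            tmins.append(t_values[sel].min())
    tmins = np.maximum.accumulate(np.asarray(tmins))  # isotonic: t rises with CC
    centers = np.asarray(centers)
    p = sps.t.sf(tmins, df=df)
    return Envelope(cc_centers=centers, t_min=tmins, p=p, df=df)


def _max_cluster_sizes(
    mask: GrayMask,
    fwhm_mm: float,
    z_thresholds: np.ndarray,
    n_iterations: int,
    seed: int,
    connectivity_rule: str = "faces",
) -> np.ndarray:
    """Monte-Carlo null distribution of the maximum supra-threshold cluster size.

    Each iteration draws white Gaussian noise on the mask's bounding grid,
    smooths it to ``fwhm_mm``, standardizes over in-mask voxels, thresholds at
    each z, and records the largest connected cluster inside the mask.
    Returns (n_iterations, n_thresholds) of max sizes.
    """
    from scipy.ndimage import gaussian_filter

    structure = _STRUCTURES[connectivity_rule]
    m = mask.data
    if m.sum() < 2:
        raise ValueError("mask too small for cluster simulation")
    sigma_vox = None
    if fwhm_mm > 0:
        sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / mask.voxel_size_mm
    rng = np.random.default_rng(seed)
    z_thresholds = np.atleast_1d(np.asarray(z_thresholds, dtype=np.float64))
    out = np.zeros((n_iterations, z_thresholds.size), dtype=np.int64)
    for it in range(n_iterations):
        field = rng.standard_normal(m.shape)
        if sigma_vox is not None:
            field = gaussian_filter(field, sigma=sigma_vox)
        vals = field[m]
        field = (field - vals.mean()) / vals.std()
        for zi, z in enumerate(z_thresholds):
            supra = (field >= z) & m
            if not supra.any():
                continue
            labels, n_lab = ndimage.label(supra, structure=structure)
            if n_lab:
                out[it, zi] = np.bincount(labels.ravel())[1:].max()
    return out


def _smin_from_max_sizes(max_sizes: np.ndarray, alpha: float) -> int:
    """Smallest s with P(max cluster >= s) <= alpha, estimated from samples."""
    if alpha >= 1:
        return 1
    n = len(max_sizes)
    srt = np.sort(max_sizes)
    for s in range(1, int(srt[-1]) + 2):
        frac = (n - np.searchsorted(srt, s, side="left")) / n
        if frac <= alpha:
            return s
    return int(srt[-1]) + 1


def cluster_size_threshold(
    mask: GrayMask, voxel_p: float, fwhm_mm: float, cfg: SignificanceConfig
) -> int:
    """Minimum cluster extent guaranteeing FWER <= alpha at a voxel-wise p."""
    cfg.validate()
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must lie in (0, 1)")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if cfg.alpha_fwer >= 1:
        return 1
    z = sps.norm.isf(voxel_p)
    sizes = _max_cluster_sizes(
        mask, fwhm_mm, np.array([z]), cfg.n_iterations, cfg.seed, cfg.connectivity_rule
    )[:, 0]
    return _smin_from_max_sizes(sizes, cfg.alpha_fwer)


@dataclass
class FWERCurve:
    """Minimum cluster size for FWER <= alpha as a function of minimum CC.

    ``s_min`` is non-increasing along the (increasing) ``min_cc`` grid.
    ``provenance`` records mask hash, fwhm, alpha, iteration count and seed.
    """

    min_cc: np.ndarray
    s_min: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.min_cc = np.asarray(self.min_cc, dtype=np.float64)
        self.s_min = np.asarray(self.s_min, dtype=np.int64)
        if np.any(np.diff(self.min_cc) <= 0):
            raise ValueError("min_cc grid must be strictly increasing")
        if np.any(self.s_min < 1) or np.any(np.diff(self.s_min) > 0):
            raise ValueError("s_min must be >= 1 and non-increasing in min_cc")

    def covers(self, cc: float) -> bool:
        return cc >= self.min_cc[0]

    def required_size(self, cc: float) -> int:
        """S_min at a cluster's minimum CC (conservative step lookup: the
        nearest grid point at or below cc)."""
        if not self.covers(cc):
            raise ValueError(f"min CC {cc} below the curve's domain")
        idx = int(np.searchsorted(self.min_cc, cc, side="right") - 1)
        return int(self.s_min[idx])


def fwer_curve(
    mask: GrayMask,
    envelope: Envelope,
    fwhm_mm: float,
    cfg: SignificanceConfig,
    cc_grid: np.ndarray,
) -> FWERCurve:
    """FWER cluster-extent curve over a grid of minimum CC values.

    All grid points share one simulation run (one noise field per iteration,
    thresholded at each grid point's z), so the curve is internally consistent;
    monotonicity is enforced with a running minimum.
    """
    cfg.validate()
    cc_grid = np.asarray(cc_grid, dtype=np.float64)
    ps = np.array([envelope.p_at(c) for c in cc_grid])
    ps = np.clip(ps, 1e-300, 1 - 1e-12)
    zs = sps.norm.isf(ps)
    sizes = _max_cluster_sizes(
        mask, fwhm_mm, zs, cfg.n_iterations, cfg.seed, cfg.connectivity_rule
    )
    s_min = np.array(
        [_smin_from_max_sizes(sizes[:, i], cfg.alpha_fwer) for i in range(len(cc_grid))]
    )
    s_min = np.minimum.accumulate(s_min)
    prov = {
        "mask_hash": mask.ordering_hash(),
        "fwhm_mm": float(fwhm_mm),
        "alpha": cfg.alpha_fwer,
        "n_iterations": cfg.n_iterations,
        "seed": cfg.seed,
    }
    return FWERCurve(min_cc=cc_grid, s_min=s_min, provenance=prov)


def is_significant(cluster: tuple[int, float], curve: FWERCurve, cfg: SignificanceConfig) -> bool:
    """Significance decision for a cluster (size S, minimum internal mean CC).

    True iff S >= max(size_floor, curve(min_CC)); clusters whose minimum CC
    falls below the curve's domain are not significant.
    """
    size, min_cc = cluster
    if not np.isfinite(min_cc) or not curve.covers(min_cc):
        return False
    return size >= max(cfg.size_floor, curve.required_size(min_cc))


def split_half(ccs: list[CCMatrix], seed: int) -> tuple[MeanCCMatrix, MeanCCMatrix]:
    """Seeded pseudorandom equal split of the subject list, averaged per half."""
    n = len(ccs)
    if n < 6:
        raise ValueError("need at least 6 subjects to split")
    if n % 2:
        raise ValueError("subject count must be even")
    perm = np.random.default_rng(seed).permutation(n)
    half = n // 2
    a = group_average([ccs[i] for i in perm[:half]])
    b = group_average([ccs[i] for i in perm[half:]])
    return a, b


def null_cc_tail(tau: float, n_timepoints: int) -> float:
    """Analytic one-sided tail P(r >= tau) of the null Pearson distribution
    with df = n_timepoints - 2 (Gaussian data, no temporal filtering)."""
    df = n_timepoints - 2
    t = tau * np.sqrt(df / (1.0 - tau**2))
    return float(sps.t.sf(t, df=df))


def null_mean_cc_tail(c: float, tau: float, n_timepoints: int, n_subjects: int) -> float:
    """Upper bound on P(mean thresholded CC >= c) for a null voxel pair.

    A pair's mean over subjects is positive only if at least one subject's CC
    clears the threshold tau, so the union bound
    1 - (1 - q)^N with q = P(r >= tau) dominates the tail for every c > 0.
    """
    if c <= 0:
        return 1.0
    q = null_cc_tail(tau, n_timepoints)
    return float(1.0 - (1.0 - q) ** n_subjects)


def analytic_envelope(tau: float, n_timepoints: int, n_subjects: int, cc_grid: np.ndarray) -> Envelope:
    """Envelope built from the analytic null tail of the mean thresholded CC.

    Used when the empirical t-vs-CC scatter is degenerate (e.g. null data with
    almost no retained pairs); maps each grid CC to the null probability that a
    pair's subject-mean thresholded CC reaches it.
    """
    cc_grid = np.asarray(cc_grid, dtype=np.float64)
    p = np.array([null_mean_cc_tail(c, tau, n_timepoints, n_subjects) for c in cc_grid])
    p = np.minimum.accumulate(np.clip(p, 1e-300, 1.0))
    df = n_subjects - 1
    t = sps.t.isf(np.clip(p, 1e-300, 1 - 1e-12), df=df)
    return Envelope(cc_centers=cc_grid, t_min=t, p=p, df=df)
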