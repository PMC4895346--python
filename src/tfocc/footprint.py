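"""Shape-based evaluation of DNase footprint profiles.

Binned tag-count profiles around binding sites are softly partitioned into
a "typical" class sharing a common footprint shape — evaluated at a small
grid of discrete displacements ("shift states") — and an "atypical" class
whose shape converges to flat background.  The EM returns, per site, the
posterior probability ``p`` of the typical class and the re-centering
shift ``s`` (in bases) that best aligns the site with the aggregate shape.

The emission model is a multinomial over bins conditioned on the profile
total, so class membership is driven by profile *shape*, not sequencing
depth.  Both class shapes are learned; the typical label is assigned after
convergence to the class with the higher center-to-flank contrast, which
makes the labeling deterministic under label-swapped initializations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .pwm import SiteList
from .tracks import TagTrack


@dataclass
class ProfileMatrix:
    """Sites x bins tag counts with the extraction geometry."""

    counts: np.ndarray          # n_sites x n_bins, nonnegative
    binsize: int
    halfwidth: int
    max_shift: int
    site_ids: np.ndarray

    @property
    def margin_bins(self) -> int:
        return self.max_shift // self.binsize

    @property
    def core_bins(self) -> int:
        return (2 * self.halfwidth) // self.binsize

    def __post_init__(self):
        expected = self.core_bins + 2 * self.margin_bins
        if self.counts.shape[1] != expected:
            raise ValueError(
                f"expected {expected} bins, got {self.counts.shape[1]}")
        if (self.counts < 0).any():
            raise ValueError("profile counts must be nonnegative")


@dataclass
class PartitionResult:
    """Per-site typical-class probability and optimal shift."""

    p: np.ndarray               # posterior probability of "typical"
    s: np.ndarray               # re-centering shift in bases
    typical_profile: np.ndarray  # learned typical shape (core bins, sums to 1)
    atypical_profile: np.ndarray
    loglik_trace: np.ndarray
    flagged: np.ndarray          # True where the profile was all-zero
    n_iter: int
    converged: bool


def extract_profiles(track: TagTrack, sites: SiteList, halfwidth: int = 500,
                     binsize: int = 10, max_shift: int = 50) -> ProfileMatrix:
    """Bin pooled-strand tag counts around each site center.

    The core region ``[center - halfwidth, center + halfwidth)`` is binned
    in ``binsize`` windows, extended by ``max_shift`` bases on each side so
    that every shift state is evaluated on fully observed counts.
    """
    if halfwidth % binsize or max_shift % binsize:
        raise ValueError("binsize must divide halfwidth and max_shift")
    margin = max_shift // binsize
    nbins = (2 * halfwidth) // binsize + 2 * margin
    window_start = -halfwidth - max_shift
    counts = np.zeros((len(sites), nbins))
    frame = sites.frame
    for chrom, sub in frame.groupby("chrom", sort=False):
        for strand in ("+", "-"):
            pos, mult = track.strand_arrays(chrom, strand)
            if len(pos) == 0:
                continue
            for row in sub.itertuples():
                lo = row.center + window_start
                offsets = pos - lo
                mask = (offsets >= 0) & (offsets < nbins * binsize)
                np.add.at(counts[row.Index], offsets[mask] // binsize,
                          mult[mask])
    return ProfileMatrix(counts, binsize, halfwidth, max_shift,
                         frame["id"].to_numpy())


def _contrast(shape: np.ndarray) -> float:
    """Center-to-flank contrast of a normalized shape vector."""
    nbins = len(shape)
    quarter = max(1, nbins // 4)
    center = shape[nbins // 2 - quarter // 2: nbins // 2 + (quarter + 1) // 2]
    flank = np.concatenate([shape[:quarter], shape[-quarter:]])
    return float(center.mean() - flank.mean())


def _windowed(counts: np.ndarray, margin: int, core: int, k: int) -> np.ndarray:
    """Core-window counts at shift state ``k`` (bins, ``-margin..margin``)."""
    start = margin + k
    return counts[:, start:start + core]


def _init_shapes(counts, margin, core, alpha, rng, randomize=False):
    """Initial shapes: typical from the top decile by best-shift contrast."""
    n = counts.shape[0]
    shifts = range(-margin, margin + 1)
    best_contrast = np.full(n, -np.inf)
    best_window = np.zeros((n, core))
    for k in shifts:
        win = _windowed(counts, margin, core, k)
        totals = win.sum(axis=1)
        safe = np.where(totals > 0, totals, 1.0)
        shapes = win / safe[:, None]
        con = np.array([_contrast(s) for s in shapes])
        better = con > best_contrast
        best_contrast[better] = con[better]
        best_window[better] = win[better]
    order = np.argsort(best_contrast)[::-1]
    top = order[: max(1, n // 10)]
    typical = best_window[top].sum(axis=0) + alpha
    if randomize:
        typical = typical * rng.uniform(0.5, 1.5, size=core)
    typical /= typical.sum()
    flat = np.full(core, 1.0 / core)
    return typical, flat


def partition_profiles(profiles: ProfileMatrix, n_shift_states: int = 11,
                       prior_typical: float = 0.5, max_iter: int = 200,
                       tol: float = 1e-6, seed: int = 0,
                       init_shapes=None, alpha: float = 0.5) -> PartitionResult:
    """EM partition of profiles into shape-bearing and background classes.

    Every hypothesis explains the full extraction window (core plus shift
    margins): the typical class places its core shape at one of
    ``n_shift_states`` displacements (uniform shift prior) with a learned
    "edge" probability mass spread uniformly over the bins outside the
    shifted core, so likelihoods are comparable across shift states; the
    atypical class is a free multinomial over all bins that converges to
    flat background.  ``alpha`` is a Dirichlet pseudo-count per bin on the
    shape estimates.  ``init_shapes`` may supply ``(typical_core,
    atypical_full)`` starting shapes (e.g. swapped, for symmetry checks);
    by default the typical shape starts from the top decile of profiles by
    center-to-flank contrast.

    The shape/shift decomposition is identifiable only up to translation
    for interior shift states; shift states clipped at the grid edge
    anchor the maximum-likelihood gauge, and a guarded recentering move
    (roll the shape, re-adapt, keep the better branch) lets the EM escape
    translated local optima while keeping the objective trace
    non-decreasing.
    """
    counts = profiles.counts
    n = counts.shape[0]
    if n < 2:
        raise ValueError("at least two profiles are required")
    margin = profiles.margin_bins
    core = profiles.core_bins
    nbins = counts.shape[1]
    n_edge = nbins - core                      # bins outside any shifted core
    if n_shift_states != 2 * margin + 1:
        raise ValueError(
            f"profiles extracted for {2 * margin + 1} shift states, "
            f"got n_shift_states={n_shift_states}")
    rng = np.random.default_rng(seed)
    if init_shapes is None:
        shape_t, _ = _init_shapes(counts, margin, core, alpha, rng)
        shape_b = np.full(nbins, 1.0 / nbins)
    else:
        shape_t = np.asarray(init_shapes[0], dtype=float)
        shape_t = shape_t / shape_t.sum()
        shape_b = np.asarray(init_shapes[1], dtype=float)
        if len(shape_b) == core:               # pad a core-only init
            pad = np.full(margin, shape_b.mean())
            shape_b = np.concatenate([pad, shape_b, pad])
        shape_b = shape_b / shape_b.sum()
    if len(shape_t) != core or len(shape_b) != nbins:
        raise ValueError("init shapes have wrong bin counts")
    eps = n_edge / nbins                       # initial edge probability mass
    pi = float(prior_typical)
    ks = np.arange(-margin, margin + 1)
    K = len(ks)
    windows = np.stack([_windowed(counts, margin, core, int(k)) for k in ks],
                       axis=1)                 # n x K x core
    totals = counts.sum(axis=1)
    in_core = windows.sum(axis=2)              # n x K
    out_core = totals[:, None] - in_core
    zero = totals == 0

    def _estep(shape_t, shape_b, eps, pi):
        """Joint posteriors and the Dirichlet-penalized log-likelihood."""
        log_t = (windows @ np.log((1.0 - eps) * shape_t)
                 + out_core * np.log(eps / n_edge)
                 + np.log(pi) - np.log(K))
        log_b = counts @ np.log(shape_b) + np.log(1.0 - pi)
        joint = np.concatenate([log_t, log_b[:, None]], axis=1)  # n x (K+1)
        norm = logsumexp(joint, axis=1)
        resp = np.exp(joint - norm[:, None])
        penalty = alpha * (np.log(shape_t).sum() + np.log(shape_b).sum())
        return resp, float(norm.sum() + penalty)

    def _mstep(resp):
        """MAP updates with per-bin Dirichlet pseudo-count alpha."""
        r_t, r_b = resp[:, :K], resp[:, K]
        aligned = alpha + np.einsum("nk,nkc->c", r_t, windows)
        new_t = aligned / aligned.sum()
        edge = float((resp[:, :K] * out_core).sum())
        inside = float((resp[:, :K] * in_core).sum())
        # exact conditional maximizer; clipped only to keep logs finite
        new_eps = float(np.clip(edge / max(edge + inside, 1e-12),
                                1e-9, 1 - 1e-9))
        full = alpha + r_b @ counts
        new_b = full / full.sum()
        new_pi = float(np.clip(r_t.sum() / n, 1e-6, 1 - 1e-6))
        return new_t, new_b, new_eps, new_pi

    def _adapt(shape_t, shape_b, eps, pi, steps: int = 5):
        for _ in range(steps):
            resp, _ = _estep(shape_t, shape_b, eps, pi)
            shape_t, shape_b, eps, pi = _mstep(resp)
        _, obj = _estep(shape_t, shape_b, eps, pi)
        return (shape_t, shape_b, eps, pi), obj

    trace = []
    resp_t = resp_b = None
    for iteration in range(max_iter):
        resp, objective = _estep(shape_t, shape_b, eps, pi)
        resp_t = resp[:, :K]
        resp_b = resp[:, K]
        if trace and objective - trace[-1] < -1e-8 * max(1.0, abs(trace[-1])):
            raise AssertionError("EM objective decreased")
        converged = bool(trace) and (objective - trace[-1]) < tol
        trace.append(objective)
        if converged:
            break
        shape_t, shape_b, eps, pi = _mstep(resp)
        # guarded recentering against translated local optima
        mass = resp_t.sum(axis=0)
        if mass.sum() > 0:
            drift = int(np.rint(float((mass @ ks) / mass.sum())))
            if drift != 0:
                plain, obj_plain = _adapt(shape_t, shape_b, eps, pi)
                rolled, obj_rolled = _adapt(np.roll(shape_t, drift),
                                            shape_b, eps, pi)
                shape_t, shape_b, eps, pi = (rolled if obj_rolled
                                             >= obj_plain else plain)
    else:
        converged = False

    # deterministic labeling: typical = higher center-to-flank contrast
    if _contrast(shape_t) >= _contrast(shape_b[margin:margin + core]):
        typical, atypical = shape_t, shape_b
        p = resp_t.sum(axis=1)
        shift_post = resp_t
    else:
        typical, atypical = shape_b[margin:margin + core], None
        p = resp_b
        # the unshifted class won: all mass at shift 0
        shift_post = np.zeros((n, K))
        shift_post[:, margin] = 1.0
        atypical = np.concatenate([[shape_t.mean()] * margin, shape_t,
                                   [shape_t.mean()] * margin])
        atypical = atypical / atypical.sum()
    best_k = ks[np.argmax(shift_post, axis=1)]
    # s re-centers the site: a footprint displaced downstream by k bins
    # needs an upstream correction of k * binsize
    s = (-best_k * profiles.binsize).astype(int)

    p = np.clip(p, 0.0, 1.0)
    s = s.copy()
    p[zero] = prior_typical
    s[zero] = 0
    return PartitionResult(p=p, s=s, typical_profile=typical,
                           atypical_profile=atypical,
                           loglik_trace=np.array(trace), flagged=zero,
                           n_iter=len(trace), converged=converged)
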