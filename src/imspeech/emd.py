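"""Empirical mode decomposition: univariate, multivariate, and noise-assisted.

Univariate EMD sifts a signal into intrinsic mode functions (IMFs) by
repeatedly subtracting the mean of the cubic-spline envelopes of its local
maxima and minima; the IMFs plus the final residue reconstruct the input
exactly (the construction is telescoping).

Multivariate EMD (MEMD) generalizes the local mean to an n-dimensional signal
by projecting it onto K quasi-uniform direction vectors on the unit
(n-1)-sphere, spline-interpolating the full signal at each projection's
extrema, and averaging the per-direction envelopes.  All channels are sifted
jointly, so every channel shares a common number of IMFs and the same
oscillation lands in the same IMF index across channels (mode alignment).

Noise-assisted MEMD (NA-MEMD) appends q independent white-Gaussian-noise
channels before MEMD; the noise forces the quasi-dyadic filter-bank behaviour
of the decomposition, and the noise channels' IMFs are discarded afterwards.

Choices the method leaves open, with the defaults used here (all exposed):
direction vectors from a Hammersley low-discrepancy sequence mapped to the
sphere (K = 64); sift stoppage by the envelope-amplitude criterion with
thresholds (0.05, 0.5) and tolerance 0.05, at most 100 sift iterations;
mirror extension of the two outermost extrema at each boundary before spline
fitting; natural cubic splines; plateau extrema resolved to the plateau
midpoint; q = 1 noise channel at 5% of the mean channel variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import solve_banded
from scipy.signal import periodogram
from scipy.stats import norm as _norm_dist

from .io import ConfigurationError, MultichannelRecording

logger = logging.getLogger("imspeech")

DEFAULT_STOP = (0.05, 0.5, 0.05)  # (theta1, theta2, alpha)
MAX_SIFT_ITERATIONS = 100
_MIN_LENGTH = 16


class InsufficientExtremaError(ValueError):
    """Signal has too few extrema to fit an envelope (monotone residue)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class IMFSet:
    """Stack of intrinsic mode functions plus residue.

    ``imfs`` has shape (channels, n_imfs, samples), ordered fastest mode
    first; ``residue`` has shape (channels, samples).  The sum of all IMFs and
    the residue reconstructs each channel exactly.
    """

    imfs: np.ndarray
    residue: np.ndarray
    source_rate: float

    def __post_init__(self) -> None:
        self.imfs = np.asarray(self.imfs, dtype=float)
        self.residue = np.atleast_2d(np.asarray(self.residue, dtype=float))
        if self.imfs.ndim == 2:  # single channel convenience
            self.imfs = self.imfs[None, :, :]

    @property
    def n_channels(self) -> int:
        return self.residue.shape[0]

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=1) + self.residue


@dataclass
class EnvelopePair:
    """Upper/lower spline envelopes and their pointwise mean."""

    upper: np.ndarray
    lower: np.ndarray
    mean: np.ndarray


@dataclass
class DirectionSet:
    """K unit direction vectors on the (dim-1)-sphere."""

    vectors: np.ndarray  # (K, dim)
    scheme: str

    @property
    def K(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class ProjectionExtrema:
    """A direction's projected signal and the sample times of its maxima."""

    projection: np.ndarray
    maxima_times: np.ndarray
    minima_times: np.ndarray


@dataclass
class MultivariateEnvelope:
    """Per-direction envelope curves and their average (the local mean)."""

    curves: np.ndarray  # (K_used, dim, samples)
    mean: np.ndarray  # (dim, samples)


# ---------------------------------------------------------------------------
# extrema and envelopes
# ---------------------------------------------------------------------------

def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima, plateaus taken at their midpoint.

    An index i is a maximum iff the signal strictly rises into it and falls
    after it (a flat run counts as one extremum at the run's midpoint).
    Constant and monotone signals have no interior extrema.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ConfigurationError("need at least 3 samples to locate extrema")
    d = np.diff(x)
    nz = np.flatnonzero(d)
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    s = np.sign(d[nz])
    change = np.flatnonzero(s[:-1] != s[1:])
    # plateau spans samples nz[i]+1 .. nz[i+1]; its midpoint is the extremum
    idx = (nz[change] + 1 + nz[change + 1]) // 2
    maxima = idx[s[change] > 0]
    minima = idx[s[change] < 0]
    return maxima.astype(int), minima.astype(int)


def _mirrored_knots(idx: np.ndarray, values: np.ndarray, n_samples: int,
                    n_mirror: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to ``n_mirror`` outermost knots beyond each boundary.

    ``values`` is (n_knots, dim): the signal columns at the knot times.
    Mirroring reflects knot times about the first/last sample, which is the
    conventional end-effect control for spline envelopes.  Interior extrema
    never sit on the boundary samples, so the mirrored times are strictly
    outside [0, n_samples).
    """
    m = min(n_mirror, len(idx))
    pre_t = (-idx[:m])[::-1]
    post_t = (2 * (n_samples - 1) - idx[-m:])[::-1]
    times = np.concatenate([pre_t, idx, post_t])
    vals = np.concatenate([values[:m][::-1], values, values[-m:][::-1]], axis=0)
    return times, vals


def envelope(x: np.ndarray, extrema: np.ndarray) -> np.ndarray:
    """Natural cubic spline through ``(index, x[index])``, at every sample.

    Passes exactly through the supplied knots; with two knots it degenerates
    to the straight line through them.  Boundary extension is the caller's
    responsibility (see :func:`mean_envelope`).
    """
    extrema = np.asarray(extrema, dtype=int)
    if extrema.size < 2:
        raise InsufficientExtremaError("need at least 2 knots for an envelope")
    spline = CubicSpline(extrema, np.asarray(x, float)[extrema], bc_type="natural")
    return spline(np.arange(len(x)))


def _spline_at(times: np.ndarray, values: np.ndarray, n_samples: int) -> np.ndarray:
    """Natural cubic spline through (times, values), shape (n_samples, dim).

    Direct tridiagonal solve for the knot second derivatives (natural ends:
    M_0 = M_last = 0) and vectorized piecewise evaluation on the sample grid.
    Equivalent to ``CubicSpline(..., bc_type="natural")`` but without the
    per-call overhead, which dominates the sifting inner loop.
    """
    t = np.asarray(times, dtype=float)
    y = values if values.ndim == 2 else values[:, None]
    m = t.size
    x = np.arange(n_samples, dtype=float)
    if m == 2:
        slope = (y[1] - y[0]) / (t[1] - t[0])
        return y[0] + np.outer(x - t[0], slope.ravel()).reshape(n_samples, -1)
    h = t[1:] - t[:-1]  # (m-1,)
    dy = (y[1:] - y[:-1]) / h[:, None]
    M = np.zeros((m, y.shape[1]))
    if m > 2:
        # tridiagonal system for interior second derivatives (Thomas solve;
        # the system is symmetric positive definite, no pivoting needed)
        rhs = 6.0 * (dy[1:] - dy[:-1])
        diag = 2.0 * (h[:-1] + h[1:])
        off = h[1:-1]
        n2 = m - 2
        w = np.empty(n2)
        g = np.empty_like(rhs)
        w[0] = diag[0]
        g[0] = rhs[0]
        for i in range(1, n2):
            f = off[i - 1] / w[i - 1]
            w[i] = diag[i] - f * off[i - 1]
            g[i] = rhs[i] - f * g[i - 1]
        Mi = M[1:-1]
        Mi[n2 - 1] = g[n2 - 1] / w[n2 - 1]
        for i in range(n2 - 2, -1, -1):
            Mi[i] = (g[i] - off[i] * Mi[i + 1]) / w[i]
    seg = np.clip(np.searchsorted(t, x, side="right") - 1, 0, m - 2)
    hs = h[seg][:, None]
    a = (t[seg + 1] - x)[:, None]
    b = (x - t[seg])[:, None]
    return (M[seg] * a ** 3 + M[seg + 1] * b ** 3) / (6 * hs) \
        + (y[seg] / hs - M[seg] * hs / 6) * a \
        + (y[seg + 1] / hs - M[seg + 1] * hs / 6) * b


def mean_envelope(x: np.ndarray) -> EnvelopePair:
    """Upper/lower envelopes (mirror-extended knots) and their mean."""
    x = np.asarray(x, dtype=float)
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise InsufficientExtremaError(
            f"{maxima.size} maxima / {minima.size} minima: monotone residue"
        )
    tmax, vmax = _mirrored_knots(maxima, x[maxima, None], x.size)
    tmin, vmin = _mirrored_knots(minima, x[minima, None], x.size)
    upper = _spline_at(tmax, vmax, x.size)[:, 0]
    lower = _spline_at(tmin, vmin, x.size)[:, 0]
    return EnvelopePair(upper=upper, lower=lower, mean=(upper + lower) / 2)


# ---------------------------------------------------------------------------
# univariate sifting
# ---------------------------------------------------------------------------

def _stop_sifting(mean_abs: np.ndarray, amplitude: np.ndarray,
                  stop_constants: tuple[float, float, float]) -> bool:
    """Envelope-amplitude stoppage: |m|/a below theta1 on 1-alpha of samples
    and below theta2 everywhere."""
    theta1, theta2, alpha = stop_constants
    amp = np.maximum(amplitude, 1e-12)
    sx = mean_abs / amp
    return bool(np.mean(sx > theta1) <= alpha and np.all(sx < theta2))


def sift(x: np.ndarray, stop_constants: tuple[float, float, float] = DEFAULT_STOP,
         max_iterations: int = MAX_SIFT_ITERATIONS) -> np.ndarray:
    """Extract one detail (candidate IMF) by iterated envelope-mean removal."""
    h = np.asarray(x, dtype=float).copy()
    for _ in range(max_iterations):
        try:
            env = mean_envelope(h)
        except InsufficientExtremaError:
            break
        amplitude = (env.upper - env.lower) / 2
        if _stop_sifting(np.abs(env.mean), amplitude, stop_constants):
            break
        h -= env.mean
    else:
        logger.warning("sift reached %d iterations without converging", max_iterations)
    return h


def emd(x: np.ndarray, max_imfs: int = 9,
        stop_constants: tuple[float, float, float] = DEFAULT_STOP,
        max_sift_iterations: int = MAX_SIFT_ITERATIONS,
        source_rate: float = 1.0) -> IMFSet:
    """Univariate empirical mode decomposition.

    Extracts details until the residue is monotone (fewer than three extrema)
    or ``max_imfs`` is reached.  The returned set reconstructs the input
    exactly by construction.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < _MIN_LENGTH:
        raise ConfigurationError(f"signal too short for EMD (< {_MIN_LENGTH})")
    residue = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        maxima, minima = find_extrema(residue)
        if maxima.size + minima.size < 3 or maxima.size < 2 or minima.size < 2:
            break
        detail = sift(residue, stop_constants, max_sift_iterations)
        imfs.append(detail)
        residue = residue - detail
    stack = np.array(imfs) if imfs else np.empty((0, x.size))
    return IMFSet(imfs=stack[None, :, :], residue=residue[None, :], source_rate=source_rate)


# ---------------------------------------------------------------------------
# direction vectors
# ---------------------------------------------------------------------------

def _van_der_corput(n: np.ndarray, base: int) -> np.ndarray:
    out = np.zeros(n.shape, dtype=float)
    denom = np.ones_like(out)
    n = n.copy()
    while np.any(n > 0):
        denom *= base
        out += (n % base) / denom
        n //= base
    return out


_PRIMES = [2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59, 61,
           67, 71, 73, 79, 83, 89, 97, 101, 103, 107, 109, 113, 127, 131, 137,
           139, 149, 151, 157, 163, 167, 173, 179, 181, 191, 193, 197, 199,
           211, 223, 227, 229, 233, 239, 241, 251, 257, 263, 269, 271, 277,
           281, 283, 293, 307, 311, 313]


def direction_set(dim: int, K: int, scheme: str = "hammersley",
                  seed: int = 0) -> DirectionSet:
    """K quasi-uniform unit vectors on the (dim-1)-sphere.

    ``hammersley``: a Hammersley low-discrepancy point set in the unit cube
    (Cranley-Patterson rotated by ``seed``) pushed through the inverse normal
    CDF and normalized — quasi-uniform on the sphere in any dimension.
    ``uniform_angle``: equally spaced angles, dim = 2 only.
    """
    if dim < 1:
        raise ConfigurationError("dim must be >= 1")
    if K < dim:
        raise ConfigurationError(f"need K >= dim, got K={K}, dim={dim}")
    if scheme == "uniform_angle":
        if dim != 2:
            raise ConfigurationError("uniform_angle scheme requires dim == 2")
        angles = 2 * np.pi * np.arange(K) / K
        vectors = np.column_stack([np.cos(angles), np.sin(angles)])
    elif scheme == "hammersley":
        if dim > len(_PRIMES) + 1:
            raise ConfigurationError(f"hammersley scheme supports dim <= {len(_PRIMES) + 1}")
        i = np.arange(K)
        cube = np.empty((K, dim))
        cube[:, 0] = (i + 0.5) / K
        for j in range(1, dim):
            cube[:, j] = _van_der_corput(i + 1, _PRIMES[j - 1])
        rng = np.random.default_rng(seed)
        cube = (cube + rng.uniform(0, 1, size=dim)[None, :]) % 1.0
        cube = np.clip(cube, 1e-12, 1 - 1e-12)
        gauss = _norm_dist.ppf(cube)
        norms = np.linalg.norm(gauss, axis=1)
        norms[norms < 1e-10] = 1.0
        vectors = gauss / norms[:, None]
    else:
        raise ConfigurationError(f"unknown direction scheme {scheme!r}")
    return DirectionSet(vectors=vectors, scheme=scheme)


# ---------------------------------------------------------------------------
# multivariate EMD
# ---------------------------------------------------------------------------

def project(h: np.ndarray, vector: np.ndarray) -> ProjectionExtrema:
    """Project a (dim, samples) signal onto one direction and find extrema."""
    p = np.asarray(vector, float) @ np.asarray(h, float)
    maxima, minima = find_extrema(p)
    return ProjectionExtrema(projection=p, maxima_times=maxima, minima_times=minima)


def _local_mean(h: np.ndarray, directions: DirectionSet,
                collect_curves: bool = False):
    """(mean, amplitude, curves) of the direction-averaged envelopes.

    For each direction, the signal is spline-interpolated (componentwise) at
    the projection's maxima and at its minima; the direction's envelope curve
    is the average of those two, and the local mean is the average over all
    usable directions.  Returns None when no direction has enough extrema.
    """
    h = np.asarray(h, dtype=float)
    n = h.shape[1]
    mean_acc = np.zeros_like(h)
    amp_acc = np.zeros(n)
    curves: list[np.ndarray] = []
    used = 0
    projections = directions.vectors @ h  # (K, n)
    for k in range(directions.K):
        maxima, minima = find_extrema(projections[k])
        if maxima.size < 2 or minima.size < 2:
            continue
        tmax, vmax = _mirrored_knots(maxima, h[:, maxima].T, n)
        tmin, vmin = _mirrored_knots(minima, h[:, minima].T, n)
        e_max = _spline_at(tmax, vmax, n)  # (n, dim)
        e_min = _spline_at(tmin, vmin, n)
        curve = (e_max + e_min).T / 2
        mean_acc += curve
        amp_acc += np.linalg.norm(e_max - e_min, axis=1) / 2
        if collect_curves:
            curves.append(curve)
        used += 1
    if used == 0:
        return None
    return mean_acc / used, amp_acc / used, curves


def multivariate_envelope(h: np.ndarray, directions: DirectionSet) -> MultivariateEnvelope | None:
    """Average of per-direction spline envelopes of the full signal."""
    out = _local_mean(h, directions, collect_curves=True)
    if out is None:
        return None
    mean, amplitude, curves = out
    env = MultivariateEnvelope(curves=np.array(curves), mean=mean)
    env._amplitude = amplitude  # per-sample amplitude for the stop rule
    return env


def _decomposition_exhausted(h: np.ndarray, directions: DirectionSet) -> bool:
    """True when every projection has fewer than three extrema."""
    projections = directions.vectors @ h
    for k in range(directions.K):
        maxima, minima = find_extrema(projections[k])
        if maxima.size + minima.size >= 3:
            return False
    return True


def memd(v: MultichannelRecording | np.ndarray, n_directions: int = 64,
         max_imfs: int = 9,
         stop_constants: tuple[float, float, float] = DEFAULT_STOP,
         max_sift_iterations: int = MAX_SIFT_ITERATIONS,
         directions: DirectionSet | None = None,
         source_rate: float | None = None) -> IMFSet:
    """Multivariate EMD over all channels jointly.

    All channels share a common number of IMFs and the same mode index across
    channels by construction.  Pass ``directions`` explicitly to override the
    Hammersley set (required for signals with a single channel).
    """
    if isinstance(v, MultichannelRecording):
        x = v.data.copy()
        rate = v.sampling_rate
    else:
        x = np.atleast_2d(np.asarray(v, dtype=float)).copy()
        rate = source_rate if source_rate is not None else 1.0
    dim, n = x.shape
    if n < _MIN_LENGTH:
        raise ConfigurationError(f"signal too short for MEMD (< {_MIN_LENGTH})")
    if directions is None:
        if dim < 2:
            raise ConfigurationError("MEMD needs >= 2 channels (or explicit directions)")
        directions = direction_set(dim, n_directions)
    elif directions.dim != dim:
        raise ConfigurationError("direction vectors do not match signal dimension")

    residue = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        if _decomposition_exhausted(residue, directions):
            break
        h = residue.copy()
        for _it in range(max_sift_iterations):
            out = _local_mean(h, directions)
            if out is None:
                break
            mean, amplitude, _ = out
            if _stop_sifting(np.linalg.norm(mean, axis=0), amplitude,
                             stop_constants):
                break
            h -= mean
        else:
            logger.warning("multivariate sift hit %d iterations", max_sift_iterations)
        imfs.append(h)
        residue = residue - h
    stack = (np.stack(imfs, axis=1) if imfs else np.empty((dim, 0, n)))
    return IMFSet(imfs=stack, residue=residue, source_rate=rate)


def na_memd(v: MultichannelRecording | np.ndarray, q: int = 1,
            noise_power_fraction: float = 0.05, n_directions: int = 64,
            max_imfs: int = 9, seed: int = 0,
            stop_constants: tuple[float, float, float] = DEFAULT_STOP,
            max_sift_iterations: int = MAX_SIFT_ITERATIONS,
            source_rate: float | None = None) -> IMFSet:
    """Noise-assisted MEMD.

    Appends ``q`` independent white-Gaussian-noise channels whose variance is
    ``noise_power_fraction`` times the mean channel variance, runs MEMD on the
    (n+q)-channel composite, and discards the noise channels' IMFs, returning
    modes for the original n channels only.  Deterministic for a fixed seed.
    """
    if q < 1:
        raise ConfigurationError("q must be >= 1")
    if isinstance(v, MultichannelRecording):
        x = v.data
        rate = v.sampling_rate
    else:
        x = np.atleast_2d(np.asarray(v, dtype=float))
        rate = source_rate if source_rate is not None else 1.0
    n_ch, n = x.shape
    variances = x.var(axis=1)
    if np.any(variances == 0):
        raise ConfigurationError("zero-variance channel: noise scaling undefined")
    rng = np.random.default_rng(seed)
    noise_sd = np.sqrt(noise_power_fraction * variances.mean())
    noise = noise_sd * rng.standard_normal((q, n))
    stacked = np.vstack([x, noise])
    full = memd(stacked, n_directions=n_directions, max_imfs=max_imfs,
                stop_constants=stop_constants,
                max_sift_iterations=max_sift_iterations, source_rate=rate)
    return IMFSet(imfs=full.imfs[:n_ch], residue=full.residue[:n_ch],
                  source_rate=rate)


def imf_dominant_frequency(imf: np.ndarray, rate: float) -> float:
    """Frequency of the periodogram maximum; NaN for an all-zero signal."""
    imf = np.asarray(imf, dtype=float)
    if not np.any(imf):
        return float("nan")
    freqs, power = periodogram(imf, fs=rate)
    return float(freqs[np.argmax(power)])
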