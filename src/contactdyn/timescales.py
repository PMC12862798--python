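"""Time-scale analysis of ensemble-averaged contact responses.

The ensemble mean of a contact distance after a perturbation at t = 0 is
expanded in exponentials on a fixed logarithmic grid of time constants,

    r_j(t) = sum_k a_kj exp(-t / tau_k) + c_j ,

with tau_k log-spaced (10 per decade by default) and the amplitudes a_kj
determined by a maximum-entropy regularized fit: minimize chi - lam * S_ent,
where chi is the (SEM-weighted) root-mean-square deviation between model
and data and S_ent a Skilling entropy that penalizes spectral structure not
demanded by the data.  Signed amplitudes are represented by two
non-negative channels, a_k = a_k(+) - a_k(-), each entering the entropy

    S_ent = (1 / 2K) sum_{k, +/-} [ a - m - a ln(a / m) ]

relative to a flat prior amplitude m (the 1/2K normalization makes the
regularization weight lam independent of grid size).  The constant offset
c_j is fitted freely, outside the entropy.

The overall response of a system is summarized by the dynamical content

    D(tau_k) = sum_j |a_kj|^2 ,

whose peaks mark the characteristic time scales; restricting the sum to
the features of one contact cluster attributes each peak to a cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize

from .contacts import DistanceSeries

__all__ = [
    "ResponseEnsemble",
    "TimescaleGrid",
    "MaxEntConfig",
    "RelaxationSpectrum",
    "DynamicalContentProfile",
    "PowerLawFit",
    "ensemble_average",
    "build_tau_grid",
    "refine_linear",
    "log_resample",
    "gaussian_lowpass",
    "extension_level",
    "preprocess",
    "find_peaks_log",
    "maxent_fit",
    "dynamical_content",
    "powerlaw_fit",
    "lambda_scan",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ResponseEnsemble:
    """Ensemble-averaged response of one feature.

    mean/sem are the pointwise average and standard error over the
    trajectories alive at each time; n_traj records how many contribute
    (long-time points may use fewer trajectories when runs have mixed
    lengths).
    """

    feature: str
    times: np.ndarray  # ns
    mean: np.ndarray  # nm (or 1/nm for inverse-distance features)
    sem: np.ndarray
    n_traj: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.n_traj = np.asarray(self.n_traj, dtype=int)
        if not (self.times.shape == self.mean.shape == self.sem.shape == self.n_traj.shape):
            raise ValueError("times, mean, sem, n_traj must share one shape")
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("mean contains non-finite values")
        if np.any(self.sem < 0):
            raise ValueError("sem must be non-negative")


@dataclass
class TimescaleGrid:
    """Log-spaced time constants tau_k (ns) with fixed per-decade density."""

    taus: np.ndarray
    per_decade: int
    includes_constant: bool = True

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus, dtype=float)
        if self.taus.size < 1 or np.any(np.diff(self.taus) <= 0):
            raise ValueError("taus must be strictly increasing")

    @property
    def n(self) -> int:
        return self.taus.size


@dataclass(frozen=True)
class MaxEntConfig:
    """Configuration of preprocessing and the maximum-entropy fit.

    lam : regularization weight on the entropy term (>= 0).
    interp_factor : linear-interpolation refinement before log-resampling.
    frames_per_decade : density of the log-spaced time grid.
    filter_sigma : Gaussian low-pass width in (log-spaced) frames.
    extend_decades : constant extension beyond the data window.
    entropy_prior : prior amplitude m; if None, 10% of the data's
        peak-to-peak range per feature.
    weight_mode : "sem" (1/sem^2 weights) or "uniform".
    """

    lam: float = 10.0
    interp_factor: int = 4
    frames_per_decade: int = 750
    filter_sigma: float = 6.0
    extend_decades: int = 1
    entropy_prior: float | None = None
    weight_mode: str = "sem"
    max_iter: int = 2000
    tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.interp_factor < 1 or self.frames_per_decade < 1:
            raise ValueError("interp_factor and frames_per_decade must be >= 1")
        if self.filter_sigma < 0 or self.extend_decades < 0:
            raise ValueError("filter_sigma and extend_decades must be >= 0")
        if self.entropy_prior is not None and self.entropy_prior <= 0:
            raise ValueError("entropy_prior must be positive")
        if self.weight_mode not in ("sem", "uniform"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


@dataclass
class RelaxationSpectrum:
    """Fitted amplitude spectrum of one feature on a TimescaleGrid."""

    feature: str
    grid: TimescaleGrid
    amplitudes: np.ndarray  # signed, a(+) - a(-)
    offset: float
    chi2: float  # weighted mean squared residual
    entropy: float  # normalized Skilling entropy at the solution
    lam: float
    prior: float
    converged: bool = True
    n_iter: int = 0
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape != (self.grid.n,):
            raise ValueError("amplitudes must match the tau grid")

    @property
    def chi(self) -> float:
        return float(np.sqrt(self.chi2))

    def reconstruct(self, times: np.ndarray) -> np.ndarray:
        """Evaluate the multiexponential model on ``times`` (ns)."""
        t = np.asarray(times, dtype=float)
        return _basis(t, self.grid.taus) @ self.amplitudes + self.offset


@dataclass
class DynamicalContentProfile:
    """Total and per-cluster dynamical content on a shared tau grid."""

    grid: TimescaleGrid
    total: np.ndarray
    per_cluster: dict[str, np.ndarray]
    peaks: list[tuple[float, float]]  # (tau_ns, height), total profile

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total, dtype=float)
        if self.total.shape != (self.grid.n,):
            raise ValueError("total must match the tau grid")


@dataclass
class PowerLawFit:
    """Least-squares power law r(t) ~ prefactor * t**alpha on a log-log window."""

    feature: str
    alpha: float
    prefactor: float
    window: tuple[float, float]
    r2: float
    baseline: str = "raw"


# ---------------------------------------------------------------------------
# ensemble averaging


def ensemble_average(series_list: Sequence[DistanceSeries]) -> ResponseEnsemble:
    """Pointwise mean and SEM over trajectories of one feature.

    Trajectories must share the time origin (t = 0 at the perturbation) and
    frame interval but may differ in length: at each time the statistics
    are taken over the trajectories still alive, and ``n_traj`` records how
    many (the SEM visibly grows where the short runs end).  SEM is 0 where
    only one trajectory remains.
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("need at least one trajectory")
    names = {s.name for s in series_list}
    if len(names) > 1:
        raise ValueError(f"series mix features: {sorted(names)}")
    dts = {round(float(s.times[1] - s.times[0]), 12) for s in series_list if s.times.size > 1}
    if len(dts) > 1:
        raise ValueError("trajectories have differing frame intervals")
    longest = max(series_list, key=lambda s: s.times.size)
    n_times = longest.times.size
    times = longest.times

    total = np.zeros(n_times)
    total_sq = np.zeros(n_times)
    count = np.zeros(n_times, dtype=int)
    for s in series_list:
        m = s.values.size
        total[:m] += s.values
        total_sq[:m] += s.values**2
        count[:m] += 1
    if np.any(count == 0):
        keep = count > 0
        logger.warning("truncating grid to %d points with coverage", keep.sum())
        times, total, total_sq, count = times[keep], total[keep], total_sq[keep], count[keep]
    mean = total / count
    sem = np.zeros_like(mean)
    multi = count > 1
    var = np.zeros_like(mean)
    var[multi] = (total_sq[multi] - count[multi] * mean[multi] ** 2) / (count[multi] - 1)
    sem[multi] = np.sqrt(np.maximum(var[multi], 0.0) / count[multi])
    return ResponseEnsemble(
        feature=series_list[0].name, times=times, mean=mean, sem=sem, n_traj=count
    )


# ---------------------------------------------------------------------------
# tau grid and preprocessing


def build_tau_grid(
    t_min: float,
    t_max: float,
    per_decade: int = 10,
    extend_decades: int = 0,
    includes_constant: bool = True,
) -> TimescaleGrid:
    """Log-spaced tau grid from t_min to t_max * 10**extend_decades (ns).

    Consecutive time constants differ by the factor 10**(1/per_decade);
    e.g. four decades at 10 per decade give 41 grid points.
    """
    if not 0 < t_min < t_max:
        raise ValueError("need 0 < t_min < t_max")
    if per_decade < 1:
        raise ValueError("per_decade must be >= 1")
    upper = t_max * 10.0**extend_decades
    # epsilon guard so exact decade spans land on the boundary point
    n_steps = int(np.ceil(per_decade * np.log10(upper / t_min) - 1e-9))
    taus = t_min * 10.0 ** (np.arange(n_steps + 1) / per_decade)
    return TimescaleGrid(taus=taus, per_decade=per_decade, includes_constant=includes_constant)


def refine_linear(
    times: np.ndarray, values: np.ndarray, factor: int
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation refining a grid: n frames -> (n-1)*factor + 1."""
    times = np.asarray(times, dtype=float)
    n_fine = (times.size - 1) * factor + 1
    t_fine = np.linspace(times[0], times[-1], n_fine)
    return t_fine, np.interp(t_fine, times, values)


def log_resample(
    times: np.ndarray, values: np.ndarray, frames_per_decade: int
) -> tuple[np.ndarray, np.ndarray]:
    """Resample onto a log-spaced grid so each decade contributes equally.

    The grid runs from the first positive time to the last time at about
    ``frames_per_decade`` frames per decade.
    """
    times = np.asarray(times, dtype=float)
    t_lo = times[0] if times[0] > 0 else times[times > 0][0]
    t_hi = times[-1]
    n_decades = np.log10(t_hi / t_lo)
    n_log = max(int(round(n_decades * frames_per_decade)) + 1, 2)
    t_log = np.geomspace(t_lo, t_hi, n_log)
    return t_log, np.interp(t_log, times, values)


def gaussian_lowpass(values: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian low-pass filter, std in frames, edge values replicated."""
    if sigma <= 0:
        return np.asarray(values, dtype=float)
    return gaussian_filter1d(np.asarray(values, dtype=float), sigma, mode="nearest")


def extension_level(times: np.ndarray, values: np.ndarray) -> float:
    """Boundary-extension constant: mean over the last half decade."""
    times = np.asarray(times, dtype=float)
    tail = times >= times[-1] / np.sqrt(10.0)
    return float(np.asarray(values, dtype=float)[tail].mean())


def preprocess(response: ResponseEnsemble, config: MaxEntConfig | None = None) -> ResponseEnsemble:
    """Condition a uniformly sampled response for the log-time fit.

    Four steps, in order: (1) linear interpolation refines the uniform grid
    by ``interp_factor`` (n frames -> (n-1)*factor + 1); (2) resampling onto
    a log-spaced time axis so each decade contributes equally, about
    ``frames_per_decade`` frames; (3) Gaussian low-pass filtering with
    standard deviation ``filter_sigma`` in (log-spaced) frames, suppressing
    fast fluctuations; (4) extension of the data by ``extend_decades``
    orders of magnitude with a constant, the average over the last half
    decade of the filtered data, which stabilizes the fit at the upper
    boundary.  SEM and n_traj are carried through the interpolation and
    resampling (not the filter); constants are exact fixed points of the
    whole chain.
    """
    config = config or MaxEntConfig()
    t = response.times
    if t.size < 2:
        raise ValueError("need at least two frames to preprocess")

    # (1) linear interpolation, factor interp_factor
    t_fine, mean = refine_linear(t, response.mean, config.interp_factor)
    sem = np.interp(t_fine, t, response.sem)
    n_traj = np.interp(t_fine, t, response.n_traj)

    # (2) log-spaced resampling at ~frames_per_decade per decade
    t_log, mean = log_resample(t_fine, mean, config.frames_per_decade)
    sem = np.interp(t_log, t_fine, sem)
    n_traj = np.interp(t_log, t_fine, n_traj)
    t_hi = t_log[-1]

    # (3) Gaussian low-pass along the log-spaced axis
    mean = gaussian_lowpass(mean, config.filter_sigma)

    # (4) constant extension by extend_decades, level = mean of last half decade
    if config.extend_decades > 0:
        level = extension_level(t_log, mean)
        n_ext = config.extend_decades * config.frames_per_decade
        ratio = 10.0 ** (1.0 / config.frames_per_decade)
        t_ext = t_hi * ratio ** np.arange(1, n_ext + 1)
        t_log = np.concatenate([t_log, t_ext])
        mean = np.concatenate([mean, np.full(n_ext, level)])
        sem = np.concatenate([sem, np.full(n_ext, sem[-1])])
        n_traj = np.concatenate([n_traj, np.full(n_ext, n_traj[-1])])

    return ResponseEnsemble(
        feature=response.feature,
        times=t_log,
        mean=mean,
        sem=sem,
        n_traj=np.round(n_traj).astype(int),
    )


# ---------------------------------------------------------------------------
# maximum-entropy fit


def _basis(times: np.ndarray, taus: np.ndarray) -> np.ndarray:
    return np.exp(-np.outer(times, 1.0 / taus))


def _nnls_start(
    B: np.ndarray, d: np.ndarray, w: np.ndarray, K: int, m: float
) -> np.ndarray | None:
    """Sparse two-channel start from weighted non-negative least squares.

    Both channels are lifted by the prior amplitude m (net amplitudes
    unchanged), placing inactive channels at the entropy optimum instead of
    at zero where the entropy gradient vanishes.
    """
    from scipy.optimize import nnls

    sw = np.sqrt(w)
    ones = np.ones(d.size)
    A = np.column_stack([B, -B, ones, -ones]) * sw[:, None]
    try:
        x, _ = nnls(A, d * sw, maxiter=max(10_000, 30 * A.shape[1]))
    except RuntimeError:  # did not converge; the flat start remains
        return None
    return np.concatenate([x[:K] + m, x[K : 2 * K] + m, [x[2 * K] - x[2 * K + 1]]])


def _weights(response: ResponseEnsemble, mode: str) -> np.ndarray:
    if mode == "uniform":
        w = np.ones_like(response.mean)
    else:
        sem = response.sem.copy()
        pos = sem > 0
        if not pos.any():
            w = np.ones_like(sem)
        else:
            sem[~pos] = sem[pos].min()
            w = 1.0 / sem**2
    return w / w.sum()


def maxent_fit(
    response: ResponseEnsemble,
    grid: TimescaleGrid,
    config: MaxEntConfig | None = None,
) -> RelaxationSpectrum:
    """Fit signed amplitudes a_k on the tau grid by max-ent regularization.

    Minimizes chi - lam * S_ent over the two non-negative channels and the
    constant offset, where chi is the weighted RMS residual and S_ent the
    normalized two-channel Skilling entropy.  Deterministic: L-BFGS-B from
    two fixed starts -- the flat prior a(+/-) = m with the offset at the
    long-time plateau, and a non-negative least-squares solution (which is
    naturally sparse, anchoring concentrated spectra that the flat start
    cannot reach through the shallow valley of near-collinear exponentials)
    -- keeping the lower objective.  Non-convergence returns the best
    iterate with ``converged=False`` and a warning; the winning start's
    per-iteration objective trace is kept for diagnostics.
    """
    config = config or MaxEntConfig()
    t = response.times
    d = response.mean
    if not np.all(np.isfinite(d)):
        raise ValueError("response contains non-finite data")
    w = _weights(response, config.weight_mode)
    B = _basis(t, grid.taus)
    K = grid.n

    m = config.entropy_prior
    if m is None:
        ptp = float(d.max() - d.min())
        m = 0.1 * ptp if ptp > 0 else 1e-6
    lam = config.lam

    def unpack(x):
        return x[:K], x[K : 2 * K], x[2 * K]

    def objective_grad(x):
        ap, an, c = unpack(x)
        a = ap - an
        r = B @ a + c - d
        msr = float(w @ r**2)
        chi = np.sqrt(msr) if msr > 0 else 0.0
        # entropy (normalized per channel), max 0 at a+/- = m
        s = (np.sum(ap - m - ap * np.log(ap / m)) + np.sum(an - m - an * np.log(an / m))) / (2 * K)
        f = chi - lam * s
        wr = w * r
        if chi > 1e-150:
            g_amp = (B.T @ wr) / chi
            g_c = wr.sum() / chi
        else:
            g_amp = np.zeros(K)
            g_c = 0.0
        g = np.empty_like(x)
        g[:K] = g_amp + lam * np.log(ap / m) / (2 * K)
        g[K : 2 * K] = -g_amp + lam * np.log(an / m) / (2 * K)
        g[2 * K] = g_c
        return f, g

    floor = m * 1e-10
    bounds = [(floor, None)] * (2 * K) + [(None, None)]
    starts = [np.concatenate([np.full(2 * K, m), [float(d[-1])]])]
    nnls_start = _nnls_start(B, d, w, K, m)
    if nnls_start is not None:
        starts.append(nnls_start)

    res = None
    trace: list[float] = []
    for x0 in starts:
        this_trace: list[float] = []
        cand = minimize(
            objective_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            callback=lambda xk: this_trace.append(objective_grad(xk)[0]),
            options={"maxiter": config.max_iter, "ftol": config.tol, "gtol": 1e-10},
        )
        if res is None or cand.fun < res.fun:
            res, trace = cand, this_trace
    if not res.success and "ITERATIONS" in str(res.message).upper():
        logger.warning("maxent_fit for %s did not converge: %s", response.feature, res.message)
    ap, an, c = unpack(res.x)
    a = ap - an
    r = B @ a + c - d
    chi2 = float(w @ r**2)
    s = (np.sum(ap - m - ap * np.log(ap / m)) + np.sum(an - m - an * np.log(an / m))) / (2 * K)
    return RelaxationSpectrum(
        feature=response.feature,
        grid=grid,
        amplitudes=a,
        offset=float(c),
        chi2=chi2,
        entropy=float(s),
        lam=lam,
        prior=m,
        converged=bool(res.success),
        n_iter=int(res.nit),
        objective_trace=np.asarray(trace),
    )


# ---------------------------------------------------------------------------
# dynamical content


def find_peaks_log(
    taus: np.ndarray, profile: np.ndarray, floor_fraction: float = 0.01
) -> list[tuple[float, float]]:
    """Strict local maxima of a profile on the tau grid above a floor.

    Peaks below ``floor_fraction`` of the global maximum are suppressed so
    the reported peak list matches what a log-axis plot visibly shows.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0 or profile.max() <= 0:
        return []
    floor = floor_fraction * profile.max()
    peaks = []
    for k in range(profile.size):
        left = profile[k - 1] if k > 0 else -np.inf
        right = profile[k + 1] if k < profile.size - 1 else -np.inf
        if profile[k] > left and profile[k] > right and profile[k] >= floor:
            peaks.append((float(taus[k]), float(profile[k])))
    return peaks


def dynamical_content(
    spectra: Sequence[RelaxationSpectrum],
    partition=None,
    floor_fraction: float = 0.01,
) -> DynamicalContentProfile:
    """Dynamical content D(tau_k) = sum_j |a_kj|^2, optionally by cluster.

    With a partition, per-cluster profiles D_n restrict the feature sum to
    cluster n; features outside every cluster contribute to a "noise"
    profile, so the cluster profiles plus noise sum to the total exactly at
    every tau_k.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("need at least one spectrum")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid.n != grid.n or not np.allclose(s.grid.taus, grid.taus):
            raise ValueError("spectra must share one tau grid")

    A2 = np.vstack([s.amplitudes**2 for s in spectra])  # (n_features, K)

    per_cluster: dict[str, np.ndarray] = {}
    if partition is not None:
        assignment = _feature_assignment(partition, [s.feature for s in spectra])
        cluster_ids = sorted({c for c in assignment.values() if c != "noise"})
        for cid in cluster_ids:
            rows = [j for j, s in enumerate(spectra) if assignment[s.feature] == cid]
            per_cluster[str(cid)] = A2[rows].sum(axis=0) if rows else np.zeros(grid.n)
        noise_rows = [j for j, s in enumerate(spectra) if assignment[s.feature] == "noise"]
        per_cluster["noise"] = A2[noise_rows].sum(axis=0) if noise_rows else np.zeros(grid.n)
        # total assembled from the group sums so the decomposition identity
        # D_total = sum_n D_n + D_noise holds exactly, not just to rounding
        total = np.sum(list(per_cluster.values()), axis=0)
    else:
        total = A2.sum(axis=0)

    peaks = find_peaks_log(grid.taus, total, floor_fraction)
    return DynamicalContentProfile(grid=grid, total=total, per_cluster=per_cluster, peaks=peaks)


def _feature_assignment(partition, feature_names: list[str]) -> dict[str, object]:
    """Normalize a partition-like object to feature name -> cluster id."""
    if isinstance(partition, dict):
        assignment = {str(k): v for k, v in partition.items()}
    else:  # ClusterPartition
        assignment = {}
        for j, cid in partition.assignment.items():
            name = partition.features[j] if partition.features else str(j)
            assignment[name] = cid if cid >= 0 else "noise"
    return {name: assignment.get(name, "noise") for name in feature_names}


# ---------------------------------------------------------------------------
# power-law tails


def powerlaw_fit(
    response: ResponseEnsemble,
    window: tuple[float, float],
    baseline: str = "raw",
) -> PowerLawFit:
    """Fit r(t) ~ prefactor * t**alpha on a log-log window.

    ``baseline="raw"`` fits log r directly; ``baseline="shift"`` fits
    log |r(t) - r(t_lo)|, removing the value at the window start so the fit
    sees the response relative to its entry point.  Microsecond tails of
    contact distances typically give alpha between 0.3 (subdiffusive) and
    0.5 (free diffusion).
    """
    t_lo, t_hi = window
    if not 0 < t_lo < t_hi:
        raise ValueError("window must satisfy 0 < t_lo < t_hi")
    if t_hi / t_lo < 10.0 - 1e-9:
        raise ValueError("window must span at least one decade")
    sel = (response.times >= t_lo) & (response.times <= t_hi)
    if sel.sum() < 3:
        raise ValueError("too few points in window")
    t = response.times[sel]
    r = response.mean[sel]
    if baseline == "shift":
        y = np.abs(r - r[0])
        t, y = t[1:], y[1:]  # the anchor point itself is identically zero
    elif baseline == "raw":
        y = r
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    if np.any(y <= 0):
        raise ValueError(f"non-positive values in window under baseline={baseline!r}")
    logt, logy = np.log(t), np.log(y)
    alpha, logc = np.polyfit(logt, logy, 1)
    fitted = alpha * logt + logc
    ss_res = float(((logy - fitted) ** 2).sum())
    ss_tot = float(((logy - logy.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        feature=response.feature,
        alpha=float(alpha),
        prefactor=float(np.exp(logc)),
        window=(float(t_lo), float(t_hi)),
        r2=r2,
        baseline=baseline,
    )


# ---------------------------------------------------------------------------
# lambda scan


def lambda_scan(
    response: ResponseEnsemble,
    grid: TimescaleGrid,
    lambdas: Sequence[float],
    config: MaxEntConfig | None = None,
) -> list[dict]:
    """One max-ent fit per regularization weight lambda.

    Reports chi2, entropy and the number of spectral peaks per lambda --
    the table used to choose lambda per system (stronger regularization
    trades residual for a smoother spectrum; chi2 is non-decreasing in
    lambda).
    """
    lambdas = list(lambdas)
    if any(l < 0 for l in lambdas):
        raise ValueError("lambdas must be non-negative")
    if sorted(lambdas) != lambdas:
        raise ValueError("lambdas must be sorted ascending")
    base = config or MaxEntConfig()
    out = []
    for lam in lambdas:
        cfg = replace(base, lam=float(lam))
        spec = maxent_fit(response, grid, cfg)
        peaks = find_peaks_log(grid.taus, np.abs(spec.amplitudes), 0.05)
        out.append(
            {
                "lam": float(lam),
                "chi2": spec.chi2,
                "entropy": spec.entropy,
                "n_peaks": len(peaks),
                "spectrum": spec,
            }
        )
    return out
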