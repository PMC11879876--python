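"""Viscoelastic moduli from tracer microrheology and Green-Kubo stress traces.

Two independent routes to the gel's elasticity:

* *Microrheology*: the mean squared displacement of an embedded tracer bead
  is converted to complex moduli G'(w), G''(w) with the generalized
  Stokes-Einstein relation in the local power-law (logarithmic-derivative)
  approximation, which is the standard particle-tracking estimator and is
  stable on log-spaced lag grids.
* *Green-Kubo*: the stress-relaxation modulus
  ``G(t) = V/(3 k_B T) * sum_{a<b} <P_ab(0) P_ab(t)>`` over the three
  off-diagonal pressure-tensor components; the elastic plateau is the ``a``
  parameter of a stretched-exponential fit ``g(t) = a exp(-(t/tau)^b)``.

Scaling analysis: log-log power-law fits (optionally with a fixed
breakpoint, e.g. at the overlap volume fraction rho* = 0.056) and the
exponent algebra combining structural and topological slopes into predicted
elasticity exponents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

KB_T = 1.0  # energy unit: epsilon; T = 1 throughout


@dataclass
class MsdSeries:
    """Tracer mean squared displacement on a strictly increasing lag grid."""

    lags: np.ndarray  # tau_Br
    msd: np.ndarray  # sigma^2
    tracer_radius: float
    temperature: float = 1.0

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if np.any(self.msd < 0):
            raise ValueError("MSD must be non-negative")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lag grid must be strictly increasing")


@dataclass
class StressSeries:
    """Off-diagonal pressure-tensor samples P_xy, P_xz, P_yz over time."""

    times: np.ndarray
    components: np.ndarray  # (n, 3)
    volume: float
    temperature: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim != 2 or self.components.shape[1] != 3:
            raise ValueError("stress components must have shape (n, 3)")
        if len(self.times) != len(self.components):
            raise ValueError("times and components length mismatch")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class ModulusSpectrum:
    """Storage and loss moduli on a positive increasing frequency grid."""

    omega: np.ndarray
    g_storage: np.ndarray
    g_loss: np.ndarray

    @property
    def plateau(self) -> float:
        """Elastic plateau G'_p: storage modulus at the largest frequency."""
        return float(self.g_storage[-1])

    def storage_at(self, omega: float) -> float:
        """G'(omega) by log-log interpolation (for reading plateau regions
        that sit away from the grid edge, e.g. a harmonic trap's low-
        frequency plateau)."""
        return float(
            np.exp(
                np.interp(
                    np.log(omega), np.log(self.omega),
                    np.log(np.maximum(self.g_storage, 1e-300)),
                )
            )
        )

    def loss_at(self, omega: float) -> float:
        """G''(omega) by log-log interpolation."""
        return float(
            np.exp(
                np.interp(
                    np.log(omega), np.log(self.omega),
                    np.log(np.maximum(self.g_loss, 1e-300)),
                )
            )
        )


@dataclass
class RelaxationFit:
    """Stretched-exponential fit g(t) = a exp(-(t/tau)^b) to G(t)."""

    times: np.ndarray
    g: np.ndarray
    a: float  # elastic plateau
    tau: float  # network relaxation time
    b: float  # stretching exponent
    covariance: np.ndarray | None = None

    def model(self, t: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-((np.asarray(t) / self.tau) ** self.b))


@dataclass
class ScalingFit:
    """Power-law fit(s) y ~ x^slope on log-log axes, optionally segmented."""

    slopes: list[float]
    stderrs: list[float]
    breakpoint: float | None = None
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    @property
    def slope(self) -> float:
        return self.slopes[0]

    @property
    def stderr(self) -> float:
        return self.stderrs[0]


# ---------------------------------------------------------------------------
# MSD

def compute_msd(
    track: np.ndarray,
    dt: float,
    tracer_radius: float = 2.5,
    n_lags: int = 60,
    temperature: float = 1.0,
) -> MsdSeries:
    """Time-origin-averaged MSD of an unwrapped tracer track.

    Uses the FFT autocorrelation identity for the full O(n log n)
    origin-average, then keeps a log-spaced subset of lags.
    """
    track = np.asarray(track, dtype=float)
    if track.ndim != 2 or track.shape[1] != 3:
        raise ValueError("track must have shape (n, 3)")
    n = len(track)
    if n < 100:
        raise ValueError("need at least 100 track samples")
    msd_full = _msd_fft(track)
    all_lags = np.arange(1, n)
    idx = np.unique(
        np.clip(
            np.round(np.geomspace(1, n - 1, n_lags)).astype(int) - 1, 0, n - 2
        )
    )
    return MsdSeries(
        lags=all_lags[idx] * dt,
        msd=np.maximum(msd_full[1:][idx], 0.0),  # clip FFT roundoff
        tracer_radius=tracer_radius,
        temperature=temperature,
    )


def _msd_fft(r: np.ndarray) -> np.ndarray:
    """All-lag origin-averaged MSD via the FFT correlation trick."""
    n = len(r)
    nfft = 1 << (2 * n - 1).bit_length()
    s2 = np.zeros(n)
    for dim in range(r.shape[1]):
        f = np.fft.rfft(r[:, dim], nfft)
        acf = np.fft.irfft(f * np.conj(f), nfft)[:n]
        s2 += acf
    sq = np.sum(r * r, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(sq)])
    total = cum[-1]
    counts = n - np.arange(n)
    # sum over origins t0 of |r(t0+t)|^2 + |r(t0)|^2:
    #   sum_{k>=m} sq[k] = total - cum[m];  sum_{k<n-m} sq[k] = cum[n-m]
    sumsq = (total - cum[:n]) + cum[::-1][:n]
    return (sumsq - 2 * s2) / counts


# ---------------------------------------------------------------------------
# GSER (Mason local power-law approximation)

def gser_moduli(msd: MsdSeries) -> ModulusSpectrum:
    """Complex moduli from a tracer MSD via the generalized Stokes-Einstein
    relation in the local power-law approximation:

        |G*(1/t)| = k_B T / (pi a MSD(t) Gamma[1 + alpha(t)]),
        alpha(t) = d ln MSD / d ln t,

    split into G' = |G*| cos(pi alpha / 2) and G'' = |G*| sin(pi alpha / 2).
    Points whose raw logarithmic slope falls outside [-0.2, 1.2] (noise) are
    masked; alpha is clipped to [0, 1] before use.
    """
    if np.any(msd.msd[1:-1] <= 0):
        raise ValueError("MSD must be positive in the grid interior")
    log_t = np.log(msd.lags)
    log_m = np.log(np.maximum(msd.msd, 1e-300))
    alpha_raw = np.gradient(log_m, log_t)
    valid = (alpha_raw > -0.2) & (alpha_raw < 1.2)
    alpha = np.clip(alpha_raw, 0.0, 1.0)
    a = msd.tracer_radius
    gmag = (
        msd.temperature
        * KB_T
        / (np.pi * a * msd.msd * special.gamma(1.0 + alpha))
    )
    g_storage = gmag * np.cos(np.pi * alpha / 2.0)
    g_loss = gmag * np.sin(np.pi * alpha / 2.0)
    omega = 1.0 / msd.lags
    order = np.argsort(omega[valid])
    return ModulusSpectrum(
        omega=omega[valid][order],
        g_storage=g_storage[valid][order],
        g_loss=g_loss[valid][order],
    )


# ---------------------------------------------------------------------------
# Green-Kubo

def green_kubo_relaxation(
    stress: StressSeries,
    max_lag_fraction: float = 0.1,
    n_off_diagonal: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Stress-relaxation modulus G(t) from off-diagonal stress autocorrelation.

    ``G(t) = V / (n k_B T) * sum_c <P_c(0) P_c(t)>`` with the sum over the
    three distinct off-diagonal components (``n_off_diagonal = 3``; set 6 to
    read the sum as running over ordered index pairs, which doubles the
    amplitude but not the shape). Components are mean-subtracted; lags are
    limited to ``max_lag_fraction`` of the series length.
    """
    n = len(stress.times)
    max_lag = int(n * max_lag_fraction)
    if max_lag < 2:
        raise ValueError("stress series too short for requested maximum lag")
    acf_sum = np.zeros(max_lag)
    for c in range(3):
        x = stress.components[:, c] - stress.components[:, c].mean()
        acf_sum += _autocorrelation(x, max_lag)
    prefactor = stress.volume / (3.0 * KB_T * stress.temperature)
    if n_off_diagonal == 6:
        prefactor *= 2.0
    lags = np.arange(max_lag) * stress.dt
    return lags, prefactor * acf_sum


def _autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Unbiased sample autocorrelation <x(0) x(t)> up to max_lag via FFT."""
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[:max_lag]
    return acf / (n - np.arange(max_lag))


def fit_stretched_exponential(
    times: np.ndarray, g: np.ndarray
) -> RelaxationFit:
    """Fit g(t) = a exp(-(t/tau)^b) by constrained nonlinear least squares.

    Initialization: a = G at the first lag, tau at the 1/e crossing, b = 1.
    The fitted ``a`` is the reported elastic plateau.
    """
    times = np.asarray(times, dtype=float)
    g = np.asarray(g, dtype=float)
    if len(g) < 20:
        raise ValueError("need at least 20 points for a stretched-exponential fit")
    head = g[: max(2, len(g) // 10)].mean()
    tail = g[-max(2, len(g) // 10):].mean()
    if tail > head:
        raise ValueError("series is rising, not decaying; refusing to fit")
    a0 = g[0] if g[0] > 0 else max(g.max(), 1e-12)
    below = np.nonzero(g < a0 / np.e)[0]
    tau0 = times[below[0]] if len(below) and times[below[0]] > 0 else (
        times[-1] / 2 if times[-1] > 0 else 1.0
    )
    mask = times > 0
    try:
        popt, pcov = optimize.curve_fit(
            lambda t, a, tau, b: a * np.exp(-((t / tau) ** b)),
            times[mask],
            g[mask],
            p0=(a0, tau0, 1.0),
            bounds=([0.0, 1e-12, 1e-3], [np.inf, np.inf, 2.0]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"stretched-exponential fit did not converge: {err}"
        ) from err
    return RelaxationFit(
        times=times, g=g, a=float(popt[0]), tau=float(popt[1]), b=float(popt[2]),
        covariance=pcov,
    )


# ---------------------------------------------------------------------------
# plateau / crossover

def extract_plateau_crossover(spectrum: ModulusSpectrum) -> dict:
    """Elastic plateau, crossover frequency and unbinding time.

    G'_p is read at the largest frequency. The crossover w0 is where
    G' - G'' changes sign (log-linear interpolation); the sticky-end
    unbinding time is tau_u = 1/w0. If the spectrum contains no crossover
    the plateau is still returned with ``crossover_found = False``.
    """
    if len(spectrum.omega) < 2:
        raise ValueError("spectrum must contain at least two frequencies")
    plateau = spectrum.plateau
    diff = spectrum.g_storage - spectrum.g_loss
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if len(sign_change) == 0:
        return {
            "plateau": plateau, "omega0": None, "tau_u": None,
            "crossover_found": False,
        }
    k = sign_change[-1]
    w1, w2 = spectrum.omega[k], spectrum.omega[k + 1]
    d1, d2 = diff[k], diff[k + 1]
    log_w0 = np.log(w1) + (np.log(w2) - np.log(w1)) * (0 - d1) / (d2 - d1)
    omega0 = float(np.exp(log_w0))
    return {
        "plateau": plateau, "omega0": omega0, "tau_u": 1.0 / omega0,
        "crossover_found": True,
    }


# ---------------------------------------------------------------------------
# scaling laws

def fit_power_law(
    x: np.ndarray,
    y: np.ndarray,
    breakpoint: float | None = None,
) -> ScalingFit:
    """Least-squares power-law fit on log-log axes.

    With a fixed ``breakpoint`` the data are split at x < breakpoint /
    x >= breakpoint and a slope +- standard error is fitted per segment
    (each segment needs >= 3 points).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit needs strictly positive data")
    if breakpoint is None:
        segments = [np.ones_like(x, dtype=bool)]
    else:
        segments = [x < breakpoint, x >= breakpoint]
    slopes, stderrs = [], []
    for mask in segments:
        if mask.sum() < 3:
            raise ValueError("each segment needs at least 3 points")
        res = stats.linregress(np.log(x[mask]), np.log(y[mask]))
        slopes.append(float(res.slope))
        stderrs.append(float(res.stderr) if np.isfinite(res.stderr) else 0.0)
    return ScalingFit(slopes=slopes, stderrs=stderrs, breakpoint=breakpoint, x=x, y=y)


def predict_scaling_exponents(
    n_minloop_slope: tuple[float, float] | None = None,
    xi_slope: tuple[float, float] | None = None,
    z_slope: tuple[float, float] | None = None,
    lmin_slope: tuple[float, float] | None = None,
    valence: int = 3,
) -> dict:
    """Predicted elasticity exponents from structural/topological slopes.

    Each input is a (slope, stderr) pair for the log-log dependence of the
    named observable on volume fraction. Outputs:

    * ``mesh_exponent``: G'_p ~ N_minloop / xi^3 -> n + 3 |s_xi|
    * ``link_exponent``: G'_p ~ N_minloop <Z>    -> n + s_Z
    * ``geometric_z_exponent``: <Z> ~ rho <l_min>^3 -> 1 + 3 s_lmin
    * phantom-network comparators rho^1 (prefactor (f-2)/f) and rho^(1/3)

    Standard errors are propagated in quadrature; the algebra itself is
    exact (a pure function of the constituent slopes).
    """
    out: dict = {
        "phantom_exponent": 1.0,
        "phantom_prefactor": (valence - 2) / valence,
        "disordered_phantom_exponent": 1.0 / 3.0,
    }
    if n_minloop_slope is not None and xi_slope is not None:
        val = n_minloop_slope[0] + 3.0 * abs(xi_slope[0])
        err = float(np.hypot(n_minloop_slope[1], 3.0 * xi_slope[1]))
        out["mesh_exponent"] = (val, err)
    if n_minloop_slope is not None and z_slope is not None:
        val = n_minloop_slope[0] + z_slope[0]
        err = float(np.hypot(n_minloop_slope[1], z_slope[1]))
        out["link_exponent"] = (val, err)
    if lmin_slope is not None:
        out["geometric_z_exponent"] = (
            1.0 + 3.0 * lmin_slope[0],
            3.0 * lmin_slope[1],
        )
    if len(out) == 3:
        raise ValueError("no constituent slopes supplied")
    return out
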