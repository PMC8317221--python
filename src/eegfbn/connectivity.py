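"""MVAR model fitting and frequency-domain directed connectivity.

Per epoch, a stationary multivariate autoregressive (MVAR) model

    x(n) = sum_{r=1..p} A_r x(n-r) + w(n)

is fitted by least squares (ARFIT-style; Yule-Walker available), with the
order p chosen by an information criterion (Schwarz/BIC by default).  The
coefficients are transformed to the frequency domain,

    Abar(f) = I - sum_r A_r exp(-i 2 pi r f / fs),      H(f) = Abar(f)^{-1},

from which two directed-influence spectra are computed for each ordered
channel pair (source j -> target i):

* partial directed coherence (PDC), column-normalized:
      pdc_ij(f) = |Abar_ij(f)| / sqrt(a_j(f)^H a_j(f)),
  where a_j is the j-th column of Abar — the *direct* influence of j on i
  relative to all of j's outflows;

* directed transfer function (DTF), row-normalized:
      dtf_ij(f) = |H_ij(f)| / sqrt(h_i(f) h_i(f)^H),
  where h_i is the i-th row of H — the total (direct plus cascaded)
  inflow from j relative to all of i's inflows.

Both lie in [0, 1]; PDC columns and DTF rows have unit sum of squares at
every frequency.  Spectra are averaged over the classical EEG bands to
yield one directed adjacency matrix per (method, band).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

#: Band definitions in Hz, closed intervals at both edges.  A frequency bin
#: falling on a shared edge (e.g. 4.0 Hz) counts in both adjacent bands; the
#: printed gaps (14-15 Hz, 30-30.5 Hz) belong to no named band.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (15.0, 30.0),
    "gamma": (30.5, 50.0),
    "all": (0.0, 50.0),
}

#: Default frequency grid: 0-64 Hz in 0.5 Hz steps (129 bins at 128 Hz).
DEFAULT_FREQ_STEP = 0.5


def default_freqs(sampling_rate: float = 128.0, step: float = DEFAULT_FREQ_STEP) -> np.ndarray:
    """Frequency grid from 0 to Nyquist inclusive."""
    nyq = sampling_rate / 2.0
    return np.arange(0.0, nyq + step / 2.0, step)


@dataclass
class MVARFit:
    """Estimated MVAR coefficients and residual covariance for one epoch."""

    order: int
    coeffs: np.ndarray  # (p, N, N)
    noise_cov: np.ndarray  # (N, N)
    channel_labels: list[str]
    criterion_value: float = float("nan")

    def __post_init__(self) -> None:
        p, n, m = self.coeffs.shape
        if p < 1 or n != m or n != len(self.channel_labels):
            raise ValueError("coefficient tensor inconsistent with channels")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-8):
            raise ValueError("residual covariance is not symmetric")


@dataclass
class ConnectivitySpectrum:
    """channels x channels x frequency tensor of directed magnitudes in [0,1].

    ``values[i, j, f]`` is the influence of source channel j on target
    channel i at ``freqs[f]``.
    """

    method: str  # "PDC" or "DTF"
    freqs: np.ndarray
    values: np.ndarray  # (N, N, F)
    channel_labels: list[str]


@dataclass
class BandAdjacencySet:
    """Band-averaged directed adjacency matrices for one method."""

    method: str
    bands: dict[str, np.ndarray]  # name -> (N, N)
    band_defs: dict[str, tuple[float, float]]
    channel_labels: list[str]


def _lagged_design(x: np.ndarray, p: int, offset: int | None = None):
    """Response and lagged-regressor matrices for LS estimation.

    ``offset`` fixes the first predicted sample (>= p); passing a common
    offset across candidate orders makes criterion values comparable.
    """
    n_ch, n = x.shape
    if offset is None:
        offset = p
    y = x[:, offset:].T  # (n_eff, N)
    cols = [x[:, offset - r : n - r].T for r in range(1, p + 1)]
    X = np.concatenate(cols, axis=1)  # (n_eff, N*p)
    return y, X


def fit_mvar(
    epoch: np.ndarray,
    p: int,
    channel_labels: Sequence[str] | None = None,
    method: str = "ls",
) -> MVARFit:
    """Fit a stationary MVAR(p) model to one epoch (channels x samples).

    ``method="ls"`` (default) solves the lagged least-squares problem;
    ``method="yw"`` solves the multivariate Yule-Walker moment equations.
    Channels are demeaned before fitting.  The residual covariance uses
    the degrees-of-freedom-corrected denominator ``n_eff - N*p``.
    """
    x = np.asarray(epoch, dtype=float)
    if x.ndim != 2:
        raise ValueError("epoch must be channels x samples")
    n_ch, n = x.shape
    if p < 1:
        raise ValueError("order must be >= 1")
    if n <= n_ch * p + p:
        raise ValueError(
            f"epoch too short: need more than {n_ch * p + p} samples to fit "
            f"MVAR({p}) on {n_ch} channels, got {n}"
        )
    labels = (
        list(channel_labels)
        if channel_labels is not None
        else [f"CH{i + 1}" for i in range(n_ch)]
    )
    x = x - x.mean(axis=1, keepdims=True)

    if method == "ls":
        y, X = _lagged_design(x, p)
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            cc = np.corrcoef(x)
            pairs = [
                (labels[i], labels[j])
                for i in range(n_ch)
                for j in range(i + 1, n_ch)
                if abs(cc[i, j]) > 1 - 1e-10
            ]
            raise np.linalg.LinAlgError(
                f"rank-deficient regressor matrix; collinear channels: {pairs}"
            )
        resid = y - X @ coef
        dof = max(y.shape[0] - n_ch * p, 1)
        sigma = resid.T @ resid / dof
        coeffs = np.stack(
            [coef[r * n_ch : (r + 1) * n_ch].T for r in range(p)]
        )
    elif method == "yw":
        coeffs, sigma = _yule_walker(x, p)
    else:
        raise ValueError(f"unknown estimation method {method!r}")
    sigma = (sigma + sigma.T) / 2.0
    return MVARFit(p, coeffs, sigma, labels)


def _yule_walker(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Multivariate Yule-Walker estimates from sample autocovariances."""
    n_ch, n = x.shape
    gamma = [x[:, k:] @ x[:, : n - k].T / n for k in range(p + 1)]

    def gam(k: int) -> np.ndarray:
        return gamma[k] if k >= 0 else gamma[-k].T

    # big[(i,j)] = Gamma(j - i), covariance of the stacked lag vector
    big = np.block([[gam(j - i) for j in range(p)] for i in range(p)])
    rhs = np.concatenate([gam(r + 1) for r in range(p)], axis=1)  # (N, N*p)
    stacked = np.linalg.solve(big.T, rhs.T).T  # [A_1 ... A_p]
    coeffs = np.stack([stacked[:, r * n_ch : (r + 1) * n_ch] for r in range(p)])
    sigma = gam(0) - sum(coeffs[r] @ gam(r + 1).T for r in range(p))
    return coeffs, sigma


def select_order(
    epoch: np.ndarray,
    p_min: int = 1,
    p_max: int = 20,
    criterion: str = "bic",
) -> int:
    """Choose the MVAR order minimizing an information criterion.

    Candidate models over [p_min, p_max] are fitted on a common effective
    sample (the first ``p_max`` samples are conditioned on for every
    candidate) so criterion values are comparable; ties break to the
    smallest order.  ``criterion`` is "bic" (Schwarz, default) or "aic".
    """
    x = np.asarray(epoch, dtype=float)
    n_ch, n = x.shape
    if not 1 <= p_min <= p_max:
        raise ValueError("need 1 <= p_min <= p_max")
    min_n = n_ch * p_max + p_max + 1
    if n <= min_n:
        raise ValueError(
            f"epoch too short for order selection up to {p_max}: "
            f"need more than {min_n} samples, got {n}"
        )
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    if p_min == p_max:
        return p_min
    x = x - x.mean(axis=1, keepdims=True)
    best_p, best_score = p_min, np.inf
    for p in range(p_min, p_max + 1):
        y, X = _lagged_design(x, p, offset=p_max)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        n_eff = y.shape[0]
        sigma_ml = resid.T @ resid / n_eff
        sign, logdet = np.linalg.slogdet(sigma_ml)
        if sign <= 0:
            continue
        k = p * n_ch * n_ch
        penalty = np.log(n_eff) if criterion == "bic" else 2.0
        score = logdet + penalty * k / n_eff
        if score < best_score - 1e-12:
            best_p, best_score = p, score
    return best_p


def spectral_transfer(
    fit: MVARFit,
    freqs: Sequence[float],
    sampling_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-domain coefficient matrix Abar(f) and transfer matrix H(f).

    Returns ``(Abar, H)``, both of shape (N, N, F) complex, with
    ``Abar(f) = I - sum_r A_r exp(-i 2 pi r f / fs)`` and ``H = Abar^{-1}``.
    """
    f = np.asarray(freqs, dtype=float)
    nyq = sampling_rate / 2.0
    if np.any(f < 0) or np.any(f > nyq + 1e-9):
        raise ValueError(f"frequencies must lie in [0, {nyq}] Hz")
    p, n, _ = fit.coeffs.shape
    r = np.arange(1, p + 1)
    # phase[r, f] = exp(-i 2 pi r f / fs)
    phase = np.exp(-2j * np.pi * np.outer(r, f / sampling_rate))
    abar = np.eye(n)[:, :, None] - np.einsum("rij,rf->ijf", fit.coeffs, phase)
    stacked = np.moveaxis(abar, 2, 0)  # (F, N, N)
    conds = np.linalg.cond(stacked)
    bad = np.nonzero(~np.isfinite(conds) | (conds > 1e12))[0]
    if bad.size:
        raise np.linalg.LinAlgError(
            f"Abar(f) is singular near f = {f[bad[0]]:.3g} Hz "
            "(near-unit-root model)"
        )
    h = np.moveaxis(np.linalg.inv(stacked), 0, 2)
    return abar, h


def pdc(
    fit: MVARFit,
    freqs: Sequence[float] | None = None,
    sampling_rate: float = 128.0,
) -> ConnectivitySpectrum:
    """Partial directed coherence spectrum (column-normalized)."""
    f = default_freqs(sampling_rate) if freqs is None else np.asarray(freqs, float)
    abar, _ = spectral_transfer(fit, f, sampling_rate)
    mag = np.abs(abar)
    denom = np.sqrt(np.sum(mag**2, axis=0, keepdims=True))  # column norms
    if np.any(denom <= 0):
        raise ZeroDivisionError("zero column norm in Abar(f)")
    return ConnectivitySpectrum("PDC", f, mag / denom, list(fit.channel_labels))


def dtf(
    fit: MVARFit,
    freqs: Sequence[float] | None = None,
    sampling_rate: float = 128.0,
) -> ConnectivitySpectrum:
    """Directed transfer function spectrum (row-normalized)."""
    f = default_freqs(sampling_rate) if freqs is None else np.asarray(freqs, float)
    _, h = spectral_transfer(fit, f, sampling_rate)
    mag = np.abs(h)
    denom = np.sqrt(np.sum(mag**2, axis=1, keepdims=True))  # row norms
    if np.any(denom <= 0):
        raise ZeroDivisionError("zero row norm in H(f)")
    return ConnectivitySpectrum("DTF", f, mag / denom, list(fit.channel_labels))


def band_average(
    spec: ConnectivitySpectrum,
    band_defs: Mapping[str, tuple[float, float]] | None = None,
) -> BandAdjacencySet:
    """Average a connectivity spectrum over frequency bands.

    Each band matrix entry (i, j) is the arithmetic mean of
    ``values[i, j, f]`` over grid bins with ``low <= f <= high``
    (closed interval at both edges).
    """
    defs = dict(DEFAULT_BANDS if band_defs is None else band_defs)
    bands: dict[str, np.ndarray] = {}
    for name, (low, high) in defs.items():
        mask = (spec.freqs >= low - 1e-9) & (spec.freqs <= high + 1e-9)
        if not np.any(mask):
            raise ValueError(
                f"band {name!r} [{low}, {high}] Hz contains no frequency bin; "
                "use a finer frequency grid"
            )
        bands[name] = spec.values[:, :, mask].mean(axis=2)
    return BandAdjacencySet(spec.method, bands, defs, list(spec.channel_labels))


def epoch_connectivity(
    epoch: np.ndarray,
    sampling_rate: float = 128.0,
    channel_labels: Sequence[str] | None = None,
    p_min: int = 1,
    p_max: int = 20,
    criterion: str = "bic",
    order: int | None = None,
    band_defs: Mapping[str, tuple[float, float]] | None = None,
    freq_step: float = DEFAULT_FREQ_STEP,
) -> tuple[BandAdjacencySet, BandAdjacencySet]:
    """Convenience: epoch -> (PDC bands, DTF bands) with order selection.

    ``order`` overrides the information-criterion search when given.
    """
    p = order if order is not None else select_order(epoch, p_min, p_max, criterion)
    fit = fit_mvar(epoch, p, channel_labels=channel_labels)
    f = default_freqs(sampling_rate, freq_step)
    pdc_bands = band_average(pdc(fit, f, sampling_rate), band_defs)
    dtf_bands = band_average(dtf(fit, f, sampling_rate), band_defs)
    return pdc_bands, dtf_bands
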