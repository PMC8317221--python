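"""Synthetic VAR cohort generation with known directed coupling.

Every downstream stage of the pipeline (MVAR fitting, PDC/DTF spectra,
graph metrics, classification) is validated against ground truth produced
here: stable vector-autoregressive processes

    x(n) = sum_{r=1..p} A_r x(n-r) + w(n)

whose off-diagonal coefficients define a known directed influence graph.
A two-group cohort emulates trained high-proficiency (Hp) and untrained
low-proficiency (Lp) operators: the Hp regime has denser and stronger
inter-channel coupling, so Hp networks come out with more and heavier
suprathreshold edges — the effect the analysis stage must recover.

Innovations are Gaussian with diagonal covariance (the minimal white-noise
assumption).  Sub-seeds for per-subject models are derived from the master
seed with a splitmix64 mix so that streams are reproducible yet
uncorrelated.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import DEFAULT_CHANNELS, RawRecording

#: Margin below 1 required of the companion spectral radius.
STABILITY_MARGIN = 0.02
#: How many times coefficient drawing is retried before giving up.
RETRY_BUDGET = 100


@dataclass(frozen=True)
class CouplingSpec:
    """Describes how off-diagonal (directed) VAR coupling is drawn.

    Parameters
    ----------
    density : float
        Probability in [0, 1] that any ordered channel pair (j -> i) gets
        a directed coupling coefficient.
    magnitude : (float, float)
        Range of absolute off-diagonal coefficient values.
    self_range : (float, float)
        Range of lag-1 diagonal (self-regression) coefficients.
    lag_decay : float
        Diagonal coefficients at lag r are the lag-1 diagonals scaled by
        ``lag_decay**(r-1)``, giving the process genuine order-p memory;
        directed (off-diagonal) coupling lives at lag 1 only, which keeps
        dense regimes inside the stability region.
    edges : sequence of (source, target, magnitude), optional
        Explicit edge list overriding random placement (used for
        hand-constructed models with known spectra).
    allow_negative : bool
        Draw random signs for off-diagonal couplings.  Directed-influence
        magnitudes (PDC/DTF) are sign-blind, and mixed signs keep dense
        models stable.
    """

    density: float = 0.25
    magnitude: tuple[float, float] = (0.2, 0.4)
    self_range: tuple[float, float] = (0.2, 0.4)
    lag_decay: float = 0.3
    edges: tuple[tuple[int, int, float], ...] | None = None
    allow_negative: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError(f"density must be in [0, 1], got {self.density}")
        lo, hi = self.magnitude
        if lo < 0 or hi < lo:
            raise ValueError("magnitude range must satisfy 0 <= low <= high")


#: Hp (trained) regime: dense, strong coupling.
HP_COUPLING = CouplingSpec(density=0.40, magnitude=(0.25, 0.45))
#: Lp (untrained) regime: sparse, weak coupling.
LP_COUPLING = CouplingSpec(density=0.15, magnitude=(0.10, 0.25))


@dataclass
class VARGroundTruth:
    """A stable VAR(p) model with its true directed coupling graph."""

    order: int
    coeffs: np.ndarray  # (p, N, N)
    noise_cov: np.ndarray  # (N, N)
    sampling_rate: float
    true_edges: frozenset[tuple[int, int]]  # (source j, target i)
    seed: int

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        """Companion-form matrix (Np x Np) of the VAR(p) recursion."""
        p, n, _ = self.coeffs.shape
        comp = np.zeros((n * p, n * p))
        comp[:n] = np.concatenate(list(self.coeffs), axis=1)
        if p > 1:
            comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def is_stable(self, margin: float = STABILITY_MARGIN) -> bool:
        return self.spectral_radius() < 1.0 - margin


@dataclass
class SyntheticSubject:
    """One simulated operator: a recording plus its generating model."""

    subject_id: str
    group: str  # "Hp" or "Lp"
    recording: RawRecording
    truth: VARGroundTruth


def splitmix64(*values: int) -> int:
    """Deterministically mix integers into a 64-bit sub-seed.

    The splitmix64 finalizer applied to the running combination of the
    inputs; successive indices produce decorrelated streams.
    """
    mask = (1 << 64) - 1
    z = 0
    for v in values:
        z = (z + (int(v) & mask) + 0x9E3779B97F4A7C15) & mask
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        z = z ^ (z >> 31)
    return z


def _edge_set(coeffs: np.ndarray) -> frozenset[tuple[int, int]]:
    """Ordered (source, target) pairs with a nonzero coefficient at any lag."""
    nz = np.any(coeffs != 0.0, axis=0)
    np.fill_diagonal(nz, False)
    return frozenset((int(j), int(i)) for i, j in zip(*np.nonzero(nz)))


def make_var_model(
    n_channels: int,
    order: int,
    coupling: CouplingSpec,
    seed: int,
    sampling_rate: float = 1000.0,
    noise_scale: float = 1.0,
) -> VARGroundTruth:
    """Draw a stable VAR model with the requested directed coupling.

    Diagonal lag-1 coefficients are drawn uniformly from
    ``coupling.self_range`` and decay by ``lag_decay`` at higher lags;
    off-diagonal couplings are placed at lag 1 on ordered channel pairs
    chosen with probability ``coupling.density`` (or on the explicit
    ``coupling.edges``), with magnitudes uniform in ``coupling.magnitude``.
    Drawing is retried (fresh coefficients, same stream) until the
    companion spectral radius is below ``1 - STABILITY_MARGIN``.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    if order < 1:
        raise ValueError("order must be >= 1")
    rng = np.random.default_rng(seed)

    for _ in range(RETRY_BUDGET):
        base = np.zeros((n_channels, n_channels))
        np.fill_diagonal(base, rng.uniform(*coupling.self_range, size=n_channels))
        if coupling.edges is not None:
            for src, tgt, mag in coupling.edges:
                if src == tgt:
                    raise ValueError("explicit edges must be off-diagonal")
                base[tgt, src] = mag
        elif coupling.density > 0:
            off = ~np.eye(n_channels, dtype=bool)
            pick = rng.random((n_channels, n_channels)) < coupling.density
            mags = rng.uniform(*coupling.magnitude, size=(n_channels, n_channels))
            if coupling.allow_negative:
                mags *= rng.choice([-1.0, 1.0], size=mags.shape)
            base[off & pick] = mags[off & pick]
        diag_part = np.diag(np.diag(base))
        coeffs = np.stack(
            [base]
            + [diag_part * coupling.lag_decay ** r for r in range(1, order)]
        )
        model = VARGroundTruth(
            order=order,
            coeffs=coeffs,
            noise_cov=noise_scale * np.eye(n_channels),
            sampling_rate=sampling_rate,
            true_edges=_edge_set(coeffs),
            seed=seed,
        )
        if model.is_stable():
            return model
    raise RuntimeError(
        f"no stable VAR({order}) model found in {RETRY_BUDGET} tries; "
        f"the coupling magnitude range {coupling.magnitude} (or self_range "
        f"{coupling.self_range}) is likely too large for {n_channels} channels"
    )


def simulate_var(
    model: VARGroundTruth,
    n_samples: int,
    burn_in: int = 1000,
    seed: int = 0,
    channel_labels: Sequence[str] | None = None,
) -> RawRecording:
    """Simulate the VAR recursion with Gaussian innovations.

    ``burn_in`` initial samples (started from zeros) are discarded so the
    retained signal is approximately stationary.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    if not model.is_stable():
        raise ValueError(
            f"refusing to simulate an unstable model "
            f"(spectral radius {model.spectral_radius():.4f})"
        )
    p, n, _ = model.coeffs.shape
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(model.noise_cov)
    total = n_samples + burn_in
    innov = rng.standard_normal((total, n)) @ chol.T
    # stacked coefficients (N, N*p) acting on the flattened lag window
    stacked = np.concatenate(list(model.coeffs), axis=1)
    x = np.zeros((total + p, n))
    for t in range(total):
        window = x[t : t + p][::-1].reshape(-1)  # [x(t-1); ...; x(t-p)]
        x[t + p] = stacked @ window + innov[t]
    data = x[p + burn_in :].T
    labels = (
        list(channel_labels)
        if channel_labels is not None
        else [f"CH{i + 1}" for i in range(n)]
    )
    return RawRecording(labels, model.sampling_rate, data)


def make_cohort(
    n_per_group: int = 10,
    hp_coupling: CouplingSpec = HP_COUPLING,
    lp_coupling: CouplingSpec = LP_COUPLING,
    duration_s: float = 300.0,
    sampling_rate: float = 1000.0,
    seed: int = 0,
    n_channels: int = len(DEFAULT_CHANNELS),
    order: int = 3,
    channel_labels: Sequence[str] = DEFAULT_CHANNELS,
    burn_in: int = 1000,
) -> list[SyntheticSubject]:
    """Assemble a two-group synthetic cohort of simulated operators.

    Each subject gets a fresh model drawn with a splitmix64 sub-seed of
    (master seed, subject index); Hp subjects use ``hp_coupling`` and Lp
    subjects ``lp_coupling``.  Defaults emulate the study design this
    package targets: 10 subjects per group, 8 channels labelled with the
    10-20 electrode names, 5 minutes at 1,000 Hz.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if hp_coupling.density < lp_coupling.density or (
        hp_coupling.magnitude[1] < lp_coupling.magnitude[1]
    ):
        warnings.warn(
            "Hp coupling is not at least as dense/strong as Lp coupling; "
            "group labels will not reflect a connectivity advantage",
            stacklevel=2,
        )
    if duration_s < 10.0:
        warnings.warn(
            f"duration {duration_s} s is shorter than one default 10 s epoch; "
            "downstream segmentation will fail",
            stacklevel=2,
        )
    labels = list(channel_labels)
    if len(labels) != n_channels:
        labels = [f"CH{i + 1}" for i in range(n_channels)]
    n_samples = int(round(duration_s * sampling_rate))
    subjects: list[SyntheticSubject] = []
    for k in range(2 * n_per_group):
        group = "Hp" if k < n_per_group else "Lp"
        spec = hp_coupling if group == "Hp" else lp_coupling
        sub_seed = splitmix64(seed, k) % (1 << 32)
        model = make_var_model(
            n_channels, order, spec, seed=sub_seed, sampling_rate=sampling_rate
        )
        rec = simulate_var(
            model,
            n_samples,
            burn_in=burn_in,
            seed=splitmix64(seed, k, 1) % (1 << 32),
            channel_labels=labels,
        )
        idx = k % n_per_group + 1
        subjects.append(
            SyntheticSubject(f"{group}{idx:02d}", group, rec, model)
        )
    return subjects


# ---------------------------------------------------------------------------
# Export

def write_text(rec: RawRecording, data_path: str | Path) -> None:
    """Write a recording as delimited text (one row per channel) + JSON sidecar."""
    data_path = Path(data_path)
    np.savetxt(data_path, rec.data, delimiter=",", fmt="%.6f")
    sidecar = Path(str(data_path) + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "channel_labels": list(rec.channel_labels),
                "sampling_rate": rec.sampling_rate,
            },
            indent=2,
        )
    )


def write_truth(subject: SyntheticSubject, path: str | Path) -> None:
    """Write a subject's ground truth (coefficients, edges, seed) to JSON."""
    t = subject.truth
    payload = {
        "subject_id": subject.subject_id,
        "group": subject.group,
        "order": t.order,
        "coeffs": t.coeffs.tolist(),
        "noise_cov": t.noise_cov.tolist(),
        "sampling_rate": t.sampling_rate,
        "true_edges": sorted(list(e) for e in t.true_edges),
        "seed": t.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def _edf_field(value: object, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _edf_number(v: float, width: int = 8) -> str:
    """Shortest decimal representation of ``v`` that fits the header field."""
    for prec in range(8, -1, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= width:
            return s
    raise ValueError(f"cannot represent {v} in {width} ascii bytes")


def write_edf(rec: RawRecording, path: str | Path, physical_dim: str = "uV") -> None:
    """Write a recording as a standard 16-bit EDF file.

    One data record per second (requires an integer sampling rate); the
    trailing partial second, if any, is dropped.  Samples are scaled to the
    per-channel physical min/max over the full signal.
    """
    sr = rec.sampling_rate
    if abs(sr - round(sr)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(sr))  # samples per 1 s record
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one 1 s EDF data record")
    ns = rec.n_channels
    data = rec.data[:, : n_records * spr]

    pmins = data.min(axis=1)
    pmaxs = data.max(axis=1)
    flat = pmaxs - pmins < 1e-12
    pmaxs[flat] = pmins[flat] + 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmaxs - pmins)
    digital = np.rint((data - pmins[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X X X X", 80),
            _edf_field(now.strftime("%d.%m.%y"), 8),
            _edf_field(now.strftime("%H.%M.%S"), 8),
            _edf_field(256 * (ns + 1), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(1, 8),
            _edf_field(ns, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_edf_field(lab, 16) for lab in rec.channel_labels),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field(physical_dim, 8) for _ in range(ns)),
            b"".join(_edf_field(_edf_number(v), 8) for v in pmins),
            b"".join(_edf_field(_edf_number(v), 8) for v in pmaxs),
            b"".join(_edf_field(dmin, 8) for _ in range(ns)),
            b"".join(_edf_field(dmax, 8) for _ in range(ns)),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field(spr, 8) for _ in range(ns)),
            b"".join(_edf_field("", 32) for _ in range(ns)),
        ]
    )
    records = digital.reshape(ns, n_records, spr)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            records[:, r, :].tofile(fh)
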