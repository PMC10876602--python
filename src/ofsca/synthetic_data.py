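"""Synthetic long-range-correlated trajectories and study cohorts.

This module generates the test bed for the whole pipeline: fractional
Gaussian noise (fGn) with a prescribed Hurst exponent, two-component
angular mixtures of independent fGn series, and full synthetic cohorts
mimicking a posturography study design (groups x conditions x repeated
trials with group-dependent suborthogonality offsets).

The fGn synthesis uses exact circulant-embedding (Davies-Harte) spectral
synthesis, which reproduces the theoretical fGn autocovariance

    gamma(k) = 0.5 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})

exactly (unit theoretical variance) in O(n log n); a Cholesky factorization
of the covariance matrix is used as a fallback for very short series or in
the rare case of a non-PSD circulant embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SingularMixingError
from .trajectory import Trajectory2D

__all__ = [
    "FgnSeries",
    "MixSpec",
    "GroupSpec",
    "CohortSpec",
    "fgn_autocovariance",
    "generate_fgn",
    "mix_components",
    "mixing_matrix",
    "make_mixed_trajectory",
    "simulate_cohort",
    "default_cohort_spec",
]

#: angular separation (in degrees, mod 180) below which two orientations are
#: treated as collinear and mixing is refused
COLLINEARITY_TOL_DEG = 1e-9


def fgn_autocovariance(hurst: float, lags) -> np.ndarray:
    """Theoretical autocovariance of unit-variance fGn at integer ``lags``."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1.0) ** h2 - 2.0 * k**h2 + np.abs(k - 1.0) ** h2)


@dataclass
class FgnSeries:
    """A sampled fractional Gaussian noise series."""

    values: np.ndarray
    hurst: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("an fGn series needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fGn series contains non-finite values")
        if not (0.0 < self.hurst < 1.0):
            raise ValueError(f"Hurst exponent must be in (0, 1), got {self.hurst}")

    def __len__(self) -> int:
        return self.values.size


def _davies_harte(hurst: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact spectral synthesis of fGn via circulant embedding.

    Returns ``None``-free array of length ``n`` or raises ``FloatingPointError``
    if the circulant eigenvalues are substantially negative (handled by the
    Cholesky fallback in :func:`generate_fgn`).
    """
    g = fgn_autocovariance(hurst, np.arange(n + 1))
    # first row of the 2n circulant embedding: g0..gn, g_{n-1}..g1
    row = np.concatenate([g, g[-2:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        raise FloatingPointError("circulant embedding not PSD")
    lam = np.clip(lam, 0.0, None)
    m = row.size  # 2n
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    # Re(F (sqrt(lam) z)) / sqrt(m) has covariance equal to the circulant
    x = np.fft.fft(np.sqrt(lam) * z).real / np.sqrt(m)
    return x[:n]


def _cholesky_fgn(hurst: float, n: int, rng: np.random.Generator) -> np.ndarray:
    cov = fgn_autocovariance(hurst, np.subtract.outer(np.arange(n), np.arange(n)))
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return chol @ rng.standard_normal(n)


def generate_fgn(hurst: float, n: int,
                 seed: int | np.random.SeedSequence) -> FgnSeries:
    """Generate unit-variance fractional Gaussian noise.

    Parameters
    ----------
    hurst : float
        Hurst exponent in (0, 1); 0.5 gives white noise, > 0.5 persistent
        long-range correlation.
    n : int
        Series length (>= 2).
    seed : int or numpy SeedSequence
        Seed for the pseudo-random generator; output is deterministic
        (bitwise) for a fixed seed.
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError(f"Hurst exponent must be in (0, 1), got {hurst}")
    if n < 2:
        raise ValueError(f"series length must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    if n < 64:
        values = _cholesky_fgn(hurst, n, rng)
    else:
        try:
            values = _davies_harte(hurst, n, rng)
        except FloatingPointError:  # pragma: no cover - embedding is PSD for fGn
            values = _cholesky_fgn(hurst, n, rng)
    return FgnSeries(values=values, hurst=hurst, seed=seed)


def _angular_separation_deg(a: float, b: float) -> float:
    """Separation of two orientations in degrees, reduced to [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def mixing_matrix(theta1_deg: float, theta2_deg: float) -> np.ndarray:
    """The 2x2 angular mixing matrix ``[[cos t1, cos t2], [sin t1, sin t2]]``.

    Trig values within float rounding of zero are snapped to 0 so that
    axis-aligned orientations (0, 90 deg) mix exactly.
    """
    t1, t2 = np.deg2rad([theta1_deg, theta2_deg])
    m = np.array([[np.cos(t1), np.cos(t2)], [np.sin(t1), np.sin(t2)]])
    m[np.abs(m) < 1e-15] = 0.0
    return m


def mix_components(eps1, eps2, theta1_deg: float, theta2_deg: float,
                   fs: float = 100.0) -> Trajectory2D:
    """Mix two component series at orientations ``theta1``/``theta2`` (degrees).

    ``c1 = eps1*cos(theta1) + eps2*cos(theta2)``;
    ``c2 = eps1*sin(theta1) + eps2*sin(theta2)``.
    """
    v1 = eps1.values if isinstance(eps1, FgnSeries) else np.asarray(eps1, float)
    v2 = eps2.values if isinstance(eps2, FgnSeries) else np.asarray(eps2, float)
    if v1.size != v2.size:
        raise ValueError(f"component length mismatch: {v1.size} != {v2.size}")
    sep = _angular_separation_deg(theta1_deg, theta2_deg)
    if sep < COLLINEARITY_TOL_DEG:
        raise SingularMixingError(
            f"orientations {theta1_deg} and {theta2_deg} deg are collinear (mod 180)"
        )
    m = mixing_matrix(theta1_deg, theta2_deg)
    c1 = m[0, 0] * v1 + m[0, 1] * v2
    c2 = m[1, 0] * v1 + m[1, 1] * v2
    return Trajectory2D(c1, c2, fs=fs)


@dataclass
class MixSpec:
    """Generative parameters for a two-component mixed-fGn trajectory.

    Angles are orientations in degrees in [0, 180); ``h1 > h2`` by the
    package-wide convention that component 1 carries the stronger
    long-range correlation.
    """

    h1: float = 0.60
    h2: float = 0.40
    theta1: float = 15.0
    theta2: float = 75.0
    n: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.h2 < self.h1 < 1.0):
            raise ValueError(
                f"need 0 < h2 < h1 < 1, got h1={self.h1}, h2={self.h2}"
            )
        if _angular_separation_deg(self.theta1, self.theta2) < COLLINEARITY_TOL_DEG:
            raise ValueError("theta1 and theta2 must differ (mod 180 deg)")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def make_mixed_trajectory(spec: MixSpec, fs: float = 100.0):
    """Build the mixed-fGn trajectory described by ``spec``.

    Each component is standardized to zero mean, unit sample variance
    before mixing (component amplitudes are not part of the model).
    Returns ``(trajectory, truth)`` where ``truth`` is a dict of the latent
    generative values.
    """
    ss = np.random.SeedSequence([np.uint32(spec.seed)])
    s1, s2 = ss.spawn(2)
    eps1 = generate_fgn(spec.h1, spec.n, s1)
    eps2 = generate_fgn(spec.h2, spec.n, s2)
    v1 = (eps1.values - eps1.values.mean()) / eps1.values.std()
    v2 = (eps2.values - eps2.values.mean()) / eps2.values.std()
    traj = mix_components(v1, v2, spec.theta1, spec.theta2, fs=fs)
    truth = {
        "h1": spec.h1,
        "h2": spec.h2,
        "theta1": spec.theta1 % 180.0,
        "theta2": spec.theta2 % 180.0,
        "delta_theta": _angular_separation_deg(spec.theta1, spec.theta2),
        "seed": spec.seed,
        "eps1": v1,
        "eps2": v2,
    }
    return traj, truth


# --------------------------------------------------------------------------
# cohort simulation


@dataclass
class GroupSpec:
    """One participant group of a synthetic cohort."""

    label: str
    n_participants: int
    delta_offset: float  # degrees added to the baseline separation
    h1_mean: float = 0.70
    h2_mean: float = 0.45

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("group needs >= 1 participant")


@dataclass
class CohortSpec:
    """Generative description of a synthetic posturography study.

    The realized true separation of a trial is::

        baseline_delta + group.delta_offset + condition_offset
        + participant_effect + trial_noise

    resampled (bounded retries) until it lies in (0, 90] degrees; the first
    component orientation is drawn uniformly per trial, the second placed at
    the realized separation.
    """

    groups: list[GroupSpec]
    condition_offsets: dict = field(default_factory=lambda: {
        (0, 0): 0.0, (1, 0): -3.8, (0, 1): -6.4, (1, 1): -10.2,
    })
    trials_per_condition: int = 3
    n_samples: int = 3000
    fs: float = 100.0
    baseline_delta: float = 90.0
    between_participant_sd: float = 4.0
    within_trial_sd: float = 4.0
    h_sd: float = 0.05
    min_h_gap: float = 0.10
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")

    @property
    def n_trials(self) -> int:
        cond = len(self.condition_offsets)
        return sum(g.n_participants for g in self.groups) * cond * self.trials_per_condition


def default_cohort_spec(seed: int = 0, n_samples: int = 3000) -> CohortSpec:
    """The study-like default cohort: 27 YA / 22 OA / 32 PN / 32 PM.

    Group offsets mirror the magnitude ordering of the study's group
    contrasts (YA baseline ~90 deg, OA ~ -6, Parkinson's ~ -20).
    """
    return CohortSpec(
        groups=[
            GroupSpec("YA", 27, 0.0),
            GroupSpec("OA", 22, -6.0),
            GroupSpec("PN", 32, -21.0),
            GroupSpec("PM", 32, -19.0),
        ],
        n_samples=n_samples,
        seed=seed,
    )


def _draw_truncated(rng, mean, sd, lo, hi, max_retries):
    for _ in range(max_retries):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return x
    raise RuntimeError(
        f"could not draw a separation in ({lo}, {hi}] around {mean} "
        f"after {max_retries} retries"
    )


def simulate_cohort(spec: CohortSpec):
    """Simulate a full cohort of mixed-fGn trials.

    Returns ``(trials, truth)``: ``trials`` is a list of
    ``(meta_dict, Trajectory2D)`` and ``truth`` a tidy DataFrame with one
    row per trial recording every latent value (true orientations,
    separation, Hurst exponents, per-trial seed). Fully reproducible from
    ``spec.seed``; per-trial randomness is derived from a deterministic
    (seed, trial-counter) sequence.
    """
    trials = []
    rows = []
    counter = 0
    for group in spec.groups:
        for p in range(group.n_participants):
            pid = f"{group.label}{p:03d}"
            prng = np.random.default_rng(
                np.random.SeedSequence([np.uint32(spec.seed), 1, counter])
            )
            participant_effect = prng.normal(0.0, spec.between_participant_sd)
            for (eyes_closed, unstable), cond_offset in sorted(
                spec.condition_offsets.items()
            ):
                for trial_index in range(spec.trials_per_condition):
                    trng = np.random.default_rng(
                        np.random.SeedSequence([np.uint32(spec.seed), 2, counter,
                                                eyes_closed, unstable, trial_index])
                    )
                    mean_sep = (spec.baseline_delta + group.delta_offset
                                + cond_offset + participant_effect)
                    sep = _draw_truncated(trng, mean_sep, spec.within_trial_sd,
                                          0.0, 90.0, spec.max_retries)
                    h1 = float(np.clip(trng.normal(group.h1_mean, spec.h_sd),
                                       0.55, 0.95))
                    h2 = float(np.clip(trng.normal(group.h2_mean, spec.h_sd),
                                       0.05, h1 - spec.min_h_gap))
                    theta1 = float(trng.uniform(0.0, 180.0))
                    theta2 = (theta1 - sep) % 180.0
                    trial_seed = int(trng.integers(0, 2**31 - 1))
                    traj, _ = make_mixed_trajectory(
                        MixSpec(h1=h1, h2=h2, theta1=theta1, theta2=theta2,
                                n=spec.n_samples, seed=trial_seed),
                        fs=spec.fs,
                    )
                    meta = {
                        "participant_id": pid,
                        "group": group.label,
                        "eyes_closed": eyes_closed,
                        "unstable": unstable,
                        "trial_index": trial_index,
                        "fs": spec.fs,
                    }
                    trials.append((meta, traj))
                    rows.append({**meta,
                                 "true_theta1": theta1, "true_theta2": theta2,
                                 "true_delta_theta": sep,
                                 "true_h1": h1, "true_h2": h2,
                                 "participant_effect": participant_effect,
                                 "trial_seed": trial_seed})
            counter += 1
    truth = pd.DataFrame(rows)
    return trials, truth
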