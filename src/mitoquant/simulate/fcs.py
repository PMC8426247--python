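"""FCS curve simulators: a Brownian-dynamics particle oracle and a fast
analytic-curve generator with planted outliers.

The particle oracle integrates point emitters in a periodic box; each
particle switches between a freely diffusing state and an immobile bound
state with rates ``k*on`` (binding) and ``koff`` (release).  The
fluorescence trace is the sum of 3-D Gaussian observation-volume weights
over particles, and the autocorrelation is estimated on log-spaced lags.
Particle numbers are drawn Poisson per independent segment and the
correlation numerator/denominator are pooled across segments, so the
estimator is grand-canonical and free of the fixed-N amplitude
suppression of a closed box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numba
import numpy as np

from ..fcs_kinetics import AcfCurve, ObservationVolume, acf_full_model

__all__ = ["FcsSimParams", "AcfDatasetTruth", "simulate_particle_acf", "generate_acf_dataset"]


@dataclass(frozen=True)
class FcsSimParams:
    """Parameters of a simulated FCS experiment.

    ``duration`` is the length of one measurement segment (the paper's
    unit is a 5 s measurement); the particle oracle runs ``n_repeats``
    independent segments and pools them.
    """

    n_mean: float = 5.0            # mean molecules in the observation volume
    Df: float = 20.0               # um^2/s
    kstar_on: float = 0.0          # 1/s
    koff: float = 1.0              # 1/s
    beam_waist_w: float = 0.2      # um
    structural_parameter_s: float = 5.0
    duration: float = 5.0          # s per segment / measurement
    timestep: float = 2e-5         # s, particle oracle only
    box_size: float = 2.0          # um, periodic box edge
    n_curves: int = 5
    outlier_rate: float = 0.0
    noise_sd: float = 0.02         # relative to G(0)
    n_repeats: int = 8             # independent segments of the particle oracle
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kstar_on < 0 or self.koff < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must lie in [0, 1]")
        if self.n_curves < 1:
            raise ValueError("need at least one curve")
        if self.n_mean <= 0:
            raise ValueError("n_mean must be positive")
        if self.box_size < 10 * self.beam_waist_w:
            raise ValueError("box must be at least 10 beam waists wide")

    @property
    def volume(self) -> ObservationVolume:
        return ObservationVolume(self.beam_waist_w, self.structural_parameter_s)

    @property
    def bound_fraction(self) -> float:
        tot = self.kstar_on + self.koff
        return self.kstar_on / tot if tot > 0 else 0.0


@dataclass
class AcfDatasetTruth:
    """Ground truth of a generated curve set."""

    params: FcsSimParams
    model_g: np.ndarray
    keep_flags: list[bool]  # False for planted outliers


@numba.njit(cache=True)
def _trace(n_particles, n_steps, dt, step_sd, p_bind, p_release, f_bound0,
           box, cx, inv_w2, inv_wz2, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    pos = np.random.uniform(0.0, box, (n_particles, 3))
    bound = np.empty(n_particles, dtype=numba.boolean)
    for i in range(n_particles):
        bound[i] = np.random.random() < f_bound0
    out = np.empty(n_steps)
    for t in range(n_steps):
        f = 0.0
        for i in range(n_particles):
            u = np.random.random()
            if bound[i]:
                if u < p_release:
                    bound[i] = False
            else:
                if u < p_bind:
                    bound[i] = True
                else:
                    for k in range(3):
                        x = pos[i, k] + np.random.normal() * step_sd
                        x = x % box
                        pos[i, k] = x
            dx = pos[i, 0] - cx
            if dx > box / 2:
                dx -= box
            elif dx < -box / 2:
                dx += box
            dy = pos[i, 1] - cx
            if dy > box / 2:
                dy -= box
            elif dy < -box / 2:
                dy += box
            dz = pos[i, 2] - cx
            if dz > box / 2:
                dz -= box
            elif dz < -box / 2:
                dz += box
            arg = (dx * dx + dy * dy) * inv_w2 + dz * dz * inv_wz2
            if arg < 14.0:  # weight > ~7e-13; farther particles contribute nothing
                f += np.exp(-2.0 * arg)
        out[t] = f
    return out


def _raw_autocorr(f: np.ndarray, max_lag: int) -> np.ndarray:
    """Unbiased raw correlation <F(t) F(t+k)> for k = 0..max_lag via FFT."""
    n = f.size
    m = 1 << int(np.ceil(np.log2(2 * n)))
    ft = np.fft.rfft(f, m)
    r = np.fft.irfft(ft * np.conj(ft), m)[: max_lag + 1]
    counts = n - np.arange(max_lag + 1)
    return r / counts


def simulate_particle_acf(params: FcsSimParams) -> AcfCurve:
    """Brownian-dynamics oracle: simulate particles, return the pooled
    normalized autocorrelation on log-spaced lags with per-lag standard
    errors (scatter across independent segments).
    """
    dt = params.timestep
    tau_d = params.beam_waist_w**2 / (4.0 * params.Df) if params.Df > 0 else np.inf
    if dt > tau_d / 10 or (params.koff > 0 and dt > 0.1 / params.koff):
        warnings.warn("timestep coarse relative to diffusion/binding timescales")
    vol = params.volume
    conc = params.n_mean / vol.volume_um3
    lam = conc * params.box_size**3
    if lam < 1:
        raise ValueError("fewer than one particle expected in the box")
    n_steps = int(round(params.duration / dt))
    if n_steps < 8:
        raise ValueError("duration too short for the chosen timestep")
    # log-spaced integer lags, from dt to a tenth of the segment
    max_lag = min(max(n_steps // 10, 10), n_steps - 2)
    lag_idx = np.unique(
        np.round(np.geomspace(1, max_lag, 48)).astype(int)
    )
    rng = np.random.default_rng(params.seed)
    p_bind = -np.expm1(-params.kstar_on * dt)
    p_release = -np.expm1(-params.koff * dt)
    step_sd = np.sqrt(2.0 * params.Df * dt)
    inv_w2 = 1.0 / params.beam_waist_w**2
    inv_wz2 = 1.0 / (params.beam_waist_w * params.structural_parameter_s) ** 2
    s1 = np.empty(params.n_repeats)
    s2 = np.empty((params.n_repeats, lag_idx.size))
    raw0 = np.empty((params.n_repeats, lag_idx.size))
    for m in range(params.n_repeats):
        n_p = int(rng.poisson(lam))
        n_p = max(n_p, 1)
        f = _trace(
            n_p, n_steps, dt, step_sd, p_bind, p_release, params.bound_fraction,
            params.box_size, params.box_size / 2.0, inv_w2, inv_wz2,
            int(rng.integers(0, 2**31 - 1)),
        )
        s1[m] = f.mean()
        raw = _raw_autocorr(f, int(lag_idx[-1]))
        raw0[m] = raw[lag_idx]
        s2[m] = raw[lag_idx]
    denom = s1.mean() ** 2
    g = s2.mean(axis=0) / denom - 1.0
    g_per = raw0 / denom - 1.0
    se = g_per.std(axis=0, ddof=1) / np.sqrt(params.n_repeats) if params.n_repeats > 1 else None
    return AcfCurve(lags=lag_idx * dt, g=g, se=se, nucleus_id="particle-oracle")


def generate_acf_dataset(
    params: FcsSimParams,
    lags: np.ndarray | None = None,
) -> tuple[list[AcfCurve], AcfDatasetTruth]:
    """Noisy analytic-model curves with a planted fraction of outliers.

    Generates ``n_curves`` curves from the reaction-diffusion model with
    i.i.d. Gaussian noise of ``noise_sd`` relative to the amplitude;
    ``floor(outlier_rate * n_curves)`` curves are corrupted (amplitude
    scaled by U(2, 5), or an additive linear drift, alternating) and
    flagged False in the ground truth.
    """
    if lags is None:
        lags = np.geomspace(1e-5, 1.0, 48)
    rng = np.random.default_rng(params.seed)
    g_model = acf_full_model(
        lags, params.n_mean, params.Df, params.kstar_on, params.koff, params.volume
    )
    g0 = g_model[0]
    n_out = int(np.floor(params.outlier_rate * params.n_curves))
    outlier_ids = set(rng.choice(params.n_curves, size=n_out, replace=False).tolist())
    curves, flags = [], []
    for i in range(params.n_curves):
        g = g_model + params.noise_sd * g0 * rng.standard_normal(lags.size)
        if i in outlier_ids:
            if (i % 2) == 0:
                g = g * rng.uniform(2.0, 5.0)
            else:
                g = g + g0 * np.linspace(0.0, rng.uniform(1.0, 3.0), lags.size)
        curves.append(AcfCurve(lags=lags, g=g, curve_id=f"curve{i}"))
        flags.append(i not in outlier_ids)
    return curves, AcfDatasetTruth(params=params, model_g=g_model, keep_flags=flags)


def simulate_nucleus(
    params: FcsSimParams, n_measurements: int | None = None
) -> tuple[list[AcfCurve], AcfDatasetTruth]:
    """Convenience wrapper: one nucleus = ``n_curves`` measurements."""
    if n_measurements is not None:
        params = replace(params, n_curves=n_measurements)
    return generate_acf_dataset(params)
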