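"""Brownian-dynamics control in a spherical cell.

Free diffusion of non-interacting point particles (vesicle proxies) between
a reflecting spherical nucleus and a reflecting spherical plasma membrane.
At equilibrium the particle density is uniform over the allowed shell, so
the fraction of particles per radial slice is proportional to the slice
volume — the property used to check that distance distributions measured in
irregular reconstructed cell shapes are not artifacts of deformation.

Defaults follow the original control: 1000 μs total, configurations
sampled every 50 μs once the trajectory has run at least 900 μs.  The
diffusion coefficient only sets how fast equilibrium is reached; the
default is large enough that the RMS free displacement over the burn-in
exceeds the cell diameter (fully mixed well before sampling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BDConfig:
    """Simulation parameters (lengths nm, times μs, D in nm²/μs)."""

    cell_radius_nm: float = 3600.0
    nucleus_radius_nm: float = 1700.0
    n_particles: int = 1000
    diffusion_coefficient: float = 1.0e4
    timestep_us: float = 1.0
    total_time_us: float = 1000.0
    sample_interval_us: float = 50.0
    burn_in_us: float = 900.0
    seed: int = 0
    reflection: str = "specular"  # or "reject" (resample the step)

    def validate(self) -> None:
        if not 0 <= self.nucleus_radius_nm < self.cell_radius_nm:
            raise ValueError("need 0 <= nucleus radius < cell radius")
        if self.timestep_us <= 0 or self.timestep_us > self.sample_interval_us:
            raise ValueError("need 0 < timestep <= sample_interval")
        if not self.burn_in_us < self.total_time_us:
            raise ValueError("burn-in must be shorter than the total time")
        if self.n_particles <= 0:
            raise ValueError("need at least one particle")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.reflection not in ("specular", "reject"):
            raise ValueError("reflection must be 'specular' or 'reject'")

    @property
    def step_sigma_nm(self) -> float:
        """Per-axis Gaussian step SD √(2·D·dt)."""
        return float(np.sqrt(2.0 * self.diffusion_coefficient * self.timestep_us))


def _uniform_shell(rng, n, r_inner, r_outer) -> np.ndarray:
    """Uniform positions in a spherical shell by rejection from the cube."""
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = rng.uniform(-r_outer, r_outer, size=(2 * (n - filled) + 16, 3))
        r = np.linalg.norm(cand, axis=1)
        good = cand[(r <= r_outer) & (r >= r_inner)]
        take = min(len(good), n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def _reflect_radial(pos: np.ndarray, r_inner: float, r_outer: float) -> np.ndarray:
    """Mirror positions across the violated sphere surface (radially)."""
    for _ in range(16):
        r = np.linalg.norm(pos, axis=1)
        out = r > r_outer
        if out.any():
            pos[out] *= ((2.0 * r_outer - r[out]) / r[out])[:, None]
        if r_inner > 0:
            r = np.linalg.norm(pos, axis=1)
            inn = r < r_inner
            if inn.any():
                pos[inn] *= ((2.0 * r_inner - r[inn]) / np.maximum(r[inn], 1e-9))[:, None]
        r = np.linalg.norm(pos, axis=1)
        if not (np.any(r > r_outer) or (r_inner > 0 and np.any(r < r_inner))):
            break
    else:
        # pathological step (dt far too large): clamp to mid-shell radius
        r = np.linalg.norm(pos, axis=1)
        bad = (r > r_outer) | (r < r_inner)
        mid = (r_inner + r_outer) / 2.0
        pos[bad] *= (mid / np.maximum(r[bad], 1e-9))[:, None]
    return pos


def simulate(config: BDConfig) -> tuple[np.ndarray, np.ndarray]:
    """Run the simulation; returns (sample_times_us, positions).

    ``positions`` has shape ``(n_frames, n_particles, 3)`` in nm; frames are
    taken at every multiple of ``sample_interval_us`` that is ≥ the burn-in
    (the start configuration counts as t = 0 and is never sampled unless
    burn_in is 0).
    """
    config.validate()
    shell = config.cell_radius_nm - config.nucleus_radius_nm
    if config.step_sigma_nm > shell:
        import warnings

        dt_suggest = (shell / 2.0) ** 2 / (2.0 * max(config.diffusion_coefficient, 1e-12))
        warnings.warn(
            f"step SD {config.step_sigma_nm:.0f} nm exceeds the shell thickness "
            f"{shell:.0f} nm; consider timestep <= {dt_suggest:.3g} us",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    pos = _uniform_shell(rng, config.n_particles, config.nucleus_radius_nm, config.cell_radius_nm)
    r0 = np.linalg.norm(pos, axis=1)
    if np.any(r0 > config.cell_radius_nm) or np.any(r0 < config.nucleus_radius_nm):
        raise ValueError("particle initialized outside the allowed shell")

    n_steps = int(round(config.total_time_us / config.timestep_us))
    sample_every = max(int(round(config.sample_interval_us / config.timestep_us)), 1)
    sigma = config.step_sigma_nm
    frames, times = [], []
    for step in range(1, n_steps + 1):
        if sigma > 0:
            trial = pos + rng.normal(0.0, sigma, size=pos.shape)
            if config.reflection == "specular":
                pos = _reflect_radial(trial, config.nucleus_radius_nm, config.cell_radius_nm)
            else:  # reject: redraw the step for violating particles
                for _ in range(64):
                    r = np.linalg.norm(trial, axis=1)
                    bad = (r > config.cell_radius_nm) | (r < config.nucleus_radius_nm)
                    if not bad.any():
                        break
                    trial[bad] = pos[bad] + rng.normal(0.0, sigma, size=(int(bad.sum()), 3))
                else:
                    trial = _reflect_radial(trial, config.nucleus_radius_nm, config.cell_radius_nm)
                pos = trial
        t = step * config.timestep_us
        if step % sample_every == 0 and t >= config.burn_in_us:
            frames.append(pos.copy())
            times.append(t)
    return np.asarray(times), np.asarray(frames)


def radial_profile(
    samples: np.ndarray,
    cell_radius_nm: float,
    nucleus_radius_nm: float = 0.0,
    n_shells: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Fractions per equal-width shell of normalized PM distance, + analytic.

    PM distance of a particle at radius r is R − r, normalized by R.  Shells
    divide the allowed range [0, 1 − r_n/R] evenly.  Returns
    ``(simulated_fractions, analytic_volume_fractions)``; at equilibrium
    they agree within sampling error.
    """
    if samples.size == 0:
        raise ValueError("no samples")
    pos = samples.reshape(-1, 3)
    R, rn = cell_radius_nm, nucleus_radius_nm
    d = (R - np.linalg.norm(pos, axis=1)) / R
    d_max = 1.0 - rn / R
    edges = np.linspace(0.0, d_max, n_shells + 1)
    idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_shells - 1)
    counts = np.bincount(idx, minlength=n_shells)
    fractions = counts / len(d)
    outer = (1.0 - edges[:-1]) ** 3
    inner = (1.0 - edges[1:]) ** 3
    analytic = (outer - inner) / (1.0 - (rn / R) ** 3)
    return fractions, analytic
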