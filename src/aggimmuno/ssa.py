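"""Exact stochastic simulation of the aggregate--BCR binding network.

Direct-method (Gillespie) event simulation of the same sequential binding
scheme integrated deterministically in :mod:`aggimmuno.crosslink`, run at
small copy numbers in a virtual reaction volume.  Used purely as a
validation oracle for the ODE engine: for mass-action kinetics the direct
method is exact, so replicate means at matched parameters must agree with
the ODE solution up to finite-copy-number fluctuations.

Bimolecular propensities use the per-molecule rate c = k_on / (N_A * V)
with k_on converted from pM^-1 day^-1; unimolecular dissociation rates are
used unchanged.  Statistical factors (free sites, bound sites) match the
deterministic fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import pM_to_molecules_per_L
from .crosslink import CrosslinkParams, rate_schedule

__all__ = ["SsaConfig", "SsaResult", "simulate_ssa", "counts_from_params"]

MAX_TOTAL_MOLECULES = 10_000


def counts_from_params(params: CrosslinkParams, volume_L: float) -> tuple[int, int]:
    """Initial integer copy numbers (aggregates, BCRs) in the virtual volume."""
    a = int(round(pM_to_molecules_per_L(params.Aga0) * volume_L))
    b = int(round(pM_to_molecules_per_L(params.BCR0) * volume_L))
    return a, b


@dataclass(frozen=True)
class SsaConfig:
    """Configuration of the stochastic oracle.

    ``volume_L`` sets the copy-number scale; the total initial molecule
    count must stay at or below 10^4 (the oracle targets small instances).
    """

    params: CrosslinkParams
    volume_L: float
    t_end: float
    seed: int
    n_replicates: int = 100

    def __post_init__(self) -> None:
        if self.volume_L <= 0:
            raise ValueError(f"volume must be > 0 L, got {self.volume_L}")
        if self.t_end <= 0:
            raise ValueError(f"t_end must be > 0, got {self.t_end}")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        a, b = counts_from_params(self.params, self.volume_L)
        if a + b > MAX_TOTAL_MOLECULES:
            raise ValueError(
                f"total initial molecules {a + b} exceeds the oracle limit "
                f"{MAX_TOTAL_MOLECULES}; shrink the volume"
            )


@dataclass
class SsaResult:
    """Replicate statistics of the species counts at t_end.

    ``mean`` and ``stderr`` are length n+2 arrays ordered like the ODE
    state vector: free aggregate, free BCR, Ag_aBCR_1..Ag_aBCR_n.
    """

    mean: np.ndarray
    stderr: np.ndarray
    samples: np.ndarray  # shape (n_replicates, n + 2)
    config: SsaConfig
    initial_counts: tuple[int, int]

    def mean_concentration_pM(self) -> np.ndarray:
        return self.mean / pM_to_molecules_per_L(1.0) / self.config.volume_L


def _run_one(
    rng: np.random.Generator,
    a0: int,
    b0: int,
    n: int,
    c_bind: float,
    k_off: np.ndarray,
    t_end: float,
) -> np.ndarray:
    # state: x[0] = free aggregate, x[1] = free BCR, x[2 + i] = Ag_aBCR_{i+1}
    x = np.zeros(n + 2, dtype=np.int64)
    x[0], x[1] = a0, b0
    free_sites = np.arange(n, 0, -1)  # n - i + 1 for step i = 1..n
    bonds = np.arange(1, n + 1)
    t = 0.0
    while True:
        prev = np.empty(n, dtype=np.int64)
        prev[0] = x[0]
        prev[1:] = x[2:-1]
        a_bind = c_bind * x[1] * free_sites * prev
        a_diss = bonds * k_off * x[2:]
        total = a_bind.sum() + a_diss.sum()
        if total <= 0.0:
            break  # absorbing state (e.g. k_on = 0 and nothing bound)
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        u = rng.random() * total
        cum = np.cumsum(np.concatenate([a_bind, a_diss]))
        j = int(np.searchsorted(cum, u, side="right"))
        if j < n:  # binding step j+1: prev complex + BCR -> complex
            i = j  # forms Ag_aBCR_{i+1}
            if i == 0:
                x[0] -= 1
            else:
                x[1 + i] -= 1
            x[2 + i] += 1
            x[1] -= 1
        else:  # dissociation from Ag_aBCR_{i+1}
            i = j - n
            x[2 + i] -= 1
            if i == 0:
                x[0] += 1
            else:
                x[1 + i] += 1
            x[1] += 1
    return x


def simulate_ssa(config: SsaConfig) -> SsaResult:
    """Replicate means and standard errors of species counts at ``t_end``.

    Reproducible given ``seed``: replicate r uses an independent stream
    spawned from (seed, r).  A zero-propensity deadlock before ``t_end``
    simply freezes the state (valid absorbing outcome).
    """
    p = config.params
    a0, b0 = counts_from_params(p, config.volume_L)
    _, k_off = rate_schedule(p.k_on, p.Ka, p.decay_base, p.n)
    # pM^-1 day^-1 -> per-molecule-pair per day in volume V
    c_bind = p.k_on / (pM_to_molecules_per_L(1.0) * config.volume_L)
    samples = np.empty((config.n_replicates, p.n + 2))
    for r in range(config.n_replicates):
        rng = np.random.default_rng([config.seed, r])
        samples[r] = _run_one(rng, a0, b0, p.n, c_bind, k_off, config.t_end)
    mean = samples.mean(axis=0)
    stderr = samples.std(axis=0, ddof=1) / np.sqrt(config.n_replicates)
    return SsaResult(mean=mean, stderr=stderr, samples=samples,
                     config=config, initial_counts=(a0, b0))
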