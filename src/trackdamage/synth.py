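"""Synthetic electron-track generator.

A seeded toy model that stands in for a full track-structure transport
engine: events are laid down along an isotropic random walk with
exponentially distributed step lengths, so the spatial density of
inelastic events — the only track property the cluster analysis and
yield model consume — is directly controlled by the mean free path.
Per-event deposited energies are drawn from a normal distribution
truncated at the 1 eV transport cut-off.

``generate_blob`` builds degenerate fixtures: *n* events uniform in a
ball.  With radius ≤ half the linkage distance every pair links and
every site sees all *n* events, giving exact, analytically known
cluster sizes for classification tests.

All randomness comes from :func:`numpy.random.default_rng` (PCG64), a
named, versioned generator, so identical parameters and seed give
bit-identical event sets across runs and releases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .events import EDEP_CUTOFF_EV, EventSet

__all__ = ["TrackParams", "generate_track", "generate_blob"]


@dataclass(frozen=True)
class TrackParams:
    """Parameters of the random-walk track model.

    Defaults emulate a low-energy electron slowing down in liquid
    water: a few-nm mean free path between inelastic events and a mean
    energy loss of a few tens of eV per event.

    Attributes
    ----------
    n_events : int
        Number of events to place (exactly).
    mean_free_path_nm : float
        Mean step length between successive events, nm.  Smaller values
        give denser tracks and hence more linkages and larger clusters.
    edep_mean_eV, edep_sd_eV : float
        Mean and standard deviation of the per-event deposited energy,
        truncated below at the 1 eV cut-off.
    p_ionization : float
        Probability that an event is an ionization (vs. excitation);
        the kind label is carried through but never weighted.
    seed : int
        RNG seed; the generator is a pure function of its arguments.
    """

    n_events: int = 1000
    mean_free_path_nm: float = 5.0
    edep_mean_eV: float = 30.0
    edep_sd_eV: float = 10.0
    p_ionization: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if not self.mean_free_path_nm > 0:
            raise ValueError("mean_free_path_nm must be > 0")
        if self.edep_mean_eV < EDEP_CUTOFF_EV:
            raise ValueError(f"edep_mean_eV must be >= {EDEP_CUTOFF_EV} eV")
        if self.edep_sd_eV < 0:
            raise ValueError("edep_sd_eV must be >= 0")
        if not 0.0 <= self.p_ionization <= 1.0:
            raise ValueError("p_ionization must be in [0, 1]")


def _random_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Isotropic unit vectors (normalized standard-normal triples)."""
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # a zero norm has probability 0; guard anyway
    norms[norms == 0.0] = 1.0
    return v / norms


def _truncated_edep(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    a = (EDEP_CUTOFF_EV - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def generate_track(p: TrackParams) -> EventSet:
    """Generate one synthetic track as an :class:`EventSet`.

    Events sit at the cumulative positions of an isotropic random walk
    starting at the origin, with step lengths ~ Exponential(mean free
    path).  The walk carries no energy bookkeeping: per-event deposits
    are independent of geometry, because the yield equations only use
    their sum.
    """
    rng = np.random.default_rng(p.seed)
    n = p.n_events
    if n == 0:
        return EventSet.empty()
    steps = rng.exponential(p.mean_free_path_nm, size=n)
    coords = np.cumsum(_random_directions(rng, n) * steps[:, None], axis=0)
    edep = _truncated_edep(rng, n, p.edep_mean_eV, p.edep_sd_eV)
    kind = np.where(rng.random(n) < p.p_ionization, "ION", "EXC")
    return EventSet(np.zeros(n, dtype=np.int64), coords, kind, edep)


def generate_blob(
    n: int,
    radius_nm: float,
    seed: int = 0,
    edep_eV: float = 30.0,
) -> EventSet:
    """Generate *n* events uniform in a ball of ``radius_nm`` at the origin.

    For ``radius_nm <= lc_nm / 2`` every pair of events is within the
    linkage distance ``lc_nm``, so every site exists and has cluster
    size exactly *n* — the canonical fixture for exact classification
    tests.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not radius_nm > 0:
        raise ValueError("radius_nm must be > 0")
    if edep_eV < EDEP_CUTOFF_EV:
        raise ValueError(f"edep_eV must be >= {EDEP_CUTOFF_EV} eV")
    rng = np.random.default_rng(seed)
    if n == 0:
        return EventSet.empty()
    # uniform in a ball: isotropic direction times radius * U^(1/3)
    r = radius_nm * rng.random(n) ** (1.0 / 3.0)
    coords = _random_directions(rng, n) * r[:, None]
    kind = np.where(rng.random(n) < 0.5, "ION", "EXC")
    return EventSet(np.zeros(n, dtype=np.int64), coords, kind, np.full(n, float(edep_eV)))
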