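"""Independent brute-force validators for the deterministic kinetics.

A Gillespie exact-stochastic simulator runs the same reaction scheme on
integer molecule counts in a small virtual volume, and closed-form kinetics
(pseudo-first-order decay) provide analytic anchors.  Nothing here shares
integration code with :mod:`flashrod.kinetics`; that independence is the
point.

Propensity convention matches the deterministic rate laws: for a
self-reaction 2A -> P with elementary-event constant k, the propensity is
(k / N_A V) n_A (n_A - 1), whose mean-field limit is the deterministic
d[A]/dt = -2 k [A]^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import ReactionScheme

__all__ = [
    "SsaConfig",
    "SsaTrajectory",
    "ssa_simulate",
    "analytic_pseudo_first_order",
    "counts_from_concentrations",
]

N_A = 6.02214076e23


@dataclass(frozen=True)
class SsaConfig:
    """Virtual-volume stochastic run configuration.

    The default 1e-18 L keeps desk-scale counts: 30 uM O2 is ~18 molecules,
    1 M substrate ~6e5, 6.5 mM glutathione ~3.9e3.
    """

    volume_l: float = 1e-18
    t_end: float = 1.0
    seed: int = 0
    max_events: int = 2_000_000
    sample_times: tuple[float, ...] = ()


@dataclass
class SsaTrajectory:
    times: np.ndarray
    species_names: list[str]
    counts: np.ndarray  # (n_times, n_species), integer counts
    n_events: int
    truncated: bool = False

    def count(self, species: str) -> np.ndarray:
        return self.counts[:, self.species_names.index(species)]


def counts_from_concentrations(
    state0: dict[str, float], scheme: ReactionScheme, volume_l: float
) -> np.ndarray:
    """Round molar concentrations to integer molecule counts in the volume."""
    n = np.zeros(len(scheme.species), dtype=np.int64)
    for name, conc in state0.items():
        n[scheme.index(name)] = int(round(conc * N_A * volume_l))
    return n


def ssa_simulate(
    scheme: ReactionScheme,
    state0: dict[str, float] | np.ndarray,
    config: SsaConfig,
    k_eff: np.ndarray | None = None,
) -> SsaTrajectory:
    """Exact-stochastic (direct-method) trajectory of integer counts.

    ``state0`` in molar is rounded to counts via the virtual volume; an
    integer array is used as-is.  Counts are recorded at ``sample_times``
    (plus t_end), piecewise-constant between events.
    """
    rng = np.random.default_rng(config.seed)
    names = scheme.species_names
    n_s = len(names)
    if isinstance(state0, dict):
        n = counts_from_concentrations(state0, scheme, config.volume_l)
    else:
        n = np.asarray(state0, dtype=np.int64).copy()
        if n.shape != (n_s,):
            raise ValueError("state0 count vector has wrong length")

    reactions = scheme.reactions
    ks = np.array([r.k for r in reactions]) if k_eff is None else np.asarray(k_eff, float)
    i1 = np.array([scheme.index(r.reactants[0]) for r in reactions])
    i2 = np.array(
        [scheme.index(r.reactants[1]) if len(r.reactants) == 2 else -1 for r in reactions]
    )
    uni = i2 < 0
    selfr = np.array([r.self_reaction for r in reactions])
    # stochastic rate constants: per-event propensity factors
    c = np.where(uni, ks, ks / (N_A * config.volume_l))
    # net count changes per reaction, dense (n_reactions, n_species)
    delta = np.zeros((len(reactions), n_s), dtype=np.int64)
    for j, rxn in enumerate(reactions):
        for name, d in rxn.net_stoichiometry().items():
            delta[j, scheme.index(name)] = d

    sample_times = sorted(set(list(config.sample_times) + [config.t_end]))
    out = np.empty((len(sample_times), n_s), dtype=np.int64)
    next_sample = 0

    t = 0.0
    n_events = 0
    truncated = False
    i2c = np.where(uni, 0, i2)  # safe index; factor overridden below
    while True:
        pair = np.where(
            uni, 1.0, np.where(selfr, np.maximum(n[i2c] - 1, 0), n[i2c])
        )
        a = c * n[i1] * pair
        total = a.sum()
        if total <= 0.0:
            t_next = np.inf
        else:
            t_next = t + rng.exponential(1.0 / total)
        while next_sample < len(sample_times) and sample_times[next_sample] < t_next:
            out[next_sample] = n
            next_sample += 1
        if next_sample >= len(sample_times) or t_next > config.t_end:
            break
        if n_events >= config.max_events:
            truncated = True
            while next_sample < len(sample_times):
                out[next_sample] = n
                next_sample += 1
            break
        j = int(np.searchsorted(np.cumsum(a), rng.uniform(0.0, total)))
        j = min(j, len(reactions) - 1)
        n += delta[j]
        t = t_next
        n_events += 1

    return SsaTrajectory(
        times=np.asarray(sample_times),
        species_names=list(names),
        counts=out,
        n_events=n_events,
        truncated=truncated,
    )


def analytic_pseudo_first_order(k: float, scavenger_conc: float, t: float) -> float:
    """Survival fraction exp(-k * conc * t) of a species against a fixed
    excess scavenger (scavenging power = k * conc, s^-1)."""
    if k < 0 or scavenger_conc < 0 or t < 0:
        raise ValueError("k, concentration and t must be >= 0")
    return float(np.exp(-k * scavenger_conc * t))
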