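"""Gibbs sampling of one risk gene per locus.

Each locus's conditional is proportional to (network prior) x (evidence
score). Sampling proceeds in two cycles: the first starts from a uniform
random selection, the second restarts from the first cycle's final state;
posterior probabilities (PP) are the per-gene selection frequencies of the
second cycle. A cycle stops when the Euclidean norm of the change in the
full frequency vector between successive sweeps falls below E_Gibbs
(default 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import EvidenceScores, GeneNetwork, LocusMap, PosteriorTable
from .network import build_transition, network_prior, rwr_propagator

logger = logging.getLogger(__name__)

__all__ = ["SamplerConfig", "SamplerState", "conditional_distribution", "run_cycle", "run_gibbs"]

EVIDENCE_FLOOR = 1e-6  # keeps conditional weights strictly positive


@dataclass
class SamplerConfig:
    e_gibbs: float = 0.01
    min_sweeps: int = 10
    max_sweeps: int = 5_000
    seed: int = 0
    restart_prob: float = 0.5
    floor_eps: float = 1e-6
    combine: str = "mean"
    scan: str = "systematic"  # or "random"
    pp_source: str = "cycle2"  # or "pooled"

    def __post_init__(self) -> None:
        if self.e_gibbs <= 0:
            raise ValueError("e_gibbs must be > 0")
        if self.min_sweeps < 1:
            raise ValueError("min_sweeps must be >= 1")
        if self.scan not in {"systematic", "random"}:
            raise ValueError(f"unknown scan order {self.scan!r}")
        if self.pp_source not in {"cycle2", "pooled"}:
            raise ValueError(f"unknown pp_source {self.pp_source!r}")


@dataclass
class SamplerState:
    """Selection counts and frequencies accumulated over one cycle."""

    selection: list[str]  # current pick per non-empty locus
    counts: list[dict[str, int]]  # per locus, gene -> times selected
    totals: list[int]  # per locus, number of samplings
    sweep: int = 0
    converged: bool = False
    freq_trace: list[np.ndarray] = field(default_factory=list)
    state_trace: list[tuple[str, ...]] = field(default_factory=list)

    def frequencies(self) -> np.ndarray:
        """Flat per-(locus, candidate-slot) frequency vector Freq_i."""
        out = []
        for counts, total in zip(self.counts, self.totals):
            denom = max(total, 1)
            out.extend(c / denom for c in counts.values())
        return np.asarray(out)


def conditional_distribution(
    candidates: list[str],
    selected_others: list[str],
    evidence: EvidenceScores,
    networks: list[GeneNetwork],
    config: SamplerConfig,
    _propagators=None,
) -> np.ndarray:
    """P(X_l | X_{-l}, N, D): network prior times evidence, normalized."""
    prior = network_prior(
        candidates,
        selected_others,
        networks,
        r=config.restart_prob,
        floor_eps=config.floor_eps,
        combine=config.combine,
        _propagators=_propagators,
    )
    ev = np.array([max(evidence.get(g, 0.0), EVIDENCE_FLOOR) for g in candidates])
    weights = prior * ev
    total = weights.sum()
    assert total > 0, "conditional weights must be positive (floors guarantee this)"
    return weights / total


def _prepare_propagators(loci: LocusMap, networks: list[GeneNetwork], r: float):
    """Dense RWR kernels over the shared universe, computed once per run."""
    if not networks:
        return None
    universe = list(loci.all_candidates())
    seen = set(universe)
    for net in networks:
        for node in net.nodes:
            if node not in seen:
                universe.append(node)
                seen.add(node)
    props = []
    for net in networks:
        T = build_transition(net, universe)
        props.append((T, rwr_propagator(T, r), set(net.nodes)))
    return props


def run_cycle(
    loci: LocusMap,
    evidence: EvidenceScores,
    networks: list[GeneNetwork],
    config: SamplerConfig,
    init: list[str],
    rng: np.random.Generator | None = None,
    record_states: bool = False,
    _propagators=None,
) -> SamplerState:
    """One cycle of Gibbs sweeps from a given initial selection.

    Per sweep each non-empty locus is resampled from its conditional given
    the current picks at the other loci; counts and the frequency vector are
    updated after every individual sampling. The cycle stops when
    ||Freq_i - Freq_{i-1}||_2 < e_gibbs (and sweep >= min_sweeps), or at
    max_sweeps with a convergence warning.
    """
    active = loci.nonempty
    if len(init) != len(active):
        raise ValueError("init must select one gene per non-empty locus")
    for sel, locus in zip(init, active):
        if sel not in locus.candidates:
            raise ValueError(f"init gene {sel!r} is not a candidate of its locus")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if _propagators is None and networks:
        _propagators = _prepare_propagators(loci, networks, config.restart_prob)

    state = SamplerState(
        selection=list(init),
        counts=[{g: 0 for g in locus.candidates} for locus in active],
        totals=[0] * len(active),
    )
    L = len(active)
    prev_freq = state.frequencies()
    for sweep in range(1, config.max_sweeps + 1):
        order = rng.permutation(L) if config.scan == "random" else range(L)
        for li in order:
            locus = active[li]
            others = [state.selection[j] for j in range(L) if j != li]
            probs = conditional_distribution(
                list(locus.candidates), others, evidence, networks, config,
                _propagators=_propagators,
            )
            pick = locus.candidates[rng.choice(len(probs), p=probs)]
            state.selection[li] = pick
            state.counts[li][pick] += 1
            state.totals[li] += 1
        state.sweep = sweep
        freq = state.frequencies()
        state.freq_trace.append(freq)
        if record_states:
            state.state_trace.append(tuple(state.selection))
        delta = float(np.linalg.norm(freq - prev_freq))
        prev_freq = freq
        if sweep >= config.min_sweeps and delta < config.e_gibbs:
            state.converged = True
            break
    if not state.converged:
        logger.warning(
            "Gibbs cycle hit max_sweeps=%d without converging (last delta %.3g)",
            config.max_sweeps, delta,
        )
    return state


def run_gibbs(
    loci: LocusMap,
    evidence: EvidenceScores,
    networks: list[GeneNetwork],
    config: SamplerConfig,
    record_states: bool = False,
) -> PosteriorTable:
    """Two-cycle Gibbs sampling yielding per-gene posterior probabilities.

    Cycle 1 starts from a uniform-random selection per locus; cycle 2 from
    cycle 1's final selection. PP is the per-gene selection frequency of
    cycle 2 (or of both cycles pooled with ``pp_source="pooled"``). Genes
    in several loci get merged PP = max over their loci.
    """
    active = loci.nonempty
    if not active:
        raise ValueError("no non-empty loci to sample")
    rng = np.random.default_rng(config.seed)
    propagators = _prepare_propagators(loci, networks, config.restart_prob)

    init1 = [locus.candidates[rng.integers(len(locus.candidates))] for locus in active]
    cycle1 = run_cycle(loci, evidence, networks, config, init1, rng=rng,
                       _propagators=propagators)
    cycle2 = run_cycle(loci, evidence, networks, config, list(cycle1.selection),
                       rng=rng, record_states=record_states, _propagators=propagators)

    active_idx = [i for i, locus in enumerate(loci) if not locus.is_empty]
    per_locus: dict[int, dict[str, float]] = {}
    for pos, li in enumerate(active_idx):
        if config.pp_source == "pooled":
            total = cycle1.totals[pos] + cycle2.totals[pos]
            counts = {
                g: cycle1.counts[pos][g] + cycle2.counts[pos][g]
                for g in cycle2.counts[pos]
            }
        else:
            total = cycle2.totals[pos]
            counts = cycle2.counts[pos]
        per_locus[li] = {g: c / total for g, c in counts.items()}

    merged: dict[str, float] = {}
    for pps in per_locus.values():
        for g, pp in pps.items():
            merged[g] = max(merged.get(g, 0.0), pp)

    table = PosteriorTable(
        per_locus=per_locus,
        merged=merged,
        freq_trace=cycle2.freq_trace,
        sweeps=(cycle1.sweep, cycle2.sweep),
        converged=(cycle1.converged, cycle2.converged),
    )
    if record_states:
        table.state_trace = cycle2.state_trace  # type: ignore[attr-defined]
    return table
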