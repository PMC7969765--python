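"""Gibbs sampler: conditionals, convergence, exactness on small chains."""

import itertools

import numpy as np
import pytest

from locusrisk.datatypes import EvidenceScores
from locusrisk.gibbs import SamplerConfig, conditional_distribution, run_cycle, run_gibbs

from conftest import make_locus_map, make_network


def flat_evidence(genes, value=1.0):
    return EvidenceScores(scores={g: value for g in genes})


class TestConditional:
    def test_single_candidate(self):
        probs = conditional_distribution(
            ["A"], ["X"], flat_evidence(["A"]), [], SamplerConfig()
        )
        np.testing.assert_allclose(probs, [1.0])

    def test_uniform_prior_equal_evidence(self):
        probs = conditional_distribution(
            list("ABCD"), ["X"], flat_evidence("ABCD"), [], SamplerConfig()
        )
        np.testing.assert_allclose(probs, 0.25)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_hand_arithmetic_prior_times_evidence(self, monkeypatch):
        # prior (0.25, 0.75) x evidence (2, 1) -> (0.5, 0.75) -> (0.4, 0.6)
        import locusrisk.gibbs as gibbs_mod

        monkeypatch.setattr(
            gibbs_mod, "network_prior", lambda *a, **k: np.array([0.25, 0.75])
        )
        probs = conditional_distribution(
            ["A", "B"], ["X"], EvidenceScores(scores={"A": 2.0, "B": 1.0}),
            [make_network([("A", "B", 1.0)])], SamplerConfig(),
        )
        np.testing.assert_allclose(probs, [0.4, 0.6], atol=1e-12)


class TestRunCycle:
    def test_single_candidate_loci_converge_immediately(self):
        lm = make_locus_map([["A"], ["B"], ["C"]])
        ev = flat_evidence("ABC")
        state = run_cycle(lm, ev, [], SamplerConfig(seed=1), init=["A", "B", "C"])
        assert state.converged
        assert state.sweep >= 10  # min_sweeps guard
        np.testing.assert_allclose(state.frequencies(), 1.0)

    def test_bad_init_rejected(self):
        lm = make_locus_map([["A", "B"]])
        with pytest.raises(ValueError):
            run_cycle(lm, flat_evidence("AB"), [], SamplerConfig(), init=["Z"])

    def test_frequencies_sum_per_locus(self):
        lm = make_locus_map([["A", "B", "C"], ["D", "E"]])
        ev = EvidenceScores(scores={"A": 3.0, "B": 1.0, "C": 0.5, "D": 2.0, "E": 2.0})
        state = run_cycle(lm, ev, [], SamplerConfig(seed=5), init=["A", "D"])
        for counts, total in zip(state.counts, state.totals):
            assert sum(counts.values()) == total


class TestRunGibbs:
    def test_seed_determinism(self):
        lm = make_locus_map([["A", "B"], ["C", "D", "E"]])
        ev = EvidenceScores(scores={g: v for g, v in zip("ABCDE", [1, 2, 3, 1, 2])})
        net = make_network([("A", "C", 1.0), ("B", "E", 2.0)])
        t1 = run_gibbs(lm, ev, [net], SamplerConfig(seed=42))
        t2 = run_gibbs(lm, ev, [net], SamplerConfig(seed=42))
        assert t1.per_locus == t2.per_locus
        assert t1.merged == t2.merged

    def test_uninformative_symmetric_pp(self):
        k, n_loci = 5, 8
        lm = make_locus_map(
            [[f"L{i}G{j}" for j in range(k)] for i in range(n_loci)]
        )
        genes = lm.all_candidates()
        table = run_gibbs(
            lm, flat_evidence(genes), [],
            SamplerConfig(seed=9, e_gibbs=0.005, max_sweeps=5000),
        )
        T = table.sweeps[1]  # samplings per locus in cycle 2
        bound = 3 * np.sqrt((1 / k) * (1 - 1 / k) / T)
        for pps in table.per_locus.values():
            assert sum(pps.values()) == pytest.approx(1.0, abs=1e-9)
            for pp in pps.values():
                assert abs(pp - 1 / k) < bound

    def test_per_locus_pp_sums_to_one(self):
        lm = make_locus_map([["A", "B", "C"], ["B", "D"]])
        ev = EvidenceScores(scores={g: v for g, v in zip("ABCD", [1, 5, 2, 1])})
        table = run_gibbs(lm, ev, [], SamplerConfig(seed=3))
        for pps in table.per_locus.values():
            assert sum(pps.values()) == pytest.approx(1.0, abs=1e-9)
        # shared gene B merged by max over loci
        assert table.merged["B"] == pytest.approx(
            max(table.per_locus[0]["B"], table.per_locus[1]["B"])
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(e_gibbs=0.0)
        with pytest.raises(ValueError):
            SamplerConfig(min_sweeps=0)


def exact_sweep_stationary(lm, evidence, networks, config):
    """Stationary distribution of the systematic-sweep chain by enumeration.

    Builds the per-locus update matrices from the model's own conditionals,
    composes them into the one-sweep transition matrix, and returns its
    stationary left eigenvector over joint states.
    """
    cand_lists = [list(l.candidates) for l in lm.nonempty]
    states = list(itertools.product(*[range(len(c)) for c in cand_lists]))
    s_index = {s: i for i, s in enumerate(states)}
    n = len(states)
    T_total = np.eye(n)
    for li in range(len(cand_lists)):
        T_l = np.zeros((n, n))
        for s in states:
            others = [cand_lists[j][s[j]] for j in range(len(cand_lists)) if j != li]
            probs = conditional_distribution(
                cand_lists[li], others, evidence, networks, config
            )
            for xi, p in enumerate(probs):
                s2 = list(s)
                s2[li] = xi
                T_l[s_index[tuple(s2)], s_index[s]] += p
        T_total = T_l @ T_total
    evals, evecs = np.linalg.eig(T_total)
    i = np.argmin(np.abs(evals - 1.0))
    pi = np.real(evecs[:, i])
    pi = np.abs(pi)
    return states, pi / pi.sum()


@pytest.mark.parametrize("shape", [(2, 2), (3, 2), (2, 3)])
def test_empirical_stationary_matches_enumeration(shape):
    """Long-run sweep-state frequencies match the exact chain stationary law."""
    n_loci, k = shape
    rng = np.random.default_rng(1000 + 10 * n_loci + k)
    lm = make_locus_map([[f"L{i}G{j}" for j in range(k)] for i in range(n_loci)])
    genes = lm.all_candidates()
    ev = EvidenceScores(scores={g: float(rng.uniform(0.5, 3.0)) for g in genes})
    edges = [
        (a, b, float(rng.uniform(0.5, 2.0)))
        for idx, a in enumerate(genes) for b in genes[idx + 1:]
        if rng.random() < 0.4
    ]
    net = make_network(edges, nodes=genes)
    cfg = SamplerConfig(seed=77, min_sweeps=30_000, max_sweeps=30_000, e_gibbs=1e-12)

    states, exact = exact_sweep_stationary(lm, ev, [net], cfg)
    state = run_cycle(
        lm, ev, [net], cfg, init=[c[0] for c in (l.candidates for l in lm.nonempty)],
        record_states=True,
    )
    cand_lists = [list(l.candidates) for l in lm.nonempty]
    idx = {s: i for i, s in enumerate(states)}
    counts = np.zeros(len(states))
    for sel in state.state_trace:
        key = tuple(c.index(g) for c, g in zip(cand_lists, sel))
        counts[idx[key]] += 1
    empirical = counts / counts.sum()
    tv = 0.5 * np.abs(empirical - exact).sum()
    assert tv < 0.02
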