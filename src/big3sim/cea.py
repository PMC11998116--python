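"""Fully incremental cost-utility analysis, PSA and acceptability curves.

Strategies are compared on mean discounted cost (€) and effect (QALYs) per
person.  The incremental analysis sorts strategies by cost, removes strongly
dominated ones (more costly, no more effective), then iteratively removes
extendedly (weakly) dominated ones until the incremental cost-utility ratios
(ICURs) along the efficiency frontier are strictly increasing.  The
probabilistic sensitivity analysis re-simulates every strategy per parameter
draw with common random numbers; the cost-effectiveness acceptability curve
(CEAC) reports, per willingness-to-pay λ, the fraction of draws in which each
strategy maximises net monetary benefit λ·effect − cost (ties split equally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet
from .population import CohortConfig, generate_cohort
from .screening import StrategySpec
from .engine import run_strategy, RunResult

FRONTIER = "frontier"
WEAK = "weakly_dominated"
STRONG = "strongly_dominated"


@dataclass(frozen=True)
class StrategyOutcome:
    label: str
    cost: float
    effect: float


@dataclass
class FrontierEntry:
    label: str
    cost: float
    effect: float
    classification: str
    incremental_cost: float | None = None   # vs previous frontier strategy
    incremental_effect: float | None = None
    icur: float | None = None
    tied: bool = False


@dataclass
class CeaFrontier:
    entries: list[FrontierEntry]

    @property
    def frontier(self) -> list[FrontierEntry]:
        return [e for e in self.entries if e.classification == FRONTIER]

    @property
    def frontier_labels(self) -> list[str]:
        return [e.label for e in self.frontier]

    def classification(self, label: str) -> str:
        for e in self.entries:
            if e.label == label:
                return e.classification
        raise KeyError(label)

    def icurs(self) -> dict[str, float]:
        return {e.label: e.icur for e in self.frontier if e.icur is not None}


def incremental_analysis(outcomes: list[StrategyOutcome]) -> CeaFrontier:
    """Classify strategies and compute frontier ICURs.

    Exact ties in (cost, effect) are kept on the frontier together and
    flagged.  A single strategy is its own frontier with no ICUR.
    """
    if not outcomes:
        raise ValueError("need at least one strategy outcome")
    if any(o.effect < 0 for o in outcomes):
        raise ValueError("effects must be >= 0")
    order = sorted(range(len(outcomes)),
                   key=lambda i: (outcomes[i].cost, -outcomes[i].effect))
    cls = {i: FRONTIER for i in order}
    tied = {i: False for i in order}

    # strong dominance: some other strategy costs no more and yields no less,
    # with at least one strict inequality
    for i in order:
        for j in order:
            if i == j:
                continue
            oi, oj = outcomes[i], outcomes[j]
            if (oj.cost <= oi.cost and oj.effect >= oi.effect
                    and (oj.cost < oi.cost or oj.effect > oi.effect)):
                cls[i] = STRONG
                break
            if oj.cost == oi.cost and oj.effect == oi.effect:
                tied[i] = True

    cand = [i for i in order if cls[i] != STRONG]
    # drop exact duplicates from the candidate chain (kept flagged on frontier)
    chain: list[int] = []
    for i in cand:
        if chain and outcomes[i].cost == outcomes[chain[-1]].cost \
                and outcomes[i].effect == outcomes[chain[-1]].effect:
            continue
        chain.append(i)

    # extended dominance: remove middle strategies until ICURs strictly increase
    changed = True
    while changed and len(chain) > 2:
        changed = False
        for k in range(1, len(chain) - 1):
            a, b, c = (outcomes[chain[k - 1]], outcomes[chain[k]],
                       outcomes[chain[k + 1]])
            icur_ab = _ratio(b.cost - a.cost, b.effect - a.effect)
            icur_bc = _ratio(c.cost - b.cost, c.effect - b.effect)
            if icur_ab >= icur_bc:
                cls[chain[k]] = WEAK
                del chain[k]
                changed = True
                break

    entries = []
    prev = None
    for i in order:
        o = outcomes[i]
        e = FrontierEntry(label=o.label, cost=o.cost, effect=o.effect,
                          classification=cls[i], tied=tied[i])
        if cls[i] == FRONTIER and i in chain:
            if prev is not None:
                e.incremental_cost = o.cost - prev.cost
                e.incremental_effect = o.effect - prev.effect
                e.icur = _ratio(e.incremental_cost, e.incremental_effect)
            prev = o
        entries.append(e)
    return CeaFrontier(entries=entries)


def _ratio(dc: float, de: float) -> float:
    if de <= 0:
        return np.inf if dc > 0 else -np.inf
    return dc / de


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PsaSample:
    draw: int
    outcomes: dict[str, tuple[float, float]]  # label -> (cost, effect)
    params: ParameterSet | None = None


def psa(cohort_config: CohortConfig, strategies: list[StrategySpec],
        params: ParameterSet, n_draws: int, seed: int,
        keep_params: bool = False,
        progress: bool = False) -> list[PsaSample]:
    """Run the probabilistic analysis: full re-simulation per parameter draw.

    Each draw samples a complete parameter set, regenerates the cohort and
    simulates every strategy with common random numbers for that draw.
    """
    params.require_valid()
    samples: list[PsaSample] = []
    for i in range(n_draws):
        ss = np.random.SeedSequence([seed, i])
        rng = np.random.default_rng(ss)
        p_i = params.sample_psa(rng)
        run_seed = int(ss.generate_state(2)[1] % (2**31))
        cohort = generate_cohort(cohort_config, p_i, seed=run_seed)
        outs = {}
        for s in strategies:
            rr = run_strategy(cohort, s, p_i, run_seed)
            outs[s.name] = (rr.mean_cost, rr.mean_qaly)
        samples.append(PsaSample(draw=i, outcomes=outs,
                                 params=p_i if keep_params else None))
        if progress:
            print(f"  PSA draw {i + 1}/{n_draws}", flush=True)
    return samples


@dataclass
class CeacCurve:
    wtp: np.ndarray
    labels: list[str]
    probabilities: np.ndarray  # (n_wtp, n_strategies)

    def probability_at(self, wtp_value: float, label: str) -> float:
        j = self.labels.index(label)
        i = int(np.argmin(np.abs(self.wtp - wtp_value)))
        return float(self.probabilities[i, j])

    def best_at(self, wtp_value: float) -> str:
        i = int(np.argmin(np.abs(self.wtp - wtp_value)))
        return self.labels[int(np.argmax(self.probabilities[i]))]


def ceac(samples: list[PsaSample], wtp_grid=None) -> CeacCurve:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid."""
    if not samples:
        raise ValueError("need at least one PSA sample")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 150_001.0, 1000.0)
    wtp = np.asarray(wtp_grid, dtype=float)
    labels = list(samples[0].outcomes.keys())
    costs = np.asarray([[s.outcomes[l][0] for l in labels] for s in samples])
    effects = np.asarray([[s.outcomes[l][1] for l in labels] for s in samples])
    probs = np.zeros((len(wtp), len(labels)))
    for i, lam in enumerate(wtp):
        nmb = lam * effects - costs          # (draws, strategies)
        mx = nmb.max(axis=1, keepdims=True)
        win = nmb >= mx - 1e-12              # ties split equally
        probs[i] = (win / win.sum(axis=1, keepdims=True)).mean(axis=0)
    return CeacCurve(wtp=wtp, labels=labels, probabilities=probs)


def outcomes_from_results(results: list[RunResult]) -> list[StrategyOutcome]:
    return [StrategyOutcome(r.strategy, r.mean_cost, r.mean_qaly) for r in results]
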