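"""Toy passage model of the two-step HR + counterselection workflow.

This model is a package-invented sanity check, not an empirical result:
each passage, every edited virion infects productively while a wildtype
virion escapes counterselection with probability ``escape_prob``; both
lineages amplify identically afterwards, so amplification cancels in the
edited fraction and the expectation obeys

    f' = f / (f + (1 - f) * escape_prob).

With an efficient guide (escape_prob << f0) a single enrichment passage
takes a percent-scale edited fraction to essentially one, which is the
qualitative regime the workflow relies on. A stochastic mode draws
wildtype survivor counts binomially at a stated population size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class SimulationError(ValueError):
    """Degenerate or invalid passage model."""


@dataclass
class PassageModel:
    f0: float  # initial edited fraction
    escape_prob: float  # per-wildtype-virion escape probability
    n_passages: int = 1
    population: int = 100_000  # virions sampled into each passage
    amplification: float = 1000.0  # per-passage gain (cancels in the fraction)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f0 <= 1.0 or not 0.0 <= self.escape_prob <= 1.0:
            raise SimulationError("f0 and escape_prob must lie in [0, 1]")
        if self.n_passages < 1 or self.population < 1:
            raise SimulationError("need at least one passage and one virion")
        if self.f0 == 0.0 and self.escape_prob == 0.0:
            raise SimulationError(
                "no edited phage and no escape: the population goes extinct"
            )


def expected_trajectory(model: PassageModel) -> list[float]:
    """Edited fraction after each passage under the expectation recursion."""
    f = model.f0
    out = [f]
    for _ in range(model.n_passages):
        denom = f + (1.0 - f) * model.escape_prob
        f = f / denom if denom > 0 else 1.0
        out.append(f)
    return out


def simulate_enrichment(
    model: PassageModel, stochastic: bool = False, rng: np.random.Generator | None = None
) -> list[float]:
    """Per-passage edited fraction; deterministic expectation by default,
    binomial sampling of survivors when ``stochastic``."""
    if not stochastic:
        return expected_trajectory(model)
    rng = rng or np.random.default_rng(model.seed)
    f = model.f0
    out = [f]
    for _ in range(model.n_passages):
        n_edited = rng.binomial(model.population, f)
        n_wt = model.population - n_edited
        survivors_wt = rng.binomial(n_wt, model.escape_prob) if n_wt else 0
        total = n_edited + survivors_wt
        if total == 0:
            out.append(0.0)
            f = 0.0
            continue
        f = n_edited / total
        out.append(f)
    return out


def stochastic_mean_final_fraction(
    model: PassageModel, n_replicates: int = 10_000
) -> tuple[float, float]:
    """Mean and standard error of the final edited fraction over replicate
    stochastic runs (vectorized over replicates)."""
    rng = np.random.default_rng(model.seed)
    f = np.full(n_replicates, model.f0)
    for _ in range(model.n_passages):
        n_edited = rng.binomial(model.population, f)
        n_wt = model.population - n_edited
        survivors = rng.binomial(n_wt, model.escape_prob)
        total = n_edited + survivors
        with np.errstate(invalid="ignore"):
            f = np.where(total > 0, n_edited / np.maximum(total, 1), 0.0)
    mean = float(f.mean())
    sem = float(f.std(ddof=1) / np.sqrt(n_replicates))
    return mean, sem
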