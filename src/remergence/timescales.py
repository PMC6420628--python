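"""Closed-form mutational-exploration timescales.

With an effective population size N_e, a per-base per-division mutation
rate mu, and a genome of G base pairs, each genome experiences mu*G
mutations per generation and the population as a whole mu*G*N_e; a given
base pair is therefore hit somewhere in the population about every
1/(mu*N_e) generations, or three times that to realize all three
alternative bases.  With the default yeast-like parameters the
neighborhood of the reference genome is explored almost completely on
evolutionary timescales.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

__all__ = ["ExplorationEstimate", "exploration_timescales"]


@dataclass(frozen=True)
class ExplorationEstimate:
    muts_per_genome_per_gen: float
    muts_per_population_per_gen: float
    generations_per_bp_hit: float
    generations_all_three_alts: float
    n_e: float
    mu: float
    genome_size: float

    def to_dict(self) -> dict:
        return asdict(self)


def exploration_timescales(
    n_e: float = 1e6, mu: float = 5e-10, genome_size: float = 1.2e7
) -> ExplorationEstimate:
    """Mutational exploration timescales from population parameters.

    Defaults: N_e = 1e6, mu = 5e-10 per bp per division, G = 1.2e7 bp.
    All inputs must be positive; the small-mu limit reports ``inf``
    rather than overflowing.
    """
    if n_e <= 0 or mu <= 0 or genome_size <= 0:
        raise ValueError("n_e, mu and genome_size must all be positive")
    per_genome = mu * genome_size
    per_population = per_genome * n_e
    try:
        per_bp = 1.0 / (mu * n_e)
    except ZeroDivisionError:  # pragma: no cover - mu > 0 guards this
        per_bp = float("inf")
    if mu * n_e == 0.0:
        per_bp = float("inf")
    return ExplorationEstimate(
        muts_per_genome_per_gen=per_genome,
        muts_per_population_per_gen=per_population,
        generations_per_bp_hit=per_bp,
        generations_all_three_alts=3.0 * per_bp,
        n_e=n_e,
        mu=mu,
        genome_size=genome_size,
    )
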