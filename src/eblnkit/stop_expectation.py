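"""Closed-form expectations for premature stop-codon accumulation.

Under neutral evolution at rate ``r`` substitutions/site/year, a coding
sequence of ``C`` codons accumulates ``r * 3C * t`` substitutions in
``t`` years; if a fraction ``f`` of random substitutions creates a stop
codon, the expected number of premature termination codons is

    E[stops] = r * 3 * f * C * t

and the Poisson approximation to the chance of remaining stop-free is
``exp(-E)``.  Under equal substitution rates and equal codon
frequencies the stop fraction is an exact enumeration over the genetic
code: 23 of the 549 single-base changes from sense codons yield a stop,
i.e. about 4.19% ("4%") — one third of the 12% sometimes assumed, which
is the crux of the corrected expectations computed here.
"""

from __future__ import annotations

import dataclasses
import math
from fractions import Fraction

import pandas as pd

from .seq_core import BASES, SENSE_CODONS, STOP_CODONS

__all__ = [
    "ExpectationInputs",
    "expected_substitutions",
    "expected_stop_count",
    "stop_generation_codon_my",
    "neutral_stop_fraction_uniform",
    "poisson_zero_probability",
    "expectation_grid",
    "DEFAULT_RATES",
    "DEFAULT_TIMES_MY",
]

#: substitutions/site/year grid used in the neutral-decay analyses
DEFAULT_RATES = (1.0e-9, 1.5e-9, 2.2e-9)
#: single-lineage (root-to-tip) divergence times, million years
DEFAULT_TIMES_MY = (44.2, 54.1)


@dataclasses.dataclass(frozen=True)
class ExpectationInputs:
    """Inputs of the analytic stop-count expectation.

    rate_per_site_year:
        Neutral substitution rate r (substitutions/site/year).
    n_codons:
        Length C of the reading frame, codons.
    time_years:
        Single-lineage (root-to-tip) elapsed time t, years.
    stop_fraction:
        Probability f that a random substitution creates a stop codon
        (0.04 under uniform assumptions; 0.12 in the claim corrected
        here).
    """

    rate_per_site_year: float
    n_codons: int
    time_years: float
    stop_fraction: float

    def __post_init__(self) -> None:
        if self.rate_per_site_year <= 0 or self.n_codons <= 0:
            raise ValueError("rate and n_codons must be positive")
        if self.time_years < 0:
            raise ValueError("time must be >= 0")
        if not 0.0 < self.stop_fraction < 1.0:
            raise ValueError("stop_fraction must be in (0, 1)")


def expected_substitutions(rate: float, n_sites: int, time: float) -> float:
    """Expected substitutions in ``n_sites`` sites over ``time`` years."""
    return rate * n_sites * time


def expected_stop_count(inputs: ExpectationInputs) -> float:
    """Expected premature termination codons: r * 3 * f * C * t."""
    return (
        inputs.rate_per_site_year
        * 3.0
        * inputs.stop_fraction
        * inputs.n_codons
        * inputs.time_years
    )


def stop_generation_codon_my(rate: float, stop_fraction: float) -> float:
    """Codons x million years per expected stop: 1 / (r * 3 * f * 1e6).

    At r = 1.2e-9 and f = 0.12 this is ~2310 — 'one stop per 2,310
    codons per million years'.
    """
    if rate <= 0 or not 0 < stop_fraction < 1:
        raise ValueError("rate must be > 0 and stop_fraction in (0, 1)")
    return 1.0 / (rate * 3.0 * stop_fraction * 1.0e6)


def neutral_stop_fraction_uniform(exact: bool = False) -> float | Fraction:
    """Stop fraction under equal rates and equal codon frequencies.

    Exhaustive enumeration over the 61 sense codons x 9 single-base
    changes each: the fraction of changes yielding TAA/TAG/TGA.
    Evaluates to 23/549 (~0.0419, printed as 4%).
    """
    to_stop = 0
    total = 0
    for codon in SENSE_CODONS:
        for p in range(3):
            for base in BASES:
                if base == codon[p]:
                    continue
                total += 1
                if codon[:p] + base + codon[p + 1 :] in STOP_CODONS:
                    to_stop += 1
    frac = Fraction(to_stop, total)
    return frac if exact else float(frac)


def poisson_zero_probability(expected_count: float) -> float:
    """Poisson probability of zero events: exp(-expected_count)."""
    if expected_count < 0:
        raise ValueError("expected_count must be >= 0")
    return math.exp(-expected_count)


def expectation_grid(
    n_codons: int,
    stop_fraction: float,
    rates: tuple[float, ...] = DEFAULT_RATES,
    times_my: tuple[float, ...] = DEFAULT_TIMES_MY,
) -> pd.DataFrame:
    """Analytic expectations over a rate x time grid.

    One row per (rate, time) cell with the expected stop count and its
    Poisson zero-probability.
    """
    rows = []
    for rate in rates:
        for t_my in times_my:
            inputs = ExpectationInputs(
                rate_per_site_year=rate,
                n_codons=n_codons,
                time_years=t_my * 1.0e6,
                stop_fraction=stop_fraction,
            )
            mean = expected_stop_count(inputs)
            rows.append(
                {
                    "rate_per_site_year": rate,
                    "time_my": t_my,
                    "expected_stops": mean,
                    "poisson_p_zero": poisson_zero_probability(mean),
                }
            )
    return pd.DataFrame(rows)
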