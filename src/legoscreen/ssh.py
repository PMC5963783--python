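"""Kinetic model of PCR-based suppression subtractive hybridization (SSH).

Adapter-A- and adapter-B-ligated tester fragments are melted together with
an excess of adapter-free driver cDNA and allowed to re-anneal. Re-annealing
is second order: for species *i* with total complementary single-strand
concentration ``c_i = t_i + E·d_i`` the remaining single-stranded
adapter-ligated tester decays as

    s_i(tau) = t_i / (1 + k · c_i · tau)

— abundant fragments, which meet complementary partners more often,
re-anneal faster, so equally expressed species converge to similar
single-strand levels (normalization) while tester-specific species (small
``d_i``) retain more single strands (enrichment). After the first
hybridization the A and B reactions are mixed; new duplexes form in a
second second-order step whose rate is raised by the volume-exclusion agent
PEG, and only A–B hybrids are exponentially amplified by suppression PCR
(A–A and B–B products fold back on their own inverted adapters and are
suppressed).

Cross-hybridization between distinct fragments is ignored: every species
anneals only with its own complement. The driver is adapter-free; its
single-strand remnant after the first hybridization competes in the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: dimensionless target for k·c_max·t1 when no rate constant is supplied —
#: strong but incomplete removal of the most abundant species.
AUTO_KCT = 10.0


@dataclass
class SpeciesPool:
    """Per-fragment tester and driver concentrations (arbitrary units)."""

    species_ids: tuple[str, ...]
    tester: np.ndarray
    driver: np.ndarray

    def __post_init__(self) -> None:
        self.species_ids = tuple(self.species_ids)
        self.tester = np.asarray(self.tester, dtype=float)
        self.driver = np.asarray(self.driver, dtype=float)
        if not (len(self.species_ids) == self.tester.size == self.driver.size):
            raise ValidationError("species ids, tester and driver must be indexed identically")
        if (self.tester < 0).any() or (self.driver < 0).any():
            raise ValidationError("concentrations must be non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpeciesPool":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(df["species_id"]), df["tester_conc"].to_numpy(), df["driver_conc"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species_id": self.species_ids, "tester_conc": self.tester, "driver_conc": self.driver}
        )


@dataclass
class HybridParams:
    """Kinetic parameters of the two hybridization steps.

    ``rate_k`` is per concentration unit per hour; when None it is
    auto-calibrated so that k·c·t1 = 10 for the most abundant species.
    ``peg_rate_multiplier`` scales the second-hybridization rate (PEG raises
    the effective concentration; 0 models omitting PEG).
    """

    rate_k: float | None = None
    t1_hours: float = 45.0
    t2_hours: float = 24.0
    driver_excess: float = 60.0
    peg_rate_multiplier: float = 3.0
    pcr_cycles: int = 16

    def __post_init__(self) -> None:
        if self.rate_k is not None and self.rate_k <= 0:
            raise ValidationError("rate_k must be positive")
        if self.t1_hours < 0 or self.t2_hours < 0:
            raise ValidationError("hybridization times must be non-negative")
        if self.driver_excess <= 0:
            raise ValidationError("driver_excess must be positive")
        if self.peg_rate_multiplier < 0:
            raise ValidationError("peg_rate_multiplier must be non-negative")


@dataclass
class SingleStrandPool:
    """Per-species single-strand concentrations of one reaction."""

    species_ids: tuple[str, ...]
    conc: np.ndarray

    def __post_init__(self) -> None:
        self.species_ids = tuple(self.species_ids)
        self.conc = np.asarray(self.conc, dtype=float)


@dataclass
class FirstHybridizationResult:
    ss_A: SingleStrandPool  # adapter-A reaction, single-stranded tester
    ss_B: SingleStrandPool  # adapter-B reaction
    driver_ss: SingleStrandPool  # driver remnant per reaction (carried into the mix)
    duplexed_A: np.ndarray  # tester strands annealed, per species (mass balance)
    rate_k: float  # the rate constant actually used


def effective_rate_k(params: HybridParams, total_conc: np.ndarray) -> float:
    if params.rate_k is not None:
        return params.rate_k
    c_max = float(np.max(total_conc))
    if c_max <= 0 or params.t1_hours <= 0:
        return 1.0
    return AUTO_KCT / (c_max * params.t1_hours)


def first_hybridization(pool: SpeciesPool, params: HybridParams) -> FirstHybridizationResult:
    """Closed-form second-order decay of adapter-ligated single strands.

    The adapter-A and adapter-B reactions contain the same tester mixed with
    ``driver_excess`` × driver, so their single-strand profiles coincide;
    both are returned explicitly because downstream steps treat them as
    separate reactions.
    """
    total = pool.tester + params.driver_excess * pool.driver
    k = effective_rate_k(params, total)
    decay = 1.0 + k * total * params.t1_hours
    ss = pool.tester / decay
    driver_ss = params.driver_excess * pool.driver / decay
    return FirstHybridizationResult(
        ss_A=SingleStrandPool(pool.species_ids, ss),
        ss_B=SingleStrandPool(pool.species_ids, ss.copy()),
        driver_ss=SingleStrandPool(pool.species_ids, driver_ss),
        duplexed_A=pool.tester - ss,
        rate_k=k,
    )


def second_hybridization(
    pool_a: SingleStrandPool,
    pool_b: SingleStrandPool,
    params: HybridParams,
    driver_ss: SingleStrandPool | None = None,
    rate_k: float | None = None,
) -> SingleStrandPool:
    """A–B duplex yield after mixing the two first-hybridization reactions.

    Annealing is second order with rate ``k · peg_rate_multiplier`` over
    ``t2_hours``; among the duplexes a species forms, the A–B fraction
    follows random pairing, so the yield is proportional to ``sA·sB`` and
    never exceeds ``min(sA, sB)``.
    """
    if pool_a.species_ids != pool_b.species_ids:
        raise ValidationError("A and B pools must cover identical species sets")
    sa, sb = pool_a.conc, pool_b.conc
    dr = np.zeros_like(sa)
    if driver_ss is not None:
        if driver_ss.species_ids != pool_a.species_ids:
            raise ValidationError("driver remnant must cover the same species set")
        # both first-hybridization reactions contribute their driver remnant
        dr = 2.0 * driver_ss.conc
    total = sa + sb + dr
    k = rate_k if rate_k is not None else effective_rate_k(params, total)
    k2 = k * params.peg_rate_multiplier
    with np.errstate(divide="ignore", invalid="ignore"):
        annealed_fraction = np.where(total > 0, k2 * total * params.t2_hours / (1.0 + k2 * total * params.t2_hours), 0.0)
        ab_yield = np.where(total > 0, annealed_fraction * sa * sb / total, 0.0)
    return SingleStrandPool(pool_a.species_ids, ab_yield)


def suppression_pcr(duplex_yields: SingleStrandPool, cycles: int = 16) -> pd.Series:
    """Composition after exponential amplification of A–B duplexes only.

    Amplification is species-independent (2**cycles for every A–B duplex),
    so it preserves rank order; A–A and B–B species contribute nothing. The
    result is normalized to sum to 1.
    """
    y = duplex_yields.conc * (2.0 ** cycles)
    total = y.sum()
    if total <= 0:
        raise ValidationError("empty subtracted library: no A–B duplexes to amplify")
    return pd.Series(y / total, index=list(duplex_yields.species_ids), name="subtracted_share")


def run_ssh(pool: SpeciesPool, params: HybridParams | None = None) -> pd.Series:
    """First hybridization → mixing with PEG → suppression PCR."""
    params = params or HybridParams()
    first = first_hybridization(pool, params)
    duplexes = second_hybridization(
        first.ss_A, first.ss_B, params, driver_ss=first.driver_ss, rate_k=first.rate_k
    )
    return suppression_pcr(duplexes, params.pcr_cycles)
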