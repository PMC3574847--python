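"""Randomization and binomial tests linking symbiont groups to host background.

Two label-shuffling tests mirror the study design on maternally co-transmitted
markers: (1) is carriage of the divergent symbiont lineage (Group 2)
associated with the southern host mtDNA haplogroup? and (2) are infected
individuals disproportionately carriers of mtDNA haplotypes from the
North/South contact ("mixed") region?  Both shuffle the focal indicator across
individuals with its total fixed and report the plain proportion of null
statistics >= observed (an add-one variant is available; the plain proportion
matches the convention of small randomization designs with ~100 draws).

A one-sided exact binomial test asks, per host mtDNA haplotype, whether more
individuals are infected than uninfected under a fair-coin null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .errors import InputError, NoTestError, ParameterError
from .seq_io import HostMetaTable

__all__ = [
    "RandomizationResult",
    "test_group2_south",
    "test_infection_mixedregion",
    "binomial_infection_test",
    "per_haplotype_binomial",
]


@dataclass(frozen=True)
class RandomizationResult:
    statistic: str
    observed: float
    p_value: float
    n_rand: int
    seed: int | None
    add_one: bool
    null_stats: np.ndarray = field(compare=False, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "statistic": self.statistic,
                    "observed": self.observed,
                    "p_value": self.p_value,
                    "n_rand": self.n_rand,
                    "seed": self.seed,
                    "add_one": self.add_one,
                }
            ]
        )


def _randomization_p(observed: float, null_stats: np.ndarray, add_one: bool) -> float:
    ge = int((null_stats >= observed).sum())
    if add_one:
        return (1.0 + ge) / (1.0 + len(null_stats))
    return ge / len(null_stats)


def _shuffled(indicator: np.ndarray, n_rand: int, rng: np.random.Generator) -> np.ndarray:
    """(n_rand, n) matrix of the indicator shuffled with its total preserved."""
    return rng.permuted(np.tile(indicator, (n_rand, 1)), axis=1)


def test_group2_south(
    meta: HostMetaTable,
    n_rand: int = 100,
    seed: int | None = None,
    add_one: bool = False,
) -> RandomizationResult:
    """Count of individuals carrying Group 2 AND a southern mtDNA haplogroup,
    against Group-2 carriage shuffled across individuals."""
    if n_rand < 1:
        raise ParameterError("n_rand must be >= 1")
    g2 = meta.df["group2"].to_numpy(dtype=np.int64)
    south = (meta.df["mtdna_haplogroup"] == "South").to_numpy(dtype=np.int64)
    if g2.sum() == 0:
        raise NoTestError("no Group 2 carriers in the metadata")
    observed = float((g2 & south).sum())
    rng = np.random.default_rng(seed)
    null = _shuffled(g2, n_rand, rng) @ south
    return RandomizationResult(
        statistic="n_group2_and_south",
        observed=observed,
        p_value=_randomization_p(observed, null, add_one),
        n_rand=n_rand,
        seed=seed,
        add_one=add_one,
        null_stats=null.astype(float),
    )


def test_infection_mixedregion(
    meta: HostMetaTable,
    n_rand: int = 100,
    seed: int | None = None,
    add_one: bool = False,
) -> RandomizationResult:
    """Proportion of infected individuals whose mtDNA haplotype is a
    mixed-region haplotype, against infection status shuffled across
    individuals with prevalence preserved."""
    if n_rand < 1:
        raise ParameterError("n_rand must be >= 1")
    inf = meta.df["infected"].to_numpy(dtype=np.int64)
    mixed = meta.df["mixed_region"].to_numpy(dtype=np.int64)
    n_inf = inf.sum()
    if n_inf == 0:
        raise NoTestError("no infected individuals in the metadata")
    observed = float((inf & mixed).sum()) / n_inf
    rng = np.random.default_rng(seed)
    null = (_shuffled(inf, n_rand, rng) @ mixed) / n_inf
    return RandomizationResult(
        statistic="prop_infected_mixed_region",
        observed=observed,
        p_value=_randomization_p(observed, null, add_one),
        n_rand=n_rand,
        seed=seed,
        add_one=add_one,
        null_stats=null.astype(float),
    )


def binomial_infection_test(k_infected: int, n_total: int) -> float:
    """One-sided exact binomial tail P(X >= k | n, 1/2)."""
    if n_total < 1 or not (0 <= k_infected <= n_total):
        raise InputError(f"need 0 <= k <= n and n >= 1, got k={k_infected}, n={n_total}")
    return float(binom.sf(k_infected - 1, n_total, 0.5))


def per_haplotype_binomial(meta: HostMetaTable) -> pd.DataFrame:
    """Per host mtDNA haplotype: infected vs uninfected counts and the
    one-sided binomial p for an excess of infected individuals."""
    rows = []
    for hap, sub in meta.df.groupby("mtdna_haplotype", sort=True):
        k = int(sub["infected"].sum())
        n = len(sub)
        rows.append(
            {
                "mtdna_haplotype": hap,
                "n_infected": k,
                "n_uninfected": n - k,
                "binomial_p": binomial_infection_test(k, n),
            }
        )
    return pd.DataFrame(rows)
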