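"""Synthetic clone libraries and host metadata with known ground truth.

The generator emulates the sampling design the analysis assumes: 10 collection
sites with 2-8 sequenced flies each (47 in total), 2-20 cloned amplicon
sequences per fly, two divergent symbiont lineages (the larger one split into
three subgroups), occasional superinfected flies carrying both lineages,
per-clone polymerase error, occasional within-host recombinant clones, and
host mtDNA haplotypes structured into northern/southern haplogroups with a
contact ("mixed") region.  Every stochastic event — templates, error
positions, splice breakpoints — is recorded in a ground-truth log so that
pipeline stages can be scored against what was actually simulated.

Strain geometry uses disjoint substitution position sets, so all inter-strain
distances are exact sums by construction: the two lineages sit ``d_between``
substitutions apart (far beyond any parsimony connection limit), subgroup
centroids sit ``subgroup_offset`` steps from the lineage-1 ancestor (above the
subgroup cut, below the connection limit), and leaf strains sit 1-3 steps from
their centroid.

Per-site clone error uses the cycle-compounded probability
``1 - (1 - rate_e) ** cycles`` rather than a branching-process PCR model; it
matches the Poisson mean of the artifact filter to first order and keeps the
simulator analytically checkable.  No indels are simulated (downstream
statistics exclude gap columns anyway).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .seq_io import CloneRecord, HostMetaTable

__all__ = [
    "SimulationParams",
    "StrainSet",
    "GroundTruth",
    "simulate_strains",
    "simulate_clone_library",
    "simulate_host_metadata",
    "simulate_bundle",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# site code -> (number of flies, latitude, longitude); counts sum to 47 with
# 2-8 flies per site, in the range sampled by the study design they emulate.
_DEFAULT_SITES: tuple[tuple[str, int, float, float], ...] = (
    ("JN", 8, 1.33, 32.74),
    ("MS", 6, 1.63, 31.69),
    ("BN", 6, 0.93, 33.98),
    ("BV", 5, 0.31, 33.30),
    ("MF", 5, 2.28, 31.56),
    ("KK", 5, 0.37, 30.28),
    ("BU", 4, 0.25, 33.97),
    ("BK", 3, 1.02, 33.88),
    ("OS", 3, 1.53, 33.50),
    ("DR", 2, 0.75, 31.10),
)


@dataclass(frozen=True)
class SimulationParams:
    """Defaults define the study conditions the pipeline is tested under."""

    length: int = 600
    sites: tuple[tuple[str, int, float, float], ...] = _DEFAULT_SITES
    clones_min: int = 2
    clones_max: int = 20
    # strain geometry
    d_between: int = 40
    subgroup_offset: int = 7
    leaf_steps_max: int = 3
    n_leaves_per_subgroup: int = 4
    n_leaves_group2: int = 2
    centroid_weight: float = 5.0
    # per-fly composition
    max_strains_group1: int = 3
    max_strains_group2: int = 2
    superinfection_rate: float = 0.25  # base P(Group 2) for a northern fly
    theta: float = 1.5  # log-odds shift of Group 2 carriage for southern flies
    # clone error / recombination process
    rate_e: float = 1e-4
    cycles: int = 35
    recombinant_rate: float = 0.05
    # replicate verification
    n_replicate_flies: int = 3
    replicate_site: str = "JN"
    # host structure
    p_south: float = 0.5
    n_mtdna_haplotypes: int = 40
    n_mixed_haplotypes: int = 15
    infection_base_rate: float = 0.3
    theta_infection: float = 0.7  # log-odds shift of infection for mixed-region haplotypes

    def __post_init__(self) -> None:
        probs = (
            self.superinfection_rate,
            self.recombinant_rate,
            self.p_south,
            self.infection_base_rate,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ParameterError("all probabilities must lie in [0, 1]")
        if not (0.0 <= self.rate_e < 1.0):
            raise ParameterError("rate_e must be in [0, 1)")
        needed = (
            self.d_between
            + 2 * self.subgroup_offset
            + self.leaf_steps_max * (3 * self.n_leaves_per_subgroup + self.n_leaves_group2)
        )
        if needed > self.length:
            raise ParameterError(
                f"strain geometry needs {needed} distinct sites but length is {self.length}"
            )
        if not (1 <= self.clones_min <= self.clones_max):
            raise ParameterError("need 1 <= clones_min <= clones_max")

    @property
    def n_flies(self) -> int:
        return sum(n for _, n, _, _ in self.sites)

    @property
    def per_site_error(self) -> float:
        return 1.0 - (1.0 - self.rate_e) ** self.cycles


@dataclass(frozen=True)
class StrainSet:
    """True strain sequences with lineage/subgroup labels and sampling weights."""

    sequences: dict[str, str]
    lineage: dict[str, str]  # strain id -> "Group1" | "Group2"
    subgroup: dict[str, str]  # strain id -> "1a" | "1b" | "1c" | "2"
    weights: dict[str, float]

    def ids_in_lineage(self, lineage: str) -> list[str]:
        return sorted(s for s, l in self.lineage.items() if l == lineage)


@dataclass
class CloneEvent:
    """How one emitted clone was produced from its template(s).

    ``matches_strain`` records which true strain, if any, the *final* emitted
    sequence equals — a splice whose breakpoint misses every differing site,
    or an error that lands exactly on a sister strain's private substitution,
    yields a genuine observation of that strain and is booked as one.
    """

    clone_label: str
    individual_id: str
    template: str
    second_template: str | None
    breakpoint: int | None
    error_positions: tuple[int, ...]
    matches_strain: str | None

    @property
    def is_recombinant(self) -> bool:
        return self.second_template is not None

    @property
    def is_error_free(self) -> bool:
        return not self.error_positions and not self.is_recombinant


@dataclass
class GroundTruth:
    """Event log sufficient to reconstruct every emitted clone."""

    strains: StrainSet
    fly_strains: dict[str, dict[str, float]]  # individual -> strain -> frequency
    clone_events: list[CloneEvent] = field(default_factory=list)

    def strain_observed_counts(self) -> dict[str, int]:
        """Per strain: number of emitted clones whose sequence equals it exactly."""
        counts = {s: 0 for s in self.strains.sequences}
        for ev in self.clone_events:
            if ev.matches_strain is not None:
                counts[ev.matches_strain] += 1
        return counts

    def strains_observed_at_least(self, k: int) -> set[str]:
        return {s for s, c in self.strain_observed_counts().items() if c >= k}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "strains": {
                s: {
                    "sequence": self.strains.sequences[s],
                    "lineage": self.strains.lineage[s],
                    "subgroup": self.strains.subgroup[s],
                }
                for s in sorted(self.strains.sequences)
            },
            "fly_strains": self.fly_strains,
            "clone_events": [asdict(ev) for ev in self.clone_events],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _substitute(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with a uniformly chosen *different* base."""
    out = seq.copy()
    for pos in positions:
        choices = _BASES[_BASES != out[pos]]
        out[pos] = choices[rng.integers(0, 3)]
    return out


def simulate_strains(params: SimulationParams, seed: int | np.random.Generator | None = None) -> StrainSet:
    """Draw the true strain sequences on disjoint substitution position sets."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anc = _random_sequence(params.length, rng)
    needed = (
        params.d_between
        + 2 * params.subgroup_offset
        + params.leaf_steps_max * (3 * params.n_leaves_per_subgroup + params.n_leaves_group2)
    )
    pool = rng.choice(params.length, size=needed, replace=False)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = pool[cursor : cursor + k]
        cursor += k
        return out

    sequences: dict[str, str] = {}
    lineage: dict[str, str] = {}
    subgroup: dict[str, str] = {}
    weights: dict[str, float] = {}

    def add(sid: str, seq: np.ndarray, lin: str, sub: str, w: float) -> None:
        sequences[sid] = seq.tobytes().decode("ascii")
        lineage[sid] = lin
        subgroup[sid] = sub
        weights[sid] = w

    g2_anc = _substitute(anc, take(params.d_between), rng)
    centroids = {
        "1a": anc,
        "1b": _substitute(anc, take(params.subgroup_offset), rng),
        "1c": _substitute(anc, take(params.subgroup_offset), rng),
    }
    for sub, centroid in centroids.items():
        add(f"s{sub}-0", centroid, "Group1", sub, params.centroid_weight)
        for leaf in range(1, params.n_leaves_per_subgroup + 1):
            k = int(rng.integers(1, params.leaf_steps_max + 1))
            add(f"s{sub}-{leaf}", _substitute(centroid, take(k), rng), "Group1", sub, 1.0)
    add("s2-0", g2_anc, "Group2", "2", params.centroid_weight)
    for leaf in range(1, params.n_leaves_group2 + 1):
        k = int(rng.integers(1, params.leaf_steps_max + 1))
        add(f"s2-{leaf}", _substitute(g2_anc, take(k), rng), "Group2", "2", 1.0)
    return StrainSet(sequences=sequences, lineage=lineage, subgroup=subgroup, weights=weights)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def simulate_host_metadata(
    params: SimulationParams,
    seed: int | np.random.Generator | None = None,
    n_individuals: int | None = None,
) -> HostMetaTable:
    """Host metadata table.

    Default (n_individuals None): the sequenced flies — one row per fly at the
    configured sites, all infected, Group 1 always carried, Group 2 carriage
    drawn with log-odds shifted by ``theta`` for southern flies.

    With ``n_individuals`` set (e.g. 366): a field-screened cohort across the
    same sites with infection status drawn with log-odds shifted by
    ``theta_infection`` for carriers of mixed-region haplotypes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # mtDNA haplotype pool: geometric frequencies, a slice of them flagged as
    # occurring in the North/South contact region; haplogroup is a property of
    # the haplotype (maternal inheritance), split by the target southern share.
    n_hap = params.n_mtdna_haplotypes
    hap_ids = [f"mt{h:02d}" for h in range(1, n_hap + 1)]
    freqs = 0.85 ** np.arange(n_hap)
    freqs /= freqs.sum()
    n_south = int(round(params.p_south * n_hap))
    is_south = np.zeros(n_hap, dtype=bool)
    is_south[rng.choice(n_hap, size=n_south, replace=False)] = True
    is_mixed = np.zeros(n_hap, dtype=bool)
    is_mixed[rng.choice(n_hap, size=params.n_mixed_haplotypes, replace=False)] = True

    if n_individuals is None:
        rows = []
        base = _logit(params.superinfection_rate)
        for site, n_flies, lat, lon in params.sites:
            for f in range(1, n_flies + 1):
                hap = int(rng.choice(n_hap, p=freqs))
                south = bool(is_south[hap])
                g2 = bool(rng.random() < _sigmoid(base + params.theta * south))
                rows.append(
                    {
                        "individual_id": f"{site}{f:02d}",
                        "site_code": site,
                        "latitude": lat,
                        "longitude": lon,
                        "mtdna_haplotype": hap_ids[hap],
                        "mtdna_haplogroup": "South" if south else "North",
                        "mixed_region": bool(is_mixed[hap]),
                        "infected": True,
                        "group1": True,
                        "group2": g2,
                    }
                )
        return HostMetaTable(pd.DataFrame(rows))

    rows = []
    base_inf = _logit(params.infection_base_rate)
    site_cycle = [s for s, _, _, _ in params.sites]
    coords = {s: (lat, lon) for s, _, lat, lon in params.sites}
    for i in range(n_individuals):
        site = site_cycle[i % len(site_cycle)]
        hap = int(rng.choice(n_hap, p=freqs))
        mixed = bool(is_mixed[hap])
        infected = bool(rng.random() < _sigmoid(base_inf + params.theta_infection * mixed))
        lat, lon = coords[site]
        rows.append(
            {
                "individual_id": f"SCR{i + 1:04d}",
                "site_code": site,
                "latitude": lat,
                "longitude": lon,
                "mtdna_haplotype": hap_ids[hap],
                "mtdna_haplogroup": "South" if is_south[hap] else "North",
                "mixed_region": mixed,
                "infected": infected,
                "group1": infected,
                "group2": False,
            }
        )
    return HostMetaTable(pd.DataFrame(rows))


def simulate_clone_library(
    strains: StrainSet,
    params: SimulationParams,
    seed: int | np.random.Generator | None = None,
    meta: HostMetaTable | None = None,
) -> tuple[list[CloneRecord], GroundTruth]:
    """Emit cloned amplicon sequences for every fly, with the event log.

    Each clone picks a template by its fly's strain frequencies, acquires
    per-site substitution errors with the cycle-compounded probability, and —
    in flies carrying more than one strain — is spliced from two co-resident
    templates at a uniform breakpoint with probability ``recombinant_rate``.
    Flies at the replicate-verification site get their clones split across two
    independent PCR replicates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if meta is None:
        meta = simulate_host_metadata(params, rng)
    g1_ids = strains.ids_in_lineage("Group1")
    g2_ids = strains.ids_in_lineage("Group2")
    g1_w = np.array([strains.weights[s] for s in g1_ids])
    g2_w = np.array([strains.weights[s] for s in g2_ids])
    enc = {s: np.frombuffer(seq.encode(), dtype=np.uint8) for s, seq in strains.sequences.items()}
    strain_of_seq = {seq: s for s, seq in strains.sequences.items()}

    rep_flies: set[str] = set(
        meta.df.loc[meta.df["site_code"] == params.replicate_site, "individual_id"]
        .head(params.n_replicate_flies)
        .tolist()
    )

    clones: list[CloneRecord] = []
    fly_strains: dict[str, dict[str, float]] = {}
    events: list[CloneEvent] = []
    p_err = params.per_site_error

    for row in meta.df.itertuples(index=False):
        carried: list[str] = []
        n_g1 = int(rng.integers(1, params.max_strains_group1 + 1))
        carried += list(
            rng.choice(g1_ids, size=min(n_g1, len(g1_ids)), replace=False, p=g1_w / g1_w.sum())
        )
        if row.group2:
            n_g2 = int(rng.integers(1, params.max_strains_group2 + 1))
            carried += list(
                rng.choice(g2_ids, size=min(n_g2, len(g2_ids)), replace=False, p=g2_w / g2_w.sum())
            )
        if not carried:
            raise ParameterError(f"fly {row.individual_id} carries no strains")
        freq = rng.dirichlet(np.ones(len(carried)))
        fly_strains[row.individual_id] = dict(zip(carried, freq.tolist()))

        n_clones = int(rng.integers(params.clones_min, params.clones_max + 1))
        for c in range(1, n_clones + 1):
            template = carried[int(rng.choice(len(carried), p=freq))]
            second: str | None = None
            breakpoint: int | None = None
            seq = enc[template]
            if len(carried) >= 2 and rng.random() < params.recombinant_rate:
                others = [s for s in carried if s != template]
                second = others[int(rng.integers(0, len(others)))]
                breakpoint = int(rng.integers(1, params.length))
                seq = np.concatenate([enc[template][:breakpoint], enc[second][breakpoint:]])
            n_err = int(rng.binomial(params.length, p_err))
            err_pos = np.sort(rng.choice(params.length, size=n_err, replace=False)) if n_err else np.empty(0, dtype=int)
            out = _substitute(seq, err_pos, rng)
            out_str = out.tobytes().decode("ascii")
            replicate = (1 + c % 2) if row.individual_id in rep_flies else 1
            clone_id = f"c{c:03d}"
            clones.append(
                CloneRecord(
                    clone_id=clone_id,
                    individual_id=row.individual_id,
                    site_code=row.site_code,
                    pcr_replicate=replicate,
                    sequence=out_str,
                )
            )
            events.append(
                CloneEvent(
                    clone_label=f"{row.site_code}|{row.individual_id}|r{replicate}|{clone_id}",
                    individual_id=row.individual_id,
                    template=template,
                    second_template=second,
                    breakpoint=breakpoint,
                    error_positions=tuple(int(p) for p in err_pos),
                    matches_strain=strain_of_seq.get(out_str),
                )
            )
    truth = GroundTruth(strains=strains, fly_strains=fly_strains, clone_events=events)
    return clones, truth


def simulate_bundle(
    params: SimulationParams | None = None,
    seed: int | None = None,
) -> tuple[list[CloneRecord], HostMetaTable, GroundTruth]:
    """Strains + metadata + clone library from one seed (the common entry point)."""
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    strains = simulate_strains(params, rng)
    meta = simulate_host_metadata(params, rng)
    clones, truth = simulate_clone_library(strains, params, rng, meta=meta)
    return clones, meta, truth
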