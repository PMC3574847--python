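"""Classify clone haplotypes as genuine variants or PCR/cloning artifacts.

Amplifying a low-density endosymbiont template through consecutive PCRs
inflates apparent sequence diversity: polymerase errors accumulate along each
clone's replication lineage, so singleton haplotypes one or a few substitutions
away from an abundant sequence are suspect.  The model here is deliberately
simple and uses exactly the quantities the experiment defines:

* the polymerase error rate ``rate_e`` (errors per bp per cycle),
* the effective number of cycles ``cycles`` (summed over consecutive PCRs),
* the amplicon length ``length``.

Per clone, the number of errors is Poisson with mean lambda = rate_e * length
* cycles.  A singleton at substitution distance d from its nearest retained
neighbour is attributable to PCR error when, among the n clones sequenced, at
least one clone plausibly accumulates >= d errors:

    p_one = P(Poisson(lambda) >= d)          (per clone)
    p     = 1 - (1 - p_one) ** n_clones      (anywhere in the library)

Singletons with p >= alpha are flagged as artifacts.  Haplotypes observed two
or more times (within or among individuals), or verified in two independent
PCR replicates of the same individual, are genuine by the multiplicity /
reconditioning rules and never tested.

Two datasets are emitted: "complete" (everything not attributable to error,
singletons included) and "conservative" (only haplotypes seen >= 2 times).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import poisson

from ._distance import VALID_CODE_MAX, encode
from .errors import LogicError, ParameterError, PipelineError
from .seq_io import CloneRecord, HaplotypeTable, collapse_haplotypes

__all__ = [
    "ErrorModel",
    "FilterDecision",
    "FilterResult",
    "expected_errors",
    "artifact_probability",
    "nearest_retained",
    "reconditioning_consistency",
    "build_datasets",
]


@dataclass(frozen=True)
class ErrorModel:
    """Polymerase error model: rate per bp per cycle, effective cycles, amplicon length."""

    rate_e: float = 4e-4
    cycles: int = 70
    length: int = 600

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate_e < 1.0):
            raise ParameterError(f"rate_e must be in [0, 1), got {self.rate_e}")
        if self.cycles < 1:
            raise ParameterError(f"cycles must be >= 1, got {self.cycles}")
        if self.length < 1:
            raise ParameterError(f"length must be >= 1, got {self.length}")

    @property
    def per_site_error(self) -> float:
        """Probability a given site of a clone ends up substituted (cycle-compounded)."""
        return 1.0 - (1.0 - self.rate_e) ** self.cycles


def expected_errors(model: ErrorModel) -> float:
    """Mean number of polymerase errors per clone, lambda = rate_e * length * cycles."""
    return model.rate_e * model.length * model.cycles


def artifact_probability(distance: int, model: ErrorModel, n_clones: int) -> float:
    """P(at least one of n_clones clones accumulates >= distance errors).

    ``distance`` is the substitution distance from the candidate to its
    nearest retained neighbour (gap/N columns excluded).
    """
    if distance < 1:
        raise LogicError("candidate identical to a retained haplotype; should have been collapsed")
    if n_clones < 1:
        raise ParameterError("n_clones must be >= 1")
    lam = expected_errors(model)
    if lam == 0.0:
        return 0.0
    p_one = float(poisson.sf(distance - 1, lam))
    # log-space pool correction is stable for tiny p_one and large n
    return float(-np.expm1(n_clones * np.log1p(-p_one)))


def nearest_retained(sequence: str, pool: HaplotypeTable) -> tuple[str, int]:
    """Nearest retained neighbour of a candidate sequence.

    Ties: smallest distance, then largest count, then lexicographic sequence.
    """
    enc_pool = encode(pool.sequences)
    q = encode([sequence])[0]
    ok = (q <= VALID_CODE_MAX) & (enc_pool <= VALID_CODE_MAX)
    dists = ((q != enc_pool) & ok).sum(axis=1)
    order = sorted(
        range(len(pool)),
        key=lambda i: (int(dists[i]), -pool.haplotypes[i].count, pool.sequences[i]),
    )
    best = order[0]
    return pool.ids[best], int(dists[best])


def reconditioning_consistency(clones: list[CloneRecord]) -> dict[str, dict[str, set[int]]]:
    """Map sequence -> individual -> set of PCR replicates in which it was seen.

    A haplotype observed in >= 2 independent replicates of one individual is
    replicate-verified and exempt from artifact removal.
    """
    seen: dict[str, dict[str, set[int]]] = {}
    for c in sorted(clones, key=lambda c: (c.individual_id, c.pcr_replicate, c.clone_id)):
        seen.setdefault(c.sequence, {}).setdefault(c.individual_id, set()).add(c.pcr_replicate)
    return seen


def replicate_verified(clones: list[CloneRecord]) -> set[str]:
    """Sequences seen in two or more replicates of the same individual."""
    return {
        seq
        for seq, by_ind in reconditioning_consistency(clones).items()
        if any(len(reps) >= 2 for reps in by_ind.values())
    }


@dataclass(frozen=True)
class FilterDecision:
    haplotype_id: str
    count: int
    rule: str  # multiplicity | replicate-verified | singleton-retained | artifact
    nearest_id: str | None
    distance: int | None
    lam: float
    probability: float | None


@dataclass(frozen=True)
class FilterResult:
    complete: HaplotypeTable
    conservative: HaplotypeTable
    artifacts: HaplotypeTable
    decisions: tuple[FilterDecision, ...] = field(compare=False)

    def decision_frame(self) -> pd.DataFrame:
        return pd.DataFrame([d.__dict__ for d in self.decisions])


def build_datasets(
    clones: list[CloneRecord],
    model: ErrorModel | None = None,
    alpha: float = 0.05,
) -> FilterResult:
    """Apply the multiplicity, reconditioning and error-model rules.

    Retention logic:

    1. haplotypes with total count >= 2, and replicate-verified haplotypes,
       are retained unconditionally;
    2. each remaining singleton is tested against its nearest retained
       neighbour: flagged as artifact iff its artifact probability >= alpha
       (i.e. the observed distance is within the error-plausible range);
    3. conservative = retained haplotypes with count >= 2.
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    table = collapse_haplotypes(clones)
    if model is None:
        model = ErrorModel(length=table.alignment_length)
    lam = expected_errors(model)
    n_clones = len(clones)
    verified_seqs = replicate_verified(clones)

    decisions: list[FilterDecision] = []
    retained_ids: set[str] = set()
    singletons = []
    for h in table:
        if h.count >= 2:
            retained_ids.add(h.haplotype_id)
            decisions.append(
                FilterDecision(h.haplotype_id, h.count, "multiplicity", None, None, lam, None)
            )
        elif h.sequence in verified_seqs:
            retained_ids.add(h.haplotype_id)
            decisions.append(
                FilterDecision(h.haplotype_id, h.count, "replicate-verified", None, None, lam, None)
            )
        else:
            singletons.append(h)

    artifact_ids: set[str] = set()
    if singletons and retained_ids:
        pool = table.subset(retained_ids)
        for h in singletons:
            nid, d = nearest_retained(h.sequence, pool)
            prob = artifact_probability(d, model, n_clones)
            if prob >= alpha:
                artifact_ids.add(h.haplotype_id)
                decisions.append(FilterDecision(h.haplotype_id, h.count, "artifact", nid, d, lam, prob))
            else:
                retained_ids.add(h.haplotype_id)
                decisions.append(
                    FilterDecision(h.haplotype_id, h.count, "singleton-retained", nid, d, lam, prob)
                )
    else:
        # no retained pool to test against: singletons cannot be attributed to
        # error relative to anything, keep them in the complete dataset
        for h in singletons:
            retained_ids.add(h.haplotype_id)
            decisions.append(
                FilterDecision(h.haplotype_id, h.count, "singleton-retained", None, None, lam, None)
            )

    if not retained_ids:
        raise PipelineError("dataset empty after filtering")

    complete = table.subset(retained_ids)
    conservative = HaplotypeTable(tuple(h for h in complete if h.count >= 2))
    artifacts = table.subset(artifact_ids)
    order = {hid: i for i, hid in enumerate(table.ids)}
    decisions.sort(key=lambda d: order[d.haplotype_id])
    return FilterResult(
        complete=complete,
        conservative=conservative,
        artifacts=artifacts,
        decisions=tuple(decisions),
    )
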