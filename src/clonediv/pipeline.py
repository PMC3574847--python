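"""End-to-end orchestration: filter -> screen -> network -> diversity -> AMOVA -> association.

A single :class:`PipelineConfig` drives the run; one global seed derives every
stage seed through a documented splitting rule (``SeedSequence(seed,
spawn_key=(stage_index,))``), so any stochastic stage can be re-run in
isolation and reproduce its output.  Every run writes a config snapshot and a
manifest of output files with SHA-256 checksums: identical seed and inputs
imply identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import association, diversity, network, recomb, seq_io
from .amova import amova as run_amova
from .amova import expand_by_group
from .artifact_filter import ErrorModel, build_datasets
from .errors import InputError, NoTestError, PipelineError
from .seq_io import (
    Alignment,
    HaplotypeTable,
    HostMetaTable,
    LabelScheme,
    collapse_haplotypes,
    parse_clone_labels,
    read_alignment,
)
from .simulate import SimulationParams, simulate_bundle, simulate_host_metadata

logger = logging.getLogger("clonediv")

# stage name -> index used in the seed-splitting rule
STAGES = (
    "simulate",
    "filter",
    "recomb",
    "network",
    "diversity",
    "amova",
    "association",
)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the global seed."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(seed, spawn_key=(idx,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything a run needs; serialized next to the outputs for provenance."""

    outdir: str = "clonediv-run"
    input_fasta: str | None = None
    hosts_tsv: str | None = None
    screened_tsv: str | None = None
    simulate: bool = False
    seed: int = 0
    # error model
    rate_e: float = 4e-4
    cycles: int = 70
    # significance levels
    alpha_artifact: float = 0.05
    alpha_recomb: float = 0.05
    # resampling sizes
    n_perm_recomb: int = 10_000
    n_perm_amova: int = 10_000
    n_rand_assoc: int = 100
    # network
    connection_confidence: float = 0.95
    fixed_limit: int | None = None
    subgroup_threshold: int = 5
    # label parsing
    label_delimiter: str = "|"
    skip_recomb: bool = False

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class ValidationReport:
    ok: bool
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def validate_inputs(
    alignment: Alignment,
    clones: list[seq_io.CloneRecord],
    meta: HostMetaTable,
) -> ValidationReport:
    """Check alignment integrity, label parse coverage and metadata coverage."""
    errors: list[str] = []
    warnings: list[str] = []
    clone_inds = {c.individual_id for c in clones}
    missing = sorted(clone_inds - meta.individuals)
    if missing:
        errors.append(f"individuals in FASTA missing from metadata: {missing}")
    extra = sorted(meta.individuals - clone_inds)
    if extra:
        warnings.append(f"metadata individuals without clones: {extra}")
    site_of = meta.site_of()
    for c in clones:
        if c.individual_id in site_of and site_of[c.individual_id] != c.site_code:
            errors.append(
                f"site mismatch for {c.individual_id}: {c.site_code} in FASTA, "
                f"{site_of[c.individual_id]} in metadata"
            )
            break
    return ValidationReport(ok=not errors, errors=errors, warnings=warnings)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _individual_groups(table: HaplotypeTable, groups: dict[str, str]) -> dict[str, set[str]]:
    """Which symbiont groups each individual carries, from its haplotypes."""
    out: dict[str, set[str]] = {}
    for h in table:
        for ind in h.carrier_counts:
            out.setdefault(ind, set()).add(groups[h.haplotype_id])
    return out


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Execute all stages; returns the manifest (paths + checksums + counts)."""
    if dry_run:
        return {"stages": list(STAGES), "outdir": config.outdir, "dry_run": True}

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "counts": {}, "files": {}}
    scheme = LabelScheme(delimiter=config.label_delimiter)

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        sim_seed = stage_seed(config.seed, "simulate")
        params = SimulationParams()
        clones, meta, truth = simulate_bundle(params, seed=sim_seed)
        screened = simulate_host_metadata(
            params, seed=sim_seed + 1, n_individuals=366
        )
        alignment = seq_io.clones_to_alignment(clones, scheme)
        seq_io.write_alignment(alignment, outdir / "clones.fasta")
        meta.write_tsv(outdir / "hosts.tsv")
        screened.write_tsv(outdir / "screened_hosts.tsv")
        truth.to_json(outdir / "truth.json")
    else:
        if not config.input_fasta or not config.hosts_tsv:
            raise InputError("input_fasta and hosts_tsv are required unless simulate=True")
        alignment = read_alignment(config.input_fasta)
        clones = parse_clone_labels(alignment, scheme)
        meta = HostMetaTable.from_tsv(config.hosts_tsv)
        screened = (
            HostMetaTable.from_tsv(config.screened_tsv) if config.screened_tsv else None
        )

    report = validate_inputs(alignment, clones, meta)
    for w in report.warnings:
        logger.warning("validate: %s", w)
    if not report.ok:
        raise PipelineError(f"input validation failed: {report.errors}")
    manifest["counts"]["clones"] = len(clones)
    logger.info("inputs: %d clones, %d individuals", len(clones), len(meta))

    # --- artifact filter --------------------------------------------------
    model = ErrorModel(rate_e=config.rate_e, cycles=config.cycles, length=alignment.length)
    filt = build_datasets(clones, model=model, alpha=config.alpha_artifact)
    complete, conservative = filt.complete, filt.conservative
    filt.decision_frame().to_csv(outdir / "filter_decisions.tsv", sep="\t", index=False)
    filt.artifacts.write_fasta(outdir / "artifacts.fasta")
    logger.info(
        "filter: %d haplotypes -> complete %d, conservative %d, artifacts %d",
        len(collapse_haplotypes(clones)), len(complete), len(conservative), len(filt.artifacts),
    )

    # --- recombinant screen ----------------------------------------------
    if not config.skip_recomb:
        rec = recomb.geneconv_test(
            complete,
            n_perm=config.n_perm_recomb,
            seed=stage_seed(config.seed, "recomb"),
            alpha=config.alpha_recomb,
        )
        rec.write_tsv(outdir / "recomb_report.tsv")
        complete = complete.drop(rec.flagged)
        conservative = conservative.drop(rec.flagged)
        manifest["counts"]["recombinants_flagged"] = len(rec.flagged)
        logger.info("recomb: flagged %d haplotypes", len(rec.flagged))
    if len(complete) == 0:
        raise PipelineError("dataset empty after recombinant screening")
    complete.write_fasta(outdir / "complete.fasta")
    complete.write_tsv(outdir / "complete.tsv")
    conservative.write_fasta(outdir / "conservative.fasta")
    conservative.write_tsv(outdir / "conservative.tsv")
    manifest["counts"]["complete_haplotypes"] = len(complete)
    manifest["counts"]["conservative_haplotypes"] = len(conservative)

    # --- networks and group assignment -----------------------------------
    limit = (
        config.fixed_limit
        if config.fixed_limit is not None
        else network.connection_limit(alignment.length, config.connection_confidence)
    )
    manifest["counts"]["connection_limit"] = limit
    nets = {}
    for name, table in (("complete", complete), ("conservative", conservative)):
        if len(table) == 0:
            continue
        net = network.build_networks(table, limit)
        network.assign_groups(net, config.subgroup_threshold)
        net.edges_frame().to_csv(outdir / f"network_{name}_edges.tsv", sep="\t", index=False)
        net.labels_frame().to_csv(outdir / f"network_{name}_labels.tsv", sep="\t", index=False)
        nets[name] = net
        logger.info("network[%s]: %d components at limit %d", name, net.n_components, limit)

    # --- diversity --------------------------------------------------------
    haplogroup = meta.haplogroup_of()
    site = meta.site_of()
    for name, table in (("complete", complete), ("conservative", conservative)):
        if len(table) == 0:
            continue
        rows = diversity.summarize_groups(table, site, dataset_label="entire")
        diversity.summaries_to_frame(rows).to_csv(
            outdir / f"diversity_{name}_by_site.tsv", sep="\t", index=False
        )
        hg_rows = diversity.summarize_groups(table, haplogroup, dataset_label="entire")
        net = nets[name]
        by_group: list[diversity.DiversitySummary] = []
        labels = {
            hid: (net.subgroup_labels.get(hid) or net.group_labels[hid])
            for hid in net.group_labels
        }
        for label in sorted(set(labels.values())):
            ids = {hid for hid, lab in labels.items() if lab == label}
            sub = table.subset(ids)
            by_group.extend(diversity.summarize_groups(sub, dataset_label=label))
        frame = diversity.summaries_to_frame(hg_rows + by_group)
        frame.to_csv(outdir / f"diversity_{name}_by_group.tsv", sep="\t", index=False)

    # --- AMOVA ------------------------------------------------------------
    amova_frames = []
    for name, table in (("complete", complete), ("conservative", conservative)):
        if len(table) == 0:
            continue
        dist, labels = expand_by_group(table, haplogroup)
        res = run_amova(
            dist, labels, n_perm=config.n_perm_amova, seed=stage_seed(config.seed, "amova")
        )
        amova_frames.append(res.to_frame(comparison=f"North vs South ({name})"))
        logger.info("amova[%s]: pct_among=%.2f p=%.3g", name, res.pct_among, res.p_value)
    if amova_frames:
        import pandas as pd

        pd.concat(amova_frames, ignore_index=True).to_csv(
            outdir / "amova.tsv", sep="\t", index=False
        )

    # --- association tests -------------------------------------------------
    import pandas as pd

    assoc_frames = []
    assoc_seed = stage_seed(config.seed, "association")
    # observed Group 2 carriage comes from the network assignment, not metadata
    net = nets.get("complete")
    carried = _individual_groups(complete, net.group_labels)
    obs_meta = meta.df.copy()
    obs_meta["group2"] = obs_meta["individual_id"].map(
        lambda i: "Group2" in carried.get(i, set())
    )
    obs_meta["group1"] = obs_meta["individual_id"].map(
        lambda i: "Group1" in carried.get(i, set())
    )
    try:
        r1 = association.test_group2_south(
            HostMetaTable(obs_meta), n_rand=config.n_rand_assoc, seed=assoc_seed
        )
        assoc_frames.append(r1.to_frame())
    except NoTestError as exc:
        logger.warning("association group2/south: %s", exc)
    if screened is not None:
        try:
            r2 = association.test_infection_mixedregion(
                screened, n_rand=config.n_rand_assoc, seed=assoc_seed + 1
            )
            assoc_frames.append(r2.to_frame())
        except NoTestError as exc:
            logger.warning("association infection/mixed: %s", exc)
        association.per_haplotype_binomial(screened).to_csv(
            outdir / "binomial_by_haplotype.tsv", sep="\t", index=False
        )
    if assoc_frames:
        pd.concat(assoc_frames, ignore_index=True).to_csv(
            outdir / "association.tsv", sep="\t", index=False
        )

    # --- provenance --------------------------------------------------------
    config.to_yaml(outdir / "config.yaml")
    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest["files"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
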