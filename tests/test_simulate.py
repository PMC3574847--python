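"""Generator invariants: geometry, determinism, error process, ground truth."""

import dataclasses

import numpy as np
import pytest

from clonediv._distance import hamming
from clonediv.errors import ParameterError
from clonediv.simulate import (
    SimulationParams,
    simulate_bundle,
    simulate_clone_library,
    simulate_host_metadata,
    simulate_strains,
)


class TestStrainGeometry:
    def test_lineages_separated_by_at_least_d_between(self, default_params):
        strains = simulate_strains(default_params, seed=1)
        for a in strains.ids_in_lineage("Group1"):
            for b in strains.ids_in_lineage("Group2"):
                assert hamming(strains.sequences[a], strains.sequences[b]) >= default_params.d_between

    def test_centroid_distances_exact(self, default_params):
        strains = simulate_strains(default_params, seed=2)
        seq = strains.sequences
        assert hamming(seq["s1a-0"], seq["s1b-0"]) == default_params.subgroup_offset
        assert hamming(seq["s1a-0"], seq["s1c-0"]) == default_params.subgroup_offset
        assert hamming(seq["s1b-0"], seq["s1c-0"]) == 2 * default_params.subgroup_offset
        assert hamming(seq["s1a-0"], seq["s2-0"]) == default_params.d_between

    def test_leaves_within_reach_of_centroid(self, default_params):
        strains = simulate_strains(default_params, seed=3)
        for sid, sub in strains.subgroup.items():
            centroid = strains.sequences[f"s{sub}-0"]
            d = hamming(strains.sequences[sid], centroid)
            assert d <= default_params.leaf_steps_max

    def test_geometry_must_fit_amplicon(self):
        with pytest.raises(ParameterError):
            SimulationParams(length=60)

    def test_same_seed_byte_identical(self, default_params):
        s1 = simulate_strains(default_params, seed=9)
        s2 = simulate_strains(default_params, seed=9)
        assert s1.sequences == s2.sequences


class TestCloneLibrary:
    def test_no_error_no_recombination_is_exact(self, default_params):
        params = dataclasses.replace(default_params, rate_e=0.0, recombinant_rate=0.0)
        strains = simulate_strains(params, seed=4)
        clones, truth = simulate_clone_library(strains, params, seed=4)
        templates = {ev.clone_label: ev.template for ev in truth.clone_events}
        for c in clones:
            label = f"{c.site_code}|{c.individual_id}|r{c.pcr_replicate}|{c.clone_id}"
            assert c.sequence == strains.sequences[templates[label]]
            assert truth.clone_events[0].matches_strain is not None

    def test_clone_counts_in_configured_range(self, bundle, default_params):
        clones, _, _ = bundle
        per_fly = {}
        for c in clones:
            per_fly[c.individual_id] = per_fly.get(c.individual_id, 0) + 1
        assert len(per_fly) == default_params.n_flies == 47
        assert all(default_params.clones_min <= n <= default_params.clones_max for n in per_fly.values())

    def test_error_free_fraction_matches_analytic_rate(self, default_params):
        """Pooled over seeds: P(error-free clone) = (1 - p_site)^L within 3 s.e."""
        p_clean = (1.0 - default_params.per_site_error) ** default_params.length
        clean = total = 0
        for seed in range(20):
            _, truth = simulate_clone_library(
                simulate_strains(default_params, seed=seed), default_params, seed=seed
            )
            rec_free = [ev for ev in truth.clone_events if not ev.is_recombinant]
            clean += sum(not ev.error_positions for ev in rec_free)
            total += len(rec_free)
        se = np.sqrt(p_clean * (1 - p_clean) / total)
        assert abs(clean / total - p_clean) < 3 * se

    def test_recombinant_reconstructible_from_truth(self, default_params):
        """Spliced clones match parent A before and parent B after the breakpoint
        at every non-error position."""
        found = 0
        for seed in range(12):
            strains = simulate_strains(default_params, seed=seed)
            clones, truth = simulate_clone_library(strains, default_params, seed=seed)
            by_label = {
                f"{c.site_code}|{c.individual_id}|r{c.pcr_replicate}|{c.clone_id}": c
                for c in clones
            }
            for ev in truth.clone_events:
                if not ev.is_recombinant:
                    continue
                found += 1
                seq = by_label[ev.clone_label].sequence
                pa = strains.sequences[ev.template]
                pb = strains.sequences[ev.second_template]
                errs = set(ev.error_positions)
                for pos in range(default_params.length):
                    if pos in errs:
                        continue
                    expected = pa[pos] if pos < ev.breakpoint else pb[pos]
                    assert seq[pos] == expected
        assert found > 0

    def test_replicate_flies_split_across_two_pcrs(self, bundle, default_params):
        clones, _, _ = bundle
        reps = {}
        for c in clones:
            reps.setdefault(c.individual_id, set()).add(c.pcr_replicate)
        two_rep = {i for i, r in reps.items() if r == {1, 2}}
        assert len(two_rep) == default_params.n_replicate_flies
        assert all(i.startswith(default_params.replicate_site) for i in two_rep)

    def test_full_bundle_deterministic(self, default_params):
        c1, m1, _ = simulate_bundle(default_params, seed=5)
        c2, m2, _ = simulate_bundle(default_params, seed=5)
        assert c1 == c2
        assert m1.df.equals(m2.df)


class TestHostMetadata:
    def test_screened_cohort_size(self, default_params):
        meta = simulate_host_metadata(default_params, seed=0, n_individuals=366)
        assert len(meta) == 366

    def test_extreme_theta_forces_group2_south(self, default_params):
        # theta -> infinity with a vanishing baseline: carriage becomes
        # exclusive to southern flies
        params = dataclasses.replace(default_params, theta=50.0, superinfection_rate=1e-4)
        carriers = south = 0
        for seed in range(30):
            df = simulate_host_metadata(params, seed=seed).df
            carriers += df["group2"].sum()
            south += (df["group2"] & (df["mtdna_haplogroup"] == "South")).sum()
        assert carriers > 0 and south == carriers

    def test_zero_theta_odds_ratio_near_one(self, default_params):
        """Aggregated over datasets the Group2 x South odds ratio is ~1."""
        params = dataclasses.replace(default_params, theta=0.0)
        table = np.zeros((2, 2))
        for seed in range(200):
            df = simulate_host_metadata(params, seed=seed).df
            g2 = df["group2"].to_numpy()
            south = (df["mtdna_haplogroup"] == "South").to_numpy()
            table[0, 0] += (g2 & south).sum()
            table[0, 1] += (g2 & ~south).sum()
            table[1, 0] += (~g2 & south).sum()
            table[1, 1] += (~g2 & ~south).sum()
        odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
        assert 0.8 < odds < 1.25

    def test_haplogroup_is_property_of_haplotype(self, default_params):
        meta = simulate_host_metadata(default_params, seed=8, n_individuals=366)
        per_hap = meta.df.groupby("mtdna_haplotype")["mtdna_haplogroup"].nunique()
        assert (per_hap == 1).all()
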