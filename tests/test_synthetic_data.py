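"""The generator must plant exactly what the downstream stages are meant to
recover, deterministically under a fixed seed."""

import numpy as np
import pytest

from vmte.cpg_metrics import cpg_score
from vmte.genomics_io import read_fasta
from vmte.repeat_sequences import element_sequence
from vmte.signal_projection import mean_signal_per_element
from vmte.synthetic_data import (
    SimulationConfig,
    simulate,
    simulate_binding_coverage,
    simulate_methylation,
    simulate_peaks,
    simulate_repeat_genome,
    stage_rng,
)


@pytest.fixture(scope="module")
def small_config():
    return SimulationConfig(
        seed=7, n_clades=3, instances_per_clade=12, proviruses_per_clade=2,
        n_individuals=4, n_novel_loci=3, escape_clade=3, n_background_peaks=10,
        n_extra_subfamilies=4, n_responsive=2, n_background_genes=10,
    )


@pytest.fixture(scope="module")
def small_truth(small_config):
    _, _, truth = simulate_repeat_genome(small_config)
    return truth


class TestConfigValidation:
    def test_probabilities_and_counts_checked(self):
        with pytest.raises(ValueError):
            SimulationConfig(within_clade_divergence=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(n_clades=0)
        with pytest.raises(ValueError):
            SimulationConfig(escape_clade=9)
        with pytest.raises(ValueError):
            SimulationConfig(proviruses_per_clade=40, instances_per_clade=50)

    def test_binding_profile_bounds_checked(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                binding_factors={"K": (0, 400, (1.0, 1.0, 1.0, 1.0))}
            )

    def test_slot_too_small_rejected(self):
        with pytest.raises(ValueError):
            simulate_repeat_genome(SimulationConfig(slot_size=2_000))


class TestRepeatGenome:
    def test_counts_and_labels(self, small_config, small_truth):
        cfg = small_config
        ltrs = small_truth.ltr_instances(cfg)
        assert len(ltrs) == cfg.n_clades * cfg.instances_per_clade
        labels = {small_truth.clade[i.instance_id] for i in ltrs}
        assert labels == set(cfg.clade_labels)
        ints = [i for i in small_truth.instances if i.subfamily == cfg.int_subfamily]
        assert len(ints) == cfg.n_clades * cfg.proviruses_per_clade

    def test_every_instance_has_one_truth_sequence(self, small_truth):
        ids = [i.instance_id for i in small_truth.instances]
        assert len(ids) == len(set(ids))
        assert set(ids) == set(small_truth.element_sequences)

    def test_minus_strand_is_reverse_complemented_into_genome(self, small_truth):
        minus = [i for i in small_truth.instances if i.interval.strand == "-"]
        assert minus, "expected some minus-strand placements"
        for inst in minus:
            assert (
                element_sequence(small_truth.genome, inst.interval)
                == small_truth.element_sequences[inst.instance_id]
            )

    def test_both_strands_used(self, small_truth):
        strands = {i.interval.strand for i in small_truth.instances}
        assert strands == {"+", "-"}

    def test_instances_do_not_overlap(self, small_truth):
        by_chrom = {}
        for i in small_truth.instances:
            by_chrom.setdefault(i.interval.chrom, []).append(i.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda v: v.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_determinism(self, small_config, tmp_path):
        d1 = simulate(small_config)
        d2 = simulate(small_config)
        p1, p2 = tmp_path / "a", tmp_path / "b"
        d1.write(p1)
        d2.write(p2)
        assert (p1 / "genome.fa").read_bytes() == (p2 / "genome.fa").read_bytes()
        assert (p1 / "repeats.out").read_bytes() == (p2 / "repeats.out").read_bytes()
        assert (p1 / "methylation.tsv").read_bytes() == (p2 / "methylation.tsv").read_bytes()
        assert (p1 / "truth.json").read_bytes() == (p2 / "truth.json").read_bytes()

    def test_consensus_cpg_enriched_background_depleted(self, small_truth):
        assert cpg_score(small_truth.consensus).score > 1.0
        assert cpg_score(small_truth.genome["chr1"][:100_000]).score < 0.5


class TestBinding:
    def test_noise_free_profile_is_exact(self, small_config, small_truth):
        cfg = SimulationConfig(
            **{**small_config.__dict__, "binding_noise": False,
               "binding_factors": {"K": (50, 150, (4.0, 3.0, 1.0))}}
        )
        tracks = simulate_binding_coverage(small_truth, cfg)
        track = tracks["K"]
        inst = small_truth.ltr_instances(cfg)[0]
        h = {"clade1": 4.0, "clade2": 3.0, "clade3": 1.0}[
            small_truth.clade[inst.instance_id]
        ]
        iv = inst.interval
        if iv.strand == "-":
            window = track.values[iv.chrom][iv.end - 150 : iv.end - 50]
        else:
            window = track.values[iv.chrom][iv.start + 50 : iv.start + 150]
        assert (window == h).all()

    def test_escape_clade_lowest_mean_signal(self, sim_dataset, sim_config):
        truth = sim_dataset.truth
        track = sim_dataset.binding["KAP1"]
        means = {}
        for label in sim_config.clade_labels:
            vals = [
                mean_signal_per_element(track, i)
                for i in truth.ltr_instances(sim_config)
                if truth.clade[i.instance_id] == label
            ]
            means[label] = np.mean(vals)
        assert min(means, key=means.get) == sim_config.escape_label

    def test_fixed_seed_identical_tracks(self, small_config, small_truth):
        t1 = simulate_binding_coverage(small_truth, small_config)
        t2 = simulate_binding_coverage(small_truth, small_config)
        for f in t1:
            for c in t1[f].values:
                assert np.array_equal(t1[f].values[c], t2[f].values[c])


class TestMethylation:
    def test_variable_elements_vary_more_across_individuals(
        self, sim_dataset, sim_config
    ):
        truth = sim_dataset.truth
        df = _element_individual_means(
            sim_dataset.methylation, truth.ltr_instances(sim_config)
        )
        sds = df.groupby("instance")["level"].std()
        vm_sd = np.mean(
            [sds[i] for i in sds.index if truth.vm_status[i] == "variable"]
        )
        sil_sd = np.mean(
            [sds[i] for i in sds.index if truth.vm_status[i] == "silenced"]
        )
        assert vm_sd > sil_sd

    def test_silenced_elements_stay_methylated(self, sim_dataset, sim_config):
        truth = sim_dataset.truth
        df = _element_individual_means(
            sim_dataset.methylation, truth.ltr_instances(sim_config)
        )
        silenced = df[
            df["instance"].map(lambda i: truth.vm_status[i] == "silenced")
        ]
        assert (silenced["level"] >= 0.7).all()

    def test_fixed_seed_identical_calls(self, small_config, small_truth):
        a = simulate_methylation(small_truth, small_config)
        b = simulate_methylation(small_truth, small_config)
        assert a == b


def _element_individual_means(calls, instances):
    """Per (element, individual) mean methylated fraction, mapping each CpG
    to its (non-overlapping) containing element."""
    import pandas as pd

    insts = sorted(instances, key=lambda i: i.interval.start)
    starts = np.array([i.interval.start for i in insts])
    ends = np.array([i.interval.end for i in insts])
    ids = np.array([i.instance_id for i in insts])
    rows = []
    for c in calls:
        j = int(np.searchsorted(starts, c.position, side="right")) - 1
        if j >= 0 and c.position < ends[j]:
            rows.append(
                {"instance": ids[j], "sample": c.sample_id,
                 "frac": c.methylated_reads / c.total_reads}
            )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["instance", "sample"])["frac"].mean().rename("level").reset_index()
    )


class TestContextAndStrains:
    def test_constitutive_gene_within_50kb_of_planted_class(
        self, sim_dataset, sim_config
    ):
        truth = sim_dataset.truth
        const = sim_dataset.expression.fpkm.min(axis=1) > 2.0
        const_ivs = [
            g.interval for g, ok in zip(sim_dataset.expression.genes, const) if ok
        ]
        for inst in truth.ltr_instances(sim_config):
            if truth.context_class[inst.instance_id] != "constitutive_proximal":
                continue
            gaps = [
                max(max(inst.interval.start, g.start) - min(inst.interval.end, g.end), 0)
                for g in const_ivs
                if g.chrom == inst.interval.chrom
            ]
            assert min(gaps) <= 50_000

    def test_deletions_fully_cover_their_instances(self, sim_dataset):
        truth = sim_dataset.truth
        by_id = {i.instance_id: i for i in truth.instances}
        for iid, strains in truth.deleted_strains.items():
            inst = by_id[iid]
            for s in strains:
                assert any(
                    d.start <= inst.interval.start and d.end >= inst.interval.end
                    for d in sim_dataset.deletions[s]
                    if d.chrom == inst.interval.chrom
                )

    def test_strain_tree_covers_all_strains(self, sim_dataset, sim_config):
        assert len(sim_dataset.strain_tree.strains) == sim_config.n_strains


class TestPeaks:
    def test_planted_novel_counts_and_support(self, sim_dataset, sim_config):
        truth = sim_dataset.truth
        assert len(truth.novel_locus_ids) == sim_config.n_novel_loci
        by_id = {i.instance_id: i for i in truth.instances}
        for iid in truth.novel_locus_ids:
            iv = by_id[iid].interval
            mut_hits = sum(
                any(p.interval.overlaps(iv) for p in peaks)
                for peaks in sim_dataset.peak_sets["mut"].values()
            )
            wt_hits = sum(
                any(p.interval.overlaps(iv) for p in peaks)
                for peaks in sim_dataset.peak_sets["wt"].values()
            )
            assert mut_hits >= 2
            assert wt_hits == 0

    def test_mutant_coverage_ratio_at_planted_loci(self, sim_dataset):
        truth = sim_dataset.truth
        by_id = {i.instance_id: i for i in truth.instances}
        mut = sim_dataset.peak_tracks["mut"]
        wt = sim_dataset.peak_tracks["wt"]
        for iid in truth.novel_locus_ids:
            iv = by_id[iid].interval
            m = float(np.mean(mut.values[iv.chrom][iv.start : iv.end]))
            w = float(np.mean(wt.values[iv.chrom][iv.start : iv.end]))
            assert (m + 0.5) / (w + 0.5) >= 3.0

    def test_too_few_escaped_copies_rejected(self, small_config, small_truth):
        cfg = SimulationConfig(**{**small_config.__dict__, "n_novel_loci": 1000})
        with pytest.raises(ValueError, match="escaped"):
            simulate_peaks(small_truth, cfg)


def test_stage_rngs_are_independent_substreams():
    a = stage_rng(11, "genome").integers(0, 2**31)
    b = stage_rng(11, "binding").integers(0, 2**31)
    assert a != b
    assert a == stage_rng(11, "genome").integers(0, 2**31)


def test_written_fasta_round_trips(small_config, tmp_path):
    ds = simulate(small_config)
    ds.write(tmp_path)
    genome = read_fasta(tmp_path / "genome.fa")
    assert genome == ds.truth.genome
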