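"""The synthetic-data generator: determinism, planted structure, noise model."""

import numpy as np
import pytest

from somgrn.motifs import expand_iupac, reverse_complement
from somgrn.synthetic import (
    SyntheticConfig,
    generate_bundle,
    generate_expression_matrix,
    generate_genome,
    generate_planted_grn,
    knockout_variant,
)

SMALL = dict(
    n_chromosomes=1,
    chromosome_length=2_000_000,
    n_genes=30,
    n_tfs=2,
    targets_per_tf=5,
    n_distractor_regions=20,
)


class TestGenerateGenome:
    def test_seed_determinism(self):
        cfg = SyntheticConfig(seed=1, **SMALL)
        g1, genes1 = generate_genome(cfg)
        g2, genes2 = generate_genome(cfg)
        assert g1 == g2
        assert genes1 == genes2

    def test_bounds_and_non_overlap(self):
        cfg = SyntheticConfig(seed=0, n_chromosomes=1, chromosome_length=10_000,
                              n_genes=2, n_tfs=1, targets_per_tf=1, gene_length=1_000)
        genome, genes = generate_genome(cfg)
        assert len(genes) == 2
        for g in genes:
            assert 0 <= g.tss < 10_000
        assert len(genome["chr1"]) == 10_000

    def test_nucleotide_frequencies_uniform(self):
        cfg = SyntheticConfig(seed=3, n_chromosomes=1, chromosome_length=100_000,
                              n_genes=5)
        genome, _ = generate_genome(cfg)
        seq = genome["chr1"]
        n = len(seq)
        se = np.sqrt(0.25 * 0.75 / n)
        for b in "ACGT":
            assert abs(seq.count(b) / n - 0.25) < 3 * se

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(SyntheticConfig(chromosome_length=5_000, n_genes=150))

    def test_impossible_placement_names_constraint(self):
        cfg = SyntheticConfig(n_chromosomes=1, chromosome_length=10_000,
                              n_genes=20, n_tfs=1, targets_per_tf=1, gene_length=2_000)
        with pytest.raises(ValueError, match="overlap"):
            generate_genome(cfg)


class TestPlantedGrn:
    def test_cardinality_and_distinct_crms(self):
        cfg = SyntheticConfig(seed=2, **SMALL)
        _, genes = generate_genome(cfg)
        grn = generate_planted_grn(cfg, genes)
        assert len(grn.edges) == 10
        assert len({(e.crm.chrom, e.crm.start) for e in grn.edges}) == 10
        assert len(grn.tf_consensus) == 2

    def test_crm_within_1mb_of_target_tss(self):
        cfg = SyntheticConfig(seed=2, **SMALL)
        _, genes = generate_genome(cfg)
        tss = {g.gene_id: g.tss for g in genes}
        grn = generate_planted_grn(cfg, genes)
        for e in grn.edges:
            assert abs(e.crm.midpoint - tss[e.target]) <= 1_000_000

    def test_oversized_request_rejected(self):
        cfg = SyntheticConfig(seed=2, **{**SMALL, "targets_per_tf": 50})
        _, genes = generate_genome(cfg)
        with pytest.raises(ValueError, match="genes"):
            generate_planted_grn(cfg, genes)

    def test_knockout_substitution_rules(self):
        assert knockout_variant("AATMHACA") == "AAGMHAAA"
        assert knockout_variant("ACAAWRG") == "ATAGWRG"

    def test_foxh1_consensus_expansion(self):
        words = expand_iupac("AATMHACA")
        assert len(words) == 6
        for w in words:
            assert w[0] == "A" and w[1] == "A" and w[2] == "T"
            assert w[3] in "AC" and w[4] in "ACT"
            assert w[5] == "A" and w[6] == "C" and w[7] == "A"


class TestPlantedSites:
    def test_all_sites_match_pattern_and_string_rescan(self, small_bundle):
        b = small_bundle
        crm_sites = b.planted_sites[b.planted_sites["kind"] == "crm"]
        assert len(crm_sites) > 0
        for row in crm_sites.itertuples():
            pattern = b.grn.tf_consensus[row.tf]
            w = len(pattern)
            written = b.genome[row.chrom][row.start : row.start + w]
            word = written if row.strand == "+" else reverse_complement(written)
            # exact string-search oracle recovers the planted word
            assert word in expand_iupac(pattern)
            assert word == row.word

    def test_decoys_carry_variant_and_no_original_match(self, small_bundle):
        b = small_bundle
        decoys = [r for r in b.regions if r.kind == "decoy"]
        assert decoys
        for dec in decoys:
            seq = b.region_sequence(dec.interval)
            pattern = b.grn.tf_consensus[dec.tf]
            variant_words = set(expand_iupac(knockout_variant(pattern)))
            original = set(expand_iupac(pattern))
            original |= {reverse_complement(w) for w in original}
            found_variant = any(
                seq[i : i + len(pattern)] in variant_words
                or reverse_complement(seq[i : i + len(pattern)]) in variant_words
                for i in range(len(seq) - len(pattern) + 1)
            )
            assert found_variant
            for i in range(len(seq) - len(pattern) + 1):
                assert seq[i : i + len(pattern)] not in original

    def test_every_edge_has_site_and_covered_crm(self, small_bundle):
        b = small_bundle
        site_tfs = set(zip(b.planted_sites["tf"], b.planted_sites["chrom"]))
        for i, e in enumerate(b.grn.edges):
            in_crm = b.planted_sites[
                (b.planted_sites["tf"] == e.tf)
                & (b.planted_sites["start"] >= e.crm.start)
                & (b.planted_sites["start"] < e.crm.end)
            ]
            assert len(in_crm) >= 1
            covered = any(
                p.chrom == e.crm.chrom and p.start < e.crm.end and e.crm.start < p.end
                for peaks in b.peak_sets.values()
                for p in peaks
            )
            assert covered


class TestExpressionMatrix:
    def test_zero_noise_exact_means(self):
        cfg = SyntheticConfig(seed=4, noise_sd=0.0, **SMALL)
        genome, genes = generate_genome(cfg)
        grn = generate_planted_grn(cfg, genes)
        m1, _ = generate_expression_matrix(cfg, grn, genes)
        m2, _ = generate_expression_matrix(cfg, grn, genes)
        assert np.array_equal(m1.to_numpy(), m2.to_numpy())
        # control and MO columns agree exactly for non-targets at zero noise
        tf = grn.tf_ids[0]
        targets = {e.target for e in grn.edges if e.tf == tf}
        non_targets = [g for g in m1.index if g not in targets]
        assert np.allclose(
            m1.loc[non_targets, f"{tf}_MO_rep1"], m1.loc[non_targets, f"{tf}_ctrl_rep1"]
        )

    def test_knockdown_ratio_recovered(self):
        cfg = SyntheticConfig(seed=5, n_chromosomes=1, chromosome_length=8_000_000,
                              n_genes=230, n_tfs=1, targets_per_tf=200,
                              n_distractor_regions=0)
        _, genes = generate_genome(cfg)
        grn = generate_planted_grn(cfg, genes)
        mat, _ = generate_expression_matrix(cfg, grn, genes)
        tf = grn.tf_ids[0]
        targets = sorted({e.target for e in grn.edges})
        ratio = (mat.loc[targets, f"{tf}_MO_rep1"] / mat.loc[targets, f"{tf}_ctrl_rep1"])
        # log-normal noise: E[log2 ratio] = log2(0.25), SE = sqrt(2)*sd/sqrt(n)
        se = np.sqrt(2) * cfg.noise_sd / np.sqrt(len(targets))
        assert abs(np.log2(ratio).mean() - np.log2(0.25)) < 2 * se

        non_targets = [g for g in mat.index if g not in set(targets) | {tf}]
        r0 = np.log2(mat.loc[non_targets, f"{tf}_MO_rep1"] / mat.loc[non_targets, f"{tf}_ctrl_rep1"])
        se0 = np.sqrt(2) * cfg.noise_sd / np.sqrt(len(non_targets))
        assert abs(r0.mean()) < 2.5 * se0

    def test_unknown_perturbed_tf_rejected(self):
        cfg = SyntheticConfig(seed=4, perturbations=[("not_a_gene", "9")], **SMALL)
        _, genes = generate_genome(cfg)
        grn = generate_planted_grn(cfg, genes)
        with pytest.raises(ValueError, match="unknown TF"):
            generate_expression_matrix(cfg, grn, genes)

    def test_module_separation_recoverable(self):
        # at noise_sd 0.25 and >=50 genes/module, module means separate by >4 SE
        cfg = SyntheticConfig(seed=6, n_chromosomes=1, chromosome_length=8_000_000,
                              n_genes=160, n_tfs=2, targets_per_tf=55,
                              n_expression_modules=3, noise_sd=0.25,
                              n_distractor_regions=0)
        _, genes = generate_genome(cfg)
        grn = generate_planted_grn(cfg, genes)
        mat, _ = generate_expression_matrix(cfg, grn, genes)
        log = np.log2(mat.filter(like="wt_") + 1)
        mods = {}
        for gid in mat.index:
            mods.setdefault(grn.target_module.get(gid, -1), []).append(gid)
        profiles = {}
        for m, gids in mods.items():
            if len(gids) >= 50:
                sub = log.loc[gids]
                profiles[m] = (sub.mean(axis=0), sub.std(axis=0) / np.sqrt(len(gids)))
        keys = list(profiles)
        assert len(keys) >= 2
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                mu_a, se_a = profiles[keys[i]]
                mu_b, se_b = profiles[keys[j]]
                sep = np.abs(mu_a - mu_b) / np.sqrt(se_a**2 + se_b**2)
                assert sep.max() > 4


class TestChromatinData:
    def test_same_seed_identical_peaks(self):
        cfg = SyntheticConfig(seed=8, **SMALL)
        b1 = generate_bundle(cfg)
        b2 = generate_bundle(cfg)
        for exp in b1.peak_sets:
            assert b1.peak_sets[exp] == b2.peak_sets[exp]
        assert b1.genome == b2.genome

    def test_ep300_separation_active_vs_heterochromatin(self, small_bundle):
        from somgrn.partition import partition_genome, quantify_rpkm

        b = small_bundle
        ps = partition_genome(list(b.peak_sets.values()), min_size=200,
                              chrom_lengths=b.chrom_lengths)
        sig = quantify_rpkm(b.reads, ps, b.total_mapped)
        # locate partitions by truth kind
        active, hetero = [], []
        for pid, iv in enumerate(ps):
            for r in b.regions:
                if r.interval.overlaps(iv):
                    if r.kind in ("crm", "decoy"):
                        active.append(pid)
                    elif r.state == "heterochromatin":
                        hetero.append(pid)
                    break
        a = sig.loc[active, "Ep300_stage9"]
        h = sig.loc[hetero, "Ep300_stage9"]
        # planted 10x separation: active mean well above heterochromatin mean
        assert a.mean() > 2 * h.mean()
        sep = (a.mean() - 10 * h.mean()) / np.sqrt(a.var() / len(a) + 100 * h.var() / len(h))
        assert abs(sep) < 4  # consistent with the planted ratio

    def test_zero_signature_emits_nothing(self):
        from somgrn.synthetic import ChromatinState, generate_chromatin_data, make_regions

        cfg = SyntheticConfig(seed=9, **SMALL)
        genome, genes = generate_genome(cfg)
        grn = generate_planted_grn(cfg, genes)
        rng = np.random.default_rng(0)
        regions = make_regions(cfg, grn, genes, rng)
        states = [ChromatinState(name=s, signature={}) for s in
                  {r.state for r in regions}]
        peaks, reads, _ = generate_chromatin_data(cfg, regions, states, rng)
        assert all(len(v) == 0 for v in peaks.values())
        assert all(len(v) == 0 for v in reads.values())

    def test_unknown_state_rejected(self):
        from somgrn.synthetic import generate_chromatin_data, make_regions

        cfg = SyntheticConfig(seed=9, **SMALL)
        genome, genes = generate_genome(cfg)
        grn = generate_planted_grn(cfg, genes)
        rng = np.random.default_rng(0)
        regions = make_regions(cfg, grn, genes, rng)
        with pytest.raises(ValueError, match="state"):
            generate_chromatin_data(cfg, regions, [], rng)


def test_bundle_determinism_and_bounds():
    cfg = SyntheticConfig(seed=10, **SMALL)
    b1 = generate_bundle(cfg)
    b2 = generate_bundle(cfg)
    assert b1.expression.equals(b2.expression)
    assert b1.planted_sites.equals(b2.planted_sites)
    assert (b1.expression.to_numpy() >= 0).all()
    L = cfg.chromosome_length
    for r in b1.regions:
        assert 0 <= r.interval.start < r.interval.end <= L


def test_bundle_writer_round_trip(tmp_path):
    from somgrn.synthetic import write_bundle

    cfg = SyntheticConfig(seed=11, n_chromosomes=1, chromosome_length=100_000,
                          n_genes=4, n_tfs=1, targets_per_tf=2,
                          crm_max_dist=8_000, n_distractor_regions=4)
    b = generate_bundle(cfg)
    write_bundle(b, tmp_path)
    from Bio import SeqIO

    recs = list(SeqIO.parse(tmp_path / "genome.fa", "fasta"))
    assert str(recs[0].seq) == b.genome["chr1"]
    assert (tmp_path / "grn_truth.json").exists()
    assert (tmp_path / "expression.tsv").exists()
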