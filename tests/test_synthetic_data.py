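import numpy as np
import pytest

from codonsel.codon_core import CodonCounts, identify_major_codons
from codonsel.bias_measures import fop
from codonsel.sfs_selection import SelectionParams, expected_sfs
from codonsel.synthetic_data import (
    PREFERRED_PAIR,
    SimConfig,
    simulate_alignment,
    simulate_annotations,
    simulate_sfs,
    split_by_arrangement,
    write_dataset,
)


class TestSimulateSFS:
    def test_seed_determinism(self):
        params = SelectionParams(0.01, 0.02, 0.5)
        a = simulate_sfs(params, 10, 5000, seed=3)
        b = simulate_sfs(params, 10, 5000, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_expected_mode(self):
        params = SelectionParams(0.01, 0.02, 0.5)
        e = simulate_sfs(params, 10, 1000, mode="expected")
        np.testing.assert_allclose(e, expected_sfs(params, 10) * 1000)

    def test_neutral_symmetric_spectrum(self):
        params = SelectionParams(0.01, 0.01, 0.0)
        c = simulate_sfs(params, 12, 10**6, seed=9)
        # symmetric classes agree within 3 binomial standard deviations
        for i in range(6):
            j = 12 - i
            sd = np.sqrt(c[i] + c[j] + 1)
            assert abs(c[i] - c[j]) < 3.5 * sd

    def test_law_of_large_numbers(self):
        params = SelectionParams(0.008, 0.018, 1.1)
        p = expected_sfs(params, 15)
        c = simulate_sfs(params, 15, 10**6, seed=4)
        tvd = 0.5 * np.abs(c / c.sum() - p).sum()
        assert tvd < 0.005

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_sfs(SelectionParams(0.01, 0.01), 10, 0, seed=1)


class TestSimulateAlignment:
    def test_preferred_pairs_are_one_step_gc_vs_at(self):
        for aa, (pref, unpref) in PREFERRED_PAIR.items():
            assert sum(a != b for a, b in zip(pref, unpref)) == 1
            assert pref[2] in "GC" or aa not in PREFERRED_PAIR

    def test_structure_and_determinism(self):
        cfg = SimConfig(n_genes=3, codons_per_gene=50, seed=8)
        a1 = simulate_alignment(cfg)
        a2 = simulate_alignment(SimConfig(n_genes=3, codons_per_gene=50, seed=8))
        assert len(a1) == 3
        assert a1[0].n == 47
        assert a1[0].length == 150
        assert a1[0].outgroup is not None
        assert [x.sequences for x in a1] == [x.sequences for x in a2]
        assert a1[0].sequences != simulate_alignment(
            SimConfig(n_genes=3, codons_per_gene=50, seed=9)
        )[0].sequences

    def test_strong_selection_gives_high_fop(self, majors_study):
        cfg = SimConfig(
            n_genes=4, codons_per_gene=300, seed=5,
            params=SelectionParams(0.005, 0.011, 8.0, 1.0, 0.0),
            background_codon_noise=0.0, theta_nonsyn_factor=0.0,
        )
        alns = simulate_alignment(cfg)
        pooled = CodonCounts("p")
        for a in alns:
            pooled = pooled + CodonCounts.from_sequence(a.sequences[0], a.gene_id)
        majors = identify_major_codons(pooled)
        assert fop(pooled, majors) > 0.9

    def test_gc_favouring_selection_yields_gc_ending_majors(self):
        cfg = SimConfig(
            n_genes=10, codons_per_gene=400, seed=13,
            params=SelectionParams(0.005, 0.011, 1.5, 1.0, 0.0),
        )
        alns = simulate_alignment(cfg)
        pooled = CodonCounts("p")
        for a in alns:
            pooled = pooled + CodonCounts.from_sequence(a.sequences[0], a.gene_id)
        table = identify_major_codons(pooled)
        majors = [r for r in table.rows if r.is_major]
        gc_ending = sum(1 for r in majors if r.codon[2] in "GC")
        assert gc_ending / len(majors) >= 0.9

    def test_neutral_unbiased_gc3_near_half(self):
        from codonsel.codon_core import nucleotide_composition

        cfg = SimConfig(
            n_genes=10, codons_per_gene=500, seed=17,
            params=SelectionParams(0.01, 0.01, 0.0, 1.0, 0.0),
            background_codon_noise=0.0, theta_nonsyn_factor=0.0,
        )
        alns = simulate_alignment(cfg)
        rec = nucleotide_composition([a.sequences[0] for a in alns], frame_aware=True)
        assert rec.gc3 == pytest.approx(0.5, abs=0.03)

    def test_split_by_arrangement(self):
        cfg = SimConfig(n_genes=1, codons_per_gene=30, seed=2)
        aln = simulate_alignment(cfg)[0]
        subs = split_by_arrangement(aln)
        assert set(subs) == {"AR", "ST", "PP", "TL", "CH"}
        assert subs["AR"].n == 15
        assert sum(s.n for s in subs.values()) == 47


class TestAnnotations:
    def test_sorted_nonoverlapping_and_regions(self):
        cfg = SimConfig(n_genes=50, codons_per_gene=200, seed=6)
        ann = simulate_annotations(cfg)
        assert (ann.start.diff().dropna() > 0).all()
        assert (ann.end.iloc[:-1].to_numpy() <= ann.start.iloc[1:].to_numpy()).all()
        first, last = cfg.breakpoints
        mids = (ann.start + ann.end) // 2
        exp = np.where(mids < first, "proximal",
                       np.where(mids <= last, "inverted", "distal"))
        assert (ann.region == exp).all()
        assert (ann.rho > 0).all()

    def test_determinism(self):
        cfg = SimConfig(n_genes=20, seed=4)
        a = simulate_annotations(cfg)
        b = simulate_annotations(cfg)
        assert a.equals(b)


class TestWriteDataset:
    def test_files_written_and_byte_identical(self, tmp_path):
        cfg = SimConfig(n_genes=2, codons_per_gene=40, seed=12)
        d1 = write_dataset(cfg, tmp_path / "a")
        d2 = write_dataset(cfg, tmp_path / "b")
        f1 = sorted((d1 / "alignments").glob("*.fasta"))
        f2 = sorted((d2 / "alignments").glob("*.fasta"))
        assert len(f1) == 2
        for p1, p2 in zip(f1, f2):
            assert p1.read_bytes() == p2.read_bytes()
        assert (d1 / "rho.tsv").exists()
        assert (d1 / "genes.gff3").exists()
        assert (d1 / "manifest.json").exists()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=0, seed=1)
        with pytest.raises(ValueError):
            SimConfig(outgroup_divergence=0.5, seed=1)
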