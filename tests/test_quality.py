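"""Quality metrics: contiguity, internal consistency, accuracy, dataset stats."""

import numpy as np
import pytest

from omsweep import (
    AlignParams,
    ErrorProfile,
    MapContig,
    MoleculeSet,
    RunStats,
    ScoreNull,
    accuracy,
    align_pair,
    all_pairs_overlaps,
    assemble_olc,
    confidence,
    contiguity,
    dataset_stats,
    filter_molecules,
    internal_consistency,
    load_packaged_run_stats,
    pvalue_from_confidence,
    quality_report,
    simulate_molecules,
    sort_molecules,
    split_molecules,
)
from conftest import make_contig

PARAMS = AlignParams(1.5, 0.15, 40.0, 1.11e-4)


def _contig(cid, length):
    return MapContig(cid, float(length), (length / 2.0,), (1,), (1,))


def _oracle_n50(lengths):
    ls = sorted(lengths, reverse=True)
    total = sum(ls)
    acc = 0.0
    for x in ls:
        acc += x
        if acc >= total / 2:
            return x
    return 0.0


class TestContiguity:
    def test_single_contig(self):
        assert contiguity([_contig(1, 100)]) == (100.0, 100.0, 100.0)

    def test_descending_cumulative_convention(self):
        contigs = [_contig(i + 1, l) for i, l in enumerate((5, 4, 3, 2, 1))]
        total, n50, longest = contiguity(contigs)
        assert (total, n50, longest) == (15.0, 4.0, 5.0)
        assert n50 == _oracle_n50((5, 4, 3, 2, 1))

    def test_empty(self):
        assert contiguity([]) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_invariant_chain_and_oracle(self, seed):
        rng = np.random.default_rng(seed)
        contigs = [make_contig(rng, i + 1) for i in range(rng.integers(1, 12))]
        total, n50, longest = contiguity(contigs)
        assert n50 <= longest <= total
        assert n50 == _oracle_n50([c.length_bp for c in contigs])


class TestInternalConsistency:
    def _asm(self, contigs, placements, singletons):
        from omsweep.assemble import AssemblyResult, Placement

        return AssemblyResult(
            contigs,
            {m: Placement(c, 0.0, "+") for m, c in placements.items()},
            set(singletons),
        )

    def test_two_molecule_contig_depth(self):
        from omsweep import Molecule

        contig = MapContig(1, 10_000.0, (2_000.0, 5_000.0), (2, 2), (2, 2))
        ms = MoleculeSet([Molecule(1, 10_000.0, (2_000.0,)),
                          Molecule(2, 10_000.0, (5_000.0,))])
        asm = self._asm([contig], {1: 1, 2: 1}, [])
        depth, prop = internal_consistency(asm, ms)
        assert depth == 2.0
        assert prop == 1.0

    def test_all_singletons(self):
        from omsweep import Molecule

        ms = MoleculeSet([Molecule(i + 1, 10_000.0, (500.0,)) for i in range(4)])
        asm = self._asm([], {}, ms.ids)
        depth, prop = internal_consistency(asm, ms)
        assert (depth, prop) == (0.0, 0.0)

    def test_depth_tracks_true_coverage(self, small_reference):
        """Mean label depth is bounded by the truth per-site molecule
        coverage of the placed molecules and grows with coverage."""

        def run(coverage, seed):
            ms, truth = simulate_molecules(
                small_reference, coverage_fold=coverage,
                err=ErrorProfile(1.5, 0.15, 40.0, 1.0, seed=seed),
            )
            null = ScoreNull.fit(ms, PARAMS, n_null=60)
            filt = sort_molecules(filter_molecules(ms, 100, 6))
            overlaps = all_pairs_overlaps(split_molecules(filt, 3), PARAMS, null)
            asm = assemble_olc(filt, overlaps)
            depth, _ = internal_consistency(asm, filt)
            ref_pos = np.asarray(small_reference.labels_bp)
            cov = np.zeros(ref_pos.size)
            for mid in asm.placements:
                _, s, e, _ = truth.origins[mid]
                cov += (ref_pos > s) & (ref_pos <= e)
            covered = cov[cov > 0]
            return depth, covered.mean() if covered.size else 0.0

        d_lo, cov_lo = run(8, seed=41)
        d_hi, cov_hi = run(20, seed=41)
        assert 0.0 < d_hi <= cov_hi  # cannot observe more molecules than span
        assert d_hi > d_lo  # deeper data -> deeper consensus labels


class TestAccuracy:
    def test_single_contig_aggregate_is_own_confidence(self, small_reference):
        ref = small_reference
        sub_labels = [p for p in ref.labels_bp if 200_000 < p <= 700_000]
        contig = MapContig(
            1, 500_000.0,
            tuple(round(p - 200_000.0, 1) for p in sub_labels),
            (2,) * len(sub_labels), (2,) * len(sub_labels),
        )
        conf, unaligned = accuracy([contig], ref, PARAMS, null_reps=60, seed=3)
        assert unaligned == 0
        al = align_pair(ref, contig, PARAMS, max_skip=5)
        from omsweep import alignment_pvalue

        expected = confidence(
            alignment_pvalue(al, ref, contig, PARAMS, null_reps=60, seed=3, max_skip=5)
        )
        assert conf == pytest.approx(expected)

    def test_true_fragment_beats_null(self, small_reference):
        """A contig that is literally a slice of the reference must align
        with significant (not chance-level) confidence."""
        ref = small_reference
        sub = [p for p in ref.labels_bp if 100_000 < p <= 800_000]
        contig = MapContig(1, 700_000.0, tuple(round(p - 100_000.0, 1) for p in sub),
                           (2,) * len(sub), (2,) * len(sub))
        conf, _ = accuracy([contig], ref, PARAMS, null_reps=100, seed=5)
        assert conf is not None
        assert conf > confidence(1.11e-4)  # beyond the loosest cutoff

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            accuracy([_contig(1, 1000)], [], PARAMS)


class TestDatasetStats:
    def test_packaged_table_aggregates(self):
        runs = load_packaged_run_stats()
        s = dataset_stats(runs, 900.0)
        assert len(runs) == 19
        assert round(s.total_gbp, 2) == 217.28
        assert round(s.weighted_mean_n50_kbp, 2) == 165.37
        assert round(s.weighted_mean_density, 1) == 9.2
        assert s.max_density == 11.3
        assert s.coverage_fold == 241

    def test_single_run_is_identity(self):
        runs = [RunStats("x", 1000.0, 150.0, 9.0)]
        s = dataset_stats(runs, 500.0)
        assert s.weighted_mean_n50_kbp == 150.0
        assert s.weighted_mean_density == 9.0
        assert s.total_gbp == 1.0
        assert s.coverage_fold == 2

    def test_equal_weights_average(self):
        runs = [RunStats("a", 500.0, 100.0, 8.0), RunStats("b", 500.0, 200.0, 10.0)]
        s = dataset_stats(runs, 100.0)
        assert s.weighted_mean_n50_kbp == 150.0
        assert s.weighted_mean_density == 9.0

    @pytest.mark.parametrize("seed", range(5))
    def test_weighted_means_bounded_by_inputs(self, seed):
        rng = np.random.default_rng(seed)
        runs = [
            RunStats(f"r{i}", float(rng.uniform(100, 5000)),
                     float(rng.uniform(100, 250)), float(rng.uniform(5, 13)))
            for i in range(rng.integers(2, 12))
        ]
        s = dataset_stats(runs, 900.0)
        n50s = [r.molecule_n50_kbp for r in runs]
        dens = [r.labels_per_100kbp for r in runs]
        assert min(n50s) <= s.weighted_mean_n50_kbp <= max(n50s)
        assert min(dens) <= s.weighted_mean_density <= max(dens)

    def test_empty_runs_rejected(self):
        with pytest.raises(ValueError):
            dataset_stats([], 900.0)


class TestConfidenceConversion:
    def test_published_confidence_p_pairs(self):
        """The printed p-values and confidences must agree through the
        -log10 definition at the precision of a confidence given to 0.1."""
        for conf_printed, p_printed in ((21.4, 3.9e-22), (27.8, 1.5e-28)):
            assert confidence(p_printed) == pytest.approx(conf_printed, abs=0.05)
            p_back = pvalue_from_confidence(conf_printed)
            assert abs(np.log10(p_back) - np.log10(p_printed)) <= 0.05


def test_quality_report_invariants(small_reference):
    ms, _ = simulate_molecules(
        small_reference, err=ErrorProfile(seed=55), n_molecules=50
    )
    null = ScoreNull.fit(ms, PARAMS, n_null=50)
    filt = sort_molecules(filter_molecules(ms, 100, 6))
    overlaps = all_pairs_overlaps(split_molecules(filt, 3), PARAMS, null)
    asm = assemble_olc(filt, overlaps)
    rep = quality_report(asm, filt)
    assert rep.n50_bp <= rep.longest_contig_bp <= rep.total_length_bp
    assert 0.0 <= rep.nonsingleton_proportion <= 1.0


def test_rank_correlation_reports_spearman():
    """Across a sweep, the N50-vs-confidence rank correlation is a number
    in [-1, 1] matching an independent Spearman computation."""
    import scipy.stats as st
    from omsweep import QualityReport, rank_correlation

    reports = [
        QualityReport(1_000_000.0, n50, n50, 5.0, 0.5, conf)
        for n50, conf in ((300_000.0, 25.0), (350_000.0, 22.0),
                          (400_000.0, 27.0), (250_000.0, 21.0))
    ]
    rho, pval = rank_correlation(reports)
    exp_rho, exp_p = st.spearmanr([r.n50_bp for r in reports],
                                  [r.weighted_mean_confidence for r in reports])
    assert rho == pytest.approx(float(exp_rho))
    assert -1.0 <= rho <= 1.0
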