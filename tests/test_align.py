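"""Pairwise alignment: DP vs exhaustive enumeration, symmetry, significance."""

import itertools
import math

import numpy as np
import pytest

from omsweep import (
    AlignParams,
    Molecule,
    ScoreNull,
    align_pair,
    alignment_pvalue,
    confidence,
    pvalue_from_confidence,
)
from omsweep.align import SD_MIN_BP, shuffle_gaps

_SQRT2PI = math.sqrt(2.0 * math.pi)


# ---------------------------------------------------------------------------
# independent oracle: enumerate every monotone matching and score it from
# the model definition written out longhand
# ---------------------------------------------------------------------------

def _oracle_constants(m, n, len_a, len_b, p):
    density = (m + n) / (len_a + len_b)
    w = 1.0 / density
    p_fp = min(0.9, max(1e-4, (p.fp_per_100kbp / 1e5) / density))
    q = min(0.99, max(1e-6, p_fp + (1.0 - p_fp) * p.fn_rate))
    mb = math.log((1.0 - p_fp) * max(1.0 - p.fn_rate, 1e-6))
    return mb, math.log(q), p.sizing_sd_bp_per_kbp / 1000.0, math.log(w)


def _score_matching(u, v, pairs, p, len_a, len_b):
    mb, skip, c, lnw = _oracle_constants(len(u), len(v), len_a, len_b, p)
    total = mb
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        da, db = u[i2] - u[i1], v[j2] - v[j1]
        k, l = i2 - i1, j2 - j1
        sd = max(SD_MIN_BP, c * math.sqrt(da * da / k + db * db / l))
        z = (db - da) / sd
        total += (
            mb
            - 0.5 * z * z
            - math.log(sd * _SQRT2PI)
            + lnw
            + (k - 1 + l - 1) * skip
        )
    return total


def _oracle_best(a: Molecule, b: Molecule, p: AlignParams) -> float | None:
    """Max score over all monotone matchings with >= 2 pairs, both
    orientations."""
    u = list(a.labels_bp)
    best = None
    for v in (list(b.labels_bp), [b.length_bp - x for x in reversed(b.labels_bp)]):
        for k in range(2, min(len(u), len(v)) + 1):
            for ia in itertools.combinations(range(len(u)), k):
                for jb in itertools.combinations(range(len(v)), k):
                    s = _score_matching(u, v, list(zip(ia, jb)), p, a.length_bp, b.length_bp)
                    if best is None or s > best:
                        best = s
    return best


def _random_molecule(rng, mol_id, n_labels):
    length = float(rng.uniform(40_000, 120_000))
    pos = np.sort(rng.uniform(500.0, length, size=n_labels))
    while np.any(np.diff(pos) < 1.0):
        pos = np.sort(rng.uniform(500.0, length, size=n_labels))
    return Molecule(mol_id, round(length, 1), tuple(round(float(x), 1) for x in pos))


PARAMS = AlignParams(1.5, 0.15, 40.0, 1.11e-4)


class TestDpAgainstBruteForce:
    @pytest.mark.parametrize("case", range(120))
    def test_dp_equals_exhaustive_enumeration(self, case):
        rng = np.random.default_rng(1000 + case)
        a = _random_molecule(rng, 1, int(rng.integers(2, 7)))
        b = _random_molecule(rng, 2, int(rng.integers(2, 7)))
        oracle = _oracle_best(a, b, PARAMS)
        al = align_pair(a, b, PARAMS, max_skip=6)
        assert al is not None
        assert al.score == pytest.approx(oracle, abs=1e-6)


class TestAlignmentStructure:
    def test_self_alignment_is_identity(self, noisy_sim):
        ms, _ = noisy_sim
        for mol in ms.molecules[:5]:
            if mol.n_labels < 2:
                continue
            al = align_pair(mol, mol, PARAMS)
            assert al.orientation == "forward"
            assert al.matched_pairs == tuple((i, i) for i in range(mol.n_labels))
            assert al.offset_bp == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, noisy_sim):
        ms, _ = noisy_sim
        mols = [m for m in ms.molecules if m.n_labels >= 3][:8]
        for a, b in itertools.combinations(mols, 2):
            r1, r2 = align_pair(a, b, PARAMS), align_pair(b, a, PARAMS)
            if r1 is None:
                assert r2 is None
                continue
            assert r1.score == pytest.approx(r2.score, abs=1e-6)

    def test_reversing_b_flips_orientation_not_score(self, noisy_sim):
        ms, _ = noisy_sim
        mols = [m for m in ms.molecules if m.n_labels >= 3]
        checked = 0
        for a, b in itertools.combinations(mols, 2):
            r = align_pair(a, b, PARAMS)
            if r is None:
                continue
            flipped = Molecule(
                b.molecule_id,
                b.length_bp,
                tuple(round(b.length_bp - x, 1) for x in reversed(b.labels_bp)),
            )
            rf = align_pair(a, flipped, PARAMS)
            assert rf is not None
            assert rf.score == pytest.approx(r.score, abs=1e-5)
            assert rf.orientation != r.orientation
            checked += 1
            if checked >= 10:
                break
        assert checked >= 5

    def test_score_decreases_with_interval_discrepancy(self):
        """Growing one matched interval's discrepancy strictly lowers the
        best score (within the model's sane discrepancy range)."""
        u = (10_000.0, 20_000.0, 30_000.0, 40_000.0)
        a = Molecule(1, 50_000.0, u)
        prev = None
        for delta in (0.0, 300.0, 600.0, 1_000.0):
            vb = (10_000.0, 20_000.0, 30_000.0 + delta, 40_000.0 + delta)
            b = Molecule(2, 50_000.0 + delta, vb)
            al = align_pair(a, b, PARAMS)
            assert al is not None
            if prev is not None:
                assert al.score < prev
            prev = al.score

    def test_too_few_labels_returns_none(self):
        a = Molecule(1, 10_000.0, (5_000.0,))
        b = Molecule(2, 10_000.0, (2_000.0, 6_000.0))
        assert align_pair(a, b, PARAMS) is None

    def test_nonfinite_positions_rejected(self):
        a = Molecule(1, 10_000.0, (2_000.0, 6_000.0))
        bad = Molecule.__new__(Molecule)
        object.__setattr__(bad, "molecule_id", 2)
        object.__setattr__(bad, "length_bp", 10_000.0)
        object.__setattr__(bad, "labels_bp", (2_000.0, float("nan")))
        object.__setattr__(bad, "channel", 1)
        object.__setattr__(bad, "source_run", None)
        with pytest.raises(ValueError):
            align_pair(a, bad, PARAMS)


class TestSignificance:
    def test_permutation_pvalue_floor(self, noisy_sim):
        """With +1 smoothing the p-value can never drop below 1/(reps+1)."""
        ms, _ = noisy_sim
        a = ms.molecules[0]
        al = align_pair(a, a, PARAMS)
        p = alignment_pvalue(al, a, a, PARAMS, null_reps=49, seed=3, method="permutation")
        assert p >= 1.0 / 50.0

    def test_pvalue_monotone_in_score(self, noisy_sim):
        """For one fixed null distribution the empirical tail is
        non-increasing in the observed score."""
        ms, _ = noisy_sim
        a, b = ms.molecules[0], ms.molecules[1]
        al = align_pair(a, b, PARAMS)
        if al is None:
            pytest.skip("no alignment for this pair")
        import dataclasses

        weaker = dataclasses.replace(al, score=al.score - 2.0)
        p_hi = alignment_pvalue(al, a, b, PARAMS, null_reps=99, seed=5)
        p_lo = alignment_pvalue(weaker, a, b, PARAMS, null_reps=99, seed=5)
        assert p_hi <= p_lo

    def test_unrelated_molecules_not_significant(self):
        """Independent molecules of similar density should fail the loosest
        published cutoff in >= 95% of trials."""
        rng = np.random.default_rng(0)
        n_sig = 0
        trials = 20
        for t in range(trials):
            a = _random_molecule(rng, 1, 14)
            b = _random_molecule(rng, 2, 14)
            al = align_pair(a, b, PARAMS)
            if al is None:
                continue
            p = alignment_pvalue(al, a, b, PARAMS, null_reps=99, seed=t)
            if p <= 1.11e-4:
                n_sig += 1
        assert n_sig <= max(1, int(0.05 * trials))

    def test_gumbel_tail_extends_below_resolution(self, noisy_sim):
        ms, _ = noisy_sim
        a = ms.molecules[0]
        al = align_pair(a, a, PARAMS)  # very strong observed score
        p = alignment_pvalue(al, a, a, PARAMS, null_reps=99, seed=1, method="gumbel")
        assert p < 1.0 / 100.0

    def test_score_null_deterministic(self, noisy_sim):
        ms, _ = noisy_sim
        n1 = ScoreNull.fit(ms, PARAMS, n_null=50)
        n2 = ScoreNull.fit(ms, PARAMS, n_null=50)
        assert (n1.loc, n1.scale, n1.frac_aligned) == (n2.loc, n2.scale, n2.frac_aligned)

    def test_shuffle_preserves_length_and_count(self, noisy_sim):
        ms, _ = noisy_sim
        rng = np.random.default_rng(0)
        mol = next(m for m in ms if m.n_labels >= 5)
        sh = shuffle_gaps(mol, rng)
        assert sh.length_bp == mol.length_bp
        assert abs(sh.n_labels - mol.n_labels) <= 1  # rounding collisions only


class TestConfidence:
    def test_identity_points(self):
        assert confidence(1.0) == 0.0
        assert pvalue_from_confidence(0.0) == 1.0

    def test_round_trip(self):
        for p in (0.5, 1e-3, 3.9e-22, 1.5e-28):
            assert pvalue_from_confidence(confidence(p)) == pytest.approx(p, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            confidence(0.0)
        with pytest.raises(ValueError):
            confidence(1.5)
        with pytest.raises(ValueError):
            pvalue_from_confidence(-1.0)
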