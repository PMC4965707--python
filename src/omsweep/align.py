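"""Pairwise overlap alignment of restriction maps under an explicit error model.

The score of an alignment is a log-likelihood ratio between the error
model (two maps sampled from a common genomic locus) and chance:

* a matched interval pair of lengths ``(da, db)`` spanning ``(k, l)``
  label steps contributes a Gaussian sizing term ``log N(db - da; 0, sd^2)``
  with ``sd = sizing_sd_bp_per_kbp x sqrt(da^2/k + db^2/l) / 1000`` — the
  discrepancy carries the per-gap noise of *both* maps — floored at
  ``sd_min``, minus a chance baseline in which the discrepancy is uniform
  over the pooled mean inter-label distance ``W``;
* every matched pair additionally pays ``log((1-p_fp)(1-fn))`` — the
  probability that both labels are real and neither site dropped out —
  where ``p_fp`` is the expected false-positive fraction of observed
  labels given the pooled label density;
* every label skipped inside the overlap contributes
  ``log(p_fp + (1-p_fp) fn)``: it is explained as a false positive on its
  own map or a dropout on the other.

Alignment is ends-free (overlap-style): labels outside the overlap window
cost nothing.  Both orientations are tried; only ``b`` is ever reversed
(reflected through its length).  Significance is assessed by a
permutation null — the inter-label gaps of ``b`` are shuffled and
realigned — optionally extended with a fitted Gumbel tail for p-values
below permutation resolution.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace
import numpy as np
import scipy.stats as st

from ._dp import overlap_dp
from .io_formats import MapContig, Molecule, MoleculeSet

DEFAULT_MAX_SKIP = 3
SD_MIN_BP = 50.0
_EPS_SCORE = 1e-9


@dataclass(frozen=True)
class AlignParams:
    """Error-model parameters for pairwise alignment.

    ``pvalue_threshold`` is the significance cutoff for accepting an
    overlap; ``fp_per_100kbp``, ``fn_rate`` and ``sizing_sd_bp_per_kbp``
    describe the assumed data error profile.
    """

    fp_per_100kbp: float = 1.5
    fn_rate: float = 0.15
    sizing_sd_bp_per_kbp: float = 40.0
    pvalue_threshold: float = 1.11e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.pvalue_threshold < 1.0:
            raise ValueError("pvalue_threshold must be in (0,1)")
        if not 0.0 <= self.fn_rate <= 1.0:
            raise ValueError("fn_rate must be in [0,1]")
        if self.fp_per_100kbp < 0:
            raise ValueError("fp_per_100kbp must be non-negative")
        if self.sizing_sd_bp_per_kbp <= 0:
            raise ValueError("sizing_sd_bp_per_kbp must be positive")


@dataclass(frozen=True)
class PairAlignment:
    """A scored, oriented overlap between two maps.

    ``matched_pairs`` are (index in a, index in b) with both coordinates
    strictly increasing; for ``orientation == "reverse"`` the b indices
    refer to the reversed label sequence (use :meth:`b_indices_original`
    to map back).  ``offset_bp`` is the position of b's start (in its
    reported orientation) in a's coordinate frame.
    """

    id_a: int
    id_b: int
    orientation: str  # "forward" | "reverse"
    offset_bp: float
    matched_pairs: tuple[tuple[int, int], ...]
    unmatched_a: int
    unmatched_b: int
    score: float
    pvalue: float = 1.0
    n_labels_b: int = 0

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)

    def b_indices_original(self) -> tuple[int, ...]:
        if self.orientation == "forward":
            return tuple(j for _, j in self.matched_pairs)
        n = self.n_labels_b
        return tuple(n - 1 - j for _, j in self.matched_pairs)

    def with_pvalue(self, pvalue: float) -> "PairAlignment":
        return replace(self, pvalue=pvalue)


def _labels(x: Molecule | MapContig) -> tuple[np.ndarray, float, int]:
    if isinstance(x, Molecule):
        return np.asarray(x.labels_bp, dtype=float), x.length_bp, x.molecule_id
    return np.asarray(x.labels_bp, dtype=float), x.length_bp, x.contig_id


def scoring_constants(
    m: int, n: int, len_a: float, len_b: float, p: AlignParams
) -> tuple[float, float, float, float]:
    """Derive (match_base, skip_cost, c_rel, ln_w) from the error model.

    The pooled label density of the two maps sets both the expected FP
    fraction of observed labels and the chance-model scale ``W`` (the mean
    inter-label distance).
    """
    density = (m + n) / (len_a + len_b)  # labels per bp
    w = 1.0 / density
    p_fp = min(0.9, max(1e-4, (p.fp_per_100kbp / 1e5) / density))
    q_skip = min(0.99, max(1e-6, p_fp + (1.0 - p_fp) * p.fn_rate))
    match_base = math.log((1.0 - p_fp) * max(1.0 - p.fn_rate, 1e-6))
    return match_base, math.log(q_skip), p.sizing_sd_bp_per_kbp / 1000.0, math.log(w)


def _best_cell(A, countA, u, v):
    """Best >= 2 matched-pair cell; ties by more pairs, then smaller
    |offset| of the implied placement, then smaller indices."""
    smax = float(A.max())
    if smax < -1e250:
        return None
    ties = np.argwhere(A >= smax - _EPS_SCORE)
    best = None
    for i, j in ties:
        key = (int(countA[i, j]), -abs(float(u[i] - v[j])), -int(i), -int(j))
        if best is None or key > best[0]:
            best = (key, int(i), int(j))
    _, i, j = best
    return float(A[i, j]), int(countA[i, j]), None, i, j


def _traceback(backA_i, backA_j, backB_i, backB_j, i, j):
    pairs = [(int(i), int(j))]
    i, j = int(backA_i[i, j]), int(backA_j[i, j])
    while i >= 0:
        pairs.append((int(i), int(j)))
        i, j = int(backB_i[i, j]), int(backB_j[i, j])
    pairs.reverse()
    return tuple(pairs)


def align_pair(
    a: Molecule | MapContig,
    b: Molecule | MapContig,
    p: AlignParams,
    max_skip: int = DEFAULT_MAX_SKIP,
) -> PairAlignment | None:
    """Best-scoring oriented overlap of ``b`` against ``a``, or ``None``.

    Returns ``None`` when no alignment with at least two matched pairs
    exists (e.g. either map has fewer than two labels).
    """
    u, len_a, id_a = _labels(a)
    v, len_b, id_b = _labels(b)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite label positions")
    if u.size < 2 or v.size < 2:
        return None
    match_base, skip_cost, c_rel, ln_w = scoring_constants(
        u.size, v.size, len_a, len_b, p
    )

    candidates = []
    for orientation in ("forward", "reverse"):
        vv = v if orientation == "forward" else (len_b - v)[::-1].copy()
        A, countA, bai, baj, bbi, bbj = overlap_dp(
            u, vv, match_base, skip_cost, c_rel, SD_MIN_BP, ln_w, max_skip
        )
        cell = _best_cell(A, countA, u, vv)
        if cell is None:
            continue
        score, npairs, _, i, j = cell
        pairs = _traceback(bai, baj, bbi, bbj, i, j)
        offsets = [u[pi] - vv[pj] for pi, pj in pairs]
        offset = float(np.mean(offsets))
        i0, j0 = pairs[0]
        unmatched_a = (pairs[-1][0] - i0 + 1) - len(pairs)
        unmatched_b = (pairs[-1][1] - j0 + 1) - len(pairs)
        candidates.append(
            PairAlignment(
                id_a=id_a,
                id_b=id_b,
                orientation=orientation,
                offset_bp=offset,
                matched_pairs=pairs,
                unmatched_a=int(unmatched_a),
                unmatched_b=int(unmatched_b),
                score=float(score),
                n_labels_b=int(v.size),
            )
        )
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0]
    f, r = candidates
    if f.score > r.score - _EPS_SCORE:
        # forward wins outright or by the tie-break chain
        if f.score >= r.score + _EPS_SCORE:
            return f
        key_f = (f.n_matched, -abs(f.offset_bp), 1)
        key_r = (r.n_matched, -abs(r.offset_bp), 0)
        return f if key_f >= key_r else r
    return r


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def shuffle_gaps(mol: Molecule, rng: np.random.Generator) -> Molecule:
    """Permute the inter-label gaps (including flanks): same length and
    label count, destroyed spatial pattern."""
    pos = np.asarray(mol.labels_bp)
    bounds = np.concatenate([[0.0], pos, [mol.length_bp]])
    gaps = rng.permutation(np.diff(bounds))
    new = np.cumsum(gaps)[:-1]
    new = np.round(np.clip(new, 0.1, mol.length_bp), 1)
    new = np.unique(new)
    return Molecule(mol.molecule_id, mol.length_bp, tuple(float(x) for x in new))


def alignment_pvalue(
    al: PairAlignment,
    a: Molecule | MapContig,
    b: Molecule | MapContig,
    p: AlignParams,
    null_reps: int = 200,
    seed: int = 0,
    method: str = "auto",
    max_skip: int = DEFAULT_MAX_SKIP,
) -> float:
    """Permutation p-value of an observed alignment score.

    The gaps of ``b`` are shuffled ``null_reps`` times and realigned to
    ``a``; the p-value is ``(1 + #{null >= observed}) / (null_reps + 1)``.
    ``method="gumbel"`` fits a Gumbel to the null scores and returns its
    upper tail; ``"auto"`` uses the permutation count when at least one
    null score reaches the observed one and the Gumbel tail otherwise
    (thresholds far below ``1/(null_reps+1)`` are unreachable by counting).
    """
    if null_reps < 1:
        raise ValueError("null_reps must be >= 1")
    if method not in ("permutation", "gumbel", "auto"):
        raise ValueError(f"unknown method {method!r}")
    if isinstance(b, MapContig):
        b = Molecule(b.contig_id, b.length_bp, b.labels_bp)
    rng = np.random.default_rng(seed)
    null_scores = []
    for _ in range(null_reps):
        nb = shuffle_gaps(b, rng)
        r = align_pair(a, nb, p, max_skip=max_skip)
        null_scores.append(r.score if r is not None else -np.inf)
    null_scores = np.asarray(null_scores)
    exceed = int(np.sum(null_scores >= al.score))
    p_perm = (1 + exceed) / (null_reps + 1)
    if method == "permutation":
        return p_perm
    finite = null_scores[np.isfinite(null_scores)]
    if finite.size < 10:
        return p_perm
    loc, scale = st.gumbel_r.fit(finite)
    frac = finite.size / null_scores.size
    p_gum = float(np.clip(frac * st.gumbel_r.sf(al.score, loc, scale), 1e-300, 1.0))
    if method == "gumbel":
        return p_gum
    return p_perm if exceed > 0 else min(p_perm, p_gum)


class ScoreNull:
    """Pooled chance-score distribution for a dataset and error profile.

    Fitted once per (molecule set, FP, FN): random molecule pairs are
    drawn, one member's gaps are shuffled to destroy genuine co-locality,
    and the resulting alignment scores are fitted with a Gumbel.  The
    upper tail then converts any pair score to a p-value — cheap enough
    for all-pairs screening and able to resolve thresholds far below what
    per-pair permutation could reach.
    """

    def __init__(self, loc: float, scale: float, frac_aligned: float, n_fit: int):
        self.loc = loc
        self.scale = scale
        self.frac_aligned = frac_aligned
        self.n_fit = n_fit

    @classmethod
    def fit(
        cls,
        ms: MoleculeSet,
        p: AlignParams,
        n_null: int = 200,
        seed: int | None = None,
        max_skip: int = DEFAULT_MAX_SKIP,
    ) -> "ScoreNull":
        if len(ms) < 2:
            raise ValueError("need at least two molecules to fit a null")
        if seed is None:
            seed = derive_null_seed(ms, p)
        rng = np.random.default_rng(seed)
        mols = ms.molecules
        scores = []
        n_attempt = 0
        while n_attempt < n_null:
            n_attempt += 1
            i, j = rng.choice(len(mols), size=2, replace=False)
            b = shuffle_gaps(mols[j], rng)
            r = align_pair(mols[i], b, p, max_skip=max_skip)
            scores.append(r.score if r is not None else -np.inf)
        arr = np.asarray(scores)
        finite = arr[np.isfinite(arr)]
        if finite.size < 10:
            # degenerate (nearly label-free data): a flat, conservative null
            return cls(0.0, 1.0, max(finite.size, 1) / arr.size, int(finite.size))
        loc, scale = st.gumbel_r.fit(finite)
        return cls(float(loc), float(scale), finite.size / arr.size, int(finite.size))

    def pvalue(self, score: float) -> float:
        tail = st.gumbel_r.sf(score, self.loc, self.scale)
        return float(np.clip(self.frac_aligned * tail, 1e-300, 1.0))


def derive_null_seed(ms: MoleculeSet, p: AlignParams) -> int:
    """Deterministic null-fit seed from molecule content and (FP, FN) only,
    so that memoized and per-combination runs see the identical null."""
    h = hashlib.sha256()
    h.update(f"{p.fp_per_100kbp}|{p.fn_rate}|{p.sizing_sd_bp_per_kbp}".encode())
    for m in ms.molecules:
        h.update(f"{m.molecule_id}:{m.length_bp}:{m.labels_bp}".encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# confidence
# ---------------------------------------------------------------------------

def confidence(pvalue: float) -> float:
    """Confidence = -log10(p-value) of an alignment."""
    if not 0.0 < pvalue <= 1.0:
        raise ValueError(f"pvalue must be in (0,1], got {pvalue}")
    return -math.log10(pvalue)


def pvalue_from_confidence(conf: float) -> float:
    """Inverse conversion: p = 10^(-confidence)."""
    if conf < 0:
        raise ValueError(f"confidence must be non-negative, got {conf}")
    return 10.0 ** (-conf)
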