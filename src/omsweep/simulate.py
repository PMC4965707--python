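"""Synthetic references and noisy nanochannel molecules.

The generator emulates the statistical structure of Irys-style single
molecule data under the error model the assembler assumes:

* a long-tailed molecule length distribution (shifted exponential with a
  hard minimum, defaults targeting a length-weighted N50 of ~165 kbp);
* false positive labels as a Poisson process along each molecule;
* false negative labels as independent site dropout;
* Gaussian sizing noise applied per inter-label interval, with standard
  deviation proportional to the interval length;
* an optional global stretch factor.

FP and FN events are placed uniformly at random — the same assumption the
alignment model makes.  A truth sidecar (:class:`SimTruth`) records each
molecule's genomic origin and each label's provenance so that assemblies
can be scored against a known answer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import MapContig, Molecule, MoleculeSet

# Nicking enzyme recognition motifs used for dual-enzyme labeling of the
# cotton genome; kept as convenient defaults for in-silico digestion.
NT_BSPQ1 = "GCTCTTC"
NT_BBVCI = "CCTCAGC"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ErrorProfile:
    """Error model for simulated molecules.

    fp_per_100kbp
        Density of false labels (labels observed away from any true site),
        per 100 kbp of molecule length.
    fn_rate
        Proportion of true restriction sites that go unlabeled.
    sizing_sd_bp_per_kbp
        Standard deviation of inter-label distance noise, in bp per kbp of
        interval length (the default 40 gives ~400 bp at a 10 kbp interval,
        matching the magnitude of standard variance-linear sizing-error
        models for nanochannel data at the modal interval length).
    stretch_factor
        Global multiplicative length scaling (1.0 = no stretch).
    """

    fp_per_100kbp: float = 1.5
    fn_rate: float = 0.15
    sizing_sd_bp_per_kbp: float = 40.0
    stretch_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fn_rate <= 1.0:
            raise ValueError(f"fn_rate must be in [0,1], got {self.fn_rate}")
        if self.fp_per_100kbp < 0 or self.sizing_sd_bp_per_kbp < 0:
            raise ValueError("error rates must be non-negative")
        if self.stretch_factor <= 0:
            raise ValueError("stretch_factor must be positive")


NOISELESS = ErrorProfile(0.0, 0.0, 0.0, 1.0)


@dataclass(frozen=True)
class LengthModel:
    """Molecule length distribution: ``min_kbp`` + Exponential(mean - min).

    The default mean of 163 kbp with a 100 kbp floor puts the
    length-weighted median (molecule N50) at ~165 kbp.
    """

    mean_kbp: float = 163.0
    min_kbp: float = 100.0
    distribution: str = "truncexp"

    def __post_init__(self) -> None:
        if self.mean_kbp <= self.min_kbp:
            raise ValueError("mean_kbp must exceed min_kbp")
        if self.distribution != "truncexp":
            raise ValueError(f"unknown length distribution {self.distribution!r}")


@dataclass
class SimTruth:
    """Ground truth for a simulated molecule set.

    ``origins[mol_id] = (contig_id, start_bp, end_bp, orientation)`` with
    orientation +1/-1; ``label_provenance[mol_id][k]`` is the index of the
    reference label that produced label *k*, or -1 for a false positive.
    """

    origins: dict[int, tuple[int, float, float, int]] = field(default_factory=dict)
    label_provenance: dict[int, tuple[int, ...]] = field(default_factory=dict)

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["#molecule_id\tcontig_id\tstart_bp\tend_bp\torientation\tprovenance"]
        for mol_id in sorted(self.origins):
            cid, start, end, orient = self.origins[mol_id]
            prov = ",".join(str(i) for i in self.label_provenance.get(mol_id, ()))
            lines.append(f"{mol_id}\t{cid}\t{start:.1f}\t{end:.1f}\t{orient}\t{prov}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SimTruth":
        truth = cls()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            mol, cid, start, end, orient, prov = (line.split("\t") + [""])[:6]
            mol_id = int(mol)
            truth.origins[mol_id] = (int(cid), float(start), float(end), int(orient))
            truth.label_provenance[mol_id] = tuple(
                int(x) for x in prov.split(",") if x != ""
            )
        return truth


# ---------------------------------------------------------------------------
# references
# ---------------------------------------------------------------------------

def digest_sequence(
    sequence: str,
    motifs: str | tuple[str, ...] | list[str],
    contig_id: int = 1,
) -> MapContig:
    """In-silico digestion: one label per motif occurrence on either strand.

    Label position is the 1-based start of the occurrence in forward-strand
    coordinates; hits from all motifs (and their reverse complements) are
    merged into a single channel and duplicate positions collapsed.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if isinstance(motifs, str):
        motifs = (motifs,)
    if not motifs or any(not m for m in motifs):
        raise ValueError("motifs must be non-empty")
    seq = sequence.upper()
    positions: set[int] = set()
    for motif in motifs:
        motif = motif.upper()
        rc = motif.translate(_COMPLEMENT)[::-1]
        patterns = {motif, rc}
        for pat in patterns:
            for match in re.finditer(f"(?={re.escape(pat)})", seq):
                positions.add(match.start() + 1)
    labels = tuple(float(p) for p in sorted(positions))
    n = len(labels)
    return MapContig(
        contig_id=contig_id,
        length_bp=float(len(seq)),
        labels_bp=labels,
        occurrence=(1,) * n,
        coverage=(1,) * n,
    )


def expected_density(contig: MapContig) -> float:
    """Labels per 100 kbp of the map."""
    if contig.length_bp <= 0:
        raise ValueError("contig length must be positive")
    return contig.n_labels / contig.length_bp * 1e5


def random_reference(
    length_bp: float,
    density_per_100kbp: float = 10.5,
    seed: int = 0,
    contig_id: int = 1,
    min_gap_bp: float = 500.0,
) -> MapContig:
    """A synthetic reference map with Poisson-distributed label positions.

    Sites closer than ``min_gap_bp`` are thinned, mimicking the optical
    resolution limit below which adjacent labels are not separable.
    """
    rng = np.random.default_rng(seed)
    n = rng.poisson(length_bp * density_per_100kbp / 1e5)
    raw = np.sort(rng.uniform(1.0, length_bp, size=n))
    kept: list[float] = []
    for pos in raw:
        if not kept or pos - kept[-1] >= min_gap_bp:
            kept.append(round(float(pos), 1))
    k = len(kept)
    return MapContig(contig_id, float(length_bp), tuple(kept), (1,) * k, (1,) * k)


# ---------------------------------------------------------------------------
# molecules
# ---------------------------------------------------------------------------

def simulate_molecules(
    ref: MapContig | list[MapContig],
    coverage_fold: float | None = None,
    length_model: LengthModel = LengthModel(),
    err: ErrorProfile = ErrorProfile(),
    n_molecules: int | None = None,
) -> tuple[MoleculeSet, SimTruth]:
    """Draw noisy molecules from random intervals of the reference map(s).

    Molecules are drawn until the total simulated length reaches
    ``coverage_fold`` times the reference length (or until ``n_molecules``
    molecules, if given).  Each molecule takes a uniformly random interval
    of a reference contig (contig chosen with probability proportional to
    length) and a random orientation, then passes through the error model
    in ``err``.  Reproducible for a fixed ``err.seed``.
    """
    refs = [ref] if isinstance(ref, MapContig) else list(ref)
    if not refs:
        raise ValueError("reference is empty")
    if coverage_fold is None and n_molecules is None:
        raise ValueError("give coverage_fold or n_molecules")
    if coverage_fold is not None and coverage_fold <= 0:
        raise ValueError("coverage_fold must be positive")

    ref_lengths = np.array([r.length_bp for r in refs])
    total_ref = float(ref_lengths.sum())
    min_bp = length_model.min_kbp * 1000.0
    if min_bp > ref_lengths.max():
        raise ValueError(
            f"minimum molecule length {min_bp} bp exceeds the longest "
            f"reference contig ({ref_lengths.max()} bp)"
        )
    scale_bp = (length_model.mean_kbp - length_model.min_kbp) * 1000.0

    rng = np.random.default_rng(err.seed)
    target_bp = None if coverage_fold is None else coverage_fold * total_ref
    contig_prob = ref_lengths / total_ref

    molecules: list[Molecule] = []
    truth = SimTruth()
    simulated_bp = 0.0
    mol_id = 0
    while True:
        if n_molecules is not None:
            if mol_id >= n_molecules:
                break
        elif simulated_bp >= target_bp:  # type: ignore[operator]
            break
        mol_id += 1
        ridx = int(rng.choice(len(refs), p=contig_prob))
        contig = refs[ridx]
        clen = contig.length_bp
        length = min(min_bp + rng.exponential(scale_bp), clen)
        start = float(rng.uniform(0.0, clen - length))
        end = start + length
        orient = 1 if rng.random() < 0.5 else -1

        ref_pos = np.asarray(contig.labels_bp)
        lo = int(np.searchsorted(ref_pos, start, side="left"))
        hi = int(np.searchsorted(ref_pos, end, side="right"))
        site_idx = np.arange(lo, hi)
        # molecule-frame positions of true sites, honoring orientation
        if orient == 1:
            mol_pos = ref_pos[lo:hi] - start
        else:
            mol_pos = (end - ref_pos[lo:hi])[::-1]
            site_idx = site_idx[::-1]
        # clamp exact-boundary sites into (0, length]
        keep_window = (mol_pos > 0.0) & (mol_pos <= length)
        mol_pos, site_idx = mol_pos[keep_window], site_idx[keep_window]

        # false negatives: independent dropout of true sites
        if err.fn_rate > 0:
            keep = rng.random(mol_pos.size) >= err.fn_rate
            mol_pos, site_idx = mol_pos[keep], site_idx[keep]
        # false positives: Poisson process along the molecule
        n_fp = rng.poisson(err.fp_per_100kbp * length / 1e5)
        fp_pos = rng.uniform(0.0, length, size=n_fp)
        pos = np.concatenate([mol_pos, fp_pos])
        prov = np.concatenate([site_idx, np.full(n_fp, -1, dtype=int)])
        order = np.argsort(pos, kind="stable")
        pos, prov = pos[order], prov[order]

        # sizing noise per inter-label interval, length preserved by rescale
        if err.sizing_sd_bp_per_kbp > 0 and pos.size > 0:
            bounds = np.concatenate([[0.0], pos, [length]])
            gaps = np.diff(bounds)
            sds = err.sizing_sd_bp_per_kbp * gaps / 1000.0
            noisy = np.maximum(gaps + rng.normal(0.0, 1.0, gaps.size) * sds, 1.0)
            noisy *= length / noisy.sum()
            pos = np.cumsum(noisy)[:-1]

        length_out = length * err.stretch_factor
        pos = pos * err.stretch_factor
        pos = np.clip(np.round(pos, 1), 0.1, round(length_out, 1))
        length_out = round(length_out, 1)
        # collapse duplicates introduced by rounding
        uniq_mask = np.concatenate([[True], np.diff(pos) > 0]) if pos.size else np.array([], bool)
        pos, prov = pos[uniq_mask], prov[uniq_mask]

        molecules.append(Molecule(mol_id, length_out, tuple(float(p) for p in pos)))
        truth.origins[mol_id] = (contig.contig_id, start, end, orient)
        truth.label_provenance[mol_id] = tuple(int(i) for i in prov)
        simulated_bp += length

    meta = {
        "BNX File Version": "1.2",
        "Label Channels": "1",
        "Simulated": (
            f"fp={err.fp_per_100kbp},fn={err.fn_rate},"
            f"sizing_sd={err.sizing_sd_bp_per_kbp},stretch={err.stretch_factor},"
            f"seed={err.seed}"
        ),
    }
    return MoleculeSet(molecules, meta), truth
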