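"""Assembly quality: contiguity, internal consistency, reference accuracy,
and dataset-level summary statistics.

Contiguity is total length, contig N50 (first contig at which the
descending cumulative length reaches half the total) and longest contig.
Internal consistency is the mean label depth (average number of molecules
observing each consensus label) and the proportion of molecules not
excluded as singletons.  Accuracy aligns each contig to a reference map
and reports the contig-length-weighted mean confidence, where confidence
is the negative base-10 logarithm of the alignment p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .align import AlignParams, align_pair, alignment_pvalue, confidence
from .assemble import AssemblyResult
from .io_formats import MapContig, MoleculeSet


@dataclass
class QualityReport:
    total_length_bp: float
    n50_bp: float
    longest_contig_bp: float
    mean_label_depth: float
    nonsingleton_proportion: float
    weighted_mean_confidence: float | None = None
    n_unaligned_contigs: int | None = None
    params: object | None = None

    def __post_init__(self) -> None:
        if not (self.n50_bp <= self.longest_contig_bp <= self.total_length_bp + 1e-9):
            raise ValueError("require N50 <= longest <= total length")
        if not 0.0 <= self.nonsingleton_proportion <= 1.0:
            raise ValueError("nonsingleton_proportion must be in [0,1]")


def contiguity(contigs: Sequence[MapContig]) -> tuple[float, float, float]:
    """(total_length, n50, longest). Empty input yields zeros."""
    lengths = sorted((c.length_bp for c in contigs), reverse=True)
    if not lengths:
        return 0.0, 0.0, 0.0
    total = float(sum(lengths))
    half = total / 2.0
    acc = 0.0
    n50 = lengths[-1]
    for length in lengths:
        acc += length
        if acc >= half:
            n50 = length
            break
    return total, float(n50), float(lengths[0])


def internal_consistency(
    asm: AssemblyResult, filtered_input: MoleculeSet
) -> tuple[float, float]:
    """(mean_label_depth, nonsingleton_proportion).

    Label depth averages the per-label occurrence over all consensus
    labels (0.0 for an assembly with no contigs).  The singleton
    denominator is the post-filter molecule count.
    """
    occ = [o for c in asm.contigs for o in c.occurrence]
    depth = float(np.mean(occ)) if occ else 0.0
    n = len(filtered_input)
    prop = 1.0 - len(asm.singletons) / n if n else 0.0
    return depth, prop


def accuracy(
    contigs: Sequence[MapContig],
    reference: MapContig | Sequence[MapContig],
    p: AlignParams,
    null_reps: int = 100,
    seed: int = 0,
    max_skip: int = 5,
) -> tuple[float | None, int]:
    """Contig-length-weighted mean confidence of contig-to-reference
    alignments; contigs with no alignment are excluded from the mean and
    returned as a count."""
    refs = [reference] if isinstance(reference, MapContig) else list(reference)
    if not refs:
        raise ValueError("reference is empty")
    confs, weights = [], []
    unaligned = 0
    for contig in contigs:
        best_p = None
        for ref in refs:
            al = align_pair(ref, contig, p, max_skip=max_skip)
            if al is None:
                continue
            pv = alignment_pvalue(
                al, ref, contig, p, null_reps=null_reps, seed=seed, max_skip=max_skip
            )
            if best_p is None or pv < best_p:
                best_p = pv
        if best_p is None:
            unaligned += 1
            continue
        confs.append(confidence(best_p))
        weights.append(contig.length_bp)
    if not confs:
        return None, unaligned
    return float(np.average(confs, weights=weights)), unaligned


def quality_report(
    asm: AssemblyResult,
    filtered_input: MoleculeSet,
    reference: MapContig | Sequence[MapContig] | None = None,
    align_params: AlignParams | None = None,
    null_reps: int = 100,
    seed: int = 0,
) -> QualityReport:
    total, n50, longest = contiguity(asm.contigs)
    depth, prop = internal_consistency(asm, filtered_input)
    conf = None
    unaligned = None
    if reference is not None:
        if align_params is None:
            raise ValueError("align_params required for accuracy scoring")
        conf, unaligned = accuracy(
            asm.contigs, reference, align_params, null_reps=null_reps, seed=seed
        )
    return QualityReport(
        total_length_bp=total,
        n50_bp=n50,
        longest_contig_bp=longest,
        mean_label_depth=depth,
        nonsingleton_proportion=prop,
        weighted_mean_confidence=conf,
        n_unaligned_contigs=unaligned,
        params=asm.params,
    )


# ---------------------------------------------------------------------------
# dataset-level statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunStats:
    """Per-flow-cell run summary: data quantity, molecule N50, label density."""

    date_run: str
    quantity_mbp: float
    molecule_n50_kbp: float
    labels_per_100kbp: float

    def __post_init__(self) -> None:
        if min(self.quantity_mbp, self.molecule_n50_kbp, self.labels_per_100kbp) <= 0:
            raise ValueError("run statistics must be positive")


@dataclass(frozen=True)
class DatasetStats:
    total_gbp: float
    weighted_mean_n50_kbp: float
    weighted_mean_density: float
    max_density: float
    coverage_fold: int


def load_packaged_run_stats() -> list[RunStats]:
    """The bundled per-flow-cell run table of the G. raimondii (cotton)
    nanochannel mapping dataset."""
    with resources.files("omsweep.data").joinpath("cotton_irys_runs.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment=None)
    return [
        RunStats(r.date_run, r.quantity_mbp, r.molecule_n50_kbp, r.labels_per_100kbp)
        for r in df.itertuples()
    ]


def read_run_stats(path: str | Path) -> list[RunStats]:
    df = pd.read_csv(path, sep="\t")
    return [
        RunStats(r.date_run, r.quantity_mbp, r.molecule_n50_kbp, r.labels_per_100kbp)
        for r in df.itertuples()
    ]


def dataset_stats(
    runs: Sequence[RunStats], genome_size_mbp: float
) -> DatasetStats:
    """Quantity-weighted dataset aggregates.

    Total data in Gbp, quantity-weighted mean molecule N50 and label
    density, maximum density, and the fold coverage of a genome of
    ``genome_size_mbp`` (rounded to the nearest integer).
    """
    if not runs:
        raise ValueError("runs is empty")
    if genome_size_mbp <= 0:
        raise ValueError("genome_size_mbp must be positive")
    q = np.array([r.quantity_mbp for r in runs])
    n50 = np.array([r.molecule_n50_kbp for r in runs])
    dens = np.array([r.labels_per_100kbp for r in runs])
    total_mbp = float(q.sum())
    return DatasetStats(
        total_gbp=total_mbp / 1000.0,
        weighted_mean_n50_kbp=float((q * n50).sum() / total_mbp),
        weighted_mean_density=float((q * dens).sum() / total_mbp),
        max_density=float(dens.max()),
        coverage_fold=int(round(total_mbp / genome_size_mbp)),
    )


def rank_correlation(reports: Sequence[QualityReport]) -> tuple[float, float]:
    """Spearman rank correlation between contig N50 and weighted mean
    confidence across a sweep — reported, not asserted, since whether
    contiguity predicts accuracy is a property of the data."""
    pairs = [
        (r.n50_bp, r.weighted_mean_confidence)
        for r in reports
        if r.weighted_mean_confidence is not None
    ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 scored assemblies")
    rho, pval = st.spearmanr([a for a, _ in pairs], [b for _, b in pairs])
    return float(rho), float(pval)
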