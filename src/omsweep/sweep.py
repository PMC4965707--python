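"""Trial-and-error parameter sweeps with reuse of compatible intermediates.

Of the five swept parameters, only some alter what a pipeline step
actually computes; the rest merely filter its output.  Projecting each
full parameter combination onto the *effective* parameters of each step
yields a step key; distinct keys form a small DAG that is executed once
per node instead of once per combination:

========  =====================================================
step      effective parameters
========  =====================================================
sort      (none)
split     (none)
pairwise  false-positive rate, false-negative rate
assembly  all five
========  =====================================================

Filter-only parameters are run at the most lenient value in the active
grid (smallest minimum length and label count, largest significance
threshold) so that one shared run dominates every combination that
depends on it; each assembly node then re-filters molecules and
alignments down to its own stringent values.  Executed nodes are cached
on disk keyed by a content hash of (step type, effective parameters,
input data, code version), so a warm re-run performs zero recomputation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__ as _CODE_VERSION
from .align import AlignParams, PairAlignment, ScoreNull, derive_null_seed, DEFAULT_MAX_SKIP
from .assemble import (
    MERGE_RADIUS_BP,
    MIN_OCCURRENCE_FRAC,
    PLACEMENT_TOLERANCE_BP,
    AssemblyResult,
    all_pairs_overlaps,
    assemble_olc,
    filter_molecules,
    sort_molecules,
    split_molecules,
)
from .io_formats import MapContig, Molecule, MoleculeSet
from .quality import QualityReport, quality_report

log = logging.getLogger(__name__)

STEP_TYPES = ("sort", "split", "pairwise", "assembly")
GRID_FIELDS = (
    "pvalue_threshold", "fp_per_100kbp", "fn_rate", "min_length_kbp", "min_labels",
)
_EFFECTIVE: dict[str, tuple[str, ...]] = {
    "sort": (),
    "split": (),
    "pairwise": ("fp_per_100kbp", "fn_rate"),
    "assembly": GRID_FIELDS,
}

# The published five-parameter grid that yields 405 assemblies.
DEFAULT_GRID: dict[str, list] = {
    "pvalue_threshold": [1.11e-4, 1.11e-6, 1.11e-8, 1.11e-10, 1.11e-12],
    "fp_per_100kbp": [0.5, 1.5, 2.5],
    "fn_rate": [0.15, 0.30, 0.45],
    "min_length_kbp": [100.0, 150.0, 180.0],
    "min_labels": [6, 8, 10],
}


@dataclass(frozen=True, order=True)
class ParameterSet:
    """One full combination of the five swept parameters."""

    pvalue_threshold: float
    fp_per_100kbp: float
    fn_rate: float
    min_length_kbp: float
    min_labels: int

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in GRID_FIELDS}


@dataclass(frozen=True)
class StepKey:
    """A pipeline step identified by its effective-parameter projection."""

    step_type: str
    effective_params: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.step_type not in STEP_TYPES:
            raise ValueError(f"unknown step_type {self.step_type!r}")


def project_step_key(step_type: str, p: ParameterSet) -> StepKey:
    """Project a full combination onto the parameters effective for a step."""
    if step_type not in STEP_TYPES:
        raise ValueError(f"unknown step_type {step_type!r}")
    fields = _EFFECTIVE[step_type]
    return StepKey(step_type, tuple((f, getattr(p, f)) for f in fields))


@dataclass(frozen=True)
class LenientDominators:
    """The most lenient filter-only values in a grid: one run at these
    values dominates (is a superset of) every stringent dependent."""

    pvalue_threshold: float
    min_length_kbp: float
    min_labels: int


def lenient_dominators(grid: dict[str, Sequence]) -> LenientDominators:
    return LenientDominators(
        pvalue_threshold=max(grid["pvalue_threshold"]),
        min_length_kbp=min(grid["min_length_kbp"]),
        min_labels=min(grid["min_labels"]),
    )


@dataclass
class SweepPlan:
    """The deduplicated step DAG for a parameter grid."""

    grid: dict[str, list]
    parameter_sets: list[ParameterSet]
    nodes: dict[StepKey, list[ParameterSet]]  # node -> dependent combinations

    @property
    def counts(self) -> dict[str, int]:
        out = {t: 0 for t in STEP_TYPES}
        for key in self.nodes:
            out[key.step_type] += 1
        return out

    def pairwise_parent(self, p: ParameterSet) -> StepKey:
        return project_step_key("pairwise", p)


def plan_sweep(grid: dict[str, Sequence]) -> SweepPlan:
    """Build the step DAG for a grid of per-parameter value lists."""
    for fld in GRID_FIELDS:
        if fld not in grid or not list(grid[fld]):
            raise ValueError(f"grid dimension {fld!r} is missing or empty")
    grid = {f: list(grid[f]) for f in GRID_FIELDS}
    combos = [
        ParameterSet(*values)
        for values in product(*(grid[f] for f in GRID_FIELDS))
    ]
    nodes: dict[StepKey, list[ParameterSet]] = {}
    for p in combos:
        for step_type in STEP_TYPES:
            nodes.setdefault(project_step_key(step_type, p), []).append(p)
    return SweepPlan(grid=grid, parameter_sets=combos, nodes=nodes)


# ---------------------------------------------------------------------------
# execution with on-disk memoization
# ---------------------------------------------------------------------------

def _molecules_digest(ms: MoleculeSet) -> str:
    h = hashlib.sha256()
    for m in ms.molecules:
        h.update(f"{m.molecule_id}:{m.length_bp!r}:{m.labels_bp!r}".encode())
    return h.hexdigest()


def _node_digest(step_type: str, effective: tuple, context: tuple, data_hash: str) -> str:
    payload = json.dumps(
        [step_type, list(map(list, effective)), list(context), data_hash, _CODE_VERSION]
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:24]


class _Cache:
    """Content-addressed node cache: payload.json + meta.json with a
    checksum; a checksum mismatch triggers a re-run with a warning."""

    def __init__(self, root: str | Path | None):
        self.root = None if root is None else Path(root)
        if self.root is not None:
            self.root.mkdir(parents=True, exist_ok=True)

    def load(self, digest: str):
        if self.root is None:
            return None
        node = self.root / digest
        meta_p, payload_p = node / "meta.json", node / "payload.json"
        if not (meta_p.exists() and payload_p.exists()):
            return None
        raw = payload_p.read_bytes()
        meta = json.loads(meta_p.read_text())
        if hashlib.sha256(raw).hexdigest() != meta.get("checksum"):
            warnings.warn(
                f"cache node {digest} failed its checksum; re-running", stacklevel=2
            )
            return None
        return json.loads(raw.decode())

    def store(self, digest: str, payload: object) -> None:
        if self.root is None:
            return
        node = self.root / digest
        node.mkdir(parents=True, exist_ok=True)
        raw = json.dumps(payload).encode()
        (node / "payload.json").write_bytes(raw)
        (node / "meta.json").write_text(
            json.dumps({"checksum": hashlib.sha256(raw).hexdigest(),
                        "code_version": _CODE_VERSION})
        )


def _alignment_to_row(al: PairAlignment) -> list:
    return [
        al.id_a, al.id_b, al.orientation, repr(al.offset_bp),
        [list(p) for p in al.matched_pairs], al.unmatched_a, al.unmatched_b,
        repr(al.score), repr(al.pvalue), al.n_labels_b,
    ]


def _alignment_from_row(row: list) -> PairAlignment:
    return PairAlignment(
        id_a=row[0], id_b=row[1], orientation=row[2], offset_bp=float(row[3]),
        matched_pairs=tuple(tuple(p) for p in row[4]),
        unmatched_a=row[5], unmatched_b=row[6],
        score=float(row[7]), pvalue=float(row[8]), n_labels_b=row[9],
    )


@dataclass
class SweepResult:
    assembly: AssemblyResult
    report: QualityReport


@dataclass
class SweepOutcome:
    plan: SweepPlan
    results: dict[ParameterSet, SweepResult]
    executed: list[StepKey] = field(default_factory=list)


def run_sweep(
    ms: MoleculeSet,
    plan: SweepPlan,
    cache_dir: str | Path | None,
    sizing_sd_bp_per_kbp: float = 40.0,
    n_chunks: int = 4,
    n_null: int = 200,
    max_skip: int = DEFAULT_MAX_SKIP,
    placement_tolerance_bp: float = PLACEMENT_TOLERANCE_BP,
    merge_radius_bp: float = MERGE_RADIUS_BP,
    min_occurrence_frac: float = MIN_OCCURRENCE_FRAC,
    reference: MapContig | Sequence[MapContig] | None = None,
) -> SweepOutcome:
    """Execute every step node of the plan at most once, memoized on disk.

    Per-node caching keys on (step type, effective parameters, input
    content, code version); pairwise nodes additionally key on the
    lenient dominator triple they were executed with, since that decides
    which alignments are retained.  A warm second run executes zero nodes.
    """
    dom = lenient_dominators(plan.grid)
    data_hash = _molecules_digest(ms)
    cache = _Cache(cache_dir)
    executed: list[StepKey] = []
    mols_by_id = ms.by_id()

    # ---- sort node (single): lenient filter, then length-descending sort
    sort_key = StepKey("sort", ())
    sort_digest = _node_digest(
        "sort", (), (dom.min_length_kbp, dom.min_labels), data_hash
    )
    payload = cache.load(sort_digest)
    if payload is None:
        filtered = filter_molecules(ms, dom.min_length_kbp, dom.min_labels)
        ordered = sort_molecules(filtered)
        payload = {"order": ordered.ids}
        cache.store(sort_digest, payload)
        executed.append(sort_key)
        log.info("sort: %d molecules after lenient filter", len(ordered))
    sorted_ids: list[int] = payload["order"]
    sorted_ms = MoleculeSet([mols_by_id[i] for i in sorted_ids], dict(ms.metadata))

    # ---- split node (single)
    split_key = StepKey("split", ())
    split_digest = _node_digest("split", (), (n_chunks,), _digest_ids(sorted_ids, data_hash))
    payload = cache.load(split_digest)
    if payload is None:
        chunks = split_molecules(sorted_ms, n_chunks)
        payload = {"chunks": [c.ids for c in chunks]}
        cache.store(split_digest, payload)
        executed.append(split_key)
    chunk_ids: list[list[int]] = payload["chunks"]
    chunks = [
        MoleculeSet([mols_by_id[i] for i in ids], dict(ms.metadata))
        for ids in chunk_ids
    ]

    # ---- pairwise nodes: one per distinct (FP, FN); lenient everywhere else
    pairwise_payloads: dict[StepKey, list[PairAlignment]] = {}
    pairwise_keys = {
        key for key in plan.nodes if key.step_type == "pairwise"
    }
    for key in sorted(pairwise_keys, key=lambda k: k.effective_params):
        eff = dict(key.effective_params)
        params = AlignParams(
            fp_per_100kbp=eff["fp_per_100kbp"],
            fn_rate=eff["fn_rate"],
            sizing_sd_bp_per_kbp=sizing_sd_bp_per_kbp,
            pvalue_threshold=dom.pvalue_threshold,
        )
        digest = _node_digest(
            "pairwise",
            key.effective_params,
            (dom.pvalue_threshold, dom.min_length_kbp, dom.min_labels,
             sizing_sd_bp_per_kbp, max_skip, n_null, n_chunks),
            data_hash,
        )
        payload = cache.load(digest)
        if payload is None:
            null = ScoreNull.fit(
                ms, params, n_null=n_null, seed=derive_null_seed(ms, params),
                max_skip=max_skip,
            )
            alignments = all_pairs_overlaps(chunks, params, null, max_skip=max_skip)
            payload = {"alignments": [_alignment_to_row(a) for a in alignments]}
            cache.store(digest, payload)
            executed.append(key)
            log.info(
                "pairwise fp=%g fn=%g: %d significant overlaps",
                eff["fp_per_100kbp"], eff["fn_rate"], len(alignments),
            )
        pairwise_payloads[key] = [_alignment_from_row(r) for r in payload["alignments"]]

    # ---- assembly nodes: one per full combination
    results: dict[ParameterSet, SweepResult] = {}
    for p in plan.parameter_sets:
        key = project_step_key("assembly", p)
        digest = _node_digest(
            "assembly",
            key.effective_params,
            (sizing_sd_bp_per_kbp, max_skip, n_null, n_chunks,
             placement_tolerance_bp, merge_radius_bp, min_occurrence_frac),
            data_hash,
        )
        cached = cache.load(digest)
        filtered = filter_molecules(sorted_ms, p.min_length_kbp, p.min_labels)
        if cached is None:
            keep_ids = set(filtered.ids)
            alignments = [
                a
                for a in pairwise_payloads[plan.pairwise_parent(p)]
                if a.id_a in keep_ids
                and a.id_b in keep_ids
                and a.pvalue <= p.pvalue_threshold
            ]
            asm = assemble_olc(
                filtered,
                alignments,
                placement_tolerance_bp=placement_tolerance_bp,
                merge_radius_bp=merge_radius_bp,
                min_occurrence_frac=min_occurrence_frac,
                params=p,
            )
            align_params = AlignParams(
                fp_per_100kbp=p.fp_per_100kbp,
                fn_rate=p.fn_rate,
                sizing_sd_bp_per_kbp=sizing_sd_bp_per_kbp,
                pvalue_threshold=p.pvalue_threshold,
            )
            report = quality_report(
                asm, filtered,
                reference=reference,
                align_params=align_params if reference is not None else None,
            )
            cache.store(digest, _assembly_payload(asm, report))
            executed.append(key)
        else:
            asm, report = _assembly_from_payload(cached, p)
        results[p] = SweepResult(assembly=asm, report=report)
    return SweepOutcome(plan=plan, results=results, executed=executed)


def _digest_ids(ids: list[int], data_hash: str) -> str:
    return hashlib.sha256((",".join(map(str, ids)) + data_hash).encode()).hexdigest()


def _assembly_payload(asm: AssemblyResult, report: QualityReport) -> dict:
    return {
        "contigs": [
            [c.contig_id, repr(c.length_bp), [repr(x) for x in c.labels_bp],
             list(c.occurrence), list(c.coverage)]
            for c in asm.contigs
        ],
        "placements": {
            str(mid): [pl.contig_id, repr(pl.offset_bp), pl.orientation]
            for mid, pl in asm.placements.items()
        },
        "singletons": sorted(asm.singletons),
        "report": {
            "total_length_bp": report.total_length_bp,
            "n50_bp": report.n50_bp,
            "longest_contig_bp": report.longest_contig_bp,
            "mean_label_depth": report.mean_label_depth,
            "nonsingleton_proportion": report.nonsingleton_proportion,
            "weighted_mean_confidence": report.weighted_mean_confidence,
            "n_unaligned_contigs": report.n_unaligned_contigs,
        },
    }


def _assembly_from_payload(payload: dict, p: ParameterSet) -> tuple[AssemblyResult, QualityReport]:
    from .assemble import Placement

    contigs = [
        MapContig(row[0], float(row[1]), tuple(float(x) for x in row[2]),
                  tuple(row[3]), tuple(row[4]))
        for row in payload["contigs"]
    ]
    placements = {
        int(mid): Placement(row[0], float(row[1]), row[2])
        for mid, row in payload["placements"].items()
    }
    asm = AssemblyResult(contigs, placements, set(payload["singletons"]), p)
    rep = payload["report"]
    report = QualityReport(params=p, **rep)
    return asm, report


# ---------------------------------------------------------------------------
# naive reference runner and resource accounting
# ---------------------------------------------------------------------------

def run_naive(
    ms: MoleculeSet,
    parameter_sets: Sequence[ParameterSet],
    sizing_sd_bp_per_kbp: float = 40.0,
    n_chunks: int = 4,
    n_null: int = 200,
    max_skip: int = DEFAULT_MAX_SKIP,
    placement_tolerance_bp: float = PLACEMENT_TOLERANCE_BP,
    merge_radius_bp: float = MERGE_RADIUS_BP,
    min_occurrence_frac: float = MIN_OCCURRENCE_FRAC,
    reference: MapContig | Sequence[MapContig] | None = None,
) -> dict[ParameterSet, SweepResult]:
    """Run every combination end to end with no reuse: the correctness
    oracle for the memoized engine."""
    results: dict[ParameterSet, SweepResult] = {}
    for p in parameter_sets:
        params = AlignParams(
            fp_per_100kbp=p.fp_per_100kbp,
            fn_rate=p.fn_rate,
            sizing_sd_bp_per_kbp=sizing_sd_bp_per_kbp,
            pvalue_threshold=p.pvalue_threshold,
        )
        filtered = sort_molecules(filter_molecules(ms, p.min_length_kbp, p.min_labels))
        chunks = split_molecules(filtered, n_chunks)
        null = ScoreNull.fit(
            ms, params, n_null=n_null, seed=derive_null_seed(ms, params),
            max_skip=max_skip,
        )
        alignments = all_pairs_overlaps(chunks, params, null, max_skip=max_skip)
        asm = assemble_olc(
            filtered, alignments,
            placement_tolerance_bp=placement_tolerance_bp,
            merge_radius_bp=merge_radius_bp,
            min_occurrence_frac=min_occurrence_frac,
            params=p,
        )
        report = quality_report(
            asm, filtered,
            reference=reference,
            align_params=params if reference is not None else None,
        )
        results[p] = SweepResult(assembly=asm, report=report)
    return results


def resource_report(plan: SweepPlan, executed: Sequence[StepKey]) -> pd.DataFrame:
    """Steps executed vs. the one-run-per-combination naive count."""
    n_combo = len(plan.parameter_sets)
    counts = plan.counts
    executed_counts = {t: 0 for t in STEP_TYPES}
    for key in executed:
        executed_counts[key.step_type] += 1
    rows = []
    for t in STEP_TYPES:
        planned = counts[t]
        rows.append(
            {
                "step": t,
                "nodes_planned": planned,
                "nodes_executed": executed_counts[t],
                "naive_runs": n_combo,
                "savings_ratio": n_combo / planned if planned else float("nan"),
            }
        )
    rows.append(
        {
            "step": "total",
            "nodes_planned": sum(counts.values()),
            "nodes_executed": sum(executed_counts.values()),
            "naive_runs": n_combo * len(STEP_TYPES),
            "savings_ratio": n_combo * len(STEP_TYPES) / sum(counts.values()),
        }
    )
    return pd.DataFrame(rows)
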