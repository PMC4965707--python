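"""Reading and writing the text formats used for nanochannel map data.

Two formats are supported:

* **BNX** — one record per imaged molecule: a ``0`` line with the molecule
  id and length, followed by a ``1`` line with the label positions (the
  molecule length is appended as the final value of the ``1`` line, the
  common single-channel convention).  ``QX``-prefixed quality rows are
  accepted and ignored.
* **CMAP** — consensus / reference maps: one tab-separated row per label
  with per-label ``Coverage`` and ``Occurrence`` counts, grouped by contig.

Both are plain UTF-8 text with ``#``-prefixed headers.  Positions are
written with one decimal place, so round trips are stable to 0.1 bp.
Unknown header keys are preserved verbatim on round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


class FormatError(ValueError):
    """Malformed record in a BNX/CMAP file (the message names the line)."""


class UnsupportedDialectError(FormatError):
    """The file declares a format version this reader does not implement."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Molecule:
    """One nicked, labeled DNA molecule: a length plus ordered label positions.

    Positions are continuous distances in bp from the molecule start, in
    ``(0, length_bp]``, strictly increasing.
    """

    molecule_id: int
    length_bp: float
    labels_bp: tuple[float, ...]
    channel: int = 1
    source_run: str | None = None

    def __post_init__(self) -> None:
        if self.molecule_id <= 0:
            raise ValueError(f"molecule_id must be positive, got {self.molecule_id}")
        if not self.length_bp > 0:
            raise ValueError(f"length_bp must be positive, got {self.length_bp}")
        prev = 0.0
        for pos in self.labels_bp:
            if not (prev < pos <= self.length_bp):
                raise ValueError(
                    f"molecule {self.molecule_id}: label at {pos} violates "
                    f"0 < p[i-1] < p[i] <= length ({self.length_bp})"
                )
            prev = pos

    @property
    def n_labels(self) -> int:
        return len(self.labels_bp)


@dataclass(frozen=True)
class MapContig:
    """A consensus (or reference) restriction map with per-label support.

    ``occurrence[i]`` is the number of molecules in which consensus label
    *i* was actually observed; ``coverage[i]`` is the number of molecules
    spanning its position, so ``occurrence <= coverage`` everywhere.
    """

    contig_id: int
    length_bp: float
    labels_bp: tuple[float, ...]
    occurrence: tuple[int, ...]
    coverage: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.contig_id <= 0:
            raise ValueError(f"contig_id must be positive, got {self.contig_id}")
        if not self.length_bp > 0:
            raise ValueError(f"length_bp must be positive, got {self.length_bp}")
        if not (len(self.occurrence) == len(self.coverage) == len(self.labels_bp)):
            raise ValueError(
                f"contig {self.contig_id}: labels/occurrence/coverage lengths differ"
            )
        prev = float("-inf")
        for i, pos in enumerate(self.labels_bp):
            if pos <= prev:
                raise ValueError(
                    f"contig {self.contig_id}: labels not strictly increasing at {pos}"
                )
            prev = pos
            if self.occurrence[i] < 0 or self.coverage[i] < 0:
                raise ValueError(f"contig {self.contig_id}: negative support counts")
            if self.occurrence[i] > self.coverage[i]:
                raise ValueError(
                    f"contig {self.contig_id}: occurrence > coverage at label {i}"
                )

    @property
    def n_labels(self) -> int:
        return len(self.labels_bp)


@dataclass
class MoleculeSet:
    """A collection of molecules plus the header metadata of their file."""

    molecules: list[Molecule] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [m.molecule_id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate molecule ids in MoleculeSet")

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self) -> Iterator[Molecule]:
        return iter(self.molecules)

    def __getitem__(self, i: int) -> Molecule:
        return self.molecules[i]

    @property
    def ids(self) -> list[int]:
        return [m.molecule_id for m in self.molecules]

    def by_id(self) -> dict[int, Molecule]:
        return {m.molecule_id: m for m in self.molecules}

    def total_length_bp(self) -> float:
        return sum(m.length_bp for m in self.molecules)


# ---------------------------------------------------------------------------
# BNX
# ---------------------------------------------------------------------------

_BNX_VERSION_KEY = "BNX File Version"
_SUPPORTED_BNX = ("1.0", "1.1", "1.2", "1.3")


def _fmt(pos: float) -> str:
    return f"{pos:.1f}"


def write_bnx(ms: MoleculeSet, path: str | Path) -> Path:
    """Write a single-channel BNX 1.x file. Returns the path written."""
    path = Path(path)
    meta = dict(ms.metadata)
    meta.setdefault(_BNX_VERSION_KEY, "1.2")
    meta.setdefault("Label Channels", "1")
    lines: list[str] = []
    for key, value in meta.items():
        lines.append(f"# {key}:\t{value}")
    lines.append("#0h\tLabelChannel\tMoleculeID\tLength")
    lines.append("#0f\tint\tint\tfloat")
    lines.append("#1h\tLabelChannel\tLabelPositions[N]")
    lines.append("#1f\tint\tfloat")
    for m in ms.molecules:
        lines.append(f"0\t{m.channel}\t{m.molecule_id}\t{_fmt(m.length_bp)}")
        pos = "\t".join(_fmt(p) for p in (*m.labels_bp, m.length_bp))
        lines.append(f"1\t{pos}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_bnx(path: str | Path) -> MoleculeSet:
    """Parse a single-channel BNX 1.x file into a :class:`MoleculeSet`."""
    path = Path(path)
    metadata: dict[str, str] = {}
    molecules: list[Molecule] = []
    pending: tuple[int, int, float] | None = None  # (channel, id, length)
    pending_line = 0

    def finish(labels: tuple[float, ...], lineno: int) -> None:
        nonlocal pending
        assert pending is not None
        channel, mol_id, length = pending
        try:
            molecules.append(
                Molecule(mol_id, length, labels, channel=channel)
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        pending = None

    version_checked = False
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body and not body.startswith(("0h", "0f", "1h", "1f")):
                    key, _, value = body.partition(":")
                    metadata[key.strip()] = value.strip()
                continue
            if not version_checked:
                version = metadata.get(_BNX_VERSION_KEY)
                if version is None or version not in _SUPPORTED_BNX:
                    raise UnsupportedDialectError(
                        f"{path}: unsupported or missing BNX version {version!r} "
                        f"(supported: {', '.join(_SUPPORTED_BNX)})"
                    )
                version_checked = True
            fields = line.split("\t")
            tag = fields[0]
            if tag == "0":
                if pending is not None:
                    raise FormatError(
                        f"{path}:{pending_line}: molecule record without label line"
                    )
                if len(fields) < 4:
                    raise FormatError(f"{path}:{lineno}: short molecule line")
                pending = (int(fields[1]), int(fields[2]), float(fields[3]))
                pending_line = lineno
            elif tag == "1":
                if pending is None:
                    raise FormatError(f"{path}:{lineno}: label line without molecule")
                vals = [float(v) for v in fields[1:]]
                # trailing value equal to the molecule length is the end marker
                if vals and abs(vals[-1] - pending[2]) <= 0.05:
                    vals = vals[:-1]
                finish(tuple(vals), lineno)
            elif tag.startswith("QX"):
                continue  # quality rows are accepted and ignored
            else:
                raise FormatError(f"{path}:{lineno}: unknown record tag {tag!r}")
    if pending is not None:
        raise FormatError(f"{path}:{pending_line}: molecule record without label line")
    if not version_checked:
        version = metadata.get(_BNX_VERSION_KEY)
        if version is None or version not in _SUPPORTED_BNX:
            raise UnsupportedDialectError(
                f"{path}: unsupported or missing BNX version {version!r} "
                f"(supported: {', '.join(_SUPPORTED_BNX)})"
            )
    return MoleculeSet(molecules, metadata)


# ---------------------------------------------------------------------------
# CMAP
# ---------------------------------------------------------------------------

_CMAP_COLUMNS = (
    "CMapId", "ContigLength", "NumSites", "SiteID", "LabelChannel",
    "Position", "StdDev", "Coverage", "Occurrence",
)


def write_cmap(contigs: Iterable[MapContig], path: str | Path) -> Path:
    """Write contigs as a 9-column CMAP file. Returns the path written."""
    path = Path(path)
    lines = [
        "# CMAP File Version:\t0.1",
        "# Label Channels:\t1",
        "#h\t" + "\t".join(_CMAP_COLUMNS),
        "#f\tint\tfloat\tint\tint\tint\tfloat\tfloat\tint\tint",
    ]
    for contig in contigs:
        n = contig.n_labels
        for site_id, (pos, occ, cov) in enumerate(
            zip(contig.labels_bp, contig.occurrence, contig.coverage), start=1
        ):
            lines.append(
                "\t".join(
                    (
                        str(contig.contig_id), _fmt(contig.length_bp), str(n),
                        str(site_id), "1", _fmt(pos), "0.0", str(cov), str(occ),
                    )
                )
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_cmap(path: str | Path) -> list[MapContig]:
    """Parse a CMAP file; rows may be interleaved across contig ids."""
    path = Path(path)
    rows: dict[int, list[tuple[int, float, float, int, int]]] = {}
    lengths: dict[int, float] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            try:
                cid = int(fields[0])
                length = float(fields[1])
                site_id = int(fields[3])
                channel = int(fields[4])
                pos = float(fields[5])
                cov = int(fields[7])
                occ = int(fields[8])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if channel == 0:
                continue  # end-of-contig marker rows in some dialects
            rows.setdefault(cid, []).append((site_id, pos, float(fields[6]), cov, occ))
            lengths[cid] = length
    contigs: list[MapContig] = []
    for cid in sorted(rows):
        recs = sorted(rows[cid], key=lambda r: (r[1], r[0]))
        try:
            contigs.append(
                MapContig(
                    contig_id=cid,
                    length_bp=lengths[cid],
                    labels_bp=tuple(r[1] for r in recs),
                    occurrence=tuple(r[4] for r in recs),
                    coverage=tuple(r[3] for r in recs),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: contig {cid}: {exc}") from exc
    return contigs


# ---------------------------------------------------------------------------
# FASTA (consumed by the simulator)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning ``{name: sequence}`` (uppercased)."""
    path = Path(path)
    seqs: dict[str, list[str]] = {}
    name: str | None = None
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise FormatError(f"{path}: duplicate sequence name {name!r}")
                seqs[name] = []
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence data before first header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}
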