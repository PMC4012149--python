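"""Core domain types for partitioning-scheme selection.

The object hierarchy mirrors standard partitioning terminology:

* a *data block* is a user-specified set of alignment sites (a gene, an
  intron, one codon position of an exon, ...);
* a *subset* is a collection of one or more data blocks that share a single
  substitution model;
* a *partitioning scheme* is a set of subsets containing every data block
  exactly once — a set partition of the blocks.

External coordinates (config files, RAxML partition files, NEXUS sets
blocks) are 1-based inclusive; everything internal is 0-based.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO, SeqIO

__all__ = [
    "Alignment",
    "DataBlock",
    "Subset",
    "PartitioningScheme",
    "WeightVector",
    "RunConfig",
    "AlignmentFormatError",
    "ConfigError",
    "parse_alignment",
    "parse_block_spec",
    "parse_config",
    "validate_scheme",
    "write_scheme",
    "parse_raxml_partition",
]

VALID_CHARS = set("ACGTURYSWKMBDHVN-?.")


class AlignmentFormatError(ValueError):
    """Raised when an alignment file violates the expected format."""


class ConfigError(ValueError):
    """Raised for invalid run configuration or block definitions."""


@dataclass(frozen=True)
class Alignment:
    """A taxa x sites DNA character matrix.

    Characters are uppercase IUPAC nucleotide codes with ``-``/``?``/``.``
    treated downstream as fully ambiguous. ``U`` is mapped to ``T`` on input.
    """

    taxon_names: tuple[str, ...]
    matrix: np.ndarray  # dtype '<U1', shape (n_taxa, n_sites)

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise AlignmentFormatError("alignment matrix must be 2-D")
        if self.matrix.shape[0] != len(self.taxon_names):
            raise AlignmentFormatError("row count does not match taxon count")
        if self.n_sites < 1:
            raise AlignmentFormatError("alignment must contain at least one site")
        if len(set(self.taxon_names)) != len(self.taxon_names):
            dupes = {t for t in self.taxon_names if self.taxon_names.count(t) > 1}
            raise AlignmentFormatError(f"duplicate taxon names: {sorted(dupes)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, taxon: str) -> str:
        idx = self.taxon_names.index(taxon)
        return "".join(self.matrix[idx])


@dataclass(frozen=True)
class DataBlock:
    """A named, user-specified set of alignment sites (0-based indices)."""

    name: str
    sites: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ConfigError(f"data block {self.name!r} has no sites")
        object.__setattr__(self, "sites", tuple(sorted(set(self.sites))))
        if self.sites[0] < 0:
            raise ConfigError(f"data block {self.name!r} has negative site indices")


@dataclass(frozen=True)
class Subset:
    """A collection of one or more data blocks sharing one model.

    ``sites`` is always the exact union of the member blocks' sites; the
    identity of a subset for caching purposes is its site set.
    """

    blocks: frozenset[str]
    sites: tuple[int, ...]

    @classmethod
    def from_blocks(cls, blocks: Iterable[DataBlock]) -> "Subset":
        blocks = list(blocks)
        if not blocks:
            raise ConfigError("a subset must contain at least one data block")
        names = frozenset(b.name for b in blocks)
        sites: set[int] = set()
        for b in blocks:
            sites.update(b.sites)
        return cls(blocks=names, sites=tuple(sorted(sites)))

    def merge(self, other: "Subset") -> "Subset":
        return Subset(
            blocks=self.blocks | other.blocks,
            sites=tuple(sorted(set(self.sites) | set(other.sites))),
        )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sort_key(self) -> tuple:
        # deterministic ordering: smallest contained site index, then names
        return (self.sites[0], tuple(sorted(self.blocks)))


@dataclass(frozen=True)
class PartitioningScheme:
    """A set partition of the data blocks into subsets."""

    subsets: frozenset[Subset]

    @classmethod
    def singletons(cls, blocks: Iterable[DataBlock]) -> "PartitioningScheme":
        return cls(frozenset(Subset.from_blocks([b]) for b in blocks))

    def sorted_subsets(self) -> list[Subset]:
        return sorted(self.subsets, key=Subset.sort_key)

    def __len__(self) -> int:
        return len(self.subsets)

    def merge(self, a: Subset, b: Subset) -> "PartitioningScheme":
        if a not in self.subsets or b not in self.subsets:
            raise ValueError("both subsets must belong to the scheme")
        rest = self.subsets - {a, b}
        return PartitioningScheme(rest | {a.merge(b)})


@dataclass(frozen=True)
class WeightVector:
    """Relative importance of the four parameter categories in subset
    similarity: overall rate, base frequencies, GTR exchangeabilities, and
    the gamma shape alpha."""

    w_rate: float = 1.0
    w_freqs: float = 0.0
    w_gtr: float = 0.0
    w_alpha: float = 0.0

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(w < 0 for w in vals):
            raise ConfigError("weights must be non-negative")
        if all(w == 0 for w in vals):
            raise ConfigError(
                "all-zero weights are not allowed: every pair of subsets "
                "would look equally similar"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.w_rate, self.w_freqs, self.w_gtr, self.w_alpha)


SEARCH_MODES = ("exhaustive", "greedy", "hcluster", "rcluster")
CRITERIA = ("AIC", "AICc", "BIC")


@dataclass
class RunConfig:
    """Fully specified analysis configuration."""

    alignment_path: Path
    blocks: list[DataBlock]
    criterion: str = "BIC"
    search: str = "greedy"
    weights: WeightVector = field(default_factory=WeightVector)
    rcluster_percent: float = 10.0
    branchlengths: str = "linked"
    user_tree_path: Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ConfigError(f"criterion must be one of {CRITERIA}, got {self.criterion!r}")
        if self.search not in SEARCH_MODES:
            raise ConfigError(f"search must be one of {SEARCH_MODES}, got {self.search!r}")
        if not (0.0 <= self.rcluster_percent <= 100.0):
            raise ConfigError("rcluster_percent must lie in [0, 100]")
        if self.branchlengths != "linked":
            raise ConfigError("only linked branch lengths are supported")
        _check_block_overlap(self.blocks)


def _check_block_overlap(blocks: Sequence[DataBlock]) -> None:
    seen: dict[int, str] = {}
    for b in blocks:
        for s in b.sites:
            if s in seen:
                raise ConfigError(
                    f"data blocks {seen[s]!r} and {b.name!r} overlap at site {s + 1}"
                )
            seen[s] = b.name


# ---------------------------------------------------------------------------
# alignment input


def parse_alignment(path: str | Path, format: str | None = None) -> Alignment:
    """Read a DNA alignment from FASTA or relaxed sequential PHYLIP.

    ``format`` is ``"fasta"`` or ``"phylip"``; when omitted it is sniffed
    from the first non-blank character (``>`` means FASTA).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        head = path.read_text().lstrip()[:1]
        format = "fasta" if head == ">" else "phylip"
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentFormatError(f"{path}: no FASTA records found")
        names = [r.id for r in records]
        seqs = [str(r.seq) for r in records]
    elif format == "phylip":
        try:
            aln = AlignIO.read(str(path), "phylip-relaxed")
        except ValueError as exc:
            raise AlignmentFormatError(f"{path}: {exc}") from exc
        names = [r.id for r in aln]
        seqs = [str(r.seq) for r in aln]
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    return _build_alignment(names, seqs, str(path))


def _build_alignment(names: Sequence[str], seqs: Sequence[str], origin: str) -> Alignment:
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        expected = len(seqs[0])
        for n, s in zip(names, seqs):
            if len(s) != expected:
                raise AlignmentFormatError(
                    f"{origin}: taxon {n!r} has {len(s)} sites, expected {expected}"
                )
    cleaned = []
    for n, s in zip(names, seqs):
        s = s.upper().replace("U", "T")
        bad = set(s) - VALID_CHARS
        if bad:
            raise AlignmentFormatError(
                f"{origin}: taxon {n!r} contains invalid characters {sorted(bad)}"
            )
        cleaned.append(s)
    matrix = np.array([list(s) for s in cleaned], dtype="<U1")
    return Alignment(taxon_names=tuple(names), matrix=matrix)


# ---------------------------------------------------------------------------
# block definitions

_RANGE_RE = re.compile(r"^(\d+)\s*-\s*(\d+)(?:\s*\\\s*(\d+))?$")


def parse_block_spec(spec: str) -> DataBlock:
    r"""Parse one block definition like ``Gene1_pos1 = 1-789\3;``.

    Coordinates are 1-based inclusive; an optional ``\stride`` takes every
    stride-th site starting at the range start (codon-position notation).
    Comma-separated ranges are unioned.
    """
    spec = spec.strip().rstrip(";").strip()
    if "=" not in spec:
        raise ConfigError(f"block definition {spec!r} lacks '='")
    name, _, rhs = spec.partition("=")
    name = name.strip()
    if not name:
        raise ConfigError(f"block definition {spec!r} lacks a name")
    sites: set[int] = set()
    for part in rhs.split(","):
        part = part.strip()
        m = _RANGE_RE.match(part)
        if not m:
            raise ConfigError(f"block {name!r}: cannot parse range {part!r}")
        start, end = int(m.group(1)), int(m.group(2))
        stride = int(m.group(3)) if m.group(3) else 1
        if start < 1:
            raise ConfigError(f"block {name!r}: coordinates are 1-based, got {start}")
        if start > end:
            raise ConfigError(f"block {name!r}: start {start} > end {end}")
        if stride < 1:
            raise ConfigError(f"block {name!r}: stride must be >= 1, got {stride}")
        sites.update(range(start - 1, end, stride))
    return DataBlock(name=name, sites=tuple(sorted(sites)))


# ---------------------------------------------------------------------------
# config files (PartitionFinder-style dialect)


def parse_config(path: str | Path) -> RunConfig:
    """Read a PartitionFinder-style configuration file.

    Recognised top-level options: ``alignment``, ``branchlengths``,
    ``models``, ``model_selection``, ``user_tree_topology``, ``seed``.
    The ``[data_blocks]`` section holds one block definition per line; the
    ``[schemes]`` section holds ``search``, ``weights`` and
    ``rcluster_percent``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    options: dict[str, str] = {}
    block_lines: list[str] = []
    section = None
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            continue
        if section == "data_blocks":
            block_lines.append(line)
        else:
            if "=" not in line:
                raise ConfigError(f"{path}: cannot parse option line {raw!r}")
            key, _, val = line.partition("=")
            options[key.strip().lower()] = val.strip().rstrip(";").strip()

    if "alignment" not in options:
        raise ConfigError(f"{path}: missing 'alignment' option")
    if not block_lines:
        raise ConfigError(f"{path}: no [data_blocks] defined")
    blocks = [parse_block_spec(line) for line in block_lines]
    names = [b.name for b in blocks]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigError(f"{path}: duplicate block names {dupes}")

    models = options.get("models", "GTR+G")
    if models.replace(" ", "") not in {"GTR+G", "GTR+GAMMA"}:
        raise ConfigError(f"{path}: only the GTR+G model is supported, got {models!r}")

    weights = WeightVector(*_parse_float_list(options.get("weights", "1,0,0,0"), 4))
    user_tree = options.get("user_tree_topology")
    return RunConfig(
        alignment_path=(path.parent / options["alignment"]).resolve(),
        blocks=blocks,
        criterion=_canonical_criterion(options.get("model_selection", "BIC")),
        search=options.get("search", "greedy").lower(),
        weights=weights,
        rcluster_percent=float(options.get("rcluster_percent", "10")),
        branchlengths=options.get("branchlengths", "linked").lower(),
        user_tree_path=(path.parent / user_tree).resolve() if user_tree else None,
        seed=int(options.get("seed", "0")),
    )


def _canonical_criterion(text: str) -> str:
    lut = {"aic": "AIC", "aicc": "AICc", "bic": "BIC"}
    key = text.strip().lower()
    if key not in lut:
        raise ConfigError(f"unknown model_selection criterion {text!r}")
    return lut[key]


def _parse_float_list(text: str, n: int) -> list[float]:
    parts = [p for p in re.split(r"[,\s]+", text.strip().strip('"')) if p]
    if len(parts) != n:
        raise ConfigError(f"expected {n} comma-separated numbers, got {text!r}")
    return [float(p) for p in parts]


# ---------------------------------------------------------------------------
# scheme validation and output


def validate_scheme(
    scheme: PartitioningScheme, blocks: Sequence[DataBlock]
) -> list[str]:
    """Check that every data block appears in exactly one subset.

    Returns a list of violation messages; an empty list means the scheme is
    a valid set partition of the blocks.
    """
    violations: list[str] = []
    known = {b.name for b in blocks}
    counts: dict[str, int] = {name: 0 for name in known}
    for sub in scheme.subsets:
        for name in sub.blocks:
            if name not in known:
                violations.append(f"subset references unknown block {name!r}")
            else:
                counts[name] += 1
    for name, c in sorted(counts.items()):
        if c == 0:
            violations.append(f"block {name!r} missing from the scheme")
        elif c > 1:
            violations.append(f"block {name!r} appears in {c} subsets")
    return violations


def _sites_to_ranges(sites: Sequence[int]) -> list[tuple[int, int, int]]:
    """Greedily express a sorted site list as 1-based (start, end, stride)
    runs, preferring stride-1 runs and falling back to strided runs (codon
    notation) when the gap pattern is regular."""
    sites = list(sites)
    runs: list[tuple[int, int, int]] = []
    i = 0
    while i < len(sites):
        if i + 1 < len(sites):
            stride = sites[i + 1] - sites[i]
        else:
            stride = 1
        j = i + 1
        while j < len(sites) and sites[j] - sites[j - 1] == stride:
            j += 1
        runs.append((sites[i] + 1, sites[j - 1] + 1, stride))
        i = j
    return runs


def _format_ranges(sites: Sequence[int]) -> str:
    parts = []
    for start, end, stride in _sites_to_ranges(sites):
        if stride == 1:
            parts.append(f"{start}-{end}" if start != end else f"{start}-{end}")
        else:
            parts.append(f"{start}-{end}\\{stride}")
    return ", ".join(parts)


def write_scheme(
    scheme: PartitioningScheme,
    fits: Mapping | None = None,
    format: str = "raxml_partition",
) -> str:
    """Render a partitioning scheme as text.

    Formats: ``raxml_partition`` (one ``DNA, subsetK = ranges`` line per
    subset), ``nexus_sets`` (charset + charpartition block) and
    ``text_report`` (human-readable, optionally with per-subset fits keyed
    by subset in ``fits``). Subsets are ordered by smallest contained site.
    """
    subsets = scheme.sorted_subsets()
    if format == "raxml_partition":
        lines = [
            f"DNA, subset{k + 1} = {_format_ranges(sub.sites)}"
            for k, sub in enumerate(subsets)
        ]
        return "\n".join(lines) + "\n"
    if format == "nexus_sets":
        lines = ["#NEXUS", "begin sets;"]
        for k, sub in enumerate(subsets):
            ranges = _format_ranges(sub.sites).replace(",", "")
            lines.append(f"    charset subset{k + 1} = {ranges};")
        names = " ".join(
            f"subset{k + 1}:subset{k + 1}{',' if k < len(subsets) - 1 else ''}"
            for k in range(len(subsets))
        )
        lines.append(f"    charpartition scheme = {names};")
        lines.append("end;")
        return "\n".join(lines) + "\n"
    if format == "text_report":
        lines = [f"Scheme with {len(subsets)} subset(s)"]
        for k, sub in enumerate(subsets):
            lines.append(
                f"  subset{k + 1}: blocks [{', '.join(sorted(sub.blocks))}] "
                f"({sub.n_sites} sites) = {_format_ranges(sub.sites)}"
            )
            if fits is not None and sub in fits:
                f = fits[sub]
                lines.append(
                    f"    lnL={f.lnL:.4f} rate={f.rate_multiplier:.4f} "
                    f"alpha={f.gamma.alpha:.4f}"
                )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown scheme output format {format!r}")


def parse_raxml_partition(text: str) -> list[DataBlock]:
    """Parse a RAxML-style partition file back into data blocks (used for
    round-trip checks of :func:`write_scheme`)."""
    blocks = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if not line.upper().startswith("DNA,"):
            raise ConfigError(f"cannot parse partition line {line!r}")
        blocks.append(parse_block_spec(line.split(",", 1)[1]))
    return blocks
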