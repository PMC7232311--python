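"""Readers and writers for the external formats the pipeline touches.

Formats: FASTA (sequences), TSV count tables with sample metadata, Newick
trees with numeric internal-node support labels, TSV taxonomy maps, and the
YAML/JSON run configuration.

Conventions fixed here:

* residues are upper-cased and U is mapped to T on read; anything outside
  ``{A, C, G, T, N}`` is a hard error;
* bootstrap supports are read ONLY from internal node labels (RAxML-style
  Newick); a non-numeric internal label is a hard error;
* count tables are samples-as-rows by default (``orientation="samples"``);
* all-zero samples are retained with a logged warning — downstream
  rarefaction drops them explicitly, keeping the exclusion auditable.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACGTN")
VALID_BASINS = frozenset({"S", "C", "N"})
VALID_SITE_CLASSES = frozenset({"coastal", "deep"})

#: metadata columns expected in a count table, in canonical order
META_COLUMNS = ("basin", "site_class", "depth_m")


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One OTU or reference sequence.

    Parameters
    ----------
    id:
        Unique whitespace-free token.
    residues:
        Upper-case string over ``{A, C, G, T, N}``.
    role:
        ``"focal"`` (an OTU under study) or ``"reference"``.
    taxonomy:
        Optional ordered rank list, highest rank first.
    description:
        Free text carried through from the FASTA header.
    """

    id: str
    residues: str
    role: str = "focal"
    taxonomy: Optional[tuple[str, ...]] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"sequence id must be non-empty and whitespace-free: {self.id!r}")
        if len(self.residues) < 1:
            raise FormatError(f"sequence {self.id!r} has empty residues")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-IUPAC-DNA residues {sorted(bad)!r}"
            )
        if self.role not in ("focal", "reference"):
            raise FormatError(f"sequence {self.id!r}: unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> str:
    """Upper-case and map U->T. Validation happens in SequenceRecord."""
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path, role: str = "focal") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Residues are normalized (upper-case, U->T); duplicate ids, empty files
    and non-IUPAC residues are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r} (record {i + 1})")
        seen.add(rec.id)
        residues = normalize_residues(str(rec.seq))
        bad = set(residues) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} (record {i + 1}) has invalid residues {sorted(bad)!r}"
            )
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, residues=residues, role=role, description=desc))
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 80) -> None:
    """Write records as wrapped FASTA."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_taxonomy(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a two-column TSV mapping sequence id -> semicolon-joined ranks."""
    taxa: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sid, ranks = parts
            if sid in taxa:
                raise FormatError(f"{path}:{lineno}: duplicate id {sid!r}")
            taxa[sid] = tuple(r.strip() for r in ranks.split(";") if r.strip())
    return taxa


def write_taxonomy(taxa: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in taxa:
            fh.write(f"{sid}\t{';'.join(taxa[sid])}\n")


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

@dataclass
class CommunityMatrix:
    """Non-negative integer sample x OTU read counts with sample metadata.

    ``counts[i, j]`` is the read count of OTU ``otu_ids[j]`` in sample
    ``sample_ids[i]``. ``sample_meta`` is a DataFrame indexed by sample id
    with columns ``basin`` (S/C/N), ``site_class`` (coastal/deep) and
    ``depth_m``.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at sample {self.sample_ids[i]!r}, OTU {self.otu_ids[j]!r}"
            )
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise FormatError("duplicate OTU ids in count table")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in count table")
        bad_basin = set(self.sample_meta["basin"]) - VALID_BASINS
        if bad_basin:
            raise FormatError(f"unknown basin code(s) {sorted(bad_basin)!r}")
        zero = [s for s, t in zip(self.sample_ids, self.sample_totals()) if t == 0]
        if zero:
            logger.warning("count table contains all-zero sample(s): %s", ", ".join(zero))

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def otu_total(self, otu_id: str) -> int:
        return int(self.counts[:, self.otu_ids.index(otu_id)].sum())

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


def read_count_table(path: str | Path, orientation: str = "samples") -> CommunityMatrix:
    """Read a TSV count table with metadata columns basin/site_class/depth_m.

    ``orientation="samples"`` (default) expects one row per sample; with
    ``orientation="otus"`` the count block is transposed on read (metadata
    rows are then keyed by the reserved row ids ``basin``, ``site_class``,
    ``depth_m``).
    """
    if orientation not in ("samples", "otus"):
        raise ValueError(f"orientation must be 'samples' or 'otus', got {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if orientation == "otus":
        df = df.T
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s) {missing}")
    meta = df[list(META_COLUMNS)].copy()
    meta["depth_m"] = meta["depth_m"].astype(float)
    block = df.drop(columns=list(META_COLUMNS))
    counts = np.empty(block.shape, dtype=np.int64)
    for i, sid in enumerate(block.index):
        for j, oid in enumerate(block.columns):
            cell = block.iat[i, j]
            try:
                val = int(cell)
                if float(cell) != val:
                    raise ValueError
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {cell!r} at sample {sid!r}, OTU {oid!r}"
                ) from None
            if val < 0:
                raise FormatError(
                    f"{path}: negative count {val} at sample {sid!r}, OTU {oid!r}"
                )
            counts[i, j] = val
    return CommunityMatrix(
        sample_ids=list(block.index),
        otu_ids=list(block.columns),
        counts=counts,
        sample_meta=meta,
    )


def write_count_table(matrix: CommunityMatrix, path: str | Path) -> None:
    """Write a samples-as-rows TSV with leading metadata columns."""
    df = matrix.sample_meta.copy()
    df.index = matrix.sample_ids
    for j, oid in enumerate(matrix.otu_ids):
        df[oid] = matrix.counts[:, j]
    df.index.name = "sample_id"
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A node of a rooted support tree. Tips carry ``label``; internal nodes
    may carry a bootstrap ``support`` in [0, 100]."""

    children: list["TreeNode"] = field(default_factory=list)
    label: Optional[str] = None
    support: Optional[float] = None
    length: Optional[float] = None
    parent: Optional["TreeNode"] = field(default=None, repr=False, compare=False)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.postorder() if n.is_tip]


class SupportTree:
    """Rooted tree whose tips are sequence ids and whose internal nodes may
    carry bootstrap supports in [0, 100]."""

    def __init__(self, root: TreeNode):
        self.root = root
        root.parent = None
        for node in root.postorder():
            for child in node.children:
                child.parent = node
        labels = root.tip_labels()
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise FormatError(f"duplicate tip label(s) in tree: {dup}")
        self._tips = {n.label: n for n in root.postorder() if n.is_tip}
        for node in root.postorder():
            if node.support is not None and not (0 <= node.support <= 100):
                raise FormatError(f"support {node.support} outside [0, 100]")

    @property
    def tip_ids(self) -> set[str]:
        return set(self._tips)

    def tip(self, label: str) -> TreeNode:
        return self._tips[label]

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def internal_nodes(self, include_root: bool = False) -> list[TreeNode]:
        nodes = [n for n in self.root.postorder() if not n.is_tip]
        if not include_root:
            nodes = [n for n in nodes if n is not self.root]
        return nodes

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_tip:
                s = node.label
            else:
                s = "(" + ",".join(render(c) for c in node.children) + ")"
                if node.support is not None:
                    s += format(node.support, "g")
            if node.length is not None:
                s += f":{node.length:g}"
            return s

        return render(self.root) + ";"


def _from_dendropy(dnode: dendropy.Node) -> TreeNode:
    node = TreeNode()
    if dnode.is_leaf():
        if dnode.taxon is not None:
            node.label = dnode.taxon.label.replace(" ", "_")
        else:
            node.label = dnode.label
        if node.label is None:
            raise FormatError("tree contains an unlabeled tip")
    else:
        raw = dnode.label
        if raw is not None:
            try:
                node.support = float(raw)
            except ValueError:
                raise FormatError(
                    f"non-numeric internal node label {raw!r}; internal labels "
                    "must be bootstrap supports"
                ) from None
    node.length = dnode.edge.length
    for child in dnode.child_nodes():
        node.children.append(_from_dendropy(child))
    return node


def parse_newick(newick: str) -> SupportTree:
    """Parse a Newick string with RAxML-style numeric internal labels."""
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"malformed Newick: {exc}") from exc
    return SupportTree(_from_dendropy(dtree.seed_node))


def read_newick(path: str | Path) -> SupportTree:
    """Read a Newick file; internal node labels are bootstrap supports."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text().strip()
    if not text:
        raise FormatError(f"{path}: empty Newick file")
    return parse_newick(text)


def write_newick(tree: SupportTree, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths, thresholds and the master seed for a full pipeline run.

    Threshold fields mirror the defaults of
    :class:`~otuflock.reference_match.HitFilter`,
    :class:`~otuflock.reference_match.ClassifyParams` and
    :class:`~otuflock.flock_detection.FlockParams`.
    """

    focal_fasta: Optional[str] = None
    reference_fasta: Optional[str] = None
    taxonomy_tsv: Optional[str] = None
    count_table: Optional[str] = None
    tree_newick: Optional[str] = None
    out_dir: str = "otuflock_out"
    seed: int = 0
    count_orientation: str = "samples"
    # hit filter
    min_coverage: float = 0.70
    min_aligned_length: int = 200
    max_evalue: Optional[float] = None
    # divergence bands
    similar_max_divergence: float = 0.01
    unclear_max_divergence: float = 0.10
    type2_identity_ceiling: float = 0.90
    band_lo: float = 0.80
    abundant_min_fraction: float = 0.01
    rare_max_fraction: float = 0.0001
    # flock criteria
    min_support: float = 60.0
    min_focal: int = 3
    max_mean_divergence: float = 0.03
    max_abundance_ratio: float = 100.0
    min_abundance_set: int = 3
    require_dominant_in_set: bool = True
    # community stats
    rarefaction_depth: str | int = "min"
    # when no tree is supplied, build an NJ+bootstrap fixture tree from the
    # (gap-free, equal-length) focal + reference sequences
    build_tree_if_missing: bool = False
    bootstrap_reps: int = 100

    def __post_init__(self) -> None:
        for name in ("similar_max_divergence", "unclear_max_divergence",
                     "type2_identity_ceiling", "band_lo", "min_coverage"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise FormatError(f"config threshold {name}={v} outside (0, 1)")
        if not (0 < self.min_support <= 100):
            raise FormatError(f"min_support={self.min_support} outside (0, 100]")
        if not (0 < self.similar_max_divergence < self.unclear_max_divergence < 1):
            raise FormatError("require 0 < similar_max_divergence < unclear_max_divergence < 1")
        if not self.band_lo < self.type2_identity_ceiling:
            raise FormatError("band_lo must lie below type2_identity_ceiling")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}
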