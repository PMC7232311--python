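"""Pairwise alignment, nearest-reference search, and divergence-band classifiers.

The aligner is a deterministic semi-global (free end-gap) Needleman-Wunsch
surrogate for a local BLAST search: all inputs are the same amplicon, so an
end-gap-free global alignment of the overlapping span is the standard
replacement and removes seed-heuristic nondeterminism.

Identity convention (fixed for reproducibility): the denominator is the
number of alignment columns inside the aligned core (end-gap overhangs
trimmed) where not both sequences are gaps; ``N`` never counts as a match.
Divergence is ``1 - identity``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import SequenceRecord

#: The relative costs are tuned for same-amplicon comparisons: end gaps are
#: near-free (semi-global) but not exactly free, and a mismatch is cheaper
#: than twice an end-gap column, so terminal substitutions stay aligned
#: instead of sliding into the overhang; an internal single-base indel
#: (cost 2) is preferred over sacrificing 3+ matches.
DEFAULT_SCORING = {
    "match": 1.0,
    "mismatch": -0.5,
    "gap_open": -1.0,
    "gap_extend": -1.0,
    "end_gap": -0.5,
}

#: distribution statuses, in increasing divergence order
STATUS_SIMILAR = "similar"
STATUS_UNCLEAR = "unclear"
STATUS_POTENTIAL_ENDEMIC = "potential_endemic"

ABUNDANT = "abundant"
INTERMEDIATE = "intermediate"
RARE = "rare"


@dataclass(frozen=True)
class PairwiseAlignment:
    """A semi-global pairwise alignment and its derived quantities.

    ``gapped_query``/``gapped_subject`` cover the full alignment including
    end-gap overhangs; ``matches``/``aligned_columns`` are computed on the
    trimmed core only (columns between the first and last position where
    both sequences carry a residue).
    """

    gapped_query: str
    gapped_subject: str
    matches: int
    aligned_columns: int
    query_coverage: float
    subject_coverage: float

    def __post_init__(self) -> None:
        if len(self.gapped_query) != len(self.gapped_subject):
            raise ValueError("gapped strings must have equal length")
        if self.matches > self.aligned_columns:
            raise ValueError("matches cannot exceed aligned columns")

    @property
    def identity(self) -> float:
        if self.aligned_columns == 0:
            return 0.0
        return self.matches / self.aligned_columns

    @property
    def divergence(self) -> float:
        return 1.0 - self.identity


@dataclass(frozen=True)
class ReferenceHit:
    """Best-scoring alignment of a query OTU against one reference."""

    query_id: str
    reference_id: str
    identity: float
    aligned_length: int
    coverage: float
    passed_filters: bool


@dataclass(frozen=True)
class HitFilter:
    """Acceptance thresholds for reference hits.

    ``max_evalue`` is None by default: e-value statistics are meaningless
    against small internal reference sets; supply a value only when hits
    carry e-values from an external search.
    """

    min_coverage: float = 0.70
    min_aligned_length: int = 200
    max_evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_coverage <= 0 or self.min_aligned_length <= 0:
            raise ValueError("filter thresholds must be positive")

    def passes(self, identity: float, aligned_length: int, coverage: float,
               evalue: Optional[float] = None) -> bool:
        if coverage <= self.min_coverage:
            return False
        if aligned_length < self.min_aligned_length:
            return False
        if self.max_evalue is not None:
            if evalue is None or evalue >= self.max_evalue:
                return False
        return True


@dataclass(frozen=True)
class ClassifyParams:
    """Divergence-band and abundance-class thresholds."""

    similar_max_divergence: float = 0.01
    unclear_max_divergence: float = 0.10
    type2_identity_ceiling: float = 0.90
    band_lo: float = 0.80
    abundant_min_fraction: float = 0.01
    rare_max_fraction: float = 0.0001

    def __post_init__(self) -> None:
        if not (0 < self.similar_max_divergence < self.unclear_max_divergence < 1):
            raise ValueError("require 0 < similar_max < unclear_max < 1")
        if not self.band_lo < self.type2_identity_ceiling:
            raise ValueError("band_lo must be below type2_identity_ceiling")


@functools.lru_cache(maxsize=8)
def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float,
                  end_gap: float) -> Align.PairwiseAligner:
    # N scores as a mismatch against everything, including itself
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == b and a != "N":
                mat[a, b] = match
            else:
                mat[a, b] = mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_internal_gap_score = gap_open + gap_extend
    aligner.extend_internal_gap_score = gap_extend
    # near-free end gaps: semi-global overlap alignment
    aligner.open_end_gap_score = end_gap
    aligner.extend_end_gap_score = end_gap
    return aligner


def align_pair(query: SequenceRecord | str, subject: SequenceRecord | str,
               scoring: Optional[Mapping[str, float]] = None) -> PairwiseAlignment:
    """Optimal semi-global alignment of two sequences.

    Ties between equal-score alignments are broken deterministically by the
    aligner's fixed traceback order (gaps placed leftmost-first).
    """
    q = query.residues if isinstance(query, SequenceRecord) else query
    s = subject.residues if isinstance(subject, SequenceRecord) else subject
    if not q or not s:
        raise ValueError("cannot align empty sequences")
    params = dict(DEFAULT_SCORING)
    if scoring:
        params.update(scoring)
    aligner = _make_aligner(params["match"], params["mismatch"],
                            params["gap_open"], params["gap_extend"],
                            params["end_gap"])
    aln = aligner.align(q, s)[0]
    gq, gs = str(aln[0]), str(aln[1])
    return _from_gapped(gq, gs, len(q), len(s))


def _from_gapped(gq: str, gs: str, qlen: int, slen: int) -> PairwiseAlignment:
    a = np.frombuffer(gq.encode(), dtype="S1")
    b = np.frombuffer(gs.encode(), dtype="S1")
    gap = np.bytes_(b"-")
    both = (a != gap) & (b != gap)
    if not both.any():
        return PairwiseAlignment(gq, gs, 0, 0, 0.0, 0.0)
    lo, hi = np.argmax(both), len(both) - np.argmax(both[::-1]) - 1
    core = slice(lo, hi + 1)
    ca, cb = a[core], b[core]
    not_both_gap = ~((ca == gap) & (cb == gap))
    n_col = int(not_both_gap.sum())
    is_n = (ca == np.bytes_(b"N")) | (cb == np.bytes_(b"N"))
    matches = int(((ca == cb) & ~is_n & (ca != gap)).sum())
    qcov = int((ca != gap).sum()) / qlen
    scov = int((cb != gap).sum()) / slen
    return PairwiseAlignment(gq, gs, matches, n_col, qcov, scov)


def percent_identity(alignment: PairwiseAlignment) -> float:
    """Fraction of matching columns over the aligned core."""
    return alignment.identity


def pairwise_divergence(a: SequenceRecord | str, b: SequenceRecord | str,
                        scoring: Optional[Mapping[str, float]] = None) -> float:
    """1 - identity of the optimal pairwise alignment."""
    return align_pair(a, b, scoring).divergence


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites between equal-length gap-free sequences."""
    if len(a) != len(b):
        raise ValueError("p_distance requires equal-length sequences")
    x = np.frombuffer(a.encode(), dtype="S1")
    y = np.frombuffer(b.encode(), dtype="S1")
    return float((x != y).mean())


def best_reference_hit(query: SequenceRecord,
                       references: Sequence[SequenceRecord],
                       hit_filter: HitFilter = HitFilter(),
                       scoring: Optional[Mapping[str, float]] = None,
                       evalues: Optional[Mapping[str, float]] = None) -> Optional[ReferenceHit]:
    """Highest-identity reference hit passing the filter, or None.

    Ties are broken by longer aligned length, then lexicographically smaller
    reference id. ``evalues`` optionally maps reference id -> e-value from an
    external search (used only when the filter carries ``max_evalue``).
    """
    if not references:
        raise ValueError("reference set is empty")
    best: Optional[ReferenceHit] = None
    for ref in references:
        aln = align_pair(query, ref, scoring)
        ev = evalues.get(ref.id) if evalues else None
        hit = ReferenceHit(
            query_id=query.id,
            reference_id=ref.id,
            identity=aln.identity,
            aligned_length=aln.aligned_columns,
            coverage=aln.query_coverage,
            passed_filters=hit_filter.passes(aln.identity, aln.aligned_columns,
                                             aln.query_coverage, ev),
        )
        if not hit.passed_filters:
            continue
        if best is None or _hit_key(hit) > _hit_key(best):
            best = hit
    return best


def _hit_key(hit: ReferenceHit) -> tuple:
    # larger is better; reference_id inverted for lexicographic-smallest wins
    return (hit.identity, hit.aligned_length, _neg_str(hit.reference_id))


class _neg_str(str):
    """Reverses string ordering so max() prefers lexicographically smaller ids."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def classify_distribution_status(divergence: float,
                                 params: ClassifyParams = ClassifyParams()) -> str:
    """Band a divergence into similar / unclear / potential_endemic.

    ``d <= similar_max`` -> similar; ``similar_max < d <= unclear_max`` ->
    unclear; ``d > unclear_max`` -> potential_endemic (both thresholds
    inclusive on the low side).
    """
    if not (0 <= divergence <= 1):
        raise ValueError(f"divergence {divergence} outside [0, 1]")
    if divergence <= params.similar_max_divergence:
        return STATUS_SIMILAR
    if divergence <= params.unclear_max_divergence:
        return STATUS_UNCLEAR
    return STATUS_POTENTIAL_ENDEMIC


def in_band_80_90(identity: float, params: ClassifyParams = ClassifyParams()) -> bool:
    """True iff identity lies in [band_lo, type2_ceiling), default [0.80, 0.90).

    Half-open at the top so band membership is consistent with the strict
    <90% ceiling used for Type 2 endemism.
    """
    return params.band_lo <= identity < params.type2_identity_ceiling


def classify_abundance(otu_reads: int, total_reads: int,
                       params: ClassifyParams = ClassifyParams()) -> str:
    """Class by dataset-wide read fraction: >1% abundant, <0.01% rare,
    otherwise intermediate (boundaries fall to intermediate)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if otu_reads < 0:
        raise ValueError("otu_reads must be non-negative")
    frac = otu_reads / total_reads
    if frac > params.abundant_min_fraction:
        return ABUNDANT
    if frac < params.rare_max_fraction:
        return RARE
    return INTERMEDIATE


class DivergenceCache:
    """Lazily computed, cached pairwise divergences between named sequences."""

    def __init__(self, records: Iterable[SequenceRecord],
                 scoring: Optional[Mapping[str, float]] = None):
        self._seqs = {r.id: r.residues for r in records}
        self._scoring = scoring
        self._cache: dict[frozenset, float] = {}

    def __call__(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        key = frozenset((a, b))
        if key not in self._cache:
            sa, sb = self._seqs[a], self._seqs[b]
            if len(sa) == len(sb):
                # equal-length amplicons are compared site-by-site: identical
                # to the aligner on indel-free pairs and immune to overlap
                # shrinkage on very divergent ones
                d = p_distance(sa, sb)
            else:
                d = pairwise_divergence(sa, sb, self._scoring)
            self._cache[key] = d
        return self._cache[key]
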