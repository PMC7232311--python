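"""Classify candidate clades into species flocks, divergent clades, or
intragenomic-variation candidates, and type each OTU's endemism.

A candidate clade (support strictly > 60, >= 3 focal OTUs) is labeled:

* ``intragenomic_candidate`` — the abundance-compatibility rule fails: no
  set of >= 3 member OTUs whose read counts differ by < 100x and that
  contains the clade's most abundant OTU (the dominant-plus-trace pattern of
  divergent rRNA gene copies within one genome);
* ``flock`` — abundance passes and mean pairwise divergence among focal
  members is < 3%;
* ``divergent_clade`` — abundance passes but divergence is >= 3%;
* ``rejected`` — the clade is suppressed (nested inside an accepted flock or
  intragenomic clade) or degenerate (fewer than 2 focal members with reads).

Nested handling: flock-labeled clades are collapsed to maximal ones so a
radiation is counted once, and every candidate nested inside an accepted
flock or intragenomic clade is rejected (sub-structure of a variant cloud
must not resurface as a flock). Candidates nested inside a divergent clade
are kept: a tight radiation inside a loosely supported backbone clade is
still a flock.

Endemism typing precedence is Type 1 > Type 2 > Type 3: flock membership
wins; otherwise identity < 90% to the best passing reference hit (or no
passing hit) gives Type 2; otherwise an OTU with no supported
reference-containing ancestor clade is Type 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .io_formats import SupportTree
from .reference_match import ReferenceHit
from .tree_ops import CandidateClade, focal_clades, smallest_supported_clade_with_reference

LABEL_FLOCK = "flock"
LABEL_DIVERGENT = "divergent_clade"
LABEL_INTRAGENOMIC = "intragenomic_candidate"
LABEL_REJECTED = "rejected"

TYPE1 = "type1_flock"
TYPE2 = "type2_divergent"
TYPE3 = "type3_unplaced"
TYPE_NONE = "none"


@dataclass(frozen=True)
class FlockParams:
    """Thresholds of the flock criteria."""

    min_support: float = 60.0
    min_focal: int = 3
    max_mean_divergence: float = 0.03
    max_abundance_ratio: float = 100.0
    min_abundance_set: int = 3
    require_dominant_in_set: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.max_mean_divergence < 1):
            raise ValueError("max_mean_divergence must lie in (0, 1)")
        if self.max_abundance_ratio <= 1:
            raise ValueError("max_abundance_ratio must exceed 1")
        if self.min_focal < 3:
            raise ValueError("a flock needs at least 3 members")


@dataclass(frozen=True)
class AbundanceResult:
    passes: bool
    compatible_set: frozenset


@dataclass
class FlockCall:
    """One classified candidate clade with its evidence trail."""

    clade: CandidateClade
    label: str
    mean_pairwise_divergence: Optional[float]
    abundance_set: frozenset = frozenset()
    evidence: str = ""

    @property
    def member_ids(self) -> frozenset:
        return self.clade.focal_tip_ids


@dataclass(frozen=True)
class EndemismCall:
    otu_id: str
    type: str
    evidence: str = ""


DistanceSource = Callable[[str, str], float]


def mean_pairwise_divergence(focal_ids: Iterable[str],
                             distances: DistanceSource) -> float:
    """Arithmetic mean of pairwise divergences over all unordered focal pairs.

    Only focal OTUs enter the mean; non-focal tips inside the clade are the
    caller's responsibility to exclude.
    """
    ids = sorted(set(focal_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 focal ids for a pairwise mean")
    total, n = 0.0, 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            total += distances(ids[i], ids[j])
            n += 1
    return total / n


def abundance_compatible(total_reads: Mapping[str, int],
                         params: FlockParams = FlockParams()) -> AbundanceResult:
    """Largest set of OTUs whose read counts differ by < max_abundance_ratio.

    With ``require_dominant_in_set`` (default) the set must contain the
    clade's most abundant OTU, so a dominant-plus-trace clade fails even when
    the trace OTUs are mutually comparable. Passes iff the set has at least
    ``min_abundance_set`` members. Zero-read OTUs must be excluded upstream.
    """
    if not total_reads:
        raise ValueError("no read counts supplied")
    if any(v < 1 for v in total_reads.values()):
        bad = [k for k, v in total_reads.items() if v < 1]
        raise ValueError(f"read counts must be >= 1 (zero-read OTUs excluded upstream): {bad}")
    items = sorted(total_reads.items(), key=lambda kv: (-kv[1], kv[0]))
    reads = [v for _, v in items]
    if params.require_dominant_in_set:
        # any valid set containing the maximum is {x : max/x < ratio}; all its
        # members are pairwise compatible because max bounds every ratio
        dominant = reads[0]
        chosen = frozenset(k for k, v in items if dominant / v < params.max_abundance_ratio)
    else:
        # ratio-compatible sets are contiguous windows in sorted order
        best: list[tuple[str, int]] = []
        lo = 0
        for hi in range(len(items)):
            while items[lo][1] / items[hi][1] >= params.max_abundance_ratio:
                lo += 1
            if hi - lo + 1 > len(best):
                best = items[lo:hi + 1]
        chosen = frozenset(k for k, _ in best)
    return AbundanceResult(passes=len(chosen) >= params.min_abundance_set,
                           compatible_set=chosen)


def classify_clade(clade: CandidateClade, divergence: Optional[float],
                   abundance: AbundanceResult,
                   params: FlockParams = FlockParams()) -> FlockCall:
    """Label one candidate clade from its divergence and abundance evidence."""
    if not abundance.passes:
        return FlockCall(clade, LABEL_INTRAGENOMIC, divergence, abundance.compatible_set,
                         evidence=f"abundance rule failed: compatible set size "
                                  f"{len(abundance.compatible_set)} < {params.min_abundance_set}")
    if divergence is None:
        return FlockCall(clade, LABEL_REJECTED, None, abundance.compatible_set,
                         evidence="fewer than 2 focal members with reads")
    if divergence < params.max_mean_divergence:
        return FlockCall(clade, LABEL_FLOCK, divergence, abundance.compatible_set,
                         evidence=f"mean divergence {divergence:.4f} < {params.max_mean_divergence}")
    return FlockCall(clade, LABEL_DIVERGENT, divergence, abundance.compatible_set,
                     evidence=f"mean divergence {divergence:.4f} >= {params.max_mean_divergence}")


def detect_flocks(tree: SupportTree, focal_ids: Iterable[str],
                  distances: DistanceSource,
                  total_reads: Mapping[str, int],
                  params: FlockParams = FlockParams()) -> list[FlockCall]:
    """Classify every candidate clade of the tree.

    Every candidate receives exactly one FlockCall; suppressed (nested)
    candidates are labeled ``rejected`` with the container recorded in their
    evidence. Calls are ordered by clade size descending, then first tip id.
    """
    focal = frozenset(focal_ids)
    candidates = focal_clades(tree, focal, params.min_support, params.min_focal)
    candidates.sort(key=lambda c: (-len(c.tip_ids), min(c.tip_ids)))

    provisional: list[FlockCall] = []
    for cand in candidates:
        with_reads = {o: int(total_reads.get(o, 0)) for o in cand.focal_tip_ids}
        with_reads = {o: r for o, r in with_reads.items() if r > 0}
        if len(with_reads) < 2:
            provisional.append(FlockCall(cand, LABEL_REJECTED, None,
                                         evidence="fewer than 2 focal members with reads"))
            continue
        div = mean_pairwise_divergence(with_reads, distances)
        abund = abundance_compatible(with_reads, params)
        provisional.append(classify_clade(cand, div, abund, params))

    # suppression pass: largest-first; flocks and intragenomic clades absorb
    # everything nested inside them, divergent clades do not
    accepted_blockers: list[FlockCall] = []
    final: list[FlockCall] = []
    for call in provisional:
        container = next((b for b in accepted_blockers
                          if call.clade.tip_ids < b.clade.tip_ids), None)
        if container is not None:
            final.append(FlockCall(call.clade, LABEL_REJECTED,
                                   call.mean_pairwise_divergence, call.abundance_set,
                                   evidence=f"nested inside {container.label} clade "
                                            f"({min(container.clade.tip_ids)}...)"))
            continue
        final.append(call)
        if call.label in (LABEL_FLOCK, LABEL_INTRAGENOMIC):
            accepted_blockers.append(call)
    return final


def type_endemism(otu_id: str, flock_calls: Sequence[FlockCall],
                  best_hit: Optional[ReferenceHit], tree: SupportTree,
                  reference_ids: Iterable[str],
                  min_support: float = 60.0,
                  type2_identity_ceiling: float = 0.90) -> EndemismCall:
    """Assign the endemism type of one OTU (precedence Type 1 > 2 > 3)."""
    for call in flock_calls:
        if call.label == LABEL_FLOCK and otu_id in call.member_ids:
            return EndemismCall(otu_id, TYPE1,
                                evidence=f"member of flock clade ({min(call.clade.tip_ids)}...)")
    if best_hit is None or not best_hit.passed_filters:
        return EndemismCall(otu_id, TYPE2, evidence="no passing reference hit")
    if best_hit.identity < type2_identity_ceiling:
        return EndemismCall(
            otu_id, TYPE2,
            evidence=f"best hit {best_hit.reference_id} identity {best_hit.identity:.4f} < "
                     f"{type2_identity_ceiling}")
    placement = smallest_supported_clade_with_reference(tree, otu_id, reference_ids, min_support)
    if placement is None:
        return EndemismCall(otu_id, TYPE3,
                            evidence="no supported ancestor clade containing a reference")
    return EndemismCall(otu_id, TYPE_NONE,
                        evidence=f"placed with support {placement.support:g}")
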