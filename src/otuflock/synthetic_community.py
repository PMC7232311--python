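"""Synthetic post-clustering datasets with planted ground truth.

Generates OTU representative sequences, a reference set, and a sample x OTU
count table whose statistical structure matches what the downstream analysis
assumes: star-radiation "flocks" at a controlled mean pairwise divergence,
planted endemics at > 10% distance from every reference, dominant-plus-
satellite intragenomic variant clouds (trace-abundance satellites at 95-99%
identity), and lognormal background abundances with per-sample Dirichlet
perturbation grouped by sampling depth.

Sequences carry no indels, so planted p-distances and alignment identities
coincide exactly and every generator contract is assertable without
tolerance inflation. All randomness flows from one seed; identical config +
seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CommunityMatrix,
    SequenceRecord,
    write_count_table,
    write_fasta,
)
from .reference_match import p_distance

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class InfeasibleConfigError(ValueError):
    """The generator cannot satisfy the planted-truth contracts."""


# ---------------------------------------------------------------------------
# Config and truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlockSpec:
    n_tips: int
    target_divergence: float


@dataclass(frozen=True)
class CloudSpec:
    n_satellites: int
    identity_range: tuple[float, float] = (0.95, 0.99)
    dominant_reads: int = 30000
    satellite_read_cap: int = 100


@dataclass(frozen=True)
class EndemicSpec:
    n: int
    distance_range: tuple[float, float] = (0.12, 0.20)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic dataset generator.

    ``depth_range`` defaults to the per-sample read-depth range of a deeply
    sequenced V4 survey; tests override it downward for speed.
    """

    n_references: int = 6
    n_background_otus: int = 12
    flocks: list[FlockSpec] = field(default_factory=list)
    clouds: list[CloudSpec] = field(default_factory=list)
    endemic_otus: EndemicSpec = field(default_factory=lambda: EndemicSpec(n=0))
    n_samples: int = 4
    depth_range: tuple[int, int] = (47195, 142260)
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    seed: int = 0
    seq_length: int = 380
    background_distance_range: tuple[float, float] = (0.01, 0.08)
    flock_anchor_distance: float = 0.18
    cloud_anchor_distance: float = 0.05
    flock_abundance_boost: float = 2.0
    group_concentration: float = 400.0
    sample_concentration_deep: float = 2000.0
    sample_concentration_surface: float = 500.0

    def __post_init__(self) -> None:
        if self.n_references < 1:
            raise InfeasibleConfigError("need at least one reference")
        if self.depth_range[0] < 1 or self.depth_range[0] > self.depth_range[1]:
            raise InfeasibleConfigError(f"bad depth_range {self.depth_range}")
        for f in self.flocks:
            if not (0 < f.target_divergence < 0.5):
                raise InfeasibleConfigError(
                    f"flock target divergence {f.target_divergence} outside (0, 0.5)")
            if f.n_tips < 3:
                raise InfeasibleConfigError("flocks need >= 3 tips")
        lo, hi = self.endemic_otus.distance_range
        if self.endemic_otus.n > 0 and lo <= 0.10:
            raise InfeasibleConfigError(
                "endemic distance_range overlaps the 0.10 reference radius")
        if self.endemic_otus.n > 0 and not (lo <= hi < 0.5):
            raise InfeasibleConfigError(f"bad endemic distance_range {(lo, hi)}")
        blo, bhi = self.background_distance_range
        if not (0 < blo <= bhi <= 0.10):
            raise InfeasibleConfigError(
                "background OTUs must stay within 0.10 of their reference")


@dataclass
class SyntheticTruth:
    """Planted labels: who belongs to which flock/cloud, who is endemic."""

    flock_ids: dict[str, str] = field(default_factory=dict)        # otu -> flock id
    cloud_ids: dict[str, str] = field(default_factory=dict)        # otu -> cloud id
    dominants: set[str] = field(default_factory=set)               # dominant per cloud
    endemics: set[str] = field(default_factory=set)
    flock_target_divergence: dict[str, float] = field(default_factory=dict)
    cloud_identity_range: dict[str, tuple[float, float]] = field(default_factory=dict)

    def members_of_flock(self, flock_id: str) -> set[str]:
        return {o for o, f in self.flock_ids.items() if f == flock_id}

    def members_of_cloud(self, cloud_id: str) -> set[str]:
        return {o for o, c in self.cloud_ids.items() if c == cloud_id}

    def validate(self, otu_ids: Sequence[str]) -> None:
        known = set(otu_ids)
        for pool in (self.flock_ids, self.cloud_ids):
            unknown = set(pool) - known
            if unknown:
                raise ValueError(f"truth labels reference unknown OTUs: {sorted(unknown)}")
        for fid in set(self.flock_ids.values()):
            if len(self.members_of_flock(fid)) < 3:
                raise ValueError(f"flock {fid} has fewer than 3 members")
        for cid in set(self.cloud_ids.values()):
            doms = self.members_of_cloud(cid) & self.dominants
            if len(doms) != 1:
                raise ValueError(f"cloud {cid} must have exactly one dominant")

    def to_json(self) -> str:
        payload = {
            "flock_ids": self.flock_ids,
            "cloud_ids": self.cloud_ids,
            "dominants": sorted(self.dominants),
            "endemics": sorted(self.endemics),
            "flock_target_divergence": self.flock_target_divergence,
            "cloud_identity_range": {k: list(v) for k, v in self.cloud_identity_range.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            flock_ids=d["flock_ids"],
            cloud_ids=d["cloud_ids"],
            dominants=set(d["dominants"]),
            endemics=set(d["endemics"]),
            flock_target_divergence=d["flock_target_divergence"],
            cloud_identity_range={k: tuple(v) for k, v in d["cloud_identity_range"].items()},
        )


@dataclass
class SyntheticDataset:
    focal_records: list[SequenceRecord]
    reference_records: list[SequenceRecord]
    matrix: CommunityMatrix
    truth: SyntheticTruth

    @property
    def alignment_records(self) -> list[SequenceRecord]:
        """Gap-free equal-length pseudo-alignment of focal + reference sequences."""
        return self.focal_records + self.reference_records


# ---------------------------------------------------------------------------
# Sequence-level primitives
# ---------------------------------------------------------------------------

def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def evolve_sequence(ancestor: str, substitutions: int,
                    seed: int | np.random.Generator = 0) -> str:
    """Mutate exactly ``substitutions`` distinct positions, each to a
    different base, so p-distance(ancestor, result) = substitutions / length."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(ancestor)
    if substitutions > L:
        raise ValueError(f"cannot place {substitutions} substitutions in length {L}")
    if substitutions < 0:
        raise ValueError("substitutions must be non-negative")
    arr = np.frombuffer(ancestor.encode(), dtype="S1").copy()
    positions = rng.choice(L, size=substitutions, replace=False)
    for pos in positions:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode()


def plant_flock(ancestor: str, n_tips: int, target_divergence: float,
                seed: int | np.random.Generator = 0) -> list[str]:
    """Star radiation: each tip receives ~target/2 * length substitutions from
    the ancestor, so the mean pairwise p-distance lands near the target.

    Tips are guaranteed mutually distinct; the realized mean pairwise
    divergence is within +-20% relative of the target (asserted).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_tips < 3:
        raise ValueError("flocks need at least 3 tips")
    L = len(ancestor)
    k = round(target_divergence * L / 2)
    if k < 1:
        raise ValueError(
            f"target divergence {target_divergence} too small for length {L}: tips "
            "must be mutually distinct")
    tips: list[str] = []
    for _ in range(n_tips):
        for _attempt in range(50):
            tip = evolve_sequence(ancestor, k, rng)
            if tip not in tips:
                tips.append(tip)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not generate a distinct flock tip")
    realized = _mean_pairwise(tips)
    if not (0.8 * target_divergence <= realized <= 1.2 * target_divergence):
        # collisions only shrink the realized divergence; retry deterministically
        return plant_flock(ancestor, n_tips, target_divergence, rng)
    return tips


def _mean_pairwise(seqs: Sequence[str]) -> float:
    total, n = 0.0, 0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            total += p_distance(seqs[i], seqs[j])
            n += 1
    return total / n


@dataclass
class Cloud:
    """A dominant sequence plus trace-abundance satellite variants."""

    dominant_seq: str
    satellite_seqs: list[str]
    dominant_reads: int
    satellite_reads: list[int]
    identity_range: tuple[float, float]


def plant_cloud(dominant: str, n_satellites: int,
                identity_range: tuple[float, float] = (0.95, 0.99),
                dominant_reads: int = 30000, satellite_read_cap: int = 100,
                seed: int | np.random.Generator = 0,
                satellite_reads: Optional[Sequence[int]] = None) -> Cloud:
    """Satellites at identity within ``identity_range`` of the dominant, each
    with fewer than ``satellite_read_cap`` reads."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = identity_range
    if not (0 < lo <= hi < 1):
        raise ValueError(f"identity_range {identity_range} must satisfy 0 < lo <= hi < 1")
    L = len(dominant)
    kmin = max(1, math.ceil((1 - hi) * L))
    kmax = math.floor((1 - lo) * L)
    if kmin > kmax:
        raise ValueError(f"identity_range {identity_range} unrealizable at length {L}")
    if satellite_reads is not None:
        if len(satellite_reads) != n_satellites:
            raise ValueError("satellite_reads length must equal n_satellites")
        if any(not (1 <= r < satellite_read_cap) for r in satellite_reads):
            raise ValueError(f"satellite reads must lie in [1, {satellite_read_cap})")
        reads = list(int(r) for r in satellite_reads)
    else:
        reads = [int(r) for r in rng.integers(1, satellite_read_cap, size=n_satellites)]
    seqs: list[str] = []
    for _ in range(n_satellites):
        for _attempt in range(50):
            k = int(rng.integers(kmin, kmax + 1))
            sat = evolve_sequence(dominant, k, rng)
            if sat != dominant and sat not in seqs:
                seqs.append(sat)
                break
        else:  # pragma: no cover
            raise RuntimeError("could not generate a distinct satellite")
    return Cloud(dominant_seq=dominant, satellite_seqs=seqs,
                 dominant_reads=int(dominant_reads), satellite_reads=reads,
                 identity_range=(lo, hi))


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Compose references, background, flocks, clouds and endemics into a
    complete dataset with counts and truth labels.

    Contracts enforced by construction and verified here: planted endemics
    are > 0.10 from every reference (brute-force scan); background OTUs have
    a nearest reference within 0.10; per-sample depths are uniform on
    ``depth_range``; row sums of the count matrix equal the drawn depths
    exactly.
    """
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    truth = SyntheticTruth()

    refs = [SequenceRecord(id=f"REF_{i + 1:03d}", residues=random_sequence(L, rng),
                           role="reference")
            for i in range(config.n_references)]
    ref_seqs = [r.residues for r in refs]

    focal: list[SequenceRecord] = []

    def add_focal(name: str, seq: str) -> None:
        focal.append(SequenceRecord(id=name, residues=seq, role="focal"))

    for i in range(config.n_background_otus):
        anchor = ref_seqs[i % len(ref_seqs)]
        blo, bhi = config.background_distance_range
        d = rng.uniform(blo, bhi)
        add_focal(f"OTU_B{i + 1:03d}", evolve_sequence(anchor, max(1, round(d * L)), rng))

    for fi, spec in enumerate(config.flocks):
        fid = f"flock_{fi + 1}"
        anchor = ref_seqs[fi % len(ref_seqs)]
        ancestor = evolve_sequence(anchor, round(config.flock_anchor_distance * L), rng)
        tips = plant_flock(ancestor, spec.n_tips, spec.target_divergence, rng)
        for ti, seq in enumerate(tips):
            name = f"OTU_F{fi + 1}_{ti + 1:02d}"
            add_focal(name, seq)
            truth.flock_ids[name] = fid
        truth.flock_target_divergence[fid] = spec.target_divergence

    clouds: list[tuple[str, Cloud, list[str]]] = []
    for ci, spec in enumerate(config.clouds):
        cid = f"cloud_{ci + 1}"
        anchor = ref_seqs[(ci + 1) % len(ref_seqs)]
        dom_seq = evolve_sequence(anchor, max(1, round(config.cloud_anchor_distance * L)), rng)
        cloud = plant_cloud(dom_seq, spec.n_satellites, spec.identity_range,
                            spec.dominant_reads, spec.satellite_read_cap, rng)
        dom_name = f"OTU_C{ci + 1}_DOM"
        add_focal(dom_name, cloud.dominant_seq)
        truth.cloud_ids[dom_name] = cid
        truth.dominants.add(dom_name)
        names = [dom_name]
        for si, seq in enumerate(cloud.satellite_seqs):
            name = f"OTU_C{ci + 1}_S{si + 1:03d}"
            add_focal(name, seq)
            truth.cloud_ids[name] = cid
            names.append(name)
        truth.cloud_identity_range[cid] = cloud.identity_range
        clouds.append((cid, cloud, names))

    elo, ehi = config.endemic_otus.distance_range
    for ei in range(config.endemic_otus.n):
        anchor_idx = ei % len(ref_seqs)
        for _attempt in range(50):
            d = rng.uniform(elo, ehi)
            seq = evolve_sequence(ref_seqs[anchor_idx], round(d * L), rng)
            if min(p_distance(seq, r) for r in ref_seqs) > 0.10:
                break
        else:
            raise InfeasibleConfigError(
                "could not place an endemic > 0.10 from every reference; widen "
                "distance_range or shrink the reference set")
        name = f"OTU_E{ei + 1:03d}"
        add_focal(name, seq)
        truth.endemics.add(name)

    if len({r.id for r in focal}) != len(focal):
        raise InfeasibleConfigError("duplicate focal ids generated")
    truth.validate([r.id for r in focal])

    matrix = _draw_counts(config, focal, truth, clouds, rng)
    _verify_contracts(config, focal, refs, truth, matrix)
    return SyntheticDataset(focal_records=focal, reference_records=refs,
                            matrix=matrix, truth=truth)


def _draw_counts(config: GeneratorConfig, focal: Sequence[SequenceRecord],
                 truth: SyntheticTruth,
                 clouds: Sequence[tuple[str, "Cloud", list[str]]],
                 rng: np.random.Generator) -> CommunityMatrix:
    otu_ids = [r.id for r in focal]
    n_samples = config.n_samples
    depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1,
                          size=n_samples)

    depth_m_cycle = [1.0, 15.0, 25.0, 50.0]
    basins = ["S", "C", "N"]
    sample_ids = [f"SAMP_{i + 1:02d}" for i in range(n_samples)]
    depth_m = [depth_m_cycle[i % 4] for i in range(n_samples)]
    meta = {
        "basin": [basins[i % 3] for i in range(n_samples)],
        "site_class": ["coastal" if i % 5 == 4 else "deep" for i in range(n_samples)],
        "depth_m": depth_m,
    }

    cloud_otus: set[str] = set(truth.cloud_ids)
    counts = np.zeros((n_samples, len(otu_ids)), dtype=np.int64)
    col = {o: j for j, o in enumerate(otu_ids)}

    # fixed-total cloud OTUs are split across samples proportional to depth
    weights = depths / depths.sum()
    for _cid, cloud, names in clouds:
        for name, total in zip(names, [cloud.dominant_reads] + cloud.satellite_reads):
            counts[:, col[name]] += rng.multinomial(total, weights)

    remainders = depths - counts.sum(axis=1)
    if np.any(remainders <= 0):
        raise InfeasibleConfigError(
            "cloud read totals exceed the sample depths; raise depth_range")

    free = [o for o in otu_ids if o not in cloud_otus]
    if free:
        base = np.exp(rng.normal(config.abundance_mu, config.abundance_sigma, len(free)))
        for fid in set(truth.flock_ids.values()):
            members = sorted(truth.members_of_flock(fid))
            flock_base = float(np.exp(rng.normal(config.abundance_mu,
                                                 config.abundance_sigma)))
            for m in members:
                base[free.index(m)] = (config.flock_abundance_boost * flock_base
                                       * rng.uniform(0.7, 1.4))
        base /= base.sum()

        deep = np.asarray(depth_m) >= 25.0
        group_base = {
            g: rng.dirichlet(np.maximum(base * config.group_concentration, 1e-3))
            for g in (False, True)
        }
        for i in range(n_samples):
            conc = (config.sample_concentration_deep if deep[i]
                    else config.sample_concentration_surface)
            p = rng.dirichlet(np.maximum(group_base[deep[i]] * conc, 1e-3))
            row = rng.multinomial(int(remainders[i]), p)
            for o, c in zip(free, row):
                counts[i, col[o]] += c

        # guarantee every planted OTU is observed: shift single reads from the
        # most abundant free OTU (keeps row sums equal to the drawn depths)
        totals = counts.sum(axis=0)
        donor = col[max(free, key=lambda o: counts[:, col[o]].sum())]
        for o in free:
            if totals[col[o]] == 0:
                src = int(np.argmax(counts[:, donor]))
                counts[src, donor] -= 1
                counts[src, col[o]] += 1
                logger.warning("bumped zero-read OTU %s to 1 read", o)

    return CommunityMatrix(sample_ids=sample_ids, otu_ids=otu_ids, counts=counts,
                           sample_meta=pd.DataFrame(meta, index=sample_ids))


def _verify_contracts(config: GeneratorConfig, focal: Sequence[SequenceRecord],
                      refs: Sequence[SequenceRecord], truth: SyntheticTruth,
                      matrix: CommunityMatrix) -> None:
    ref_seqs = [r.residues for r in refs]
    by_id = {r.id: r.residues for r in focal}
    for name in truth.endemics:
        d = min(p_distance(by_id[name], s) for s in ref_seqs)
        if d <= 0.10:
            raise InfeasibleConfigError(f"endemic {name} is within 0.10 of a reference")
    structured = set(truth.flock_ids) | set(truth.cloud_ids) | truth.endemics
    for rec in focal:
        if rec.id in structured:
            continue
        d = min(p_distance(rec.residues, s) for s in ref_seqs)
        if d > 0.10:
            raise InfeasibleConfigError(f"background OTU {rec.id} strayed beyond 0.10")
    totals = matrix.sample_totals()
    lo, hi = config.depth_range
    if np.any(totals < lo) or np.any(totals > hi):
        raise InfeasibleConfigError("sample depth outside the configured range")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write focal.fasta, references.fasta, counts.tsv, truth.json and
    alignment.fasta; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "focal_fasta": out / "focal.fasta",
        "reference_fasta": out / "references.fasta",
        "count_table": out / "counts.tsv",
        "truth": out / "truth.json",
        "alignment": out / "alignment.fasta",
    }
    write_fasta(ds.focal_records, paths["focal_fasta"])
    write_fasta(ds.reference_records, paths["reference_fasta"])
    write_count_table(ds.matrix, paths["count_table"])
    paths["truth"].write_text(ds.truth.to_json() + "\n")
    write_fasta(ds.alignment_records, paths["alignment"])
    return paths


def config_from_dict(data: dict) -> GeneratorConfig:
    """Build a GeneratorConfig from plain YAML/JSON data."""
    data = dict(data)
    if "flocks" in data:
        data["flocks"] = [FlockSpec(**f) for f in data["flocks"]]
    if "clouds" in data:
        data["clouds"] = [CloudSpec(**{**c, "identity_range": tuple(c.get("identity_range", (0.95, 0.99)))})
                          for c in data["clouds"]]
    if "endemic_otus" in data:
        e = dict(data["endemic_otus"])
        if "distance_range" in e:
            e["distance_range"] = tuple(e["distance_range"])
        data["endemic_otus"] = EndemicSpec(**e)
    for key in ("depth_range", "background_distance_range"):
        if key in data:
            data[key] = tuple(data[key])
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown generator config key(s): {sorted(unknown)}")
    return GeneratorConfig(**data)
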