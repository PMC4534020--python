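"""Ground-truthed simulation of a physical-mapping experiment.

Generates, from a single seed, everything the downstream stages consume: a
chromosome model with two arms and a gene-density gradient, an arm-specific
BAC library with foreign-chromosome contamination, whole-genome-profiling
(WGP) tag fingerprints, PCR markers with ortholog links to a reference
homologous chromosome, a radiation-hybrid (RH) panel and a terminal-deletion
panel.  Tags are integer site identifiers on a fixed genomic lattice, so two
clones that overlap share the sites of their overlap exactly (minus dropout);
real sequence tags map onto this abstraction through any exact-match
dictionary.

Coordinates are 0-based, half-open throughout this module.  Randomness comes
from one master seed; each component derives a child generator through
``numpy.random.SeedSequence(seed, spawn_key=(k,))`` with a fixed component
key (0 chromosome, 1 library, 2 tags, 3 RH panel, 4 deletion panel,
5 markers/orthologs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

# Component keys of the documented child-seed scheme.
_KEY_CHROMOSOME = 0
_KEY_LIBRARY = 1
_KEY_TAGS = 2
_KEY_RH = 3
_KEY_DELETION = 4
_KEY_MARKERS = 5


def child_rng(seed: int, component: int) -> np.random.Generator:
    """Derive the documented per-component child generator from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(component,)))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeModel:
    """A linear chromosome with a centromere boundary splitting two arms.

    ``arm_boundary`` is the centromere midpoint: positions below it belong to
    the short (S) arm, positions at or above it to the long (L) arm.
    """

    name: str
    length: int
    arm_boundary: int
    gene_positions: np.ndarray
    nor_interval: tuple[int, int] | None = None
    repeat_density_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InvalidParameterError("chromosome length must be positive")
        if not 0 < self.arm_boundary < self.length:
            raise InvalidParameterError("arm_boundary must lie inside the chromosome")
        g = np.asarray(self.gene_positions, dtype=np.int64)
        object.__setattr__(self, "gene_positions", g)
        if g.size and (np.any(np.diff(g) <= 0) or g[0] < 0 or g[-1] >= self.length):
            raise InvalidParameterError(
                "gene positions must be strictly increasing within [0, length)"
            )
        if self.repeat_density_profile is not None:
            p = np.asarray(self.repeat_density_profile, dtype=float)
            if np.any(p < 0) or np.any(p > 1):
                raise InvalidParameterError("repeat fractions must lie in [0, 1]")
            object.__setattr__(self, "repeat_density_profile", p)

    def arm_of(self, position: int) -> str:
        return "S" if position < self.arm_boundary else "L"


@dataclass(frozen=True)
class BACClone:
    id: str
    origin_chromosome: str
    start: int
    end: int
    is_contaminant: bool

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise InvalidParameterError("BAC insert length must be positive")

    @property
    def insert_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RHLine:
    """One radiation-hybrid (or deletion) line: the chromosome intervals it retains."""

    id: str
    retained_intervals: tuple[tuple[int, int], ...]
    retention_prob_r: float
    n_breaks: int

    def retains(self, position: int) -> bool:
        return any(s <= position < e for s, e in self.retained_intervals)


@dataclass
class GroundTruth:
    """Bookkeeping linking every simulated entity to its true coordinates."""

    bac_position: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    marker_position: dict[str, int] = field(default_factory=dict)
    line_intervals: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)
    gene_ortholog: dict[str, tuple[str, float] | None] = field(default_factory=dict)
    tag_position: dict[int, int] = field(default_factory=dict)
    tag_origin: dict[int, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Chromosome
# ---------------------------------------------------------------------------

def _sample_arm_offsets(rng, n: int, gradient: float) -> np.ndarray:
    """Relative distances from centromere with pdf f(t) ∝ 1 + gradient*t on [0,1].

    Inverse-CDF sampling: solve gradient*t^2/2 + t = u*(1 + gradient/2).
    """
    u = rng.random(n)
    if gradient == 0:
        return u
    y = u * (1.0 + gradient / 2.0)
    return (-1.0 + np.sqrt(1.0 + 2.0 * gradient * y)) / gradient


def simulate_chromosome(
    length: int,
    arm_boundary: int,
    n_genes: int,
    density_gradient: float = 0.0,
    seed: int = 0,
    name: str = "chr6B",
    nor_interval: tuple[int, int] | None = None,
) -> ChromosomeModel:
    """Simulate a chromosome with genes whose density rises toward the telomeres.

    ``density_gradient`` g sets a linear intensity 1 + g*t in the relative
    distance t from the centromere along each arm; g = 0 is uniform.
    """
    if length <= 0 or n_genes < 0:
        raise InvalidParameterError("length must be positive and n_genes non-negative")
    if not 0 < arm_boundary < length:
        raise InvalidParameterError("arm_boundary must lie inside the chromosome")
    rng = child_rng(seed, _KEY_CHROMOSOME)
    arm_len = np.array([arm_boundary, length - arm_boundary], dtype=float)
    # Each arm's share of genes is proportional to its integrated intensity,
    # which scales with arm length alone (both arms share the gradient).
    p_short = arm_len[0] / arm_len.sum()
    positions: set[int] = set()
    while len(positions) < n_genes:
        k = n_genes - len(positions)
        on_short = rng.random(k) < p_short
        t = _sample_arm_offsets(rng, k, density_gradient)
        pos = np.where(
            on_short,
            arm_boundary - 1 - np.floor(t * arm_len[0]),
            arm_boundary + np.floor(t * arm_len[1]),
        ).astype(np.int64)
        positions.update(int(p) for p in pos if 0 <= p < length)
    genes = np.array(sorted(positions), dtype=np.int64)
    return ChromosomeModel(
        name=name,
        length=length,
        arm_boundary=arm_boundary,
        gene_positions=genes,
        nor_interval=nor_interval,
    )


# ---------------------------------------------------------------------------
# BAC library
# ---------------------------------------------------------------------------

def simulate_bac_library(
    model: ChromosomeModel,
    coverage: float,
    insert_mean: int = 130_000,
    insert_sd: int = 13_000,
    purity: float = 0.92,
    seed: int = 0,
    n_foreign_chromosomes: int = 3,
) -> list[BACClone]:
    """Simulate an arm-sorted BAC library at the given fold coverage.

    A fraction 1 - purity of clones originates from foreign chromosomes
    (flow-sorting contamination); those clones carry coordinates on a foreign
    chromosome of the same length.
    """
    if not 0 < purity <= 1:
        raise InvalidParameterError("purity must lie in (0, 1]")
    if coverage <= 0:
        raise InvalidParameterError("coverage must be positive")
    rng = child_rng(seed, _KEY_LIBRARY)
    expected = coverage * model.length / insert_mean
    n_clones = int(rng.poisson(expected))
    clones: list[BACClone] = []
    for i in range(n_clones):
        contaminant = bool(rng.random() > purity)
        origin = (
            f"foreign{int(rng.integers(n_foreign_chromosomes)) + 1}"
            if contaminant
            else model.name
        )
        ln = int(np.clip(rng.normal(insert_mean, insert_sd), 20_000, None))
        ln = min(ln, model.length - 1)
        start = int(rng.integers(0, model.length - ln))
        clones.append(
            BACClone(
                id=f"B{i:06d}",
                origin_chromosome=origin,
                start=start,
                end=start + ln,
                is_contaminant=contaminant,
            )
        )
    return clones


# ---------------------------------------------------------------------------
# WGP tag fingerprints
# ---------------------------------------------------------------------------

def simulate_wgp_tags(
    model: ChromosomeModel,
    clones: Sequence[BACClone],
    mean_tags_per_bac: float = 20.6,
    dropout: float = 0.02,
    tag_universe: int | None = None,
    seed: int = 0,
    shared_repeat_fraction: float = 0.02,
) -> tuple[dict[str, frozenset[int]], dict[int, str], dict[int, int]]:
    """Assign WGP tags (integer site IDs on a fixed lattice) to each clone.

    Sites sit every ``mean insert / mean_tags_per_bac`` bp, so a clone of mean
    length covers ``mean_tags_per_bac`` sites on average and overlapping
    clones share the sites of their overlap.  Each foreign chromosome has a
    disjoint site universe, except that a ``shared_repeat_fraction`` of
    foreign sites collide with target-universe IDs (repeat sequences shared
    across chromosomes), which keeps the contamination screen non-trivial.
    Each tag is dropped independently with probability ``dropout``.

    Returns ``(fingerprints, tag_origin, tag_position)``: clone id to tag set,
    tag id to chromosome-group label, and target tag id to bp position.
    """
    if mean_tags_per_bac <= 0:
        raise InvalidParameterError("mean_tags_per_bac must be positive")
    if not 0 <= dropout < 1:
        raise InvalidParameterError("dropout must lie in [0, 1)")
    rng = child_rng(seed, _KEY_TAGS)
    mean_insert = (
        float(np.mean([c.insert_length for c in clones])) if clones else 130_000.0
    )
    spacing = max(1, int(round(mean_insert / mean_tags_per_bac)))
    n_sites = model.length // spacing + 1
    foreign_names = sorted({c.origin_chromosome for c in clones if c.is_contaminant})
    required = n_sites * (1 + len(foreign_names))
    if tag_universe is not None and tag_universe < required:
        raise InvalidParameterError(
            f"tag_universe {tag_universe} smaller than the {required} required sites"
        )

    tag_origin: dict[int, str] = {}
    tag_position: dict[int, int] = {}
    for s in range(n_sites):
        tag_origin[s] = model.name
        tag_position[s] = s * spacing
    # Per-foreign-chromosome universes, with rare collisions into the target
    # universe standing in for repeats shared across chromosomes.
    foreign_map: dict[str, np.ndarray] = {}
    for j, fname in enumerate(foreign_names):
        base = (j + 1) * n_sites
        ids = base + np.arange(n_sites)
        collide = rng.random(n_sites) < shared_repeat_fraction
        ids[collide] = rng.integers(0, n_sites, size=int(collide.sum()))
        foreign_map[fname] = ids
        for s in range(n_sites):
            if not collide[s]:
                tag_origin[int(ids[s])] = fname

    fingerprints: dict[str, frozenset[int]] = {}
    for clone in clones:
        lo = -(-clone.start // spacing)  # ceil
        hi = (clone.end - 1) // spacing
        sites = np.arange(lo, hi + 1)
        if clone.is_contaminant:
            ids = foreign_map[clone.origin_chromosome][sites]
        else:
            ids = sites
        if dropout > 0:
            ids = ids[rng.random(ids.size) >= dropout]
        fingerprints[clone.id] = frozenset(int(t) for t in ids)
    return fingerprints, tag_origin, tag_position


# ---------------------------------------------------------------------------
# RH and deletion panels
# ---------------------------------------------------------------------------

def simulate_rh_panel(
    model: ChromosomeModel,
    n_lines: int = 355,
    mean_breaks: float = 8.0,
    retention_r: float = 0.25,
    seed: int = 0,
) -> list[RHLine]:
    """Simulate an irradiation panel: Poisson breaks, independent fragment retention."""
    if not 0 < retention_r < 1:
        raise InvalidParameterError("retention_r must lie in (0, 1)")
    if mean_breaks < 0 or n_lines <= 0:
        raise InvalidParameterError("mean_breaks must be >= 0 and n_lines positive")
    rng = child_rng(seed, _KEY_RH)
    lines = []
    for i in range(n_lines):
        k = int(rng.poisson(mean_breaks))
        breaks = np.sort(rng.integers(1, model.length, size=k))
        bounds = np.concatenate(([0], breaks, [model.length]))
        keep = rng.random(len(bounds) - 1) < retention_r
        intervals: list[list[int]] = []
        for j, kept in enumerate(keep):
            if not kept:
                continue
            s, e = int(bounds[j]), int(bounds[j + 1])
            if s == e:
                continue
            if intervals and intervals[-1][1] == s:
                intervals[-1][1] = e
            else:
                intervals.append([s, e])
        ivals = tuple((s, e) for s, e in intervals)
        n_interior = sum(1 for s, e in ivals for b in (s, e) if 0 < b < model.length)
        lines.append(
            RHLine(
                id=f"RH{i:04d}",
                retained_intervals=ivals,
                retention_prob_r=retention_r,
                n_breaks=n_interior,
            )
        )
    return lines


def simulate_deletion_lines(
    model: ChromosomeModel,
    n_lines: int = 21,
    n_short_breakpoints: int = 6,
    n_long_breakpoints: int = 12,
    seed: int = 0,
) -> list[RHLine]:
    """Simulate terminal-deletion stocks: each line lacks a distal arm segment.

    Distinct breakpoints are drawn inside each arm; when ``n_lines`` exceeds
    the number of distinct breakpoints, the surplus lines re-use existing
    breakpoints (independent stocks truncated at the same site).
    """
    n_distinct = n_short_breakpoints + n_long_breakpoints
    if n_lines < n_distinct:
        raise InvalidParameterError("n_lines must cover all distinct breakpoints")
    rng = child_rng(seed, _KEY_DELETION)
    s_arm = model.arm_boundary
    bp_s = np.sort(
        rng.choice(
            np.arange(int(0.05 * s_arm), int(0.95 * s_arm)),
            size=n_short_breakpoints,
            replace=False,
        )
    )
    l_lo, l_hi = s_arm + int(0.05 * (model.length - s_arm)), int(0.95 * model.length)
    bp_l = np.sort(rng.choice(np.arange(l_lo, l_hi), size=n_long_breakpoints, replace=False))
    specs = [("S", int(b)) for b in bp_s] + [("L", int(b)) for b in bp_l]
    extra = rng.integers(0, n_distinct, size=n_lines - n_distinct)
    all_specs = specs + [specs[i] for i in extra]
    lines = []
    for i, (arm, b) in enumerate(all_specs):
        if arm == "S":  # distal S segment [0, b) lost
            ivals = ((b, model.length),)
        else:  # distal L segment [b, length) lost
            ivals = ((0, b),)
        lines.append(
            RHLine(id=f"DEL{i:02d}_{arm}", retained_intervals=ivals,
                   retention_prob_r=1.0, n_breaks=1)
        )
    return lines


# ---------------------------------------------------------------------------
# Markers and ortholog links
# ---------------------------------------------------------------------------

def simulate_markers_and_orthologs(
    model: ChromosomeModel,
    n_markers: int,
    nonsyntenic_fraction: float = 477 / 2015,
    rearrangements: Sequence[Mapping] = (),
    seed: int = 0,
    ref_chromosome: str = "ref2",
    ref_scale: float = 0.1,
    n_ref_chromosomes: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place markers on the chromosome and link genic ones to a reference homolog.

    Markers are drawn from gene positions first (genic markers) and topped up
    with uniform intergenic positions (ISBP-like markers).  Syntenic genes
    receive reference positions colinear with their chromosome positions
    (scaled by ``ref_scale``), except inside the supplied inversion or
    translocation blocks; nonsyntenic genes link to an off-chromosome
    position or get no link.

    Each rearrangement spec is a mapping with keys ``kind`` (``inversion``,
    ``translocation`` or ``translocation+inversion``), ``start``, ``end``
    (bp on the simulated chromosome) and, for translocations, ``offset``
    (bp displacement on the reference).

    Returns ``(markers, links)`` data frames.
    """
    if not 0 <= nonsyntenic_fraction <= 1:
        raise InvalidParameterError("nonsyntenic_fraction must lie in [0, 1]")
    blocks = sorted(rearrangements, key=lambda b: b["start"])
    for a, b in zip(blocks, blocks[1:]):
        if b["start"] < a["end"]:
            raise InvalidParameterError("rearrangement blocks must not overlap")
    rng = child_rng(seed, _KEY_MARKERS)
    genes = model.gene_positions
    n_genic = min(n_markers, genes.size)
    genic_idx = np.sort(rng.choice(genes.size, size=n_genic, replace=False)) if n_genic else []
    positions = [int(genes[i]) for i in genic_idx]
    kinds = ["genic"] * n_genic
    while len(positions) < n_markers:
        p = int(rng.integers(0, model.length))
        if p not in positions:
            positions.append(p)
            kinds.append("isbp")
    order = np.argsort(positions, kind="stable")
    markers = pd.DataFrame(
        {
            "marker_id": [f"M{i:04d}" for i in range(n_markers)],
            "position": [positions[i] for i in order],
            "kind": [kinds[i] for i in order],
        }
    )

    rows = []
    for _, row in markers[markers["kind"] == "genic"].iterrows():
        pos = int(row["position"])
        syntenic = bool(rng.random() >= nonsyntenic_fraction)
        if not syntenic:
            if rng.random() < 0.7:
                chrom = f"ref{int(rng.integers(n_ref_chromosomes)) + 1}"
                if chrom == ref_chromosome:
                    chrom = ref_chromosome + "x"
                rows.append((row["marker_id"], pos, chrom,
                             float(rng.integers(0, model.length)) * ref_scale, False))
            continue
        ref = pos * ref_scale
        for blk in blocks:
            if blk["start"] <= pos < blk["end"]:
                kind = blk["kind"]
                if "inversion" in kind:
                    ref = (blk["start"] + blk["end"] - 1 - pos) * ref_scale
                if "translocation" in kind:
                    ref = ref + blk.get("offset", 0.0) * ref_scale
                break
        rows.append((row["marker_id"], pos, ref_chromosome, float(ref), True))
    links = pd.DataFrame(
        rows, columns=["gene_id", "position", "ref_chromosome", "ref_position", "syntenic"]
    )
    return markers, links


# ---------------------------------------------------------------------------
# Derived observations
# ---------------------------------------------------------------------------

def genotype_calls(
    lines: Sequence[RHLine],
    marker_positions: Mapping[str, int],
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Score marker presence/absence across panel lines (lines x markers).

    Values are 1.0 / 0.0 with NaN for missing calls; genotyping error flips a
    call independently with probability ``error_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    names = sorted(marker_positions)
    data = np.zeros((len(lines), len(names)))
    for i, line in enumerate(lines):
        for j, m in enumerate(names):
            data[i, j] = 1.0 if line.retains(marker_positions[m]) else 0.0
    if error_rate > 0:
        flips = rng.random(data.shape) < error_rate
        data[flips] = 1.0 - data[flips]
    if missing_rate > 0:
        data[rng.random(data.shape) < missing_rate] = np.nan
    return pd.DataFrame(data, index=[ln.id for ln in lines], columns=names)


def anchor_table(
    clones: Sequence[BACClone], marker_positions: Mapping[str, int]
) -> pd.DataFrame:
    """PCR-screen result: every target-origin clone containing a marker position."""
    rows = [
        (m, c.id)
        for m, pos in sorted(marker_positions.items())
        for c in clones
        if not c.is_contaminant and c.start <= pos < c.end
    ]
    return pd.DataFrame(rows, columns=["marker_id", "bac_id"])


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    model: ChromosomeModel
    clones: list[BACClone]
    fingerprints: dict[str, frozenset[int]]
    markers: pd.DataFrame
    links: pd.DataFrame
    rh_lines: list[RHLine]
    deletion_lines: list[RHLine]
    rh_calls: pd.DataFrame
    deletion_calls: pd.DataFrame
    anchors: pd.DataFrame
    truth: GroundTruth


def simulate_dataset(
    seed: int = 0,
    length: int = 40_000_000,
    arm_boundary: int = 18_000_000,
    n_genes: int = 400,
    density_gradient: float = 1.0,
    coverage: float = 9.0,
    insert_mean: int = 130_000,
    purity: float = 0.9,
    mean_tags_per_bac: float = 20.6,
    dropout: float = 0.02,
    n_markers: int = 120,
    n_rh_lines: int = 355,
    mean_breaks: float = 8.0,
    retention_r: float = 0.25,
    nonsyntenic_fraction: float = 477 / 2015,
    rearrangements: Sequence[Mapping] = (),
) -> SimulatedDataset:
    """Generate a complete, internally consistent synthetic experiment."""
    model = simulate_chromosome(
        length, arm_boundary, n_genes, density_gradient=density_gradient, seed=seed
    )
    clones = simulate_bac_library(
        model, coverage, insert_mean=insert_mean, purity=purity, seed=seed
    )
    fingerprints, tag_origin, tag_position = simulate_wgp_tags(
        model, clones, mean_tags_per_bac=mean_tags_per_bac, dropout=dropout, seed=seed
    )
    markers, links = simulate_markers_and_orthologs(
        model,
        n_markers,
        nonsyntenic_fraction=nonsyntenic_fraction,
        rearrangements=rearrangements,
        seed=seed,
    )
    marker_pos = dict(zip(markers["marker_id"], markers["position"]))
    rh_lines = simulate_rh_panel(
        model, n_lines=n_rh_lines, mean_breaks=mean_breaks,
        retention_r=retention_r, seed=seed,
    )
    deletion_lines = simulate_deletion_lines(model, seed=seed)
    rh_calls = genotype_calls(rh_lines, marker_pos, seed=seed)
    deletion_calls = genotype_calls(deletion_lines, marker_pos, seed=seed)
    anchors = anchor_table(clones, marker_pos)
    truth = GroundTruth(
        bac_position={c.id: (c.origin_chromosome, c.start, c.end) for c in clones},
        marker_position=marker_pos,
        line_intervals={ln.id: ln.retained_intervals for ln in rh_lines + deletion_lines},
        gene_ortholog={
            r.gene_id: (r.ref_chromosome, r.ref_position) for r in links.itertuples()
        },
        tag_position=tag_position,
        tag_origin=tag_origin,
    )
    return SimulatedDataset(
        model=model,
        clones=clones,
        fingerprints=fingerprints,
        markers=markers,
        links=links,
        rh_lines=rh_lines,
        deletion_lines=deletion_lines,
        rh_calls=rh_calls,
        deletion_calls=deletion_calls,
        anchors=anchors,
        truth=truth,
    )
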