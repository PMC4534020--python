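"""Anchoring of BAC contigs onto the RH map and integrated-map summaries.

Markers anchored to member clones place each contig at an RH locus; chimeric
contigs (marker positions split across distant map regions) are detected and
split at the largest consensus-band gap; co-located contigs are ranked by the
reference positions of their syntenic genes.  Summary operations reproduce
the integrated-map accounting: contigs on the map, anchored-but-unmapped and
unanchored, with cumulative sizes and chromosome coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import spearmanr

from .assembly import Contig, Fingerprint, _make_contig, AssemblyParams
from .errors import InvalidParameterError, PipelineWarning
from .rhmap import RHMap


@dataclass(frozen=True)
class MarkerAnchor:
    marker_id: str
    bac_id: str
    contig_id: str
    source: str = "library-screen"


@dataclass
class ContigPlacement:
    contig_id: str
    locus_index: int | None
    position_cR: float | None
    orientation: str = "unknown"  # "+", "-", "unknown"
    within_locus_rank: int = 0
    basis: str = "unanchored"  # "rh", "rh+synteny", "unanchored"
    arm: str | None = None


def resolve_anchors(
    anchors: Sequence[MarkerAnchor], rhmap: RHMap
) -> dict[str, list[tuple[str, str, int, float]]]:
    """Group anchors by contig as (marker, bac, locus index, cR) tuples."""
    out: dict[str, list[tuple[str, str, int, float]]] = {}
    for a in anchors:
        locus = rhmap.locus_of_marker(a.marker_id)
        if locus is None:
            continue
        out.setdefault(a.contig_id, []).append(
            (a.marker_id, a.bac_id, locus, float(rhmap.positions_cR[locus]))
        )
    return out


# ---------------------------------------------------------------------------
# Chimera detection
# ---------------------------------------------------------------------------

def detect_and_split_chimeras(
    contig: Contig,
    anchors: Sequence[MarkerAnchor],
    rhmap: RHMap,
    params: AssemblyParams,
    fingerprints: Mapping[str, Fingerprint],
    gap_cR: float = 50.0,
) -> list[Contig]:
    """Split a contig whose anchored markers map to two distant RH regions.

    The contig is chimeric iff its marker centiray positions fall into two
    clusters separated by more than ``gap_cR``.  The split point is the
    largest consensus-band gap between member clones carrying markers of the
    two clusters; members are divided by CB side, and each child is
    re-assembled from its members.  Three or more clusters split at the
    largest gap only, with a warning.
    """
    mine = [a for a in anchors if a.contig_id == contig.id]
    pts = []
    for a in mine:
        locus = rhmap.locus_of_marker(a.marker_id)
        if locus is not None:
            pts.append((float(rhmap.positions_cR[locus]), a.bac_id))
    if len(pts) < 2:
        return [contig]
    pts.sort()
    crs = np.array([p[0] for p in pts])
    gaps = np.diff(crs)
    big = np.flatnonzero(gaps > gap_cR)
    if big.size == 0:
        return [contig]
    if big.size > 1:
        warnings.warn(
            f"contig {contig.id}: {big.size + 1} marker clusters; "
            "splitting at the largest gap only",
            PipelineWarning,
        )
    cut = int(big[np.argmax(gaps[big])]) + 1
    cluster_a = {b for _cr, b in pts[:cut]}
    cluster_b = {b for _cr, b in pts[cut:]}

    marked = sorted(
        (m for m in contig.members if m.bac_id in cluster_a | cluster_b),
        key=lambda m: (m.cb_start, m.bac_id),
    )
    side = {m.bac_id: ("A" if m.bac_id in cluster_a else "B") for m in marked}
    best_gap, boundary = -1, None
    for u, v in zip(marked, marked[1:]):
        if side[u.bac_id] != side[v.bac_id]:
            gap = v.cb_start - u.cb_end
            if gap > best_gap:
                best_gap, boundary = gap, (u.cb_end + v.cb_start) / 2.0
    if boundary is None:
        return [contig]
    left = [m.bac_id for m in contig.members if m.cb_start < boundary]
    right = [m.bac_id for m in contig.members if m.cb_start >= boundary]
    if not left or not right:
        return [contig]
    children = []
    for tag, ids in (("1", left), ("2", right)):
        fps = [fingerprints[b] for b in ids]
        if len(fps) == 1:
            child = Contig(
                id=f"{contig.id}.{tag}",
                members=[replace(contig.members[0], bac_id=ids[0])],
                unique_tags=len(fps[0].tags),
                estimated_size=len(fps[0].tags) * params.cb_unit,
                tags=fps[0].tags,
            )
        else:
            child = _make_contig(f"{contig.id}.{tag}", fps, params)
        child.status = "split-child"
        children.append(child)
    return children


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

def place_contigs(
    contigs: Sequence[Contig],
    anchors: Sequence[MarkerAnchor],
    rhmap: RHMap,
    arm_boundary_locus: int | None = None,
) -> list[ContigPlacement]:
    """Assign each contig to the median locus of its anchored markers.

    The median (not mean) locus is robust to a single mis-anchored marker;
    an even marker count takes the more distal of the two middle loci.
    Orientation comes from the sign of the Spearman rank correlation between
    the CB coordinates of marker-carrying clones and the marker centiray
    positions; it needs markers at two or more distinct loci, otherwise it
    stays unknown.  Contigs without resolvable markers report unanchored.
    """
    resolved = resolve_anchors(anchors, rhmap)
    placements = []
    for c in contigs:
        hits = resolved.get(c.id, [])
        if not hits:
            placements.append(
                ContigPlacement(contig_id=c.id, locus_index=None, position_cR=None)
            )
            continue
        loci = sorted(h[2] for h in hits)
        locus = loci[len(loci) // 2]
        cb_of = {m.bac_id: m.cb_start for m in c.members}
        orientation = "unknown"
        if len(set(loci)) >= 2:
            xs = [cb_of[b] for _m, b, _l, _cr in hits if b in cb_of]
            ys = [cr for _m, b, _l, cr in hits if b in cb_of]
            if len(xs) >= 2 and len(set(xs)) > 1 and len(set(ys)) > 1:
                rho = spearmanr(xs, ys).statistic
                if rho > 0:
                    orientation = "+"
                elif rho < 0:
                    orientation = "-"
        arm = None
        if arm_boundary_locus is not None:
            arm = "S" if locus < arm_boundary_locus else "L"
        placements.append(
            ContigPlacement(
                contig_id=c.id,
                locus_index=locus,
                position_cR=float(rhmap.positions_cR[locus]),
                orientation=orientation,
                basis="rh",
                arm=arm,
            )
        )
    return placements


# ---------------------------------------------------------------------------
# Within-locus ordering by synteny
# ---------------------------------------------------------------------------

def order_within_locus_by_synteny(
    placements: Sequence[ContigPlacement],
    ortholog_positions: Mapping[str, Sequence[float]],
) -> list[ContigPlacement]:
    """Rank contigs sharing one locus by their syntenic genes' reference positions.

    ``ortholog_positions`` maps contig_id to the reference-chromosome
    positions of its syntenic genes.  Contigs with links are ranked by the
    median reference position and flagged basis="rh+synteny"; contigs
    without links keep a stable rank after the ranked ones.
    """
    loci = {p.locus_index for p in placements}
    if len(loci) != 1:
        raise InvalidParameterError("placements must share a single locus")
    linked = [
        p for p in placements if ortholog_positions.get(p.contig_id)
    ]
    unlinked = [p for p in placements if not ortholog_positions.get(p.contig_id)]
    linked.sort(
        key=lambda p: (float(np.median(ortholog_positions[p.contig_id])), p.contig_id)
    )
    out = []
    for rank, p in enumerate(linked + unlinked):
        basis = "rh+synteny" if p in linked else p.basis
        out.append(replace_placement(p, within_locus_rank=rank, basis=basis))
    return out


def replace_placement(p: ContigPlacement, **kw) -> ContigPlacement:
    d = dict(
        contig_id=p.contig_id,
        locus_index=p.locus_index,
        position_cR=p.position_cR,
        orientation=p.orientation,
        within_locus_rank=p.within_locus_rank,
        basis=p.basis,
        arm=p.arm,
    )
    d.update(kw)
    return ContigPlacement(**d)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def integrated_summary(
    placements: Sequence[ContigPlacement],
    contigs: Sequence[Contig],
    chromosome_sizes: Mapping[str, float] | None = None,
    anchored_unmapped: Sequence[str] = (),
    arm_of_contig: Mapping[str, str] | None = None,
) -> dict:
    """Integrated-map accounting: mapped / anchored-not-mapped / unanchored rows.

    Each row carries, per arm and for the whole chromosome, the contig count,
    cumulative size (Mb) and coverage percentage against the supplied sizes
    (defaults 415 / 498 / 914 Mb).  ``anchored_unmapped`` lists contigs
    anchored by markers absent from the RH map; ``arm_of_contig`` supplies
    arm labels for contigs without a placement arm.
    """
    sizes = chromosome_sizes or {"S": 415e6, "L": 498e6, "whole": 914e6}
    size_of = {c.id: c.estimated_size for c in contigs}
    by_contig = {p.contig_id: p for p in placements}
    rows: dict[str, dict[str, list]] = {
        row: {a: [] for a in ("S", "L", "whole")}
        for row in ("on_rh_map", "anchored_not_mapped", "unanchored")
    }
    for c in contigs:
        p = by_contig.get(c.id)
        if p is not None and p.locus_index is not None:
            row = "on_rh_map"
            arm = p.arm
        elif c.id in set(anchored_unmapped):
            row = "anchored_not_mapped"
            arm = (arm_of_contig or {}).get(c.id)
        else:
            row = "unanchored"
            arm = (arm_of_contig or {}).get(c.id)
        rows[row]["whole"].append(c.id)
        if arm in ("S", "L"):
            rows[row][arm].append(c.id)
    out = {}
    for row, arms in rows.items():
        out[row] = {}
        for arm, ids in arms.items():
            mb = sum(size_of.get(i, 0) for i in ids) / 1e6
            denom = sizes.get(arm if arm != "whole" else "whole")
            out[row][arm] = {
                "count": len(ids),
                "mb": mb,
                "coverage_pct": 100.0 * mb * 1e6 / denom if denom else float("nan"),
            }
    return out


def map_order_key(p: ContigPlacement) -> tuple:
    return (p.locus_index, p.within_locus_rank, p.contig_id)


def region_summary(
    placements: Sequence[ContigPlacement],
    contigs: Sequence[Contig],
    from_contig: str,
    to_contig: str,
) -> dict:
    """Contig counts and cumulative Mb over a closed map interval, split by arm."""
    placed = {p.contig_id: p for p in placements if p.locus_index is not None}
    if from_contig not in placed or to_contig not in placed:
        raise InvalidParameterError("both endpoint contigs must be placed on the map")
    size_of = {c.id: c.estimated_size for c in contigs}
    lo = map_order_key(placed[from_contig])
    hi = map_order_key(placed[to_contig])
    if hi < lo:
        lo, hi = hi, lo
    inside = [p for p in placed.values() if lo <= map_order_key(p) <= hi]
    out = {"S": {"n_contigs": 0, "mb": 0.0}, "L": {"n_contigs": 0, "mb": 0.0}}
    total = 0.0
    for p in inside:
        mb = size_of.get(p.contig_id, 0) / 1e6
        total += mb
        if p.arm in out:
            out[p.arm]["n_contigs"] += 1
            out[p.arm]["mb"] += mb
    out["total_mb"] = total
    out["n_contigs"] = len(inside)
    return out
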