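"""Gene density, synteny classification and rearrangement detection.

Genes reach the physical map through two routes: non-redundant genic markers
anchored by PCR screening, and annotated genes on external sequence contigs
transferred through uniquely mapping WGP tags.  Ordered ortholog links
against a homologous reference chromosome are then segmented into monotone
runs; a run against the dominant direction is an inversion, a run displaced
from its colinear expectation a translocation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assembly import Contig
from .errors import InvalidParameterError


@dataclass(frozen=True)
class OrthologLink:
    gene_id: str
    wheat_position: float  # cumulative bp on the physical map
    ref_chromosome: str
    ref_position: float
    syntenic: bool


@dataclass(frozen=True)
class RearrangementBlock:
    kind: str  # "inversion" | "translocation" | "translocation+inversion"
    wheat_start: float
    wheat_end: float
    gene_start_id: str
    gene_end_id: str
    n_genes: int
    cr_start: float | None = None
    cr_end: float | None = None


# ---------------------------------------------------------------------------
# Marker de-duplication
# ---------------------------------------------------------------------------

def dedupe_gene_markers(
    entries: Mapping[str, int],
    identity_fn: Callable[[str, str], float] | None = None,
    clusters: Mapping[str, str] | None = None,
    identity: float = 0.98,
) -> list[str]:
    """One representative gene marker per similarity cluster.

    ``entries`` maps marker id to sequence length.  Either precomputed
    ``clusters`` (id -> cluster label) or a pairwise ``identity_fn`` must be
    supplied; greedy clustering joins a marker to the first representative
    with identity >= the threshold.  The longest member represents each
    cluster, ties broken by id.
    """
    if clusters is not None:
        best: dict[str, str] = {}
        for mid in sorted(entries, key=lambda m: (-entries[m], m)):
            best.setdefault(clusters[mid], mid)
        return sorted(best.values())
    if identity_fn is None:
        raise InvalidParameterError("supply either clusters or identity_fn")
    reps: list[str] = []
    for mid in sorted(entries, key=lambda m: (-entries[m], m)):
        if not any(identity_fn(mid, r) >= identity for r in reps):
            reps.append(mid)
    return sorted(reps)


# ---------------------------------------------------------------------------
# Tag-mediated gene transfer
# ---------------------------------------------------------------------------

def assign_genes_via_tags(
    tag_hits: Mapping[int, str],
    seq_contig_genes: Mapping[str, Sequence[str]],
    contigs: Sequence[Contig],
    co_located: Callable[[str, str], bool] | None = None,
) -> tuple[dict[str, str], list[str], list[str]]:
    """Transfer genes from sequence contigs to BAC contigs via unique tag hits.

    ``tag_hits`` maps a WGP tag (unique, exact hit only) to a sequence
    contig.  A sequence contig hit by tags from BAC contigs that are not
    co-located (default: not the same contig) is discarded entirely; the
    rest transfer their genes to the hitting BAC contig.

    Returns ``(assignments, discarded_seq_contigs, unassigned_genes)``;
    assigned + discarded + unassigned genes conserve the input gene count.
    """
    tag_owner = {t: c.id for c in contigs for t in c.tags}
    hitters: dict[str, set[str]] = {}
    for tag, seq_contig in tag_hits.items():
        owner = tag_owner.get(tag)
        if owner is not None:
            hitters.setdefault(seq_contig, set()).add(owner)
    same = co_located or (lambda a, b: a == b)
    assignments: dict[str, str] = {}
    discarded: list[str] = []
    for seq_contig, genes in sorted(seq_contig_genes.items()):
        owners = sorted(hitters.get(seq_contig, ()))
        if not owners:
            continue
        if any(not same(a, b) for a in owners for b in owners):
            discarded.append(seq_contig)
            continue
        for g in genes:
            assignments[g] = owners[0]
    discarded_genes = {
        g for sc in discarded for g in seq_contig_genes[sc]
    }
    unassigned = sorted(
        g
        for sc, genes in seq_contig_genes.items()
        for g in genes
        if g not in assignments and g not in discarded_genes
    )
    return assignments, discarded, unassigned


# ---------------------------------------------------------------------------
# Gene density
# ---------------------------------------------------------------------------

def gene_density_profile(
    contig_order: Sequence[str],
    gene_assignments: Mapping[str, str],
    contig_sizes: Mapping[str, float],
    syntenic: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Genes/Mb per contig, in map order, with syntenic/nonsyntenic sub-profiles."""
    counts = {c: 0 for c in contig_order}
    syn_counts = {c: 0 for c in contig_order}
    nonsyn_counts = {c: 0 for c in contig_order}
    for gene, contig in gene_assignments.items():
        if contig not in counts:
            continue
        counts[contig] += 1
        if syntenic is not None:
            if syntenic.get(gene, False):
                syn_counts[contig] += 1
            else:
                nonsyn_counts[contig] += 1
    rows = []
    for i, c in enumerate(contig_order):
        size_mb = contig_sizes[c] / 1e6
        if size_mb <= 0:
            raise InvalidParameterError(f"contig {c} has non-positive size")
        rows.append(
            {
                "map_rank": i,
                "contig_id": c,
                "n_genes": counts[c],
                "size_mb": size_mb,
                "density": counts[c] / size_mb,
                "syntenic_density": syn_counts[c] / size_mb,
                "nonsyntenic_density": nonsyn_counts[c] / size_mb,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rearrangement detection
# ---------------------------------------------------------------------------

def _monotone_runs(
    ref: np.ndarray, min_block_size: int, outlier_per: int = 10
) -> list[tuple[int, int, int]]:
    """Maximal monotone runs (start, end inclusive, direction) over a sequence.

    Up to one interrupting outlier per ``outlier_per`` consumed genes is
    skipped, since real ortholog tables are noisy; skipped indices stay
    inside the run's span.
    """
    n = len(ref)
    runs = []
    i = 0
    while i < n - 1:
        j = i + 1
        while j < n and ref[j] == ref[i]:
            j += 1
        if j >= n:
            break
        direction = 1 if ref[j] > ref[i] else -1
        last = j
        skips = 0
        length = 2
        k = j + 1
        while k < n:
            ok = (ref[k] - ref[last]) * direction > 0
            if ok:
                last = k
                length += 1
                k += 1
            elif skips + 1 <= max(1, length // outlier_per):
                skips += 1
                k += 1
            else:
                break
        runs.append((i, last, direction))
        i = last
    return [r for r in runs if r[1] - r[0] + 1 >= min_block_size]


def detect_rearrangements(
    links: Sequence[OrthologLink],
    min_block_size: int = 3,
    translocation_offset: float = 5e6,
    outlier_per: int = 10,
) -> list[RearrangementBlock]:
    """Detect inversion/translocation blocks from ordered ortholog links.

    Links (syntenic only, one reference chromosome) must be sorted by wheat
    map position.  The reference-position sequence is segmented into maximal
    monotone runs; a run against the dominant direction — or a complete
    reversal — is an inversion, a run whose reference interval is displaced
    by more than ``translocation_offset`` from the colinear interpolation
    between its neighbours is a translocation, and both together a
    translocation (inversion).
    """
    links = [l for l in links if l.syntenic]
    if len(links) < min_block_size:
        return []
    wheat = np.array([l.wheat_position for l in links], dtype=float)
    if np.any(np.diff(wheat) < 0):
        raise InvalidParameterError("links must be sorted by wheat position")
    ref = np.array([l.ref_position for l in links], dtype=float)
    runs = _monotone_runs(ref, min_block_size, outlier_per)
    if not runs:
        return []
    # dominant direction weighted by run length
    weight = {1: 0, -1: 0}
    for s, e, d in runs:
        weight[d] += e - s + 1
    dominant = 1 if weight[1] >= weight[-1] else -1
    if len(runs) == 1:
        s, e, d = runs[0]
        if d == -1:  # whole-span reversal against the reference orientation
            return [_block("inversion", links, s, e)]
        return []
    # colinear expectation: fit on genes of dominant-direction runs
    dom_idx = np.concatenate(
        [np.arange(s, e + 1) for s, e, d in runs if d == dominant]
    )
    coeffs = np.polyfit(wheat[dom_idx], ref[dom_idx], 1)
    expected = np.polyval(coeffs, wheat)
    blocks = []
    for s, e, d in runs:
        displacement = float(np.median(np.abs(ref[s:e + 1] - expected[s:e + 1])))
        inverted = d != dominant
        displaced = displacement > translocation_offset
        if inverted and displaced:
            blocks.append(_block("translocation+inversion", links, s, e))
        elif inverted:
            blocks.append(_block("inversion", links, s, e))
        elif displaced:
            blocks.append(_block("translocation", links, s, e))
    return blocks


def _block(kind: str, links: Sequence[OrthologLink], s: int, e: int) -> RearrangementBlock:
    return RearrangementBlock(
        kind=kind,
        wheat_start=links[s].wheat_position,
        wheat_end=links[e].wheat_position,
        gene_start_id=links[s].gene_id,
        gene_end_id=links[e].gene_id,
        n_genes=e - s + 1,
    )


# ---------------------------------------------------------------------------
# Link export
# ---------------------------------------------------------------------------

def synteny_link_table(links: Sequence[OrthologLink]) -> pd.DataFrame:
    """Per-link table (wheat position, reference chromosome/position) for plotting."""
    return pd.DataFrame(
        [
            {
                "gene_id": l.gene_id,
                "wheat_position": l.wheat_position,
                "ref_chromosome": l.ref_chromosome,
                "ref_position": l.ref_position,
                "syntenic": l.syntenic,
            }
            for l in links
        ],
        columns=["gene_id", "wheat_position", "ref_chromosome", "ref_position", "syntenic"],
    )


def link_counts(links: Sequence[OrthologLink]) -> pd.Series:
    """Link counts per reference chromosome."""
    table = synteny_link_table(links)
    if table.empty:
        return pd.Series(dtype=int)
    return table.groupby("ref_chromosome").size().sort_index()
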