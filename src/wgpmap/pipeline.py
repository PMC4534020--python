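"""End-to-end orchestration: simulate -> assemble -> screen -> map -> integrate.

Each stage function consumes the result of the previous one, mirroring the
CLI subcommands; ``run`` executes everything from a :class:`RunConfig` and is
the entry point used for whole-pipeline evaluation against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
import numpy as np

from . import assembly as asm
from . import comparative as cmp
from . import contamination as scr
from . import integration as intg
from . import rhmap as rh
from . import simgen
from .config import RunConfig


@dataclass
class PipelineResult:
    config: RunConfig
    dataset: simgen.SimulatedDataset | None = None
    params: asm.AssemblyParams | None = None
    kept: list[asm.Fingerprint] = dc_field(default_factory=list)
    excluded: list[asm.Fingerprint] = dc_field(default_factory=list)
    assembly: asm.AssemblyResult | None = None
    chosen_exponent: int | None = None
    contigs: list[asm.Contig] = dc_field(default_factory=list)
    singletons: list[asm.Fingerprint] = dc_field(default_factory=list)
    eliminated_foreign: list[asm.Contig] = dc_field(default_factory=list)
    eliminated_small: list[asm.Contig] = dc_field(default_factory=list)
    foreign_calls: dict = dc_field(default_factory=dict)
    rh_map: rh.RHMap | None = None
    locus_partition: list = dc_field(default_factory=list)
    collapsed: rh.RHGenotypeMatrix | None = None
    anchors: list[intg.MarkerAnchor] = dc_field(default_factory=list)
    placements: list[intg.ContigPlacement] = dc_field(default_factory=list)
    arm_of_locus: dict = dc_field(default_factory=dict)
    gene_assignments: dict = dc_field(default_factory=dict)
    rearrangements: list = dc_field(default_factory=list)


def run_simulate(config: RunConfig) -> PipelineResult:
    p = dict(config.simulate)
    p.pop("break_distribution", None)
    result = PipelineResult(config=config)
    result.dataset = simgen.simulate_dataset(seed=config.seed, **p)
    return result


def run_assemble(result: PipelineResult) -> PipelineResult:
    ds = result.dataset
    cfg = result.config.assemble
    fps = [
        asm.Fingerprint(bac_id=b, tags=t) for b, t in sorted(ds.fingerprints.items())
        if t
    ]
    kept, excluded, lo, hi = asm.filter_bacs_by_tag_count(
        fps, low_factor=cfg["low_factor"], high_factor=cfg["high_factor"]
    )
    gel = cfg["gel_length_G"] or len({t for f in kept for t in f.tags})
    spacing = cfg["cb_unit"] or int(
        round(
            result.config.simulate["insert_mean"]
            / result.config.simulate["mean_tags_per_bac"]
        )
    )
    params = asm.AssemblyParams(
        gel_length_G=gel,
        cb_unit=spacing,
        from_end=cfg["from_end"],
        initial_cutoff_exponent=cfg["initial_cutoff_exponent"],
        final_cutoff_exponent=cfg["final_cutoff_exponent"],
        step_exponent=cfg["step_exponent"],
        dq_fraction=cfg["dq_fraction"],
        dq_step=cfg["dq_step"],
    )
    result.params = params
    result.kept, result.excluded = kept, excluded
    result.assembly = asm.stepwise_assembly(kept, params)
    # coverage target: the converged cumulative size of the most relaxed
    # round, the data-driven estimate of assemblable content (a fragmented
    # mid-assembly overestimates it by double-counting overlap tags)
    result.chosen_exponent = asm.select_final_cutoff(
        result.assembly.ledger,
        coverage_target=result.assembly.ledger[-1].cumulative_size,
    )
    contigs, singles = result.assembly.state_at(result.chosen_exponent)
    result.contigs, result.singletons = list(contigs), list(singles)
    return result


def run_screen(result: PipelineResult) -> PipelineResult:
    ds = result.dataset
    cfg = result.config.screen
    origins = ds.truth.tag_origin
    by_id = {f.bac_id: f for f in result.kept}
    calls = {
        b: scr.flag_foreign_bac(f, origins, ds.model.name, margin=cfg["margin"])
        for b, f in by_id.items()
    }
    flags = {b: c.flag for b, c in calls.items()}
    retained, foreign = scr.eliminate_low_confidence_contigs(
        result.contigs, flags, fraction=cfg["fraction"]
    )
    retained, small = scr.eliminate_redundant_small_contigs(
        retained, min_members=cfg["min_members"], containment=cfg["containment"]
    )
    result.foreign_calls = calls
    result.contigs = retained
    result.eliminated_foreign = foreign
    result.eliminated_small = small
    return result


def run_rhmap(result: PipelineResult) -> PipelineResult:
    ds = result.dataset
    cfg = result.config.rhmap
    matrix = rh.RHGenotypeMatrix.from_dataframe(ds.rh_calls)
    partition, collapsed = rh.collapse_coretained(matrix)
    groups = rh.group_markers(
        collapsed, lod_min=cfg["lod_min"], d_max_cR=cfg["d_max_cR"]
    )
    rh_map = rh.order_loci(groups[0], collapsed)
    by_name = {loc[0]: loc for loc in partition}
    rh_map.loci = [list(by_name[n]) for n in rh_map.locus_names]

    # orient the map S-telomere first using the arm labels known from the
    # arm-specific libraries (ground truth in simulation)
    arm_of_locus = {
        name: ds.model.arm_of(ds.truth.marker_position[name])
        for name in rh_map.locus_names
    }
    n_loci = rh_map.n_loci
    s_ranks = [i for i, n in enumerate(rh_map.locus_names) if arm_of_locus[n] == "S"]
    if s_ranks and np.mean(s_ranks) > n_loci / 2:
        rh_map.locus_names = rh_map.locus_names[::-1]
        rh_map.loci = rh_map.loci[::-1]
        gaps = np.diff(rh_map.positions_cR)[::-1]
        rh_map.positions_cR = np.concatenate(([0.0], np.cumsum(gaps)))

    matrix_loci = collapsed.subset(rh_map.locus_names)
    rh_map.obligate_breaks_total = rh.count_obligate_breaks(
        rh_map.locus_names, matrix_loci
    )
    del_matrix = rh.RHGenotypeMatrix.from_dataframe(
        ds.deletion_calls[rh_map.locus_names]
    )
    rh_map.bins = rh.assign_deletion_bins(
        rh_map.locus_names, del_matrix, arm_of_locus=arm_of_locus
    )
    result.rh_map = rh_map
    result.locus_partition = partition
    result.collapsed = collapsed
    result.arm_of_locus = arm_of_locus
    return result


def run_integrate(result: PipelineResult, gap_cR: float | None = None) -> PipelineResult:
    ds = result.dataset
    gap = gap_cR if gap_cR is not None else result.config.integrate["gap_cR"]
    member_of = {
        m.bac_id: c.id for c in result.contigs for m in c.members
    }
    anchors = [
        intg.MarkerAnchor(marker_id=r.marker_id, bac_id=r.bac_id,
                          contig_id=member_of[r.bac_id])
        for r in ds.anchors.itertuples()
        if r.bac_id in member_of
    ]
    fps_by_id = {f.bac_id: f for f in result.kept}
    split_contigs = []
    for c in result.contigs:
        split_contigs.extend(
            intg.detect_and_split_chimeras(
                c, anchors, result.rh_map, result.params, fps_by_id, gap_cR=gap
            )
        )
    member_of = {m.bac_id: c.id for c in split_contigs for m in c.members}
    anchors = [
        intg.MarkerAnchor(marker_id=r.marker_id, bac_id=r.bac_id,
                          contig_id=member_of[r.bac_id])
        for r in ds.anchors.itertuples()
        if r.bac_id in member_of
    ]
    result.contigs = split_contigs
    result.anchors = anchors

    names = result.rh_map.locus_names
    boundary = next(
        (i for i, n in enumerate(names) if result.arm_of_locus[n] == "L"), len(names)
    )
    placements = intg.place_contigs(
        result.contigs, anchors, result.rh_map, arm_boundary_locus=boundary
    )
    # per-locus synteny ranking for co-located contigs
    links = ds.links
    marker_contig = {
        a.marker_id: a.contig_id for a in anchors
    }
    ortho_pos: dict[str, list[float]] = {}
    for r in links.itertuples():
        if r.syntenic and r.gene_id in marker_contig:
            ortho_pos.setdefault(marker_contig[r.gene_id], []).append(r.ref_position)
    by_locus: dict[int, list[intg.ContigPlacement]] = {}
    for p in placements:
        if p.locus_index is not None:
            by_locus.setdefault(p.locus_index, []).append(p)
    final = [p for p in placements if p.locus_index is None]
    for locus, group in sorted(by_locus.items()):
        if len(group) > 1:
            final.extend(intg.order_within_locus_by_synteny(group, ortho_pos))
        else:
            final.extend(group)
    result.placements = final

    # fill bin sizes and per-bin obligate breaks
    locus_rank = {n: i for i, n in enumerate(names)}
    size_of = {c.id: c.estimated_size for c in result.contigs}
    placed = {p.contig_id: p for p in final if p.locus_index is not None}
    matrix_loci = result.collapsed.subset(names)
    for b in result.rh_map.bins:
        ranks = sorted(locus_rank[l] for l in b.loci)
        b.obligate_breaks = rh.count_obligate_breaks(
            names, matrix_loci, locus_range=(ranks[0], ranks[-1] + 1)
        )
        in_bin = [
            p for p in placed.values() if p.locus_index in set(ranks)
        ]
        b.mapped_contig_size_mb = sum(size_of[p.contig_id] for p in in_bin) / 1e6
    return result


def run_compare(result: PipelineResult) -> PipelineResult:
    ds = result.dataset
    cfg = result.config.compare
    # tag-mediated gene transfer: survey sequence contigs around each gene
    tag_pos = ds.truth.tag_position
    spacing = int(
        round(
            result.config.simulate["insert_mean"]
            / result.config.simulate["mean_tags_per_bac"]
        )
    )
    seq_contig_genes: dict[str, list[str]] = {}
    tag_hits: dict[int, str] = {}
    hit_count: dict[int, int] = {}
    links = ds.links
    for r in links.itertuples():
        sc = f"SSC_{r.gene_id}"
        seq_contig_genes[sc] = [r.gene_id]
        lo = (r.position - 40_000) // spacing
        hi = (r.position + 40_000) // spacing
        for t in range(max(0, int(lo)), int(hi) + 1):
            if t in tag_pos:
                hit_count[t] = hit_count.get(t, 0) + 1
                tag_hits[t] = sc
    unique_hits = {t: sc for t, sc in tag_hits.items() if hit_count[t] == 1}
    assignments, _discarded, _unassigned = cmp.assign_genes_via_tags(
        unique_hits, seq_contig_genes, result.contigs
    )
    result.gene_assignments = assignments

    # ordered ortholog links in cumulative map coordinates
    placed = {
        p.contig_id: p for p in result.placements if p.locus_index is not None
    }
    size_of = {c.id: c.estimated_size for c in result.contigs}
    offset, offsets = 0, {}
    for p in sorted(placed.values(), key=intg.map_order_key):
        offsets[p.contig_id] = offset
        offset += size_of[p.contig_id]
    syn = links[links.syntenic]
    rows = []
    for r in syn.itertuples():
        contig = assignments.get(r.gene_id)
        if contig in offsets:
            rows.append(
                cmp.OrthologLink(
                    gene_id=r.gene_id,
                    wheat_position=offsets[contig] + size_of[contig] / 2,
                    ref_chromosome=r.ref_chromosome,
                    ref_position=r.ref_position,
                    syntenic=True,
                )
            )
    rows.sort(key=lambda l: l.wheat_position)
    result.rearrangements = cmp.detect_rearrangements(
        rows,
        min_block_size=cfg["min_block_size"],
        translocation_offset=cfg["translocation_offset"],
    )
    return result


def run(config: RunConfig, upto: str = "compare") -> PipelineResult:
    stages = ["simulate", "assemble", "screen", "rhmap", "integrate", "compare"]
    funcs = {
        "simulate": run_simulate,
        "assemble": run_assemble,
        "screen": run_screen,
        "rhmap": run_rhmap,
        "integrate": run_integrate,
        "compare": run_compare,
    }
    result = run_simulate(config)
    for stage in stages[1:]:
        if stages.index(stage) > stages.index(upto):
            break
        result = funcs[stage](result)
    return result
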