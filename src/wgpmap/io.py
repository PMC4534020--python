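"""Readers and writers for the pipeline's plain-text exchange formats.

All writers are deterministic given identical inputs: rows follow stable sort
orders and floats are formatted at fixed precision (sizes in Mb at 1 decimal
place, resolutions at 2).  BED output is 0-based half-open; AGP and GFF3 are
1-based inclusive; each file states its convention in a header comment.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import __version__
from .assembly import Contig, Fingerprint, RoundSummary
from .errors import InvalidParameterError
from .integration import ContigPlacement
from .rhmap import RHMap
from .simgen import ChromosomeModel


# ---------------------------------------------------------------------------
# Fingerprints TSV
# ---------------------------------------------------------------------------

def write_fingerprints(fingerprints: Sequence[Fingerprint], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bac_id\ttags\n")
        for f in sorted(fingerprints, key=lambda f: f.bac_id):
            fh.write(f"{f.bac_id}\t{','.join(str(t) for t in sorted(f.tags))}\n")


def read_fingerprints(path: str | Path) -> list[Fingerprint]:
    """Read the bac_id / comma-separated-tags TSV written by write_fingerprints.

    Duplicate bac_ids raise an error naming the clone; duplicate tags within
    one clone collapse to a set with a warning.
    """
    out: list[Fingerprint] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("bac_id"):
            raise InvalidParameterError("fingerprint TSV must start with a bac_id header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            bac_id, _, tag_field = line.partition("\t")
            if bac_id in seen:
                raise InvalidParameterError(f"duplicate bac_id {bac_id!r}")
            seen.add(bac_id)
            raw = [int(t) for t in tag_field.split(",")] if tag_field else []
            tags = frozenset(raw)
            if len(tags) != len(raw):
                warnings.warn(f"clone {bac_id}: duplicate tags collapsed to a set")
            out.append(Fingerprint(bac_id=bac_id, tags=tags))
    return out


# ---------------------------------------------------------------------------
# Genotype CSV
# ---------------------------------------------------------------------------

def write_genotypes(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, na_rep="NA")


def read_genotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, na_values=["NA"])


# ---------------------------------------------------------------------------
# Contig and ledger tables
# ---------------------------------------------------------------------------

def write_contig_table(contigs: Sequence[Contig], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tn_members\tmembers\tcb_starts\tunique_tags\tsize_bp\tstatus\n")
        for c in sorted(contigs, key=lambda c: c.id):
            fh.write(
                "\t".join(
                    [
                        c.id,
                        str(c.n_members),
                        ",".join(m.bac_id for m in c.members),
                        ",".join(str(m.cb_start) for m in c.members),
                        str(c.unique_tags),
                        str(c.estimated_size),
                        c.status,
                    ]
                )
                + "\n"
            )


def write_ledger(ledger: Sequence[RoundSummary], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "cutoff_exponent": r.cutoff_exponent,
                "n_contigs": r.n_contigs,
                "n_q_contigs": r.n_q_contigs,
                "n_singletons": r.n_singletons,
                "cumulative_size": r.cumulative_size,
            }
            for r in ledger
        ]
    ).to_csv(path, index=False)


def write_fpc_like(contigs: Sequence[Contig], path: str | Path) -> None:
    """Minimal FPC-style plain-text export of contigs and clone placements."""
    with open(path, "w") as fh:
        for c in sorted(contigs, key=lambda c: c.id):
            fh.write(f"Ctg{c.id}  members={c.n_members}  tags={c.unique_tags}\n")
            for m in c.members:
                fh.write(f"  BAC {m.bac_id} Map \"{c.id}\" Ends Left {m.cb_start} Right {m.cb_end}\n")


# ---------------------------------------------------------------------------
# RH map TSV
# ---------------------------------------------------------------------------

def write_rh_map(rhmap: RHMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tmarkers\tposition_cR\tbin\n")
        bin_of = {}
        for b in rhmap.bins:
            for locus in b.loci:
                bin_of[locus] = b.name
        for name, markers, pos in zip(
            rhmap.locus_names, rhmap.loci, rhmap.positions_cR
        ):
            fh.write(
                f"{name}\t{','.join(markers)}\t{pos:.1f}\t{bin_of.get(name, '')}\n"
            )


def write_bin_resolution(rhmap: RHMap, path: str | Path) -> None:
    rows = []
    for b in rhmap.bins:
        res = b.resolution_mb_per_break
        rows.append(
            {
                "bin": b.name,
                "n_loci": len(b.loci),
                "mapped_contig_size_mb": f"{b.mapped_contig_size_mb:.1f}",
                "obligate_breaks": b.obligate_breaks,
                "resolution_mb_per_break": "NA" if res is None else f"{res:.2f}",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GFF3 / BED / AGP
# ---------------------------------------------------------------------------

def write_gff3(model: ChromosomeModel, path: str | Path) -> None:
    """Simulated gene models as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {model.name} 1 {model.length}\n")
        for i, pos in enumerate(model.gene_positions):
            start = int(pos) + 1
            fh.write(
                f"{model.name}\twgpmap\tgene\t{start}\t{start + 999}\t.\t+\t.\t"
                f"ID=gene{i:05d}\n"
            )


def write_bed(
    placements: Sequence[ContigPlacement],
    contigs: Sequence[Contig],
    path: str | Path,
    object_name: str = "map",
) -> None:
    """Contig placements in cumulative map coordinates (0-based half-open)."""
    size_of = {c.id: c.estimated_size for c in contigs}
    placed = sorted(
        (p for p in placements if p.locus_index is not None),
        key=lambda p: (p.locus_index, p.within_locus_rank, p.contig_id),
    )
    with open(path, "w") as fh:
        fh.write("# BED: 0-based, half-open map coordinates\n")
        pos = 0
        for p in placed:
            size = size_of.get(p.contig_id, 0)
            strand = p.orientation if p.orientation in "+-" else "."
            fh.write(f"{object_name}\t{pos}\t{pos + size}\t{p.contig_id}\t0\t{strand}\n")
            pos += size


def write_agp(
    placements: Sequence[ContigPlacement],
    contigs: Sequence[Contig],
    path: str | Path,
    object_name: str = "map",
    gap_length: int = 100,
) -> None:
    """AGP 2.1 export of the ordered, oriented contigs (1-based inclusive).

    Component lines are type W with orientation +/-/?; inter-contig gaps are
    type U, length 100, gap_type contig, linkage no.
    """
    size_of = {c.id: c.estimated_size for c in contigs}
    placed = sorted(
        (p for p in placements if p.locus_index is not None),
        key=lambda p: (p.locus_index, p.within_locus_rank, p.contig_id),
    )
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        fh.write("# coordinates: 1-based, inclusive\n")
        pos = 0
        part = 0
        for i, p in enumerate(placed):
            if i > 0:
                part += 1
                fh.write(
                    f"{object_name}\t{pos + 1}\t{pos + gap_length}\t{part}\tU\t"
                    f"{gap_length}\tcontig\tno\tna\n"
                )
                pos += gap_length
            size = size_of.get(p.contig_id, 0)
            if size <= 0:
                raise InvalidParameterError(f"contig {p.contig_id} has no size")
            part += 1
            orient = p.orientation if p.orientation in "+-" else "?"
            fh.write(
                f"{object_name}\t{pos + 1}\t{pos + size}\t{part}\tW\t"
                f"{p.contig_id}\t1\t{size}\t{orient}\n"
            )
            pos += size


def read_agp(path: str | Path) -> pd.DataFrame:
    """Read back an AGP file (component W lines only) with basic validation."""
    rows = []
    last_end = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise InvalidParameterError("AGP lines must have 9 columns")
            obj, start, end, part, kind = fields[:5]
            start, end = int(start), int(end)
            if start != last_end + 1:
                raise InvalidParameterError(
                    f"AGP object coordinates must be contiguous at part {part}"
                )
            last_end = end
            if kind == "W":
                rows.append(
                    {
                        "object": obj,
                        "object_start": start,
                        "object_end": end,
                        "component_id": fields[5],
                        "orientation": fields[8],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    *,
    command: str,
    seed: int | None,
    params: Mapping,
    inputs: Iterable[str | Path] = (),
    started: float | None = None,
) -> None:
    manifest = {
        "tool": "wgpmap",
        "version": __version__,
        "command": command,
        "seed": seed,
        "params": dict(params),
        "inputs": {str(p): sha256_of(p) for p in inputs},
        "wall_time_s": None if started is None else round(time.time() - started, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
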