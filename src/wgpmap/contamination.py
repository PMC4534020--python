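"""Screening of foreign-chromosome BACs and low-confidence contigs.

Arm-sorted chromosome fractions are 85-92% pure, so a BAC library carries
clones from other chromosomes.  Each WGP tag can be assigned (by an external
homology search, abstracted here as a plug-in table) to a chromosome group;
a clone whose tags vote predominantly for a non-target group is flagged
foreign, and contigs dominated by such clones are eliminated.  Small contigs
whose tags are almost entirely contained in a larger contig are shadows of
low-quality duplicate fingerprints and are dropped as redundant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .assembly import Contig, Fingerprint

TagOriginTable = Mapping[int, str]


@dataclass(frozen=True)
class ForeignCall:
    flag: str  # "target" | "foreign" | "indeterminate"
    counts: dict[str, int]


def flag_foreign_bac(
    fingerprint: Fingerprint,
    origins: TagOriginTable,
    target_group: str,
    margin: int = 4,
) -> ForeignCall:
    """Vote a clone's tags by chromosome group of origin.

    The clone is foreign iff the best non-target group outnumbers the target
    group by strictly more than ``margin`` tags.  Clones whose tags are all
    unassigned are indeterminate, not foreign.
    """
    counts = Counter(origins.get(t, "unassigned") for t in fingerprint.tags)
    assigned = {g: n for g, n in counts.items() if g != "unassigned"}
    if not assigned:
        return ForeignCall("indeterminate", dict(counts))
    target = assigned.get(target_group, 0)
    best_other = max(
        (n for g, n in assigned.items() if g != target_group), default=0
    )
    flag = "foreign" if best_other - target > margin else "target"
    return ForeignCall(flag, dict(counts))


def eliminate_low_confidence_contigs(
    contigs: Sequence[Contig],
    foreign_flags: Mapping[str, str],
    fraction: float = 0.66,
) -> tuple[list[Contig], list[Contig]]:
    """Drop contigs in which foreign clones exceed ``fraction`` of the members.

    ``foreign_flags`` maps bac_id to the flag from :func:`flag_foreign_bac`;
    indeterminate clones count in the denominator but not as foreign.
    """
    retained, eliminated = [], []
    for c in contigs:
        n_foreign = sum(
            1 for m in c.members if foreign_flags.get(m.bac_id) == "foreign"
        )
        if n_foreign / c.n_members > fraction:
            c.status = "eliminated-foreign"
            eliminated.append(c)
        else:
            retained.append(c)
    return retained, eliminated


def eliminate_redundant_small_contigs(
    contigs: Sequence[Contig],
    min_members: int = 3,
    containment: float = 0.8,
) -> tuple[list[Contig], list[Contig]]:
    """Drop small contigs whose tags are contained in one larger contig.

    A contig with fewer than ``min_members`` members is eliminated iff at
    least ``containment`` of its unique tags also occur in a single larger
    retained contig (a depth/containment proxy for redundant shadows of
    duplicated low-quality fingerprints).
    """
    hosts = [c for c in contigs if c.n_members >= min_members]
    retained, eliminated = [], []
    for c in contigs:
        if c.n_members >= min_members:
            retained.append(c)
            continue
        contained = any(
            h is not c
            and h.n_members > c.n_members
            and len(c.tags & h.tags) / len(c.tags) >= containment
            for h in hosts
        )
        if contained:
            c.status = "eliminated-small"
            eliminated.append(c)
        else:
            retained.append(c)
    return retained, eliminated


def screen_report(
    contigs: Sequence[Contig], calls: Mapping[str, ForeignCall]
) -> list[dict]:
    """Per-contig vote tallies for the elimination report."""
    rows = []
    for c in contigs:
        tally = Counter()
        for m in c.members:
            if m.bac_id in calls:
                tally[calls[m.bac_id].flag] += 1
        rows.append(
            {
                "contig_id": c.id,
                "n_members": c.n_members,
                "n_foreign": tally["foreign"],
                "n_indeterminate": tally["indeterminate"],
                "status": c.status,
            }
        )
    return rows
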