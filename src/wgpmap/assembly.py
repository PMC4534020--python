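"""BAC fingerprint contig assembly from whole-genome-profiling tags.

The engine follows the FPC-style workflow used for large cereal physical
maps: clones are compared by the Sulston score (the probability that two
fingerprints share at least the observed number of tags by chance), clustered
by single linkage at a stringent initial cut-off, then merged stepwise at
progressively relaxed cut-offs where only end-to-end / single-to-end joins
are allowed, with Questionable (Q) clone screening after every round.  Contig
sizes are expressed in consensus-band (CB) units, one unit being the average
genomic spacing between adjacent tags.

With a tag-match tolerance of 0 the Sulston score has the closed form

    q = 1 - (1 - 1/G)^n_H,     score = P(X >= m),  X ~ Binomial(n_L, q)

where G is the gel length (number of distinct possible tags), n_L <= n_H the
two tag counts and m the number of shared tags.  Scores far below the double-
precision floor are handled in log10 space throughout.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import (
    DisconnectedContigWarning,
    EmptyInputError,
    InvalidParameterError,
    SplitLoopWarning,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Parameters and domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssemblyParams:
    """FPC-style assembly parameters.

    ``gel_length_G`` is the count of distinct possible tags; ``cb_unit`` the
    bp value of one consensus-band interval; ``from_end`` the end-region
    window (in tag units) inside which a clone counts as an end clone for
    merge rounds.  Cut-offs are base-10 exponents: the initial assembly runs
    at 1e<initial>, relaxing by ``step_exponent`` per round up to 1e<final>.
    Contigs whose Q-clone fraction exceeds ``dq_fraction`` are re-assembled
    at a cut-off ``dq_step`` steps more stringent.
    """

    gel_length_G: int
    tolerance: int = 0
    cb_unit: int = 5220
    from_end: int = 12
    initial_cutoff_exponent: int = -75
    final_cutoff_exponent: int = -12
    step_exponent: int = 5
    dq_fraction: float = 0.10
    dq_step: int = 3

    def __post_init__(self) -> None:
        if self.gel_length_G <= 0:
            raise InvalidParameterError("gel_length_G must be positive")
        if self.tolerance != 0:
            raise InvalidParameterError("only tolerance 0 (exact tag identity) is supported")
        if self.initial_cutoff_exponent > self.final_cutoff_exponent:
            raise InvalidParameterError(
                "initial cut-off exponent must be <= final cut-off exponent"
            )
        if not 0 < self.dq_fraction < 1:
            raise InvalidParameterError("dq_fraction must lie in (0, 1)")

    @property
    def cutoff_exponents(self) -> list[int]:
        return list(
            range(
                self.initial_cutoff_exponent,
                self.final_cutoff_exponent + 1,
                self.step_exponent,
            )
        )


@dataclass(frozen=True)
class Fingerprint:
    bac_id: str
    tags: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tags", frozenset(self.tags))

    @property
    def n_tags(self) -> int:
        return len(self.tags)


@dataclass(frozen=True)
class ClonePlacement:
    """A member clone's consensus-band interval within its contig."""

    bac_id: str
    cb_start: int
    cb_end: int  # half-open, in tag units
    n_tags: int


@dataclass
class Contig:
    id: str
    members: list[ClonePlacement]
    unique_tags: int
    estimated_size: int
    tags: frozenset[int]
    q_clone_ids: set[str] = field(default_factory=set)
    status: str = "retained"

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def cb_span(self) -> int:
        return max(m.cb_end for m in self.members)

    @property
    def q_fraction(self) -> float:
        return len(self.q_clone_ids) / len(self.members)

    @property
    def member_ids(self) -> list[str]:
        return [m.bac_id for m in self.members]


class FilterResult(NamedTuple):
    kept: list[Fingerprint]
    excluded: list[Fingerprint]
    lower: int
    upper: int


# ---------------------------------------------------------------------------
# Tag-count filter
# ---------------------------------------------------------------------------

def filter_bacs_by_tag_count(
    fingerprints: Sequence[Fingerprint],
    low_factor: float = 0.3,
    high_factor: float = 2.5,
    thresholds: tuple[int, int] | None = None,
) -> FilterResult:
    """Drop clones with unusually few or many tags relative to the dataset mean.

    A clone is kept iff ceil(low_factor*mean) <= n_tags <= floor(high_factor*mean);
    explicit ``thresholds`` override the computed pair.
    """
    if not fingerprints:
        raise EmptyInputError("no fingerprints supplied")
    if thresholds is None:
        mean = float(np.mean([f.n_tags for f in fingerprints]))
        lower = math.ceil(low_factor * mean)
        upper = math.floor(high_factor * mean)
    else:
        lower, upper = thresholds
    kept = [f for f in fingerprints if lower <= f.n_tags <= upper]
    excluded = [f for f in fingerprints if not lower <= f.n_tags <= upper]
    log.info(
        "tag-count filter: kept %d of %d clones (thresholds %d..%d)",
        len(kept), len(fingerprints), lower, upper,
    )
    return FilterResult(kept, excluded, lower, upper)


# ---------------------------------------------------------------------------
# Sulston score
# ---------------------------------------------------------------------------

def _log10_binom_sf(m: int, n: int, q: float) -> float:
    """log10 P(X >= m) for X ~ Binomial(n, q), stable for extreme tails."""
    if m <= 0:
        return 0.0
    if m > n:
        return -math.inf
    k = np.arange(m, n + 1)
    logpmf = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * math.log(q) + (n - k) * math.log1p(-q)
    )
    return float(logsumexp(logpmf)) / math.log(10)


def sulston_log10(n1: int, n2: int, m: int, gel_length_G: int) -> float:
    """log10 Sulston score for tag counts ``n1``/``n2`` sharing ``m`` tags."""
    if gel_length_G <= 0:
        raise InvalidParameterError("gel length G must be positive")
    if n1 <= 0 or n2 <= 0:
        raise InvalidParameterError("both fingerprints must carry tags")
    n_lo, n_hi = min(n1, n2), max(n1, n2)
    if gel_length_G < n_hi:
        raise InvalidParameterError("gel length G must be >= the larger tag count")
    q = -math.expm1(n_hi * math.log1p(-1.0 / gel_length_G))
    return _log10_binom_sf(m, n_lo, q)


def sulston_score(f1: Fingerprint, f2: Fingerprint, params: AssemblyParams) -> float:
    """Probability of sharing at least the observed tags by chance (symmetric).

    Underflows to 0.0 below ~1e-308; use :func:`sulston_log10` when the
    magnitude matters at extreme overlaps.
    """
    m = len(f1.tags & f2.tags)
    return 10.0 ** max(
        sulston_log10(f1.n_tags, f2.n_tags, m, params.gel_length_G), -5000.0
    )


# ---------------------------------------------------------------------------
# Single-linkage clustering and the consensus-band map
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller label becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def _candidate_pairs(fps: Sequence[Fingerprint]) -> set[tuple[str, str]]:
    """All clone pairs sharing at least one tag, via an inverted tag index."""
    index: dict[int, list[str]] = {}
    for f in fps:
        for t in f.tags:
            index.setdefault(t, []).append(f.bac_id)
    pairs: set[tuple[str, str]] = set()
    for ids in index.values():
        if len(ids) < 2:
            continue
        ids = sorted(ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs.add((ids[i], ids[j]))
    return pairs


def _flag_q_clones(
    fps: Mapping[str, Fingerprint],
    placements: Mapping[str, tuple[int, int]],
    tag_coord_shifted: Mapping[int, int],
) -> set[str]:
    """A clone is Questionable if <50% of its tags sit inside its CB window.

    The window is [cb_start, cb_start + 1.5*n_tags): a correctly placed clone
    keeps all its tags within roughly its own span even when neighbours
    contribute interleaved tags it dropped, while a clone glued together from
    distant regions scatters tags far beyond it.
    """
    q: set[str] = set()
    for bac_id, (start, _end) in placements.items():
        f = fps[bac_id]
        window_end = start + math.ceil(1.5 * f.n_tags)
        inside = sum(1 for t in f.tags if start <= tag_coord_shifted[t] < window_end)
        if inside / f.n_tags < 0.5:
            q.add(bac_id)
    return q


def _make_contig(
    contig_id: str, fps: Sequence[Fingerprint], params: AssemblyParams
) -> Contig:
    coord = _consensus_tag_coords(fps)
    placements = {
        f.bac_id: (
            min(coord[t] for t in f.tags),
            max(coord[t] for t in f.tags) + 1,
        )
        for f in fps
    }
    by_id = {f.bac_id: f for f in fps}
    members = [
        ClonePlacement(bac_id=b, cb_start=s, cb_end=e, n_tags=by_id[b].n_tags)
        for b, (s, e) in sorted(placements.items(), key=lambda kv: (kv[1][0], kv[0]))
    ]
    all_tags = frozenset().union(*(f.tags for f in fps))
    q = _flag_q_clones(by_id, placements, coord)
    return Contig(
        id=contig_id,
        members=members,
        unique_tags=len(all_tags),
        estimated_size=len(all_tags) * params.cb_unit,
        tags=all_tags,
        q_clone_ids=q,
    )


def _consensus_tag_coords(fps: Sequence[Fingerprint]) -> dict[int, int]:
    """Greedy seriation of a clone set into consensus-band tag coordinates.

    Seeds at the clone with the most tags, then repeatedly attaches the
    unplaced clone sharing the most already-placed tags, extending the tag
    coordinate axis on the side suggested by the placed overlap.  Ties break
    by bac_id so the map is independent of input order.  Coordinates are
    shifted so the smallest is 0.
    """
    coord: dict[int, int] = {}
    remaining = {f.bac_id: f for f in fps}
    seed = max(remaining.values(), key=lambda f: (f.n_tags, f.bac_id))
    for i, t in enumerate(sorted(seed.tags)):
        coord[t] = i
    del remaining[seed.bac_id]
    while remaining:
        best = max(
            remaining.values(),
            key=lambda f: (sum(1 for t in f.tags if t in coord), f.bac_id),
        )
        del remaining[best.bac_id]
        known = [coord[t] for t in best.tags if t in coord]
        new_tags = sorted(t for t in best.tags if t not in coord)
        if not new_tags:
            continue
        lo, hi = min(coord.values()), max(coord.values())
        side_right = True if not known else np.mean(known) >= (lo + hi) / 2
        if side_right:
            for k, t in enumerate(new_tags):
                coord[t] = hi + 1 + k
        else:
            for k, t in enumerate(new_tags):
                coord[t] = lo - len(new_tags) + k
    shift = -min(coord.values())
    return {t: c + shift for t, c in coord.items()}


def build_contigs(
    fingerprints: Sequence[Fingerprint],
    cutoff: float,
    params: AssemblyParams,
    id_prefix: str = "CTG",
) -> tuple[list[Contig], list[Fingerprint]]:
    """Single-linkage clustering of fingerprints at one Sulston cut-off.

    Two clones join the same contig iff they are connected by a chain of
    pairs scoring at or below ``cutoff``.  Returns multi-member contigs and
    the remaining singletons separately.
    """
    log_cut = math.log10(cutoff) if cutoff > 0 else -math.inf
    fps = sorted(fingerprints, key=lambda f: f.bac_id)
    by_id = {f.bac_id: f for f in fps}
    uf = _UnionFind(by_id)
    for a, b in sorted(_candidate_pairs(fps)):
        fa, fb = by_id[a], by_id[b]
        m = len(fa.tags & fb.tags)
        if sulston_log10(fa.n_tags, fb.n_tags, m, params.gel_length_G) <= log_cut:
            uf.union(a, b)
    groups: dict[str, list[Fingerprint]] = {}
    for f in fps:
        groups.setdefault(uf.find(f.bac_id), []).append(f)
    contigs, singletons = [], []
    for i, root in enumerate(sorted(groups)):
        members = groups[root]
        if len(members) == 1:
            singletons.append(members[0])
        else:
            contigs.append(_make_contig(f"{id_prefix}{i:04d}", members, params))
    return contigs, singletons


# ---------------------------------------------------------------------------
# Stepwise assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoundSummary:
    cutoff_exponent: int
    n_contigs: int
    n_q_contigs: int
    n_singletons: int
    cumulative_size: int


@dataclass
class AssemblyResult:
    params: AssemblyParams
    rounds: list[tuple[RoundSummary, list[Contig], list[Fingerprint]]]

    @property
    def ledger(self) -> list[RoundSummary]:
        return [r[0] for r in self.rounds]

    def state_at(self, exponent: int) -> tuple[list[Contig], list[Fingerprint]]:
        for summary, contigs, singles in self.rounds:
            if summary.cutoff_exponent == exponent:
                return contigs, singles
        raise KeyError(f"no assembly round at cut-off exponent {exponent}")


def _end_clones(contig: Contig, from_end: int) -> list[str]:
    span = contig.cb_span
    lo = min(m.cb_start for m in contig.members)
    return [
        m.bac_id
        for m in contig.members
        if m.cb_start <= lo + from_end or m.cb_end >= span - from_end
    ]


def _dq_pass(
    contigs: list[Contig],
    singles: list[Fingerprint],
    fps_by_id: Mapping[str, Fingerprint],
    exponent: int,
    params: AssemblyParams,
    next_id: int,
) -> tuple[list[Contig], list[Fingerprint], int, bool]:
    """Re-assemble Q-contigs at a more stringent cut-off; True if anything split."""
    dq_exp = max(
        params.initial_cutoff_exponent,
        exponent - params.dq_step * params.step_exponent,
    )
    out, changed = [], False
    for c in contigs:
        if c.q_fraction <= params.dq_fraction or dq_exp >= exponent:
            out.append(c)
            continue
        members = [fps_by_id[m.bac_id] for m in c.members]
        subs, subsingles = build_contigs(
            members, 10.0 ** dq_exp, params, id_prefix=f"{c.id}."
        )
        if len(subs) == 1 and not subsingles:
            out.append(c)  # did not split; keep and report as a Q-contig
            continue
        changed = True
        for s in subs:
            s.id = f"CTG{next_id:04d}"
            s.status = "split-child"
            next_id += 1
            out.append(s)
        singles.extend(subsingles)
    return out, singles, next_id, changed


def stepwise_assembly(
    fingerprints: Sequence[Fingerprint],
    params: AssemblyParams,
    dq_max_iter: int = 5,
) -> AssemblyResult:
    """Stepwise FPC-style assembly with end merges and Q-contig screening.

    Round 0 is a full single-linkage assembly at the initial cut-off.  Each
    later round relaxes the cut-off by ``step_exponent`` orders of magnitude
    and admits only merges in which the joining clone pair sits within
    ``from_end`` tag units of a contig end (or is a singleton).  After every
    round, contigs with more than ``dq_fraction`` Questionable clones are
    re-assembled at a more stringent cut-off; the per-round ledger records
    contig, Q-contig and singleton counts and cumulative size.
    """
    exponents = params.cutoff_exponents
    fps_by_id = {f.bac_id: f for f in fingerprints}
    contigs, singles = build_contigs(fingerprints, 10.0 ** exponents[0], params)
    next_id = len(contigs) + len(singles)
    rounds: list[tuple[RoundSummary, list[Contig], list[Fingerprint]]] = []

    for round_no, exponent in enumerate(exponents):
        if round_no > 0:
            contigs, singles, next_id = _merge_round(
                contigs, singles, fps_by_id, exponent, params, next_id
            )
        for it in range(dq_max_iter):
            contigs, singles, next_id, changed = _dq_pass(
                contigs, singles, fps_by_id, exponent, params, next_id
            )
            if not changed:
                break
        else:
            warnings.warn(
                f"Q-contig re-assembly did not converge within {dq_max_iter} "
                f"passes at cut-off 1e{exponent}",
                SplitLoopWarning,
            )
        summary = RoundSummary(
            cutoff_exponent=exponent,
            n_contigs=len(contigs),
            n_q_contigs=sum(1 for c in contigs if c.q_fraction > params.dq_fraction),
            n_singletons=len(singles),
            cumulative_size=sum(c.estimated_size for c in contigs),
        )
        rounds.append((summary, [replace_contig(c) for c in contigs], list(singles)))
    return AssemblyResult(params=params, rounds=rounds)


def replace_contig(c: Contig) -> Contig:
    """Shallow snapshot so later rounds do not mutate recorded states."""
    return Contig(
        id=c.id,
        members=list(c.members),
        unique_tags=c.unique_tags,
        estimated_size=c.estimated_size,
        tags=c.tags,
        q_clone_ids=set(c.q_clone_ids),
        status=c.status,
    )


def _merge_round(
    contigs: list[Contig],
    singles: list[Fingerprint],
    fps_by_id: Mapping[str, Fingerprint],
    exponent: int,
    params: AssemblyParams,
    next_id: int,
) -> tuple[list[Contig], list[Fingerprint], int]:
    """One end-to-end / single-to-end merge round at cut-off 1e``exponent``."""
    log_cut = float(exponent)
    units: dict[str, list[Fingerprint]] = {}
    end_ids: dict[str, list[str]] = {}
    for c in contigs:
        units[c.id] = [fps_by_id[m.bac_id] for m in c.members]
        end_ids[c.id] = _end_clones(c, params.from_end)
    for f in singles:
        uid = f"single:{f.bac_id}"
        units[uid] = [f]
        end_ids[uid] = [f.bac_id]

    owner = {b: uid for uid, ids in end_ids.items() for b in ids}
    end_fps = [fps_by_id[b] for b in sorted(owner)]
    uf = _UnionFind(units)
    for a, b in sorted(_candidate_pairs(end_fps)):
        ua, ub = owner[a], owner[b]
        if uf.find(ua) == uf.find(ub) or ua == ub:
            continue
        fa, fb = fps_by_id[a], fps_by_id[b]
        m = len(fa.tags & fb.tags)
        if sulston_log10(fa.n_tags, fb.n_tags, m, params.gel_length_G) <= log_cut:
            uf.union(ua, ub)

    merged: dict[str, list[Fingerprint]] = {}
    for uid, fps in units.items():
        merged.setdefault(uf.find(uid), []).extend(fps)
    new_contigs, new_singles = [], []
    for root in sorted(merged):
        fps = merged[root]
        if len(fps) == 1:
            new_singles.append(fps[0])
        elif root in {c.id for c in contigs} and len(merged[root]) == len(
            units.get(root, [])
        ):
            # unchanged contig: keep its identity and cached CB map
            new_contigs.append(next(c for c in contigs if c.id == root))
        else:
            new_contigs.append(_make_contig(f"CTG{next_id:04d}", fps, params))
            next_id += 1
    return new_contigs, new_singles, next_id


def select_final_cutoff(
    ledger: Sequence[RoundSummary],
    coverage_target: float,
    band: float = 0.15,
) -> int:
    """Pick the cut-off balancing Q-contigs, contig count and map coverage.

    Among rounds whose cumulative size lies within ``band`` of
    ``coverage_target`` (bp), return the exponent minimising first the
    Q-contig count and then the contig count, breaking remaining ties toward
    the more stringent cut-off.  If no round falls inside the band, the round
    closest to the target is used.
    """
    if not ledger:
        raise EmptyInputError("empty assembly ledger")
    in_band = [
        r
        for r in ledger
        if abs(r.cumulative_size - coverage_target) <= band * coverage_target
    ]
    pool = in_band if in_band else sorted(
        ledger, key=lambda r: abs(r.cumulative_size - coverage_target)
    )[:1]
    best = min(pool, key=lambda r: (r.n_q_contigs, r.n_contigs, r.cutoff_exponent))
    return best.cutoff_exponent


# ---------------------------------------------------------------------------
# Minimal tiling path
# ---------------------------------------------------------------------------

def select_mtp(contig: Contig) -> list[str]:
    """Greedy furthest-reach minimal tiling path over member CB intervals.

    Consecutive picks overlap by at least one tag unit.  If the CB map has a
    coverage gap the cover restarts per component and a warning is emitted;
    the result is minimal for interval inputs.
    """
    ivals = sorted((m.cb_start, m.cb_end, m.bac_id) for m in contig.members)
    target_end = max(e for _s, e, _b in ivals)
    chosen: list[str] = []
    covered = ivals[0][0]
    i = 0
    n = len(ivals)
    while covered < target_end:
        best = None
        while i < n and ivals[i][0] <= max(covered - 1, ivals[0][0]):
            if best is None or ivals[i][1] > best[1]:
                best = ivals[i]
            i += 1
        if best is None or best[1] <= covered:
            # coverage gap: jump to the next component
            nxt = next((iv for iv in ivals if iv[0] > covered), None)
            if nxt is None:
                break
            warnings.warn(
                f"contig {contig.id} has a CB coverage gap at {covered}",
                DisconnectedContigWarning,
            )
            covered = nxt[0]
            continue
        chosen.append(best[2])
        covered = best[1]
    return chosen


# ---------------------------------------------------------------------------
# Assembly statistics
# ---------------------------------------------------------------------------

def assembly_stats(contigs: Sequence[Contig], arm_size: float | None = None) -> dict:
    """N50/L50 and coverage summary of a contig set.

    N50 is the size of the contig at which the descending cumulative size
    first reaches half the total; L50 is its 1-based rank.
    """
    if not contigs:
        raise EmptyInputError("no contigs to summarise")
    sizes = sorted((c.estimated_size for c in contigs), reverse=True)
    total = sum(sizes)
    acc = 0
    n50 = l50 = 0
    for rank, s in enumerate(sizes, start=1):
        acc += s
        if acc * 2 >= total:
            n50, l50 = s, rank
            break
    out = {
        "n_contigs": len(contigs),
        "cumulative_size": total,
        "N50": n50,
        "L50": l50,
    }
    if arm_size:
        out["coverage_pct"] = 100.0 * total / arm_size
    return out
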