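"""Radiation-hybrid map construction from presence/absence genotypes.

The statistical model is the equal-retention haploid RH model: between two
markers, the chromosome breaks with probability theta, and every fragment is
retained independently with a single retention probability r.  The two-point
cell probabilities are

    P(11) = r(1-theta) + r^2 theta
    P(10) = P(01) = r theta (1-r)
    P(00) = (1-r)(1-theta) + (1-r)^2 theta

Distances are expressed in centirays through the Haldane-analog metric
d = -100 ln(1 - theta), which is additive under the Markov-chain multipoint
model used for ordering.  Map lengths in centirays are therefore internally
consistent but not numerically comparable to maps built by other engines.

Lines with a missing call at either marker are dropped pairwise in two-point
estimation; the multipoint likelihood marginalises missing calls with the
forward algorithm over the retained/absent hidden state.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import (
    ContiguityWarning,
    InvalidParameterError,
    UndefinedEstimateError,
)

_EPS = 1e-9


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class RHGenotypeMatrix:
    """Presence/absence calls of markers across panel lines.

    ``calls`` is lines x markers with values 1.0, 0.0 or NaN (missing).
    """

    lines: list[str]
    markers: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.lines), len(self.markers)):
            raise InvalidParameterError("calls must be lines x markers")
        valid = np.isnan(self.calls) | (self.calls == 0) | (self.calls == 1)
        if not valid.all():
            raise InvalidParameterError("calls must be 1, 0 or missing")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RHGenotypeMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.lines, columns=self.markers)

    def column(self, marker: str) -> np.ndarray:
        return self.calls[:, self.markers.index(marker)]

    def subset(self, markers: Sequence[str]) -> "RHGenotypeMatrix":
        idx = [self.markers.index(m) for m in markers]
        return RHGenotypeMatrix(list(self.lines), list(markers), self.calls[:, idx])

    @property
    def overall_retention(self) -> float:
        return float(np.nanmean(self.calls))


# ---------------------------------------------------------------------------
# Two-point estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoPointEstimate:
    theta_hat: float
    r_hat: float
    lod: float
    d_cR: float
    n_informative: int


def _cell_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = int(np.sum((x == 0) & (y == 0)))
    return n11, n10, n01, n00


def _loglik_cells(theta: float, r: float, n11: int, n10: int, n01: int, n00: int) -> float:
    p11 = r * (1 - theta) + r * r * theta
    p10 = r * theta * (1 - r)
    p00 = (1 - r) * (1 - theta) + (1 - r) ** 2 * theta
    ll = 0.0
    for n, p in ((n11, p11), (n10 + n01, p10), (n00, p00)):
        if n:
            if p <= 0:
                return -math.inf
            ll += n * math.log(p)
    return ll


def centiray(theta: float) -> float:
    """Haldane-analog RH distance, -100 ln(1-theta); infinite at theta = 1."""
    if theta >= 1:
        return math.inf
    return -100.0 * math.log1p(-theta)


def two_point(m1: str, m2: str, matrix: RHGenotypeMatrix) -> TwoPointEstimate:
    """Maximum-likelihood two-point breakage/retention estimate for a marker pair.

    r is estimated in closed form from the marginal presence frequency;
    theta by bounded 1-D optimisation of the multinomial likelihood.  The LOD
    compares the joint fit against independent markers (theta = 1, r re-fit,
    which has the same closed form).
    """
    n11, n10, n01, n00 = _cell_counts(matrix.column(m1), matrix.column(m2))
    n = n11 + n10 + n01 + n00
    if n == 0:
        raise UndefinedEstimateError(f"no informative lines for {m1} x {m2}")
    r_hat = (2 * n11 + n10 + n01) / (2 * n)
    r_hat = min(max(r_hat, _EPS), 1 - _EPS)
    if n10 + n01 == 0:
        theta_hat = 0.0
    else:
        res = minimize_scalar(
            lambda t: -_loglik_cells(t, r_hat, n11, n10, n01, n00),
            bounds=(_EPS, 1 - _EPS),
            method="bounded",
            options={"xatol": 1e-8},
        )
        theta_hat = float(res.x)
        if theta_hat < 1e-6:
            theta_hat = 0.0
    ll_joint = _loglik_cells(theta_hat, r_hat, n11, n10, n01, n00)
    ll_null = _loglik_cells(1.0, r_hat, n11, n10, n01, n00)
    lod = max((ll_joint - ll_null) / math.log(10), 0.0)
    return TwoPointEstimate(
        theta_hat=theta_hat,
        r_hat=r_hat,
        lod=lod,
        d_cR=centiray(theta_hat),
        n_informative=n,
    )


def two_point_all_pairs(
    matrix: RHGenotypeMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (theta, r, lod, n) over all marker pairs.

    Solves the score equation of the two-point likelihood in closed form
    (it is a quadratic in theta); agrees with :func:`two_point` to the
    optimiser tolerance and is used by grouping and ordering, which need
    all-pairs tables.
    """
    c = matrix.calls
    one = (c == 1).astype(float)
    zero = (c == 0).astype(float)
    n11 = one.T @ one
    n10 = one.T @ zero
    n01 = zero.T @ one
    n00 = zero.T @ zero
    n = n11 + n10 + n01 + n00
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (2 * n11 + n10 + n01) / (2 * n)
    r = np.clip(r, _EPS, 1 - _EPS)
    c1, c2, c0 = n11, n10 + n01, n00
    a = 1 - r
    # theta^2 * a r N - theta * (a c1 + r c0 + (a+r) c2) + c2 = 0
    A2 = a * r * n
    A1 = a * c1 + r * c0 + (a + r) * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = np.sqrt(np.maximum(A1 * A1 - 4 * A2 * c2, 0.0))
        theta = np.where(c2 == 0, 0.0, (A1 - disc) / (2 * A2))
    theta = np.clip(theta, 0.0, 1 - _EPS)
    theta[n == 0] = np.nan

    def ll(th):
        p11 = r * (1 - th) + r * r * th
        p10 = r * th * (1 - r)
        p00 = (1 - r) * (1 - th) + a * a * th
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (
                np.where(c1 > 0, c1 * np.log(p11), 0.0)
                + np.where(c2 > 0, c2 * np.log(p10), 0.0)
                + np.where(c0 > 0, c0 * np.log(p00), 0.0)
            )
        return out

    lod = np.maximum((ll(theta) - ll(np.ones_like(theta))) / math.log(10), 0.0)
    return theta, r, lod, n.astype(int)


def group_markers(
    matrix: RHGenotypeMatrix, lod_min: float = 4.0, d_max_cR: float = 100.0
) -> list[list[str]]:
    """Linkage groups: connected components of the qualifying two-point graph.

    An edge requires LOD >= ``lod_min`` AND distance <= ``d_max_cR``.
    """
    theta, _r, lod, n = two_point_all_pairs(matrix)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -100.0 * np.log1p(-theta)
    g = nx.Graph()
    g.add_nodes_from(matrix.markers)
    k = len(matrix.markers)
    for i in range(k):
        for j in range(i + 1, k):
            if n[i, j] == 0 or np.isnan(theta[i, j]):
                continue
            if lod[i, j] >= lod_min and d[i, j] <= d_max_cR:
                g.add_edge(matrix.markers[i], matrix.markers[j])
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), c[0]))


# ---------------------------------------------------------------------------
# Locus collapsing
# ---------------------------------------------------------------------------

def collapse_coretained(
    matrix: RHGenotypeMatrix,
) -> tuple[list[list[str]], RHGenotypeMatrix]:
    """Merge markers with identical calls on every shared informative line.

    Markers merge (transitively) when they agree wherever both are observed
    and share at least one informative line.  Returns the locus partition
    (marker names per locus, in matrix order) and a collapsed matrix whose
    columns are locus consensus calls (first non-missing value per line).
    """
    c = matrix.calls
    one = (c == 1).astype(float)
    zero = (c == 0).astype(float)
    valid = (~np.isnan(c)).astype(float)
    disagree = one.T @ zero + zero.T @ one
    shared = valid.T @ valid
    k = len(matrix.markers)
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            if disagree[i, j] == 0 and shared[i, j] >= 1:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(i)
    partition = [
        [matrix.markers[i] for i in idx] for _root, idx in sorted(groups.items())
    ]
    cols, names = [], []
    for loc in partition:
        idx = [matrix.markers.index(m) for m in loc]
        block = c[:, idx]
        consensus = np.full(block.shape[0], np.nan)
        for j in range(block.shape[1]):
            fill = np.isnan(consensus) & ~np.isnan(block[:, j])
            consensus[fill] = block[fill, j]
        cols.append(consensus)
        names.append(loc[0])  # locus named for its first marker
    collapsed = RHGenotypeMatrix(list(matrix.lines), names, np.column_stack(cols))
    return partition, collapsed


# ---------------------------------------------------------------------------
# Multipoint likelihood
# ---------------------------------------------------------------------------

def multipoint_loglik(
    order: Sequence[str],
    matrix: RHGenotypeMatrix,
    thetas: Sequence[float],
    r: float,
    epsilon: float = 0.0,
) -> float:
    """Forward-algorithm log-likelihood of a locus order.

    Per line, a two-state Markov chain (retained/absent) runs along the
    order: the initial state is retained with probability r; at each step the
    state persists with probability 1 - theta_i, otherwise it is re-drawn
    (retained with probability r).  A genotyping error ``epsilon`` flips an
    observed call; missing calls are marginalised.
    """
    thetas = np.asarray(thetas, dtype=float)
    if len(thetas) != len(order) - 1:
        raise InvalidParameterError("need len(order) - 1 adjacent breakage probabilities")
    if np.any((thetas < 0) | (thetas > 1)):
        raise InvalidParameterError("breakage probabilities must lie in [0, 1]")
    if not 0 < r < 1:
        raise InvalidParameterError("retention r must lie in (0, 1)")
    obs = matrix.subset(list(order)).calls  # lines x loci
    n_lines = obs.shape[0]

    def emission(col: np.ndarray) -> np.ndarray:
        e = np.ones((n_lines, 2))
        is1 = col == 1
        is0 = col == 0
        e[is1, 0] = epsilon
        e[is1, 1] = 1 - epsilon
        e[is0, 0] = 1 - epsilon
        e[is0, 1] = epsilon
        return e

    alpha = np.tile([1 - r, r], (n_lines, 1)) * emission(obs[:, 0])
    ll = np.zeros(n_lines)
    scale = alpha.sum(axis=1)
    ll += np.log(scale)
    alpha /= scale[:, None]
    for i, theta in enumerate(thetas):
        T = np.array(
            [
                [(1 - theta) + theta * (1 - r), theta * r],
                [theta * (1 - r), (1 - theta) + theta * r],
            ]
        )
        alpha = (alpha @ T) * emission(obs[:, i + 1])
        scale = alpha.sum(axis=1)
        if np.any(scale <= 0):
            return -math.inf
        ll += np.log(scale)
        alpha /= scale[:, None]
    return float(ll.sum())


# ---------------------------------------------------------------------------
# Locus ordering
# ---------------------------------------------------------------------------

@dataclass
class DeletionBin:
    name: str
    loci: list[str]
    pattern: tuple
    obligate_breaks: int = 0
    mapped_contig_size_mb: float = 0.0

    @property
    def resolution_mb_per_break(self) -> float | None:
        if self.obligate_breaks <= 0:
            return None
        return self.mapped_contig_size_mb / self.obligate_breaks


@dataclass
class RHMap:
    """An ordered linkage group with centiray positions."""

    loci: list[list[str]]  # markers per locus, map order
    locus_names: list[str]
    positions_cR: np.ndarray
    r_hat: float
    obligate_breaks_total: int = 0
    bins: list[DeletionBin] = field(default_factory=list)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def n_markers(self) -> int:
        return sum(len(l) for l in self.loci)

    @property
    def total_length_cR(self) -> float:
        return float(self.positions_cR[-1]) if len(self.positions_cR) else 0.0

    def locus_of_marker(self, marker: str) -> int | None:
        for i, markers in enumerate(self.loci):
            if marker in markers:
                return i
        return None


class _OrderScorer:
    """Likelihood evaluation of candidate orders with cached pairwise thetas.

    With complete data and no genotyping error the hidden retention states
    are observed, so the multipoint likelihood decomposes into an initial
    term plus one term per adjacency; those terms are precomputed for every
    locus pair, making an order evaluation O(k).  With missing calls the
    full forward algorithm is used instead.
    """

    def __init__(self, loci: list[str], matrix: RHGenotypeMatrix):
        self.loci = loci
        self.matrix = matrix.subset(loci)
        theta, _r, lod, _n = two_point_all_pairs(self.matrix)
        np.nan_to_num(theta, copy=False, nan=1 - _EPS)
        self.theta = np.clip(theta, 1e-6, 1 - 1e-6)
        self.lod = lod
        self.index = {name: i for i, name in enumerate(loci)}
        self.r = min(max(self.matrix.overall_retention, _EPS), 1 - _EPS)
        c = self.matrix.calls
        self._complete = not np.any(np.isnan(c))
        if self._complete:
            one = (c == 1).astype(float)
            zero = (c == 0).astype(float)
            n11, n10 = one.T @ one, one.T @ zero
            n01, n00 = zero.T @ one, zero.T @ zero
            r, th = self.r, self.theta
            t11 = (1 - th) + th * r
            t00 = (1 - th) + th * (1 - r)
            self._adj = (
                n11 * np.log(t11)
                + n10 * np.log(th * (1 - r))
                + n01 * np.log(th * r)
                + n00 * np.log(t00)
            )
            self._init = one.sum(axis=0) * math.log(r) + zero.sum(axis=0) * math.log(
                1 - r
            )

    def thetas_for(self, order: Sequence[str]) -> np.ndarray:
        idx = [self.index[m] for m in order]
        return self.theta[idx[:-1], idx[1:]]

    def loglik(self, order: Sequence[str]) -> float:
        if self._complete:
            idx = np.array([self.index[m] for m in order])
            return float(self._init[idx[0]] + self._adj[idx[:-1], idx[1:]].sum())
        return multipoint_loglik(order, self.matrix, self.thetas_for(order), self.r)


def order_loci(
    group: Sequence[str],
    matrix: RHGenotypeMatrix,
    window: int = 5,
    max_passes: int = 20,
) -> RHMap:
    """Order the loci of one linkage group by maximum multipoint likelihood.

    Search: greedy chaining seeded at the strongest two-point pair, maximum-
    likelihood insertion of the remaining loci, then 2-opt segment reversals
    and a sliding-window ripple (all permutations within each window) until
    no improvement.  Adjacent breakage probabilities are re-estimated from
    the cached two-point table on the final order; the orientation placing
    the lexicographically smaller terminal locus first is canonical.
    """
    group = list(group)
    if len(group) == 1:
        return RHMap(
            loci=[[group[0]]],
            locus_names=list(group),
            positions_cR=np.array([0.0]),
            r_hat=float(np.nanmean(matrix.column(group[0]))),
        )
    scorer = _OrderScorer(group, matrix)
    k = len(group)
    iu = np.triu_indices(k, 1)
    best_pair = np.argmax(scorer.lod[iu])
    a, b = iu[0][best_pair], iu[1][best_pair]
    order = [group[a], group[b]]
    placed = {a, b}
    # insert remaining loci, most linked to the placed set first
    while len(order) < k:
        cand = max(
            (i for i in range(k) if i not in placed),
            key=lambda i: (max(scorer.lod[i, j] for j in placed), -i),
        )
        name = group[cand]
        best_ll, best_pos = -math.inf, 0
        for pos in range(len(order) + 1):
            trial = order[:pos] + [name] + order[pos:]
            ll = scorer.loglik(trial)
            if ll > best_ll:
                best_ll, best_pos = ll, pos
        order.insert(best_pos, name)
        placed.add(cand)

    best_ll = scorer.loglik(order)
    for _ in range(max_passes):
        improved = False
        # 2-opt segment reversals
        for i in range(k - 1):
            for j in range(i + 2, k + 1):
                trial = order[:i] + order[i:j][::-1] + order[j:]
                ll = scorer.loglik(trial)
                if ll > best_ll + 1e-9:
                    order, best_ll, improved = trial, ll, True
        # sliding-window ripple
        w = min(window, k)
        for s in range(k - w + 1):
            base = order[:s]
            tail = order[s + w:]
            for perm in itertools.permutations(order[s:s + w]):
                trial = base + list(perm) + tail
                ll = scorer.loglik(trial)
                if ll > best_ll + 1e-9:
                    order, best_ll, improved = trial, ll, True
        if not improved:
            break

    if order[-1] < order[0]:
        order = order[::-1]
    adj_thetas = scorer.thetas_for(order)
    positions = np.concatenate(
        ([0.0], np.cumsum([-100.0 * math.log1p(-t) for t in adj_thetas]))
    )
    rh = RHMap(
        loci=[[name] for name in order],
        locus_names=order,
        positions_cR=positions,
        r_hat=scorer.r,
    )
    rh.obligate_breaks_total = count_obligate_breaks(order, matrix)
    return rh


# ---------------------------------------------------------------------------
# Obligate breaks, deletion bins, summaries
# ---------------------------------------------------------------------------

def count_obligate_breaks(
    order: Sequence[str],
    matrix: RHGenotypeMatrix,
    locus_range: tuple[int, int] | None = None,
) -> int:
    """Total adjacent 1<->0 transitions along the order, summed over lines.

    Missing calls are dropped per line before counting.  ``locus_range``
    restricts to the half-open slice of the order (bin scope).
    """
    order = list(order)
    if locus_range is not None:
        order = order[locus_range[0]:locus_range[1]]
    obs = matrix.subset(order).calls
    total = 0
    for row in obs:
        vals = row[~np.isnan(row)]
        if vals.size > 1:
            total += int(np.sum(vals[1:] != vals[:-1]))
    return total


def assign_deletion_bins(
    order: Sequence[str],
    deletion_calls: RHGenotypeMatrix,
    arm_of_locus: Mapping[str, str] | None = None,
) -> list[DeletionBin]:
    """Partition ordered loci into deletion bins by presence pattern.

    Loci sharing an identical presence pattern across the terminal-deletion
    lines form one bin; bins are reported in map order.  With terminal
    deletions alone the two pericentromeric segments of the arms share the
    all-present pattern, so an optional arm label per locus (known from the
    arm-specific libraries) splits that pattern at the centromere.  A
    non-contiguous pattern along the order triggers a warning listing the
    offending loci.
    """
    keys = []
    for locus in order:
        col = deletion_calls.column(locus)
        pattern = tuple("?" if np.isnan(v) else int(v) for v in col)
        arm = arm_of_locus[locus] if arm_of_locus is not None else ""
        keys.append((arm, pattern))
    bins: list[DeletionBin] = []
    seen: dict[tuple, int] = {}
    for locus, key in zip(order, keys):
        if bins and bins[-1].pattern == key:
            bins[-1].loci.append(locus)
        elif key in seen:
            warnings.warn(
                f"locus {locus} repeats the deletion pattern of bin "
                f"{bins[seen[key]].name} non-contiguously",
                ContiguityWarning,
            )
            bins[seen[key]].loci.append(locus)
        else:
            seen[key] = len(bins)
            bins.append(
                DeletionBin(name=f"BIN{len(bins):02d}", loci=[locus], pattern=key)
            )
    # Name each bin after the deletion line whose breakpoint separates it
    # from its map neighbour (the bin's defining breakpoint).
    for i, b in enumerate(bins):
        neighbour = bins[i + 1] if i + 1 < len(bins) else (bins[i - 1] if i else None)
        line = None
        if neighbour is not None:
            for j, (x, y) in enumerate(zip(b.pattern[1], neighbour.pattern[1])):
                if x != y:
                    line = deletion_calls.lines[j]
                    break
        arm = b.pattern[0]
        b.name = f"{arm}BIN{i:02d}_{line or 'whole'}"
    return bins


def resolution_summaries(
    total_cR: float,
    n_loci: int,
    mapped_mb: float,
    obligate_breaks: int,
    bins: Sequence[DeletionBin] = (),
) -> dict:
    """Map-resolution arithmetic: cR/locus, kb/cR, Mb/break and per-bin values."""
    out = {
        "cR_per_locus": total_cR / n_loci if n_loci else math.nan,
        "kb_per_cR": (mapped_mb * 1000.0) / total_cR if total_cR else math.nan,
        "mb_per_break": mapped_mb / obligate_breaks if obligate_breaks else None,
        "kb_per_break": (
            mapped_mb * 1000.0 / obligate_breaks if obligate_breaks else None
        ),
    }
    out["per_bin_resolution"] = {
        b.name: b.resolution_mb_per_break for b in bins
    }
    return out


def map_summaries(rhmap: RHMap, contig_sizes: Sequence[float] | Mapping[str, float]) -> dict:
    """Resolution summary of a built map given the mapped contig sizes (bp)."""
    sizes = (
        list(contig_sizes.values())
        if isinstance(contig_sizes, Mapping)
        else list(contig_sizes)
    )
    mapped_mb = sum(sizes) / 1e6
    return resolution_summaries(
        rhmap.total_length_cR,
        rhmap.n_loci,
        mapped_mb,
        rhmap.obligate_breaks_total,
        rhmap.bins,
    )


def build_rh_map(
    matrix: RHGenotypeMatrix,
    lod_min: float = 4.0,
    d_max_cR: float = 100.0,
) -> list[RHMap]:
    """Collapse co-retained markers, group, and order each linkage group."""
    partition, collapsed = collapse_coretained(matrix)
    by_name = {loc[0]: loc for loc in partition}
    groups = group_markers(collapsed, lod_min=lod_min, d_max_cR=d_max_cR)
    maps = []
    for grp in groups:
        rh = order_loci(grp, collapsed)
        rh.loci = [list(by_name[name]) for name in rh.locus_names]
        maps.append(rh)
    return maps
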