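"""Paired-end-tag (PET) interaction ingestion and filtering.

ChIA-PET libraries contain two populations of paired tags: *self-ligation*
PETs, an artifact of circularization of a single chromatin fragment (both
tags map within a short genomic distance), and *inter-ligation* PETs that
capture genuine long-range contacts between two distinct regions.  On a
log-log plot of interaction frequency against genomic distance the two
populations appear as two distinct power-law regimes; the intersection of
two fitted lines separates them and is used as the distance cutoff below
which PETs are discarded.

This module reads BEDPE-like interaction files, intersects replicates,
removes inter-chromosomal PETs, fits the two-regime breakpoint and applies
the self-ligation distance filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

ANCHOR_COLUMNS = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"]


@dataclass(frozen=True)
class PETInteraction:
    """One paired-anchor interaction record (0-based half-open anchors)."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    support: int = 1


class InteractionSet:
    """A deduplicated, canonically ordered set of PET interactions.

    Canonical order places the lexicographically smaller anchor
    (chrom, start, end) first, so that A-B and B-A records collapse onto
    the same row.  Backed by a pandas DataFrame with columns
    ``chrom_a, start_a, end_a, chrom_b, start_b, end_b, support``.
    """

    def __init__(self, df: pd.DataFrame, provenance: list[str] | None = None):
        df = df.copy()
        if "support" not in df.columns:
            df["support"] = 1
        df = _canonicalize(df)
        df = df.drop_duplicates(subset=ANCHOR_COLUMNS).reset_index(drop=True)
        self.df = df
        self.provenance: list[str] = list(provenance or [])

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield PETInteraction(
                row.chrom_a, row.start_a, row.end_a,
                row.chrom_b, row.start_b, row.end_b, row.support,
            )

    @classmethod
    def from_records(cls, records, provenance=None) -> "InteractionSet":
        rows = []
        for r in records:
            if isinstance(r, PETInteraction):
                rows.append((r.chrom_a, r.start_a, r.end_a,
                             r.chrom_b, r.start_b, r.end_b, r.support))
            else:
                rows.append(tuple(r[:6]) + (r[6] if len(r) > 6 else 1,))
        df = pd.DataFrame(rows, columns=ANCHOR_COLUMNS + ["support"])
        return cls(df, provenance)

    def to_bedpe(self, path) -> None:
        self.df[ANCHOR_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Put the lexicographically smaller anchor first on every row."""
    a = list(zip(df["chrom_a"], df["start_a"], df["end_a"]))
    b = list(zip(df["chrom_b"], df["start_b"], df["end_b"]))
    swap = np.array([x > y for x, y in zip(a, b)])
    if swap.any():
        df = df.copy()
        for ca, cb in (("chrom_a", "chrom_b"), ("start_a", "start_b"),
                       ("end_a", "end_b")):
            tmp = df.loc[swap, ca].copy()
            df.loc[swap, ca] = df.loc[swap, cb]
            df.loc[swap, cb] = tmp
    return df


def read_interactions(path) -> InteractionSet:
    """Read a tab-separated BEDPE-like file (>= 6 columns) into an
    :class:`InteractionSet`.

    Malformed lines (too few fields, non-integer or negative coordinates,
    inverted intervals) raise ``ValueError`` naming the 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 6 tab-separated "
                    f"columns, got {len(fields)}")
            try:
                sa, ea = int(fields[1]), int(fields[2])
                sb, eb = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinate") from exc
            if min(sa, ea, sb, eb) < 0:
                raise ValueError(f"{path}: line {lineno}: negative coordinate")
            if sa >= ea or sb >= eb:
                raise ValueError(
                    f"{path}: line {lineno}: inverted or empty anchor interval")
            rows.append((fields[0], sa, ea, fields[3], sb, eb, 1))
    df = pd.DataFrame(rows, columns=ANCHOR_COLUMNS + ["support"])
    return InteractionSet(df, provenance=[f"read:{path}"])


def intersect_replicates(rep1: InteractionSet, rep2: InteractionSet) -> InteractionSet:
    """Retain rep1 interactions supported by rep2.

    Two interactions match when anchor A overlaps anchor A' AND anchor B
    overlaps anchor B' by >= 1 bp (after canonical ordering), also allowing
    the swapped anchor pairing.  Matched records get ``support = 2``.
    """
    if len(rep1) == 0 or len(rep2) == 0:
        warnings.warn("replicate intersection on an empty interaction set")
        return InteractionSet(pd.DataFrame(columns=ANCHOR_COLUMNS + ["support"]),
                              rep1.provenance + ["intersect:empty"])

    trees_a: dict[str, IntervalTree] = {}
    trees_b: dict[str, IntervalTree] = {}
    for idx, row in enumerate(rep2.df.itertuples(index=False)):
        trees_a.setdefault(row.chrom_a, IntervalTree()).addi(
            row.start_a, row.end_a, idx)
        trees_b.setdefault(row.chrom_b, IntervalTree()).addi(
            row.start_b, row.end_b, idx)

    def _hits(trees, chrom, start, end):
        tree = trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    keep = []
    for i, row in enumerate(rep1.df.itertuples(index=False)):
        straight = (_hits(trees_a, row.chrom_a, row.start_a, row.end_a)
                    & _hits(trees_b, row.chrom_b, row.start_b, row.end_b))
        if straight:
            keep.append(i)
            continue
        swapped = (_hits(trees_a, row.chrom_b, row.start_b, row.end_b)
                   & _hits(trees_b, row.chrom_a, row.start_a, row.end_a))
        if swapped:
            keep.append(i)
    out = rep1.df.iloc[keep].copy()
    out["support"] = 2
    return InteractionSet(out, rep1.provenance + ["intersect:both-replicates"])


def filter_interchromosomal(s: InteractionSet) -> tuple[InteractionSet, float]:
    """Drop inter-chromosomal records; return the retained set and the
    removed fraction."""
    if len(s) == 0:
        return s, 0.0
    intra = s.df["chrom_a"] == s.df["chrom_b"]
    frac_removed = 1.0 - intra.mean()
    out = InteractionSet(s.df[intra], s.provenance + ["filter:intra-chromosomal"])
    return out, float(frac_removed)


def pet_distance(i: PETInteraction) -> float:
    """Genomic distance between the two anchor midpoints (nt)."""
    if i.chrom_a != i.chrom_b:
        raise ValueError("pet_distance requires an intra-chromosomal record")
    mid_a = (i.start_a + i.end_a) / 2.0
    mid_b = (i.start_b + i.end_b) / 2.0
    return abs(mid_b - mid_a)


def pet_distances(s: InteractionSet) -> np.ndarray:
    """Vectorized midpoint distances; requires an intra-chromosomal set."""
    df = s.df
    if (df["chrom_a"] != df["chrom_b"]).any():
        raise ValueError("distance computation requires an intra-chromosomal set")
    mid_a = (df["start_a"] + df["end_a"]).to_numpy() / 2.0
    mid_b = (df["start_b"] + df["end_b"]).to_numpy() / 2.0
    return np.abs(mid_b - mid_a)


@dataclass
class BreakpointFit:
    """Two-line fit of the log10-log10 distance histogram.

    ``breakpoint_nt`` is the x-coordinate (on the nt scale) where the two
    fitted lines intersect; ``reliable`` is False when the intersection
    escaped the neighborhood of the SSE-optimal split and the split
    boundary was used instead.
    """

    breakpoint_nt: float
    slope_lo: float
    intercept_lo: float
    slope_hi: float
    intercept_hi: float
    sse: float
    n_bins_used: int
    reliable: bool = True
    bin_centers_log10: np.ndarray = field(default_factory=lambda: np.array([]))
    log10_counts: np.ndarray = field(default_factory=lambda: np.array([]))


def fit_distance_breakpoint(distances, n_bins: int = 50,
                            min_bins_per_side: int = 5,
                            window_bins: int = 3) -> BreakpointFit:
    """Fit two power laws to the distance histogram and locate their
    crossing point.

    Distances are binned into ``n_bins`` logarithmic bins; empty bins are
    dropped; every candidate split with at least ``min_bins_per_side``
    occupied bins on each side is scored by the total residual sum of
    squares of the two straight-line fits in log10-log10 space.  Each line
    is fitted by count-weighted least squares: the variance of a log bin
    count is approximately 1/count under Poisson sampling, so near-empty
    tail bins would otherwise dominate the split criterion.  The breakpoint
    is the intersection of the two lines of the best split, clamped (with
    ``reliable=False``) to the split boundary when it falls more than
    ``window_bins`` bins away — which happens for near-parallel lines,
    i.e. when the data follow a single power law.
    """
    d = np.asarray(distances, dtype=float)
    d = d[d > 0]
    if d.size < 1000:
        raise ValueError(
            f"breakpoint fit needs >= 1000 positive distances, got {d.size}")
    if d.max() / d.min() < 100:
        raise ValueError("breakpoint fit needs >= 2 decades of distance support")

    edges = np.logspace(np.log10(d.min()), np.log10(d.max()), n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    occupied = counts > 0
    x = np.log10(centers[occupied])
    y = np.log10(counts[occupied])
    w = counts[occupied].astype(float)
    n_used = x.size
    if n_used < 2 * min_bins_per_side:
        raise ValueError(
            f"only {n_used} occupied bins; need >= {2 * min_bins_per_side}")

    best = None
    for split in range(min_bins_per_side, n_used - min_bins_per_side + 1):
        (m1, b1), res1 = _wls_line(x[:split], y[:split], w[:split])
        (m2, b2), res2 = _wls_line(x[split:], y[split:], w[split:])
        sse = res1 + res2
        if best is None or sse < best[0]:
            best = (sse, split, m1, b1, m2, b2)
    sse, split, m1, b1, m2, b2 = best

    bin_width = x[1] - x[0] if n_used > 1 else 0.0
    lo_edge = x[split - 1] - window_bins * bin_width
    hi_edge = x[split] + window_bins * bin_width
    if abs(m1 - m2) < 1e-9:
        x_star, reliable = 0.5 * (x[split - 1] + x[split]), False
    else:
        x_star = (b2 - b1) / (m1 - m2)
        reliable = lo_edge <= x_star <= hi_edge
        if not reliable:
            x_star = 0.5 * (x[split - 1] + x[split])
    return BreakpointFit(
        breakpoint_nt=float(10 ** x_star),
        slope_lo=float(m1), intercept_lo=float(b1),
        slope_hi=float(m2), intercept_hi=float(b2),
        sse=float(sse), n_bins_used=int(n_used), reliable=bool(reliable),
        bin_centers_log10=x, log10_counts=y,
    )


def _wls_line(x: np.ndarray, y: np.ndarray,
              w: np.ndarray) -> tuple[tuple[float, float], float]:
    """Weighted least-squares line; returns ((slope, intercept), weighted
    residual sum of squares)."""
    wn = w / w.sum()
    xb = float(np.dot(wn, x))
    yb = float(np.dot(wn, y))
    slope = float(np.dot(wn, (x - xb) * (y - yb)) / np.dot(wn, (x - xb) ** 2))
    intercept = yb - slope * xb
    resid = y - (slope * x + intercept)
    return (slope, intercept), float(np.dot(w, resid ** 2))


def filter_self_ligation(s: InteractionSet, cutoff_nt: float) -> tuple[InteractionSet, int]:
    """Drop records whose anchor-midpoint distance is strictly below the
    cutoff (records at exactly the cutoff are retained)."""
    if cutoff_nt < 0:
        raise ValueError("cutoff must be >= 0")
    if len(s) == 0:
        return s, 0
    dist = pet_distances(s)
    keep = dist >= cutoff_nt
    n_removed = int((~keep).sum())
    out = InteractionSet(s.df[keep],
                         s.provenance + [f"filter:self-ligation<{cutoff_nt}"])
    return out, n_removed
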