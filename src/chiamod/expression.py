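"""Expression processing: RPKM conversion and detection rules.

RPKM = counts / (gene length in kb) / (mapped reads in millions).  The
detection threshold separating expressed from background features is read
off the bimodal distribution of log RPKM values: a kernel-density estimate
has two modes (non-expressed noise floor and expressed genes) and the
threshold is the deepest local minimum between them.  Detection then
requires genes to exceed the threshold in both replicates, while lncRNAs
— lower expressed overall — count as detected when positive in both
replicates or above the threshold in at least one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

DEFAULT_GENE_THRESHOLD = 0.041


def rpkm(counts, length_nt, library_size) -> np.ndarray | float:
    """Reads Per Kilobase of transcript per Million mapped reads."""
    counts = np.asarray(counts, dtype=float)
    length_nt = np.asarray(length_nt, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(length_nt <= 0):
        raise ValueError("feature length must be positive")
    if np.any(library_size <= 0):
        raise ValueError("library size must be positive")
    out = counts / (length_nt / 1e3) / (library_size / 1e6)
    return float(out) if out.ndim == 0 else out


class UnimodalDensityError(ValueError):
    """Raised when the log-expression density has no valley between two
    modes; carries the evaluated density grid for diagnostics."""

    def __init__(self, message, grid=None, density=None):
        super().__init__(message)
        self.grid = grid
        self.density = density


def detection_threshold(rpkm_values, grid_points: int = 512,
                        bw_method=None) -> float:
    """Detection threshold from the bimodal log-RPKM distribution.

    A Gaussian KDE of the natural-log RPKM values is evaluated on a grid;
    the threshold is the deepest local minimum between the two highest
    modes, reported back on the RPKM scale.  Unimodal densities raise
    :class:`UnimodalDensityError`.
    """
    x = np.asarray(rpkm_values, dtype=float)
    x = x[x > 0]
    if x.size < 200:
        raise ValueError("threshold estimation needs >= 200 positive values")
    logx = np.log(x)
    kde = gaussian_kde(logx, bw_method=bw_method)
    grid = np.linspace(logx.min(), logx.max(), grid_points)
    dens = kde(grid)

    interior = np.arange(1, grid_points - 1)
    maxima = interior[(dens[interior] > dens[interior - 1])
                      & (dens[interior] >= dens[interior + 1])]
    minima = interior[(dens[interior] < dens[interior - 1])
                      & (dens[interior] <= dens[interior + 1])]
    if maxima.size < 2 or minima.size == 0:
        raise UnimodalDensityError(
            "log-expression density is unimodal; no detection threshold",
            grid=grid, density=dens)
    top_two = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    between = minima[(minima > lo) & (minima < hi)]
    if between.size == 0:
        raise UnimodalDensityError(
            "no local minimum between the two highest modes",
            grid=grid, density=dens)
    valley = between[np.argmin(dens[between])]
    return float(np.exp(grid[valley]))


@dataclass(frozen=True)
class DetectionRule:
    """Class-specific detection logic with the RPKM threshold."""

    gene_threshold: float = DEFAULT_GENE_THRESHOLD
    gene_requires_both: bool = True

    def __post_init__(self):
        if self.gene_threshold <= 0:
            raise ValueError("threshold must be positive")


def apply_detection(expr: pd.DataFrame, classes: pd.Series | dict,
                    rule: DetectionRule | None = None,
                    rep_columns: tuple[str, str] = ("rep1", "rep2")) -> set[str]:
    """Detected-feature set from two replicate RPKM columns.

    Genes: RPKM above the threshold in both replicates (configurable to
    'either' via the rule).  lncRNAs: RPKM > 0 in both replicates, or
    above the threshold in at least one.
    """
    rule = rule or DetectionRule()
    missing = [c for c in rep_columns if c not in expr.columns]
    if missing:
        raise ValueError(f"missing replicate columns: {missing}")
    classes = pd.Series(classes)
    thr = rule.gene_threshold
    r1 = expr[rep_columns[0]]
    r2 = expr[rep_columns[1]]
    detected = set()
    for feat in expr.index:
        cls = classes.get(feat, "gene")
        a, b = float(r1.loc[feat]), float(r2.loc[feat])
        if cls == "lncRNA":
            ok = (a > 0 and b > 0) or (a > thr or b > thr)
        else:
            ok = (a > thr and b > thr) if rule.gene_requires_both \
                else (a > thr or b > thr)
        if ok:
            detected.add(feat)
    return detected


def counts_to_rpkm(counts: pd.DataFrame, library_sizes: dict) -> pd.DataFrame:
    """Convert a counts table (columns: length plus one column per
    replicate) into RPKM, given per-replicate library sizes."""
    if "length" not in counts.columns:
        raise ValueError("counts table needs a 'length' column")
    out = {}
    for rep, lib in library_sizes.items():
        if rep not in counts.columns:
            raise ValueError(f"missing replicate count column: {rep}")
        out[rep] = rpkm(counts[rep].to_numpy(),
                        counts["length"].to_numpy(), lib)
    return pd.DataFrame(out, index=counts.index)
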