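"""Segregating sites, nucleotide diversity, Watterson's theta and Tajima's D.

All statistics operate on :class:`~plastomarkers.alignment.MultipleAlignment`
and support two gap policies:

``exclude_column``
    Any column containing '-' or 'N' is dropped entirely before anything is
    counted (the default; matches counting segregating sites "excluding
    gaps" on a whole-genome alignment).
``pairwise``
    Gapped cells are dropped per column (for S) or per sequence pair (for
    diversity), so partially gapped columns still contribute.

Tajima's D is returned with every intermediate constant (a1..e2) so the
computation can be audited; when S = 0 the statistic is *undefined*, not
zero — an invariant alignment carries no frequency-spectrum information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .alignment import BASES, MultipleAlignment

GapPolicy = Literal["exclude_column", "pairwise"]

__all__ = [
    "TajimaComponents",
    "WindowStats",
    "tajima_constants",
    "segregating_sites",
    "nucleotide_diversity",
    "tajimas_d",
    "window_scan",
]


def tajima_constants(n: int) -> dict[str, float]:
    """The standard constants of Tajima's D variance for sample size n."""
    if n < 2:
        raise ValueError("Tajima constants require n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


@dataclass
class TajimaComponents:
    """Tajima's D together with every quantity entering its formula.

    ``pi`` is in *count* units (mean pairwise differences), the scale the D
    formula uses; per-site diversity is ``pi / usable_sites``.
    """

    n: int
    S: int
    pi: float
    theta_w: float
    usable_sites: int
    constants: dict[str, float] = field(repr=False)
    var_d: float = float("nan")
    D: float = float("nan")
    defined: bool = False
    low_n: bool = False

    @property
    def pi_per_site(self) -> float:
        if self.usable_sites == 0:
            return float("nan")
        return self.pi / self.usable_sites


@dataclass
class WindowStats:
    """Per-window diversity summary over half-open column interval [start, end)."""

    start: int
    end: int
    gap_fraction: float
    usable_sites: int
    S: int
    pi_per_site: float
    D: float
    d_defined: bool
    available: bool
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# column-wise kernels
# ---------------------------------------------------------------------------

def _base_counts(matrix: np.ndarray) -> np.ndarray:
    """(4, L) counts of A, C, G, T per column."""
    return np.stack([(matrix == b).sum(axis=0) for b in BASES])


def _column_stats(aln: MultipleAlignment):
    """Per-column usable mask, segregating indicator and pairwise-difference
    counts under the exclude_column policy."""
    counts = _base_counts(aln.matrix)
    n = aln.n_taxa
    usable = counts.sum(axis=0) == n
    distinct = (counts > 0).sum(axis=0)
    seg = usable & (distinct >= 2)
    total_pairs = n * (n - 1) // 2
    same_pairs = (counts * (counts - 1) // 2).sum(axis=0)
    pi_col = np.where(usable, total_pairs - same_pairs, 0).astype(float)
    return usable, seg, pi_col, total_pairs


def _require_pairs(aln: MultipleAlignment) -> None:
    if aln.n_taxa < 2:
        raise ValueError("at least 2 sequences are required")


# ---------------------------------------------------------------------------
# public statistics
# ---------------------------------------------------------------------------

def segregating_sites(
    aln: MultipleAlignment, gap_policy: GapPolicy = "exclude_column"
) -> tuple[int, np.ndarray]:
    """Count segregating sites; returns (S, column indices of the sites).

    A site segregates iff >= 2 distinct bases among {A,C,G,T} remain after
    the gap policy is applied.
    """
    _require_pairs(aln)
    counts = _base_counts(aln.matrix)
    distinct = (counts > 0).sum(axis=0)
    if gap_policy == "exclude_column":
        usable = counts.sum(axis=0) == aln.n_taxa
        seg = usable & (distinct >= 2)
    elif gap_policy == "pairwise":
        seg = distinct >= 2
    else:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    idx = np.flatnonzero(seg)
    return int(idx.size), idx


def nucleotide_diversity(
    aln: MultipleAlignment, gap_policy: GapPolicy = "exclude_column"
) -> float:
    """Nucleotide diversity per usable site (mean over all sequence pairs)."""
    _require_pairs(aln)
    if gap_policy == "exclude_column":
        usable, _, pi_col, total_pairs = _column_stats(aln)
        n_usable = int(usable.sum())
        if n_usable == 0:
            return float("nan")
        return float(pi_col.sum() / total_pairs / n_usable)
    if gap_policy == "pairwise":
        missing = aln.missing_mask()
        n = aln.n_taxa
        props = []
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~(missing[i] | missing[j])
                m = int(ok.sum())
                if m == 0:
                    continue
                diff = int((aln.matrix[i, ok] != aln.matrix[j, ok]).sum())
                props.append(diff / m)
        if not props:
            return float("nan")
        return float(np.mean(props))
    raise ValueError(f"unknown gap policy {gap_policy!r}")


def _tajima_from_counts(n: int, S: int, pi_count: float, usable: int) -> TajimaComponents:
    consts = tajima_constants(n)
    theta_w = S / consts["a1"]
    comp = TajimaComponents(
        n=n, S=S, pi=pi_count, theta_w=theta_w, usable_sites=usable,
        constants=consts, low_n=n < 4,
    )
    if S > 0:
        var_d = consts["e1"] * S + consts["e2"] * S * (S - 1)
        comp.var_d = var_d
        if var_d > 0:
            comp.D = (pi_count - theta_w) / math.sqrt(var_d)
            comp.defined = True
    return comp


def tajimas_d(
    aln: MultipleAlignment, gap_policy: GapPolicy = "exclude_column"
) -> TajimaComponents:
    """Tajima's D with all auditing components.

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)); undefined (NaN, flagged)
    when S = 0.
    """
    _require_pairs(aln)
    if gap_policy == "exclude_column":
        usable, seg, pi_col, total_pairs = _column_stats(aln)
        S = int(seg.sum())
        pi_count = float(pi_col.sum() / total_pairs)
        return _tajima_from_counts(aln.n_taxa, S, pi_count, int(usable.sum()))
    if gap_policy == "pairwise":
        S, _ = segregating_sites(aln, "pairwise")
        # mean pairwise difference count with pairwise deletion
        missing = aln.missing_mask()
        n = aln.n_taxa
        diffs = []
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~(missing[i] | missing[j])
                diffs.append(int((aln.matrix[i, ok] != aln.matrix[j, ok]).sum()))
        pi_count = float(np.mean(diffs)) if diffs else 0.0
        usable_sites = int((~missing.any(axis=0)).sum())
        return _tajima_from_counts(n, S, pi_count, usable_sites)
    raise ValueError(f"unknown gap policy {gap_policy!r}")


def window_scan(
    aln: MultipleAlignment,
    window: int = 500,
    step: int = 100,
    max_gap_fraction: float = 0.2,
    min_usable: int = 100,
) -> list[WindowStats]:
    """Sliding-window scan of gap fraction, S, pi/site and Tajima's D.

    Windows whose gap fraction exceeds ``max_gap_fraction`` or whose usable
    column count falls below ``min_usable`` are emitted flagged unavailable
    (their statistics are not trustworthy, but the coordinates remain so the
    scan is gap-free in genome space).
    """
    _require_pairs(aln)
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    L = aln.length
    truncated = False
    if window > L:
        window = L
        truncated = True

    usable, seg, pi_col, total_pairs = _column_stats(aln)
    gapfrac_col = aln.column_gap_fraction()

    # prefix sums for O(1) window aggregation
    cum_usable = np.concatenate([[0], np.cumsum(usable)])
    cum_seg = np.concatenate([[0], np.cumsum(seg)])
    cum_pi = np.concatenate([[0.0], np.cumsum(pi_col)])
    cum_gap = np.concatenate([[0.0], np.cumsum(gapfrac_col)])

    out: list[WindowStats] = []
    for start in range(0, L - window + 1, step):
        end = start + window
        u = int(cum_usable[end] - cum_usable[start])
        S = int(cum_seg[end] - cum_seg[start])
        pi_count = float(cum_pi[end] - cum_pi[start]) / total_pairs
        gap_fraction = float(cum_gap[end] - cum_gap[start]) / window
        flags: list[str] = []
        if truncated:
            flags.append("truncated")
        available = True
        if gap_fraction > max_gap_fraction:
            flags.append("gap_fraction_exceeded")
            available = False
        if u < min_usable:
            flags.append("too_few_usable_sites")
            available = False
        comp = _tajima_from_counts(aln.n_taxa, S, pi_count, u)
        pi_site = pi_count / u if u else float("nan")
        out.append(
            WindowStats(
                start=start, end=end, gap_fraction=gap_fraction, usable_sites=u,
                S=S, pi_per_site=pi_site, D=comp.D, d_defined=comp.defined,
                available=available, flags=tuple(flags),
            )
        )
    return out


def window_stats_frame(stats: list[WindowStats]):
    """WindowStats as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "start": [w.start for w in stats],
            "end": [w.end for w in stats],
            "gap_fraction": [w.gap_fraction for w in stats],
            "usable_sites": [w.usable_sites for w in stats],
            "S": [w.S for w in stats],
            "pi_per_site": [w.pi_per_site for w in stats],
            "D": [w.D for w in stats],
            "flags": [";".join(w.flags) for w in stats],
        }
    )
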