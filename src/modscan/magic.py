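"""Pair-level modulation statistics (MAGIC).

For a candidate modulator m, samples are split into m-on (top fraction by m's
expression) and m-off (bottom fraction) groups.  Each group's gene-gene
Pearson correlation matrix C_M is mapped to the standard-normal domain by a
scaled Fisher z-transform

    I_M(i,j) = sqrt(k - 3) * atanh(C_M(i,j)),

where k is the per-group sample count, so that I_M has approximately unit
variance under a fixed population correlation.  The MAGIC p-value tests
whether the pair's correlation differs between the groups; the MAGIC score is
the absolute change between correlations projected back from I to an assigned
sample size N', an effect-size filter.  Pairs passing both thresholds are the
candidate's modulated edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "ModulatorPartition",
    "DifferentialEdge",
    "PairStatistics",
    "partition_samples",
    "group_correlations",
    "fisher_transform",
    "inverse_fisher",
    "magic_pvalue",
    "pair_statistics",
    "call_differential_edges",
    "write_edges_tsv",
]

_CLIP = 1.0 - 1e-12  # |correlation| ceiling before atanh
_TINY = np.finfo(np.float64).tiny

ON_INTENSIFIED = "on_intensified"
OFF_INTENSIFIED = "off_intensified"


@dataclass(frozen=True)
class ModulatorPartition:
    """On/off sample groups for one candidate modulator.

    ``on_samples`` are the column indices of the samples with the highest
    ``fraction`` of the modulator's expression, ``off_samples`` the lowest;
    both have size k = floor(fraction * N).
    """

    modulator_gene: str
    on_samples: np.ndarray
    off_samples: np.ndarray
    fraction: float

    def __post_init__(self) -> None:
        on = np.asarray(self.on_samples, dtype=np.intp)
        off = np.asarray(self.off_samples, dtype=np.intp)
        object.__setattr__(self, "on_samples", on)
        object.__setattr__(self, "off_samples", off)
        if on.size != off.size:
            raise ValueError("on and off groups must have equal size")
        if np.intersect1d(on, off).size:
            raise ValueError("on and off groups overlap")
        if not 0.0 < self.fraction <= 0.5:
            raise ValueError("fraction must be in (0, 0.5]")

    @property
    def k(self) -> int:
        return int(self.on_samples.size)

    def swapped(self) -> "ModulatorPartition":
        return ModulatorPartition(
            self.modulator_gene, self.off_samples, self.on_samples, self.fraction
        )


def group_size(n_samples: int, fraction: float) -> int:
    """Per-group sample count k = floor(fraction * N)."""
    return int(np.floor(fraction * n_samples + 1e-9))


def partition_samples(E, modulator: str, fraction: float = 0.25) -> ModulatorPartition:
    """Split samples into the modulator's top/bottom ``fraction`` by expression.

    Ties at the group boundary are broken by a stable sort on (expression
    value, sample order), so the partition is deterministic for a fixed input.
    Requires k - 3 >= 1 so the Fisher scale sqrt(k - 3) is defined.
    """
    idx = E.gene_index(modulator)
    n = E.n_samples
    k = group_size(n, fraction)
    if 2 * k > n:
        raise ValueError(f"2*k = {2 * k} exceeds N = {n}")
    if k - 3 < 1:
        raise ValueError(
            f"group size k={k} too small: need k >= 4 (N >= {int(np.ceil(4 / fraction))} "
            f"at fraction {fraction})"
        )
    order = np.argsort(E.values[idx], kind="stable")
    off = order[:k]
    on = order[n - k :]
    return ModulatorPartition(modulator, on, off, fraction)


def _corr_matrix(values: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows; rows with zero variance give NaN."""
    x = values - values.mean(axis=1, keepdims=True)
    norm = np.sqrt((x * x).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = x / norm[:, None]
    c = z @ z.T
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, np.where(norm > 0.0, 1.0, np.nan))
    return c


def group_correlations(E, part: ModulatorPartition) -> tuple[np.ndarray, np.ndarray]:
    """G x G Pearson correlation matrices over the on- and off-group samples."""
    if part.k < 4:
        raise ValueError("group size must be >= 4")
    c_on = _corr_matrix(E.values[:, part.on_samples])
    c_off = _corr_matrix(E.values[:, part.off_samples])
    return c_on, c_off


def fisher_transform(c, n_samples: float):
    """Normalized interaction I = sqrt(N/4 - 3)/2 * ln((1+c)/(1-c)).

    ``n_samples`` is the *total* sample count; the per-group size is N/4 when
    each group holds a quarter of the samples.  For a general per-group size k
    pass ``n_samples = 4 * k``.  |c| is clipped just below 1, so c = +/-1 maps
    to a large finite value.
    """
    scale2 = n_samples / 4.0 - 3.0
    if scale2 <= 0:
        raise ValueError(f"need N/4 - 3 > 0, got N = {n_samples}")
    cc = np.clip(np.asarray(c, dtype=np.float64), -_CLIP, _CLIP)
    out = np.sqrt(scale2) * np.arctanh(cc)
    return out if out.ndim else float(out)


def inverse_fisher(i, n_assigned: float, mode: str = "exact"):
    """Project a normalized interaction back to a correlation at sample size N'.

    ``mode="exact"`` computes tanh(I / sqrt(N'-3)), the algebraic inverse of
    the forward transform when N' equals the group size.  ``mode="verbatim"``
    computes tanh(I) / sqrt(N'-3), the published projection, which saturates
    at 1/sqrt(N'-3).  Both are odd and bounded.
    """
    s2 = n_assigned - 3.0
    if s2 <= 0:
        raise ValueError(f"need N' - 3 > 0, got N' = {n_assigned}")
    i = np.asarray(i, dtype=np.float64)
    if mode == "exact":
        out = np.tanh(i / np.sqrt(s2))
    elif mode == "verbatim":
        out = np.tanh(i) / np.sqrt(s2)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if out.ndim else float(out)


def magic_pvalue(i_on, i_off, statistic: str = "signed"):
    """Two-sided p-value for a change in interaction strength between groups.

    Under the null that both groups share one population correlation, each
    normalized interaction is approximately standard normal around a common
    mean, so I_on - I_off ~ Normal(0, 2).  ``statistic="signed"`` applies the
    normal tail to |I_on - I_off| (the classical two-sample Fisher-z test,
    calibrated for any shared correlation).  ``statistic="magnitude"`` applies
    it to delta-I = ||I_on| - |I_off||, the quantity averaged by the ACI
    score; because ||a|-|b|| <= |a-b| this variant is conservative, strongly
    so for pairs with near-zero correlation in both groups.
    """
    i_on = np.asarray(i_on, dtype=np.float64)
    i_off = np.asarray(i_off, dtype=np.float64)
    if statistic == "signed":
        stat = np.abs(i_on - i_off)
    elif statistic == "magnitude":
        stat = np.abs(np.abs(i_on) - np.abs(i_off))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    # 2 * (1 - Phi(stat / sqrt(2))) == erfc(stat / 2)
    p = np.maximum(special.erfc(stat / 2.0), _TINY)
    return p if p.ndim else float(p)


@dataclass
class PairStatistics:
    """All pairwise quantities for one modulator partition (G x G matrices)."""

    c_on: np.ndarray
    c_off: np.ndarray
    i_on: np.ndarray
    i_off: np.ndarray
    delta_i: np.ndarray  # ||I_on| - |I_off||
    p: np.ndarray
    adj_on: np.ndarray
    adj_off: np.ndarray
    score: np.ndarray
    valid: np.ndarray  # pairs where both correlations are defined
    k: int


def pair_statistics(
    values: np.ndarray,
    on: np.ndarray,
    off: np.ndarray,
    inverse_mode: str = "exact",
    statistic: str = "signed",
    n_assigned: Optional[float] = None,
) -> PairStatistics:
    """Compute every pair-level quantity for one partition, vectorized."""
    k = int(np.asarray(on).size)
    c_on = _corr_matrix(values[:, on])
    c_off = _corr_matrix(values[:, off])
    valid = np.isfinite(c_on) & np.isfinite(c_off)
    i_on = fisher_transform(np.nan_to_num(c_on), 4 * k)
    i_off = fisher_transform(np.nan_to_num(c_off), 4 * k)
    delta = np.abs(np.abs(i_on) - np.abs(i_off))
    p = magic_pvalue(i_on, i_off, statistic=statistic)
    na = float(k) if n_assigned is None else float(n_assigned)
    adj_on = inverse_fisher(i_on, na, mode=inverse_mode)
    adj_off = inverse_fisher(i_off, na, mode=inverse_mode)
    score = np.abs(adj_on - adj_off)
    return PairStatistics(c_on, c_off, i_on, i_off, delta, p, adj_on, adj_off, score, valid, k)


@dataclass(frozen=True)
class DifferentialEdge:
    """A gene pair whose correlation changes significantly between groups."""

    gene_i: str
    gene_j: str
    c_on: float
    c_off: float
    i_on: float
    i_off: float
    delta_i: float
    magic_p: float
    c_adj_on: float
    c_adj_off: float
    magic_score: float
    direction: str  # ON_INTENSIFIED if |c_adj_on| > |c_adj_off| else OFF_INTENSIFIED

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_i, self.gene_j)


def call_differential_edges(
    E,
    part: ModulatorPartition,
    p_max: float = 1e-5,
    score_min: float = 0.4,
    inverse_mode: str = "exact",
    statistic: str = "signed",
    n_assigned: Optional[float] = None,
    include_modulator: bool = False,
) -> list[DifferentialEdge]:
    """Extract the modulated gene pairs for one candidate modulator.

    Returns the unordered pairs (i < j in matrix order) with
    ``magic_p < p_max`` and ``magic_score >= score_min``.  Pairs touching the
    modulator itself are excluded unless ``include_modulator``; pairs with an
    undefined correlation in either group (constant gene within a group) are
    always excluded.
    """
    if not 0.0 < p_max <= 1.0:
        raise ValueError("p_max must be in (0, 1]")
    if score_min < 0.0:
        raise ValueError("score_min must be >= 0")
    st = pair_statistics(
        E.values,
        part.on_samples,
        part.off_samples,
        inverse_mode=inverse_mode,
        statistic=statistic,
        n_assigned=n_assigned,
    )
    G = E.n_genes
    sel = np.triu(st.valid, 1) & (st.p < p_max) & (st.score >= score_min)
    if not include_modulator:
        m = E.gene_index(part.modulator_gene)
        sel[m, :] = False
        sel[:, m] = False
    ii, jj = np.nonzero(sel)
    edges = []
    for a, b in zip(ii, jj):
        direction = (
            ON_INTENSIFIED if abs(st.adj_on[a, b]) > abs(st.adj_off[a, b]) else OFF_INTENSIFIED
        )
        edges.append(
            DifferentialEdge(
                gene_i=E.gene_ids[a],
                gene_j=E.gene_ids[b],
                c_on=float(st.c_on[a, b]),
                c_off=float(st.c_off[a, b]),
                i_on=float(st.i_on[a, b]),
                i_off=float(st.i_off[a, b]),
                delta_i=float(st.delta_i[a, b]),
                magic_p=float(st.p[a, b]),
                c_adj_on=float(st.adj_on[a, b]),
                c_adj_off=float(st.adj_off[a, b]),
                magic_score=float(st.score[a, b]),
                direction=direction,
            )
        )
    return edges


def edges_to_frame(edges: Sequence[DifferentialEdge]) -> pd.DataFrame:
    cols = [
        "gene_i",
        "gene_j",
        "c_on",
        "c_off",
        "c_adj_on",
        "c_adj_off",
        "delta_i",
        "magic_p",
        "magic_score",
        "direction",
    ]
    return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in edges], columns=cols)


def write_edges_tsv(edges: Sequence[DifferentialEdge], path: str | Path) -> None:
    edges_to_frame(edges).to_csv(path, sep="\t", index=False)
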