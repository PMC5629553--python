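"""Expression-matrix container and delimited-text I/O.

The screen operates on a genes x samples matrix of normalized (log-scale)
expression values E = {e_{g,n}}.  Loaders normalize orientation so that genes
are always rows internally; missing values are rejected by default because
group-wise Pearson correlations assume complete columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_SAMPLES_FOR_SCREEN = 16  # fraction 0.25 then gives k = 4, so k - 3 >= 1


def _find_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression matrix with unique identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup_g = _find_duplicates(self.gene_ids)
        if dup_g:
            raise ValueError(f"duplicate gene ids: {dup_g}")
        dup_s = _find_duplicates(self.sample_ids)
        if dup_s:
            raise ValueError(f"duplicate sample ids: {dup_s}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None

    @property
    def constant_genes(self) -> list[str]:
        """Genes with zero variance across all samples (correlation undefined)."""
        sd = self.values.std(axis=1)
        return [g for g, s in zip(self.gene_ids, sd) if s == 0.0]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in genes]
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx], list(self.sample_ids), self.values[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=np.float64))


def load_expression(
    path: str | Path,
    genes_in_rows: bool = True,
    missing: str = "error",
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read a delimited expression matrix (header = sample ids, first column = gene id).

    Parameters
    ----------
    genes_in_rows
        If False the file is transposed on load (samples in rows).
    missing
        ``"error"`` rejects any missing cell; ``"drop_genes"`` removes genes
        with at least one missing value so downstream correlations never see
        missingness.
    """
    if missing not in ("error", "drop_genes"):
        raise ValueError(f"unknown missing policy {missing!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if not genes_in_rows:
        df = df.T

    dup_rows = _find_duplicates(list(df.index))
    if dup_rows:
        raise ValueError(f"{path}: duplicate gene ids: {dup_rows}")
    dup_cols = _find_duplicates(list(df.columns))
    if dup_cols:
        raise ValueError(f"{path}: duplicate sample ids: {dup_cols}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    non_numeric = numeric.isna() & df.notna()
    if non_numeric.to_numpy().any():
        r, c = np.argwhere(non_numeric.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        if missing == "error":
            r, c = np.argwhere(numeric.isna().to_numpy())[0]
            raise ValueError(
                f"{path}: missing value at gene {df.index[r]!r}, "
                f"sample {df.columns[c]!r} (use missing='drop_genes' to drop)"
            )
        n_before = len(numeric)
        numeric = numeric.dropna(axis=0)
        logger.info("dropped %d genes with missing values", n_before - len(numeric))

    E = ExpressionMatrix.from_frame(numeric)
    const = E.constant_genes
    if const:
        logger.warning(
            "%d all-constant gene rows retained (correlation undefined): %s",
            len(const),
            const[:10],
        )
    logger.info("loaded expression matrix: G=%d genes, N=%d samples", E.n_genes, E.n_samples)
    return E


def write_expression(E: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    # %.17g round-trips IEEE doubles exactly
    E.to_frame().to_csv(path, sep=sep, index_label="gene_id", float_format="%.17g")


def load_probe_map(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a two-column probe -> gene TSV (header optional)."""
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: probe map needs two columns (probe_id, gene_id)")
    df = df.iloc[:, :2]
    df.columns = ["probe_id", "gene_id"]
    if df.iloc[0].str.lower().tolist() == ["probe_id", "gene_id"]:
        df = df.iloc[1:].reset_index(drop=True)
    dups = df["probe_id"][df["probe_id"].duplicated()].unique().tolist()
    if dups:
        raise ValueError(f"{path}: probes mapped more than once: {dups}")
    return df


def probe_cv(values: np.ndarray) -> np.ndarray:
    """Coefficient of variation per row: sd / |mean|; NaN where the mean is 0."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0.0, sd / np.abs(mean), np.nan)
    return cv


def collapse_probes_cv(
    probe_matrix: ExpressionMatrix,
    probe_map: pd.DataFrame,
    cv_min: float = 0.0,
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level, keeping the most variable probe.

    Per gene the probe with the largest coefficient of variation across samples
    is kept; genes whose best probe has CV below ``cv_min`` are dropped as
    non-informative.  Probes with mean exactly zero have undefined CV and are
    excluded from the argmax.
    """
    if cv_min < 0:
        raise ValueError("cv_min must be nonnegative")
    mapping = dict(zip(probe_map["probe_id"], probe_map["gene_id"]))
    unmapped = [p for p in probe_matrix.gene_ids if p not in mapping]
    if unmapped:
        raise ValueError(f"probes absent from map: {unmapped[:10]}")

    cv = probe_cv(probe_matrix.values)
    best: dict[str, tuple[float, int]] = {}
    for i, probe in enumerate(probe_matrix.gene_ids):
        if np.isnan(cv[i]):
            continue  # zero-mean probe: CV undefined
        gene = mapping[probe]
        if gene not in best or cv[i] > best[gene][0]:
            best[gene] = (cv[i], i)

    kept = sorted((g, idx) for g, (c, idx) in best.items() if c >= cv_min)
    if not kept:
        raise ValueError("no gene passed the CV filter")
    genes = [g for g, _ in kept]
    rows = [idx for _, idx in kept]
    logger.info(
        "collapsed %d probes to %d genes (cv_min=%g)",
        probe_matrix.n_genes,
        len(genes),
        cv_min,
    )
    return ExpressionMatrix(genes, list(probe_matrix.sample_ids), probe_matrix.values[rows])
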