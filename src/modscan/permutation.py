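"""Permutation null distributions and empirical p-values.

The observed four parameters of a candidate modulator are compared against
the parameters obtained when the on/off split is drawn at random, independent
of any gene's expression.  Randomizing the partition (equivalently, permuting
the modulator's values against the rest of the matrix) preserves the
co-expression structure while destroying the modulator-partition link, which
is what makes the null informative — a joint column permutation of the whole
matrix would leave every correlation and every derived partition unchanged.

Because the random partition does not involve the modulator, one shared null
serves every candidate in a run; a per-modulator null (recomputed with that
gene's pairs excluded) is available for exactness.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import ScreenConfig
from .magic import group_size
from .modularity import PARAMETERS, four_parameters


@dataclass
class NullDistributions:
    """Per-parameter null vectors from random sample partitions."""

    n_perm: int
    seed: int
    aci: np.ndarray
    n_nodes: np.ndarray
    n_edges: np.ndarray
    connectivity: np.ndarray
    scope: str = "shared"

    def __post_init__(self) -> None:
        for p in PARAMETERS:
            v = np.asarray(getattr(self, p), dtype=np.float64)
            setattr(self, p, v)
            if v.shape != (self.n_perm,):
                raise ValueError(f"null vector {p} must have length n_perm={self.n_perm}")

    def values(self, parameter: str) -> np.ndarray:
        if parameter not in PARAMETERS:
            raise KeyError(f"unknown parameter {parameter!r}")
        return getattr(self, parameter)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({p: getattr(self, p) for p in PARAMETERS})

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for p in PARAMETERS:
            h.update(np.ascontiguousarray(getattr(self, p)).tobytes())
        return h.hexdigest()

    def save(self, prefix: str | Path, config: Optional[ScreenConfig] = None) -> None:
        """Persist null vectors as TSV with a JSON sidecar (seed, n_perm, config)."""
        prefix = Path(prefix)
        self.to_frame().to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
        sidecar = {
            "n_perm": self.n_perm,
            "seed": self.seed,
            "scope": self.scope,
            "hash": self.content_hash(),
            "config": config.to_dict() if config is not None else None,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    @classmethod
    def load(cls, prefix: str | Path) -> "NullDistributions":
        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
        meta = json.loads(prefix.with_suffix(".json").read_text())
        null = cls(
            n_perm=meta["n_perm"],
            seed=meta["seed"],
            scope=meta.get("scope", "shared"),
            **{p: df[p].to_numpy() for p in PARAMETERS},
        )
        if meta.get("hash") and null.content_hash() != meta["hash"]:
            raise ValueError(f"{prefix}: null vectors do not match sidecar hash")
        return null


def random_partition(rng: np.random.Generator, n_samples: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw disjoint on/off index sets of size k by shuffling the sample vector."""
    perm = rng.permutation(n_samples)
    return perm[n_samples - k :], perm[:k]


def build_null(
    E,
    config: ScreenConfig,
    n_perm: Optional[int] = None,
    seed: Optional[int] = None,
    exclude_gene: Optional[str] = None,
) -> NullDistributions:
    """Null distributions of the four parameters under random partitions.

    Each permutation draws a uniformly random pair of disjoint k-sample groups
    (k = floor(fraction * N)) and computes all four parameters on E with that
    partition.  ``exclude_gene`` removes one gene's pairs (per-modulator
    scope); the shared null keeps every pair.
    """
    n_perm = config.n_perm if n_perm is None else int(n_perm)
    seed = config.seed if seed is None else int(seed)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    k = group_size(E.n_samples, config.fraction)
    rng = np.random.default_rng(seed)
    exclude_idx = None if exclude_gene is None else E.gene_index(exclude_gene)
    out = {p: np.empty(n_perm) for p in PARAMETERS}
    for t in range(n_perm):
        on, off = random_partition(rng, E.n_samples, k)
        aci, n_nodes, n_edges, conn = four_parameters(
            E.values, on, off, config, exclude_gene_index=exclude_idx
        )
        out["aci"][t] = aci
        out["n_nodes"][t] = n_nodes
        out["n_edges"][t] = n_edges
        out["connectivity"][t] = conn
    scope = "shared" if exclude_gene is None else "per-modulator"
    return NullDistributions(n_perm=n_perm, seed=seed, scope=scope, **out)


def empirical_pvalue(observed, null: np.ndarray):
    """Add-one empirical p-value: (1 + #{null >= observed}) / (1 + n_perm).

    Never zero, maximal (= 1) when every null value ties or exceeds the
    observation, and equal to 1/(n_perm + 1) when the observation exceeds all
    null values.  ``observed`` may be a scalar or an array.
    """
    null = np.asarray(null, dtype=np.float64)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    obs = np.asarray(observed, dtype=np.float64)
    sorted_null = np.sort(null)
    n_ge = null.size - np.searchsorted(sorted_null, obs, side="left")
    p = (1.0 + n_ge) / (1.0 + null.size)
    return p if p.ndim else float(p)
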