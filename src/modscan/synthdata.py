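"""Synthetic expression matrices with planted modulator structure.

The generator emulates the modulated-pair model the screen is built to
detect: a planted modulator gene is a standard Gaussian whose rank implicitly
stratifies the samples, and each of its target pairs is drawn with a
conditional Pearson correlation of ``rho_on`` in the top-fraction stratum,
``rho_off`` in the bottom stratum, and (by default) a linear dose-response
interpolation in between.  All marginals are standard Gaussian; every gene
not named in the planted structure is independent background (optionally
equicorrelated at ``background_rho``).

A ground-truth manifest accompanies every matrix so recovery can be scored
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix

__all__ = ["PlantedModulator", "SyntheticSpec", "generate", "benchmark_spec"]


@dataclass
class PlantedModulator:
    """One modulator gene and the target pairs whose correlation it controls."""

    modulator: str
    pairs: list[tuple[str, str]]
    rho_on: float
    rho_off: float
    fraction: float = 0.25

    def __post_init__(self) -> None:
        if not -1.0 < self.rho_on < 1.0 or not -1.0 < self.rho_off < 1.0:
            raise ValueError("|rho_on| and |rho_off| must be < 1")
        if not 0.0 < self.fraction <= 0.5:
            raise ValueError("fraction must be in (0, 0.5]")
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"degenerate pair ({a}, {b})")
            if self.modulator in (a, b):
                raise ValueError(f"target pair ({a}, {b}) includes the modulator")


@dataclass
class SyntheticSpec:
    """Specification of a synthetic expression matrix.

    ``n_genes`` counts all genes including modulators and targets; background
    genes are auto-named to fill up to ``n_genes``.  ``noise_sd`` adds white
    Gaussian noise to every entry (attenuating all planted correlations by
    1 / (1 + noise_sd^2)); ``interpolation`` is ``"linear"`` (dose-response
    across the middle stratum) or ``"step"`` (middle samples at the midpoint
    correlation).
    """

    n_genes: int
    n_samples: int
    planted: list[PlantedModulator] = field(default_factory=list)
    background_rho: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        if self.interpolation not in ("linear", "step"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        if not 0.0 <= self.background_rho < 1.0:
            raise ValueError("background_rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        named = self.named_genes()
        if len(named) > self.n_genes:
            raise ValueError(
                f"planted structure names {len(named)} genes but n_genes={self.n_genes}"
            )
        owner: dict[str, str] = {}
        for pm in self.planted:
            for a, b in pm.pairs:
                for g in (a, b):
                    if owner.setdefault(g, pm.modulator) != pm.modulator:
                        raise ValueError(
                            f"target gene {g!r} is shared by modulators "
                            f"{owner[g]!r} and {pm.modulator!r}"
                        )

    def named_genes(self) -> list[str]:
        names: list[str] = []
        seen: set[str] = set()
        for pm in self.planted:
            for g in [pm.modulator] + [g for pair in pm.pairs for g in pair]:
                if g not in seen:
                    seen.add(g)
                    names.append(g)
        return names

    def gene_ids(self) -> list[str]:
        names = self.named_genes()
        width = max(4, len(str(self.n_genes)))
        existing = set(names)
        i = 1
        while len(names) < self.n_genes:
            g = f"G{i:0{width}d}"
            if g not in existing:
                names.append(g)
            i += 1
        return names

    def sample_ids(self) -> list[str]:
        width = max(4, len(str(self.n_samples)))
        return [f"S{i:0{width}d}" for i in range(1, self.n_samples + 1)]


def _per_sample_rho(
    mod_values: np.ndarray, rho_on: float, rho_off: float, fraction: float, interpolation: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample target correlation and stratum labels from the modulator rank."""
    n = mod_values.size
    k = int(np.floor(fraction * n + 1e-9))
    order = np.argsort(mod_values, kind="stable")
    rho = np.empty(n)
    stratum = np.empty(n, dtype=object)
    rho[order[:k]] = rho_off
    stratum[order[:k]] = "off"
    rho[order[n - k :]] = rho_on
    stratum[order[n - k :]] = "on"
    mid = order[k : n - k]
    stratum[mid] = "mid"
    if mid.size:
        if interpolation == "step" or mid.size == 1:
            rho[mid] = 0.5 * (rho_on + rho_off)
        else:
            t = (np.arange(mid.size) + 0.5) / mid.size
            rho[mid] = rho_off + t * (rho_on - rho_off)
    return rho, stratum


def _components(pairs: Sequence[tuple[str, str]]) -> list[list[tuple[str, str]]]:
    """Group pairs into connected components via shared genes."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        parent[find(a)] = find(b)
    groups: dict[str, list[tuple[str, str]]] = {}
    for p in pairs:
        groups.setdefault(find(p[0]), []).append(p)
    return list(groups.values())


def generate(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw the matrix; returns (matrix, pair manifest, per-sample strata).

    The manifest has one row per planted pair (modulator, gene_i, gene_j,
    rho_on, rho_off, fraction); the strata table has one row per
    (sample, modulator) with the stratum label and the conditional
    correlation applied to that sample's target pairs.  Fully reproducible
    from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    gidx = {g: i for i, g in enumerate(genes)}
    n = spec.n_samples
    values = np.empty((spec.n_genes, n))
    filled = np.zeros(spec.n_genes, dtype=bool)

    manifest_rows = []
    strata_rows = []
    sids = spec.sample_ids()
    for pm in spec.planted:
        mi = gidx[pm.modulator]
        if not filled[mi]:
            values[mi] = rng.standard_normal(n)
            filled[mi] = True
        rho_s, stratum = _per_sample_rho(
            values[mi], pm.rho_on, pm.rho_off, pm.fraction, spec.interpolation
        )
        for s in range(n):
            strata_rows.append(
                {
                    "sample_id": sids[s],
                    "modulator": pm.modulator,
                    "stratum": stratum[s],
                    "rho": rho_s[s],
                }
            )
        for a, b in pm.pairs:
            manifest_rows.append(
                {
                    "modulator": pm.modulator,
                    "gene_i": a,
                    "gene_j": b,
                    "rho_on": pm.rho_on,
                    "rho_off": pm.rho_off,
                    "fraction": pm.fraction,
                }
            )
        for comp in _components(pm.pairs):
            comp_genes = sorted({g for pair in comp for g in pair})
            ci = {g: i for i, g in enumerate(comp_genes)}
            m = len(comp_genes)
            if len(comp) == 1:
                # disjoint pair: closed-form Gaussian mixing, PD by construction
                a, b = comp[0]
                xa = rng.standard_normal(n)
                eps = rng.standard_normal(n)
                values[gidx[a]] = xa
                values[gidx[b]] = rho_s * xa + np.sqrt(1.0 - rho_s**2) * eps
            else:
                # shared genes: per-sample Cholesky of the component matrix
                z = rng.standard_normal((n, m))
                for s in range(n):
                    R = np.eye(m)
                    for a, b in comp:
                        R[ci[a], ci[b]] = R[ci[b], ci[a]] = rho_s[s]
                    try:
                        L = np.linalg.cholesky(R)
                    except np.linalg.LinAlgError:
                        raise ValueError(
                            f"correlation matrix for genes {comp_genes} at rho="
                            f"{rho_s[s]:.3f} is not positive definite"
                        ) from None
                    row = L @ z[s]
                    for g in comp_genes:
                        values[gidx[g], s] = row[ci[g]]
            for g in comp_genes:
                filled[gidx[g]] = True

    background = ~filled
    nb = int(background.sum())
    if nb:
        if spec.background_rho > 0.0:
            common = rng.standard_normal(n)
            noise = rng.standard_normal((nb, n))
            values[background] = (
                np.sqrt(spec.background_rho) * common
                + np.sqrt(1.0 - spec.background_rho) * noise
            )
        else:
            values[background] = rng.standard_normal((nb, n))

    if spec.noise_sd > 0.0:
        values = values + rng.normal(0.0, spec.noise_sd, values.shape)

    E = ExpressionMatrix(genes, spec.sample_ids(), values)
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["modulator", "gene_i", "gene_j", "rho_on", "rho_off", "fraction"],
    )
    strata = pd.DataFrame(strata_rows, columns=["sample_id", "modulator", "stratum", "rho"])
    return E, manifest, strata


def benchmark_spec(
    n_genes: int = 300,
    n_samples: int = 400,
    n_pairs: int = 100,
    rho_on: float = 0.7,
    rho_off: float = 0.0,
    fraction: float = 0.25,
    seed: int = 0,
    noise_sd: float = 0.0,
    topology: str = "triangle",
) -> SyntheticSpec:
    """Standard recovery benchmark: one modulator controlling ``n_pairs`` pairs.

    ``topology="triangle"`` (default) arranges the pairs as three-gene
    cliques (A-B, B-C, A-C; positive definite for any |rho| < 1 since the
    determinant is (1-rho)^2 (1+2rho)), so the true modulated network has
    connectivity near 2 and all four modularity parameters are informative.
    ``topology="chain"`` uses open three-gene paths (requires |rho| <
    1/sqrt(2); connectivity at most 4/3, which a chance two-edge path in a
    null network can tie).  ``topology="matching"`` uses disjoint pairs;
    a matching's connectivity is exactly 1, the minimum over nonempty
    networks, so the connectivity parameter carries no signal there.
    """
    if topology in ("triangle", "chain"):
        per, clique = (3, True) if topology == "triangle" else (2, False)
        n_comp, rem = divmod(n_pairs, per)
        pairs = []
        g = 0
        for _ in range(n_comp):
            a, b, c = (f"T{g + i:04d}" for i in range(1, 4))
            pairs += [(a, b), (b, c)] + ([(a, c)] if clique else [])
            g += 3
        if rem == 2:
            a, b, c = (f"T{g + i:04d}" for i in range(1, 4))
            pairs += [(a, b), (b, c)]
            g += 3
        elif rem == 1:
            pairs.append((f"T{g + 1:04d}", f"T{g + 2:04d}"))
            g += 2
        n_targets = g
    elif topology == "matching":
        pairs = [(f"T{2 * i + 1:04d}", f"T{2 * i + 2:04d}") for i in range(n_pairs)]
        n_targets = 2 * n_pairs
    else:
        raise ValueError(f"unknown topology {topology!r}")
    if 1 + n_targets > n_genes:
        raise ValueError("n_genes too small for the requested pair count")
    planted = PlantedModulator("MOD1", pairs, rho_on, rho_off, fraction)
    return SyntheticSpec(
        n_genes=n_genes,
        n_samples=n_samples,
        planted=[planted],
        seed=seed,
        noise_sd=noise_sd,
    )


def write_truth(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)
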