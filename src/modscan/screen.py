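"""Genome-wide modulator screen: profile, test, intersect, rank.

Every gene is profiled as a candidate modulator, its four parameters are
converted to empirical p-values against the permutation null, the four
per-parameter significant lists are intersected into the key-modulator set,
and candidates are ranked by the average z-value of the four parameters.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from . import __version__ as _version
from .config import ScreenConfig
from .data_io import MIN_SAMPLES_FOR_SCREEN, ExpressionMatrix
from .magic import group_size, partition_samples
from .modularity import PARAMETERS, ModularityProfile, profile_modulator
from .permutation import NullDistributions, build_null, empirical_pvalue

logger = logging.getLogger(__name__)

_PCOLS = {"aci": "p_aci", "n_nodes": "p_nodes", "n_edges": "p_edges", "connectivity": "p_conn"}
_RCOLS = {"aci": "rank_aci", "n_nodes": "rank_nodes", "n_edges": "rank_edges", "connectivity": "rank_conn"}


@dataclass
class ScreenResult:
    """Output of one genome-wide screen."""

    profiles: pd.DataFrame  # one row per profiled gene, parameters + p-values
    ranked: pd.DataFrame  # profiles with ranks and avg_z, sorted
    significant_sets: dict[str, list[str]]  # per-parameter gene lists at the cutoff
    key_modulators: list[str]  # intersection of the four lists
    null: NullDistributions
    config: ScreenConfig
    run_log: dict

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ranked.to_csv(outdir / "modulators_ranked.tsv", sep="\t", index=False)
        for p, genes in self.significant_sets.items():
            pd.Series(genes, name="gene").to_csv(
                outdir / f"significant_{p}.tsv", sep="\t", index=False
            )
        pd.Series(self.key_modulators, name="gene").to_csv(
            outdir / "key_modulators.tsv", sep="\t", index=False
        )
        self.null.save(outdir / "null_distributions", self.config)
        (outdir / "run_log.json").write_text(json.dumps(self.run_log, indent=2, sort_keys=True))


def _profile_batch(E: ExpressionMatrix, genes: Sequence[str], config: ScreenConfig):
    return [profile_modulator(E, g, config) for g in genes]


def profiles_to_frame(profiles: Sequence[ModularityProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [p.gene for p in profiles],
            "aci": [p.aci for p in profiles],
            "n_nodes": [p.n_nodes for p in profiles],
            "n_edges": [p.n_edges for p in profiles],
            "connectivity": [p.connectivity for p in profiles],
        }
    )


def rank_modulators(profiles: pd.DataFrame, z_log_scale: bool = False) -> pd.DataFrame:
    """Attach per-parameter ranks and the average-z composite, then sort.

    For each parameter, z = (value - mean) / sd across all profiled genes
    (optionally on log1p-transformed values); avg_z is the mean of the four
    z's.  Per-parameter rank 1 is the largest value, ties share the minimal
    rank.  Final order: avg_z descending, then gene id ascending.
    """
    if len(profiles) < 2:
        raise ValueError("ranking needs at least two profiled genes")
    out = profiles.copy()
    zs = []
    for p in PARAMETERS:
        v = out[p].to_numpy(dtype=np.float64)
        x = np.log1p(v) if z_log_scale else v
        sd = x.std(ddof=1)
        if sd == 0.0:
            warnings.warn(f"parameter {p} has zero spread; its z set to 0", stacklevel=2)
            z = np.zeros_like(x)
        else:
            z = (x - x.mean()) / sd
        zs.append(z)
        out[_RCOLS[p]] = stats.rankdata(-v, method="min").astype(int)
    out["avg_z"] = np.mean(zs, axis=0)
    out = out.sort_values(["avg_z", "gene"], ascending=[False, True]).reset_index(drop=True)
    out.insert(1, "rank", np.arange(1, len(out) + 1))
    return out


def run_screen(E: ExpressionMatrix, config: ScreenConfig) -> ScreenResult:
    """Profile every candidate gene and assemble the key-modulator set.

    Deterministic given the configuration seed; results are independent of
    ``batch_size`` and ``n_jobs`` because candidate profiles are mutually
    independent and reassembled in gene order.
    """
    if E.n_genes < 2:
        raise ValueError("screen needs at least 2 genes")
    if E.n_samples < MIN_SAMPLES_FOR_SCREEN:
        raise ValueError(f"screen needs at least {MIN_SAMPLES_FOR_SCREEN} samples")
    candidates = list(config.genes) if config.genes is not None else list(E.gene_ids)
    for g in candidates:
        E.gene_index(g)  # fail fast on unknown candidates

    shared_null = None
    if config.null_scope == "shared" or not candidates:
        shared_null = build_null(E, config)

    profiles: list[ModularityProfile] = []
    if candidates:
        batches = [
            candidates[i : i + config.batch_size]
            for i in range(0, len(candidates), config.batch_size)
        ]
        results = Parallel(n_jobs=config.n_jobs)(
            delayed(_profile_batch)(E, batch, config) for batch in batches
        )
        for r in results:
            profiles.extend(r)

    df = profiles_to_frame(profiles)
    if config.null_scope == "shared":
        nulls = {g: shared_null for g in candidates}
    else:
        nulls = {g: build_null(E, config, exclude_gene=g) for g in candidates}
    sig_sets: dict[str, list[str]] = {}
    for p in PARAMETERS:
        if candidates:
            pvals = np.array(
                [
                    empirical_pvalue(df.loc[i, p], nulls[df.loc[i, "gene"]].values(p))
                    for i in range(len(df))
                ]
            )
        else:
            pvals = np.array([])
        df[_PCOLS[p]] = pvals
        sig_sets[p] = sorted(df.loc[df[_PCOLS[p]] < config.empirical_cutoff, "gene"])

    key = sorted(set.intersection(*(set(s) for s in sig_sets.values()))) if candidates else []
    ranked = rank_modulators(df, config.z_log_scale) if len(df) >= 2 else df.copy()

    if shared_null is not None:
        null = shared_null
    elif nulls:
        null = nulls[candidates[0]]
    else:
        null = build_null(E, config)
    run_log = {
        "modscan_version": _version,
        "n_genes": E.n_genes,
        "n_samples": E.n_samples,
        "n_candidates": len(candidates),
        "group_size": group_size(E.n_samples, config.fraction),
        "config": config.to_dict(),
        "n_key_modulators": len(key),
        "significant_set_sizes": {p: len(s) for p, s in sig_sets.items()},
        "null_hash": null.content_hash(),
    }
    logger.info(
        "screen done: %d candidates, key modulators: %d", len(candidates), len(key)
    )
    return ScreenResult(df, ranked, sig_sets, key, null, config, run_log)


def sample_status(
    E: ExpressionMatrix, modulators: Sequence[str], fraction: float = 0.25
) -> pd.DataFrame:
    """Per-sample counts of modulators for which the sample is on/off/effective.

    For each modulator its top-k samples are "on" and bottom-k "off"
    (k = floor(fraction * N)); a modulator is effective in a sample when the
    sample falls in either group.  The mean over samples of n_on equals
    len(modulators) * k / N exactly (every modulator marks exactly k samples).
    """
    n_on = np.zeros(E.n_samples, dtype=int)
    n_off = np.zeros(E.n_samples, dtype=int)
    for m in modulators:
        part = partition_samples(E, m, fraction)
        n_on[part.on_samples] += 1
        n_off[part.off_samples] += 1
    return pd.DataFrame(
        {
            "sample_id": E.sample_ids,
            "n_on": n_on,
            "n_off": n_off,
            "n_effective": n_on + n_off,
        }
    )
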