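"""Preranked gene-set enrichment analysis.

Genes are ranked by their trait correlation coefficient (descending).  The
enrichment score (ES) of a set is the extremum of the weighted
Kolmogorov-Smirnov running sum: walking down the ranked list, hitting a set
member increments the sum by |weight|^weight_exp normalized by the sum over
hits, and missing decrements by 1 / (N - Nh).  Significance uses a
gene-label permutation null (random sets of the same size), from which the
normalized enrichment score NES = ES / mean(|null ES of the same sign|) and
a pooled positive/negative-null FDR are derived, flagged at FDR < 0.25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RankedList",
    "enrichment_score",
    "nes_fdr",
    "read_gmt",
    "write_gmt",
]


@dataclass
class RankedList:
    """Genes ordered by descending ranking weight (Pearson r)."""

    genes: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.genes) != len(self.weights):
            raise ValueError("genes and weights differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        if not np.isfinite(self.weights).all():
            raise ValueError("ranking weights must be finite")
        if np.any(np.diff(self.weights) > 1e-12):
            raise ValueError("weights must be sorted in descending order")

    @classmethod
    def from_correlations(cls, cor: pd.DataFrame) -> "RankedList":
        """Build from a correlation result table (index gene_id, column r)."""
        r = cor["r"].dropna().sort_values(ascending=False, kind="stable")
        return cls(list(r.index), r.to_numpy())


def _running_sum(
    hit_mask: np.ndarray, weights: np.ndarray, weight_exp: float
) -> np.ndarray:
    n = len(weights)
    nh = int(hit_mask.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set overlaps none or all of the ranked list")
    w = np.abs(weights) ** weight_exp
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all hit weights zero (e.g. r == 0); fall back to equal increments
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~hit_mask) / (n - nh)
    return np.cumsum(steps)


def enrichment_score(
    ranked: RankedList, gene_set, weight_exp: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score of ``gene_set`` on the ranked list.

    Returns (ES, running-sum profile).  ES is the extremum of the running
    sum (the value of largest magnitude; positive ES means enrichment at the
    top of the list).
    """
    gene_set = set(gene_set)
    hit = np.fromiter((g in gene_set for g in ranked.genes), bool, len(ranked.genes))
    running = _running_sum(hit, ranked.weights, weight_exp)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def _leading_edge(ranked: RankedList, gene_set: set, running: np.ndarray) -> list[str]:
    i = int(np.argmax(np.abs(running)))
    if running[i] >= 0:
        span = ranked.genes[: i + 1]
    else:
        span = ranked.genes[i + 1:]
    return [g for g in span if g in gene_set]


def nes_fdr(
    ranked: RankedList,
    gene_sets: dict[str, set],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exp: float = 1.0,
    fdr_threshold: float = 0.25,
) -> pd.DataFrame:
    """NES, permutation p and pooled FDR for a collection of gene sets.

    The null permutes gene labels: for each set size, ``n_perm`` random sets
    of that size are scored on the same ranked list.  NES divides each ES by
    the mean |null ES| of its sign; FDR compares, per sign, the pooled
    normalized null tail beyond each observed NES with the observed tail.
    """
    if len(gene_sets) < 2:
        raise ValueError("need >= 2 gene sets for pooled FDR")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low for a permutation null",
                      stacklevel=2)
    if seed is None:
        raise ValueError("seed is mandatory for the permutation null")
    rng = np.random.default_rng(seed)
    n = len(ranked.genes)

    obs: dict[str, tuple[float, list[str]]] = {}
    null_by_size: dict[int, np.ndarray] = {}
    weights = ranked.weights
    for name, gs in gene_sets.items():
        gs = set(gs) & set(ranked.genes)
        es, running = enrichment_score(
            RankedList(ranked.genes, weights), gs, weight_exp
        )
        obs[name] = (es, _leading_edge(ranked, gs, running))
        size = len(gs)
        if size not in null_by_size:
            null_es = np.empty(n_perm)
            for b in range(n_perm):
                idx = rng.choice(n, size=size, replace=False)
                mask = np.zeros(n, dtype=bool)
                mask[idx] = True
                run = _running_sum(mask, weights, weight_exp)
                null_es[b] = run[np.argmax(np.abs(run))]
            null_by_size[size] = null_es

    rows = []
    all_nes_null: list[np.ndarray] = []
    nes_obs: dict[str, float] = {}
    for name, gs in gene_sets.items():
        size = len(set(gs) & set(ranked.genes))
        es, le = obs[name]
        null = null_by_size[size]
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        denom = pos_mean if es >= 0 else neg_mean
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        same = null[null >= 0] if es >= 0 else null[null < 0]
        p_perm = ((np.abs(same) >= abs(es)).sum() + 1) / (len(same) + 1) if len(same) else np.nan
        nes_null = np.where(null >= 0, null / pos_mean, null / neg_mean)
        all_nes_null.append(nes_null)
        nes_obs[name] = nes
        rows.append({"set_name": name, "es": es, "nes": nes, "p_perm": p_perm,
                     "leading_edge": ",".join(le)})

    pooled = np.concatenate(all_nes_null)
    obs_nes = np.array([nes_obs[r["set_name"]] for r in rows])
    for row, nes in zip(rows, obs_nes):
        if not np.isfinite(nes):
            row["fdr"] = np.nan
            continue
        if nes >= 0:
            num = (pooled >= nes).mean()
            den = (obs_nes >= nes).mean()
        else:
            num = (pooled <= nes).mean()
            den = (obs_nes <= nes).mean()
        row["fdr"] = min(1.0, num / den) if den > 0 else 1.0
    out = pd.DataFrame(rows, columns=["set_name", "es", "nes", "p_perm", "fdr",
                                      "leading_edge"])
    out["significant"] = out["fdr"] < fdr_threshold
    return out.sort_values("set_name", kind="stable").reset_index(drop=True)


def read_gmt(path) -> dict[str, set]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(gene_sets: dict[str, set], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")
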