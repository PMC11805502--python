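"""Pre-ranked gene set enrichment and hypergeometric overrepresentation.

Pre-ranked GSEA walks down a ranked gene list accumulating a weighted
Kolmogorov-Smirnov-style running sum: hitting a set member adds
|score|^p / sum_set |score|^p, missing subtracts 1/(N - |S|).  The
enrichment score (ES) is the signed maximum deviation of the running sum
(on an exact magnitude tie the positive extreme is reported);
its null distribution comes from gene-label permutations (random sets of
the same size drawn from the ranked list), giving a permutation p-value
(add-one smoothed) and a normalized ES (ES divided by the mean |null ES|
of matching sign).  Sets are filtered to members present in the ranked
list and to sizes within [min_size, max_size] (defaults 15 and 500).

ORA tests a selected gene list against each set with the upper-tail
hypergeometric probability P(X >= overlap) in the given universe; both
analyses adjust p-values across sets with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "rank_genes",
    "enrichment_score",
    "PreRankedGSEA",
    "gsea_prerank",
    "ora_hypergeometric",
    "bh_adjust",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (flat membership lists, GMT-style)."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} contains duplicate ids")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description,
    then member gene ids."""
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need name, description "
                    f"and at least one member)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = tuple(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def rank_genes(de: pd.DataFrame, mode: str = "signed_p") -> pd.Series:
    """Build a ranked gene list from a differential-expression table.

    ``signed_p``: score = -log10(p) * sign(effect) — the ranking used for
    moderated-test output where small p means strong evidence either way.
    ``signed_log2_ratio``: score = effect (log2 fold change) directly.

    Genes are sorted by descending score with a stable tie-break on gene id
    for determinism.  p = 0 is capped at 0.1x the smallest positive p.
    """
    if mode not in ("signed_p", "signed_log2_ratio"):
        raise ValueError(f"unknown ranking mode {mode!r}")
    effect = de["log2fc"].to_numpy(dtype=float)
    if mode == "signed_log2_ratio":
        score = effect
    else:
        p = de["pvalue"].to_numpy(dtype=float)
        if not np.isfinite(p).all() or not np.isfinite(effect).all():
            raise ValueError("p-values and effects must be finite")
        if (p == 0).any():
            smallest = p[p > 0].min() if (p > 0).any() else 1e-300
            p = np.where(p == 0, smallest * 0.1, p)
        score = -np.log10(p) * np.sign(effect)
    ranked = pd.Series(score, index=de.index.astype(str), name="score")
    if ranked.index.has_duplicates:
        raise ValueError("ranked list has duplicate gene ids")
    order = sorted(range(len(ranked)), key=lambda i: (-ranked.iloc[i], ranked.index[i]))
    return ranked.iloc[order]


def _es_from_hits(
    hit_pos: np.ndarray, weights: np.ndarray, n_total: int
) -> tuple[float, int]:
    """ES and the 0-based rank position of its extremum.

    ``hit_pos`` are sorted 0-based positions of set members in the ranked
    list; ``weights`` the corresponding |score|^p values.  The running sum
    attains its extrema immediately after a hit (candidate maxima) or
    immediately before a hit (candidate minima), so only those 2m points
    need evaluation.
    """
    m = hit_pos.size
    denom = weights.sum()
    if denom > 0:
        gains = np.cumsum(weights) / denom
    else:  # all-zero scores: fall back to unweighted increments
        gains = np.arange(1, m + 1) / m
    miss = 1.0 / (n_total - m)
    k = np.arange(m)
    after = gains - (hit_pos - k) * miss  # value just after each hit
    before = np.concatenate([[0.0], gains[:-1]]) - (hit_pos - k) * miss  # just before
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    es_max = after[i_max]
    es_min = before[i_min]
    # ES is mathematically bounded by [-1, 1]; clamp float round-off
    if es_max >= -es_min:
        return float(np.clip(es_max, -1.0, 1.0)), int(hit_pos[i_max])
    return float(np.clip(es_min, -1.0, 1.0)), int(hit_pos[i_min])


def enrichment_score(
    ranked: pd.Series, members: Sequence[str], weight: float = 1.0
) -> float:
    """ES of one gene set against a ranked list (members not in the list are
    ignored)."""
    idx = {g: i for i, g in enumerate(ranked.index)}
    hits = np.array(sorted(idx[g] for g in members if g in idx))
    if hits.size == 0 or hits.size == len(ranked):
        raise ValueError("set must hit some but not all genes of the ranked list")
    weights = np.abs(ranked.to_numpy(dtype=float)[hits]) ** weight
    es, _ = _es_from_hits(hits, weights, len(ranked))
    return es


class PreRankedGSEA(BaseEstimator):
    """Pre-ranked GSEA with a gene-label permutation null.

    Parameters
    ----------
    weight : float
        Exponent p of the |score|^p hit increments (1.0 = classic weighted
        statistic, 0.0 = unweighted Kolmogorov-Smirnov).
    n_perm : int
        Number of permutations for the null (a warning is emitted below 100).
    min_size, max_size : int
        Set-size bounds applied *after* restriction to genes present in the
        ranked list; out-of-bounds sets are skipped and recorded in
        ``skipped_``.
    random_state : int, optional
        Seed of the permutation stream; fixed seed gives bit-identical
        results.
    """

    def __init__(
        self,
        weight: float = 1.0,
        n_perm: int = 1000,
        min_size: int = 15,
        max_size: int = 500,
        random_state: int | None = None,
    ):
        self.weight = weight
        self.n_perm = n_perm
        self.min_size = min_size
        self.max_size = max_size
        self.random_state = random_state

    def fit(self, ranked: pd.Series, gene_sets: GeneSetCollection) -> "PreRankedGSEA":
        if self.n_perm < 100:
            warnings.warn(
                f"n_perm={self.n_perm} < 100: permutation p-values will be coarse",
                RuntimeWarning,
                stacklevel=2,
            )
        rng = np.random.default_rng(self.random_state)
        n = len(ranked)
        scores = ranked.to_numpy(dtype=float)
        weights_all = np.abs(scores) ** self.weight
        idx = {g: i for i, g in enumerate(ranked.index)}

        rows = []
        skipped: list[tuple[str, int]] = []
        for name, members in gene_sets:
            hits = np.array(sorted(idx[g] for g in set(members) if g in idx))
            m = hits.size
            if m < self.min_size or m > self.max_size or m >= n:
                skipped.append((name, m))
                continue
            es, extremum = _es_from_hits(hits, weights_all[hits], n)
            null = np.empty(self.n_perm)
            for b in range(self.n_perm):
                perm = np.sort(rng.choice(n, size=m, replace=False))
                null[b], _ = _es_from_hits(perm, weights_all[perm], n)
            same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
            if same_sign.size:
                pval = (1.0 + (np.abs(same_sign) >= abs(es)).sum()) / (
                    1.0 + same_sign.size
                )
                nes = es / np.abs(same_sign).mean()
            else:
                pval = 1.0 / (1.0 + self.n_perm)
                nes = np.nan
            if es >= 0:
                leading = int((hits <= extremum).sum())
            else:
                leading = int((hits >= extremum).sum())
            rows.append(
                {
                    "set": name,
                    "size": m,
                    "es": es,
                    "nes": nes,
                    "pvalue": pval,
                    "leading_edge_size": leading,
                }
            )
        results = pd.DataFrame(
            rows, columns=["set", "size", "es", "nes", "pvalue", "leading_edge_size"]
        )
        if len(results):
            results["qvalue"] = bh_adjust(results["pvalue"].to_numpy())
        else:
            results["qvalue"] = np.array([], dtype=float)
        self.results_ = results
        self.skipped_ = skipped
        return self


def gsea_prerank(
    ranked: pd.Series,
    gene_sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 15,
    max_size: int = 500,
    seed: int | None = None,
) -> pd.DataFrame:
    """Functional wrapper over :class:`PreRankedGSEA`; returns the result table."""
    est = PreRankedGSEA(
        weight=weight,
        n_perm=n_perm,
        min_size=min_size,
        max_size=max_size,
        random_state=seed,
    ).fit(ranked, gene_sets)
    return est.results_


def ora_hypergeometric(
    selected: Sequence[str],
    universe: Sequence[str],
    gene_sets: GeneSetCollection,
) -> pd.DataFrame:
    """Overrepresentation analysis: upper-tail hypergeometric test per set.

    ``selected`` (e.g. the DEG list) must be a subset of ``universe`` (all
    genes tested).  Set membership is intersected with the universe before
    testing.  p = P(X >= overlap) for X hypergeometric with the set as
    successes; q-values are Benjamini-Hochberg across sets.
    """
    universe_set = set(universe)
    selected_set = set(selected)
    offenders = sorted(selected_set - universe_set)
    if offenders:
        raise ValueError(f"selected genes not in universe: {offenders}")
    m_univ = len(universe_set)
    n_sel = len(selected_set)
    rows = []
    for name, members in gene_sets:
        in_univ = set(members) & universe_set
        k_set = len(in_univ)
        overlap = len(in_univ & selected_set)
        # P(X >= overlap), X ~ Hypergeom(M=m_univ, n=k_set, N=n_sel)
        p = float(stats.hypergeom.sf(overlap - 1, m_univ, k_set, n_sel)) if k_set else 1.0
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": k_set,
                "universe_size": m_univ,
                "selected_size": n_sel,
                "pvalue": min(p, 1.0),
            }
        )
    results = pd.DataFrame(rows)
    results["padj"] = bh_adjust(results["pvalue"].to_numpy())
    return results


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
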