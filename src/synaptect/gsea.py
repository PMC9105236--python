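"""Gene-set enrichment: signal-to-noise ranking, weighted running-sum
enrichment score, permutation NES/FDR, and leading-edge extraction.

The statistic is the weighted Kolmogorov–Smirnov running sum: walking the
ranked gene list, membership hits increment the sum proportionally to
|metric|^p (normalized to 1 over the set) and misses decrement it by
1/(N − n); the enrichment score (ES) is the signed extremum.  Significance
comes from phenotype-label permutations (gene-set permutation as a
small-sample fallback): NES divides the ES by the mean magnitude of
same-sign null scores, and the FDR q pools positive and negative nulls
separately.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

MIN_SET_SIZE = 5
#: Below this per-group sample size, phenotype permutation is too coarse and
#: gene-set permutation is used instead.
PHENOTYPE_PERMUTATION_MIN_N = 7


@dataclasses.dataclass
class GeneSet:
    name: str
    members: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


@dataclasses.dataclass
class EnrichmentResult:
    """ES/NES/FDR and leading-edge membership for one gene set."""

    name: str
    size: int
    es: float
    nes: float
    p_perm: float
    fdr_q: float
    leading_edge: list[str]
    direction: str  # group in which the set is enriched


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT (name, description, members — tab separated, one set per line).

    Duplicate members within a line are deduplicated with a warning.
    """
    sets: list[GeneSet] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 member): {line[:80]!r}")
        name, desc, raw = parts[0], parts[1], parts[2:]
        members = list(dict.fromkeys(m for m in raw if m))
        if len(members) != len([m for m in raw if m]):
            warnings.warn(f"gene set {name!r}: duplicate members deduplicated", stacklevel=2)
        sets.append(GeneSet(name=name, members=members, description=desc))
    return sets


def _snr_metric(x: np.ndarray, pos_mask: np.ndarray) -> np.ndarray:
    """Signal-to-noise ratio (μ_pos − μ_neg)/(σ_pos + σ_neg) per gene."""
    a, b = x[:, pos_mask], x[:, ~pos_mask]
    mu = a.mean(axis=1) - b.mean(axis=1)
    sd = a.std(axis=1, ddof=1) + b.std(axis=1, ddof=1)
    sd = np.maximum(sd, np.finfo(float).eps)
    return mu / sd


def rank_genes(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    positive_group: str | None = None,
) -> pd.Series:
    """Rank genes by signal-to-noise ratio, descending; ties broken by name.

    ``positive_group`` (default: the first label encountered) is the group
    whose higher expression gives a positive metric, hence a positive ES for
    sets enriched in it.
    """
    lab = np.asarray(labels)
    uniq = pd.unique(lab)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    pos = positive_group if positive_group is not None else uniq[0]
    if pos not in uniq:
        raise ValueError(f"positive_group {pos!r} not among labels {list(uniq)}")
    metric = _snr_metric(matrix.to_numpy(dtype=float), lab == pos)
    names = np.asarray(matrix.index, dtype=str)
    order = np.lexsort((names, -metric))
    return pd.Series(metric[order], index=names[order], name="snr")


def enrichment_score(
    ranking: pd.Series, gene_set: GeneSet, weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS running statistic for one set on a ranked list.

    Returns ``(es, running_sum)`` where ``running_sum`` has one entry per
    ranked gene and ``es`` is its extremum of largest magnitude (first such
    position on ties).  With ``weight_p = 0`` this is the classic unweighted
    KS statistic.
    """
    names = np.asarray(ranking.index, dtype=str)
    metric = ranking.to_numpy(dtype=float)
    members = set(gene_set.members) & set(names)
    n, big_n = len(members), len(names)
    if n == 0 or n == big_n:
        raise ValueError("gene set must be a proper nonempty subset of the ranked universe")
    hit = np.isin(names, list(members))
    w = np.abs(metric) ** weight_p
    nr = w[hit].sum()
    inc = np.where(hit, (w / nr if nr > 0 else np.where(hit, 1.0 / n, 0.0)), 0.0)
    if nr == 0:
        inc = np.where(hit, 1.0 / n, 0.0)
    dec = np.where(hit, 0.0, 1.0 / (big_n - n))
    running = np.cumsum(inc - dec)
    i_ext = int(np.argmax(np.abs(running)))
    return float(running[i_ext]), running


def leading_edge(ranking: pd.Series, gene_set: GeneSet, weight_p: float = 1.0) -> list[str]:
    """Set members at or before the running-sum extremum, on the enriched side.

    For a positive ES these are the members ranked at or above the extremum;
    for a negative ES the members at or below it (walking from the bottom).
    """
    es, running = enrichment_score(ranking, gene_set, weight_p)
    names = np.asarray(ranking.index, dtype=str)
    hit = np.isin(names, list(set(gene_set.members) & set(names)))
    i_ext = int(np.argmax(np.abs(running)))
    if es >= 0:
        mask = hit & (np.arange(len(names)) <= i_ext)
    else:
        mask = hit & (np.arange(len(names)) > i_ext)
    return [g for g in names[mask]]


def _es_fast(positions: np.ndarray, weights: np.ndarray, big_n: int) -> float:
    """ES from sorted 0-based hit positions and their |metric|^p weights."""
    n = len(positions)
    nr = weights.sum()
    hit_cum = np.cumsum(weights / nr) if nr > 0 else np.arange(1, n + 1) / n
    miss = (positions - np.arange(n)) / (big_n - n)
    after = hit_cum - miss
    before = np.concatenate(([0.0], hit_cum[:-1])) - miss
    cand = np.concatenate((after, before))
    return float(cand[np.argmax(np.abs(cand))])


def permutation_significance(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    sets: list[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    positive_group: str | None = None,
) -> list[EnrichmentResult]:
    """Permutation-based NES / p / FDR q for a collection of gene sets.

    Phenotype-label permutation when both groups have at least
    ``PHENOTYPE_PERMUTATION_MIN_N`` samples, otherwise gene-set permutation.
    Sets smaller than ``MIN_SET_SIZE`` after intersection with the expression
    universe, or as large as the universe, are skipped with a warning.
    Deterministic for a given seed.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    lab = np.asarray(labels)
    uniq = pd.unique(lab)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    pos = positive_group if positive_group is not None else uniq[0]
    neg = [g for g in uniq if g != pos][0]

    x = matrix.to_numpy(dtype=float)
    names = np.asarray(matrix.index, dtype=str)
    big_n = len(names)
    name_to_row = {g: i for i, g in enumerate(names)}

    usable, member_rows = [], []
    for gs in sets:
        rows = np.array(sorted(name_to_row[g] for g in gs.members if g in name_to_row))
        if len(rows) < MIN_SET_SIZE or len(rows) >= big_n:
            warnings.warn(
                f"gene set {gs.name!r} skipped (size {len(rows)} outside "
                f"[{MIN_SET_SIZE}, {big_n - 1}])",
                stacklevel=2,
            )
            continue
        usable.append(gs)
        member_rows.append(rows)
    if not usable:
        return []

    pos_mask = lab == pos

    def es_all_sets(metric: np.ndarray) -> np.ndarray:
        order = np.argsort(-metric, kind="stable")
        position = np.empty(big_n, dtype=int)
        position[order] = np.arange(big_n)
        w_abs = np.abs(metric) ** weight_p
        out = np.empty(len(member_rows))
        for k, rows in enumerate(member_rows):
            p_hits = np.sort(position[rows])
            out[k] = _es_fast(p_hits, w_abs[order][p_hits], big_n)
        return out

    metric_obs = _snr_metric(x, pos_mask)
    es_obs = es_all_sets(metric_obs)

    use_phenotype = min(pos_mask.sum(), (~pos_mask).sum()) >= PHENOTYPE_PERMUTATION_MIN_N
    null_es = np.empty((n_perm, len(member_rows)))
    if use_phenotype:
        for i in range(n_perm):
            null_es[i] = es_all_sets(_snr_metric(x, rng.permutation(pos_mask)))
    else:
        order = np.argsort(-metric_obs, kind="stable")
        w_ord = np.abs(metric_obs[order]) ** weight_p
        for k, rows in enumerate(member_rows):
            sz = len(rows)
            for i in range(n_perm):
                p_hits = np.sort(rng.choice(big_n, size=sz, replace=False))
                null_es[i, k] = _es_fast(p_hits, w_ord[p_hits], big_n)

    def normalize(es: np.ndarray, nulls: np.ndarray) -> np.ndarray:
        """NES = ES / mean |same-sign null ES| (per set)."""
        out = np.zeros_like(es)
        for k in range(nulls.shape[1] if nulls.ndim == 2 else len(es)):
            col = nulls[:, k]
            e = es[k]
            same = col[col >= 0] if e >= 0 else col[col < 0]
            denom = np.abs(same).mean() if len(same) else np.abs(col).mean()
            out[k] = e / denom if denom > 0 else 0.0
        return out

    nes_obs = normalize(es_obs, null_es)
    nes_null = np.empty_like(null_es)
    for k in range(null_es.shape[1]):
        col = null_es[:, k]
        pos_n = col[col >= 0]
        neg_n = col[col < 0]
        mpos = np.abs(pos_n).mean() if len(pos_n) else 1.0
        mneg = np.abs(neg_n).mean() if len(neg_n) else 1.0
        nes_null[:, k] = np.where(col >= 0, col / mpos if mpos > 0 else 0.0,
                                  col / mneg if mneg > 0 else 0.0)

    pooled = nes_null.ravel()
    results = []
    ranking_obs = rank_genes(matrix, lab, positive_group=pos)
    for k, gs in enumerate(usable):
        e, z = es_obs[k], nes_obs[k]
        col = null_es[:, k]
        same = col[col >= 0] if e >= 0 else col[col < 0]
        p = (np.sum(np.abs(same) >= abs(e)) / len(same)) if len(same) else 1.0
        if z >= 0:
            num = np.mean(pooled >= z) if len(pooled) else 1.0
            den = np.mean(nes_obs >= z)
        else:
            num = np.mean(pooled <= z) if len(pooled) else 1.0
            den = np.mean(nes_obs <= z)
        q = float(np.clip(num / den if den > 0 else 1.0, 0.0, 1.0))
        le = leading_edge(ranking_obs, GeneSet(gs.name, list(gs.members)), weight_p)
        results.append(
            EnrichmentResult(
                name=gs.name,
                size=len(member_rows[k]),
                es=float(e),
                nes=float(z),
                p_perm=float(p),
                fdr_q=q,
                leading_edge=le,
                direction=pos if e >= 0 else neg,
            )
        )
    return results


def results_to_tsv(results: list[EnrichmentResult], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            {
                "name": r.name,
                "size": r.size,
                "es": r.es,
                "nes": r.nes,
                "p_perm": r.p_perm,
                "fdr_q": r.fdr_q,
                "direction": r.direction,
                "leading_edge": ",".join(r.leading_edge),
            }
            for r in results
        ]
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
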