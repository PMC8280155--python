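"""Preranked gene-set enrichment analysis.

Implements the classical weighted Kolmogorov-Smirnov running-sum
enrichment statistic on a user-ranked gene list: walking down the list,
the running sum rises by ``|ranking_value|**weight / N_R`` at each gene
in the set (N_R normalises the hit increments to sum to one) and falls by
``1 / (N - N_hit)`` at each gene outside it; the enrichment score (ES) is
the running-sum value of maximal absolute deviation from zero. With
``weight_exponent = 0`` the statistic reduces to the unweighted
two-sample KS statistic (up to sign).

Significance is assessed by gene-label permutation: each permutation
shuffles the gene labels of the ranked list (equivalently, assigns the
set random positions), all sets sharing the same shuffles. The ES of
each set is normalised by the mean of the same-sign null ES values (NES);
the nominal p is the same-sign null tail fraction, and the FDR q follows
the canonical pooled-null ratio of same-sign tail fractions
(null vs observed), capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "GeneSet",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "read_ranked_list",
    "enrichment_score",
    "gsea_preranked",
]


class RankedList:
    """Genes ordered by a ranking statistic, descending.

    Ties in the ranking value are broken by gene id (lexicographic,
    ascending) so the order is strict and deterministic.
    """

    def __init__(self, items: Iterable[tuple[str, float]] | pd.Series):
        if isinstance(items, pd.Series):
            pairs = list(items.items())
        else:
            pairs = list(items)
        genes = [g for g, _ in pairs]
        if len(set(genes)) != len(genes):
            raise ValueError("ranked list contains duplicate gene ids")
        pairs.sort(key=lambda gv: (-gv[1], gv[0]))
        self.genes: np.ndarray = np.array([g for g, _ in pairs], dtype=object)
        self.values: np.ndarray = np.array([v for _, v in pairs], dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ranking values must be finite")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def positions_of(self, members: Iterable[str]) -> np.ndarray:
        """Sorted 0-based positions of the members present in the list."""
        pos = sorted(self._index[g] for g in members if g in self._index)
        return np.asarray(pos, dtype=np.intp)

    def reversed(self) -> "RankedList":
        return RankedList(zip(self.genes, -self.values))

    @classmethod
    def from_de_table(cls, table: pd.DataFrame, metric: str = "log2_fc"
                      ) -> "RankedList":
        """Rank a DE table by ``log2_fc`` or ``signed_log10_p``."""
        if metric == "log2_fc":
            values = table["log2_fc"].to_numpy(dtype=float)
        elif metric == "signed_log10_p":
            p = np.clip(table["p_value"].to_numpy(dtype=float), 1e-300, 1.0)
            values = np.sign(table["log2_fc"].to_numpy(dtype=float)) * -np.log10(p)
        else:
            raise ValueError(f"unknown ranking metric {metric!r}")
        return cls(zip(table["gene_id"], values))


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        members = frozenset(self.members)
        if not members:
            raise ValueError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    n_hits_in_universe: int
    leading_edge: frozenset[str]

    def __post_init__(self) -> None:
        if not -1.0 <= self.es <= 1.0:
            raise ValueError("es must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# GMT IO


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT gene-set collection (name, description, members per line)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            sets.append(GeneSet(name, frozenset(members), description))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    """Write gene sets to GMT with members sorted for canonical output."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]))
            fh.write("\n")


def read_ranked_list(path: str | Path) -> RankedList:
    """Read a two-column TSV ``gene_id, ranking_value``."""
    table = pd.read_csv(path, sep="\t")
    if "gene_id" not in table.columns or "ranking_value" not in table.columns:
        raise ValueError(f"{path}: expected columns gene_id, ranking_value")
    return RankedList(zip(table["gene_id"], table["ranking_value"]))


# ---------------------------------------------------------------------------
# Enrichment score


def _es_from_positions(weights: np.ndarray, positions: np.ndarray,
                       n_genes: int) -> np.ndarray:
    """Vectorised ES for one or many sets of hit positions.

    ``weights`` are the per-position hit increments ``|r|**w`` of the
    full ranked list; ``positions`` is an ``(n, k)`` array of sorted hit
    positions. The extremes of the running sum can only occur right
    after a hit (maximum candidates) or right before one (minimum
    candidates), so only those ``2k`` values are evaluated per row.
    """
    positions = np.atleast_2d(positions)
    n_rows, k = positions.shape
    if not 0 < k < n_genes:
        raise ValueError("need 0 < n_hits < n_genes")
    miss_step = 1.0 / (n_genes - k)
    w = weights[positions]
    total = w.sum(axis=1, keepdims=True)
    uniform = total <= 0
    if np.any(uniform):  # all-zero ranking values in the set: unweighted
        w = np.where(uniform, 1.0, w)
        total = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) / total
    offsets = np.arange(k)
    misses_before = (positions - offsets) * miss_step
    after_hit = cum - misses_before
    before_hit = np.concatenate(
        [np.zeros((n_rows, 1)), cum[:, :-1]], axis=1
    ) - misses_before
    peaks_hi = after_hit.max(axis=1)
    peaks_lo = before_hit.min(axis=1)
    es = np.where(np.abs(peaks_hi) >= np.abs(peaks_lo), peaks_hi, peaks_lo)
    return es


def enrichment_score(ranked: RankedList, gene_set: GeneSet,
                     weight_exponent: float = 1.0
                     ) -> tuple[float, np.ndarray, frozenset[str]]:
    """ES, full running sum and leading edge of one set on one list."""
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    n = len(ranked)
    positions = ranked.positions_of(gene_set.members)
    k = len(positions)
    if k == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} has no overlap with the ranked list"
        )
    if k >= n:
        raise ValueError("gene set covers the whole ranked list")
    weights = np.abs(ranked.values) ** weight_exponent
    hit = np.zeros(n, dtype=bool)
    hit[positions] = True
    hit_w = np.where(hit, weights, 0.0)
    total = hit_w.sum()
    if total <= 0:
        hit_w = hit.astype(float)
        total = hit_w.sum()
    running = np.cumsum(hit_w / total - (~hit) / (n - k))
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es >= 0:
        leading = ranked.genes[positions[positions <= peak]]
    else:
        leading = ranked.genes[positions[positions >= peak]]
    return es, running, frozenset(leading)


def gsea_preranked(
    ranked: RankedList,
    collection: Sequence[GeneSet],
    n_permutations: int = 1000,
    min_size: int = 15,
    max_size: int = 500,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> list[EnrichmentResult]:
    """Preranked GSEA over a gene-set collection with permutation FDR.

    Null ES values come from gene-label permutations of the ranked list,
    shared across sets; fixing ``seed`` makes every reported number
    bit-reproducible. Sets falling outside ``[min_size, max_size]`` after
    restriction to the ranked universe are dropped. Results are sorted by
    NES ascending (most negative first).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    n = len(ranked)
    weights = np.abs(ranked.values) ** weight_exponent
    kept: list[tuple[GeneSet, np.ndarray]] = []
    for gs in collection:
        positions = ranked.positions_of(gs.members)
        if min_size <= len(positions) <= max_size and len(positions) < n:
            kept.append((gs, positions))
        else:
            logger.debug("dropping set %s (overlap %d)", gs.name, len(positions))
    if not kept:
        raise ValueError("no gene set within size limits overlaps the list")

    rng = np.random.default_rng(seed)
    # one label shuffle per permutation, shared by every set
    perms = np.vstack([rng.permutation(n) for _ in range(n_permutations)])

    observed: list[tuple[GeneSet, float, frozenset[str], int, np.ndarray]] = []
    for gs, positions in kept:
        es, _, leading = enrichment_score(ranked, gs, weight_exponent)
        null_positions = np.sort(perms[:, positions], axis=1)
        null_es = _es_from_positions(weights, null_positions, n)
        observed.append((gs, es, leading, len(positions), null_es))

    # same-sign normalisation
    nes_list: list[float] = []
    pvals: list[float] = []
    null_nes_pool: list[np.ndarray] = []
    for gs, es, leading, k, null_es in observed:
        pos_null = null_es[null_es >= 0]
        neg_null = null_es[null_es < 0]
        pos_mean = pos_null.mean() if pos_null.size else np.nan
        neg_mean = np.abs(neg_null).mean() if neg_null.size else np.nan
        scaled = np.where(
            null_es >= 0,
            null_es / pos_mean if pos_null.size else np.nan,
            null_es / neg_mean if neg_null.size else np.nan,
        )
        null_nes_pool.append(scaled[np.isfinite(scaled)])
        if es >= 0:
            same = pos_null
            nes = es / pos_mean if pos_null.size else 0.0
            p = ((same >= es).sum() + 1) / (same.size + 1) if same.size else 1.0
        else:
            same = neg_null
            nes = es / neg_mean if neg_null.size else 0.0
            p = ((same <= es).sum() + 1) / (same.size + 1) if same.size else 1.0
        nes_list.append(float(nes))
        pvals.append(float(min(1.0, p)))

    pooled = np.concatenate(null_nes_pool)
    nes_arr = np.asarray(nes_list)
    n_pos_obs = (nes_arr >= 0).sum()
    n_neg_obs = (nes_arr < 0).sum()
    n_pos_null = (pooled >= 0).sum()
    n_neg_null = (pooled < 0).sum()

    results: list[EnrichmentResult] = []
    for (gs, es, leading, k, _), nes, p in zip(observed, nes_list, pvals):
        if nes >= 0:
            null_tail = ((pooled >= nes).sum() / n_pos_null) if n_pos_null else 1.0
            obs_tail = (nes_arr >= nes).sum() / n_pos_obs if n_pos_obs else 1.0
        else:
            null_tail = ((pooled <= nes).sum() / n_neg_null) if n_neg_null else 1.0
            obs_tail = (nes_arr <= nes).sum() / n_neg_obs if n_neg_obs else 1.0
        fdr = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0
        results.append(
            EnrichmentResult(
                set_name=gs.name,
                es=es,
                nes=nes,
                nominal_p=p,
                fdr_q=float(fdr),
                n_hits_in_universe=k,
                leading_edge=leading,
            )
        )
    results.sort(key=lambda r: (r.nes, r.set_name))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "nominal_p": [r.nominal_p for r in results],
            "fdr_q": [r.fdr_q for r in results],
            "n_hits_in_universe": [r.n_hits_in_universe for r in results],
            "leading_edge": [",".join(sorted(r.leading_edge)) for r in results],
        }
    )
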