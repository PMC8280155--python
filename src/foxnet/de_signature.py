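"""Codirectional differential-expression signatures.

Given per-gene DE tables (log2 fold change, p-value, optional BH-adjusted
FDR) for two independent cell models treated with the same compound, this
module thresholds each table (default: 2-fold or larger change, FDR
strictly below 0.1, optionally restricted to protein-coding genes) and
intersects the resulting up/down gene sets. Genes significantly changed in
the *same* direction in both models — the codirectional intersection — are
the most reliable responders and form the compound's signature gene list;
genes significant in both models but in opposite directions are reported
as discordant.

Multiple-testing correction, where a table lacks an FDR column, is the
Benjamini-Hochberg step-up procedure implemented here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DeSignature",
    "read_de_table",
    "benjamini_hochberg",
    "filter_de",
    "codirectional_intersection",
]

#: Canonical DE-table column names.
DE_COLUMNS = ["gene_id", "log2_fc", "p_value", "fdr", "biotype"]


@dataclass
class DeSignature:
    """Codirectional intersection of two models' significant gene sets."""

    up_both: frozenset[str]
    down_both: frozenset[str]
    discordant: frozenset[str]
    per_model_significant: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = (self.up_both, self.down_both, self.discordant)
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                if a & b:
                    raise ValueError(
                        "up_both, down_both and discordant must be disjoint"
                    )

    @property
    def combined(self) -> frozenset[str]:
        """The signature gene list: codirectional genes of both directions."""
        return self.up_both | self.down_both

    @property
    def significant_in_both(self) -> frozenset[str]:
        return self.up_both | self.down_both | self.discordant

    def counts(self) -> dict[str, int]:
        return {
            "up_both": len(self.up_both),
            "down_both": len(self.down_both),
            "discordant": len(self.discordant),
            "significant_in_both": len(self.significant_in_both),
            "combined": len(self.combined),
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "up_both": sorted(self.up_both),
            "down_both": sorted(self.down_both),
            "discordant": sorted(self.discordant),
            "per_model_significant": {
                k: sorted(v) for k, v in self.per_model_significant.items()
            },
            "counts": self.counts(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def read_de_table(path: str | Path,
                  column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a per-gene DE table from TSV.

    Expected columns ``gene_id, log2_fc, p_value[, fdr][, biotype]``;
    ``column_map`` renames source columns to this layout (e.g.
    ``{"logFC": "log2_fc", "PValue": "p_value", "FDR": "fdr"}``).
    """
    table = pd.read_csv(path, sep="\t")
    if column_map:
        table = table.rename(columns=dict(column_map))
    missing = [c for c in ("gene_id", "log2_fc", "p_value") if c not in table.columns]
    if missing:
        raise ValueError(f"DE table {path} lacks columns {missing}")
    return table


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} p_(j) * n / j`` over the ascending order
    statistics, capped at 1 and mapped back to the input order. The
    output dominates the input elementwise (``q >= p``).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return np.array([])
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


def filter_de(
    table: pd.DataFrame,
    fold_threshold: float = 2.0,
    fdr_threshold: float = 0.1,
    biotype_filter: str | None = None,
) -> tuple[frozenset[str], frozenset[str]]:
    """Threshold a DE table into (up, down) significant gene sets.

    A gene is *up* when its fold change (``2**log2_fc``) is at least
    ``fold_threshold`` and its FDR is strictly below ``fdr_threshold``;
    *down* when the fold change is at most ``1/fold_threshold`` at the
    same FDR. The fold boundary is inclusive, the FDR boundary strict.
    ``biotype_filter`` (e.g. ``"protein_coding"``) restricts the universe
    before thresholding. Tables without an ``fdr`` column get one from
    :func:`benjamini_hochberg`; when both are present and disagree by more
    than 1e-6 the supplied column wins with a logged warning.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    table = table.copy()
    if biotype_filter is not None:
        if "biotype" not in table.columns:
            raise ValueError("biotype_filter given but table has no biotype column")
        table = table[table["biotype"] == biotype_filter]
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in DE table")
    recomputed = benjamini_hochberg(table["p_value"].to_numpy())
    if "fdr" in table.columns and table["fdr"].notna().all():
        supplied = table["fdr"].to_numpy(dtype=float)
        if np.any((supplied < 0) | (supplied > 1)):
            raise ValueError("fdr values must lie in [0, 1]")
        if np.max(np.abs(supplied - recomputed)) > 1e-6:
            logger.warning(
                "supplied FDR column disagrees with recomputed BH by more "
                "than 1e-6; trusting the supplied column"
            )
        fdr = supplied
    else:
        fdr = recomputed
    log2_fc = table["log2_fc"].to_numpy(dtype=float)
    log2_bound = np.log2(fold_threshold)
    significant = fdr < fdr_threshold
    up = table.loc[significant & (log2_fc >= log2_bound), "gene_id"]
    down = table.loc[significant & (log2_fc <= -log2_bound), "gene_id"]
    return frozenset(up), frozenset(down)


def codirectional_intersection(
    model_a: tuple[Iterable[str], Iterable[str]],
    model_b: tuple[Iterable[str], Iterable[str]],
    model_names: tuple[str, str] = ("model_a", "model_b"),
) -> DeSignature:
    """Intersect two models' (up, down) sets into a codirectional signature."""
    up_a, down_a = map(frozenset, model_a)
    up_b, down_b = map(frozenset, model_b)
    for name, up, down in ((model_names[0], up_a, down_a),
                           (model_names[1], up_b, down_b)):
        both = up & down
        if both:
            raise ValueError(
                f"gene {sorted(both)[0]!r} appears in both up and down of "
                f"{name}"
            )
    signature = DeSignature(
        up_both=up_a & up_b,
        down_both=down_a & down_b,
        discordant=(up_a & down_b) | (down_a & up_b),
        per_model_significant={
            model_names[0]: up_a | down_a,
            model_names[1]: up_b | down_b,
        },
    )
    logger.info("codirectional intersection: %s", signature.counts())
    return signature
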