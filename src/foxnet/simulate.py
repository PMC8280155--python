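"""Synthetic inputs with stored ground truth for every pipeline stage.

Three generators:

* :func:`simulate_screen` — a LINCS-like panel of z-score signatures
  across seven cell lines with knockdowns of a proxy target and its
  network partners, one *planted* inhibitor compound whose signature is a
  controlled mixture ``alpha * z_kd + sqrt(1 - alpha**2) * noise`` of the
  proxy knockdown signature and independent noise (so its marginal stays
  standard normal and its expected correlation with the knockdown is
  ``alpha``), and pure-noise decoy compounds.
* :func:`simulate_de_tables` — paired DE tables with planted counts of
  shared-up, shared-down, discordant and model-specific significant
  genes, so the downstream thresholding/intersection stage can be
  checked for exact count recovery.
* :func:`simulate_ranked_list` — a ranked gene list with one gene set's
  members planted uniformly inside the top (or bottom) fraction of the
  ranks, for enrichment-recovery tests.

Noise is i.i.d. standard normal per gene; gene-gene correlation structure
is deliberately not emulated. All generators are bit-reproducible under a
fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from foxnet.de_signature import benjamini_hochberg
from foxnet.gsea import GeneSet, RankedList
from foxnet.signature_core import (
    PerturbationType,
    Signature,
    SignatureCollection,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenSimConfig",
    "DeSimConfig",
    "simulate_screen",
    "simulate_de_tables",
    "simulate_ranked_list",
]

#: The seven cell lines most densely profiled in the LINCS compendium.
DEFAULT_CELL_LINES = ("A549", "MCF7", "VCAP", "HA1E", "A375", "HCC515", "HT29")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions for the synthetic compound screen.

    ``mixing_weight`` is the planted inhibitor's alpha: its signature in
    each cell line is ``alpha * z_kd + sqrt(1 - alpha**2) * noise``.
    """

    n_genes: int = 978
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    n_decoy_compounds: int = 49
    n_partner_genes: int = 3
    mixing_weight: float = 0.7
    partner_mixing_weight: float = 0.5
    n_replicates: int = 1
    replicate_noise: float = 0.3
    proxy_target: str = "NPM1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing_weight <= 1.0:
            raise ValueError("mixing_weight must lie in [0, 1]")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _mix(alpha: float, base: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(base.shape)
    return alpha * base + np.sqrt(1.0 - alpha**2) * noise


def _replicates(latent: np.ndarray, n_replicates: int, replicate_noise: float,
                rng: np.random.Generator) -> list[np.ndarray]:
    if n_replicates == 1:
        return [latent]
    s = replicate_noise
    return [
        np.sqrt(1.0 - s**2) * latent + s * rng.standard_normal(latent.shape)
        for _ in range(n_replicates)
    ]


def simulate_screen(config: ScreenSimConfig | None = None
                    ) -> tuple[SignatureCollection, dict]:
    """Generate a synthetic screen panel and its ground truth.

    Emits, per cell line: one knockdown signature set (replicates) for the
    proxy target and for each partner gene; the planted inhibitor
    compound, mixed with the proxy knockdown's latent signature at
    ``mixing_weight`` (and nothing else); and ``n_decoy_compounds``
    pure-noise compounds. Returns ``(collection, truth)`` where truth
    names the planted compound and the partner genes.
    """
    config = config or ScreenSimConfig()
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    gene_index = pd.Index(genes)
    partners = [f"PARTNER{i + 1}" for i in range(config.n_partner_genes)]

    signatures: list[Signature] = []
    meta_rows: list[dict] = []

    def add(perturbation_id: str, cell_line: str, ptype: PerturbationType,
            target: str | None, latent: np.ndarray) -> None:
        for i, values in enumerate(
            _replicates(latent, config.n_replicates, config.replicate_noise, rng)
        ):
            signatures.append(
                Signature(
                    perturbation_id=perturbation_id,
                    cell_line=cell_line,
                    values=pd.Series(values, index=gene_index),
                    perturbation_type=ptype,
                    target_gene=target,
                    replicate=i,
                )
            )
            meta_rows.append(
                {
                    "perturbation_id": perturbation_id,
                    "cell_line": cell_line,
                    "perturbation_type": ptype.value,
                    "target_gene": target if target is not None else "",
                    "replicate": i,
                }
            )

    planted_id = "CPD_PLANTED"
    decoy_ids = [f"CPD{i:04d}" for i in range(config.n_decoy_compounds)]
    for cell_line in config.cell_lines:
        kd_latent = rng.standard_normal(config.n_genes)
        add(f"sh{config.proxy_target}", cell_line, PerturbationType.KNOCKDOWN,
            config.proxy_target, kd_latent)
        for partner in partners:
            # partner knockdowns share part of the network response
            partner_latent = _mix(config.partner_mixing_weight, kd_latent, rng)
            add(f"sh{partner}", cell_line, PerturbationType.KNOCKDOWN,
                partner, partner_latent)
        add(planted_id, cell_line, PerturbationType.COMPOUND, None,
            _mix(config.mixing_weight, kd_latent, rng))
        for decoy in decoy_ids:
            add(decoy, cell_line, PerturbationType.COMPOUND, None,
                rng.standard_normal(config.n_genes))

    collection = SignatureCollection(
        signatures, gene_universe=genes, metadata=pd.DataFrame(meta_rows)
    )
    truth = {
        "planted_compound": planted_id,
        "decoy_compounds": decoy_ids,
        "proxy_target": config.proxy_target,
        "partners": partners,
        "mixing_weight": config.mixing_weight,
        "seed": config.seed,
    }
    return collection, truth


# ---------------------------------------------------------------------------
# DE tables


@dataclass(frozen=True)
class DeSimConfig:
    """Planted intersection structure for a pair of DE tables."""

    n_genes: int = 16275
    n_up_shared: int = 577
    n_down_shared: int = 687
    n_discordant: int = 77
    n_model_specific: int = 200
    effect_size: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        planted = (
            self.n_up_shared
            + self.n_down_shared
            + self.n_discordant
            + 2 * self.n_model_specific
        )
        if planted > self.n_genes:
            raise ValueError(
                f"planted gene counts ({planted}) exceed n_genes "
                f"({self.n_genes})"
            )


def simulate_de_tables(config: DeSimConfig | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired DE tables with controlled codirectional structure.

    Planted genes get ``|log2_fc| ~= effect_size`` (jittered upward so the
    fold-change boundary is safely cleared) and p-values uniform on
    (0, 1e-4); null genes get log2_fc near 0 and uniform p-values. FDR
    columns are Benjamini-Hochberg q-values of each table's p-values.
    Thresholding both tables at 2-fold / FDR < 0.1 and intersecting
    recovers the planted counts exactly.
    """
    config = config or DeSimConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"ENSG{i:08d}" for i in range(n)]

    order = rng.permutation(n)
    cursor = 0

    def take(count: int) -> np.ndarray:
        nonlocal cursor
        block = order[cursor:cursor + count]
        cursor += count
        return block

    up_shared = take(config.n_up_shared)
    down_shared = take(config.n_down_shared)
    discordant = take(config.n_discordant)
    specific_a = take(config.n_model_specific)
    specific_b = take(config.n_model_specific)

    def build_table() -> tuple[np.ndarray, np.ndarray]:
        # null fold changes stay strictly inside the 2-fold boundary so the
        # planted intersection structure is recovered exactly
        log2_fc = np.clip(rng.normal(0.0, 0.2, n), -0.9, 0.9)
        p = rng.uniform(0.0, 1.0, n)
        return log2_fc, p

    def plant(log2_fc: np.ndarray, p: np.ndarray, idx: np.ndarray,
              sign: int) -> None:
        magnitude = config.effect_size + rng.uniform(0.0, 1.0, idx.size)
        if config.effect_size < 1.0:
            # below the 2-fold boundary: keep planted genes sub-threshold
            magnitude = np.full(idx.size, config.effect_size)
        log2_fc[idx] = sign * magnitude
        p[idx] = rng.uniform(1e-12, 1e-4, idx.size)

    fc_a, p_a = build_table()
    fc_b, p_b = build_table()
    plant(fc_a, p_a, up_shared, +1)
    plant(fc_b, p_b, up_shared, +1)
    plant(fc_a, p_a, down_shared, -1)
    plant(fc_b, p_b, down_shared, -1)
    half = config.n_discordant // 2
    plant(fc_a, p_a, discordant[:half], +1)
    plant(fc_b, p_b, discordant[:half], -1)
    plant(fc_a, p_a, discordant[half:], -1)
    plant(fc_b, p_b, discordant[half:], +1)
    plant(fc_a, p_a, specific_a, +1)
    plant(fc_b, p_b, specific_b, -1)

    def finish(log2_fc: np.ndarray, p: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": genes,
                "log2_fc": log2_fc,
                "p_value": p,
                "fdr": benjamini_hochberg(p),
                "biotype": "protein_coding",
            }
        )

    gene_arr = np.asarray(genes, dtype=object)
    truth = {
        "n_up_shared": config.n_up_shared,
        "n_down_shared": config.n_down_shared,
        "n_discordant": config.n_discordant,
        "n_model_specific": config.n_model_specific,
        "up_shared_genes": sorted(gene_arr[up_shared]),
        "down_shared_genes": sorted(gene_arr[down_shared]),
        "discordant_genes": sorted(gene_arr[discordant]),
        "effect_size": config.effect_size,
        "seed": config.seed,
    }
    return finish(fc_a, p_a), finish(fc_b, p_b), truth


# ---------------------------------------------------------------------------
# Ranked lists


def simulate_ranked_list(
    n_genes: int = 2000,
    planted_set_size: int = 30,
    top_fraction: float = 0.1,
    seed: int = 0,
    placement: str = "top",
    set_name: str = "PLANTED_SET",
) -> tuple[RankedList, GeneSet, dict]:
    """A ranked list with one gene set planted in the top/bottom ranks.

    ``placement="top"`` puts the set's members uniformly at random within
    the top ``top_fraction`` of ranks (positive enrichment expected);
    ``"bottom"`` mirrors this at the other end (negative expected);
    ``"random"`` scatters them uniformly over the whole list (null).
    """
    if placement not in ("top", "bottom", "random"):
        raise ValueError(f"unknown placement {placement!r}")
    window = int(round(n_genes * top_fraction))
    if placement != "random" and planted_set_size > window:
        raise ValueError(
            f"planted_set_size {planted_set_size} exceeds the "
            f"{window}-rank placement window"
        )
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    # strictly decreasing ranking values; jitter keeps them generic
    values = np.sort(rng.normal(0.0, 1.0, n_genes))[::-1]
    if placement == "top":
        slots = rng.choice(window, size=planted_set_size, replace=False)
    elif placement == "bottom":
        slots = n_genes - 1 - rng.choice(window, size=planted_set_size,
                                         replace=False)
    else:
        slots = rng.choice(n_genes, size=planted_set_size, replace=False)
    members = frozenset(genes[i] for i in slots)
    ranked = RankedList(zip(genes, values))
    truth = {
        "planted_positions": sorted(int(s) for s in slots),
        "placement": placement,
        "set_name": set_name,
        "seed": seed,
    }
    return ranked, GeneSet(set_name, members), truth
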