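"""Perturbation signatures: data model, IO, replicate consensus, similarity.

A *signature* is the vector of per-gene differential-expression z-scores
produced by one perturbation (a gene knockdown, a compound treatment or a
control) in one cell line versus its controls, in the style of the LINCS
L1000 compendium. Signatures are stored column-wise in a GCT-like
tab-separated matrix (genes x perturbations) with an optional companion
metadata table describing each perturbation column.

Replicate signatures are aggregated into a consensus with a MODZ-style
weighting: each replicate is weighted by its total rank correlation with
the other replicates (floored at a small positive value so that an
anti-correlated outlier cannot flip the sign of its weight), and the
weights are normalised to sum to one. Median and plain-mean aggregation
are available as simpler alternatives.

Similarity between two signatures is Spearman (default) or Pearson
correlation over the genes the two signatures share; genes present in only
one signature are dropped, never imputed.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationType",
    "Signature",
    "SignatureCollection",
    "ConsensusSpec",
    "read_signatures",
    "write_signatures",
    "consensus_signature",
    "signature_similarity",
]


class PerturbationType(str, enum.Enum):
    """Kind of perturbation behind a signature."""

    KNOCKDOWN = "knockdown"
    COMPOUND = "compound"
    CONTROL = "control"


@dataclass(frozen=True)
class Signature:
    """Per-gene z-score vector for one perturbation in one cell line.

    Parameters
    ----------
    perturbation_id
        Opaque identifier of the perturbation (compound or shRNA id).
    cell_line
        Cell line the signature was measured in (e.g. ``"MCF7"``).
    values
        Mapping gene id -> z-score. Stored internally as a pandas Series
        indexed by gene id.
    perturbation_type
        ``knockdown``, ``compound`` or ``control``.
    target_gene
        For knockdowns, the symbol of the silenced gene.
    replicate
        Replicate index, used to disambiguate technical/biological
        replicates of the same perturbation in the same cell line.
    """

    perturbation_id: str
    cell_line: str
    values: pd.Series
    perturbation_type: PerturbationType = PerturbationType.COMPOUND
    target_gene: str | None = None
    replicate: int = 0

    def __post_init__(self) -> None:
        values = self.values
        if not isinstance(values, pd.Series):
            values = pd.Series(dict(values), dtype=float)
        values = values.astype(float)
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id in signature: {dup!r}")
        if len(values) < 2:
            raise ValueError("a signature needs at least 2 genes")
        if not np.all(np.isfinite(values.to_numpy())):
            raise ValueError("signature z-scores must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "perturbation_type", PerturbationType(self.perturbation_type)
        )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SignatureCollection:
    """A set of signatures over a common, ordered gene universe."""

    signatures: list[Signature]
    gene_universe: list[str]
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        universe = pd.Index(self.gene_universe)
        if universe.has_duplicates:
            dup = universe[universe.duplicated()][0]
            raise ValueError(f"duplicate gene id in gene universe: {dup!r}")
        seen: set[tuple[str, str, int]] = set()
        for sig in self.signatures:
            if not sig.genes.isin(universe).all():
                missing = sig.genes[~sig.genes.isin(universe)][0]
                raise ValueError(
                    f"signature {sig.perturbation_id!r} contains gene "
                    f"{missing!r} outside the gene universe"
                )
            key = (sig.perturbation_id, sig.cell_line, sig.replicate)
            if key in seen:
                raise ValueError(
                    "duplicate (perturbation_id, cell_line, replicate): "
                    f"{key}"
                )
            seen.add(key)
        self.gene_universe = list(universe)

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    def subset(self, **field_values) -> "SignatureCollection":
        """Signatures whose fields match all given values.

        ``collection.subset(cell_line="MCF7", perturbation_type="knockdown")``
        """
        sigs = [
            s
            for s in self.signatures
            if all(
                getattr(s, name) == value for name, value in field_values.items()
            )
        ]
        return SignatureCollection(sigs, self.gene_universe, self.metadata)

    def replicates_of(self, perturbation_id: str, cell_line: str | None = None
                      ) -> list[Signature]:
        return [
            s
            for s in self.signatures
            if s.perturbation_id == perturbation_id
            and (cell_line is None or s.cell_line == cell_line)
        ]

    @property
    def cell_lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.signatures:
            seen.setdefault(s.cell_line, None)
        return list(seen)

    @property
    def perturbation_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.signatures:
            seen.setdefault(s.perturbation_id, None)
        return list(seen)


class ConsensusMethod(str, enum.Enum):
    WEIGHTED_MODZ = "weighted_modz"
    MEDIAN = "median"
    MEAN = "mean"


@dataclass(frozen=True)
class ConsensusSpec:
    """How replicate signatures are collapsed into a consensus.

    ``weighted_modz`` weights each replicate proportionally to
    ``max(weight_floor, sum of its correlations with the other replicates)``,
    normalised to sum to one; ``median``/``mean`` are elementwise.
    """

    method: ConsensusMethod = ConsensusMethod.WEIGHTED_MODZ
    weight_floor: float = 0.01
    correlation: str = "spearman"

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", ConsensusMethod(self.method))
        if self.weight_floor <= 0:
            raise ValueError("weight_floor must be > 0")
        if self.correlation not in ("spearman", "pearson"):
            raise ValueError(f"unknown correlation {self.correlation!r}")


# ---------------------------------------------------------------------------
# IO

_META_COLUMNS = [
    "perturbation_id",
    "cell_line",
    "perturbation_type",
    "target_gene",
    "replicate",
]


def _column_id(sig: Signature, unique_ids: bool) -> str:
    """Matrix column header for a signature.

    The bare perturbation id when ids are unique in the collection;
    otherwise disambiguated with cell line and replicate index.
    """
    if unique_ids:
        return sig.perturbation_id
    return f"{sig.perturbation_id}:{sig.cell_line}:{sig.replicate}"


def read_signatures(path: str | Path, format: str = "gct_like_tsv",
                    metadata_path: str | Path | None = None) -> SignatureCollection:
    """Read a GCT-like TSV signature matrix (genes x perturbations).

    The first header field names the gene-id column; the remaining header
    fields are perturbation column ids. A companion metadata table
    ``<path stem>.meta.tsv`` (columns ``perturbation_id, cell_line,
    perturbation_type, target_gene, replicate``) is read automatically when
    present, or can be pointed to explicitly with ``metadata_path``.
    """
    if format != "gct_like_tsv":
        raise ValueError(f"unsupported signature format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    fields = header.split("\t")
    if len(fields) < 2 or any(f == "" for f in fields):
        raise ValueError(
            f"malformed header in {path}: expected a gene-id column followed "
            "by at least one perturbation column"
        )
    matrix = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")

    if metadata_path is None:
        candidate = path.parent / (path.name.removesuffix(".tsv") + ".meta.tsv")
        metadata_path = candidate if candidate.exists() else None
    metadata = None
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, sep="\t", dtype=str)
        missing = [c for c in _META_COLUMNS[:3] if c not in metadata.columns]
        if missing:
            raise ValueError(
                f"metadata table {metadata_path} lacks columns {missing}"
            )
        if "replicate" in metadata.columns:
            metadata["replicate"] = metadata["replicate"].astype(int)
        # columns are matched on column_id when present (the layout this
        # package writes), falling back to the bare perturbation id
        key = "column_id" if "column_id" in metadata.columns else "perturbation_id"
        meta_by_id = metadata.set_index(key, drop=False)
        if meta_by_id.index.has_duplicates:
            meta_by_id = meta_by_id[~meta_by_id.index.duplicated()]
    signatures = []
    for column in matrix.columns:
        kwargs: dict = dict(
            perturbation_id=column,
            cell_line="unknown",
            perturbation_type=PerturbationType.COMPOUND,
            target_gene=None,
            replicate=0,
        )
        if metadata is not None and column in meta_by_id.index:
            row = meta_by_id.loc[column]
            kwargs["perturbation_id"] = row["perturbation_id"]
            kwargs["cell_line"] = row["cell_line"]
            kwargs["perturbation_type"] = PerturbationType(row["perturbation_type"])
            target = row.get("target_gene")
            kwargs["target_gene"] = None if pd.isna(target) or target == "" else target
            if "replicate" in row.index and not pd.isna(row["replicate"]):
                kwargs["replicate"] = int(row["replicate"])
        signatures.append(Signature(values=matrix[column], **kwargs))
    return SignatureCollection(
        signatures, gene_universe=list(matrix.index), metadata=metadata
    )


def write_signatures(collection: SignatureCollection, path: str | Path,
                     gene_column: str = "gene_id") -> None:
    """Write a collection back to the canonical GCT-like TSV layout.

    Columns follow the collection's signature order; rows follow the gene
    universe. Formatting is canonical (``repr`` of the float, dot decimal
    separator) so that read -> write -> read round-trips byte-identically
    on files produced by this writer.
    """
    path = Path(path)
    ids = [s.perturbation_id for s in collection.signatures]
    unique_ids = len(set(ids)) == len(ids)
    columns = {
        _column_id(s, unique_ids): s.values.reindex(collection.gene_universe)
        for s in collection.signatures
    }
    matrix = pd.DataFrame(
        columns, index=pd.Index(collection.gene_universe, name=gene_column)
    )
    matrix.to_csv(path, sep="\t", float_format=None)
    if collection.metadata is not None or not unique_ids:
        meta = pd.DataFrame(
            {
                "column_id": [_column_id(s, unique_ids)
                              for s in collection.signatures],
                "perturbation_id": ids,
                "cell_line": [s.cell_line for s in collection.signatures],
                "perturbation_type": [s.perturbation_type.value
                                      for s in collection.signatures],
                "target_gene": [s.target_gene or ""
                                for s in collection.signatures],
                "replicate": [s.replicate for s in collection.signatures],
            }
        )
        meta_path = path.parent / (path.name.removesuffix(".tsv") + ".meta.tsv")
        meta.to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Consensus aggregation


def _pairwise_correlations(matrix: np.ndarray, method: str) -> np.ndarray:
    """Full replicate-by-replicate correlation matrix (rows = replicates)."""
    if method == "spearman":
        ranked = np.apply_along_axis(sps.rankdata, 1, matrix)
    else:
        ranked = matrix
    return np.corrcoef(ranked)


def consensus_signature(replicates: Sequence[Signature],
                        spec: ConsensusSpec | None = None) -> Signature:
    """Collapse replicate signatures into a single consensus signature.

    All replicates must share ``cell_line``, ``perturbation_id`` and gene
    set. A single replicate is returned unchanged (with ``replicate`` reset
    to 0). The MODZ-style default weights each replicate by its summed
    correlation with the others, floored at ``spec.weight_floor`` and
    normalised to sum to one; the result does not depend on replicate
    order.
    """
    spec = spec or ConsensusSpec()
    replicates = list(replicates)
    if not replicates:
        raise ValueError("consensus_signature requires at least one replicate")
    first = replicates[0]
    genes = first.genes
    for rep in replicates[1:]:
        if rep.perturbation_id != first.perturbation_id:
            raise ValueError("replicates mix perturbation ids")
        if rep.cell_line != first.cell_line:
            raise ValueError("replicates mix cell lines")
        if len(rep.genes) != len(genes) or set(rep.genes) != set(genes):
            raise ValueError("replicates have mismatched gene sets")
    if len(replicates) == 1:
        return replace(first, replicate=0)

    matrix = np.vstack([rep.values.reindex(genes).to_numpy() for rep in replicates])
    method = spec.method
    if method is ConsensusMethod.MEAN:
        consensus = matrix.mean(axis=0)
    elif method is ConsensusMethod.MEDIAN:
        consensus = np.median(matrix, axis=0)
    else:
        corr = _pairwise_correlations(matrix, spec.correlation)
        np.fill_diagonal(corr, 0.0)
        raw = corr.sum(axis=1)
        weights = np.maximum(spec.weight_floor, raw)
        weights = weights / weights.sum()
        consensus = weights @ matrix
    return replace(first, values=pd.Series(consensus, index=genes), replicate=0)


def modz_weights(replicates: Sequence[Signature],
                 spec: ConsensusSpec | None = None) -> np.ndarray:
    """Normalised MODZ replicate weights (exposed for inspection/tests)."""
    spec = spec or ConsensusSpec()
    genes = replicates[0].genes
    matrix = np.vstack([rep.values.reindex(genes).to_numpy() for rep in replicates])
    corr = _pairwise_correlations(matrix, spec.correlation)
    np.fill_diagonal(corr, 0.0)
    weights = np.maximum(spec.weight_floor, corr.sum(axis=1))
    return weights / weights.sum()


# ---------------------------------------------------------------------------
# Similarity


def signature_similarity(a: Signature, b: Signature, method: str = "spearman",
                         top_n: int | None = None) -> float:
    """Correlation between two signatures over their shared genes.

    Genes absent from either signature are dropped (intersection
    semantics). With ``top_n`` the comparison is restricted to the
    ``top_n`` shared genes with the largest ``|z|`` in ``a`` — the usual
    "query gene set" asymmetry of connectivity-map matching; without it
    the measure is symmetric. Rank ties are resolved with average ranks.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown similarity method {method!r}")
    shared = a.genes.intersection(b.genes)
    if len(shared) < 3:
        raise ValueError(
            f"signatures share only {len(shared)} genes; need at least 3"
        )
    va = a.values.loc[shared]
    if top_n is not None:
        if top_n < 3:
            raise ValueError("top_n must be at least 3")
        shared = va.abs().nlargest(min(top_n, len(shared))).index
        va = va.loc[shared]
    vb = b.values.loc[shared]
    x = va.to_numpy()
    y = vb.to_numpy()
    if method == "spearman":
        result = sps.spearmanr(x, y).statistic
    else:
        result = sps.pearsonr(x, y).statistic
    if np.isnan(result):  # constant input after restriction
        return 0.0
    return float(result)
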