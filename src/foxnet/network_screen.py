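"""Network-proxy compound screen: features, scoring, ranking, panel tables.

The discovery stage of the pipeline. Because no knockdown signature may
exist for the protein of interest itself (in the motivating application,
FOXM1), a *proxy* knockdown is used: a gene whose silencing collapses the
same regulatory network (NPM1, whose product stabilises FOXM1). For every
compound and every cell line profiled, the screen computes

* ``direct_corr`` — correlation of the compound's signature with the proxy
  knockdown's signature in the same cell line, and
* indirect, "guilt-by-association" correlations with knockdowns of the
  proxy's protein-interaction partners (best and mean over partners).

A compound is *supported* in a cell line when its direct correlation
reaches the support threshold; compounds supported in at least
``min_support`` cell lines (default 4) qualify as candidates. Candidates
are ranked either by a deterministic composite score or, when labelled
training compounds are supplied, by the positive-class probability of a
random-forest classifier over the same feature vectors.

The module also builds target-panel consensus tables (consensus z-score of
each panel gene under each perturbation) and compares candidate compounds
on such a table by *universality* (number of panel genes suppressed below a
z threshold) and *potency* (mean panel z).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from foxnet.signature_core import (
    ConsensusSpec,
    PerturbationType,
    Signature,
    SignatureCollection,
    consensus_signature,
    read_signatures,
    signature_similarity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkNeighborhood",
    "CellLineFeatures",
    "ScreenFeatures",
    "CandidateRanking",
    "PanelTable",
    "read_network",
    "build_screen_features",
    "composite_score",
    "rank_candidates",
    "panel_consensus_table",
    "compare_candidates",
    "load_foxm1_target_panel",
    "FOXM1_TARGET_PANEL",
]

#: The eight direct FOXM1-activated target genes used for panel scoring.
FOXM1_TARGET_PANEL = [
    "BIRC5",
    "CCNB1",
    "CCNB2",
    "CDK1",
    "CDC20",
    "CDC25A",
    "PLK1",
    "UBE2C",
]


@dataclass(frozen=True)
class NetworkNeighborhood:
    """A proxy target gene and its protein-interaction partners."""

    proxy_target: str
    partners: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        partners = tuple(self.partners)
        if self.proxy_target in partners:
            raise ValueError("proxy_target must not be among its partners")
        object.__setattr__(self, "partners", partners)


def read_network(path: str | Path, proxy_target: str) -> NetworkNeighborhood:
    """Build a neighborhood from a two-column TSV edge list.

    Partners are the genes directly connected to ``proxy_target``.
    """
    edges = pd.read_csv(path, sep="\t", header=None, names=["gene_a", "gene_b"],
                        dtype=str, comment="#")
    partners: list[str] = []
    for _, row in edges.iterrows():
        if row.gene_a == proxy_target and row.gene_b != proxy_target:
            partners.append(row.gene_b)
        elif row.gene_b == proxy_target and row.gene_a != proxy_target:
            partners.append(row.gene_a)
    # preserve first-seen order, drop duplicates
    seen: dict[str, None] = {}
    for p in partners:
        seen.setdefault(p, None)
    return NetworkNeighborhood(proxy_target, tuple(seen))


@dataclass(frozen=True)
class CellLineFeatures:
    """Per-cell-line correlation features for one compound."""

    direct_corr: float
    best_indirect_corr: float = math.nan
    mean_indirect_corr: float = math.nan


@dataclass
class ScreenFeatures:
    """Screening features for one compound across cell lines."""

    compound_id: str
    per_cell_line: dict[str, CellLineFeatures]
    support_threshold: float
    support_count: int = field(init=False)
    n_cell_lines: int = field(init=False)

    def __post_init__(self) -> None:
        for cl, feats in self.per_cell_line.items():
            for value in (feats.direct_corr, feats.best_indirect_corr,
                          feats.mean_indirect_corr):
                if not math.isnan(value) and not -1.0 <= value <= 1.0:
                    raise ValueError(
                        f"correlation {value} for {self.compound_id!r} in "
                        f"{cl!r} outside [-1, 1]"
                    )
        self.n_cell_lines = len(self.per_cell_line)
        self.support_count = sum(
            1
            for feats in self.per_cell_line.values()
            if feats.direct_corr >= self.support_threshold
        )

    @property
    def supported_cell_lines(self) -> list[str]:
        return [
            cl
            for cl, feats in self.per_cell_line.items()
            if feats.direct_corr >= self.support_threshold
        ]


@dataclass
class CandidateRanking:
    """Ordered screen result: (compound_id, score, qualified)."""

    entries: list[tuple[str, float, bool]]

    def __post_init__(self) -> None:
        scores = [score for _, score, _ in self.entries]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValueError("ranking scores must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["compound_id", "score", "qualified"]
        )

    def rank_of(self, compound_id: str) -> int:
        """1-based rank of a compound."""
        for i, (cid, _, _) in enumerate(self.entries, start=1):
            if cid == compound_id:
                return i
        raise KeyError(compound_id)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PanelTable:
    """Consensus z-scores of a gene panel under selected perturbations."""

    panel_genes: list[str]
    perturbations: list[str]
    values: pd.DataFrame  # genes x perturbations

    def __post_init__(self) -> None:
        if list(self.values.index) != list(self.panel_genes):
            raise ValueError("values index must equal panel_genes")
        if list(self.values.columns) != list(self.perturbations):
            raise ValueError("values columns must equal perturbations")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("panel table values must be finite")


# ---------------------------------------------------------------------------


def _consensus_by_cell_line(collection: SignatureCollection,
                            perturbation_id: str,
                            spec: ConsensusSpec) -> dict[str, Signature]:
    out: dict[str, Signature] = {}
    for cell_line in collection.cell_lines:
        reps = collection.replicates_of(perturbation_id, cell_line)
        if reps:
            out[cell_line] = consensus_signature(reps, spec)
    return out


def build_screen_features(
    compound_sigs: SignatureCollection,
    kd_sigs: SignatureCollection,
    network: NetworkNeighborhood,
    support_threshold: float = 0.3,
    top_n: int | None = None,
    method: str = "spearman",
    consensus: ConsensusSpec | None = None,
) -> list[ScreenFeatures]:
    """Correlate every compound with the proxy-target knockdown per cell line.

    Cell lines lacking either the compound's or the proxy knockdown's
    signature are skipped (not zero-filled). Knockdown signatures are
    matched by ``target_gene``; replicates are collapsed to a consensus
    before correlating.
    """
    consensus = consensus or ConsensusSpec()
    kd_by_gene: dict[str, dict[str, Signature]] = {}
    for gene in (network.proxy_target, *network.partners):
        per_line: dict[str, Signature] = {}
        for cell_line in kd_sigs.cell_lines:
            reps = [
                s
                for s in kd_sigs.signatures
                if s.target_gene == gene
                and s.cell_line == cell_line
                and s.perturbation_type is PerturbationType.KNOCKDOWN
            ]
            if reps:
                from dataclasses import replace as _replace

                # pool all shRNAs/replicates targeting the gene in this line
                pooled = [
                    _replace(s, perturbation_id=f"kd:{gene}", replicate=i)
                    for i, s in enumerate(reps)
                ]
                per_line[cell_line] = consensus_signature(pooled, consensus)
        if per_line:
            kd_by_gene[gene] = per_line
    if network.proxy_target not in kd_by_gene:
        raise ValueError(
            f"no knockdown signature found for proxy target "
            f"{network.proxy_target!r} in any cell line"
        )
    proxy_kd = kd_by_gene[network.proxy_target]

    features: list[ScreenFeatures] = []
    compound_ids = [
        pid
        for pid in compound_sigs.perturbation_ids
        if any(
            s.perturbation_type is not PerturbationType.KNOCKDOWN
            for s in compound_sigs.replicates_of(pid)
        )
    ]
    for compound_id in compound_ids:
        per_line_sigs = _consensus_by_cell_line(compound_sigs, compound_id,
                                                consensus)
        per_cell_line: dict[str, CellLineFeatures] = {}
        for cell_line, compound_sig in per_line_sigs.items():
            if cell_line not in proxy_kd:
                continue
            direct = signature_similarity(
                compound_sig, proxy_kd[cell_line], method=method, top_n=top_n
            )
            partner_corrs = [
                signature_similarity(
                    compound_sig, kd_by_gene[p][cell_line], method=method,
                    top_n=top_n
                )
                for p in network.partners
                if p in kd_by_gene and cell_line in kd_by_gene[p]
            ]
            if partner_corrs:
                best = max(partner_corrs)
                mean = float(np.mean(partner_corrs))
            else:
                best = mean = math.nan
            per_cell_line[cell_line] = CellLineFeatures(direct, best, mean)
        if not per_cell_line:
            logger.warning(
                "compound %s shares no cell line with the proxy knockdown",
                compound_id,
            )
        features.append(
            ScreenFeatures(compound_id, per_cell_line, support_threshold)
        )
    return features


def composite_score(features: ScreenFeatures, lambda_indirect: float = 0.5,
                    min_support: int = 4) -> tuple[float, bool]:
    """Deterministic candidate score.

    Mean, over the supported cell lines, of
    ``direct_corr + lambda_indirect * best_indirect_corr`` (the indirect
    term is omitted where no partner knockdown was available). Compounds
    supported in fewer than ``min_support`` cell lines are unqualified and
    scored ``-inf`` so that qualified compounds always outrank them.

    Returns ``(score, qualified)``.
    """
    if lambda_indirect < 0:
        raise ValueError("lambda_indirect must be >= 0")
    if features.n_cell_lines == 0 or features.support_count < min_support:
        return -math.inf, False
    if features.support_count == 0:  # qualified only when min_support == 0
        return -math.inf, True
    terms = []
    for cell_line in features.supported_cell_lines:
        feats = features.per_cell_line[cell_line]
        term = feats.direct_corr
        if not math.isnan(feats.best_indirect_corr):
            term += lambda_indirect * feats.best_indirect_corr
        terms.append(term)
    return float(np.mean(terms)), True


def _feature_matrix(feature_table: Sequence[ScreenFeatures]
                    ) -> tuple[np.ndarray, list[str]]:
    """Fixed-length flattened feature vectors over the union of cell lines.

    Missing cell lines contribute zeros; the last column is support_count.
    """
    cell_lines = sorted({cl for f in feature_table for cl in f.per_cell_line})
    rows = []
    for f in feature_table:
        row: list[float] = []
        for cl in cell_lines:
            feats = f.per_cell_line.get(cl)
            if feats is None:
                row += [0.0, 0.0, 0.0]
            else:
                row += [
                    feats.direct_corr,
                    0.0 if math.isnan(feats.best_indirect_corr)
                    else feats.best_indirect_corr,
                    0.0 if math.isnan(feats.mean_indirect_corr)
                    else feats.mean_indirect_corr,
                ]
        row.append(float(f.support_count))
        rows.append(row)
    return np.asarray(rows, dtype=float), cell_lines


def rank_candidates(
    feature_table: Sequence[ScreenFeatures],
    training: Mapping[str, int] | None = None,
    seed: int = 0,
    lambda_indirect: float = 0.5,
    min_support: int = 4,
    training_features: Sequence[ScreenFeatures] | None = None,
) -> CandidateRanking:
    """Rank compounds by composite score or a trained classifier.

    Without ``training``, compounds are ordered by
    :func:`composite_score`. With ``training`` — a mapping
    ``compound_id -> label`` (1 = known network inhibitor, 0 = not) over
    compounds in ``training_features`` (default: ``feature_table``
    itself) — a random-forest classifier is fitted on the flattened
    feature vectors and compounds are ordered by predicted positive-class
    probability. Qualified compounds (support in at least ``min_support``
    cell lines) always outrank unqualified ones; ties break on
    ``compound_id`` for a stable, reproducible ordering.
    """
    feature_table = list(feature_table)
    if training is not None:
        labels = set(training.values())
        if len(labels) < 2:
            raise ValueError(
                "training labels contain a single class; fall back to "
                "composite_score ranking (omit `training`)"
            )
        from sklearn.ensemble import RandomForestClassifier

        train_feats = list(training_features
                           if training_features is not None else feature_table)
        pool = train_feats + feature_table
        matrix, _ = _feature_matrix(pool)
        x_train_rows = []
        y_train = []
        by_id = {f.compound_id: i for i, f in enumerate(pool)}
        for compound_id, label in training.items():
            if compound_id not in by_id:
                raise KeyError(
                    f"training compound {compound_id!r} has no features"
                )
            x_train_rows.append(matrix[by_id[compound_id]])
            y_train.append(int(label))
        counts = {lbl: y_train.count(lbl) for lbl in set(y_train)}
        if min(counts.values()) < 2:
            raise ValueError(
                "each training label needs at least 2 compounds; fall back "
                "to composite_score ranking"
            )
        clf = RandomForestClassifier(n_estimators=200, random_state=seed)
        clf.fit(np.asarray(x_train_rows), np.asarray(y_train))
        test_matrix = matrix[len(train_feats):]
        positive = list(clf.classes_).index(1)
        probs = clf.predict_proba(test_matrix)[:, positive]
        scored = [
            (f.compound_id, float(p),
             f.n_cell_lines > 0 and f.support_count >= min_support)
            for f, p in zip(feature_table, probs)
        ]
    else:
        scored = []
        for f in feature_table:
            score, qualified = composite_score(f, lambda_indirect, min_support)
            scored.append((f.compound_id, score, qualified))
    scored.sort(key=lambda t: (not t[2], -t[1] if math.isfinite(t[1]) else math.inf,
                               t[0]))
    return CandidateRanking(scored)


# ---------------------------------------------------------------------------
# Target-panel tables


def load_foxm1_target_panel() -> PanelTable:
    """The packaged FOXM1 target-panel consensus table.

    Consensus z-scores of the eight direct FOXM1-activated targets under
    NPM1/AURKB/MYC knockdown and treatment with the two candidate
    compounds, as reported for the LINCS-based screen.
    """
    with resources.as_file(
        resources.files("foxnet.data") / "foxm1_target_panel.tsv"
    ) as path:
        values = pd.read_csv(path, sep="\t", index_col=0)
    return PanelTable(list(values.index), list(values.columns), values)


def panel_consensus_table(
    collection: SignatureCollection,
    panel: Sequence[str],
    perturbations: Sequence[str],
    spec: ConsensusSpec | None = None,
) -> PanelTable:
    """Consensus z of each panel gene under each requested perturbation.

    All signatures of a perturbation (across cell lines and replicates)
    are collapsed with :func:`consensus_signature` semantics applied over
    the pooled set, then restricted to the panel genes.
    """
    spec = spec or ConsensusSpec()
    panel = list(panel)
    missing = [g for g in panel if g not in collection.gene_universe]
    if missing:
        raise ValueError(f"panel gene {missing[0]!r} not in gene universe")
    columns = {}
    for pid in perturbations:
        sigs = collection.replicates_of(pid)
        if not sigs:
            raise ValueError(f"no signatures for perturbation {pid!r}")
        # pool across cell lines: relabel so consensus preconditions hold
        from dataclasses import replace as _replace

        pooled = [
            _replace(s, cell_line="pooled", replicate=i)
            for i, s in enumerate(sigs)
        ]
        cons = consensus_signature(pooled, spec)
        absent = [g for g in panel if g not in cons.genes]
        if absent:
            raise ValueError(
                f"panel gene {absent[0]!r} missing from perturbation {pid!r}"
            )
        columns[pid] = cons.values.loc[panel]
    values = pd.DataFrame(columns, index=pd.Index(panel))
    return PanelTable(panel, list(perturbations), values)


def compare_candidates(
    table: PanelTable,
    candidates: Sequence[str],
    suppression_threshold: float = -1.0,
) -> list[tuple[str, int, float]]:
    """Order candidate perturbations by panel suppression.

    ``n_suppressed`` counts panel genes with consensus z at or below the
    (negative) threshold — the *universality* of network suppression;
    ``mean_z`` over the panel measures *potency*. Candidates are ordered
    by ``n_suppressed`` descending, then ``mean_z`` ascending (more
    negative first).
    """
    if suppression_threshold >= 0:
        raise ValueError("suppression_threshold must be negative")
    results = []
    for candidate in candidates:
        if candidate not in table.values.columns:
            raise KeyError(f"unknown candidate {candidate!r}")
        column = table.values[candidate]
        n_suppressed = int((column <= suppression_threshold).sum())
        results.append((candidate, n_suppressed, float(column.mean())))
    results.sort(key=lambda t: (-t[1], t[2], t[0]))
    return results
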