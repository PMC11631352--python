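"""Dataset audits: organelle/Unassigned content, reclassification flows,
organelle filtering, and fold-changes in unknown content.

These operations quantify what changes when a feature table is re-annotated
against an organelle-extended reference: how much of each sample is
mitochondrial, chloroplast, or Unassigned; where read mass flows between the
two annotations; and how many samples see a >= 10-fold drop in unknown reads.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .classify import Classification
from .lineage import RANKS

logger = logging.getLogger(__name__)

FLOW_DOMAINS = ("Bacteria", "Archaea", "Eukaryota")


@dataclass
class CompositionSummary:
    """Per-sample fractions of Unassigned / mitochondria / chloroplast / other.

    ``fractions`` has one row per sample with columns p_unassigned,
    p_mitochondria, p_chloroplast, p_other (NaN for zero-read samples, which
    are also listed in ``empty_samples``).
    """

    fractions: pd.DataFrame
    empty_samples: list = field(default_factory=list)

    @property
    def samples(self):
        return list(self.fractions.index)


def _category(assignment: Classification | None) -> str:
    if assignment is None:
        return "unassigned"
    lin = assignment.lineage
    if lin.is_mitochondrion:
        return "mitochondria"
    if lin.is_chloroplast:
        return "chloroplast"
    if lin.is_unassigned:
        return "unassigned"
    return "other"


def composition_summary(table: pd.DataFrame,
                        assignments: dict[str, Classification]) -> CompositionSummary:
    """Accumulate reads per sample into the four audit categories."""
    cats = ("unassigned", "mitochondria", "chloroplast", "other")
    missing = [f for f in table.index if f not in assignments]
    if missing:
        logger.warning("%d features lack assignments; treated as Unassigned",
                       len(missing))
    cat_of = {f: _category(assignments.get(f)) for f in table.index}
    sums = pd.DataFrame(0.0, index=cats, columns=table.columns)
    for cat in cats:
        feats = [f for f in table.index if cat_of[f] == cat]
        sums.loc[cat] = table.loc[feats].sum(axis=0)
    totals = sums.sum(axis=0)
    empty = [s for s in table.columns if totals[s] == 0]
    fractions = (sums / totals).T
    fractions.columns = [f"p_{c}" for c in cats]
    return CompositionSummary(fractions=fractions, empty_samples=empty)


def flow_label(assignment: Classification | None, level: str = "domain") -> str:
    """Category label for flow tables; organelle labels override the rank."""
    if assignment is None:
        return "Unassigned"
    lin = assignment.lineage
    if lin.is_mitochondrion:
        return "Mitochondria"
    if lin.is_chloroplast:
        return "Chloroplast"
    if lin.is_unassigned:
        return "Unassigned"
    label = lin.label_at(level)
    if level == "domain":
        return label if label in FLOW_DOMAINS else "other"
    return label if label else "other"


def reclassification_flow(assign_base: dict[str, Classification],
                          assign_ext: dict[str, Classification],
                          table: pd.DataFrame, level: str = "domain") -> pd.DataFrame:
    """Read-count mass flowing (label under base) → (label under extended).

    Returns a DataFrame with columns label_from, label_to, mass; total mass
    equals the table's grand total.
    """
    if level not in RANKS:
        raise ValueError(f"unknown rank {level!r}")
    flows: dict[tuple[str, str], float] = {}
    totals = table.sum(axis=1)
    for f in table.index:
        key = (flow_label(assign_base.get(f), level),
               flow_label(assign_ext.get(f), level))
        flows[key] = flows.get(key, 0) + int(totals[f])
    rows = [{"label_from": a, "label_to": b, "mass": m}
            for (a, b), m in sorted(flows.items())]
    return pd.DataFrame(rows, columns=["label_from", "label_to", "mass"])


def filter_organelles(table: pd.DataFrame,
                      assignments: dict[str, Classification]) -> pd.DataFrame:
    """Drop rows classified as mitochondrial or chloroplast; counts untouched
    (no renormalization), all-zero rows retained."""
    keep = [f for f in table.index
            if not (f in assignments and
                    (assignments[f].lineage.is_mitochondrion or
                     assignments[f].lineage.is_chloroplast))]
    return table.loc[keep]


@dataclass
class FoldChangeReport:
    folds: pd.Series              # per-sample fold (may hold inf / NaN)
    n_at_least_threshold: int
    n_evaluable: int              # samples with base unknown fraction > 0
    threshold: float


def unknown_fold_change(base: CompositionSummary, ext: CompositionSummary,
                        threshold: float = 10.0) -> FoldChangeReport:
    """Per-sample fold-reduction of the Unassigned fraction (base / extended).

    Extended fraction 0 with base > 0 counts as +inf (>= threshold); base
    fraction 0 is undefined and excluded from the denominator.
    """
    s_base = set(base.samples)
    s_ext = set(ext.samples)
    if s_base != s_ext:
        raise ValueError(f"sample sets differ: only-base={sorted(s_base - s_ext)} "
                         f"only-ext={sorted(s_ext - s_base)}")
    pb = base.fractions["p_unassigned"]
    pe = ext.fractions["p_unassigned"].reindex(pb.index)
    folds = {}
    n_eval = 0
    n_hit = 0
    for s in pb.index:
        b, e = pb[s], pe[s]
        if math.isnan(b) or math.isnan(e) or b == 0:
            folds[s] = float("nan")
            continue
        n_eval += 1
        fold = math.inf if e == 0 else b / e
        folds[s] = fold
        if fold >= threshold:
            n_hit += 1
    return FoldChangeReport(folds=pd.Series(folds), n_at_least_threshold=n_hit,
                            n_evaluable=n_eval, threshold=threshold)


def unique_feature_summary(table: pd.DataFrame,
                           assignments: dict[str, Classification]) -> CompositionSummary:
    """Like composition_summary but counting unique features once each
    (presence/absence), for unique-sequence rather than read-proportion folds."""
    presence = (table > 0).astype(int)
    return composition_summary(presence, assignments)
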