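"""Candidate target selection and four-key lexicographic ranking.

A protein is a candidate ADC target for a cancer type when strictly
more than half of that cancer's patients score High or Medium by IHC
and (optionally) the transmembrane consensus filter passes: at least
five of the six topology predictors call exactly one membrane-spanning
segment, i.e. a confidently single-pass protein with a contiguous
extracellular domain for antibody binding.

Candidates are ordered lexicographically, safety first:

1. fewest healthy tissues at High-or-Medium (combined off-target burden),
2. fewest healthy tissues at High,
3. fewest healthy tissues at Medium,
4. highest fraction of cancer patients at High-or-Medium,

with residual ties broken by gene symbol for determinism.  The ordered
criteria carry no weights; lexicographic order is the parameter-free
reading of "ranked by (1)...(4)".
"""

from __future__ import annotations

import csv
import logging
from typing import Dict, List, Sequence, Tuple

from .store import Vault, patients_total
from .types import (
    LEVEL_RANK,
    CancerIHCSummary,
    RankKeys,
    RankedTarget,
    TMPrediction,
    ValidationError,
)

__all__ = [
    "tm_consensus_filter",
    "patient_fraction",
    "healthy_tissue_counts",
    "rank_targets",
    "export_ranking",
]

logger = logging.getLogger(__name__)


def tm_consensus_filter(
    predictions: Sequence[TMPrediction],
    min_agree: int = 5,
    required_segments: int = 1,
) -> bool:
    """True iff >= ``min_agree`` predictors call exactly ``required_segments``.

    Missing predictors count as disagreement (the count is over the
    predictions actually present, against a fixed quorum of
    ``min_agree``).  Duplicate predictor labels are an error.
    """
    labels = [p.predictor for p in predictions]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"predictor: duplicate labels {dupes}")
    agreeing = sum(p.n_segments == required_segments for p in predictions)
    return agreeing >= min_agree


def patient_fraction(s: CancerIHCSummary) -> float:
    """Fraction of patients at High-or-Medium, in [0, 1]."""
    return (s.n_high + s.n_medium) / patients_total(s)


def healthy_tissue_counts(
    vault: Vault, protein_id: str, tissue_collapse: str = "max"
) -> Tuple[int, int, int]:
    """(K1, K2, K3) healthy off-target counts for one protein.

    Under ``tissue_collapse="max"`` each tissue contributes its maximum
    level over cell types: K2 = #tissues at High, K3 = #tissues at
    Medium, K1 = K2 + K3.  Under ``"per_cell_type"`` the counting unit
    is the (tissue, cell type) pair instead.  A protein with no healthy
    rows counts (0, 0, 0) — absence of evidence is treated as no
    detected expression and surfaced through the ``data_gap`` flag.
    """
    if tissue_collapse == "max":
        levels = vault.healthy_level_by_tissue(protein_id).values()
    elif tissue_collapse == "per_cell_type":
        levels = [lvl for _, _, lvl in vault.healthy_levels_per_cell_type(protein_id)]
    else:
        raise ValidationError(
            f"tissue_collapse: {tissue_collapse!r} not in {{max, per_cell_type}}"
        )
    k2 = sum(lvl == "High" for lvl in levels)
    k3 = sum(lvl == "Medium" for lvl in levels)
    return (k2 + k3, k2, k3)


def rank_targets(
    vault: Vault,
    cancer_type: str,
    min_patient_fraction: float = 0.5,
    apply_tm_filter: bool = True,
    min_agree: int = 5,
    required_segments: int = 1,
    tissue_collapse: str = "max",
) -> List[RankedTarget]:
    """Ordered candidate list for ``cancer_type``.

    Candidates are proteins with patient_fraction strictly greater than
    ``min_patient_fraction``; with ``apply_tm_filter`` they must also
    pass the transmembrane consensus filter.  Sorted by (K1 asc, K2
    asc, K3 asc, K4 desc), residual ties by gene symbol; ranks are
    consecutive from 1.  An empty candidate set returns an empty list.
    """
    targets: List[Tuple[tuple, RankedTarget]] = []
    for s in vault.cancer_summaries(cancer_type):
        frac = patient_fraction(s)
        if not frac > min_patient_fraction:
            continue
        passed_tm = tm_consensus_filter(
            vault.tm_predictions(s.protein_id), min_agree, required_segments
        )
        if apply_tm_filter and not passed_tm:
            continue
        k1, k2, k3 = healthy_tissue_counts(vault, s.protein_id, tissue_collapse)
        data_gap = not vault.healthy_level_by_tissue(s.protein_id)
        prot = vault.protein(s.protein_id)
        keys = RankKeys(k1, k2, k3, frac)
        rt = RankedTarget(s.protein_id, prot.gene_symbol, keys, rank=0,
                          passed_tm_filter=passed_tm, data_gap=data_gap)
        targets.append((keys.sort_key(prot.gene_symbol), rt))
    if not targets:
        logger.info("rank_targets: empty candidate set for %r", cancer_type)
        return []
    targets.sort(key=lambda item: item[0])
    return [
        RankedTarget(rt.protein_id, rt.gene_symbol, rt.keys, rank=i + 1,
                     passed_tm_filter=rt.passed_tm_filter, data_gap=rt.data_gap)
        for i, (_, rt) in enumerate(targets)
    ]


def export_ranking(targets: Sequence[RankedTarget], path) -> None:
    """Write the ranked list as CSV (K4 with 4 decimal places)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["rank", "protein_id", "gene_symbol", "K1", "K2", "K3", "K4",
                    "passed_tm_filter", "data_gap"])
        for t in targets:
            w.writerow([t.rank, t.protein_id, t.gene_symbol,
                        t.keys.k1, t.keys.k2, t.keys.k3, f"{t.keys.k4:.4f}",
                        t.passed_tm_filter, t.data_gap])
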