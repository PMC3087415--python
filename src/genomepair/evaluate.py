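"""Scoring of pipeline output against simulator ground truth."""

from __future__ import annotations

import pandas as pd

from .model import ComparisonResults
from .orthologs import GenomePartition
from .origins import LABELS
from .synthetic import TruthTable

#: causal truth event -> expected origin-classifier label
_EVENT_TO_LABEL = {
    "split": "split",
    "duplication": "duplication",
    "lateral_transfer": "lateral_transfer",
    "deletion_in_partner": "deletion",
}


def ortholog_scores(truth: TruthTable, part: GenomePartition) -> dict:
    """Pair-level precision/recall of the computed map vs the truth map.

    ``precision``/``recall`` compare exact pairs against
    ``truth.ortholog_map``; ``precision_ancestry`` additionally credits
    pairs whose two genes descend from the same ancestral gene (an intact
    gene matched to a fragment of its true ortholog, or to a paralogous
    copy, still identifies common origin).
    """
    found = {(p.id_a, p.id_b) for p in part.pairs} | {
        (p.id_a, p.id_b) for p in part.rna_pairs
    }
    tp = truth.ortholog_map & found
    anc_ok = sum(
        1 for a, b in found
        if truth.ancestor_ids.get(a) == truth.ancestor_ids.get(b)
    )
    return {
        "n_found": len(found),
        "n_truth": len(truth.ortholog_map),
        "precision": len(tp) / len(found) if found else 1.0,
        "recall": len(tp) / len(truth.ortholog_map) if truth.ortholog_map else 1.0,
        "precision_ancestry": anc_ok / len(found) if found else 1.0,
    }


def origin_confusion(truth: TruthTable, res: ComparisonResults) -> pd.DataFrame:
    """(true event class, predicted label) rows for every scored unique CDS.

    Genes whose only event is a partner-side split (``split_partner``) have
    genuinely ambiguous status and are excluded from scoring.
    """
    rows = []
    for genome, lineage in (("A", "A"), ("B", "B")):
        expected = truth.expected_unique(lineage)
        predicted = {l.locus_tag: l.label for l in res.origin_labels[genome]}
        for tag, label in predicted.items():
            event = expected.get(tag)
            if event is None or event == "split_partner":
                continue
            rows.append(
                {"genome": genome, "locus_tag": tag,
                 "true_label": _EVENT_TO_LABEL[event], "predicted": label}
            )
    return pd.DataFrame(rows, columns=["genome", "locus_tag", "true_label", "predicted"])


def origin_scores(truth: TruthTable, res: ComparisonResults) -> pd.DataFrame:
    """Per-class precision/recall of the origin classifier (both genomes)."""
    conf = origin_confusion(truth, res)
    rows = []
    for label in LABELS:
        if label == "unclassified":
            continue
        tp = int(((conf.true_label == label) & (conf.predicted == label)).sum())
        fp = int(((conf.true_label != label) & (conf.predicted == label)).sum())
        fn = int(((conf.true_label == label) & (conf.predicted != label)).sum())
        rows.append(
            {
                "label": label,
                "tp": tp, "fp": fp, "fn": fn,
                "precision": tp / (tp + fp) if tp + fp else float("nan"),
                "recall": tp / (tp + fn) if tp + fn else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def inversion_recovery(truth: TruthTable, res: ComparisonResults) -> dict:
    """Do the antiparallel dot-plot points recover the planted inversions?

    Returns the set comparison between ortholog pairs predicted antiparallel
    and pairs whose B member is a planted inversion-block gene.
    """
    inv_b = {tag for lin, tag, ev in truth.events
             if lin == "B" and ev == "inversion_member"}
    anti = {p.id_b for p in res.points if p.orientation == "antiparallel"}
    coli = {p.id_b for p in res.points if p.orientation == "colinear"}
    return {
        "n_inverted_genes": len(inv_b),
        "anti_correct": len(anti & inv_b),
        "anti_false": len(anti - inv_b),
        "colinear_in_block": len(coli & inv_b),
        "exact": (anti - inv_b == set()) and (coli & inv_b == set()),
    }
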