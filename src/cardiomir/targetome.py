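"""Per-miRNA targetome derivation and Venn decomposition.

A targetome is the set of genes both *predicted* as seed-family targets of a
miRNA and *observed* downregulated upon its transfection.  Predictions come
in the assay-foreign species (mouse), are reduced to the best score per
(family, gene) pair, translated to the assay species (rat) through homology
groups, and finally intersected with the fold-change 'down' calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from cardiomir.exceptions import InputError
from cardiomir.expression import DE_DOWN

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HomologyTranslation:
    """Outcome of a mouse->rat homology translation."""

    rat_genes: frozenset
    unmapped: frozenset

    @property
    def n_dropped(self) -> int:
        return len(self.unmapped)


@dataclass
class Targetome:
    """Predicted-and-downregulated gene set for one miRNA."""

    mirna: str
    predicted_rat_genes: set = field(default_factory=set)
    downregulated_targets: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.downregulated_targets <= self.predicted_rat_genes:
            raise InputError("downregulated_targets must be a subset of predictions")


def best_score_per_gene(predictions: pd.DataFrame, family: str) -> dict[str, float]:
    """Strongest (numerically lowest) score per mouse gene for one family.

    Prediction tables may carry several rows per (family, gene) pair, one per
    target site; the convention (context-score style) is that more negative
    means a stronger interaction, so the minimum is kept.  The score is
    carried for reporting but never thresholded downstream.
    """
    sub = predictions[predictions["family"] == family]
    if sub.empty:
        warnings.warn(f"family {family!r} not present in prediction table", stacklevel=2)
        return {}
    return sub.groupby("mouse_gene")["score"].min().to_dict()


def families_for_mirna(predictions: pd.DataFrame, mirna: str) -> list[str]:
    """Seed families associated with a miRNA in the prediction table."""
    fams = predictions.loc[predictions["mirna"] == mirna, "family"].unique()
    return sorted(fams)


def translate_homology(mouse_genes, homology: pd.DataFrame) -> HomologyTranslation:
    """Translate mouse genes to rat genes through shared homology groups.

    Any rat gene sharing a group with an input mouse gene is returned;
    many-to-one mappings collapse as sets.  Mouse genes belonging to no group
    are dropped and reported.
    """
    mouse_genes = set(mouse_genes)
    mouse_rows = homology[homology["species"] == "mouse"]
    groups_of = mouse_rows[mouse_rows["gene_id"].isin(mouse_genes)]
    hit_groups = set(groups_of["group_id"])
    mapped_mouse = set(groups_of["gene_id"])
    unmapped = mouse_genes - mapped_mouse
    rat_rows = homology[
        (homology["species"] == "rat") & homology["group_id"].isin(hit_groups)
    ]
    if unmapped:
        log.info("homology translation dropped %d mouse genes with no group", len(unmapped))
    return HomologyTranslation(
        rat_genes=frozenset(rat_rows["gene_id"]), unmapped=frozenset(unmapped)
    )


def derive_targetome(predicted_rat, de_records: pd.DataFrame, mirna: str) -> Targetome:
    """Intersect translated predictions with the miRNA's 'down' DE calls."""
    predicted_rat = set(predicted_rat)
    sub = de_records[de_records["mirna"] == mirna]
    if sub.empty:
        raise InputError(f"miRNA {mirna!r} absent from DE table")
    down = set(sub.loc[sub["de_status"] == DE_DOWN, "gene_id"])
    return Targetome(
        mirna=mirna,
        predicted_rat_genes=predicted_rat,
        downregulated_targets=predicted_rat & down,
    )


def build_targetome(
    predictions: pd.DataFrame,
    homology: pd.DataFrame,
    de_records: pd.DataFrame,
    mirna: str,
) -> Targetome:
    """Full chain: best score -> homology translation -> DE intersection."""
    mouse_genes: set[str] = set()
    for fam in families_for_mirna(predictions, mirna):
        mouse_genes |= set(best_score_per_gene(predictions, fam))
    translation = translate_homology(mouse_genes, homology)
    return derive_targetome(translation.rat_genes, de_records, mirna)


def venn_counts(sets: dict) -> dict[str, int]:
    """Counts of the 7 membership regions of three labelled sets plus totals.

    Region keys join labels with '&' ('A', 'A&B', 'A&B&C', ...); totals are
    'total_<label>'.  Region counts always sum to the union's cardinality.
    """
    if len(sets) != 3:
        raise InputError("venn_counts expects exactly three labelled sets")
    (la, a), (lb, b), (lc, c) = sets.items()
    a, b, c = set(a), set(b), set(c)
    regions = {
        la: len(a - b - c),
        lb: len(b - a - c),
        lc: len(c - a - b),
        f"{la}&{lb}": len((a & b) - c),
        f"{la}&{lc}": len((a & c) - b),
        f"{lb}&{lc}": len((b & c) - a),
        f"{la}&{lb}&{lc}": len(a & b & c),
    }
    regions[f"total_{la}"] = len(a)
    regions[f"total_{lb}"] = len(b)
    regions[f"total_{lc}"] = len(c)
    return regions
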