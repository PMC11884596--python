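"""Statistical characterization of functional vs non-functional sites.

On any curated dataset this module rebuilds the descriptive comparison of
the two site classes: model-confidence (pLDDT) distributions, secondary
structure composition, and the degree / eigenvector-centrality of each
site in its protein's whole-residue contact network, each compared between
groups with a two-tailed unpaired t-test (Welch by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .graphs import (
    GraphConfig,
    collapse_ss3,
    compute_protein_features,
)
from .io import ProteinRecord, SiteRecord

logger = logging.getLogger(__name__)

PLDDT_CATEGORY_EDGES = (50.0, 70.0, 90.0)
PLDDT_CATEGORY_NAMES = ("very_low", "low", "high", "very_high")


def plddt_category(value: float) -> str:
    """AlphaFold confidence band: very low (<50), low (50–70), high (70–90)."""
    return PLDDT_CATEGORY_NAMES[int(np.digitize(value, PLDDT_CATEGORY_EDGES))]


def build_feature_table(
    proteins: list[ProteinRecord],
    sites: list[SiteRecord],
    graph_config: GraphConfig | None = None,
) -> pd.DataFrame:
    """One row per site: pLDDT, secondary structure, degree, centrality, label.

    Degree and centrality come from the whole-protein contact graph.  Sites
    whose protein is missing are skipped with a warning.
    """
    graph_config = graph_config or GraphConfig()
    by_acc = {p.accession: p for p in proteins}
    cache: dict[str, object] = {}
    rows = []
    for site in sites:
        protein = by_acc.get(site.accession)
        if protein is None or site.position > len(protein):
            logger.warning(
                "skipping site %s:%d (no structure)", site.accession, site.position
            )
            continue
        if site.accession not in cache:
            cache[site.accession] = compute_protein_features(protein, graph_config)
        feats = cache[site.accession]
        i = site.position - 1
        ss8 = feats.ss8[i]
        rows.append(
            {
                "accession": site.accession,
                "position": site.position,
                "plddt": float(protein.plddt[i]),
                "plddt_category": plddt_category(protein.plddt[i]),
                "ss8": ss8,
                "ss3": collapse_ss3(np.array([ss8]))[0],
                "degree": float(feats.degree[i]),
                "eigenvector_centrality": float(feats.centrality[i]),
                "functional_label": site.functional_label,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    feature: str
    t_statistic: float
    p_value: float
    mean_positive: float
    mean_negative: float

    @property
    def direction(self) -> str:
        return "positive>negative" if self.mean_positive > self.mean_negative else (
            "negative>positive" if self.mean_negative > self.mean_positive else "equal"
        )


def compare_groups(
    table: pd.DataFrame, feature: str, welch: bool = True
) -> GroupComparison:
    """Two-tailed unpaired t-test between functional and non-functional sites.

    Welch's unequal-variance form is the default; ``welch=False`` restores
    the pooled-variance (Student) variant.  Two zero-variance groups with
    equal means are reported as t = 0, p = 1.
    """
    pos = table.loc[table["functional_label"] == 1, feature].to_numpy(float)
    neg = table.loc[table["functional_label"] == 0, feature].to_numpy(float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each group needs at least 2 observations")
    if pos.std() == 0 and neg.std() == 0 and pos.mean() == neg.mean():
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = sps.ttest_ind(pos, neg, equal_var=not welch)
    return GroupComparison(
        feature=feature,
        t_statistic=float(t_stat),
        p_value=float(p_val),
        mean_positive=float(pos.mean()),
        mean_negative=float(neg.mean()),
    )


def class_composition(table: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Per-class fractions of a categorical feature, split by group.

    Rows are the two groups (functional / non-functional); columns the
    feature classes; every row sums to 1.
    """
    out = (
        table.groupby("functional_label")[feature]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    out.index = out.index.map({0: "non_functional", 1: "functional"})
    return out
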