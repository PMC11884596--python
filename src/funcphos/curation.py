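"""Dataset curation: labeling, filtering, redundancy reduction, splitting.

The functional-site dataset treats any site carrying a regulatory-function
or disease-association annotation as positive and unannotated sites as
negative.  Because negatives vastly outnumber positives, they are
undersampled (1:1 by default) into several independent negative sets; each
balanced dataset is split 4:1 into train/test, and the training part is
partitioned into stratified folds for cross-validation.

The enzyme-activity dataset keeps only sites tagged with an enzymatic
activity direction; "inhibited" wins when both directions are annotated,
so conflicting records never yield contradictory labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io import ProteinRecord, SiteRecord, check_site_consistency

logger = logging.getLogger(__name__)

INDUCED_TAG = "enzymatic activity, induced"
INHIBITED_TAG = "enzymatic activity, inhibited"


@dataclass
class CurationConfig:
    identity_threshold: float = 0.8
    pos_neg_ratio: int = 1          # negatives per positive
    train_fraction: float = 0.8     # the 4:1 train/test split
    n_negative_sets: int = 3
    n_folds: int = 5
    group_by_protein: bool = False  # keep each protein on one side of the split
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in (0.5, 1.0]")
        if self.pos_neg_ratio < 1:
            raise ValueError("pos_neg_ratio must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_negative_sets < 1:
            raise ValueError("n_negative_sets must be >= 1")


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def label_functional(sites: list[SiteRecord]) -> list[SiteRecord]:
    """Functional = any regulatory-function or disease annotation present."""
    out = []
    for site in sites:
        out.append(replace(site, functional_label=int(bool(site.annotations))))
    return out


def label_regulatory(sites: list[SiteRecord]) -> list[SiteRecord]:
    """Keep enzyme sites with an activity tag; inhibited overrides induced."""
    out = []
    for site in sites:
        tags = {a.lower() for a in site.annotations}
        if INHIBITED_TAG in tags:
            out.append(replace(site, regulatory_label="inhibited"))
        elif INDUCED_TAG in tags:
            out.append(replace(site, regulatory_label="induced"))
        # sites without an activity direction are dropped
    return out


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_isoforms_removed: int = 0
    n_without_structure: int = 0
    n_sites_mismatched: int = 0
    n_sites_orphaned: int = 0


def filter_proteins(
    records: list[ProteinRecord],
    sites: list[SiteRecord],
    structure_accessions: set[str] | None = None,
) -> tuple[list[ProteinRecord], list[SiteRecord], FilterReport]:
    """Apply the curation filters in order; order-stable and idempotent.

    1. drop isoform accessions (hyphen-suffixed, UniProt convention);
    2. drop proteins whose accession has no structure (when a structure
       inventory is given);
    3. drop sites whose residue letter mismatches the sequence at the
       stated position, and sites whose protein was removed.
    """
    report = FilterReport()
    kept: list[ProteinRecord] = []
    for rec in records:
        if "-" in rec.accession:
            report.n_isoforms_removed += 1
            continue
        if structure_accessions is not None and rec.accession not in structure_accessions:
            report.n_without_structure += 1
            continue
        kept.append(rec)
    by_acc = {rec.accession: rec for rec in kept}
    kept_sites: list[SiteRecord] = []
    for site in sites:
        protein = by_acc.get(site.accession)
        if protein is None:
            report.n_sites_orphaned += 1
            continue
        if not check_site_consistency(site, protein):
            report.n_sites_mismatched += 1
            continue
        kept_sites.append(site)
    logger.info(
        "filters: %d isoforms, %d without structure, %d mismatched sites, "
        "%d orphaned sites removed",
        report.n_isoforms_removed, report.n_without_structure,
        report.n_sites_mismatched, report.n_sites_orphaned,
    )
    return kept, kept_sites, report


# ---------------------------------------------------------------------------
# redundancy reduction
# ---------------------------------------------------------------------------

_KMER = 5


def _kmer_anchored_identity(a: str, b: str) -> float:
    """Ungapped identity anchored on shared k-mers.

    Every shared k-mer proposes an offset between the two sequences; the
    offset with the most matched positions wins.  Identity is matches over
    the shorter length, so identical sequences score 1 and sequences with
    no shared k-mer score 0.
    """
    if not a or not b:
        return 0.0
    index: dict[str, list[int]] = {}
    for i in range(len(a) - _KMER + 1):
        index.setdefault(a[i : i + _KMER], []).append(i)
    offsets = set()
    for j in range(len(b) - _KMER + 1):
        for i in index.get(b[j : j + _KMER], ()):
            offsets.add(i - j)
    if not offsets:
        return 0.0
    shorter = min(len(a), len(b))
    best = 0
    for off in offsets:
        lo = max(0, off)
        hi = min(len(a), len(b) + off)
        if hi <= lo:
            continue
        matches = sum(a[i] == b[i - off] for i in range(lo, hi))
        best = max(best, matches)
    return best / shorter


def reduce_redundancy(
    records: list[ProteinRecord] | list[str],
    threshold: float = 0.8,
) -> tuple[list, dict[int, int]]:
    """Greedy longest-first sequence clustering at an identity threshold.

    Returns the representatives (longest member of each cluster) and a map
    input-index → representative input-index.  Accepts ProteinRecords or
    bare sequences.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1.0]")
    seqs = [r.sequence if isinstance(r, ProteinRecord) else r for r in records]
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
    rep_of: dict[int, int] = {}
    reps: list[int] = []
    for i in order:
        for rep in reps:
            if _kmer_anchored_identity(seqs[rep], seqs[i]) >= threshold:
                rep_of[i] = rep
                break
        else:
            reps.append(i)
            rep_of[i] = i
    return [records[i] for i in reps], rep_of


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    """Site assignments for one negative set.

    ``site_indices`` index into the labeled site list passed to
    :func:`make_splits`; ``tags`` holds "test" or "train-fold-k" per entry.
    """

    negative_set: int
    site_indices: np.ndarray
    tags: list[str]

    def train_fold(self, fold: int) -> np.ndarray:
        """Training-site indices for one CV round (all folds except `fold`)."""
        mask = [
            t.startswith("train-fold-") and t != f"train-fold-{fold}"
            for t in self.tags
        ]
        return self.site_indices[np.array(mask, bool)]

    def val_fold(self, fold: int) -> np.ndarray:
        mask = [t == f"train-fold-{fold}" for t in self.tags]
        return self.site_indices[np.array(mask, bool)]

    @property
    def test_indices(self) -> np.ndarray:
        mask = [t == "test" for t in self.tags]
        return self.site_indices[np.array(mask, bool)]

    @property
    def train_indices(self) -> np.ndarray:
        mask = [t != "test" for t in self.tags]
        return self.site_indices[np.array(mask, bool)]


def make_splits(
    labels: np.ndarray,
    config: CurationConfig,
    groups: np.ndarray | None = None,
) -> list[SplitAssignment]:
    """Undersample negatives and build train/test + CV-fold assignments.

    ``labels`` is the per-site binary vector (1 = positive); one
    :class:`SplitAssignment` is returned per independent negative set.
    When ``config.group_by_protein`` is set, ``groups`` must give a protein
    id per site and no protein spans train and test.
    """
    labels = np.asarray(labels, int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    n_sample = min(len(neg), config.pos_neg_ratio * len(pos))
    if len(pos) < config.n_folds or n_sample < config.n_folds:
        raise ValueError(
            f"need at least {config.n_folds} sites per class, have "
            f"{len(pos)} positives / {n_sample} negatives"
        )
    if config.group_by_protein and groups is None:
        raise ValueError("group_by_protein requires per-site group ids")

    assignments = []
    for set_idx in range(config.n_negative_sets):
        rng = np.random.default_rng([config.seed, set_idx])
        sampled_neg = rng.choice(neg, size=n_sample, replace=False)
        idx = np.concatenate([pos, np.sort(sampled_neg)])
        y = labels[idx]

        if config.group_by_protein:
            uniq = np.unique(groups[idx])
            shuffled = rng.permutation(uniq)
            n_train_groups = int(round(config.train_fraction * len(uniq)))
            train_groups = set(shuffled[:n_train_groups].tolist())
            is_train = np.array([g in train_groups for g in groups[idx]])
        else:
            is_train = np.zeros(len(idx), bool)
            for cls in (0, 1):
                cls_pos = np.flatnonzero(y == cls)
                n_train = int(round(config.train_fraction * len(cls_pos)))
                chosen = rng.choice(cls_pos, size=n_train, replace=False)
                is_train[chosen] = True

        tags = np.array(["test"] * len(idx), dtype=object)
        train_rows = np.flatnonzero(is_train)
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        for fold, (_, val) in enumerate(skf.split(train_rows, y[train_rows])):
            tags[train_rows[val]] = f"train-fold-{fold}"
        assignments.append(
            SplitAssignment(
                negative_set=set_idx,
                site_indices=idx,
                tags=tags.tolist(),
            )
        )
    return assignments
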