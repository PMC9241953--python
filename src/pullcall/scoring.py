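"""The bait-normalized spectral-count scoring chain.

Stage order for one condition (one bait, several replicate pulldowns):

1. ``length_normalize`` — divide each protein's summed count by its length
   in amino acids, per assay.  Longer proteins yield more detectable
   peptides; this removes that bias (the same idea as spectral abundance
   factors).
2. ``bait_normalize`` — divide every value by the bait's value in the same
   assay, making assays of different pulldown efficiency comparable; the
   bait maps to exactly 1.0 everywhere.
3. ``merge_and_log2`` — pool all non-bait, non-zero (protein, assay) values
   across assays as independent observations and take log2.  Each
   exclusion (bait, zero cell) is recorded so the observation count is
   auditable.
4. ``classify`` — after a mixture fit (see :mod:`pullcall.gmm`), score each
   protein by the high-component posterior of its mean log2 value and call
   it an interactor when the posterior exceeds 0.5 strictly AND its summed
   raw count is at least 5.

``phase_sort`` is an unrelated small utility: it filters a differential-
expression table at a strict |log2 fold change| > 1.5 (and an optional
adjusted-P cutoff, default 0.1) and partitions the survivors by annotated
cell-cycle peak phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gmm
from .errors import NotConvergedError, ValidationError
from .io_tables import PHASES, CountTable, DETable, InteractorCall, PhaseAnnotation

__all__ = [
    "ObservationSet",
    "length_normalize",
    "bait_normalize",
    "merge_and_log2",
    "classify",
    "phase_sort",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ObservationSet:
    """Pooled log2 bait-normalized values ready for mixture training.

    ``entries`` has columns protein_id, assay_id, log2_value; it contains
    no bait records and no zero-count records.  ``excluded`` logs every
    dropped (protein, assay) cell with its reason.
    """

    entries: pd.DataFrame
    excluded: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.entries["log2_value"].to_numpy())):
            raise ValidationError("log2 observations must be finite")

    @property
    def values(self) -> np.ndarray:
        return self.entries["log2_value"].to_numpy()

    def per_protein_mean(self) -> pd.Series:
        """Mean log2 value across the assays in which each protein was seen."""
        return self.entries.groupby("protein_id")["log2_value"].mean()


def _apply_pseudocount(table: CountTable, pseudocount: float) -> pd.DataFrame:
    counts = table.counts.astype(float)
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    return counts + pseudocount if pseudocount else counts


def length_normalize(table: CountTable, pseudocount: float = 0.0) -> pd.DataFrame:
    """Counts divided by protein length (amino acids), per assay.

    Returns a proteins x assays frame of real values; zero counts map to
    zero.  Raises if any protein in the table lacks a length.
    """
    if table.lengths is None:
        raise ValidationError("no protein lengths attached to this table")
    missing = sorted(set(table.proteins) - set(table.lengths.index))
    if missing:
        raise ValidationError(f"no length for protein(s): {missing}")
    counts = _apply_pseudocount(table, pseudocount)
    return counts.div(table.lengths.reindex(counts.index), axis=0)


def bait_normalize(values: pd.DataFrame, bait_id: str) -> pd.DataFrame:
    """Divide every value by the bait's value in the same assay.

    The bait row becomes exactly 1.0 in every assay; prey values become
    bait-relative abundances, comparable across pulldowns of differing
    efficiency.
    """
    if bait_id not in values.index:
        raise ValidationError(f"bait {bait_id!r} not present in normalized values")
    bait_row = values.loc[bait_id]
    if (bait_row <= 0).any():
        bad = list(values.columns[bait_row <= 0])
        raise ValidationError(f"bait value is not positive in assay(s) {bad}")
    return values.div(bait_row, axis=1)


def merge_and_log2(
    values: pd.DataFrame, bait_id: str, min_observations: int = 10
) -> ObservationSet:
    """Pool bait-normalized values across assays and apply log2.

    Every (protein, assay) cell is a separate observation.  Bait cells and
    zero cells are excluded (log2(0) is undefined and the bait is 0 by
    construction on the log2 scale); each exclusion is recorded with a
    reason.  Raises if fewer than ``min_observations`` remain.
    """
    excluded: list[tuple[str, str, str]] = []
    records = []
    long = values.stack()  # (protein_id, assay_id) -> value
    for (protein, assay), value in long.items():
        if protein == bait_id:
            excluded.append((protein, assay, "bait"))
        elif value <= 0.0:
            excluded.append((protein, assay, "zero-count"))
        else:
            records.append((protein, assay, float(np.log2(value))))
    entries = pd.DataFrame(records, columns=["protein_id", "assay_id", "log2_value"])
    if len(entries) < min_observations:
        raise ValidationError(
            f"only {len(entries)} usable observations (< {min_observations}); "
            "mixture is unfittable"
        )
    return ObservationSet(entries=entries, excluded=excluded)


def classify(
    obs: ObservationSet,
    fit: gmm.MixtureFit,
    table: CountTable,
    posterior_threshold: float = 0.5,
    count_threshold: int = 5,
    count_mode: str = "total",
) -> list[InteractorCall]:
    """Call interactors from a fitted mixture.

    Each non-bait protein is scored by the posterior probability of the
    high-abundance component at its mean log2 value; it is called an
    interactor when the posterior exceeds ``posterior_threshold``
    *strictly* and its raw count clears ``count_threshold``.  With
    ``count_mode='total'`` (default) the count filter applies to the sum
    across assays; with ``'any_assay'`` a single assay must reach the
    threshold on its own.  Proteins never observed (all-zero counts) get
    posterior 0 and verdict false.  The bait is reported first with
    sentinel posterior 1.0 and ``is_bait`` set.
    """
    if not fit.converged:
        raise NotConvergedError("mixture fit did not converge; refit before classifying")
    if not (0.0 < posterior_threshold < 1.0):
        raise ValidationError("posterior_threshold must lie in (0, 1)")
    if count_threshold < 0:
        raise ValidationError("count_threshold must be >= 0")
    if count_mode not in ("total", "any_assay"):
        raise ValidationError("count_mode must be 'total' or 'any_assay'")

    high = gmm.select_high_component(fit)
    means = obs.per_protein_mean()
    totals = table.total_counts()
    maxima = table.counts.max(axis=1)

    calls: list[InteractorCall] = [
        InteractorCall(
            protein_id=table.bait_id,
            total_raw_count=int(totals[table.bait_id]),
            mean_log2_score=0.0,
            posterior=1.0,
            is_interactor=True,
            is_bait=True,
        )
    ]
    for protein in table.prey_ids:
        total = int(totals[protein])
        if protein in means.index:
            score = float(means[protein])
            post = float(gmm.posterior(fit, score)[high])
        else:
            score, post = float("nan"), 0.0
        count_ok = (
            total >= count_threshold
            if count_mode == "total"
            else int(maxima[protein]) >= count_threshold
        )
        calls.append(
            InteractorCall(
                protein_id=protein,
                total_raw_count=total,
                mean_log2_score=score,
                posterior=post,
                is_interactor=bool(post > posterior_threshold and count_ok),
            )
        )
    return calls


def phase_sort(
    de: DETable,
    annotation: PhaseAnnotation,
    lfc_threshold: float = 1.5,
    padj_threshold: float | None = 0.1,
) -> dict[str, list[str]]:
    """Partition responsive transcripts by cell-cycle peak phase.

    Retains transcripts with |log2 fold change| strictly greater than
    ``lfc_threshold`` and, when ``padj_threshold`` is set, adjusted P at or
    below it (rows with missing adjusted P fail the filter, matching the
    usual treatment of independent-filtering NAs).  Survivors are split by
    annotated peak phase; unannotated transcripts fall into NONCYCLICAL
    with a logged warning.  The three groups are disjoint and together
    equal the retained set.
    """
    f = de.frame
    keep = f["log2_change"].abs() > lfc_threshold
    if padj_threshold is not None:
        keep &= f["adjusted_p"].le(padj_threshold).fillna(False)
    groups: dict[str, list[str]] = {phase: [] for phase in PHASES}
    for tid in f.loc[keep, "transcript_id"]:
        if tid in annotation.phases.index:
            groups[annotation.phases[tid]].append(tid)
        else:
            logger.warning("transcript %s lacks a phase annotation; sorting as NONCYCLICAL", tid)
            groups["NONCYCLICAL"].append(tid)
    return groups
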