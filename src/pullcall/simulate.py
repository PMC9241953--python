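"""Synthetic AP-MS pulldown generator with ground truth.

Emulates the statistical structure the scoring chain assumes: a dominant
bait protein present in every replicate pulldown, a small set of true
interactors whose bait-relative abundance is high, and a large background
population of nonspecific proteins at low bait-relative abundance.  Counts
are integer and overdispersed (negative binomial), protein lengths span
roughly 100–3000 residues, and background proteins drop out of individual
assays at a configurable rate — true interactors never drop out, mirroring
the reproducible detection that specific partners show across replicates.

Generative model (per fixed seed, fully deterministic):

1. lengths ~ DiscreteUniform(length_range) for bait and all preys;
2. each prey draws a latent bait-relative log2 abundance from its
   population's Gaussian (background or interactor);
3. per assay, the bait count ~ NegBin(mean=bait_count_mean, size=dispersion),
   clamped to >= 1 (a pulldown without bait is invalid);
4. the expected prey count is 2^latent * bait_count * length(prey) /
   length(bait) — constructed so the pipeline's length- and
   bait-normalization recovers the latent log2 value in expectation;
5. the observed count ~ NegBin around that expectation with the configured
   dispersion;
6. background cells are zeroed with probability ``dropout_prob``.

Because the latent abundances live on the same bait-relative log2 scale the
mixture is fitted on, parameter recovery by the full pipeline is a direct
test of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_tables import CountTable, InteractorCall

__all__ = ["SimConfig", "SimTruth", "simulate", "evaluate_calls", "write_truth"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic pulldown study.

    Defaults describe three replicate pulldowns of one bait with 10 true
    interactors against 300 background proteins, a 5-log2-unit separation
    between the two populations, overdispersed counts (negative-binomial
    size 5) and 15% per-assay background dropout.
    """

    n_background: int = 300
    n_interactors: int = 10
    n_assays: int = 3
    bait_count_mean: float = 400.0
    background_log2_mean: float = -7.0
    background_log2_sd: float = 1.2
    interactor_log2_mean: float = -2.0
    interactor_log2_sd: float = 0.8
    length_range: tuple[int, int] = (100, 3000)
    dispersion: float = 5.0
    dropout_prob: float = 0.15
    seed: int = 0
    bait_id: str = "BAIT"

    def __post_init__(self) -> None:
        if self.n_background < 0 or self.n_interactors < 0 or self.n_assays < 1:
            raise ValidationError("population sizes must be non-negative, n_assays >= 1")
        if self.interactor_log2_mean <= self.background_log2_mean:
            raise ValidationError(
                "interactor_log2_mean must exceed background_log2_mean"
            )
        if self.background_log2_sd <= 0 or self.interactor_log2_sd <= 0:
            raise ValidationError("population standard deviations must be positive")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValidationError("dropout_prob must lie in [0, 1]")
        if self.dispersion <= 0 or self.bait_count_mean <= 0:
            raise ValidationError("dispersion and bait_count_mean must be positive")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValidationError("length_range must satisfy 1 <= min <= max")


@dataclass(frozen=True)
class SimTruth:
    """A synthetic dataset with its ground-truth interactor labels."""

    table: CountTable
    labels: dict[str, bool] = field(repr=False)
    config: SimConfig = field(repr=False)
    latent_log2: dict[str, float] = field(repr=False, default_factory=dict)


def _negbin(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative-binomial draws as a gamma-Poisson mixture (mean/size form)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    lam = rng.gamma(shape=size_param, scale=mean / size_param)
    return rng.poisson(lam)


def simulate(config: SimConfig | None = None) -> SimTruth:
    """Generate one synthetic pulldown study. Deterministic for a fixed seed."""
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed)
    n_prey = config.n_background + config.n_interactors

    prey_ids = [f"PREY_{i:04d}" for i in range(n_prey)]
    is_interactor = np.zeros(n_prey, dtype=bool)
    is_interactor[: config.n_interactors] = True

    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=n_prey + 1)  # last entry = bait
    bait_length = int(lengths[-1])

    latent = np.where(
        is_interactor,
        rng.normal(config.interactor_log2_mean, config.interactor_log2_sd, n_prey),
        rng.normal(config.background_log2_mean, config.background_log2_sd, n_prey),
    )

    assay_ids = [f"assay{a + 1}" for a in range(config.n_assays)]
    bait_counts = np.maximum(
        _negbin(rng, np.full(config.n_assays, config.bait_count_mean), config.dispersion),
        1,
    )

    # expected prey count chosen so (count/len) / (bait_count/bait_len) == 2^latent
    expected = (
        2.0 ** latent[:, None]
        * bait_counts[None, :]
        * lengths[:n_prey, None]
        / bait_length
    )
    counts = _negbin(rng, expected, config.dispersion)
    if config.dropout_prob > 0:
        drop = rng.random((n_prey, config.n_assays)) < config.dropout_prob
        drop[is_interactor, :] = False  # specific partners are seen in every assay
        counts = np.where(drop, 0, counts)

    matrix = pd.DataFrame(
        np.vstack([counts, bait_counts[None, :]]),
        index=pd.Index(prey_ids + [config.bait_id], name="protein_id"),
        columns=pd.Index(assay_ids, name="assay_id"),
        dtype=np.int64,
    )
    length_series = pd.Series(
        lengths.astype(np.int64), index=matrix.index, name="length"
    )
    table = CountTable(counts=matrix, bait_id=config.bait_id, lengths=length_series)
    labels = dict(zip(prey_ids, (bool(b) for b in is_interactor)))
    latent_map = dict(zip(prey_ids, (float(v) for v in latent)))
    return SimTruth(table=table, labels=labels, config=config, latent_log2=latent_map)


def evaluate_calls(truth: SimTruth, calls: list[InteractorCall]) -> dict[str, float]:
    """Confusion-matrix summary of calls against ground truth (bait excluded).

    Returns sensitivity, specificity, the raw confusion counts and the
    number of false discoveries.  Raises if a non-bait call is missing
    from the truth labels or a labeled protein is missing from the calls.
    """
    verdicts = {}
    for c in calls:
        if c.is_bait or c.protein_id == truth.table.bait_id:
            continue
        if c.protein_id not in truth.labels:
            raise ValidationError(f"called protein {c.protein_id!r} has no truth label")
        verdicts[c.protein_id] = c.is_interactor
    missing = set(truth.labels) - set(verdicts)
    if missing:
        raise ValidationError(f"calls do not cover labeled protein(s): {sorted(missing)[:5]}")

    tp = sum(1 for p, lab in truth.labels.items() if lab and verdicts[p])
    fn = sum(1 for p, lab in truth.labels.items() if lab and not verdicts[p])
    fp = sum(1 for p, lab in truth.labels.items() if not lab and verdicts[p])
    tn = sum(1 for p, lab in truth.labels.items() if not lab and not verdicts[p])
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "false_discoveries": fp,
    }


def write_truth(truth: SimTruth, path) -> None:
    """Write the two-column ground-truth file (protein_id, is_interactor)."""
    rows = ["protein_id\tis_interactor"]
    for protein in truth.table.prey_ids:
        rows.append(f"{protein}\t{str(truth.labels[protein]).lower()}")
    from pathlib import Path

    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")
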