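"""Intra-/inter-rater agreement: per-measure correlations and a
timeline-level concordance audit.

``measure_agreement`` computes, for each measure, the Pearson
product-moment correlation across animals between two raters' values, with
the two-tailed p-value from the t reference with n-2 degrees of freedom.

``timeline_concordance`` samples two scorings of the same trial on a fixed
grid and reports percent agreement and Cohen's kappa over the resulting
label confusion — a numeric stand-in for eyeballing two visual-map rows.
Point behaviors have no duration and are excluded from concordance; they
enter ``measure_agreement`` as counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import AgreementError, InsufficientDataError
from .timeline import ScoredTrial, state_labels

__all__ = [
    "MeasureVectorPair",
    "MeasureCorrelation",
    "Concordance",
    "measure_agreement",
    "timeline_concordance",
    "paired_measure_vectors",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeasureVectorPair:
    """One measure's values for the same animals from two raters."""

    measure: str
    a: tuple[float, ...]
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", tuple(float(x) for x in self.a))
        object.__setattr__(self, "b", tuple(float(x) for x in self.b))
        if len(self.a) != len(self.b):
            raise AgreementError(
                f"measure {self.measure!r}: rater vectors differ in length "
                f"({len(self.a)} vs {len(self.b)})"
            )


@dataclass(frozen=True)
class MeasureCorrelation:
    """Pearson r with two-tailed p for one measure; r is None if undefined."""

    measure: str
    r: float | None
    p_two_tailed: float | None
    n: int
    reason: str | None = None


@dataclass(frozen=True)
class Concordance:
    percent_agreement: float
    kappa: float
    sample_step_s: float
    n_samples: int


def measure_agreement(
    pairs: Sequence[MeasureVectorPair],
) -> dict[str, MeasureCorrelation]:
    """Pearson correlation (two-tailed) per measure across animals.

    Requires n >= 3 per pair.  A pair with zero variance in either vector
    yields ``r=None`` with a reason rather than a number.
    """
    out: dict[str, MeasureCorrelation] = {}
    for pair in pairs:
        n = len(pair.a)
        if n < 3:
            raise InsufficientDataError(
                f"measure {pair.measure!r}: need n >= 3 animals, got {n}"
            )
        a = np.asarray(pair.a)
        b = np.asarray(pair.b)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            out[pair.measure] = MeasureCorrelation(
                pair.measure, None, None, n, reason="zero variance in one rater's values"
            )
            continue
        res = stats.pearsonr(a, b)
        out[pair.measure] = MeasureCorrelation(
            pair.measure, float(res.statistic), float(res.pvalue), n
        )
    return out


def paired_measure_vectors(
    by_rater: Mapping[str, Mapping[str, Mapping[str, float]]],
    rater_a: str,
    rater_b: str,
) -> list[MeasureVectorPair]:
    """Align two raters' per-animal measure tables into vector pairs.

    ``by_rater[rater][subject_id][measure] -> value``.  Animals present for
    only one rater are dropped pairwise with a logged warning, not imputed.
    """
    ta, tb = by_rater[rater_a], by_rater[rater_b]
    shared = sorted(set(ta) & set(tb))
    missing = sorted(set(ta) ^ set(tb))
    if missing:
        logger.warning(
            "dropping %d animal(s) present for only one rater: %s",
            len(missing),
            ", ".join(missing),
        )
    if not shared:
        return []
    measures = [m for m in ta[shared[0]] if all(m in ta[s] and m in tb[s] for s in shared)]
    return [
        MeasureVectorPair(
            m,
            tuple(ta[s][m] for s in shared),
            tuple(tb[s][m] for s in shared),
        )
        for m in measures
    ]


def timeline_concordance(
    a: ScoredTrial, b: ScoredTrial, step_s: float = 0.1
) -> Concordance:
    """Sample-wise agreement between two scorings of the same trial.

    Both timelines are sampled at the midpoints of consecutive ``step_s``
    windows; each sample is labeled with its state behavior (or ``"gap"``).
    Returns percent agreement and Cohen's kappa over the confusion matrix.
    """
    if not step_s > 0:
        raise AgreementError("step_s must be > 0")
    if abs(a.duration_s - b.duration_s) > 1e-9:
        raise AgreementError(
            f"duration mismatch: {a.duration_s:g} vs {b.duration_s:g} s"
        )
    n = int(math.floor(a.duration_s / step_s + 1e-9))
    if n < 1:
        raise AgreementError("step_s larger than the trial duration")
    mids = (np.arange(n) + 0.5) * step_s
    la = state_labels(a, mids)
    lb = state_labels(b, mids)

    matches = la == lb
    percent = 100.0 * float(np.count_nonzero(matches)) / n

    labels = sorted(set(la.tolist()) | set(lb.tolist()))
    index = {lab: i for i, lab in enumerate(labels)}
    ia = np.fromiter((index[x] for x in la), dtype=int, count=n)
    ib = np.fromiter((index[x] for x in lb), dtype=int, count=n)
    k = len(labels)
    confusion = np.zeros((k, k))
    np.add.at(confusion, (ia, ib), 1.0)
    confusion /= n
    po = float(np.trace(confusion))
    pe = float(confusion.sum(axis=1) @ confusion.sum(axis=0))
    if pe >= 1.0 - 1e-12:
        # single shared label: perfect agreement by construction
        kappa = 1.0 if po >= 1.0 - 1e-12 else 0.0
    else:
        kappa = (po - pe) / (1.0 - pe)
    return Concordance(percent, kappa, step_s, n)
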