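"""Sex attribution for counted passages (Criterion 5).

The only visual cue separating the sexes is the ovipositor, which points
backward: when a cricket enters the camera's field of view head-first its
rear is not yet framed, so the segmenter systematically votes *male* for
the first frames of every passage.  Criterion 5 therefore discards the
first few detection frames of each cluster before reducing the per-frame
class votes to a single sex.

Three reduction rules are available.  The default, ``female_override``,
attributes the whole trajectory to a female as soon as one frame shows
the ovipositor: a male vote can arise from a mere occlusion, but a female
vote can hardly arise on a true male.  ``majority`` and
``prob_weighted_majority`` are provided for ablation studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .counting import TrajectoryCluster
from .stream_model import FEMALE, MALE

__all__ = ["GenderRule", "GenderCount", "assign_sex", "gender_counts"]

Attribution = Literal["female_override", "majority", "prob_weighted_majority"]


@dataclass
class GenderRule:
    """How per-frame class votes become one sex per passage.

    discard_first:
        Number of *detection* frames (not wall-clock frames) dropped from
        the head of each cluster before voting; default 3, the typical
        depth of the entry misclassification.
    attribution:
        Vote-reduction rule, see module docstring.
    """

    discard_first: int = 3
    attribution: Attribution = "female_override"

    def __post_init__(self) -> None:
        if self.discard_first < 0:
            raise ValueError("discard_first must be >= 0")
        if self.attribution not in (
            "female_override",
            "majority",
            "prob_weighted_majority",
        ):
            raise ValueError(f"unknown attribution {self.attribution!r}")


@dataclass
class GenderCount:
    """Sex tally over the kept clusters.

    ``unresolved`` counts clusters whose vote set is empty after the
    initial-frame discard (or tied, under the majority rules); they are
    part of the passage total but excluded from the sex totals.
    """

    females: int = 0
    males: int = 0
    unresolved: int = 0

    @property
    def total(self) -> int:
        return self.females + self.males + self.unresolved


def assign_sex(cluster: TrajectoryCluster, rule: GenderRule) -> str:
    """Reduce one cluster's class votes to ``'male'``/``'female'``/``'unresolved'``."""
    votes = cluster.classes[rule.discard_first:]
    probs = cluster.probs[rule.discard_first:]
    if votes.size == 0:
        return "unresolved"
    n_female = int(np.sum(votes == FEMALE))
    n_male = int(np.sum(votes == MALE))
    if rule.attribution == "female_override":
        if n_female > 0:
            return "female"
        if n_male > 0:
            return "male"
        return "unresolved"
    if rule.attribution == "majority":
        if n_female > n_male:
            return "female"
        if n_male > n_female:
            return "male"
        return "unresolved"
    w_female = float(probs[votes == FEMALE].sum())
    w_male = float(probs[votes == MALE].sum())
    if w_female > w_male:
        return "female"
    if w_male > w_female:
        return "male"
    return "unresolved"


def gender_counts(
    kept_clusters: Sequence[TrajectoryCluster], rule: GenderRule
) -> GenderCount:
    """Tally :func:`assign_sex` over the kept clusters."""
    count = GenderCount()
    for cluster in kept_clusters:
        sex = assign_sex(cluster, rule)
        if sex == "female":
            count.females += 1
        elif sex == "male":
            count.males += 1
        else:
            count.unresolved += 1
    return count
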