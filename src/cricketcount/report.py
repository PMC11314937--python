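"""End-to-end pipeline, error arithmetic and criteria ablation.

The counting work flow chains the five correction criteria:

1. layer truncation (keep the first two layers),
2. kinematic layer sorting,
3. small-cluster rejection,
4. backward-direction rejection,
5. initial-frame rejection before sex attribution,

and reduces a detection stream to a :class:`CountResult`: total passages
plus the per-sex split.  Each criterion can be disabled independently,
which is how the ablation table quantifies what every correction buys.
Counting errors are reported as signed percentages against a reference
(manual or simulated ground-truth) count — positive means
overestimation, negative underestimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import pandas as pd

from .counting import (
    CountingConfig,
    FilterResult,
    clusters_to_table,
    count_passages,
    filter_clusters,
    segment_clusters,
)
from .gender import GenderRule, assign_sex, gender_counts
from .layer_sorting import SwapRule, sort_layers
from .stream_model import InfoMatrix, truncate_layers

__all__ = [
    "ReferenceCounts",
    "PipelineConfig",
    "CountResult",
    "ConfigurationError",
    "PipelineError",
    "percent_error",
    "run_pipeline",
    "ablation_table",
    "format_ablation",
]

CRITERIA = ("c1", "c2", "c3", "c4", "c5")
_DESCRIPTIONS = {
    "c1": "layer selection",
    "c2": "layer sorting",
    "c3": "small cluster rejection",
    "c4": "negative velocity rejection",
    "c5": "initial frames rejection",
}


class ConfigurationError(ValueError):
    """The pipeline configuration is incomplete or inconsistent."""


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class ReferenceCounts:
    """Independent (e.g. manual) counts to measure errors against."""

    total: int
    females: int | None = None
    males: int | None = None


@dataclass
class PipelineConfig:
    """Composition of all stage configurations plus criterion toggles.

    Disabling a criterion reproduces the corresponding uncorrected
    behaviour: no ``c1`` keeps only the first layer, no ``c2`` skips
    sorting, no ``c3`` sets the minimum cluster size to 1, no ``c4``
    keeps backward clusters, no ``c5`` votes on every cluster frame.
    """

    counting: CountingConfig = field(default_factory=CountingConfig)
    gender: GenderRule = field(default_factory=GenderRule)
    max_layers: int = 2
    c1_layer_truncation: bool = True
    c2_layer_sorting: bool = True
    c3_small_cluster_rejection: bool = True
    c4_direction_rejection: bool = True
    c5_initial_frame_rejection: bool = True
    sort_rule: SwapRule = "conjunctive"
    max_link_gap: int | None = 25
    reference: ReferenceCounts | None = None
    error_decimals: int = 1
    error_rounding: Literal["half_away", "truncate"] = "half_away"

    def criterion_enabled(self, name: str) -> bool:
        return {
            "c1": self.c1_layer_truncation,
            "c2": self.c2_layer_sorting,
            "c3": self.c3_small_cluster_rejection,
            "c4": self.c4_direction_rejection,
            "c5": self.c5_initial_frame_rejection,
        }[name]

    def with_criterion(self, name: str, enabled: bool) -> "PipelineConfig":
        key = {
            "c1": "c1_layer_truncation",
            "c2": "c2_layer_sorting",
            "c3": "c3_small_cluster_rejection",
            "c4": "c4_direction_rejection",
            "c5": "c5_initial_frame_rejection",
        }[name]
        return replace(self, **{key: enabled})


@dataclass
class CountResult:
    """Passage count split by sex, with bookkeeping and optional errors."""

    total: int
    females: int
    males: int
    unresolved: int
    n_clusters: int = 0
    n_rejected_small: int = 0
    n_rejected_backward: int = 0
    n_swapped_frames: int = 0
    n_dropped_records: int = 0
    errors: dict[str, float] | None = None
    variants: dict[str, int] | None = None
    cluster_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "total": self.total,
            "females": self.females,
            "males": self.males,
            "unresolved": self.unresolved,
            "n_clusters": self.n_clusters,
            "n_rejected_small": self.n_rejected_small,
            "n_rejected_backward": self.n_rejected_backward,
            "n_swapped_frames": self.n_swapped_frames,
            "n_dropped_records": self.n_dropped_records,
        }
        if self.errors is not None:
            out["errors"] = self.errors
        if self.variants is not None:
            out["variants"] = self.variants
        return out


def percent_error(
    estimate: float,
    reference: float,
    decimals: int = 1,
    mode: Literal["half_away", "truncate"] = "half_away",
) -> float:
    """Signed percent error ``100 * (estimate - reference) / reference``.

    Positive means overestimation, negative underestimation.  Rounding is
    half-away-from-zero by default; ``truncate`` chops toward zero
    instead (both conventions circulate in printed error tables).
    """
    if reference <= 0:
        raise ValueError("reference count must be positive")
    raw = 100.0 * (estimate - reference) / reference
    scale = 10.0**decimals
    mag = abs(raw) * scale
    if mode == "half_away":
        mag = math.floor(mag + 0.5)
    elif mode == "truncate":
        mag = math.floor(mag)
    else:
        raise ValueError(f"unknown rounding mode {mode!r}")
    return math.copysign(mag / scale, raw) if raw != 0 else 0.0


def run_pipeline(matrix: InfoMatrix, config: PipelineConfig | None = None) -> CountResult:
    """Run the full counting work flow on a detection stream."""
    if config is None:
        config = PipelineConfig()

    max_layers = config.max_layers if config.c1_layer_truncation else 1
    try:
        work, dropped = truncate_layers(matrix, max_layers)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("layer_truncation", exc) from exc

    n_swapped = 0
    if config.c2_layer_sorting and work.n_layers >= 2:
        try:
            work, diag = sort_layers(
                work,
                rule=config.sort_rule,
                max_link_gap=config.max_link_gap,
            )
            n_swapped = len(diag.swapped_frames)
        except Exception as exc:
            raise PipelineError("layer_sorting", exc) from exc

    try:
        clusters = segment_clusters(
            work,
            gap_tolerance=config.counting.gap_tolerance_frames,
            jump_split_px=config.counting.jump_split_px,
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("segmentation", exc) from exc

    counting_cfg = config.counting
    if not config.c3_small_cluster_rejection:
        counting_cfg = replace(counting_cfg, min_cluster_size=1)
    if not config.c4_direction_rejection:
        counting_cfg = replace(counting_cfg, direction_mode="keep_all")
    try:
        filtered = filter_clusters(clusters, counting_cfg)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("filtering", exc) from exc

    if counting_cfg.direction_mode == "net_flow":
        n_fwd = sum(c.direction == "forward" for c in filtered.kept)
        total = n_fwd - (len(filtered.kept) - n_fwd)
    else:
        total = count_passages(filtered.kept)

    rule = config.gender
    if not config.c5_initial_frame_rejection:
        rule = replace(rule, discard_first=0)
    try:
        sexes = [assign_sex(c, rule) for c in filtered.kept]
        tally = gender_counts(filtered.kept, rule)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("gender", exc) from exc

    errors = None
    ref = config.reference
    if ref is not None:
        errors = {
            "total": percent_error(
                total, ref.total, config.error_decimals, config.error_rounding
            )
        }
        if ref.females:
            errors["females"] = percent_error(
                tally.females, ref.females, config.error_decimals, config.error_rounding
            )
        if ref.males:
            errors["males"] = percent_error(
                tally.males, ref.males, config.error_decimals, config.error_rounding
            )

    return CountResult(
        total=total,
        females=tally.females,
        males=tally.males,
        unresolved=tally.unresolved,
        n_clusters=len(clusters),
        n_rejected_small=len(filtered.rejected_small),
        n_rejected_backward=len(filtered.rejected_backward),
        n_swapped_frames=n_swapped,
        n_dropped_records=dropped,
        errors=errors,
        cluster_table=clusters_to_table(filtered, sexes),
    )


def ablation_table(
    matrix: InfoMatrix, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Quantify each criterion: error with it disabled vs the all-on residual.

    One row per criterion; the ``*_error`` columns hold the counting and
    sex errors with that criterion disabled (all others on), and the
    ``residual_*`` columns repeat the all-criteria-on errors for
    comparison.  Requires reference counts in the configuration.
    """
    if config is None:
        config = PipelineConfig()
    if config.reference is None:
        raise ConfigurationError("ablation requires reference counts")
    ref = config.reference
    if ref.females is None or ref.males is None:
        raise ConfigurationError("ablation requires per-sex reference counts")

    def errors_of(res: CountResult) -> tuple[float, float, float]:
        assert res.errors is not None
        return (
            res.errors["total"],
            res.errors.get("females", float("nan")),
            res.errors.get("males", float("nan")),
        )

    base = run_pipeline(matrix, config)
    res_total, res_f, res_m = errors_of(base)

    rows = []
    variants: dict[str, int] = {"all_on": base.total}
    for name in CRITERIA:
        off = run_pipeline(matrix, config.with_criterion(name, False))
        tot, fem, mal = errors_of(off)
        variants[f"{name}_off"] = off.total
        rows.append(
            {
                "criterion": name,
                "description": _DESCRIPTIONS[name],
                "total_error": tot,
                "female_error": fem,
                "male_error": mal,
                "residual_total_error": res_total,
                "residual_female_error": res_f,
                "residual_male_error": res_m,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["variants"] = variants
    return table


def format_ablation(table: pd.DataFrame) -> str:
    """Pretty fixed-width rendering of an ablation table."""
    lines = [
        f"{'criterion':<33}{'off: total%':>12}{'female%':>10}{'male%':>10}"
        f"{'residual total%':>17}"
    ]
    for _, row in table.iterrows():
        lines.append(
            f"{row['criterion'] + ' ' + row['description']:<33}"
            f"{row['total_error']:>+12.1f}{row['female_error']:>+10.1f}"
            f"{row['male_error']:>+10.1f}{row['residual_total_error']:>+17.1f}"
        )
    return "\n".join(lines)
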