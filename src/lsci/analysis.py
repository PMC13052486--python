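"""Group comparison of ROI contrast traces and perfusion classification.

Each frame's ROI-mean contrast is one observation; two condition groups
(perfused vs compromised, flow vs no-flow) are compared with a two-sample
two-sided Student's t-test.  Speckle contrast is inversely related to flow,
so the lower-contrast group is the higher-flow ("perfused-like") one.

The default test pools variances (classic Student form); a Welch option is
provided because frame-trace variances often differ visibly between
conditions.  Frames are treated as exchangeable observations despite temporal
autocorrelation — a caveat recorded in every comparison's metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from lsci.core import InvalidInputError
from lsci.contrast import FrameSeriesStats

AUTOCORRELATION_CAVEAT = (
    "per-frame ROI means are treated as exchangeable observations; "
    "temporal autocorrelation within a trace is not modeled"
)


@dataclass
class GroupComparison:
    """Two-sample comparison of per-frame ROI-mean contrast traces."""

    group_a_label: str
    group_b_label: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float
    overlap_free: bool
    lower_contrast_group: str
    test_variant: str = "pooled"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise InvalidInputError("each group needs at least 2 observations")
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidInputError(f"p-value outside [0, 1]: {self.p_value}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "group_a": {"label": self.group_a_label, "mean_k": self.mean_a,
                        "sd_k": self.sd_a, "n_frames": self.n_a},
            "group_b": {"label": self.group_b_label, "mean_k": self.mean_b,
                        "sd_k": self.sd_b, "n_frames": self.n_b},
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "overlap_free": self.overlap_free,
            "lower_contrast_group": self.lower_contrast_group,
            "test_variant": self.test_variant,
            "metadata": self.metadata,
        }


def compare_groups(
    stats_a: FrameSeriesStats,
    stats_b: FrameSeriesStats,
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sided t-test between two ROI contrast traces.

    Parameters
    ----------
    stats_a, stats_b : frame-series traces with >= 2 frames each.
    equal_var : pooled-variance Student test if True (default), Welch if
        False.

    Returns
    -------
    GroupComparison
        Summary statistics, t and two-sided p, a flag for non-overlapping
        trace ranges, and which group has the lower (higher-flow) contrast.
    """
    a = np.asarray(stats_a.per_frame_mean_k, dtype=float)
    b = np.asarray(stats_b.per_frame_mean_k, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("each trace needs at least 2 frames for a t-test")
    with warnings.catch_warnings():
        # constant traces (e.g. frozen static speckle) are expected inputs
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(t):  # both groups constant with zero pooled variance
        t, p = 0.0, 1.0
    overlap_free = (a.max() < b.min()) or (b.max() < a.min())
    label_a = stats_a.group_label or "group_a"
    label_b = stats_b.group_label or "group_b"
    lower = label_a if a.mean() <= b.mean() else label_b
    return GroupComparison(
        group_a_label=label_a,
        group_b_label=label_b,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=len(a),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=len(b),
        t_statistic=float(t),
        p_value=float(p),
        overlap_free=bool(overlap_free),
        lower_contrast_group=lower,
        test_variant="pooled" if equal_var else "welch",
        metadata={"caveat": AUTOCORRELATION_CAVEAT,
                  "roi_a": stats_a.roi_label, "roi_b": stats_b.roi_label},
    )


@dataclass
class PerfusionDecision:
    """Qualitative perfusion call for a compared pair of regions.

    ``status`` is ``"classified"`` when the contrast difference is
    significant at ``alpha`` and ``"indeterminate"`` otherwise.  The call is
    relative (which region behaves perfused-like); no absolute flow speed is
    asserted — contrast is a qualitative flow indicator.
    """

    status: str
    perfused_like: str | None
    compromised_like: str | None
    p_value: float
    alpha: float

    def to_dict(self) -> dict[str, Any]:
        return {
            "status": self.status,
            "perfused_like": self.perfused_like,
            "compromised_like": self.compromised_like,
            "p_value": self.p_value,
            "alpha": self.alpha,
        }


def classify_perfusion(comparison: GroupComparison, alpha: float = 0.05) -> PerfusionDecision:
    """Label the lower-contrast group perfused-like when p < alpha."""
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError(f"alpha must be in (0, 1), got {alpha}")
    if comparison.p_value < alpha:
        lower = comparison.lower_contrast_group
        higher = (
            comparison.group_b_label
            if lower == comparison.group_a_label
            else comparison.group_a_label
        )
        return PerfusionDecision(
            status="classified",
            perfused_like=lower,
            compromised_like=higher,
            p_value=comparison.p_value,
            alpha=alpha,
        )
    return PerfusionDecision(
        status="indeterminate",
        perfused_like=None,
        compromised_like=None,
        p_value=comparison.p_value,
        alpha=alpha,
    )
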