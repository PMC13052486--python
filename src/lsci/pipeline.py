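"""End-to-end pipeline: read -> (motion filter) -> contrast -> ROI trace -> compare.

A single JSON config names the input stacks, ROIs and parameters for one or
two condition groups; the pipeline writes per-group trace CSVs, rendered
contrast maps, a comparison/classification JSON (for two groups), and a
processing log that records every parameter needed to reproduce the run.
The pipeline is deterministic: re-running the same config yields
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from lsci.core import LsciError
from lsci.analysis import classify_perfusion, compare_groups
from lsci.contrast import compute_contrast_map, series_roi_stats
from lsci.io import read_roi_mask, read_stack, write_series_csv
from lsci.motionfilter import apply_filter, filter_stack
from lsci.render import RenderSpec, write_render

logger = logging.getLogger(__name__)


class PipelineStageError(LsciError):
    """Failure inside a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class GroupInput:
    """One condition group: a stack, its ROI and a label."""

    label: str
    stack_path: str
    roi_path: str


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (JSON-serializable)."""

    groups: list[GroupInput]
    output_dir: str
    window_size: int = 5
    max_frames: int = 30
    motion_filter_enabled: bool = False
    motion_threshold: float = 0.025
    equal_var: bool = True
    alpha: float = 0.05
    render_range: tuple[float, float] = (0.0, 0.4)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        mf = d.get("motion_filter", {})
        return cls(
            groups=[
                GroupInput(label=g["label"], stack_path=g["stack"], roi_path=g["roi"])
                for g in d["groups"]
            ],
            output_dir=d["output_dir"],
            window_size=int(d.get("window_size", 5)),
            max_frames=int(d.get("max_frames", 30)),
            motion_filter_enabled=bool(mf.get("enabled", False)),
            motion_threshold=float(mf.get("threshold", 0.025)),
            equal_var=d.get("test", "pooled") == "pooled",
            alpha=float(d.get("alpha", 0.05)),
            render_range=tuple(d.get("render_range", (0.0, 0.4))),  # type: ignore[arg-type]
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict[str, Any]:
        return {
            "groups": [
                {"label": g.label, "stack": g.stack_path, "roi": g.roi_path}
                for g in self.groups
            ],
            "output_dir": self.output_dir,
            "window_size": self.window_size,
            "max_frames": self.max_frames,
            "motion_filter": {
                "enabled": self.motion_filter_enabled,
                "threshold": self.motion_threshold,
            },
            "test": "pooled" if self.equal_var else "welch",
            "alpha": self.alpha,
            "render_range": list(self.render_range),
        }


@dataclass
class PipelineResult:
    """Outputs of one run: traces, comparison, file paths, warnings, log."""

    traces: dict[str, Any]
    comparison: Any | None
    decision: Any | None
    filter_results: dict[str, Any]
    output_files: list[str]
    warnings: list[str] = field(default_factory=list)
    processing_log: list[dict[str, Any]] = field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis chain for one or two condition groups.

    Stages per group: read stack, optionally motion-filter it, compute the
    per-frame ROI contrast trace, write the trace CSV and a rendered contrast
    map of the first kept frame.  With exactly two groups, a two-sample
    t-test comparison and perfusion classification are written as JSON.
    Any stage failure raises :class:`PipelineStageError` naming the stage.
    """
    if not 1 <= len(config.groups) <= 2:
        raise PipelineStageError("config", f"expected 1 or 2 groups, got {len(config.groups)}")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    render_spec = RenderSpec(k_min=config.render_range[0], k_max=config.render_range[1])

    traces: dict[str, Any] = {}
    filter_results: dict[str, Any] = {}
    files: list[str] = []
    warnings_log: list[str] = []
    proc_log: list[dict[str, Any]] = [{"operation": "config", "params": config.to_dict()}]

    for grp in config.groups:
        try:
            stack = read_stack(grp.stack_path)
            roi = read_roi_mask(grp.roi_path)
        except Exception as exc:
            raise PipelineStageError("read", f"group '{grp.label}': {exc}") from exc

        if config.motion_filter_enabled:
            try:
                fres = filter_stack(
                    stack, threshold=config.motion_threshold, window_size=config.window_size
                )
            except Exception as exc:
                raise PipelineStageError("motion_filter", f"group '{grp.label}': {exc}") from exc
            filter_results[grp.label] = fres
            if fres.rejected_indices:
                warnings_log.append(
                    f"group '{grp.label}': motion filter rejected frames "
                    f"{fres.rejected_indices} ({fres.rejection_fraction:.1%})"
                )
            stack = apply_filter(stack, fres)
            proc_log.append(
                {"operation": "motion_filter", "params": {"group": grp.label, **fres.to_dict()}}
            )

        try:
            trace = series_roi_stats(
                stack, roi, group_label=grp.label,
                max_frames=config.max_frames, window_size=config.window_size,
            )
        except Exception as exc:
            raise PipelineStageError("contrast", f"group '{grp.label}': {exc}") from exc
        if len(trace) < config.max_frames:
            warnings_log.append(
                f"group '{grp.label}': only {len(trace)} frames available "
                f"(max_frames={config.max_frames})"
            )
        traces[grp.label] = trace
        csv_path = out_dir / f"stats_{grp.label}.csv"
        write_series_csv(trace, csv_path)
        files.append(str(csv_path))
        proc_log.append(
            {
                "operation": "series_roi_stats",
                "params": {
                    "group": grp.label,
                    "window_size": config.window_size,
                    "max_frames": config.max_frames,
                    "n_frames_used": len(trace),
                },
            }
        )

        try:
            cmap = compute_contrast_map(stack.frame(0), window_size=config.window_size)
            png_path = out_dir / f"contrast_{grp.label}_frame0.png"
            write_render(png_path, cmap, render_spec)
            files.append(str(png_path))
        except Exception as exc:
            raise PipelineStageError("render", f"group '{grp.label}': {exc}") from exc

    comparison = None
    decision = None
    if len(config.groups) == 2:
        la, lb = (g.label for g in config.groups)
        try:
            comparison = compare_groups(traces[la], traces[lb], equal_var=config.equal_var)
            decision = classify_perfusion(comparison, alpha=config.alpha)
        except Exception as exc:
            raise PipelineStageError("compare", str(exc)) from exc
        if filter_results:
            comparison.metadata["motion_filter_note"] = (
                "motion filter removed frames before testing; "
                "significance is reported, not asserted"
            )
        cmp_path = out_dir / "comparison.json"
        cmp_path.write_text(
            json.dumps(
                {"comparison": comparison.to_dict(), "decision": decision.to_dict()},
                indent=2, sort_keys=True,
            )
        )
        files.append(str(cmp_path))

    log_path = out_dir / "pipeline_log.json"
    log_path.write_text(
        json.dumps(
            {"processing_log": proc_log, "warnings": warnings_log},
            indent=2, sort_keys=True,
        )
    )
    files.append(str(log_path))

    return PipelineResult(
        traces=traces,
        comparison=comparison,
        decision=decision,
        filter_results=filter_results,
        output_files=files,
        warnings=warnings_log,
        processing_log=proc_log,
    )
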