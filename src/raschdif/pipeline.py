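"""End-to-end orchestration: read -> collapse -> fit -> diagnose -> DIF loop
-> group comparison -> reports, driven by a config and fully seeded.

Every number in the human-readable report is also written to a
machine-readable artifact (JSON/CSV); the manifest records the config,
package version, seed and checksums needed to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .data import ResponseMatrix, read_responses, write_responses
from .diagnostics import (
    CollapseMap,
    check_threshold_ordering,
    collapse_categories,
    evc_data,
)
from .dif import (
    DIFSettings,
    ResolutionTrace,
    assign_class_intervals,
    group_comparison,
    quantify_resolved_item,
    sequential_resolution,
    subsample_equal_groups,
)
from .estimation import EstimationSettings
from .simulate import (
    five_category_preset,
    hbsc_like_preset,
    null_preset,
    simulate,
    standard_collapse_maps,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

_PRESETS = {
    "hbsc_like": hbsc_like_preset,
    "five_category": five_category_preset,
    "null": null_preset,
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything a run needs; mirrors the analysis choices of a survey-scale
    DIF study (equal-group subsampling, notional fit sample size, Bonferroni
    significance policy)."""

    input_path: str | None = None  # CSV of responses, or...
    preset: str | None = None  # ...a named synthetic preset
    schema: dict[str, int] | None = None  # item_id -> m for CSV input
    collapse: dict[str, list[int]] | None = None  # item_id -> category map
    apply_standard_collapse: bool = False  # the 5->3 merge for preset data
    target_group_n: int | None = None  # equal-group subsample size
    adjusted_n: int | None = 1500
    n_intervals: int = 10
    min_interval_size: int = 30
    alpha: float = 0.05
    correction: str | None = "bonferroni"
    max_resolution_steps: int | None = None
    seed: int = 0
    output_dir: str = "raschdif_out"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.preset is None):
            raise ConfigError("exactly one of input_path / preset is required")
        if self.preset is not None and self.preset not in _PRESETS:
            raise ConfigError(
                f"unknown preset {self.preset!r}; choose from {sorted(_PRESETS)}"
            )
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def dif_settings(self) -> DIFSettings:
        return DIFSettings(
            n_intervals=self.n_intervals,
            min_interval_size=self.min_interval_size,
            alpha=self.alpha,
            correction=self.correction,
            adjusted_n=self.adjusted_n,
            max_steps=self.max_resolution_steps,
            estimation=EstimationSettings(),
        )


@dataclass
class RunManifest:
    config: dict
    package_version: str
    seed: int
    started: str
    finished: str
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _serialize_state(state) -> dict:
    return {
        "label": state.label,
        "items": [
            {
                "item_id": it.item_id,
                "delta": it.delta,
                "tau": list(it.tau),
                "group_tag": it.group_tag,
            }
            for it in state.items
        ],
        "psi": state.psi,
        "overall_fit_p": state.overall_fit_p,
        "group_means_internal": state.group_means,
        "dif_table": state.dif_table.table.to_dict(orient="records"),
        "notes": state.dif_table.notes,
    }


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full workflow and write all reports under the output dir.

    Reported person means use the 'higher = better health' orientation
    (the sign-flip of the internal problems scale); the report header says
    so.  Raises with the stage name on failure; partial outputs written up
    to that point are left in place.
    """
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))
    logger.info(
        "run settings: intervals=%d, correction=%s, adjusted_n=%s, "
        "target_group_n=%s, seed=%d",
        config.n_intervals, config.correction, config.adjusted_n,
        config.target_group_n, config.seed,
    )

    stage = "read"
    try:
        if config.preset:
            design = _PRESETS[config.preset](seed=config.seed)
            data, truth = simulate(design)
            (out / "truth.json").write_text(truth.to_json())
        else:
            data = read_responses(config.input_path, config.schema)
        write_responses(data, out / "input_data.csv")

        stage = "subsample"
        if config.target_group_n:
            data = subsample_equal_groups(data, config.target_group_n, rng_seed)

        stage = "collapse"
        maps = []
        if config.apply_standard_collapse:
            maps = standard_collapse_maps(data.item_ids)
        elif config.collapse:
            maps = [
                CollapseMap(iid, tuple(mp)) for iid, mp in config.collapse.items()
            ]
        if maps:
            data = collapse_categories(data, maps)

        stage = "dif"
        settings = config.dif_settings()
        trace: ResolutionTrace = sequential_resolution(data, settings)

        stage = "report"
        for i, state in enumerate(trace.states):
            state.dif_table.table.to_csv(
                out / f"dif_table_{state.label}.csv", index=False
            )
        ordering = check_threshold_ordering(trace.initial.items)
        pd.DataFrame(
            [
                {"item_id": r.item_id, "ordered": r.ordered,
                 "thresholds": " ".join(f"{t:.4f}" for t in r.thresholds)}
                for r in ordering
            ]
        ).to_csv(out / "threshold_ordering.csv", index=False)

        trace_payload = {
            "states": [_serialize_state(s) for s in trace.states],
            "resolved_items": trace.resolved_items,
            "stopping_reason": trace.stopping_reason,
            "settings": {
                "n_intervals": settings.n_intervals,
                "min_interval_size": settings.min_interval_size,
                "alpha": settings.alpha,
                "correction": settings.correction,
                "adjusted_n": settings.adjusted_n,
            },
        }
        (out / "resolution_trace.json").write_text(
            json.dumps(trace_payload, indent=2)
        )

        report = group_comparison(trace)
        (out / "group_comparison.json").write_text(
            json.dumps(
                {
                    "orientation": "higher = better health",
                    "sets": report.sets,
                    "group_means": report.group_means,
                    "differences": {
                        s: {f"{a}-{b}": v for (a, b), v in d.items()}
                        for s, d in report.differences.items()
                    },
                    "difference_in_differences": {
                        f"{sa}|{sb}": {f"{a}-{b}": v for (a, b), v in d.items()}
                        for (sa, sb), d in report.difference_in_differences.items()
                    },
                    "psi": report.psi,
                    "overall_fit_p": report.overall_fit_p,
                },
                indent=2,
            )
        )
        frame = report.to_frame()
        with open(out / "group_comparison.txt", "w") as fh:
            fh.write("Group comparison (person means; higher = better health)\n\n")
            fh.write(frame.to_string(float_format=lambda v: f"{v:.5f}"))
            fh.write("\n")

        # EVC exports for every resolved item, from the final item set
        final = trace.states[-1]
        intervals = assign_class_intervals(
            final.persons, settings.n_intervals, settings.min_interval_size
        )
        quantities = {}
        for item_id in trace.resolved_items:
            comp = quantify_resolved_item(final, item_id)
            quantities[item_id] = {
                "delta": comp.delta,
                "slope": comp.slope,
                "delta_differences": {
                    f"{a}-{b}": v for (a, b), v in comp.delta_differences.items()
                },
            }
            for it in final.items:
                if it.group_tag and it.item_id.startswith(f"{item_id}::"):
                    evc = evc_data(final.data, it, final.persons, intervals)
                    pd.DataFrame(
                        {"beta": evc.grid, "expected": evc.expected}
                    ).to_csv(out / f"evc_curve_{it.item_id.replace('::', '_')}.csv",
                             index=False)
                    evc.observed.to_csv(
                        out / f"evc_observed_{it.item_id.replace('::', '_')}.csv",
                        index=False,
                    )
        (out / "resolved_item_comparison.json").write_text(
            json.dumps(quantities, indent=2)
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        package_version=_pkg_version,
        seed=config.seed,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest.outputs[p.name] = _sha256(p)
    (out / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2)
    )
    return manifest
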