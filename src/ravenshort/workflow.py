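"""End-to-end runs: configuration, the stage pipeline, and report rendering.

`run_pipeline` chains clean → split → grid search → validation → stability →
baseline → reliability → ceiling → IRT comparison and collects everything in
a :class:`ReportBundle` whose every number is regenerable from the
configuration and its seeds alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .cohorts import COHORTS, cohort_config
from .data import (
    CleaningReport,
    ItemResponseMatrix,
    clean_responses,
    read_response_table,
    sum_score,
)
from .errors import ConfigurationError, RavenshortError
from .evaluation import (
    BaselineDistribution,
    CeilingReport,
    ReliabilityReport,
    StabilityResult,
    ceiling_diagnostics,
    cronbach_alpha,
    monte_carlo_stability,
    random_subset_baseline,
    validate_form,
)
from .irt import MethodComparison, compare_methods, fit_2pl, select_items_by_information
from .items import format_item_list
from .pipeline import (
    GridConfig,
    SearchResult,
    SplitAssignment,
    grid_search,
    length_sweep,
    make_splits,
    split_matrix,
)
from .simulate import GeneratorConfig, simulate_responses

logger = logging.getLogger("ravenshort")

ALL_STAGES = (
    "clean",
    "split",
    "select",
    "validate",
    "stability",
    "baseline",
    "reliability",
    "ceiling",
    "irt",
)


@dataclass
class RunConfig:
    """Everything needed to reproduce one full analysis run.

    Exactly one of ``input_path`` (a delimited response table) or
    ``generator`` / ``cohort`` (synthetic data) must be given. Every random
    operation traces to one of the recorded seeds.
    """

    input_path: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    cohort: Optional[str] = None  # preset name, e.g. "younger" / "older"
    cohort_seed: int = 0
    min_age: Optional[float] = None
    practice_items: Tuple[str, ...] = ()
    split_seed: int = 0
    stratify_by_source: bool = True
    grid: GridConfig = field(default_factory=GridConfig)
    max_length: int = 15
    mc_iterations: int = 100
    mc_seed: int = 0
    baseline_k: int = 15
    baseline_draws: int = 100
    baseline_seed: int = 0
    irt_quadrature: int = 21
    stages: Tuple[str, ...] = ALL_STAGES
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        n_inputs = sum(x is not None for x in (self.input_path, self.generator, self.cohort))
        if n_inputs != 1:
            raise ConfigurationError(
                "exactly one of input_path, generator or cohort must be set"
            )
        if self.cohort is not None and self.cohort not in COHORTS:
            raise ConfigurationError(
                f"unknown cohort {self.cohort!r}; known: {sorted(COHORTS)}"
            )
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigurationError(f"unknown stage(s) {unknown}; known: {list(ALL_STAGES)}")

    def to_dict(self) -> dict:
        d = {
            "input_path": self.input_path,
            "generator": self.generator.to_dict() if self.generator else None,
            "cohort": self.cohort,
            "cohort_seed": self.cohort_seed,
            "min_age": self.min_age,
            "practice_items": list(self.practice_items),
            "split_seed": self.split_seed,
            "stratify_by_source": self.stratify_by_source,
            "grid": self.grid.to_dict(),
            "max_length": self.max_length,
            "mc_iterations": self.mc_iterations,
            "mc_seed": self.mc_seed,
            "baseline_k": self.baseline_k,
            "baseline_draws": self.baseline_draws,
            "baseline_seed": self.baseline_seed,
            "irt_quadrature": self.irt_quadrature,
            "stages": list(self.stages),
            "output_dir": self.output_dir,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("generator"):
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        grid = d.get("grid")
        if isinstance(grid, dict):
            d["grid"] = GridConfig(**grid)
        if d.get("practice_items") is not None:
            d["practice_items"] = tuple(d["practice_items"])
        if d.get("stages") is not None:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All tables and diagnostics of one run, plus provenance."""

    config: RunConfig
    cleaning: Optional[CleaningReport] = None
    split_sizes: Optional[Dict[str, int]] = None
    search: Optional[SearchResult] = None
    sweep_table: Optional[pd.DataFrame] = None
    validation_correlation: Optional[float] = None
    stability: Optional[StabilityResult] = None
    baseline: Optional[BaselineDistribution] = None
    reliability: Optional[ReliabilityReport] = None
    ceiling_short: Optional[CeilingReport] = None
    ceiling_full: Optional[CeilingReport] = None
    comparison: Optional[MethodComparison] = None
    stage_seconds: Dict[str, float] = field(default_factory=dict)

    def provenance(self) -> dict:
        try:
            version = metadata.version("ravenshort")
        except metadata.PackageNotFoundError:  # pragma: no cover
            version = "unknown"
        return {
            "package_version": version,
            "config_hash": self.config.config_hash(),
            "seeds": {
                "cohort_seed": self.config.cohort_seed,
                "split_seed": self.config.split_seed,
                "mc_seed": self.config.mc_seed,
                "baseline_seed": self.config.baseline_seed,
            },
        }

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance(),
            "config": self.config.to_dict(),
            "cleaning": self.cleaning.to_dict() if self.cleaning else None,
            "split_sizes": self.split_sizes,
            "search": self.search.to_dict() if self.search else None,
            "sweep_table": (
                self.sweep_table.to_dict(orient="records")
                if self.sweep_table is not None
                else None
            ),
            "validation_correlation": self.validation_correlation,
            "stability": self.stability.to_dict() if self.stability else None,
            "baseline": self.baseline.to_dict() if self.baseline else None,
            "reliability": self.reliability.to_dict() if self.reliability else None,
            "ceiling_short": self.ceiling_short.to_dict() if self.ceiling_short else None,
            "ceiling_full": self.ceiling_full.to_dict() if self.ceiling_full else None,
            "comparison": self.comparison.to_dict() if self.comparison else None,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _load_input(config: RunConfig) -> ItemResponseMatrix:
    if config.input_path is not None:
        return read_response_table(config.input_path)
    if config.generator is not None:
        return simulate_responses(config.generator)
    spec = COHORTS[config.cohort]
    gen = cohort_config(spec, seed=config.cohort_seed)
    return simulate_responses(gen)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the requested stages in order and assemble the report bundle.

    Stage errors propagate wrapped with the stage name. Stages after
    ``select`` require ``select`` (and ``split``) to be in the stage list.
    """
    bundle = ReportBundle(config=config)
    stages = set(config.stages)
    need_select = stages & {"validate", "stability", "baseline", "reliability", "ceiling", "irt"}
    if need_select and not {"clean", "split", "select"} <= stages:
        raise ConfigurationError(
            "stages after 'select' require 'clean', 'split' and 'select' to run"
        )
    if "select" in stages and "split" not in stages:
        raise ConfigurationError("stage 'select' requires stage 'split'")

    def timed(stage, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except RavenshortError as exc:
            raise type(exc)(f"stage {stage!r}: {exc}") from exc
        bundle.stage_seconds[stage] = time.perf_counter() - t0
        logger.info("stage %s finished in %.2fs", stage, bundle.stage_seconds[stage])
        return out

    matrix = _load_input(config)

    # presets carry their own cleaning conventions unless overridden
    min_age, practice = config.min_age, config.practice_items
    if config.cohort is not None:
        spec = COHORTS[config.cohort]
        min_age = spec.min_age if min_age is None else min_age
        practice = tuple(spec.practice_items) if not practice else practice

    if "clean" in stages:
        matrix, bundle.cleaning = timed(
            "clean", lambda: clean_responses(matrix, min_age=min_age, practice_items=practice)
        )

    train = test = validation = None
    if "split" in stages:
        assignment = timed(
            "split",
            lambda: make_splits(
                matrix, seed=config.split_seed, stratify_by_source=config.stratify_by_source
            ),
        )
        bundle.split_sizes = assignment.sizes()
        train, test, validation = split_matrix(matrix, assignment)

    full_items = matrix.administered_items
    if "select" in stages:
        bundle.search = timed(
            "select",
            lambda: grid_search(train, test, grid=config.grid, max_length=config.max_length),
        )
        bundle.sweep_table = length_sweep(
            bundle.search, validation_matrix=validation, full_items=full_items
        )
    chosen = bundle.search.chosen if bundle.search else None

    if "validate" in stages:
        bundle.validation_correlation = timed(
            "validate", lambda: validate_form(chosen.items, validation, full_items)
        )
    if "stability" in stages:
        dev_ids = train.person_ids + test.person_ids
        dev = matrix.subset_persons(dev_ids)
        bundle.stability = timed(
            "stability",
            lambda: monte_carlo_stability(
                dev,
                grid=config.grid,
                n_iterations=config.mc_iterations,
                master_seed=config.mc_seed,
                max_length=config.max_length,
                stratify_by_source=config.stratify_by_source,
            ),
        )
    if "baseline" in stages:
        ref = bundle.validation_correlation
        bundle.baseline = timed(
            "baseline",
            lambda: random_subset_baseline(
                validation,
                full_items,
                k=config.baseline_k,
                n_draws=config.baseline_draws,
                seed=config.baseline_seed,
                reference_correlation=ref,
            ),
        )
    if "reliability" in stages:
        bundle.reliability = timed(
            "reliability", lambda: cronbach_alpha(validation, chosen.items)
        )
    if "ceiling" in stages:
        bundle.ceiling_short = timed(
            "ceiling", lambda: ceiling_diagnostics(sum_score(validation, chosen.items))
        )
        bundle.ceiling_full = ceiling_diagnostics(sum_score(validation, full_items))
    if "irt" in stages:
        def _irt() -> MethodComparison:
            dev = matrix.subset_persons(train.person_ids + test.person_ids)
            model = fit_2pl(dev, n_quadrature=config.irt_quadrature)
            irt_form = select_items_by_information(model, k=config.max_length)
            forms = {"penalized": chosen.items, "irt": irt_form}
            return compare_methods(forms, validation, full_items)

        bundle.comparison = timed("irt", _irt)
    return bundle


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

KNOWN_FORMATS = ("json", "csv", "txt")


def render_report(bundle: ReportBundle, output_dir, formats: Sequence[str] = KNOWN_FORMATS) -> List[Path]:
    """Write the bundle: one JSON master file, CSV per table, plain-text summary."""
    unknown = [f for f in formats if f not in KNOWN_FORMATS]
    if unknown:
        raise ConfigurationError(f"unknown report format(s) {unknown}; known: {list(KNOWN_FORMATS)}")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    if "json" in formats:
        p = out / "report.json"
        p.write_text(bundle.to_json(indent=2), encoding="utf-8")
        written.append(p)
    if "csv" in formats:
        if bundle.sweep_table is not None:
            p = out / "length_sweep.csv"
            bundle.sweep_table.to_csv(p, index=False)
            written.append(p)
        if bundle.stability is not None:
            p = out / "stability.csv"
            freq = bundle.stability.selection_frequency
            chosen = set(bundle.search.chosen.items) if bundle.search else set()
            pd.DataFrame(
                {
                    "item": freq.index,
                    "selection_frequency": freq.to_numpy(),
                    "in_chosen_form": [i in chosen for i in freq.index],
                }
            ).to_csv(p, index=False)
            written.append(p)
        if bundle.baseline is not None:
            p = out / "baseline.csv"
            pd.DataFrame({"correlation": bundle.baseline.correlations}).to_csv(p, index=False)
            written.append(p)
        if bundle.comparison is not None:
            p = out / "method_comparison.csv"
            bundle.comparison.table.to_csv(p, index=False)
            written.append(p)
        if bundle.ceiling_short is not None:
            p = out / "score_histogram_short.csv"
            bundle.ceiling_short.histogram.rename_axis("score").rename("mass").to_csv(p)
            written.append(p)
    if "txt" in formats:
        p = out / "summary.txt"
        p.write_text(render_summary(bundle), encoding="utf-8")
        written.append(p)
    return written


def render_summary(bundle: ReportBundle) -> str:
    """Plain-text summary naming the chosen items in report list style."""
    lines = ["Short-form construction summary", "=" * 31]
    if bundle.cleaning:
        c = bundle.cleaning
        lines.append(
            f"Cleaning: {c.n_input} rows in, {c.n_output} out "
            f"(missing {c.n_missing_removed}, duplicates {c.n_duplicates_removed}, "
            f"under-age {c.n_underage_removed}; practice items dropped: "
            f"{', '.join(c.practice_items_dropped) or 'none'})"
        )
    else:
        lines.append("Cleaning: not run")
    if bundle.split_sizes:
        s = bundle.split_sizes
        lines.append(
            f"Split: train {s['train']}, test {s['test']}, validation {s['validation']}"
        )
    else:
        lines.append("Split: not run")
    if bundle.search:
        ch = bundle.search.chosen
        lines.append(
            f"Chosen short form ({ch.length} items, lambda={ch.lambda_}, alpha={ch.alpha}, "
            f"test r={ch.test_correlation:.3f}): {format_item_list(ch.items)}"
        )
    else:
        lines.append("Selection: not run")
    if bundle.validation_correlation is not None:
        lines.append(f"Validation correlation: r = {bundle.validation_correlation:.3f}")
    else:
        lines.append("Validation: not run")
    if bundle.stability:
        freq = bundle.stability.selection_frequency
        stable = freq[freq >= 0.5]
        lines.append(
            f"Stability ({bundle.stability.n_iterations} iterations): "
            f"{len(stable)} items selected in >=50% of runs"
        )
    else:
        lines.append("Stability: not run")
    if bundle.baseline:
        s = bundle.baseline.summary
        pct = bundle.baseline.percentile_outperformed
        extra = f"; chosen form outperforms {pct:.0%} of draws" if pct is not None else ""
        lines.append(
            f"Random {bundle.baseline.k}-item baseline ({bundle.baseline.n_draws} draws): "
            f"mean r = {s['mean']:.3f} (min {s['min']:.3f}, max {s['max']:.3f}){extra}"
        )
    else:
        lines.append("Baseline: not run")
    if bundle.reliability:
        lines.append(
            f"Cronbach's alpha (short form, validation set): {bundle.reliability.cronbach_alpha:.3f}"
        )
    else:
        lines.append("Reliability: not run")
    if bundle.ceiling_short:
        lines.append(
            f"Ceiling (short form): skewness {bundle.ceiling_short.skewness:.3f}, "
            f"top-decile mass {bundle.ceiling_short.top_decile_mass:.3f}"
        )
    else:
        lines.append("Ceiling: not run")
    if bundle.comparison is not None:
        for row in bundle.comparison.table.itertuples(index=False):
            lines.append(
                f"Method {row.method}: r = {row.r:.3f}, alpha = {row.alpha:.3f}, "
                f"{row.length} items"
            )
    else:
        lines.append("IRT comparison: not run")
    return "\n".join(lines) + "\n"
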