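"""One-command analysis pipeline: load -> descriptives -> category
summaries -> disproportionality screen -> delimited tables + manifest.

Every emitted table is deterministic for a given input and seed; the
run log doubles as the data-quality report (Not-specified coercions,
Haldane corrections) and the manifest records the config echo, dataset
hash and every file written.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .descriptives import STRATIFIERS, category_summary, distribution_by, flag_drug, format_percent
from .disproportionality import DisproportionalityModel, screen_frame
from .icsr import RunConfig, as_frame, linelist_sha256, read_linelist, write_linelist, frame_to_cases
from .simulate import ScenarioConfig, generate_frame, reference_scenario

logger = logging.getLogger(__name__)


@dataclass
class RunArtifacts:
    """Paths produced by one pipeline run."""

    out_dir: Path
    tables: dict[str, Path] = field(default_factory=dict)
    log: Path | None = None
    manifest: Path | None = None


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "-", name).strip("-").lower()


def emit_descriptives(frame, config: RunConfig, out_dir: Path) -> dict[str, Path]:
    tables: dict[str, Path] = {}
    for drug in config.target_drugs:
        sub = frame[flag_drug(frame, drug)]
        for var in STRATIFIERS:
            name = f"descriptive_{_slug(drug)}_{var}.csv"
            path = out_dir / name
            distribution_by(sub, var).to_frame().to_csv(path, index=False, lineterminator="\n")
            tables[name] = path
    return tables


def emit_category_summaries(frame, config: RunConfig, out_dir: Path) -> dict[str, Path]:
    tables: dict[str, Path] = {}
    overview_rows = []
    for drug in config.target_drugs:
        for category in config.categories:
            summ = category_summary(frame, drug, category)
            name = f"category_{_slug(drug)}_{_slug(category.name)}.csv"
            path = out_dir / name
            summ.to_frame().to_csv(path, index=False, lineterminator="\n")
            tables[name] = path
            overview_rows.append(
                {
                    "drug": drug,
                    "category": category.name,
                    "n_cases": summ.n_cases,
                    "n_total": summ.n_total,
                    "percent": summ.percent_str,
                    "fatal_n": summ.fatal_n,
                    "fatal_percent": (
                        format_percent(summ.fatal_n, summ.n_cases) if summ.n_cases else ""
                    ),
                }
            )
    path = out_dir / "category_summaries.csv"
    pd.DataFrame(overview_rows).to_csv(path, index=False, lineterminator="\n")
    tables["category_summaries.csv"] = path
    return tables


def emit_screen(frame, config: RunConfig, out_dir: Path) -> dict[str, Path]:
    path = out_dir / "screen.csv"
    if config.comparator_drugs:
        results = DisproportionalityModel(frame, config).fit()
        results.to_csv(path)
    else:
        screen_frame([]).to_csv(path, index=False, lineterminator="\n")
    return {"screen.csv": path}


def run_pipeline(
    linelist: str | Path,
    config: RunConfig,
    out_dir: str | Path,
    scenario: ScenarioConfig | None = None,
    delimiter: str = ",",
) -> RunArtifacts:
    """Run the full pipeline.

    ``linelist`` is a line-list path, or the string ``"synthetic"`` to
    generate the input from ``scenario`` (default: the built-in
    reference scenario seeded from the config).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("adrscreen")
    old_level = root.level
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        if str(linelist) == "synthetic":
            if scenario is None:
                scenario = reference_scenario(seed=config.seed)
            frame = generate_frame(scenario)
            source = out_dir / "synthetic_linelist.csv"
            write_linelist(frame_to_cases(frame), source, delimiter=delimiter)
            logger.info("generated %d synthetic cases (seed %d)", len(frame), scenario.seed)
        else:
            source = Path(linelist)
            frame = as_frame(read_linelist(source, delimiter=delimiter))
            logger.info("read %d cases from %s", len(frame), source)
        tables: dict[str, Path] = {}
        tables.update(emit_descriptives(frame, config, out_dir))
        tables.update(emit_category_summaries(frame, config, out_dir))
        tables.update(emit_screen(frame, config, out_dir))
        if str(linelist) == "synthetic":
            tables["synthetic_linelist.csv"] = source
        manifest_path = out_dir / "manifest.txt"
        config_echo = yaml.safe_dump(
            {
                "target_drugs": list(config.target_drugs),
                "comparator_drugs": list(config.comparator_drugs),
                "categories": [c.name for c in config.categories],
                "zero_cell_policy": config.zero_cell_policy,
                "alpha": config.alpha,
                "seed": config.seed,
            },
            sort_keys=True,
        )
        lines = [
            f"adrscreen {__version__}",
            f"dataset: {source.name}",
            f"dataset_sha256: {linelist_sha256(source)}",
            "config:",
            *("  " + ln for ln in config_echo.strip().splitlines()),
            "files:",
            *("  " + name for name in sorted(tables)),
            "  run.log",
        ]
        manifest_path.write_text("\n".join(lines) + "\n")
        return RunArtifacts(out_dir=out_dir, tables=tables, log=log_path, manifest=manifest_path)
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()
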