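"""End-to-end analysis driver: score, stratify, optimise cutoffs, evaluate.

``run_full_analysis`` takes an :class:`AnalysisConfig`, runs every requested
stratum x marker combination — confusion table and the nine-metric suite at
either a fixed cutoff or the per-stratum Youden-optimal one, AUC with CI,
and the Youden operating point — plus a stage-stratified ROMA evaluation
and a baseline comparison table, and writes a report bundle:

* ``report.json``  — every number at full precision (the machine surface);
* ``metrics_<stratum>.tsv`` — one-decimal presentation tables;
* ``run_log.txt``  — seed, config hash and package version.

Rounding happens only in the TSV layer; reruns with the same config and
seed produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .baseline import baseline_table
from .cohort import Cohort, STRATA, read_cohort, stratify
from .diagnostics import METRIC_ORDER, MarkerEvaluation, evaluate_marker
from .roc import auc, youden_cutoff
from .score import marker_scores, truth_labels

__all__ = ["AnalysisConfig", "run_full_analysis", "load_config"]

MARKERS = ("ca125", "he4", "roma")
DEFAULT_STRATA = ("total", "premenopause", "postmenopause")
STAGE_STRATA = ("early_stage", "advanced_stage")


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a full run needs; hashable into the run log."""

    input_path: str
    output_dir: str
    strata: tuple[str, ...] = DEFAULT_STRATA
    #: per-marker cutoff policy: a float (fixed) or the string "youden"
    cutoffs: dict = field(default_factory=lambda: {m: "youden" for m in MARKERS})
    stage_analysis: bool = True
    baseline: bool = True
    seed: int = 0
    ci_method: str = "hanley-mcneil"
    quiet: bool = False

    def __post_init__(self) -> None:
        for name in self.strata:
            if name not in STRATA:
                raise ValueError(f"unknown stratum {name!r}")
        for marker, policy in self.cutoffs.items():
            if marker not in MARKERS:
                raise ValueError(f"unknown marker {marker!r}")
            if policy != "youden" and not (
                isinstance(policy, (int, float)) and policy > 0
            ):
                raise ValueError(
                    f"cutoff for {marker} must be 'youden' or a positive number"
                )

    def canonical_json(self) -> str:
        # output_dir is deliberately excluded: where a bundle is written must
        # not change its content or digest
        d = {
            "input_path": self.input_path,
            "strata": list(self.strata),
            "cutoffs": self.cutoffs,
            "stage_analysis": self.stage_analysis,
            "baseline": self.baseline,
            "seed": self.seed,
            "ci_method": self.ci_method,
        }
        return json.dumps(d, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an AnalysisConfig from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if "strata" in data:
        data["strata"] = tuple(data["strata"])
    return AnalysisConfig(**data)


def _json_safe(x):
    if isinstance(x, float):
        if math.isnan(x):
            return None
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
    return x


def _walk_json(obj):
    if isinstance(obj, dict):
        return {k: _walk_json(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_walk_json(v) for v in obj]
    return _json_safe(obj)


def _fmt(value: float, ndigits: int = 1) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if isinstance(value, float) and math.isinf(value):
        return "inf" if value > 0 else "-inf"
    return f"{value:.{ndigits}f}"


def _evaluation_block(
    cohort: Cohort, marker: str, policy, ci_method: str
) -> dict:
    scores = marker_scores(cohort, marker)
    truth = truth_labels(cohort)
    youden = youden_cutoff(scores, truth)
    cutoff = youden.cutoff if policy == "youden" else float(policy)
    if not math.isfinite(cutoff):
        # degenerate stratum (e.g. all scores tied); fall back to min score
        cutoff = min(scores.values())
    ev: MarkerEvaluation = evaluate_marker(scores, truth, cutoff)
    area = auc(scores, truth, ci_method=ci_method)
    return {
        "marker": marker,
        "cutoff_policy": policy if policy == "youden" else "fixed",
        "evaluation": ev.to_dict(),
        "auc": area.to_dict(),
        "youden": {
            "cutoff": youden.cutoff,
            "j": youden.youden_j,
            "sensitivity": youden.sensitivity,
            "specificity": youden.specificity,
        },
    }


def _stratum_tsv(stratum: str, blocks: list[dict]) -> str:
    """One-decimal presentation table, markers as columns."""
    lines = []
    header = ["metric"] + [
        f"{b['marker']} (>= {_fmt(b['evaluation']['cutoff'], 2)})" for b in blocks
    ]
    lines.append("\t".join(header))
    for count in ("tp", "fp", "fn", "tn"):
        lines.append(
            "\t".join(
                [count.upper()]
                + [str(b["evaluation"]["confusion"][count]) for b in blocks]
            )
        )
    for metric in METRIC_ORDER:
        cells = []
        for b in blocks:
            m = b["evaluation"]["metrics"][metric]
            nd = 2 if metric in ("lr_negative", "cohens_kappa") else 1
            v = m["value"]
            v = math.nan if v is None else (math.inf if v == "inf" else v)
            lo, hi = m["ci_low"], m["ci_high"]
            lo = math.nan if lo is None else (math.inf if lo == "inf" else lo)
            hi = math.nan if hi is None else (math.inf if hi == "inf" else hi)
            cells.append(f"{_fmt(v, nd)} ({_fmt(lo, 2)} - {_fmt(hi, 2)})")
        lines.append("\t".join([metric] + cells))
    lines.append(
        "\t".join(
            ["auc"]
            + [
                f"{_fmt(b['auc']['value'], 3)} "
                f"({_fmt(b['auc']['ci_low'], 3)} - {_fmt(b['auc']['ci_high'], 3)})"
                for b in blocks
            ]
        )
    )
    return "\n".join(lines) + "\n"


def run_full_analysis(
    config: AnalysisConfig, cohort: Cohort | None = None
) -> dict:
    """Run the complete pipeline and write the report bundle.

    ``cohort`` may be passed directly (e.g. a freshly simulated one);
    otherwise it is read from ``config.input_path``.  Returns the full
    unrounded report dictionary that is also written to ``report.json``.
    """
    if cohort is None:
        cohort = read_cohort(config.input_path)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def log(msg: str) -> None:
        if not config.quiet:
            print(msg, file=sys.stderr)

    log(f"romadx {__version__} | config {config.digest()} | seed {config.seed}")
    log(
        f"cohort: {len(cohort)} records "
        f"({cohort.n_benign} benign / {cohort.n_malignant} malignant)"
    )

    report: dict = {
        "version": __version__,
        "config": json.loads(config.canonical_json()),
        "config_digest": config.digest(),
        "cohort": {
            "n": len(cohort),
            "n_benign": cohort.n_benign,
            "n_malignant": cohort.n_malignant,
            "counts": {
                f"{path}/{status}": n for (path, status), n in sorted(cohort.counts().items())
            },
        },
        "strata": {},
    }

    strata_to_run = list(config.strata)
    if config.stage_analysis:
        has_stage = any(r.stage is not None for r in cohort if r.is_malignant)
        if has_stage:
            strata_to_run += [s for s in STAGE_STRATA if s not in strata_to_run]
        else:
            log("stage analysis skipped: no stage data")

    tsv_paths = []
    for name in strata_to_run:
        try:
            sub = stratify(cohort, name)
        except ValueError as exc:
            raise ValueError(f"stratum {name!r}: {exc}") from exc
        if sub.n_benign == 0 or sub.n_malignant == 0:
            log(f"stratum {name}: skipped (single-class: "
                f"{sub.n_benign} benign / {sub.n_malignant} malignant)")
            report["strata"][name] = {"n": len(sub), "skipped": "single-class"}
            continue
        markers = ("roma",) if name in STAGE_STRATA else MARKERS
        blocks = []
        for marker in markers:
            try:
                blocks.append(
                    _evaluation_block(
                        sub, marker, config.cutoffs.get(marker, "youden"),
                        config.ci_method,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"stratum {name!r}, marker {marker!r}: {exc}") from exc
        report["strata"][name] = {
            "n": len(sub),
            "n_benign": sub.n_benign,
            "n_malignant": sub.n_malignant,
            "markers": {b["marker"]: b for b in blocks},
        }
        tsv = _stratum_tsv(name, [_walk_json(b) for b in blocks])
        tsv_path = out / f"metrics_{name}.tsv"
        tsv_path.write_text(tsv)
        tsv_paths.append(tsv_path.name)
        log(f"stratum {name}: n={len(sub)}, markers={','.join(markers)}")

    if config.baseline:
        table = baseline_table(cohort)
        table.to_csv(out / "baseline.tsv", sep="\t", index=False, lineterminator="\n")
        report["baseline"] = table.to_dict(orient="records")

    report_json = json.dumps(_walk_json(report), indent=2, sort_keys=True)
    (out / "report.json").write_text(report_json + "\n")
    (out / "run_log.txt").write_text(
        f"romadx version: {__version__}\n"
        f"config digest: {config.digest()}\n"
        f"seed: {config.seed}\n"
        f"strata written: {', '.join(tsv_paths)}\n"
    )
    log(f"report bundle written to {out}")
    return report
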